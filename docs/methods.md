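# Methods

## The system being modeled

Micropatterned human gastruloids (700 µm discs of hESCs) patterned by an
edge-initiated, inward-moving wave of Nodal signaling; juxtaposition
cocultures in which induced sender cells abut non-producing receivers
across a straight border. The package quantifies fluorescence images of
both geometries and simulates the two candidate propagation mechanisms so
the pipeline can be validated end to end on synthetic data with known
truth.

## Relay model

State per cell: Nodal transcript N, Nodal protein P, Lefty L, adaptation
A, signaling S (all arbitrary units, nonnegative). Protein exchange is
strictly juxtacrine: each cell's local pools are its own plus its
immediate hexagonal neighbors' (`P_local = P + Σ_nbr P`), reflecting the
observation that Nodal protein is not found beyond the receiver tier that
touches the senders. Signaling is the Lefty-inhibited local protein,
`S = P_local/(1 + β·L_local)`; transcription follows a Hill response in S
above threshold θ; Lefty production is driven by `max(0, S − A)` where A
relaxes toward S with time constant τ_A, so Lefty fires transiently on a
*rise* in signaling and shuts off under sustained signaling (adaptive
expression). Integration is explicit Euler; a step that would drive any
state negative aborts with a diagnostic rather than silently clipping.

### Default rates

No kinetic measurements exist for this system; all rates are package
choices, fixed once, with one deliberate calibration: the wild-type front
should cross a 350 µm colony radius in roughly the ~40 h experimental
patterning window.

| parameter | value | meaning |
|---|---|---|
| α | 4.0 a.u./h | max Nodal transcription rate |
| k_N, k_P | 1.0, 2.0 /h | transcript / protein decay |
| k_tl | 2.0 /h | translation + secretion |
| θ, h | 0.5 a.u., 4 | signaling threshold, Hill coefficient |
| β | 1.5 /a.u. | Lefty inhibition strength |
| α_L, k_L | 3.0 a.u./h, 0.75 /h | Lefty production gain / decay |
| τ_A | 1.0 h | adaptation time constant |
| Δt | 0.02 h | Euler step |
| n_induced | 2.0 a.u. | clamped N in SENDER cells |
| cell diameter | 10 µm | lattice spacing and tier unit |

With these values the wild-type front reaches the colony center in ~32 h
and the Lefty1/2-KO front in ~11 h. The Lefty feedback parameters were
chosen in the *damped* regime: the closed loop (L decays → S rises →
adaptation lags → L re-fires) supports relaxation oscillations behind the
front when adaptation is slow (τ_A ≳ 2–3 h at these gains); τ_A = 1 h
keeps the Lefty response a single decaying pulse at each position, which
is the observed behavior (a traveling transcription wave, not repeated
firing).

Design choices that were genuinely open:

- **Lefty acts on the summed local signal** (`S = P_local/(1+β·L_local)`)
  rather than on each neighbor's contribution before summation; nothing
  in the data distinguishes these, and inhibiting the sum keeps S a
  simple ratio.
- **Lefty range equals Nodal range** (one tier). In gastruloids Lefty
  protein tracks its transcription wave, i.e. acts near its source;
  juxtaposition gradients over several tiers are attributed to the much
  longer timescale there, not modeled as a different transport mode.
- **Edge induction**: in colony mode the outermost cell ring is clamped
  as SENDER, standing in for the upstream BMP/Wnt cascade (out of scope).
- **Hill rather than hard threshold** (h = 4): differentiable, recovers a
  threshold as h → ∞.
- **SENDER clamps N**; transient ("induced-WT") sources are instead
  expressed through `initial_N` with genotype WT, which is how the
  bidirectional-maintenance property (senders need signaling back from
  receivers) is probed — the effect is only visible away from
  autoactivation saturation, so that test raises θ to 1.0.

## Differential-diffusivity model

Two uncoupled linear reaction–diffusion fields integrated explicitly on a
regular grid (1D or 2D, rectangle or inscribed disc), with a flux-form
5-point Laplacian: no-flux boundaries are implemented by zeroing fluxes
across domain boundaries, which conserves total mass exactly when
production and degradation vanish (asserted to 1e-6 in tests, observed at
machine precision). The stability condition Δt ≤ dx²/(4·max D) is checked
before integration. Defaults (D_N = 4, D_L = 64 µm²/h, k = 0.01/h) give
decay lengths λ_N = 20 µm and λ_L = 80 µm — a two-tier activator against
an eight-tier inhibitor, the regime the model requires (D_L > D_N is
enforced as a type invariant). The closed-form checks are the 1D
steady-state exponential and the ratio λ_L/λ_N = √((D_L·k_N)/(D_N·k_L)).

## Synthetic images

The renderer emulates low-magnification epifluorescence: nuclear channel
as anti-aliased disks (hex-packed in colonies, dart-thrown in scattered
fields), signal channels from a radial profile, a per-cell simulator
state (nearest-cell Voronoi assignment), or a border-distance law
(exponential `a·exp(−d/λ)+c` or a one-tier band); optional Gaussian PSF,
Poisson shot noise, Gaussian read noise and hot pixels, all behind one
seed (bit-identical re-renders). Default noise: 2 µm pixels, background
10 counts, gain 100 counts per unit signal, PSF σ = 1 µm, read noise
SD 2. Every render returns a ground-truth record (center, radius, border,
generating profiles, decay lengths, nucleus centers, per-cell states).

What the synthetic data does **not** emulate: cell-shape heterogeneity
and texture, uneven illumination, focus drift, z-structure in the 2D
renders, cell movement and division in time-lapses, and spot-level
(single-molecule) FISH statistics. Passing recovery tests therefore shows
the pipeline's estimators are correct and unbiased under a known noise
model — not that segmentation or background correction would be as easy
on real micrographs.

## Quantification conventions

- **Radial profiles**: pixel-center distances from the intensity-weighted
  colony centroid, half-open 10 µm bins starting at r = 0, arithmetic
  per-bin mean; the conservation identity Σ mean·count = Σ binned
  intensity is exact up to float summation order. A 350 µm colony spans
  35 bins.
- **Colony detection**: Otsu on the (background-subtracted) nuclear
  channel, closing, hole filling, largest component; radius from
  component area (√(A/π)); colonies whose radius deviates >20% from the
  expected 700 µm pattern are rejected with a reason code (the automated
  version of selecting fully filled colonies by DAPI).
- **Kymographs**: per-frame radial profiles, with pie-segment bookkeeping
  (default 12) combined count-weighted, so each row is exactly the
  whole-frame profile and segments from several colonies can be pooled.
- **Cross-colony ensembles**: per-bin mean and SEM (n−1 sample SD / √n)
  across colonies; n = 1 yields a flagged NaN SEM. "Normalized mean
  intensity" is per-colony division by the profile's maximum bin — the
  exact normalization behind published normalized panels is not stated
  anywhere, so other modes are selectable and none is asserted canonical.
- **Border profiles**: unsigned Euclidean distance (exact EDT,
  center-to-center, so a 4-adjacent pixel is one pixel away) from the
  sender mask, half-open 5 µm bins ("several-micron" is not a number; 5
  is a configurable choice); sender-territory intensity is summarized
  separately rather than mixed into bin 0.
- **Decay fits**: `a·exp(−d/λ)+c` by least squares, initialized from a
  log-linear fit; profiles with <5% relative dynamic range are flagged
  `no_decay`, non-convergence is flagged, and flagged fits cannot be
  converted to ranges.
- **Cell tiers**: range ÷ cell diameter (default 10 µm; the conversion
  constant is configurable since no measured value exists). From a raw
  binned profile the range is the lower edge of the first bin below
  threshold_frac × the first-bin value — the smallest distance where the
  step-function mean sits below threshold.
- **Per-cell readouts**: nuclear labels from smooth→Otsu→watershed (a
  classical, training-free substitute for the interactive ML segmentation
  used in the original workflow); cytoplasm as a 3 µm dilated ring
  (nearest-seed collision rule, deterministic); time series averaged
  hierarchically (cells → field mean → across-field mean ± SEM), which
  differs from pooled averaging whenever fields have unequal cell counts
  and is pinned by a counterexample test.

## Numerical and degenerate-input policy

Explicit simulators validate their stability conditions up front and
fail loudly. Empty bins carry count 0 and NaN means. Blank images
segment to zero labels (not an error); constant marker channels, empty or
full sender masks, and zero cytoplasmic means raise or return flagged
sentinels instead of numbers. The outlier filter replaces only pixels
deviating from the local median by more than k·(1.4826·local MAD) and is
the identity for k = ∞. All pipeline randomness derives from one config
seed fanned out by fixed per-stage offsets.

## Problem sizes

Test and demonstration runs use full-size 350 µm colonies (~4200 cells)
for the front-kinetics and adaptation results, 90–150 µm colonies and
160–260 px frames for orchestration and recovery checks, and a 240-point
1D strip for diffusion steady states — sizes chosen so the whole suite
and the acceptance script each complete in well under a minute of
simulation time per study while keeping ≥30 bins/tiers of spatial
resolution in every readout.

## Known limitations

- Relay rates are not fitted to any data; only qualitative signatures
  (front existence and ordering, one-tier containment, adaptive pulse)
  are claimed, not absolute speeds.
- The two mechanisms are simulated separately; no hybrid
  (relay + diffusion) model is provided.
- No drift registration or cell tracking: time-lapse quantification is
  field-level, and kymographs assume a static colony geometry.
- The EDT border distance is center-to-center, which offsets geometric
  border distances by up to one pixel at the border; fits absorb this in
  the offset but tier readouts of sub-pixel-wide features inherit it.
- 2D renders only; the z-profile readout consumes real z-stacks but the
  generator does not produce optically sectioned volumes.
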