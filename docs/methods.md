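# Methods

This note documents the models behind `roadblock_smx`, the default
parameter choices, and what the synthetic data do and do not emulate.

## System

A linear DNA template carries (coordinates in bp downstream of the
transcription start site): a promoter at 0, a stall site at +22 where
elongation complexes are halted by nucleotide deprivation before the
run, one or two LacI operators, and a terminator.  The SFM presets are
1523 bp with a near operator (Os or O2) at 271 bp — 253 and 261 bp
variants exist as named presets, reflecting alternative construct
annotations — a far O1 at 669 bp and the terminator at 1298 bp.  The
magnetic-tweezer preset is 3025 bp with a single O1 at 689 bp and the
terminator at 1298 bp.

LacI kinetics are parametrized per operator by `k_off` (1/s), `k_on`
(1/(M·s), default 7.9e9) and a `loop_off_factor ≥ 1` that divides
`k_off` while the operator is engaged in a LacI-mediated loop (the
bivalently bound tetramer has increased effective affinity).  Reference
mean occupancies: in vivo 2326 / 434 / 102 s for Os / O1 / O2; in vitro
200 s for O1 (0.3/min).  In vitro lifetimes for Os and O2 are not
directly measured; the preset scales the O1 anchor by the in vivo
lifetime ratios (Os ≈ 1072 s, O2 ≈ 47 s).  At the working 7.5 nM
repressor concentration every operator is near saturation
(`c/(c + k_off/k_on)` > 0.99) and a vacant operator rebinds within
~17 ms, so initial occupancy is drawn from the two-state equilibrium
and no rebinding race is modelled after a polymerase transit.

## Snapshot generator

Each molecule is inactive (promoter-stuck, Gaussian jitter, default sd
30 bp, default fraction 0.2) or active.  Active complexes step 1 bp at
a time with exponential waiting times at a per-molecule rate, starting
from the stall site.  On reaching an occupied operator the complex
waits for a single exponential dissociation event (rate `k_off`, or
`k_off / loop_off_factor` if the molecule is looped) and then passes
immediately.  Positions are read out at the quench time (default 60 s)
with Gaussian tracing noise (default 15 bp — contour-measurement error
is not independently known; this is of the order of the polymerase
footprint) and clipped to the template.  Complexes that reach the
terminator release the polymerase and appear as molecules without a
bound RNAP.  The loop state is a per-molecule flag fixed for the whole
window; looped molecules have both operators bound.

**Rate heterogeneity.** Per-molecule rates are Gamma-dispersed about
the ensemble mean (default shape 1, i.e. exponential static
heterogeneity; `None` gives identical rates).  This choice makes the
generated ensemble match the structure the downstream analyses assume:
with exponentially dispersed rates the active positions at time T are
themselves exponentially distributed with mean `v·T`, which is exactly
the promoter-Gaussian-plus-decaying-exponential picture the mixture fit
implements, and it makes the rate estimator `λ/T` consistent.  It also
reproduces the observed benchmark that roughly half of all molecules
progress past the near operator within the 60 s window.  Time-consuming
alternatives (random initiation delays, irreversible arrest) are
available as config fields (`initiation_delay_mean`, `stop_rate`,
default off); both exponentialize the ensemble too but depress its mean
below `v·T`, and a sharp quench with homogeneous rates instead piles
positions into a narrow bump at `v·T`.  Static inter-molecule rate
dispersion of this magnitude is a strong assumption; it should be read
as the minimal mechanism consistent with the ensemble statistics, not
as a measured property.

## Mixture fit and rate estimate

Positions are binned (default 50 bp) and the expected counts of
`w·N(μ, σ) + (1−w)·Exp(λ)` are integrated over each bin (CDF
differences, so components narrower than one bin are not
over-weighted) and fitted by bounded least squares with two starts; a
maximum-likelihood refinement of the same model is available as a
cross-check.  On a finite template the active component is optionally
right-truncated at the terminator (`support_max`): complexes that would
progress past it have left the ensemble, and λ keeps its meaning as the
underlying mean progress.  The elongation-rate estimate is `λ/T`.

At the study's scale (2000 molecules, 60 s, 10.3 bp/s) the sampling
spread of the recovered rate is about 3–6% (one sd); an oracle
maximum-likelihood estimate of a truncated-exponential scale on the
same draws shows the same spread, i.e. it is intrinsic to the truncated
sample, not to the fitting procedure.

Note an arithmetic tension carried by the source quantities themselves:
a fitted mean progress of 660 bp over 60 s gives 11.0 bp/s, while the
rate is quoted as 10.3 bp/s.  The package simply reports `λ/T` and
leaves the choice of λ to the caller.

## Zones, survival, pass fractions

The survival curve uses the strict-inequality convention
`S(x) = #{p > x}/n` on a regular grid.  Zone classification uses a
contact halfwidth (default 30 bp, roughly the polymerase footprint plus
particle radius at SFM resolution): zone I within the halfwidth of the
promoter, III within it of the near operator, II between, IV between
the operators with far-operator contact folded in (the taxonomy defines
no separate far-contact class), V beyond the far operator window.  Pass
fractions report numerator and denominator and can be conditioned on
complexes that at least reached the obstacle; both conventions are
reported because ensemble pass percentages are ambiguous in that
respect.  Loop and occupancy tallies carry 95% Wilson intervals.

## Trace generator

Extension is `−(bp transcribed)·extension_per_bp + drift + noise`, in
µm, negative downward, sampled at 164 Hz.  `extension_per_bp` defaults
to 0.29 nm/bp, a linear conversion calibrated so the stall→O1 distance
of the tweezer template (667 bp) sits at the −0.2 µm pause mark and the
terminator at about −0.35 µm; the force-dependent worm-like-chain
conversion is deliberately not modelled and the factor is exposed in
the config.  One exponential pause (mean `1/k_off`) is inserted when
the complex reaches the operator, with exact truth returned.  Traces
terminate at the terminator with probability 0.5, otherwise run off
until the bead reaches the surface (extension floored at −0.5 µm).
Drift (none / linear / random walk, default random walk at 3 nm/√s) is
shared bit-for-bit between tether and reference bead; each carries
independent Gaussian noise (default 15 nm).  Initiation delays are
exponential (default mean 20 s).  The post-NTP turbulence interval of
real recordings is not simulated; traces begin clean, matching how real
traces are analyzed after excluding that interval.

## Trace processing

Moving averages (60-point drift window on the mean stuck-bead signal,
200-point smoothing) are centered with symmetric shrink at the edges:
the effective window at index i is `2·min(w/2, i, n−1−i)+1` samples.
This keeps a linear signal exact everywhere and introduces no phase lag
that would bias intersection times.  Pause candidates are stretches
where the windowed local slope (30 s regression window) stays above
20% of the median elongation slope for at least 20 s, bounded to the
transcribing span; each candidate is refined by the three-line fit with
elongation windows of up to 40 s on either side, offset from the
plateau edges by half the slope window plus 2 s so transition samples
stay out of the line fits.  The pause line's slope is fitted, not
constrained to zero (a zero-slope mode exists).  All thresholds are
exposed, so the manual workflow — choosing the three sections by eye —
is reproduced by calling the three-line fit directly.  Detection
depends only on slopes and is invariant under constant offsets.
Outcomes are classified from the final 30 s plateau against the
terminator (−0.35 µm) and runoff (−0.5 µm) marks with a 0.03 µm
tolerance.

## Bead images and 3D tracking

The synthetic diffraction kernel is
`I(r; z) = bg + A·exp(−r/ρ)·cos(2πr/Λ(z))` with
`Λ(z) = Λ₀(1 + z/z_s)` (defaults Λ₀ = 580 nm = 8 px at 72.5 nm/px,
z_s = 4000 nm, ρ = 1200 nm): radially symmetric about the true center,
ring radius growing smoothly with defocus, injective in z over the
±1000 nm range (verified by brute-force profile comparison).  The
"moderate noise" calibration level is ring amplitude / noise sd = 5.

XY localization follows the gradient radial-symmetry construction:
intensity gradients on the dual half-pixel grid from diagonal
differences of 2×2 blocks, 3×3 boxcar smoothing, weights equal to
gradient power divided by distance from the gradient centroid, and the
closed-form weighted least-squares point minimizing distance to the
gradient lines.  No iteration or initial guess.  Measured accuracy on
the synthetic kernel: ≲1e-4 px noiseless, ~0.09 px RMSE at the
calibration noise level.

Radial profiles use 1-px annuli with linear interpolation of
fractional radii out to the largest annulus fully contained in the
frame; LUT and live profiles share this binning exactly and a
bin-width mismatch is an error.  Z estimation normalizes profiles to
zero mean and unit variance before SSD matching (robust to
illumination drift; a raw-SSD mode is retained), takes the SSD argmin
over the LUT, and refines with the parabola vertex through the three
SSD values around the minimum.  An exact grid hit (zero SSD) returns
the grid height directly; at the LUT edges the edge height is returned
flagged rather than extrapolated, since a vertex outside the sampled
range is unvalidated.  With a 100 nm LUT step the depth error on
noiseless off-grid frames is ~2 nm RMSE, comfortably within the
10–20 nm depth-resolution regime of this tracking scheme.

## Problem sizes and determinism

All generators take a seed and are bit-reproducible.  The test suite
uses the assay-scale sizes throughout: 2000-molecule ensembles, 50
simulated traces at 164 Hz × 800 s for pause recovery, 500 noisy frames
for lateral accuracy, a 21-plane LUT.  The acceptance script uses an
8000-molecule ensemble for the rate estimate (sampling sd ~3%) and
derives all sub-seeds from its single `--seed`.

## Known limitations

* The roadblock model is wait-for-dissociation only: no active
  dislodging, no transcription around the obstacle, no rebinding race
  after a transit, no loop breakdown/reformation within the window.
* Supercoiling, polymerase backtracking, force-dependent elongation,
  and the worm-like-chain force-extension relation are not modelled.
* The synthetic diffraction kernel is a stylized stand-in for real
  bead optics; tracking accuracies measured on it demonstrate the
  correctness of the algorithms, not instrument performance.
* Snapshot "molecules without RNAP" arise only via termination; real
  ensembles also contain templates that never bound polymerase.
* The exponential-dispersion rate model reproduces ensemble shape and
  means, not single-molecule kinetic detail (pause-free velocities,
  ubiquitous short pauses).
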