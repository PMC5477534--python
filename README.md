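# roadblock-smx

Single-molecule analysis of transcription elongation through protein
roadblocks.  The package implements the quantitative machinery for two
complementary assays on DNA templates carrying lac repressor (LacI)
operators:

* **Snapshot ensembles** (scanning force microscopy): transcription is
  run for a fixed interval (60 s), quenched with EDTA, and the position
  of every RNA polymerase along the DNA contour is measured.  The
  package normalizes contour positions, builds survival-of-progress
  curves, fits the position distribution with a promoter Gaussian plus
  a decaying exponential, estimates the elongation rate, classifies
  progress into the five standard zones relative to the two operators,
  and computes roadblock pass fractions and loop/occupancy tallies.
* **Real-time tether traces** (magnetic tweezers): a DNA-tethered
  paramagnetic bead reports polymerase progress as tether shortening at
  164 Hz.  The package tracks beads in 3D (radial-symmetry subpixel XY;
  lookup-table Z with parabolic sub-step refinement), computes tether
  extension against a reference bead, removes mechanical drift with
  stuck-bead moving averages, smooths, detects pauses at the operator
  extension mark, and times them with the three-line piecewise fit.

A synthetic-data module generates snapshot ensembles, tweezer traces
(with exact pause truth), and defocused bead diffraction images, so the
entire pipeline is testable without laboratory data.  A kinetics module
carries the occupancy arithmetic the measurements are compared against:
mean occupancy `1/k_off`, binding wait `1/(k_on·[LacI])`, and the
wait-for-dissociation pass probability `1 − exp(−k_off·w)`.

## The statistics at the core

For an ensemble of polymerase positions `x_i` the probability of
progress past position `x` is the survival fraction

    S(x) = 1 − F̂(x) = #{x_i > x} / n .

The position histogram is fitted with

    f(x) = w·N(x; μ, σ) + (1 − w)·Exp(x; λ) ,

where the Gaussian describes promoter-stuck (inactive) complexes and
the exponential the active population; the mean progress λ divided by
the incubation time T estimates the elongation rate `v = λ/T`.

Bead height is estimated by matching the radial intensity profile
`Î(r)` against a lookup table `I_r[z_k]`, taking
`k* = argmin_k Σ_r (I_r[z_k] − Î(r))²` and refining with the vertex of
a parabola through the squared differences at `k*−1, k*, k*+1`.  Pause
durations are the distance between the intersections of least-squares
lines fitted to the pre-pause, pause, and post-pause trace sections.

## Worked example

```python
import roadblock_smx as rb

# Simulate a 60 s EDTA-quenched ensemble without LacI and recover the rate
tpl = rb.template_preset("Os400O1")
kin = [rb.in_vitro_kinetics(op) for op, _ in tpl.operators]
cfg = rb.SnapshotConfig(laci_concentration=0.0, n_molecules=2000, seed=1000)
records = rb.simulate_tec_snapshot(tpl, kin, cfg)
positions = [r.rnap_bp for r in records if r.rnap_bp is not None]
fit = rb.fit_position_mixture(positions, support_max=tpl.terminator_bp)
print(f"lambda = {fit.lambda_bp:.0f} bp, w_inactive = {fit.w_inactive:.2f}, "
      f"rate = {rb.estimate_elongation_rate(fit, 60.0):.2f} bp/s")

# Time a roadblock pause in a simulated tweezer trace
mt = rb.template_preset("MT-O1")
tether, reference, truth = rb.simulate_mt_trace(mt, rb.in_vitro_kinetics("O1"),
                                                rb.TraceConfig(seed=3003))
trace = rb.smooth(rb.drift_correct(tether, [reference]), 200)
event = rb.detect_pauses(trace, expected_marks=(-0.2,))[0]
print(f"pause {event.duration:.0f} s at {event.extension_at_pause:.3f} um "
      f"(truth {truth.duration:.0f} s)")
```

Output:

```
lambda = 592 bp, w_inactive = 0.20, rate = 9.87 bp/s
pause 199 s at -0.194 um (truth 201 s)
```

The recovered mean progress (~600 bp in 60 s) reflects the configured
10.3 bp/s mean rate and the 20% promoter-stuck fraction; the pause
appears at the extension corresponding to the O1 operator (−0.2 µm)
and its fitted duration tracks the simulated dissociation wait.

A command line mirrors the library:

```
roadblock-smx simulate snapshot --n 2000 --seed 1 --out sim/
roadblock-smx analyze-sfm --records sim/records.csv --out results/
roadblock-smx simulate trace --seed 1 --out mt/
roadblock-smx analyze-mt --trace mt/tether.csv --stuck mt/reference.csv --out results/
roadblock-smx kinetics report --mean 246 --se 23
```

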