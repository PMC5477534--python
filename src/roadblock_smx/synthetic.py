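"""Synthetic single-molecule data with the statistical structure the
analyses assume.

Three generators cover the three observation channels:

``simulate_tec_snapshot``
    EDTA-quenched snapshot ensembles.  Active elongation complexes take
    single-bp steps with exponential waiting times at a per-molecule
    rate (statically dispersed about the ensemble mean), and on
    reaching an occupied operator wait for an exponential dissociation
    event before passing (no re-binding race).  Complexes reaching the
    terminator release the polymerase.  Positions are read out at the
    incubation time with Gaussian tracing noise.  Inactive complexes
    stay at the promoter with Gaussian jitter.

``simulate_mt_trace``
    Tether-extension time series at the camera rate.  Transcription
    shortens the tether linearly in transcribed bases; a pause of
    exponential duration is inserted when the complex reaches the
    operator.  Tether and reference (stuck) bead share one drift
    realization and carry independent Gaussian noise; the exact pause
    bookkeeping is returned for recovery tests.

``render_bead_image`` / ``build_lut_stack``
    Defocused bead diffraction patterns: a radially symmetric
    concentric-ring kernel whose ring spacing grows linearly with
    defocus, so the radial profile varies smoothly and injectively with
    z.  Used to exercise subpixel XY localization and LUT z tracking.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .kinetics import LACI_CONCENTRATION_DEFAULT, OperatorKinetics
from .sfm import MoleculeRecord
from .templates import TemplateMap
from .traces import ExtensionTrace

__all__ = [
    "SnapshotConfig",
    "TraceConfig",
    "BeadImageConfig",
    "PauseTruth",
    "simulate_tec_snapshot",
    "simulate_mt_trace",
    "render_bead_image",
    "build_lut_stack",
]


@dataclass(frozen=True)
class SnapshotConfig:
    """Conditions of one snapshot (SFM) transcription run.

    Defaults are the study conditions: 10.3 bp/s mean rate for 60 s at
    7.5 nM LacI.  Per-molecule elongation rates are Gamma-dispersed
    about the mean (``rate_dispersion_shape``; shape 1 = exponential
    static heterogeneity, None = identical rates).  This is what shapes
    the active-position ensemble into the decaying exponential with
    mean progress v*T that the downstream analyses assume; random
    initiation delays (``initiation_delay_mean``) and irreversible
    arrest (``stop_rate``) are additionally available but default off.
    Complexes that reach the terminator release and leave the
    polymerase-bearing ensemble.  ``looped`` is the probability that a
    molecule is in the looped state for the whole window (loops neither
    break nor form within 60 s).
    """

    elongation_rate: float = 10.3  # bp/s, ensemble mean
    duration: float = 60.0  # s
    laci_concentration: float = LACI_CONCENTRATION_DEFAULT  # M
    inactive_fraction: float = 0.2
    promoter_jitter_sd: float = 30.0  # bp
    tracing_noise_sd: float = 15.0  # bp
    rate_dispersion_shape: float | None = 1.0  # Gamma shape; None = homogeneous
    stop_rate: float = 0.0  # 1/s
    initiation_delay_mean: float = 0.0  # s
    looped: float = 0.0  # probability
    n_molecules: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elongation_rate <= 0 or self.duration <= 0:
            raise ValidationError("elongation_rate and duration must be > 0")
        if not (0.0 <= self.inactive_fraction <= 1.0):
            raise ValidationError("inactive_fraction must be in [0, 1]")
        if not (0.0 <= float(self.looped) <= 1.0):
            raise ValidationError("looped must be a flag or probability in [0, 1]")
        if self.promoter_jitter_sd < 0 or self.tracing_noise_sd < 0 or self.stop_rate < 0:
            raise ValidationError("sds and stop_rate must be >= 0")
        if self.initiation_delay_mean < 0:
            raise ValidationError("initiation_delay_mean must be >= 0")
        if self.rate_dispersion_shape is not None and self.rate_dispersion_shape <= 0:
            raise ValidationError("rate_dispersion_shape must be > 0 or None")
        if self.laci_concentration < 0:
            raise ValidationError("laci_concentration must be >= 0")
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")


def simulate_tec_snapshot(
    template: TemplateMap,
    kinetics: list[OperatorKinetics],
    config: SnapshotConfig,
) -> list[MoleculeRecord]:
    """Simulate one EDTA-quenched ensemble; one record per molecule.

    Operator initial occupancy is Bernoulli at the two-state binding
    equilibrium for ``laci_concentration``; looped molecules have both
    operators occupied with dissociation slowed by ``loop_off_factor``.
    Once LacI dissociates the polymerase passes immediately.
    """
    kin = {k.operator_id: k for k in kinetics}
    ops = template.operators
    for oid, _ in ops:
        if oid not in kin:
            raise ConfigurationError(f"no kinetics supplied for operator {oid!r}")

    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    v, T = config.elongation_rate, config.duration

    inactive = rng.random(n) < config.inactive_fraction
    can_loop = len(ops) == 2
    looped = (rng.random(n) < float(config.looped)) & can_loop

    occupied: dict[str, np.ndarray] = {}
    pause_by_op: dict[str, np.ndarray] = {}
    for oid, _pos in ops:
        k = kin[oid]
        occ = rng.random(n) < k.equilibrium_occupancy(config.laci_concentration)
        occ = occ | looped  # a loop requires LacI bound at both operators
        k_eff = np.where(looped, k.k_off / k.loop_off_factor, k.k_off)
        pause_by_op[oid] = np.where(occ, rng.exponential(1.0 / k_eff), 0.0)
        occupied[oid] = occ

    # Motion time: the incubation window less the initiation delay,
    # censored by random irreversible arrest.
    if config.initiation_delay_mean > 0:
        window = np.maximum(T - rng.exponential(config.initiation_delay_mean, n), 0.0)
    else:
        window = np.full(n, T)
    if config.stop_rate > 0:
        t_motion = np.minimum(window, rng.exponential(1.0 / config.stop_rate, n))
    else:
        t_motion = window

    # Static rate heterogeneity: per-molecule multiplier with mean 1.
    if config.rate_dispersion_shape is not None:
        shape = config.rate_dispersion_shape
        rate_mult = rng.gamma(shape, 1.0 / shape, n)
    else:
        rate_mult = np.ones(n)

    active = ~inactive
    n_active = int(active.sum())
    max_steps = template.terminator_bp - template.stall_bp
    positions = np.zeros(n)
    terminated = np.zeros(n, dtype=bool)
    if n_active:
        waits = rng.exponential(1.0 / v, size=(n_active, max_steps))
        waits /= np.maximum(rate_mult[active][:, None], 1e-12)
        cum = np.cumsum(waits, axis=1)  # cum[:, j-1] = time position stall+j is reached
        for oid, op_bp in ops:
            d = op_bp - template.stall_bp
            if 0 < d < max_steps:
                # the step leaving the operator is delayed by the dissociation wait
                cum[:, d:] += pause_by_op[oid][active][:, None]
        steps = (cum <= t_motion[active][:, None]).sum(axis=1)
        positions[active] = template.stall_bp + steps
        # complexes that reach the terminator release the polymerase
        terminated[active] = steps >= max_steps
    if inactive.any():
        positions[inactive] = template.promoter_bp + rng.normal(
            0.0, config.promoter_jitter_sd, int(inactive.sum())
        )
    true_positions = positions.copy()
    if config.tracing_noise_sd > 0:
        positions = positions + rng.normal(0.0, config.tracing_noise_sd, n)
    positions = np.clip(positions, 0.0, template.length_bp)

    records = []
    for i in range(n):
        laci = []
        for oid, op_bp in ops:
            # LacI is recorded if initially bound and not yet bypassed
            if occupied[oid][i] and true_positions[i] <= op_bp:
                laci.append(float(op_bp))
        records.append(
            MoleculeRecord(
                molecule_id=f"mol{i:05d}",
                rnap_bp=None if terminated[i] else float(positions[i]),
                laci_positions=laci,
                looped=bool(looped[i]) and len(laci) == 2,
                template=template,
            )
        )
    return records


@dataclass(frozen=True)
class TraceConfig:
    """Conditions of one magnetic-tweezer transcription recording.

    ``extension_per_bp`` converts transcribed bases to tether
    shortening; 0.29 nm/bp places the O1 pause of the standard tether at
    −0.2 µm and the terminator at about −0.35 µm.  Drift is shared
    bit-for-bit between the tether and the reference bead.  Tether
    shortening is floored at ``runoff_depth_um`` (bead on the chamber
    surface).
    """

    sample_rate: float = 164.0  # Hz
    extension_per_bp: float = 0.29  # nm/bp
    noise_sd: float = 15.0  # nm
    drift_model: str = "random_walk"  # none | linear | random_walk
    drift_rate_nm_s: float = 1.0  # linear model, nm/s
    drift_rw_sd_nm: float = 3.0  # random-walk model, nm per sqrt(s)
    initiation_delay_mean: float = 20.0  # s
    total_duration: float = 800.0  # s
    elongation_rate: float = 10.3  # bp/s
    laci_concentration: float | None = 1e-8  # M; None disables the roadblock
    terminate_probability: float = 0.5
    runoff_depth_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")
        if self.extension_per_bp <= 0:
            raise ValidationError("extension_per_bp must be > 0")
        if self.noise_sd < 0 or self.drift_rw_sd_nm < 0:
            raise ValidationError("noise magnitudes must be >= 0")
        if self.drift_model not in ("none", "linear", "random_walk"):
            raise ValidationError(f"unknown drift_model {self.drift_model!r}")
        if self.elongation_rate <= 0 or self.total_duration <= 0:
            raise ValidationError("elongation_rate and total_duration must be > 0")
        if self.initiation_delay_mean < 0:
            raise ValidationError("initiation_delay_mean must be >= 0")
        if not (0.0 <= self.terminate_probability <= 1.0):
            raise ValidationError("terminate_probability must be in [0, 1]")
        if self.total_duration < self.initiation_delay_mean:
            warnings.warn("total_duration is shorter than the mean initiation delay")


@dataclass
class PauseTruth:
    """Exact bookkeeping of the simulated roadblock pause."""

    occupied: bool
    t_start: float | None  # s, arrival at the operator
    t_end: float | None  # s, dissociation
    duration: float | None  # s
    pause_extension_um: float | None  # expected extension mark of the pause
    outcome: str  # terminated | runoff
    initiation_delay_s: float


def _drift_nm(config: TraceConfig, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if config.drift_model == "none":
        return np.zeros_like(t)
    if config.drift_model == "linear":
        return config.drift_rate_nm_s * t
    dt = 1.0 / config.sample_rate
    steps = rng.normal(0.0, config.drift_rw_sd_nm * math.sqrt(dt), t.size)
    steps[0] = 0.0
    return np.cumsum(steps)


def simulate_mt_trace(
    template: TemplateMap,
    kinetics: OperatorKinetics,
    config: TraceConfig,
) -> tuple[ExtensionTrace, ExtensionTrace, PauseTruth]:
    """Simulate a tether trace, its stuck reference bead, and the truth.

    extension(t) = −(bp transcribed by t) × extension_per_bp + shared
    drift + noise, in µm.  The pause at the (single) operator has
    exponential duration with mean 1/k_off when the operator is
    initially occupied (Bernoulli at the binding equilibrium).
    """
    ops = template.operators
    if len(ops) != 1:
        raise ValidationError("simulate_mt_trace expects a single-operator template")
    (op_id, op_bp), = ops
    if kinetics.operator_id != op_id:
        raise ConfigurationError(
            f"kinetics are for {kinetics.operator_id!r} but the template carries {op_id!r}"
        )

    rng = np.random.default_rng(config.seed)
    v = config.elongation_rate
    delay = rng.exponential(config.initiation_delay_mean) if config.initiation_delay_mean else 0.0

    if config.laci_concentration is None:
        occupied = False
    else:
        occupied = rng.random() < kinetics.equilibrium_occupancy(config.laci_concentration)
    pause = rng.exponential(1.0 / kinetics.k_off) if occupied else 0.0

    terminate = rng.random() < config.terminate_probability
    runoff_bp = template.stall_bp + math.ceil(1e3 * config.runoff_depth_um / config.extension_per_bp)
    end_bp = template.terminator_bp if terminate else min(runoff_bp, template.length_bp)
    n_steps = end_bp - template.stall_bp
    cum = np.cumsum(rng.exponential(1.0 / v, n_steps))

    d = op_bp - template.stall_bp
    truth = PauseTruth(
        occupied=occupied,
        t_start=None,
        t_end=None,
        duration=None,
        pause_extension_um=None,
        outcome="terminated" if terminate else "runoff",
        initiation_delay_s=delay,
    )
    if occupied and 0 < d <= n_steps:
        t_arrive = delay + cum[d - 1]
        cum[d:] += pause
        truth.t_start = float(t_arrive)
        truth.t_end = float(t_arrive + pause)
        truth.duration = float(pause)
        truth.pause_extension_um = -d * config.extension_per_bp / 1e3

    n = int(round(config.total_duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    bp = np.searchsorted(delay + cum, t, side="right")
    ext_nm = np.maximum(-bp * config.extension_per_bp, -1e3 * config.runoff_depth_um)

    drift = _drift_nm(config, t, rng)
    noise_t = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
    noise_r = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
    tether = ExtensionTrace(
        time=t,
        extension=(ext_nm + drift + noise_t) / 1e3,
        sample_rate=config.sample_rate,
        bead_id="tether",
        history=["simulate_mt_trace"],
    )
    reference = ExtensionTrace(
        time=t,
        extension=(drift + noise_r) / 1e3,
        sample_rate=config.sample_rate,
        bead_id="reference",
        history=["simulate_mt_trace"],
    )
    return tether, reference, truth


@dataclass(frozen=True)
class BeadImageConfig:
    """Optics of the synthetic defocused-bead renderer.

    The noiseless pattern is radially symmetric about the true center:

        I(r; z) = background + amplitude * exp(−r/decay) * cos(2π r / Λ(z)),
        Λ(z) = ring_spacing_nm * (1 + z / z_scale_nm),

    so ring spacing (and the radius of every ring) grows linearly with
    defocus and the radial profile is injective over ``z_range``.  The
    "moderate noise" calibration level is amplitude/noise_sd = 5.
    """

    pixel_size: float = 72.5  # nm/pixel
    image_size: int = 64  # pixels per side
    amplitude: float = 1.0
    background: float = 2.0
    ring_spacing_nm: float = 580.0  # Λ at z = 0 (8 px)
    z_scale_nm: float = 4000.0
    decay_nm: float = 1200.0
    z_range: tuple[float, float] = (-1000.0, 1000.0)  # nm
    z_step: float = 100.0  # nm
    noise_sd: float = 0.2  # intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.image_size < 8:
            raise ValidationError("pixel_size must be > 0 and image_size >= 8")
        if self.z_step <= 0:
            raise ValidationError("z_step must be > 0")
        if self.z_range[1] <= self.z_range[0]:
            raise ValidationError("z_range must be increasing")
        if 1 + self.z_range[0] / self.z_scale_nm <= 0:
            raise ValidationError("z_range extends beyond the kernel's validity (Λ <= 0)")
        if self.noise_sd < 0 or self.amplitude <= 0 or self.decay_nm <= 0:
            raise ValidationError("amplitude, decay_nm must be > 0 and noise_sd >= 0")


def render_bead_image(
    config: BeadImageConfig,
    x: float = 0.0,
    y: float = 0.0,
    z: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one bead frame centered at (x, y) nm from the frame center.

    Deterministic for a given config/seed; pass an external ``rng`` to
    draw a stream of independently noisy frames.  The center must stay
    at least 2 px inside the frame and z within ``z_range``.
    """
    N, px = config.image_size, config.pixel_size
    half = (N - 1) / 2.0
    cx, cy = half + x / px, half + y / px
    if not (1.0 <= cx <= N - 2 and 1.0 <= cy <= N - 2):
        raise ValidationError("bead center lies outside the usable frame")
    if not (config.z_range[0] - 1e-9 <= z <= config.z_range[1] + 1e-9):
        raise ValidationError(f"z={z} outside z_range {config.z_range}")
    yy, xx = np.mgrid[0:N, 0:N].astype(float)
    r_nm = np.hypot(xx - cx, yy - cy) * px
    lam = config.ring_spacing_nm * (1.0 + z / config.z_scale_nm)
    img = config.background + config.amplitude * np.exp(-r_nm / config.decay_nm) * np.cos(
        2.0 * np.pi * r_nm / lam
    )
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    return img


def build_lut_stack(config: BeadImageConfig) -> list[tuple[float, np.ndarray]]:
    """Noiseless, centered calibration frames over the z grid, ascending."""
    z0, z1 = config.z_range
    z_values = np.arange(z0, z1 + 0.5 * config.z_step, config.z_step)
    if z_values.size < 3:
        raise ValidationError("LUT needs at least 3 planes for parabolic refinement")
    noiseless = dataclasses.replace(config, noise_sd=0.0)
    return [(float(z), render_bead_image(noiseless, 0.0, 0.0, z)) for z in z_values]
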