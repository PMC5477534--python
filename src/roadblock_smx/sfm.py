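"""Statistics over EDTA-quenched transcription snapshot ensembles.

Each imaged molecule contributes one :class:`MoleculeRecord`: the RNA
polymerase position along the DNA contour (bp from the TSS), the LacI
particle positions, and whether the molecule is looped.  The module
provides the ensemble statistics used to quantify elongation progress:

* survival-of-progress curves, S(x) = 1 − empirical CDF of polymerase
  position — the probability that a complex progressed past x;
* a Gaussian + exponential mixture fit to the position histogram: the
  Gaussian describes promoter-stuck (inactive) complexes, the decaying
  exponential the active elongating population, whose mean progress
  divided by the incubation time estimates the elongation rate;
* the five-zone taxonomy of progress relative to the two operators
  (I promoter, II before the near operator, III in contact with it,
  IV between the operators, V beyond the far operator);
* roadblock pass fractions and loop/occupancy tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, ValidationError
from .templates import TemplateMap

__all__ = [
    "MoleculeRecord",
    "SurvivalCurve",
    "MixtureFit",
    "ZoneLabel",
    "normalize_contour_positions",
    "survival_curve",
    "fit_position_mixture",
    "estimate_elongation_rate",
    "classify_zone",
    "pass_fraction",
    "ensemble_summaries",
]

#: Contour length the measured DNA length is normalized to, bp.
REFERENCE_LENGTH_BP = 1524


@dataclass
class MoleculeRecord:
    """One imaged molecule: particle positions along the DNA contour.

    Positions are in bp from the TSS after normalization; before
    normalization they are raw contour units (nm or px) together with
    ``contour_length_measured`` in the same units.  ``rnap_bp`` is None
    for molecules without a bound polymerase.
    """

    molecule_id: str
    rnap_bp: float | None = None
    laci_positions: list[float] = field(default_factory=list)
    looped: bool = False
    contour_length_measured: float | None = None
    template: TemplateMap | None = None

    def __post_init__(self) -> None:
        self.laci_positions = [float(p) for p in self.laci_positions]
        if self.looped and not self.laci_positions:
            raise ValidationError(
                f"record {self.molecule_id}: looped implies at least one LacI particle"
            )


def normalize_contour_positions(
    record: MoleculeRecord, reference_length: float = REFERENCE_LENGTH_BP
) -> MoleculeRecord:
    """Rescale raw contour positions to bp of the reference length.

    Every position is multiplied by ``reference_length /
    contour_length_measured``; the streptavidin-marked downstream end
    orients the molecule so position 0 is the upstream (TSS) end.
    """
    L = record.contour_length_measured
    if L is None or L <= 0:
        raise ValidationError(
            f"record {record.molecule_id}: measured contour length must be positive"
        )
    scale = reference_length / L
    for p in [record.rnap_bp or 0.0, *record.laci_positions]:
        if p > L * (1 + 1e-9):
            raise ValidationError(
                f"record {record.molecule_id}: raw position {p} exceeds contour length {L}"
            )
    return replace(
        record,
        rnap_bp=None if record.rnap_bp is None else record.rnap_bp * scale,
        laci_positions=[p * scale for p in record.laci_positions],
        contour_length_measured=reference_length,
    )


@dataclass
class SurvivalCurve:
    """Fraction of complexes found beyond each grid position."""

    grid: np.ndarray  # bp
    survival: np.ndarray  # fraction in [0, 1]
    n: int


def survival_curve(positions, grid_step: float = 10.0) -> SurvivalCurve:
    """Survival of progress S(x) = #{positions > x} / n on a regular grid.

    Strict inequality (right-continuous step convention): S just below
    the minimum is 1, S at and beyond the maximum is 0.
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    if pos.size == 0:
        raise ValidationError("survival_curve requires at least one position")
    if grid_step <= 0:
        raise ValidationError("grid_step must be > 0")
    lo = min(0.0, np.floor(pos[0] / grid_step) * grid_step)
    grid = np.arange(lo, pos[-1] + 2 * grid_step, grid_step)
    surv = (pos.size - np.searchsorted(pos, grid, side="right")) / pos.size
    return SurvivalCurve(grid=grid, survival=surv, n=pos.size)


@dataclass
class MixtureFit:
    """Gaussian (inactive) + exponential (active) position mixture."""

    w_inactive: float
    mu: float  # bp, promoter peak center
    sigma: float  # bp
    lambda_bp: float  # bp, mean progress of the active population
    sse_or_loglik: float
    bin_width: float
    method: str = "lsq"

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_inactive <= 1.0):
            raise ValidationError("w_inactive must be in [0, 1]")
        if self.sigma <= 0 or self.lambda_bp <= 0:
            raise ValidationError("sigma and lambda_bp must be > 0")


def _expon_cdf(x, lam, support_max):
    if support_max is None:
        return stats.expon.cdf(x, scale=lam)
    # right-truncated exponential: finite template, complexes reaching the
    # end leave the observable ensemble
    denom = -np.expm1(-support_max / lam)
    return np.clip(-np.expm1(-np.minimum(x, support_max) / lam) / denom, 0.0, 1.0)


def _mixture_counts(edges, n, w, mu, sigma, lam, support_max=None):
    """Expected bin counts: the mixture CDF integrated over each bin.

    Integrating (rather than evaluating the pdf at bin centers) keeps
    components narrower than a bin honest about their total mass."""
    cdf = w * stats.norm.cdf(edges, mu, sigma) + (1 - w) * _expon_cdf(edges, lam, support_max)
    return n * np.diff(cdf)


def fit_position_mixture(
    positions,
    bin_width: float = 50.0,
    method: str = "lsq",
    support_max: float | None = None,
) -> MixtureFit:
    """Fit the promoter-peak + elongating-tail mixture to positions.

    ``method='lsq'`` (default) minimizes the squared error between the
    binned histogram and the mixture expectation; ``method='mle'``
    refines the least-squares solution by maximum likelihood on the
    unbinned positions.  ``lambda_bp`` is the exponential mean progress
    of the active component.  ``support_max`` right-truncates the
    exponential at the end of the observable template (the terminator):
    complexes progressing past it terminate and leave the ensemble, so
    on a finite template the active component is a truncated
    exponential while ``lambda_bp`` keeps its meaning as the underlying
    mean progress.
    """
    x = np.asarray(positions, dtype=float)
    if x.size < 30:
        warnings.warn(f"only {x.size} positions; mixture fit below the recommended n >= 30")
    if x.size < 4:
        raise ValidationError("too few positions for a mixture fit")
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    lo = np.floor(min(0.0, x.min()) / bin_width) * bin_width
    edges = np.arange(lo, x.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(x, edges)
    if np.count_nonzero(counts) < 2:
        raise FitError("degenerate histogram: fewer than two occupied bins")
    centers = 0.5 * (edges[:-1] + edges[1:])
    n, bw = x.size, bin_width
    xmax = float(x.max())

    below = x[x < max(2 * bin_width, 100.0)]
    above = x[x >= max(2 * bin_width, 100.0)]
    starts = []
    for w0 in (np.clip(below.size / n, 0.02, 0.9), 0.02):
        mu0 = float(below.mean()) if below.size else 0.0
        s0 = float(np.clip(below.std(), 5.0, 100.0)) if below.size > 1 else 20.0
        lam0 = float(np.clip(above.mean() if above.size else x.mean() + bw, 10.0, None))
        starts.append((w0, mu0, s0, lam0))

    bounds = ([0.0, lo - 100.0, 1.0, 1.0], [1.0, xmax + 100.0, 500.0, 10.0 * xmax + 1e3])
    best = None
    last_err = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            popt, _ = optimize.curve_fit(
                lambda _x, w, mu, sg, lam: _mixture_counts(edges, n, w, mu, sg, lam, support_max),
                centers,
                counts,
                p0=p0,
                bounds=bounds,
                maxfev=20000,
            )
        except RuntimeError as err:  # pragma: no cover - optimizer failure path
            last_err = err
            continue
        sse = float(np.sum((counts - _mixture_counts(edges, n, *popt, support_max)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise FitError(f"mixture fit did not converge: {last_err}")
    (w, mu, sigma, lam), sse = best

    if method == "lsq":
        return MixtureFit(w, mu, sigma, lam, sse, bin_width, "lsq")
    if method != "mle":
        raise ValidationError(f"unknown method {method!r}; use 'lsq' or 'mle'")

    def nll(p):
        w_, mu_, sg_, lam_ = p
        if support_max is None:
            e_dens = stats.expon.pdf(x, scale=lam_)
        else:
            e_dens = np.where(
                x <= support_max,
                np.exp(-x / lam_) / (lam_ * -np.expm1(-support_max / lam_)),
                0.0,
            )
        dens = w_ * stats.norm.pdf(x, mu_, sg_) + (1 - w_) * e_dens
        return -np.sum(np.log(np.maximum(dens, 1e-300)))

    res = optimize.minimize(
        nll,
        [w, mu, sigma, lam],
        method="L-BFGS-B",
        bounds=list(zip(*bounds)),
    )
    if not res.success:
        raise FitError(f"MLE refinement failed: {res.message}")
    w, mu, sigma, lam = res.x
    return MixtureFit(w, mu, sigma, lam, float(-res.fun), bin_width, "mle")


def estimate_elongation_rate(fit: MixtureFit | float, duration: float) -> float:
    """Mean elongation rate: active mean progress / incubation time (bp/s)."""
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    lam = fit.lambda_bp if isinstance(fit, MixtureFit) else float(fit)
    if lam < 0:
        raise ValidationError("mean progress must be >= 0")
    return lam / duration


@dataclass(frozen=True)
class ZoneLabel:
    zone: str  # I..V
    contact_halfwidth: float  # bp


def classify_zone(
    record: MoleculeRecord | float,
    template: TemplateMap | None = None,
    contact_halfwidth: float = 30.0,
) -> ZoneLabel:
    """Assign a progress zone relative to the two operators.

    I: within ``contact_halfwidth`` of the promoter.  II: past the
    promoter window but before the near-operator window.  III: in
    contact with the near operator (|pos − near| <= halfwidth).  IV:
    between the operators; contact with the far operator folds into IV.
    V: beyond the far operator window.
    """
    if isinstance(record, MoleculeRecord):
        if record.rnap_bp is None:
            raise ValidationError(f"record {record.molecule_id} has no RNAP position")
        pos = float(record.rnap_bp)
        template = template or record.template
    else:
        pos = float(record)
    if template is None:
        raise ValidationError("a template is required for zone classification")
    near, far = template.near_operator_bp, template.far_operator_bp
    if near is None or far is None:
        raise ValidationError("zone classification needs both operators on the template")
    hw = float(contact_halfwidth)
    if hw <= 0:
        raise ValidationError("contact_halfwidth must be > 0")
    if hw >= near - hw or near + hw >= far - hw:
        raise ValidationError("contact windows overlap; reduce contact_halfwidth")
    if pos <= hw:
        zone = "I"
    elif abs(pos - near) <= hw:
        zone = "III"
    elif pos < near:
        zone = "II"
    elif pos <= far + hw:
        zone = "IV"
    else:
        zone = "V"
    return ZoneLabel(zone, hw)


def pass_fraction(
    records,
    boundary_bp: float,
    condition_on_reached: bool = False,
    contact_halfwidth: float = 30.0,
) -> tuple[float, int, int]:
    """Fraction of complexes found past ``boundary_bp``.

    Returns (fraction, numerator, denominator).  With
    ``condition_on_reached`` the denominator is restricted to complexes
    that at least reached the obstacle (pos >= boundary − halfwidth).
    """
    pos = np.array(
        [r.rnap_bp if isinstance(r, MoleculeRecord) else float(r) for r in records], dtype=float
    )
    if pos.size == 0 or np.any(~np.isfinite(pos)):
        raise ValidationError("pass_fraction requires records with RNAP positions")
    denom_mask = pos >= boundary_bp - contact_halfwidth if condition_on_reached else np.ones_like(pos, bool)
    denom = int(denom_mask.sum())
    if denom == 0:
        raise ValidationError("no complexes reached the obstacle; fraction undefined")
    num = int((pos[denom_mask] > boundary_bp).sum())
    return num / denom, num, denom


def ensemble_summaries(
    records: list[MoleculeRecord],
    template: TemplateMap | None = None,
    contact_halfwidth: float = 30.0,
) -> pd.DataFrame:
    """Loop-fraction and operator-occupancy tallies with binomial CIs.

    A LacI particle within ``contact_halfwidth`` of an operator counts
    as occupying it.  Confidence intervals are 95% Wilson.
    """
    from statsmodels.stats.proportion import proportion_confint

    if not records:
        raise ValidationError("no records to summarize")
    template = template or records[0].template
    rows = {"looped": [r.looped for r in records]}
    if template is not None:
        for label, pos in zip(("near_occupied", "far_occupied"), template.operators):
            _, op_bp = pos
            rows[label] = [
                any(abs(p - op_bp) <= contact_halfwidth for p in r.laci_positions)
                for r in records
            ]
    out = []
    n = len(records)
    for label, flags in rows.items():
        k = int(np.sum(flags))
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        out.append(
            {"statistic": label, "count": k, "n": n, "fraction": k / n,
             "ci_low": float(lo), "ci_high": float(hi)}
        )
    return pd.DataFrame(out)
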