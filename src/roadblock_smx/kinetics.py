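"""LacI-operator binding kinetics and the roadblock occupancy arithmetic.

The quantities here are the simple but load-bearing numbers of the
roadblock picture: an operator-bound repressor occupies its site for an
average of ``1/k_off`` seconds; a vacant operator in a repressor bath of
concentration ``c`` waits an average of ``1/(k_on * c)`` seconds before
being filled; and an elongation complex that reaches an occupied operator
and simply waits for dissociation passes within a window ``w`` with
probability ``1 - exp(-k_off * w)``.

Reference lifetimes (seconds) used throughout:

===========  =======  ========================================
operator     source   mean occupancy (1/k_off)
===========  =======  ========================================
Os           in vivo  2326
O1           in vivo  434
O2           in vivo  102
O1           in vitro 200   (k_off = 0.3 / min)
===========  =======  ========================================

In vitro lifetimes for Os and O2 are not directly measured; the
``in_vitro_kinetics`` preset scales the in vitro O1 anchor by the in vivo
lifetime ratios (Os ≈ 1072 s, O2 ≈ 47 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "OperatorKinetics",
    "OccupancyEntry",
    "OccupancyTable",
    "occupancy_time",
    "binding_wait",
    "pass_probability",
    "compare_pause_to_occupancy",
    "in_vitro_kinetics",
    "default_occupancy_table",
    "IN_VIVO_LIFETIME_S",
    "O1_IN_VITRO_K_OFF",
    "LACI_K_ON",
    "LACI_CONCENTRATION_DEFAULT",
]

#: Mean in vivo operator occupancy, seconds.
IN_VIVO_LIFETIME_S = {"Os": 2326.0, "O1": 434.0, "O2": 102.0}

#: In vitro O1 dissociation rate, 0.3 per minute, in 1/s.
O1_IN_VITRO_K_OFF = 0.3 / 60.0

#: LacI-operator association rate constant, 1/(M s), in vitro.
LACI_K_ON = 7.9e9

#: Working repressor concentration of the SFM assays, molar (7.5 nM).
LACI_CONCENTRATION_DEFAULT = 7.5e-9

_PER_SECOND = {"1/s", "/s", "s^-1", "per_s"}
_PER_MINUTE = {"1/min", "/min", "min^-1", "per_min"}


def _to_per_second(rate: float, unit: str) -> float:
    if unit in _PER_SECOND:
        return rate
    if unit in _PER_MINUTE:
        return rate / 60.0
    raise ValidationError(f"unknown rate unit {unit!r}; use '1/s' or '1/min'")


@dataclass(frozen=True)
class OperatorKinetics:
    """Association/dissociation parameters of one operator.

    ``loop_off_factor`` (>= 1) divides ``k_off`` while the operator is
    engaged in a LacI-mediated loop, modelling the increased effective
    affinity of a bivalently bound tetramer.
    """

    operator_id: str
    k_off: float  # 1/s
    k_on: float = LACI_K_ON  # 1/(M s)
    loop_off_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.k_off <= 0:
            raise ValidationError(f"k_off must be > 0, got {self.k_off}")
        if self.k_on <= 0:
            raise ValidationError(f"k_on must be > 0, got {self.k_on}")
        if self.loop_off_factor < 1:
            raise ValidationError("loop_off_factor must be >= 1")

    def effective_k_off(self, looped: bool) -> float:
        """Dissociation rate, reduced by ``loop_off_factor`` when looped."""
        return self.k_off / self.loop_off_factor if looped else self.k_off

    def equilibrium_occupancy(self, concentration: float) -> float:
        """Two-state binding equilibrium c / (c + K_d), K_d = k_off/k_on."""
        if concentration < 0:
            raise ValidationError("concentration must be >= 0")
        kd = self.k_off / self.k_on
        return concentration / (concentration + kd)


def occupancy_time(k_off: float, unit: str = "1/s") -> float:
    """Mean occupancy lifetime 1/k_off in seconds.

    Per-minute rates are accepted via ``unit='1/min'`` (e.g. the in vitro
    O1 rate 0.3/min gives 200 s).
    """
    k = _to_per_second(k_off, unit)
    if k <= 0:
        raise ValidationError(f"dissociation rate must be > 0, got {k_off}")
    return 1.0 / k


def binding_wait(k_on: float, concentration: float) -> float:
    """Mean wait 1/(k_on * c) in seconds for a vacant operator to bind LacI.

    At the in vitro association rate 7.9e9 /M/s and 7.5 nM LacI this is
    about 17 ms — rebinding after a polymerase transit is effectively
    instantaneous at working concentrations.
    """
    if k_on <= 0 or concentration <= 0:
        raise ValidationError("k_on and concentration must be > 0")
    return 1.0 / (k_on * concentration)


def pass_probability(wait_window: float, k_off: float) -> float:
    """Probability 1 - exp(-k_off * w) that a waiting TEC passes within w.

    This is the wait-for-dissociation model: the polymerase cannot
    dislodge the repressor and advances only once it stochastically
    dissociates within the remaining window ``wait_window``.
    """
    if wait_window < 0:
        raise ValidationError("wait_window must be >= 0")
    if k_off < 0:
        raise ValidationError("k_off must be >= 0")
    return -math.expm1(-k_off * wait_window)


@dataclass(frozen=True)
class OccupancyEntry:
    operator_id: str
    lifetime_s: float
    source: str  # "in_vivo" | "in_vitro"

    def __post_init__(self) -> None:
        if self.lifetime_s <= 0:
            raise ValidationError("lifetime must be > 0")


@dataclass(frozen=True)
class OccupancyTable:
    """Reference mean-occupancy lifetimes, by operator and provenance."""

    entries: tuple[OccupancyEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))


def default_occupancy_table() -> OccupancyTable:
    """The standard comparison set: in vivo Os/O1/O2 plus in vitro O1."""
    rows = [OccupancyEntry(op, t, "in_vivo") for op, t in IN_VIVO_LIFETIME_S.items()]
    rows.append(OccupancyEntry("O1", occupancy_time(O1_IN_VITRO_K_OFF), "in_vitro"))
    return OccupancyTable(tuple(rows))


def in_vitro_kinetics(operator_id: str, loop_off_factor: float = 1.0) -> OperatorKinetics:
    """In vitro kinetics preset for Os, O1 or O2.

    O1 uses the measured in vitro rate (0.3/min).  Os and O2 scale the O1
    lifetime by the in vivo lifetime ratios, for lack of direct in vitro
    measurements.
    """
    if operator_id not in IN_VIVO_LIFETIME_S:
        raise ValidationError(f"no kinetics preset for operator {operator_id!r}")
    lifetime = (1.0 / O1_IN_VITRO_K_OFF) * (
        IN_VIVO_LIFETIME_S[operator_id] / IN_VIVO_LIFETIME_S["O1"]
    )
    return OperatorKinetics(operator_id, 1.0 / lifetime, LACI_K_ON, loop_off_factor)


def compare_pause_to_occupancy(
    pause_mean_se: tuple[float, float], table: OccupancyTable
) -> list[dict]:
    """Compare a measured mean pause with tabulated occupancy lifetimes.

    Returns one row per table entry with the signed difference
    (measured - expected) in seconds and, when the standard error is
    positive, a z-style distance ``difference / se``.
    """
    mean, se = pause_mean_se
    if not np.isfinite(mean) or se < 0:
        raise ValidationError("pause summary must be (finite mean, se >= 0)")
    if not table.entries:
        raise ValidationError("occupancy table is empty")
    rows = []
    for entry in table.entries:
        diff = mean - entry.lifetime_s
        rows.append(
            {
                "operator_id": entry.operator_id,
                "source": entry.source,
                "lifetime_s": entry.lifetime_s,
                "pause_mean_s": mean,
                "pause_se_s": se,
                "difference_s": diff,
                "z": diff / se if se > 0 else None,
            }
        )
    return rows
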