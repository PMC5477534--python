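"""Annotated linear DNA templates for roadblock transcription assays.

Coordinates are 0-based offsets from the transcription start site (TSS),
in base pairs, increasing in the direction of transcription.  Every
template carries a promoter at 0, a stall site (+22, where elongation
complexes are halted by nucleotide deprivation before the experiment
starts), up to two LacI operators, and a terminator.

Presets
-------
``Os400O1`` / ``O2400O1``
    1523 bp SFM templates: a "near" operator (Os or O2) 271 bp from the
    TSS, a "far" O1 operator at 669 bp, the lambda t1 terminator at
    1298 bp.  The near-operator distance is also printed as 253 bp and
    261 bp in different places of the source construct maps; the
    ``-near253`` / ``-near261`` variants expose those values.
``MT-O1``
    3025 bp magnetic-tweezer template with a single O1 operator 689 bp
    from the TSS and the terminator at 1298 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ValidationError

__all__ = ["TemplateMap", "template_preset", "TEMPLATE_PRESETS"]

_OPERATOR_IDS = {"Os", "O1", "O2", "O3"}


@dataclass(frozen=True)
class TemplateMap:
    """Linear map of one transcription template.

    All positions are bp downstream of the TSS (``promoter_bp`` = 0 by
    construction).  ``near_operator_bp`` < ``far_operator_bp`` <
    ``terminator_bp`` is enforced whenever the operators are present.
    """

    name: str
    length_bp: int
    terminator_bp: int
    promoter_bp: int = 0
    stall_bp: int = 22
    near_operator_bp: int | None = None
    far_operator_bp: int | None = None
    near_operator_id: str | None = None
    far_operator_id: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"length_bp must be positive, got {self.length_bp}")
        if not (0 <= self.promoter_bp <= self.stall_bp):
            raise ValidationError("require 0 <= promoter_bp <= stall_bp")
        if not (self.stall_bp < self.terminator_bp <= self.length_bp):
            raise ValidationError("require stall_bp < terminator_bp <= length_bp")
        for pos, oid, label in (
            (self.near_operator_bp, self.near_operator_id, "near"),
            (self.far_operator_bp, self.far_operator_id, "far"),
        ):
            if (pos is None) != (oid is None):
                raise ValidationError(f"{label} operator position and id must be set together")
            if oid is not None and oid not in _OPERATOR_IDS:
                raise ValidationError(f"unknown operator id {oid!r}")
            if pos is not None and not (self.stall_bp < pos < self.terminator_bp):
                raise ValidationError(f"{label} operator must lie between stall site and terminator")
        if self.near_operator_bp is not None and self.far_operator_bp is not None:
            if not (self.near_operator_bp < self.far_operator_bp):
                raise ValidationError("require near_operator_bp < far_operator_bp")

    @property
    def operators(self) -> list[tuple[str, int]]:
        """(operator_id, position_bp) pairs in transcription order."""
        out = []
        if self.near_operator_bp is not None:
            out.append((self.near_operator_id, self.near_operator_bp))
        if self.far_operator_bp is not None:
            out.append((self.far_operator_id, self.far_operator_bp))
        return out


def _sfm(name: str, near_id: str, near_bp: int) -> TemplateMap:
    return TemplateMap(
        name=name,
        length_bp=1523,
        terminator_bp=1298,
        near_operator_bp=near_bp,
        far_operator_bp=669,
        near_operator_id=near_id,
        far_operator_id="O1",
    )


TEMPLATE_PRESETS: dict[str, TemplateMap] = {
    "Os400O1": _sfm("Os400O1", "Os", 271),
    "O2400O1": _sfm("O2400O1", "O2", 271),
    "Os400O1-near253": _sfm("Os400O1-near253", "Os", 253),
    "Os400O1-near261": _sfm("Os400O1-near261", "Os", 261),
    "O2400O1-near253": _sfm("O2400O1-near253", "O2", 253),
    "O2400O1-near261": _sfm("O2400O1-near261", "O2", 261),
    "MT-O1": TemplateMap(
        name="MT-O1",
        length_bp=3025,
        terminator_bp=1298,
        near_operator_bp=689,
        near_operator_id="O1",
    ),
}


def template_preset(name: str) -> TemplateMap:
    """Return a copy of a named template preset.

    Raises :class:`ValidationError` for unknown names, listing the
    available presets.
    """
    try:
        tpl = TEMPLATE_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown template preset {name!r}; available: {sorted(TEMPLATE_PRESETS)}"
        ) from None
    return replace(tpl)
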