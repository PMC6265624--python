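"""Genetic-model contrasts and control-group Hardy-Weinberg statistics.

A genotype-count pair (cases, controls) supports five standard 2x2
contrasts of a biallelic SNP:

======================  ==========================  ==========================
model                   exposed                     unexposed
======================  ==========================  ==========================
allele                  2*RR + RW (R alleles)       2*WW + RW (W alleles)
heterozygote            RW                          WW
homozygote              RR                          WW
dominant                RR + RW                     WW
recessive               RR                          RW + WW
======================  ==========================  ==========================

where R is the effect allele and W the reference allele.  The allele
contrast counts alleles (two per subject); the heterozygote and homozygote
contrasts drop the excluded genotype class entirely.
"""

from __future__ import annotations

import enum
import warnings as _warnings
from dataclasses import dataclass, replace

from scipy import stats

from .studies import GenotypeCounts

__all__ = [
    "Model",
    "ContrastTable",
    "HweResult",
    "build_contrast",
    "apply_continuity_correction",
    "hwe_test",
    "effect_allele_freq",
]


class Model(str, enum.Enum):
    ALLELE = "allele"
    HETEROZYGOTE = "heterozygote"
    HOMOZYGOTE = "homozygote"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"

    @classmethod
    def coerce(cls, token: "Model | str") -> "Model":
        if isinstance(token, cls):
            return token
        try:
            return cls(str(token).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown genetic model {token!r}; expected one of {[m.value for m in cls]}"
            ) from None


#: Label of the pooled-results row for each model, in field notation.
MODEL_LABELS = {
    Model.ALLELE: "R-allele vs. W-allele",
    Model.HETEROZYGOTE: "WR vs. WW",
    Model.HOMOZYGOTE: "RR vs. WW",
    Model.DOMINANT: "RR+WR vs. WW",
    Model.RECESSIVE: "RR vs. WR+WW",
}


@dataclass(frozen=True)
class ContrastTable:
    """A 2x2 exposure table for one study under one genetic model.

    Cells are floats because a 0.5 continuity correction may be applied;
    uncorrected tables hold exact integers.
    """

    model: Model
    case_exposed: float
    case_unexposed: float
    control_exposed: float
    control_unexposed: float
    corrected: bool = False
    correction_value: float = 0.0

    def __post_init__(self) -> None:
        for c in self.cells:
            if c < 0:
                raise ValueError("contrast table cells must be nonnegative")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.case_exposed, self.case_unexposed,
                self.control_exposed, self.control_unexposed)

    @property
    def n(self) -> float:
        return sum(self.cells)


@dataclass(frozen=True)
class HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (df=1)."""

    chi_square: float
    df: int
    p_value: float
    effect_allele_freq: float


def _split(counts: GenotypeCounts, model: Model) -> tuple[int, int]:
    rr, rw, ww = counts.as_tuple()
    if model is Model.ALLELE:
        return 2 * rr + rw, 2 * ww + rw
    if model is Model.HETEROZYGOTE:
        return rw, ww
    if model is Model.HOMOZYGOTE:
        return rr, ww
    if model is Model.DOMINANT:
        return rr + rw, ww
    if model is Model.RECESSIVE:
        return rr, rw + ww
    raise AssertionError(model)


def build_contrast(
    counts_case: GenotypeCounts, counts_control: GenotypeCounts, model: Model | str
) -> ContrastTable:
    """Build the uncorrected 2x2 exposure table for one genetic model."""
    model = Model.coerce(model)
    ce, cu = _split(counts_case, model)
    te, tu = _split(counts_control, model)
    return ContrastTable(model, ce, cu, te, tu)


def apply_continuity_correction(table: ContrastTable) -> ContrastTable:
    """Add 0.5 to every cell when any cell is zero; otherwise return as is.

    The correction is applied per contrast (a zero in the homozygote table
    does not alter the allele table of the same study).  An all-zero table
    is degenerate and triggers a warning in addition to the correction.
    """
    if all(c > 0 for c in table.cells):
        return table
    if all(c == 0 for c in table.cells):
        _warnings.warn(
            "degenerate contrast table: all four cells are zero", stacklevel=2
        )
    return replace(
        table,
        case_exposed=table.case_exposed + 0.5,
        case_unexposed=table.case_unexposed + 0.5,
        control_exposed=table.control_exposed + 0.5,
        control_unexposed=table.control_unexposed + 0.5,
        corrected=True,
        correction_value=0.5,
    )


def effect_allele_freq(counts: GenotypeCounts) -> float:
    """Effect-allele frequency (2*RR + RW) / (2*N) from genotype counts."""
    if counts.total == 0:
        raise ValueError("cannot compute allele frequency of an empty group")
    return (2 * counts.rr + counts.rw) / (2 * counts.total)


def hwe_test(counts_control: GenotypeCounts) -> HweResult:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (df=1).

    The allele frequency is estimated from the observed counts; expected
    genotype counts are N*p^2, 2*N*p*(1-p), N*(1-p)^2.  No Yates
    continuity correction is applied.  A monomorphic group (p in {0, 1})
    is in trivial equilibrium: chi-square 0, p-value 1, with a warning.
    """
    n = counts_control.total
    if n == 0:
        raise ValueError("cannot test HWE on an empty control group")
    p = effect_allele_freq(counts_control)
    if p in (0.0, 1.0):
        _warnings.warn("monomorphic control group: HWE test is vacuous", stacklevel=2)
        return HweResult(0.0, 1, 1.0, p)
    expected = (n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p))
    observed = counts_control.as_tuple()
    chi = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HweResult(chi, 1, float(stats.chi2.sf(chi, 1)), p)
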