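"""Genetic-model contrasts: genotype counts -> 2x2 case-control tables.

Exposure is always defined with respect to allele 2 (the risk allele /
genotype 22), so odds ratios above 1 mean increased disease odds for
carriers of the variant.  Five dichotomisations are supported:

===========  ==========================  =====================
model        exposed                     unexposed
===========  ==========================  =====================
allele       allele-2 count (2*n22+n12)  allele-1 count
dominant     n22 + n12 (carriers)        n11
recessive    n22                         n12 + n11
homozygote   n22                         n11 (n12 dropped)
heterozygote n12                         n11 (n22 dropped)
===========  ==========================  =====================
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .study_data import GenotypeCounts

__all__ = ["GeneticModel", "ContrastTable", "build_contrast"]


class GeneticModel(str, Enum):
    ALLELE = "allele"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    HOMOZYGOTE = "homozygote"
    HETEROZYGOTE = "heterozygote"

    def comparison_label(self, allele1: str = "A", allele2: str = "G") -> str:
        """Human-readable contrast, e.g. ``"G vs. A"`` or ``"GG+AG vs. AA"``."""
        a1, a2 = allele1, allele2
        return {
            GeneticModel.ALLELE: f"{a2} vs. {a1}",
            GeneticModel.DOMINANT: f"{a2}{a2}+{a1}{a2} vs. {a1}{a1}",
            GeneticModel.RECESSIVE: f"{a2}{a2} vs. {a1}{a2}+{a1}{a1}",
            GeneticModel.HOMOZYGOTE: f"{a2}{a2} vs. {a1}{a1}",
            GeneticModel.HETEROZYGOTE: f"{a1}{a2} vs. {a1}{a1}",
        }[self]


@dataclass(frozen=True)
class ContrastTable:
    """A 2x2 table: (a, b) exposed/unexposed cases, (c, d) controls."""

    a: int
    b: int
    c: int
    d: int
    model: GeneticModel
    study_id: str = ""

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def swap_arms(self) -> "ContrastTable":
        """Exchange case and control rows (inverts the odds ratio)."""
        return ContrastTable(self.c, self.d, self.a, self.b,
                             self.model, self.study_id)


def _dichotomise(g: GenotypeCounts, model: GeneticModel) -> tuple[int, int]:
    if model is GeneticModel.ALLELE:
        return 2 * g.n22 + g.n12, 2 * g.n11 + g.n12
    if model is GeneticModel.DOMINANT:
        return g.n22 + g.n12, g.n11
    if model is GeneticModel.RECESSIVE:
        return g.n22, g.n12 + g.n11
    if model is GeneticModel.HOMOZYGOTE:
        return g.n22, g.n11
    if model is GeneticModel.HETEROZYGOTE:
        return g.n12, g.n11
    raise ValueError(f"unknown genetic model {model!r}")


def build_contrast(case: GenotypeCounts, control: GenotypeCounts,
                   model: GeneticModel, study_id: str = "") -> ContrastTable:
    """Derive the 2x2 contrast table for one study under one genetic model.

    Zero cells are legal here; they are handled downstream by the
    continuity correction in effect estimation.
    """
    model = GeneticModel(model)
    a, b = _dichotomise(case, model)
    c, d = _dichotomise(control, model)
    return ContrastTable(a, b, c, d, model, study_id)
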