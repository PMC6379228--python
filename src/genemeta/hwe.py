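"""Pearson chi-square test of Hardy-Weinberg equilibrium.

Under random mating at risk-allele frequency q the genotype proportions are
(1-q)^2, 2q(1-q), q^2.  The plain Pearson statistic (no continuity
correction) over the three genotype classes is referred to chi-square with
1 degree of freedom (3 classes - 1 - one estimated allele frequency).
Deviation in a control arm flags possible genotyping or sampling problems;
flagged studies are reported but not excluded from pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .study_data import GenotypeCounts

__all__ = ["HWEResult", "hwe_test"]

ALPHA = 0.05


@dataclass(frozen=True)
class HWEResult:
    allele2_freq: float
    chi2: float
    df: int
    p_value: float
    in_hwe: bool
    monomorphic: bool = False


def hwe_test(g: GenotypeCounts, alpha: float = ALPHA) -> HWEResult:
    """Test one arm's genotype counts for Hardy-Weinberg equilibrium.

    A monomorphic arm (allele frequency 0 or 1) carries no information
    about HWE: the statistic is defined as 0 and the arm is flagged.
    """
    n = g.total
    q = (2 * g.n22 + g.n12) / (2 * n)
    if q in (0.0, 1.0):
        return HWEResult(allele2_freq=q, chi2=0.0, df=1, p_value=1.0,
                         in_hwe=True, monomorphic=True)
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q ** 2)
    chi2 = sum((obs - exp) ** 2 / exp
               for obs, exp in zip(g.as_tuple(), expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(allele2_freq=q, chi2=float(chi2), df=1, p_value=p,
                     in_hwe=p >= alpha)
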