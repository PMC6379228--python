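"""Publication-bias diagnostics: Egger's regression and Begg's rank test.

Egger's test regresses the standardised effect ``log_or/se`` on precision
``1/se`` by ordinary least squares and tests the intercept against zero
with a t reference on k-2 degrees of freedom: a funnel plot that is
symmetric about the underlying effect yields an intercept near zero.

Begg's test computes Kendall's rank correlation between the
variance-stabilised deviations of the effects from the inverse-variance
fixed pooled mean and their variances, with the continuity-corrected
normal approximation for the p-value.  Both require at least three studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import InsufficientStudiesError
from .meta import EffectEstimate, _iv_mean

__all__ = ["EggerResult", "BeggResult", "BiasResult",
           "egger_test", "begg_test", "bias_tests"]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    t: float
    p_value: float
    k: int


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    z: float
    p_value: float
    k: int


@dataclass(frozen=True)
class BiasResult:
    egger: EggerResult
    begg: BeggResult

    @property
    def k(self) -> int:
        return self.egger.k


def egger_test(estimates: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's weighted linear regression test for funnel asymmetry."""
    k = len(estimates)
    if k < 3:
        raise InsufficientStudiesError("Egger's test requires at least 3 studies")
    x = [1.0 / e.se for e in estimates]
    y = [e.log_or / e.se for e in estimates]
    fit = stats.linregress(x, y)
    t = fit.intercept / fit.intercept_stderr
    p = float(2 * stats.t.sf(abs(t), df=k - 2))
    return EggerResult(intercept=float(fit.intercept),
                       se=float(fit.intercept_stderr),
                       t=float(t), p_value=p, k=k)


def begg_test(estimates: Sequence[EffectEstimate]) -> BeggResult:
    """Begg and Mazumdar's rank correlation test.

    Deviations from the pooled mean are standardised by
    ``sqrt(v_i - 1/sum(1/v_j))`` so that they are uncorrelated with the
    variances under the null of no small-study effect.
    """
    k = len(estimates)
    if k < 3:
        raise InsufficientStudiesError("Begg's test requires at least 3 studies")
    mu, sw = _iv_mean(estimates)
    v = [e.se ** 2 for e in estimates]
    t_star = [(e.log_or - mu) / math.sqrt(max(vi - 1.0 / sw, 1e-12))
              for e, vi in zip(estimates, v)]
    # Kendall's S: concordant minus discordant pairs (ties contribute 0).
    s = 0
    for i in range(k):
        for j in range(i + 1, k):
            s += _sign(t_star[j] - t_star[i]) * _sign(v[j] - v[i])
    n_pairs = k * (k - 1) // 2
    tau = s / n_pairs
    var_s = k * (k - 1) * (2 * k + 5) / 18.0
    z = max(0.0, abs(s) - 1.0) / math.sqrt(var_s)  # continuity correction
    p = float(2 * stats.norm.sf(z))
    return BeggResult(kendall_tau=tau, z=z, p_value=p, k=k)


def bias_tests(estimates: Sequence[EffectEstimate]) -> BiasResult:
    """Run both publication-bias tests on one set of study estimates."""
    return BiasResult(egger=egger_test(estimates), begg=begg_test(estimates))


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)
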