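"""Effect estimation, pooling, heterogeneity, subgroup and sensitivity analyses.

Per-study effects are Woolf log odds ratios with standard error
``sqrt(1/a + 1/b + 1/c + 1/d)`` (Haldane-Anscombe 0.5 added to all four
cells of a table that contains a zero).  Fixed-effect pooling is
Mantel-Haenszel with the Robins-Breslow-Greenland variance for the pooled
log OR; random-effects pooling is DerSimonian-Laird with the moment
estimator of the between-study variance tau^2.  Heterogeneity is Cochran's
Q about the inverse-variance fixed mean, summarised as
I^2 = max(0, (Q - df) / Q).  The pooling method is selected per analysis:
random effects iff I^2 >= 50%, otherwise fixed (the threshold is a
parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from scipy import stats

from .contrasts import ContrastTable, GeneticModel, build_contrast
from .errors import InsufficientStudiesError, UndefinedEffectError
from .study_data import Dataset, StudyRecord

__all__ = [
    "PoolingMethod",
    "EffectEstimate",
    "Heterogeneity",
    "PooledResult",
    "estimate_effect",
    "heterogeneity",
    "select_method",
    "pool_fixed_mh",
    "pool_random_dl",
    "pool",
    "contrast_tables",
    "subgroup_analysis",
    "sensitivity_loo",
    "I2_RANDOM_THRESHOLD",
]

Z95 = stats.norm.ppf(0.975)

#: Random effects are used when I^2 (percent) reaches this threshold.
I2_RANDOM_THRESHOLD = 50.0


class PoolingMethod(str, Enum):
    FIXED_MH = "fixed_mh"
    RANDOM_DL = "random_dl"


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study Woolf log odds ratio with 95% confidence interval."""

    study_id: str
    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    corrected: bool = False


@dataclass(frozen=True)
class Heterogeneity:
    """Cochran's Q about the inverse-variance fixed mean, with I^2 (%)."""

    q_stat: float
    df: int
    p_value: float
    i2: float
    degenerate: bool = False  # fewer than two studies


@dataclass(frozen=True)
class PooledResult:
    model: GeneticModel | None
    method: PoolingMethod
    k: int
    or_value: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    q_stat: float
    df: int
    p_het: float
    i2: float
    tau2: float
    weights: Mapping[str, float]


def estimate_effect(t: ContrastTable) -> EffectEstimate:
    """Woolf log-OR and 95% CI for one 2x2 table.

    If any cell is zero, 0.5 is added to all four cells
    (Haldane-Anscombe) and the estimate is flagged ``corrected``.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise UndefinedEffectError(
            f"{t.study_id or 'table'}: an arm is empty, odds ratio undefined")
    corrected = 0 in t.cells()
    a, b, c, d = ((x + 0.5 for x in t.cells()) if corrected else t.cells())
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        study_id=t.study_id,
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        corrected=corrected,
    )


def _iv_mean(estimates: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Inverse-variance fixed pooled log-OR and the sum of weights."""
    w = [1.0 / e.se ** 2 for e in estimates]
    sw = sum(w)
    mu = sum(wi * e.log_or for wi, e in zip(w, estimates)) / sw
    return mu, sw


def heterogeneity(estimates: Sequence[EffectEstimate]) -> Heterogeneity:
    """Cochran's Q, its chi-square p-value on k-1 df, and I^2 (percent).

    With fewer than two studies heterogeneity is undefined; a degenerate
    result (Q=0, p=1, I^2=0) is returned and flagged.
    """
    k = len(estimates)
    if k < 2:
        return Heterogeneity(0.0, 0, 1.0, 0.0, degenerate=True)
    mu, _ = _iv_mean(estimates)
    q = sum((e.log_or - mu) ** 2 / e.se ** 2 for e in estimates)
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    return Heterogeneity(q, df, p, i2)


def select_method(q_stat: float, df: int, i2: float,
                  threshold: float = I2_RANDOM_THRESHOLD) -> PoolingMethod:
    """Choose the pooling method from the heterogeneity summary.

    Random effects iff I^2 >= ``threshold`` percent, else fixed effects.
    """
    return (PoolingMethod.RANDOM_DL if i2 >= threshold
            else PoolingMethod.FIXED_MH)


def _dl_tau2(estimates: Sequence[EffectEstimate], q: float, df: int) -> float:
    w = [1.0 / e.se ** 2 for e in estimates]
    sw = sum(w)
    denom = sw - sum(wi ** 2 for wi in w) / sw
    if denom <= 0:
        return 0.0
    return max(0.0, (q - df) / denom)


def pool_fixed_mh(tables: Sequence[ContrastTable]) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled odds ratio.

    The pooled OR is ``sum(a_i d_i / n_i) / sum(b_i c_i / n_i)`` over the
    uncorrected cells (Mantel-Haenszel tolerates zero cells); the variance
    of its log is the Robins-Breslow-Greenland estimator.  Heterogeneity is
    computed from the per-study Woolf estimates and attached.  With a
    single table the result reduces to that study's own estimate.
    """
    if not tables:
        raise InsufficientStudiesError("no tables to pool")
    models = {t.model for t in tables}
    if len(models) > 1:
        raise ValueError(f"tables mix genetic models: {sorted(m.value for m in models)}")
    r_sum = s_sum = 0.0
    pr = ps_qr = qs = 0.0
    for t in tables:
        n = t.n
        ri = t.a * t.d / n
        si = t.b * t.c / n
        pi = (t.a + t.d) / n
        qi = (t.b + t.c) / n
        r_sum += ri
        s_sum += si
        pr += pi * ri
        ps_qr += pi * si + qi * ri
        qs += qi * si
    if r_sum == 0 or s_sum == 0:
        raise UndefinedEffectError("Mantel-Haenszel pooled OR undefined: "
                                   "all tables have an empty diagonal")
    or_mh = r_sum / s_sum
    var = (pr / (2 * r_sum ** 2) + ps_qr / (2 * r_sum * s_sum)
           + qs / (2 * s_sum ** 2))
    se = math.sqrt(var)
    log_or = math.log(or_mh)
    z = log_or / se
    estimates = [estimate_effect(t) for t in tables]
    het = heterogeneity(estimates)
    # MH weights are proportional to b*c/n.
    weights = {t.study_id: (t.b * t.c / t.n) / s_sum for t in tables}
    return PooledResult(
        model=tables[0].model,
        method=PoolingMethod.FIXED_MH,
        k=len(tables),
        or_value=or_mh,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        z=z,
        p_value=float(2 * stats.norm.sf(abs(z))),
        q_stat=het.q_stat,
        df=het.df,
        p_het=het.p_value,
        i2=het.i2,
        tau2=0.0,
        weights=weights,
    )


def pool_random_dl(estimates: Sequence[EffectEstimate],
                   model: GeneticModel | None = None) -> PooledResult:
    """DerSimonian-Laird random-effects pooled odds ratio.

    tau^2 is the moment estimator ``max(0, (Q - df) / (sum w - sum w^2 /
    sum w))`` with fixed inverse-variance weights ``w = 1/se^2``; the pooled
    estimate uses weights ``1 / (se^2 + tau^2)``.  When Q <= df the result
    coincides with inverse-variance fixed pooling.
    """
    if len(estimates) < 2:
        raise InsufficientStudiesError(
            "random-effects pooling requires at least two studies")
    het = heterogeneity(estimates)
    tau2 = _dl_tau2(estimates, het.q_stat, het.df)
    w = [1.0 / (e.se ** 2 + tau2) for e in estimates]
    sw = sum(w)
    mu = sum(wi * e.log_or for wi, e in zip(w, estimates)) / sw
    se = math.sqrt(1.0 / sw)
    z = mu / se
    return PooledResult(
        model=model,
        method=PoolingMethod.RANDOM_DL,
        k=len(estimates),
        or_value=math.exp(mu),
        ci_low=math.exp(mu - Z95 * se),
        ci_high=math.exp(mu + Z95 * se),
        z=z,
        p_value=float(2 * stats.norm.sf(abs(z))),
        q_stat=het.q_stat,
        df=het.df,
        p_het=het.p_value,
        i2=het.i2,
        tau2=tau2,
        weights={e.study_id: wi / sw for wi, e in zip(w, estimates)},
    )


def pool(tables: Sequence[ContrastTable], method: str = "auto",
         i2_threshold: float = I2_RANDOM_THRESHOLD) -> PooledResult:
    """Pool 2x2 tables, selecting fixed vs random from heterogeneity.

    ``method`` may be ``"auto"`` (select by I^2), ``"fixed"`` or
    ``"random"``.  A single table is always reported through the
    Mantel-Haenszel path, which reduces to the study's own estimate.
    """
    if not tables:
        raise InsufficientStudiesError("no tables to pool")
    if len(tables) == 1:
        return _single_study_result(tables[0])
    if method == "auto":
        estimates = [estimate_effect(t) for t in tables]
        het = heterogeneity(estimates)
        chosen = select_method(het.q_stat, het.df, het.i2, i2_threshold)
    elif method == "fixed":
        chosen = PoolingMethod.FIXED_MH
    elif method == "random":
        chosen = PoolingMethod.RANDOM_DL
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    if chosen is PoolingMethod.FIXED_MH:
        return pool_fixed_mh(tables)
    return pool_random_dl([estimate_effect(t) for t in tables],
                          model=tables[0].model)


def _single_study_result(table: ContrastTable) -> PooledResult:
    """Pass-through for k=1: the study's own Woolf estimate.

    Equals the Mantel-Haenszel reduction for a single table (the RBG
    variance collapses to the Woolf variance) but stays defined when the
    table has a zero cell, via the continuity correction.
    """
    e = estimate_effect(table)
    z = e.log_or / e.se
    return PooledResult(
        model=table.model,
        method=PoolingMethod.FIXED_MH,
        k=1,
        or_value=e.or_value,
        ci_low=e.ci_low,
        ci_high=e.ci_high,
        z=z,
        p_value=float(2 * stats.norm.sf(abs(z))),
        q_stat=0.0,
        df=0,
        p_het=1.0,
        i2=0.0,
        tau2=0.0,
        weights={e.study_id: 1.0},
    )


def contrast_tables(records: Sequence[StudyRecord] | Dataset,
                    model: GeneticModel) -> list[ContrastTable]:
    """Build one contrast table per study record."""
    return [build_contrast(r.case_counts, r.control_counts, model, r.study_id)
            for r in records]


_SUBGROUP_KEYS = {"soc": "soc", "method": "method"}


def subgroup_analysis(ds: Dataset, snp: str, model: GeneticModel,
                      by: str,
                      i2_threshold: float = I2_RANDOM_THRESHOLD,
                      ) -> dict[str, PooledResult]:
    """Pool each stratum of ``by`` ("soc" or "method") independently.

    The fixed/random choice is made per subgroup; a singleton subgroup
    reports the single study's own estimate.
    """
    key = _SUBGROUP_KEYS.get(by.lower())
    if key is None:
        raise KeyError(f"unknown subgroup key {by!r}; expected 'soc' or 'method'")
    records = list(ds.for_snp(snp))
    groups: dict[str, list[StudyRecord]] = {}
    for rec in records:
        groups.setdefault(getattr(rec, key), []).append(rec)
    return {label: pool(contrast_tables(recs, model), "auto", i2_threshold)
            for label, recs in groups.items()}


def sensitivity_loo(ds: Dataset, snp: str, model: GeneticModel,
                    i2_threshold: float = I2_RANDOM_THRESHOLD,
                    ) -> list[tuple[str, PooledResult]]:
    """Leave-one-out sensitivity analysis.

    Re-runs the full pipeline (heterogeneity, method selection, pooling)
    on each k-1 subset; returns (omitted study_id, pooled result) pairs in
    record order.
    """
    records = list(ds.for_snp(snp))
    if len(records) < 2:
        raise InsufficientStudiesError(
            "leave-one-out requires at least two studies")
    out = []
    for i, omitted in enumerate(records):
        rest = records[:i] + records[i + 1:]
        out.append((omitted.study_id,
                    pool(contrast_tables(rest, model), "auto", i2_threshold)))
    return out
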