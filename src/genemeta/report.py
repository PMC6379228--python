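"""End-to-end analysis driver and report writers.

:func:`run_analysis` ties the pipeline together for each requested SNP:
HWE screening of control arms, per-study contrast tables and Woolf
estimates, heterogeneity and fixed/random selection, total and subgroup
pooling, leave-one-out sensitivity, and publication-bias tests.  The
resulting :class:`AnalysisReport` serialises to a tidy TSV (one row per
snp x model x stratum — the machine-readable twin of a genetic-model
summary table), to versioned JSON (full precision, round-trippable) and to
Markdown for reading.

Single-study SNPs are passed through unpooled ("not pooled" flag);
two-study SNPs are pooled but the bias tests are skipped with a notice.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import pandas as pd

from . import __version__
from .bias import BeggResult, BiasResult, EggerResult, bias_tests
from .contrasts import GeneticModel
from .errors import GenemetaError
from .hwe import HWEResult, hwe_test
from .meta import (I2_RANDOM_THRESHOLD, EffectEstimate, PooledResult,
                   PoolingMethod, contrast_tables, estimate_effect, pool,
                   sensitivity_loo, subgroup_analysis)
from .study_data import Dataset, read_study_table

__all__ = ["AnalysisRow", "AnalysisReport", "run_analysis", "write_report",
           "read_report_json", "forest_data", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

ALL_MODELS = tuple(GeneticModel)
DEFAULT_SUBGROUPS = ("soc", "method")

#: flags attached to analysis rows
POOLED = "pooled"
NOT_POOLED = "not pooled"  # single-study pass-through


@dataclass(frozen=True)
class AnalysisRow:
    """One pooled (or pass-through) analysis: snp x model x stratum."""

    snp: str
    gene: str
    comparison: str
    model: GeneticModel
    stratum: str  # "total", "soc:HB", "method:PCR", ...
    flag: str  # POOLED or NOT_POOLED
    pooled: PooledResult
    estimates: tuple[EffectEstimate, ...]


@dataclass(frozen=True)
class HWEEntry:
    study_id: str
    snp: str
    result: HWEResult


@dataclass(frozen=True)
class SensitivityEntry:
    snp: str
    model: GeneticModel
    omitted: str
    pooled: PooledResult


@dataclass(frozen=True)
class BiasEntry:
    snp: str
    model: GeneticModel
    result: BiasResult


@dataclass(frozen=True)
class AnalysisReport:
    rows: tuple[AnalysisRow, ...]
    hwe: tuple[HWEEntry, ...]
    bias: tuple[BiasEntry, ...]
    sensitivity: tuple[SensitivityEntry, ...]
    notices: tuple[str, ...]
    metadata: dict

    def row(self, snp: str, model: GeneticModel,
            stratum: str = "total") -> AnalysisRow:
        for r in self.rows:
            if (r.snp, r.model, r.stratum) == (snp, GeneticModel(model), stratum):
                return r
        raise KeyError(f"no analysis row for ({snp!r}, {model!r}, {stratum!r})")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def run_analysis(source,
                 snps: Sequence[str] | None = None,
                 models: Sequence[GeneticModel] | None = None,
                 subgroups: Sequence[str] = DEFAULT_SUBGROUPS,
                 i2_threshold: float = I2_RANDOM_THRESHOLD,
                 dialect: str = "csv") -> AnalysisReport:
    """Run the full meta-analysis pipeline.

    ``source`` is a study-table path or an in-memory :class:`Dataset`.
    ``snps`` restricts the analysis to the given SNP labels (default: all
    SNPs present); ``models`` restricts the genetic models (default: all
    five).  Returns an empty report when the SNP filter matches nothing.
    """
    if isinstance(source, Dataset):
        ds, digest = source, "in-memory"
    else:
        ds, digest = read_study_table(source, dialect), _digest(source)
    models = tuple(GeneticModel(m) for m in (models or ALL_MODELS))
    wanted = ds.snps() if snps is None else [s for s in ds.snps() if s in snps]

    rows: list[AnalysisRow] = []
    hwe_entries: list[HWEEntry] = []
    bias_entries: list[BiasEntry] = []
    sens_entries: list[SensitivityEntry] = []
    notices: list[str] = []

    for snp in wanted:
        sub = ds.for_snp(snp)
        records = list(sub)
        k = len(records)
        gene = records[0].gene
        a1, a2 = records[0].allele1, records[0].allele2
        for rec in records:
            hwe_entries.append(HWEEntry(rec.study_id, snp,
                                        hwe_test(rec.control_counts)))
        if k == 1:
            notices.append(f"{snp}: single study, reported without pooling")
        elif k == 2:
            notices.append(f"{snp}: two studies, publication-bias tests skipped")
        for model in models:
            tables = contrast_tables(records, model)
            estimates = tuple(estimate_effect(t) for t in tables)
            total = pool(tables, "auto", i2_threshold)
            flag = POOLED if k > 1 else NOT_POOLED
            comparison = model.comparison_label(a1, a2)
            rows.append(AnalysisRow(snp, gene, comparison, model, "total",
                                    flag, total, estimates))
            if k > 1:
                for key in subgroups:
                    for label, res in subgroup_analysis(
                            sub, snp, model, key, i2_threshold).items():
                        ids = set(res.weights)
                        ests = tuple(e for e in estimates if e.study_id in ids)
                        rows.append(AnalysisRow(
                            snp, gene, comparison, model, f"{key}:{label}",
                            POOLED if len(ests) > 1 else NOT_POOLED,
                            res, ests))
                for omitted, res in sensitivity_loo(sub, snp, model,
                                                    i2_threshold):
                    sens_entries.append(SensitivityEntry(snp, model, omitted,
                                                         res))
            if k >= 3:
                bias_entries.append(BiasEntry(snp, model,
                                              bias_tests(list(estimates))))

    metadata = {
        "package": "genemeta",
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
        "input_digest": digest,
        "config": {
            "snps": list(wanted),
            "models": [m.value for m in models],
            "subgroups": list(subgroups),
            "i2_threshold": i2_threshold,
        },
    }
    return AnalysisReport(tuple(rows), tuple(hwe_entries), tuple(bias_entries),
                          tuple(sens_entries), tuple(notices), metadata)


# ---------------------------------------------------------------------------
# tabular / forest-plot views

def _round(x: float, nd: int) -> float:
    return float(round(x, nd))

def report_frame(report: AnalysisReport, full_precision: bool = False
                 ) -> pd.DataFrame:
    """Tidy table: one row per (snp, model, stratum, method).

    ORs and CI bounds are rounded to 2 decimals and p-values to 3 unless
    ``full_precision`` is set.
    """
    rows = []
    bias_by_key = {(b.snp, b.model): b.result for b in report.bias}
    for r in report.rows:
        p = r.pooled
        b = bias_by_key.get((r.snp, r.model)) if r.stratum == "total" else None
        rec = {
            "snp": r.snp, "gene": r.gene, "comparison": r.comparison,
            "model": r.model.value, "stratum": r.stratum, "flag": r.flag,
            "method": p.method.value, "k": p.k,
            "or": p.or_value, "ci_low": p.ci_low, "ci_high": p.ci_high,
            "p_value": p.p_value, "q_stat": p.q_stat, "df": p.df,
            "p_het": p.p_het, "i2": p.i2, "tau2": p.tau2,
            "egger_p": b.egger.p_value if b else None,
            "begg_p": b.begg.p_value if b else None,
        }
        if not full_precision:
            for col in ("or", "ci_low", "ci_high"):
                rec[col] = _round(rec[col], 2)
            for col in ("p_value", "p_het", "egger_p", "begg_p"):
                if rec[col] is not None:
                    rec[col] = _round(rec[col], 3)
            rec["q_stat"] = _round(rec["q_stat"], 3)
            rec["i2"] = _round(rec["i2"], 1)
            rec["tau2"] = _round(rec["tau2"], 4)
        rows.append(rec)
    return pd.DataFrame(rows)


def forest_data(report: AnalysisReport, snp: str, model: GeneticModel,
                stratum: str = "total") -> pd.DataFrame:
    """Per-study OR/CI/weight rows plus one pooled row, for external plotting."""
    row = report.row(snp, model, stratum)
    recs = [{"study": e.study_id, "or": e.or_value, "ci_low": e.ci_low,
             "ci_high": e.ci_high, "weight": row.pooled.weights.get(e.study_id)}
            for e in row.estimates]
    recs.append({"study": f"pooled ({row.pooled.method.value})",
                 "or": row.pooled.or_value, "ci_low": row.pooled.ci_low,
                 "ci_high": row.pooled.ci_high, "weight": 1.0})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# serialisation

def _report_to_dict(report: AnalysisReport) -> dict:
    return {
        "metadata": report.metadata,
        "rows": [asdict(r) for r in report.rows],
        "hwe": [asdict(e) for e in report.hwe],
        "bias": [asdict(e) for e in report.bias],
        "sensitivity": [asdict(e) for e in report.sensitivity],
        "notices": list(report.notices),
    }


def _pooled_from_dict(d: dict) -> PooledResult:
    d = dict(d)
    d["model"] = GeneticModel(d["model"]) if d["model"] is not None else None
    d["method"] = PoolingMethod(d["method"])
    return PooledResult(**d)


def _row_from_dict(d: dict) -> AnalysisRow:
    return AnalysisRow(
        snp=d["snp"], gene=d["gene"], comparison=d["comparison"],
        model=GeneticModel(d["model"]), stratum=d["stratum"], flag=d["flag"],
        pooled=_pooled_from_dict(d["pooled"]),
        estimates=tuple(EffectEstimate(**e) for e in d["estimates"]),
    )


def _report_from_dict(d: dict) -> AnalysisReport:
    return AnalysisReport(
        rows=tuple(_row_from_dict(r) for r in d["rows"]),
        hwe=tuple(HWEEntry(e["study_id"], e["snp"], HWEResult(**e["result"]))
                  for e in d["hwe"]),
        bias=tuple(BiasEntry(e["snp"], GeneticModel(e["model"]),
                             BiasResult(egger=EggerResult(**e["result"]["egger"]),
                                        begg=BeggResult(**e["result"]["begg"])))
                   for e in d["bias"]),
        sensitivity=tuple(SensitivityEntry(e["snp"], GeneticModel(e["model"]),
                                           e["omitted"],
                                           _pooled_from_dict(e["pooled"]))
                          for e in d["sensitivity"]),
        notices=tuple(d["notices"]),
        metadata=d["metadata"],
    )


def read_report_json(path) -> AnalysisReport:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path, "r", encoding="utf-8") as fh:
        return _report_from_dict(json.load(fh))


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 1e-3 else f"{p:.3f}"


def _markdown(report: AnalysisReport) -> str:
    lines = ["| SNP | Comparison | Stratum | k | OR (95% CI) | P-value | P het |",
             "| --- | --- | --- | --- | --- | --- | --- |"]
    for r in report.rows:
        p = r.pooled
        ci = f"{p.or_value:.2f} ({p.ci_low:.2f}, {p.ci_high:.2f})"
        het = "-" if p.df == 0 else _fmt_p(p.p_het)
        label = f"{r.stratum} ({p.method.value})" if r.flag == POOLED else \
            f"{r.stratum} ({r.flag})"
        lines.append(f"| {r.snp} | {r.comparison} | {label} | {p.k} | {ci} | "
                     f"{_fmt_p(p.p_value)} | {het} |")
    if report.notices:
        lines += ["", "Notes:"] + [f"- {n}" for n in report.notices]
    return "\n".join(lines) + "\n"


def write_report(report: AnalysisReport, path, fmt: str = "tsv") -> None:
    """Write a report as ``tsv``, ``json`` (full precision) or ``md``."""
    fmt = fmt.lower()
    if fmt == "tsv":
        report_frame(report).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_report_to_dict(report), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif fmt in ("md", "markdown"):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_markdown(report))
    else:
        raise GenemetaError(f"unknown report format {fmt!r}")
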