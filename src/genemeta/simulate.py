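"""Synthetic multi-study case-control genotype data with known truth.

Each simulated study i draws a study-specific log odds ratio
``theta_i = ln(true_allelic_or) + Normal(0, tau^2)`` (tau is the
between-study SD on the log-OR scale), converts the control risk-allele
frequency q0 to the case frequency ``q1_i = q0*e^theta / (1 - q0 +
q0*e^theta)`` (allelic odds shifted by theta), and samples genotype counts
multinomially under Hardy-Weinberg proportions at q0 (controls) and q1_i
(cases).  Source-of-controls and genotyping-method labels are assigned
categorically so the subgroup machinery can run on simulated data.

Defaults mirror the Fas -670-style study conditions: nine studies of
150 cases / 150 controls, control risk-allele frequency 0.30 and a true
allelic odds ratio of 1.5 with no between-study heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import ConfigError
from .study_data import Dataset, GenotypeCounts, StudyRecord

__all__ = ["SimulationConfig", "simulate_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    k: int = 9
    n_case: Union[int, Sequence[int]] = 150
    n_control: Union[int, Sequence[int]] = 150
    q0: float = 0.30
    true_allelic_or: float = 1.5
    tau: float = 0.0
    seed: int = 0
    soc_probs: Mapping[str, float] = field(
        default_factory=lambda: {"HB": 0.8, "PB": 0.2})
    method_probs: Mapping[str, float] = field(
        default_factory=lambda: {"PCR-RFLP": 0.67, "PCR": 0.33})
    gene: str = "SIM"
    snp: str = "sim A/G"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be at least 1")
        if not 0.0 < self.q0 < 1.0:
            raise ConfigError("q0 must lie strictly inside (0, 1)")
        if self.true_allelic_or <= 0:
            raise ConfigError("true_allelic_or must be positive")
        if self.tau < 0:
            raise ConfigError("tau must be non-negative")
        for name in ("soc_probs", "method_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        for arm in ("n_case", "n_control"):
            sizes = self.per_study(arm)
            if len(sizes) != self.k:
                raise ConfigError(f"{arm} list length must equal k={self.k}")
            if any(n < 1 for n in sizes):
                raise ConfigError(f"{arm} sizes must be positive")

    def per_study(self, arm: str) -> list[int]:
        value = getattr(self, arm)
        if isinstance(value, int):
            return [value] * self.k
        return [int(n) for n in value]


def _case_frequency(q0: float, theta: float) -> float:
    odds = q0 / (1.0 - q0) * math.exp(theta)
    q1 = odds / (1.0 + odds)
    if not 0.0 < q1 < 1.0:
        raise ConfigError(f"degenerate case allele frequency {q1}")
    return q1


def _hwe_draw(rng: np.random.Generator, n: int, q: float) -> GenotypeCounts:
    p = ((1 - q) ** 2, 2 * q * (1 - q), q ** 2)
    n11, n12, n22 = rng.multinomial(n, p)
    return GenotypeCounts(int(n11), int(n12), int(n22))


def simulate_dataset(cfg: SimulationConfig) -> Dataset:
    """Draw one multi-study dataset; deterministic for a given seed.

    Per-study generators are spawned from one seed sequence, so study i's
    counts do not depend on how many studies precede it.
    """
    n_cases = cfg.per_study("n_case")
    n_controls = cfg.per_study("n_control")
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.k)
    soc_labels = list(cfg.soc_probs)
    soc_p = [cfg.soc_probs[s] for s in soc_labels]
    method_labels = list(cfg.method_probs)
    method_p = [cfg.method_probs[m] for m in method_labels]
    width = len(str(cfg.k))
    records = []
    for i in range(cfg.k):
        rng = np.random.default_rng(streams[i])
        theta = math.log(cfg.true_allelic_or) + rng.normal(0.0, cfg.tau)
        q1 = _case_frequency(cfg.q0, theta)
        case = _hwe_draw(rng, n_cases[i], q1)
        control = _hwe_draw(rng, n_controls[i], cfg.q0)
        records.append(StudyRecord(
            study_id=f"sim{i + 1:0{width}d}",
            author=f"Sim {i + 1}",
            year=2000 + i,
            nationality="simulated",
            gene=cfg.gene,
            snp=cfg.snp,
            allele1="A",
            allele2="G",
            method=method_labels[rng.choice(len(method_labels), p=method_p)],
            soc=soc_labels[rng.choice(len(soc_labels), p=soc_p)],
            ethnicity="simulated",
            case_counts=case,
            control_counts=control,
            nos_selection=3,
            nos_comparability=1,
            nos_exposure=2,
        ))
    return Dataset(records)
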