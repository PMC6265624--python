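"""Synthetic case-control genotype-count study sets with known truth.

The generator emulates the retrospective design of the studies the
pipeline consumes.  Controls are drawn from Hardy-Weinberg proportions at
an effect-allele frequency p; cases are drawn from the HWE distribution
tilted by genotype odds multipliers, so the case genotype distribution is

    P(case genotype g) proportional to HWE_g(p) * m_g,

with multipliers (m_RR, m_RW, m_WW) determined by the per-copy allelic
odds ratio psi and the inheritance mode:

    multiplicative  (psi^2, psi, 1)   -- the allele-contrast estimand is psi
    dominant        (psi,   psi, 1)   -- the dominant-model estimand is psi
    recessive       (psi,   1,   1)   -- the recessive-model estimand is psi

Between-study heterogeneity is modelled as a normal deviation of each
study's log psi with standard deviation tau.  Per-study allele
frequencies and arm sizes may be single values or uniform ranges, to
emulate the spread of frequencies and sample sizes across real study
collections.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .studies import ControlSource, Ethnicity, GenotypeCounts, StudyRecord

__all__ = ["Inheritance", "SimulationConfig", "SimulatedStudySet", "genotype_probs", "simulate_studies"]


Inheritance = ("multiplicative", "dominant", "recessive")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and design of a simulated study collection.

    ``cases_per_study``, ``controls_per_study`` and ``effect_allele_freq``
    accept either a single value or a (low, high) range sampled uniformly
    per study.
    """

    n_studies: int = 5
    cases_per_study: int | tuple[int, int] = 1000
    controls_per_study: int | tuple[int, int] = 1000
    effect_allele_freq: float | tuple[float, float] = 0.3
    allelic_or: float = 1.0
    tau: float = 0.0
    inheritance: str = "multiplicative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.allelic_or <= 0:
            raise ValueError("allelic_or must be positive")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.inheritance not in Inheritance:
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        lo, hi = _as_range(self.effect_allele_freq)
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("effect_allele_freq must lie strictly inside (0, 1)")
        for name in ("cases_per_study", "controls_per_study"):
            lo, hi = _as_range(getattr(self, name))
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range {lo}..{hi} is degenerate")


@dataclass(frozen=True)
class SimulatedStudySet:
    """Simulated records plus the truth that generated them."""

    records: tuple[StudyRecord, ...]
    config: SimulationConfig
    study_log_or: tuple[float, ...]   # realized per-study log allelic OR
    study_freq: tuple[float, ...]     # realized per-study allele frequency

    def truth_dict(self) -> dict:
        d = asdict(self.config)
        d["study_log_or"] = list(self.study_log_or)
        d["study_freq"] = list(self.study_freq)
        return d

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=2)


def _as_range(v) -> tuple[float, float]:
    if isinstance(v, (tuple, list)):
        if len(v) != 2:
            raise ValueError(f"range must have two endpoints, got {v!r}")
        return float(v[0]), float(v[1])
    return float(v), float(v)


def _draw(rng: np.random.Generator, v, integer: bool):
    lo, hi = _as_range(v)
    if lo == hi:
        return int(lo) if integer else lo
    if integer:
        return int(rng.integers(int(lo), int(hi) + 1))
    return float(rng.uniform(lo, hi))


def genotype_probs(p: float, psi: float, inheritance: str = "multiplicative"):
    """Case and control genotype probability triples (RR, RW, WW).

    Controls follow Hardy-Weinberg proportions (p^2, 2p(1-p), (1-p)^2);
    cases follow the same proportions tilted by the genotype odds
    multipliers of the inheritance mode and renormalised.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie strictly inside (0, 1)")
    if psi <= 0:
        raise ValueError("psi must be positive")
    q = 1.0 - p
    control = np.array([p * p, 2 * p * q, q * q])
    mult = {
        "multiplicative": np.array([psi * psi, psi, 1.0]),
        "dominant": np.array([psi, psi, 1.0]),
        "recessive": np.array([psi, 1.0, 1.0]),
    }[inheritance]
    case = control * mult
    case = case / case.sum()
    return case, control


def simulate_studies(config: SimulationConfig) -> SimulatedStudySet:
    """Draw a reproducible study collection under the configured truth.

    Per study i: log psi_i ~ Normal(log psi, tau^2); control genotype
    counts ~ Multinomial(n_controls, HWE(p_i)); case counts ~
    Multinomial(n_cases, tilted HWE).  Identical config and seed give an
    identical study set.
    """
    rng = np.random.default_rng(config.seed)
    records, log_ors, freqs = [], [], []
    for i in range(config.n_studies):
        p = _draw(rng, config.effect_allele_freq, integer=False)
        n_cases = _draw(rng, config.cases_per_study, integer=True)
        n_controls = _draw(rng, config.controls_per_study, integer=True)
        log_psi = rng.normal(math.log(config.allelic_or), config.tau)
        case_p, control_p = genotype_probs(p, math.exp(log_psi), config.inheritance)
        case_counts = rng.multinomial(n_cases, case_p)
        control_counts = rng.multinomial(n_controls, control_p)
        records.append(
            StudyRecord(
                study_id=f"sim{i + 1:03d}",
                author=f"Sim{i + 1}",
                year=2020,
                snp="rsSIM",
                ethnicity=Ethnicity.OTHER,
                source=ControlSource.PB,
                case_counts=GenotypeCounts(*map(int, case_counts)),
                control_counts=GenotypeCounts(*map(int, control_counts)),
                reported_case_total=int(n_cases),
                reported_control_total=int(n_controls),
            )
        )
        log_ors.append(log_psi)
        freqs.append(p)
    return SimulatedStudySet(tuple(records), config, tuple(log_ors), tuple(freqs))
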