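"""Enrichment summary statistics.

Given an observed predicted-DMI count O and the random distribution R from
the permutation engine:

* empirical p-value  p = |{i : R_i >= O}| / n   (ties count; displayed as
  "<1/n" when no shuffle reaches O)
* enrichment         O / mean(R)
* per-DMI FDR        min(mean(R), O) / O        (0 when O == 0)
* normalized D       D_i = (O - R_i) / mean(R)  so enrichment = 1 + mean(D)

Full precision is kept internally; rounding (enrichment 3 s.f., FDR 4 d.p.)
is applied only to display strings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedStatError
from .io import (
    DMIDefinitionTable,
    DomainCompositionTable,
    MotifOccurrenceTable,
    PPIDataset,
)
from .mapping import (
    DMIStrategy,
    PotentialDMI,
    PredictedDMISet,
    build_potential_dmis,
    extract_predicted_dmis,
)
from .permutation import RandomDMIDistribution, ShuffleConfig, random_dmi_distribution

logger = logging.getLogger(__name__)


def format_sigfig(x: float, sig: int = 3) -> str:
    """Format to ``sig`` significant figures without exponent notation."""
    if math.isinf(x):
        return "inf"
    if math.isnan(x):
        return "nan"
    return f"{x:.{sig}g}" if abs(x) < 10 ** (sig + 3) else f"{x:.0f}"


@dataclass(frozen=True)
class PValue:
    """Numeric empirical p-value plus its display string."""

    value: float
    display: str

    def __float__(self) -> float:
        return self.value


def empirical_pvalue(observed: int, random_counts: Sequence[int] | np.ndarray) -> PValue:
    """Probability of seeing at least ``observed`` DMIs in random data."""
    r = np.asarray(random_counts)
    if r.size == 0:
        raise UndefinedStatError("empirical p-value needs a non-empty random distribution")
    n = int(r.size)
    exceed = int((r >= observed).sum())
    p = exceed / n
    display = f"<{1.0 / n:g}" if exceed == 0 else f"{p:g}"
    return PValue(value=p, display=display)


def enrichment_ratio(observed: int, mean_random: float) -> float:
    """Observed count over mean random count; inf when the mean is zero."""
    if mean_random == 0:
        logger.warning("mean random DMI count is 0; enrichment reported as infinite")
        return math.inf if observed > 0 else math.nan
    return observed / mean_random


def dmi_fdr(observed: int, mean_random: float) -> float:
    """Fraction of predicted DMIs explained on average by random association.

    The mean random count is capped at the observed count, so the result
    lies in [0, 1]; defined as 0 when nothing is predicted.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if observed == 0:
        return 0.0
    return min(mean_random, observed) / observed


def normalized_D(observed: int, random_counts: Sequence[int] | np.ndarray) -> np.ndarray:
    """Elementwise (O - R_i) / mean(R); requires mean(R) > 0."""
    r = np.asarray(random_counts, dtype=float)
    if r.size == 0:
        raise UndefinedStatError("normalized D needs a non-empty random distribution")
    mean_random = r.mean()
    if mean_random == 0:
        raise UndefinedStatError("normalized D is undefined when mean random count is 0")
    return (observed - r) / mean_random


@dataclass
class EnrichmentResult:
    """Bundle of all per-run enrichment statistics."""

    observed: int
    random: RandomDMIDistribution
    p_value: PValue
    enrichment: float
    fdr: float
    D: Optional[np.ndarray]
    n_shuffles: int
    predicted: PredictedDMISet
    potential: set[PotentialDMI]
    strategy: DMIStrategy
    seed: int | None = None

    @property
    def mean_random(self) -> float:
        return self.random.mean

    @property
    def enrichment_display(self) -> str:
        return format_sigfig(self.enrichment, 3)

    @property
    def fdr_display(self) -> str:
        return f"{self.fdr:.4f}"


def run_enrichment(
    ppi: PPIDataset,
    motifs: MotifOccurrenceTable | None,
    dmi_defs: DMIDefinitionTable,
    domains: DomainCompositionTable | None,
    strategy: DMIStrategy,
    cfg: ShuffleConfig,
) -> EnrichmentResult:
    """End-to-end enrichment analysis; deterministic given ``cfg.seed``."""
    potential = build_potential_dmis(ppi, motifs, dmi_defs, domains, strategy)
    predicted = extract_predicted_dmis(potential, ppi)
    observed = len(predicted)
    random = random_dmi_distribution(ppi, potential, cfg)
    p = empirical_pvalue(observed, random.counts)
    enr = enrichment_ratio(observed, random.mean)
    fdr = dmi_fdr(observed, random.mean)
    if random.mean > 0:
        d = normalized_D(observed, random.counts)
    else:
        logger.warning("normalized D undefined (mean random count 0); stored as None")
        d = None
    logger.info(
        "strategy=%s potential=%d predicted=%d mean_random=%.4g p=%s",
        strategy.label, len(potential), observed, random.mean, p.display,
    )
    return EnrichmentResult(
        observed=observed,
        random=random,
        p_value=p,
        enrichment=enr,
        fdr=fdr,
        D=d,
        n_shuffles=cfg.n_shuffles,
        predicted=predicted,
        potential=potential,
        strategy=strategy,
        seed=cfg.seed,
    )
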