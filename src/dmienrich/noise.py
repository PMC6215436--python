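"""Robustness analysis: degrade the motif table with random proteins.

Increasing proportions of motif-carrying proteins are replaced by proteins
drawn at random from a background pool and the enrichment analysis is
re-run, yielding one normalized-D distribution per noise level.
Replacement acts at the protein level: all occurrence rows of a selected
carrier are renamed to the replacement protein, so per-carrier motif
content is preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import (
    DMIDefinitionTable,
    DomainCompositionTable,
    MotifOccurrenceTable,
    PPIDataset,
)
from .mapping import DMIStrategy
from .permutation import ShuffleConfig
from .stats import EnrichmentResult, run_enrichment

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.25, 0.50, 0.75, 1.00)


@dataclass(frozen=True)
class NoiseConfig:
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    background_pool: tuple[str, ...] | None = None
    seed: int | None = None
    n_shuffles: int = 1000

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("noise fractions must lie in [0, 1]")
        object.__setattr__(self, "fractions", tuple(sorted(self.fractions)))


@dataclass
class NoiseRun:
    fraction: float
    perturbed_motifs: MotifOccurrenceTable
    result: EnrichmentResult


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def perturb_motif_table(
    motifs: MotifOccurrenceTable,
    fraction: float,
    pool: tuple[str, ...] | list[str],
    rng: np.random.Generator,
) -> MotifOccurrenceTable:
    """Rename round(fraction * n_carriers) carriers to random pool proteins.

    Carriers and replacements are both sampled without replacement, and
    replacements that would collide with a surviving carrier are excluded,
    so the number of distinct carriers is conserved.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    carriers = sorted(motifs.carriers)
    n_replace = _round_half_away(fraction * len(carriers))
    if n_replace == 0:
        return MotifOccurrenceTable(rows=list(motifs.rows), occurrence_source=motifs.occurrence_source)
    selected = set(rng.choice(carriers, size=n_replace, replace=False).tolist())
    survivors = set(carriers) - selected
    candidates = [p for p in pool if p not in survivors]
    n_excluded = len(pool) - len(candidates)
    if n_excluded:
        logger.info("noise pool: excluded %d protein(s) colliding with surviving carriers", n_excluded)
    if len(candidates) < n_replace:
        raise ValueError(
            f"background pool too small: need {n_replace} replacement proteins, "
            f"have {len(candidates)} usable candidates"
        )
    replacements = rng.choice(candidates, size=n_replace, replace=False).tolist()
    rename = dict(zip(sorted(selected), replacements))
    overlap = selected & set(replacements)
    if overlap:
        logger.info("noise pool overlaps replaced carriers for %d protein(s)", len(overlap))
    rows = [(rename.get(m, m), motif) for m, motif in motifs.rows]
    return MotifOccurrenceTable(rows=rows, occurrence_source=motifs.occurrence_source)


def default_pool(ppi: PPIDataset) -> tuple[str, ...]:
    """Fallback background pool: every protein appearing in the PPI data."""
    return tuple(sorted(ppi.mproteins | ppi.dproteins))


def noise_sweep(
    ppi: PPIDataset,
    motifs: MotifOccurrenceTable,
    dmi_defs: DMIDefinitionTable,
    domains: DomainCompositionTable | None,
    strategy: DMIStrategy,
    noise_cfg: NoiseConfig,
) -> list[NoiseRun]:
    """One enrichment run per noise fraction; deterministic given the seed.

    All fractions share the same shuffle seed, so a fraction-0 run is
    identical to the unperturbed analysis.
    """
    pool = noise_cfg.background_pool or default_pool(ppi)
    shuffle_cfg = ShuffleConfig(n_shuffles=noise_cfg.n_shuffles, seed=noise_cfg.seed)
    runs: list[NoiseRun] = []
    for k, fraction in enumerate(noise_cfg.fractions):
        rng = np.random.default_rng(None if noise_cfg.seed is None else [noise_cfg.seed, k])
        perturbed = perturb_motif_table(motifs, fraction, pool, rng)
        result = run_enrichment(ppi, perturbed, dmi_defs, domains, strategy, shuffle_cfg)
        runs.append(NoiseRun(fraction=fraction, perturbed_motifs=perturbed, result=result))
    return runs
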