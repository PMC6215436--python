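"""Degree-preserving randomization of the interaction dataset.

The dProtein column is shuffled while the mProtein column stays fixed, so
every protein keeps its number of partners on both sides.  Shuffles that
would introduce a duplicate pair are rejected and redrawn; a targeted
pair-swap repair kicks in if rejection keeps failing, guaranteeing
termination on feasible inputs (any canonical dataset admits at least the
identity assignment).  Original pairs may reappear by chance — only
within-dataset redundancy is forbidden.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleShuffleError
from .io import PPIDataset
from .mapping import PotentialDMI, potential_pair_weights

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShuffleConfig:
    n_shuffles: int = 1000
    seed: int | None = None
    max_retries_per_shuffle: int = 100

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.max_retries_per_shuffle < 1:
            raise ValueError("max_retries_per_shuffle must be >= 1")


@dataclass
class RandomDMIDistribution:
    """Predicted-DMI count of each shuffled dataset plus the mean."""

    counts: np.ndarray
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-d array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.mean = float(self.counts.mean())

    @property
    def n_shuffles(self) -> int:
        return int(self.counts.size)


def _repair(
    mcol: list[str],
    dcol: list[str],
    rng: np.random.Generator,
    max_passes: int = 50,
) -> list[str]:
    """Resolve duplicate pairs by swapping dProtein entries between rows.

    A swap is accepted only if neither resulting pair already exists, so
    the number of collisions never increases.  Raises if no progress can
    be made.
    """
    n = len(dcol)
    dcol = list(dcol)
    budget = max(max_passes, 10 * n)

    def excess(counts: Counter, pairs: set[tuple[str, str]]) -> int:
        return sum(max(0, counts[p] - 1) for p in pairs)

    def try_fix_row(i: int, counts: Counter) -> bool:
        """Swap row i's dProtein with some row j if it reduces duplication."""
        old_i = (mcol[i], dcol[i])
        for j in rng.permutation(n):
            j = int(j)
            if j == i or dcol[i] == dcol[j]:
                continue
            old_j = (mcol[j], dcol[j])
            new_i = (mcol[i], dcol[j])
            new_j = (mcol[j], dcol[i])
            touched = {old_i, old_j, new_i, new_j}
            before = excess(counts, touched)
            counts[old_i] -= 1
            counts[old_j] -= 1
            counts[new_i] += 1
            counts[new_j] += 1
            if excess(counts, touched) < before:
                dcol[i], dcol[j] = dcol[j], dcol[i]
                return True
            counts[old_i] += 1
            counts[old_j] += 1
            counts[new_i] -= 1
            counts[new_j] -= 1
        return False

    for _ in range(budget):
        counts = Counter(zip(mcol, dcol))
        extras = [i for i, pair in enumerate(zip(mcol, dcol)) if counts[pair] > 1]
        if not extras:
            return dcol
        # each accepted swap strictly reduces total duplicate excess
        if not any(try_fix_row(i, counts) for i in extras):
            break
    raise InfeasibleShuffleError(
        "could not remove duplicate pairs by swapping; the dataset is too "
        "constrained for a duplicate-free shuffle"
    )


def shuffle_ppi(
    ppi: PPIDataset,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> PPIDataset:
    """One degree-preserving, duplicate-free shuffle of the dataset."""
    mcol = [m for m, _ in ppi.pairs]
    dvals = np.array([d for _, d in ppi.pairs], dtype=object)
    n = len(dvals)
    last = None
    for _ in range(max_retries):
        cand = dvals[rng.permutation(n)]
        pairs = list(zip(mcol, cand))
        if len(set(pairs)) == n:
            return PPIDataset(pairs=pairs, source_label=ppi.source_label)
        last = list(cand)
    logger.debug("rejection sampling exhausted %d retries; repairing", max_retries)
    err: InfeasibleShuffleError | None = None
    for _ in range(10):  # repair may stall in a local minimum; restart fresh
        try:
            repaired = _repair(mcol, last, rng)
            return PPIDataset(pairs=list(zip(mcol, repaired)), source_label=ppi.source_label)
        except InfeasibleShuffleError as exc:
            err = exc
            last = list(dvals[rng.permutation(n)])
    raise err


def check_shuffle_invariants(original: PPIDataset, shuffled: PPIDataset) -> None:
    """Assert degree conservation and non-redundancy of a shuffled dataset."""
    if [m for m, _ in original.pairs] != [m for m, _ in shuffled.pairs]:
        raise AssertionError("mProtein column changed under shuffle")
    if Counter(d for _, d in original.pairs) != Counter(d for _, d in shuffled.pairs):
        raise AssertionError("dProtein multiset changed under shuffle")
    if len(shuffled.pair_set()) != len(shuffled.pairs):
        raise AssertionError("shuffled dataset contains duplicate pairs")


def random_dmi_distribution(
    ppi: PPIDataset,
    potential: set[PotentialDMI],
    cfg: ShuffleConfig,
    *,
    verify: bool = True,
) -> RandomDMIDistribution:
    """Predicted-DMI counts over ``cfg.n_shuffles`` randomized datasets.

    Deterministic for a fixed ``cfg.seed``.  With ``verify`` (the default)
    every shuffle is checked for degree conservation and non-redundancy.
    """
    rng = np.random.default_rng(cfg.seed)
    weights = potential_pair_weights(potential)
    counts = np.zeros(cfg.n_shuffles, dtype=np.int64)
    for i in range(cfg.n_shuffles):
        shuffled = shuffle_ppi(ppi, rng, max_retries=cfg.max_retries_per_shuffle)
        if verify:
            check_shuffle_invariants(ppi, shuffled)
        counts[i] = sum(weights.get(p, 0) for p in shuffled.pairs)
    return RandomDMIDistribution(counts=counts)
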