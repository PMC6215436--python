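"""Strategy-dependent mapping of DMI links onto an interaction dataset.

A "potential DMI" is a link between a motif-side protein and a domain-side
protein that is plausible given the motif/DMI/domain annotation, restricted
to proteins present in the interaction data.  A "predicted DMI" is a
potential DMI whose (mProtein, dProtein) pair is actually observed.

Three mapping modes of decreasing stringency are supported:

* ``elmi-protein`` — the DMI file links mProteins directly to dProteins
  (motif and domain tables unused).
* ``elmc-protein`` — motif occurrences joined to motif->dProtein links
  (domain table unused).
* ``elmc-domain``  — motif occurrences joined to motif->domain links and
  then to the dProtein domain composition.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Optional

from .errors import ConfigError
from .io import (
    DMIDefinitionTable,
    DomainCompositionTable,
    MotifOccurrenceTable,
    PPIDataset,
)


class StrategyMode(str, Enum):
    ELMI_PROTEIN = "elmi-protein"
    ELMC_PROTEIN = "elmc-protein"
    ELMC_DOMAIN = "elmc-domain"


#: DMI-definition schema required by each mapping mode
MODE_SCHEMA = {
    StrategyMode.ELMI_PROTEIN: "protein-protein",
    StrategyMode.ELMC_PROTEIN: "motif-protein",
    StrategyMode.ELMC_DOMAIN: "motif-domain",
}


@dataclass(frozen=True)
class DMIStrategy:
    """Mapping mode plus the label of the motif-occurrence source."""

    mode: StrategyMode
    occurrence_source: str = "known"

    def __post_init__(self) -> None:
        mode = StrategyMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if self.occurrence_source not in ("known", "predicted"):
            raise ValueError("occurrence_source must be 'known' or 'predicted'")

    @property
    def label(self) -> str:
        return f"{self.occurrence_source}:{self.mode.value}"


class PotentialDMI(NamedTuple):
    """One plausible domain-motif link; unused fields are None."""

    mprotein: str
    motif: Optional[str]
    domain: Optional[str]
    dprotein: str


@dataclass
class PredictedDMISet:
    """Potential DMIs realized by observed pairs, with unique-entity counts."""

    dmis: list[PotentialDMI]
    n_unique_mproteins: int = field(init=False)
    n_unique_motifs: int = field(init=False)
    n_unique_domains: int = field(init=False)
    n_unique_dproteins: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_unique_mproteins = len({t.mprotein for t in self.dmis})
        self.n_unique_motifs = len({t.motif for t in self.dmis if t.motif is not None})
        self.n_unique_domains = len({t.domain for t in self.dmis if t.domain is not None})
        self.n_unique_dproteins = len({t.dprotein for t in self.dmis})

    def __len__(self) -> int:
        return len(self.dmis)


def build_potential_dmis(
    ppi: PPIDataset,
    motifs: MotifOccurrenceTable | None,
    dmi_defs: DMIDefinitionTable,
    domains: DomainCompositionTable | None,
    strategy: DMIStrategy,
) -> set[PotentialDMI]:
    """All plausible DMI tuples restricted to proteins present in ``ppi``.

    The mProtein of every tuple occurs in the mProtein column of the
    interaction data and the dProtein in the dProtein column; the two roles
    are restricted independently (the network is asymmetric).
    """
    mode = StrategyMode(strategy.mode)
    expected = MODE_SCHEMA[mode]
    if dmi_defs.schema_kind != expected:
        raise ConfigError(
            f"strategy {mode.value!r} requires a {expected!r} DMI file, "
            f"got {dmi_defs.schema_kind!r}"
        )
    mset = ppi.mproteins
    dset = ppi.dproteins

    if mode is StrategyMode.ELMI_PROTEIN:
        return {
            PotentialDMI(m, None, None, d)
            for m, d in dmi_defs.rows
            if m in mset and d in dset
        }

    if motifs is None:
        raise ConfigError(f"strategy {mode.value!r} requires a motif occurrence table")

    if mode is StrategyMode.ELMC_PROTEIN:
        motif_to_dprot: dict[str, set[str]] = defaultdict(set)
        for motif, d in dmi_defs.rows:
            if d in dset:
                motif_to_dprot[motif].add(d)
        return {
            PotentialDMI(m, motif, None, d)
            for m, motif in motifs.rows
            if m in mset
            for d in motif_to_dprot.get(motif, ())
        }

    # elmc-domain
    if domains is None:
        raise ConfigError("strategy 'elmc-domain' requires a domain composition table")
    motif_to_domain: dict[str, set[str]] = defaultdict(set)
    for motif, dom in dmi_defs.rows:
        motif_to_domain[motif].add(dom)
    domain_to_dprot: dict[str, set[str]] = defaultdict(set)
    for d, dom in domains.rows:
        if d in dset:
            domain_to_dprot[dom].add(d)
    return {
        PotentialDMI(m, motif, dom, d)
        for m, motif in motifs.rows
        if m in mset
        for dom in motif_to_domain.get(motif, ())
        for d in domain_to_dprot.get(dom, ())
    }


def extract_predicted_dmis(potential: set[PotentialDMI], ppi: PPIDataset) -> PredictedDMISet:
    """Subset of potential DMIs whose (mProtein, dProtein) pair is observed."""
    pair_set = ppi.pair_set()
    dmis = sorted(
        (t for t in potential if (t.mprotein, t.dprotein) in pair_set),
        key=lambda t: (t.mprotein, t.motif or "", t.domain or "", t.dprotein),
    )
    return PredictedDMISet(dmis=dmis)


def potential_pair_weights(potential: set[PotentialDMI]) -> dict[tuple[str, str], int]:
    """Number of potential DMI tuples carried by each (mProtein, dProtein) pair.

    The predicted-DMI count of any dataset is the sum of these weights over
    its pairs; the permutation engine relies on this to score shuffles.
    """
    weights: dict[tuple[str, str], int] = defaultdict(int)
    for t in potential:
        weights[(t.mprotein, t.dprotein)] += 1
    return dict(weights)


def count_predicted(potential: set[PotentialDMI], ppi: PPIDataset) -> int:
    """Predicted-DMI count without materializing the tuple list."""
    weights = potential_pair_weights(potential)
    return sum(weights.get(p, 0) for p in ppi.pairs)
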