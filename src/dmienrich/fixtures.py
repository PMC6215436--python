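"""Synthetic input generator with a controllable planted-DMI signal.

Produces a mutually consistent quadruple of inputs (interaction pairs,
motif occurrences, DMI definitions in all three schemas, domain
composition) plus the ground-truth list of planted pairs.  Planting
operates on the most permissive (motif->domain) mapping, so stricter
strategies see nested subsets of the same signal.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    DMIDefinitionTable,
    DomainCompositionTable,
    FieldMap,
    MotifOccurrenceTable,
    PPIDataset,
)

import pandas as pd


@dataclass(frozen=True)
class FixtureSpec:
    n_mproteins: int = 20
    n_dproteins: int = 20
    n_motif_classes: int = 8
    n_domain_classes: int = 6
    ppi_density: float = 0.15
    planted_fraction: float = 0.0
    motif_per_protein: int = 2
    domain_per_protein: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mproteins", "n_dproteins", "n_motif_classes", "n_domain_classes",
                     "motif_per_protein", "domain_per_protein"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.ppi_density <= 1.0:
            raise ValueError("ppi_density must lie in (0, 1]")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")


@dataclass
class FixtureBundle:
    """All generated inputs plus the planted ground truth."""

    ppi: PPIDataset
    motifs: MotifOccurrenceTable
    dmi_protein: DMIDefinitionTable
    dmi_motif_protein: DMIDefinitionTable
    dmi_motif_domain: DMIDefinitionTable
    domains: DomainCompositionTable
    planted_pairs: list[tuple[str, str]]

    def dmi_for_mode(self, mode: str) -> DMIDefinitionTable:
        return {
            "elmi-protein": self.dmi_protein,
            "elmc-protein": self.dmi_motif_protein,
            "elmc-domain": self.dmi_motif_domain,
        }[str(mode)]

    def write_files(self, outdir: str | Path, field_map: FieldMap | None = None) -> dict[str, Path]:
        """Write the four inputs plus ground truth as CSV; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fm = field_map or FieldMap()
        paths = {
            "ppi": outdir / "ppi.csv",
            "motifs": outdir / "motifs.csv",
            "dmi_protein": outdir / "dmi_protein.csv",
            "dmi_motif_protein": outdir / "dmi_motif_protein.csv",
            "dmi_motif_domain": outdir / "dmi_motif_domain.csv",
            "domains": outdir / "domains.csv",
            "planted": outdir / "planted_pairs.csv",
        }
        self.ppi.write_csv(paths["ppi"], fm)
        self.motifs.write_csv(paths["motifs"], fm)
        self.dmi_protein.write_csv(paths["dmi_protein"], fm)
        self.dmi_motif_protein.write_csv(paths["dmi_motif_protein"], fm)
        self.dmi_motif_domain.write_csv(paths["dmi_motif_domain"], fm)
        self.domains.write_csv(paths["domains"], fm)
        pd.DataFrame(self.planted_pairs, columns=[fm.mprotein, fm.dprotein]).to_csv(
            paths["planted"], index=False, lineterminator="\n"
        )
        return paths


def _pick(rng: np.random.Generator, items: list[str], k: int) -> list[str]:
    k = min(k, len(items))
    return rng.choice(items, size=k, replace=False).tolist()


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Draw a consistent synthetic input set under ``spec``.

    ``planted_fraction`` of the interaction pairs are wired to pairs that
    realize at least one potential DMI under the motif->domain mapping; the
    remainder are wired uniformly at random.
    """
    rng = np.random.default_rng(spec.seed)
    mprots = [f"mP{i:03d}" for i in range(spec.n_mproteins)]
    dprots = [f"dP{i:03d}" for i in range(spec.n_dproteins)]
    motif_ids = [f"MOT{i:02d}" for i in range(spec.n_motif_classes)]
    domain_ids = [f"DOM{i:02d}" for i in range(spec.n_domain_classes)]

    # annotation layer: motif -> one interacting domain, uniform
    motif_domain = [(mo, str(rng.choice(domain_ids))) for mo in motif_ids]
    domain_rows = [
        (d, dom) for d in dprots for dom in _pick(rng, domain_ids, spec.domain_per_protein)
    ]
    occurrence_rows = [
        (m, mo) for m in mprots for mo in _pick(rng, motif_ids, spec.motif_per_protein)
    ]

    # pairs able to realize a potential DMI under the motif->domain mapping
    motif_to_dom = {mo: dom for mo, dom in motif_domain}
    dom_to_dprot: dict[str, set[str]] = {}
    for d, dom in domain_rows:
        dom_to_dprot.setdefault(dom, set()).add(d)
    dmi_capable: set[tuple[str, str]] = set()
    for m, mo in occurrence_rows:
        for d in dom_to_dprot.get(motif_to_dom[mo], ()):
            dmi_capable.add((m, d))

    n_cells = spec.n_mproteins * spec.n_dproteins
    n_pairs = max(1, int(round(spec.ppi_density * n_cells)))
    if n_pairs > n_cells:
        raise ValueError("ppi_density requires more pairs than exist")
    n_planted = int(round(spec.planted_fraction * n_pairs))
    n_planted = min(n_planted, len(dmi_capable))

    capable_sorted = sorted(dmi_capable)
    planted_idx = rng.choice(len(capable_sorted), size=n_planted, replace=False)
    planted = [capable_sorted[int(i)] for i in planted_idx]
    planted_set = set(planted)

    remaining = [
        (m, d) for m in mprots for d in dprots if (m, d) not in planted_set
    ]
    fill_idx = rng.choice(len(remaining), size=n_pairs - n_planted, replace=False)
    fill = [remaining[int(i)] for i in fill_idx]
    pair_list = planted + fill
    order = rng.permutation(len(pair_list))
    pair_list = [pair_list[int(i)] for i in order]

    ppi = PPIDataset(pairs=pair_list, source_label=f"fixture(seed={spec.seed})")

    # derive the stricter DMI-definition schemas from the same ground truth
    motif_protein_rows = sorted(
        {(mo, d) for mo, dom in motif_domain for d in dom_to_dprot.get(dom, ())}
    )
    protein_protein_rows = sorted(dmi_capable)

    return FixtureBundle(
        ppi=ppi,
        motifs=MotifOccurrenceTable(rows=occurrence_rows, occurrence_source="known"),
        dmi_protein=DMIDefinitionTable(schema_kind="protein-protein", rows=protein_protein_rows),
        dmi_motif_protein=DMIDefinitionTable(schema_kind="motif-protein", rows=motif_protein_rows),
        dmi_motif_domain=DMIDefinitionTable(schema_kind="motif-domain", rows=motif_domain),
        domains=DomainCompositionTable(rows=domain_rows),
        planted_pairs=planted,
    )
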