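"""Output rendering: summary/table CSVs, histogram data + plot, network export.

All tables are comma-separated UTF-8 with a header row and LF newlines.
Numeric columns in the summary carry full precision; display-rounded
values live in separate ``*_display`` columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .io import FieldMap
from .mapping import PotentialDMI, PredictedDMISet, StrategyMode
from .noise import NoiseRun
from .permutation import RandomDMIDistribution
from .stats import EnrichmentResult, format_sigfig


def _dmi_frame(dmis: Iterable[PotentialDMI], field_map: FieldMap | None = None) -> pd.DataFrame:
    fm = field_map or FieldMap()
    rows = [
        {
            fm.mprotein: t.mprotein,
            fm.motif: t.motif or "",
            fm.domain: t.domain or "",
            fm.dprotein: t.dprotein,
        }
        for t in dmis
    ]
    cols = [fm.mprotein, fm.motif, fm.domain, fm.dprotein]
    return pd.DataFrame(rows, columns=cols)


def write_dmi_table(
    dmis: Iterable[PotentialDMI], path: str | Path, field_map: FieldMap | None = None
) -> None:
    """Write potential or predicted DMI tuples (unused columns empty)."""
    _dmi_frame(dmis, field_map).to_csv(path, index=False, lineterminator="\n")


def write_summary(result: EnrichmentResult, path: str | Path) -> None:
    """One-row machine-readable summary of an enrichment run."""
    row = {
        "strategy": result.strategy.label,
        "potential_dmi": len(result.potential),
        "predicted_dmi": result.observed,
        "mean_random_dmi": result.mean_random,
        "p_value": result.p_value.value,
        "enrichment": result.enrichment,
        "fdr": result.fdr,
        "unique_mProteins": result.predicted.n_unique_mproteins,
        "unique_motifs": result.predicted.n_unique_motifs,
        "unique_domains": result.predicted.n_unique_domains,
        "unique_dProteins": result.predicted.n_unique_dproteins,
        "n_shuffles": result.n_shuffles,
        "seed": result.seed if result.seed is not None else "",
        "p_value_display": result.p_value.display,
        "enrichment_display": result.enrichment_display,
        "fdr_display": result.fdr_display,
        "mean_random_dmi_display": format_sigfig(result.mean_random, 3),
    }
    pd.DataFrame([row]).to_csv(path, index=False, lineterminator="\n")


def write_random_counts(random: RandomDMIDistribution, path: str | Path) -> None:
    """One predicted-DMI count per shuffle, one column."""
    pd.DataFrame({"random_dmi_count": random.counts}).to_csv(
        path, index=False, lineterminator="\n"
    )


def histogram_bins(random: RandomDMIDistribution) -> pd.DataFrame:
    """Integer-width bins of the random counts (frequencies sum to n)."""
    values, freqs = np.unique(random.counts, return_counts=True)
    return pd.DataFrame({"count": values, "frequency": freqs})


def write_histogram(
    random: RandomDMIDistribution,
    observed: int,
    csv_path: str | Path,
    png_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the binned random distribution and a plot with O marked."""
    bins = histogram_bins(random)
    bins.to_csv(csv_path, index=False, lineterminator="\n")
    if png_path is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.bar(bins["count"], bins["frequency"], width=1.0, color="#6699cc",
               edgecolor="white", label="random datasets")
        ax.axvline(observed, color="black", linestyle=":", label=f"observed = {observed}")
        ax.set_xlabel("predicted DMI count")
        ax.set_ylabel("number of shuffled datasets")
        ax.legend()
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return bins


def build_network(predicted: PredictedDMISet, mode: StrategyMode | str) -> nx.Graph:
    """Layered graph of the predicted DMIs.

    Node ``kind`` is one of mProtein/motif/domain/dProtein; edges follow
    the mapping chain (mProtein-motif, motif-domain, domain-dProtein), or
    mProtein-dProtein directly for the protein-level strategy.
    """
    mode = StrategyMode(mode)
    g = nx.Graph()
    for t in predicted.dmis:
        g.add_node(t.mprotein, kind="mProtein")
        g.add_node(t.dprotein, kind="dProtein")
        if mode is StrategyMode.ELMI_PROTEIN:
            g.add_edge(t.mprotein, t.dprotein)
            continue
        g.add_node(t.motif, kind="motif")
        g.add_edge(t.mprotein, t.motif)
        if mode is StrategyMode.ELMC_PROTEIN:
            g.add_edge(t.motif, t.dprotein)
        else:
            g.add_node(t.domain, kind="domain")
            g.add_edge(t.motif, t.domain)
            g.add_edge(t.domain, t.dprotein)
    return g


def export_network(
    predicted: PredictedDMISet,
    mode: StrategyMode | str,
    graphml_path: str | Path,
    edgelist_path: str | Path | None = None,
) -> nx.Graph:
    """Write the DMI network as GraphML plus an edge-list CSV."""
    g = build_network(predicted, mode)
    nx.write_graphml(g, graphml_path)
    if edgelist_path is not None:
        rows = [
            {
                "source": u,
                "source_kind": g.nodes[u]["kind"],
                "target": v,
                "target_kind": g.nodes[v]["kind"],
            }
            for u, v in g.edges()
        ]
        pd.DataFrame(rows, columns=["source", "source_kind", "target", "target_kind"]).to_csv(
            edgelist_path, index=False, lineterminator="\n"
        )
    return g


def write_noise_sweep(runs: list[NoiseRun], path: str | Path) -> pd.DataFrame:
    """Long-format normalized-D values: [fraction, shuffle_index, D]."""
    frames = []
    for run in runs:
        d = run.result.D
        if d is None:
            continue
        frames.append(
            pd.DataFrame(
                {"fraction": run.fraction, "shuffle_index": np.arange(d.size), "D": d}
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["fraction", "shuffle_index", "D"])
    )
    out.to_csv(path, index=False, lineterminator="\n")
    return out
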