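"""Shared fixtures: a hand-enumerable toy dataset and brute-force oracles."""

from __future__ import annotations

import itertools
from collections import Counter

import pytest

from dmienrich import (
    DMIDefinitionTable,
    DomainCompositionTable,
    MotifOccurrenceTable,
    PPIDataset,
)


@pytest.fixture
def toy():
    """Toy annotation setup with hand-countable cross-products.

    One motif class MOT_A interacting with domain DOM_B.  MOT_A has two
    'known' carrier proteins (K1, K2) and two extra 'predicted' carriers
    (P1, P2).  DOM_B occurs in four proteins (Q1..Q4).  Two protein-level
    interactions are annotated: (K1,Q1) and (K2,Q2), which are also the
    motif->protein partners of MOT_A.  The interaction data contains every
    carrier as an mProtein and every Q as a dProtein.

    Expected potential-DMI counts:
      elmi-protein                  -> 2
      elmc-protein  (known)         -> 2 carriers x 2 partners     = 4
      elmc-domain   (known)         -> 2 carriers x 4 domain prots = 8
      elmc-domain   (predicted)     -> 4 carriers x 4 domain prots = 16
    """
    ppi = PPIDataset(pairs=[("K1", "Q1"), ("K2", "Q2"), ("P1", "Q3"), ("P2", "Q4")])
    motifs_known = MotifOccurrenceTable(
        rows=[("K1", "MOT_A"), ("K2", "MOT_A")], occurrence_source="known"
    )
    motifs_predicted = MotifOccurrenceTable(
        rows=[("K1", "MOT_A"), ("K2", "MOT_A"), ("P1", "MOT_A"), ("P2", "MOT_A")],
        occurrence_source="predicted",
    )
    dmi_protein = DMIDefinitionTable(
        schema_kind="protein-protein", rows=[("K1", "Q1"), ("K2", "Q2")]
    )
    dmi_motif_protein = DMIDefinitionTable(
        schema_kind="motif-protein", rows=[("MOT_A", "Q1"), ("MOT_A", "Q2")]
    )
    dmi_motif_domain = DMIDefinitionTable(
        schema_kind="motif-domain", rows=[("MOT_A", "DOM_B")]
    )
    domains = DomainCompositionTable(
        rows=[("Q1", "DOM_B"), ("Q2", "DOM_B"), ("Q3", "DOM_B"), ("Q4", "DOM_B")]
    )
    return {
        "ppi": ppi,
        "motifs_known": motifs_known,
        "motifs_predicted": motifs_predicted,
        "dmi_protein": dmi_protein,
        "dmi_motif_protein": dmi_motif_protein,
        "dmi_motif_domain": dmi_motif_domain,
        "domains": domains,
    }


def brute_force_potential(ppi, motifs, dmi_defs, domains, mode):
    """Independent triple/quadruple-loop enumeration of potential DMIs."""
    mset = {m for m, _ in ppi.pairs}
    dset = {d for _, d in ppi.pairs}
    out = set()
    if mode == "elmi-protein":
        for m, d in dmi_defs.rows:
            if m in mset and d in dset:
                out.add((m, None, None, d))
    elif mode == "elmc-protein":
        for m, motif in motifs.rows:
            for motif2, d in dmi_defs.rows:
                if motif == motif2 and m in mset and d in dset:
                    out.add((m, motif, None, d))
    elif mode == "elmc-domain":
        for m, motif in motifs.rows:
            for motif2, dom in dmi_defs.rows:
                for d, dom2 in domains.rows:
                    if motif == motif2 and dom == dom2 and m in mset and d in dset:
                        out.add((m, motif, dom, d))
    else:
        raise ValueError(mode)
    return out


def brute_force_predicted(potential, ppi):
    """Predicted DMIs by direct membership scan over all pairs."""
    return {t for t in potential if (t[0], t[3]) in set(ppi.pairs)}


def exhaustive_null_counts(ppi, weights):
    """Exact null distribution of the predicted-DMI count.

    Enumerates every position-permutation of the dProtein column, keeps the
    duplicate-free ones, and tallies the weighted pair count of each —
    the distribution rejection sampling over column permutations targets.
    """
    mcol = [m for m, _ in ppi.pairs]
    dcol = [d for _, d in ppi.pairs]
    tally = Counter()
    for perm in itertools.permutations(range(len(dcol))):
        pairs = [(mcol[i], dcol[j]) for i, j in enumerate(perm)]
        if len(set(pairs)) == len(pairs):
            tally[sum(weights.get(p, 0) for p in pairs)] += 1
    return tally
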