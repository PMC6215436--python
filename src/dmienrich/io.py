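"""Core record types and delimited-file input/output.

The pipeline consumes four delimited text files: pairwise interactions
(mProtein/dProtein), motif occurrences, DMI definitions and domain
composition.  Column names are configurable through :class:`FieldMap`;
tables are canonicalized on read (whitespace-trimmed IDs, NA rows dropped,
duplicates collapsed, first-occurrence order preserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

#: valid DMI-definition schemas, keyed by the pair of columns they link
DMI_SCHEMA_KINDS = ("protein-protein", "motif-protein", "motif-domain")

OCCURRENCE_SOURCES = ("known", "predicted")


@dataclass(frozen=True)
class FieldMap:
    """Column-name overrides plus the file dialect.

    All four names must be distinct.  ``delimiter=None`` auto-detects
    comma vs tab from the header line.
    """

    mprotein: str = "mProtein"
    dprotein: str = "dProtein"
    motif: str = "Motif"
    domain: str = "Domain"
    delimiter: str | None = None
    header: bool = True

    def __post_init__(self) -> None:
        names = (self.mprotein, self.dprotein, self.motif, self.domain)
        if len(set(names)) != 4:
            raise ValueError(f"FieldMap column names must be distinct, got {names!r}")

    def with_overrides(self, **kwargs: str) -> "FieldMap":
        return replace(self, **kwargs)


@dataclass
class PPIDataset:
    """Ordered, non-redundant list of asymmetric (mProtein, dProtein) pairs."""

    pairs: list[tuple[str, str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for m, d in self.pairs:
            if not m or not d or m != m.strip() or d != d.strip():
                raise ValueError(f"IDs must be non-empty and trimmed: {(m, d)!r}")
            if (m, d) in seen:
                raise ValueError(f"duplicate pair {(m, d)!r} in canonical PPIDataset")
            seen.add((m, d))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def mproteins(self) -> set[str]:
        return {m for m, _ in self.pairs}

    @property
    def dproteins(self) -> set[str]:
        return {d for _, d in self.pairs}

    def pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    def to_frame(self, field_map: FieldMap | None = None) -> pd.DataFrame:
        fm = field_map or FieldMap()
        return pd.DataFrame(self.pairs, columns=[fm.mprotein, fm.dprotein])

    def write_csv(self, path: str | Path, field_map: FieldMap | None = None) -> None:
        self.to_frame(field_map).to_csv(path, index=False, lineterminator="\n")


@dataclass
class MotifOccurrenceTable:
    """Deduplicated (mProtein, motif-class) occurrences."""

    rows: list[tuple[str, str]]
    occurrence_source: str = "known"

    def __post_init__(self) -> None:
        if self.occurrence_source not in OCCURRENCE_SOURCES:
            raise ValueError(f"occurrence_source must be one of {OCCURRENCE_SOURCES}")
        self.rows = _dedup(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def carriers(self) -> set[str]:
        return {m for m, _ in self.rows}

    def to_frame(self, field_map: FieldMap | None = None) -> pd.DataFrame:
        fm = field_map or FieldMap()
        return pd.DataFrame(self.rows, columns=[fm.mprotein, fm.motif])

    def write_csv(self, path: str | Path, field_map: FieldMap | None = None) -> None:
        self.to_frame(field_map).to_csv(path, index=False, lineterminator="\n")


@dataclass
class DMIDefinitionTable:
    """Two-column DMI links; the linked entities depend on ``schema_kind``."""

    schema_kind: str
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.schema_kind not in DMI_SCHEMA_KINDS:
            raise ValueError(f"schema_kind must be one of {DMI_SCHEMA_KINDS}")
        self.rows = _dedup(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def columns(self, field_map: FieldMap | None = None) -> list[str]:
        fm = field_map or FieldMap()
        return {
            "protein-protein": [fm.mprotein, fm.dprotein],
            "motif-protein": [fm.motif, fm.dprotein],
            "motif-domain": [fm.motif, fm.domain],
        }[self.schema_kind]

    def to_frame(self, field_map: FieldMap | None = None) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns(field_map))

    def write_csv(self, path: str | Path, field_map: FieldMap | None = None) -> None:
        self.to_frame(field_map).to_csv(path, index=False, lineterminator="\n")


@dataclass
class DomainCompositionTable:
    """Deduplicated (dProtein, domain) membership rows."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.rows = _dedup(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self, field_map: FieldMap | None = None) -> pd.DataFrame:
        fm = field_map or FieldMap()
        return pd.DataFrame(self.rows, columns=[fm.dprotein, fm.domain])

    def write_csv(self, path: str | Path, field_map: FieldMap | None = None) -> None:
        self.to_frame(field_map).to_csv(path, index=False, lineterminator="\n")


def _dedup(rows: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for r in rows:
        t = (r[0], r[1])
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(
    path: str | Path,
    columns: Sequence[str],
    field_map: FieldMap,
    *,
    what: str,
    allow_empty: bool,
) -> list[tuple[str, str]]:
    """Read two mapped columns from a delimited file, canonicalized.

    Extra columns are ignored.  Rows with missing/empty cells are rejected
    with a logged count; duplicates collapse to first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = field_map.delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            header=0 if field_map.header else None,
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{what} file {path} is empty") from None
    if not field_map.header:
        if df.shape[1] < len(columns):
            raise SchemaError(
                f"{what} file {path}: expected at least {len(columns)} columns, "
                f"found {df.shape[1]}"
            )
        df = df.iloc[:, : len(columns)]
        df.columns = list(columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what} file {path}: missing column(s) {missing}; "
            f"found headers {list(df.columns)}"
        )
    sub = df[list(columns)].copy()
    for c in columns:
        sub[c] = sub[c].astype("string").str.strip()
    n_raw = len(sub)
    sub = sub.replace("", pd.NA).dropna()
    n_dropped = n_raw - len(sub)
    if n_dropped:
        logger.warning("%s file %s: dropped %d row(s) with missing cells", what, path, n_dropped)
    rows = _dedup((str(a), str(b)) for a, b in sub.itertuples(index=False, name=None))
    n_dup = len(sub) - len(rows)
    if n_dup:
        logger.info("%s file %s: collapsed %d duplicate row(s)", what, path, n_dup)
    if not rows:
        if allow_empty:
            logger.warning("%s file %s contains no usable data rows", what, path)
        else:
            raise EmptyInputError(f"{what} file {path} contains no usable data rows")
    return rows


def read_ppi(path: str | Path, field_map: FieldMap | None = None) -> PPIDataset:
    """Read and canonicalize the pairwise interaction file."""
    fm = field_map or FieldMap()
    rows = _read_table(path, (fm.mprotein, fm.dprotein), fm, what="PPI", allow_empty=False)
    n_self = sum(1 for m, d in rows if m == d)
    if n_self:
        logger.info("PPI file %s: %d self-interaction pair(s) retained", path, n_self)
    return PPIDataset(pairs=rows, source_label=str(path))


def read_motifs(
    path: str | Path,
    field_map: FieldMap | None = None,
    occurrence_source: str = "known",
) -> MotifOccurrenceTable:
    """Read motif occurrences (mProtein, Motif); extra columns ignored."""
    fm = field_map or FieldMap()
    rows = _read_table(path, (fm.mprotein, fm.motif), fm, what="motif occurrence", allow_empty=True)
    return MotifOccurrenceTable(rows=rows, occurrence_source=occurrence_source)


def read_dmi_definitions(
    path: str | Path,
    field_map: FieldMap | None = None,
    schema_kind: str = "motif-domain",
) -> DMIDefinitionTable:
    """Read the DMI-definition file; required columns depend on ``schema_kind``."""
    fm = field_map or FieldMap()
    if schema_kind not in DMI_SCHEMA_KINDS:
        raise ValueError(f"schema_kind must be one of {DMI_SCHEMA_KINDS}")
    cols = {
        "protein-protein": (fm.mprotein, fm.dprotein),
        "motif-protein": (fm.motif, fm.dprotein),
        "motif-domain": (fm.motif, fm.domain),
    }[schema_kind]
    rows = _read_table(path, cols, fm, what="DMI definition", allow_empty=True)
    return DMIDefinitionTable(schema_kind=schema_kind, rows=rows)


def read_domains(path: str | Path, field_map: FieldMap | None = None) -> DomainCompositionTable:
    """Read the dProtein -> domain composition file."""
    fm = field_map or FieldMap()
    rows = _read_table(path, (fm.dprotein, fm.domain), fm, what="domain composition", allow_empty=True)
    return DomainCompositionTable(rows=rows)


def symmetrize_ppi(ppi: PPIDataset) -> PPIDataset:
    """Return a dataset where every pair is present in both orientations.

    Self-pairs appear once; the operation is idempotent.
    """
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for m, d in ppi.pairs:
        for pair in ((m, d), (d, m)):
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
    return PPIDataset(pairs=out, source_label=ppi.source_label)
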