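"""Readers and writers for the external formats the pipeline touches.

Expression matrices are genes-in-rows TSV, protein-interaction networks are
2-3 column edge-list TSV (``symbol1 TAB symbol2 [TAB score]``), gene sets are
GMT, and clinical tables are CSV with a header.  Every reader validates its
input and reports what it dropped; every writer produces a file its reader
accepts unchanged (round-trip identity).

Gene identifiers are case-sensitive symbols throughout; mapping between
identifier spaces is the caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleInfo",
    "PPINetwork",
    "GeneSet",
    "ClinicalTable",
    "CLINICAL_LEVELS",
    "read_expression_matrix",
    "read_ppi_edges",
    "read_gene_sets",
    "write_gene_sets",
    "read_clinical",
    "write_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    ``data`` is indexed by unique gene symbols with unique sample-id columns
    and contains no missing values.  ``n_dropped_missing`` and
    ``n_duplicates_resolved`` record what the loader removed.
    """

    data: pd.DataFrame
    n_dropped_missing: int = 0
    n_duplicates_resolved: int = 0

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate gene symbols in expression matrix")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        if self.data.shape[1] < 2:
            raise FormatError("expression matrix needs at least 2 samples")
        if self.data.isna().any().any():
            raise FormatError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])


@dataclass(frozen=True)
class SampleInfo:
    """Tumor/normal annotation for one sample of a paired design."""

    sample_id: str
    subject_id: str
    tissue: str  # "tumor" | "normal"

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be tumor/normal, got {self.tissue!r}")

    @property
    def trait(self) -> int:
        """Numeric trait code: tumor=1, normal=0."""
        return 1 if self.tissue == "tumor" else 0


def validate_sample_info(samples: Sequence[SampleInfo]) -> None:
    """Each subject may contribute at most one tumor and one normal sample."""
    seen: set[tuple[str, str]] = set()
    for s in samples:
        key = (s.subject_id, s.tissue)
        if key in seen:
            raise ValueError(f"subject {s.subject_id} has two {s.tissue} samples")
        seen.add(key)


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network.

    Backed by a :class:`networkx.Graph`; an optional per-edge confidence in
    [0, 1] is stored in the ``score`` edge attribute.
    """

    graph: nx.Graph
    n_self_loops_removed: int = 0
    n_duplicate_edges: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def mean_degree(self) -> float:
        n = self.graph.number_of_nodes()
        return 2.0 * self.graph.number_of_edges() / n if n else 0.0

    def confidence_filtered(self, threshold: float) -> "PPINetwork":
        """Drop edges whose confidence is below ``threshold`` (unscored edges kept)."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, d in self.graph.edges(data=True):
            score = d.get("score")
            if score is None or score >= threshold:
                g.add_edge(u, v, **d)
        return PPINetwork(g)


@dataclass
class GeneSet:
    """A named gene set (GMT semantics); members are unique, order preserved."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        uniq = tuple(dict.fromkeys(self.genes))
        object.__setattr__(self, "genes", uniq)
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


#: Default categorical dictionary for clinical covariates (2x2 study design).
CLINICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "age_class": ("<=50", ">50"),
    "sex": ("female", "male"),
    "tnm": ("I", "II-IV"),
    "tumor_size": ("<=3cm", ">3cm"),
    "afp": ("<=300", ">300"),
    "expression": ("low", "high"),
}


@dataclass
class ClinicalTable:
    """Per-patient survival and categorical covariates.

    ``data`` must contain positive ``time`` (months) and ``event`` in {0, 1};
    categorical columns are validated against ``levels``.  An optional
    ``ihc_percent`` column holds percent-positive cells in [0, 100].
    """

    data: pd.DataFrame
    levels: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: dict(CLINICAL_LEVELS))

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time", "event"):
            if col not in df.columns:
                raise FormatError(f"clinical table lacks required column {col!r}")
        bad_time = df.index[~(df["time"] > 0) | ~np.isfinite(df["time"])]
        if len(bad_time):
            raise FormatError(f"nonpositive survival time in rows {list(bad_time[:5])}")
        if not df["event"].isin([0, 1]).all():
            bad = df.index[~df["event"].isin([0, 1])]
            raise FormatError(f"event flag not in {{0,1}} in rows {list(bad[:5])}")
        for col, levels in self.levels.items():
            if col in df.columns:
                unknown = set(df[col].dropna()) - set(levels)
                if unknown:
                    raise FormatError(f"unknown level(s) {sorted(unknown)} in column {col!r}")
        if "ihc_percent" in df.columns:
            pc = df["ihc_percent"].dropna()
            if ((pc < 0) | (pc > 100)).any():
                raise FormatError("ihc_percent outside [0, 100]")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV.

    The first column holds gene symbols, the header row sample ids.  Rows with
    any missing value are dropped (counted in ``n_dropped_missing``); duplicate
    gene symbols are resolved by keeping the row with the highest mean
    (counted in ``n_duplicates_resolved``).
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids in header")
    try:
        df = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise FormatError(
                    f"{path}: non-numeric value {raw[col].iloc[i]!r} at "
                    f"gene {raw.index[i]!r}, sample {col!r} (row {i + 2}, column {j + 2})"
                ) from None
        raise  # pragma: no cover - unreachable
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    n_dropped = n_before - len(df)
    n_dups = 0
    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        kept = df.iloc[order].loc[lambda d: ~d.index.duplicated(keep="first")]
        n_dups = len(df) - len(kept)
        df = kept.loc[[g for g in dict.fromkeys(df.index) if g in kept.index]]
    return ExpressionMatrix(df, n_dropped_missing=n_dropped, n_duplicates_resolved=n_dups)


def read_ppi_edges(path: str | Path) -> PPINetwork:
    """Read a 2-3 column undirected edge list (optional confidence in [0, 1]).

    Duplicate edges (order-insensitive) and self-loops are removed and
    counted.  Lines starting with ``#`` are ignored.
    """
    graph = nx.Graph()
    n_self, n_dup = 0, 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            a, b = parts[0].strip(), parts[1].strip()
            if not a or not b:
                raise FormatError(f"{path}:{lineno}: empty gene symbol")
            n_lines += 1
            if a == b:
                n_self += 1
                continue
            score = None
            if len(parts) >= 3 and parts[2].strip():
                try:
                    score = float(parts[2])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric score {parts[2]!r}") from None
                if not 0.0 <= score <= 1.0:
                    raise FormatError(f"{path}:{lineno}: score {score} outside [0, 1]")
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            if score is None:
                graph.add_edge(a, b)
            else:
                graph.add_edge(a, b, score=score)
    if n_lines == 0:
        raise FormatError(f"{path}: no edges found")
    return PPINetwork(graph, n_self_loops_removed=n_self, n_duplicate_edges=n_dup)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: ``name TAB description TAB member...`` per line."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets.append(GeneSet(parts[0], parts[1], tuple(g for g in parts[2:] if g)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_clinical(
    path: str | Path,
    levels: Mapping[str, tuple[str, ...]] | None = None,
) -> ClinicalTable:
    """Read and validate a clinical CSV (header row required)."""
    df = pd.read_csv(path)
    return ClinicalTable(df, levels=dict(levels) if levels is not None else dict(CLINICAL_LEVELS))


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
    display_precision: int | None = None,
) -> None:
    """Write a tabular result as TSV with a stable column order.

    Numbers are written at full precision (``repr`` round-trip).  When
    ``display_precision`` is given, an extra ``<col>_display`` column with
    rounded values is appended for each float column.
    """
    df = records.copy()
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
        df = df[list(columns)]
    if display_precision is not None:
        for col in list(df.columns):
            if pd.api.types.is_float_dtype(df[col]):
                df[f"{col}_display"] = df[col].map(lambda x: f"{x:.{display_precision}g}")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
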