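"""Core domain types and file I/O.

Count matrices are features x samples with integer entries; sample sheets
carry the two-group (tumor/normal) phenotype plus an optional batch label;
edge lists hold the typed regulatory prior (miRNA->gene validated targets
and TF->gene edges); DE tables are the per-feature differential-expression
records shared by every downstream stage.

Canonical on-disk formats are plain TSV. Sparse count input is accepted as
a Matrix Market coordinate triplet with ``features.txt``/``samples.txt``
sidecars. ID matching everywhere is exact, case-sensitive string equality.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "EdgeList",
    "EDGE_TYPES",
    "DE_COLUMNS",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_edge_list",
    "write_edge_list",
    "read_de_table",
    "write_de_table",
    "load_table1_fixture",
]

EDGE_TYPES = ("mirna_target", "tf_gene")

#: Column contract for DE tables (see :mod:`mirlink.diffexpr`).
DE_COLUMNS = ["feature_id", "log2fc", "p_raw", "p_adj", "direction"]


class DataValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix with a feature class tag.

    Parameters
    ----------
    counts
        DataFrame indexed by feature ID with sample IDs as columns.
        Entries must be non-negative integers.
    feature_class
        Either ``"mirna"`` or ``"mrna"``.
    """

    counts: pd.DataFrame
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in ("mirna", "mrna"):
            raise DataValidationError(
                f"feature_class must be 'mirna' or 'mrna', got {self.feature_class!r}"
            )
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate feature IDs: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample IDs: {dups[:5]}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise DataValidationError("counts must be numeric")
            if np.any(values < 0):
                f, s = np.argwhere(values < 0)[0]
                raise DataValidationError(
                    f"negative count at feature {self.counts.index[f]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
            if not np.all(np.equal(np.mod(values, 1), 0)):
                f, s = np.argwhere(np.mod(values, 1) != 0)[0]
                raise DataValidationError(
                    f"non-integer count at feature {self.counts.index[f]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
        self.counts = self.counts.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> pd.Series:
        """Raw per-sample library sizes (column sums)."""
        return self.counts.sum(axis=0)

    def subset_features(self, feature_ids: Iterable[str]) -> "CountMatrix":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return CountMatrix(self.counts.loc[keep], self.feature_class)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)], self.feature_class)


@dataclass
class SampleSheet:
    """Per-sample phenotype table: group (tumor/normal) and optional batch."""

    table: pd.DataFrame  # index sample_id; columns: group [, batch]

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise DataValidationError("duplicate sample IDs in sample sheet")
        if "group" not in self.table.columns:
            raise DataValidationError("sample sheet requires a 'group' column")
        bad = set(self.table["group"]) - {"tumor", "normal"}
        if bad:
            raise DataValidationError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def batch(self) -> pd.Series | None:
        return self.table["batch"] if "batch" in self.table.columns else None

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def check_against(self, matrix: CountMatrix, min_per_group: int = 2) -> None:
        """Every sheet sample must exist in the matrix; groups must be big enough
        for a two-group test."""
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise DataValidationError(
                f"sheet samples absent from count matrix: {sorted(missing)[:5]}"
            )
        for g in ("tumor", "normal"):
            n = (self.groups == g).sum()
            if n < min_per_group:
                raise DataValidationError(
                    f"group {g!r} has {n} samples; need at least {min_per_group}"
                )


@dataclass
class EdgeList:
    """Typed directed edges: miRNA->gene validated targets and TF->gene links."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["source", "target", "edge_type", "evidence"]
        )
    )

    def __post_init__(self) -> None:
        t = self.table
        for col in ("source", "target", "edge_type"):
            if col not in t.columns:
                raise DataValidationError(f"edge list requires column {col!r}")
        if "evidence" not in t.columns:
            t = t.assign(evidence="")
        bad = set(t["edge_type"]) - set(EDGE_TYPES)
        if bad:
            raise DataValidationError(f"unknown edge_type values: {sorted(bad)}")
        self_loops = t[(t["edge_type"] == "mirna_target") & (t["source"] == t["target"])]
        if len(self_loops):
            raise DataValidationError(
                f"self-edges not allowed for mirna_target: "
                f"{self_loops['source'].tolist()[:5]}"
            )
        triple = t[["source", "target", "edge_type"]]
        dup = triple[triple.duplicated()]
        if len(dup):
            raise DataValidationError(
                "duplicate edges: "
                + "; ".join(
                    f"({r.source} -> {r.target}, {r.edge_type})"
                    for r in dup.head(5).itertuples()
                )
            )
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def of_type(self, edge_type: str) -> pd.DataFrame:
        return self.table[self.table["edge_type"] == edge_type]

    def targets_of(self, mirna_id: str) -> list[str]:
        m = self.of_type("mirna_target")
        return list(m.loc[m["source"] == mirna_id, "target"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, feature_class: str) -> CountMatrix:
    """Read a count matrix from TSV, or from a Matrix Market triplet.

    TSV layout: header ``feature_id<TAB>sample1<TAB>...``; one feature per
    row. If *path* ends in ``.mtx`` it is read as a coordinate Matrix Market
    file with ``features.txt`` and ``samples.txt`` sidecars (one ID per
    line) in the same directory.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.sparse.coo_matrix(scipy.io.mmread(path)).toarray()
        features = (path.parent / "features.txt").read_text().split()
        samples = (path.parent / "samples.txt").read_text().split()
        if mat.shape != (len(features), len(samples)):
            raise DataValidationError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(features)} features, {len(samples)} samples)"
            )
        df = pd.DataFrame(mat, index=features, columns=samples)
        return CountMatrix(df, feature_class)

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate feature IDs in {path}: {dups[:5]}")
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        # locate the offending cell for the error message
        for i, row in enumerate(values):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise DataValidationError(
                        f"non-numeric count at feature {df.index[i]!r}, "
                        f"sample {df.columns[j]!r} in {path}"
                    ) from None
        raise DataValidationError(f"non-numeric counts in {path}")
    return CountMatrix(df, feature_class)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    df = sheet.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_edge_list(path: str | Path) -> EdgeList:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return EdgeList(df)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    edges.table.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"DE table missing columns: {sorted(missing)}")
    return df[DE_COLUMNS].copy()


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table[DE_COLUMNS].to_csv(path, sep="\t", index=False)


def load_table1_fixture() -> pd.DataFrame:
    """Published table of 49 differentially expressed miRNAs (eBL tumor vs
    germinal-center B cells), packaged as a DE-table fixture.

    The two printed p columns are stored as ``p_raw`` (BH adjusted p-value
    column) and ``p_adj`` (FDR column); the printed Up/Down call is stored
    in ``direction`` in lower case.
    """
    ref = importlib.resources.files("mirlink.data") / "table1_de_mirnas.tsv"
    with importlib.resources.as_file(ref) as p:
        if not p.exists():
            raise FileNotFoundError("packaged DE-miRNA fixture is missing")
        df = pd.read_csv(p, sep="\t")
    if list(df.columns) != DE_COLUMNS or len(df) != 49:
        raise DataValidationError("DE-miRNA fixture is corrupt")
    return df
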