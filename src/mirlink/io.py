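"""Readers and writers for every on-disk artifact of the pipeline.

Canonical tabular dialect is TSV (UTF-8, no quoting). Count matrices are
feature rows x sample columns with a header row of sample IDs and the
feature ID in the first column. Gene sets use the GMT format. miRNA-target
evidence tables follow the column layout of the public target databases
(database, mature accession, mature ID, symbol, Entrez, Ensembl,
validated/predicted, PubMed, score).

All readers are total on their declared grammar: a malformed input raises
a located error, never a silent drop. ``write`` then ``read`` is the
identity on valid artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "TargetEvidenceTable",
    "GeneSetCollection",
    "VALIDATED_DATABASES",
    "PREDICTION_DATABASES",
    "read_counts",
    "write_counts",
    "read_meta",
    "write_meta",
    "read_gmt",
    "write_gmt",
    "read_evidence",
    "write_evidence",
    "read_de",
    "write_de",
    "read_correlations",
    "write_correlations",
    "write_network",
    "read_network",
    "load_table3_evidence",
    "load_table2_clinical",
]

VALIDATED_DATABASES = frozenset({"mirtarbase", "tarbase"})
PREDICTION_DATABASES = frozenset({"diana_microt", "elmmo", "pita"})

#: normalized column names of an evidence table, in canonical order
EVIDENCE_COLUMNS = [
    "database",
    "mirna_acc",
    "mirna_id",
    "target_symbol",
    "target_entrez",
    "target_ensembl",
    "type",
    "pubmed",
    "score",
]

# header spellings used by the public database export the fixture mirrors
_EVIDENCE_HEADER_ALIASES = {
    "database": "database",
    "mature mirna acc": "mirna_acc",
    "mature mirna id": "mirna_id",
    "target symbol": "target_symbol",
    "target entrez": "target_entrez",
    "target ensembl": "target_ensembl",
    "type": "type",
    "pubmed id": "pubmed",
    "score": "score",
    "mirna_acc": "mirna_acc",
    "mirna_id": "mirna_id",
    "target_symbol": "target_symbol",
    "target_entrez": "target_entrez",
    "target_ensembl": "target_ensembl",
    "pubmed": "pubmed",
}


@dataclass
class CountMatrix:
    """Non-negative integer feature-by-sample count matrix.

    Feature and sample identifiers are ordered and unique; values is an
    ``(n_features, n_samples)`` integer array.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        dup = _first_duplicate(self.feature_ids)
        if dup is not None:
            raise ValueError(f"duplicate feature ID: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("count matrix contains non-integer values")
            values = np.round(values).astype(np.int64)
        if (values < 0).any():
            raise ValueError("count matrix contains negative values")
        self.values = values.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.feature_ids), list(sample_ids), self.values[:, idx])


@dataclass
class TargetEvidenceTable:
    """miRNA-target evidence rows from validated and prediction databases."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"evidence table missing columns: {missing}")
        df = df[EVIDENCE_COLUMNS].reset_index(drop=True)
        df["database"] = df["database"].astype(str).str.strip().str.lower()
        df["type"] = df["type"].astype(str).str.strip().str.lower()
        bad_db = sorted(set(df["database"]) - VALIDATED_DATABASES - PREDICTION_DATABASES)
        if bad_db:
            raise ValueError(f"unknown evidence database(s): {bad_db}")
        bad_type = sorted(set(df["type"]) - {"validated", "predicted"})
        if bad_type:
            raise ValueError(f"unknown evidence type(s): {bad_type}")
        # type=validated iff the row comes from an experimental database
        val_db = df["database"].isin(sorted(VALIDATED_DATABASES))
        mismatch = df.index[(df["type"] == "validated") != val_db]
        if len(mismatch):
            raise ValueError(
                f"row {mismatch[0]}: type {df.loc[mismatch[0], 'type']!r} inconsistent "
                f"with database {df.loc[mismatch[0], 'database']!r}"
            )
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
        has_score = df["score"].notna()
        if (has_score & (df["type"] == "validated")).any():
            raise ValueError("score present on a validated row")
        scores = df.loc[has_score, "score"]
        if ((scores < 0) | (scores > 1)).any():
            raise ValueError("prediction scores must lie in [0, 1]")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def unique_pairs(self) -> pd.DataFrame:
        """Distinct (miRNA ID, gene symbol) pairs, case-normalized order preserved."""
        pairs = self.frame[["mirna_id", "target_symbol"]].copy()
        key = pairs["mirna_id"].str.lower() + "\t" + pairs["target_symbol"].str.lower()
        return pairs[~key.duplicated()].reset_index(drop=True)

    def restrict_to_mirnas(self, mirna_ids) -> "TargetEvidenceTable":
        wanted = {str(m).lower() for m in mirna_ids}
        keep = self.frame["mirna_id"].str.lower().isin(wanted) | self.frame[
            "mirna_acc"
        ].str.lower().isin(wanted)
        return TargetEvidenceTable(self.frame[keep].reset_index(drop=True))


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions and a namespace tag."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    namespace: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) < 1:
                raise ValueError(f"gene set {name!r} is empty")
            dup = _first_duplicate(members)
            if dup is not None:
                raise ValueError(f"gene set {name!r} lists {dup!r} twice")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def _first_duplicate(ids) -> str | None:
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# count matrices and sample metadata


def read_counts(path) -> CountMatrix:
    """Read a feature-by-sample TSV count matrix.

    Rejects ragged rows, duplicate IDs, and negative or non-integer values,
    naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: ragged or missing values in row {row!r}")
    dup = _first_duplicate(list(df.index))
    if dup is not None:
        raise ValueError(f"{path}: duplicate feature ID {dup!r}")
    dup = _first_duplicate(list(df.columns))
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count value ({exc})") from None
    if not np.allclose(values, np.round(values)):
        bad = df.index[np.where(~np.isclose(values, np.round(values)))[0][0]]
        raise ValueError(f"{path}: non-integer count in feature {bad!r}")
    if (values < 0).any():
        bad = df.index[np.where((values < 0).any(axis=1))[0][0]]
        raise ValueError(f"{path}: negative count in feature {bad!r}")
    return CountMatrix(list(df.index), list(df.columns), values.astype(np.int64))


def write_counts(matrix: CountMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


def read_meta(path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample_id, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata missing column {col!r}")
    dup = _first_duplicate(list(df["sample_id"]))
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    return df.reset_index(drop=True)


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path, namespace: str = "") -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, namespace)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# evidence tables


def read_evidence(path) -> TargetEvidenceTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key not in _EVIDENCE_HEADER_ALIASES:
            raise ValueError(f"{path}: unrecognized evidence column {col!r}")
        rename[col] = _EVIDENCE_HEADER_ALIASES[key]
    df = df.rename(columns=rename)
    for col in EVIDENCE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    try:
        return TargetEvidenceTable(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_evidence(table: TargetEvidenceTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def load_table3_evidence() -> TargetEvidenceTable:
    """The packaged evidence fixture transcribed from the published interactome
    table (22 rows over the five differentially expressed miRNAs)."""
    with resources.as_file(
        resources.files("mirlink.data").joinpath("table3_evidence.tsv")
    ) as path:
        return read_evidence(path)


def load_table2_clinical() -> pd.DataFrame:
    """The packaged baseline-characteristics fixture (printed group summaries)."""
    with resources.as_file(
        resources.files("mirlink.data").joinpath("table2_clinical.tsv")
    ) as path:
        return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# DE and correlation tables

DE_COLUMNS = ["feature_id", "base_mean", "log2fc", "se", "stat", "pvalue", "padj"]
CORR_COLUMNS = ["mirna_id", "gene_id", "n", "r", "pvalue", "scope"]


def write_de(result: pd.DataFrame, path) -> None:
    out = result.reset_index()
    if "feature_id" not in out.columns:
        out = out.rename(columns={out.columns[0]: "feature_id"})
    out[DE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_de(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: DE table missing columns {missing}")
    return df.set_index("feature_id")


def write_correlations(records: pd.DataFrame, path) -> None:
    cols = [c for c in records.columns if c in CORR_COLUMNS or c in ("padj", "flagged")]
    records[cols].to_csv(path, sep="\t", index=False)


def read_correlations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CORR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: correlation table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# networks

NETWORK_FORMATS = ("graphml", "edge_tsv", "json")


def write_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Export a bipartite interaction network.

    Node attributes (kind, direction) and edge attributes (r, pvalue,
    validated, n_predicted_dbs, evidence databases) survive every format.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "edge_tsv":
        rows = []
        for u, v, data in network.edges(data=True):
            mirna, gene = (u, v) if network.nodes[u].get("kind") == "mirna" else (v, u)
            rows.append(
                {
                    "mirna_id": mirna,
                    "gene_id": gene,
                    **{k: data.get(k) for k in sorted(data)},
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = nx.node_link_data(network, edges="edges")
        path.write_text(json.dumps(payload, indent=1, default=str))
    else:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "json":
        payload = json.loads(Path(path).read_text())
        return nx.node_link_graph(payload, edges="edges")
    raise ValueError(f"unknown network format {format!r}")
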