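"""miRNA-mRNA interactome screen.

All-pairs Pearson correlation between (typically differentially expressed)
miRNAs and genes on log2(size-factor-normalized count + 1) expression,
two-sided p-values from the t transform t = r * sqrt((n-2)/(1-r^2)),
a strict negative-correlation filter (r < r_max AND p < alpha), an
intersection with validated/predicted target evidence, and assembly of the
resulting bipartite regulatory network.

Correlations default to the pooled sample scope: with 3-4 samples per
group, per-group coefficients are nearly degenerate (at n=3, p < 0.05
needs |r| > 0.997), so the pooled estimate across both groups is the
operative screen; per-group scopes remain available and are reported
separately, never mixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust, size_factors
from .io import CountMatrix, TargetEvidenceTable

__all__ = [
    "InteractionEdge",
    "normalized_log_expression",
    "correlate_pairs",
    "filter_negative",
    "merge_evidence",
    "build_network",
]

SCOPES = ("pooled",)  # plus any group label present in the metadata


@dataclass
class InteractionEdge:
    """A screened miRNA-gene pair with its correlation and evidence."""

    mirna_id: str
    gene_id: str
    r: float
    pvalue: float
    n: int
    scope: str
    evidence: pd.DataFrame = field(repr=False, default=None)
    validated: bool = False
    n_predicted_dbs: int = 0
    mirna_direction: str = "unknown"
    gene_direction: str = "unknown"


def normalized_log_expression(counts: CountMatrix) -> pd.DataFrame:
    """log2(count / size factor + 1) expression matrix.

    Falls back to total-count scaling (factors rescaled to geometric mean
    1) when no feature is positive in every sample.
    """
    try:
        sf = size_factors(counts)
    except ValueError:
        totals = counts.values.sum(axis=0).astype(float)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts; cannot normalize")
        sf = totals / np.exp(np.mean(np.log(totals)))
        warnings.warn(
            "median-of-ratios undefined (no all-positive feature); "
            "using total-count size factors",
            stacklevel=2,
        )
    q = counts.values / sf[None, :]
    return pd.DataFrame(
        np.log2(q + 1.0), index=counts.feature_ids, columns=counts.sample_ids
    )


def correlate_pairs(
    mirna_counts: CountMatrix,
    mrna_counts: CountMatrix,
    meta: pd.DataFrame | None = None,
    scope: str = "pooled",
    mirna_ids=None,
    gene_ids=None,
) -> pd.DataFrame:
    """Pearson correlation records for every (miRNA, gene) pair.

    Feature lists default to all features of each matrix; the usual screen
    passes the DE miRNAs. Samples are the intersection of the two matrices,
    restricted to one group when ``scope`` names a group label. Pairs where
    either feature has zero variance get r = NaN and ``flagged`` = True;
    they are excluded by downstream filtering.
    """
    shared = [s for s in mirna_counts.sample_ids if s in set(mrna_counts.sample_ids)]
    if scope != "pooled":
        if meta is None:
            raise ValueError("per-group scope requires sample metadata")
        in_group = set(meta.loc[meta["group"] == scope, "sample_id"])
        if not in_group:
            raise ValueError(f"no samples with group label {scope!r}")
        shared = [s for s in shared if s in in_group]
    n = len(shared)
    if n < 3:
        raise ValueError(f"scope {scope!r} leaves {n} shared samples; need >= 3")

    expr_m = normalized_log_expression(mirna_counts.subset_samples(shared))
    expr_g = normalized_log_expression(mrna_counts.subset_samples(shared))
    if mirna_ids is None:
        mirna_ids = list(expr_m.index)
    if gene_ids is None:
        gene_ids = list(expr_g.index)
    A = expr_m.loc[list(mirna_ids)].to_numpy()
    B = expr_g.loc[list(gene_ids)].to_numpy()

    A_c = A - A.mean(axis=1, keepdims=True)
    B_c = B - B.mean(axis=1, keepdims=True)
    norm_a = np.sqrt((A_c**2).sum(axis=1))
    norm_b = np.sqrt((B_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (A_c @ B_c.T) / np.outer(norm_a, norm_b)
    r = np.clip(r, -1.0, 1.0)
    flagged = np.isnan(r) | np.outer(norm_a == 0, norm_b == 0)
    flagged |= (norm_a == 0)[:, None] | (norm_b == 0)[None, :]
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    pvalue = 2.0 * stats.t.sf(np.abs(t), df)
    pvalue = np.where(np.isclose(np.abs(r), 1.0), np.finfo(float).tiny, pvalue)

    mi, gi = np.meshgrid(np.arange(len(mirna_ids)), np.arange(len(gene_ids)), indexing="ij")
    records = pd.DataFrame(
        {
            "mirna_id": np.asarray(mirna_ids, dtype=object)[mi.ravel()],
            "gene_id": np.asarray(gene_ids, dtype=object)[gi.ravel()],
            "n": n,
            "r": r.ravel(),
            "pvalue": pvalue.ravel(),
            "scope": scope,
            "flagged": flagged.ravel(),
        }
    )
    records.loc[records["flagged"], ["r", "pvalue"]] = np.nan
    # BH column for transparency; the screen itself filters on raw p
    records["padj"] = bh_adjust(records["pvalue"].to_numpy())
    return records


def filter_negative(
    records: pd.DataFrame, r_max: float = -0.7, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep records with r < r_max AND p < alpha (both strict).

    Flagged/NaN records never pass. A positive r_max defeats the purpose of
    a repression screen and only warns.
    """
    if r_max > 0:
        warnings.warn(
            f"r_max = {r_max} is positive; the negative-correlation screen "
            "will keep positively correlated pairs",
            stacklevel=2,
        )
    keep = (records["r"] < r_max) & (records["pvalue"] < alpha)
    keep &= records["r"].notna() & records["pvalue"].notna()
    if "flagged" in records.columns:
        keep &= ~records["flagged"].astype(bool)
    return records[keep].reset_index(drop=True)


def _match_keys(mirna_id: str) -> str:
    return str(mirna_id).strip().lower()


def merge_evidence(
    records: pd.DataFrame,
    evidence: TargetEvidenceTable,
    min_predicted_dbs: int = 1,
    accept_validated: bool = True,
) -> list[InteractionEdge]:
    """Intersect correlation records with target evidence.

    A pair becomes an edge iff it has at least one validated row (and
    ``accept_validated``) OR predictions from at least ``min_predicted_dbs``
    DISTINCT prediction databases. Matching is case-normalized on the miRNA
    mature accession or ID and the gene symbol; the output is independent
    of evidence row order.
    """
    if min_predicted_dbs < 1:
        raise ValueError("min_predicted_dbs must be >= 1")
    ev = evidence.frame
    by_pair: dict[tuple[str, str], list[int]] = {}
    for idx, row in ev.iterrows():
        gene = str(row["target_symbol"]).strip().lower()
        for key in {_match_keys(row["mirna_id"]), _match_keys(row["mirna_acc"])}:
            if key and key != "nan":
                by_pair.setdefault((key, gene), []).append(idx)

    edges: list[InteractionEdge] = []
    for rec in records.itertuples(index=False):
        key = (_match_keys(rec.mirna_id), str(rec.gene_id).strip().lower())
        row_idx = by_pair.get(key)
        if not row_idx:
            continue
        rows = ev.loc[sorted(set(row_idx))]
        validated = bool((rows["type"] == "validated").any())
        n_pred = int(rows.loc[rows["type"] == "predicted", "database"].nunique())
        if not ((validated and accept_validated) or n_pred >= min_predicted_dbs):
            continue
        edges.append(
            InteractionEdge(
                mirna_id=str(rec.mirna_id),
                gene_id=str(rec.gene_id),
                r=float(rec.r),
                pvalue=float(rec.pvalue),
                n=int(rec.n),
                scope=str(rec.scope),
                evidence=rows.reset_index(drop=True),
                validated=validated,
                n_predicted_dbs=n_pred,
            )
        )
    return edges


def build_network(
    edges: list[InteractionEdge],
    gene_de: pd.DataFrame | None = None,
    mirna_de: pd.DataFrame | None = None,
) -> tuple[nx.Graph, dict[str, int]]:
    """Bipartite miRNA-gene network with direction-annotated nodes.

    Duplicate (miRNA, gene) edges collapse to one edge with merged
    evidence. Node ``direction`` ('up'/'down', numerator group vs
    denominator) comes from the sign of the DE log2fc; features absent
    from the DE tables get 'unknown' with a warning. Returns the graph and
    a summary dict (n_mirnas, n_genes, n_edges).
    """

    def _direction(feature: str, de: pd.DataFrame | None) -> str:
        if de is not None and feature in de.index:
            return "up" if de.loc[feature, "log2fc"] > 0 else "down"
        warnings.warn(f"feature {feature!r} absent from DE table; direction unknown",
                      stacklevel=2)
        return "unknown"

    graph = nx.Graph()
    for edge in edges:
        if edge.mirna_id not in graph:
            graph.add_node(
                edge.mirna_id,
                kind="mirna",
                bipartite=0,
                direction=_direction(edge.mirna_id, mirna_de),
            )
        if edge.gene_id not in graph:
            graph.add_node(
                edge.gene_id,
                kind="gene",
                bipartite=1,
                direction=_direction(edge.gene_id, gene_de),
            )
        dbs = sorted(set(edge.evidence["database"])) if edge.evidence is not None else []
        if graph.has_edge(edge.mirna_id, edge.gene_id):
            data = graph.edges[edge.mirna_id, edge.gene_id]
            data["evidence_dbs"] = ",".join(
                sorted(set(data["evidence_dbs"].split(",")) | set(dbs))
            )
            data["validated"] = bool(data["validated"] or edge.validated)
            data["n_predicted_dbs"] = max(data["n_predicted_dbs"], edge.n_predicted_dbs)
        else:
            graph.add_edge(
                edge.mirna_id,
                edge.gene_id,
                r=edge.r,
                pvalue=edge.pvalue,
                validated=edge.validated,
                n_predicted_dbs=edge.n_predicted_dbs,
                evidence_dbs=",".join(dbs),
            )
    summary = {
        "n_mirnas": sum(1 for _, d in graph.nodes(data=True) if d["kind"] == "mirna"),
        "n_genes": sum(1 for _, d in graph.nodes(data=True) if d["kind"] == "gene"),
        "n_edges": graph.number_of_edges(),
    }
    return graph, summary
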