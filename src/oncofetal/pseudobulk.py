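"""Pseudobulk aggregation, correlation structure, and signature derivation.

The fetal/tumor co-expression module is found by (1) averaging normalized
expression over sample × cell-type groups, (2) correlating the resulting
pseudobulk profiles over the most variable genes, (3) average-linkage
hierarchical clustering on 1 − Pearson distance, and (4) selecting the
cluster that both contains fetal pseudobulks and at least one tumor
pseudobulk.  The oncofetal signature is then the top genes (by log2 fold
change, at an FDR gate) distinguishing module cells from the remaining
epithelial cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats

from .io import NormalizedMatrix, CellDataset, TUMOR_PHENOTYPES

logger = logging.getLogger("oncofetal")


@dataclass
class PseudobulkMatrix:
    """Pseudobulk × gene mean normalized expression with group metadata."""

    values: np.ndarray                   # (n_pseudobulks, n_genes)
    pb_meta: pd.DataFrame                # sample_id, phenotype, cell_type, n_cells
    gene_ids: list[str]


@dataclass
class ModuleAssignment:
    """Cluster labels per pseudobulk and the selected fetal/tumor module."""

    labels: pd.Series                    # pseudobulk index -> cluster id
    module_id: int
    module_members: list[str]
    linkage_summary: np.ndarray          # merge heights from the dendrogram


@dataclass
class Signature:
    """Ordered gene list with its derivation statistics.

    ``genes`` are sorted by descending log2 fold change; ``stats`` holds one
    row per retained gene (log2fc, p, p_adj, rank).
    """

    genes: list[str]
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------

def build_pseudobulks(
    ds: CellDataset,
    norm: NormalizedMatrix,
    group_keys: list[str] | None = None,
    min_cells: int = 10,
) -> PseudobulkMatrix:
    """Mean normalized expression per metadata group; small groups dropped.

    One row per combination of ``group_keys`` (default sample_id ×
    cell_type) with at least ``min_cells`` member cells.
    """
    group_keys = group_keys or ["sample_id", "cell_type"]
    missing = [k for k in group_keys if k not in ds.cell_meta.columns]
    if missing:
        raise ValueError(f"group keys not in metadata: {missing}")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")

    meta = ds.cell_meta
    rows, meta_rows, dropped = [], [], 0
    for key, idx in meta.groupby(group_keys, sort=True, observed=True).indices.items():
        if len(idx) < min_cells:
            dropped += 1
            continue
        key_t = key if isinstance(key, tuple) else (key,)
        rows.append(norm.values[idx].mean(axis=0))
        row_meta = dict(zip(group_keys, key_t))
        first = meta.iloc[idx[0]]
        for col in ("sample_id", "phenotype", "cell_type"):
            row_meta.setdefault(col, first[col])
        row_meta["n_cells"] = len(idx)
        row_meta["pseudobulk_id"] = "|".join(map(str, key_t))
        meta_rows.append(row_meta)
    if dropped:
        logger.info("dropped %d pseudobulk groups below min_cells=%d", dropped, min_cells)
    if not rows:
        raise ValueError("no pseudobulks: every group fell below min_cells")
    pb_meta = pd.DataFrame(meta_rows).set_index("pseudobulk_id")
    return PseudobulkMatrix(values=np.vstack(rows), pb_meta=pb_meta,
                            gene_ids=list(ds.gene_ids))


def filter_pseudobulks(pb: PseudobulkMatrix, cell_type: str = "epithelial") -> PseudobulkMatrix:
    """Restrict a pseudobulk matrix to one cell type (module detection runs
    on epithelial pseudobulks)."""
    keep = (pb.pb_meta["cell_type"] == cell_type).to_numpy()
    if not keep.any():
        raise ValueError(f"no pseudobulks of cell type {cell_type!r}")
    return PseudobulkMatrix(values=pb.values[keep], pb_meta=pb.pb_meta.loc[keep],
                            gene_ids=pb.gene_ids)


def top_variable_genes(values: np.ndarray, n_top: int = 2000) -> np.ndarray:
    """Indices of the ``n_top`` highest-variance columns (all if fewer)."""
    var = values.var(axis=0)
    if values.shape[1] <= n_top:
        return np.arange(values.shape[1])
    return np.sort(np.argsort(var)[::-1][:n_top])


def correlate_pseudobulks(
    pb: PseudobulkMatrix,
    gene_subset: list[str] | None = None,
    n_variable: int = 2000,
) -> np.ndarray:
    """Pairwise Pearson correlation of pseudobulk profiles.

    Defaults to the top ``n_variable`` most variable genes across
    pseudobulks.  Zero-variance pseudobulks get correlation 0 (flagged),
    diagonal exactly 1.
    """
    if pb.values.shape[0] < 2:
        raise ValueError("need >= 2 pseudobulks to correlate")
    if gene_subset is not None:
        lookup = {g: i for i, g in enumerate(pb.gene_ids)}
        cols = np.array([lookup[g] for g in gene_subset])
    else:
        cols = top_variable_genes(pb.values, n_variable)
    sub = pb.values[:, cols]
    sd = sub.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance pseudobulks; correlations set to 0",
                       degenerate.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def detect_comodule(
    corr: np.ndarray,
    pb_meta: pd.DataFrame,
    n_clusters: int = 4,
) -> ModuleAssignment:
    """Average-linkage clustering on 1 − r; pick the fetal + tumor cluster.

    The selected module maximizes (fraction of members with fetal phenotype)
    × (1 if the cluster also holds ≥ 1 tumor pseudobulk else 0); ties break
    to the larger cluster, then the lowest cluster id.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    n = corr.shape[0]
    if len(pb_meta) != n:
        raise ValueError("pb_meta rows must match correlation matrix")
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = ssd.squareform(dist, checks=False)
    linkage = sch.linkage(condensed, method="average")
    labels = sch.fcluster(linkage, t=n_clusters, criterion="maxclust")

    phenotype = pb_meta["phenotype"].to_numpy()
    is_fetal = phenotype == "fetal"
    is_tumor = np.isin(phenotype, TUMOR_PHENOTYPES)
    if not is_fetal.any():
        raise ValueError("no oncofetal module: no fetal pseudobulks present")

    best = None
    for cid in sorted(np.unique(labels)):
        members = labels == cid
        frac_fetal = is_fetal[members].mean()
        gate = 1.0 if is_tumor[members].any() else 0.0
        score = frac_fetal * gate
        key = (score, members.sum(), -cid)   # score desc, size desc, id asc
        if best is None or key > best[0]:
            best = (key, cid)
    score_best = best[0][0]
    if score_best == 0.0:
        raise ValueError("no oncofetal module: no cluster joins fetal and tumor pseudobulks")
    module_id = best[1]
    members = pb_meta.index[labels == module_id].tolist()
    return ModuleAssignment(
        labels=pd.Series(labels, index=pb_meta.index, name="cluster"),
        module_id=int(module_id),
        module_members=members,
        linkage_summary=linkage[:, 2],
    )


def module_cell_mask(ds: CellDataset, assignment: ModuleAssignment,
                     pb_meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Masks for module cells vs the remaining epithelial cells.

    Cells belong to the module if their (sample, cell type) pseudobulk is a
    module member; the contrast set is all other epithelial cells.
    """
    member_keys = set()
    for pb_id in assignment.module_members:
        row = pb_meta.loc[pb_id]
        member_keys.add((row["sample_id"], row["cell_type"]))
    keys = list(zip(ds.cell_meta["sample_id"], ds.cell_meta["cell_type"]))
    in_module = np.array([k in member_keys for k in keys])
    epithelial = (ds.cell_meta["cell_type"] == "epithelial").to_numpy()
    return in_module & epithelial, epithelial & ~in_module


# ---------------------------------------------------------------------------

def derive_signature(
    norm: NormalizedMatrix,
    module_cells: np.ndarray,
    other_epithelial: np.ndarray,
    gene_ids: list[str],
    n_top: int = 200,
    alpha: float = 0.05,
) -> Signature:
    """Top differential genes of module cells vs other epithelium.

    Two-sided Wilcoxon rank-sum per gene on normalized values, BH-adjusted;
    genes with adjusted p ≤ alpha and positive log2 fold change (ratio of
    group means on the expm1/CP10K scale, pseudocount 1) are ranked by
    descending log2 fold change and the top ``n_top`` kept.
    """
    module_cells = np.asarray(module_cells, dtype=bool)
    other_epithelial = np.asarray(other_epithelial, dtype=bool)
    if not module_cells.any() or not other_epithelial.any():
        raise ValueError("both cell masks must be nonempty")
    if (module_cells & other_epithelial).any():
        raise ValueError("cell masks must be disjoint")

    a = norm.values[module_cells]
    b = norm.values[other_epithelial]
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                             method="asymptotic")
    pvals = np.asarray(res.pvalue)
    # constant genes give nan p-values; treat as null
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    p_adj = stats.false_discovery_control(pvals, method="bh")
    mean_a = np.expm1(a).mean(axis=0)
    mean_b = np.expm1(b).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    keep = (p_adj <= alpha) & (log2fc > 0)
    order = np.argsort(-log2fc[keep], kind="stable")
    kept_idx = np.flatnonzero(keep)[order]
    if len(kept_idx) < n_top:
        logger.warning("only %d genes qualify (requested %d)", len(kept_idx), n_top)
    kept_idx = kept_idx[:n_top]
    genes = [gene_ids[i] for i in kept_idx]
    stats_df = pd.DataFrame({
        "gene": genes,
        "log2fc": log2fc[kept_idx],
        "p": pvals[kept_idx],
        "p_adj": p_adj[kept_idx],
        "rank": np.arange(1, len(kept_idx) + 1),
    }).set_index("gene")
    return Signature(genes=genes, stats=stats_df)


def write_signature_tsv(sig: Signature, path: str) -> None:
    pd.DataFrame({"gene": sig.genes,
                  "rank": np.arange(1, len(sig.genes) + 1)}).to_csv(
        path, sep="\t", index=False)
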