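"""Expression-derived CNV profiles and semi-supervised malignancy calls.

Genes are ordered along the genome, each gene is centered on the mean of a
normal reference (normal epithelium + endothelium), deviations are clipped
at a multiple of the reference SD, and a moving average along each
chromosome smooths single-gene noise into segment-level signal.  The
per-cell CNV score summarizes the smoothed deviation from the reference
baseline; tumor clusters whose scores exceed the pooled reference by both
an effect-size and a significance gate are called malignant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import NormalizedMatrix, chromosome_sort_key

logger = logging.getLogger("oncofetal")

_SD_FLOOR = 1e-6


@dataclass
class CnvProfile:
    """Smoothed, reference-centered residual matrix (cells × ordered genes)."""

    residuals: np.ndarray
    gene_order: list[str]               # genome order of the residual columns
    window: int
    clip: float
    reference_cells: np.ndarray         # boolean mask over cells


def _moving_average_by_chrom(x: np.ndarray, chrom_labels: np.ndarray,
                             window: int) -> np.ndarray:
    """Centered moving average per chromosome with shrinking edge windows."""
    out = np.empty_like(x)
    half = window // 2
    for chrom in pd.unique(chrom_labels):
        cols = np.flatnonzero(chrom_labels == chrom)
        n = len(cols)
        if n < window:
            logger.warning("chromosome %s has %d genes < window %d; "
                           "using full-chromosome window", chrom, n, window)
        block = x[:, cols]
        csum = np.cumsum(block, axis=1)
        csum = np.concatenate([np.zeros((x.shape[0], 1)), csum], axis=1)
        i = np.arange(n)
        lo = np.maximum(i - half, 0)
        hi = np.minimum(i + half + 1, n)
        out[:, cols] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def infer_cnv_profile(
    norm: NormalizedMatrix,
    gene_pos: pd.DataFrame,
    gene_ids: list[str],
    reference_mask: np.ndarray,
    window: int = 101,
    clip: float = 3.0,
    center_cells: bool = True,
) -> CnvProfile:
    """Reference-centered, clipped, genome-smoothed expression residuals.

    Per gene (ordered by chromosome, start): subtract the reference-cell
    mean, clip to ±``clip`` reference SDs (SD floored at a small epsilon),
    moving-average over ``window`` genes within each chromosome (shrinking
    at chromosome edges), subtract each cell's median residual
    (``center_cells``; removes library-complexity shifts, as the standard
    tool does), then re-center so the reference mean per gene is exactly 0.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    with_pos = [g for g in gene_ids if g in gene_pos.index]
    if len(with_pos) < max(window, len(gene_ids) // 2):
        raise ValueError(
            f"gene positions cover only {len(with_pos)}/{len(gene_ids)} genes")

    pos = gene_pos.loc[with_pos]
    order = sorted(range(len(with_pos)),
                   key=lambda i: (chromosome_sort_key(pos["chrom"].iloc[i]),
                                  int(pos["start"].iloc[i])))
    ordered_genes = [with_pos[i] for i in order]
    chrom_labels = pos["chrom"].to_numpy()[order]

    lookup = {g: i for i, g in enumerate(gene_ids)}
    cols = np.array([lookup[g] for g in ordered_genes])
    x = norm.values[:, cols]

    ref = x[reference_mask]
    ref_mean = ref.mean(axis=0)
    ref_sd = np.maximum(ref.std(axis=0), _SD_FLOOR)
    centered = x - ref_mean
    bound = clip * ref_sd
    centered = np.clip(centered, -bound, bound)
    smoothed = _moving_average_by_chrom(centered, chrom_labels, window)
    if center_cells:
        smoothed = smoothed - np.median(smoothed, axis=1, keepdims=True)
    residuals = smoothed - smoothed[reference_mask].mean(axis=0)
    return CnvProfile(residuals=residuals, gene_order=ordered_genes,
                      window=window, clip=clip, reference_cells=reference_mask)


def cnv_score(profile: CnvProfile, mode: str = "mad") -> np.ndarray:
    """Per-cell CNV score.

    ``mad`` (default): mean absolute residual — deviation from the reference
    baseline in either direction counts.  ``raw-mean``: literal mean of the
    residuals, which is ≈ constant under centering and kept only for
    comparison.
    """
    if mode == "mad":
        return np.abs(profile.residuals).mean(axis=1)
    if mode == "raw-mean":
        return profile.residuals.mean(axis=1)
    raise ValueError(f"unknown cnv score mode {mode!r}")


@dataclass
class MalignancyCall:
    """Per-cluster CNV evidence and the malignant/benign decision."""

    table: pd.DataFrame     # cluster, n, cnv_score_median, reference_median,
                            # effect, p, p_adj, is_malignant
    reference_median: float
    min_effect: float
    alpha: float


def classify_malignant(
    scores: np.ndarray,
    clusters: pd.Series | np.ndarray,
    reference_mask: np.ndarray,
    min_effect: float,
    alpha: float = 0.01,
    candidate_clusters: list | None = None,
) -> MalignancyCall:
    """Call clusters malignant when their CNV scores exceed the reference.

    Candidate clusters default to all clusters holding non-reference cells;
    in the semi-supervised pipeline they are the tumor-sample clusters.
    Each is compared to the pooled reference scores by a two-sided rank-sum
    test, BH-adjusted across clusters.  Malignant requires BOTH median
    difference > ``min_effect`` and adjusted p ≤ ``alpha``.
    """
    scores = np.asarray(scores, dtype=float)
    clusters = np.asarray(clusters)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    ref_scores = scores[reference_mask]
    ref_median = float(np.median(ref_scores))

    rows = []
    if candidate_clusters is None:
        candidate_labels = sorted(set(clusters[~reference_mask]))
    else:
        candidate_labels = list(candidate_clusters)
    for label in candidate_labels:
        members = (clusters == label) & ~reference_mask
        n = int(members.sum())
        if n == 1:
            logger.warning("cluster %s has a single cell; test degenerate", label)
        member_scores = scores[members]
        stat = stats.mannwhitneyu(member_scores, ref_scores,
                                  alternative="two-sided", method="asymptotic")
        med = float(np.median(member_scores))
        rows.append({"cluster": label, "n": n, "cnv_score_median": med,
                     "reference_median": ref_median, "effect": med - ref_median,
                     "p": float(stat.pvalue)})
    table = pd.DataFrame(rows).set_index("cluster")
    table["p"] = table["p"].fillna(1.0)
    table["p_adj"] = stats.false_discovery_control(table["p"].to_numpy(), method="bh")
    table["is_malignant"] = (table["effect"] > min_effect) & (table["p_adj"] <= alpha)
    return MalignancyCall(table=table, reference_median=ref_median,
                          min_effect=min_effect, alpha=alpha)


def reference_mask_from_meta(cell_meta: pd.DataFrame) -> np.ndarray:
    """Normal epithelial + all endothelial cells, the standard CNV reference."""
    normal_epi = ((cell_meta["phenotype"] == "normal")
                  & (cell_meta["cell_type"] == "epithelial")).to_numpy()
    endo = (cell_meta["cell_type"] == "endothelial").to_numpy()
    return normal_epi | endo
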