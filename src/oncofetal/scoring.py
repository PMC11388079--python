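"""Per-cell oncofetal scoring, the normal-percentile zeroing rule,
fetal-like classification, and a differentiation-potential surrogate.

The raw score is a control-matched module score: genes are binned by mean
expression, each signature gene is compared against randomly drawn control
genes from its own bin, and the per-cell score is the mean signature-minus-
control difference.  Scores are then zeroed below the 95th percentile of
normal cells, and epithelial cells with a surviving positive score are
classified fetal-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .io import CellDataset, NormalizedMatrix
from .pseudobulk import Signature, top_variable_genes

logger = logging.getLogger("oncofetal")


@dataclass
class ScoreVector:
    """Per-cell raw and threshold-adjusted oncofetal scores."""

    raw: pd.Series
    adjusted: pd.Series
    is_fetal_like: pd.Series
    threshold: float
    params: dict = field(default_factory=dict)


def score_cells(
    norm: NormalizedMatrix,
    sig: Signature,
    gene_ids: list[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Control-matched module score per cell.

    Genes with nonzero total expression are ranked by mean expression across
    cells and split into ``n_bins`` near-equal bins.  For each signature
    gene, ``n_ctrl`` control genes are drawn uniformly from its bin
    (excluding the gene itself; with replacement if the bin is smaller).
    The raw score is the mean over signature genes of (gene value − mean
    control value) per cell.  Deterministic given ``seed``.
    """
    lookup = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in sig.genes if g in lookup]
    missing = [g for g in sig.genes if g not in lookup]
    if not present:
        raise ValueError(f"no signature genes present in matrix; missing e.g. {missing[:5]}")
    if missing:
        logger.warning("%d signature genes absent from matrix", len(missing))

    values = norm.values
    gene_means = values.mean(axis=0)
    usable = np.flatnonzero(values.sum(axis=0) > 0)
    order = usable[np.argsort(gene_means[usable], kind="stable")]
    bins = np.array_split(order, min(n_bins, len(order)))
    bin_of = {}
    for b, idx in enumerate(bins):
        for g in idx:
            bin_of[int(g)] = b

    rng = np.random.default_rng(seed)
    sig_idx, ctrl_means = [], []
    for g in present:
        gi = lookup[g]
        if gi not in bin_of:
            logger.warning("signature gene %s has zero total expression; skipped", g)
            continue
        pool = np.array([j for j in bins[bin_of[gi]] if j != gi])
        if len(pool) == 0:
            ctrl = np.zeros(values.shape[0])
        else:
            replace = len(pool) < n_ctrl
            chosen = rng.choice(pool, size=n_ctrl, replace=replace)
            ctrl = values[:, chosen].mean(axis=1)
        sig_idx.append(gi)
        ctrl_means.append(ctrl)
    if not sig_idx:
        raise ValueError("all signature genes have zero total expression")
    diffs = values[:, sig_idx] - np.column_stack(ctrl_means)
    return diffs.mean(axis=1)


def zero_below_normal_percentile(
    raw: np.ndarray,
    normal_mask: np.ndarray,
    pct: float = 95.0,
) -> tuple[np.ndarray, float]:
    """Zero scores at or below the pct-th percentile of normal-cell scores.

    Returns (adjusted scores, threshold).  The threshold uses linear
    interpolation; ties at the threshold are zeroed (strict inequality).
    """
    normal_mask = np.asarray(normal_mask, dtype=bool)
    if not normal_mask.any():
        raise ValueError("normal_mask is empty")
    threshold = float(np.percentile(raw[normal_mask], pct))
    adjusted = np.where(raw > threshold, raw, 0.0)
    return adjusted, threshold


def classify_fetal_like(
    adjusted: np.ndarray,
    cell_meta: pd.DataFrame,
    raw: np.ndarray | None = None,
    threshold: float = np.nan,
    params: dict | None = None,
) -> tuple[ScoreVector, pd.DataFrame]:
    """Fetal-like = positive adjusted score restricted to epithelial cells.

    Returns the ScoreVector and per-sample proportions over epithelial
    cells (samples with no epithelium are excluded with a log note).
    """
    index = cell_meta.index
    adjusted = np.asarray(adjusted, dtype=float)
    epithelial = (cell_meta["cell_type"] == "epithelial").to_numpy()
    is_fl = (adjusted > 0) & epithelial

    rows = []
    for sample, grp in cell_meta.groupby("sample_id", sort=True):
        mask = (cell_meta["sample_id"] == sample).to_numpy() & epithelial
        n = int(mask.sum())
        if n == 0:
            logger.info("sample %s has no epithelial cells; excluded", sample)
            continue
        n_fl = int(is_fl[mask].sum())
        rows.append({"sample_id": sample, "n_cells": n, "n_fetal_like": n_fl,
                     "proportion": 100.0 * n_fl / n})
    proportions = pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame(
        columns=["n_cells", "n_fetal_like", "proportion"])

    sv = ScoreVector(
        raw=pd.Series(raw if raw is not None else adjusted, index=index, name="raw"),
        adjusted=pd.Series(adjusted, index=index, name="adjusted"),
        is_fetal_like=pd.Series(is_fl, index=index, name="is_fetal_like"),
        threshold=float(threshold),
        params=params or {},
    )
    return sv, proportions


def score_dataset(
    ds: CellDataset,
    norm: NormalizedMatrix,
    sig: Signature,
    normal_phenotypes: tuple[str, ...] = ("normal",),
    n_bins: int = 25,
    n_ctrl: int = 50,
    pct: float = 95.0,
    seed: int = 0,
) -> tuple[ScoreVector, pd.DataFrame]:
    """Convenience wrapper: score, zero against normal cells, classify."""
    raw = score_cells(norm, sig, ds.gene_ids, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    normal_mask = ds.cell_meta["phenotype"].isin(normal_phenotypes).to_numpy()
    adjusted, threshold = zero_below_normal_percentile(raw, normal_mask, pct=pct)
    params = {"n_bins": n_bins, "n_ctrl": n_ctrl, "pct": pct, "seed": seed}
    return classify_fetal_like(adjusted, ds.cell_meta, raw=raw,
                               threshold=threshold, params=params)


def differentiation_potential(
    norm: NormalizedMatrix,
    smooth_k: int = 30,
    n_variable: int = 2000,
) -> np.ndarray:
    """Detected-gene count per cell, kNN-smoothed, min-max rescaled to [0, 1].

    A surrogate for transcriptional developmental potential: cells
    expressing more genes score higher.  Smoothing averages each cell with
    its ``smooth_k`` nearest neighbors (Euclidean in the top ``n_variable``
    variable genes).  ``smooth_k=0`` disables smoothing.
    """
    n_cells = norm.values.shape[0]
    if n_cells < 2:
        raise ValueError("need >= 2 cells")
    if smooth_k >= n_cells:
        logger.warning("smooth_k=%d clamped to %d", smooth_k, n_cells - 1)
        smooth_k = n_cells - 1
    gene_counts = (norm.values > 0).sum(axis=1).astype(float)
    if smooth_k > 0:
        cols = top_variable_genes(norm.values, n_variable)
        nn = NearestNeighbors(n_neighbors=smooth_k + 1).fit(norm.values[:, cols])
        _, idx = nn.kneighbors(norm.values[:, cols])
        smoothed = gene_counts[idx].mean(axis=1)   # self + k neighbors
    else:
        smoothed = gene_counts
    lo, hi = smoothed.min(), smoothed.max()
    if hi == lo:
        return np.zeros(n_cells)
    return (smoothed - lo) / (hi - lo)
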