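"""Prioritize core oncofetal regulators from a cell-line panel.

Candidate regulators must both track the fetal-like program (Pearson r of
expression with the per-line oncofetal score above ``r_min``) and be
required for proliferation (mean CRISPR gene-effect at or below
``dep_max``; more negative = more essential).  Passing genes are ranked by
the sum of the two standardized criteria.  Lineage specificity of a single
gene is summarized by the lineage composition of the top-k most dependent
lines among those expressing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pseudobulk import Signature

logger = logging.getLogger("oncofetal")


@dataclass
class CellLinePanel:
    """Cell-line expression (TPM), dependency (gene effect), and lineage."""

    expression: pd.DataFrame        # lines × genes, TPM (>= 0)
    dependency: pd.DataFrame        # lines × genes, gene effect
    line_meta: pd.DataFrame         # indexed by line, with a lineage column

    def __post_init__(self) -> None:
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("TPM expression must be non-negative")
        if not self.expression.index.equals(self.dependency.index):
            common = self.expression.index.intersection(self.dependency.index)
            if len(common) == 0:
                raise ValueError("expression and dependency share no cell lines")
            self.expression = self.expression.loc[common]
            self.dependency = self.dependency.loc[common]


def score_cell_lines(panel: CellLinePanel, sig: Signature) -> pd.Series:
    """Per-line oncofetal score: mean z of log2(TPM+1) over signature genes."""
    genes = [g for g in sig.genes if g in panel.expression.columns]
    if not genes:
        raise ValueError("no signature genes present in the panel")
    log_expr = np.log2(panel.expression[genes].to_numpy() + 1.0)
    sd = log_expr.std(axis=0)
    usable = sd > 0
    if not usable.all():
        logger.warning("%d zero-variance signature genes excluded from line scoring",
                       (~usable).sum())
    if not usable.any():
        raise ValueError("all signature genes have zero variance across lines")
    z = (log_expr[:, usable] - log_expr[:, usable].mean(axis=0)) / sd[usable]
    return pd.Series(z.mean(axis=1), index=panel.expression.index, name="oncofetal_score")


@dataclass
class RegulatorTable:
    """Per-gene association, dependency, annotations and rank."""

    table: pd.DataFrame     # r_oncofetal, mean_dependency, is_rbp, is_tf,
                            # has_dependency, passes_filter, rank
    r_min: float
    dep_max: float

    def top(self, k: int) -> pd.DataFrame:
        ranked = self.table.dropna(subset=["rank"]).sort_values("rank")
        return ranked.head(k)


def associate_regulators(
    panel: CellLinePanel,
    line_scores: pd.Series,
    rbp_set: set[str] | None = None,
    tf_set: set[str] | None = None,
    r_min: float = 0.3,
    dep_max: float = -0.4,
) -> RegulatorTable:
    """Joint expression-association and dependency filter over panel genes.

    Per gene: Pearson r of log2(TPM+1) with the line oncofetal score
    (zero-variance genes get r = 0) and mean dependency over lines with a
    non-missing gene effect.  ``passes_filter`` requires r ≥ r_min AND mean
    dependency ≤ dep_max; passing genes are ranked by the sum of z-scored r
    and z-scored |mean dependency| (descending).
    """
    if len(panel.expression) < 3:
        raise ValueError("need >= 3 cell lines for Pearson correlation")
    rbp_set = rbp_set or set()
    tf_set = tf_set or set()

    scores = line_scores.loc[panel.expression.index].to_numpy(dtype=float)
    log_expr = np.log2(panel.expression.to_numpy() + 1.0)
    xc = log_expr - log_expr.mean(axis=0)
    sc = scores - scores.mean()
    sd_x = log_expr.std(axis=0)
    sd_s = scores.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * sc[:, None]).mean(axis=0) / (sd_x * sd_s)
    r = np.where((sd_x == 0) | (sd_s == 0), 0.0, r)

    dep = panel.dependency.reindex(columns=panel.expression.columns)
    mean_dep = dep.mean(axis=0, skipna=True).to_numpy()
    has_dep = dep.notna().any(axis=0).to_numpy()
    if (~has_dep).any():
        logger.warning("%d genes lack dependency data in every line; excluded "
                       "from ranking", (~has_dep).sum())

    genes = panel.expression.columns
    table = pd.DataFrame({
        "r_oncofetal": r,
        "mean_dependency": mean_dep,
        "is_rbp": [g in rbp_set for g in genes],
        "is_tf": [g in tf_set for g in genes],
        "has_dependency": has_dep,
    }, index=genes)
    degenerate = sd_x == 0
    table["passes_filter"] = (has_dep & ~degenerate
                              & (table["r_oncofetal"] >= r_min)
                              & (table["mean_dependency"] <= dep_max))

    # combined criterion: standardized r + standardized |dependency|,
    # z-scored over genes eligible for ranking
    elig = has_dep
    combined = np.full(len(genes), np.nan)
    if elig.sum() >= 2:
        r_e = r[elig]
        d_e = np.abs(mean_dep[elig])
        z_r = (r_e - r_e.mean()) / (r_e.std() or 1.0)
        z_d = (d_e - d_e.mean()) / (d_e.std() or 1.0)
        combined[elig] = z_r + z_d
    table["combined"] = combined

    table["rank"] = np.nan
    passing = table.index[table["passes_filter"]]
    if len(passing):
        order = table.loc[passing, "combined"].sort_values(ascending=False).index
        table.loc[order, "rank"] = np.arange(1, len(order) + 1, dtype=float)
    return RegulatorTable(table=table, r_min=r_min, dep_max=dep_max)


def lineage_specificity(
    panel: CellLinePanel,
    gene: str,
    tpm_min: float = 1.0,
    dep_max: float = -0.4,
    k: int = 10,
) -> dict:
    """Lineage composition of the top-k most dependent expressing lines.

    Among lines with expression(gene) > tpm_min, rank by ascending gene
    effect (most essential first) and count lineages among the top k.
    ``dep_max`` annotates how many of those lines also clear the
    essentiality bound.
    """
    if gene not in panel.expression.columns or gene not in panel.dependency.columns:
        raise KeyError(f"gene {gene!r} absent from expression or dependency matrix")
    expr = panel.expression[gene]
    dep = panel.dependency[gene]
    qualifying = expr.index[(expr > tpm_min) & dep.notna()]
    if len(qualifying) == 0:
        logger.warning("no cell line expresses %s above TPM %g", gene, tpm_min)
        return {"counts": {}, "top_lines": [], "most_dependent_line": None,
                "n_qualifying": 0, "n_essential": 0}
    if len(qualifying) < k:
        logger.warning("only %d lines qualify (k=%d); counting over all of them",
                       len(qualifying), k)
    ranked = dep.loc[qualifying].sort_values(kind="stable")
    top = ranked.index[:k].tolist()
    lineages = panel.line_meta.loc[top, "lineage"]
    counts = lineages.value_counts().to_dict()
    n_essential = int((dep.loc[top] <= dep_max).sum())
    return {"counts": counts, "top_lines": top,
            "most_dependent_line": top[0], "n_qualifying": int(len(qualifying)),
            "n_essential": n_essential}
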