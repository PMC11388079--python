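"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* :func:`generate_single_cell` — a multi-sample liver cohort (fetal, normal,
  adjacent and tumor samples; epithelial and endothelial cells) with a
  planted fetal-like co-expression program shared by fetal epithelium and a
  fraction of tumor epithelium, segmental copy-number changes in malignant
  cells, negative-binomial UMI counts and extra dropout.
* :func:`generate_cell_line_panel` — a cancer cell-line panel (TPM
  expression + CRISPR gene-effect dependencies) in which planted driver
  genes track the per-line fetal-like score and are strongly essential in
  high-score (liver) lines.
* :func:`generate_bulk_cohort` — a multi-source bulk expression cohort with
  per-sample latent fetal-like scores, score-associated ordinal/binary
  clinical covariates, and exponential survival whose log-hazard increases
  with the score.

Every generator is a pure function of (config, seed): the same seed yields
byte-identical outputs.  Defaults are sized so the whole pipeline runs in
seconds: 600 cells × 2,000 genes on two synthetic chromosomes, a 150-gene
program at log2 fold change 2, a 50-line panel with 3 drivers among 500
genes, and a 360 + 98 two-source survival cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CellDataset
from .regulators import CellLinePanel
from .cohort import BulkCohort


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

def _default_sample_plan() -> list[dict]:
    # (sample, phenotype, n epithelial, n endothelial, fetal-like fraction)
    # 600 cells total; tumor fractions are heterogeneous, as in real cohorts
    # where only fetal-like-rich tumors co-cluster with fetal liver
    plan = [
        ("FL1", "fetal", 60, 10, None),
        ("FL2", "fetal", 50, 10, None),
        ("NL1", "normal", 50, 10, None),
        ("NL2", "normal", 40, 10, None),
        ("ADJ1", "adjacent", 40, 10, None),
        ("ADJ2", "adjacent", 30, 10, None),
        ("HCC1", "tumor_HCC", 60, 10, 0.70),
        ("HCC2", "tumor_HCC", 50, 10, 0.65),
        ("HCC3", "tumor_HCC", 40, 10, 0.60),
        ("HB1", "tumor_HB", 40, 10, 0.70),
        ("ICC1", "tumor_ICC", 30, 10, 0.00),
    ]
    return [
        {"sample_id": s, "phenotype": p, "n_epithelial": ne,
         "n_endothelial": nd, "fetal_like_fraction": fl}
        for s, p, ne, nd, fl in plan
    ]


def _default_cnv_segments() -> list[tuple]:
    # (chromosome, start gene index within chromosome, length, fold change)
    return [("chr1", 100, 150, 2.0), ("chr1", 700, 120, 0.5), ("chr2", 200, 150, 1.5)]


@dataclass
class SynthConfig:
    """Ground-truth parameters for all three generators.

    Single-cell: ``module_genes`` genes (a contiguous block kept clear of CNV
    segments and the endothelial marker block) are multiplied by
    ``2**module_log2fc`` in fetal epithelium and in a ``fetal_like_fraction``
    of tumor epithelial cells; ``malignant_fraction`` of tumor epithelial
    cells (a superset of the fetal-like ones) carry the ``cnv_segments``.
    Counts are gamma-Poisson (negative binomial, shape ``nb_dispersion``)
    around lognormal gene means with lognormal per-cell size factors, then
    zeroed independently with probability ``dropout``.
    """

    n_genes: int = 2000
    sample_plan: list[dict] = field(default_factory=_default_sample_plan)
    module_genes: int = 150
    module_log2fc: float = 2.0
    fetal_like_fraction: float = 0.30       # fallback when the plan sets none
    malignant_fraction: float = 0.75
    adult_genes: int = 150                  # mature-hepatocyte program, lost in
    adult_fold: float = 4.0                 # fetal and fetal-like cells
    cnv_segments: list[tuple] = field(default_factory=_default_cnv_segments)
    endothelial_marker_genes: int = 200
    endothelial_marker_fold: float = 4.0
    nb_mean_log_mu: float = np.log(0.3)
    nb_mean_log_sigma: float = 1.2
    nb_dispersion: float = 2.0
    size_factor_sigma: float = 0.25
    dropout: float = 0.05
    # progenitor-like cells sample a broader transcriptome (CytoTRACE premise):
    # fetal and fetal-like cells get this library-size multiplier, which CP10K
    # normalization cancels except for gene detection
    fetal_breadth_boost: float = 2.0
    # cell-line panel
    panel_plan: dict[str, int] = field(default_factory=lambda: {
        "liver": 15, "lung": 12, "breast": 12, "colon": 11})
    n_panel_genes: int = 500
    n_panel_signature_genes: int = 50
    n_drivers: int = 3
    driver_dependency_mean: float = -1.0
    liver_score_shift: float = 1.0
    driver_expression_noise: float = 0.3
    # bulk cohort
    cohort_plan: dict[str, int] = field(default_factory=lambda: {
        "cohortA": 360, "cohortB": 98})
    n_bulk_genes: int = 500
    n_bulk_signature_genes: int = 150
    bulk_signature_noise: float = 0.5
    dataset_shifts: dict[str, float] = field(default_factory=lambda: {
        "cohortA": 0.0, "cohortB": 1.5})
    log_hr: float = 0.7
    baseline_hazard: float = np.log(2) / 50.0   # median ~50 months at score 0
    censoring_rate: float = 1.0 / 120.0
    admin_censor_time: float = 120.0
    covariate_effects: dict[str, float] = field(default_factory=lambda: {
        "grade": 0.8, "stage": 0.6, "fibrosis": 0.6, "hbv": 0.8})
    seed: int = 0

    def validate(self) -> None:
        if self.module_genes > self.n_genes:
            raise ValueError("module_genes exceeds n_genes")
        if not (0 <= self.fetal_like_fraction <= 1):
            raise ValueError("fetal_like_fraction must be in [0, 1]")
        if not (0 <= self.malignant_fraction <= 1):
            raise ValueError("malignant_fraction must be in [0, 1]")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        for _, _, _, fold in self.cnv_segments:
            if fold <= 0:
                raise ValueError("CNV fold changes must be positive")
        if self.n_drivers < 0:
            raise ValueError("n_drivers must be non-negative")


@dataclass
class GroundTruth:
    """What the generator planted, aligned to the emitted dataset."""

    module_gene_ids: list[str] = field(default_factory=list)
    fetal_like: pd.Series | None = None        # per cell_id, bool
    malignant: pd.Series | None = None         # per cell_id, bool
    cnv_segment_genes: dict[str, list[str]] = field(default_factory=dict)
    driver_gene_ids: list[str] = field(default_factory=list)
    panel_signature_gene_ids: list[str] = field(default_factory=list)
    line_scores: pd.Series | None = None       # per cell line
    bulk_signature_gene_ids: list[str] = field(default_factory=list)
    sample_scores: pd.Series | None = None     # per bulk sample


# ---------------------------------------------------------------------------
# single-cell cohort
# ---------------------------------------------------------------------------

def _gene_layout(config: SynthConfig):
    """Gene ids, positions on 2 equal chromosomes, module/marker indices, CNV map."""
    n = config.n_genes
    half = n // 2
    gene_ids = [f"G{i:04d}" for i in range(n)]
    chroms = ["chr1"] * half + ["chr2"] * (n - half)
    starts = [(i % half if i < half else i - half) * 1000 + 1 for i in range(n)]
    gene_pos = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": [s + 999 for s in starts]},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    chrom_offset = {"chr1": 0, "chr2": half}
    chrom_size = {"chr1": half, "chr2": n - half}
    seg_map: dict[str, np.ndarray] = {}
    for i, (chrom, start, length, fold) in enumerate(config.cnv_segments):
        if chrom not in chrom_offset:
            raise ValueError(f"unknown synthetic chromosome {chrom!r}")
        if start + length > chrom_size[chrom]:
            raise ValueError("CNV segment extends beyond its chromosome")
        seg_map[f"seg{i}_{chrom}_{fold}x"] = chrom_offset[chrom] + np.arange(start, start + length)

    # Program genes are scattered genome-wide (as real transcriptional
    # programs are), kept out of the CNV segments so copy-number truth and
    # program truth stay separable.  The layout permutation is fixed,
    # independent of the data seed.
    in_segment = np.zeros(n, dtype=bool)
    for idx in seg_map.values():
        in_segment[idx] = True
    candidates = np.flatnonzero(~in_segment)
    need = config.module_genes + config.adult_genes + config.endothelial_marker_genes
    if need > len(candidates):
        raise ValueError("gene universe too small for module/adult/marker programs")
    layout = np.random.default_rng(2024).permutation(candidates)
    module_idx = np.sort(layout[:config.module_genes])
    adult_idx = np.sort(layout[config.module_genes:config.module_genes + config.adult_genes])
    marker_idx = np.sort(layout[config.module_genes + config.adult_genes:need])
    return gene_ids, gene_pos, module_idx, marker_idx, adult_idx, seg_map


def generate_single_cell(config: SynthConfig | None = None,
                         seed: int | None = None) -> tuple[CellDataset, GroundTruth]:
    """Simulate the single-cell cohort; deterministic given (config, seed)."""
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    gene_ids, gene_pos, module_idx, marker_idx, adult_idx, seg_map = _gene_layout(config)
    n_genes = config.n_genes
    base_mu = rng.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sigma, size=n_genes)

    rows, cell_ids = [], []
    meta_rows = []
    fetal_like_flags, malignant_flags = [], []
    module_factor = 2.0 ** config.module_log2fc

    for plan in config.sample_plan:
        sample, pheno = plan["sample_id"], plan["phenotype"]
        is_tumor = pheno.startswith("tumor")
        fl_frac = plan.get("fetal_like_fraction")
        if fl_frac is None:
            fl_frac = config.fetal_like_fraction
        for cell_type, n_cells in (("epithelial", plan["n_epithelial"]),
                                   ("endothelial", plan["n_endothelial"])):
            if n_cells == 0:
                continue
            is_malig = np.zeros(n_cells, dtype=bool)
            is_fetal_like = np.zeros(n_cells, dtype=bool)
            if cell_type == "epithelial":
                if pheno == "fetal":
                    is_fetal_like[:] = True
                elif is_tumor:
                    n_fl = int(round(fl_frac * n_cells))
                    # fetal-like tumor cells are drawn from the malignant pool
                    n_malig = max(int(round(config.malignant_fraction * n_cells)), n_fl)
                    is_malig[:n_malig] = True
                    is_fetal_like[:n_fl] = True
            for j in range(n_cells):
                mu = base_mu.copy()
                if cell_type == "endothelial":
                    mu[marker_idx] *= config.endothelial_marker_fold
                if cell_type == "epithelial":
                    if is_fetal_like[j] or pheno == "fetal":
                        mu[module_idx] *= module_factor
                    else:
                        # differentiated epithelium keeps the adult program
                        mu[adult_idx] *= config.adult_fold
                if is_malig[j]:
                    for idx_arr, (_, _, _, fold) in zip(seg_map.values(), config.cnv_segments):
                        mu[idx_arr] = mu[idx_arr] * fold
                sf = rng.lognormal(0.0, config.size_factor_sigma)
                if cell_type == "epithelial" and (is_fetal_like[j] or pheno == "fetal"):
                    sf *= config.fetal_breadth_boost
                lam = rng.gamma(config.nb_dispersion, mu * sf / config.nb_dispersion)
                counts = rng.poisson(lam)
                if config.dropout > 0:
                    counts = counts * (rng.random(n_genes) >= config.dropout)
                cid = f"{sample}_{cell_type[:4]}_{j:03d}"
                cell_ids.append(cid)
                rows.append(counts)
                cluster = f"{sample}_{cell_type}"
                if cell_type == "epithelial" and is_tumor:
                    cluster = f"{sample}_{'malignant' if is_malig[j] else 'benign'}"
                meta_rows.append({"cell_id": cid, "sample_id": sample,
                                  "phenotype": pheno, "cell_type": cell_type,
                                  "cluster": cluster})
            fetal_like_flags.extend(is_fetal_like.tolist())
            malignant_flags.extend(is_malig.tolist())

    counts = np.asarray(rows, dtype=np.int64)
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    ds = CellDataset(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids,
                     cell_meta=meta, gene_pos=gene_pos)
    truth = GroundTruth(
        module_gene_ids=[gene_ids[i] for i in module_idx],
        fetal_like=pd.Series(fetal_like_flags, index=pd.Index(cell_ids, name="cell_id")),
        malignant=pd.Series(malignant_flags, index=pd.Index(cell_ids, name="cell_id")),
        cnv_segment_genes={name: [gene_ids[i] for i in idx] for name, idx in seg_map.items()},
    )
    return ds, truth


# ---------------------------------------------------------------------------
# cell-line panel
# ---------------------------------------------------------------------------

def generate_cell_line_panel(config: SynthConfig | None = None,
                             seed: int | None = None) -> tuple[CellLinePanel, GroundTruth]:
    """Simulate a CCLE/DepMap-style panel with planted essential drivers."""
    config = config or SynthConfig()
    config.validate()
    if config.n_drivers < 1:
        # a driver-free panel is a valid null; allow it
        pass
    rng = np.random.default_rng(config.seed if seed is None else seed)

    lines, lineages = [], []
    for lineage, n in config.panel_plan.items():
        for j in range(n):
            lines.append(f"{lineage.upper()}_{j:02d}")
            lineages.append(lineage)
    n_lines = len(lines)
    shift = np.array([config.liver_score_shift if lg == "liver" else 0.0 for lg in lineages])
    scores = rng.normal(0.0, 1.0, n_lines) + shift

    n_sig = config.n_panel_signature_genes
    n_drv = config.n_drivers
    sig_genes = [f"SIG{i:03d}" for i in range(n_sig)]
    drv_genes = [f"DRIVER{i}" for i in range(n_drv)]
    n_other = config.n_panel_genes - n_sig - n_drv
    other_genes = [f"BG{i:03d}" for i in range(n_other)]
    genes = sig_genes + drv_genes + other_genes

    # log2(TPM+1) space, then back-transformed to TPM
    log_expr = np.empty((n_lines, len(genes)))
    for k in range(n_sig):
        log_expr[:, k] = 3.0 + scores + rng.normal(0, config.bulk_signature_noise, n_lines)
    for k in range(n_drv):
        log_expr[:, n_sig + k] = (2.0 + scores
                                  + rng.normal(0, config.driver_expression_noise, n_lines))
    log_expr[:, n_sig + n_drv:] = rng.normal(3.0, 1.0, (n_lines, n_other))
    expression = pd.DataFrame(np.maximum(2.0 ** log_expr - 1.0, 0.0),
                              index=lines, columns=genes)

    dependency = pd.DataFrame(rng.normal(0.0, 0.15, (n_lines, len(genes))),
                              index=lines, columns=genes)
    high = scores > np.median(scores)
    for k in range(n_drv):
        col = drv_genes[k]
        dep = np.where(high, rng.normal(config.driver_dependency_mean, 0.1, n_lines),
                       rng.normal(0.0, 0.1, n_lines))
        dependency[col] = dep

    line_meta = pd.DataFrame({"lineage": lineages}, index=pd.Index(lines, name="line_id"))
    panel = CellLinePanel(expression=expression, dependency=dependency, line_meta=line_meta)
    truth = GroundTruth(
        driver_gene_ids=drv_genes,
        panel_signature_gene_ids=sig_genes,
        line_scores=pd.Series(scores, index=pd.Index(lines, name="line_id")),
    )
    return panel, truth


# ---------------------------------------------------------------------------
# bulk survival cohort
# ---------------------------------------------------------------------------

def _ordinal_covariate(rng: np.random.Generator, scores: np.ndarray,
                       effect: float, n_levels: int) -> np.ndarray:
    """Ordinal covariate 1..n_levels via a binomial link shifted by the score."""
    p = 1.0 / (1.0 + np.exp(-effect * scores))
    return 1 + rng.binomial(n_levels - 1, p)


def generate_bulk_cohort(config: SynthConfig | None = None,
                         seed: int | None = None) -> tuple[BulkCohort, GroundTruth]:
    """Simulate a multi-source bulk cohort with survival tied to the true score."""
    config = config or SynthConfig()
    config.validate()
    if len(config.cohort_plan) < 2:
        raise ValueError("cohort plan needs >= 2 datasets to exercise the dataset covariate")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    samples, datasets, scores = [], [], []
    for ds_name, n in config.cohort_plan.items():
        mu = config.dataset_shifts.get(ds_name, 0.0)
        s = rng.normal(mu, 1.0, n)
        for j in range(n):
            samples.append(f"{ds_name}_S{j:03d}")
            datasets.append(ds_name)
        scores.append(s)
    score = np.concatenate(scores)
    n_samples = len(samples)
    dataset = np.array(datasets)
    shift = np.array([config.dataset_shifts.get(d, 0.0) for d in dataset])
    centered = score - shift   # within-dataset score drives expression/hazard

    n_sig = config.n_bulk_signature_genes
    sig_genes = [f"BSIG{i:03d}" for i in range(n_sig)]
    other_genes = [f"BBG{i:03d}" for i in range(config.n_bulk_genes - n_sig)]
    expr = np.empty((n_samples, config.n_bulk_genes))
    expr[:, :n_sig] = (shift[:, None] + centered[:, None]
                       + rng.normal(0, config.bulk_signature_noise, (n_samples, n_sig)))
    expr[:, n_sig:] = shift[:, None] + rng.normal(0, 1.0, (n_samples, len(other_genes)))
    expression = pd.DataFrame(expr, index=samples, columns=sig_genes + other_genes)

    eff = config.covariate_effects
    clinical = pd.DataFrame({
        "sample_id": samples,
        "dataset": dataset,
        "grade": _ordinal_covariate(rng, centered, eff.get("grade", 0.0), 4),
        "stage": _ordinal_covariate(rng, centered, eff.get("stage", 0.0), 4),
        "fibrosis": _ordinal_covariate(rng, centered, eff.get("fibrosis", 0.0), 3),
        "hbv": (rng.random(n_samples)
                < 1.0 / (1.0 + np.exp(-eff.get("hbv", 0.0) * centered))).astype(int),
    }).set_index("sample_id")

    hazard = config.baseline_hazard * np.exp(config.log_hr * centered)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, n_samples)
    else:
        censor_time = np.full(n_samples, np.inf)
    censor_time = np.minimum(censor_time, config.admin_censor_time)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-3)   # strictly positive times
    survival = pd.DataFrame({"time": time, "event": event},
                            index=pd.Index(samples, name="sample_id"))

    cohort = BulkCohort(expression=expression, clinical=clinical, survival=survival)
    truth = GroundTruth(
        bulk_signature_gene_ids=sig_genes,
        sample_scores=pd.Series(centered, index=pd.Index(samples, name="sample_id")),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_synthetic_inputs(out_dir: str, config: SynthConfig | None = None,
                           seed: int | None = None) -> None:
    """Generate all three datasets and write them in the pipeline's input formats."""
    import os

    from .io import write_cell_dataset, write_gmt

    config = config or SynthConfig()
    base_seed = config.seed if seed is None else seed
    os.makedirs(out_dir, exist_ok=True)

    ds, truth = generate_single_cell(config, seed=base_seed)
    sc_dir = os.path.join(out_dir, "single_cell")
    write_cell_dataset(ds, sc_dir, dialect="mtx")
    write_gmt({"planted_module": truth.module_gene_ids},
              os.path.join(sc_dir, "truth_module.gmt"))
    pd.DataFrame({"fetal_like": truth.fetal_like, "malignant": truth.malignant}).to_csv(
        os.path.join(sc_dir, "truth_cells.tsv"), sep="\t")

    panel, ptruth = generate_cell_line_panel(config, seed=base_seed + 1)
    panel_dir = os.path.join(out_dir, "cell_lines")
    os.makedirs(panel_dir, exist_ok=True)
    panel.expression.rename_axis("line_id").to_csv(
        os.path.join(panel_dir, "expression_tpm.tsv"), sep="\t")
    panel.dependency.rename_axis("line_id").to_csv(
        os.path.join(panel_dir, "dependency.tsv"), sep="\t")
    panel.line_meta.to_csv(os.path.join(panel_dir, "line_meta.tsv"), sep="\t")
    write_gmt({"planted_drivers": ptruth.driver_gene_ids,
               "panel_signature": ptruth.panel_signature_gene_ids},
              os.path.join(panel_dir, "truth_sets.gmt"))

    cohort, ctruth = generate_bulk_cohort(config, seed=base_seed + 2)
    bulk_dir = os.path.join(out_dir, "bulk")
    os.makedirs(bulk_dir, exist_ok=True)
    cohort.expression.rename_axis("sample_id").to_csv(
        os.path.join(bulk_dir, "expression.tsv"), sep="\t")
    cohort.clinical.to_csv(os.path.join(bulk_dir, "clinical.tsv"), sep="\t")
    cohort.survival.to_csv(os.path.join(bulk_dir, "survival.tsv"), sep="\t")
    write_gmt({"bulk_signature": ctruth.bulk_signature_gene_ids},
              os.path.join(bulk_dir, "truth_signature.gmt"))
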