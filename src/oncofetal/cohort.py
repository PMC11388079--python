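"""Bulk-cohort oncofetal scoring, clinical regressions, and survival splits.

Per-sample scores are mean z-scores of signature genes, standardized within
each source dataset (guarding against batch shifts).  Clinical covariates
are tested by OLS with dataset indicators; the prognostic split uses a
maximally selected log-rank statistic: every admissible score cutoff is
scanned, the |standardized log-rank Z| is maximized, and the p-value comes
from a permutation null so the maximal-selection bias is respected.
Kaplan-Meier curves and the two-group log-rank test go through lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger("oncofetal")


@dataclass
class BulkCohort:
    """Bulk expression + clinical covariates + survival, sample-aligned."""

    expression: pd.DataFrame     # samples × genes, log scale
    clinical: pd.DataFrame       # indexed by sample_id; requires 'dataset'
    survival: pd.DataFrame       # indexed by sample_id; time (months), event 0/1

    def __post_init__(self) -> None:
        if "dataset" not in self.clinical.columns:
            raise ValueError("clinical table must carry a 'dataset' column")
        if self.clinical["dataset"].isna().any() or (self.clinical["dataset"] == "").any():
            raise ValueError("every sample needs a nonempty dataset label")
        t = self.survival["time"].to_numpy(dtype=float)
        e = self.survival["event"].to_numpy()
        if (t <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(np.unique(e)).issubset({0, 1}):
            raise ValueError("event indicator must be 0/1")


def score_bulk_samples(cohort: BulkCohort, sig) -> pd.Series:
    """Mean z-score over signature genes, standardized within each dataset."""
    genes = [g for g in sig.genes if g in cohort.expression.columns]
    if not genes:
        raise ValueError("no signature genes present in the cohort expression matrix")
    out = pd.Series(np.nan, index=cohort.expression.index, name="oncofetal_score")
    for ds_name, idx in cohort.clinical.groupby("dataset").groups.items():
        block = cohort.expression.loc[idx, genes].to_numpy(dtype=float)
        sd = block.std(axis=0)
        usable = sd > 0
        if not usable.all():
            logger.warning("dataset %s: %d zero-variance signature genes excluded",
                           ds_name, (~usable).sum())
        if not usable.any():
            raise ValueError(f"dataset {ds_name}: all signature genes zero-variance")
        z = (block[:, usable] - block[:, usable].mean(axis=0)) / sd[usable]
        out.loc[idx] = z.mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# clinical associations
# ---------------------------------------------------------------------------

def clinical_association(
    scores: pd.Series,
    cohort: BulkCohort,
    parameters: list[str],
) -> pd.DataFrame:
    """OLS of score on each clinical parameter with dataset covariates.

    One regression per parameter: score ~ parameter + dataset indicators.
    Returns coefficient, normal-theory 95% CI, two-sided p, and BH-adjusted
    p across the requested parameters.  Parameters constant within every
    dataset are inestimable and flagged.
    """
    clin = cohort.clinical
    y = scores.loc[clin.index].to_numpy(dtype=float)
    dataset_dummies = pd.get_dummies(clin["dataset"], drop_first=True, dtype=float)

    rows = []
    for param in parameters:
        if param not in clin.columns:
            raise KeyError(f"unknown clinical parameter {param!r}")
        x = pd.to_numeric(clin[param], errors="coerce")
        ok = x.notna().to_numpy()
        if x[ok].nunique() < 2:
            rows.append({"parameter": param, "coefficient": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "estimable": False})
            logger.warning("parameter %s has < 2 observed levels; skipped", param)
            continue
        within_var = x[ok].groupby(clin.loc[ok, "dataset"]).nunique()
        if (within_var <= 1).all():
            rows.append({"parameter": param, "coefficient": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "estimable": False})
            logger.warning("parameter %s constant within every dataset; inestimable",
                           param)
            continue
        X = pd.concat([x.rename("param"), dataset_dummies], axis=1).loc[ok]
        X = sm.add_constant(X.astype(float), has_constant="add")
        fit = sm.OLS(y[ok], X).fit()
        ci = fit.conf_int(alpha=0.05).loc["param"]
        rows.append({"parameter": param,
                     "coefficient": float(fit.params["param"]),
                     "ci_low": float(ci[0]), "ci_high": float(ci[1]),
                     "p": float(fit.pvalues["param"]), "estimable": True})
    table = pd.DataFrame(rows).set_index("parameter")
    est = table["estimable"] & table["p"].notna()
    table["p_adj"] = np.nan
    if est.any():
        table.loc[est, "p_adj"] = stats.false_discovery_control(
            table.loc[est, "p"].to_numpy(), method="bh")
    return table


# ---------------------------------------------------------------------------
# log-rank machinery
# ---------------------------------------------------------------------------

def _logrank_tables(time: np.ndarray, event: np.ndarray):
    """Per-sample incidence tables over the unique event times.

    Returns (at_risk, death) boolean matrices of shape (n_samples, K) where
    K is the number of unique event times, plus the total deaths and
    at-risk counts per event time.
    """
    event_times = np.unique(time[event == 1])
    at_risk = time[:, None] >= event_times[None, :]
    death = (time[:, None] == event_times[None, :]) & (event[:, None] == 1)
    d = death.sum(axis=0).astype(float)
    y = at_risk.sum(axis=0).astype(float)
    return at_risk, death, d, y


def _logrank_z_from_group_counts(y1: np.ndarray, d1: np.ndarray,
                                 d: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized log-rank Z given group-1 at-risk/death counts per event time.

    ``y1``/``d1`` may carry extra leading axes (candidates, permutations).
    Uses the hypergeometric variance with the tie correction
    d (y−d)/(y−1) · y1/y · (1 − y1/y); times with y ≤ 1 contribute nothing.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = d * y1 / y
        tie = np.where(y > 1, d * (y - d) / (y - 1), 0.0)
        var = tie * (y1 / y) * (1.0 - y1 / y)
    u = np.nansum(d1 - expected, axis=-1)
    v = np.nansum(var, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(v > 0, u / np.sqrt(np.maximum(v, 1e-300)), 0.0)
    return z


def logrank_statistic(time: np.ndarray, event: np.ndarray,
                      group: np.ndarray) -> float:
    """Standardized two-group log-rank Z for a boolean group indicator."""
    at_risk, death, d, y = _logrank_tables(np.asarray(time, float),
                                           np.asarray(event, int))
    g = np.asarray(group, dtype=bool).astype(float)
    y1 = g @ at_risk
    d1 = g @ death
    return float(_logrank_z_from_group_counts(y1, d1, d, y))


# ---------------------------------------------------------------------------
# optimal cutpoint
# ---------------------------------------------------------------------------

@dataclass
class CutpointSplit:
    """A maximally selected survival split on the score scale."""

    cutoff: float
    n_high: int
    n_low: int
    logrank_stat: float              # standardized Z at the selected cutoff
    p: float                         # permutation p for max |Z|
    pct_high: int = field(init=False)

    def __post_init__(self) -> None:
        total = self.n_high + self.n_low
        if total == 0:
            raise ValueError("empty split")
        self.pct_high = int(round(100.0 * self.n_high / total))


def split_percent(n_high: int, n_low: int) -> int:
    """Integer percent of samples in the high group (rounded)."""
    return CutpointSplit(cutoff=np.nan, n_high=n_high, n_low=n_low,
                         logrank_stat=np.nan, p=np.nan).pct_high


def _candidate_sizes(scores: np.ndarray, min_prop: float) -> tuple[np.ndarray, np.ndarray]:
    """Distinct cutoffs and the high-group size each induces (score > cutoff)."""
    n = len(scores)
    distinct = np.unique(scores)            # ascending
    m = n - np.searchsorted(np.sort(scores), distinct, side="right")
    min_n = int(np.ceil(min_prop * n))
    ok = (m >= min_n) & (n - m >= min_n)
    return distinct[ok], m[ok]


def optimal_cutpoint(
    scores: pd.Series | np.ndarray,
    survival: pd.DataFrame,
    min_prop: float = 0.1,
    n_permutations: int = 1000,
    seed: int = 0,
) -> CutpointSplit:
    """Maximally selected log-rank cutpoint with a permutation p-value.

    Scans every distinct score value as a candidate cutoff (high group =
    score > cutoff) subject to both groups holding ≥ ``min_prop`` of the
    samples, picks the cutoff maximizing |standardized log-rank Z| (ties →
    lower cutoff), and reports p = (1 + #{permuted max ≥ observed max}) /
    (n_permutations + 1) under random reassignment of scores to samples.
    """
    if not (0 < min_prop < 0.5):
        raise ValueError("min_prop must be in (0, 0.5)")
    scores = np.asarray(scores, dtype=float)
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("need >= 2 events for a cutpoint search")

    cutoffs, sizes = _candidate_sizes(scores, min_prop)
    if len(cutoffs) == 0:
        raise ValueError("no candidate cutoff satisfies the min_prop constraint")

    at_risk, death, d, y = _logrank_tables(time, event)
    at_risk = at_risk.astype(float)
    death = death.astype(float)

    def max_abs_z(order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Z per candidate size for samples taken top-down in ``order``."""
        y1_cum = np.cumsum(at_risk[order], axis=0)
        d1_cum = np.cumsum(death[order], axis=0)
        z = _logrank_z_from_group_counts(y1_cum[sizes - 1], d1_cum[sizes - 1], d, y)
        return z, np.abs(z)

    # observed: order samples by descending score (stable for reproducibility)
    obs_order = np.argsort(-scores, kind="stable")
    z_obs, abs_obs = max_abs_z(obs_order)
    best = int(np.argmax(abs_obs))
    # ties → lower cutoff (larger high group); scan from the end
    best_val = abs_obs[best]
    tied = np.flatnonzero(np.isclose(abs_obs, best_val))
    best = int(tied[np.argmin(cutoffs[tied])])
    observed_max = float(best_val)

    rng = np.random.default_rng(seed)
    n = len(scores)
    exceed = 0
    chunk = max(1, int(4e6 // (n * at_risk.shape[1] + 1)))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        perms = np.argsort(rng.random((b, n)), axis=1)       # b random orders
        y1 = np.cumsum(at_risk[perms], axis=1)[:, sizes - 1, :]
        d1 = np.cumsum(death[perms], axis=1)[:, sizes - 1, :]
        z = _logrank_z_from_group_counts(y1, d1, d, y)
        exceed += int((np.abs(z).max(axis=1) >= observed_max - 1e-12).sum())
        done += b
    p = (1.0 + exceed) / (n_permutations + 1.0)

    n_high = int(sizes[best])
    return CutpointSplit(cutoff=float(cutoffs[best]), n_high=n_high,
                         n_low=n - n_high, logrank_stat=float(z_obs[best]), p=p)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    """Two-group log-rank test with per-group KM step functions."""

    statistic: float          # chi-square, 1 df
    p: float
    curves: dict[str, pd.DataFrame]


def logrank_km(groups: np.ndarray | pd.Series, survival: pd.DataFrame) -> KMResult:
    """Two-group log-rank chi-square (1 df) and KM curves.

    ``groups`` is a binary/boolean label per sample.  With zero events the
    statistic is 0 by convention (warned).
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)

    curves = {}
    for lab in labels:
        mask = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=str(lab))
        sf = kmf.survival_function_
        curves[str(lab)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})

    if event.sum() == 0:
        logger.warning("no events in either group; log-rank statistic set to 0")
        return KMResult(statistic=0.0, p=1.0, curves=curves)
    mask = groups == labels[0]
    if event[mask].sum() == 0 or event[~mask].sum() == 0:
        logger.warning("a group has zero events; log-rank test is one-sided in effect")
    res = logrank_test(time[mask], time[~mask], event_observed_A=event[mask],
                       event_observed_B=event[~mask])
    return KMResult(statistic=float(res.test_statistic), p=float(res.p_value),
                    curves=curves)
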