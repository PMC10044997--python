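"""Test-set evaluation and the cohort's descriptive statistics.

Sensitivity is the fraction of retinal-detachment eyes labelled 2 (true
positives over all test-set RD eyes); specificity the fraction of PVD eyes
labelled 1.  Association in the 2x2 confusion matrix is tested with
Fisher's exact test.  The ROC uses the classifier posterior for label 2 as
the score; because a class-specific-variance QDA can make the score
U-shaped in the underlying features, the score may be centred to its median
(s -> |s - median|) before ROC construction.  Confidence intervals come
from a class-stratified percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """2x2 counts: rows = true class (PVD, RD), columns = label (1, 2)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        counts = np.array(
            [[np.sum((y_true == t) & (y_pred == p)) for p in (1, 2)] for t in (1, 2)]
        )
        return cls(counts)


def sens_spec(cm: ConfusionMatrix) -> tuple[float, float]:
    """(sensitivity, specificity) from the 2x2 confusion matrix."""
    c = cm.counts
    rd_total, pvd_total = c[1].sum(), c[0].sum()
    if rd_total == 0 or pvd_total == 0:
        raise ValueError("both class totals must be positive")
    return float(c[1, 1] / rd_total), float(c[0, 0] / pvd_total)


def fisher_exact(cm: ConfusionMatrix) -> float:
    """Two-sided Fisher's exact p for the 2x2 table."""
    return float(stats.fisher_exact(cm.counts, alternative="two-sided")[1])


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    centered: bool
    fpr_grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    sens_ci_low: np.ndarray = field(default_factory=lambda: np.empty(0))
    sens_ci_high: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("AUC must lie inside its confidence interval")


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    """ROC by threshold sweep; returns thresholds, sens, spec, trapezoid AUC."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    pos = (y == 2).astype(float)
    neg = 1.0 - pos
    tp = np.concatenate([[0.0], np.cumsum(pos)])
    fp = np.concatenate([[0.0], np.cumsum(neg)])
    # keep the last index of each distinct score (threshold boundaries)
    distinct = np.concatenate([np.nonzero(np.diff(s))[0] + 1, [len(s)]])
    keep = np.concatenate([[0], distinct])
    tpr = tp[keep] / max(pos.sum(), 1)
    fpr = fp[keep] / max(neg.sum(), 1)
    thr = np.concatenate([[np.inf], s[distinct - 1]])
    auc = float(np.trapezoid(tpr, fpr))
    return thr, tpr, 1.0 - fpr, auc


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank statistic (ties counted half): fast bootstrap path."""
    pos, neg = scores[labels == 2], scores[labels == 1]
    n1, n2 = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def bootstrap_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 5000,
    center: bool = False,
    seed: int = 0,
    stratified: bool = True,
    fpr_grid: np.ndarray | None = None,
) -> RocResult:
    """ROC with percentile bootstrap confidence intervals.

    If ``center``, scores are transformed to |s - median(s)| (median over
    all test scores) before ROC construction, in each bootstrap replicate
    as well.  The bootstrap resamples (score, label) pairs within each true
    class by default, preserving prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not (np.any(labels == 1) and np.any(labels == 2)):
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: ROC is uninformative (AUC 0.5)")

    def transform(s: np.ndarray) -> np.ndarray:
        return np.abs(s - np.median(s)) if center else s

    thr, sens, spec, auc = _roc_points(transform(scores), labels)

    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(labels == 2)
    idx_neg = np.flatnonzero(labels == 1)
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    aucs = np.empty(n_boot)
    sens_curves = np.empty((n_boot, len(fpr_grid)))
    for b in range(n_boot):
        if stratified:
            take = np.concatenate([
                rng.choice(idx_pos, size=len(idx_pos), replace=True),
                rng.choice(idx_neg, size=len(idx_neg), replace=True),
            ])
        else:
            take = rng.choice(len(scores), size=len(scores), replace=True)
        s_b = transform(scores[take])
        y_b = labels[take]
        aucs[b] = _auc_mann_whitney(s_b, y_b)
        _, tpr_b, spec_b, _ = _roc_points(s_b, y_b)
        sens_curves[b] = np.interp(fpr_grid, 1.0 - spec_b, tpr_b)
    ci_low, ci_high = np.percentile(aucs, [2.5, 97.5])
    ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
    lo_band, hi_band = np.percentile(sens_curves, [2.5, 97.5], axis=0)
    return RocResult(
        thresholds=thr, sensitivity=sens, specificity=spec, auc=auc,
        ci_low=float(ci_low), ci_high=float(ci_high), n_boot=n_boot,
        centered=center, fpr_grid=fpr_grid,
        sens_ci_low=lo_band, sens_ci_high=hi_band,
    )


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def regional_table(eyes) -> pd.DataFrame:
    """Long-format per-scan table: one row per (eye, gaze) with the regional
    irregularity (30-bin total in mm) and eye metadata."""
    from .irregularity import regional_irregularity

    rows = []
    for e in eyes:
        for gaze, spect in e.spectra.items():
            rows.append({
                "eye_id": e.eye_id,
                "diagnosis": e.diagnosis,
                "axial_length_mm": e.axial_length_mm,
                "age_years": e.age_years,
                "gaze": gaze,
                "regional_irregularity_mm": regional_irregularity(spect),
            })
    return pd.DataFrame(rows)


def descriptive_stats(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """The study's descriptive battery on a regional-irregularity table.

    Spearman correlations of axial length with total and regional
    irregularity (overall and per diagnostic group); pooled-variance t-tests
    for group contrasts; one-way ANOVA across the four regions with Tukey
    HSD pairwise flags (observations = scans).  Groups with fewer than 3
    eyes are skipped with a note.
    """
    out: dict = {"alpha": alpha, "skipped": []}
    totals = (
        table.groupby(["eye_id", "diagnosis", "axial_length_mm", "age_years"], sort=False)
        ["regional_irregularity_mm"].sum().reset_index(name="total_irregularity_mm")
    )

    def spearman(df, xcol, ycol):
        rho, p = stats.spearmanr(df[xcol], df[ycol])
        return {"rho": float(rho), "p": float(p), "n": len(df)}

    corr: dict = {"all": spearman(totals, "axial_length_mm", "total_irregularity_mm")}
    for g, df in totals.groupby("diagnosis"):
        if len(df) < 3:
            out["skipped"].append(f"spearman:{g}")
            continue
        corr[g] = spearman(df, "axial_length_mm", "total_irregularity_mm")
    corr_regional: dict = {}
    for gaze, df in table.groupby("gaze"):
        corr_regional[gaze] = spearman(df, "axial_length_mm", "regional_irregularity_mm")
    out["spearman_axial_total"] = corr
    out["spearman_axial_regional"] = corr_regional

    ttests: dict = {}
    groups = {g: df for g, df in totals.groupby("diagnosis")}
    for a, b in (("RD", "PVD"), ("tear", "PVD"), ("RD", "tear")):
        if a in groups and b in groups and len(groups[a]) >= 3 and len(groups[b]) >= 3:
            t, p = stats.ttest_ind(
                groups[a]["total_irregularity_mm"], groups[b]["total_irregularity_mm"],
                equal_var=True,
            )
            ttests[f"{a}_vs_{b}_total"] = {"t": float(t), "p": float(p)}
        else:
            out["skipped"].append(f"ttest:{a}_vs_{b}")
    for gaze, df in table.groupby("gaze"):
        sub = {g: d for g, d in df.groupby("diagnosis")}
        if "RD" in sub and "PVD" in sub and len(sub["RD"]) >= 3 and len(sub["PVD"]) >= 3:
            t, p = stats.ttest_ind(
                sub["RD"]["regional_irregularity_mm"], sub["PVD"]["regional_irregularity_mm"],
                equal_var=True,
            )
            ttests[f"RD_vs_PVD_{gaze}"] = {"t": float(t), "p": float(p)}
    out["ttests"] = ttests

    by_region = [df["regional_irregularity_mm"].to_numpy() for _, df in table.groupby("gaze")]
    region_names = [g for g, _ in table.groupby("gaze")]
    f, p = stats.f_oneway(*by_region)
    out["anova_regions"] = {
        "F": float(f), "p": float(p),
        "df": (len(by_region) - 1, sum(map(len, by_region)) - len(by_region)),
        "means": {g: float(np.mean(v)) for g, v in zip(region_names, by_region)},
        "sds": {g: float(np.std(v, ddof=1)) for g, v in zip(region_names, by_region)},
    }
    tukey = stats.tukey_hsd(*by_region)
    out["tukey"] = {
        f"{region_names[i]}_vs_{region_names[j]}": {
            "p": float(tukey.pvalue[i, j]),
            "significant": bool(tukey.pvalue[i, j] < alpha),
        }
        for i in range(len(region_names)) for j in range(i + 1, len(region_names))
    }
    return out


def summary_ttest(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Pooled two-sample t-test from printed summary statistics."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), float(p)
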