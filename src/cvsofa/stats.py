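"""Discrimination and calibration analysis for ordinal severity scores.

AUROC is the Mann-Whitney statistic (ties count 1/2); variance, confidence
intervals and the paired two-score comparison use DeLong's nonparametric
structural-components method, the field default for correlated ROC curves.
A seeded bootstrap is available as an alternative CI method. Calibration is
reported two ways: observed mortality per integer score level with Wilson
95% intervals, and a univariable logistic recalibration (intercept/slope)
of outcome on score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RocResult",
    "EvalReport",
    "auroc_point",
    "auroc",
    "delong_variance",
    "delong_paired_test",
    "bootstrap_ci",
    "score_mortality_table",
    "calibration_curve",
    "baseline_table",
    "run_validation",
]


@dataclass(frozen=True)
class RocResult:
    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    variance: float

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def _check_binary(outcomes: np.ndarray) -> None:
    if not np.isin(outcomes, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    if outcomes.min() == outcomes.max():
        raise ValueError("outcomes are degenerate (all 0 or all 1)")


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged), as in DeLong's fast algorithm."""
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, outcomes: np.ndarray):
    """AUROC and DeLong structural components V10 (per positive) and V01
    (per negative)."""
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def auroc_point(scores, outcomes) -> float:
    """Mann-Whitney AUROC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    _check_binary(outcomes)
    auc, _, _ = _delong_components(scores, outcomes)
    return float(auc)


def delong_variance(scores, outcomes) -> tuple[float, tuple[float, float]]:
    """DeLong variance of the AUROC and the 95% CI (clipped to [0, 1])."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    _check_binary(outcomes)
    if (outcomes == 1).sum() < 2 or (outcomes == 0).sum() < 2:
        raise ValueError("need at least 2 positives and 2 negatives")
    auc, v10, v01 = _delong_components(scores, outcomes)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    se = np.sqrt(var)
    z = sps.norm.ppf(0.975)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    return float(var), (lo, hi)


def auroc(scores, outcomes) -> RocResult:
    """AUROC point estimate with DeLong 95% CI.

    Falls back to the trivially wide [0, 1] interval (variance NaN) when
    fewer than two positives or negatives make the DeLong variance
    undefined.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    _check_binary(outcomes)
    auc = auroc_point(scores, outcomes)
    n_pos = int((outcomes == 1).sum())
    n_neg = int((outcomes == 0).sum())
    try:
        var, (lo, hi) = delong_variance(scores, outcomes)
    except ValueError:
        var, (lo, hi) = float("nan"), (0.0, 1.0)
    return RocResult(auc, lo, hi, n_pos, n_neg, var)


def delong_paired_test(score_a, score_b, outcomes) -> float:
    """Two-sided p-value for H0: AUROC(A) == AUROC(B) on the same subjects
    (DeLong paired z-test). Identical scores give p = 1."""
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if score_a.shape != score_b.shape:
        raise ValueError("paired scores must have identical length")
    _check_binary(outcomes)
    if (outcomes == 1).sum() < 2 or (outcomes == 0).sum() < 2:
        raise ValueError("need at least 2 positives and 2 negatives")
    auc_a, v10a, v01a = _delong_components(score_a, outcomes)
    auc_b, v10b, v01b = _delong_components(score_b, outcomes)
    m, n = len(v10a), len(v01a)
    var_a = v10a.var(ddof=1) / m + v01a.var(ddof=1) / n
    var_b = v10b.var(ddof=1) / m + v01b.var(ddof=1) / n
    cov = (
        np.cov(v10a, v10b, ddof=1)[0, 1] / m
        + np.cov(v01a, v01b, ddof=1)[0, 1] / n
    )
    var_diff = var_a + var_b - 2 * cov
    if var_diff <= 0:
        return 1.0 if np.isclose(auc_a, auc_b) else 0.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(2.0 * sps.norm.sf(abs(z)))


def bootstrap_ci(
    scores, outcomes, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for the AUROC (alternative to DeLong)."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    _check_binary(outcomes)
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        y = outcomes[idx]
        if y.min() == y.max():
            continue
        aucs.append(auroc_point(scores[idx], y))
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def score_mortality_table(scores, outcomes) -> pd.DataFrame:
    """Distribution and observed mortality per integer score level, with
    Wilson 95% intervals."""
    scores = np.asarray(scores)
    outcomes = np.asarray(outcomes, dtype=int)
    levels = np.unique(scores)
    rows = []
    total = len(scores)
    for lvl in levels:
        mask = scores == lvl
        n = int(mask.sum())
        deaths = int(outcomes[mask].sum())
        lo, hi = proportion_confint(deaths, n, alpha=0.05, method="wilson")
        rows.append(
            {
                "score_level": int(lvl),
                "n": n,
                "proportion": n / total,
                "deaths": deaths,
                "observed_mortality": deaths / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def calibration_curve(scores, outcomes) -> tuple[pd.DataFrame, dict]:
    """Univariable logistic recalibration of outcome on score.

    Returns the per-level calibration table (observed + predicted
    mortality) and a fit summary with intercept, slope, their standard
    errors, and a ``flagged`` marker for degenerate fits (constant score or
    perfect separation); the table's observed part is valid regardless.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    table = score_mortality_table(scores, outcomes)
    fit: dict = {
        "intercept": float("nan"),
        "slope": float("nan"),
        "intercept_se": float("nan"),
        "slope_se": float("nan"),
        "flagged": False,
    }
    if np.ptp(scores) == 0 or outcomes.min() == outcomes.max():
        fit["flagged"] = True
        table["predicted_mortality"] = float("nan")
        return table, fit
    X = sm.add_constant(scores)
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.GLM(outcomes, X, family=sm.families.Binomial()).fit()
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            fit["flagged"] = True
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        fit.update(
            intercept=float(params[0]),
            slope=float(params[1]),
            intercept_se=float(bse[0]),
            slope_se=float(bse[1]),
        )
        if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > 50):
            fit["flagged"] = True  # separation: ML estimate diverges
        lin = fit["intercept"] + fit["slope"] * table["score_level"].to_numpy()
        table["predicted_mortality"] = 1.0 / (1.0 + np.exp(-lin))
    except Exception:
        fit["flagged"] = True
        table["predicted_mortality"] = float("nan")
    return table, fit


def _continuous_test(a: np.ndarray, b: np.ndarray, method: str) -> float:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    if method == "t":
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _categorical_test(flags: np.ndarray, groups: np.ndarray) -> float:
    tab = pd.crosstab(flags, groups)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 1.0
    chi2, p, _, _ = sps.chi2_contingency(tab.to_numpy(), correction=False)
    return float(p)


def baseline_table(
    stays: pd.DataFrame,
    scores: pd.DataFrame,
    continuous_test: str = "t",
) -> pd.DataFrame:
    """Survivors vs non-survivors descriptive comparison.

    Continuous rows report mean +/- SD and a Student t (default) or
    Wilcoxon rank-sum p-value; categorical rows report n (%) and a
    chi-square p-value (no continuity correction).
    """
    df = scores.merge(
        stays[["stay_id", "age_years", "sex", "hospital_death"]], on="stay_id"
    )
    died = df["hospital_death"].to_numpy(dtype=bool)
    rows = []

    def cont(name: str, values: pd.Series) -> None:
        v = values.to_numpy(dtype=float)
        rows.append(
            {
                "variable": name,
                "type": "continuous",
                "overall": f"{np.nanmean(v):.2f} ± {np.nanstd(v, ddof=1):.2f}",
                "survivors": f"{np.nanmean(v[~died]):.2f} ± {np.nanstd(v[~died], ddof=1):.2f}",
                "non_survivors": f"{np.nanmean(v[died]):.2f} ± {np.nanstd(v[died], ddof=1):.2f}",
                "p_value": _continuous_test(v[~died], v[died], continuous_test),
            }
        )

    def cat(name: str, flags: pd.Series) -> None:
        f = flags.to_numpy(dtype=bool)
        def fmt(mask):
            n = int(f[mask].sum())
            return f"{n} ({100.0 * n / max(mask.sum(), 1):.1f}%)"
        rows.append(
            {
                "variable": name,
                "type": "categorical",
                "overall": fmt(np.ones_like(f, dtype=bool)),
                "survivors": fmt(~died),
                "non_survivors": fmt(died),
                "p_value": _categorical_test(f, died),
            }
        )

    cont("age_years", df["age_years"])
    cat("male_sex", df["sex"] == "male")
    cont("map_min", df["map_min"])
    cont("lactate_max", df["lactate_max"])
    cont("max_sustained_neq", df["max_sustained_neq"])
    cat("vasopressor_use", df["any_vasopressor"])
    cont("total_original", df["total_original"])
    cont("total_m3", df["total_m3"])
    return pd.DataFrame(rows)


SCORE_NAMES = [
    "cv_original",
    "cv_m2",
    "cv_m3",
    "total_original",
    "total_m2",
    "total_m3",
]

PAIRED_COMPARISONS = [
    ("cv_m3", "cv_original"),
    ("total_m3", "total_original"),
    ("cv_m2", "cv_original"),
    ("total_m2", "total_original"),
]


@dataclass
class EvalReport:
    """Full validation output: AUROCs with CIs, paired comparisons,
    per-level distribution/mortality and calibration per score."""

    n: int
    mortality: float
    roc: dict[str, RocResult]
    paired_p: dict[str, float]
    distribution: dict[str, pd.DataFrame]
    calibration: dict[str, pd.DataFrame]
    calibration_fit: dict[str, dict]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mortality": self.mortality,
            "auroc": {k: v.as_dict() for k, v in self.roc.items()},
            "paired_p": dict(self.paired_p),
            "calibration_fit": {k: dict(v) for k, v in self.calibration_fit.items()},
            "distribution": {
                k: df.to_dict(orient="records") for k, df in self.distribution.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)


def run_validation(
    scores: pd.DataFrame,
    outcomes,
    score_names: list[str] | None = None,
) -> EvalReport:
    """Run the full discrimination/calibration analysis on a scored cohort.

    ``outcomes`` is the per-row binary in-hospital death indicator aligned
    with ``scores``. Deterministic: identical inputs give byte-identical
    JSON serialization.
    """
    names = score_names or SCORE_NAMES
    outcomes = np.asarray(outcomes, dtype=int)
    if len(outcomes) != len(scores):
        raise ValueError("outcomes must align with scores rows")
    roc = {}
    distribution = {}
    calibration = {}
    calibration_fit = {}
    for name in names:
        vals = scores[name].to_numpy(dtype=float)
        roc[name] = auroc(vals, outcomes)
        distribution[name] = score_mortality_table(vals, outcomes)
        calibration[name], calibration_fit[name] = calibration_curve(vals, outcomes)
    paired = {}
    for a, b in PAIRED_COMPARISONS:
        if a in names and b in names:
            try:
                paired[f"{a}_vs_{b}"] = delong_paired_test(
                    scores[a].to_numpy(dtype=float),
                    scores[b].to_numpy(dtype=float),
                    outcomes,
                )
            except ValueError:
                paired[f"{a}_vs_{b}"] = None  # too few events to compare
    return EvalReport(
        n=len(scores),
        mortality=float(outcomes.mean()),
        roc=roc,
        paired_p=paired,
        distribution=distribution,
        calibration=calibration,
        calibration_fit=calibration_fit,
    )


def write_report(report: EvalReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    dist = pd.concat(
        [df.assign(score=name) for name, df in report.distribution.items()],
        ignore_index=True,
    )
    dist.to_csv(outdir / "distribution_mortality.csv", index=False)
    cal = pd.concat(
        [df.assign(score=name) for name, df in report.calibration.items()],
        ignore_index=True,
    )
    cal.to_csv(outdir / "calibration.csv", index=False)
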