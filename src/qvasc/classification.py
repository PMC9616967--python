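"""Statistical layer: malignancy scoring and group statistics.

Implements the analysis stage that sits on top of the biomarker panel:

* a multivariable logistic malignancy-probability model,
  probability = logit^-1(B + sum_m C_m * P_m) with
  logit^-1(a) = 1 / (1 + exp(-a)), fitted by maximum likelihood;
* ROC analysis with AUC, bootstrap confidence interval and an operating
  point (sensitivity / specificity / PPV / NPV) chosen by Youden's J unless
  a fixed probability threshold is supplied;
* two-sided Wilcoxon rank-sum comparisons of a biomarker between benign and
  malignant groups, optionally within lesion-size strata;
* pairwise Pearson correlations among biomarkers with a low-correlation
  flag at |r| < 0.45.

Missing values are removed listwise per analysis and the retained counts
reported.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = [
    "FEATURE_SETS",
    "PredictionModel",
    "ROCResult",
    "malignancy_probability",
    "fit_model",
    "roc_analysis",
    "compare_groups",
    "correlation_matrix",
    "LOW_CORRELATION_CUTOFF",
]

#: named feature subsets for the prediction-model families
FEATURE_SETS = {
    "new": ["MD_mean", "mvFD", "BA_mean", "SVP"],
    "initial": ["NB", "NV", "VD", "D_mean", "D_max", "DM_mean", "DM_max"],
    "combined": ["MD_mean", "mvFD", "BA_mean", "SVP",
                 "NB", "NV", "VD", "D_mean", "D_max", "DM_mean", "DM_max"],
    "combined_birads": ["MD_mean", "mvFD", "BA_mean", "SVP",
                        "NB", "NV", "VD", "D_mean", "D_max", "DM_mean",
                        "DM_max", "BIRADS"],
}

#: |r| below this marks a low-correlation (nearly independent) biomarker pair
LOW_CORRELATION_CUTOFF = 0.45

_SEPARATION_COEF_LIMIT = 50.0


@dataclass
class PredictionModel:
    """Fitted logistic malignancy model: intercept B, coefficients C_m."""

    intercept: float
    coefficients: dict[str, float]
    features: list[str]
    threshold: float = 0.5
    n_used: int = 0
    n_dropped: int = 0
    separation_flag: bool = False

    def linear_predictor(self, features) -> np.ndarray:
        x = _feature_matrix(features, self.features)
        coefs = np.array([self.coefficients[f] for f in self.features])
        return self.intercept + x @ coefs

    def predict_proba(self, features) -> np.ndarray:
        """Malignancy probability, strictly inside (0, 1)."""
        a = self.linear_predictor(features)
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-a))
        return np.clip(p, np.finfo(float).tiny, np.nextafter(1.0, 0.0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PredictionModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _feature_matrix(features, names: list[str]) -> np.ndarray:
    """Row(s) of feature values in model order; raises naming any missing."""
    if isinstance(features, pd.DataFrame):
        missing = [f for f in names if f not in features.columns]
        if missing:
            raise ValueError(f"missing feature(s): {', '.join(missing)}")
        return features[names].to_numpy(dtype=float)
    if isinstance(features, (dict, pd.Series)):
        missing = [f for f in names if f not in features or
                   (isinstance(features, pd.Series) and pd.isna(features[f]))]
        missing = [f for f in names if f not in dict(features)]
        if missing:
            raise ValueError(f"missing feature(s): {', '.join(missing)}")
        return np.array([[float(features[f]) for f in names]])
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != len(names):
        raise ValueError(f"expected {len(names)} features, got {x.shape[1]}")
    return x


def malignancy_probability(model: PredictionModel, features) -> float | np.ndarray:
    """probability = logit^-1(B + sum C_m P_m) for one lesion or a table.

    ``features`` may be a dict/Series (one lesion -> float), a DataFrame or
    a 2-D array (one probability per row), or a 1-D array in model feature
    order (-> float).
    """
    single = isinstance(features, (dict, pd.Series)) or (
        not isinstance(features, pd.DataFrame)
        and np.ndim(np.asarray(features, dtype=object)) == 1)
    p = model.predict_proba(features)
    return float(p[0]) if single else p


def fit_model(cohort: pd.DataFrame, feature_set: str | list[str] = "combined",
              label_col: str = "label", threshold: float | None = None) -> PredictionModel:
    """Maximum-likelihood logistic fit of label ~ biomarkers.

    ``feature_set`` is a named family ("new", "initial", "combined",
    "combined_birads") or an explicit feature list. Labels may be 0/1 or
    "benign"/"malignant". Rows with any missing feature are dropped
    listwise and counted. Perfect separation is flagged and the coefficients
    reported from a vanishing-ridge refit rather than raising.
    """
    features = FEATURE_SETS[feature_set] if isinstance(feature_set, str) else list(feature_set)
    if isinstance(feature_set, str) and feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; "
                         f"valid: {sorted(FEATURE_SETS)}")
    y = _binary_labels(cohort[label_col])
    X = cohort[features].apply(pd.to_numeric, errors="coerce")
    X = X.replace([np.inf, -np.inf], np.nan)
    keep = X.notna().all(axis=1) & y.notna()
    n_dropped = int((~keep).sum())
    X, y = X[keep], y[keep].astype(int)
    if y.nunique() < 2:
        raise ValueError("both classes must be present to fit the model")
    if len(y) <= len(features):
        raise ValueError("need more observations than features")

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=Warning)
            res = sm.Logit(y.to_numpy(), sm.add_constant(X.to_numpy())).fit(
                disp=0, maxiter=200)
        params = res.params
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > _SEPARATION_COEF_LIMIT:
            raise RuntimeError("diverging coefficients")
    except Exception:
        # (quasi-)separation or non-convergence: negligible-ridge refit
        separation = True
        clf = LogisticRegression(penalty="l2", C=1e6, max_iter=5000)
        clf.fit(X.to_numpy(), y.to_numpy())
        params = np.concatenate([clf.intercept_, clf.coef_[0]])
        warnings.warn("perfect or quasi-perfect separation detected; "
                      "coefficients from a vanishing-ridge refit", stacklevel=2)

    model = PredictionModel(
        intercept=float(params[0]),
        coefficients={f: float(c) for f, c in zip(features, params[1:])},
        features=features,
        n_used=int(len(y)),
        n_dropped=n_dropped,
        separation_flag=separation,
    )
    if threshold is not None:
        model.threshold = float(threshold)
    else:
        probs = model.predict_proba(X)
        model.threshold = float(_youden_threshold(probs, y.to_numpy()))
    return model


def _binary_labels(col: pd.Series) -> pd.Series:
    if col.dtype == object or str(col.dtype) == "string":
        mapping = {"benign": 0, "malignant": 1, "0": 0, "1": 1}
        return col.astype(str).str.lower().map(mapping)
    return col.astype(float)


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    return thr[int(np.argmax(j))]


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_positive: int
    n_negative: int
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lo, hi = self.auc_ci
        return (f"AUC {100*self.auc:.1f}% (95% CI: {100*lo:.0f}-{100*hi:.0f}%)"
                f" | Sen {100*self.sensitivity:.1f}% | Sp {100*self.specificity:.1f}%"
                f" | PPV {100*self.ppv:.1f}% | NPV {100*self.npv:.1f}%"
                f" | threshold {self.threshold:.3f}"
                f" (M={self.n_positive}, B={self.n_negative})")


def roc_analysis(scores, labels, threshold: float | None = None,
                 n_boot: int = 2000, seed: int | None = 0,
                 alpha: float = 0.05) -> ROCResult:
    """Empirical ROC with trapezoidal AUC, bootstrap CI and operating point.

    The operating point maximizes Youden's J unless ``threshold`` is given;
    predictions use score >= threshold. The AUC confidence interval is a
    seeded nonparametric percentile bootstrap over lesions.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(_binary_labels(pd.Series(labels)), dtype=float)
    ok = np.isfinite(scores) & np.isfinite(labels)
    scores, labels = scores[ok], labels[ok].astype(int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis requires both classes")

    fpr, tpr, _ = roc_curve(labels, scores)
    a = float(_trapezoid_auc(fpr, tpr))
    thr = float(threshold) if threshold is not None else float(
        _youden_threshold(scores, labels))

    pred = scores >= thr
    tp = int(np.sum(pred & (labels == 1)))
    fn = n_pos - tp
    fp = int(np.sum(pred & (labels == 0)))
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg
    ppv = tp / (tp + fp) if tp + fp else math.nan
    npv = tn / (tn + fn) if tn + fn else math.nan

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(labels), len(labels))
        yb = labels[idx]
        if yb.min() == yb.max():
            continue
        fb, tb, _ = roc_curve(yb, scores[idx])
        boots.append(_trapezoid_auc(fb, tb))
    if boots:
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:  # pragma: no cover - degenerate resampling
        lo = hi = a
    return ROCResult(auc=a, auc_ci=(float(lo), float(hi)), threshold=thr,
                     sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
                     n_positive=n_pos, n_negative=n_neg, fpr=fpr, tpr=tpr)


# --------------------------------------------------------------------------
# group comparison and correlation
# --------------------------------------------------------------------------

def compare_groups(cohort: pd.DataFrame, biomarker: str,
                   label_col: str = "label",
                   strata_col: str | None = None) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of a biomarker, per stratum.

    Returns one row per stratum (plus an unstratified "all" row when
    ``strata_col`` is given) with group sizes, means, 95% CIs of the mean
    and the rank-sum p-value. The exact permutation distribution is used
    for small untied samples (scipy default). Strata with fewer than two
    observations in either group are skipped with a note.
    """
    y = _binary_labels(cohort[label_col])
    vals = pd.to_numeric(cohort[biomarker], errors="coerce")
    vals = vals.replace([np.inf, -np.inf], np.nan)

    strata: list[tuple[str, pd.Series]] = [("all", pd.Series(True, index=cohort.index))]
    if strata_col is not None:
        for s in sorted(cohort[strata_col].dropna().unique(), key=str):
            strata.append((str(s), cohort[strata_col] == s))

    rows = []
    for name, sel in strata:
        keep = sel & vals.notna() & y.notna()
        g0 = vals[keep & (y == 0)].to_numpy()
        g1 = vals[keep & (y == 1)].to_numpy()
        row = {"stratum": name, "biomarker": biomarker,
               "n_benign": len(g0), "n_malignant": len(g1)}
        if len(g0) < 2 or len(g1) < 2:
            row.update(p_value=math.nan, note="skipped: <2 observations per group")
            rows.append(row)
            continue
        stat = stats.mannwhitneyu(g0, g1, alternative="two-sided")
        for grp, g in (("benign", g0), ("malignant", g1)):
            m = float(np.mean(g))
            sem = float(np.std(g, ddof=1) / np.sqrt(len(g))) if len(g) > 1 else 0.0
            h = 1.959963984540054 * sem
            row[f"mean_{grp}"] = m
            row[f"ci95_lo_{grp}"] = m - h
            row[f"ci95_hi_{grp}"] = m + h
        row["p_value"] = float(stat.pvalue)
        row["note"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_matrix(cohort: pd.DataFrame,
                       biomarkers: list[str] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations among biomarkers.

    Returns (r, low_flag): a symmetric unit-diagonal correlation matrix and
    a boolean matrix flagging |r| < 0.45 pairs (nearly independent
    contributions). Requires >= 3 complete rows; zero-variance features get
    NaN against every partner.
    """
    if biomarkers is None:
        biomarkers = [c for c in cohort.columns
                      if c in ("NB", "NV", "VD", "D_mean", "D_max", "DM_mean",
                               "DM_max", "MD_mean", "MD_max", "mvFD",
                               "BA_mean", "BA_max", "VDR", "SVP")]
    X = cohort[biomarkers].apply(pd.to_numeric, errors="coerce")
    X = X.replace([np.inf, -np.inf], np.nan).dropna()
    if len(X) < 3:
        raise ValueError("need at least 3 complete rows for correlations")
    r = X.corr(method="pearson")
    for c in biomarkers:  # unit diagonal even for constant columns
        if X[c].nunique() > 1:
            r.loc[c, c] = 1.0
    low = r.abs() < LOW_CORRELATION_CUTOFF
    low &= r.notna()
    np.fill_diagonal(low.values, False)
    return r, low
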