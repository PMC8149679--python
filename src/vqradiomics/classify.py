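"""Glioma-grade classification on codeword histograms.

A logistic regression relates the per-volume codeword counts to the binary
grade (HGG-like = positive class):

    logit(p) = beta_0 + sum_k beta_k c_k

The counts are standardized before fitting. The maximum-likelihood fit is
unregularized; when the classes are perfectly separable (common at desk
scale, where histograms are strongly informative) the fit falls back to an
l2-penalized fit with a warning. Per-codeword significance uses the effect
likelihood-ratio test: refit without the codeword and compare twice the
objective difference to chi-square(1). Codewords that are significant and
whose count distributions differ between grades by a rank test (gated by
Shapiro–Wilk normality checks) become the grade's *responsible vectors*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .histogram import HistogramFeature

__all__ = [
    "GradeModel",
    "EffectLRResult",
    "ResponsibleVectorSet",
    "ClassificationReport",
    "fit_grade_model",
    "effect_lr_test",
    "univariate_lr_test",
    "identify_responsible_vectors",
    "crossvalidate",
    "performance_under_perturbation",
    "metrics_from_confusion",
]


def counts_matrix(histograms: list[HistogramFeature]) -> np.ndarray:
    return np.stack([h.counts for h in histograms]).astype(np.float64)


def grades_vector(histograms: list[HistogramFeature]) -> np.ndarray:
    g = np.array([h.grade for h in histograms])
    if np.any(g == None):  # noqa: E711 - object comparison on purpose
        raise ValueError("all volumes need a grade label")
    return g.astype(int)


@dataclass
class GradeModel:
    intercept: float
    coefficients: np.ndarray  # per codeword, on the standardized scale
    feature_subset: np.ndarray  # codeword indices entering the model
    regularization: str  # {"none", "l2"}
    l2_lambda: float
    feature_means: np.ndarray
    feature_stds: np.ndarray
    objective: float  # log-likelihood (penalized when regularized)
    converged: bool
    n_samples: int

    def _standardize(self, counts: np.ndarray) -> np.ndarray:
        return (counts[:, self.feature_subset] - self.feature_means) / self.feature_stds

    def decision(self, counts: np.ndarray) -> np.ndarray:
        return self.intercept + self._standardize(np.atleast_2d(counts)) @ self.coefficients

    def predict_proba(self, counts: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(counts)))

    def predict(self, counts: np.ndarray) -> np.ndarray:
        return (self.predict_proba(counts) >= 0.5).astype(int)


def _log_likelihood(x: np.ndarray, y: np.ndarray, intercept: float,
                    coef: np.ndarray) -> float:
    eta = intercept + x @ coef
    # log(1 + exp(eta)) computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def penalized_objective(x: np.ndarray, y: np.ndarray, intercept: float,
                        coef: np.ndarray, l2_lambda: float) -> float:
    """Log-likelihood minus (lambda/2)||coef||^2 (intercept unpenalized)."""
    return _log_likelihood(x, y, intercept, coef) - 0.5 * l2_lambda * float(coef @ coef)


def _fit_l2(x: np.ndarray, y: np.ndarray, l2_lambda: float):
    lr = LogisticRegression(C=1.0 / l2_lambda, solver="lbfgs",
                            tol=1e-12, max_iter=10000)
    lr.fit(x, y)
    return float(lr.intercept_[0]), lr.coef_[0].astype(np.float64)


def _fit_mle(x: np.ndarray, y: np.ndarray):
    """Unregularized maximum-likelihood logistic fit; None on separation."""
    import statsmodels.api as sm
    x1 = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.Logit(y, x1).fit(disp=0, maxiter=500)
        except Exception:
            return None
    params = np.asarray(res.params, dtype=np.float64)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    return float(params[0]), params[1:]


def fit_grade_model(histograms: list[HistogramFeature], grades=None,
                    regularization: str = "auto", l2_lambda: float = 1.0,
                    feature_subset=None) -> GradeModel:
    """Fit the logistic grade model on standardized codeword counts."""
    x_raw = counts_matrix(histograms)
    y = np.asarray(grades if grades is not None else grades_vector(histograms), dtype=int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two volumes per class")
    subset = (np.arange(x_raw.shape[1]) if feature_subset is None
              else np.asarray(feature_subset, dtype=int))
    xs = x_raw[:, subset]
    mu = xs.mean(axis=0)
    sd = xs.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    x = (xs - mu) / sd

    mode = regularization
    fit = None
    if mode not in ("auto", "none", "l2"):
        raise ValueError(f"unknown regularization {regularization!r}")
    if mode in ("auto", "none"):
        fit = _fit_mle(x, y)
        if fit is None:
            if mode == "none":
                warnings.warn(
                    "maximum-likelihood fit failed (perfect separation?); "
                    f"falling back to l2(lambda={l2_lambda})", RuntimeWarning,
                    stacklevel=2)
            mode = "l2"
        else:
            mode = "none"
    if fit is None:
        fit = _fit_l2(x, y, l2_lambda)
    intercept, coef = fit
    lam = l2_lambda if mode == "l2" else 0.0
    return GradeModel(
        intercept=intercept,
        coefficients=coef,
        feature_subset=subset,
        regularization=mode,
        l2_lambda=lam,
        feature_means=mu,
        feature_stds=sd,
        objective=penalized_objective(x, y, intercept, coef, lam),
        converged=True,
        n_samples=len(y),
    )


@dataclass
class EffectLRResult:
    statistic: np.ndarray  # per codeword
    p_value: np.ndarray


def effect_lr_test(model: GradeModel, histograms: list[HistogramFeature],
                   grades=None) -> EffectLRResult:
    """Effect likelihood-ratio test for every codeword in the model.

    For codeword k the model is refit without it; the statistic
    2*(objective_full - objective_reduced) is referred to chi-square(1).
    No multiplicity correction is applied. Under the l2 fallback the
    penalized objective is used consistently, which keeps the statistic
    nonnegative.
    """
    x_raw = counts_matrix(histograms)
    y = np.asarray(grades if grades is not None else grades_vector(histograms), dtype=int)
    k_all = model.feature_subset
    stats = np.full(x_raw.shape[1], np.nan)
    pvals = np.full(x_raw.shape[1], np.nan)
    for pos, k in enumerate(k_all):
        keep = np.delete(k_all, pos)
        try:
            reduced = fit_grade_model(
                histograms, y,
                regularization=model.regularization,
                l2_lambda=model.l2_lambda if model.regularization == "l2" else 1.0,
                feature_subset=keep,
            )
        except Exception:  # pragma: no cover - non-convergent reduced fit
            warnings.warn(f"reduced fit without codeword {k} failed", RuntimeWarning,
                          stacklevel=2)
            continue
        stat = 2.0 * (model.objective - reduced.objective)
        if stat < -1e-6:
            warnings.warn(
                f"negative LR statistic {stat:.3g} for codeword {k}", RuntimeWarning,
                stacklevel=2)
        stat = max(stat, 0.0)
        stats[k] = stat
        pvals[k] = sps.chi2.sf(stat, df=1)
    return EffectLRResult(statistic=stats, p_value=pvals)


def univariate_lr_test(histograms: list[HistogramFeature], grades=None) -> EffectLRResult:
    """Marginal effect likelihood-ratio test per codeword.

    Each codeword's counts enter a single-covariate logistic model that is
    compared against the intercept-only model: 2*(l_k - l_null) is referred
    to chi-square(1). When a codeword separates the classes completely the
    supremum of the likelihood is 1, so l_k = 0 exactly (the limiting
    unregularized fit). Unlike the leave-one-out test, this marginal test
    retains power when several informative codewords are correlated, which
    is the typical desk-scale regime.
    """
    x_all = counts_matrix(histograms)
    y = np.asarray(grades if grades is not None else grades_vector(histograms), dtype=int)
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    ll_null = n1 * np.log(n1 / n) + n0 * np.log(n0 / n)
    stats = np.zeros(x_all.shape[1])
    pvals = np.ones(x_all.shape[1])
    for k in range(x_all.shape[1]):
        xk = x_all[:, k]
        if np.ptp(xk) == 0:  # constant covariate carries no information
            stats[k], pvals[k] = 0.0, 1.0
            continue
        sd = xk.std()
        xs = (xk - xk.mean()) / sd
        if (xs[y == 0].max() < xs[y == 1].min()
                or xs[y == 1].max() < xs[y == 0].min()):
            llk = 0.0  # complete separation: likelihood supremum is 1
        else:
            fit = _fit_mle(xs[:, None], y)
            if fit is None:  # quasi-separation: supremum approached at the boundary
                llk = 0.0
            else:
                llk = _log_likelihood(xs[:, None], y, fit[0], fit[1])
        stat = max(2.0 * (llk - ll_null), 0.0)
        stats[k] = stat
        pvals[k] = sps.chi2.sf(stat, df=1)
    return EffectLRResult(statistic=stats, p_value=pvals)


@dataclass
class ResponsibleVectorSet:
    """Codewords significantly tied to one grade or the other."""

    lgg_responsible: list[int]
    hgg_responsible: list[int]
    records: pd.DataFrame  # per-candidate test results
    alpha: float
    test_used: str

    def side(self, grade_side: str) -> list[int]:
        if grade_side.upper() == "HGG":
            return self.hgg_responsible
        if grade_side.upper() == "LGG":
            return self.lgg_responsible
        raise ValueError(f"unknown side {grade_side!r}")


def identify_responsible_vectors(histograms: list[HistogramFeature], grades=None,
                                 lr_pvalues: np.ndarray | None = None,
                                 alpha: float = 0.05,
                                 test: str = "rank-sum",
                                 correction: str = "none",
                                 exclude: tuple[int, ...] = ()) -> ResponsibleVectorSet:
    """Split significant codewords into LGG- and HGG-responsible sets.

    Candidates are codewords with LR-test p < alpha. Normality of the
    per-class count distributions is checked (and recorded) with
    Shapiro–Wilk; the class comparison itself uses the Mann–Whitney
    rank-sum test by default (``test="signed-rank"`` pairs sorted
    subsamples of equal size and applies the Wilcoxon signed-rank test
    instead). A candidate joins the responsible set of the class in which
    its counts are significantly more frequent.

    ``correction="bh"`` applies a Benjamini–Hochberg step-up over the K
    LR p-values before the candidate cut. Strongly informative codewords
    sit many orders of magnitude below alpha, so this prunes chance
    admissions without touching genuine effects.
    """
    if lr_pvalues is None:
        raise ValueError("lr_pvalues (effect LR test) are required")
    x = counts_matrix(histograms)
    y = np.asarray(grades if grades is not None else grades_vector(histograms), dtype=int)
    pvals = np.asarray(lr_pvalues, dtype=float)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        ok = np.isfinite(pvals)
        sig = np.zeros_like(pvals, dtype=bool)
        if ok.any():
            sig[ok] = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")[0]
    elif correction in (None, "none"):
        sig = pvals < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    candidates = [int(k) for k in np.flatnonzero(sig) if k not in exclude]
    rows = []
    lgg, hgg = [], []
    for k in candidates:
        c0 = x[y == 0, k]
        c1 = x[y == 1, k]
        sw0 = sw1 = np.nan
        for cls, arr in ((0, c0), (1, c1)):
            if arr.size < 3:
                warnings.warn(
                    f"class {cls} has fewer than 3 volumes; normality test skipped",
                    RuntimeWarning, stacklevel=2)
                continue
            try:
                p = float(sps.shapiro(arr).pvalue)
            except Exception:
                p = np.nan
            if cls == 0:
                sw0 = p
            else:
                sw1 = p
        if np.all(c0 == c0[0]) and np.all(c1 == c1[0]) and c0[0] == c1[0]:
            comp_p, direction = 1.0, None
        elif test == "rank-sum":
            comp_p = float(sps.mannwhitneyu(c1, c0, alternative="two-sided").pvalue)
            direction = None
        elif test == "signed-rank":
            n = min(c0.size, c1.size)
            a = np.sort(c1)[:n]
            b = np.sort(c0)[:n]
            if np.all(a == b):
                comp_p = 1.0
            else:
                comp_p = float(sps.wilcoxon(a, b).pvalue)
            direction = None
        else:
            raise ValueError(f"unknown test {test!r}")
        if comp_p < alpha:
            direction = "HGG" if np.median(c1) > np.median(c0) or (
                np.median(c1) == np.median(c0) and c1.mean() > c0.mean()
            ) else "LGG"
            (hgg if direction == "HGG" else lgg).append(k)
        rows.append({
            "codeword": k,
            "lr_p": float(np.asarray(lr_pvalues)[k]),
            "comparison_p": comp_p,
            "shapiro_p_lgg": sw0,
            "shapiro_p_hgg": sw1,
            "mean_count_lgg": float(c0.mean()),
            "mean_count_hgg": float(c1.mean()),
            "direction": direction,
        })
    records = pd.DataFrame(
        rows, columns=["codeword", "lr_p", "comparison_p", "shapiro_p_lgg",
                       "shapiro_p_hgg", "mean_count_lgg", "mean_count_hgg",
                       "direction"])
    return ResponsibleVectorSet(lgg_responsible=lgg, hgg_responsible=hgg,
                                records=records, alpha=alpha, test_used=test)


# ---------------------------------------------------------------------- #
# evaluation


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy, precision, recall, specificity and NPV (HGG positive)."""
    def ratio(a, b):
        return a / b if b else np.nan

    return {
        "accuracy": ratio(tp + tn, tp + fp + fn + tn),
        "precision": ratio(tp, tp + fp),
        "recall": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "npv": ratio(tn, tn + fn),
    }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    return tp, fp, fn, tn


@dataclass
class ClassificationReport:
    per_fold: pd.DataFrame
    mean: dict[str, float]
    std: dict[str, float]
    final_model: GradeModel | None = None

    def summary(self) -> dict[str, str]:
        return {k: f"{self.mean[k]:.3f} ± {self.std[k]:.3f}" for k in self.mean}


_METRICS = ["accuracy", "precision", "recall", "specificity", "npv"]


def crossvalidate(histograms: list[HistogramFeature], grades=None, k_folds: int = 5,
                  seed: int = 0, regularization: str = "auto",
                  l2_lambda: float = 1.0) -> ClassificationReport:
    """Stratified k-fold cross-validation, then a final refit on all samples."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    x = counts_matrix(histograms)
    y = np.asarray(grades if grades is not None else grades_vector(histograms), dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold} lacks one of the classes")
        model = fit_grade_model([histograms[i] for i in tr], y[tr],
                                regularization=regularization, l2_lambda=l2_lambda)
        pred = model.predict(x[te])
        tp, fp, fn, tn = _confusion(y[te], pred)
        rows.append({"fold": fold, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                     **metrics_from_confusion(tp, fp, fn, tn)})
    per_fold = pd.DataFrame(rows)
    final = fit_grade_model(histograms, y, regularization=regularization,
                            l2_lambda=l2_lambda)
    return ClassificationReport(
        per_fold=per_fold,
        mean={m: float(np.nanmean(per_fold[m])) for m in _METRICS},
        std={m: float(np.nanstd(per_fold[m])) for m in _METRICS},
        final_model=final,
    )


def performance_under_perturbation(volumes, net, model: GradeModel,
                                   kinds: tuple[str, ...] = ("scale", "shift"),
                                   magnitudes: tuple[float, ...] = (0.0, 0.5, 1.0),
                                   target_size=None) -> pd.DataFrame:
    """Evaluate a fixed grade model on histograms of perturbed volumes."""
    from .histogram import PerturbationSpec, extract_histogram
    from .pipeline import PreprocessedVolume, preprocess_volume

    pres = [
        v if isinstance(v, PreprocessedVolume) else preprocess_volume(v, target_size)
        for v in volumes
    ]
    y = np.array([p.grade for p in pres], dtype=int)
    rows = []
    for kind in kinds:
        for mag in magnitudes:
            spec = PerturbationSpec(kind=kind, magnitude=float(mag))
            hists = [extract_histogram(p, net, perturbation=spec) for p in pres]
            pred = model.predict(counts_matrix(hists))
            tp, fp, fn, tn = _confusion(y, pred)
            rows.append({"kind": kind, "magnitude": float(mag),
                         "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                         **metrics_from_confusion(tp, fp, fn, tn)})
    return pd.DataFrame(rows)
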