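"""Site assignment by linear discriminant / canonical variate analysis.

A fitted model holds per-site centroids, the pooled within-site
covariance, and the canonical axes (generalized eigenvectors of the
between- vs within-site scatter, with proportion of trace per axis).
Classification assigns each sample to the site with the highest Gaussian
discriminant score, which under equal priors is the nearest centroid in
Mahalanobis distance. Accuracy is validated by bootstrap
cross-validation (within-class resampling, out-of-bag evaluation), and a
model fitted on one year can be frozen and used to predict another
year's samples, scored both exactly and with a geographic distance
tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.stats as st

logger = logging.getLogger(__name__)

__all__ = [
    "LDAModel",
    "fit_lda",
    "predict",
    "BootstrapCVResult",
    "bootstrap_cv_accuracy",
    "loo_cv_accuracy",
    "mahalanobis_site_distance",
    "pool_sites",
    "suggest_pooling",
    "consensus_assign",
    "CrossYearResult",
    "cross_year_predict",
    "confusion_matrix",
    "accuracy_from_confusion",
    "tolerant_accuracy_from_confusion",
    "year_shift_test",
]

#: condition-number threshold beyond which the pooled covariance is ridged
_COND_MAX = 1e8


@dataclass
class LDAModel:
    classes: np.ndarray               # sorted site labels
    centroids: np.ndarray             # k x p grand means per class
    pooled_cov: np.ndarray            # p x p within-class covariance
    priors: np.ndarray                # k, sum to 1
    axes: np.ndarray                  # p x d canonical axes
    prop_trace: np.ndarray            # d, proportion of trace per axis
    feature_names: list = field(default_factory=list)
    ridge: float = 0.0
    n_per_class: np.ndarray | None = None

    @property
    def discriminant_basis(self) -> np.ndarray:
        return self.axes

    def scores(self, X) -> pd.DataFrame:
        """Canonical (LD) scores of samples, centered on the grand mean."""
        Xa, index = _as_array(X, self.feature_names)
        grand = self.priors @ self.centroids
        S = (Xa - grand) @ self.axes
        cols = [f"LD{i+1}" for i in range(S.shape[1])]
        return pd.DataFrame(S, index=index, columns=cols)


def _as_array(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        if feature_names:
            missing = [c for c in feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"feature matrix missing columns {missing}")
            X = X[feature_names]
        return X.to_numpy(float), list(X.index)
    Xa = np.asarray(X, dtype=float)
    return Xa, list(range(len(Xa)))


def fit_lda(matrix, labels, ridge: float | None = None,
            priors: str = "equal") -> LDAModel:
    """Fit centroids, pooled covariance and canonical axes.

    Parameters
    ----------
    matrix : samples x features (DataFrame or array), complete cases.
    labels : per-sample site labels, aligned with matrix rows.
    ridge : explicit ridge added to the pooled covariance diagonal;
        default ``None`` applies ``1e-6 * trace/p`` only when the
        condition number exceeds 1e8 (always logged).
    priors : "equal" (default; sites are compared, not prevalences) or
        "empirical".
    """
    Xa, index = _as_array(matrix)
    y = np.asarray(pd.Series(labels).astype(str))
    if len(y) != len(Xa):
        raise ValueError("labels length does not match matrix rows")
    keep = ~np.isnan(Xa).any(axis=1)
    Xa, y = Xa[keep], y[keep]
    classes, inv = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    n, p = Xa.shape
    k = len(classes)
    counts = np.bincount(inv)
    small = classes[counts < 2]
    if len(small):
        raise ValueError(f"class(es) with < 2 samples: {list(small)}")
    if p >= n - k:
        warnings.warn(f"p = {p} >= n - k = {n - k}; forcing regularization")
        if ridge is None:
            ridge = 0.0  # trigger the automatic ridge below

    centroids = np.vstack([Xa[inv == i].mean(0) for i in range(k)])
    W = np.zeros((p, p))
    for i in range(k):
        diff = Xa[inv == i] - centroids[i]
        W += diff.T @ diff
    W /= (n - k)

    auto = 1e-6 * np.trace(W) / p
    if ridge is None:
        if np.linalg.cond(W) > _COND_MAX:
            ridge = auto
            logger.info("pooled covariance ill-conditioned; ridge %.3g applied", ridge)
        else:
            ridge = 0.0
    elif ridge == 0.0 and np.linalg.cond(W) > _COND_MAX:
        ridge = auto
        logger.info("pooled covariance ill-conditioned; ridge %.3g applied", ridge)
    Wr = W + ridge * np.eye(p)

    grand = counts @ centroids / n
    B = np.zeros((p, p))
    for i in range(k):
        d = centroids[i] - grand
        B += counts[i] * np.outer(d, d)
    B /= max(k - 1, 1)

    evals, evecs = la.eigh(B, Wr)
    order = np.argsort(evals)[::-1]
    d = min(k - 1, p)
    evals, evecs = evals[order][:d], evecs[:, order][:, :d]
    pos = np.clip(evals, 0.0, None)
    prop = pos / pos.sum() if pos.sum() > 0 else np.zeros(d)

    pri = (np.full(k, 1.0 / k) if priors == "equal"
           else counts / counts.sum())
    names = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else []
    return LDAModel(classes=classes, centroids=centroids, pooled_cov=Wr,
                    priors=pri, axes=evecs, prop_trace=prop,
                    feature_names=names, ridge=float(ridge),
                    n_per_class=counts)


def predict(model: LDAModel, matrix, true_labels=None) -> pd.DataFrame:
    """Assign each sample to a site.

    Returns a DataFrame with ``predicted_site``, softmax ``posterior``
    columns (one per class, summing to 1), a ``tie`` flag (broken
    lexicographically, since classes are sorted), and — when
    *true_labels* is given — ``true_site`` and ``correct``.
    """
    Xa, index = _as_array(matrix, model.feature_names)
    cho = la.cho_factor(model.pooled_cov)
    k = len(model.classes)
    d2 = np.empty((len(Xa), k))
    for i in range(k):
        diff = (Xa - model.centroids[i]).T
        d2[:, i] = np.sum(diff * la.cho_solve(cho, diff), axis=0)
    scores = -0.5 * d2 + np.log(model.priors)
    best = np.argmax(scores, axis=1)  # first max -> lexicographic tie-break
    sorted_scores = np.sort(scores, axis=1)
    tie = np.isclose(sorted_scores[:, -1], sorted_scores[:, -2],
                     rtol=0, atol=1e-12)
    stable = scores - scores.max(axis=1, keepdims=True)
    post = np.exp(stable)
    post /= post.sum(axis=1, keepdims=True)
    out = pd.DataFrame({"sample_id": index,
                        "predicted_site": model.classes[best],
                        "tie": tie})
    for i, c in enumerate(model.classes):
        out[f"post_{c}"] = post[:, i]
    if true_labels is not None:
        truth = pd.Series(true_labels).astype(str).to_numpy()
        out.insert(1, "true_site", truth)
        out.insert(3, "correct", truth == out["predicted_site"].to_numpy())
    return out


@dataclass
class BootstrapCVResult:
    accuracy: float            # pooled out-of-bag accuracy
    resubstitution: float
    ci_low: float
    ci_high: float
    n_boot: int
    per_class: pd.Series | None = None
    replicate_accuracy: np.ndarray | None = None


def bootstrap_cv_accuracy(matrix, labels, n_boot: int = 999,
                          seed: int | None = None,
                          ridge: float | None = None) -> BootstrapCVResult:
    """Bootstrap-CV classification accuracy.

    Each replicate resamples rows with replacement *within class*, fits,
    and scores the out-of-bag rows; accuracies pool correct counts over
    replicates, with a percentile CI over per-replicate accuracies.
    Plain resubstitution accuracy is reported alongside.
    """
    if seed is None:
        raise ValueError("seed is required for the bootstrap")
    Xa, _ = _as_array(matrix)
    y = np.asarray(pd.Series(labels).astype(str))
    model = fit_lda(Xa, y, ridge=ridge)
    resub = float((predict(model, Xa)["predicted_site"] == y).mean())

    rng = np.random.default_rng(seed)
    classes, inv = np.unique(y, return_inverse=True)
    idx_by_class = [np.flatnonzero(inv == i) for i in range(len(classes))]
    correct_total = np.zeros(len(classes))
    seen_total = np.zeros(len(classes))
    rep_acc = np.full(n_boot, np.nan)
    empty_oob = 0
    for b in range(n_boot):
        train_idx, oob_mask = [], np.ones(len(y), dtype=bool)
        for idx in idx_by_class:
            draw = rng.choice(idx, size=len(idx), replace=True)
            train_idx.append(draw)
            oob_mask[np.unique(draw)] = False
        train_idx = np.concatenate(train_idx)
        oob = np.flatnonzero(oob_mask)
        if len(oob) == 0 or len(np.unique(y[train_idx])) < 2:
            empty_oob += 1
            continue
        try:
            m = fit_lda(Xa[train_idx], y[train_idx], ridge=ridge)
        except ValueError:
            empty_oob += 1
            continue
        pred = predict(m, Xa[oob])["predicted_site"].to_numpy()
        ok = pred == y[oob]
        rep_acc[b] = ok.mean()
        for ci, c in enumerate(classes):
            mask = y[oob] == c
            correct_total[ci] += ok[mask].sum()
            seen_total[ci] += mask.sum()
    if empty_oob > n_boot / 2:
        warnings.warn("out-of-bag set empty or degenerate in > 50% of replicates")
    good = rep_acc[np.isfinite(rep_acc)]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = pd.Series(correct_total / seen_total, index=classes,
                              name="oob_accuracy")
    acc = float(correct_total.sum() / seen_total.sum()) if seen_total.sum() else np.nan
    lo, hi = (np.percentile(good, [2.5, 97.5]) if len(good) else (np.nan, np.nan))
    return BootstrapCVResult(accuracy=acc, resubstitution=resub,
                             ci_low=float(lo), ci_high=float(hi),
                             n_boot=n_boot, per_class=per_class,
                             replicate_accuracy=rep_acc)


def loo_cv_accuracy(matrix, labels, ridge: float | None = None) -> float:
    """Leave-one-out cross-validated accuracy (sensitivity alternative
    to the bootstrap out-of-bag estimate)."""
    Xa, _ = _as_array(matrix)
    y = np.asarray(pd.Series(labels).astype(str))
    correct = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        try:
            m = fit_lda(Xa[mask], y[mask], ridge=ridge)
        except ValueError:
            continue
        correct += predict(m, Xa[i:i + 1])["predicted_site"].iloc[0] == y[i]
    return correct / len(y)


def mahalanobis_site_distance(model: LDAModel) -> pd.DataFrame:
    """Pairwise Mahalanobis distances between site centroids."""
    cho = la.cho_factor(model.pooled_cov)
    k = len(model.classes)
    D = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        diff = model.centroids[i] - model.centroids[j]
        D[i, j] = D[j, i] = np.sqrt(diff @ la.cho_solve(cho, diff))
    return pd.DataFrame(D, index=model.classes, columns=model.classes)


def pool_sites(labels, pooling_map: dict) -> pd.Series:
    """Relabel sites by a user-confirmed pooling map (identity if absent)."""
    lab = pd.Series(labels).astype(str)
    unknown = sorted(set(pooling_map) - set(lab.unique()))
    if unknown:
        raise ValueError(f"pooling map names unknown site(s): {unknown}")
    return lab.map(lambda s: pooling_map.get(s, s))


def suggest_pooling(mahal: pd.DataFrame, geo: pd.DataFrame | None = None,
                    mahal_threshold: float = 2.0,
                    km_threshold: float = 1.0) -> list[tuple[str, str]]:
    """Site pairs close in isotope (Mahalanobis) and geographic space.

    Only a suggestion: pooling is never applied without an explicit map.
    """
    pairs = []
    for a, b in combinations(mahal.index, 2):
        close_iso = mahal.loc[a, b] <= mahal_threshold
        close_geo = geo is None or (str(a) in geo.index and str(b) in geo.index
                                    and geo.loc[str(a), str(b)] <= km_threshold)
        if close_iso and close_geo:
            pairs.append((a, b))
    return pairs


def consensus_assign(assignments: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-fish consensus over tissue-level assignments.

    A fish is ``site_specific`` when at least 3 of its available tissues
    were assigned to its true site; with fewer than 3 tissues available
    all of them must be correct.
    """
    cols = [c for c in assignments.columns if c not in ("fish_id", "tissue")]
    merged = assignments[cols].merge(meta[["sample_id", "fish_id", "tissue"]],
                                     on="sample_id", how="left")
    if merged["fish_id"].isna().any():
        missing = merged.loc[merged["fish_id"].isna(), "sample_id"].tolist()[:5]
        raise ValueError(f"samples missing from metadata: {missing}")
    rows = []
    for fish, grp in merged.groupby("fish_id", sort=True):
        n_tissues = grp["tissue"].nunique()
        if n_tissues == 0:
            raise ValueError(f"fish {fish}: no tissues available")
        n_correct = int(grp["correct"].sum())
        specific = n_correct >= 3 if n_tissues >= 3 else n_correct == n_tissues
        rows.append((fish, n_tissues, n_correct, specific))
    return pd.DataFrame(rows, columns=["fish_id", "n_tissues", "n_correct",
                                       "site_specific"])


def confusion_matrix(true_labels, predicted_labels,
                     classes=None) -> pd.DataFrame:
    """Labeled confusion matrix; rows = true site, columns = predicted."""
    t = pd.Series(np.asarray(true_labels, dtype=str), name="true")
    p = pd.Series(np.asarray(predicted_labels, dtype=str), name="predicted")
    if classes is None:
        classes = sorted(set(t) | set(p))
    cm = pd.crosstab(t, p).reindex(index=classes, columns=classes,
                                   fill_value=0)
    cm.index.name, cm.columns.name = "true", "predicted"
    return cm.astype(int)


def accuracy_from_confusion(cm: pd.DataFrame) -> float:
    """Exact-site accuracy: trace over total of a labeled confusion matrix."""
    arr = cm.to_numpy(float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("confusion matrix must be square")
    return float(np.trace(arr) / arr.sum())


def tolerant_accuracy_from_confusion(cm: pd.DataFrame,
                                     site_dist: pd.DataFrame,
                                     tolerance_km: float = 1.0) -> float:
    """Accuracy also crediting predictions within *tolerance_km* of truth."""
    total = float(cm.to_numpy().sum())
    credit = 0.0
    for t in cm.index:
        for p in cm.columns:
            n = cm.loc[t, p]
            if not n:
                continue
            if t == p or (str(t) in site_dist.index and str(p) in site_dist.columns
                          and site_dist.loc[str(t), str(p)] <= tolerance_km):
                credit += n
    return credit / total


@dataclass
class CrossYearResult:
    confusion: pd.DataFrame
    exact_accuracy: float
    tolerant_accuracy: float
    tolerance_km: float
    assignments: pd.DataFrame
    model: LDAModel


def cross_year_predict(train_matrix, train_labels, test_matrix, test_labels,
                       site_dist: pd.DataFrame | None = None,
                       tolerance_km: float = 1.0,
                       ridge: float | None = None) -> CrossYearResult:
    """Freeze a model on year A and score its predictions of year B.

    The training year's class centroids and pooled covariance are the
    classifier; nothing is refitted on the test year. Exact accuracy is
    trace/total of the confusion matrix; tolerant accuracy additionally
    credits predictions whose site lies within *tolerance_km* of the
    true site in the supplied distance matrix.
    """
    model = fit_lda(train_matrix, train_labels, ridge=ridge)
    assignments = predict(model, test_matrix, true_labels=test_labels)
    if site_dist is not None:
        dist = []
        for t, p in zip(assignments["true_site"], assignments["predicted_site"]):
            if t == p:
                dist.append(0.0)
            elif str(t) in site_dist.index and str(p) in site_dist.columns:
                dist.append(float(site_dist.loc[str(t), str(p)]))
            else:
                dist.append(np.inf)
        assignments["within_tolerance"] = (np.asarray(dist) <= tolerance_km)
    else:
        assignments["within_tolerance"] = assignments["correct"]
    cm = confusion_matrix(assignments["true_site"],
                          assignments["predicted_site"])
    exact = accuracy_from_confusion(cm)
    tolerant = (tolerant_accuracy_from_confusion(cm, site_dist, tolerance_km)
                if site_dist is not None else exact)
    return CrossYearResult(confusion=cm, exact_accuracy=exact,
                           tolerant_accuracy=tolerant,
                           tolerance_km=tolerance_km,
                           assignments=assignments, model=model)


def year_shift_test(matrix: pd.DataFrame, meta: pd.DataFrame, variable: str,
                    years: tuple[int, int] | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-(site, tissue) mean change of one variable between two years.

    Welch two-sample t-test per cell; cells with a year missing are
    omitted rather than raised.
    """
    df = meta.set_index("sample_id").join(matrix[variable].rename("_y"),
                                          how="inner").dropna(subset=["_y"])
    yrs = years or tuple(sorted(df["year"].unique()))
    if len(yrs) != 2:
        raise ValueError(f"need exactly two years, got {yrs}")
    y0, y1 = yrs
    rows = []
    for (site, tissue), grp in df.groupby(["site_id", "tissue"], sort=True):
        a = grp.loc[grp["year"] == y1, "_y"].to_numpy(float)
        b = grp.loc[grp["year"] == y0, "_y"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = st.ttest_ind(a, b, equal_var=False)
        rows.append((site, tissue, variable, float(a.mean() - b.mean()),
                     float(t), float(p), bool(p < alpha), len(b), len(a)))
    return pd.DataFrame(rows, columns=["site_id", "tissue", "variable",
                                       "mean_change", "t", "p", "significant",
                                       f"n_{y0}", f"n_{y1}"])
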