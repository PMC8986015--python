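"""Two-group sex classification: LDA with leave-one-out cross-validation,
significant-PC feature selection, confusion metrics with prevalence-weighted
accuracy, ROC/AUC, Box's M, and observer-agreement statistics.

Conventions
-----------
* The positive class is female (``F``) throughout; swap ``positive_class``
  to change it. The prevalence-weighted accuracy formula

      accuracy = sensitivity * prevalence + specificity * (1 - prevalence)

  is symmetric under consistent relabeling, and prevalence is always an
  explicit argument.
* Priors default to equal; proportional (sample-frequency) priors are
  available and every report echoes the choice.
* AUC is computed as the two-sample rank-sum statistic (ties counted half),
  which equals the trapezoidal area under the ROC staircase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassifierSpec",
    "LDAModel",
    "ClassificationReport",
    "BoxMResult",
    "select_significant_pcs",
    "lda_fit",
    "lda_loo_cv",
    "weighted_accuracy",
    "roc_auc",
    "boxs_m",
    "observer_agreement",
]


@dataclass
class ClassifierSpec:
    feature_set: str = "pcs"
    priors: str = "equal"  # "equal" or "proportional"
    positive_class: str = "F"

    def __post_init__(self):
        if self.priors not in ("equal", "proportional"):
            raise ValueError(f"unknown priors {self.priors!r}")


def select_significant_pcs(
    scores, sex_labels, alpha: float = 0.05, method: str = "ttest",
    n_perm: int = 999, seed: int | None = None,
) -> list[int]:
    """Indices (in PC order) of score columns whose F/M group means differ
    significantly (two-sided, per-column, at level alpha).

    ``method`` is ``"ttest"`` (default) or ``"permutation"`` (mean-difference
    permutation test per column). Accepts a ShapeSpace or a plain matrix.
    """
    mat = scores.scores if hasattr(scores, "scores") else np.asarray(scores, float)
    sex = np.asarray(sex_labels)
    f = mat[sex == "F"]
    m = mat[sex == "M"]
    if len(f) == 0 or len(m) == 0:
        raise ValueError("both sexes must be present")
    selected = []
    rng = np.random.default_rng(seed)
    for j in range(mat.shape[1]):
        if method == "ttest":
            _, p = stats.ttest_ind(f[:, j], m[:, j], equal_var=True)
        elif method == "permutation":
            obs = abs(f[:, j].mean() - m[:, j].mean())
            col = mat[:, j]
            nf = len(f)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(len(col))
                d = abs(col[perm[:nf]].mean() - col[perm[nf:]].mean())
                if d >= obs - 1e-15:
                    count += 1
            p = (count + 1) / (n_perm + 1)
        else:
            raise ValueError(f"unknown method {method!r}")
        if p < alpha:
            selected.append(j)
    return selected


@dataclass
class LDAModel:
    """Gaussian equal-covariance (Fisher) linear discriminant.

    ``weights`` = Sigma^-1 (mu_pos - mu_neg); the decision score is
    ``weights @ x - threshold``, positive for the positive class.
    """

    classes: tuple  # (negative, positive)
    means: dict
    pooled_covariance: np.ndarray
    weights: np.ndarray
    threshold: float
    priors: dict
    ridge_used: bool = False

    def decision_scores(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        return x @ self.weights - self.threshold

    def predict(self, x):
        s = self.decision_scores(x)
        neg, pos = self.classes
        return np.where(s > 0, pos, neg)


def lda_fit(
    features: np.ndarray,
    labels,
    spec: ClassifierSpec | None = None,
    ridge_fallback: bool = True,
) -> LDAModel:
    """Fit a two-class LDA with pooled covariance and declared priors.

    A singular pooled covariance triggers ridge regularization
    (lambda = 1e-8 * trace / p) with a warning when ``ridge_fallback`` is on,
    and an error otherwise.
    """
    spec = spec or ClassifierSpec()
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    pos = spec.positive_class
    if pos not in classes:
        raise ValueError(f"positive class {pos!r} not in labels {classes}")
    neg = classes[0] if classes[1] == pos else classes[1]
    xn, xp = x[y == neg], x[y == pos]
    if len(xn) < 2 or len(xp) < 2:
        raise ValueError("each class needs n >= 2")
    n, p = x.shape
    cov = (
        (len(xn) - 1) * np.cov(xn, rowvar=False).reshape(p, p)
        + (len(xp) - 1) * np.cov(xp, rowvar=False).reshape(p, p)
    ) / (n - 2)
    ridge_used = False
    try:
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        if not ridge_fallback:
            raise np.linalg.LinAlgError("singular pooled covariance")
        lam = 1e-8 * np.trace(cov) / p
        if lam <= 0:
            lam = 1e-12
        cov = cov + lam * np.eye(p)
        ridge_used = True
        warnings.warn("singular pooled covariance: ridge regularization applied",
                      stacklevel=2)
    mu_n, mu_p = xn.mean(axis=0), xp.mean(axis=0)
    w = np.linalg.solve(cov, mu_p - mu_n)
    if spec.priors == "equal":
        pri = {neg: 0.5, pos: 0.5}
    else:
        pri = {neg: len(xn) / n, pos: len(xp) / n}
    # threshold from equal-covariance Gaussian posteriors:
    # w.x > 0.5*w.(mu_p+mu_n) - log(pi_pos/pi_neg)
    threshold = 0.5 * float(w @ (mu_p + mu_n)) - float(np.log(pri[pos] / pri[neg]))
    return LDAModel(
        classes=(neg, pos),
        means={neg: mu_n, pos: mu_p},
        pooled_covariance=cov,
        weights=w,
        threshold=threshold,
        priors=pri,
        ridge_used=ridge_used,
    )


def weighted_accuracy(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Prevalence-weighted accuracy: sens * prev + spec * (1 - prev).

    Equals raw accuracy (TP+TN)/n when ``prevalence`` is the sample
    prevalence of the positive class.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return sensitivity * prevalence + specificity * (1.0 - prevalence)


def roc_auc(scores, labels, positive_class="F") -> tuple[np.ndarray, float]:
    """ROC staircase and rank-based AUC of a continuous score.

    Returns ``(points, auc)`` where ``points`` is an (m, 2) array of
    (false-positive rate, true-positive rate) pairs from (0,0) to (1,1),
    thresholds taken at every distinct score (descending; higher score =>
    positive call). The AUC is the Mann-Whitney statistic with ties counted
    half, which equals the trapezoidal area under the staircase.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return np.column_stack([fpr, tpr]), float(auc)


@dataclass
class ClassificationReport:
    """Confusion counts and derived metrics (positive class = F by default)."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str
    priors: str
    predictions: pd.DataFrame
    roc_points: np.ndarray = field(default=None, repr=False)
    auc: float | None = None
    feature_set: str = ""

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n

    @property
    def accuracy_weighted(self) -> float:
        return weighted_accuracy(self.sensitivity, self.specificity, self.prevalence)

    @property
    def percent_correct(self) -> dict:
        """Per-class cross-validated correct percentages (table layout)."""
        return {
            "positive": 100.0 * self.sensitivity,
            "negative": 100.0 * self.specificity,
        }


def lda_loo_cv(
    features: np.ndarray, labels, spec: ClassifierSpec | None = None
) -> ClassificationReport:
    """Leave-one-out cross-validated LDA: each specimen is predicted by a
    model fitted on the remaining n-1, and the report aggregates the
    cross-validated predictions (confusion, per-class %, weighted accuracy,
    ROC/AUC of the cross-validated decision scores)."""
    spec = spec or ClassifierSpec()
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs n >= 3")
    scores = np.empty(n)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = lda_fit(x[mask], y[mask], spec)
        scores[i] = model.decision_scores(x[i])[0]
        preds[i] = model.predict(x[i])[0]
    pos = spec.positive_class
    is_pos = y == pos
    pred_pos = preds == pos
    tp = int(np.sum(is_pos & pred_pos))
    fn = int(np.sum(is_pos & ~pred_pos))
    fp = int(np.sum(~is_pos & pred_pos))
    tn = int(np.sum(~is_pos & ~pred_pos))
    roc_points, auc = roc_auc(scores, y, positive_class=pos)
    predictions = pd.DataFrame(
        {
            "true": y,
            "predicted": preds.astype(str),
            "score": scores,
            "cross_validated": True,
        }
    )
    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        positive_class=pos, priors=spec.priors,
        predictions=predictions, roc_points=roc_points, auc=auc,
        feature_set=spec.feature_set,
    )


@dataclass
class BoxMResult:
    m_statistic: float
    log_determinants: dict
    pooled_log_determinant: float
    chi_square: float
    df: int
    p_value: float


def boxs_m(features: np.ndarray, labels) -> BoxMResult:
    """Box's M test of homogeneity of group covariance matrices with the
    standard chi-square approximation."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    groups = pd.unique(y)
    g = len(groups)
    if g < 2:
        raise ValueError("at least two groups required")
    n, p = x.shape
    covs, ns, logdets = {}, {}, {}
    pooled = np.zeros((p, p))
    for lv in groups:
        xg = x[y == lv]
        if len(xg) <= p:
            raise ValueError(
                f"group {lv!r} has n={len(xg)} <= p={p}: covariance singular"
            )
        c = np.cov(xg, rowvar=False).reshape(p, p)
        covs[lv] = c
        ns[lv] = len(xg)
        sign, ld = np.linalg.slogdet(c)
        if sign <= 0:
            raise ValueError(f"group {lv!r} covariance not positive definite")
        logdets[lv] = float(ld)
        pooled += (len(xg) - 1) * c
    pooled /= (n - g)
    sign, ld_pool = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise ValueError("pooled covariance not positive definite")
    m = (n - g) * ld_pool - sum((ns[lv] - 1) * logdets[lv] for lv in groups)
    c1 = (
        (2 * p ** 2 + 3 * p - 1) / (6 * (p + 1) * (g - 1))
        * (sum(1 / (ns[lv] - 1) for lv in groups) - 1 / (n - g))
    )
    chi2 = m * (1 - c1)
    df = (g - 1) * p * (p + 1) // 2
    p_val = float(stats.chi2.sf(chi2, df))
    return BoxMResult(
        m_statistic=float(m),
        log_determinants={lv: logdets[lv] for lv in groups},
        pooled_log_determinant=float(ld_pool),
        chi_square=float(chi2),
        df=df,
        p_value=p_val,
    )


def observer_agreement(
    ratings: pd.DataFrame, positive_class: str = "F"
) -> dict:
    """Intra-/inter-observer agreement and per-observer accuracy from a
    rating table (columns: specimen_id, observer, round, rating, truth).

    Returns a dict with:
      * ``intra_observer``: % round-1/round-2 agreement per observer
        (observers with a single round are omitted with a warning);
      * ``inter_observer_disagreement``: % disagreement per observer pair on
        common round-1 specimens;
      * ``accuracy``: per observer (round 1 vs truth) per-class correct %,
        sensitivity/specificity and prevalence-weighted accuracy.
    """
    df = ratings.copy()
    df["round"] = df["round"].astype(int)
    observers = sorted(df["observer"].unique())

    intra: dict[str, float] = {}
    for obs in observers:
        sub = df[df["observer"] == obs]
        r1 = sub[sub["round"] == 1].set_index("specimen_id")["rating"]
        r2 = sub[sub["round"] == 2].set_index("specimen_id")["rating"]
        common = r1.index.intersection(r2.index)
        if len(common) == 0:
            warnings.warn(
                f"observer {obs!r} has a single round: intra-observer metric omitted",
                stacklevel=2,
            )
            continue
        intra[obs] = 100.0 * float((r1[common] == r2[common]).mean())

    inter: dict[tuple[str, str], float] = {}
    r1_tables = {
        obs: df[(df["observer"] == obs) & (df["round"] == 1)]
        .set_index("specimen_id")["rating"]
        for obs in observers
    }
    for i, a in enumerate(observers):
        for b in observers[i + 1:]:
            common = r1_tables[a].index.intersection(r1_tables[b].index)
            if len(common):
                inter[(a, b)] = 100.0 * float(
                    (r1_tables[a][common] != r1_tables[b][common]).mean()
                )

    accuracy: dict[str, dict] = {}
    if "truth" in df.columns:
        for obs in observers:
            sub = df[(df["observer"] == obs) & (df["round"] == 1)].dropna(subset=["truth"])
            if sub.empty:
                continue
            truth = sub["truth"].to_numpy()
            rated = sub["rating"].to_numpy()
            is_pos = truth == positive_class
            pred_pos = rated == positive_class
            tp = int((is_pos & pred_pos).sum())
            fn = int((is_pos & ~pred_pos).sum())
            tn = int((~is_pos & ~pred_pos).sum())
            fp = int((~is_pos & pred_pos).sum())
            sens = tp / (tp + fn) if tp + fn else float("nan")
            spec = tn / (tn + fp) if tn + fp else float("nan")
            prev = (tp + fn) / len(sub)
            wacc = (
                weighted_accuracy(sens, spec, prev)
                if np.isfinite(sens) and np.isfinite(spec)
                else float("nan")
            )
            accuracy[obs] = {
                "percent_correct_positive": 100.0 * sens,
                "percent_correct_negative": 100.0 * spec,
                "sensitivity": sens,
                "specificity": spec,
                "weighted_accuracy": wacc,
                "n": len(sub),
            }
    return {
        "intra_observer": intra,
        "inter_observer_disagreement": inter,
        "accuracy": accuracy,
    }
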