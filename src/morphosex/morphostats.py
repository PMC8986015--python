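"""Multivariate shape statistics and univariate measurement statistics.

Covers principal component analysis in shape and form space,
variance-explained multivariate regressions of shape on size (lnCS), sex and
geographic origin, the two-stage allometry-corrected sex effect, permutation
tests of group mean Procrustes distances, residual-randomization Procrustes
ANOVA with sequential (type-I) sums of squares, and the univariate t-test /
effect-size statistics used for linear measurements.

Effect sizes
------------
Cohen's D is reported in two conventions because the source convention of
published sacrum tables is often unstated: (a) the classic pooled
within-group SD, and (b) the mean difference divided by the *total-sample*
SD reconstructed from group n/mean/SD (within + between variance with group
sizes n as weights). Convention (b) reproduces the published sacral
summary-table values.

Permutation p-values use the add-one estimator p = (#{perm >= obs} + 1) /
(B + 1), so p is always in (0, 1]; exact enumeration is available for tiny
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ShapeSpace",
    "RegressionResult",
    "GroupComparison",
    "UnivariateStats",
    "AnovaTable",
    "pca",
    "variance_explained_regression",
    "allometry_corrected_sex_effect",
    "permutation_mean_difference",
    "procrustes_anova",
    "ttest_and_effect",
    "summary_from_groups",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class ShapeSpace:
    """Centered PCA of a (form- or shape-space) data matrix."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray  # p x n_columns, rows are unit PC vectors
    mean_vector: np.ndarray
    space_kind: str = "shape"

    @property
    def percent_variance(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return 100.0 * self.eigenvalues / total

    @property
    def n_components(self) -> int:
        return self.eigenvalues.shape[0]


def pca(data_matrix: np.ndarray, space_kind: str = "shape") -> ShapeSpace:
    """Centered PCA via SVD; keeps p = min(n-1, columns) components.

    ``scores @ loadings`` reconstructs the centered data exactly (the
    retained components span the full sample variation).
    """
    x = np.asarray(data_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("pca requires an n x q matrix with n >= 2")
    n = x.shape[0]
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    p = min(n - 1, x.shape[1])
    u, s, vt = u[:, :p], s[:p], vt[:p]
    eig = s ** 2 / (n - 1)
    scores = u * s
    return ShapeSpace(
        scores=scores, eigenvalues=eig, loadings=vt, mean_vector=mean,
        space_kind=space_kind,
    )


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _encode_predictor(predictor) -> np.ndarray:
    """Numeric 1D/2D predictors pass through; categorical ones are
    dummy-coded (first level dropped). Always returns n x q, no intercept."""
    arr = np.asarray(predictor)
    if arr.dtype.kind in "fiub" and arr.ndim <= 2:
        x = arr.astype(float)
        x = x[:, None] if x.ndim == 1 else x
    else:
        levels = pd.unique(arr)
        if len(levels) < 2:
            raise ValueError("constant predictor")
        x = np.column_stack(
            [(arr == lv).astype(float) for lv in levels[1:]]
        )
    if x.shape[1] == 0 or np.allclose(x.std(axis=0), 0):
        raise ValueError("constant predictor")
    return x


def _fit_percent(y: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Multivariate OLS of all columns of y on [1, x]; returns
    (percent of total variance explained, coefficient matrix)."""
    n = y.shape[0]
    design = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    yc = y - y.mean(axis=0)
    ss_total = float((yc ** 2).sum())
    fc = fitted - fitted.mean(axis=0)
    ss_model = float((fc ** 2).sum())
    if ss_total <= 0:
        raise ValueError("response matrix has zero variance")
    return 100.0 * ss_model / ss_total, coef


@dataclass
class RegressionResult:
    predictor: str
    percent_variance_explained: float
    coefficients: np.ndarray
    permutation_p: float | None = None
    n_permutations: int | None = None
    # allometry-residual analyses also log the share of the original total
    percent_of_total: float | None = None


def variance_explained_regression(
    shape_matrix: np.ndarray,
    predictor,
    predictor_name: str = "predictor",
    n_perm: int = 0,
    seed: int | None = None,
) -> RegressionResult:
    """Multivariate regression of all shape columns on one predictor block;
    reports 100 * SS_model / SS_total summed over columns, optionally with a
    permutation p-value (rows of the predictor shuffled)."""
    y = np.asarray(shape_matrix, dtype=float)
    x = _encode_predictor(predictor)
    if y.shape[0] != x.shape[0]:
        raise ValueError("shape matrix and predictor differ in length")
    if y.shape[0] <= x.shape[1] + 1:
        raise ValueError("n must exceed the number of predictor levels")
    percent, coef = _fit_percent(y, x)
    p_val = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(x.shape[0])
            pct, _ = _fit_percent(y, x[perm])
            if pct >= percent:
                count += 1
        p_val = (count + 1) / (n_perm + 1)
    return RegressionResult(
        predictor=predictor_name,
        percent_variance_explained=percent,
        coefficients=coef,
        permutation_p=p_val,
        n_permutations=n_perm if n_perm > 0 else None,
    )


def allometry_corrected_sex_effect(
    shape_matrix: np.ndarray,
    lncs: np.ndarray,
    sex_binary,
    n_perm: int = 0,
    seed: int | None = None,
) -> RegressionResult:
    """Two-stage allometry correction: regress shape on lnCS, then regress
    the allometric residuals on binary sex.

    ``percent_variance_explained`` is the sex share of the *residual*
    variance; ``percent_of_total`` is the same sum of squares as a share of
    the original total shape variance (the figure usually quoted).
    """
    y = np.asarray(shape_matrix, dtype=float)
    lncs = np.asarray(lncs, dtype=float)
    sex = np.asarray(sex_binary)
    if len(pd.unique(sex)) < 2:
        raise ValueError("both sexes must be present")
    _, coef1 = _fit_percent(y, lncs[:, None])
    design1 = np.column_stack([np.ones(len(y)), lncs])
    residuals = y - design1 @ coef1
    yc = y - y.mean(axis=0)
    ss_total_orig = float((yc ** 2).sum())
    res = variance_explained_regression(
        residuals, sex, predictor_name="sex|lnCS", n_perm=n_perm, seed=seed
    )
    rc = residuals - residuals.mean(axis=0)
    ss_res_total = float((rc ** 2).sum())
    ss_sex = res.percent_variance_explained / 100.0 * ss_res_total
    res.percent_of_total = 100.0 * ss_sex / ss_total_orig
    return res


# ---------------------------------------------------------------------------
# Permutation test of group mean differences
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    group_labels: tuple
    observed_statistic: float
    n_permutations: int
    p_value: float
    group_sizes: dict = field(default_factory=dict)
    exact: bool = False


def _group_mean_distance(flat: np.ndarray, mask_a: np.ndarray) -> float:
    ma = flat[mask_a].mean(axis=0)
    mb = flat[~mask_a].mean(axis=0)
    return float(np.linalg.norm(ma - mb))


def permutation_mean_difference(
    data,
    labels,
    n_perm: int = 10000,
    seed: int | None = None,
    exact: bool = False,
) -> GroupComparison:
    """Permutation test of the Procrustes distance between two group mean
    configurations (Euclidean distance between mean vectors for matrices).

    ``exact=True`` enumerates all label assignments (tiny samples only) and
    returns p = #{stat >= observed} / #assignments, which includes the
    identity assignment so p > 0. Otherwise p uses the add-one estimator
    over ``n_perm`` random permutations.
    """
    arr = np.asarray(data, dtype=float)
    flat = arr.reshape(arr.shape[0], -1)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(
            f"exactly two groups required, got {len(groups)}: use pairwise "
            "calls for more"
        )
    mask_a = labels == groups[0]
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    observed = _group_mean_distance(flat, mask_a)
    n = flat.shape[0]

    if exact:
        count = 0
        total = 0
        for combo in combinations(range(n), n_a):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            total += 1
            if _group_mean_distance(flat, m) >= observed - 1e-12:
                count += 1
        p = count / total
        return GroupComparison(
            group_labels=tuple(groups), observed_statistic=observed,
            n_permutations=total, p_value=p,
            group_sizes={groups[0]: n_a, groups[1]: n_b}, exact=True,
        )

    rng = np.random.default_rng(seed)
    count = 0
    # vectorized in blocks: permuted group-A means via index matrices
    block = 256
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        idx_a = order[:, :n_a]
        idx_b = order[:, n_a:]
        ma = flat[idx_a].mean(axis=1)
        mb = flat[idx_b].mean(axis=1)
        d = np.linalg.norm(ma - mb, axis=1)
        count += int((d >= observed - 1e-12).sum())
        done += b
    p = (count + 1) / (n_perm + 1)
    return GroupComparison(
        group_labels=tuple(groups), observed_statistic=observed,
        n_permutations=n_perm, p_value=p,
        group_sizes={groups[0]: n_a, groups[1]: n_b}, exact=False,
    )


# ---------------------------------------------------------------------------
# Procrustes ANOVA (sequential SS, residual randomization)
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    terms: list[str]
    ss: np.ndarray
    df: np.ndarray
    percent: np.ndarray
    f_statistics: np.ndarray
    p_values: np.ndarray
    ss_residual: float
    df_residual: int
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "term": self.terms,
                "df": self.df,
                "SS": self.ss,
                "percent": self.percent,
                "F": self.f_statistics,
                "p": self.p_values,
            }
        )
        df.loc[len(df)] = ["Residual", self.df_residual, self.ss_residual,
                           np.nan, np.nan, np.nan]
        return df


def _term_columns(values, name: str) -> tuple[np.ndarray, int]:
    x = _encode_predictor(values)
    return x, x.shape[1]


def procrustes_anova(
    shape_matrix: np.ndarray,
    factors: dict | pd.DataFrame,
    include_interaction: bool = False,
    n_perm: int = 999,
    seed: int | None = None,
) -> AnovaTable:
    """Sequential (type-I) Procrustes ANOVA over all shape columns.

    Terms enter in the declared factor order; with ``include_interaction``
    the pairwise interaction of the (exactly two) factors is added last.
    p-values come from residual randomization (RRPP): for each term the
    residuals of the reduced model (terms before it) are permuted, added
    back to the reduced fit, and the term's F statistic recomputed.
    """
    y = np.asarray(shape_matrix, dtype=float)
    n = y.shape[0]
    if isinstance(factors, pd.DataFrame):
        factor_items = [(str(c), factors[c].to_numpy()) for c in factors.columns]
    else:
        factor_items = [(str(k), np.asarray(v)) for k, v in factors.items()]
    blocks: list[tuple[str, np.ndarray, int]] = []
    for name, vals in factor_items:
        x, dfq = _term_columns(vals, name)
        blocks.append((name, x, dfq))
    if include_interaction:
        if len(factor_items) != 2:
            raise ValueError("interaction requires exactly two factors")
        (na, xa, _), (nb, xb, _) = blocks
        inter = np.einsum("ni,nj->nij", xa, xb).reshape(n, -1)
        blocks.append((f"{na}:{nb}", inter, inter.shape[1]))

    # sequentially orthonormalized design: Q_0 = intercept, then one
    # orthonormal block per term
    q_prev = np.ones((n, 1)) / np.sqrt(n)
    q_blocks: list[np.ndarray] = []
    terms: list[str] = []
    dfs: list[int] = []
    for name, x, dfq in blocks:
        resid = x - q_prev @ (q_prev.T @ x)
        q, r = np.linalg.qr(resid)
        keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())
        if keep.sum() < dfq:
            raise ValueError(
                f"rank-deficient design: term {name!r} aliased with earlier "
                "terms"
            )
        qk = q[:, keep]
        q_blocks.append(qk)
        q_prev = np.column_stack([q_prev, qk])
        terms.append(name)
        dfs.append(int(keep.sum()))
    rank_full = q_prev.shape[1]
    if n <= rank_full:
        raise ValueError("n must exceed the model rank")

    yc = y - y.mean(axis=0)
    ss_total = float((yc ** 2).sum())
    proj = [qb.T @ y for qb in q_blocks]
    ss_terms = np.array([float((p ** 2).sum()) for p in proj])
    ss_resid = ss_total - ss_terms.sum()
    df_terms = np.array(dfs)
    df_resid = n - rank_full
    f_obs = (ss_terms / df_terms) / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    p_vals = np.ones(len(terms))
    if n_perm > 0:
        counts = np.zeros(len(terms), dtype=int)
        for t_i in range(len(terms)):
            # reduced model: intercept + terms before t_i
            q_red = np.column_stack([np.ones((n, 1)) / np.sqrt(n)] + q_blocks[:t_i])
            fit_red = q_red @ (q_red.T @ y)
            resid_red = y - fit_red
            qt = q_blocks[t_i]
            q_all = np.column_stack(q_blocks)
            for _ in range(n_perm):
                perm = rng.permutation(n)
                y_star = fit_red + resid_red[perm]
                ss_t = float(((qt.T @ y_star) ** 2).sum())
                ycs = y_star - y_star.mean(axis=0)
                ss_tot_s = float((ycs ** 2).sum())
                # residual SS of the full model on the randomized data
                ss_res_s = ss_tot_s - float(((q_all.T @ y_star) ** 2).sum())
                f_s = (ss_t / df_terms[t_i]) / (ss_res_s / df_resid)
                if f_s >= f_obs[t_i] - 1e-12:
                    counts[t_i] += 1
        p_vals = (counts + 1) / (n_perm + 1)

    return AnovaTable(
        terms=terms,
        ss=ss_terms,
        df=df_terms,
        percent=100.0 * ss_terms / ss_total,
        f_statistics=f_obs,
        p_values=p_vals,
        ss_residual=ss_resid,
        df_residual=df_resid,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# Univariate statistics (linear measurements)
# ---------------------------------------------------------------------------

@dataclass
class UnivariateStats:
    """Two-group summary in the layout of published measurement tables."""

    groups: dict  # label -> {n, mean, sd, min, max}
    average_difference: float
    t_statistic: float
    p_value: float
    cohens_d_pooled: float
    cohens_d_total: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _total_sd(n1, m1, s1, n2, m2, s2) -> float:
    """Total-sample SD reconstructed from group summaries: within + between
    variance with group sizes n as weights."""
    n = n1 + n2
    grand = (n1 * m1 + n2 * m2) / n
    within = (n1 * s1 ** 2 + n2 * s2 ** 2) / n
    between = (n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2) / n
    return float(np.sqrt(within + between))


def _pooled_sd(n1, s1, n2, s2) -> float:
    return float(np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)))


def summary_from_groups(
    n_f: int, mean_f: float, sd_f: float,
    n_m: int, mean_m: float, sd_m: float,
) -> UnivariateStats:
    """Univariate statistics from group summaries alone (no raw data):
    average difference, pooled-variance t-test, and Cohen's D in both the
    pooled-SD and total-sample-SD conventions."""
    if n_f < 2 or n_m < 2:
        raise ValueError("each group needs n >= 2")
    if sd_f < 0 or sd_m < 0:
        raise ValueError("SD must be nonnegative")
    t, p = stats.ttest_ind_from_stats(
        mean_f, sd_f, n_f, mean_m, sd_m, n_m, equal_var=True
    )
    diff = abs(mean_m - mean_f)
    sd_pool = _pooled_sd(n_f, sd_f, n_m, sd_m)
    sd_tot = _total_sd(n_f, mean_f, sd_f, n_m, mean_m, sd_m)
    return UnivariateStats(
        groups={
            "F": {"n": n_f, "mean": mean_f, "sd": sd_f, "min": None, "max": None},
            "M": {"n": n_m, "mean": mean_m, "sd": sd_m, "min": None, "max": None},
        },
        average_difference=diff,
        t_statistic=float(t),
        p_value=float(p),
        cohens_d_pooled=diff / sd_pool if sd_pool > 0 else 0.0,
        cohens_d_total=diff / sd_tot if sd_tot > 0 else 0.0,
    )


def ttest_and_effect(values, sex_labels) -> UnivariateStats:
    """Independent two-sided pooled-variance t-test of F vs M raw values,
    with per-group summaries and both Cohen's D conventions. Agrees with
    ``summary_from_groups`` applied to this data's summaries."""
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex_labels)
    vf = values[sex == "F"]
    vm = values[sex == "M"]
    if len(vf) < 2 or len(vm) < 2:
        raise ValueError("both sexes need n >= 2")
    res = summary_from_groups(
        len(vf), float(vf.mean()), float(vf.std(ddof=1)),
        len(vm), float(vm.mean()), float(vm.std(ddof=1)),
    )
    res.groups["F"].update(min=float(vf.min()), max=float(vf.max()))
    res.groups["M"].update(min=float(vm.min()), max=float(vm.max()))
    return res
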