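"""Multivariate statistics for feature matrices with missing values.

This module carries the census analysis proper: pairwise correlation
screening with Benjamini-Hochberg FDR control, principal-variable ranking
(variance each variable explains), probabilistic PCA estimated by EM over
observed entries only ("PCA with missing values"), promax rotation and
projection of held-out cells, Bayesian chained-equation multiple
imputation, cloud-geometry measures (median pairwise distances, the AGNES
agglomerative-nesting coefficient, local PCA), ordination quality, group
comparisons (rank-sum / ANOVA / Welch / variance-ratio F, eta-squared), and
sequential (type-I) regression variance partitioning.

Unless noted, every distance or component computation standardizes columns
to mean 0, SD 1 on observed entries first.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PCAModel", "pairwise_correlations", "fdr_adjust",
    "explained_variance_single", "explained_variance_subset", "vbpca_fit",
    "promax_rotate", "project", "impute", "cloud_median_distance",
    "agnes_coefficient", "local_pca_variance", "ordination_quality",
    "group_compare", "variance_ratio_test", "sequential_regression",
    "rank_renormalize", "imputed_subsample_stat", "compare_cloud_sizes",
    "standardize",
]


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column z-scores on observed entries; returns (z, means, sds)."""
    mean = matrix.mean(axis=0, skipna=True)
    sd = matrix.std(axis=0, skipna=True, ddof=1).replace(0.0, 1.0).fillna(1.0)
    return (matrix - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# Correlation screening
# ---------------------------------------------------------------------------

def pairwise_correlations(matrix: pd.DataFrame, method: str = "pearson",
                          min_n: int = 3) -> pd.DataFrame:
    """All C(p, 2) pairwise-complete correlations with p-values and n.

    Pairs with fewer than `min_n` shared observations, or with a constant
    variable, get NaN r and p but are still listed (the pair count is part
    of the analysis).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    cols = list(matrix.columns)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        x, y = matrix[a].to_numpy(float), matrix[b].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        r = p = np.nan
        if n >= min_n and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            if method == "pearson":
                r, p = sps.pearsonr(x[ok], y[ok])
            else:
                r, p = sps.spearmanr(x[ok], y[ok])
        rows.append({"var_a": a, "var_b": b, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def fdr_adjust(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up; returns (significant mask, implied p threshold).

    The implied threshold is the largest raw p-value that passed (NaN when
    nothing passes); NaN p-values never pass.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.nan
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    mask = np.zeros(p.size, dtype=bool)
    finite = np.isfinite(p)
    if finite.any():
        rej, _, _, _ = multipletests(p[finite], alpha=alpha, method="fdr_bh")[:4]
        mask[finite] = rej
    threshold = float(np.max(p[mask])) if mask.any() else np.nan
    return mask, threshold


# ---------------------------------------------------------------------------
# Principal variables
# ---------------------------------------------------------------------------

def explained_variance_single(corr: pd.DataFrame) -> pd.Series:
    """Share of total dataset variance explained by each single variable.

    For standardized data this is the mean over all p variables (self
    included) of the squared correlation r_ij^2 -- the squared-RM criterion
    for singleton subsets. A variable uncorrelated with every other one
    scores exactly 1/p, the noise floor. Missing correlations are averaged
    over the available entries.
    """
    c = np.asarray(corr, dtype=float).copy()
    np.fill_diagonal(c, 1.0)
    r2 = c**2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        share = np.nanmean(r2, axis=1)
    return pd.Series(share, index=corr.columns if hasattr(corr, "columns") else None)


def explained_variance_subset(matrix: pd.DataFrame, subset: list[str],
                              ridge: float = 0.0) -> float:
    """Mean over all variables of the R^2 from regressing each on the subset.

    Operates on complete rows (or an imputed matrix); a singular subset
    design is ridge-stabilized with a warning.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    z, _, _ = standardize(matrix)
    data = z.dropna(axis=0, how="any")
    x = data[list(subset)].to_numpy(float)
    x = np.column_stack([np.ones(len(x)), x])
    gram = x.T @ x
    if np.linalg.cond(gram) > 1e10:
        warnings.warn("singular subset design; ridge-stabilized")
        ridge = max(ridge, 1e-8 * np.trace(gram) / gram.shape[0])
    ginv = np.linalg.inv(gram + ridge * np.eye(gram.shape[0]))
    hat = x @ ginv @ x.T
    r2s = []
    for col in data.columns:
        y = data[col].to_numpy(float)
        yc = y - y.mean()
        tss = float(yc @ yc)
        if tss <= 0:
            r2s.append(1.0 if col in subset else 0.0)
            continue
        resid = y - hat @ y
        rss = float(resid @ resid)
        r2s.append(max(0.0, 1.0 - rss / tss))
    return float(np.mean(r2s))


# ---------------------------------------------------------------------------
# PCA with missing values
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Probabilistic PCA model over observed entries.

    ``loadings`` are variables x components (post-rotation if rotated);
    ``scores`` reproduce the fitted low-rank approximation together with the
    loadings; ``explained`` are per-component shares of total observed
    variance (pre-rotation ordering, non-increasing).
    """

    loadings: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    scores: pd.DataFrame
    explained: np.ndarray
    noise_var: float
    rotation: np.ndarray
    converged: bool = True
    n_iter: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def vbpca_fit(matrix: pd.DataFrame, n_components: int = 2,
              tol: float = 1e-6, max_iter: int = 5000,
              standardize_input: bool = True) -> PCAModel:
    """Probabilistic PCA with missing values, estimated by EM.

    The model is y_i = W x_i + mu + eps with isotropic noise; the E-step
    uses only the observed entries of each cell, so no imputation is
    involved. Initialization is deterministic (SVD of the mean-imputed
    matrix). Convergence: relative change of the expected observed-entry
    reconstruction error below `tol`, else a non-converged flag after
    `max_iter` iterations.
    """
    y_raw = matrix.to_numpy(dtype=float)
    n, p = y_raw.shape
    obs = np.isfinite(y_raw)
    if obs.mean() < 0.5:
        raise ValueError("more than 50% of entries are missing")
    if standardize_input:
        z, mean0, sd0 = standardize(matrix)
        y = z.to_numpy(dtype=float)
    else:
        mean0 = pd.Series(0.0, index=matrix.columns)
        sd0 = pd.Series(1.0, index=matrix.columns)
        y = y_raw.copy()
    y0 = np.where(obs, y, 0.0)
    k = n_components
    # deterministic init from the SVD of the mean-imputed matrix
    u, s, vt = np.linalg.svd(y0, full_matrices=False)
    w = (vt[:k].T * s[:k]) / np.sqrt(n)
    sigma2 = max(float(np.var(y0[obs])) - float(np.sum(s[:k]**2)) / (n * p), 1e-6)
    mu = np.zeros(p)
    ey = np.where(obs, y, np.nan)
    prev_err = np.inf
    converged = False
    it = 0
    eye_k = np.eye(k)
    for it in range(1, max_iter + 1):
        xm = np.zeros((n, k))
        xxsum_j = [np.zeros((k, k)) for _ in range(p)]
        xx_rows = np.zeros((n, k, k))
        for i in range(n):
            o = obs[i]
            wo = w[o]
            m = np.linalg.inv(eye_k + wo.T @ wo / sigma2)
            xm[i] = m @ wo.T @ (ey[i, o] - mu[o]) / sigma2
            xx_rows[i] = m + np.outer(xm[i], xm[i])
        # M-step per variable over the rows observing it
        w_new = np.zeros_like(w)
        mu_new = np.zeros(p)
        for j in range(p):
            rows = obs[:, j]
            if not rows.any():
                continue
            mu_new[j] = float(np.mean(ey[rows, j] - xm[rows] @ w[j]))
            a = xx_rows[rows].sum(axis=0)
            b = (ey[rows, j] - mu_new[j]) @ xm[rows]
            w_new[j] = np.linalg.solve(a + 1e-12 * eye_k, b)
        # noise variance over observed entries
        se = 0.0
        n_obs = 0
        for i in range(n):
            o = obs[i]
            resid = ey[i, o] - mu_new[o] - w_new[o] @ xm[i]
            m = xx_rows[i] - np.outer(xm[i], xm[i])
            se += float(resid @ resid) + float(np.sum((w_new[o] @ m) * w_new[o]))
            n_obs += int(o.sum())
        sigma2_new = max(se / n_obs, 1e-12)
        err = se / n_obs
        w, mu, sigma2 = w_new, mu_new, sigma2_new
        if np.isfinite(prev_err) and abs(prev_err - err) <= tol * max(prev_err, 1e-12):
            converged = True
            break
        prev_err = err
    # final scores (posterior means) and component ordering by loading norm
    scores = np.zeros((n, k))
    for i in range(n):
        o = obs[i]
        wo = w[o]
        m = np.linalg.inv(eye_k + wo.T @ wo / sigma2)
        scores[i] = m @ wo.T @ (ey[i, o] - mu[o]) / sigma2
    order = np.argsort(-np.linalg.norm(w, axis=0))
    w = w[:, order]
    scores = scores[:, order]
    # sign convention: largest-magnitude loading positive
    for c in range(k):
        col = w[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            w[:, c] = -col
            scores[:, c] = -scores[:, c]
    # per-component shares of total observed variance: lambda_c = |w_c|^2 + sigma2
    col_var = np.array([np.var(ey[obs[:, j], j], ddof=1) if obs[:, j].sum() > 1 else 0.0
                        for j in range(p)])
    total = float(np.sum(col_var))
    lam = np.linalg.norm(w, axis=0)**2 + sigma2
    explained = lam / total if total > 0 else np.full(k, np.nan)
    comp_names = [f"C{c + 1}" for c in range(k)]
    return PCAModel(
        loadings=pd.DataFrame(w, index=matrix.columns, columns=comp_names),
        mean=mean0 + sd0 * pd.Series(mu, index=matrix.columns),
        sd=sd0,
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        explained=explained,
        noise_var=float(sigma2),
        rotation=np.eye(k),
        converged=converged,
        n_iter=it,
        meta={"mu_internal": mu},
    )


def _varimax(lam: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Rotation matrix maximizing the varimax criterion."""
    p, k = lam.shape
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        b = lam @ rot
        u, s, vt = np.linalg.svd(
            lam.T @ (b**3 - b @ np.diag(np.sum(b**2, axis=0)) / p))
        rot = u @ vt
        var_new = float(np.sum(s))
        if var_new - var_old < tol * max(var_new, 1e-12):
            break
        var_old = var_new
    return rot


def promax_rotate(model: PCAModel, power: int = 4) -> PCAModel:
    """Promax oblique rotation of the fitted components.

    Varimax first, then an oblique Procrustes rotation toward the
    element-wise power-`power` target of the varimax solution. Scores are
    counter-rotated so that scores @ loadings' is unchanged.
    """
    lam = model.loadings.to_numpy(float)
    if lam.shape[1] < 2:
        raise ValueError("need at least 2 components to rotate")
    rot_v = _varimax(lam)
    lam_v = lam @ rot_v
    target = lam_v * np.abs(lam_v) ** (power - 1)
    coef, *_ = np.linalg.lstsq(lam_v, target, rcond=None)
    d = np.diag(np.linalg.inv(coef.T @ coef))
    coef = coef @ np.diag(np.sqrt(d))
    total = rot_v @ coef
    lam_new = lam @ total
    scores_new = model.scores.to_numpy(float) @ np.linalg.inv(total).T
    return PCAModel(
        loadings=pd.DataFrame(lam_new, index=model.loadings.index,
                              columns=model.loadings.columns),
        mean=model.mean, sd=model.sd,
        scores=pd.DataFrame(scores_new, index=model.scores.index,
                            columns=model.scores.columns),
        explained=model.explained, noise_var=model.noise_var,
        rotation=model.rotation @ total, converged=model.converged,
        n_iter=model.n_iter, meta=dict(model.meta),
    )


def project(model: PCAModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Score new cells in the model's component space.

    Each cell is standardized with the model's means/SDs and scored by
    regression on its observed entries (the PPCA posterior mean), then
    carried through the model's rotation. A cell with no observed variables
    gets NaN scores.
    """
    cols = list(model.loadings.index)
    # model.mean already folds in the EM mean offset
    y = ((matrix[cols] - model.mean[cols]) / model.sd[cols]).to_numpy(float)
    # un-rotated loadings
    rot = model.rotation
    w = model.loadings.to_numpy(float) @ np.linalg.inv(rot)
    k = w.shape[1]
    sigma2 = model.noise_var
    out = np.full((len(matrix), k), np.nan)
    eye_k = np.eye(k)
    for i in range(len(matrix)):
        o = np.isfinite(y[i])
        if not o.any():
            continue
        wo = w[o]
        m = np.linalg.inv(eye_k + wo.T @ wo / sigma2)
        out[i] = m @ wo.T @ y[i, o] / sigma2
    out = out @ np.linalg.inv(rot).T
    return pd.DataFrame(out, index=matrix.index, columns=model.scores.columns)


# ---------------------------------------------------------------------------
# Multiple imputation
# ---------------------------------------------------------------------------

def impute(matrix: pd.DataFrame, n_imputations: int = 50, seed: int = 0,
           n_sweeps: int = 5, ridge: float = 1e-3) -> list[pd.DataFrame]:
    """Bayesian chained-equation imputations of a feature matrix.

    Each imputation runs `n_sweeps` Gibbs-style sweeps: every column with
    missing entries is regressed (ridge-stabilized Bayesian linear model) on
    all other columns, regression coefficients and residual variance are
    drawn from their posterior, and missing entries are filled with draws
    from the posterior predictive. Columns with fewer than 3 observations
    are mean-imputed with a warning. Imputation k is reproducible from
    (seed, k).
    """
    if matrix.isna().to_numpy().mean() >= 0.5:
        raise ValueError("more than 50% of entries are missing")
    z, mean0, sd0 = standardize(matrix)
    zv = z.to_numpy(float)
    n, p = zv.shape
    miss = ~np.isfinite(zv)
    sparse_cols = [j for j in range(p) if (~miss[:, j]).sum() < 3]
    if sparse_cols:
        warnings.warn("columns with <3 observations are mean-imputed")
    out = []
    for k in range(n_imputations):
        rng = np.random.default_rng([int(seed) % (2**31), k])
        x = zv.copy()
        for j in range(p):
            col = x[:, j]
            col[miss[:, j]] = 0.0  # standardized mean
        if miss.any():
            for _ in range(n_sweeps):
                for j in range(p):
                    mj = miss[:, j]
                    if not mj.any() or j in sparse_cols:
                        continue
                    others = [c for c in range(p) if c != j]
                    xo = np.column_stack([np.ones(n), x[:, others]])
                    obs = ~mj
                    a = xo[obs].T @ xo[obs] + ridge * np.eye(xo.shape[1])
                    b = xo[obs].T @ x[obs, j]
                    ainv = np.linalg.inv(a)
                    beta_hat = ainv @ b
                    resid = x[obs, j] - xo[obs] @ beta_hat
                    dof = max(int(obs.sum()) - xo.shape[1], 1)
                    sigma2 = float(resid @ resid) / sps.chi2.rvs(dof, random_state=rng)
                    beta = rng.multivariate_normal(
                        beta_hat, sigma2 * ainv, method="cholesky")
                    x[mj, j] = xo[mj] @ beta + np.sqrt(sigma2) * rng.standard_normal(mj.sum())
        frame = pd.DataFrame(x, index=matrix.index, columns=matrix.columns)
        out.append(frame * sd0 + mean0)
    return out


# ---------------------------------------------------------------------------
# Cloud geometry and heterogeneity
# ---------------------------------------------------------------------------

def cloud_median_distance(points, metric: str = "euclidean") -> float:
    """Median of all pairwise distances of a point cloud."""
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 points")
    return float(np.median(pdist(x, metric=metric)))


def agnes_coefficient(points) -> float:
    """Agglomerative nesting coefficient (average linkage, Euclidean).

    For each observation, m(i) = (height of its first merge) / (height of
    the final merge); the coefficient is mean(1 - m(i)). 0 for evenly
    spread points, -> 1 for tight well-separated clusters.
    """
    x = np.asarray(points, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 points")
    z = linkage(x, method="average")
    n = x.shape[0]
    final = z[-1, 2]
    if final <= 0:
        return 0.0
    first = np.full(n, np.nan)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        for cl in (a, b):
            if cl < n and np.isnan(first[cl]):
                first[cl] = h
        members[n + step] = members.pop(a) + members.pop(b)
    return float(np.mean(1.0 - first / final))


def local_pca_variance(points, n_components: int = 2) -> float:
    """Share of total variance captured by the first components of a
    standard PCA on standardized columns of one group's (complete) matrix."""
    x = np.asarray(points, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 points")
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=min(n_components, min(z.shape) - 1), svd_solver="full")
    pca.fit(z)
    return float(np.sum(pca.explained_variance_ratio_))


def ordination_quality(coords_2d, full_points) -> float:
    """Squared Pearson correlation between 2D and full-space pairwise distances."""
    d2 = pdist(np.asarray(coords_2d, dtype=float))
    df = pdist(np.asarray(full_points, dtype=float))
    if d2.size != df.size:
        raise ValueError("coordinate sets must describe the same points")
    if np.std(d2) == 0 or np.std(df) == 0:
        return np.nan
    r, _ = sps.pearsonr(d2, df)
    return float(r**2)


def imputed_subsample_stat(matrix: pd.DataFrame, stat, n_imputations: int = 50,
                           n_subsamples: int = 10, subsample_size: int = 50,
                           seed: int = 0, standardize_input: bool = True) -> np.ndarray:
    """Evaluate a cloud statistic over imputations x subsamples.

    For each of `n_imputations` chained-equation imputations, draws
    `n_subsamples` subsets of `subsample_size` cells (without replacement)
    and applies `stat` (an array -> float callable) to the standardized
    subset. Returns the flat array of n_imputations * n_subsamples values.
    """
    completed = impute(matrix, n_imputations=n_imputations, seed=seed)
    values = []
    for k, frame in enumerate(completed):
        if standardize_input:
            z, _, _ = standardize(frame)
        else:
            z = frame
        arr = z.to_numpy(float)
        rng = np.random.default_rng([int(seed) % (2**31), 10_000 + k])
        n = arr.shape[0]
        size = min(subsample_size, n)
        for _ in range(n_subsamples):
            idx = rng.choice(n, size=size, replace=False)
            values.append(float(stat(arr[idx])))
    return np.asarray(values)


def compare_cloud_sizes(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                        metric: str = "cityblock", n_imputations: int = 50,
                        n_subsamples: int = 10, subsample_size: int = 50,
                        seed: int = 0) -> dict:
    """Median pairwise-distance cloud sizes of two groups, with a Welch t-test.

    Runs the full multiple-imputation + subsampling procedure on each group
    and compares the resulting sets of medians. Standardization is joint
    (columns scaled by the pooled mean and SD), so between-group differences
    in spread are preserved.
    """
    pooled = pd.concat([matrix_a, matrix_b], axis=0)
    _, mean, sd = standardize(pooled)
    za = (matrix_a - mean) / sd
    zb = (matrix_b - mean) / sd
    stat = lambda x: cloud_median_distance(x, metric=metric)  # noqa: E731
    a = imputed_subsample_stat(za, stat, n_imputations, n_subsamples,
                               subsample_size, seed=seed, standardize_input=False)
    b = imputed_subsample_stat(zb, stat, n_imputations, n_subsamples,
                               subsample_size, seed=seed + 1, standardize_input=False)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return {"medians_a": a, "medians_b": b, "mean_a": float(a.mean()),
            "mean_b": float(b.mean()), "ratio": float(b.mean() / a.mean()),
            "t": float(t), "p": float(p)}


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def variance_ratio_test(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """F-test for equality of variances of two samples.

    ``alternative='greater'`` tests for var(b) > var(a) -- the directional
    question "did variability increase?" that variance-inflation screens ask.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        return np.nan, np.nan
    f = np.var(a, ddof=1) / np.var(b, ddof=1)
    dfa, dfb = a.size - 1, b.size - 1
    if alternative == "greater":
        p = sps.f.cdf(f, dfa, dfb)  # small f = var(b) inflated
    elif alternative == "two-sided":
        p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    return float(f), float(min(p, 1.0))


def _eta_squared(groups: list[np.ndarray]) -> float:
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand)**2 for g in groups)
    ss_total = float(np.sum((allv - grand)**2))
    return float(ss_between / ss_total) if ss_total > 0 else np.nan


def group_compare(matrix: pd.DataFrame, grouping, min_n: int = 3,
                  correction: str | None = "fdr_bh",
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable comparison across groups.

    For two groups: Mann-Whitney rank-sum p, Welch t-test p and the
    variance-ratio F-test p; for any number of groups: one-way ANOVA p and
    the eta-squared effect size (SS_between / SS_total). Group means, SDs
    and the direction of change are reported alongside. `correction`
    ("fdr_bh", "bonferroni" or None) adds adjusted significance masks per
    test family.
    """
    grouping = pd.Series(grouping, index=matrix.index)
    levels = [g for g in pd.unique(grouping) if pd.notna(g)]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for var in matrix.columns:
        samples = []
        stats_row: dict = {"variable": var}
        for g in levels:
            vals = matrix.loc[grouping == g, var].dropna().to_numpy(float)
            samples.append(vals)
            stats_row[f"mean_{g}"] = vals.mean() if vals.size else np.nan
            stats_row[f"sd_{g}"] = vals.std(ddof=1) if vals.size > 1 else np.nan
        usable = [s for s in samples if s.size >= min_n]
        if len(usable) < 2:
            rows.append(stats_row)
            continue
        if len(samples) == 2 and all(s.size >= min_n for s in samples):
            a, b = samples
            try:
                stats_row["p_mw"] = float(sps.mannwhitneyu(
                    a, b, alternative="two-sided").pvalue)
            except ValueError:
                stats_row["p_mw"] = 1.0
            stats_row["p_welch"] = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
            _, stats_row["p_var"] = variance_ratio_test(a, b)
            stats_row["direction"] = float(np.sign(b.mean() - a.mean()))
        if all(s.size >= min_n for s in samples):
            if all(np.std(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
                stats_row["p_anova"] = 1.0
            else:
                stats_row["p_anova"] = float(sps.f_oneway(*samples).pvalue)
            stats_row["eta_sq"] = _eta_squared(samples)
        rows.append(stats_row)
    table = pd.DataFrame(rows).set_index("variable")
    if correction:
        for col in ("p_mw", "p_anova", "p_var", "p_welch"):
            if col in table:
                p = table[col].to_numpy(float)
                sig = np.zeros(p.size, dtype=bool)
                finite = np.isfinite(p)
                if finite.any():
                    sig[finite] = multipletests(p[finite], alpha=alpha,
                                                method=correction)[0]
                table[f"sig_{col[2:]}"] = sig
    return table


# ---------------------------------------------------------------------------
# Sequential regression
# ---------------------------------------------------------------------------

def sequential_regression(matrix: pd.DataFrame, response: str,
                          predictors: list[str],
                          include_interactions: bool = False) -> pd.DataFrame:
    """Sequential (type-I) variance partitioning of a linear model.

    Terms enter in the given order (pairwise interaction products after the
    main effects when requested); each term's share of total response
    variance is its sequential sum of squares over SS_total, with an F-test
    against the full-model residual. Complete cases only; collinear terms
    are dropped with a warning.
    """
    cols = [response] + list(predictors)
    data = matrix[cols].dropna(axis=0, how="any")
    n = len(data)
    if n < len(predictors) + 2:
        raise ValueError("not enough complete cases")
    y = data[response].to_numpy(float)
    terms: list[tuple[str, np.ndarray]] = [
        (name, data[name].to_numpy(float)) for name in predictors]
    if include_interactions:
        zcols = {name: (data[name] - data[name].mean()).to_numpy(float)
                 for name in predictors}
        for a, b in itertools.combinations(predictors, 2):
            terms.append((f"{a}:{b}", zcols[a] * zcols[b]))
    yc = y - y.mean()
    ss_total = float(yc @ yc)
    design = np.ones((n, 1))
    rss_prev = ss_total
    kept, ss_terms, dropped = [], [], []
    for name, col in terms:
        cand = np.column_stack([design, col])
        if np.linalg.matrix_rank(cand) <= design.shape[1]:
            dropped.append(name)
            continue
        beta, *_ = np.linalg.lstsq(cand, y, rcond=None)
        rss = float(np.sum((y - cand @ beta)**2))
        ss_terms.append(rss_prev - rss)
        kept.append(name)
        design, rss_prev = cand, rss
    if dropped:
        warnings.warn(f"collinear terms dropped: {dropped}")
    df_res = n - design.shape[1]
    ms_res = rss_prev / df_res if df_res > 0 else np.nan
    rows = []
    for name, ss in zip(kept, ss_terms):
        if ms_res and np.isfinite(ms_res) and ms_res > 0:
            f = ss / ms_res
            p = float(sps.f.sf(f, 1, df_res))
        else:
            f, p = np.inf, 0.0
        rows.append({"term": name, "ss": ss,
                     "share": ss / ss_total if ss_total > 0 else np.nan,
                     "F": f, "p_F": p})
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["ss_total"] = ss_total
    out.attrs["rss"] = rss_prev
    out.attrs["n"] = n
    return out


# ---------------------------------------------------------------------------
# Rank renormalization
# ---------------------------------------------------------------------------

def rank_renormalize(values) -> np.ndarray:
    """De-band values by rank-transforming and mapping ranks back to the
    original units with a least-squares cubic polynomial.

    The map is strictly order-preserving (ties broken by stable input
    order); NaNs pass through unchanged.
    """
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    finite = np.isfinite(v)
    x = v[finite]
    if x.size < 4:
        raise ValueError("need at least 4 finite values")
    ranks = sps.rankdata(x, method="ordinal")
    coef = np.polyfit(ranks, x, 3)
    mapped = np.polyval(coef, ranks)
    # enforce strict monotonicity along the rank order
    order = np.argsort(ranks)
    eps = 1e-9 * max(np.ptp(x), 1.0)
    seq = mapped[order]
    for i in range(1, seq.size):
        if seq[i] <= seq[i - 1]:
            seq[i] = seq[i - 1] + eps
    mapped[order] = seq
    out[finite] = mapped
    return out
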