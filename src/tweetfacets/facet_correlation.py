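"""Cross-facet correlation analysis of the condition x variable matrix.

The profile matrix (one row per condition community, one column per variable)
is filtered for very small communities, stripped of the two size totals, and
standardized column-wise.  Two analyses follow:

* pairwise Pearson correlation between each engagement variable and every
  user/content variable;
* first-pair canonical correlation analysis (CCA) between an engagement block
  and a user or content block: find weight vectors a, b maximising
  corr(X a, Y b).  The maximised correlation r is the canonical correlation;
  a, b are the canonical weights, and each variable's correlation with its own
  canonical variate is its canonical loading.

The CCA is solved by Cholesky whitening of the block covariances followed by
an SVD of the whitened cross-covariance — equivalent to the generalized
eigenproblem on Sxx^-1 Sxy Syy^-1 Syx — with an optional ridge term guarding
near-collinear blocks.  Significance and small-sample bias are assessed with a
seeded row-permutation null (an extension; the source analysis reports none).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .community_profile import FACET_OF, TABLE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "CCAResult",
    "ENGAGEMENT_VARS",
    "USER_VARS",
    "CONTENT_VARS",
    "TOTAL_VARS",
    "filter_communities",
    "drop_totals",
    "standardize",
    "pearson",
    "pairwise_engagement_correlation",
    "cca_first",
    "canonical_loadings",
    "permutation_null",
    "adjusted_canonical_correlation",
    "pooled_adjusted_correlation",
    "cross_facet_cca",
    "quartile_engagement_summary",
    "rank_communities",
]

ENGAGEMENT_VARS = [c for c in TABLE_COLUMNS if FACET_OF[c] == "engagement"]
USER_VARS = [c for c in TABLE_COLUMNS if FACET_OF[c] == "user"]
CONTENT_VARS = [c for c in TABLE_COLUMNS if FACET_OF[c] == "content"]
TOTAL_VARS = [c for c in TABLE_COLUMNS if FACET_OF[c] == "totals"]


@dataclass
class ProfileMatrix:
    """Condition x variable matrix with a facet tag per column."""

    data: pd.DataFrame
    facets: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.facets:
            self.facets = {c: FACET_OF.get(c, "other") for c in self.data.columns}
        missing = [c for c in self.data.columns if c not in self.facets]
        if missing:
            raise ValueError(f"columns without a facet tag: {missing}")
        if self.data.isna().any().any():
            raise ValueError("profile matrix contains missing cells")

    def block(self, facet: str) -> pd.DataFrame:
        cols = [c for c in self.data.columns if self.facets[c] == facet]
        return self.data[cols]

    @property
    def conditions(self) -> list[str]:
        return list(self.data.index)


def filter_communities(
    profiles: pd.DataFrame, min_tweets: int = 100, min_users: int = 50
) -> pd.DataFrame:
    """Drop communities with fewer than ``min_tweets`` tweets or ``min_users`` users.

    The bounds are inclusive: a community at exactly (100, 50) is retained.
    """
    keep = (profiles["total_tweets"] >= min_tweets) & (profiles["total_users"] >= min_users)
    excluded = int((~keep).sum())
    if excluded:
        logger.info("filter_communities: excluded %d of %d communities", excluded, len(profiles))
    out = profiles.loc[keep]
    if out.empty:
        raise ValueError(
            f"all {len(profiles)} communities excluded at thresholds "
            f"(min_tweets={min_tweets}, min_users={min_users}); lower them")
    return out


def drop_totals(profiles: pd.DataFrame) -> pd.DataFrame:
    """Remove the size totals from the analysis matrix (idempotent)."""
    return profiles.drop(columns=[c for c in TOTAL_VARS if c in profiles.columns])


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (sample SD, ddof=1); constant columns become zeros."""
    if len(matrix) < 2:
        raise ValueError("standardize: need at least 2 rows")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        logger.warning("standardize: zero-variance column(s) set to 0: %s", degenerate)
    sd = sd.replace(0.0, 1.0)
    return (matrix - mean) / sd


def pearson(x, y) -> float:
    """Product-moment correlation; NaN (flagged) when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson: need equal-length vectors with >= 3 entries")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("pearson: zero-variance input; correlation undefined")
        return float("nan")
    return float(scipy.stats.pearsonr(x, y).statistic)


def pairwise_engagement_correlation(matrix: ProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson r of every engagement variable against every user/content variable.

    Returns a table (engagement_var, other_var, facet, r, n) sorted by |r|
    descending, ties by variable names.
    """
    pm = matrix if isinstance(matrix, ProfileMatrix) else ProfileMatrix(matrix)
    df = pm.data
    eng = [c for c in df.columns if pm.facets[c] == "engagement"]
    others = [c for c in df.columns if pm.facets[c] in ("user", "content")]
    rows = []
    for e in eng:
        for o in others:
            rows.append({
                "engagement_var": e,
                "other_var": o,
                "facet": pm.facets[o],
                "r": pearson(df[e], df[o]),
                "n": len(df),
            })
    out = pd.DataFrame(rows, columns=["engagement_var", "other_var", "facet", "r", "n"])
    if not out.empty:
        out = out.reindex(
            out.assign(abs_r=out["r"].abs().fillna(-1.0))
            .sort_values(["abs_r", "engagement_var", "other_var"],
                         ascending=[False, True, True]).index
        ).reset_index(drop=True)
    return out


@dataclass
class CCAResult:
    """First canonical pair between two variable blocks."""

    r: float
    weights_x: pd.Series
    weights_y: pd.Series
    loadings_x: pd.Series
    loadings_y: pd.Series
    variate_x: pd.Series
    variate_y: pd.Series
    n: int


def _offending_columns(block: pd.DataFrame, tol: float = 1e-10) -> list[str]:
    """Columns rendering a centered block rank-deficient (QR with pivoting)."""
    arr = np.asarray(block, dtype=float)
    arr = arr - arr.mean(axis=0)
    _, r_mat, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r_mat))
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    bad = [block.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol * scale]
    bad += [block.columns[p] for p in piv[len(diag):]]
    return sorted(map(str, bad))


def cca_first(X: pd.DataFrame, Y: pd.DataFrame, ridge: float = 1e-8) -> CCAResult:
    """First-pair canonical correlation between blocks X and Y.

    Expects blocks on comparable (ideally standardized) scales with the same
    rows and more rows than columns in each block.  Weights are scaled so each
    canonical variate has unit sample variance; the signs of both weight
    vectors are flipped together so the X variable with the largest |weight|
    gets a positive weight, keeping corr(CX, CY) = r >= 0.
    """
    if list(X.index) != list(Y.index):
        raise ValueError("cca_first: X and Y must share the same rows")
    n, p = X.shape
    q = Y.shape[1]
    if n <= max(p, q):
        raise ValueError(f"cca_first: need more rows ({n}) than columns ({max(p, q)})")
    Xc = np.asarray(X, dtype=float)
    Yc = np.asarray(Y, dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    Yc = Yc - Yc.mean(axis=0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    if ridge:
        # relative ridge keeps r exactly invariant to per-column rescaling
        Sxx = Sxx + ridge * np.diag(np.diag(Sxx))
        Syy = Syy + ridge * np.diag(np.diag(Syy))
    else:
        for block, cov in ((X, Sxx), (Y, Syy)):
            eig = np.linalg.eigvalsh(cov)
            if eig[0] <= 1e-10 * max(eig[-1], 1e-300):
                raise np.linalg.LinAlgError(
                    "cca_first: rank-deficient block (offending columns: "
                    f"{_offending_columns(block)}); set ridge > 0")
    try:
        Lx = np.linalg.cholesky(Sxx)
        Ly = np.linalg.cholesky(Syy)
    except np.linalg.LinAlgError as exc:
        bad = _offending_columns(X) + _offending_columns(Y)
        raise np.linalg.LinAlgError(
            f"cca_first: rank-deficient block (offending columns: {bad}); "
            "set ridge > 0") from exc
    K = scipy.linalg.solve_triangular(Lx, Sxy, lower=True)
    K = scipy.linalg.solve_triangular(Ly, K.T, lower=True).T
    U, s, Vt = np.linalg.svd(K)
    r = float(min(s[0], 1.0))
    a = scipy.linalg.solve_triangular(Lx.T, U[:, 0], lower=False)
    b = scipy.linalg.solve_triangular(Ly.T, Vt[0], lower=False)
    # flip both together: largest-|weight| X variable positive, r unchanged
    if a[int(np.argmax(np.abs(a)))] < 0:
        a, b = -a, -b
    cx = Xc @ a
    cy = Yc @ b
    weights_x = pd.Series(a, index=X.columns, name="weight_x")
    weights_y = pd.Series(b, index=Y.columns, name="weight_y")
    variate_x = pd.Series(cx, index=X.index, name="CX")
    variate_y = pd.Series(cy, index=Y.index, name="CY")
    return CCAResult(
        r=r,
        weights_x=weights_x,
        weights_y=weights_y,
        loadings_x=canonical_loadings(X, variate_x),
        loadings_y=canonical_loadings(Y, variate_y),
        variate_x=variate_x,
        variate_y=variate_y,
        n=n,
    )


def canonical_loadings(block: pd.DataFrame, variate: pd.Series) -> pd.Series:
    """Correlation of every block column with the canonical variate.

    Zero-variance columns yield NaN (flagged in the log by :func:`pearson`).
    """
    if list(block.index) != list(variate.index):
        raise ValueError("canonical_loadings: variate rows differ from block rows")
    vals = {c: pearson(block[c], variate) for c in block.columns}
    return pd.Series(vals, name="loading")


def permutation_null(
    X: pd.DataFrame, Y: pd.DataFrame, n_perm: int = 999,
    rng: np.random.Generator | int | None = None, ridge: float = 1e-8,
    strata: np.ndarray | None = None, n_strata: int = 10,
) -> np.ndarray:
    """Canonical correlations under row permutation of Y (the independence null).

    When ``strata`` is given (one size value per row, e.g. total tweets), rows
    are permuted only within ``n_strata`` equal-count size bands.  Profile
    variables of small communities are uniformly noisier in both blocks; the
    restricted permutation preserves that shared heteroscedasticity under the
    null instead of mistaking it for cross-facet signal.
    """
    rng = np.random.default_rng(rng)
    ys = np.asarray(Y, dtype=float)
    n = len(ys)
    if strata is not None:
        strata = np.asarray(strata)
        if strata.shape[0] != n:
            raise ValueError("permutation_null: strata must have one value per row")
        bands = np.array_split(np.argsort(strata, kind="stable"), min(n_strata, n))
    out = np.empty(n_perm)
    for i in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for band in bands:
                perm[band] = rng.permutation(perm[band])
        yp = pd.DataFrame(ys[perm], index=Y.index, columns=Y.columns)
        out[i] = cca_first(X, yp, ridge=ridge).r
    return out


def adjusted_canonical_correlation(r: float, null_rs: np.ndarray) -> float:
    """Small-sample-debiased canonical correlation.

    The leading squared canonical correlation under a low-rank signal inflates
    approximately by the null (permutation) eigenvalue level scaled by the
    residual variance, so the permutation mean is subtracted on the squared
    scale and renormalized — the same observed-minus-expected over
    max-minus-expected form as a chance-adjusted index:
    r_adj = sqrt(max(0, (r^2 - m) / (1 - m))) with m = mean(r_null^2).
    """
    m = float(np.mean(np.square(null_rs)))
    if m >= 1.0:
        return 0.0
    return float(np.sqrt(max(0.0, (r**2 - m) / (1.0 - m))))


def pooled_adjusted_correlation(rs, null_means_sq) -> float:
    """Combine per-replicate canonical correlations into one debiased estimate.

    Averages the chance-adjusted *squared* correlations (signed, so replicate
    noise cancels instead of folding at zero) across replicates before taking
    the root: sqrt(max(0, mean((r_i^2 - m_i) / (1 - m_i)))) where m_i is the
    replicate's mean squared permutation-null correlation.
    """
    rs = np.asarray(rs, dtype=float)
    ms = np.asarray(null_means_sq, dtype=float)
    if rs.shape != ms.shape or rs.size == 0:
        raise ValueError("pooled_adjusted_correlation: need matching non-empty arrays")
    adj_sq = (rs**2 - ms) / (1.0 - ms)
    return float(np.sqrt(max(0.0, float(np.mean(adj_sq)))))


def cross_facet_cca(
    profiles: pd.DataFrame,
    facet: str = "content",
    min_tweets: int = 100,
    min_users: int = 50,
    ridge: float = 1e-8,
    n_perm: int = 0,
    rng: np.random.Generator | int | None = None,
    stratify_by_size: bool = True,
) -> tuple[CCAResult, dict]:
    """Filter, standardize and run first-pair CCA of a facet against engagement.

    Returns the CCA result plus a stats dict with the retained community count
    and, when ``n_perm > 0``, the permutation p-value and the bias-adjusted
    canonical correlation.  The permutation null is stratified by community
    size (total tweets) unless ``stratify_by_size`` is off.
    """
    kept = filter_communities(profiles, min_tweets=min_tweets, min_users=min_users)
    z = standardize(drop_totals(kept))
    pm = ProfileMatrix(z)
    X = pm.block(facet)
    Y = pm.block("engagement")
    if X.empty or Y.empty:
        raise ValueError(f"cross_facet_cca: no columns for facet {facet!r}")
    res = cca_first(X, Y, ridge=ridge)
    stats: dict = {"n_communities": res.n, "facet": facet}
    if n_perm > 0:
        strata = kept["total_tweets"].to_numpy() if stratify_by_size else None
        null = permutation_null(X, Y, n_perm=n_perm, rng=rng, ridge=ridge,
                                strata=strata)
        stats["p_value"] = float((1 + np.sum(null >= res.r)) / (n_perm + 1))
        stats["null_mean_r"] = float(null.mean())
        stats["null_mean_sq"] = float(np.mean(np.square(null)))
        stats["r_adjusted"] = adjusted_canonical_correlation(res.r, null)
    return res, stats


def quartile_engagement_summary(profiles: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Split communities into quartile bands of ``variable``.

    Per band: the variable's min-max range, the number of communities, and the
    mean community size in users.  Band edges are type-7 quartiles; bands are
    closed on the right (a community at exactly Q1 falls in the first band).
    """
    if variable not in profiles.columns:
        raise KeyError(variable)
    if len(profiles) < 4:
        raise ValueError("quartile_engagement_summary: need >= 4 communities")
    v = profiles[variable].to_numpy(dtype=float)
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    band = np.digitize(v, [q1, q2, q3], right=True)  # 0..3
    rows = []
    labels = ["0-25%", "25-50%", "50-75%", "75-100%"]
    for b in range(4):
        mask = band == b
        sub = profiles.loc[mask]
        rows.append({
            "variable": variable,
            "quartile": labels[b],
            "value_min": float(v[mask].min()) if mask.any() else float("nan"),
            "value_max": float(v[mask].max()) if mask.any() else float("nan"),
            "n_communities": int(mask.sum()),
            "mean_total_users": float(sub["total_users"].mean()) if mask.any() else float("nan"),
        })
    return pd.DataFrame(rows)


def rank_communities(
    profiles: pd.DataFrame, by: str = "tweets", k: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k and bottom-k communities by total tweets or users.

    Ties are broken by condition name ascending, so the ordering is
    deterministic.  Returns (top, bottom), each with the ranking column.
    """
    col = {"tweets": "total_tweets", "users": "total_users"}.get(by)
    if col is None:
        raise ValueError(f"rank_communities: by must be 'tweets' or 'users', got {by!r}")
    if k > len(profiles) // 2:
        raise ValueError(f"rank_communities: k={k} exceeds half of {len(profiles)} communities")
    df = profiles[[col]].rename_axis("condition").reset_index()
    top = df.sort_values([col, "condition"], ascending=[False, True]).head(k)
    bottom = df.sort_values([col, "condition"], ascending=[True, True]).head(k)
    return top.reset_index(drop=True), bottom.reset_index(drop=True)
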