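"""Bulk and cell-type-specific methylome-wide association testing.

Every CpG is tested against a binary treatment with measured covariates,
estimated cell-type proportions and latent-confounder principal components
in the design.  The bulk model is ordinary OLS with the treatment
coefficient tested; the cell-type model is the statistical-deconvolution
interaction regression

    m = sum_k p_k * alpha_k + sum_k (p_k * x) * beta_k + covariates + PCs

with no global intercept (the proportion main effects sum to the intercept
role because proportions sum to one); each interaction coefficient beta_k is
the treatment effect in cell type k.  Effect sizes are reported as partial
correlations r = t / sqrt(t^2 + df), which are scale-free in the methylation
scores.  Multiplicity is controlled by Benjamini-Hochberg q-values within
each analysis unit (methylome-wide significance q < 0.1) with a suggestive
threshold of p < 1e-6, and test calibration is monitored by the genomic
inflation factor lambda.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: methylome-wide significance: FDR controlled at this q-value level
Q_SIGNIFICANT = 0.1
#: suggestive significance p-value threshold
P_SUGGESTIVE = 1e-6

#: median of the chi-square distribution with 1 df (lambda denominator)
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

DEFAULT_COVARIATES = (
    "sex",
    "birth_year",
    "gestational_age",
    "batch",
    "enrichment_efficiency",
    "pct_aligned",
)

RESULT_COLUMNS = [
    "chrom",
    "pos",
    "analysis_unit",
    "beta",
    "t",
    "df",
    "partial_r",
    "p",
    "q",
    "suggestive",
    "significant",
    "reason_code",
]


class DesignError(ValueError):
    """Raised for unusable regression designs (rank deficiency, single class)."""


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_covariate_design(
    metadata: pd.DataFrame, covariates: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Numeric covariate design from a metadata table (no intercept column).

    Categorical columns (``batch``) are dummy coded with the first level as
    reference; every column is centered and scaled to unit variance (constant
    columns are dropped).  The treatment column is never included.
    """
    names = covariates if covariates is not None else DEFAULT_COVARIATES
    cols: dict[str, np.ndarray] = {}
    for name in names:
        if name == "treatment":
            raise DesignError("treatment is the tested variable, not a covariate")
        if name not in metadata.columns:
            continue
        col = metadata[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for dname in dummies.columns:
                cols[dname] = dummies[dname].to_numpy()
        else:
            cols[name] = col.to_numpy(float)
    out = {}
    for name, v in cols.items():
        sd = v.std()
        if sd == 0:
            continue
        out[name] = (v - v.mean()) / sd
    return pd.DataFrame(out, index=metadata.index)


def _aliased_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns linearly dependent on the columns preceding them (greedy QR)."""
    aliased = []
    kept: list[int] = []
    for k in range(x.shape[1]):
        cand = x[:, kept + [k]]
        if np.linalg.matrix_rank(cand) <= len(kept):
            aliased.append(names[k])
        else:
            kept.append(k)
    return aliased


def residualize_covariates(meth: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Replace every CpG's scores by OLS residuals on [intercept + covariates].

    With ``covariates=None`` this centers each CpG.  Raises
    :class:`DesignError` listing the aliased columns if the design is
    rank-deficient.
    """
    n = meth.shape[1]
    if covariates is None or covariates.shape[1] == 0:
        x = np.ones((n, 1))
        names = ["intercept"]
    else:
        if not covariates.index.equals(meth.columns):
            covariates = covariates.loc[meth.columns]
        x = np.column_stack([np.ones(n), covariates.to_numpy(float)])
        names = ["intercept"] + list(covariates.columns)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError(
            f"rank-deficient covariate design; aliased columns: {_aliased_columns(x, names)}"
        )
    m = meth.to_numpy(float).T  # n x J
    coef, *_ = np.linalg.lstsq(x, m, rcond=None)
    resid = m - x @ coef
    return pd.DataFrame(resid.T, index=meth.index, columns=meth.columns)


def select_principal_components(
    residuals: pd.DataFrame, mode: str = "fixed", n_fixed: int = 2
) -> tuple[int, pd.DataFrame]:
    """Principal components of the covariate-residualized methylation data.

    Per-CpG residuals are standardized, the sample x sample covariance is
    eigendecomposed, and sample-level PC scores are returned.  ``fixed`` mode
    returns ``n_fixed`` components (default 2); ``elbow`` picks the count
    maximizing the second difference of the sorted eigenvalue curve, the
    numerical analogue of reading a scree plot.
    """
    n = residuals.shape[1]
    if n < 3:
        raise DesignError("need at least 3 samples for PCA")
    if mode not in ("fixed", "elbow"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fixed" and n_fixed >= n:
        raise DesignError(f"n_fixed={n_fixed} must be below the sample count {n}")
    m = residuals.to_numpy(float)
    sd = m.std(axis=1, ddof=0)
    keep = sd > 0
    z = (m[keep] - m[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    cov = (z.T @ z) / max(z.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if mode == "fixed":
        n_pcs = n_fixed
    else:
        lam = np.clip(evals, 0, None)
        if len(lam) < 3:
            n_pcs = 1
        else:
            second_diff = lam[:-2] - 2 * lam[1:-1] + lam[2:]
            n_pcs = int(np.argmax(second_diff)) + 1
    scores = evecs[:, :n_pcs] * np.sqrt(np.clip(evals[:n_pcs], 0, None))
    pcs = pd.DataFrame(
        scores, index=residuals.columns, columns=[f"PC{i+1}" for i in range(n_pcs)]
    )
    return n_pcs, pcs


# ---------------------------------------------------------------------------
# association testing
# ---------------------------------------------------------------------------

def _check_treatment(x: np.ndarray) -> None:
    if len(np.unique(x)) < 2:
        raise DesignError("treatment must contain both classes")


def _vectorized_ols(
    x: np.ndarray, m: np.ndarray, test_cols: list[int]
) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS of every CpG (columns of m, n x J) on the shared design x.

    Returns (betas, ts, df) where betas/ts have shape (len(test_cols), J).
    """
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise DesignError(
            f"rank-deficient design; aliased columns at indices "
            f"{_aliased_columns(x, [str(i) for i in range(p)])}"
        )
    df = n - rank
    if df <= 0:
        raise DesignError(f"no residual degrees of freedom (n={n}, rank={rank})")
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ (x.T @ m)  # p x J
    resid = m - x @ coef
    sigma2 = (resid**2).sum(axis=0) / df
    betas = coef[test_cols]
    ses = np.sqrt(np.outer(np.diag(xtx_inv)[test_cols], sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = betas / ses
    return betas, ts, df


def _assemble_results(
    index: pd.MultiIndex,
    unit: str,
    beta: np.ndarray,
    t: np.ndarray,
    df: int,
    invalid: np.ndarray,
    reason: np.ndarray,
    q_threshold: float,
    suggestive_threshold: float,
) -> pd.DataFrame:
    t = np.where(invalid, np.nan, t)
    beta = np.where(invalid, np.nan, beta)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
        r = t / np.sqrt(t**2 + df)
    p = np.where(invalid, np.nan, p)
    # a t of exactly 0 gives p = 1.0, inside the (0, 1] contract
    q = bh_qvalues(p)
    out = pd.DataFrame(
        {
            "chrom": index.get_level_values("chrom"),
            "pos": index.get_level_values("pos").astype(np.int64),
            "analysis_unit": unit,
            "beta": beta,
            "t": t,
            "df": df,
            "partial_r": r,
            "p": p,
            "q": q,
            "suggestive": p < suggestive_threshold,
            "significant": q < q_threshold,
            "reason_code": reason,
        },
        columns=RESULT_COLUMNS,
    )
    return out


def run_bulk_mwas(
    meth: pd.DataFrame,
    metadata: pd.DataFrame,
    proportions: pd.DataFrame | None = None,
    pcs: pd.DataFrame | None = None,
    covariates: tuple[str, ...] | None = None,
    q_threshold: float = Q_SIGNIFICANT,
    suggestive_threshold: float = P_SUGGESTIVE,
) -> pd.DataFrame:
    """Whole-blood MWAS: per CpG, OLS of scores on treatment plus covariates.

    The design is [intercept, treatment, covariates, K-1 cell proportions,
    PCs]; the last declared cell type is dropped to avoid collinearity with
    the intercept (proportions sum to one).  Reports the treatment
    coefficient with t, df = n - rank(design), two-sided p from the t
    distribution, partial correlation r = t/sqrt(t^2+df), and BH q.  CpGs
    with zero variance are reported with undefined p and excluded from the
    multiplicity count.
    """
    x_t = metadata.loc[meth.columns, "treatment"].to_numpy(float)
    _check_treatment(x_t)
    z = build_covariate_design(metadata.loc[meth.columns], covariates)
    parts = [np.ones((len(x_t), 1)), x_t[:, None], z.to_numpy()]
    if proportions is not None and proportions.shape[1] > 1:
        p_mat = proportions.loc[meth.columns].to_numpy(float)
        parts.append(p_mat[:, :-1])  # drop last cell type
    if pcs is not None and pcs.shape[1] > 0:
        parts.append(pcs.loc[meth.columns].to_numpy(float))
    design = np.column_stack(parts)
    m = meth.to_numpy(float).T
    zero_var = m.std(axis=0) == 0
    betas, ts, df = _vectorized_ols(design, m, [1])
    reason = np.where(zero_var, "zero_variance", "")
    return _assemble_results(
        meth.index, "bulk", betas[0], ts[0], df, zero_var, reason,
        q_threshold, suggestive_threshold,
    )


def run_celltype_mwas(
    meth: pd.DataFrame,
    metadata: pd.DataFrame,
    proportions: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    covariates: tuple[str, ...] | None = None,
    q_threshold: float = Q_SIGNIFICANT,
    suggestive_threshold: float = P_SUGGESTIVE,
    condition_limit: float = 1e8,
) -> pd.DataFrame:
    """Cell-type-specific MWAS via the deconvolution interaction regression.

    Per CpG fits ``m = sum_k p_k a_k + sum_k (p_k x) b_k + covariates + PCs``
    without a global intercept and tests each proportion-by-treatment
    interaction coefficient b_k, yielding one analysis unit per cell type
    (K rows per CpG).  If the interaction design is near-collinear
    (condition number above ``condition_limit``) all CpGs are flagged
    unstable with undefined p rather than reporting unreliable tests.
    """
    x_t = metadata.loc[meth.columns, "treatment"].to_numpy(float)
    _check_treatment(x_t)
    props = proportions.loc[meth.columns]
    row_sums = props.to_numpy(float).sum(axis=1)
    if np.abs(row_sums - 1.0).max() > 1e-6 or (props.to_numpy() < -1e-12).any():
        raise DesignError("proportion rows must be nonnegative and sum to 1")
    cell_types = list(props.columns)
    k = len(cell_types)
    z = build_covariate_design(metadata.loc[meth.columns], covariates)
    p_mat = props.to_numpy(float)
    parts = [p_mat, p_mat * x_t[:, None], z.to_numpy()]
    if pcs is not None and pcs.shape[1] > 0:
        parts.append(pcs.loc[meth.columns].to_numpy(float))
    design = np.column_stack(parts)
    unstable = np.linalg.cond(design) > condition_limit
    m = meth.to_numpy(float).T
    zero_var = m.std(axis=0) == 0
    test_cols = list(range(k, 2 * k))
    betas, ts, df = _vectorized_ols(design, m, test_cols)
    frames = []
    for ki, cell in enumerate(cell_types):
        invalid = zero_var | unstable
        reason = np.where(
            zero_var, "zero_variance", "unstable_design" if unstable else ""
        )
        frames.append(
            _assemble_results(
                meth.index, cell, betas[ki], ts[ki], df, invalid, reason,
                q_threshold, suggestive_threshold,
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# supporting statistics
# ---------------------------------------------------------------------------

def bh_qvalues(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values are propagated.

    q_(i) = min_{j >= i} p_(j) * m / j capped at 1, with m the number of
    non-missing p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] <= 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full_like(p, np.nan)
    if mask.sum() > 0:
        _, q_valid, _, _ = multipletests(p[mask], method="fdr_bh")
        q[mask] = q_valid
    return q


def genomic_inflation_lambda(pvalues: np.ndarray | pd.Series) -> float:
    """Genomic inflation factor: median observed chi-square over null median.

    Two-sided p-values are converted to squared z-scores; lambda is their
    median divided by the chi-square(1 df) median (~0.4549).  A value near 1
    indicates calibrated tests.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 100:
        raise ValueError(f"need at least 100 p-values, got {len(p)}")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    z2 = stats.norm.isf(p / 2.0) ** 2
    return float(np.median(z2) / _CHI2_1_MEDIAN)


def binary_correlation(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of two 0/1 vectors with a two-sided t-test p.

    Used e.g. to check that treatment assignment is uncorrelated with a
    later binary outcome (a confounding check); equals the phi coefficient
    of the 2x2 table.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    for name, v in (("a", a), ("b", b)):
        if len(np.unique(v)) < 2:
            raise ValueError(f"vector {name} is constant")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
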