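"""Reference-based estimation of per-sample cell-type proportions.

Each sample's methylation scores at CpGs shared with a purified-cell
reference panel are regressed on the panel profiles under a nonnegativity
constraint; the solution is renormalized to the simplex.  This is the
standard reference-based deconvolution input for cell-type-specific MWAS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls


class PanelError(ValueError):
    """Raised for unusable reference panels (no shared sites, collinearity)."""


def _validate_panel(panel: pd.DataFrame) -> None:
    if panel.shape[1] < 2:
        raise PanelError("reference panel needs at least 2 cell types")
    if panel.index.duplicated().any():
        dups = panel.index[panel.index.duplicated()].tolist()[:5]
        raise PanelError(f"duplicate CpG keys in panel: {dups}")
    if not np.isfinite(panel.to_numpy()).all():
        raise PanelError("reference panel contains non-finite entries")


def _check_rank(a: np.ndarray, cell_types: list[str]) -> None:
    rank = np.linalg.matrix_rank(a)
    if rank < a.shape[1]:
        # name the collinear columns: those whose residual on the others is ~0
        collinear = []
        for k in range(a.shape[1]):
            others = np.delete(a, k, axis=1)
            coef, *_ = np.linalg.lstsq(others, a[:, k], rcond=None)
            resid = a[:, k] - others @ coef
            denom = np.linalg.norm(a[:, k])
            if denom == 0 or np.linalg.norm(resid) / denom < 1e-8:
                collinear.append(cell_types[k])
        raise PanelError(
            "reference panel is rank-deficient on the shared sites; "
            f"collinear cell types: {collinear or cell_types}"
        )


def _solve_qp(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least squares on the probability simplex (nonneg + sum-to-one)."""
    k = a.shape[1]
    x0 = np.full(k, 1.0 / k)
    res = minimize(
        lambda w: 0.5 * np.sum((a @ w - b) ** 2),
        x0,
        jac=lambda w: a.T @ (a @ w - b),
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return np.clip(res.x, 0.0, None)


def estimate_proportions(
    meth: pd.DataFrame,
    panel: pd.DataFrame,
    site_subset: pd.MultiIndex | None = None,
    method: str = "nnls",
) -> pd.DataFrame:
    """Estimate simplex cell-type weights for every sample.

    Parameters
    ----------
    meth : DataFrame, (chrom, pos) x sample
        CpG methylation scores.
    panel : DataFrame, (chrom, pos) x cell type
        Reference profiles of purified cell types.
    site_subset : optional
        Restrict the fit to these CpG keys (intersected with the shared set).
    method : {"nnls", "qp"}
        ``nnls`` (default): nonnegative least squares followed by sum-to-one
        renormalization.  ``qp``: least squares constrained to the simplex.

    Returns
    -------
    DataFrame, sample x cell type, rows nonnegative and summing to 1.

    Notes
    -----
    Estimates are computed on the intersection of CpG keys, so CpGs absent
    from the panel never influence the fit.  The fit is not invariant to
    rescaling the scores of a sample unless the panel is rescaled
    identically, because the regression compares absolute score levels.
    """
    _validate_panel(panel)
    shared = meth.index.intersection(panel.index)
    if site_subset is not None:
        shared = shared.intersection(site_subset)
    if len(shared) == 0:
        raise PanelError("no CpG keys shared between methylation matrix and panel")
    if len(shared) < panel.shape[1]:
        raise PanelError(
            f"only {len(shared)} shared CpGs for {panel.shape[1]} cell types"
        )
    cell_types = list(panel.columns)
    a = panel.loc[shared].to_numpy(float)
    _check_rank(a, cell_types)
    y = meth.loc[shared].to_numpy(float)

    out = np.empty((meth.shape[1], len(cell_types)))
    for i in range(meth.shape[1]):
        if method == "nnls":
            w, _ = nnls(a, y[:, i])
        elif method == "qp":
            w = _solve_qp(a, y[:, i])
        else:
            raise ValueError(f"unknown method {method!r}")
        total = w.sum()
        if total == 0:
            w = np.full(len(cell_types), 1.0 / len(cell_types))
        else:
            w = w / total
        out[i] = w
    return pd.DataFrame(out, index=meth.columns, columns=cell_types)


def select_marker_sites(panel: pd.DataFrame, top_t: int = 100) -> pd.MultiIndex:
    """Top-``top_t`` contrast CpGs per cell type (marker-selection mode).

    Contrast of a CpG for cell type k is the distance between the panel value
    for k and the nearest other cell type; the union over cell types is
    returned for use as ``site_subset``.
    """
    _validate_panel(panel)
    mu = panel.to_numpy(float)
    keep: set[int] = set()
    for ki in range(mu.shape[1]):
        others = np.delete(mu, ki, axis=1)
        contrast = np.abs(others - mu[:, [ki]]).min(axis=1)
        keep.update(np.argsort(-contrast)[:top_t].tolist())
    rows = sorted(keep)
    return panel.index[rows]
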