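"""Voxelwise structure-behavior general linear model.

Gray-matter volume at every voxel is regressed on one imagery score of
interest plus the five nuisance covariates (age, gender, total gray matter,
digit span, years of musical training) and an intercept. The contrast of
interest is the t statistic of the imagery column with ``df = n - p``; with
n = 74 subjects and 7 design columns this gives the t(67) reported for the
structural effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .behavioral import NUISANCE_COLUMNS
from .errors import EmptyMaskError, GridMismatchError, ValidationError
from .volumes import VolumeMap, VoxelGrid

logger = logging.getLogger(__name__)

DFPair = tuple[int, int]


@dataclass
class DesignMatrix:
    """Subject-by-regressor design with named columns.

    Column 0 is always the intercept; exactly one column is the covariate of
    interest. Row order must match the subject order of the map stack.
    """

    matrix: np.ndarray
    columns: tuple[str, ...]
    interest: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("design matrix must be 2D")
        if len(self.columns) != self.matrix.shape[1]:
            raise ValidationError("column names do not match matrix width")
        if self.interest not in self.columns:
            raise ValidationError(f"interest column {self.interest!r} not in design")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValidationError("design matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def interest_index(self) -> int:
        return self.columns.index(self.interest)

    def nuisance_only(self) -> "DesignMatrix":
        """Drop the interest column (used for residualization / permutation)."""
        keep = [j for j, c in enumerate(self.columns) if c != self.interest]
        cols = tuple(self.columns[j] for j in keep)
        dm = object.__new__(DesignMatrix)
        dm.matrix = self.matrix[:, keep]
        dm.columns = cols
        dm.interest = ""
        return dm


def build_design(
    cohort: pd.DataFrame,
    interest: str,
    nuisances: Sequence[str] = NUISANCE_COLUMNS,
) -> DesignMatrix:
    """Assemble [intercept | interest | nuisances] from a cohort table.

    Exactly one covariate of interest is allowed per fit: the two auditory
    subscales are too highly correlated to enter one design together, so the
    API accepts a single ``interest`` column name.
    """
    if interest in nuisances:
        raise ValidationError(f"{interest!r} cannot be both interest and nuisance")
    cols = [interest, *nuisances]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    n = len(cohort)
    mat = np.column_stack([np.ones(n)] + [cohort[c].to_numpy(dtype=float) for c in cols])
    return DesignMatrix(mat, ("intercept", interest, *nuisances), interest)


@dataclass
class StatMap:
    """A voxelwise statistic map restricted to an analysis mask.

    ``values`` is NaN outside the mask; ``df`` is an int for t maps and a
    (df1, df2) pair for F maps.
    """

    grid: VoxelGrid
    values: np.ndarray
    kind: str  # "t" or "F"
    df: Union[int, DFPair]
    mask: np.ndarray  # bool, voxels where the statistic is defined

    def __post_init__(self) -> None:
        if self.kind not in ("t", "F"):
            raise ValidationError(f"statistic kind must be 't' or 'F', got {self.kind!r}")
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValidationError("values/mask shape must match grid shape")

    def to_volume(self) -> VolumeMap:
        return VolumeMap(self.grid, self.values, kind=self.kind)


def _stack_to_matrix(
    gm_maps: Sequence[VolumeMap], mask: Optional[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, VoxelGrid]:
    grid = gm_maps[0].grid
    for m in gm_maps[1:]:
        if m.grid != grid:
            raise GridMismatchError("all subject maps must share one grid")
    if mask is None:
        mask_arr = np.ones(grid.shape, dtype=bool)
    else:
        mask_arr = np.asarray(mask, dtype=bool)
        if mask_arr.shape != grid.shape:
            raise GridMismatchError("mask shape does not match map grid")
    data = np.stack([np.asarray(m.values, dtype=float)[mask_arr] for m in gm_maps])
    return data, mask_arr, grid


def ols_t_values(Y: np.ndarray, X: np.ndarray, contrast_index: int) -> np.ndarray:
    """OLS t statistics for one design column, vectorized over response columns.

    ``Y`` is (n_subjects, n_voxels); returns t with NaN where the residual
    variance is exactly zero.
    """
    n, p = X.shape
    df = n - p
    # thin QR: beta = R^-1 Q'y and RSS = ||y||^2 - ||Q'y||^2, avoiding the
    # explicit residual pass over the (large) voxel axis
    Q, R = np.linalg.qr(X)
    Qty = Q.T @ Y
    beta = np.linalg.solve(R, Qty)
    rss = np.maximum((Y**2).sum(axis=0) - (Qty**2).sum(axis=0), 0.0)
    # zero residual variance up to round-off: the response is an exact linear
    # combination of the design, so the t statistic is undefined
    total = (Y**2).sum(axis=0)
    degenerate = rss <= 100 * np.finfo(float).eps * np.maximum(total, 1.0)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    c = np.zeros(p)
    c[contrast_index] = 1.0
    var_c = float(c @ xtx_inv @ c)
    se = np.sqrt(sigma2 * var_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[contrast_index] / se
    t[degenerate | (se == 0)] = np.nan
    return t


def fit_voxelwise_t(
    gm_maps: Sequence[VolumeMap],
    design: DesignMatrix,
    contrast: Optional[str] = None,
    mask: Optional[np.ndarray] = None,
    sign: int = +1,
) -> StatMap:
    """Voxelwise OLS of gray matter on the design; t map for the interest column.

    ``sign=-1`` tests the negative contrast (mirror image of the t map).
    Voxels with zero residual variance are excluded from the output mask and
    their count is logged.
    """
    if design.n_subjects != len(gm_maps):
        raise ValidationError(
            f"{len(gm_maps)} maps but design has {design.n_subjects} rows"
        )
    if design.n_subjects < design.n_columns + 2:
        raise ValidationError("need at least 2 more subjects than design columns")
    if sign not in (+1, -1):
        raise ValidationError("sign must be +1 or -1")
    contrast = contrast or design.interest
    if contrast not in design.columns:
        raise ValidationError(f"unknown contrast column {contrast!r}")
    Y, mask_arr, grid = _stack_to_matrix(gm_maps, mask)
    t = sign * ols_t_values(Y, design.matrix, design.columns.index(contrast))
    bad = ~np.isfinite(t)
    if bad.any():
        logger.info("excluding %d voxels with zero residual variance", int(bad.sum()))
    values = np.full(grid.shape, np.nan)
    final_mask = mask_arr.copy()
    final_mask[mask_arr] = ~bad
    values[final_mask] = t[~bad]
    return StatMap(grid, values, "t", design.n_subjects - design.n_columns, final_mask)


def adjusted_roi_gm(
    gm_maps: Sequence[VolumeMap],
    nuisance_design: DesignMatrix,
    cluster_mask: np.ndarray,
) -> np.ndarray:
    """Per-subject mean gray matter over a cluster, residualized on the nuisances.

    This is the quantity plotted against vividness in scatterplots of the
    structural effect ("gray matter residuals"): ROI means with intercept and
    nuisance variance regressed out.
    """
    mask = np.asarray(cluster_mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cluster mask is empty")
    Y, _, _ = _stack_to_matrix(gm_maps, mask)
    roi_mean = Y.mean(axis=1)
    X = nuisance_design.matrix
    coef, *_ = np.linalg.lstsq(X, roi_mean, rcond=None)
    return roi_mean - X @ coef


def z_from_t(t, df: int):
    """Map t deviates to standard-normal deviates with the same tail probability.

    Symmetric in the sign of t; large |t| uses log-space survival functions to
    avoid underflow.
    """
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("t values must be finite")
    logp = stats.t.logsf(np.abs(arr), df)
    z = -stats.norm.ppf(np.exp(np.clip(logp, -700, 0)))
    # fall back to an asymptotic guard where the tail underflows
    z = np.where(np.isfinite(z), z, np.abs(arr))
    out = np.sign(arr) * z
    return float(out) if arr.ndim == 0 else out


def z_from_f(f, df: DFPair):
    """Standard-normal deviate with the same upper-tail probability as F."""
    arr = np.asarray(f, dtype=float)
    logp = stats.f.logsf(arr, *df)
    z = stats.norm.isf(np.exp(np.clip(logp, -700, 0)))
    z = np.where(np.isfinite(z), z, np.sqrt(np.maximum(arr, 0)))
    return float(z) if arr.ndim == 0 else z
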