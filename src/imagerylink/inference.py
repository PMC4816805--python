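"""Permutation-based multiple-comparison correction.

Two corrections are provided, both by max-statistic permutation:

* cluster-level family-wise error (FWE): supra-threshold connected
  components at an uncorrected cluster-forming threshold (p < 0.005 by
  default), with the null distribution of the *maximum* cluster size built
  by permutation;
* peak-level FWE inside a small a-priori sphere (small volume correction),
  using the null distribution of the maximum statistic over the sphere.

For the structure-behavior GLM the permutation scheme is Freedman-Lane: the
data are residualized on the nuisance model, the residual rows are permuted,
the nuisance fit is added back, and the full model is refit. This preserves
the nuisance structure under the null hypothesis that the covariate of
interest has no effect, and requires only exchangeability - no smoothness
estimation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from typing import Iterator, Optional, Protocol, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import EmptyMaskError, ValidationError
from .glm import DesignMatrix, StatMap, z_from_f, z_from_t, _stack_to_matrix
from .volumes import SphereMask, VolumeMap, VoxelGrid

DFPair = tuple[int, int]

#: voxel connectivity -> scipy structuring-element order (faces / edges / corners)
CONNECTIVITY_ORDERS = {6: 1, 18: 2, 26: 3}

DEFAULT_CONNECTIVITY = 18
DEFAULT_FORMING_P = 0.005


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in CONNECTIVITY_ORDERS:
        raise ValidationError(f"connectivity must be one of {set(CONNECTIVITY_ORDERS)}")
    return ndimage.generate_binary_structure(3, CONNECTIVITY_ORDERS[connectivity])


def stat_cutoff(forming_p: float, kind: str, df: Union[int, DFPair]) -> float:
    """Convert an uncorrected per-voxel p threshold to a statistic cutoff."""
    if not 0 < forming_p < 1:
        raise ValidationError(f"forming threshold p must be in (0,1), got {forming_p}")
    if kind == "t":
        return float(stats.t.isf(forming_p, df))
    if kind == "F":
        return float(stats.f.isf(forming_p, *df))
    raise ValidationError(f"unknown statistic kind {kind!r}")


@dataclass
class ClusterTable:
    """Supra-threshold clusters with (optionally) corrected p-values.

    ``table`` columns: size, peak_x_mm, peak_y_mm, peak_z_mm, peak_stat,
    peak_z, p_fwe (NaN when uncorrected).
    """

    table: pd.DataFrame
    forming_threshold_p: float
    cutoff: float
    connectivity: int
    n_perm: Optional[int] = None
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def min_p_fwe(self) -> float:
        if len(self.table) == 0 or self.table["p_fwe"].isna().all():
            return float("nan")
        return float(self.table["p_fwe"].min())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _cluster_decompose(
    binary: np.ndarray, structure: np.ndarray
) -> tuple[np.ndarray, int, np.ndarray]:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return labels, 0, np.zeros(0, dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, n, sizes


def label_clusters(
    stat_map: StatMap,
    forming_threshold_p: float = DEFAULT_FORMING_P,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> ClusterTable:
    """Connected components of strictly supra-threshold voxels (uncorrected).

    An empty table (not an error) is returned when no voxel exceeds the
    cluster-forming cutoff.
    """
    structure = _structure(connectivity)
    cutoff = stat_cutoff(forming_threshold_p, stat_map.kind, stat_map.df)
    with np.errstate(invalid="ignore"):
        binary = (stat_map.values > cutoff) & stat_map.mask
    labels, n, sizes = _cluster_decompose(binary, structure)
    rows = []
    for lab in range(1, n + 1):
        peak_idx = ndimage.maximum_position(
            np.nan_to_num(stat_map.values, nan=-np.inf), labels=labels, index=lab
        )
        peak_stat = float(stat_map.values[peak_idx])
        peak_mm = stat_map.grid.index_to_world(np.asarray(peak_idx))
        if stat_map.kind == "t":
            peak_z = z_from_t(peak_stat, stat_map.df)
        else:
            peak_z = z_from_f(peak_stat, stat_map.df)
        rows.append(
            {
                "size": int(sizes[lab - 1]),
                "peak_x_mm": peak_mm[0],
                "peak_y_mm": peak_mm[1],
                "peak_z_mm": peak_mm[2],
                "peak_stat": peak_stat,
                "peak_z": float(peak_z),
                "p_fwe": np.nan,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["size", "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_stat", "peak_z", "p_fwe"],
    ).sort_values("size", ascending=False, ignore_index=True)
    return ClusterTable(table, forming_threshold_p, cutoff, connectivity)


class PermutationEngine(Protocol):
    """Produces observed and permuted voxelwise statistic maps on one mask."""

    grid: VoxelGrid
    mask: np.ndarray
    kind: str
    df: Union[int, DFPair]

    def observed(self) -> np.ndarray:  # 1D over mask voxels
        ...

    def permuted(self, rng: np.random.Generator) -> np.ndarray:
        ...

    def n_distinct_permutations(self) -> float:
        ...


@dataclass
class FreedmanLaneEngine:
    """Freedman-Lane permutation engine for the voxelwise OLS contrast t.

    Holds the masked subject-by-voxel data matrix; each permutation shuffles
    the rows of the nuisance-model residuals, adds back the nuisance fit and
    refits the full design.
    """

    design: DesignMatrix
    grid: VoxelGrid
    mask: np.ndarray
    Y: np.ndarray = field(repr=False)
    sign: int = +1
    kind: str = "t"

    def __post_init__(self) -> None:
        X = self.design.matrix
        Z = self.design.nuisance_only().matrix
        # orthonormal bases keep every per-permutation product low rank:
        # permuting the rows of the n-by-p bases is equivalent to (and much
        # cheaper than) permuting the n-by-V residual matrix
        Qz, _ = np.linalg.qr(Z)
        self._Qz = Qz
        self._Bz = Qz.T @ self.Y  # nuisance-fit coefficients, (pz, V)
        self._resid = self.Y - Qz @ self._Bz
        self._rss_resid = (self._resid**2).sum(axis=0)
        self._fitted_sq = (self._Bz**2).sum(axis=0)  # ||fitted||^2 per voxel
        Q, Rmat = np.linalg.qr(X)
        self._Q = Q
        self._QtF = (Q.T @ Qz) @ self._Bz
        c = self.design.interest_index
        r_inv = np.linalg.inv(Rmat)
        self._beta_row = r_inv[c]  # beta_c = beta_row @ (Q' Y)
        self._var_c = float((r_inv @ r_inv.T)[c, c])
        self.df = self.design.n_subjects - self.design.n_columns

    def _t_from_perm(self, inv_perm: Optional[np.ndarray]) -> np.ndarray:
        """Contrast t for Y* = P.resid + fitted without materializing Y*."""
        if inv_perm is None:
            qt_y = self._Q.T @ self._resid + self._QtF
            cross = 0.0  # residuals are orthogonal to the nuisance fit
        else:
            qt_y = self._Q[inv_perm].T @ self._resid + self._QtF
            cross = (self._Bz * (self._Qz[inv_perm].T @ self._resid)).sum(axis=0)
        total = self._rss_resid + 2.0 * cross + self._fitted_sq
        rss = np.maximum(total - (qt_y**2).sum(axis=0), 0.0)
        degenerate = rss <= 100 * np.finfo(float).eps * np.maximum(total, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (self._beta_row @ qt_y) / np.sqrt(rss / self.df * self._var_c)
        t[degenerate] = 0.0
        return self.sign * t

    @classmethod
    def from_maps(
        cls,
        gm_maps: Sequence[VolumeMap],
        design: DesignMatrix,
        mask: Optional[np.ndarray] = None,
        sign: int = +1,
    ) -> "FreedmanLaneEngine":
        Y, mask_arr, grid = _stack_to_matrix(gm_maps, mask)
        if not mask_arr.any():
            raise EmptyMaskError("analysis mask is empty")
        return cls(design, grid, mask_arr, Y, sign)

    def observed(self) -> np.ndarray:
        return self._t_from_perm(None)

    def permuted(self, rng: np.random.Generator) -> np.ndarray:
        perm = rng.permutation(self.design.n_subjects)
        return self.permuted_fixed(perm)

    def permuted_fixed(self, perm: np.ndarray) -> np.ndarray:
        return self._t_from_perm(np.argsort(np.asarray(perm)))

    def n_distinct_permutations(self) -> float:
        return float(math.factorial(self.design.n_subjects))


def _null_iter(
    engine: PermutationEngine, n_perm: int, seed: Optional[int]
) -> tuple[Iterator[np.ndarray], int]:
    """Iterator over permuted statistic vectors, with exhaustive fallback.

    When the exchangeability group has fewer than ``n_perm`` distinct
    elements, all of them are enumerated instead (with a warning) and the
    identity is included, which makes the plus-one correction exact.
    """
    n_distinct = engine.n_distinct_permutations()
    if n_distinct < n_perm and hasattr(engine, "permuted_fixed"):
        warnings.warn(
            f"only {int(n_distinct)} distinct permutations available; "
            "enumerating exhaustively",
            stacklevel=3,
        )
        n_subj = engine.design.n_subjects  # type: ignore[attr-defined]
        perms = list(iter_permutations(range(n_subj)))

        def exhaustive() -> Iterator[np.ndarray]:
            for p in perms:
                yield engine.permuted_fixed(np.asarray(p))

        return exhaustive(), len(perms)

    rng = np.random.default_rng(seed)

    def sampled() -> Iterator[np.ndarray]:
        for _ in range(n_perm):
            yield engine.permuted(rng)

    return sampled(), n_perm


def cluster_fwe_engine(
    engine: PermutationEngine,
    forming_threshold_p: float = DEFAULT_FORMING_P,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> ClusterTable:
    """Cluster-level FWE p-values from the max-cluster-size permutation null."""
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    structure = _structure(connectivity)
    cutoff = stat_cutoff(forming_threshold_p, engine.kind, engine.df)
    grid, mask = engine.grid, engine.mask

    def to_3d(flat: np.ndarray) -> np.ndarray:
        vol = np.full(grid.shape, -np.inf)
        vol[mask] = flat
        return vol

    obs_map = StatMap(
        grid,
        np.where(mask, to_3d(engine.observed()), np.nan),
        engine.kind,
        engine.df,
        mask,
    )
    table = label_clusters(obs_map, forming_threshold_p, connectivity)
    null_iter, m = _null_iter(engine, n_perm, seed)
    max_sizes = np.zeros(m, dtype=int)
    for b, stat_flat in enumerate(null_iter):
        binary = to_3d(stat_flat) > cutoff
        _, _, sizes = _cluster_decompose(binary, structure)
        if sizes.size:
            max_sizes[b] = int(sizes.max())
    exhaustive = m != n_perm
    for i, size in enumerate(table.table["size"].to_numpy()):
        exceed = int((max_sizes >= size).sum())
        if exhaustive:
            p = exceed / m  # identity included, p > 0 guaranteed
        else:
            p = (exceed + 1) / (m + 1)
        table.table.loc[i, "p_fwe"] = p
    table.n_perm = m
    table.seed = seed
    return table


def cluster_fwe(
    gm_maps: Sequence[VolumeMap],
    design: DesignMatrix,
    contrast_sign: int = +1,
    forming_threshold_p: float = DEFAULT_FORMING_P,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    connectivity: int = DEFAULT_CONNECTIVITY,
    mask: Optional[np.ndarray] = None,
) -> ClusterTable:
    """Cluster-level FWE correction for the structure-behavior GLM contrast."""
    engine = FreedmanLaneEngine.from_maps(gm_maps, design, mask=mask, sign=contrast_sign)
    return cluster_fwe_engine(engine, forming_threshold_p, n_perm, seed, connectivity)


@dataclass
class SVCResult:
    """Small-volume-corrected peak: statistic, world coordinate, FWE p."""

    peak_stat: float
    peak_mm: tuple[float, float, float]
    peak_z: float
    p_fwe: float
    n_voxels: int
    n_perm: int
    seed: Optional[int]


def svc_peak_fwe(
    engine: PermutationEngine,
    sphere: SphereMask,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> SVCResult:
    """Peak-level FWE within a sphere ROI via the max-statistic permutation null.

    Restricting the max statistic to the sphere is the permutation analogue
    of small volume correction: the null distribution is that of the maximum
    over the sphere's voxels only.
    """
    grid, mask = engine.grid, engine.mask
    if sphere.grid != grid:
        raise ValidationError("sphere grid does not match engine grid")
    in_mask_flat = np.flatnonzero(mask.ravel())
    sphere_flat = sphere.flat_indices()
    # positions of sphere voxels inside the masked (flattened) value vector
    positions = np.searchsorted(in_mask_flat, sphere_flat)
    valid = (positions < in_mask_flat.size) & (
        in_mask_flat[np.minimum(positions, in_mask_flat.size - 1)] == sphere_flat
    )
    if not valid.any():
        raise EmptyMaskError("sphere lies entirely outside the analysis mask")
    positions = positions[valid]
    sphere_idx = sphere.voxel_indices[valid]

    obs = engine.observed()[positions]
    peak_pos = int(np.argmax(obs))
    peak_stat = float(obs[peak_pos])
    peak_mm = tuple(grid.index_to_world(sphere_idx[peak_pos]))
    null_iter, m = _null_iter(engine, n_perm, seed)
    exceed = 0
    for stat_flat in null_iter:
        if stat_flat[positions].max() >= peak_stat:
            exceed += 1
    p = exceed / m if m != n_perm else (exceed + 1) / (m + 1)
    if engine.kind == "t":
        peak_z = z_from_t(peak_stat, engine.df)
    else:
        peak_z = z_from_f(peak_stat, engine.df)
    return SVCResult(peak_stat, peak_mm, float(peak_z), float(p), int(valid.sum()), m, seed)
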