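"""Second-level one-way repeated-measures ANOVA over sound conditions.

Per-subject, per-condition t maps (intelligible vocal sounds versus rest)
are compared voxelwise with the classical within-subject decomposition:

    F = MS_condition / MS_error,  df = (k - 1, (k - 1)(n - 1))

so with k = 5 conditions and n = 56 subjects the map carries F(4, 220).
Cluster-level correction delegates to the permutation machinery, permuting
condition labels independently within each subject (the exchangeability
scheme implied by the within-subject null of no condition effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import GridMismatchError, ValidationError
from .glm import StatMap
from .inference import (
    DEFAULT_CONNECTIVITY,
    DEFAULT_FORMING_P,
    ClusterTable,
    cluster_fwe_engine,
)
from .volumes import VolumeMap, VoxelGrid

VOCAL_CONDITIONS = ("neutral", "laughter", "scream", "pleasure", "disgust")
ROTATED_CONDITION = "rotated"


@dataclass
class ConditionStack:
    """Subjects x conditions x voxels on one grid.

    Every subject must have every condition; ``data`` is (n_subjects,
    n_conditions, *grid.shape).
    """

    data: np.ndarray
    conditions: tuple[str, ...]
    grid: VoxelGrid
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5 or self.data.shape[2:] != self.grid.shape:
            raise ValidationError(
                f"data must be (n_subj, n_cond, *grid.shape), got {self.data.shape}"
            )
        if self.data.shape[1] != len(self.conditions):
            raise ValidationError("condition labels do not match data axis 1")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("missing (non-finite) condition maps in the stack")
        if not self.subject_ids:
            self.subject_ids = tuple(f"sub-{i:03d}" for i in range(self.data.shape[0]))

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_maps(
        cls,
        maps: Sequence[Sequence[VolumeMap]],
        conditions: Sequence[str],
        subject_ids: Sequence[str] = (),
    ) -> "ConditionStack":
        """Build a stack from per-subject lists of per-condition maps."""
        grid = maps[0][0].grid
        for subj in maps:
            if len(subj) != len(conditions):
                raise ValidationError("every subject must have every condition")
            for m in subj:
                if m.grid != grid:
                    raise GridMismatchError("all condition maps must share one grid")
        data = np.stack([[m.values for m in subj] for subj in maps])
        return cls(data, tuple(conditions), grid, tuple(subject_ids))

    def select(self, conditions: Sequence[str]) -> "ConditionStack":
        idx = [self.conditions.index(c) for c in conditions]
        return ConditionStack(
            self.data[:, idx], tuple(conditions), self.grid, self.subject_ids
        )


def rm_anova_f_values(data: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Voxelwise repeated-measures F from an (n, k, V) array.

    Classical sums-of-squares decomposition with the subject main effect
    removed; returns (F over V, (df1, df2)).
    """
    n, k = data.shape[:2]
    if k < 2 or n < 2:
        raise ValidationError(f"need >= 2 conditions and >= 2 subjects, got k={k}, n={n}")
    grand = data.mean(axis=(0, 1), keepdims=True)
    subj = data.mean(axis=1, keepdims=True)
    cond = data.mean(axis=0, keepdims=True)
    ss_cond = n * ((cond - grand) ** 2).sum(axis=(0, 1))
    resid = data - subj - cond + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    f = np.where(ss_err == 0, np.where(ss_cond == 0, 0.0, np.inf), f)
    return f, (df1, df2)


def rm_anova_f(
    stack: ConditionStack,
    conditions: Sequence[str] = VOCAL_CONDITIONS,
    mask: Optional[np.ndarray] = None,
) -> StatMap:
    """F map for the condition effect over the selected (vocal) conditions."""
    sub = stack.select(conditions) if tuple(conditions) != stack.conditions else stack
    if mask is None:
        mask_arr = np.ones(sub.grid.shape, dtype=bool)
    else:
        mask_arr = np.asarray(mask, dtype=bool)
        if mask_arr.shape != sub.grid.shape:
            raise GridMismatchError("mask shape does not match stack grid")
    flat = sub.data.reshape(sub.n_subjects, sub.n_conditions, -1)[:, :, mask_arr.ravel()]
    f, df = rm_anova_f_values(flat)
    values = np.full(sub.grid.shape, np.nan)
    values[mask_arr] = f
    return StatMap(sub.grid, values, "F", df, mask_arr)


@dataclass
class ConditionPermutationEngine:
    """Permutation engine shuffling condition labels within each subject."""

    stack_flat: np.ndarray = field(repr=False)  # (n, k, V_masked)
    grid: VoxelGrid
    mask: np.ndarray
    kind: str = "F"

    def __post_init__(self) -> None:
        n, k = self.stack_flat.shape[:2]
        self.df = (k - 1, (k - 1) * (n - 1))

    @classmethod
    def from_stack(
        cls,
        stack: ConditionStack,
        conditions: Sequence[str] = VOCAL_CONDITIONS,
        mask: Optional[np.ndarray] = None,
    ) -> "ConditionPermutationEngine":
        sub = stack.select(conditions) if tuple(conditions) != stack.conditions else stack
        if mask is None:
            mask_arr = np.ones(sub.grid.shape, dtype=bool)
        else:
            mask_arr = np.asarray(mask, dtype=bool)
        flat = sub.data.reshape(sub.n_subjects, sub.n_conditions, -1)[
            :, :, mask_arr.ravel()
        ]
        return cls(flat, sub.grid, mask_arr)

    def observed(self) -> np.ndarray:
        f, _ = rm_anova_f_values(self.stack_flat)
        return np.nan_to_num(f, nan=0.0)

    def permuted(self, rng: np.random.Generator) -> np.ndarray:
        n, k = self.stack_flat.shape[:2]
        shuffled = np.empty_like(self.stack_flat)
        for s in range(n):
            shuffled[s] = self.stack_flat[s, rng.permutation(k)]
        f, _ = rm_anova_f_values(shuffled)
        return np.nan_to_num(f, nan=0.0)

    def n_distinct_permutations(self) -> float:
        n, k = self.stack_flat.shape[:2]
        return float(math.factorial(k)) ** n


def anova_cluster_report(
    stack: ConditionStack,
    forming_threshold_p: float = DEFAULT_FORMING_P,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    connectivity: int = DEFAULT_CONNECTIVITY,
    conditions: Sequence[str] = VOCAL_CONDITIONS,
    mask: Optional[np.ndarray] = None,
) -> ClusterTable:
    """Cluster-corrected report of the condition-effect F map."""
    engine = ConditionPermutationEngine.from_stack(stack, conditions, mask)
    return cluster_fwe_engine(engine, forming_threshold_p, n_perm, seed, connectivity)
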