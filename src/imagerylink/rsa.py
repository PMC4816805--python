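"""Sphere-ROI representational similarity analysis (RSA).

Per subject, the t maps of the five intelligible vocal-sound conditions are
sampled within a 12-mm sphere (925 voxels on the 2-mm grid), all 10
unordered condition pairs are Pearson-correlated, each r is Fisher
transformed, and the transformed values are averaged into one similarity
summary per subject. High values mean the conditions evoke similar
within-sphere patterns (low representational specificity); low values mean
distinct patterns. A second summary correlates each vocal condition with
the rotated (unintelligible) condition (5 pairs). Either summary is then
correlated - plainly or partially, with the structural nuisance set -
against imagery vividness; a negative r means more specific representations
in people reporting more vivid imagery.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavioral import NUISANCE_COLUMNS, CorrelationResult, fisher_z, partial_r, pearson_r
from .errors import DegenerateInputError, ValidationError
from .glm import StatMap
from .volumes import SphereMask

N_VOCAL = 5
N_WITHIN_PAIRS = N_VOCAL * (N_VOCAL - 1) // 2  # 10
N_VS_ROTATED_PAIRS = N_VOCAL  # 5


@dataclass(frozen=True)
class SimilaritySummary:
    """Per-subject mean Fisher-z similarity within the ROI sphere."""

    subject_id: str
    mean_z_within_vocal: float
    mean_z_vocal_vs_rotated: float
    n_voxels_roi: int


def extract_roi_vector(t_map: StatMap, sphere: SphereMask) -> np.ndarray:
    """t values at the sphere's voxels, in lexicographic index order."""
    if t_map.kind != "t":
        raise ValidationError(f"expected a t map, got kind {t_map.kind!r}")
    if sphere.grid != t_map.grid:
        raise ValidationError("sphere and map are on different grids")
    vec = t_map.values[tuple(sphere.voxel_indices.T)]
    bad = np.flatnonzero(~np.isfinite(vec))
    if bad.size:
        idx = [tuple(sphere.voxel_indices[i]) for i in bad[:5]]
        raise ValidationError(f"non-finite t values inside sphere at voxels {idx}")
    return np.asarray(vec, dtype=float)


def _pair_z(a: np.ndarray, b: np.ndarray) -> float:
    ra = np.asarray(a, dtype=float)
    rb = np.asarray(b, dtype=float)
    r = np.corrcoef(ra, rb)[0, 1]
    return float(fisher_z(r))


def _check_vectors(vectors: Sequence[np.ndarray], labels: Sequence[str]) -> list[np.ndarray]:
    vecs = [np.asarray(v, dtype=float).ravel() for v in vectors]
    length = vecs[0].size
    for v, lab in zip(vecs, labels):
        if v.size != length:
            raise ValidationError(f"condition {lab!r}: length {v.size} != {length}")
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"condition {lab!r} has zero variance in the ROI")
    return vecs


def pairwise_mean_similarity(
    vectors: Sequence[np.ndarray],
    labels: Sequence[str] = ("neutral", "laughter", "scream", "pleasure", "disgust"),
) -> float:
    """Mean Fisher-z over all k(k-1)/2 condition pairs (10 for k = 5)."""
    if len(vectors) != len(labels):
        raise ValidationError("one label per condition vector required")
    vecs = _check_vectors(vectors, labels)
    zs = [_pair_z(vecs[i], vecs[j]) for i, j in combinations(range(len(vecs)), 2)]
    return float(np.mean(zs))


def vocal_vs_rotated_similarity(
    vocal_vectors: Sequence[np.ndarray],
    rotated_vector: np.ndarray,
    labels: Sequence[str] = ("neutral", "laughter", "scream", "pleasure", "disgust"),
) -> float:
    """Mean Fisher-z of each vocal condition against the rotated condition (5 pairs)."""
    vecs = _check_vectors(list(vocal_vectors) + [rotated_vector], list(labels) + ["rotated"])
    rot = vecs[-1]
    zs = [_pair_z(v, rot) for v in vecs[:-1]]
    return float(np.mean(zs))


def summarize_subject(
    subject_id: str,
    vocal_maps: Sequence[StatMap],
    rotated_map: StatMap,
    sphere: SphereMask,
) -> SimilaritySummary:
    """Extract ROI vectors and compute both similarity summaries for one subject."""
    vocal = [extract_roi_vector(m, sphere) for m in vocal_maps]
    rot = extract_roi_vector(rotated_map, sphere)
    return SimilaritySummary(
        subject_id=subject_id,
        mean_z_within_vocal=pairwise_mean_similarity(vocal),
        mean_z_vocal_vs_rotated=vocal_vs_rotated_similarity(vocal, rot),
        n_voxels_roi=sphere.n_voxels,
    )


def summaries_to_frame(summaries: Sequence[SimilaritySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def similarity_behavior_link(
    summaries: Sequence[SimilaritySummary] | pd.DataFrame,
    cohort: pd.DataFrame,
    similarity: str = "mean_z_within_vocal",
    behavior: str = "bais_vividness",
    covariates: Optional[Sequence[str]] = None,
) -> CorrelationResult:
    """Correlate per-subject mean similarity with an imagery score.

    With ``covariates`` (e.g. the structural nuisance set
    ``behavioral.NUISANCE_COLUMNS``) a partial correlation is computed.
    A negative r means participants with more distinct condition patterns
    (higher representational specificity) report more vivid imagery.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = summaries_to_frame(summaries)
    if "subject_id" not in summaries.columns:
        raise ValidationError("summaries need a subject_id column")
    merged = summaries.merge(cohort, on="subject_id", how="outer", indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both", "subject_id"].tolist()
    if unmatched:
        raise ValidationError(f"subjects without both similarity and behavior: {unmatched}")
    x = merged[similarity].to_numpy(dtype=float)
    y = merged[behavior].to_numpy(dtype=float)
    if covariates:
        cov = merged[list(covariates)].to_numpy(dtype=float)
        return partial_r(x, y, cov)
    return pearson_r(x, y)
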