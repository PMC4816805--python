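"""Questionnaire scoring and correlation machinery.

The auditory-imagery instrument (BAIS) has two 14-item subscales rated 1-7:
vividness (clarity of the evoked sound image) and control (ease of
transforming one image into another). The visual instrument (VVIQ) has 16
items rated 1-5 where low raw scores mean vivid imagery; scores are inverted
(6 - mean) so that higher always means more vivid on both instruments.

Correlation helpers (Pearson, Fisher z, partial correlation) are the
statistics used for every brain-behavior association in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

BAIS_N_ITEMS = 14
BAIS_SCALE = (1, 7)
VVIQ_N_ITEMS = 16
VVIQ_SCALE = (1, 5)

#: default Fisher-transform clipping bound (|r| is clipped to 1 - 1e-7)
FISHER_CLIP = 1e-7

#: nuisance covariates of the structural (VBM) design, in canonical order
NUISANCE_COLUMNS = ("age", "gender", "total_gm", "digit_span", "music_years")

COHORT_COLUMNS = (
    "subject_id",
    "age",
    "gender",
    "total_gm",
    "digit_span",
    "music_years",
    "bais_vividness",
    "bais_control",
    "bais_total",
    "vviq_vividness",
)


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: imagery scores plus the five nuisance covariates."""

    subject_id: str
    age: float
    gender: int
    total_gm: float
    digit_span: float
    music_years: float
    bais_vividness: float
    bais_control: float
    bais_total: float
    vviq_vividness: float

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("bais_vividness", *BAIS_SCALE),
            ("bais_control", *BAIS_SCALE),
            ("bais_total", *BAIS_SCALE),
            ("vviq_vividness", *VVIQ_SCALE),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")
        if abs(self.bais_total - (self.bais_vividness + self.bais_control) / 2.0) > 1e-9:
            raise ValidationError("bais_total must equal the mean of the two subscales")


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation with its two-sided p-value and degrees of freedom."""

    r: float
    p_two_sided: float
    n: int
    df: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError(f"|r| must be <= 1, got {self.r}")


def _check_items(items: Sequence, n_items: int, lo: int, hi: int, label: str) -> np.ndarray:
    arr = list(items)
    if len(arr) != n_items:
        raise ValidationError(f"{label}: expected {n_items} items, got {len(arr)}")
    out = np.empty(n_items, dtype=float)
    for i, v in enumerate(arr):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValidationError(f"{label}: item {i} is missing")
        fv = float(v)
        if fv != int(fv) or not (lo <= fv <= hi):
            raise ValidationError(
                f"{label}: item {i} = {v!r} not an integer in [{lo}, {hi}]"
            )
        out[i] = fv
    return out


def score_bais(
    vividness_items: Sequence[int], control_items: Sequence[int]
) -> tuple[float, float, float]:
    """Score the two 14-item auditory-imagery subscales.

    Returns ``(vividness, control, total)`` where each subscale score is the
    arithmetic mean of its items and the total is the mean of the two
    subscale scores.
    """
    viv = _check_items(vividness_items, BAIS_N_ITEMS, *BAIS_SCALE, label="vividness")
    ctl = _check_items(control_items, BAIS_N_ITEMS, *BAIS_SCALE, label="control")
    v, c = float(viv.mean()), float(ctl.mean())
    return v, c, (v + c) / 2.0


def score_vviq(item_responses: Sequence[int]) -> float:
    """Score the 16-item visual-imagery questionnaire, inverted.

    Raw responses run 1 (perfectly vivid) to 5 (no image); the returned score
    is ``6 - mean(raw)`` so that 5 means maximally vivid, aligned with the
    auditory scale direction.
    """
    items = _check_items(item_responses, VVIQ_N_ITEMS, *VVIQ_SCALE, label="vviq")
    return 6.0 - float(items.mean())


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size < 3:
        raise ValidationError(f"{name}: need length >= 3, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name}: non-finite values present")
    return v


def pearson_r(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    xv, yv = _as_vector(x, "x"), _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValidationError(f"length mismatch: {xv.size} vs {yv.size}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError("zero variance in x or y")
    n = xv.size
    r, p = stats.pearsonr(xv, yv)
    return CorrelationResult(float(r), float(p), n, n - 2)


def fisher_z(r, clip: Optional[float] = FISHER_CLIP):
    """Variance-stabilizing Fisher transform z = atanh(r).

    ``clip`` bounds |r| at ``1 - clip`` before the transform so that
    degenerate perfect correlations stay finite; pass ``clip=None`` to
    disable clipping, in which case |r| == 1 raises.
    """
    arr = np.asarray(r, dtype=float)
    if clip is None:
        if np.any(np.abs(arr) >= 1.0):
            raise DegenerateInputError("|r| == 1 with clipping disabled")
        out = np.arctanh(arr)
    else:
        out = np.arctanh(np.clip(arr, -1.0 + clip, 1.0 - clip))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def partial_r(x, y, covariates=None) -> CorrelationResult:
    """Correlation between x and y after regressing both on the covariates.

    Both vectors are residualized on ``[intercept | covariates]`` by ordinary
    least squares and the residuals are Pearson-correlated; the p-value uses
    ``df = n - 2 - k`` for k covariate columns. With no covariates this is
    exactly :func:`pearson_r`.
    """
    xv, yv = _as_vector(x, "x"), _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValidationError(f"length mismatch: {xv.size} vs {yv.size}")
    n = xv.size
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValidationError(f"covariates have {cov.shape[0]} rows, expected {n}")
    k = cov.shape[1]
    if n <= k + 2:
        raise ValidationError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValidationError(f"rank-deficient covariates (collinear columns: {bad})")
    # residualize through the QR-based least-squares projector
    coef_x, *_ = np.linalg.lstsq(design, xv, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, yv, rcond=None)
    rx = xv - design @ coef_x
    ry = yv - design @ coef_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateInputError("residual is (numerically) the zero vector")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    t = r * np.sqrt(df / max(1.0 - r * r, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r, p, n, df)


def _collinear_columns(design: np.ndarray) -> list[int]:
    """0-based covariate column indices implicated in rank deficiency."""
    bad = []
    q, rmat = np.linalg.qr(design)
    diag = np.abs(np.diag(rmat))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    for j, d in enumerate(diag):
        if d < tol and j > 0:  # column 0 is the intercept
            bad.append(j - 1)
    return bad or list(range(design.shape[1] - 1))


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (statistic, p); thin scipy wrapper."""
    xv = _as_vector(x, "x")
    res = stats.shapiro(xv)
    return float(res.statistic), float(res.pvalue)


def load_cohort(path) -> pd.DataFrame:
    """Load a cohort CSV (one row per subject, SubjectRecord columns).

    Validates presence of all required columns and scale ranges.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")
    records_to_validate = df.to_dict("records")
    for row in records_to_validate:
        SubjectRecord(**{k: row[k] for k in COHORT_COLUMNS})
    return df


def save_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
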