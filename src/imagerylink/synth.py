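"""Synthetic cohorts, gray-matter maps and condition t-maps with known truth.

The generators emulate the statistical structure the analysis stages assume:

* a cohort of adults (default n = 74; ages 20-81) whose imagery scores are
  correlated latent Gaussians mapped into the questionnaire ranges
  (vividness-control rho = 0.68, auditory-visual vividness rho = 0.57 by
  default) plus five nuisance covariates with realistic means and spreads;
* modulated-gray-matter-like maps on a 1.5 mm grid with an implanted
  ellipsoidal region whose volume tracks vividness - the implant slope is
  calibrated against the generated noise so the ROI gray-matter-vividness
  correlation targets the configured value (0.46 by default);
* five vocal-condition t-maps plus one rotated-condition t-map per subject
  on a 2 mm grid, sharing a common auditory pattern, with condition-specific
  patterns confined to a target sphere whose amplitude ("distinctness") is
  coupled to vividness so that the mean within-sphere similarity correlates
  with vividness at the configured value (-0.34 by default) and the cohort
  mean within-vocal similarity sits near 0.83.

Every generator is a pure function of (config, seed). Ground-truth
artifacts (effect masks, latent couplings) are returned alongside the data
and must never be consumed by analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .anova import ROTATED_CONDITION, VOCAL_CONDITIONS, ConditionStack
from .errors import ValidationError
from .volumes import VolumeMap, VoxelGrid, gaussian_smooth, make_sphere_mask

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the synthetic data generators."""

    n_structural: int = 74
    n_functional: int = 56
    # behavioral correlation targets
    rho_viv_control: float = 0.68
    rho_viv_vviq: float = 0.57
    rho_control_vviq: float = 0.40
    # structural effect
    gm_roi_r: float = 0.46
    # ellipsoid of ~11.5 mL, the volume scale of the structural cluster the
    # analysis is expected to recover
    effect_center_mm: tuple[float, float, float] = (-6.0, -13.0, 20.0)
    effect_semiaxes_mm: tuple[float, float, float] = (13.0, 15.0, 14.0)
    gm_baseline: float = 0.55
    gm_noise_sd: float = 0.6  # white-noise SD before smoothing
    gm_noise_smooth_fwhm_mm: float = 4.0
    smoothing_fwhm_mm: float = 10.0
    struct_shape: tuple[int, int, int] = (48, 56, 48)
    struct_voxel_mm: float = 1.5
    # functional / RSA coupling
    rsa_coupling_r: float = -0.34
    mean_within_similarity: float = 0.83
    similarity_sd: float = 0.10
    sphere_center_mm: tuple[float, float, float] = (-8.0, -2.0, 12.0)
    sphere_radius_mm: float = 12.0
    tmap_noise_var: float = 0.03
    rotated_shared_gain: float = 0.7
    func_shape: tuple[int, int, int] = (49, 57, 49)
    func_voxel_mm: float = 2.0

    def __post_init__(self) -> None:
        for name in ("rho_viv_control", "rho_viv_vviq", "rho_control_vviq",
                     "gm_roi_r", "rsa_coupling_r"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValidationError(f"{name}={v} must lie in (-1, 1)")
        if min(self.n_structural, self.n_functional) < 10:
            raise ValidationError("need at least 10 subjects")
        eigvals = np.linalg.eigvalsh(self.behavioral_correlation())
        if eigvals.min() <= 0:
            raise ValidationError("behavioral correlation target is not positive definite")

    def behavioral_correlation(self) -> np.ndarray:
        """Target correlation of the (vividness, control, visual) latents."""
        return np.array(
            [
                [1.0, self.rho_viv_control, self.rho_viv_vviq],
                [self.rho_viv_control, 1.0, self.rho_control_vviq],
                [self.rho_viv_vviq, self.rho_control_vviq, 1.0],
            ]
        )

    def structural_grid(self) -> VoxelGrid:
        return VoxelGrid.isotropic(self.struct_shape, self.struct_voxel_mm)

    def functional_grid(self) -> VoxelGrid:
        return VoxelGrid.isotropic(self.func_shape, self.func_voxel_mm)


# cohort descriptive targets: (mean, sd, low, high)
_SCALE_PARAMS = {
    "bais_vividness": (4.96, 0.95, 1.0, 7.0),
    "bais_control": (5.28, 0.95, 1.0, 7.0),
    "vviq_vividness": (3.63, 0.81, 1.0, 5.0),
}
_AGE = (42.61, 17.11, 20.0, 81.0)
_DIGIT_SPAN = (7.08, 1.21, 4, 9)
_MUSIC_YEARS = (6.03, 4.47, 1.0, 20.0)
_P_FEMALE = 40.0 / 74.0
_P_MUSICIAN = 30.0 / 74.0
_TOTAL_GM = (620.0, 60.0)  # arbitrary volume units (ml-like)


def gen_cohort(config: SynthConfig = SynthConfig(), seed: int = 0,
               n: Optional[int] = None) -> pd.DataFrame:
    """Draw a cohort table; deterministic per (config, seed).

    Latent scores are multivariate normal with the configured correlation
    matrix, then affinely mapped to each questionnaire's mean/SD and clipped
    to the scale range (truncation is mild at these targets, so sample
    correlations track the latent targets closely).
    """
    n = int(n if n is not None else config.n_structural)
    rng = np.random.default_rng(seed)
    latent = rng.multivariate_normal(
        np.zeros(3), config.behavioral_correlation(), size=n,
        method="cholesky",
    )
    cols = {}
    for j, (name, (mu, sd, lo, hi)) in enumerate(_SCALE_PARAMS.items()):
        cols[name] = np.clip(mu + sd * latent[:, j], lo, hi)
    cols["bais_total"] = (cols["bais_vividness"] + cols["bais_control"]) / 2.0
    cols["age"] = np.clip(rng.normal(_AGE[0], _AGE[1], n), _AGE[2], _AGE[3])
    cols["gender"] = rng.binomial(1, _P_FEMALE, n)
    cols["total_gm"] = rng.normal(_TOTAL_GM[0], _TOTAL_GM[1], n)
    cols["digit_span"] = np.clip(
        np.round(rng.normal(_DIGIT_SPAN[0], _DIGIT_SPAN[1], n)),
        _DIGIT_SPAN[2], _DIGIT_SPAN[3],
    )
    musician = rng.random(n) < _P_MUSICIAN
    years = np.clip(rng.normal(_MUSIC_YEARS[0], _MUSIC_YEARS[1], n),
                    _MUSIC_YEARS[2], _MUSIC_YEARS[3])
    cols["music_years"] = np.where(musician, years, 0.0)
    df = pd.DataFrame(cols)
    df.insert(0, "subject_id", [f"sub-{i:03d}" for i in range(n)])
    return df[
        ["subject_id", "age", "gender", "total_gm", "digit_span", "music_years",
         "bais_vividness", "bais_control", "bais_total", "vviq_vividness"]
    ]


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _ellipsoid_mask(grid: VoxelGrid, center_mm, semiaxes_mm) -> np.ndarray:
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = grid.index_to_world(idx)
    rel = (world - np.asarray(center_mm)) / np.asarray(semiaxes_mm)
    inside = (rel**2).sum(axis=1) <= 1.0
    return inside.reshape(grid.shape)


def gen_gm_maps(
    cohort: pd.DataFrame, config: SynthConfig = SynthConfig(), seed: int = 0
) -> tuple[list[VolumeMap], dict]:
    """Per-subject smoothed modulated-GM-like maps with an implanted effect.

    The implant is an ellipsoid whose gray matter rises with the subject's
    standardized vividness score. The slope is set from the empirical SD of
    the ROI-mean smoothed noise so that the ROI gray-matter-vividness
    correlation targets ``config.gm_roi_r``; sampling noise around the
    target remains because the noise is not orthogonal to vividness in any
    finite sample. Maps are returned already smoothed at the configured
    FWHM. Returns ``(maps, truth)`` where ``truth`` holds the effect mask
    and calibration internals (never to be fed to the analysis stages).
    """
    grid = config.structural_grid()
    n = len(cohort)
    rng = np.random.default_rng(seed)
    effect = _ellipsoid_mask(grid, config.effect_center_mm, config.effect_semiaxes_mm)
    if not effect.any():
        raise ValidationError("effect region lies outside the structural grid")
    zv = _standardize(cohort["bais_vividness"].to_numpy(dtype=float))

    # head-like baseline: high central gray matter falling off toward the edges
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = grid.index_to_world(idx)
    extent = np.asarray(grid.shape) * np.asarray(grid.voxel_size_mm) / 2.0
    rad2 = ((world / (0.7 * extent)) ** 2).sum(axis=1).reshape(grid.shape)
    baseline = config.gm_baseline * np.exp(-0.5 * rad2)
    baseline_s = gaussian_smooth(
        VolumeMap(grid, baseline), config.smoothing_fwhm_mm
    ).values

    effect_s = gaussian_smooth(
        VolumeMap(grid, effect.astype(float)), config.smoothing_fwhm_mm
    ).values
    roi = effect
    m_effect = float(effect_s[roi].mean())

    # anatomy noise smoothed jointly at (intrinsic + analysis) width
    total_fwhm = float(
        np.hypot(config.gm_noise_smooth_fwhm_mm, config.smoothing_fwhm_mm)
    )
    noise_roi_means = np.empty(n)
    noise_maps = []
    for s in range(n):
        white = rng.standard_normal(grid.shape) * config.gm_noise_sd
        sm = gaussian_smooth(VolumeMap(grid, white), total_fwhm).values
        noise_maps.append(sm)
        noise_roi_means[s] = sm[roi].mean()
    sigma_roi = float(noise_roi_means.std(ddof=1))
    r = config.gm_roi_r
    slope = sigma_roi * r / np.sqrt(1.0 - r * r) / m_effect

    maps = []
    for s in range(n):
        vol = baseline_s + noise_maps[s] + slope * zv[s] * effect_s
        maps.append(VolumeMap(grid, np.maximum(vol, 0.0), kind="gray_matter"))
    truth = {
        "effect_mask": roi,
        "slope": slope,
        "zv": zv,
        "sigma_roi_noise": sigma_roi,
        "smoothed_effect_roi_mean": m_effect,
    }
    return maps, truth


def gen_condition_tmaps(
    cohort: pd.DataFrame, config: SynthConfig = SynthConfig(), seed: int = 0
) -> tuple[ConditionStack, dict]:
    """Per-subject t-maps for 5 vocal conditions + 1 rotated condition.

    Model per subject s and vocal condition c, at every voxel:

        map = A + d_s * P_c * [in sphere] + noise

    with a shared pattern A (unit variance), condition-specific patterns P_c
    confined to the target sphere, and white noise. Within the sphere the
    expected pairwise condition correlation is 1 / (1 + d_s^2 + sigma^2), so
    the per-subject distinctness d_s controls similarity directly. d_s is
    derived by inverting a linear model on the Fisher-z scale whose latent is
    coupled to standardized vividness at |rsa_coupling_r| (negative coupling:
    vivid imagers get more distinct patterns). The rotated condition shares
    a damped copy of A plus its own pattern family.
    """
    grid = config.functional_grid()
    n = min(int(config.n_functional), len(cohort))
    sub = cohort.iloc[:n]
    rng = np.random.default_rng(seed)
    sphere = make_sphere_mask(config.sphere_center_mm, config.sphere_radius_mm, grid)
    flat = sphere.flat_indices()
    V = grid.n_voxels
    n_roi = flat.size

    A = rng.standard_normal(V)
    P = rng.standard_normal((len(VOCAL_CONDITIONS), n_roi))
    Q = rng.standard_normal(n_roi)

    zv = _standardize(sub["bais_vividness"].to_numpy(dtype=float))
    rho = abs(config.rsa_coupling_r)
    sign = np.sign(config.rsa_coupling_r) or -1.0
    eps = rng.standard_normal(n)
    w = sign * rho * zv + np.sqrt(1.0 - rho * rho) * eps  # corr(w, zv) = sign*rho
    z0 = np.arctanh(config.mean_within_similarity)
    lam = config.similarity_sd / (1.0 - config.mean_within_similarity**2)
    z_target = z0 + lam * w
    r_target = np.tanh(z_target)
    d2 = np.maximum(1.0 / r_target - 1.0 - config.tmap_noise_var, 0.0)
    d = np.sqrt(d2)

    sigma = np.sqrt(config.tmap_noise_var)
    conditions = (*VOCAL_CONDITIONS, ROTATED_CONDITION)
    data = np.empty((n, len(conditions), V))
    for s in range(n):
        for c in range(len(VOCAL_CONDITIONS)):
            vol = A + sigma * rng.standard_normal(V)
            vol[flat] += d[s] * P[c]
            data[s, c] = vol
        rot = config.rotated_shared_gain * A + sigma * rng.standard_normal(V)
        rot[flat] += d[s] * Q
        data[s, -1] = rot
    stack = ConditionStack(
        data.reshape(n, len(conditions), *grid.shape),
        conditions,
        grid,
        tuple(sub["subject_id"]),
    )
    truth = {
        "sphere": sphere,
        "distinctness": d,
        "z_target": z_target,
        "latent_w": w,
        "zv": zv,
    }
    return stack, truth
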