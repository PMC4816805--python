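"""Stage orchestration: simulate -> vbm -> anova -> rsa -> report.

A run is configured by a YAML/dict document and produces, under one output
directory, the simulated inputs, statistic maps, cluster tables
(CSV mirroring the usual VBM/fMRI table layout), a correlation report JSON,
and a manifest with content checksums so deterministic stages can be
verified to reproduce bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import anova as anova_mod
from . import behavioral, glm, inference, rsa, synth, volumes
from .errors import ValidationError

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "vbm", "anova", "rsa", "report")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "imagerylink_out",
    "stages": list(ALL_STAGES),
    "n_perm": 500,
    "synth": {},
    "vbm": {
        "interest": "bais_vividness",
        "forming_p": 0.005,
        "absolute_threshold": 0.05,
        "connectivity": 18,
    },
    "anova": {"forming_p": 0.005, "connectivity": 18},
    "rsa": {"sphere": None},  # "x,y,z,r" string; None -> synth sphere spec
}


def parse_sphere_spec(spec: str) -> tuple[tuple[float, float, float], float]:
    """Parse an ``x,y,z,radius`` millimeter string into (center, radius)."""
    parts = [p.strip() for p in str(spec).split(",")]
    if len(parts) != 4:
        raise ValidationError(f"sphere spec must be 'x,y,z,radius', got {spec!r}")
    x, y, z, r = (float(p) for p in parts)
    return (x, y, z), r


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(config: Union[str, Path, dict, None]) -> dict:
    if config is None:
        return dict(DEFAULT_CONFIG)
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValidationError("config must be a mapping")
    return _merge(DEFAULT_CONFIG, config)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record: config hash, seeds, outputs with checksums."""

    config_hash: str
    seed: int
    stages: list[str]
    outputs: dict[str, dict[str, str]]
    timestamps: dict[str, float]

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


class PipelineRun:
    """Holds paths and lazily-loaded intermediates for one configured run."""

    def __init__(self, config: Union[str, Path, dict, None] = None,
                 outdir: Optional[Union[str, Path]] = None,
                 seed: Optional[int] = None):
        self.config = load_config(config)
        if outdir is not None:
            self.config["outdir"] = str(outdir)
        if seed is not None:
            self.config["seed"] = int(seed)
        self.outdir = Path(self.config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(self.config["seed"])
        self.synth_config = synth.SynthConfig(**self.config.get("synth", {}))
        self.outputs: dict[str, dict[str, str]] = {}
        self.timestamps: dict[str, float] = {}

    # ---- bookkeeping ---------------------------------------------------

    def _register(self, name: str, path: Path) -> Path:
        self.outputs[name] = {"path": str(path), "sha256": _sha256(path)}
        return path

    def path(self, name: str) -> Path:
        return self.outdir / name

    def _require(self, name: str, stage_hint: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise ValidationError(
                f"missing {p.name}; run the '{stage_hint}' stage first"
            )
        return p

    # ---- stages --------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg, seed = self.synth_config, self.seed
        cohort = synth.gen_cohort(cfg, seed=seed)
        behavioral.save_cohort(cohort, self.path("cohort.csv"))
        self._register("cohort", self.path("cohort.csv"))

        gm_maps, gm_truth = synth.gen_gm_maps(cohort, cfg, seed=seed + 1)
        volumes.write_volume_stack(gm_maps, self.path("gm.nii.gz"))
        self._register("gm_stack", self.path("gm.nii.gz"))
        volumes.write_volume(
            volumes.VolumeMap(
                gm_maps[0].grid, gm_truth["effect_mask"].astype(np.uint8), "mask"
            ),
            self.path("truth_effect_mask.nii.gz"),
        )
        self._register("truth_effect_mask", self.path("truth_effect_mask.nii.gz"))

        stack, rsa_truth = synth.gen_condition_tmaps(cohort, cfg, seed=seed + 2)
        for c, cond in enumerate(stack.conditions):
            maps = [
                volumes.VolumeMap(stack.grid, stack.data[s, c]) for s in range(stack.n_subjects)
            ]
            volumes.write_volume_stack(maps, self.path(f"func_{cond}.nii.gz"))
            self._register(f"func_{cond}", self.path(f"func_{cond}.nii.gz"))

        truth = {
            "gm_slope": float(gm_truth["slope"]),
            "gm_sigma_roi_noise": float(gm_truth["sigma_roi_noise"]),
            "rsa_distinctness": [float(v) for v in rsa_truth["distinctness"]],
            "rsa_sphere_center_mm": list(cfg.sphere_center_mm),
            "rsa_sphere_radius_mm": cfg.sphere_radius_mm,
            "functional_subjects": list(stack.subject_ids),
        }
        with open(self.path("truth.json"), "w") as fh:
            json.dump(truth, fh, indent=2)
        self._register("truth", self.path("truth.json"))
        with open(self.path("config_echo.yaml"), "w") as fh:
            yaml.safe_dump(self.config, fh)
        self._register("config_echo", self.path("config_echo.yaml"))

    def _load_cohort(self) -> pd.DataFrame:
        return behavioral.load_cohort(self._require("cohort.csv", "simulate"))

    def stage_vbm(self) -> None:
        vcfg = self.config["vbm"]
        cohort = self._load_cohort()
        gm_maps = volumes.read_volume_stack(self._require("gm.nii.gz", "simulate"))
        gm_maps = [volumes.VolumeMap(m.grid, m.values, "gray_matter") for m in gm_maps]
        mask = volumes.absolute_mask(gm_maps, vcfg["absolute_threshold"])
        design = glm.build_design(cohort, vcfg["interest"])
        tmap = glm.fit_voxelwise_t(gm_maps, design, mask=mask.values.astype(bool))
        volumes.write_volume(tmap.to_volume(), self.path("vbm_tmap.nii.gz"))
        self._register("vbm_tmap", self.path("vbm_tmap.nii.gz"))
        zvals = np.full(tmap.grid.shape, np.nan)
        zvals[tmap.mask] = glm.z_from_t(tmap.values[tmap.mask], tmap.df)
        volumes.write_volume(
            volumes.VolumeMap(tmap.grid, np.nan_to_num(zvals)), self.path("vbm_zmap.nii.gz")
        )
        self._register("vbm_zmap", self.path("vbm_zmap.nii.gz"))

        table = inference.cluster_fwe(
            gm_maps,
            design,
            forming_threshold_p=vcfg["forming_p"],
            n_perm=int(self.config["n_perm"]),
            seed=self.seed + 10,
            connectivity=vcfg["connectivity"],
            mask=mask.values.astype(bool),
        )
        table.to_csv(self.path("vbm_clusters.csv"))
        self._register("vbm_clusters", self.path("vbm_clusters.csv"))
        with open(self.path("vbm_inference.json"), "w") as fh:
            json.dump(
                {
                    "n_perm": table.n_perm,
                    "seed": table.seed,
                    "forming_threshold_p": table.forming_threshold_p,
                    "cutoff": table.cutoff,
                    "connectivity": table.connectivity,
                    "df": tmap.df,
                },
                fh,
                indent=2,
            )
        self._register("vbm_inference", self.path("vbm_inference.json"))

        # residualized ROI gray matter for the largest significant cluster
        if len(table) and np.isfinite(table.min_p_fwe):
            best = table.table.iloc[0]
            cutoff = table.cutoff
            with np.errstate(invalid="ignore"):
                supra = (tmap.values > cutoff) & tmap.mask
            from scipy import ndimage as ndi

            labels, _ = ndi.label(
                supra, structure=inference._structure(table.connectivity)
            )
            peak_idx = tuple(
                int(round(v))
                for v in tmap.grid.world_to_index(
                    [best["peak_x_mm"], best["peak_y_mm"], best["peak_z_mm"]]
                )
            )
            cluster_mask = labels == labels[peak_idx]
            resid = glm.adjusted_roi_gm(gm_maps, design.nuisance_only(), cluster_mask)
            out = pd.DataFrame(
                {"subject_id": cohort["subject_id"], "roi_gm_residual": resid}
            )
            out.to_csv(self.path("vbm_roi_residuals.csv"), index=False)
            self._register("vbm_roi_residuals", self.path("vbm_roi_residuals.csv"))

    def _load_condition_stack(self) -> anova_mod.ConditionStack:
        conditions = (*anova_mod.VOCAL_CONDITIONS, anova_mod.ROTATED_CONDITION)
        per_cond = {}
        for cond in conditions:
            maps = volumes.read_volume_stack(
                self._require(f"func_{cond}.nii.gz", "simulate")
            )
            per_cond[cond] = maps
        n = len(per_cond[conditions[0]])
        with open(self._require("truth.json", "simulate")) as fh:
            subject_ids = json.load(fh)["functional_subjects"]
        maps = [[per_cond[c][s] for c in conditions] for s in range(n)]
        return anova_mod.ConditionStack.from_maps(maps, conditions, subject_ids)

    def stage_anova(self) -> None:
        acfg = self.config["anova"]
        stack = self._load_condition_stack()
        fmap = anova_mod.rm_anova_f(stack)
        volumes.write_volume(fmap.to_volume(), self.path("anova_fmap.nii.gz"))
        self._register("anova_fmap", self.path("anova_fmap.nii.gz"))
        table = anova_mod.anova_cluster_report(
            stack,
            forming_threshold_p=acfg["forming_p"],
            n_perm=int(self.config["n_perm"]),
            seed=self.seed + 20,
            connectivity=acfg["connectivity"],
        )
        table.to_csv(self.path("anova_clusters.csv"))
        self._register("anova_clusters", self.path("anova_clusters.csv"))
        with open(self.path("anova_inference.json"), "w") as fh:
            json.dump(
                {
                    "n_perm": table.n_perm,
                    "seed": table.seed,
                    "forming_threshold_p": table.forming_threshold_p,
                    "df": list(fmap.df),
                },
                fh,
                indent=2,
            )
        self._register("anova_inference", self.path("anova_inference.json"))

    def stage_rsa(self) -> None:
        rcfg = self.config["rsa"]
        stack = self._load_condition_stack()
        cohort = self._load_cohort()
        if rcfg.get("sphere"):
            center, radius = parse_sphere_spec(rcfg["sphere"])
        else:
            center = self.synth_config.sphere_center_mm
            radius = self.synth_config.sphere_radius_mm
        sphere = volumes.make_sphere_mask(center, radius, stack.grid)
        summaries = []
        vocal_idx = [stack.conditions.index(c) for c in anova_mod.VOCAL_CONDITIONS]
        rot_idx = stack.conditions.index(anova_mod.ROTATED_CONDITION)
        for s, sid in enumerate(stack.subject_ids):
            vocal_maps = [
                glm.StatMap(stack.grid, stack.data[s, c], "t", 1,
                            np.ones(stack.grid.shape, bool))
                for c in vocal_idx
            ]
            rot_map = glm.StatMap(stack.grid, stack.data[s, rot_idx], "t", 1,
                                  np.ones(stack.grid.shape, bool))
            summaries.append(rsa.summarize_subject(sid, vocal_maps, rot_map, sphere))
        frame = rsa.summaries_to_frame(summaries)
        frame.to_csv(self.path("rsa_summaries.csv"), index=False)
        self._register("rsa_summaries", self.path("rsa_summaries.csv"))

        sub_cohort = cohort[cohort["subject_id"].isin(frame["subject_id"])]
        report = {"n_voxels_roi": int(sphere.n_voxels)}
        for key in ("mean_z_within_vocal", "mean_z_vocal_vs_rotated"):
            plain = rsa.similarity_behavior_link(frame, sub_cohort, similarity=key)
            partial = rsa.similarity_behavior_link(
                frame, sub_cohort, similarity=key,
                covariates=behavioral.NUISANCE_COLUMNS,
            )
            report[key] = {
                "r": plain.r, "p": plain.p_two_sided, "n": plain.n,
                "partial_r": partial.r, "partial_p": partial.p_two_sided,
            }
        with open(self.path("rsa_report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        self._register("rsa_report", self.path("rsa_report.json"))

    def stage_report(self) -> None:
        cohort = self._load_cohort()
        rep: dict = {"behavioral": {}}
        vc = behavioral.pearson_r(cohort["bais_vividness"], cohort["bais_control"])
        vv = behavioral.pearson_r(cohort["bais_vividness"], cohort["vviq_vividness"])
        rep["behavioral"]["vividness_vs_control"] = {"r": vc.r, "p": vc.p_two_sided, "n": vc.n}
        rep["behavioral"]["auditory_vs_visual_vividness"] = {
            "r": vv.r, "p": vv.p_two_sided, "n": vv.n,
        }
        roi_path = self.path("vbm_roi_residuals.csv")
        if roi_path.exists():
            roi = pd.read_csv(roi_path).merge(cohort, on="subject_id")
            rr = behavioral.pearson_r(roi["roi_gm_residual"], roi["bais_vividness"])
            pr = behavioral.partial_r(
                roi["roi_gm_residual"], roi["bais_vividness"],
                roi[["bais_control"]].to_numpy(),
            )
            rep["vbm_roi"] = {
                "r_gm_vividness": rr.r, "p": rr.p_two_sided,
                "partial_r_controlling_control": pr.r, "partial_p": pr.p_two_sided,
            }
        clusters_path = self.path("vbm_clusters.csv")
        if clusters_path.exists():
            tab = pd.read_csv(clusters_path)
            if len(tab):
                rep["vbm_top_cluster"] = tab.iloc[0].to_dict()
        rsa_path = self.path("rsa_report.json")
        if rsa_path.exists():
            with open(rsa_path) as fh:
                rep["rsa"] = json.load(fh)
        with open(self.path("report.json"), "w") as fh:
            json.dump(rep, fh, indent=2)
        self._register("report", self.path("report.json"))

    # ---- driver --------------------------------------------------------

    def run(self) -> RunManifest:
        stage_fns = {
            "simulate": self.stage_simulate,
            "vbm": self.stage_vbm,
            "anova": self.stage_anova,
            "rsa": self.stage_rsa,
            "report": self.stage_report,
        }
        requested = list(self.config["stages"])
        unknown = [s for s in requested if s not in stage_fns]
        if unknown:
            raise ValidationError(f"unknown stages: {unknown}")
        ordered = [s for s in ALL_STAGES if s in requested]
        for stage in ordered:
            logger.info("stage=%s seed=%d", stage, self.seed)
            t0 = time.time()
            stage_fns[stage]()
            self.timestamps[stage] = time.time() - t0
        canonical = yaml.safe_dump(self.config, sort_keys=True)
        manifest = RunManifest(
            config_hash=hashlib.sha256(canonical.encode()).hexdigest(),
            seed=self.seed,
            stages=ordered,
            outputs=self.outputs,
            timestamps=self.timestamps,
        )
        manifest.to_json(self.outdir / "manifest.json")
        return manifest


def run_pipeline(
    config: Union[str, Path, dict, None] = None,
    outdir: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
) -> RunManifest:
    """Execute the requested stages in dependency order; returns the manifest."""
    return PipelineRun(config, outdir=outdir, seed=seed).run()
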