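"""End-to-end orchestration: simulate -> behavior -> GLM -> ROI -> RSA -> PCA.

Each stage consumes and produces files only, so stages are independently
re-runnable; a run manifest records the configuration snapshot, seeds, per-
stage outputs with checksums, timings and warnings.  Re-running with the
same configuration resumes from cached stage outputs and reproduces
identical checksums for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, evaluate, glm, io, pca, roi, rsa, synth
from .config import CONDITION_NAMES, StudyConfig, from_yaml, to_yaml

__all__ = ["run_all", "RunManifest"]


@dataclasses.dataclass
class RunManifest:
    config_path: str
    seed: int
    stages: dict
    warnings: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Caches a stage on disk: skipped when its done-marker exists."""

    def __init__(self, out_dir: Path, name: str, manifest: RunManifest):
        self.dir = out_dir / name
        self.name = name
        self.manifest = manifest
        self.marker = self.dir / ".done"

    def cached(self) -> bool:
        return self.marker.exists()

    def finish(self, t0: float) -> None:
        files = sorted(
            str(p.relative_to(self.dir))
            for p in self.dir.rglob("*")
            if p.is_file() and p.name != ".done"
        )
        self.marker.write_text("ok")
        self.manifest.stages[self.name] = {
            "outputs": {f: _checksum(self.dir / f) for f in files},
            "seconds": round(time.time() - t0, 3),
            "cached": False,
        }

    def record_cached(self) -> None:
        files = sorted(
            str(p.relative_to(self.dir))
            for p in self.dir.rglob("*")
            if p.is_file() and p.name != ".done"
        )
        self.manifest.stages[self.name] = {
            "outputs": {f: _checksum(self.dir / f) for f in files},
            "seconds": 0.0,
            "cached": True,
        }


def run_all(
    config: StudyConfig | str | Path,
    out_dir: str | Path,
    n_sims: int = 500,
    resume: bool = True,
) -> RunManifest:
    """Run every stage on one synthetic cohort; returns the manifest.

    ``config`` may be a :class:`StudyConfig` or a path to its YAML form.
    Stage outputs land under ``out_dir/<stage>/``; deleting a stage
    directory and re-running recomputes that stage and everything after it
    (downstream stages check their own caches only, so stale downstream
    caches should be removed together — the manifest records checksums to
    detect this).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(config, (str, Path)):
        cfg = from_yaml(config)
    else:
        cfg = config
    cfg_path = out_dir / "config.yaml"
    to_yaml(cfg, cfg_path)
    manifest = RunManifest(str(cfg_path), cfg.seed, {}, [])
    aff = cfg.affine()

    def stage(name):
        st = _Stage(out_dir, name, manifest)
        if resume and st.cached():
            st.record_cached()
            return st, True
        if st.dir.exists():
            for p in sorted(st.dir.rglob("*"), reverse=True):
                p.unlink() if p.is_file() else p.rmdir()
        st.dir.mkdir(parents=True, exist_ok=True)
        return st, False

    # ------------------------------------------------------------------ simulate
    st, cached = stage("simulate")
    if not cached:
        t0 = time.time()
        for i, (trials, series, truth) in enumerate(synth.generate_cohort(cfg)):
            io.save_trials(trials, st.dir / f"sub-{i:02d}_trials.tsv")
            io.save_volume(series, aff, st.dir / f"sub-{i:02d}_bold.nii.gz")
            io.save_ground_truth(truth, cfg, st.dir / f"sub-{i:02d}")
        st.finish(t0)

    def load_subject(i):
        trials = io.load_trials(st_sim_dir / f"sub-{i:02d}_trials.tsv")
        series, _ = io.load_volume(st_sim_dir / f"sub-{i:02d}_bold.nii.gz", aff)
        return trials, series

    st_sim_dir = out_dir / "simulate"

    # ------------------------------------------------------------------ behavior
    st, cached = stage("behavior")
    if not cached:
        t0 = time.time()
        tabs = [io.load_trials(st_sim_dir / f"sub-{i:02d}_trials.tsv") for i in range(cfg.n_subjects)]
        all_trials = pd.concat(tabs, ignore_index=True)
        vs = behavior.compute_value_saliency(all_trials)
        vs[["subject_id", "trial_index", "category", "level", "rating", "value", "saliency"]].to_csv(
            st.dir / "value_saliency.tsv", sep="\t", index=False
        )
        table, outliers = behavior.cell_means_with_outlier_removal(all_trials)
        anova = behavior.rm_anova(table)
        anova.to_csv(st.dir / "anova.tsv", sep="\t", index=False)
        if outliers:
            manifest.warnings.append(f"behavior: removed outlier cells {outliers}")
        st.finish(t0)

    # ------------------------------------------------------------------ glm fit
    st, cached = stage("glm")
    if not cached:
        t0 = time.time()
        for i in range(cfg.n_subjects):
            trials, series = load_subject(i)
            n_scans = series.shape[-1]
            # univariate pathway: 6 mm smoothing
            clean, _ = glm.preprocess(series, cfg.voxel_size_mm, smooth_fwhm_mm=6.0)
            des = glm.build_design(trials, n_scans, cfg.tr_s, "main")
            betas, _ = glm.fit_ols(clean, des)
            for name in ("na_cue", "na_cue_value", "na_cue_saliency"):
                io.save_volume(betas[name], aff, st.dir / f"sub-{i:02d}_{name}.nii.gz")
            # pattern pathway: no smoothing, 16-condition design
            clean_mv, _ = glm.preprocess(series, cfg.voxel_size_mm, smooth_fwhm_mm=0.0)
            des16 = glm.build_design(trials, n_scans, cfg.tr_s, "cond16")
            betas16, _ = glm.fit_ols(clean_mv, des16)
            stack = np.stack([betas16[c] for c in CONDITION_NAMES])
            io.save_volume(np.moveaxis(stack, 0, -1), aff, st.dir / f"sub-{i:02d}_cond16.nii.gz")
        st.finish(t0)
    st_glm_dir = out_dir / "glm"

    # ------------------------------------------------------------------ group maps
    st, cached = stage("group")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1001]))
    mask = np.ones(cfg.grid_shape, dtype=bool)
    if not cached:
        t0 = time.time()
        for name in ("na_cue_value", "na_cue_saliency"):
            stack = np.asarray(
                [
                    io.load_volume(st_glm_dir / f"sub-{i:02d}_{name}.nii.gz", aff)[0]
                    for i in range(cfg.n_subjects)
                ]
            )
            t_map, df = glm.group_ttest(stack, mask)
            fwhm = evaluate.smoothness_from_maps(stack, mask, cfg.voxel_size_mm)
            k = glm.cluster_threshold(
                t_map.shape, mask, fwhm, cfg.voxel_size_mm, 0.005, 0.05, n_sims, rng
            )
            t_crit = stats.t.isf(0.005 / 2.0, df)
            clusters, surviving = glm.apply_threshold(t_map, t_crit, k)
            io.save_volume(t_map, aff, st.dir / f"group_{name}_t.nii.gz")
            io.save_volume(surviving.astype(float), aff, st.dir / f"group_{name}_mask.nii.gz")
            tab = glm.clusters_to_table(clusters)
            tab.insert(0, "cluster_k", k)
            tab.to_csv(st.dir / f"group_{name}_clusters.tsv", sep="\t", index=False)
        st.finish(t0)
    st_group_dir = out_dir / "group"

    # ------------------------------------------------------------------ LOSO ROI + stats
    st, cached = stage("roi")
    if not cached:
        t0 = time.time()
        value_stack = np.asarray(
            [
                io.load_volume(st_glm_dir / f"sub-{i:02d}_na_cue_value.nii.gz", aff)[0]
                for i in range(cfg.n_subjects)
            ]
        )
        sal_stack = np.asarray(
            [
                io.load_volume(st_glm_dir / f"sub-{i:02d}_na_cue_saliency.nii.gz", aff)[0]
                for i in range(cfg.n_subjects)
            ]
        )
        value_rois = [e.roi for e in cfg.effects if e.kind == "value_linear"]
        if value_rois:
            seed_mask = value_rois[0]
            loso = roi.loso_define(
                value_stack, seed_mask, cfg.voxel_size_mm, radius_mm=5.0,
                mask=mask, n_sims=n_sims, rng=rng,
            )
            if loso.undefined_folds:
                manifest.warnings.append(f"roi: undefined LOSO folds {loso.undefined_folds}")
            v_betas, s_betas = [], []
            for i, m in enumerate(loso.masks):
                if m is None:
                    v_betas.append(np.nan)
                    s_betas.append(np.nan)
                else:
                    io.save_volume(m.astype(float), aff, st.dir / f"sub-{i:02d}_loso.nii.gz")
                    v_betas.append(roi.extract_roi_betas(value_stack[i], m))
                    s_betas.append(roi.extract_roi_betas(sal_stack[i], m))
            if loso.n_defined >= 3:
                stats_tab = roi.roi_effect_tests(np.asarray(v_betas), np.asarray(s_betas))
                stats_tab.to_csv(st.dir / "loso_value_roi_stats.tsv", sep="\t", index=False)
        else:
            manifest.warnings.append("roi: no value effect in config; LOSO stage skipped")
        st.finish(t0)

    # ------------------------------------------------------------------ RSA
    st, cached = stage("rsa")
    if not cached:
        t0 = time.time()
        rho_stacks: dict[str, list] = {}
        for i in range(cfg.n_subjects):
            vol, _ = io.load_volume(st_glm_dir / f"sub-{i:02d}_cond16.nii.gz", aff)
            betas16 = np.moveaxis(vol, -1, 0)
            trials = io.load_trials(st_sim_dir / f"sub-{i:02d}_trials.tsv")
            mods = synth.condition_modulators(trials)
            models = {
                "category": rsa.build_model_rdm("category"),
                "value": rsa.build_model_rdm("value", mods),
                "saliency": rsa.build_model_rdm("saliency", mods),
            }
            rhos = rsa.searchlight(betas16, mask, models)
            for name, vol_r in rhos.items():
                rho_stacks.setdefault(name, []).append(vol_r)
        for name, stack_list in rho_stacks.items():
            stack = np.asarray(stack_list)
            z_map, p_map = rsa.group_inference(stack)
            fwhm = evaluate.smoothness_from_maps(stack, mask, cfg.voxel_size_mm)
            k = glm.cluster_threshold(
                z_map.shape, mask, fwhm, cfg.voxel_size_mm, 0.005, 0.05, n_sims, rng,
                two_tailed=False,
            )
            io.save_volume(np.nan_to_num(z_map), aff, st.dir / f"rsa_{name}_z.nii.gz")
            supra = np.nan_to_num(p_map, nan=1.0) < 0.005
            clusters, surviving = glm.apply_threshold(
                np.where(supra, 1.0, 0.0), 0.5, k, two_tailed=False
            )
            io.save_volume(surviving.astype(float), aff, st.dir / f"rsa_{name}_mask.nii.gz")
            tab = glm.clusters_to_table(clusters)
            tab.insert(0, "cluster_k", k)
            tab.to_csv(st.dir / f"rsa_{name}_clusters.tsv", sep="\t", index=False)
        st.finish(t0)

    # ------------------------------------------------------------------ PCA
    st, cached = stage("pca")
    if not cached:
        t0 = time.time()
        pattern_rois = [e.roi for e in cfg.effects if e.kind == "category_pattern"]
        target = pattern_rois[0] if pattern_rois else (
            cfg.effects[0].roi if cfg.effects else mask
        )
        results, cond_means = [], []
        for i in range(cfg.n_subjects):
            vol, _ = io.load_volume(st_glm_dir / f"sub-{i:02d}_cond16.nii.gz", aff)
            betas16 = np.moveaxis(vol, -1, 0)
            trials = io.load_trials(st_sim_dir / f"sub-{i:02d}_trials.tsv")
            results.append(pca.fit_roi_pca(betas16[:, target], k=3))
            cond_means.append(synth.condition_modulators(trials))
        var_tab = pd.DataFrame(
            {"subject_id": range(len(results)),
             **{f"pc{j + 1}_variance": [r.variance_fraction[j] for r in results] for j in range(3)}}
        )
        var_tab.to_csv(st.dir / "variance_explained.tsv", sep="\t", index=False)
        _, hist = pca.loading_histogram(results)
        hist.to_csv(st.dir / "loading_histogram.tsv", sep="\t", index=False)
        regs = [pca.pc_mixed_regression(results, cond_means, c) for c in range(3)]
        pd.concat(regs, ignore_index=True).to_csv(
            st.dir / "pc_regressions.tsv", sep="\t", index=False
        )
        st.finish(t0)

    manifest.to_json(out_dir / "manifest.json")
    return manifest
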