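"""End-to-end orchestration: simulate -> correct -> preprocess -> sample ->
decode -> infer, producing figure-equivalent tables from one configuration.

Per contrast the pipeline writes: per-session ODC contrast maps across depth,
ocular percent-signal-change depth profiles, decoding depth profiles with
bootstrap CI and FDR-adjusted p-values, a session-repeatability table
(Spearman + spatial permutation test), optionally a feature-count sweep
matrix, extrastriate (V2/V3 halves) decoding profiles and the V3-to-V1
surface distance histogram, plus a machine-readable manifest with all seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .decode import (DecoderConfig, build_session_samples, feature_count_sweep,
                     leave_one_run_out, select_features)
from .design import RunDesign
from .layers import min_distance_to_region
from .preproc import glm_contrast, highpass_filter
from .stats import depth_profile_inference, permutation_test, spearman
from .synthgen import (GE_BOLD, SE_BOLD, VASO, AcquisitionModel, CortexPatch,
                       make_cortex_patch, simulate_odc_pattern, simulate_run,
                       simulate_vaso_pair)
from .vaso import bold_correct

HIGHPASS_CUTOFF_HZ = 1.0 / 270.0

_MODEL_FACTORY = {GE_BOLD: AcquisitionModel.ge_bold, SE_BOLD: AcquisitionModel.se_bold,
                  VASO: AcquisitionModel.vaso}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""

    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {err}")


def simulate_session(patch: CortexPatch, cmap, model: AcquisitionModel,
                     design_proto: RunDesign, n_runs: int, seed: int,
                     target_tr_s: float = 3.0):
    """Simulate (and for VASO, BOLD-correct) the runs of one session.

    Returns ``(runs, designs)`` where every run is on the analysis TR grid
    (``target_tr_s``); VASO runs are the corrected nulled/not-nulled ratio.
    """
    rng = np.random.default_rng(seed)
    runs, designs = [], []
    for _ in range(n_runs):
        run_seed = int(rng.integers(0, 2 ** 31 - 1))
        design = RunDesign.pseudorandom(run_seed, tr_s=model.tr_s,
                                        run_duration_s=design_proto.run_duration_s,
                                        baseline_s=design_proto.baseline_s,
                                        block_s=design_proto.block_s,
                                        n_blocks=design_proto.n_blocks)
        if model.contrast == VASO:
            nulled, not_nulled = simulate_vaso_pair(patch, cmap, design, model,
                                                    seed=run_seed)
            corrected, _ = bold_correct(nulled, not_nulled, target_tr_s)
            runs.append(corrected)
            designs.append(replace(design, tr_s=target_tr_s))
        else:
            runs.append(simulate_run(patch, cmap, design, model, seed=run_seed))
            designs.append(design)
    return runs, designs


def ocular_psc_profile(cmap_glm, feats: np.ndarray, sign_flip: float = 1.0) -> np.ndarray:
    """Ocular response magnitude (percent signal change) per depth.

    Half the left-minus-right PSC difference, signed by the vertex's own
    contrast so left- and right-preferring vertices contribute positively,
    averaged over the per-depth selected vertices.
    """
    diff = (cmap_glm.psc_left - cmap_glm.psc_right) / 2.0 * sign_flip
    n_depths = diff.shape[1]
    out = np.empty(n_depths)
    for d in range(n_depths):
        vals = diff[feats[d], d]
        out[d] = float(np.mean(vals * np.sign(cmap_glm.z[feats[d], d] * sign_flip)))
    return out


def _process_session(patch, samples_vertex_space, runs, designs, cfg: DecoderConfig,
                     do_decode: bool):
    """Highpass + GLM + (optionally) decoding for one simulated session."""
    runs_f = [highpass_filter(r, HIGHPASS_CUTOFF_HZ) for r in runs]
    glm = glm_contrast(runs_f, designs)
    samples = build_session_samples(runs_f, designs, patch)
    all_runs = np.unique(samples.run_id)
    feats = select_features(samples, cfg, all_runs)  # session-level ROI for PSC
    feats_full = samples.vertex_index[feats]
    decoding = leave_one_run_out(samples, cfg) if do_decode else None
    return glm, samples, feats_full, decoding


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the complete synthetic study analysis; returns the manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    p = config.patch
    patch = make_cortex_patch(p.n_x, p.n_y, p.spacing_mm, p.thickness_mm,
                              p.curvature_amp, n_intermediate=p.n_intermediate)
    d = config.design
    design_proto = RunDesign(run_duration_s=d.run_duration_s, baseline_s=d.baseline_s,
                             block_s=d.block_s, n_blocks=d.n_blocks, tr_s=d.tr_s)
    fractions = patch.depth_fractions
    mid_depth = int(np.argmin(np.abs(fractions - 0.5)))
    cfg = config.decoder
    manifest = {"version": __version__, "seed": config.seed,
                "config": _config_dict(config), "outputs": [], "stages": {}}

    cmap_seeds = [int(rng.integers(0, 2 ** 31 - 1)) for _ in range(config.study.n_participants)]
    cmaps = [simulate_odc_pattern(patch, config.odc.period_mm, config.odc.anisotropy,
                                  config.odc.sigmoid_gain, seed=s) for s in cmap_seeds]
    manifest["participant_map_seeds"] = cmap_seeds

    for contrast in config.study.contrasts:
        cdir = out / contrast
        cdir.mkdir(exist_ok=True)
        model = _MODEL_FACTORY[contrast]()
        sign_flip = -1.0 if contrast == VASO else 1.0
        acc_rows, psc_rows, rep_rows, rep_depth_rows, map_rows = [], [], [], [], []
        acc_by_participant, psc_by_participant = [], []
        region_rows = []
        sweep_matrix = None
        try:
            for pi in range(config.study.n_participants):
                sess_acc, sess_psc, sess_zmid = [], [], []
                for si in range(config.study.sessions_per_contrast):
                    sess_seed = int(rng.integers(0, 2 ** 31 - 1))
                    jitter = 1.0 + config.study.amplitude_jitter_sd * float(rng.standard_normal())
                    sess_model = replace(model,
                                         amplitude_base=model.amplitude_base * max(jitter, 0.0))
                    runs, designs = simulate_session(patch, cmaps[pi], sess_model,
                                                     design_proto,
                                                     config.study.runs_per_session,
                                                     sess_seed)
                    glm, samples, feats_full, decoding = _process_session(
                        patch, None, runs, designs, cfg, config.stages.decode)
                    psc_profile = ocular_psc_profile(glm, feats_full, sign_flip)
                    sess_psc.append(psc_profile)
                    v1 = patch.region_label == "V1"
                    sess_zmid.append(sign_flip * glm.z[v1, mid_depth])
                    if config.stages.write_maps:
                        for di, frac in enumerate(fractions):
                            map_rows.append(pd.DataFrame({
                                "participant": pi + 1, "session": si + 1,
                                "depth_fraction": frac,
                                "vertex": np.arange(patch.n_vertices),
                                "z": sign_flip * glm.z[:, di],
                                "psc_left": glm.psc_left[:, di],
                                "psc_right": glm.psc_right[:, di]}))
                    for di, frac in enumerate(fractions):
                        psc_rows.append({"participant": pi + 1, "session": si + 1,
                                         "depth_fraction": frac,
                                         "psc": psc_profile[di]})
                    if decoding is not None:
                        sess_acc.append(decoding.mean_accuracy)
                        for di, frac in enumerate(fractions):
                            acc_rows.append({"participant": pi + 1, "session": si + 1,
                                             "depth_fraction": frac,
                                             "accuracy": decoding.mean_accuracy[di]})
                    if (config.stages.regions and contrast == GE_BOLD
                            and config.stages.decode):
                        for reg in ("V2a", "V2b", "V3a", "V3b"):
                            n_eligible = samples.eligible(reg).size
                            reg_cfg = replace(cfg, n_features=min(cfg.n_features,
                                                                  n_eligible))
                            res = leave_one_run_out(samples, reg_cfg, region=reg)
                            for di, frac in enumerate(fractions):
                                region_rows.append({"participant": pi + 1,
                                                    "session": si + 1, "region": reg,
                                                    "depth_fraction": frac,
                                                    "accuracy": res.mean_accuracy[di]})
                    if (config.stages.sweep and sweep_matrix is None
                            and config.stages.decode):
                        sweep_matrix = feature_count_sweep(samples, cfg,
                                                           config.sweep_grid)
                    del samples
                # between-session repeatability
                if len(sess_zmid) >= 2:
                    perm_seed = int(rng.integers(0, 2 ** 31 - 1))
                    rho = spearman(sess_zmid[0], sess_zmid[1])
                    perm = permutation_test(sess_zmid[0], sess_zmid[1],
                                            n_perm=config.stats.n_perm,
                                            subsample_frac=config.stats.subsample_frac,
                                            seed=perm_seed)
                    rep_rows.append({"participant": pi + 1, "rho": rho,
                                     "rho_subset": perm.rho_observed,
                                     "k_exceed": perm.k_exceed,
                                     "p_corrected": perm.p_corrected,
                                     "n_permutations": perm.n_permutations,
                                     "subset_size": perm.subset_size,
                                     "seed": perm_seed})
                if sess_acc:
                    acc_by_participant.append(np.mean(sess_acc, axis=0))
                psc_by_participant.append(np.mean(sess_psc, axis=0))
        except PipelineStageError:
            raise
        except Exception as err:
            raise PipelineStageError(f"{contrast}:simulate+analyze", err) from err

        _write_csv(pd.DataFrame(psc_rows), cdir / "psc_profiles.csv", manifest)
        if map_rows:
            _write_csv(pd.concat(map_rows, ignore_index=True),
                       cdir / "contrast_maps.csv", manifest)
        if rep_rows:
            _write_csv(pd.DataFrame(rep_rows), cdir / "repeatability.csv", manifest)
        if acc_rows:
            _write_csv(pd.DataFrame(acc_rows), cdir / "accuracy_profiles.csv", manifest)
        if region_rows:
            _write_csv(pd.DataFrame(region_rows), cdir / "region_accuracy.csv", manifest)
        if sweep_matrix is not None:
            sw = pd.DataFrame(sweep_matrix, index=list(config.sweep_grid),
                              columns=[f"{f:.1f}" for f in fractions])
            sw.index.name = "n_features"
            sw.to_csv(cdir / "feature_sweep.csv")
            manifest["outputs"].append(str(cdir / "feature_sweep.csv"))

        try:
            if len(psc_by_participant) >= 2:
                psc_inf = depth_profile_inference(np.vstack(psc_by_participant), fractions,
                                                  chance=0.0, n_boot=config.stats.n_boot,
                                                  seed=int(rng.integers(0, 2 ** 31 - 1)))
                _write_inference(psc_inf, cdir / "psc_inference.csv", manifest)
            if len(acc_by_participant) >= 2:
                acc_inf = depth_profile_inference(np.vstack(acc_by_participant), fractions,
                                                  chance=config.stats.chance,
                                                  n_boot=config.stats.n_boot,
                                                  seed=int(rng.integers(0, 2 ** 31 - 1)))
                _write_inference(acc_inf, cdir / "accuracy_inference.csv", manifest)
        except Exception as err:
            raise PipelineStageError(f"{contrast}:inference", err) from err
        manifest["stages"][contrast] = "ok"

    if config.stages.distances:
        try:
            rows = []
            for name, surf in (("GM_WM", patch.inner_surface),
                               ("GM_CSF", patch.outer_surface)):
                dist, summary = min_distance_to_region(surf, patch.region_label,
                                                       ("V3a", "V3b"), "V1")
                for lo, hi, cnt in zip(summary["hist_edges_mm"][:-1],
                                       summary["hist_edges_mm"][1:],
                                       summary["hist_counts"]):
                    rows.append({"surface": name, "bin_lo_mm": lo, "bin_hi_mm": hi,
                                 "count": int(cnt), "mean_mm": summary["mean_mm"],
                                 "min_mm": summary["min_mm"]})
            _write_csv(pd.DataFrame(rows), out / "distances_v3_to_v1.csv", manifest)
        except Exception as err:
            raise PipelineStageError("distances", err) from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["outputs"].append(str(path))


def _write_inference(inf, path: Path, manifest: dict) -> None:
    df = pd.DataFrame({"depth_fraction": inf.depth_fractions, "mean": inf.mean,
                       "ci_low": inf.ci_low, "ci_high": inf.ci_high,
                       "p": inf.p, "p_fdr": inf.p_fdr})
    _write_csv(df, path, manifest)


def _config_dict(config: PipelineConfig) -> dict:
    raw = asdict(config)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        return obj

    return _clean(raw)
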