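"""End-to-end orchestration of the synthetic comparative study.

Stages (each also exposed as a CLI subcommand) communicate through a
BIDS-inspired directory tree::

    out/
      config.json                 study configuration
      truth/                      ground-truth masks + sidecar
      sub-XX/func/                simulated runs, events, motion
      derivatives/glm/            condition/contrast maps per run
      derivatives/blocks/         per-block (single-trial) beta maps
      derivatives/rsa/            per-set similarity maps
      derivatives/group/          fROI tables, ANOVAs, cluster tables
      manifest.json, report.md

All randomness flows from the config seed through named substreams
(:func:`froipipe.config.derive_seed`), so rerunning a study with the
same config reproduces every file exactly.
"""

from __future__ import annotations

import json
import hashlib
import logging
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import froi as froi_mod
from . import glm as glm_mod
from . import rsa as rsa_mod
from . import stimprops as stimprops_mod
from . import synthdata as synth
from .config import StudyConfig, derive_seed
from .inference import permutation_paired_test

__all__ = [
    "run_study",
    "stage_simulate",
    "stage_stimprops",
    "stage_glm",
    "stage_froi",
    "stage_rsa",
    "stage_infer",
]

log = logging.getLogger("froipipe")

#: First-level contrast weights, run 1 (localizer half).
RUN1_CONTRASTS = {
    "all_gt_baseline": {c: 1 / 6 for c in synth.CONDITIONS},
    "faces_gt_bodies": {"dog_face": 0.5, "human_face": 0.5, "dog_body": -0.5, "human_body": -0.5},
    "bodies_gt_faces": {"dog_body": 0.5, "human_body": 0.5, "dog_face": -0.5, "human_face": -0.5},
    "faces_gt_objects": {"dog_face": 0.5, "human_face": 0.5, "object": -1.0},
    "bodies_gt_objects": {"dog_body": 0.5, "human_body": 0.5, "object": -1.0},
}

#: First-level contrast weights, run 2 (independent test half).
RUN2_CONTRASTS = {
    "faces_gt_scrambled": {"dog_face": 0.5, "human_face": 0.5, "scrambled": -1.0},
    "bodies_gt_scrambled": {"dog_body": 0.5, "human_body": 0.5, "scrambled": -1.0},
    "objects_gt_scrambled": {"object": 1.0, "scrambled": -1.0},
    "dog_face_gt_scrambled": {"dog_face": 1.0, "scrambled": -1.0},
    "dog_body_gt_scrambled": {"dog_body": 1.0, "scrambled": -1.0},
    "human_face_gt_scrambled": {"human_face": 1.0, "scrambled": -1.0},
    "human_body_gt_scrambled": {"human_body": 1.0, "scrambled": -1.0},
}

#: fROI recipes: preference contrast, target contrast, test conditions.
ROI_TYPES = {
    "body": ("bodies_gt_faces", "bodies_gt_objects"),
    "face": ("faces_gt_bodies", "faces_gt_objects"),
}

#: RSA trial sets computed once per participant.
RSA_SETS = {
    "faces": ["dog_face", "human_face"],
    "bodies": ["dog_body", "human_body"],
    "animate": ["dog_face", "human_face", "dog_body", "human_body"],
    "objects": ["object"],
    "dog_face": ["dog_face"],
    "human_face": ["human_face"],
    "dog_body": ["dog_body"],
    "human_body": ["human_body"],
}

#: comparison id -> (set A, set B) from RSA_SETS.
RSA_COMPARISONS = {
    "a": ("faces", "objects"),
    "b": ("bodies", "objects"),
    "c": ("animate", "objects"),
    "d": ("faces", "bodies"),
    "e": ("dog_face", "human_face"),
    "f": ("dog_body", "human_body"),
}


def _sub(i: int) -> str:
    return f"sub-{i + 1:02d}"


def _load_config(out: Path) -> StudyConfig:
    return StudyConfig.from_file(out / "config.json")


def _load_img(path: Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def _load_masks(out: Path) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    brain, affine = _load_img(out / "truth" / "brain.nii.gz")
    regions = {}
    for p in sorted((out / "truth").glob("region-*.nii.gz")):
        name = p.name[len("region-") : -len(".nii.gz")]
        regions[name] = _load_img(p)[0] > 0.5
    return brain > 0.5, regions, affine


def _design_from_events(events: pd.DataFrame, tr: float, n_scans: int) -> synth.RunDesign:
    blocks = [
        synth.Block(float(r.onset), float(r.duration), str(r.trial_type))
        for r in events.itertuples()
    ]
    return synth.RunDesign(blocks, [], tr, n_scans)


def _timed(name: str, seed, fn, *args, **kwargs):
    t0 = time.perf_counter()
    result = fn(*args, **kwargs)
    log.info("stage=%s seed=%s wall_s=%.1f", name, seed, time.perf_counter() - t0)
    return result


# ---------------------------------------------------------------------------
# Stage 1: simulate
# ---------------------------------------------------------------------------


def stage_simulate(config: StudyConfig, out: str | Path) -> None:
    """Generate ground truth, stimuli, designs, motion, and BOLD runs."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    preset = config.preset

    truth, brain = synth.default_ground_truth(
        species=config.species,
        shape=config.grid,
        voxel_mm=preset.voxel_mm,
        seed=derive_seed(config.seed, "truth"),
        noise_sd=config.noise_sd,
        hrf=preset.hrf,
    )
    truth.tr = config.tr
    synth.write_mask(brain, truth.affine, out / "truth" / "brain.nii.gz")
    for name, mask in truth.regions.items():
        synth.write_mask(mask, truth.affine, out / "truth" / f"region-{name}.nii.gz")
    (out / "truth" / "truth.json").write_text(
        json.dumps(
            {
                "amplitudes": truth.amplitudes,
                "noise_sd": truth.noise_sd,
                "baseline": truth.baseline,
                "region_sizes": {k: int(v.sum()) for k, v in sorted(truth.regions.items())},
            },
            indent=2,
            sort_keys=True,
        )
    )

    stimuli = synth.generate_stimulus_set(
        config.n_per_condition, seed=derive_seed(config.seed, "stimuli")
    )
    stimuli.to_dataframe().to_csv(out / "stimuli.tsv", sep="\t", index=False)

    for s in range(config.n_subjects):
        used: set[str] = set()
        for r in range(config.n_runs):
            sseed = derive_seed(config.seed, "subject", s, "run", r)
            order = synth.randomize_block_order(
                list(synth.CONDITIONS), config.blocks_per_condition, seed=sseed
            )
            design = synth.build_run_design(
                order,
                stimuli,
                tr=config.tr,
                jitter_range=config.jitter_range_s,
                seed=derive_seed(sseed, "design"),
                used_ids=used,
                images_per_block=config.images_per_block,
                block_duration=config.block_duration_s,
            )
            rng = np.random.default_rng(derive_seed(sseed, "spikes"))
            n_spikes = rng.binomial(design.n_scans, preset.motion_spike_rate)
            spike_spec = {
                "times": sorted(rng.choice(design.n_scans, size=n_spikes, replace=False).tolist()),
                "magnitudes": rng.uniform(0.55, 1.5, n_spikes).tolist(),
            }
            motion = synth.simulate_motion_trace(
                design.n_scans, spike_spec, seed=derive_seed(sseed, "motion")
            )
            vol = synth.simulate_bold_run(
                design, truth, motion, seed=derive_seed(sseed, "bold")
            )
            func = out / _sub(s) / "func"
            tag = f"{_sub(s)}_run-{r + 1}"
            synth.write_bold_run(vol, truth.affine, func / f"{tag}_bold.nii.gz")
            synth.write_events(design, func / f"{tag}_events.tsv")
            synth.write_motion(motion, func / f"{tag}_motion.txt")


def stage_stimprops(config: StudyConfig, out: str | Path) -> pd.DataFrame:
    """Stimulus low-level-property table and its group ANOVAs."""
    out = Path(out)
    stimuli = synth.generate_stimulus_set(
        config.n_per_condition, seed=derive_seed(config.seed, "stimuli")
    )
    table = stimprops_mod.stimulus_property_table(stimuli)
    stimprops_mod.write_property_table(table, out / "derivatives" / "stimprops" / "properties.tsv")
    anovas = stimprops_mod.property_anovas(table)
    rows = []
    for prop, tabs in anovas.items():
        for which, tab in tabs.items():
            for effect, r in tab.iterrows():
                if effect == "Residual":
                    continue
                rows.append(
                    {
                        "property": prop,
                        "anova": which,
                        "effect": effect,
                        "F": float(r["F"]),
                        "p": float(r["PR(>F)"]),
                    }
                )
    # the headline pooled stimulus check: faces vs bodies spatial extent
    faces = table.loc[table["category"] == "face", "spatial_extent"]
    bodies = table.loc[table["category"] == "body", "spatial_extent"]
    tt = stimprops_mod.two_sample_ttest(faces, bodies)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "derivatives" / "stimprops" / "anovas.tsv", sep="\t", index=False)
    pd.DataFrame([{"test": "faces_vs_bodies_spatial_extent", **tt}]).to_csv(
        out / "derivatives" / "stimprops" / "ttests.tsv", sep="\t", index=False
    )
    return table


# ---------------------------------------------------------------------------
# Stage 2: first-level GLMs
# ---------------------------------------------------------------------------


def stage_glm(out: str | Path) -> None:
    """Fit per-run GLMs, write contrast maps and per-block beta maps."""
    out = Path(out)
    config = _load_config(out)
    preset = config.preset
    brain, _, affine = _load_masks(out)
    motion_rows = []
    for s in range(config.n_subjects):
        for r in range(config.n_runs):
            tag = f"{_sub(s)}_run-{r + 1}"
            func = out / _sub(s) / "func"
            vol, _ = _load_img(func / f"{tag}_bold.nii.gz")
            events = pd.read_csv(func / f"{tag}_events.tsv", sep="\t")
            motion = synth.MotionTrace(np.loadtxt(func / f"{tag}_motion.txt"))
            design = _design_from_events(events, config.tr, vol.shape[-1])

            fd = glm_mod.compute_fd(motion, preset.fd_radius_mm)
            scrub = glm_mod.scrub_indices(fd, config.fd_threshold_mm)
            motion_rows.append(
                {
                    "subject": _sub(s),
                    "run": r + 1,
                    "mean_fd_mm": float(fd.mean()),
                    "scrubbed_fraction": scrub.fraction,
                }
            )
            X = glm_mod.build_design_matrix(
                design,
                preset.hrf,
                motion,
                scrub.indices,
                config.hpf_cutoff_s,
                conditions=synth.CONDITIONS,
            )
            fit = glm_mod.fit_glm(vol, X, brain, affine, run=r + 1)
            con_dir = out / "derivatives" / "glm" / _sub(s)
            contrasts = RUN1_CONTRASTS if r == 0 else RUN2_CONTRASTS
            for label, weights in contrasts.items():
                cmap = glm_mod.contrast_map(fit, weights, label=label)
                nib.save(
                    nib.Nifti1Image(cmap.data.astype(np.float32), affine),
                    str(_ensure(con_dir / f"run-{r + 1}_con-{label}.nii.gz")),
                )
            blocks = glm_mod.fit_single_block_glms(
                vol,
                design,
                preset.hrf,
                brain,
                motion,
                scrub.indices,
                config.hpf_cutoff_s,
                affine,
                run=r + 1,
            )
            blk_dir = out / "derivatives" / "blocks" / _sub(s)
            for b in blocks:
                name = f"run-{r + 1}_block-{b.extra['block_index']:02d}_{b.extra['condition']}.nii.gz"
                nib.save(
                    nib.Nifti1Image(b.data.astype(np.float32), affine),
                    str(_ensure(blk_dir / name)),
                )
    pd.DataFrame(motion_rows).to_csv(
        _ensure(out / "derivatives" / "group" / "motion_summary.tsv"), sep="\t", index=False
    )


def _ensure(path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def _load_contrast(out: Path, s: int, run: int, label: str) -> glm_mod.BetaMap:
    data, affine = _load_img(
        out / "derivatives" / "glm" / _sub(s) / f"run-{run}_con-{label}.nii.gz"
    )
    return glm_mod.BetaMap(data, affine, label, run)


# ---------------------------------------------------------------------------
# Stage 3: fROI analyses
# ---------------------------------------------------------------------------


def stage_froi(out: str | Path) -> dict:
    """Split-half fROI definition, group ANOVAs, sweep and resampling."""
    out = Path(out)
    config = _load_config(out)
    preset = config.preset
    brain, regions, affine = _load_masks(out)
    n = config.n_subjects

    # anatomical atlas for search spaces: whole "gyri" (ring + core), the
    # visual slab and the similarity patch
    atlas: dict[str, np.ndarray] = {}
    for name, mask in regions.items():
        if name.endswith("_core"):
            continue
        if name.endswith("_gyrus"):
            atlas[name] = mask | regions[name.replace("_gyrus", "_core")]
        else:
            atlas[name] = mask

    localizers = [_load_contrast(out, s, 1, "all_gt_baseline") for s in range(n)]
    loc_result, spaces = froi_mod.localize_visual_responsive(
        localizers,
        atlas=atlas,
        cdt_p=preset.cdt_p,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=derive_seed(config.seed, "localizer"),
        mask=brain,
        affine=affine,
    )
    gdir = _ensure(out / "derivatives" / "group" / "x").parent
    loc_result.table().to_csv(gdir / "localizer_clusters.tsv", sep="\t", index=False)

    cons = "dog" if config.species == "dog" else "human"
    het = "human" if cons == "dog" else "dog"
    oneway_rows, planned_rows, twoway_rows, recovery_rows = [], [], [], []
    summary: dict = {
        "search_spaces": sorted(s.name for s in spaces),
        "n_localizer_clusters": len(loc_result.significant_clusters),
    }
    body_table_main: pd.DataFrame | None = None
    sweep_frames: list[pd.DataFrame] = []

    for space in spaces:
        for roi_type, (pref_label, targ_label) in ROI_TYPES.items():
            per_subject: list[dict] = []
            dice_vals = []
            failed = False
            for s in range(n):
                pref = _load_contrast(out, s, 1, pref_label)
                targ = _load_contrast(out, s, 1, targ_label)
                try:
                    froi = froi_mod.define_froi(
                        pref, targ, space, top_pct=config.top_pct, name=f"{space.name}_{roi_type}"
                    )
                except ValueError:
                    failed = True
                    break
                test_maps = {
                    lab: _load_contrast(out, s, 2, lab) for lab in RUN2_CONTRASTS
                }
                per_subject.append(froi_mod.extract_froi_means(test_maps, froi))
                truth_region = regions.get(f"{roi_type}_core")
                if truth_region is not None:
                    fm = froi.mask()
                    dice_vals.append(
                        2.0 * (fm & truth_region).sum() / (fm.sum() + truth_region.sum())
                    )
                if s == 0:
                    froi_mod.write_froi(
                        froi, _ensure(out / "derivatives" / "froi" / f"{_sub(s)}_{space.name}_{roi_type}.nii.gz")
                    )
                if space.name == f"{roi_type}_gyrus":
                    sweep_frames.append(
                        froi_mod.froi_threshold_sweep(pref, targ, test_maps, space).assign(
                            subject=_sub(s), roi_type=roi_type
                        )
                    )
            if failed or not per_subject:
                continue
            tab = pd.DataFrame(per_subject)
            oneway = froi_mod.rm_anova_oneway(
                tab[["faces_gt_scrambled", "bodies_gt_scrambled", "objects_gt_scrambled"]]
            )
            oneway_rows.append(
                {
                    "space": space.name,
                    "roi_type": roi_type,
                    "F": oneway["F"],
                    "df1": oneway["df1"],
                    "df2": oneway["df2"],
                    "p": oneway["p"],
                    "eta_p2": oneway["eta_p2"],
                }
            )
            pref_cond = "bodies" if roi_type == "body" else "faces"
            for _, row in oneway["pairwise"].iterrows():
                comp = f"{row['a']}_vs_{row['b']}"
                if f"{pref_cond}_gt_scrambled" in (row["a"], row["b"]):
                    planned_rows.append(
                        {
                            "family": f"{roi_type}_froi_category_preference",
                            "space": space.name,
                            "roi_type": roi_type,
                            "comparison": comp,
                            "t": row["t"],
                            "df": row["df"],
                            "p": row["p"],
                        }
                    )
            cells = pd.DataFrame(
                {
                    "conspecific_face": tab[f"{cons}_face_gt_scrambled"],
                    "conspecific_body": tab[f"{cons}_body_gt_scrambled"],
                    "heterospecific_face": tab[f"{het}_face_gt_scrambled"],
                    "heterospecific_body": tab[f"{het}_body_gt_scrambled"],
                }
            )
            two = froi_mod.rm_anova_2x2(cells)
            for _, row in two["effects"].iterrows():
                twoway_rows.append(
                    {"space": space.name, "roi_type": roi_type, "effect": row["effect"],
                     "F": row["F"], "df1": row["df1"], "df2": row["df2"], "p": row["p"]}
                )
            if dice_vals:
                recovery_rows.append(
                    {"space": space.name, "roi_type": roi_type,
                     "mean_dice": float(np.mean(dice_vals)), "n_subjects": len(dice_vals)}
                )
            if space.name == "body_gyrus" and roi_type == "body":
                body_table_main = tab

    planned = pd.DataFrame(planned_rows)
    if len(planned):
        # FDR per question family across all fROIs asking it
        planned["q"] = np.nan
        for fam, idx in planned.groupby("family").groups.items():
            planned.loc[idx, "q"] = froi_mod.fdr_bh(planned.loc[idx, "p"].to_numpy())
    pd.DataFrame(oneway_rows).to_csv(gdir / "froi_oneway_anova.tsv", sep="\t", index=False)
    planned.to_csv(gdir / "froi_planned_comparisons.tsv", sep="\t", index=False)
    pd.DataFrame(twoway_rows).to_csv(gdir / "froi_2x2_anova.tsv", sep="\t", index=False)
    pd.DataFrame(recovery_rows).to_csv(gdir / "froi_recovery.tsv", sep="\t", index=False)
    if sweep_frames:
        sweep = pd.concat(sweep_frames, ignore_index=True)
        (
            sweep.groupby(["roi_type", "top_pct", "condition"], as_index=False)["value"].mean()
        ).to_csv(gdir / "froi_sweep.tsv", sep="\t", index=False)

    if body_table_main is not None:
        n_sub = min(config.resample_n_sub, n)
        resamp = froi_mod.resample_subsamples(
            body_table_main[["faces_gt_scrambled", "bodies_gt_scrambled", "objects_gt_scrambled"]],
            n_sub=n_sub,
            n_iter=config.resample_n_iter,
            seed=derive_seed(config.seed, "resample"),
            alpha=config.alpha,
        )
        resamp.to_csv(gdir / "froi_resampling.tsv", sep="\t", index=False)
        summary["resampling_significant_fraction"] = float(resamp["significant"].mean())
        summary["body_froi_table"] = body_table_main.round(6).to_dict("list")
    summary["recovery"] = recovery_rows
    summary["planned"] = planned.round(8).to_dict("records") if len(planned) else []
    return summary


# ---------------------------------------------------------------------------
# Stage 4: searchlight RSA
# ---------------------------------------------------------------------------


def stage_rsa(out: str | Path) -> None:
    """Per-participant similarity maps for every RSA trial set."""
    out = Path(out)
    config = _load_config(out)
    preset = config.preset
    brain, _, affine = _load_masks(out)
    for s in range(config.n_subjects):
        maps: list[glm_mod.BetaMap] = []
        blk_dir = out / "derivatives" / "blocks" / _sub(s)
        for p in sorted(blk_dir.glob("run-*_block-*.nii.gz")):
            run = int(p.name.split("_")[0].split("-")[1])
            block_index = int(p.name.split("block-")[1][:2])
            condition = p.name.split("_", 2)[2][: -len(".nii.gz")]
            data, _ = _load_img(p)
            maps.append(
                glm_mod.BetaMap(
                    data, affine, p.stem, run,
                    extra={"condition": condition, "block_index": block_index},
                )
            )
        stack = rsa_mod.TrialPatternStack.from_beta_maps(maps, brain)
        smaps = rsa_mod.searchlight_set_similarities(
            stack, preset.searchlight, RSA_SETS, config.within_species_pairs_only
        )
        for name, smap in smaps.items():
            smap.participant = _sub(s)
            rsa_mod.write_similarity_map(
                smap,
                _ensure(out / "derivatives" / "rsa" / f"{_sub(s)}_set-{name}.nii.gz"),
                preset.searchlight,
            )


# ---------------------------------------------------------------------------
# Stage 5: group inference on similarity maps
# ---------------------------------------------------------------------------


def stage_infer(out: str | Path) -> dict:
    """Permutation paired t-tests for the six similarity comparisons."""
    out = Path(out)
    config = _load_config(out)
    preset = config.preset
    _, regions, affine = _load_masks(out)
    gdir = _ensure(out / "derivatives" / "group" / "x").parent
    summary: dict = {}
    for comp, (set_a, set_b) in RSA_COMPARISONS.items():
        A = np.stack(
            [
                _load_img(out / "derivatives" / "rsa" / f"{_sub(s)}_set-{set_a}.nii.gz")[0]
                for s in range(config.n_subjects)
            ]
        )
        B = np.stack(
            [
                _load_img(out / "derivatives" / "rsa" / f"{_sub(s)}_set-{set_b}.nii.gz")[0]
                for s in range(config.n_subjects)
            ]
        )
        res = permutation_paired_test(
            A,
            B,
            n_perm=config.n_perm,
            cdt_p=preset.cdt_p,
            alpha=config.alpha,
            seed=derive_seed(config.seed, "infer", comp),
            affine=affine,
        )
        res.table().to_csv(gdir / f"rsa_clusters_{comp}.tsv", sep="\t", index=False)
        entry = {
            "n_significant_clusters": len(res.significant_clusters),
            "t_threshold": res.t_threshold,
        }
        if res.significant_clusters:
            top = res.significant_clusters[0]
            entry["largest_extent"] = top.extent
            entry["peak_ijk"] = list(top.peak_ijk)
            patch = regions.get("animacy_patch")
            if patch is not None:
                entry["peak_in_animacy_patch"] = bool(patch[top.peak_ijk])
        summary[comp] = entry
    return summary


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------


def _tree_hashes(out: Path) -> dict[str, str]:
    hashes = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in ("manifest.json", "report.md"):
            hashes[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return hashes


def run_study(config: StudyConfig, out: str | Path) -> dict:
    """Run every stage end to end and write manifest + report."""
    out = Path(out)
    seed = config.seed
    _timed("simulate", seed, stage_simulate, config, out)
    _timed("stimprops", seed, stage_stimprops, config, out)
    _timed("glm", seed, stage_glm, out)
    froi_summary = _timed("froi", seed, stage_froi, out)
    _timed("rsa", seed, stage_rsa, out)
    infer_summary = _timed("infer", seed, stage_infer, out)

    manifest = {
        "config": config.to_dict(),
        "froi": froi_summary,
        "rsa_inference": infer_summary,
        "files": _tree_hashes(out),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    (out / "report.md").write_text(_render_report(config, froi_summary, infer_summary))
    return manifest


def _render_report(config: StudyConfig, froi_summary: dict, infer_summary: dict) -> str:
    lines = [
        "# Synthetic study report",
        "",
        f"Species preset: **{config.species}**, {config.n_subjects} subjects, "
        f"grid {config.grid}, seed {config.seed}.",
        "",
        "## Functional ROIs",
        f"- search spaces localized: {', '.join(froi_summary.get('search_spaces', [])) or 'none'}"
        f" (file: derivatives/group/localizer_clusters.tsv)",
    ]
    for rec in froi_summary.get("recovery", []):
        lines.append(
            f"- {rec['roi_type']} fROI in {rec['space']}: mean Dice vs planted region "
            f"= {rec['mean_dice']:.3f} (derivatives/group/froi_recovery.tsv)"
        )
    for row in froi_summary.get("planned", []):
        lines.append(
            f"- {row['space']} ({row['roi_type']}): {row['comparison']} "
            f"t({row['df']}) = {row['t']:.2f}, q = {row['q']:.4g} "
            f"(derivatives/group/froi_planned_comparisons.tsv)"
        )
    if "resampling_significant_fraction" in froi_summary:
        lines.append(
            f"- resampling: fraction of subsamples with significant one-way ANOVA "
            f"= {froi_summary['resampling_significant_fraction']:.3f} "
            f"(derivatives/group/froi_resampling.tsv)"
        )
    lines += ["", "## Searchlight RSA group comparisons"]
    for comp, entry in infer_summary.items():
        desc = f"- ({comp}): {entry['n_significant_clusters']} significant cluster(s)"
        if "largest_extent" in entry:
            desc += f", largest extent {entry['largest_extent']}"
        if entry.get("peak_in_animacy_patch") is not None:
            desc += f", peak inside planted patch: {entry.get('peak_in_animacy_patch')}"
        desc += f" (derivatives/group/rsa_clusters_{comp}.tsv)"
        lines.append(desc)
    lines.append("")
    return "\n".join(lines)
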