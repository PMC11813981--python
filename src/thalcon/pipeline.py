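"""End-to-end orchestration.

Stages (each also exposed as a CLI subcommand) communicate through files in
the run directory, so every number in the final report is traceable to a
stage output:

* ``stage_clean``      -> clean/<id>_clean.nii, qc.tsv, clean_manifest.tsv
* ``stage_parcellate`` -> wta_<side>.nii, agreement_<side>.nii, wta_summary.tsv
* ``stage_connect``    -> connectivity.tsv
* ``stage_infer``      -> contrasts.tsv, clusters.tsv, behavior.tsv,
                          sensory.tsv, demographics.tsv, summary.json
* ``run``              -> all of the above in order.

The summary JSON is timestamp-free and fully determined by the config and
seed; the log file carries timestamps and the design-decision settings in
effect (stage order, tie rule, control duplication, permutation seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import group_inference as gi
from . import hemisphere_align as ha
from . import signal_clean as sc
from . import wta_parcellation as wta
from .core_io import (
    ROI_NAMES,
    LabelVolume,
    RoiGrouping,
    Volume4D,
    load_label_volume,
    load_volume4d,
    read_manifest,
    records_to_frame,
    resolve_rois,
    save_label_volume,
    save_volume4d,
    write_manifest,
)

log = logging.getLogger("thalcon")


@dataclasses.dataclass
class RunConfig:
    """Single-file YAML configuration for the whole pipeline."""

    manifest: str
    atlas: str
    grouping: str
    out_dir: str
    tr: float | None = None
    band_low: float = 0.01
    band_high: float = 0.08
    n_discard: int = 5
    motion_threshold_mm: float = 3.0
    group_rule: str = "average"  # winner-take-all group map rule
    cluster_forming_p: float = 0.001
    n_perm: int = 500
    seed: int = 0
    cluster_connectivity: int = 26
    control_flip_augment: bool = True
    seed_analysis: bool = True
    roi_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.cluster_forming_p < 1:
            raise ValueError("cluster_forming_p must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if self.group_rule not in ("average", "vote"):
            raise ValueError(f"unknown group_rule '{self.group_rule}'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def validate_paths(self) -> None:
        for name in ("manifest", "atlas", "grouping"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def _resolve(base: Path, p) -> Path:
    """Resolve a manifest-relative path against the manifest directory."""
    p = Path(p)
    return p if p.is_absolute() else base / p


def _out(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _setup_log(cfg: RunConfig) -> None:
    out = _out(cfg)
    if not log.handlers:
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.addHandler(logging.StreamHandler())
    log.setLevel(logging.INFO)


# ---------------------------------------------------------------------------
# Stage: clean
# ---------------------------------------------------------------------------

def stage_clean(cfg: RunConfig) -> pd.DataFrame:
    """QC and denoise every subject; write cleaned volumes and manifests."""
    _setup_log(cfg)
    cfg.validate_paths()
    out = _out(cfg)
    clean_dir = out / "clean"
    clean_dir.mkdir(exist_ok=True)
    records = read_manifest(cfg.manifest)
    log.info("clean: %d subjects; order discard(%d)->detrend->bandpass(%g-%g Hz)"
             "->regress; motion threshold %g mm (translations only)",
             len(records), cfg.n_discard, cfg.band_low, cfg.band_high,
             cfg.motion_threshold_mm)
    qc_rows = []
    kept = []
    base = Path(cfg.manifest).parent
    for rec in records:
        try:
            vol = load_volume4d(_resolve(base, rec.bold_path), tr=cfg.tr)
            motion = np.loadtxt(_resolve(base, rec.motion_path))
            confs = pd.read_csv(_resolve(base, rec.confounds_path), sep="\t")
            qc = sc.motion_qc(motion, cfg.motion_threshold_mm)
            qc_rows.append({"subject_id": rec.subject_id, "passed": qc.passed,
                            "max_translation_mm": qc.max_translation_mm,
                            "max_rotation": qc.max_rotation})
            if not qc.passed:
                log.warning("clean: excluding %s (max translation %.2f mm)",
                            rec.subject_id, qc.max_translation_mm)
                continue
            confounds = sc.ConfoundSet(motion, confs["wm"].to_numpy(),
                                       confs["csf"].to_numpy())
            cleaned = sc.clean_pipeline(vol, confounds, n_discard=cfg.n_discard,
                                        low=cfg.band_low, high=cfg.band_high)
            cleaned32 = Volume4D(cleaned.data.astype(np.float32),
                                 cleaned.affine, cleaned.tr)
            path = clean_dir / f"{rec.subject_id}_clean.nii"
            save_volume4d(cleaned32, path)
            rec.bold_path = str(path)
            kept.append(rec)
        except Exception as exc:  # noqa: BLE001 - abort with stage + subject
            raise RuntimeError(
                f"stage 'clean' failed for subject {rec.subject_id}: {exc}"
            ) from exc
    pd.DataFrame(qc_rows).to_csv(out / "qc.tsv", sep="\t", index=False)
    write_manifest(kept, out / "clean_manifest.tsv")
    return records_to_frame(kept)


# ---------------------------------------------------------------------------
# Aligned-entry loading shared by later stages
# ---------------------------------------------------------------------------

def _load_aligned(cfg: RunConfig) -> ha.AlignedCohort:
    out = _out(cfg)
    records = read_manifest(out / "clean_manifest.tsv")
    patients = []
    controls = []
    for rec in records:
        vol = load_volume4d(rec.bold_path)
        (patients if rec.is_patient else controls).append((rec, vol))
    return ha.harmonize(patients, controls,
                        flip_augment_controls=cfg.control_flip_augment)


def _load_rois(cfg: RunConfig):
    atlas = load_label_volume(cfg.atlas)
    grouping = RoiGrouping.from_file(cfg.grouping)
    return resolve_rois(atlas, grouping) + (atlas,)


# ---------------------------------------------------------------------------
# Stage: parcellate
# ---------------------------------------------------------------------------

def stage_parcellate(cfg: RunConfig) -> dict[str, wta.WtaMap]:
    """Pooled group winner-take-all parcellation of each thalamus."""
    _setup_log(cfg)
    out = _out(cfg)
    cortical, thalami, _ = _load_rois(cfg)
    cohort = _load_aligned(cfg)
    entries = cohort.all_entries()
    log.info("parcellate: pooling %d entries (%d patients + %d control entries); "
             "group rule '%s', ties -> lowest ROI index, max r<=0 -> unassigned",
             cohort.n_entries, len(cohort.patients), len(cohort.controls),
             cfg.group_rule)
    maps = {}
    summaries = []
    for side in ("left", "right"):
        cms = []
        for entry in entries:
            cortex_ts = wta.cortical_roi_timeseries(entry.volume, cortical)
            cms.append(wta.voxel_cortex_correlations(
                entry.volume, thalami[side], cortex_ts, side=side))
        gmap = wta.group_wta(cms, method=cfg.group_rule)
        maps[side] = gmap
        save_label_volume(gmap.to_label_volume(), out / f"wta_{side}.nii")
        nib.save(nib.Nifti1Image(gmap.agreement_volume(), gmap.affine),
                 str(out / f"agreement_{side}.nii"))
        summaries.append(wta.subregion_summary(gmap))
    pd.concat(summaries).to_csv(out / "wta_summary.tsv", sep="\t", index=False)
    return maps


# ---------------------------------------------------------------------------
# Stage: connect
# ---------------------------------------------------------------------------

def stage_connect(cfg: RunConfig) -> pd.DataFrame:
    """ROI-pair connectivity table for every harmonized entry and side."""
    _setup_log(cfg)
    out = _out(cfg)
    cortical, _, _ = _load_rois(cfg)
    cohort = _load_aligned(cfg)
    labels = {side: load_label_volume(out / f"wta_{side}.nii")
              for side in ("left", "right")}
    tables = []
    for entry in cohort.all_entries():
        tbl = conn.roi_pair_connectivity(
            entry.volume, cortical, labels, entry_id=entry.entry_id,
            group=entry.record.group)
        tbl["provenance"] = entry.provenance
        tbl["subject_id"] = entry.record.subject_id
        tables.append(tbl)
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "connectivity.tsv", sep="\t", index=False)
    log.info("connect: %d rows over %d entries", len(table), cohort.n_entries)
    return table


# ---------------------------------------------------------------------------
# Stage: infer
# ---------------------------------------------------------------------------

def stage_infer(cfg: RunConfig) -> dict:
    """Contrasts, seed-to-voxel cluster inference, behavior, demographics."""
    _setup_log(cfg)
    out = _out(cfg)
    table = pd.read_csv(out / "connectivity.tsv", sep="\t")
    contrasts = gi.roi_pair_contrast(table, alpha=cfg.roi_alpha)
    contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)
    summary: dict = {
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "control_flip_augment": cfg.control_flip_augment,
        "roi_contrasts": contrasts.to_dict(orient="records"),
    }

    significant = contrasts[contrasts["significant"]]
    log.info("infer: %d/%d ROI-pair contrasts significant at alpha=%g "
             "(uncorrected, mirroring the two-step design)",
             len(significant), len(contrasts), cfg.roi_alpha)

    cluster_frames = []
    if cfg.seed_analysis and len(significant):
        cluster_frames = _seed_analysis(cfg, significant, out, summary)
    if cluster_frames:
        pd.concat(cluster_frames, ignore_index=True).to_csv(
            out / "clusters.tsv", sep="\t", index=False)
    else:
        pd.DataFrame(columns=["seed_side", "seed_roi", "contrast",
                              "extent_voxels", "peak_x_mm", "peak_y_mm",
                              "peak_z_mm", "peak_t", "p_fwe"]).to_csv(
            out / "clusters.tsv", sep="\t", index=False)

    _behavior_and_subgroups(cfg, table, out, summary)

    manifest_df = records_to_frame(read_manifest(cfg.manifest))
    demo = gi.demographics_table(manifest_df)
    demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
    summary["demographics"] = demo.to_dict(orient="records")

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True,
                                                 default=float))
    return summary


def _seed_analysis(cfg: RunConfig, significant: pd.DataFrame, out: Path,
                   summary: dict) -> list[pd.DataFrame]:
    cortical, thalami, atlas = _load_rois(cfg)
    cohort = _load_aligned(cfg)
    brain = LabelVolume((atlas.data > 0).astype(np.int16), atlas.affine)
    labels = {side: load_label_volume(out / f"wta_{side}.nii")
              for side in ("left", "right")}
    seeds = [(row["side"], row["roi"]) for _, row in significant.iterrows()]
    seed_masks = {}
    for side, roi in seeds:
        idx = ROI_NAMES.index(roi) + 1
        mask = (labels[side].data == idx).astype(np.int16)
        if mask.sum() == 0:
            log.warning("infer: empty seed (%s, %s); skipped", side, roi)
            continue
        seed_masks[(side, roi)] = LabelVolume(mask, atlas.affine)
    z_maps: dict[tuple[str, str], dict[str, list[np.ndarray]]] = {
        key: {"patient": [], "control": []} for key in seed_masks}
    for entry in cohort.all_entries():
        for key, seed_mask in seed_masks.items():
            smap = conn.seed_to_voxel(entry.volume, seed_mask, brain)
            z_maps[key][entry.record.group].append(
                np.nan_to_num(smap.data, nan=0.0))
    frames = []
    summary["clusters"] = {}
    for (side, roi), groups in z_maps.items():
        if min(len(groups["patient"]), len(groups["control"])) < 5:
            log.warning("infer: seed (%s, %s) skipped: need >= 5 maps per "
                        "group for permutation inference", side, roi)
            continue
        res = gi.perm_cluster_fwe(
            np.stack(groups["patient"]), np.stack(groups["control"]),
            mask=brain.mask(), affine=atlas.affine,
            cluster_forming_p=cfg.cluster_forming_p, n_perm=cfg.n_perm,
            seed=cfg.seed, connectivity=cfg.cluster_connectivity,
            contrast_labels=("patient>control", "control>patient"))
        frame = res.to_frame()
        frame.insert(0, "seed_side", side)
        frame.insert(1, "seed_roi", roi)
        frames.append(frame)
        summary["clusters"][f"{side}:{roi}"] = {
            "n_perm": res.n_perm, "exact": res.exact,
            "t_threshold": res.t_threshold,
            "n_significant": len(res.significant()),
            "clusters": frame.to_dict(orient="records"),
        }
        log.info("infer: seed (%s, %s): %d cluster(s), %d significant",
                 side, roi, len(res.clusters), len(res.significant()))
    return frames


def _behavior_and_subgroups(cfg: RunConfig, table: pd.DataFrame, out: Path,
                            summary: dict) -> None:
    # Ipsilesional = right hemisphere after harmonization.
    pat = table[(table["group"] == "patient") & (table["side"] == "right")
                & (table["roi"] == "somatosensory")]
    manifest_df = records_to_frame(read_manifest(cfg.manifest))
    pat = pat.merge(manifest_df, on="subject_id", suffixes=("", "_m"))
    rows = []
    if len(pat) >= 3:
        z = pat["z"].to_numpy()
        for label, scores in (
            ("fma_ue_baseline", pat["fma_ue_t1"].to_numpy(dtype=float)),
            ("fma_ue_crmf", gi.cr_mf(pat["fma_ue_t2"].to_numpy(dtype=float),
                                     pat["fma_ue_t1"].to_numpy(dtype=float))),
            ("fma_le_baseline", pat["fma_le_t1"].to_numpy(dtype=float)),
            ("fma_le_crmf", gi.cr_mf(pat["fma_le_t2"].to_numpy(dtype=float),
                                     pat["fma_le_t1"].to_numpy(dtype=float))),
        ):
            try:
                res = gi.behavior_correlation(z, scores)
            except ValueError as exc:
                log.warning("infer: behavior correlation %s skipped: %s",
                            label, exc)
                continue
            rows.append({"pair": "right:somatosensory", "score": label,
                         "method": res.method, "r": res.r, "p": res.p,
                         "n": res.n})
        try:
            sub = gi.sensory_subgroup_compare(
                z, pat["fma_ue_t1"].to_numpy(dtype=float)
                + pat["fma_le_t1"].to_numpy(dtype=float),
                pat["nihss_sensory_t1"].to_numpy(dtype=float))
            sens = pd.DataFrame([
                {"measure": k, "t": v.t, "p": v.p, "df": v.df,
                 "n_impaired": v.n_a, "n_nonimpaired": v.n_b,
                 "mean_impaired": v.mean_a, "mean_nonimpaired": v.mean_b}
                for k, v in sub.items()])
            sens.to_csv(out / "sensory.tsv", sep="\t", index=False)
            summary["sensory_subgroup"] = sens.to_dict(orient="records")
        except ValueError as exc:
            log.warning("infer: sensory subgroup comparison skipped: %s", exc)
    behavior = pd.DataFrame(rows)
    behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    summary["behavior"] = behavior.to_dict(orient="records")


def run(cfg: RunConfig) -> Path:
    """Execute clean -> parcellate -> connect -> infer; return the run dir."""
    _setup_log(cfg)
    stage_clean(cfg)
    stage_parcellate(cfg)
    stage_connect(cfg)
    stage_infer(cfg)
    return _out(cfg)


def report(cfg: RunConfig) -> str:
    """Human-readable digest of an existing run (no recomputation)."""
    out = _out(cfg)
    summary = json.loads((out / "summary.json").read_text())
    lines = ["thalamocortical connectivity run report", "=" * 40,
             f"seed: {summary['seed']}  n_perm: {summary['n_perm']}",
             f"control flip augmentation: {summary['control_flip_augment']}", ""]
    lines.append("ROI-pair contrasts (patient vs control, Fisher z):")
    for row in summary["roi_contrasts"]:
        star = " *" if row["significant"] else ""
        lines.append(f"  {row['side']:>5} {row['roi']:<18} t={row['t']:+.3f} "
                     f"p={row['p']:.4f} dz={row['delta_z']:+.3f}{star}")
    for key, info in (summary.get("clusters") or {}).items():
        lines.append(f"seed {key}: {info['n_significant']} significant cluster(s) "
                     f"of {len(info['clusters'])}")
    for row in summary.get("behavior", []):
        lines.append(f"behavior {row['score']}: {row['method']} r={row['r']:+.3f} "
                     f"p={row['p']:.4f} (n={row['n']})")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
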