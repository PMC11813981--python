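"""Synthetic two-group BOLD cohort with planted ground truth.

The phantom hosts six bilateral cortical blocks and two thalamus blocks on a
left/right symmetric grid (so mid-sagittal flipping is exact). Each thalamus
is split into six contiguous sectors, one per cortical ROI — the planted
voxel-to-cortex assignment that winner-take-all parcellation must recover.

Signal model
------------
Each cortical ROI r owns a latent band-limited (0.01-0.08 Hz) unit-variance
source s_r(t). Cortical voxels of ROI r carry s_r + noise; a thalamic voxel
assigned to r carries w * s_r + noise; everything else is pure noise (plus a
small shared WM/CSF component inside the head, removed by nuisance
regression). The mixing weight w is solved per subject, side, and ROI so
that the expected post-cleaning Pearson correlation between the cortical
ROI mean and the thalamic sector mean equals a planted target:

    r* = w / sqrt((1 + s2/Vc) * (w^2 + s2/Vt))
    =>  w = r* sqrt(a b / (1 - r*^2 a)),  a = 1 + s2/Vc,  b = s2/Vt

where s2 is the voxel noise variance surviving the cleaning band-pass,
expressed relative to the surviving source variance (white noise keeps the
filter's |H|^4 spectral moment; the already-band-limited sources keep the
|H|^8 / |H|^4 ratio), and Vc/Vt are the mask sizes whose means average the
noise down. Group effects, a per-subject random effect, and the
sensory-impairment gap are all planted additively on the Fisher-z scale,
where downstream inference operates.

Clinical scores follow planted linear models on the subject's ipsilesional
somatosensory z: the baseline upper-extremity motor score increases with z
(positive slope) and the 1-year change rate decreases with z, so the
behavioral correlations have a known direction and approximate magnitude.
"""

from __future__ import annotations

import dataclasses
import functools
import json
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .core_io import (
    ROI_NAMES,
    LabelVolume,
    RoiGrouping,
    SubjectRecord,
    Volume4D,
    save_label_volume,
    save_volume4d,
    write_manifest,
)
from .signal_clean import bandpass, detrend_linear

# Atlas labels used by the phantom: cortical ROI i (0-based) has labels
# 2i+1 (left) and 2i+2 (right); thalami are 13 (left) and 14 (right).
THAL_LEFT, THAL_RIGHT = 13, 14

DEFAULT_BASELINE_Z = {name: 0.9 for name in ROI_NAMES}

#: Planted patient-minus-control connectivity deltas on the z scale, keyed
#: by (relative side, roi). Somatosensory pairs decrease bilaterally;
#: occipital pairs increase bilaterally; the temporal pair increases only
#: ipsilesionally. Unlisted pairs carry no effect.
DEFAULT_GROUP_EFFECT = {
    ("ipsi", "somatosensory"): -0.3,
    ("contra", "somatosensory"): -0.3,
    ("ipsi", "occipital"): +0.2,
    ("contra", "occipital"): +0.2,
    ("ipsi", "temporal"): +0.2,
}


@dataclasses.dataclass
class BehaviorModel:
    """Planted linear clinical-score models (see module docstring)."""

    fma_alpha: float = 23.0  # baseline UE score at the reference z
    fma_beta: float = 35.0  # UE points per unit ipsilesional somatosensory z
    fma_ref_z: float = 0.5
    fma_noise_sd: float = 8.0
    cr_intercept: float = 0.40
    cr_slope: float = -0.9  # change rate per unit z (negative: high z -> low CR)
    cr_noise_sd: float = 0.08
    integer_scores: bool = True


@dataclasses.dataclass
class PhantomTruth:
    """Everything needed to score the pipeline against the generator."""

    atlas: LabelVolume
    grouping: RoiGrouping
    cortical_masks: dict[str, LabelVolume]
    thalamus_masks: dict[str, LabelVolume]
    assignment: LabelVolume  # sector labels 1..6 over both thalami
    baseline_z: dict[str, float]
    group_effect: dict[tuple[str, str], float]
    behavior: BehaviorModel
    sensory_gap_z: float
    subject_z_sd: float
    noise_sd: float
    seed: int
    #: Noise level assumed when solving mixing weights. Defaults to
    #: ``noise_sd`` (exact pair-level planting); fixing it while varying
    #: ``noise_sd`` keeps the signal amplitude constant so that extra noise
    #: genuinely degrades recovery.
    weight_noise_sd: float | None = None

    @property
    def planting_noise_sd(self) -> float:
        return self.noise_sd if self.weight_noise_sd is None else self.weight_noise_sd

    @property
    def affine(self) -> np.ndarray:
        return self.atlas.affine

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.atlas.shape3

    def sector_mask(self, side: str, roi_index: int) -> np.ndarray:
        """Boolean mask of the thalamic sector for ROI ``roi_index`` (1..6)."""
        return (self.assignment.data == roi_index) & self.thalamus_masks[
            side
        ].mask()

    def assignment_vector(self, side: str) -> np.ndarray:
        """Sector labels in thalamus-mask voxel order (C order), 1..6."""
        mask = self.thalamus_masks[side].mask()
        return self.assignment.data[mask]


def _mirror_index(i: np.ndarray, n: int) -> np.ndarray:
    return n - 1 - i


def make_phantom(
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    seed: int = 0,
    noise_sd: float = 1.0,
    baseline_z: dict[str, float] | None = None,
    group_effect: dict[tuple[str, str], float] | None = None,
    behavior: BehaviorModel | None = None,
    sensory_gap_z: float = 0.25,
    subject_z_sd: float = 0.15,
    voxel_size_mm: float = 2.0,
    weight_noise_sd: float | None = None,
) -> PhantomTruth:
    """Build the symmetric phantom anatomy and its planted parameters.

    The grid must be at least 16 voxels along each axis (smaller grids
    cannot host the eight disjoint regions). All geometry is mirror-exact
    about the mid-sagittal plane: right-hemisphere structures are the voxel
    mirror of left-hemisphere ones, and thalamic sector labels on the right
    are copied through the mirror so flipping maps assignments exactly.
    """
    nx, ny, nz = grid_shape
    if min(grid_shape) < 16:
        raise ValueError(
            f"grid {grid_shape} too small: need >= 16 voxels per axis to host "
            "6 cortical blocks and 2 thalami disjointly"
        )
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = [-(n - 1) * voxel_size_mm / 2.0 for n in grid_shape]
    atlas = np.zeros(grid_shape, dtype=np.int16)

    # Cortical blocks: 6 ROIs at distinct (y, z) cells, mirrored in x.
    bx = max(2, nx // 6)
    by = max(2, ny // 6)
    bz = max(2, nz // 6)
    x0 = max(1, nx // 12)
    xs_left = np.arange(x0, min(x0 + bx, nx // 2 - 1))
    y_slots = [max(0, round(0.08 * (ny - by))), min(ny - by, round(0.72 * (ny - by)))]
    z_slots = [max(0, round(0.04 * (nz - bz))), round(0.48 * (nz - bz)),
               min(nz - bz, round(0.92 * (nz - bz)))]
    positions = [(yy, zz) for yy in y_slots for zz in z_slots]
    for i, (yy, zz) in enumerate(positions):
        block = np.ix_(xs_left, np.arange(yy, yy + by), np.arange(zz, zz + bz))
        atlas[block] = 2 * i + 1
        block_r = np.ix_(_mirror_index(xs_left, nx), np.arange(yy, yy + by),
                         np.arange(zz, zz + bz))
        atlas[block_r] = 2 * i + 2

    # Thalami: central boxes abutting the midline, mirrored in x.
    tx = np.arange(nx // 3, nx // 2)
    ty = np.arange(ny // 3, ny // 3 + max(3, ny // 4))
    tz = np.arange(nz // 3, nz // 3 + max(6, nz // 3))
    ty = ty[ty < ny]
    tz = tz[tz < nz]
    left_box = np.ix_(tx, ty, tz)
    if np.any(atlas[left_box] != 0):
        raise ValueError("phantom geometry overlap; grid too small")
    atlas[left_box] = THAL_LEFT
    atlas[np.ix_(_mirror_index(tx, nx), ty, tz)] = THAL_RIGHT

    # Sector assignment: sort left-thalamus voxels by (z, y, x) and split
    # into six contiguous, equal-count slabs; mirror onto the right.
    assignment = np.zeros(grid_shape, dtype=np.int16)
    left_vox = np.argwhere(atlas == THAL_LEFT)
    order = np.lexsort((left_vox[:, 0], left_vox[:, 1], left_vox[:, 2]))
    left_sorted = left_vox[order]
    if len(left_sorted) < 6:
        raise ValueError("thalamus too small for six sectors")
    for k, chunk in enumerate(np.array_split(left_sorted, 6), start=1):
        assignment[tuple(chunk.T)] = k
        mirrored = chunk.copy()
        mirrored[:, 0] = _mirror_index(mirrored[:, 0], nx)
        assignment[tuple(mirrored.T)] = k

    grouping = RoiGrouping(
        rois={name: (2 * i + 1, 2 * i + 2) for i, name in enumerate(ROI_NAMES)},
        thalamus={"left": THAL_LEFT, "right": THAL_RIGHT},
    )
    atlas_lv = LabelVolume(atlas, affine)
    cortical = {
        name: LabelVolume(np.isin(atlas, grouping.rois[name]).astype(np.int16),
                          affine)
        for name in ROI_NAMES
    }
    thalamus = {
        "left": LabelVolume((atlas == THAL_LEFT).astype(np.int16), affine),
        "right": LabelVolume((atlas == THAL_RIGHT).astype(np.int16), affine),
    }
    return PhantomTruth(
        atlas=atlas_lv,
        grouping=grouping,
        cortical_masks=cortical,
        thalamus_masks=thalamus,
        assignment=LabelVolume(assignment, affine),
        baseline_z=dict(baseline_z or DEFAULT_BASELINE_Z),
        group_effect=dict(group_effect if group_effect is not None
                          else DEFAULT_GROUP_EFFECT),
        behavior=behavior or BehaviorModel(),
        sensory_gap_z=sensory_gap_z,
        subject_z_sd=subject_z_sd,
        noise_sd=noise_sd,
        seed=seed,
        weight_noise_sd=weight_noise_sd,
    )


# ---------------------------------------------------------------------------
# Per-subject simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SubjectData:
    """Simulated per-subject artifacts (plus the latent sources for oracles)."""

    volume: Volume4D
    motion: np.ndarray  # (T, 6)
    wm: np.ndarray  # (T,)
    csf: np.ndarray  # (T,)
    sources: np.ndarray  # (T, 6), latent cortical sources
    targets: dict[tuple[str, str], float]  # (side, roi) -> planted z


def draw_subject_targets(
    truth: PhantomTruth,
    record: SubjectRecord,
    rng: np.random.Generator,
    sensory_impaired: bool | None = None,
) -> dict[tuple[str, str], float]:
    """Planted per-(anatomical side, roi) z targets for one subject.

    Patients get the group effect on the side relative to their lesion
    (ipsi = lesion side) and, when sensory-impaired, an extra negative gap
    on the ipsilesional somatosensory pair. Every target carries an
    independent N(0, subject_z_sd) random effect.
    """
    if sensory_impaired is None:
        sensory_impaired = bool(record.nihss_sensory_t1 and record.nihss_sensory_t1 > 0)
    targets = {}
    for side in ("left", "right"):
        for name in ROI_NAMES:
            z = truth.baseline_z[name]
            if record.is_patient:
                rel = "ipsi" if side == record.lesion_side else "contra"
                z += truth.group_effect.get((rel, name), 0.0)
                if sensory_impaired and name == "somatosensory" and rel == "ipsi":
                    z -= truth.sensory_gap_z
            z += rng.normal(0.0, truth.subject_z_sd)
            targets[(side, name)] = float(z)
    return targets


@functools.lru_cache(maxsize=8)
def _effective_noise_ratio(t_full: int, tr: float, n_discard: int = 5,
                           n_mc: int = 4000) -> float:
    """Post-cleaning noise-to-source variance ratio for unit white noise.

    Measured empirically (fixed internal seed, cached) through the
    detrend + zero-phase band-pass stages at the actual series length,
    because finite-length forward-backward filtering retains noticeably
    more broadband variance than the asymptotic spectral moments suggest.
    Nuisance regression is omitted: it projects source and noise through
    the same operator, which cancels in the ratio to first order.
    """
    rng = np.random.default_rng(987654321)
    t_post = t_full - n_discard
    white = rng.standard_normal((t_post, n_mc))
    kappa = float(bandpass(detrend_linear(white), tr).var())
    src = bandpass(rng.standard_normal((t_full, n_mc)), tr)
    src = (src - src.mean(axis=0)) / src.std(axis=0)
    gain = float(bandpass(detrend_linear(src[n_discard:]), tr).var())
    return kappa / gain


def _band_limited(rng: np.random.Generator, t: int, n_series: int,
                  tr: float) -> np.ndarray:
    """(T, n) unit-variance series confined to the 0.01-0.08 Hz passband."""
    raw = rng.standard_normal((t, n_series))
    filt = bandpass(raw, tr)
    sd = filt.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (filt - filt.mean(axis=0)) / sd


def _mixing_weight(z_target: float, v_cortex: int, v_sector: int,
                   sigma2_eff: float) -> float:
    r = float(np.tanh(z_target))
    if sigma2_eff <= 0:
        return 1.0 if r >= 0 else -1.0
    a = 1.0 + sigma2_eff / v_cortex
    # attainable correlations are bounded by 1/sqrt(a); stay clear of the
    # singularity so weights remain finite at any noise level
    r_lim = min(0.95, 0.95 / np.sqrt(a))
    r = float(np.clip(r, -r_lim, r_lim))
    b = sigma2_eff / v_sector
    return r * np.sqrt(a * b / (1.0 - r * r * a))


def simulate_subject(
    truth: PhantomTruth,
    record: SubjectRecord,
    n_timepoints: int = 150,
    tr: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    targets: dict[tuple[str, str], float] | None = None,
    motion_spike: bool = False,
) -> SubjectData:
    """Simulate one subject's 4D BOLD volume, motion file, and confounds.

    ``targets`` (planted z per side/ROI) is drawn from ``seed``/``rng`` when
    not supplied; the cohort planner passes precomputed targets so clinical
    scores and imaging share the same planted values. With ``motion_spike``
    a single >3 mm translation frame is injected for QC testing.
    """
    if n_timepoints < 60:
        raise ValueError(f"n_timepoints must be >= 60, got {n_timepoints}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if targets is None:
        targets = draw_subject_targets(truth, record, rng)
    t = n_timepoints
    sources = _band_limited(rng, t, len(ROI_NAMES), tr)
    wm, csf = _band_limited(rng, t, 2, tr).T
    # Effective post-cleaning noise-to-source variance ratio (white noise
    # and the band-limited sources survive the cleaning band-pass very
    # differently); calibrated empirically at this series length.
    sigma2_eff = _effective_noise_ratio(t, tr) * truth.planting_noise_sd**2

    data = rng.standard_normal((*truth.grid_shape, t)) * truth.noise_sd
    for i, name in enumerate(ROI_NAMES):
        data[truth.cortical_masks[name].mask()] += sources[:, i]
    for side in ("left", "right"):
        v_thal = truth.thalamus_masks[side].mask()
        for i, name in enumerate(ROI_NAMES, start=1):
            sector = (truth.assignment.data == i) & v_thal
            v_c = int(truth.cortical_masks[name].mask().sum())
            w = _mixing_weight(targets[(side, name)], v_c, int(sector.sum()),
                               sigma2_eff)
            data[sector] += w * sources[:, i - 1]
    head = truth.atlas.mask()
    data[head] += 0.1 * wm + 0.1 * csf

    motion = rng.normal(0.0, 0.05, size=(t, 6))
    if motion_spike:
        motion[t // 2, 0] = 3.5
    vol = Volume4D(data, truth.affine.copy(), tr)
    return SubjectData(volume=vol, motion=motion, wm=wm, csf=csf,
                       sources=sources, targets=dict(targets))


# ---------------------------------------------------------------------------
# Cohort planning (records + clinical scores, no volumes)
# ---------------------------------------------------------------------------

_DEMOGRAPHICS = {
    # mean/sd or probability per group, loosely matched to the cohort design
    "patient": {"age": (57.7, 9.0), "bmi": (26.1, 3.2), "mmse": (29.4, 1.1),
                "male": 0.744, "smoke": 0.436, "hypertension": 0.692,
                "diabetes": 0.333, "dyslipidemia": 0.564},
    "control": {"age": (52.5, 11.0), "bmi": (25.2, 3.5), "mmse": (29.6, 0.7),
                "male": 0.750, "smoke": 0.281, "hypertension": 0.594,
                "diabetes": 0.188, "dyslipidemia": 0.438},
}


@dataclasses.dataclass
class CohortPlan:
    """Planned cohort: validated records, planted z targets, child seeds."""

    records: list[SubjectRecord]
    targets: dict[str, dict[tuple[str, str], float]]
    impaired: dict[str, bool]
    subject_seeds: dict[str, int]
    seed: int

    @property
    def patients(self) -> list[SubjectRecord]:
        return [r for r in self.records if r.is_patient]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [r for r in self.records if not r.is_patient]


def _round_score(value: float, lo: int, hi: int, integer: bool) -> float:
    value = float(np.clip(value, lo, hi))
    return float(int(round(value))) if integer else value


def plan_cohort(
    truth: PhantomTruth,
    n_patients: int = 39,
    n_controls: int = 32,
    seed: int = 0,
    left_lesion_fraction: float = 17 / 39,
    impaired_fraction: float = 19 / 39,
) -> CohortPlan:
    """Draw records, planted targets, and clinical scores for a cohort.

    Lesion sides and sensory-impairment flags are assigned as fixed counts
    (rounded fractions of n_patients, default 17/39 left and 19/39
    impaired) and shuffled. The baseline upper-extremity motor score and
    the 1-year change rate both derive from the subject's planted
    ipsilesional somatosensory z through the truth's behavior model.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    beh = truth.behavior
    n_left = int(round(n_patients * left_lesion_fraction))
    n_impaired = int(round(n_patients * impaired_fraction))
    sides = np.array(["left"] * n_left + ["right"] * (n_patients - n_left))
    rng.shuffle(sides)
    impaired_flags = np.array([True] * n_impaired + [False] * (n_patients - n_impaired))
    rng.shuffle(impaired_flags)

    records: list[SubjectRecord] = []
    targets: dict[str, dict[tuple[str, str], float]] = {}
    impaired: dict[str, bool] = {}
    child_seeds = ss.spawn(n_patients + n_controls)

    for i in range(n_patients):
        sid = f"sub-p{i + 1:03d}"
        side = str(sides[i])
        imp = bool(impaired_flags[i])
        stub = SubjectRecord(subject_id=sid, group="patient", lesion_side=side)
        tg = draw_subject_targets(truth, stub, rng, sensory_impaired=imp)
        z_ss = tg[(side, "somatosensory")]

        fma_ue_t1 = _round_score(
            beh.fma_alpha + beh.fma_beta * (z_ss - beh.fma_ref_z)
            + rng.normal(0.0, beh.fma_noise_sd), 1, 66, beh.integer_scores)
        cr = float(np.clip(
            beh.cr_intercept + beh.cr_slope * (z_ss - beh.fma_ref_z)
            + rng.normal(0.0, beh.cr_noise_sd), -0.9, 0.9))
        fma_ue_t2 = _round_score(fma_ue_t1 * (1 + cr) / (1 - cr), 0, 66,
                                 beh.integer_scores)
        fma_le_t1 = _round_score(
            22.0 - (4.0 if imp else 0.0) + rng.normal(0.0, 6.0), 0, 34,
            beh.integer_scores)
        fma_le_t2 = _round_score(fma_le_t1 + 8.0 + rng.normal(0.0, 3.0), 0, 34,
                                 beh.integer_scores)
        sensory_item = int(rng.integers(1, 3)) if imp else 0
        nihss_t1 = _round_score(
            6.4 + (1.5 if imp else 0.0) + rng.normal(0.0, 2.5),
            max(1, sensory_item), 42, True)
        nihss_t2 = _round_score(0.25 * nihss_t1 + rng.normal(0.0, 1.0), 0, 42, True)

        demo = _DEMOGRAPHICS["patient"]
        extras = {
            "age": float(np.clip(round(rng.normal(*demo["age"])), 25, 80)),
            "bmi": round(float(rng.normal(*demo["bmi"])), 1),
            "mmse": float(np.clip(round(rng.normal(*demo["mmse"])), 20, 30)),
            **{k: int(rng.random() < demo[k]) for k in
               ("male", "smoke", "hypertension", "diabetes", "dyslipidemia")},
        }
        rec = SubjectRecord(
            subject_id=sid, group="patient", lesion_side=side,
            fma_ue_t1=fma_ue_t1, fma_ue_t2=fma_ue_t2,
            fma_le_t1=fma_le_t1, fma_le_t2=fma_le_t2,
            nihss_t1=nihss_t1, nihss_t2=nihss_t2,
            nihss_sensory_t1=sensory_item, extras=extras)
        records.append(rec)
        targets[sid] = tg
        impaired[sid] = imp

    for i in range(n_controls):
        sid = f"sub-c{i + 1:03d}"
        stub = SubjectRecord(subject_id=sid, group="control", lesion_side="none")
        tg = draw_subject_targets(truth, stub, rng, sensory_impaired=False)
        demo = _DEMOGRAPHICS["control"]
        extras = {
            "age": float(np.clip(round(rng.normal(*demo["age"])), 25, 80)),
            "bmi": round(float(rng.normal(*demo["bmi"])), 1),
            "mmse": float(np.clip(round(rng.normal(*demo["mmse"])), 20, 30)),
            **{k: int(rng.random() < demo[k]) for k in
               ("male", "smoke", "hypertension", "diabetes", "dyslipidemia")},
        }
        records.append(SubjectRecord(subject_id=sid, group="control",
                                     lesion_side="none", extras=extras))
        targets[sid] = tg
        impaired[sid] = False

    subject_seeds = {rec.subject_id: int(cs.generate_state(1)[0])
                     for rec, cs in zip(records, child_seeds)}
    return CohortPlan(records=records, targets=targets, impaired=impaired,
                      subject_seeds=subject_seeds, seed=seed)


def iter_subject_data(
    truth: PhantomTruth,
    plan: CohortPlan,
    n_timepoints: int = 150,
    tr: float = 2.0,
) -> Iterator[tuple[SubjectRecord, SubjectData]]:
    """Lazily simulate each planned subject (deterministic per plan seed)."""
    for record in plan.records:
        rng = np.random.default_rng(plan.subject_seeds[record.subject_id])
        yield record, simulate_subject(
            truth, record, n_timepoints=n_timepoints, tr=tr, rng=rng,
            targets=plan.targets[record.subject_id])


def simulate_cohort(
    out_dir,
    truth: PhantomTruth | None = None,
    n_patients: int = 39,
    n_controls: int = 32,
    seed: int = 0,
    n_timepoints: int = 150,
    tr: float = 2.0,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    write_volumes: bool = True,
) -> tuple[PhantomTruth, CohortPlan]:
    """Write a complete synthetic study to ``out_dir``.

    Produces per-subject BOLD NIfTI (float32), 6-column motion text files,
    WM/CSF confound files, the TSV manifest, the phantom atlas + grouping
    config + sector-assignment map, and a ground-truth JSON sufficient to
    score every downstream stage. Fully deterministic under ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if truth is None:
        truth = make_phantom(grid_shape=grid_shape, seed=seed)
    plan = plan_cohort(truth, n_patients=n_patients, n_controls=n_controls,
                       seed=seed)
    func_dir = out_dir / "func"
    func_dir.mkdir(exist_ok=True)
    for record in plan.records:
        rng = np.random.default_rng(plan.subject_seeds[record.subject_id])
        sub = simulate_subject(truth, record, n_timepoints=n_timepoints, tr=tr,
                               rng=rng, targets=plan.targets[record.subject_id])
        bold_path = func_dir / f"{record.subject_id}_bold.nii"
        motion_path = func_dir / f"{record.subject_id}_motion.txt"
        conf_path = func_dir / f"{record.subject_id}_confounds.tsv"
        if write_volumes:
            vol32 = Volume4D(sub.volume.data.astype(np.float32),
                             sub.volume.affine, sub.volume.tr)
            save_volume4d(vol32, bold_path)
        np.savetxt(motion_path, sub.motion, fmt="%.6f")
        np.savetxt(conf_path, np.column_stack([sub.wm, sub.csf]),
                   fmt="%.6f", delimiter="\t", header="wm\tcsf", comments="")
        # manifest paths are relative to the dataset directory (portable,
        # and byte-identical across runs in different locations)
        record.bold_path = str(bold_path.relative_to(out_dir))
        record.motion_path = str(motion_path.relative_to(out_dir))
        record.confounds_path = str(conf_path.relative_to(out_dir))
    write_manifest(plan.records, out_dir / "manifest.tsv")
    save_label_volume(truth.atlas, out_dir / "atlas.nii")
    save_label_volume(truth.assignment, out_dir / "assignment.nii")
    truth.grouping.to_file(out_dir / "grouping.yaml")
    _write_truth_json(truth, plan, out_dir / "truth.json", n_timepoints, tr)
    return truth, plan


def _write_truth_json(truth: PhantomTruth, plan: CohortPlan, path,
                      n_timepoints: int, tr: float) -> None:
    payload = {
        "seed": truth.seed,
        "plan_seed": plan.seed,
        "grid_shape": list(truth.grid_shape),
        "n_timepoints": n_timepoints,
        "tr": tr,
        "noise_sd": truth.noise_sd,
        "subject_z_sd": truth.subject_z_sd,
        "sensory_gap_z": truth.sensory_gap_z,
        "baseline_z": truth.baseline_z,
        "group_effect": {f"{side}:{roi}": v
                         for (side, roi), v in truth.group_effect.items()},
        "behavior": dataclasses.asdict(truth.behavior),
        "sector_labels": {side: truth.assignment_vector(side).tolist()
                          for side in ("left", "right")},
        "subject_targets": {
            sid: {f"{side}:{roi}": v for (side, roi), v in tg.items()}
            for sid, tg in plan.targets.items()},
        "sensory_impaired": plan.impaired,
        "subject_seeds": plan.subject_seeds,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
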