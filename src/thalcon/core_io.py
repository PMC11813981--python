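"""Volumetric and tabular I/O.

Reads/writes NIfTI-1 volumes, validates grid compatibility between images,
resolves an atlas-grouping config into six cortical ROI masks plus bilateral
thalamus masks, and loads/validates the subject manifest.

Conventions
-----------
* World space is RAS+ (positive x = right); voxel indices are 0-based.
* Grids are never resampled: shape must match exactly and affines must agree
  within ``GRID_ATOL``; anything else is an error.
* Label 0 is background in every label volume.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

#: Canonical cortical ROI names, in fixed order. ROI index i (1-based) in
#: winner-take-all label maps always refers to ``ROI_NAMES[i - 1]``.
ROI_NAMES = (
    "prefrontal",
    "motor",
    "temporal",
    "posterior_parietal",
    "somatosensory",
    "occipital",
)

#: Absolute tolerance for affine agreement between volumes sharing a grid.
GRID_ATOL = 1e-4

#: Score bounds (inclusive) for clinical scales.
SCORE_BOUNDS = {
    "fma_ue_t1": (0, 66),
    "fma_ue_t2": (0, 66),
    "fma_le_t1": (0, 34),
    "fma_le_t2": (0, 34),
    "nihss_t1": (0, 42),
    "nihss_t2": (0, 42),
    "nihss_sensory_t1": (0, 2),
}

GROUPS = ("patient", "control")
LESION_SIDES = ("left", "right", "none")


@dataclasses.dataclass
class Volume4D:
    """A 4D BOLD image: data indexed (x, y, z, t) plus affine and TR."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape[:3]) or self.data.shape[3] < 1:
            raise ValueError(f"degenerate shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if not self.tr > 0:
            raise ValueError(f"repetition time must be positive, got {self.tr}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclasses.dataclass
class LabelVolume:
    """A 3D integer label/mask volume; 0 is background."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded, atol=1e-6):
                raise ValueError("label volume contains non-integer values")
            self.data = rounded.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("labels must be >= 0")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    def mask(self) -> np.ndarray:
        """Boolean foreground mask (label > 0)."""
        return self.data > 0

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape


def grids_compatible(a, b, atol: float = GRID_ATOL) -> bool:
    """True when two volumes share shape and affine (within ``atol``)."""
    sa = a.shape3 if hasattr(a, "shape3") else a.data.shape[:3]
    sb = b.shape3 if hasattr(b, "shape3") else b.data.shape[:3]
    return tuple(sa) == tuple(sb) and np.allclose(a.affine, b.affine, atol=atol)


def assert_same_grid(a, b, what: str = "volumes") -> None:
    if not grids_compatible(a, b):
        raise ValueError(
            f"grid mismatch between {what}: shapes {a.data.shape[:3]} vs "
            f"{b.data.shape[:3]}; affines differ beyond tolerance {GRID_ATOL}"
        )


def load_volume4d(path, tr: float | None = None) -> Volume4D:
    """Load a 4D NIfTI image.

    Parameters
    ----------
    path : path-like
        NIfTI file holding a 4D image.
    tr : float, optional
        Repetition time override in seconds. When omitted, the TR is taken
        from the header (4th zoom); a header without a usable TR is an error.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file, non-4D image, non-finite voxels (the error names the
        offending voxel count), or missing TR.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D image, got {img.ndim}D: {path}")
    data = np.asarray(img.dataobj)
    n_bad = int(np.size(data) - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{n_bad} non-finite voxel value(s) in {path}")
    if tr is None:
        zooms = img.header.get_zooms()
        hdr_tr = float(zooms[3]) if len(zooms) >= 4 else 0.0
        if hdr_tr <= 0:
            raise ValueError(f"no repetition time in header of {path}; pass tr=")
        tr = hdr_tr
    return Volume4D(data=data, affine=np.asarray(img.affine), tr=float(tr))


def save_volume4d(vol: Volume4D, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_label_volume(path) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D label image, got {img.ndim}D: {path}")
    return LabelVolume(data=np.asarray(img.dataobj), affine=np.asarray(img.affine))


def save_label_volume(lv: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(lv.data.astype(np.int16), lv.affine), str(path))


@dataclasses.dataclass
class RoiGrouping:
    """Maps atlas labels to the six cortical ROI names plus thalamus labels.

    ``rois`` maps each ROI name to the tuple of atlas labels it groups
    (typically one label per hemisphere); ``thalamus`` maps "left"/"right"
    to the corresponding thalamus atlas label.
    """

    rois: Mapping[str, tuple[int, ...]]
    thalamus: Mapping[str, int]

    def __post_init__(self) -> None:
        self.rois = {str(k): tuple(int(v) for v in vs) for k, vs in self.rois.items()}
        self.thalamus = {str(k): int(v) for k, v in self.thalamus.items()}
        if set(self.rois) != set(ROI_NAMES):
            raise ValueError(
                f"grouping must define exactly the six ROIs {ROI_NAMES}, "
                f"got {sorted(self.rois)}"
            )
        if set(self.thalamus) != {"left", "right"}:
            raise ValueError("thalamus grouping must define 'left' and 'right'")
        seen: dict[int, str] = {}
        for name in ROI_NAMES:
            for lab in self.rois[name]:
                if lab in seen:
                    raise ValueError(
                        f"non-disjoint grouping: label {lab} assigned to both "
                        f"'{seen[lab]}' and '{name}'"
                    )
                seen[lab] = name
        for side, lab in self.thalamus.items():
            if lab in seen:
                raise ValueError(
                    f"non-disjoint grouping: thalamus label {lab} ({side}) "
                    f"already assigned to '{seen[lab]}'"
                )
            seen[lab] = f"thalamus_{side}"

    @classmethod
    def from_file(cls, path) -> "RoiGrouping":
        """Load a grouping config from YAML or JSON.

        Expected layout::

            rois:
              prefrontal: [1, 2]
              ...
            thalamus:
              left: 13
              right: 14
        """
        path = Path(path)
        text = path.read_text()
        cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(cfg, dict) or "rois" not in cfg or "thalamus" not in cfg:
            raise ValueError(f"grouping config {path} must have 'rois' and 'thalamus'")
        rois = {k: tuple(np.atleast_1d(v).astype(int)) for k, v in cfg["rois"].items()}
        return cls(rois=rois, thalamus=cfg["thalamus"])

    def to_file(self, path) -> None:
        cfg = {
            "rois": {k: [int(v) for v in vs] for k, vs in self.rois.items()},
            "thalamus": {k: int(v) for k, v in self.thalamus.items()},
        }
        Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def resolve_rois(
    atlas: LabelVolume, grouping: RoiGrouping
) -> tuple[dict[str, LabelVolume], dict[str, LabelVolume]]:
    """Resolve a grouping into six cortical masks and two thalamus masks.

    Returns
    -------
    (cortical, thalamus)
        ``cortical`` maps ROI name -> binary LabelVolume; ``thalamus`` maps
        "left"/"right" -> binary LabelVolume. Masks are pairwise disjoint by
        construction (the grouping is validated to be label-disjoint and
        atlas labels partition voxels).

    Raises
    ------
    ValueError
        When a mapped label is absent from the atlas.
    """
    present = set(np.unique(atlas.data).tolist())
    cortical: dict[str, LabelVolume] = {}
    for name in ROI_NAMES:
        labels = grouping.rois[name]
        for lab in labels:
            if lab not in present:
                raise ValueError(f"label {lab} (ROI '{name}') absent from atlas")
        mask = np.isin(atlas.data, labels)
        cortical[name] = LabelVolume(mask.astype(np.int16), atlas.affine)
    thalamus: dict[str, LabelVolume] = {}
    for side in ("left", "right"):
        lab = grouping.thalamus[side]
        if lab not in present:
            raise ValueError(f"thalamus label {lab} ({side}) absent from atlas")
        thalamus[side] = LabelVolume((atlas.data == lab).astype(np.int16), atlas.affine)
    return cortical, thalamus


@dataclasses.dataclass
class SubjectRecord:
    """One manifest row: identity, group, file paths, clinical scores.

    Controls carry ``lesion_side='none'`` and may omit all clinical scores;
    patient scores are validated against their scale bounds. ``extras`` holds
    any additional manifest columns (demographics etc.).
    """

    subject_id: str
    group: str
    lesion_side: str = "none"
    bold_path: str | None = None
    motion_path: str | None = None
    confounds_path: str | None = None
    fma_ue_t1: float | None = None
    fma_ue_t2: float | None = None
    fma_le_t1: float | None = None
    fma_le_t2: float | None = None
    nihss_t1: float | None = None
    nihss_t2: float | None = None
    nihss_sensory_t1: float | None = None
    extras: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group '{self.group}' for {self.subject_id}")
        if self.lesion_side not in LESION_SIDES:
            raise ValueError(
                f"unknown lesion_side '{self.lesion_side}' for {self.subject_id}"
            )
        if self.group == "control" and self.lesion_side != "none":
            raise ValueError(f"control {self.subject_id} must have lesion_side none")
        if self.group == "patient" and self.lesion_side == "none":
            raise ValueError(f"patient {self.subject_id} must have a lesion side")
        for field, (lo, hi) in SCORE_BOUNDS.items():
            val = getattr(self, field)
            if val is None:
                continue
            if not np.isfinite(val) or not lo <= val <= hi:
                raise ValueError(
                    f"{field}={val} out of bounds [{lo}, {hi}] for {self.subject_id}"
                )

    @property
    def is_patient(self) -> bool:
        return self.group == "patient"


_MANIFEST_FIELDS = [f.name for f in dataclasses.fields(SubjectRecord) if f.name != "extras"]


def read_manifest(path) -> list[SubjectRecord]:
    """Read and validate a TSV/CSV subject manifest.

    Required columns: subject_id, group, lesion_side. Score and path columns
    are optional; empty cells become None. Any other column lands in
    ``record.extras``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in ("subject_id", "group", "lesion_side"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} missing required column '{col}'")
    records = []
    extra_cols = [c for c in df.columns if c not in _MANIFEST_FIELDS]
    for _, row in df.iterrows():
        kwargs = {}
        for field in _MANIFEST_FIELDS:
            if field not in df.columns:
                continue
            val = row[field]
            if isinstance(val, float) and np.isnan(val):
                val = None
            kwargs[field] = val
        kwargs["extras"] = {c: row[c] for c in extra_cols}
        records.append(SubjectRecord(**kwargs))
    return records


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten records (including extras) into a DataFrame."""
    rows = []
    for r in records:
        d = {f: getattr(r, f) for f in _MANIFEST_FIELDS}
        d.update(r.extras)
        rows.append(d)
    return pd.DataFrame(rows)


def write_manifest(records: Sequence[SubjectRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
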