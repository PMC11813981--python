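"""Mid-sagittal flipping and cohort harmonization.

Patients with a left-hemisphere lesion are flipped so every lesion sits in
the right hemisphere (ipsilesional = right, contralesional = left from then
on). Controls are duplicated with a flipped copy appended, turning an
n-subject control group into a 2n-entry flip-augmented dataset. Provenance
("original"/"flipped") is recorded on every entry.

The flip is a pure voxel-axis reversal along the axis whose world direction
is closest to +/-x, and is only permitted on grids symmetric about the
world x=0 plane — no interpolation, ever. Note the flip-augmented control
entries are not statistically independent (each subject appears twice);
downstream inference exposes an originals-only mode for that reason.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .core_io import LabelVolume, SubjectRecord, Volume4D

_SYM_ATOL = 1e-4


def _lr_axis(affine: np.ndarray) -> int:
    """Voxel axis whose world direction is closest to the x (left-right) axis."""
    xrow = np.abs(affine[0, :3])
    return int(np.argmax(xrow))


def _check_flip_symmetry(affine: np.ndarray, shape3, axis: int) -> None:
    """Require that reversing ``axis`` mirrors world x about 0 exactly.

    Two conditions: no other voxel axis contributes to world x (the grid is
    not oblique in x), and voxel-center x coordinates are symmetric about 0,
    i.e. x_0 + x_{N-1} == 0.
    """
    other = [a for a in range(3) if a != axis]
    if np.any(np.abs(affine[0, other]) > _SYM_ATOL):
        raise ValueError(
            "grid is oblique in x; cannot flip without interpolation"
        )
    n = shape3[axis]
    x_first = affine[0, 3]
    x_last = affine[0, axis] * (n - 1) + affine[0, 3]
    if abs(x_first + x_last) > _SYM_ATOL:
        raise ValueError(
            f"grid not symmetric about world x=0 (edge x coordinates "
            f"{x_first:+.4f} and {x_last:+.4f}); refusing asymmetric flip"
        )


def flip_lr(vol):
    """Mirror a volume about the mid-sagittal (world x=0) plane.

    Works on :class:`Volume4D` and :class:`LabelVolume`; returns the same
    type. The affine is unchanged: voxel data are reversed along the
    left-right voxel axis, which on a symmetric grid realizes the world
    reflection exactly. ``flip_lr(flip_lr(v))`` is bit-identical to ``v``.
    """
    axis = _lr_axis(vol.affine)
    shape3 = vol.data.shape[:3]
    _check_flip_symmetry(vol.affine, shape3, axis)
    flipped = np.flip(vol.data, axis=axis).copy()
    if isinstance(vol, Volume4D):
        return Volume4D(flipped, vol.affine.copy(), vol.tr)
    if isinstance(vol, LabelVolume):
        return LabelVolume(flipped, vol.affine.copy())
    raise TypeError(f"cannot flip object of type {type(vol).__name__}")


@dataclasses.dataclass
class AlignedEntry:
    """One harmonized cohort entry with its provenance flag."""

    record: SubjectRecord
    volume: Volume4D
    provenance: str  # "original" | "flipped"

    @property
    def entry_id(self) -> str:
        suffix = "" if self.provenance == "original" else "_flipped"
        return f"{self.record.subject_id}{suffix}"


@dataclasses.dataclass
class AlignedCohort:
    """Harmonized cohort: all patient lesions on the right; controls doubled."""

    patients: list[AlignedEntry]
    controls: list[AlignedEntry]

    @property
    def n_entries(self) -> int:
        return len(self.patients) + len(self.controls)

    def all_entries(self) -> list[AlignedEntry]:
        return list(self.patients) + list(self.controls)


def harmonize(
    patients: Sequence[tuple[SubjectRecord, Volume4D]],
    controls: Sequence[tuple[SubjectRecord, Volume4D]],
    flip_augment_controls: bool = True,
) -> AlignedCohort:
    """Flip left-lesion patients and flip-augment the control set.

    Left-lesion patients are flipped (and relabelled lesion_side='right');
    right-lesion patients pass through untouched. Each control contributes
    its original volume plus, when ``flip_augment_controls`` is on, a
    flipped duplicate — 32 controls become 64 entries.

    Raises
    ------
    ValueError
        For a patient without a known lesion side.
    """
    aligned_patients: list[AlignedEntry] = []
    for record, vol in patients:
        if record.lesion_side not in ("left", "right"):
            raise ValueError(
                f"patient {record.subject_id} has lesion_side "
                f"'{record.lesion_side}'; cannot harmonize"
            )
        if record.lesion_side == "left":
            flipped_record = dataclasses.replace(record, lesion_side="right")
            aligned_patients.append(
                AlignedEntry(flipped_record, flip_lr(vol), "flipped")
            )
        else:
            aligned_patients.append(AlignedEntry(record, vol, "original"))
    aligned_controls: list[AlignedEntry] = []
    for record, vol in controls:
        aligned_controls.append(AlignedEntry(record, vol, "original"))
    if flip_augment_controls:
        for record, vol in controls:
            aligned_controls.append(AlignedEntry(record, flip_lr(vol), "flipped"))
    return AlignedCohort(patients=aligned_patients, controls=aligned_controls)
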