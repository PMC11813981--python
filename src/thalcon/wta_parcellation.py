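"""Winner-take-all thalamus parcellation.

Each thalamic voxel is correlated (Pearson) with the mean time series of the
six cortical ROIs and labelled by its strongest positive correlation, at the
individual and at the group level. The group map averages per-ROI
correlation maps across subjects on the Fisher-z scale and applies
winner-take-all to the back-transformed average (a majority-vote alternative
is available). Ties break toward the lowest ROI index; voxels whose maximum
correlation is <= 0 stay unassigned (label 0).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ROI_NAMES, LabelVolume, Volume4D, assert_same_grid

#: Correlations are clipped to +/- this bound before atanh when averaging.
_R_CLIP = 1.0 - 1e-7


def roi_mean_timeseries(vol: Volume4D, roi: LabelVolume) -> np.ndarray:
    """Unweighted mean time series over the ROI mask voxels, shape (T,)."""
    assert_same_grid(vol, roi, "volume and ROI")
    mask = roi.mask()
    if not mask.any():
        raise ValueError("empty ROI mask")
    return vol.data[mask].mean(axis=0)


def cortical_roi_timeseries(vol: Volume4D, rois: dict[str, LabelVolume]) -> np.ndarray:
    """Stack the six cortical mean series into a (T, 6) matrix (ROI order)."""
    return np.column_stack([roi_mean_timeseries(vol, rois[name]) for name in ROI_NAMES])


@dataclasses.dataclass
class CorrelationMaps:
    """Per-voxel Pearson correlations with the six cortical ROIs.

    ``r`` is (V, 6) in canonical ROI order; ``voxel_index`` is (V, 3) voxel
    coordinates inside the thalamus mask (C-order of the mask).
    """

    r: np.ndarray
    voxel_index: np.ndarray
    affine: np.ndarray
    shape3: tuple[int, int, int]
    side: str | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[1] != len(ROI_NAMES):
            raise ValueError(f"r must be (V, 6), got {self.r.shape}")
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")

    @property
    def n_voxels(self) -> int:
        return self.r.shape[0]


@dataclasses.dataclass
class WtaMap:
    """Winner-take-all labels over thalamus voxels.

    ``label`` holds the winning ROI index in 1..6 (order of
    ``core_io.ROI_NAMES``) or 0 for unassigned voxels; ``winning_r`` is the
    row-maximum correlation; ``agreement`` (group maps only) is the fraction
    of subjects whose individual winner matches the group winner.
    """

    label: np.ndarray
    winning_r: np.ndarray
    voxel_index: np.ndarray
    affine: np.ndarray
    shape3: tuple[int, int, int]
    side: str | None = None
    agreement: np.ndarray | None = None

    def to_label_volume(self) -> LabelVolume:
        out = np.zeros(self.shape3, dtype=np.int16)
        out[tuple(self.voxel_index.T)] = self.label
        return LabelVolume(out, self.affine)

    def agreement_volume(self) -> np.ndarray:
        out = np.zeros(self.shape3, dtype=float)
        if self.agreement is not None:
            out[tuple(self.voxel_index.T)] = self.agreement
        return out


def voxel_cortex_correlations(
    vol: Volume4D,
    thalamus: LabelVolume,
    cortex_ts: np.ndarray,
    side: str | None = None,
) -> CorrelationMaps:
    """Pearson r between every thalamus voxel and each cortical mean series.

    Zero-variance voxels (or cortical series) get r = 0 with a warning.
    """
    assert_same_grid(vol, thalamus, "volume and thalamus mask")
    cortex_ts = np.asarray(cortex_ts, dtype=float)
    t = vol.n_timepoints
    if t < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    if cortex_ts.shape != (t, len(ROI_NAMES)):
        raise ValueError(f"cortex_ts must be (T, 6) = ({t}, 6), got {cortex_ts.shape}")
    mask = thalamus.mask()
    voxel_index = np.argwhere(mask)
    x = vol.data[mask].astype(float)  # (V, T)
    x = x - x.mean(axis=1, keepdims=True)
    xs = x.std(axis=1)
    dead = xs == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance thalamic voxel(s); r set to 0")
        xs[dead] = 1.0
    c = cortex_ts - cortex_ts.mean(axis=0, keepdims=True)
    cs = c.std(axis=0)
    dead_c = cs == 0
    if dead_c.any():
        warnings.warn("zero-variance cortical series; r set to 0")
        cs[dead_c] = 1.0
    r = (x / xs[:, None]) @ (c / cs[None, :]) / t
    r[dead] = 0.0
    r[:, dead_c] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationMaps(r=r, voxel_index=voxel_index, affine=vol.affine,
                           shape3=vol.shape3, side=side)


def winner_take_all(cm: CorrelationMaps) -> WtaMap:
    """Label each voxel by its maximal correlation.

    argmax breaks ties toward the lowest ROI index; voxels whose maximum is
    <= 0 are labelled 0 (unassigned) but keep their winning_r.
    """
    winners = np.argmax(cm.r, axis=1)
    winning_r = cm.r[np.arange(cm.n_voxels), winners]
    label = winners.astype(np.int16) + 1
    label[winning_r <= 0] = 0
    return WtaMap(label=label, winning_r=winning_r, voxel_index=cm.voxel_index,
                  affine=cm.affine, shape3=cm.shape3, side=cm.side)


def group_wta(subject_cms: Sequence[CorrelationMaps], method: str = "average") -> WtaMap:
    """Group-level winner-take-all map from per-subject correlation maps.

    method="average" (default): per-ROI maps are Fisher-z transformed,
    averaged across subjects, back-transformed with tanh, then
    winner-take-all is applied to the average. method="vote": the group
    label is the modal individual label (ties toward the lowest index) and
    winning_r is the z-average correlation of the modal ROI.

    ``agreement`` is, per voxel, the fraction of subjects whose individual
    argmax equals the group winner.
    """
    if not subject_cms:
        raise ValueError("empty subject list")
    first = subject_cms[0]
    for cm in subject_cms[1:]:
        if cm.r.shape != first.r.shape or not np.array_equal(
            cm.voxel_index, first.voxel_index
        ):
            raise ValueError("subjects do not share the thalamus grid")
    stack = np.stack([cm.r for cm in subject_cms])  # (S, V, 6)
    z = np.arctanh(np.clip(stack, -_R_CLIP, _R_CLIP))
    mean_r = np.tanh(z.mean(axis=0))
    if method == "average":
        group_map = winner_take_all(
            CorrelationMaps(mean_r, first.voxel_index, first.affine, first.shape3,
                            side=first.side)
        )
    elif method == "vote":
        indiv = np.argmax(stack, axis=2)  # (S, V)
        counts = np.stack([(indiv == k).sum(axis=0) for k in range(len(ROI_NAMES))],
                          axis=1)
        winners = np.argmax(counts, axis=1)
        winning_r = mean_r[np.arange(mean_r.shape[0]), winners]
        label = winners.astype(np.int16) + 1
        label[winning_r <= 0] = 0
        group_map = WtaMap(label=label, winning_r=winning_r,
                           voxel_index=first.voxel_index, affine=first.affine,
                           shape3=first.shape3, side=first.side)
    else:
        raise ValueError(f"unknown group rule '{method}'")
    indiv_winners = np.argmax(stack, axis=2) + 1  # (S, V)
    group_winner = np.argmax(mean_r, axis=1) + 1
    group_map.agreement = (indiv_winners == group_winner[None, :]).mean(axis=0)
    return group_map


def render_confidence(wta: WtaMap) -> np.ndarray:
    """Display values: winning r as a percent of its ROI maximum, floored at 50.

    A voxel at the per-ROI maximum renders as 100; a voxel at half the ROI
    maximum renders as 50, the display floor. Intended for visualization
    only; monotone in winning_r within each ROI.
    """
    display = np.zeros(len(wta.label), dtype=float)
    for k in range(1, len(ROI_NAMES) + 1):
        sel = wta.label == k
        if not sel.any():
            continue
        peak = wta.winning_r[sel].max()
        if peak <= 0:
            continue
        display[sel] = np.clip(100.0 * wta.winning_r[sel] / peak, 50.0, 100.0)
    return display


def subregion_summary(wta: WtaMap) -> pd.DataFrame:
    """Voxel counts (and mean winning r) per label, for one thalamus."""
    rows = []
    for k in range(0, len(ROI_NAMES) + 1):
        sel = wta.label == k
        rows.append({
            "side": wta.side,
            "label": k,
            "roi": "unassigned" if k == 0 else ROI_NAMES[k - 1],
            "n_voxels": int(sel.sum()),
            "mean_winning_r": float(wta.winning_r[sel].mean()) if sel.any() else np.nan,
        })
    return pd.DataFrame(rows)
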