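"""ROI-to-ROI and seed-to-voxel functional connectivity on the Fisher-z scale."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .core_io import ROI_NAMES, LabelVolume, Volume4D, assert_same_grid
from .wta_parcellation import roi_mean_timeseries

#: Correlations at or above this magnitude (e.g. a seed against itself) are
#: treated as degenerate and excluded from z maps rather than carried as
#: infinite z.
R_CAP = 1.0 - 1e-12


def fisher_z(r):
    """Fisher r-to-z transform, z = atanh(r).

    Odd and strictly increasing on (-1, 1); |r| >= 1 is an error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def roi_pair_connectivity(
    vol: Volume4D,
    cortical_rois: dict[str, LabelVolume],
    wta_labels: dict[str, LabelVolume],
    entry_id: str = "",
    group: str = "",
) -> pd.DataFrame:
    """Connectivity between each cortical ROI and its thalamic subregion.

    For each side present in ``wta_labels`` ("left"/"right" label volumes
    carrying winner-take-all labels 1..6 over that thalamus) and each of the
    six ROIs: Pearson r between the cortical ROI mean series and the mean
    series over the thalamic voxels carrying that label, plus Fisher z.
    One row per (side, roi); 2 sides x 6 ROIs = 12 rows per entry. An empty
    subregion yields a NaN row and a warning. |r| >= R_CAP is clipped for z
    (flagged via ``degenerate``) so noise-free inputs stay finite.
    """
    cortex_means = {name: roi_mean_timeseries(vol, cortical_rois[name])
                    for name in ROI_NAMES}
    rows = []
    for side, labels in wta_labels.items():
        assert_same_grid(vol, labels, "volume and WTA labels")
        for idx, name in enumerate(ROI_NAMES, start=1):
            sel = labels.data == idx
            if not sel.any():
                warnings.warn(
                    f"empty thalamic subregion '{name}' ({side}) for {entry_id}"
                )
                rows.append({"entry_id": entry_id, "group": group, "side": side,
                             "roi": name, "n_voxels": 0, "r": np.nan, "z": np.nan,
                             "degenerate": False})
                continue
            thal_mean = vol.data[sel].mean(axis=0)
            r = _pearson(cortex_means[name], thal_mean)
            degenerate = bool(np.isfinite(r) and abs(r) >= R_CAP)
            r_for_z = np.clip(r, -R_CAP, R_CAP)
            z = float(np.arctanh(r_for_z)) if np.isfinite(r) else np.nan
            rows.append({"entry_id": entry_id, "group": group, "side": side,
                         "roi": name, "n_voxels": int(sel.sum()), "r": r, "z": z,
                         "degenerate": degenerate})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class StatMap:
    """A voxelwise 3D statistic map plus the contrast/quantity it encodes."""

    data: np.ndarray  # 3D, NaN outside the analysis mask
    affine: np.ndarray
    quantity: str = "z"
    n_excluded: int = 0

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.data)


def seed_to_voxel(
    vol: Volume4D,
    seed_mask: LabelVolume,
    brain_mask: LabelVolume,
) -> StatMap:
    """Fisher-z map of the seed-mean series against every brain-mask voxel.

    The seed series is the unweighted mean over seed voxels. Voxels whose
    |r| reaches R_CAP (numerically perfect correlation, e.g. the single
    voxel of a one-voxel seed) are excluded (NaN) rather than mapped to
    infinite z; their count is reported on the result.
    """
    assert_same_grid(vol, seed_mask, "volume and seed")
    assert_same_grid(vol, brain_mask, "volume and brain mask")
    seed = seed_mask.mask()
    if not seed.any():
        raise ValueError("empty seed mask")
    seed_ts = vol.data[seed].mean(axis=0).astype(float)
    seed_ts = seed_ts - seed_ts.mean()
    seed_norm = np.linalg.norm(seed_ts)
    if seed_norm == 0:
        raise ValueError("seed series has zero variance")
    mask = brain_mask.mask()
    x = vol.data[mask].astype(float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    dead = norms == 0
    norms[dead] = 1.0
    r = (x @ seed_ts) / (norms * seed_norm)
    np.clip(r, -1.0, 1.0, out=r)
    r[dead] = np.nan
    capped = np.abs(r) >= R_CAP
    r[capped] = np.nan
    z = np.arctanh(r)
    out = np.full(vol.shape3, np.nan)
    out[mask] = z
    return StatMap(data=out, affine=vol.affine, quantity="fisher_z",
                   n_excluded=int(capped.sum() + dead.sum()))
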