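"""Group statistics.

Two-sample t tests on ROI-pair Fisher-z values, permutation cluster-level
FWE correction for seed-to-voxel contrasts, behavioral correlations with a
normality-gated Pearson/Spearman choice, the motor-function change rate
(CR-MF), the sensory subgroup comparison, and the demographics table.

Cluster-level familywise error is controlled by group-label permutation
with a max-cluster-extent null: the voxelwise t map is thresholded at the
cluster-forming p (two-sided), suprathreshold voxels are grouped into
26-connected clusters signed by contrast direction, and each observed
cluster's corrected p is (1 + #{permutation max extent >= observed extent})
/ (1 + n_perm). Using the two-sided maximum over both contrast directions
controls FWE jointly across the patient>control and control>patient maps.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_io import ROI_NAMES


@dataclasses.dataclass
class TTestResult:
    t: float
    p: float
    df: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float


def two_sample_t(a, b, variant: str = "student") -> TTestResult:
    """Two-sample t test, two-tailed.

    variant="student" uses the pooled-variance Student test (default);
    "welch" uses unequal variances. Degenerate inputs: zero pooled variance
    with equal means gives t = 0, p = 1; zero variance with unequal means
    is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant '{variant}'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return TTestResult(0.0, 1.0, df, a.size, b.size,
                               float(a.mean()), float(b.mean()))
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    df = (a.size + b.size - 2) if variant == "student" else float(res.df)
    return TTestResult(float(res.statistic), float(res.pvalue), float(df),
                       a.size, b.size, float(a.mean()), float(b.mean()))


def roi_pair_contrast(
    table: pd.DataFrame,
    alpha: float = 0.05,
    variant: str = "student",
    fdr: bool = False,
) -> pd.DataFrame:
    """Patient-vs-control t tests for every (side, roi) connectivity pair.

    ``table`` needs columns group / side / roi / z (one row per entry, side,
    roi). Patients on side s are compared against control entries on the
    same side. Twelve tests (2 sides x 6 ROIs) at uncorrected two-tailed
    ``alpha``; set ``fdr`` for an additional Benjamini-Hochberg column.
    """
    rows = []
    for side in sorted(table["side"].unique()):
        for roi in ROI_NAMES:
            sel = (table["side"] == side) & (table["roi"] == roi)
            pat = table.loc[sel & (table["group"] == "patient"), "z"].dropna()
            ctl = table.loc[sel & (table["group"] == "control"), "z"].dropna()
            if pat.empty or ctl.empty:
                raise ValueError(f"empty group for pair ({side}, {roi})")
            res = two_sample_t(pat.to_numpy(), ctl.to_numpy(), variant=variant)
            rows.append({
                "side": side, "roi": roi, "t": res.t, "p": res.p, "df": res.df,
                "n_patient": res.n_a, "n_control": res.n_b,
                "mean_patient_z": res.mean_a, "mean_control_z": res.mean_b,
                "delta_z": res.mean_a - res.mean_b,
                "significant": res.p < alpha,
            })
    out = pd.DataFrame(rows)
    if fdr:
        out["p_fdr"] = _benjamini_hochberg(out["p"].to_numpy())
        out["significant_fdr"] = out["p_fdr"] < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Permutation cluster-level FWE
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Cluster:
    extent: int
    peak_mm: tuple[float, float, float]
    peak_t: float
    p_corr: float
    contrast: str  # "a>b" | "b>a"


@dataclasses.dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_perm: int
    seed: int | None
    t_threshold: float
    df: float
    exact: bool = False

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corr <= alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "contrast": c.contrast, "extent_voxels": c.extent,
            "peak_x_mm": c.peak_mm[0], "peak_y_mm": c.peak_mm[1],
            "peak_z_mm": c.peak_mm[2], "peak_t": c.peak_t, "p_fwe": c.p_corr,
        } for c in self.clusters]
        return pd.DataFrame(rows)


def _t_maps(x: np.ndarray, assign: np.ndarray, n_a: int) -> np.ndarray:
    """Pooled-variance t maps for many group assignments at once.

    x: (n, V) data; assign: (P, n) boolean, True marks group a (each row has
    exactly ``n_a`` Trues). Returns (P, V) t statistics.
    """
    n, v = x.shape
    n_b = n - n_a
    a = assign.astype(float)
    s_tot = x.sum(axis=0)
    q_tot = (x * x).sum(axis=0)
    s1 = a @ x
    q1 = a @ (x * x)
    s2 = s_tot[None, :] - s1
    q2 = q_tot[None, :] - q1
    m1 = s1 / n_a
    m2 = s2 / n_b
    ss1 = q1 - n_a * m1 * m1
    ss2 = q2 - n_b * m2 * m2
    pooled = (ss1 + ss2) / (n - 2)
    denom = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    t[~np.isfinite(t)] = 0.0
    return t


def _cluster_extents(t_3d: np.ndarray, t_crit: float, structure: np.ndarray):
    """Signed suprathreshold clusters of a 3D t map.

    Yields (extent, peak_voxel_index, peak_t, sign) for each cluster, where
    sign +1 means group a > group b.
    """
    out = []
    for sign in (1, -1):
        supra = (sign * t_3d) > t_crit
        if not supra.any():
            continue
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            voxels = np.argwhere(labels == lab)
            vals = t_3d[tuple(voxels.T)]
            peak_local = int(np.argmax(sign * vals))
            out.append((len(voxels), tuple(voxels[peak_local]),
                        float(vals[peak_local]), sign))
    return out


def _max_extent(t_3d: np.ndarray, t_crit: float, structure: np.ndarray) -> int:
    best = 0
    for sign in (1, -1):
        supra = (sign * t_3d) > t_crit
        if not supra.any():
            continue
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def perm_cluster_fwe(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    cluster_forming_p: float = 0.001,
    n_perm: int = 1000,
    seed: int | None = None,
    connectivity: int = 26,
    contrast_labels: tuple[str, str] = ("a>b", "b>a"),
    chunk: int = 100,
) -> ClusterResult:
    """Permutation cluster-extent FWE inference on two stacks of 3D maps.

    Parameters
    ----------
    maps_a, maps_b : (n_a, X, Y, Z) and (n_b, X, Y, Z) arrays
        Subject-level statistic maps (e.g. Fisher-z seed maps) per group.
    mask : 3D boolean array
        Analysis mask shared by all maps.
    cluster_forming_p : float
        Two-sided voxelwise p defining suprathreshold voxels.
    n_perm : int
        Number of random group-label permutations; if fewer distinct
        assignments exist, all are enumerated exactly.
    connectivity : {6, 26}
        Neighborhood for clustering (26 = faces+edges+corners).

    Corrected p per cluster is (1 + #{perm max extent >= extent})/(1+n_perm)
    for random permutations, or the exact proportion under enumeration. The
    attainable lower bound is 1/(1 + n_perm).
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape[0] < 5 or maps_b.shape[0] < 5:
        raise ValueError("need at least 5 maps per group")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; corrected p values are coarse")
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    mask = np.asarray(mask, dtype=bool)
    n_a, n_b = maps_a.shape[0], maps_b.shape[0]
    n = n_a + n_b
    df = n - 2
    t_crit = float(stats.t.ppf(1.0 - cluster_forming_p / 2.0, df))
    x = np.concatenate([maps_a.reshape(n_a, -1)[:, mask.ravel()],
                        maps_b.reshape(n_b, -1)[:, mask.ravel()]])

    def to_3d(t_flat: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape)
        out[mask] = t_flat
        return out

    obs_assign = np.zeros((1, n), dtype=bool)
    obs_assign[0, :n_a] = True
    t_obs = to_3d(_t_maps(x, obs_assign, n_a)[0])
    observed = _cluster_extents(t_obs, t_crit, structure)

    n_distinct = math.comb(n, n_a)
    exact = n_distinct <= n_perm
    rng = np.random.default_rng(seed)
    null_max: list[int] = []
    if exact:
        from itertools import combinations
        for combo in combinations(range(n), n_a):
            assign = np.zeros((1, n), dtype=bool)
            assign[0, list(combo)] = True
            t_flat = _t_maps(x, assign, n_a)[0]
            null_max.append(_max_extent(to_3d(t_flat), t_crit, structure))
        null_max_arr = np.array(null_max)
    else:
        done = 0
        while done < n_perm:
            batch = min(chunk, n_perm - done)
            assign = np.zeros((batch, n), dtype=bool)
            for i in range(batch):
                assign[i, rng.choice(n, size=n_a, replace=False)] = True
            t_batch = _t_maps(x, assign, n_a)
            for i in range(batch):
                null_max.append(_max_extent(to_3d(t_batch[i]), t_crit, structure))
            done += batch
        null_max_arr = np.array(null_max)

    clusters = []
    for extent, peak_vox, peak_t, sign in observed:
        count = int((null_max_arr >= extent).sum())
        if exact:
            p_corr = count / n_distinct
        else:
            p_corr = (1 + count) / (1 + n_perm)
        peak_mm = tuple(
            (np.asarray(affine) @ np.array([*peak_vox, 1.0]))[:3].tolist()
        )
        clusters.append(Cluster(
            extent=extent, peak_mm=peak_mm, peak_t=peak_t, p_corr=float(p_corr),
            contrast=contrast_labels[0] if sign > 0 else contrast_labels[1],
        ))
    clusters.sort(key=lambda c: (c.p_corr, -c.extent))
    return ClusterResult(clusters=clusters, n_perm=len(null_max_arr), seed=seed,
                         t_threshold=t_crit, df=df, exact=exact)


# ---------------------------------------------------------------------------
# Behavioral statistics
# ---------------------------------------------------------------------------

def cr_mf(fma_t2, fma_t1):
    """Change rate of motor function: (t2 - t1) / (t2 + t1), in [-1, 1].

    Antisymmetric in its arguments; undefined (NaN) when both scores are 0.
    Negative scores are an error.
    """
    t2 = np.asarray(fma_t2, dtype=float)
    t1 = np.asarray(fma_t1, dtype=float)
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise ValueError("FMA scores must be >= 0")
    denom = t1 + t2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (t2 - t1) / np.where(denom > 0, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class BehavioralResult:
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    n: int


def behavior_correlation(z, scores, normality_alpha: float = 0.05) -> BehavioralResult:
    """Correlate connectivity values with clinical scores.

    Pearson when both variables pass Shapiro-Wilk normality at
    ``normality_alpha``, otherwise Spearman; two-tailed p. Pairs with a
    missing value are dropped.
    """
    z = np.asarray(z, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if z.shape != scores.shape:
        raise ValueError("paired inputs must have equal length")
    keep = np.isfinite(z) & np.isfinite(scores)
    z, scores = z[keep], scores[keep]
    n = z.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(z) == 0 or np.ptp(scores) == 0:
        raise ValueError("constant input; correlation undefined")
    normal = (stats.shapiro(z).pvalue > normality_alpha
              and stats.shapiro(scores).pvalue > normality_alpha)
    if normal:
        res = stats.pearsonr(z, scores)
        method = "pearson"
    else:
        res = stats.spearmanr(z, scores)
        method = "spearman"
    return BehavioralResult(method=method, r=float(res.statistic),
                            p=float(res.pvalue), n=n)


def sensory_subgroup_compare(
    connectivity_z, fma_total, sensory_item
) -> dict[str, TTestResult]:
    """Impaired-vs-nonimpaired sensory subgroup t tests.

    Impairment is sensory_item > 0. Returns independent Student t tests for
    ipsilesional somatosensory-thalamic z and for the whole-extremity FMA
    (upper + lower summed), as ``{"connectivity": ..., "fma": ...}``.
    """
    z = np.asarray(connectivity_z, dtype=float)
    fma = np.asarray(fma_total, dtype=float)
    sens = np.asarray(sensory_item, dtype=float)
    if not (z.size == fma.size == sens.size):
        raise ValueError("inputs must be aligned per patient")
    impaired = sens > 0
    if impaired.sum() < 2 or (~impaired).sum() < 2:
        raise ValueError(
            f"subgroup too small: impaired n={int(impaired.sum())}, "
            f"nonimpaired n={int((~impaired).sum())}"
        )
    return {
        "connectivity": two_sample_t(z[impaired], z[~impaired]),
        "fma": two_sample_t(fma[impaired], fma[~impaired]),
    }


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, int]:
    """Pearson chi-square for a 2x2 table, no continuity correction.

    Table layout: rows are trait present/absent, columns group 1/group 2:
    [[a, c], [b, d]]. chi2 = N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be >= 0")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin in 2x2 table")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, 1))
    return float(chi2), p, 1


_CONTINUOUS_VARS = ("age", "bmi", "mmse")
_BINARY_VARS = ("male", "smoke", "hypertension", "diabetes", "dyslipidemia")


def demographics_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics table: mean +/- SD with t tests for continuous
    traits, counts (%) with 2x2 chi-square for binary traits.

    Uses whichever of age/bmi/mmse (continuous) and male/smoke/hypertension/
    diabetes/dyslipidemia (binary 0/1) columns are present.
    """
    pat = manifest[manifest["group"] == "patient"]
    ctl = manifest[manifest["group"] == "control"]
    rows = []
    for var in _CONTINUOUS_VARS:
        if var not in manifest.columns:
            continue
        a = pat[var].dropna().to_numpy(dtype=float)
        b = ctl[var].dropna().to_numpy(dtype=float)
        res = two_sample_t(a, b)
        rows.append({
            "variable": var, "test": "t",
            "patients": f"{a.mean():.1f} (±{a.std(ddof=1):.1f})",
            "controls": f"{b.mean():.1f} (±{b.std(ddof=1):.1f})",
            "statistic": res.t, "p": res.p,
        })
    for var in _BINARY_VARS:
        if var not in manifest.columns:
            continue
        a = int(pat[var].sum())
        b = len(pat) - a
        c = int(ctl[var].sum())
        d = len(ctl) - c
        chi2, p, _ = chi_square_2x2(a, b, c, d)
        rows.append({
            "variable": var, "test": "chi2",
            "patients": f"{a} ({100 * a / len(pat):.1f}%)",
            "controls": f"{c} ({100 * c / len(ctl):.1f}%)",
            "statistic": chi2, "p": p,
        })
    return pd.DataFrame(rows)
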