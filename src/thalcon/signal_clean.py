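"""BOLD denoising chain.

Stages, applied in this fixed order by :func:`clean_pipeline`:

1. discard the first ``n_discard`` volumes;
2. linear detrend of each voxel time series;
3. zero-phase Butterworth band-pass (default 0.01-0.08 Hz);
4. regression of nuisance covariates (6 motion parameters, white-matter and
   CSF signals) with an intercept.

Whole-brain global signal regression is deliberately not offered, and no
spatial smoothing is applied. Confound series are passed through the same
band-pass before regression so that the regression cannot reintroduce
out-of-band variance. Motion-based QC thresholds the three translation
columns only (strictly greater than the threshold fails); rotations are
reported but not thresholded.

All stages are linear per-series operators, so the pipeline obeys
superposition and commutes with purely spatial operations such as
left-right flipping.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sp_signal

from .core_io import Volume4D


@dataclasses.dataclass
class MotionQC:
    """Outcome of motion screening for one subject."""

    passed: bool
    max_translation_mm: float
    max_rotation: float


@dataclasses.dataclass
class ConfoundSet:
    """Nuisance regressors: 6 rigid-body motion columns plus WM and CSF."""

    motion: np.ndarray  # (T, 6)
    wm: np.ndarray  # (T,)
    csf: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        self.motion = np.atleast_2d(np.asarray(self.motion, dtype=float))
        self.wm = np.asarray(self.wm, dtype=float).ravel()
        self.csf = np.asarray(self.csf, dtype=float).ravel()
        if self.motion.shape[1] != 6:
            raise ValueError(f"motion must have 6 columns, got {self.motion.shape[1]}")
        t = self.motion.shape[0]
        if self.wm.shape[0] != t or self.csf.shape[0] != t:
            raise ValueError("wm/csf length must match motion rows")

    @property
    def n_rows(self) -> int:
        return self.motion.shape[0]

    def matrix(self) -> np.ndarray:
        """(T, 8) design block: motion columns then wm then csf."""
        return np.column_stack([self.motion, self.wm, self.csf])

    def discard_initial(self, n: int) -> "ConfoundSet":
        return ConfoundSet(self.motion[n:], self.wm[n:], self.csf[n:])


def discard_initial(vol: Volume4D, n: int = 5) -> Volume4D:
    """Drop the first ``n`` frames; remaining frames are unchanged."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if vol.n_timepoints <= n:
        raise ValueError(
            f"cannot discard {n} frames from a {vol.n_timepoints}-frame volume"
        )
    return Volume4D(vol.data[..., n:], vol.affine, vol.tr)


def motion_qc(motion: np.ndarray, threshold_mm: float = 3.0) -> MotionQC:
    """Screen a 6-column motion-parameter matrix.

    Fails if and only if any absolute translation (first three columns,
    mm) is strictly greater than ``threshold_mm``. Rotations (last three
    columns) are reported, never thresholded.
    """
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    if motion.shape[1] != 6:
        raise ValueError(f"motion matrix must have 6 columns, got {motion.shape[1]}")
    max_trans = float(np.abs(motion[:, :3]).max()) if motion.size else 0.0
    max_rot = float(np.abs(motion[:, 3:]).max()) if motion.size else 0.0
    return MotionQC(passed=max_trans <= threshold_mm, max_translation_mm=max_trans,
                    max_rotation=max_rot)


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (and mean) from each column."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 3:
        raise ValueError(f"need at least 3 timepoints to detrend, got {ts.shape[0]}")
    t = ts.shape[0]
    design = np.column_stack([np.ones(t), np.arange(t, dtype=float)])
    q, _ = np.linalg.qr(design)
    ts2d = ts if ts.ndim == 2 else ts[:, None]
    resid = ts2d - q @ (q.T @ ts2d)
    return resid if ts.ndim == 2 else resid.ravel()


def _bandpass_sos(tr: float, low: float, high: float, order: int = 2):
    nyquist = 0.5 / tr
    if low >= high:
        raise ValueError(f"band limits inverted: low={low} >= high={high}")
    if high >= nyquist:
        raise ValueError(f"high={high} Hz >= Nyquist {nyquist} Hz for tr={tr}")
    if low <= 0:
        raise ValueError("low cutoff must be positive")
    return sp_signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr,
                            output="sos")


def bandpass(ts: np.ndarray, tr: float, low: float = 0.01, high: float = 0.08,
             order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along axis 0."""
    ts = np.asarray(ts, dtype=float)
    sos = _bandpass_sos(tr, low, high, order)
    return sp_signal.sosfiltfilt(sos, ts, axis=0)


def bandpass_variance_gain(tr: float, low: float = 0.01, high: float = 0.08,
                           order: int = 2, n_freq: int = 4096,
                           power: int = 4) -> float:
    """Spectral moment mean(|H(f)|^power) of the zero-phase band-pass.

    The forward-backward filter has amplitude response |H(f)|^2, so white
    noise with flat spectrum keeps ``power=4`` of its variance, while a
    source that was itself produced by this filter (spectrum |H|^4) retains
    the ratio of the ``power=8`` and ``power=4`` moments when filtered
    again. The synthetic generator uses both to plant correlations that
    hold after cleaning.
    """
    sos = _bandpass_sos(tr, low, high, order)
    _, h = sp_signal.sosfreqz(sos, worN=n_freq, fs=1.0 / tr)
    return float(np.mean(np.abs(h) ** power))


def regress_nuisance(ts: np.ndarray, confounds) -> np.ndarray:
    """Residualize each column of ``ts`` against the confounds + intercept.

    Residuals are orthogonal to every confound column and to the intercept
    (hence zero mean). The design must be full column rank; collinear
    columns are named in the error.
    """
    ts = np.asarray(ts, dtype=float)
    ts2d = ts if ts.ndim == 2 else ts[:, None]
    conf = confounds.matrix() if isinstance(confounds, ConfoundSet) else np.asarray(
        confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != ts2d.shape[0]:
        raise ValueError(
            f"confound rows ({conf.shape[0]}) != timepoints ({ts2d.shape[0]})"
        )
    design = np.column_stack([np.ones(ts2d.shape[0]), conf])
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    if np.any(diag < 1e-10 * max(diag.max(), 1.0)):
        rank = int(np.linalg.matrix_rank(design))
        bad = _collinear_columns(design)
        raise ValueError(
            f"rank-deficient nuisance design (rank {rank} < {design.shape[1]}); "
            f"collinear confound column(s): {bad}"
        )
    resid = ts2d - q @ (q.T @ ts2d)
    return resid if ts.ndim == 2 else resid.ravel()


def _collinear_columns(design: np.ndarray) -> list[int]:
    """0-based confound column indices implicated in rank deficiency."""
    bad = []
    for j in range(1, design.shape[1]):
        others = np.delete(design, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, design[:, j], rcond=None)
        resid = design[:, j] - others @ beta
        scale = np.linalg.norm(design[:, j]) + 1e-30
        if np.linalg.norm(resid) / scale < 1e-8:
            bad.append(j - 1)  # report without the intercept offset
    return bad


def clean_pipeline(vol: Volume4D, confounds: ConfoundSet, *, n_discard: int = 5,
                   low: float = 0.01, high: float = 0.08,
                   filter_order: int = 2) -> Volume4D:
    """Run the full denoising chain: discard -> detrend -> band-pass -> regress.

    ``confounds`` may cover either the full acquisition (rows are then
    discarded in step 1 alongside the frames) or the post-discard length.
    Confound columns are detrended and band-passed identically to the data
    before regression.
    """
    out = discard_initial(vol, n_discard) if n_discard else vol
    t = out.n_timepoints
    if confounds.n_rows == t + n_discard:
        confounds = confounds.discard_initial(n_discard)
    elif confounds.n_rows != t:
        raise ValueError(
            f"confound rows ({confounds.n_rows}) match neither the full "
            f"({t + n_discard}) nor the post-discard ({t}) frame count"
        )
    shape3 = out.shape3
    # Row layout (V, T) keeps the time axis contiguous, which the filter
    # needs; the math is identical to the columnwise stage functions.
    ts = np.ascontiguousarray(out.data.reshape(-1, t), dtype=float)
    trend = np.column_stack([np.ones(t), np.arange(t, dtype=float)])
    q_trend, _ = np.linalg.qr(trend)
    ts -= (ts @ q_trend) @ q_trend.T
    sos = _bandpass_sos(out.tr, low, high, filter_order)
    ts = sp_signal.sosfiltfilt(sos, ts, axis=-1)
    conf = bandpass(detrend_linear(confounds.matrix()), out.tr, low, high,
                    order=filter_order)
    design = np.column_stack([np.ones(t), conf])
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    if np.any(diag < 1e-10 * max(diag.max(), 1.0)):
        raise ValueError(
            f"rank-deficient nuisance design; collinear confound column(s): "
            f"{_collinear_columns(design)}"
        )
    ts -= (ts @ q) @ q.T
    return Volume4D(ts.reshape(*shape3, t), out.affine, out.tr)
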