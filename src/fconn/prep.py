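"""Time-series-level preprocessing for ROI resting-state signals.

Operates on per-subject ROI-by-time matrices; everything that requires
image volumes (slice timing, realignment, spatial normalisation,
component extraction from tissue masks) is out of scope and the
corresponding nuisance signals are accepted as externally supplied
regressor columns.

The canonical order of the pipeline, applied by
:func:`preprocess_subject`, is::

    drop_initial -> detrend -> bandpass -> regress_nuisance -> scrub

Framewise displacement is always computed from the raw motion
parameters before any signal-side step. Filtering runs on the full
uniformly sampled grid first and contaminated frames are deleted
afterwards, so the frequency response of the filter is well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from fconn.errors import ComputationError, ValidationError

__all__ = [
    "MotionTrace",
    "SubjectTimeSeries",
    "compute_fd",
    "scrub",
    "drop_initial_volumes",
    "detrend_linear",
    "bandpass",
    "regress_nuisance",
    "preprocess_subject",
]

#: Radius (mm) used to convert rotational displacement (degrees) to arc
#: length; approximately the mean distance from the centre of standard
#: space to the cortical surface.
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Framewise-displacement threshold (mm) above which a frame is scrubbed.
DEFAULT_FD_THRESHOLD_MM = 0.3


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame rigid-body motion parameters for one subject.

    Parameters
    ----------
    params
        Array of shape ``(n_frames, 6)``: three translations in mm
        (x, y, z) followed by three rotations in degrees
        (pitch, roll, yaw) — the SPM ``rp_*.txt`` column convention.
    radius_mm
        Head radius used to convert rotation differences to mm of arc.
    subject_id
        Optional identifier carried through error messages and QC output.
    """

    params: np.ndarray
    radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    subject_id: str | None = None

    def __post_init__(self) -> None:
        params = np.asarray(self.params, dtype=float)
        if params.ndim != 2 or params.shape[1] != 6:
            raise ValidationError(
                f"motion parameters must be (n_frames, 6); got {params.shape}"
            )
        if not np.all(np.isfinite(params)):
            raise ValidationError("motion parameters contain non-finite values")
        object.__setattr__(self, "params", params)

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    def framewise_displacement(self) -> np.ndarray:
        """Framewise displacement in mm (first frame defined as 0)."""
        return compute_fd(self)

    def drop_initial(self, n_drop: int) -> "MotionTrace":
        """Remove the first ``n_drop`` frames (mirrors the signal side)."""
        if n_drop < 0 or n_drop >= self.n_frames:
            raise ValidationError(
                f"cannot drop {n_drop} of {self.n_frames} motion frames"
            )
        return replace(self, params=self.params[n_drop:])


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's ROI-by-time signal matrix.

    ``frame_mask`` is a boolean vector over the *original* acquisition
    frames; entries flip to ``False`` as frames are dropped or scrubbed,
    so the provenance of every retained column is recoverable.
    """

    data: np.ndarray
    tr_seconds: float
    roi_labels: tuple[str, ...] = ()
    subject_id: str | None = None
    frame_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValidationError(f"time series must be 2-D; got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValidationError(
                f"time series for subject {self.subject_id!r} has non-finite values"
            )
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        object.__setattr__(self, "data", data)
        labels = tuple(self.roi_labels) or tuple(
            f"ROI{i + 1}" for i in range(data.shape[0])
        )
        if len(labels) != data.shape[0]:
            raise ValidationError(
                f"{len(labels)} ROI labels for {data.shape[0]} rows"
            )
        object.__setattr__(self, "roi_labels", labels)
        mask = self.frame_mask
        if mask is None:
            mask = np.ones(data.shape[1], dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.sum() != data.shape[1]:
                raise ValidationError(
                    "frame_mask retains a different number of frames than "
                    "the signal matrix holds"
                )
        object.__setattr__(self, "frame_mask", mask)

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, frame_mask: np.ndarray | None = None
                  ) -> "SubjectTimeSeries":
        return replace(
            self, data=data,
            frame_mask=self.frame_mask if frame_mask is None else frame_mask,
        )


def compute_fd(motion: MotionTrace) -> np.ndarray:
    """Framewise displacement per frame, in mm.

    FD at frame ``t`` is the sum of absolute frame-to-frame changes of
    the six rigid-body parameters, with each rotation difference first
    converted from degrees to mm of arc at the trace's head radius
    (``|Δdeg| * pi/180 * r``). The first frame has no predecessor and
    its FD is defined as 0.
    """
    if motion.n_frames < 2:
        raise ValidationError("FD requires at least 2 motion frames")
    diffs = np.abs(np.diff(motion.params, axis=0))
    diffs[:, 3:] *= math.pi / 180.0 * motion.radius_mm
    fd = np.zeros(motion.n_frames)
    fd[1:] = diffs.sum(axis=1)
    return fd


def drop_initial_volumes(ts: SubjectTimeSeries, n_drop: int) -> SubjectTimeSeries:
    """Remove the first ``n_drop`` frames (magnetisation-equilibration volumes)."""
    if n_drop < 0:
        raise ValidationError("n_drop must be non-negative")
    if n_drop >= ts.n_frames:
        raise ValidationError(
            f"cannot drop {n_drop} of {ts.n_frames} frames "
            f"(subject {ts.subject_id!r}): no data would remain"
        )
    if n_drop == 0:
        return ts
    mask = ts.frame_mask.copy()
    retained = np.flatnonzero(mask)
    mask[retained[:n_drop]] = False
    return ts.with_data(ts.data[:, n_drop:], mask)


def detrend_linear(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Remove, per ROI, the least-squares linear trend over frame index."""
    if ts.n_frames < 3:
        raise ValidationError("linear detrending requires at least 3 frames")
    t = np.arange(ts.n_frames, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    return ts.with_data(ts.data - (design @ coef).T)


def bandpass(
    ts: SubjectTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.10,
) -> SubjectTimeSeries:
    """Ideal (rectangular) frequency-domain bandpass filter.

    Discrete-Fourier bins with frequency in ``[low_hz, high_hz]`` are
    retained, all others (including DC when ``low_hz > 0``) are zeroed,
    and the real inverse transform is returned. Assumes the frames are
    uniformly sampled at the series' TR, which is why filtering precedes
    scrubbing in the pipeline.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if high_hz > nyquist + 1e-12:
        raise ValidationError(
            f"high cutoff {high_hz} Hz exceeds the Nyquist frequency "
            f"{nyquist:.6g} Hz at TR={ts.tr_seconds} s"
        )
    if not 0 <= low_hz < high_hz:
        raise ValidationError("need 0 <= low_hz < high_hz")
    freqs = np.fft.rfftfreq(ts.n_frames, d=ts.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum = np.fft.rfft(ts.data, axis=1)
    spectrum[:, ~keep] = 0.0
    return ts.with_data(np.fft.irfft(spectrum, n=ts.n_frames, axis=1))


def regress_nuisance(
    ts: SubjectTimeSeries, regressors: np.ndarray
) -> SubjectTimeSeries:
    """OLS residuals of each ROI series against [intercept | regressors].

    The returned residuals are orthogonal to the intercept and to every
    regressor column. Raises if the design (with intercept) is rank
    deficient, naming the offending columns.
    """
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != ts.n_frames:
        if regressors.shape[1] == ts.n_frames:
            regressors = regressors.T
        else:
            raise ValidationError(
                f"regressors have {regressors.shape[0]} rows for "
                f"{ts.n_frames} frames"
            )
    design = np.column_stack([np.ones(ts.n_frames), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not increase the rank incrementally
        bad = []
        running = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([running, design[:, j]])
            if np.linalg.matrix_rank(cand) == running.shape[1]:
                bad.append(j - 1)  # 0-based regressor index
            else:
                running = cand
        raise ValidationError(
            f"rank-deficient nuisance design: regressor columns {bad} are "
            "collinear with the intercept or earlier columns"
        )
    coef, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    return ts.with_data(ts.data - (design @ coef).T)


def scrub(
    ts: SubjectTimeSeries,
    fd: np.ndarray,
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
) -> SubjectTimeSeries:
    """Delete frames whose framewise displacement exceeds the threshold.

    Frames are removed outright (no interpolation or censoring
    regressors); the order of surviving frames is preserved and the
    retained-frame mask is updated.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (ts.n_frames,):
        raise ValidationError(
            f"FD length {fd.shape} does not match frame count {ts.n_frames}"
        )
    keep = fd <= threshold_mm
    if not keep.any():
        raise ComputationError(
            f"scrubbing at {threshold_mm} mm removed every frame "
            f"for subject {ts.subject_id!r}"
        )
    mask = ts.frame_mask.copy()
    retained = np.flatnonzero(mask)
    mask[retained[~keep]] = False
    return ts.with_data(ts.data[:, keep], mask)


@dataclass(frozen=True)
class PreprocessResult:
    """Cleaned series plus the QC quantities reported per subject."""

    timeseries: SubjectTimeSeries
    fd: np.ndarray
    mean_fd: float
    n_scrubbed: int
    dvars: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def dvars(ts: SubjectTimeSeries) -> np.ndarray:
    """Root-mean-square signal change between consecutive frames.

    A QC statistic only; no exclusion rule is attached to it.
    """
    d = np.zeros(ts.n_frames)
    if ts.n_frames > 1:
        d[1:] = np.sqrt(np.mean(np.diff(ts.data, axis=1) ** 2, axis=0))
    return d


def preprocess_subject(
    ts: SubjectTimeSeries,
    motion: MotionTrace,
    *,
    n_drop: int = 0,
    low_hz: float = 0.01,
    high_hz: float = 0.10,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    regressors: np.ndarray | None = None,
    regress_motion: bool = True,
) -> PreprocessResult:
    """Run the full preprocessing chain on one subject.

    Order: drop initial volumes (signal and motion together), linear
    detrend, bandpass, nuisance regression (six motion parameters plus
    any supplied columns), then FD-based scrubbing. FD and mean FD are
    computed from the raw motion parameters after the initial-volume
    drop, before any signal-side step.
    """
    if motion.n_frames != ts.n_frames:
        raise ValidationError(
            f"motion trace has {motion.n_frames} frames but the series has "
            f"{ts.n_frames} (subject {ts.subject_id!r})"
        )
    if n_drop:
        ts = drop_initial_volumes(ts, n_drop)
        motion = motion.drop_initial(n_drop)
    fd = compute_fd(motion)
    ts = detrend_linear(ts)
    ts = bandpass(ts, low_hz, high_hz)
    columns: list[np.ndarray] = []
    if regress_motion:
        columns.append(motion.params)
    if regressors is not None:
        columns.append(np.atleast_2d(np.asarray(regressors, dtype=float)))
    if columns:
        ts = regress_nuisance(ts, np.column_stack(columns))
    dv = dvars(ts)
    n_before = ts.n_frames
    ts = scrub(ts, fd, fd_threshold_mm)
    return PreprocessResult(
        timeseries=ts,
        fd=fd,
        mean_fd=float(fd.mean()),
        n_scrubbed=n_before - ts.n_frames,
        dvars=dv,
    )
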