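"""Recording cleanup: trimming, blink masking, per-eye transform,
cycle segmentation and the trial-triggered "box trajectory" average.

Conventions: half-open sample-index intervals, 0-based indices, cycle phase
in [0, cycle_duration).  Eyes are masked jointly by default — a sample is
excluded if either eye is invalid — because conjugate metrics need
simultaneously valid pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import RawRecording, StimulusProtocol, SIDES

BLINK_MARGIN_SAMPLES = 200  # samples removed before and after each blink


@dataclass
class BlinkSet:
    """Sorted, non-overlapping half-open [start, end) sample-index ranges."""

    intervals: list[tuple[int, int]]
    n_samples: int

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.intervals:
            if not (0 <= start < end <= self.n_samples):
                raise ValueError(f"interval ({start},{end}) out of bounds")
            if start < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = end

    @property
    def n_blinks(self) -> int:
        return len(self.intervals)


@dataclass
class CleanRecording:
    """Trimmed, per-eye-centered recording with an inclusion mask.

    ``include_mask`` is False inside blinks and their margins; masked
    samples are excluded from every downstream statistic.  Coordinates are
    each eye's positions minus that eye's own center (no cross-eye mixing).
    """

    subject_id: str
    t: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    include_mask: np.ndarray
    center_left: tuple[float, float]
    center_right: tuple[float, float]

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass
class SegmentIndex:
    """Per-sample cycle number, side label index, and phase within cycle."""

    cycle: np.ndarray     # int, 0..n_cycles-1
    side: np.ndarray      # int index into side_order
    phase: np.ndarray     # seconds, [0, cycle_duration)
    side_order: tuple[str, ...]

    def side_name(self, idx: int) -> str:
        return self.side_order[idx]

    def side_mask(self, name: str) -> np.ndarray:
        return self.side == self.side_order.index(name)


@dataclass
class BoxTrajectory:
    """Across-cycle mean (x, y) per phase bin, per eye.

    Bins with zero valid contributions hold NaN coordinates and n == 0;
    they are flagged missing, never zero-filled.
    """

    phase_centers: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    left_n: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    right_n: np.ndarray
    cycle_duration: float

    @property
    def n_bins(self) -> int:
        return len(self.phase_centers)

    def bin_of_phase(self, phase: np.ndarray) -> np.ndarray:
        # epsilon snaps samples lying exactly on bin edges (float jitter)
        x = np.asarray(phase) / self.cycle_duration * self.n_bins
        idx = np.floor(x + 1e-9).astype(int)
        return np.minimum(idx, self.n_bins - 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eye, x, y, n in (("left", self.left_x, self.left_y, self.left_n),
                             ("right", self.right_x, self.right_y, self.right_n)):
            rows.append(pd.DataFrame({
                "phase_bin": np.arange(self.n_bins), "eye": eye,
                "x": x, "y": y, "n": n}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def trim(recording: RawRecording, protocol: StimulusProtocol) -> RawRecording:
    """Discard the lead-in/lead-out margins, keeping the central window.

    Timestamps are re-zeroed so the retained window starts at t = 0, which
    by protocol construction is a stimulus cycle boundary.
    """
    n_expected = protocol.n_samples
    if recording.n_samples != n_expected:
        raise ValueError(
            f"recording has {recording.n_samples} samples, protocol expects "
            f"{n_expected}")
    m = int(round(protocol.sampling_rate * protocol.trim_margin))
    sl = slice(m, n_expected - m if m else None)
    return RawRecording(
        recording.subject_id,
        recording.t[sl] - recording.t[sl][0],
        recording.left_x[sl].copy(), recording.left_y[sl].copy(),
        recording.right_x[sl].copy(), recording.right_y[sl].copy(),
        recording.valid_left[sl].copy(), recording.valid_right[sl].copy())


def detect_blinks(recording: RawRecording) -> BlinkSet:
    """Maximal runs where either eye's validity flag is False."""
    invalid = ~(recording.valid_left & recording.valid_right)
    return _runs_to_blinkset(invalid)


def _runs_to_blinkset(invalid: np.ndarray) -> BlinkSet:
    n = len(invalid)
    padded = np.concatenate(([False], invalid, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return BlinkSet(list(zip(starts.tolist(), ends.tolist())), n)


def apply_blink_margins(mask: np.ndarray, blinks: BlinkSet,
                        margin: int = BLINK_MARGIN_SAMPLES) -> np.ndarray:
    """Mask each blink interval widened by ``margin`` samples on both ends."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    out = mask.copy()
    n = len(out)
    for start, end in blinks.intervals:
        out[max(0, start - margin):min(n, end + margin)] = False
    return out


def build_include_mask(recording: RawRecording,
                       margin: int = BLINK_MARGIN_SAMPLES) -> tuple[np.ndarray, BlinkSet]:
    blinks = detect_blinks(recording)
    mask = recording.valid_left & recording.valid_right
    mask = apply_blink_margins(mask, blinks, margin)
    return mask, blinks


def transform_per_eye(recording: RawRecording, include_mask: np.ndarray,
                      statistic: str = "median") -> CleanRecording:
    """Center each eye on its own median (or mean) over included samples.

    No cross-eye information is used and the degree scale is unchanged.
    Raises if an eye contributes zero included samples.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    center = np.nanmedian if statistic == "median" else np.nanmean
    if not include_mask.any():
        raise ValueError("no included samples to center on")
    for eye, x in (("left", recording.left_x), ("right", recording.right_x)):
        if not np.isfinite(x[include_mask]).any():
            raise ValueError(f"{eye} eye has zero valid samples")

    cl = (float(center(recording.left_x[include_mask])),
          float(center(recording.left_y[include_mask])))
    cr = (float(center(recording.right_x[include_mask])),
          float(center(recording.right_y[include_mask])))
    return CleanRecording(
        subject_id=recording.subject_id,
        t=recording.t.copy(),
        left_x=recording.left_x - cl[0], left_y=recording.left_y - cl[1],
        right_x=recording.right_x - cr[0], right_y=recording.right_y - cr[1],
        include_mask=include_mask.copy(),
        center_left=cl, center_right=cr)


def segment(recording, protocol: StimulusProtocol) -> SegmentIndex:
    """Assign each trimmed sample its cycle, side, and phase within cycle."""
    t = recording.t
    if len(t) != protocol.n_trimmed_samples:
        raise ValueError("segment() expects a trimmed recording")
    # epsilon snaps samples lying exactly on cycle/side boundaries
    phase = np.mod(t, protocol.cycle_duration)
    cycle = np.floor(t / protocol.cycle_duration + 1e-9).astype(int)
    cycle = np.minimum(cycle, protocol.n_cycles - 1)
    side = np.minimum(np.floor(
        phase / protocol.side_duration + 1e-9).astype(int), 3)
    return SegmentIndex(cycle=cycle, side=side, phase=phase,
                        side_order=tuple(protocol.side_order))


def phase_average(values: np.ndarray, phase: np.ndarray, cycle_duration: float,
                  n_bins: int, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values`` per phase bin over masked-in samples.

    Returns (means, counts); bins with no contributing samples hold NaN.
    """
    bins = np.floor(np.asarray(phase) / cycle_duration * n_bins + 1e-9).astype(int)
    bins = np.minimum(bins, n_bins - 1)
    use = mask & np.isfinite(values)
    counts = np.bincount(bins[use], minlength=n_bins)
    sums = np.bincount(bins[use], weights=values[use], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def trial_triggered_average(clean: CleanRecording, segments: SegmentIndex,
                            protocol: StimulusProtocol,
                            n_bins_per_cycle: int = 2000) -> BoxTrajectory:
    """Across-cycle mean trajectory, synchronized by time of cycle start."""
    cd = protocol.cycle_duration
    lx, ln = phase_average(clean.left_x, segments.phase, cd, n_bins_per_cycle,
                           clean.include_mask)
    ly, _ = phase_average(clean.left_y, segments.phase, cd, n_bins_per_cycle,
                          clean.include_mask)
    rx, rn = phase_average(clean.right_x, segments.phase, cd, n_bins_per_cycle,
                           clean.include_mask)
    ry, _ = phase_average(clean.right_y, segments.phase, cd, n_bins_per_cycle,
                          clean.include_mask)
    centers = (np.arange(n_bins_per_cycle) + 0.5) * cd / n_bins_per_cycle
    return BoxTrajectory(phase_centers=centers,
                         left_x=lx, left_y=ly, left_n=ln,
                         right_x=rx, right_y=ry, right_n=rn,
                         cycle_duration=cd)


def preprocess_recording(recording: RawRecording, protocol: StimulusProtocol,
                         margin: int = BLINK_MARGIN_SAMPLES,
                         n_bins_per_cycle: int = 2000,
                         center_statistic: str = "median",
                         ) -> tuple[CleanRecording, SegmentIndex, BoxTrajectory, BlinkSet]:
    """Full cleanup chain: trim -> blink mask -> per-eye center -> segment -> TTA."""
    trimmed = trim(recording, protocol)
    mask, blinks = build_include_mask(trimmed, margin)
    clean = transform_per_eye(trimmed, mask, statistic=center_statistic)
    segments = segment(clean, protocol)
    trajectory = trial_triggered_average(clean, segments, protocol,
                                         n_bins_per_cycle)
    return clean, segments, trajectory, blinks
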