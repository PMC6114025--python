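"""Synthetic binocular gaze recordings for a box-pursuit stimulus.

The stimulus is an aperture circling the edges of a 4:3 monitor, one side
every ``side_duration`` seconds, repeated for ``n_cycles`` cycles, with a
lead-in/lead-out margin at each end of the recording.  Both pupils track the
aperture; cases additionally carry a slowly varying disconjugate offset on
one eye.  Every stochastic operation takes an explicit seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .cohort import SubjectRecord

SIDES = ("top", "right", "bottom", "left")

#: clockwise endpoints of each rectangle side, in units of (half-width, half-height)
_SIDE_ENDPOINTS = {
    "top": ((-1.0, +1.0), (+1.0, +1.0)),
    "right": ((+1.0, +1.0), (+1.0, -1.0)),
    "bottom": ((+1.0, -1.0), (-1.0, -1.0)),
    "left": ((-1.0, -1.0), (-1.0, +1.0)),
}

RECORDING_COLUMNS = ["t", "left_x", "left_y", "right_x", "right_y",
                     "valid_left", "valid_right"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Temporal/geometric layout of the box-pursuit stimulus.

    The pupil traverses ``horizontal_traverse`` degrees along the top and
    bottom sides and ``vertical_traverse`` degrees along the left and right
    sides.  The cycle phase is referenced to the end of the lead-in margin,
    so after trimming the recording starts exactly at a cycle boundary.
    """

    sampling_rate: float = 500.0
    total_duration: float = 220.0
    trim_margin: float = 10.0
    side_duration: float = 10.0
    n_cycles: int = 5
    horizontal_traverse: float = 34.0
    vertical_traverse: float = 23.0
    viewing_distance: float = 55.0  # cm, metadata only
    side_order: tuple[str, ...] = SIDES

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.horizontal_traverse <= 0 or self.vertical_traverse <= 0:
            raise ValueError("traverse extents must be positive")
        if sorted(self.side_order) != sorted(SIDES):
            raise ValueError(f"side_order must be a permutation of {SIDES}")
        expected = self.n_cycles * 4 * self.side_duration + 2 * self.trim_margin
        if abs(expected - self.total_duration) > 1e-9:
            raise ValueError(
                f"protocol durations inconsistent: {self.n_cycles} cycles of "
                f"{4 * self.side_duration} s plus 2x{self.trim_margin} s margin "
                f"!= {self.total_duration} s"
            )

    @property
    def cycle_duration(self) -> float:
        return 4.0 * self.side_duration

    @property
    def analyzed_duration(self) -> float:
        return self.total_duration - 2.0 * self.trim_margin

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.total_duration))

    @property
    def n_trimmed_samples(self) -> int:
        return int(round(self.sampling_rate * self.analyzed_duration))


@dataclass(frozen=True)
class SimSubjectParams:
    """Per-subject generative parameters.

    ``disconjugacy_sd`` is the standard deviation (degrees) of a slow
    additive offset process applied to the left eye only; 0 gives perfectly
    conjugate pursuit up to the white tracking noise.
    """

    group: str = "control"
    pursuit_gain: float = 1.0
    tracking_noise_sd: float = 0.0
    disconjugacy_sd: float = 0.0
    blink_rate: float = 0.0  # blinks per minute
    blink_duration_mean: float = 150.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("control", "case"):
            raise ValueError("group must be 'control' or 'case'")
        if self.tracking_noise_sd < 0 or self.disconjugacy_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be non-negative")
        if self.blink_duration_mean <= 0:
            raise ValueError("blink_duration_mean must be positive")


@dataclass
class RawRecording:
    """Binocular pupil-position time series with per-sample validity flags.

    Coordinates are degrees of visual angle relative to screen center;
    invalid samples (blinks, track loss) hold NaN coordinates.
    """

    subject_id: str
    t: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("left_x", "left_y", "right_x", "right_y",
                     "valid_left", "valid_right"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in field {name}")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.subject_id, *(getattr(self, f).copy() for f in
                               ("t", "left_x", "left_y", "right_x", "right_y",
                                "valid_left", "valid_right")))


def stimulus_position(protocol: StimulusProtocol, t):
    """Aperture center position (degrees) at time(s) ``t``.

    Piecewise-linear clockwise rectangular path with period
    ``4 * side_duration``; the phase origin sits at the end of the lead-in
    margin so trimmed recordings start at a cycle boundary.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0) or np.any(t > protocol.total_duration):
        raise ValueError("t outside the recording window")

    phase = np.mod(t - protocol.trim_margin, protocol.cycle_duration)
    seg = np.minimum((phase // protocol.side_duration).astype(int), 3)
    frac = phase / protocol.side_duration - seg

    hw = protocol.horizontal_traverse / 2.0
    hh = protocol.vertical_traverse / 2.0
    starts = np.empty((4, 2))
    ends = np.empty((4, 2))
    for i, side in enumerate(protocol.side_order):
        (sx, sy), (ex, ey) = _SIDE_ENDPOINTS[side]
        starts[i] = (sx * hw, sy * hh)
        ends[i] = (ex * hw, ey * hh)

    x = starts[seg, 0] + frac * (ends[seg, 0] - starts[seg, 0])
    y = starts[seg, 1] + frac * (ends[seg, 1] - starts[seg, 1])
    if scalar:
        return float(x[0]), float(y[0])
    return x, y


def _slow_offset(n: int, sd: float, rate: float, rng: np.random.Generator,
                 cutoff_hz: float = 0.5) -> np.ndarray:
    """Gaussian random walk low-passed to ~cutoff_hz, rescaled to SD=sd."""
    if sd == 0.0:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    nyq = rate / 2.0
    if cutoff_hz < nyq:
        b, a = signal.butter(2, cutoff_hz / nyq)
        walk = signal.filtfilt(b, a, walk)
    s = walk.std()
    if s == 0.0:
        return np.zeros(n)
    return walk / s * sd


def simulate_recording(params: SimSubjectParams, protocol: StimulusProtocol,
                       subject_id: str = "sim") -> RawRecording:
    """Simulate one binocular recording of the full stimulus protocol.

    Each eye's trace is ``pursuit_gain * stimulus + white noise``; the left
    eye additionally carries the slow disconjugate offset.  Blinks are
    Poisson events that flag both eyes invalid and blank the coordinates.
    Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = protocol.n_samples
    t = np.arange(n) / protocol.sampling_rate
    sx, sy = stimulus_position(protocol, t)

    g = params.pursuit_gain
    noise = params.tracking_noise_sd
    left_x = g * sx + noise * rng.standard_normal(n)
    left_y = g * sy + noise * rng.standard_normal(n)
    right_x = g * sx + noise * rng.standard_normal(n)
    right_y = g * sy + noise * rng.standard_normal(n)

    left_x += _slow_offset(n, params.disconjugacy_sd, protocol.sampling_rate, rng)
    left_y += _slow_offset(n, params.disconjugacy_sd, protocol.sampling_rate, rng)

    valid = np.ones(n, dtype=bool)
    expected_blinks = params.blink_rate * protocol.total_duration / 60.0
    n_blinks = rng.poisson(expected_blinks) if expected_blinks > 0 else 0
    for _ in range(n_blinks):
        start = rng.integers(0, n)
        dur_s = rng.exponential(params.blink_duration_mean / 1000.0)
        length = max(1, int(round(dur_s * protocol.sampling_rate)))
        valid[start:start + length] = False

    for arr in (left_x, left_y, right_x, right_y):
        arr[~valid] = np.nan

    return RawRecording(subject_id, t, left_x, left_y, right_x, right_y,
                        valid.copy(), valid.copy())


# default generative profiles; case effect sizes are tunable, not literature-derived
DEFAULT_CONTROL_PARAMS = SimSubjectParams(
    group="control", pursuit_gain=1.0, tracking_noise_sd=0.5,
    disconjugacy_sd=0.0, blink_rate=12.0, blink_duration_mean=150.0)
DEFAULT_CASE_PARAMS = SimSubjectParams(
    group="case", pursuit_gain=1.0, tracking_noise_sd=0.5,
    disconjugacy_sd=1.5, blink_rate=15.0, blink_duration_mean=150.0)


def simulate_cohort(n_control: int, n_case: int,
                    control_params: SimSubjectParams = DEFAULT_CONTROL_PARAMS,
                    case_params: SimSubjectParams = DEFAULT_CASE_PARAMS,
                    protocol: StimulusProtocol | None = None,
                    age_range: tuple[int, int] = (18, 60),
                    sex_ratio: float = 0.5,
                    ct_positive_fraction: float = 0.0,
                    jitter: float = 0.15,
                    master_seed: int = 0,
                    ) -> tuple[list[SubjectRecord], list[RawRecording]]:
    """Simulate a labeled cohort of recordings.

    Cases receive SCAT3 SSS > 40 and SAC <= 24 so that the concussion
    labeling rule recovers the generative groups; a ``ct_positive_fraction``
    of cases may be flagged CT-positive.  Per-subject seeds derive from
    ``master_seed`` so the whole cohort is reproducible.  ``jitter`` is the
    log-SD of a lognormal multiplier on per-subject noise amplitudes.
    """
    if n_control < 0 or n_case < 0:
        raise ValueError("cohort sizes must be non-negative")
    if n_control + n_case == 0:
        raise ValueError("cohort must contain at least one subject")
    protocol = protocol or StimulusProtocol()

    ss = np.random.SeedSequence(master_seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.generate_state(n_control + n_case + 1)[1:]

    records: list[SubjectRecord] = []
    recordings: list[RawRecording] = []
    groups = ["control"] * n_control + ["case"] * n_case
    for i, grp in enumerate(groups):
        sid = f"{'ctl' if grp == 'control' else 'cas'}{i:04d}"
        base = control_params if grp == "control" else case_params
        mult = float(np.exp(jitter * meta_rng.standard_normal())) if jitter else 1.0
        params = dataclasses.replace(
            base, group=grp, seed=int(subject_seeds[i]),
            tracking_noise_sd=base.tracking_noise_sd * mult,
            disconjugacy_sd=base.disconjugacy_sd * mult)

        age = int(meta_rng.integers(age_range[0], age_range[1] + 1))
        sex = "male" if meta_rng.random() < sex_ratio else "female"
        if grp == "case":
            sss = int(meta_rng.integers(41, 101))
            sac = int(meta_rng.integers(10, 25))
            ct = ("positive" if meta_rng.random() < ct_positive_fraction
                  else "negative")
        else:
            sss = int(meta_rng.integers(0, 21))
            sac = int(meta_rng.integers(25, 31))
            ct = "none"
        records.append(SubjectRecord(subject_id=sid, age=age, sex=sex,
                                     group=grp if grp == "control" else "trauma",
                                     ct_status=ct, sss=sss, sac=sac))
        recordings.append(simulate_recording(params, protocol, subject_id=sid))
    return records, recordings


def write_recording_csv(recording: RawRecording, path) -> None:
    """Write the delimited-text recording dialect (empty fields for NaN)."""
    df = pd.DataFrame({
        "t": recording.t,
        "left_x": recording.left_x, "left_y": recording.left_y,
        "right_x": recording.right_x, "right_y": recording.right_y,
        "valid_left": recording.valid_left.astype(int),
        "valid_right": recording.valid_right.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path, subject_id: str | None = None) -> RawRecording:
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"recording file missing columns: {missing}")
    if subject_id is None:
        subject_id = str(path)
    return RawRecording(
        subject_id=subject_id,
        t=df["t"].to_numpy(float),
        left_x=df["left_x"].to_numpy(float),
        left_y=df["left_y"].to_numpy(float),
        right_x=df["right_x"].to_numpy(float),
        right_y=df["right_y"].to_numpy(float),
        valid_left=df["valid_left"].to_numpy().astype(bool),
        valid_right=df["valid_right"].to_numpy().astype(bool),
    )
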