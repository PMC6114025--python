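"""The 89 named eye-tracking measures: 32 left-eye, 32 right-eye, 25 conjugate.

Naming grammar: ``{left|right|conj}_{measure}{Side?}_value`` with side
suffixes Top/Bot/Lef/Rit for distance/velocity measures and top/bot/lef/rit
for variance measures; no suffix means the whole-recording total.

Per-eye roster (32): height/width/area/aspectRatio in mean and median
variants (8), distance and velocity per side + totals (10), varX/varY per
side + totals (10), totVar, varAspect, nblinks, blinkrate.

Conjugate roster (25): varX/varY per side + totals (10), totVar, varAspect,
four BOX composite scores, left-minus-right distance differences per side +
total (5), and velocity differences per side (4).

The BOX scores are composite conjugacy scores: means of z-scored conjugate
variance measures, where the z-scoring reference population is the control
group of the dataset at hand (documented reconstruction — the exact
composites are not public).
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .preprocess import (BLINK_MARGIN_SAMPLES, BlinkSet, BoxTrajectory,
                         CleanRecording, SegmentIndex, preprocess_recording)
from .synth import RawRecording, StimulusProtocol

# side suffixes: capitalized for path measures, lowercase for variance measures
_DIST_SIDES = {"top": "Top", "bottom": "Bot", "left": "Lef", "right": "Rit"}
_VAR_SIDES = {"top": "top", "bottom": "bot", "left": "lef", "right": "rit"}
_SIDE_KEYS = ("top", "bottom", "left", "right")

PER_EYE_MEASURES: tuple[str, ...] = (
    "heightmean", "heightmedian", "widthmean", "widthmedian",
    "areamean", "areamedian", "aspectRatiomean", "aspectRatiomedian",
    "distTop", "distBot", "distLef", "distRit", "dist",
    "velTop", "velBot", "velLef", "velRit", "vel",
    "varXtop", "varXbot", "varXlef", "varXrit", "varX",
    "varYtop", "varYbot", "varYlef", "varYrit", "varY",
    "totVar", "varAspect", "nblinks", "blinkrate",
)

CONJ_MEASURES: tuple[str, ...] = (
    "varXtop", "varXbot", "varXlef", "varXrit", "varX",
    "varYtop", "varYbot", "varYlef", "varYrit", "varY",
    "totVar", "varAspect",
    "boxscore", "boxscore2", "boxscore3", "boxscore5",
    "distDiffTop", "distDiffBot", "distDiffLef", "distDiffRit", "distDiff",
    "velDiffTop", "velDiffBot", "velDiffLef", "velDiffRit",
)

BOXSCORE_CONSTITUENTS: dict[str, tuple[str, ...]] = {
    "conj_boxscore_value": ("conj_varX_value", "conj_varY_value",
                            "conj_varAspect_value"),
    "conj_boxscore2_value": ("conj_varX_value", "conj_varY_value"),
    "conj_boxscore3_value": ("conj_varX_value", "conj_varY_value",
                             "conj_totVar_value"),
    "conj_boxscore5_value": ("conj_varXtop_value", "conj_varXbot_value",
                             "conj_varXlef_value", "conj_varXrit_value",
                             "conj_varAspect_value"),
}
BOXSCORE_NAMES = tuple(BOXSCORE_CONSTITUENTS)


def metric_names() -> list[str]:
    """The full ordered roster of 89 metric names."""
    names = [f"left_{m}_value" for m in PER_EYE_MEASURES]
    names += [f"right_{m}_value" for m in PER_EYE_MEASURES]
    names += [f"conj_{m}_value" for m in CONJ_MEASURES]
    return names

METRIC_NAMES = metric_names()
assert len(METRIC_NAMES) == 89


def _var(x: np.ndarray) -> float:
    """Unbiased sample variance; NaN with fewer than 2 values."""
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return math.nan
    return float(np.var(x, ddof=1))


def _side_masks(segments: SegmentIndex) -> dict[str, np.ndarray]:
    return {k: segments.side_mask(k) for k in _SIDE_KEYS}


def _eye_arrays(clean: CleanRecording, eye: str) -> tuple[np.ndarray, np.ndarray]:
    return ((clean.left_x, clean.left_y) if eye == "left"
            else (clean.right_x, clean.right_y))


def _geometry_stats(x, y, masks, include, kind) -> dict[str, float]:
    stat = np.nanmean if kind == "mean" else np.nanmedian

    def side_stat(values, side):
        sel = values[masks[side] & include]
        sel = sel[np.isfinite(sel)]
        return float(stat(sel)) if len(sel) else math.nan

    width = side_stat(x, "right") - side_stat(x, "left")
    height = side_stat(y, "top") - side_stat(y, "bottom")
    area = height * width
    aspect = height / width if width != 0 else math.nan
    suffix = "mean" if kind == "mean" else "median"
    return {f"height{suffix}": height, f"width{suffix}": width,
            f"area{suffix}": area, f"aspectRatio{suffix}": aspect}


def box_geometry(clean: CleanRecording, segments: SegmentIndex) -> dict[str, dict[str, float]]:
    """Per-eye box height, width, area, aspect ratio (mean & median variants).

    width = central tendency of x over right-side samples minus left-side
    samples; height likewise from top/bottom; area = height*width;
    aspect ratio = height/width (missing when width is 0).
    """
    masks = _side_masks(segments)
    out = {}
    for eye in ("left", "right"):
        x, y = _eye_arrays(clean, eye)
        vals = {}
        vals.update(_geometry_stats(x, y, masks, clean.include_mask, "mean"))
        vals.update(_geometry_stats(x, y, masks, clean.include_mask, "median"))
        out[eye] = vals
    return out


def _per_cycle_aspect(x, y, segments, include, n_cycles) -> np.ndarray:
    """Aspect ratio of each cycle's box, from per-cycle side means."""
    out = np.full(n_cycles, np.nan)
    masks = _side_masks(segments)
    for c in range(n_cycles):
        in_cycle = (segments.cycle == c) & include

        def m(values, side):
            sel = values[masks[side] & in_cycle]
            sel = sel[np.isfinite(sel)]
            return float(np.mean(sel)) if len(sel) else math.nan

        width = m(x, "right") - m(x, "left")
        height = m(y, "top") - m(y, "bottom")
        if math.isfinite(width) and width != 0 and math.isfinite(height):
            out[c] = height / width
    return out


def segment_distance_velocity(clean: CleanRecording, segments: SegmentIndex,
                              sampling_rate: float) -> dict[str, dict[str, float]]:
    """Per-eye path distance and velocity per side and in total.

    Distance sums Euclidean steps between consecutive valid samples within
    the same side and cycle; velocity divides by the valid time in that
    side.  A side with fewer than 2 valid samples yields missing values.
    """
    out = {}
    for eye in ("left", "right"):
        x, y = _eye_arrays(clean, eye)
        finite = np.isfinite(x) & np.isfinite(y)
        ok = clean.include_mask & finite
        # a step i -> i+1 counts when both ends are usable and share side+cycle
        pair_ok = (ok[:-1] & ok[1:]
                   & (segments.side[:-1] == segments.side[1:])
                   & (segments.cycle[:-1] == segments.cycle[1:]))
        steps = np.hypot(np.diff(x), np.diff(y))
        vals: dict[str, float] = {}
        total_dist = 0.0
        total_time = 0.0
        any_missing = False
        for side_key, suffix in _DIST_SIDES.items():
            side_pair = pair_ok & (segments.side[:-1] == segments.side_order.index(side_key))
            n_valid = int(np.sum(ok & segments.side_mask(side_key)))
            if n_valid < 2:
                vals[f"dist{suffix}"] = math.nan
                vals[f"vel{suffix}"] = math.nan
                any_missing = True
                continue
            d = float(np.sum(steps[side_pair]))
            t_valid = n_valid / sampling_rate
            vals[f"dist{suffix}"] = d
            vals[f"vel{suffix}"] = d / t_valid
            total_dist += d
            total_time += t_valid
        vals["dist"] = math.nan if any_missing else total_dist
        vals["vel"] = (math.nan if (any_missing or total_time == 0)
                       else total_dist / total_time)
        out[eye] = vals
    return out


def variance_metrics(clean: CleanRecording, trajectory: BoxTrajectory,
                     segments: SegmentIndex, n_cycles: int,
                     per_eye_mode: str = "residual") -> dict[str, dict[str, float]]:
    """Positional variance measures, per eye and conjugate.

    Per-eye varX/varY are variances of the deviation from the
    trial-triggered mean at the same cycle phase (``residual`` mode), so
    the pursuit structure itself is not counted as noise; ``raw`` mode uses
    the plain within-side variance.  Conjugate var* are variances of the
    left-minus-right difference over simultaneously valid pairs; totVar =
    varX + varY; varAspect is the across-cycle variance of the left-right
    aspect-ratio difference.
    """
    if per_eye_mode not in ("residual", "raw"):
        raise ValueError("per_eye_mode must be 'residual' or 'raw'")
    masks = _side_masks(segments)
    include = clean.include_mask
    bins = trajectory.bin_of_phase(segments.phase)

    out: dict[str, dict[str, float]] = {"left": {}, "right": {}, "conj": {}}
    tta = {"left": (trajectory.left_x, trajectory.left_y),
           "right": (trajectory.right_x, trajectory.right_y)}
    aspects = {}
    for eye in ("left", "right"):
        x, y = _eye_arrays(clean, eye)
        if per_eye_mode == "residual":
            dev_x = x - tta[eye][0][bins]
            dev_y = y - tta[eye][1][bins]
        else:
            dev_x, dev_y = x, y
        for side_key, suffix in _VAR_SIDES.items():
            sel = masks[side_key] & include
            out[eye][f"varX{suffix}"] = _var(dev_x[sel])
            out[eye][f"varY{suffix}"] = _var(dev_y[sel])
        out[eye]["varX"] = _var(dev_x[include])
        out[eye]["varY"] = _var(dev_y[include])
        out[eye]["totVar"] = out[eye]["varX"] + out[eye]["varY"]
        aspects[eye] = _per_cycle_aspect(x, y, segments, include, n_cycles)
        out[eye]["varAspect"] = _var(aspects[eye])

    dx = clean.left_x - clean.right_x
    dy = clean.left_y - clean.right_y
    for side_key, suffix in _VAR_SIDES.items():
        sel = masks[side_key] & include
        out["conj"][f"varX{suffix}"] = _var(dx[sel])
        out["conj"][f"varY{suffix}"] = _var(dy[sel])
    out["conj"]["varX"] = _var(dx[include])
    out["conj"]["varY"] = _var(dy[include])
    out["conj"]["totVar"] = out["conj"]["varX"] + out["conj"]["varY"]
    out["conj"]["varAspect"] = _var(aspects["left"] - aspects["right"])
    return out


def blink_metrics(blinks: BlinkSet, analyzed_duration: float) -> dict[str, float]:
    """Blink count and per-minute rate over the analyzed window."""
    if analyzed_duration <= 0:
        raise ValueError("analyzed_duration must be positive")
    n = blinks.n_blinks
    return {"nblinks": float(n), "blinkrate": n / (analyzed_duration / 60.0)}


def box_scores(vector: dict[str, float],
               reference: dict[str, tuple[float, float]] | None) -> dict[str, float]:
    """BOX composite scores: means of z-scored conjugate variance measures.

    ``reference`` maps constituent name -> (mean, sd) of the z-scoring
    population (by convention the control group).  Without a reference the
    scores are missing.  A zero-sd constituent contributes z = 0.
    """
    out = {}
    for score, constituents in BOXSCORE_CONSTITUENTS.items():
        if reference is None:
            out[score] = math.nan
            continue
        zs = []
        for c in constituents:
            v = vector.get(c, math.nan)
            if not math.isfinite(v) or c not in reference:
                zs = None
                break
            mean, sd = reference[c]
            zs.append((v - mean) / sd if sd > 0 else 0.0)
        out[score] = float(np.mean(zs)) if zs else math.nan
    return out


def boxscore_reference(control_table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """(mean, sd) of every box-score constituent over a control metric table."""
    needed = sorted({c for cs in BOXSCORE_CONSTITUENTS.values() for c in cs})
    ref = {}
    for c in needed:
        vals = control_table[c].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        ref[c] = (float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
    return ref


def compute_metric_vector(recording: RawRecording, protocol: StimulusProtocol,
                          reference: dict[str, tuple[float, float]] | None = None,
                          margin: int = BLINK_MARGIN_SAMPLES,
                          n_bins_per_cycle: int = 2000,
                          per_eye_var_mode: str = "residual") -> dict[str, float]:
    """All 89 metrics for one recording, keyed by their registry names.

    BOX scores need a cohort-level z-scoring ``reference``; without one they
    are present but missing (NaN).  Deterministic for fixed input.
    """
    clean, segments, trajectory, blinks = preprocess_recording(
        recording, protocol, margin=margin, n_bins_per_cycle=n_bins_per_cycle)

    geometry = box_geometry(clean, segments)
    distvel = segment_distance_velocity(clean, segments, protocol.sampling_rate)
    variances = variance_metrics(clean, trajectory, segments,
                                 protocol.n_cycles, per_eye_var_mode)
    blink = blink_metrics(blinks, protocol.analyzed_duration)

    vector: dict[str, float] = {}
    for eye in ("left", "right"):
        merged = {**geometry[eye], **distvel[eye], **variances[eye], **blink}
        for m in PER_EYE_MEASURES:
            vector[f"{eye}_{m}_value"] = merged[m]

    conj = dict(variances["conj"])
    for side_key, suffix in _DIST_SIDES.items():
        conj[f"distDiff{suffix}"] = (distvel["left"][f"dist{suffix}"]
                                     - distvel["right"][f"dist{suffix}"])
        conj[f"velDiff{suffix}"] = (distvel["left"][f"vel{suffix}"]
                                    - distvel["right"][f"vel{suffix}"])
    conj["distDiff"] = distvel["left"]["dist"] - distvel["right"]["dist"]

    for m in CONJ_MEASURES:
        if m.startswith("boxscore"):
            continue
        vector[f"conj_{m}_value"] = conj[m]
    vector.update(box_scores(vector, reference))

    assert set(vector) == set(METRIC_NAMES)
    return {name: vector[name] for name in METRIC_NAMES}


def compute_metric_table(recordings: Iterable[RawRecording],
                         protocol: StimulusProtocol,
                         control_ids: Iterable[str] | None = None,
                         **kwargs) -> pd.DataFrame:
    """Metric table (one row per subject) with cohort-referenced BOX scores.

    ``control_ids`` names the z-scoring reference subjects; when given, the
    four BOX score columns are filled for every row from the control-group
    means/SDs of their constituents.
    """
    rows = {}
    for rec in recordings:
        rows[rec.subject_id] = compute_metric_vector(rec, protocol, **kwargs)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    table = table[METRIC_NAMES]
    if control_ids is not None:
        ref = boxscore_reference(table.loc[list(control_ids)])
        for sid in table.index:
            scores = box_scores(table.loc[sid].to_dict(), ref)
            for k, v in scores.items():
                table.loc[sid, k] = v
    return table


def write_metric_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_metric_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="subject_id")
    missing = [c for c in METRIC_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"metric table missing columns: {missing[:5]}...")
    return table
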