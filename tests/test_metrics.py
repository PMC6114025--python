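import math

import numpy as np
import pandas as pd
import pytest

from oculobox import (METRIC_NAMES, SimSubjectParams, compute_metric_table,
                      compute_metric_vector, simulate_cohort,
                      simulate_recording)
from oculobox.metrics import (BOXSCORE_CONSTITUENTS, box_scores,
                              boxscore_reference)

from conftest import make_recording

# every metric name printed in the published candidate/contrast tables
PUBLISHED_NAMES = [
    "left_areamean_value", "left_areamedian_value", "left_blinkrate_value",
    "left_distBot_value", "left_distLef_value", "left_distRit_value",
    "left_distTop_value", "left_nblinks_value", "left_varYbot_value",
    "left_varYtop_value", "left_widthmean_value", "left_widthmedian_value",
    "right_areamedian_value", "right_aspectRatiomean_value",
    "right_aspectRatiomedian_value", "right_blinkrate_value",
    "right_distBot_value", "right_distLef_value", "right_distRit_value",
    "right_distTop_value", "right_nblinks_value", "right_varXrit_value",
    "right_varYtop_value", "right_widthmean_value", "right_widthmedian_value",
    "conj_boxscore_value", "conj_boxscore2_value", "conj_boxscore3_value",
    "conj_boxscore5_value", "conj_totVar_value", "conj_varAspect_value",
    "conj_varX_value", "conj_varXbot_value", "conj_varXlef_value",
    "conj_varXrit_value", "conj_varXtop_value", "conj_varY_value",
    "conj_varYbot_value", "conj_varYlef_value", "conj_varYrit_value",
    "conj_varYtop_value",
]


@pytest.fixture(scope="module")
def noiseless_vector(protocol, noiseless_recording):
    return compute_metric_vector(noiseless_recording, protocol)


@pytest.fixture(scope="module")
def noisy_vector(protocol, noisy_recording):
    return compute_metric_vector(noisy_recording, protocol)


class TestRegistry:
    def test_total_count(self):
        assert len(METRIC_NAMES) == 89

    def test_left_right_conj_split(self):
        assert sum(n.startswith("left_") for n in METRIC_NAMES) == 32
        assert sum(n.startswith("right_") for n in METRIC_NAMES) == 32
        assert sum(n.startswith("conj_") for n in METRIC_NAMES) == 25

    def test_published_names_all_resolve(self):
        missing = set(PUBLISHED_NAMES) - set(METRIC_NAMES)
        assert not missing

    def test_naming_grammar(self):
        for name in METRIC_NAMES:
            prefix, rest = name.split("_", 1)
            assert prefix in ("left", "right", "conj")
            assert rest.endswith("_value")


class TestBoxGeometry:
    def test_noiseless_extents(self, noiseless_vector):
        v = noiseless_vector
        for eye in ("left", "right"):
            assert v[f"{eye}_widthmean_value"] == pytest.approx(34.0, abs=1e-6)
            assert v[f"{eye}_heightmean_value"] == pytest.approx(23.0, abs=1e-6)
            assert v[f"{eye}_widthmedian_value"] == pytest.approx(34.0, abs=1e-6)
            assert v[f"{eye}_aspectRatiomean_value"] == pytest.approx(
                23.0 / 34.0, rel=1e-6)
            assert v[f"{eye}_areamean_value"] == pytest.approx(
                34.0 * 23.0, rel=1e-6)

    def test_aspect_one_when_square(self, fast_protocol):
        import dataclasses
        p = dataclasses.replace(fast_protocol, vertical_traverse=34.0)
        rec = simulate_recording(SimSubjectParams(seed=0), p)
        v = compute_metric_vector(rec, p)
        assert v["left_aspectRatiomean_value"] == pytest.approx(1.0, abs=1e-9)

    def test_area_is_height_times_width(self, noisy_vector):
        v = noisy_vector
        assert v["left_areamean_value"] == pytest.approx(
            v["left_heightmean_value"] * v["left_widthmean_value"])


class TestDistanceVelocity:
    def test_noiseless_top_traverse(self, noiseless_vector):
        # 34 degrees per 10 s side, 5 cycles
        assert noiseless_vector["left_distTop_value"] == pytest.approx(
            5 * 34.0, rel=1e-3)
        assert noiseless_vector["left_velTop_value"] == pytest.approx(
            3.4, rel=1e-3)
        assert noiseless_vector["right_distLef_value"] == pytest.approx(
            5 * 23.0, rel=1e-3)
        assert noiseless_vector["left_dist_value"] == pytest.approx(
            5 * 114.0, rel=1e-3)

    def test_stationary_gaze_zero_distance(self, fast_protocol):
        n = fast_protocol.n_samples
        rec = make_recording(fast_protocol, *[np.zeros(n)] * 4)
        v = compute_metric_vector(rec, fast_protocol)
        for side in ("Top", "Bot", "Lef", "Rit"):
            assert v[f"left_dist{side}_value"] == 0.0

    def test_scaling_doubles_distance(self, fast_protocol):
        rec = simulate_recording(
            SimSubjectParams(seed=5, tracking_noise_sd=0.3), fast_protocol)
        doubled = rec.copy()
        for arr in (doubled.left_x, doubled.left_y,
                    doubled.right_x, doubled.right_y):
            arr *= 2.0
        v1 = compute_metric_vector(rec, fast_protocol)
        v2 = compute_metric_vector(doubled, fast_protocol)
        assert v2["left_dist_value"] == pytest.approx(
            2 * v1["left_dist_value"], rel=1e-9)


class TestVarianceMetrics:
    def test_conjugate_zero_when_identical(self, noiseless_vector):
        for name in METRIC_NAMES:
            if name.startswith("conj_var") or name == "conj_totVar_value":
                assert noiseless_vector[name] == pytest.approx(0.0, abs=1e-12)

    def test_injected_offset_variance_recovered(self, protocol):
        """left = right + N(0, sigma^2) i.i.d. -> conj_varX ~= sigma^2."""
        sigma = 0.3
        base = simulate_recording(SimSubjectParams(seed=0), protocol)
        rng = np.random.default_rng(42)
        rec = base.copy()
        rec.left_x = rec.right_x + sigma * rng.standard_normal(rec.n_samples)
        v = compute_metric_vector(rec, protocol)
        assert v["conj_varX_value"] == pytest.approx(sigma ** 2, rel=0.05)

    def test_totvar_is_varx_plus_vary(self, noisy_vector):
        assert noisy_vector["conj_totVar_value"] == pytest.approx(
            noisy_vector["conj_varX_value"] + noisy_vector["conj_varY_value"])
        assert noisy_vector["left_totVar_value"] == pytest.approx(
            noisy_vector["left_varX_value"] + noisy_vector["left_varY_value"])

    def test_translation_invariance(self, fast_protocol):
        """A constant offset on both eyes changes no metric (centering)."""
        rec = simulate_recording(
            SimSubjectParams(seed=6, tracking_noise_sd=0.4,
                             disconjugacy_sd=0.5), fast_protocol)
        shifted = rec.copy()
        for arr in (shifted.left_x, shifted.left_y,
                    shifted.right_x, shifted.right_y):
            arr += 3.0
        v1 = compute_metric_vector(rec, fast_protocol)
        v2 = compute_metric_vector(shifted, fast_protocol)
        for name in METRIC_NAMES:
            if name.endswith(("boxscore_value", "boxscore2_value",
                              "boxscore3_value", "boxscore5_value")):
                continue
            assert v2[name] == pytest.approx(v1[name], rel=1e-8, abs=1e-10), name

    def test_scale_equivariance(self, fast_protocol):
        """Coordinates x c: distances x c, variances x c^2."""
        c = 3.0
        rec = simulate_recording(
            SimSubjectParams(seed=9, tracking_noise_sd=0.4,
                             disconjugacy_sd=0.5), fast_protocol)
        scaled = rec.copy()
        for arr in (scaled.left_x, scaled.left_y,
                    scaled.right_x, scaled.right_y):
            arr *= c
        v1 = compute_metric_vector(rec, fast_protocol)
        v2 = compute_metric_vector(scaled, fast_protocol)
        assert v2["left_dist_value"] == pytest.approx(
            c * v1["left_dist_value"], rel=1e-9)
        assert v2["conj_varX_value"] == pytest.approx(
            c ** 2 * v1["conj_varX_value"], rel=1e-9)
        assert v2["left_varYtop_value"] == pytest.approx(
            c ** 2 * v1["left_varYtop_value"], rel=1e-9)
        # aspect ratio is scale-free
        assert v2["left_aspectRatiomean_value"] == pytest.approx(
            v1["left_aspectRatiomean_value"], rel=1e-9)


class TestBlinkMetrics:
    def test_no_blinks(self, noiseless_vector):
        assert noiseless_vector["left_nblinks_value"] == 0.0
        assert noiseless_vector["left_blinkrate_value"] == 0.0

    def test_rate_arithmetic(self):
        from oculobox.metrics import blink_metrics
        from oculobox.preprocess import BlinkSet
        blinks = BlinkSet([(i * 1000, i * 1000 + 10) for i in range(10)],
                          100_000)
        out = blink_metrics(blinks, 200.0)
        assert out["nblinks"] == 10
        assert out["blinkrate"] == pytest.approx(3.0)

    def test_left_right_equal_under_joint_masking(self, noisy_vector):
        assert (noisy_vector["left_nblinks_value"]
                == noisy_vector["right_nblinks_value"])
        assert (noisy_vector["left_blinkrate_value"]
                == noisy_vector["right_blinkrate_value"])


class TestBoxScores:
    REF = {c: (0.0, 1.0)
           for cs in BOXSCORE_CONSTITUENTS.values() for c in cs}

    def test_zero_input_baseline(self):
        vec = {c: 0.0 for c in self.REF}
        scores = box_scores(vec, self.REF)
        for name in scores:
            assert scores[name] == 0.0

    def test_monotone_in_constituents(self):
        lo = {c: 1.0 for c in self.REF}
        hi = {c: 2.0 for c in self.REF}
        s_lo = box_scores(lo, self.REF)
        s_hi = box_scores(hi, self.REF)
        for name in s_lo:
            assert s_hi[name] > s_lo[name]

    def test_missing_constituent_propagates(self):
        vec = {c: 1.0 for c in self.REF}
        vec["conj_varAspect_value"] = math.nan
        scores = box_scores(vec, self.REF)
        assert math.isnan(scores["conj_boxscore_value"])
        assert math.isfinite(scores["conj_boxscore2_value"])

    def test_no_reference_gives_missing(self, noisy_vector):
        for name in BOXSCORE_CONSTITUENTS:
            assert math.isnan(noisy_vector[name])

    def test_pairwise_correlation_on_cohort(self, fast_protocol):
        """The four composite scores are mutually correlated (> 0.8)."""
        records, recordings = simulate_cohort(
            25, 25, protocol=fast_protocol, master_seed=77)
        controls = [r.subject_id for r in records if r.group == "control"]
        table = compute_metric_table(recordings, fast_protocol,
                                     control_ids=controls)
        scores = table[list(BOXSCORE_CONSTITUENTS)]
        corr = scores.corr(method="spearman").to_numpy()
        assert corr[np.triu_indices(4, 1)].min() > 0.8


class TestMetricTable:
    def test_vector_has_89_entries(self, noisy_vector):
        assert len(noisy_vector) == 89
        assert list(noisy_vector) == METRIC_NAMES

    def test_symmetric_recording_symmetric_metrics(self, protocol,
                                                   noiseless_recording):
        v = compute_metric_vector(noiseless_recording, protocol)
        for m in ("widthmean", "heightmedian", "areamean", "aspectRatiomean",
                  "distTop", "velBot", "varXtop"):
            assert v[f"left_{m}_value"] == pytest.approx(
                v[f"right_{m}_value"], abs=1e-9)

    def test_deterministic(self, fast_protocol):
        rec = simulate_recording(
            SimSubjectParams(seed=12, tracking_noise_sd=0.5, blink_rate=10.0),
            fast_protocol)
        v1 = compute_metric_vector(rec, fast_protocol)
        v2 = compute_metric_vector(rec, fast_protocol)
        for name in METRIC_NAMES:
            assert (v1[name] == v2[name]
                    or (math.isnan(v1[name]) and math.isnan(v2[name])))

    def test_table_boxscores_referenced_to_controls(self, fast_protocol):
        records, recordings = simulate_cohort(6, 6, protocol=fast_protocol,
                                              master_seed=3)
        controls = [r.subject_id for r in records if r.group == "control"]
        table = compute_metric_table(recordings, fast_protocol,
                                     control_ids=controls)
        assert table.shape == (12, 89)
        ref = boxscore_reference(table.loc[controls])
        sid = table.index[0]
        expected = box_scores(table.loc[sid].to_dict(), ref)
        assert table.loc[sid, "conj_boxscore_value"] == pytest.approx(
            expected["conj_boxscore_value"])

    def test_tsv_roundtrip(self, fast_protocol, tmp_path):
        from oculobox.metrics import read_metric_table, write_metric_table
        records, recordings = simulate_cohort(3, 3, protocol=fast_protocol,
                                              master_seed=4)
        table = compute_metric_table(
            recordings, fast_protocol,
            control_ids=[r.subject_id for r in records
                         if r.group == "control"])
        path = tmp_path / "metrics.tsv"
        write_metric_table(table, path)
        back = read_metric_table(path)
        pd.testing.assert_frame_equal(back, table)
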