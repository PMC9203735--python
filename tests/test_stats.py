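"""Tests of edge-wise group statistics, BH-FDR, edge frequency maps, and the
clinical-score correlation."""

import numpy as np
import pytest

from effconn.gca import EdgeMatrix
from effconn.stats import (
    StudyRecord,
    StudyTable,
    bh_fdr,
    edge_frequency,
    edge_score_correlation,
    independent_t_edges,
    one_sample_edges,
    paired_t_edges,
)


def make_table(values_by_record):
    """values_by_record: list of (sid, group, session, N x N array, scores)."""
    records = []
    for sid, group, session, vals, scores in values_by_record:
        records.append(StudyRecord(
            subject_id=sid, group=group, session=session,
            edges=EdgeMatrix(np.asarray(vals, float)), scores=scores or {},
        ))
    return StudyTable(records)


def random_table(rng, n_pat=8, n_con=8, n=3, effect=None):
    recs = []
    for g, count in (("patient", n_pat), ("control", n_con)):
        for k in range(count):
            sid = f"{g}{k}"
            for sess in ("before", "after"):
                vals = 0.3 + 0.05 * rng.standard_normal((n, n))
                if effect:
                    vals = effect(vals, g, sess)
                recs.append((sid, g, sess, vals, None))
    return make_table(recs)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        adjusted, flags = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.5], atol=1e-12)
        np.testing.assert_array_equal(flags, [True, True, True, False])

    def test_all_ones_flag_nothing(self):
        _, flags = bh_fdr(np.ones(10))
        assert not flags.any()

    def test_null_uniform_fdr_controlled(self):
        rng = np.random.default_rng(0)
        false_disc = 0
        for _ in range(1000):
            _, flags = bh_fdr(rng.uniform(size=30))
            false_disc += flags.any()
        # under the global null, FDR = P(any rejection) <= q
        assert false_disc / 1000 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 1000)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.2]))


class TestOneSampleEdges:
    def test_identical_positive_matrices_all_flagged(self):
        vals = np.full((3, 3), 0.4)
        table = make_table([(f"s{k}", "patient", "before", vals, None)
                            for k in range(5)])
        res = one_sample_edges(table, "patient", "before")
        off = ~np.eye(3, dtype=bool)
        assert res.flags[off].all()

    def test_zero_variance_edges_get_p_one(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((3, 3)) * 0.1

        def rec(k):
            vals = base.copy()
            vals[0, 1] = 0.5  # constant across subjects
            vals += np.where(np.arange(9).reshape(3, 3) == 1, 0, rng.standard_normal((3, 3)) * 0.01)
            return (f"s{k}", "patient", "before", vals, None)

        table = make_table([rec(k) for k in range(4)])
        res = one_sample_edges(table, "patient", "before")
        assert np.isfinite(res.t[~np.eye(3, dtype=bool)]).all()

    def test_t_matches_formula_oracle(self):
        rng = np.random.default_rng(2)
        mats = [0.2 + 0.1 * rng.standard_normal((3, 3)) for _ in range(6)]
        table = make_table([(f"s{k}", "control", "after", m, None)
                            for k, m in enumerate(mats)])
        res = one_sample_edges(table, "control", "after")
        x = np.array([m[2, 0] for m in mats])
        expected = x.mean() / (x.std(ddof=1) / np.sqrt(6))
        assert res.t[2, 0] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_null_calibration(self):
        rng = np.random.default_rng(3)
        flagged = 0
        for _ in range(200):
            mats = [rng.standard_normal((3, 3)) for _ in range(10)]
            table = make_table([(f"s{k}", "patient", "before", m, None)
                                for k, m in enumerate(mats)])
            res = one_sample_edges(table, "patient", "before")
            flagged += res.flags.any()
        assert flagged / 200 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 200)


class TestIndependentTEdges:
    def test_planted_group_deficit_flagged_negative(self):
        rng = np.random.default_rng(4)

        def effect(vals, g, sess):
            if g == "patient":
                vals = vals.copy()
                vals[1, 0] -= 0.2
            return vals

        table = random_table(rng, effect=effect)
        res = independent_t_edges(table, "before")
        assert res.flags[1, 0] and res.t[1, 0] < 0

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(5)
        table = random_table(rng)
        res = independent_t_edges(table, "before")
        swapped = StudyTable([
            StudyRecord(r.subject_id,
                        "control" if r.group == "patient" else "patient",
                        r.session, r.edges, r.scores)
            for r in table.records
        ])
        res2 = independent_t_edges(swapped, "before")
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(res2.t[off], -res.t[off], atol=1e-10)

    def test_missing_group_rejected(self):
        table = make_table([(f"s{k}", "patient", "before", np.eye(3) * 0.1, None)
                            for k in range(4)])
        with pytest.raises(ValueError, match="group"):
            independent_t_edges(table, "before")


class TestPairedTEdges:
    def test_no_change_flags_nothing(self):
        rng = np.random.default_rng(6)
        recs = []
        for k in range(6):
            vals = 0.3 + 0.05 * rng.standard_normal((3, 3))
            recs += [(f"s{k}", "patient", "before", vals, None),
                     (f"s{k}", "patient", "after", vals, None)]
        table = make_table(recs)
        res = paired_t_edges(table, "patient")
        assert not res.flags.any()
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_array_equal(res.t[off], 0.0)

    def test_planted_training_gain_flagged_positive(self):
        rng = np.random.default_rng(7)

        def effect(vals, g, sess):
            if g == "patient" and sess == "after":
                vals = vals.copy()
                vals[2, 1] += 0.25
            return vals

        table = random_table(rng, effect=effect)
        res = paired_t_edges(table, "patient")
        assert res.flags[2, 1] and res.t[2, 1] > 0

    def test_equals_one_sample_t_of_differences(self):
        rng = np.random.default_rng(8)
        table = random_table(rng, n_pat=7, n_con=2)
        res = paired_t_edges(table, "patient")
        _, diffs = table.paired_diffs("patient")
        d = diffs[:, 0, 2]
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t[0, 2] == pytest.approx(expected, abs=1e-12)

    def test_unpaired_subject_excluded(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, n_pat=5, n_con=2)
        table.records.append(StudyRecord(
            "orphan", "patient", "before", EdgeMatrix(np.full((3, 3), 0.9))))
        res = paired_t_edges(table, "patient")  # must not crash
        assert np.isfinite(res.t[0, 1])


class TestEdgeFrequency:
    def test_unanimous_detection_gives_one(self):
        det = [np.ones((3, 3)) for _ in range(4)]
        np.testing.assert_array_equal(edge_frequency(det), np.ones((3, 3)))

    def test_half_detection_gives_half(self):
        det = [np.zeros((2, 2)), np.ones((2, 2))]
        np.testing.assert_array_equal(edge_frequency(det), np.full((2, 2), 0.5))

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError):
            edge_frequency(np.ones((3, 2, 3)))


class TestEdgeScoreCorrelation:
    def _linked_table(self, rng, noise_sd, n=10):
        recs = []
        for k in range(n):
            strength = 0.2 + 0.1 * rng.uniform()
            vals = np.full((2, 2), 0.1)
            vals[1, 0] = strength
            score = 20 + 150 * strength + noise_sd * rng.standard_normal()
            for sess in ("before", "after"):
                recs.append(StudyRecord(
                    f"s{k}", "patient", sess,
                    EdgeMatrix(vals, channel_names=["SMN", "DMN"]),
                    {"RP": score}, true_edge_strength=strength,
                ))
        return StudyTable(recs)

    def test_noiseless_link_gives_r_one(self):
        rng = np.random.default_rng(10)
        table = self._linked_table(rng, noise_sd=0.0)
        res = edge_score_correlation(table, ("SMN", "DMN"), "RP")
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_covariance_formula_oracle_small_n(self):
        x = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
        y = np.array([40.0, 55.0, 42.0, 70.0, 66.0])
        recs = []
        for k, (xi, yi) in enumerate(zip(x, y)):
            vals = np.zeros((2, 2))
            vals[1, 0] = xi
            recs.append(StudyRecord(f"s{k}", "patient", "before",
                                    EdgeMatrix(vals, channel_names=["SMN", "DMN"]),
                                    {"RP": yi}))
        table = StudyTable(recs)
        res = edge_score_correlation(table, ("SMN", "DMN"), "RP")
        cx, cy = x - x.mean(), y - y.mean()
        expected = (cx @ cy) / np.sqrt((cx @ cx) * (cy @ cy))
        assert res.r == pytest.approx(expected, abs=1e-12)

    def test_differences_mode_uses_session_changes(self):
        rng = np.random.default_rng(11)
        recs = []
        for k in range(8):
            d = 0.1 * rng.uniform()
            for sess, strength in (("before", 0.2), ("after", 0.2 + d)):
                vals = np.zeros((2, 2))
                vals[1, 0] = strength
                recs.append(StudyRecord(
                    f"s{k}", "patient", sess,
                    EdgeMatrix(vals, channel_names=["SMN", "DMN"]),
                    {"RP": 100 * strength}))
        table = StudyTable(recs)
        res = edge_score_correlation(table, ("SMN", "DMN"), "RP", mode="differences")
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.n == 8

    def test_independence_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            recs = []
            for k in range(21):
                vals = np.zeros((2, 2))
                vals[1, 0] = rng.standard_normal()
                recs.append(StudyRecord(
                    f"s{k}", "patient", "before",
                    EdgeMatrix(vals, channel_names=["SMN", "DMN"]),
                    {"RP": rng.standard_normal()}))
            res = edge_score_correlation(StudyTable(recs), ("SMN", "DMN"), "RP")
            rejections += res.p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.025)

    def test_constant_variable_rejected(self):
        recs = []
        for k in range(5):
            vals = np.zeros((2, 2))
            vals[1, 0] = 0.3
            recs.append(StudyRecord(f"s{k}", "patient", "before",
                                    EdgeMatrix(vals, channel_names=["SMN", "DMN"]),
                                    {"RP": 50.0}))
        with pytest.raises(ValueError, match="constant"):
            edge_score_correlation(StudyTable(recs), ("SMN", "DMN"), "RP")
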