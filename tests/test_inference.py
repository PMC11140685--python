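"""Group statistics: t contrasts, BH-FDR against a brute-force step-up
oracle, max/min permutation properties, the task GLM, and QC rules."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cortnet import inference as inf, synthetic as syn
from cortnet.types import GroundTruth


def bh_brute_force(p, q=0.05):
    """Step-up evaluated literally: reject all p <= p_(k) where k is the
    largest index with p_(k) <= k*q/m; q-values by the monotone minimum."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = (np.arange(1, m + 1) * q) / m
    below = np.flatnonzero(sorted_p <= thresh)
    rejected = np.zeros(m, dtype=bool)
    if below.size:
        rejected[order[: below.max() + 1]] = True
    qvals = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(qvals, 1.0)
    return rejected, out


class TestNetworkContrast:
    def test_identical_paired_vectors(self):
        row = inf.network_contrast(np.ones(5), np.ones(5), mode="paired")
        assert row["t"] == 0.0 and row["p"] == 1.0

    def test_degenerate_constant_difference(self):
        row = inf.network_contrast(np.arange(4.0) + 1, np.arange(4.0), mode="paired")
        assert row["p"] <= 1e-10 and np.isinf(row["t"])

    def test_power_at_unit_shift(self, rng):
        # paired shift delta=1 with unit-sd difference noise, n=27
        rejections = 0
        for _ in range(200):
            b = rng.standard_normal(27)
            a = b + 1.0 + rng.standard_normal(27)
            row = inf.network_contrast(a, b, mode="paired")
            rejections += row["p"] < 0.05
        assert rejections / 200 > 0.99

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            inf.network_contrast(np.ones(2), np.zeros(2), mode="paired")


class TestFdrBh:
    def test_single_p(self):
        rej, q = inf.fdr_bh([0.03])
        assert rej[0] and q[0] == pytest.approx(0.03)

    def test_hand_checked_thresholds(self):
        rej, q = inf.fdr_bh([0.01, 0.02, 0.03, 0.04], q_level=0.05)
        assert rej.all()

    def test_all_ones(self):
        rej, q = inf.fdr_bh(np.ones(5))
        assert not rej.any() and np.allclose(q, 1.0)

    def test_empty(self):
        rej, q = inf.fdr_bh([])
        assert rej.size == 0 and q.size == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_brute_force_oracle(self, pvals):
        rej, q = inf.fdr_bh(pvals, q_level=0.05)
        rej_o, q_o = bh_brute_force(pvals, q=0.05)
        assert np.array_equal(rej, rej_o)
        assert np.allclose(q, q_o)


class TestMaxMinPermutation:
    def test_sign_symmetry(self, rng):
        v = rng.standard_normal((20, 4))
        v[:, 0] += 0.8
        a = inf.maxmin_permutation_test(v, n_permutations=2000, seed=0)
        b = inf.maxmin_permutation_test(-v, n_permutations=2000, seed=0)
        assert a.fwe_p[(0, 1)] == pytest.approx(b.fwe_p[(0, 1)], abs=2 / 2000)
        assert a.observed[(0, 1)] == pytest.approx(-b.observed[(0, 1)])

    def test_fwe_not_anticonservative_vs_single_pair(self, rng):
        v = rng.standard_normal((15, 3))
        res = inf.maxmin_permutation_test(v, n_permutations=1000, seed=3)
        for (i, j), p_fwe in res.fwe_p.items():
            # single-pair permutation p (no max correction)
            single = inf.maxmin_permutation_test(
                v[:, [i, j]], n_permutations=1000, seed=3
            )
            assert p_fwe >= single.fwe_p[(0, 1)] - 2 / 1000

    def test_null_lengths(self, rng):
        res = inf.maxmin_permutation_test(
            rng.standard_normal((10, 3)), n_permutations=500, seed=0
        )
        assert res.max_null.shape == (500,) and res.min_null.shape == (500,)

    def test_fewer_than_two_tasks_rejected(self, rng):
        with pytest.raises(ValueError):
            inf.maxmin_permutation_test(rng.standard_normal((10, 1)))


class TestGlm:
    def test_fixed_effects_single_run_identity(self, labeling):
        spec = syn.default_condition_spec(condition="task", seed=2, sigma=0.3)
        design = syn.make_task_design(seed=0)
        eff = GroundTruth(glm_effects={"modulator": np.full(labeling.n_parcels, 0.4)})
        ts = syn.generate_task_run(labeling, design, eff, spec)
        res = inf.glm_univariate([(ts, design)])
        run_beta = res.run_betas[(ts.subject_id, ts.run_id)]["modulator"]
        assert np.allclose(res.subject_betas[0], run_beta)

    def test_hard_vs_easy_contrast_recovery(self, labeling):
        p = labeling.n_parcels
        spec = syn.default_condition_spec(
            condition="task", seed=5, sigma=0.0, coupling=np.zeros((8, 8))
        )
        design = syn.make_task_design(seed=0)
        eff = GroundTruth(glm_effects={"easy": np.full(p, 0.2), "hard": np.full(p, 0.9)})
        ts = syn.generate_task_run(labeling, design, eff, spec)
        res = inf.glm_univariate([(ts, design)], model="easy+hard")
        assert np.allclose(res.subject_betas[0], 0.7, atol=1e-6)

    def test_null_exchangeable_contrast_centred(self, labeling):
        p = labeling.n_parcels
        spec = syn.default_condition_spec(condition="task", seed=6, sigma=1.0)
        design = syn.make_task_design(seed=0)
        eff = GroundTruth(glm_effects={"easy": np.full(p, 0.5), "hard": np.full(p, 0.5)})
        runs = [
            (syn.generate_task_run(labeling, design, eff, spec, subject=s), design)
            for s in range(1, 9)
        ]
        res = inf.glm_univariate(runs, model="easy+hard")
        assert abs(np.mean(res.group_t)) < 0.5
        assert not inf.fdr_bh(res.group_p)[0].any()

    def test_no_correct_trials_skipped(self, labeling, rng):
        from cortnet.types import ParcelTimeSeries, TaskDesign

        design = TaskDesign(
            np.array([10.0]), np.array([3.0]), np.array(["easy"]),
            np.array([0.0]), np.array([False]),
        )
        ts = ParcelTimeSeries(rng.standard_normal((100, 5)), 1.5)
        with pytest.warns(UserWarning, match="no correct trials"):
            with pytest.raises(ValueError, match="no usable runs"):
                inf.glm_univariate([(ts, design)], model="easy+hard")


class TestQc:
    def _frame(self, traces, accs=None):
        rows = []
        for i, tr in enumerate(traces):
            rows.append(
                {"subject": f"s{i//2+1}", "task": "wm", "run": f"r{i%2+1}",
                 "fd_trace": np.asarray(tr)}
            )
        df = pd.DataFrame(rows)
        if accs is not None:
            df["accuracy"] = accs
        return df

    def test_clean_run_kept(self):
        df = self._frame([np.full(100, 0.1)] * 4, accs=[0.9, 0.9, 0.9, 0.9])
        out = inf.run_qc_filter(df, mode="york")
        assert not out["drop_run"].any()
        assert not out["drop_subject_task"].any()

    def test_spiky_run_dropped(self):
        tr = np.full(100, 0.1)
        tr[:16] = 0.3  # 16% of frames above 0.25 mm
        df = self._frame([tr, np.full(100, 0.1), np.full(100, 0.1), np.full(100, 0.1)])
        out = inf.run_qc_filter(df, mode="york")
        assert out["drop_run"].tolist() == [True, False, False, False]

    def test_high_mean_fd_dropped(self):
        df = self._frame([np.full(100, 0.25), np.full(100, 0.1),
                          np.full(100, 0.1), np.full(100, 0.1)])
        out = inf.run_qc_filter(df, mode="york")
        assert out["drop_run"].iloc[0]

    def test_single_surviving_run_drops_subject_task(self):
        tr_bad = np.full(100, 0.5)
        df = self._frame([tr_bad, np.full(100, 0.1), np.full(100, 0.1),
                          np.full(100, 0.1)])
        out = inf.run_qc_filter(df, mode="york")
        s1 = out[out.subject == "s1"]
        assert s1["drop_subject_task"].all()
        assert not out[out.subject == "s2"]["drop_subject_task"].any()

    def test_hcp_frame_rule(self):
        tr = np.full(100, 0.1)
        tr[:26] = 0.25  # 26% of frames above 0.2 mm
        df = self._frame([tr, np.full(100, 0.1), np.full(100, 0.1),
                          np.full(100, 0.1)])
        out = inf.run_qc_filter(df, mode="hcp")
        assert out["drop_run"].tolist() == [True, False, False, False]

    def test_empty_trace_rejected(self):
        df = self._frame([np.array([])])
        with pytest.raises(ValueError, match="empty FD trace"):
            inf.run_qc_filter(df, mode="york")
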