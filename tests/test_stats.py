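import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from scalphfo.simulate import simulate_cohort_rates
from scalphfo.stats import (
    WaldTypeRM,
    factorial_contrast,
    holm_adjust,
    parametric_bootstrap_p,
    run_study_designs,
    wts,
)


def _two_group_data(rng, n=20, d=2, shift=0.0):
    g1 = rng.normal(0, 1, (n, d))
    g2 = rng.normal(shift, 1, (n, d))
    return [g1, g2]


INTERACTION_2x2 = factorial_contrast([2, 2], [True, True])
BETWEEN_MAIN_2x2 = factorial_contrast([2, 2], [True, False])
WITHIN_MAIN_2x2 = factorial_contrast([2, 2], [False, True])


class TestWts:
    def test_identical_cell_means_give_zero(self, rng):
        g = rng.normal(0, 1, (30, 2))
        res = wts([g, g.copy()], BETWEEN_MAIN_2x2)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_asymptotic == pytest.approx(1.0)

    def test_invariant_to_common_shift(self, rng):
        groups = _two_group_data(rng, shift=0.7)
        r1 = wts(groups, INTERACTION_2x2)
        r2 = wts([g + 123.4 for g in groups], INTERACTION_2x2)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)

    def test_df_is_contrast_rank(self, rng):
        groups = [rng.normal(0, 1, (10, 2)) for _ in range(4)]
        H = factorial_contrast([4, 2], [True, False])  # rank 3
        assert wts(groups, H).df == 3

    def test_rank_zero_contrast_rejected(self, rng):
        with pytest.raises(ValueError, match="rank-0"):
            wts(_two_group_data(rng), np.zeros((1, 4)))

    def test_tiny_group_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            wts([rng.normal(0, 1, (1, 2)), rng.normal(0, 1, (5, 2))],
                BETWEEN_MAIN_2x2)

    def test_null_distribution_matches_chi2_1(self):
        # asymptotic-limit oracle: large balanced groups, main effect
        rng = np.random.default_rng(11)
        stats = np.empty(2000)
        for i in range(2000):
            groups = _two_group_data(rng, n=200, d=1)
            stats[i] = wts(groups, np.array([[0.5, -0.5]])).statistic
        grid = np.linspace(0.05, 8, 200)
        emp = np.searchsorted(np.sort(stats), grid) / stats.size
        ks = np.max(np.abs(emp - chi2.cdf(grid, 1)))
        assert ks < 0.05


class TestBootstrap:
    def test_zero_statistic_gives_p_one(self, rng):
        g = rng.normal(0, 1, (20, 2))
        p = parametric_bootstrap_p([g, g.copy()], BETWEEN_MAIN_2x2,
                                   n_boot=200, seed=0)
        assert p == pytest.approx(1.0, abs=1 / 201)

    def test_deterministic_under_seed(self, rng):
        groups = _two_group_data(rng, shift=0.4)
        p1 = parametric_bootstrap_p(groups, BETWEEN_MAIN_2x2, 200, seed=7)
        p2 = parametric_bootstrap_p(groups, BETWEEN_MAIN_2x2, 200, seed=7)
        assert p1 == p2

    def test_n_boot_floor(self, rng):
        with pytest.raises(ValueError, match="n_boot"):
            parametric_bootstrap_p(_two_group_data(rng), BETWEEN_MAIN_2x2,
                                   n_boot=50)

    def test_agrees_with_asymptotic_at_large_n(self):
        rng = np.random.default_rng(3)
        groups = _two_group_data(rng, n=100, d=2, shift=0.25)
        res = wts(groups, BETWEEN_MAIN_2x2)
        p_boot = parametric_bootstrap_p(groups, BETWEEN_MAIN_2x2,
                                        n_boot=2000, seed=1,
                                        observed=res.statistic)
        assert abs(p_boot - res.p_asymptotic) < 0.02


class TestHolm:
    def test_worked_example(self):
        adj = holm_adjust([0.005, 0.0137, 0.3], alpha=0.05)
        ps = [a for a, _ in adj]
        assert ps[0] == pytest.approx(0.015)
        assert ps[1] == pytest.approx(0.0274)
        assert ps[2] == pytest.approx(0.3)
        assert [r for _, r in adj] == [True, True, False]

    def test_single_p_unchanged(self):
        assert holm_adjust([0.04])[0] == (0.04, True)

    def test_empty(self):
        assert holm_adjust([]) == []

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 12)
        ours = np.array([a for a, _ in holm_adjust(list(p))])
        reject, p_sm, *_ = multipletests(p, alpha=0.05, method="holm")
        np.testing.assert_allclose(ours, p_sm, rtol=1e-12)
        assert [r for _, r in holm_adjust(list(p))] == list(reject)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_rejects_superset_of_bonferroni(self, ps):
        m = len(ps)
        bonf = [min(1.0, p * m) <= 0.05 for p in ps]
        holm = [r for _, r in holm_adjust(ps)]
        assert all(h or not b for h, b in zip(holm, bonf))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_adjusted_monotone_in_sorted_order(self, ps):
        adj = [a for a, _ in holm_adjust(ps)]
        order = np.argsort(ps)
        sorted_adj = np.array(adj)[order]
        assert (np.diff(sorted_adj) >= -1e-12).all()


class TestModelResults:
    def _fit(self, seed=0, n_boot=0, interaction=0.010):
        df = simulate_cohort_rates(18, 6, seed=seed, interaction=interaction)
        model = WaldTypeRM(df, ["ripple", "fast_ripple"],
                           within=[("HFOType", 2)], between="group",
                           between_name="Epilepsy")
        return model.fit(n_boot=n_boot, seed=seed)

    def test_effect_table_structure(self):
        res = self._fit()
        t = res.table()
        assert list(t["effect"]) == ["Epilepsy", "HFOType",
                                     "Epilepsy:HFOType"]
        assert (t["df"] == 1).all()
        assert t["p_holm"].between(0, 1).all()
        assert "WTS" in res.summary()

    def test_within_effect_invariant_to_group_relabeling(self):
        df = simulate_cohort_rates(12, 12, seed=5)
        flipped = df.copy()
        flipped["group"] = flipped["group"].map(
            {"epilepsy": "control", "control": "epilepsy"}
        )
        kw = dict(cell_columns=["ripple", "fast_ripple"],
                  within=[("HFOType", 2)], between="group")
        r1 = WaldTypeRM(df, **kw).fit(n_boot=0)
        r2 = WaldTypeRM(flipped, **kw).fit(n_boot=0)
        assert r1["HFOType"].statistic == pytest.approx(
            r2["HFOType"].statistic, rel=1e-9
        )

    def test_incomplete_cells_rejected(self):
        df = simulate_cohort_rates(6, 6, seed=0)
        df.loc[2, "fast_ripple"] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            WaldTypeRM(df, ["ripple", "fast_ripple"],
                       within=[("HFOType", 2)], between="group")

    def test_unknown_effect_rejected(self):
        df = simulate_cohort_rates(6, 6, seed=0)
        model = WaldTypeRM(df, ["ripple", "fast_ripple"],
                           within=[("HFOType", 2)], between="group")
        with pytest.raises(ValueError, match="unknown factors"):
            model.fit(effects=["Bogus"], n_boot=0)

    def test_within_only_design(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (15, 4)),
                          columns=["t_l", "t_r", "r_l", "r_r"])
        df["subject_id"] = [f"S{i}" for i in range(15)]
        model = WaldTypeRM(df, ["t_l", "t_r", "r_l", "r_r"],
                           within=[("Task", 2), ("Hemisphere", 2)])
        res = model.fit(n_boot=0)
        assert [r.effect for r in res.results] == [
            "Task", "Hemisphere", "Task:Hemisphere"
        ]


class TestStudyDesigns:
    def test_sleep_design_runs_on_rate_table(self):
        rows = []
        rng = np.random.default_rng(0)
        groups = {}
        for i in range(12):
            sid = f"P{i:02d}"
            diagnosis = "epilepsy" if i < 8 else "control"
            groups[sid] = {"diagnosis": diagnosis,
                           "focus": ["left", "right"][i % 2]}
            for hemi in ("all", "left", "right"):
                for hfo in ("ripple", "fast_ripple", "all"):
                    rows.append({
                        "subject_id": sid, "roi_name": "ROI_Sleep",
                        "hemisphere_or_all": hemi, "hfo_type": hfo,
                        "rate_per_min": float(rng.uniform(0, 0.05)),
                    })
        table = pd.DataFrame(rows)
        out = run_study_designs(table, groups, n_boot=100, seed=0)
        assert "epilepsy_by_hfo_type" in out
        assert "focus_by_hemisphere" in out
        t = out["epilepsy_by_hfo_type"].table()
        assert len(t) == 3
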