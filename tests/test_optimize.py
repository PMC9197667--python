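import numpy as np
import pandas as pd
import pytest

from entroscan.entropy import EntropyParams
from entroscan.optimize import (
    EntropyBiomarkerOptimizer,
    GridResult,
    OptimalParams,
    build_features,
    count_significant,
    default_r_grid,
    default_tau_grid,
    optimize_parameters,
    robust_r_band,
    run_grid,
    select_biomarkers,
    select_m,
    select_tau_r,
)
from entroscan.synthetic import SynthConfig, generate_cohort


def make_grid(m_values, r_values, tau_values, regions, p_fn, auc_fn):
    """Construct a GridResult with prescribed p/auc surfaces."""
    rows = []
    for m in m_values:
        for r in r_values:
            for tau in tau_values:
                for region in regions:
                    p = p_fn(m, r, tau, region)
                    auc = auc_fn(m, r, tau, region)
                    rows.append((m, r, tau, region, 10, 10, 0.0, 0.0, 0.0, p, auc, 0))
    table = pd.DataFrame(
        rows,
        columns=["m", "r", "tau", "region", "n0", "n1", "mean0", "mean1",
                 "t", "p", "auc", "n_excluded"],
    )
    return GridResult(
        table=table,
        m_values=tuple(m_values),
        r_values=tuple(r_values),
        tau_values=tuple(tau_values),
        region_labels=tuple(regions),
    )


@pytest.fixture(scope="module")
def toy_grid_result():
    """2-region toy cohort: region A group-shifted, region B pure noise."""
    cfg = SynthConfig(
        n_per_group=(15, 15),
        n_regions=2,
        n_timepoints=150,
        planted_regions=(0,),
        delta_phi=0.6,
        seed=3,
    )
    ds = generate_cohort(cfg)
    return run_grid(ds, m_values=(1,), r_values=(0.3, 0.5), tau_values=(1, 2))


class TestRunGrid:
    def test_grid_is_complete(self, small_cohort):
        grid = run_grid(small_cohort, m_values=(1, 2), r_values=(0.2, 0.5),
                        tau_values=(1, 2, 3))
        assert len(grid.table) == 2 * 2 * 3 * small_cohort.n_regions
        assert not grid.table.duplicated(subset=["m", "r", "tau", "region"]).any()

    def test_planted_region_significant_noise_region_not(self, toy_grid_result):
        t = toy_grid_result.table
        planted = t[t.region == "ROI_001"]
        noise = t[t.region == "ROI_002"]
        assert (planted[planted.tau == 1].p < 1e-4).all()
        assert (noise.p > 0.01).all()  # uniform p: not consistently tiny

    def test_deterministic_rerun_bit_identical(self, small_cohort):
        g1 = run_grid(small_cohort, m_values=(1,), r_values=(0.5,), tau_values=(1, 2))
        g2 = run_grid(small_cohort, m_values=(1,), r_values=(0.5,), tau_values=(1, 2))
        pd.testing.assert_frame_equal(g1.table, g2.table)

    def test_default_grids_match_standard_search_space(self):
        assert len(default_r_grid()) == 12
        assert default_r_grid()[0] == 0.05 and default_r_grid()[-1] == 0.60
        np.testing.assert_array_equal(default_tau_grid(), [1, 2, 3, 4, 5, 6])


class TestCountSignificant:
    def test_no_significance_gives_zero_table(self):
        grid = make_grid([1], [0.2, 0.5], [1, 2], ["A", "B"],
                         lambda *a: 0.9, lambda *a: 0.5)
        counts = count_significant(grid, 1, alpha=0.05)
        assert (counts.to_numpy() == 0).all()

    def test_alpha_one_counts_every_region(self):
        grid = make_grid([1], [0.2], [1, 2], ["A", "B", "C"],
                         lambda *a: 0.5, lambda *a: 0.5)
        counts = count_significant(grid, 1, alpha=1.0)
        assert (counts.to_numpy() == 3).all()

    def test_counts_peak_at_planted_cell(self):
        def p_fn(m, r, tau, region):
            return 0.01 if (r == 0.5 and tau == 2) else 0.5

        grid = make_grid([1], [0.2, 0.5], [1, 2, 3], ["A", "B"], p_fn, lambda *a: 0.6)
        counts = count_significant(grid, 1)
        assert counts.loc[0.5, 2] == 2
        assert counts.to_numpy().sum() == 2


class TestSelectM:
    def test_dominant_m_selected(self):
        def p_fn(m, r, tau, region):
            return 0.01 if m == 1 else 0.5

        grid = make_grid([1, 2], [0.2, 0.5], [1, 2], ["A", "B"], p_fn, lambda *a: 0.6)
        assert select_m(grid) == 1

    def test_tie_breaks_to_smaller_m(self):
        grid = make_grid([1, 2], [0.2], [1], ["A"], lambda *a: 0.01, lambda *a: 0.6)
        assert select_m(grid) == 1

    def test_larger_m_can_win(self):
        def p_fn(m, r, tau, region):
            return 0.01 if m == 2 else 0.5

        grid = make_grid([1, 2], [0.2], [1], ["A", "B"], p_fn, lambda *a: 0.6)
        assert select_m(grid) == 2


class TestRobustRBand:
    def test_significance_everywhere_gives_full_grid(self):
        grid = make_grid([1], [0.2, 0.4, 0.6], [1, 2], ["A"],
                         lambda *a: 0.01, lambda *a: 0.7)
        assert robust_r_band(grid, 1) == (0.2, 0.4, 0.6)

    def test_band_restricted_to_r_significant_at_every_tau(self):
        def p_fn(m, r, tau, region):
            return 0.01 if r in (0.45, 0.50, 0.55) else (0.01 if tau == 1 else 0.5)

        grid = make_grid([1], [0.35, 0.40, 0.45, 0.50, 0.55, 0.60], [1, 2, 3],
                         ["A"], p_fn, lambda *a: 0.7)
        assert robust_r_band(grid, 1) == (0.45, 0.50, 0.55)

    def test_empty_band_falls_back_with_warning(self):
        def p_fn(m, r, tau, region):
            # tau = 2 never significant; r = 0.4 significant at tau = 1 only
            return 0.01 if (tau == 1 and r == 0.4) else 0.5

        grid = make_grid([1], [0.2, 0.4], [1, 2], ["A"], p_fn, lambda *a: 0.7)
        with pytest.warns(UserWarning, match="falling back"):
            band = robust_r_band(grid, 1)
        assert band == (0.4,)


class TestSelectTauR:
    def test_single_peak_selected(self):
        def auc_fn(m, r, tau, region):
            return 0.9 if (r == 0.5 and tau == 3) else 0.6

        grid = make_grid([1], [0.3, 0.5], [1, 2, 3, 4], ["A"],
                         lambda *a: 0.01, auc_fn)
        opt = select_tau_r(grid, 1, (0.3, 0.5))
        assert opt.params == EntropyParams(m=1, r=0.5, tau=3)

    def test_tau_tie_breaks_to_smaller(self):
        def auc_fn(m, r, tau, region):
            return 0.9 if tau in (3, 5) else 0.6

        grid = make_grid([1], [0.5], [1, 2, 3, 4, 5], ["A"], lambda *a: 0.01, auc_fn)
        assert select_tau_r(grid, 1, (0.5,)).params.tau == 3

    def test_r_tie_breaks_to_band_midpoint(self):
        grid = make_grid([1], [0.3, 0.4, 0.5], [1], ["A"], lambda *a: 0.01,
                         lambda *a: 0.8)
        # all scores equal: midpoint of (0.3, 0.5) is 0.4
        assert select_tau_r(grid, 1, (0.3, 0.4, 0.5)).params.r == 0.4

    def test_no_significant_cell_raises(self):
        grid = make_grid([1], [0.5], [1, 2], ["A"], lambda *a: 0.9, lambda *a: 0.6)
        with pytest.raises(ValueError, match="widen"):
            select_tau_r(grid, 1, (0.5,))

    def test_trace_replay_reproduces_selection(self):
        def auc_fn(m, r, tau, region):
            return 0.55 + 0.05 * tau - 0.1 * abs(r - 0.4)

        grid = make_grid([1], [0.3, 0.4, 0.5], [1, 2, 3], ["A"],
                         lambda *a: 0.01, auc_fn)
        opt = select_tau_r(grid, 1, (0.3, 0.4, 0.5))
        scores = pd.DataFrame(opt.selection_trace["scores"])
        per_tau = scores.groupby("tau")["score"].max()
        tau_replay = int(min(t for t, s in per_tau.items() if s == per_tau.max()))
        at_tau = scores[scores.tau == tau_replay]
        r_replay = float(at_tau.loc[at_tau.score.idxmax(), "r"])
        assert (tau_replay, r_replay) == (opt.params.tau, opt.params.r)


class TestBiomarkersAndFeatures:
    def test_planted_regions_recovered(self, small_cohort):
        grid, opt = optimize_parameters(
            small_cohort, m_values=(1,), r_values=(0.3, 0.5), tau_values=(1, 2)
        )
        biomarkers = select_biomarkers(grid, opt)
        planted = {"ROI_001", "ROI_005", "ROI_009"}  # indices 0, 4, 8
        assert planted <= set(biomarkers.regions)
        assert biomarkers.table["p"].is_monotonic_increasing

    def test_alpha_zero_raises_empty_set_error(self, toy_grid_result):
        opt = OptimalParams(
            params=EntropyParams(m=1, r=0.5, tau=1), robust_r_band=(0.5,)
        )
        with pytest.raises(ValueError, match="no region"):
            select_biomarkers(toy_grid_result, opt, alpha=0.0)

    def test_identical_groups_raise_with_diagnostics(self, rng):
        from entroscan.io import StudyDataset, SubjectRecord

        # both groups share the same generative process: nothing separates them
        subs = [
            SubjectRecord(f"s{i}", i % 2, rng.normal(size=(3, 80))) for i in range(12)
        ]
        ds = StudyDataset(subs, ["A", "B", "C"], 80)
        grid = run_grid(ds, m_values=(1,), r_values=(0.5,), tau_values=(1,))
        opt = OptimalParams(
            params=EntropyParams(m=1, r=0.5, tau=1), robust_r_band=(0.5,)
        )
        cell = grid.cell(1, 0.5, 1)
        if (cell.p < 0.05).any():  # seeded: no spurious hit at alpha this small
            pytest.skip("random draw produced a spurious significant region")
        with pytest.raises(ValueError, match="nearest misses"):
            select_biomarkers(grid, opt, alpha=0.01)

    def test_feature_matrix_shape_and_order(self, small_cohort):
        grid, opt = optimize_parameters(
            small_cohort, m_values=(1,), r_values=(0.3, 0.5), tau_values=(1, 2)
        )
        biomarkers = select_biomarkers(grid, opt)
        fm = build_features(small_cohort, opt, biomarkers)
        assert fm.values.shape == (small_cohort.n_subjects, len(biomarkers))
        assert list(fm.values.columns) == biomarkers.regions
        assert list(fm.values.index) == small_cohort.subject_ids
        assert fm.dropped == []
        np.testing.assert_array_equal(fm.y, small_cohort.groups)

    def test_single_biomarker_gives_column_vector(self, small_cohort):
        grid, opt = optimize_parameters(
            small_cohort, m_values=(1,), r_values=(0.5,), tau_values=(1,)
        )
        biomarkers = select_biomarkers(grid, opt)
        one = biomarkers.table.iloc[:1]
        from entroscan.optimize import BiomarkerSet

        fm = build_features(small_cohort, opt, BiomarkerSet(table=one))
        assert fm.values.shape == (small_cohort.n_subjects, 1)


class TestEstimator:
    def test_fit_exposes_fitted_attributes(self, small_cohort):
        est = EntropyBiomarkerOptimizer(
            m_values=(1,), r_values=(0.3, 0.5), tau_values=(1, 2)
        )
        est.fit(small_cohort)
        assert est.m_ == est.optimal_params_.params.m
        assert len(est.biomarkers_) >= 1
        assert est.feature_matrix_.values.shape[0] == small_cohort.n_subjects

    def test_get_params_roundtrip(self):
        est = EntropyBiomarkerOptimizer(alpha=0.01)
        params = est.get_params()
        assert params["alpha"] == 0.01
        est2 = EntropyBiomarkerOptimizer(**params)
        assert est2.get_params() == params

    def test_transform_on_new_cohort(self, small_cohort):
        est = EntropyBiomarkerOptimizer(
            m_values=(1,), r_values=(0.3, 0.5), tau_values=(1, 2)
        ).fit(small_cohort)
        other = generate_cohort(
            SynthConfig(n_per_group=(4, 4), n_regions=12, n_timepoints=120,
                        planted_regions=(0, 4, 8), seed=99)
        )
        fm = est.transform(other)
        assert fm.values.shape == (8, len(est.biomarkers_))
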