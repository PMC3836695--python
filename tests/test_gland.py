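"""Gland builders, link topology, presets, width-depth rule and the
two-cell calibration experiment."""

import numpy as np
import pytest

from cleftsim.core import (CLEFT, CLEFT_R, CLEFT_TYPES, IPC, MATRIX, OCC,
                           DynamicsParams, run_mcs)
from cleftsim.gland import (CleftTargetUpdater, GlandConfig, ParameterSet,
                            WidthDepthRule, assign_fpp_links,
                            build_organ_model, build_single_cleft, preset,
                            two_cell_calibration)
from cleftsim.morphometrics import measure_clefts
from cleftsim.simulate import run_condition


class TestWidthDepthRule:
    def test_value_at_surface(self):
        rule = WidthDepthRule(floor=0.0)
        assert rule(0.0) == pytest.approx(402 / 11 - 5)  # 31.545...

    def test_value_at_design_depth(self):
        rule = WidthDepthRule(floor=0.0)
        assert rule(36.0) == pytest.approx(402 / 47 - 5)  # ~3.553

    def test_strictly_decreasing_and_floored(self):
        rule = WidthDepthRule(floor=8.0)
        vals = [rule(d) for d in np.linspace(0, 60, 25)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert min(vals) == 8.0


class TestBuildSingleCleft:
    def test_cleft_census(self):
        state = build_single_cleft()
        assert len(state.cell_ids(types=CLEFT_TYPES)) == 12
        assert len(state.cell_ids(types=(CLEFT,))) == 6
        assert len(state.cell_ids(types=(CLEFT_R,))) == 6

    def test_type_census_matches_closed_form(self):
        cfg = GlandConfig()
        state = build_single_cleft(cfg)
        rows, cols = cfg.epithelium_rows, cfg.epithelium_cols
        n_boundary = 2 * rows + 2 * cols - 4
        n_total = rows * cols
        n_cleft = 2 * cfg.cleft_wall_cells
        # two cleft columns remove 2 boundary (top row) cells and the rest
        # from the interior
        assert len(state.cell_ids(types=(OCC,))) == n_boundary - 2
        assert len(state.cell_ids(types=(IPC,))) == \
            n_total - n_boundary - (n_cleft - 2)

    def test_all_epithelial_cells_start_at_36_px(self):
        state = build_single_cleft()
        areas = [state.cell(c).area for c in state.cell_ids()
                 if c != 0 and state.ctype[c] not in CLEFT_TYPES]
        assert set(areas) == {36}
        # the two notch-carved cleft cells are smaller, the rest are 36
        cleft_areas = sorted(state.cell(c).area
                             for c in state.cell_ids(types=CLEFT_TYPES))
        assert cleft_areas[2:] == [36] * 10
        assert all(a >= 30 for a in cleft_areas)

    def test_initial_cleft_is_unprogressed(self):
        state = build_single_cleft()
        ms = measure_clefts(state)
        assert len(ms) == 1
        assert ms[0].depth_um < 17.8  # below the "failed" ceiling

    def test_ipc_target_perimeter_exceeds_occ(self):
        cfg = GlandConfig()
        state = build_single_cleft(cfg)
        occ = state.cell(int(state.cell_ids(types=(OCC,))[0]))
        ipc = state.cell(int(state.cell_ids(types=(IPC,))[0]))
        assert ipc.target_perimeter > occ.target_perimeter

    def test_builder_is_deterministic(self):
        a = build_single_cleft()
        b = build_single_cleft()
        assert np.array_equal(a.owner, b.owner)

    def test_too_small_lattice_rejected(self):
        with pytest.raises(ValueError, match="lattice too small"):
            GlandConfig(lattice_width=60, lattice_height=40)


class TestAssignFppLinks:
    def test_cleft_link_topology_counts(self):
        state = build_single_cleft()
        links = assign_fpp_links(state, preset("base"))
        lateral = [l for l in links if l.orientation == "lateral_cleft"]
        vertical = [l for l in links if l.orientation == "vertical_cleft"]
        assert len(lateral) == 6
        assert len(vertical) == 10  # 5 per wall

    def test_lateral_targets_follow_width_rule(self):
        state = build_single_cleft()
        rule = WidthDepthRule()
        links = assign_fpp_links(state, preset("base"), rule)
        lateral = sorted((l.rank, l.target_length) for l in links
                         if l.orientation == "lateral_cleft")
        side = 6
        for rank, L in lateral:
            assert L == pytest.approx(rule(rank * side))
        assert lateral[0][1] > lateral[-1][1]  # decreasing with depth

    def test_no_fpp_preset_creates_no_links(self):
        state = build_single_cleft()
        links = assign_fpp_links(state, preset("no_fpp"))
        assert links == [] and state.links == []


class TestPresets:
    def test_base_values(self):
        p = preset("base")
        assert p.mitosis_rate == 1.0
        assert p.occ_mitosis_fraction == 50.0
        assert p.fpp_lambda_cleft == 10.0
        assert p.fpp_lambda_occ == 10.0
        assert p.cc_cleft == 10.0
        assert p.cm_cleft == 3.0

    def test_named_variants(self):
        assert preset("rock_kd").fpp_lambda_cleft == 1.0
        assert preset("rock_kd").mitosis_rate == 0.5
        assert preset("blebbistatin").fpp_lambda_cleft == 1.0
        assert preset("blebbistatin").mitosis_rate == 1.0
        assert preset("no_fpp").fpp_enabled is False

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            preset("nonsense")

    def test_contact_table_ordering(self):
        cfg = GlandConfig()
        t = cfg.contact_table(preset("base"))
        b = cfg.j_baseline
        assert t.get(OCC, OCC) < b < t.get(IPC, IPC)
        assert t.get(IPC, MATRIX) > t.get(OCC, MATRIX)
        assert t.get(CLEFT, CLEFT_R) == 10.0
        assert t.get(CLEFT, MATRIX) == 3.0
        assert np.allclose(t.J, t.J.T)


class TestCleftTargetUpdater:
    def test_unchanged_depth_keeps_targets(self):
        state = build_single_cleft()
        assign_fpp_links(state, preset("base"))
        upd = CleftTargetUpdater()
        upd(state)
        before = [l.target_length for l in state.links]
        upd(state)
        assert [l.target_length for l in state.links] == before

    def test_targets_non_increasing_under_deepening(self):
        state = build_single_cleft()
        assign_fpp_links(state, preset("base"))
        upd = CleftTargetUpdater()
        history = []
        cl = state.meta["clefts"][0]
        y0, xc = cl["surface_y"], cl["mouth_x"]
        for extra in (0, 6, 12, 18):
            state.owner[y0: y0 + 6 + extra, xc - 1: xc + 1] = 0
            state.refresh_cache()
            upd(state)
            history.append([l.target_length for l in state.links
                            if l.orientation == "lateral_cleft"])
        for prev, cur in zip(history, history[1:]):
            assert all(c <= p + 1e-12 for p, c in zip(prev, cur))

    def test_static_ablation_keeps_build_targets(self):
        """With dynamic retargeting disabled the lateral targets stay at
        their build values for the whole run, while an enabled updater
        tightens them once the cleft deepens past the designed span."""
        res = run_condition("base", seed=0, mcs=400, dynamic_targets=False)
        st = res["simulation"].state
        rule = WidthDepthRule()
        for l in st.links:
            if l.orientation == "lateral_cleft":
                assert l.target_length == pytest.approx(rule(l.rank * 6))
        res = run_condition("base", seed=0, mcs=400, dynamic_targets=True)
        st = res["simulation"].state
        for l in st.links:
            if l.orientation == "lateral_cleft":
                assert l.target_length <= rule(l.rank * 6) + 1e-9


class TestOrganModel:
    def test_cleft_census_and_spacing(self):
        state = build_organ_model(GlandConfig(n_clefts=3))
        assert len(state.cell_ids(types=CLEFT_TYPES)) == 36
        centers = sorted(cl["mouth_x"] for cl in state.meta["clefts"])
        gaps = np.diff(centers)
        cfg = state.meta["config"]
        assert np.all(np.abs(gaps - gaps[0]) <= cfg.cell_side)

    def test_three_independent_measurements(self):
        state = build_organ_model(GlandConfig(n_clefts=3))
        ms = measure_clefts(state, n_clefts=3)
        assert len(ms) == 3

    def test_links_per_cleft(self):
        state = build_organ_model(GlandConfig(n_clefts=3))
        links = assign_fpp_links(state, preset("base"))
        for k in range(3):
            lat = [l for l in links if l.orientation == "lateral_cleft"
                   and l.cleft_index == k]
            assert len(lat) == 6


class TestTwoCellCalibration:
    def test_no_lambda_with_adhesive_contact_stays_joined(self):
        df, _ = two_cell_calibration(D_grid=[18.0], CM_grid=[3.0],
                                     lambda_grid=[0.0], mcs=400, cc=1.0,
                                     seed=0)
        assert not df["separated"].any()

    def test_large_lambda_long_target_separates(self):
        df, _ = two_cell_calibration(D_grid=[24.0], CM_grid=[1.0, 3.0, 5.0],
                                     lambda_grid=[25.0], mcs=600, seed=0)
        assert df["separated"].all()

    def test_separation_monotone_in_lambda(self):
        df, _ = two_cell_calibration(D_grid=[18.0], CM_grid=[3.0],
                                     lambda_grid=[0.0, 2.0, 25.0], mcs=400,
                                     cc=1.0, replicates=5, seed=1)
        frac = df.groupby("lam")["separated"].mean()
        assert frac.iloc[0] <= frac.iloc[-1] + 0.2  # monotone up to noise
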