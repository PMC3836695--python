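"""Hamiltonian terms against brute-force oracles and closed forms."""

import numpy as np
import pytest

from cleftsim.core import (IPC, MATRIX, OCC, ContactEnergyTable,
                           DynamicsParams, FppLink, LatticeState,
                           area_energy, attempt_copy, contact_energy,
                           delta_energy, fpp_energy, neighborhood_offsets,
                           perimeter_energy, total_energy)
from conftest import random_lattice, random_table


def brute_contact(state, table):
    """Independent oracle: loop over every unordered neighbouring pair."""
    off = neighborhood_offsets(table.neighbor_order)
    total = 0.0
    seen = set()
    for y in range(state.height):
        for x in range(state.width):
            for dx, dy in off:
                nx, ny = x + dx, y + dy
                if not (0 <= nx < state.width and 0 <= ny < state.height):
                    continue
                key = frozenset({(x, y), (nx, ny)})
                if key in seen:
                    continue
                seen.add(key)
                a, b = state.owner[y, x], state.owner[ny, nx]
                if a != b:
                    total += table.J[state.ctype[a], state.ctype[b]]
    return total


def brute_total(state, table):
    """Oracle recomputing every term from the raw grid."""
    e = brute_contact(state, table)
    for cid in range(state.n_cells):
        a = int(np.sum(state.owner == cid))
        if a == 0 or state.ctype[cid] == MATRIX:
            continue
        p = 0
        for y in range(state.height):
            for x in range(state.width):
                if state.owner[y, x] != cid:
                    continue
                for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nx, ny = x + dx, y + dy
                    if 0 <= nx < state.width and 0 <= ny < state.height \
                            and state.owner[ny, nx] != cid:
                        p += 1
        e += state.lam_area[cid] * (a - state.target_area[cid]) ** 2
        e += state.lam_perim[cid] * (p - state.target_perim[cid]) ** 2
    for l in state.links:
        ax, ay = state.cell(l.cell_a).centroid
        bx, by = state.cell(l.cell_b).centroid
        d = np.hypot(ax - bx, ay - by)
        e += l.lambda_fpp * (d - l.target_length) ** 2
    return e


class TestContactEnergy:
    def test_single_owner_lattice_is_zero(self):
        state = LatticeState(6, 6)  # all matrix
        table = ContactEnergyTable(np.full((6, 6), 7.0))
        assert contact_energy(state, table) == 0.0

    def test_two_adjacent_single_site_cells(self):
        state = LatticeState(2, 1)
        a = state.new_cell(OCC)
        b = state.new_cell(IPC)
        state.owner[0, 0] = a
        state.owner[0, 1] = b
        state.refresh_cache()
        table = ContactEnergyTable(neighbor_order=1)
        table.set(OCC, IPC, 5.0)
        assert contact_energy(state, table) == 5.0

    def test_linear_in_J(self, rng):
        state = random_lattice(rng)
        table = random_table(rng)
        doubled = ContactEnergyTable(2 * table.J, table.neighbor_order)
        assert contact_energy(state, doubled) == pytest.approx(
            2 * contact_energy(state, table))

    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_brute_force(self, rng, order):
        state = random_lattice(rng)
        table = random_table(rng, neighbor_order=order)
        assert contact_energy(state, table) == pytest.approx(
            brute_contact(state, table))


class TestCellTerms:
    def test_area_zero_at_target(self):
        state = LatticeState(10, 10)
        cid = state.new_cell(OCC, target_area=36, lam_area=2.0)
        state.owner[2:8, 2:8] = cid
        state.refresh_cache()
        assert area_energy(state.cell(cid)) == 0.0

    def test_area_quadratic(self):
        state = LatticeState(12, 10)
        cid = state.new_cell(OCC, target_area=36, lam_area=2.0)
        state.owner[2:8, 2:8] = cid
        state.owner[2:4, 8] = cid  # 38 sites
        state.refresh_cache()
        assert area_energy(state.cell(cid)) == 8.0  # 2 * 2^2

    def test_matrix_is_unconstrained(self):
        state = LatticeState(10, 10)
        state.lam_area[0] = 3.0  # even with a strength set, type wins
        state.target_area[0] = 1.0
        assert area_energy(state.cell(0)) == 0.0
        assert perimeter_energy(state.cell(0)) == 0.0

    def test_square_cell_edge_count_perimeter(self):
        state = LatticeState(12, 12)
        cid = state.new_cell(OCC, target_perim=24.0, lam_perim=1.0)
        state.owner[3:9, 3:9] = cid  # isolated 6x6 block
        state.refresh_cache()
        assert state.cell(cid).perimeter == 24
        assert perimeter_energy(state.cell(cid)) == 0.0

    def test_perimeter_quadratic(self):
        state = LatticeState(14, 10)
        cid = state.new_cell(OCC, target_perim=24.0, lam_perim=1.0)
        state.owner[3:9, 3:9] = cid
        state.owner[4, 9] = cid  # bump adds 2 edge units
        state.refresh_cache()
        assert perimeter_energy(state.cell(cid)) == pytest.approx(4.0)


class TestFppEnergy:
    def _two_cells(self, d):
        state = LatticeState(40, 10)
        a = state.new_cell(OCC)
        b = state.new_cell(IPC)
        state.owner[4, 2] = a
        state.owner[4, 2 + d] = b
        state.refresh_cache()
        return state, a, b

    def test_link_at_target_contributes_zero(self):
        state, a, b = self._two_cells(6)
        state.add_link(FppLink(a, b, 10.0, 6.0))
        assert fpp_energy(state) == pytest.approx(0.0)

    def test_stretched_link(self):
        state, a, b = self._two_cells(8)
        state.add_link(FppLink(a, b, 10.0, 6.0))
        assert fpp_energy(state) == pytest.approx(40.0)  # 10 * 2^2

    def test_no_links_is_zero(self):
        state, _, _ = self._two_cells(5)
        assert fpp_energy(state) == 0.0

    def test_dangling_link_raises(self):
        state, a, b = self._two_cells(5)
        state.add_link(FppLink(a, b, 1.0, 5.0))
        state.owner[state.owner == b] = 0
        state.refresh_cache()
        with pytest.raises(ValueError, match="dangling"):
            fpp_energy(state)


class TestTotalEnergy:
    def test_equals_sum_of_terms(self, rng):
        state = random_lattice(rng, with_links=True)
        table = random_table(rng)
        parts = contact_energy(state, table) + fpp_energy(state)
        for cid in state.cell_ids():
            parts += area_energy(state.cell(cid))
            parts += perimeter_energy(state.cell(cid))
        assert total_energy(state, table) == pytest.approx(parts)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(3):
            state = random_lattice(rng, width=20, height=20, n_cells=6,
                                   with_links=True)
            table = random_table(rng)
            assert total_energy(state, table) == pytest.approx(
                brute_total(state, table))

    def test_all_zero_parameters_give_zero(self, rng):
        state = random_lattice(rng, lam_area=0.0, lam_perim=0.0)
        table = ContactEnergyTable(np.zeros((6, 6)))
        assert total_energy(state, table) == 0.0


class TestDeltaEnergy:
    def _random_neighbor_pair(self, state, rng):
        while True:
            tx = int(rng.integers(1, state.width - 1))
            ty = int(rng.integers(1, state.height - 1))
            dx, dy = [(1, 0), (-1, 0), (0, 1), (0, -1)][int(rng.integers(4))]
            sx, sy = tx + dx, ty + dy
            if state.owner[sy, sx] != state.owner[ty, tx]:
                return (sx, sy), (tx, ty)

    def test_same_owner_short_circuits_to_zero(self, rng):
        state = random_lattice(rng)
        table = random_table(rng)
        assert delta_energy(state, table, (2, 2), (2, 2)) == 0.0

    def test_matches_apply_and_recompute(self, rng):
        """Incremental dH equals full recomputation (200 random attempts)."""
        for _ in range(10):
            state = random_lattice(rng, width=18, height=16, n_cells=4,
                                   with_links=True)
            table = random_table(rng)
            for _ in range(20):
                src, tgt = self._random_neighbor_pair(state, rng)
                before = total_energy(state, table)
                dH = delta_energy(state, table, src, tgt)
                if dH >= 1e29:  # move would orphan a linked cell
                    continue
                nxt = state.copy()
                nxt.owner[tgt[1], tgt[0]] = state.owner[src[1], src[0]]
                nxt.refresh_cache()
                after = total_energy(nxt, table)
                assert dH == pytest.approx(after - before, abs=1e-6)

    def test_mirror_symmetry(self):
        """dH of a copy attempt equals its mirror image's dH."""
        def build(flip):
            state = LatticeState(8, 5)
            a = state.new_cell(OCC, 4, 1.0, 8, 0.5)
            b = state.new_cell(OCC, 4, 1.0, 8, 0.5)
            cols_a, cols_b = (slice(1, 3), slice(5, 7))
            state.owner[2:4, cols_a] = a
            state.owner[2:4, cols_b] = b
            state.refresh_cache()
            return state
        table = ContactEnergyTable(neighbor_order=2)
        table.set(OCC, OCC, 4.0)
        table.set(OCC, MATRIX, 6.0)
        s1 = build(False)
        # grow cell a rightwards at (3,2) vs grow cell b leftwards at (4,2)
        d1 = delta_energy(s1, table, (2, 2), (3, 2))
        d2 = delta_energy(s1, table, (5, 2), (4, 2))
        assert d1 == pytest.approx(d2)

    def test_copy_from_matrix_into_cell_at_target_raises_area_term(self):
        state = LatticeState(12, 12)
        cid = state.new_cell(OCC, target_area=36, lam_area=2.0,
                             target_perim=24, lam_perim=0.0)
        state.owner[3:9, 3:9] = cid
        state.refresh_cache()
        table = ContactEnergyTable(np.zeros((6, 6)))
        # overwrite a corner site of the cell with matrix
        dH = delta_energy(state, table, (2, 3), (3, 3))
        assert dH > 0  # (a-1-A)^2 > 0 when a == A


class TestAttemptCopy:
    def test_negative_dH_always_accepted_and_law_positive(self, rng):
        """min(1, e^-dH/T): dH<0 accepted; empirical rate for dH>0 sane."""
        accept_neg, total_neg = 0, 0
        state = random_lattice(rng, lam_area=0.3, lam_perim=0.2)
        table = random_table(rng)
        params = DynamicsParams(temperature=10.0)
        for _ in range(4000):
            out = attempt_copy(state, table, params, rng, detail=True)
            accepted, dH = out
            if dH is not None and dH < 0:
                total_neg += 1
                accept_neg += accepted
        assert total_neg > 50
        assert accept_neg == total_neg

    def test_same_owner_neighbor_changes_nothing(self, rng):
        state = LatticeState(10, 10)  # all matrix: every draw is same-owner
        table = ContactEnergyTable()
        before = state.owner.copy()
        for _ in range(50):
            assert attempt_copy(state, table, DynamicsParams(), rng) is False
        assert np.array_equal(state.owner, before)
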