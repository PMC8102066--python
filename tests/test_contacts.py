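"""Contact, labeling and discretization rules, checked against a brute-force
oracle that recomputes every residue-pair minimum distance with plain loops."""

import numpy as np
import pytest

from dimerlens.contacts import (
    AnalysisConfig,
    MicrostateLabel,
    _FrameGeometry,
    discretize_trajectory,
    domain_contact_counts,
    label_microstate,
    residue_min_distances,
)
from dimerlens.errors import AnalysisError
from dimerlens.topology_io import DimerTrajectory, ProtomerTopology, Residue
from dimerlens.synthetic import build_toy_dimer


def _make_system(res_beads_a, res_beads_b, coords):
    """res_beads_*: list of (residue_index, domain, [bead ids]); coords: bead->xyz."""
    top_a = ProtomerTopology("A", tuple(
        Residue(i, d, tuple(bs)) for i, d, bs in res_beads_a))
    top_b = ProtomerTopology("B", tuple(
        Residue(i, d, tuple(bs)) for i, d, bs in res_beads_b))
    bead_ids = tuple(b for _, _, bs in res_beads_a for b in bs) + \
        tuple(b for _, _, bs in res_beads_b for b in bs)
    bead_map = {}
    for top in (top_a, top_b):
        for r in top.residues:
            for b in r.bead_ids:
                bead_map[b] = (top.protomer_id, r.index)
    frame = np.array([coords[b] for b in bead_ids], dtype=float)
    traj = DimerTrajectory(frame[None], bead_ids, bead_map, 1.0)
    return (top_a, top_b), traj


def brute_force_min_distances(traj, topology):
    """Independent O(n^2) oracle: explicit loops over residues and beads."""
    import math

    top_a, top_b = topology
    frame = {b: traj.coords[0, i] for i, b in enumerate(traj.bead_ids)}
    out = np.empty((len(top_a.residues), len(top_b.residues)))
    for ia, ra in enumerate(top_a.residues):
        for ib, rb in enumerate(top_b.residues):
            best = np.inf
            for ba in ra.bead_ids:
                for bb in rb.bead_ids:
                    dx, dy, dz = (float(p) - float(q)
                                  for p, q in zip(frame[ba], frame[bb]))
                    best = min(best, math.sqrt(dx * dx + dy * dy + dz * dz))
            out[ia, ib] = best
    return out


class TestResidueMinDistances:
    def test_single_bead_pair(self):
        tops, traj = _make_system(
            [(1, "TM1", ["a1"])], [(1, "TM1", ["b1"])],
            {"a1": (0, 0, 0), "b1": (0, 0, 0.5)},
        )
        d = residue_min_distances(traj.coords[0], traj, tops)
        assert d.shape == (1, 1) and d[0, 0] == pytest.approx(0.5)

    def test_minimum_over_beads(self):
        tops, traj = _make_system(
            [(1, "TM1", ["a1", "a2"])], [(1, "TM1", ["b1"])],
            {"a1": (0, 0, 1.5), "a2": (0, 0, 0.9), "b1": (0, 0, 0)},
        )
        d = residue_min_distances(traj.coords[0], traj, tops)
        assert d[0, 0] == pytest.approx(0.9)

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            # 2 protomers x 5 residues x 4 beads = 40 beads
            res_a = [(i, f"TM{i}", [f"a{i}:{j}" for j in range(4)]) for i in range(1, 6)]
            res_b = [(i, f"TM{i}", [f"b{i}:{j}" for j in range(4)]) for i in range(1, 6)]
            coords = {b: rng.uniform(-2, 2, 3)
                      for _, _, bs in res_a + res_b for b in bs}
            tops, traj = _make_system(res_a, res_b, coords)
            fast = residue_min_distances(traj.coords[0], traj, tops)
            slow = brute_force_min_distances(traj, tops)
            assert np.array_equal(fast, slow)  # exact equality, not approx


class TestDomainContactCounts:
    def _fixture(self, n_partners):
        """25 TM4_A residues, each contacting n_partners TM4_B residues."""
        res_a = [(i, "TM4", [f"a{i}"]) for i in range(1, 26)]
        res_b = [(i, "TM4", [f"b{i}"]) for i in range(1, 26 * n_partners + 1)]
        coords = {}
        for i in range(1, 26):
            coords[f"a{i}"] = (0, 0, i * 10.0)
        k = 1
        for i in range(1, 26):
            for _ in range(n_partners):
                coords[f"b{k}"] = (0.5, 0, i * 10.0)
                k += 1
        for j in range(k, 26 * n_partners + 1):
            coords[f"b{j}"] = (100.0 + j, 0, 0)
        return _make_system(res_a, res_b, coords)

    def test_all_beyond_cutoff(self):
        tops, traj = _make_system(
            [(1, "TM1", ["a1"])], [(1, "TM2", ["b1"])],
            {"a1": (0, 0, 0), "b1": (5, 0, 0)},
        )
        geom = _FrameGeometry(traj, tops)
        d = residue_min_distances(traj.coords[0], traj, tops, _geom=geom)
        ca, cb = domain_contact_counts(d, geom, AnalysisConfig())
        assert ca == {"TM1": 0} and cb == {"TM2": 0}

    def test_attribution_to_own_domain(self):
        tops, traj = _make_system(
            [(1, "TM4", ["a1"])], [(1, "TM5", ["b1"])],
            {"a1": (0, 0, 0), "b1": (0.5, 0, 0)},
        )
        geom = _FrameGeometry(traj, tops)
        d = residue_min_distances(traj.coords[0], traj, tops, _geom=geom)
        ca, cb = domain_contact_counts(d, geom, AnalysisConfig())
        assert ca["TM4"] == 1 and cb["TM5"] == 1

    @pytest.mark.parametrize("n_partners,pair_count", [(1, 25), (2, 50)])
    def test_pair_vs_residue_mode(self, n_partners, pair_count):
        tops, traj = self._fixture(n_partners)
        geom = _FrameGeometry(traj, tops)
        d = residue_min_distances(traj.coords[0], traj, tops, _geom=geom)
        ca_pairs, _ = domain_contact_counts(
            d, geom, AnalysisConfig(count_mode="residue_pairs"))
        ca_res, _ = domain_contact_counts(
            d, geom, AnalysisConfig(count_mode="residues"))
        assert ca_pairs["TM4"] == pair_count
        assert ca_res["TM4"] == 25


class TestLabelMicrostate:
    def test_all_zero_is_monomer(self):
        lab = label_microstate(({"TM1": 0}, {"TM1": 0}), AnalysisConfig())
        assert lab.is_monomeric

    def test_threshold_is_strict(self):
        lab = label_microstate(({"TM4": 20}, {"TM4": 21}), AnalysisConfig())
        assert lab.domains_A == frozenset()
        assert lab.domains_B == {"TM4"}

    def test_multi_domain_label(self):
        lab = label_microstate(
            ({"TM1": 21, "TM4": 22, "TM5": 3}, {"TM5": 40}), AnalysisConfig())
        assert lab.domains_A == {"TM1", "TM4"}
        assert lab.domains_B == {"TM5"}


class TestDiscretizeTrajectory:
    def test_all_monomeric(self):
        pair, traj, _ = build_toy_dimer([("monomer", 5)], seed=1)
        dt = discretize_trajectory(traj, pair)
        assert dt.n_states == 1
        assert dt.label_dict[0].is_monomeric
        assert np.all(dt.contact_matrices[0].values == 0.0)

    def test_scripted_schedule_recovered_in_order(self):
        pair, traj, truth = build_toy_dimer(
            [("TM4|TM4", 100), ("monomer", 100)], seed=2)
        dt = discretize_trajectory(traj, pair)
        assert dt.n_states == 2
        assert [str(dt.label_dict[s]) for s in dt.state_ids[::100]] == \
            ["(TM4|TM4)", "(-|-)"]
        assert [dt.label_dict[int(s)] for s in dt.state_ids] == truth

    def test_contact_matrix_of_scripted_segment(self):
        pair, traj, _ = build_toy_dimer([("TM4|TM4", 50)], seed=3)
        dt = discretize_trajectory(traj, pair)
        cm = dt.contact_matrices[0]
        i4 = cm.domains_A.index("TM4")
        assert cm.values[i4, i4] == 1.0
        far = cm.domains_A.index("TM1")
        assert cm.values[far, far] == 0.0

    def test_protomer_swap_swaps_label_and_transposes_matrix(self, toy_dimer):
        pair, traj, _ = toy_dimer
        dt_fwd = discretize_trajectory(traj, pair)
        dt_rev = discretize_trajectory(traj, (pair[1], pair[0]))
        for f in range(traj.n_frames):
            la = dt_fwd.label_dict[int(dt_fwd.state_ids[f])]
            lb = dt_rev.label_dict[int(dt_rev.state_ids[f])]
            assert lb == la.swapped()
        for sid, lab in dt_fwd.label_dict.items():
            rid = next(r for r, l in dt_rev.label_dict.items() if l == lab.swapped())
            assert np.array_equal(
                dt_rev.contact_matrices[rid].values,
                dt_fwd.contact_matrices[sid].values.T,
            )

    def test_cutoff_monotonicity(self):
        """Enlarging the contact cutoff never shrinks a label's domain sets."""
        pair, traj, _ = build_toy_dimer([("TM4|TM4", 5)], seed=8)
        small = discretize_trajectory(traj, pair, AnalysisConfig(contact_cutoff=1.0))
        large = discretize_trajectory(traj, pair, AnalysisConfig(contact_cutoff=1.3))
        for f in range(traj.n_frames):
            ls = small.label_dict[int(small.state_ids[f])]
            ll = large.label_dict[int(large.state_ids[f])]
            assert ls.domains_A <= ll.domains_A
            assert ls.domains_B <= ll.domains_B

    def test_bead_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        res_a = [(1, "TM1", ["a1", "a2", "a3"])]
        res_b = [(1, "TM1", ["b1", "b2"])]
        coords = {b: rng.uniform(-1, 1, 3) for b in "a1 a2 a3 b1 b2".split()}
        tops, traj = _make_system(res_a, res_b, coords)
        d1 = residue_min_distances(traj.coords[0], traj, tops)
        res_a2 = [(1, "TM1", ["a3", "a1", "a2"])]
        tops2, traj2 = _make_system(res_a2, res_b, coords)
        d2 = residue_min_distances(traj2.coords[0], traj2, tops2)
        assert np.array_equal(d1, d2)
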