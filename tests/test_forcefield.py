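import numpy as np
import pytest

from accommodate import dynamics
from accommodate.errors import (
    GeometryError,
    IntegrityError,
    ParameterError,
)
from accommodate.forcefield import (
    Contact,
    FLAVOR_V2,
    Topology,
    build_bonded_terms,
    build_contact_map,
    delete_segment,
    gaussianize_contacts,
    label_contact_group,
    merge_dual_basin,
    scale_contact_group,
)
from accommodate.structures import Structure
from accommodate.synthetic_systems import two_state_topology
from accommodate.topio import read_topology, write_topology

from conftest import make_chain


def brute_force_contacts(structure, cutoff=4.5, excluded=frozenset()):
    """Independent O(n^2) native-contact scan (the test oracle)."""
    out = set()
    n = len(structure)
    for i in range(n):
        for j in range(i + 1, n):
            if structure.element[i] == "H" or structure.element[j] == "H":
                continue
            if (i, j) in excluded:
                continue
            if (structure.chain[i] == structure.chain[j]
                    and structure.res_id[i] == structure.res_id[j]):
                continue
            if np.linalg.norm(structure.coord[j] - structure.coord[i]) <= cutoff:
                out.add((i, j))
    return out


class TestBondedTerms:
    def test_linear_three_bead_chain(self):
        s, conn = make_chain(3, spacing=3.8)
        bt = build_bonded_terms(s, conn)
        assert len(bt.bonds_idx) == 2
        np.testing.assert_allclose(bt.bonds_r0, 3.8)
        np.testing.assert_allclose(bt.bonds_k, 50.0)
        assert len(bt.angles_idx) == 1
        assert bt.angles_t0[0] == pytest.approx(np.pi)

    @pytest.mark.parametrize("n", [5, 9])
    def test_chain_term_counts(self, n):
        """Combinatorial counts for a chain: n-1 bonds, n-2 angles, n-3
        dihedrals."""
        s, conn = make_chain(n, jitter=0.5, seed=4)
        bt = build_bonded_terms(s, conn)
        assert len(bt.bonds_idx) == n - 1
        assert len(bt.angles_idx) == n - 2
        assert len(bt.propers_idx) == n - 3

    def test_reference_is_energy_minimum(self):
        s, conn = make_chain(6, jitter=0.6, seed=2)
        bt = build_bonded_terms(s, conn)
        top = Topology(n_atoms=6, bonded=bt, contacts=[])
        e = dynamics.energy(top, s.coord)
        assert e.bonds == pytest.approx(0.0, abs=1e-12)
        assert e.angles == pytest.approx(0.0, abs=1e-12)
        assert e.backbone_dihedrals == pytest.approx(0.0, abs=1e-12)
        f = dynamics.forces(top, s.coord)
        # only the (tiny) generic repulsion contributes at the reference
        assert np.abs(f).max() < 1e-4

    def test_bad_bond_indices_rejected(self):
        s, _ = make_chain(3)
        with pytest.raises(IntegrityError):
            build_bonded_terms(s, [(0, 7)])

    def test_zero_length_bond_rejected(self):
        s = Structure(["A", "A"], [1, 2], ["B", "B"], ["C1", "C1"],
                      ["C", "C"], [[0, 0, 0], [0, 0, 0]])
        with pytest.raises(GeometryError):
            build_bonded_terms(s, [(0, 1)])

    def test_dihedral_classes(self):
        s, conn = make_chain(5, jitter=0.5, seed=0,
                             names=["P", "O5'", "C5'", "C4'", "O3'"])
        bt = build_bonded_terms(s, conn)
        assert set(bt.propers_class.tolist()) == {0}
        assert np.all(bt.propers_k == 1.0)
        s2, conn2 = make_chain(5, jitter=0.5, seed=0)  # names C1: sidechain
        bt2 = build_bonded_terms(s2, conn2)
        assert set(bt2.propers_class.tolist()) == {1}
        assert np.all(bt2.propers_k == 0.5)


class TestContactMap:
    @pytest.mark.parametrize("d,expected", [(4.4, 1), (4.6, 0)])
    def test_cutoff_rule(self, d, expected):
        s = Structure(["A", "A"], [1, 2], ["B", "B"], ["C1", "C1"],
                      ["C", "C"], [[0, 0, 0], [d, 0, 0]])
        assert len(build_contact_map(s)) == expected

    def test_same_residue_excluded(self):
        s = Structure(["A", "A"], [1, 1], ["B", "B"], ["C1", "C2"],
                      ["C", "C"], [[0, 0, 0], [3.0, 0, 0]])
        assert build_contact_map(s) == []

    def test_hydrogens_excluded(self):
        s = Structure(["A", "A"], [1, 2], ["B", "B"], ["H1", "C1"],
                      ["H", "C"], [[0, 0, 0], [3.0, 0, 0]])
        assert build_contact_map(s) == []

    def test_bonded_pairs_excluded(self):
        s, conn = make_chain(3, spacing=4.0)
        bt = build_bonded_terms(s, conn)
        # all three atoms share a bond or an angle: nothing remains
        assert build_contact_map(s, cutoff=10.0, bonded=bt) == []

    @pytest.mark.parametrize("state", ["state_A", "state_B"])
    def test_matches_brute_force_scan(self, arm_system, state):
        st = getattr(arm_system, state)
        got = {c.pair for c in build_contact_map(st)}
        assert got == brute_force_contacts(st)

    def test_sigma_is_reference_distance(self, arm_system):
        for c in build_contact_map(arm_system.state_A):
            d = np.linalg.norm(arm_system.state_A.coord[c.j]
                               - arm_system.state_A.coord[c.i])
            assert c.sigma == pytest.approx(d, abs=1e-12)
            assert c.eps == 1.0 and c.weight == 1.0


class TestMergeDualBasin:
    def test_disjoint_sets_weighting(self):
        p1 = [Contact(0, 1, 4.0)]
        p2 = [Contact(2, 3, 3.5)]
        merged = merge_dual_basin(p1, p2, 0.13)
        by_pair = {c.pair: c for c in merged}
        assert by_pair[(0, 1)].weight == 1.0 and by_pair[(0, 1)].basin == "AT"
        assert by_pair[(2, 3)].weight == 0.13 and by_pair[(2, 3)].basin == "AA"

    def test_identity_at_weight_one(self):
        cs = [Contact(0, 1, 4.0), Contact(1, 2, 3.0)]
        merged = merge_dual_basin(cs, cs, 1.0)
        assert [(c.pair, c.sigma, c.weight) for c in merged] == \
            [(c.pair, c.sigma, 1.0) for c in cs]
        assert all(c.basin == "shared" for c in merged)

    def test_shared_pairs_keep_at_geometry(self):
        at = [Contact(0, 1, 4.0)]
        aa = [Contact(0, 1, 3.2)]
        merged = merge_dual_basin(at, aa, 0.4)
        assert merged[0].sigma == 4.0
        assert merged[0].weight == 1.0
        assert merged[0].basin == "shared"

    def test_partition_matches_set_algebra(self, arm_system):
        at_map = build_contact_map(arm_system.state_A)
        aa_map = build_contact_map(arm_system.state_B)
        merged = merge_dual_basin(at_map, aa_map, 0.13)
        at, aa = {c.pair for c in at_map}, {c.pair for c in aa_map}
        assert {c.pair for c in merged if c.basin == "AT"} == at - aa
        assert {c.pair for c in merged if c.basin == "AA"} == aa - at
        assert {c.pair for c in merged if c.basin == "shared"} == at & aa

    def test_bad_weight_and_roster(self):
        with pytest.raises(ParameterError):
            merge_dual_basin([], [], 0.0)
        with pytest.raises(IntegrityError):
            merge_dual_basin([Contact(0, 9, 4.0)], [], 0.5, n_atoms=5)


class TestScaleContactGroup:
    def setup_method(self):
        s = Structure(["M", "T"], [1, 1], ["A", "U"], ["C1", "C1"],
                      ["C", "C"], [[0, 0, 0], [4, 0, 0]])
        contacts = build_contact_map(s)
        self.contacts = label_contact_group(
            contacts, s, "codon-anticodon",
            lambda st, i, j: {st.chain[i], st.chain[j]} == {"M", "T"},
        )

    def test_group_scaling(self):
        out = scale_contact_group(self.contacts, "codon-anticodon", 0.8)
        assert [c.weight for c in out] == [0.8]

    def test_identity_factor(self):
        out = scale_contact_group(self.contacts, "codon-anticodon", 1.0)
        assert [c.weight for c in out] == [1.0]

    def test_multiplicative_composition(self):
        out = scale_contact_group(self.contacts, "codon-anticodon", 0.5)
        out = scale_contact_group(out, "codon-anticodon", 0.5)
        assert out[0].weight == pytest.approx(0.25)

    def test_unmatched_untouched_and_errors(self):
        out = scale_contact_group(self.contacts, "other-group", 0.5)
        assert [c.weight for c in out] == [1.0]
        with pytest.raises(ParameterError):
            scale_contact_group(self.contacts, "codon-anticodon", 0.0)


class TestGaussianContacts:
    def test_depth_at_sigma_matches_weighted_eps(self, arm_system):
        top = two_state_topology(arm_system, weight_AA=0.4,
                                 flavor=FLAVOR_V2)
        # place two isolated atoms at each contact's sigma and evaluate
        for c, gw in zip(top.contacts[:4], top.gauss_width[:4]):
            e = c.eps * c.weight
            sn = top.sigma_nc
            r = c.sigma
            amp = 1.0 + (sn / r) ** 12
            v = e * ((sn / r) ** 12 - amp * 1.0)
            assert v == pytest.approx(-e, rel=1e-12)

    def test_limits(self, arm_topology_v2):
        # far apart: contact energy ~ 0; near zero: repulsion dominates
        c0 = arm_topology_v2.contacts[0]
        sn = arm_topology_v2.sigma_nc
        gw = float(arm_topology_v2.gauss_width[0])
        amp = 1.0 + (sn / c0.sigma) ** 12
        for r, expect_sign in [(200.0, 0), (0.5, 1)]:
            v = (sn / r) ** 12 - amp * np.exp(-((r - c0.sigma) ** 2) / (2 * gw * gw))
            if expect_sign == 0:
                assert abs(v) < 1e-10
            else:
                assert v > 1e3

    def test_width_rule_and_errors(self, arm_topology_v1):
        top = gaussianize_contacts(arm_topology_v1, lambda c: 0.25)
        assert np.all(top.gauss_width == 0.25)
        with pytest.raises(ParameterError):
            gaussianize_contacts(arm_topology_v1, 0.0)
        with pytest.raises(ParameterError):
            gaussianize_contacts(top)  # already v2


class TestDeleteSegment:
    def test_gate_deletion_drops_gate_contacts(self, arm_system):
        top = two_state_topology(arm_system, weight_AA=0.13)
        gate = set(int(g) for g in arm_system.gate.indices)
        gate_contacts = [c for c in top.contacts
                         if c.i in gate or c.j in gate]
        new_top, new_st = delete_segment(top, arm_system.state_A,
                                         [("G", 1, 3)])
        assert len(new_st) == len(arm_system.state_A) - 3
        assert len(new_top.contacts) == len(top.contacts) - len(gate_contacts)

    def test_empty_range_is_identity(self, arm_system, arm_topology_v1):
        top, st = delete_segment(arm_topology_v1, arm_system.state_A, [])
        assert top is arm_topology_v1 and st is arm_system.state_A

    def test_energy_finite_after_deletion(self, arm_system):
        top = two_state_topology(arm_system, weight_AA=0.13)
        new_top, new_st = delete_segment(top, arm_system.state_A, [("G", 1, 3)])
        e = dynamics.energy(new_top, new_st.coord)
        assert np.isfinite(e.total)
        assert e.bonds == pytest.approx(0.0, abs=1e-12)

    def test_probe_atoms_protected(self, arm_system, arm_topology_v1):
        with pytest.raises(ParameterError, match="protected"):
            delete_segment(arm_topology_v1, arm_system.state_A,
                           [("A", 8, 8)], protected=arm_system.probe_pair)

    def test_missing_range_rejected(self, arm_system, arm_topology_v1):
        with pytest.raises(ParameterError, match="no residues"):
            delete_segment(arm_topology_v1, arm_system.state_A, [("Z", 1, 5)])


class TestTopologyIO:
    @pytest.mark.parametrize("fixture", ["arm_topology_v1", "arm_topology_v2"])
    def test_round_trip(self, request, tmp_path, fixture):
        top = request.getfixturevalue(fixture)
        path = tmp_path / "sys.top"
        write_topology(top, str(path))
        back = read_topology(str(path))
        assert back.n_atoms == top.n_atoms
        assert back.flavor == top.flavor
        np.testing.assert_array_equal(back.bonded.bonds_idx, top.bonded.bonds_idx)
        np.testing.assert_array_equal(back.bonded.bonds_r0, top.bonded.bonds_r0)
        np.testing.assert_array_equal(back.bonded.angles_t0, top.bonded.angles_t0)
        np.testing.assert_array_equal(back.bonded.propers_p0, top.bonded.propers_p0)
        assert [(c.pair, c.sigma, c.weight, c.basin) for c in back.contacts] == \
            [(c.pair, c.sigma, c.weight, c.basin) for c in top.contacts]
        # identical energies on the same coordinates
        sys_coord = np.random.default_rng(0).normal(0, 10, (top.n_atoms, 3))
        assert dynamics.energy(back, sys_coord).total == \
            pytest.approx(dynamics.energy(top, sys_coord).total, rel=1e-12)
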