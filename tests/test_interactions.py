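"""Salt-bridge detection, distance monitoring and donor-angle checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allokit.interactions import (
    ACIDIC_OXYGENS,
    BASIC_NITROGENS,
    DistanceSeries,
    detect_salt_bridges,
    donor_angle_formed,
    pair_distance_series,
    reference_carbon,
    window_populations,
)
from allokit.scenario import (
    ARG_STABLE,
    ASP_STABLE,
    GLU_SWITCH,
    ARG_SWITCH,
    default_scaffold,
)
from allokit.synthetic import apply_two_state_switch, build_toy_receptor
from allokit.trajectory import Ensemble

from conftest import make_topology, random_rotation


@pytest.mark.parametrize(
    "res,atom", [("ARG", "CZ"), ("LYS", "CE"), ("GLU", "CD"), ("ASP", "CG")]
)
def test_reference_carbons(res, atom):
    assert reference_carbon(res) == atom


def test_reference_carbon_rejects_others():
    with pytest.raises(ValueError):
        reference_carbon("SER")


def test_engineered_pair_is_detected(toy_receptor):
    """Arg/Asp pair placed at minimum N-O distance 3.0 Å forms a bridge."""
    contacts = detect_salt_bridges(toy_receptor)
    keys = {(c.acidic[:2], c.basic[:2]) for c in contacts}
    assert (ASP_STABLE, ARG_STABLE) in keys
    contact = next(c for c in contacts if c.acidic[:2] == ASP_STABLE)
    assert np.isclose(contact.min_distance[0], 3.0, atol=1e-6)
    assert contact.formed.all()


def test_pair_beyond_cutoff_is_omitted(toy_receptor):
    """Moving the Asp 0.4 Å away puts the minimum at ~3.4 Å: not reported."""
    topo = toy_receptor.topology
    coords = toy_receptor.coords.copy()
    asp = topo.residue_atom_indices(*ASP_STABLE)
    coords[:, asp, 0] += 0.4   # facing direction is x
    moved = Ensemble(topo, coords)
    contacts = detect_salt_bridges(moved)
    assert all(c.acidic[:2] != ASP_STABLE for c in contacts)


def _oracle_salt_bridges(ensemble, cutoff):
    """Exhaustive double loop over all acidic-O / basic-N atom pairs."""
    topo = ensemble.topology
    found = {}
    for i in range(topo.n_atoms):
        rn_i = topo.res_names[i]
        if rn_i not in ACIDIC_OXYGENS or topo.atom_names[i] not in ACIDIC_OXYGENS[rn_i]:
            continue
        for j in range(topo.n_atoms):
            rn_j = topo.res_names[j]
            if rn_j not in BASIC_NITROGENS or topo.atom_names[j] not in BASIC_NITROGENS[rn_j]:
                continue
            key = (
                (topo.chain_ids[i], int(topo.res_ids[i])),
                (topo.chain_ids[j], int(topo.res_ids[j])),
            )
            d = np.linalg.norm(
                ensemble.coords[:, i, :] - ensemble.coords[:, j, :], axis=1
            )
            found[key] = np.minimum(found[key], d) if key in found else d
    return {k: v for k, v in found.items() if (v <= cutoff).any()}


def _random_charged_ensemble(seed, n_res=12, n_frames=3, box=12.0):
    rng = np.random.default_rng(seed)
    rows, coord_rows = [], []
    atom_sets = {
        "ASP": [("CG", "C"), ("OD1", "O"), ("OD2", "O")],
        "GLU": [("CD", "C"), ("OE1", "O"), ("OE2", "O")],
        "ARG": [("CZ", "C"), ("NE", "N"), ("NH1", "N"), ("NH2", "N")],
        "LYS": [("CE", "C"), ("NZ", "N")],
        "SER": [("OG", "O")],
    }
    for rid in range(1, n_res + 1):
        res = rng.choice(list(atom_sets))
        for an, el in atom_sets[res]:
            rows.append((an, el, res, rid, "A"))
    topo = make_topology(rows)
    coords = rng.uniform(0, box, size=(n_frames, topo.n_atoms, 3))
    return Ensemble(topo, coords)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_detection_matches_exhaustive_oracle(seed):
    ens = _random_charged_ensemble(seed)
    contacts = detect_salt_bridges(ens, cutoff=3.2)
    oracle = _oracle_salt_bridges(ens, 3.2)
    ours = {(c.acidic[:2], c.basic[:2]): c.min_distance for c in contacts}
    assert set(ours) == set(oracle)
    for key in oracle:
        np.testing.assert_allclose(ours[key], oracle[key], atol=1e-10)
        formed = next(
            c for c in contacts if (c.acidic[:2], c.basic[:2]) == key
        ).formed
        np.testing.assert_array_equal(formed, oracle[key] <= 3.2)


def test_extended_acceptors_include_phosphoserine():
    rows = [
        ("O1P", "O", "SEP", 1, "A"),
        ("O2P", "O", "SEP", 1, "A"),
        ("NZ", "N", "LYS", 2, "A"),
    ]
    topo = make_topology(rows)
    coords = np.array([[[0, 0, 0], [1.5, 0, 0], [2.8, 0, 0.0]]], dtype=float)
    ens = Ensemble(topo, coords)
    assert detect_salt_bridges(ens, extended_acceptors=False) == []
    contacts = detect_salt_bridges(ens, extended_acceptors=True)
    assert len(contacts) == 1 and contacts[0].acidic[2] == "SEP"


class TestDistanceSeries:
    def test_constant_separation(self, toy_receptor):
        ens = Ensemble(
            toy_receptor.topology, np.repeat(toy_receptor.coords, 4, axis=0)
        )
        series = pair_distance_series(ens, GLU_SWITCH, ARG_SWITCH)
        np.testing.assert_allclose(series.distances, series.distances[0])

    def test_two_state_fixture_clusters(self, toy_receptor):
        topo = toy_receptor.topology
        a = topo.atom_index(*GLU_SWITCH, "CD")
        b = topo.atom_index(*ARG_SWITCH, "CZ")
        base = Ensemble(topo, np.repeat(toy_receptor.coords, 400, axis=0))
        switched = apply_two_state_switch(base, a, b, 4.0, 6.25, 0.5, 0.0, seed=2)
        series = pair_distance_series(switched, GLU_SWITCH, ARG_SWITCH)
        near = np.isclose(series.distances, 4.0, atol=1e-9)
        far = np.isclose(series.distances, 6.25, atol=1e-9)
        assert (near | far).all() and near.any() and far.any()

    def test_distances_are_rigid_motion_invariant(self, toy_receptor):
        rng = np.random.default_rng(0)
        rot = random_rotation(rng)
        moved = Ensemble(
            toy_receptor.topology, toy_receptor.coords @ rot.T + 4.0
        )
        d0 = pair_distance_series(toy_receptor, GLU_SWITCH, ARG_SWITCH).distances
        d1 = pair_distance_series(moved, GLU_SWITCH, ARG_SWITCH).distances
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_unresolvable_atom_is_named(self, toy_receptor):
        with pytest.raises(KeyError, match="CB"):
            pair_distance_series(
                toy_receptor, GLU_SWITCH, ARG_SWITCH, atom_rule=("CD", "CB")
            )


class TestWindowPopulations:
    def test_single_window_captures_all(self):
        series = DistanceSeries(0, 1, "x", np.full(100, 4.0))
        out = window_populations(series, 0.5, ((3.5, 4.5),))
        assert out.windows[0][2] == 1.0
        assert out.counts.sum() == 100

    def test_two_state_populations_within_binomial_bound(self, toy_receptor):
        topo = toy_receptor.topology
        a = topo.atom_index(*GLU_SWITCH, "CD")
        b = topo.atom_index(*ARG_SWITCH, "CZ")
        n = 5000
        base = Ensemble(topo, np.repeat(toy_receptor.coords, n, axis=0))
        switched = apply_two_state_switch(base, a, b, 4.0, 6.25, 0.65, 0.1, seed=9)
        series = pair_distance_series(switched, GLU_SWITCH, ARG_SWITCH)
        out = window_populations(series, 0.5, ((3.5, 4.5), (5.75, 6.75)))
        half_width = 2.576 * np.sqrt(0.65 * 0.35 / n)     # 99% binomial interval
        assert abs(out.windows[0][2] - 0.65) < half_width
        assert abs(out.windows[1][2] - 0.35) < half_width

    def test_disjoint_partition_sums_to_one(self):
        rng = np.random.default_rng(1)
        series = DistanceSeries(0, 1, "x", rng.uniform(2.0, 8.0, size=1000))
        windows = tuple((lo, lo + 2.0) for lo in (0.0, 2.0, 4.0, 6.0, 8.0))
        out = window_populations(series, 0.5, windows)
        assert abs(sum(w[2] for w in out.windows) - 1.0) < 1e-9

    def test_histogram_conserves_frames(self):
        rng = np.random.default_rng(2)
        series = DistanceSeries(0, 1, "x", rng.uniform(2.0, 8.0, size=777))
        out = window_populations(series, 0.5)
        assert out.counts.sum() == 777


class TestDonorAngle:
    @staticmethod
    def _angle_ensemble(o_pos):
        rows = [("NE", "N", "ARG", 1, "A"), ("HE", "H", "ARG", 1, "A"),
                ("OD1", "O", "ASP", 2, "A")]
        topo = make_topology(rows)
        coords = np.array([[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], list(o_pos)]])
        return Ensemble(topo, coords)

    def test_collinear_is_formed(self):
        ens = self._angle_ensemble((3.0, 0.0, 0.0))
        assert donor_angle_formed(ens, 0, 1, 2).all()

    def test_right_angle_is_broken(self):
        ens = self._angle_ensemble((1.0, 2.0, 0.0))
        assert not donor_angle_formed(ens, 0, 1, 2).any()

    def test_threshold_is_inclusive(self):
        # right-angle geometry evaluates to exactly 90 deg (cos = 0.0), so a
        # 90 deg threshold exercises the inclusive boundary without rounding
        ens = self._angle_ensemble((1.0, 2.0, 0.0))
        assert donor_angle_formed(ens, 0, 1, 2, min_angle=90.0).all()
        # and the threshold location is tight around the true angle
        theta = np.deg2rad(180.0 - 120.0)
        ens = self._angle_ensemble((1.0 + 2.0 * np.cos(theta), 2.0 * np.sin(theta), 0.0))
        assert donor_angle_formed(ens, 0, 1, 2, min_angle=120.0 - 1e-9).all()
        assert not donor_angle_formed(ens, 0, 1, 2, min_angle=120.0 + 1e-9).any()

    def test_distinct_atoms_required(self):
        ens = self._angle_ensemble((3.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            donor_angle_formed(ens, 0, 0, 2)
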