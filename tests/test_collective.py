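"""Quasi-harmonic analysis and cross-correlation matrices/networks."""

import warnings

import numpy as np
import pandas as pd
import pytest

from allokit.collective import (
    CorrelationMatrix,
    correlation_network,
    cross_correlation_matrix,
    mode_rmsf,
    quasi_harmonic_modes,
)
from allokit.constants import (
    C_CM_PER_PS,
    KB_KCAL_PER_MOL_K,
    KCAL_PER_MOL_TO_AMU_A2_PS2,
)
from allokit.fluctuations import rmsf
from allokit.scenario import _collective_mode, default_scaffold
from allokit.selection import select
from allokit.synthetic import (
    GroundTruth,
    build_ideal_helix,
    build_toy_receptor,
    sample_gaussian_ensemble,
)
from allokit.trajectory import Ensemble

from conftest import make_topology


def _quiet_qha(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return quasi_harmonic_modes(*args, **kwargs)


def _oscillator_ensemble(kappa, mass, n, seed, temperature=300.0):
    """1-D harmonic oscillator samples: x ~ N(0, k_B T / kappa)."""
    topo = make_topology([("CA", "C", "ALA", 1, "A")])
    topo.masses[0] = mass
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n) * np.sqrt(KB_KCAL_PER_MOL_K * temperature / kappa)
    coords = np.zeros((n, 1, 3))
    coords[:, 0, 0] = x
    return Ensemble(topo, coords)


def oscillator_frequency_cm(kappa, mass):
    return np.sqrt(KCAL_PER_MOL_TO_AMU_A2_PS2 * kappa / mass) / (
        2 * np.pi * C_CM_PER_PS
    )


class TestQHA:
    def test_mode_count_is_3n(self):
        helix = build_ideal_helix(5)
        rng = np.random.default_rng(0)
        coords = helix.coords[0] + rng.normal(0, 0.3, size=(100, 5, 3))
        qha = _quiet_qha(Ensemble(helix.topology, coords), select(helix.topology, "calpha"))
        assert qha.n_modes == 15
        assert qha.eigenvalues.shape == (15,)

    def test_oscillator_frequency_recovered(self):
        kappa, mass = 1.0, 12.011
        ens = _oscillator_ensemble(kappa, mass, 20_000, seed=5)
        qha = _quiet_qha(ens, select(ens.topology, "calpha"), superpose=False)
        expected = oscillator_frequency_cm(kappa, mass)
        assert abs(qha.frequencies_cm[0] - expected) / expected < 0.05

    def test_eigenvalue_sum_equals_trace(self, toy_receptor):
        gt = GroundTruth(per_atom_sigma=0.4)
        ens = sample_gaussian_ensemble(toy_receptor, gt, 500, seed=1)
        sel = select(ens.topology, "calpha")
        qha = _quiet_qha(ens, sel)
        idx = sel.indices
        from allokit.fluctuations import mean_structure, superpose_frames

        ref = mean_structure(ens, sel)
        fitted, _ = superpose_frames(ens.coords, ref, sel)
        delta = (fitted[:, idx] - ref[idx]) * np.sqrt(ens.topology.masses[idx])[None, :, None]
        x = delta.reshape(ens.n_frames, -1)
        trace = np.trace(x.T @ x / ens.n_frames)
        assert abs(qha.eigenvalues.sum() - trace) < 1e-6 * trace

    def test_modes_orthonormal(self, toy_receptor):
        gt = GroundTruth(per_atom_sigma=0.4)
        ens = sample_gaussian_ensemble(toy_receptor, gt, 400, seed=2)
        qha = _quiet_qha(ens, select(ens.topology, "calpha"))
        gram = qha.modes.T @ qha.modes
        np.testing.assert_allclose(gram, np.eye(qha.n_modes), atol=1e-6)

    def test_injected_mode_dominates(self, toy_receptor):
        mode = _collective_mode(toy_receptor)
        gt = GroundTruth(per_atom_sigma=0.3, modes=(mode,))
        ens = sample_gaussian_ensemble(toy_receptor, gt, 2000, seed=3)
        sel = select(ens.topology, "calpha")
        qha = _quiet_qha(ens, sel)
        assert qha.eigenvalues[0] > 10 * qha.eigenvalues[1]
        v = mode.vector[sel.indices].ravel()
        mw = v * np.sqrt(ens.topology.masses[sel.indices].repeat(3))
        mw /= np.linalg.norm(mw)
        assert abs(qha.modes[:, 0] @ mw) > 0.9

    def test_rigid_modes_flagged_after_superposition(self, toy_receptor):
        gt = GroundTruth(per_atom_sigma=0.4)
        ens = sample_gaussian_ensemble(toy_receptor, gt, 2000, seed=4)
        qha = _quiet_qha(ens, select(ens.topology, "calpha"))
        assert qha.n_rigid == 6

    def test_frequency_converges_with_sampling(self):
        """Median frequency error decreases monotonically with sample size."""
        kappa, mass = 1.0, 12.011
        expected = oscillator_frequency_cm(kappa, mass)
        med_errs = []
        for n in (500, 2000, 8000):
            errs = []
            for seed in range(7):
                ens = _oscillator_ensemble(kappa, mass, n, seed=seed)
                qha = _quiet_qha(ens, select(ens.topology, "calpha"), superpose=False)
                errs.append(abs(qha.frequencies_cm[0] - expected))
            med_errs.append(np.median(errs))
        assert med_errs[0] > med_errs[1] > med_errs[2]

    def test_static_ensemble_rejected(self, helix22):
        ens = Ensemble(helix22.topology, np.repeat(helix22.coords, 5, axis=0))
        with pytest.raises(ValueError, match="variance"):
            _quiet_qha(ens, select(ens.topology, "calpha"))


class TestModeRMSF:
    def test_all_modes_recover_ensemble_rmsf(self, toy_receptor):
        gt = GroundTruth(per_atom_sigma=0.4)
        ens = sample_gaussian_ensemble(toy_receptor, gt, 1500, seed=6)
        sel = select(ens.topology, "calpha")
        qha = _quiet_qha(ens, sel)
        full = mode_rmsf(qha, ens, sel, len(qha.frequencies_cm))
        direct = rmsf(ens, sel)
        ratio = full.values.to_numpy() / direct.values.to_numpy()
        assert np.all(np.abs(ratio - 1.0) < 0.1)

    def test_single_dominant_mode_peaks_on_displaced_residues(self, toy_receptor):
        # raw block mode on pre-aligned frames: the profile must localise
        # exactly on the displaced residues
        topo = toy_receptor.topology
        vec = np.zeros((toy_receptor.n_atoms, 3))
        moving_mask = (
            ((topo.res_ids >= 1) & (topo.res_ids <= 10))
            | ((topo.res_ids >= 31) & (topo.res_ids <= 40))
        ) & (topo.atom_names == "CA")
        vec[moving_mask, 2] = 1.0
        from allokit.synthetic import CollectiveMode

        gt = GroundTruth(per_atom_sigma=0.3, modes=(CollectiveMode(8.0, vec),))
        ens = sample_gaussian_ensemble(toy_receptor, gt, 2000, seed=7)
        sel = select(ens.topology, "calpha")
        qha = _quiet_qha(ens, sel, superpose=False)
        profile = mode_rmsf(qha, ens, sel, 1)
        top = {rid for _, rid in profile.values.nlargest(20).index}
        moving = set(range(1, 11)) | set(range(31, 41))
        assert top == moving

    def test_uniform_fixture_is_near_flat(self, toy_receptor):
        gt = GroundTruth(per_atom_sigma=0.5)
        ens = sample_gaussian_ensemble(toy_receptor, gt, 5000, seed=8)
        sel = select(ens.topology, "calpha")
        qha = _quiet_qha(ens, sel)
        profile = mode_rmsf(qha, ens, sel, len(qha.frequencies_cm))
        vals = profile.values.to_numpy()
        assert vals.max() / vals.min() < 1.5

    def test_mode_count_validated(self, toy_receptor):
        gt = GroundTruth(per_atom_sigma=0.4)
        ens = sample_gaussian_ensemble(toy_receptor, gt, 300, seed=9)
        sel = select(ens.topology, "calpha")
        qha = _quiet_qha(ens, sel)
        with pytest.raises(ValueError):
            mode_rmsf(qha, ens, sel, 0)
        with pytest.raises(ValueError):
            mode_rmsf(qha, ens, sel, 10_000)


def _anchored_ensemble(disp_a, disp_b, n=400):
    """Two moving atoms + two static anchors; displacements are internal."""
    rows = [
        ("CA", "C", "ALA", 1, "A"),
        ("CA", "C", "ALA", 2, "A"),
        ("CA", "C", "ALA", 3, "A"),
        ("CA", "C", "ALA", 4, "A"),
    ]
    topo = make_topology(rows)
    base = np.array(
        [[-3.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 5.0, 2.0], [0.0, -5.0, 2.0]]
    )
    rng = np.random.default_rng(0)
    amp = rng.standard_normal(n)
    coords = np.repeat(base[None], n, axis=0)
    coords[:, 0] += np.outer(amp, disp_a)
    coords[:, 1] += np.outer(amp, disp_b)
    return Ensemble(topo, coords).ensure_times(dt=10.0)


class TestCorrelations:
    def test_identical_motion_gives_plus_one(self):
        ens = _anchored_ensemble(np.array([0, 0, 0.5]), np.array([0, 0, 0.5]))
        sel = select(ens.topology, "calpha")
        cm = cross_correlation_matrix(ens, sel, 500.0, superpose=False)
        assert cm.matrix.loc["A:1", "A:2"] == pytest.approx(1.0, abs=1e-9)

    def test_antiphase_motion_gives_minus_one(self):
        ens = _anchored_ensemble(np.array([-0.5, 0, 0]), np.array([0.5, 0, 0]))
        sel = select(ens.topology, "calpha")
        cm = cross_correlation_matrix(ens, sel, 500.0, superpose=False)
        assert cm.matrix.loc["A:1", "A:2"] == pytest.approx(-1.0, abs=1e-9)

    def test_unit_diagonal_and_symmetry(self, toy_receptor):
        gt = GroundTruth(per_atom_sigma=0.4)
        ens = sample_gaussian_ensemble(toy_receptor, gt, 600, seed=10, dt=10.0)
        sel = select(ens.topology, "calpha")
        cm = cross_correlation_matrix(ens, sel, 500.0)
        m = cm.matrix.to_numpy()
        np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-9)
        np.testing.assert_allclose(m, m.T, atol=1e-9)
        assert np.nanmax(np.abs(m)) <= 1.0 + 1e-9

    def test_white_noise_has_small_off_diagonal(self, toy_receptor):
        gt = GroundTruth(per_atom_sigma=0.5)
        ens = sample_gaussian_ensemble(toy_receptor, gt, 5000, seed=11, dt=10.0)
        sel = select(ens.topology, "calpha")
        m100 = cross_correlation_matrix(ens, sel, 100.0).matrix.to_numpy()
        m500 = cross_correlation_matrix(ens, sel, 500.0).matrix.to_numpy()
        off = ~np.eye(len(m100), dtype=bool)
        assert np.abs(m100[off]).max() < 0.1
        assert np.abs(m100[off] - m500[off]).max() < 0.05

    def test_no_complete_block_rejected(self, toy_receptor):
        gt = GroundTruth(per_atom_sigma=0.4)
        ens = sample_gaussian_ensemble(toy_receptor, gt, 3, seed=12, dt=10.0)
        with pytest.raises(ValueError):
            cross_correlation_matrix(ens, select(ens.topology, "calpha"), 1e6)


class TestCorrelationNetwork:
    @staticmethod
    def _matrix(value):
        labels = [f"A:{i}" for i in (10, 50, 90)]
        m = np.eye(3)
        m[0, 1] = m[1, 0] = value
        df = pd.DataFrame(m, index=labels, columns=labels)
        residues = tuple(("A", i, "ALA") for i in (10, 50, 90))
        return CorrelationMatrix(df, residues, 500.0, 1)

    def test_strong_positive_edge(self):
        edges = correlation_network(self._matrix(0.75), ["A:10"])
        assert len(edges) == 1
        assert edges.iloc[0]["class"] == "[0.7,1.0]"
        assert edges.iloc[0].res_j == "A:50"

    def test_between_bins_yields_no_edge(self):
        edges = correlation_network(self._matrix(0.15), ["A:10"])
        assert edges.empty

    def test_anticorrelated_edge(self):
        edges = correlation_network(self._matrix(-0.15), ["A:10"])
        assert len(edges) == 1
        assert edges.iloc[0]["class"] == "[-0.2,-0.1)"

    def test_empty_focus_rejected(self):
        with pytest.raises(ValueError):
            correlation_network(self._matrix(0.5), [])
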