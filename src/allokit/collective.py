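"""Quasi-harmonic analysis and block-averaged cross-correlation matrices.

Quasi-harmonic analysis diagonalises the mass-weighted covariance of
atomic displacements about the ensemble mean,

    sigma = < sqrt(m_i) dr_i  (sqrt(m_j) dr_j)^T >,

yielding 3N modes whose eigenvalues lambda_k (amu Å²) map to effective
vibrational frequencies nu_k = (1/2 pi c) sqrt(k_B T / lambda_k) through
equipartition; large-eigenvalue modes are the low-frequency collective
motions.  Inter-residue coupling is measured by the normalised
cross-correlation

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>)

computed over consecutive time blocks (each with its own mean structure)
and averaged, which suppresses the spurious correlations a single long
average picks up from slow drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import C_CM_PER_PS, KB_KCAL_PER_MOL_K, KCAL_PER_MOL_TO_AMU_A2_PS2
from .fluctuations import FluctuationProfile, mean_structure, superpose_frames
from .selection import Selection
from .trajectory import Ensemble

__all__ = [
    "QHAResult",
    "CorrelationMatrix",
    "quasi_harmonic_modes",
    "mode_rmsf",
    "cross_correlation_matrix",
    "correlation_network",
    "NETWORK_BINS",
]

#: Correlation-network classes: one anti-correlated bin and four positive
#: bins, half-open except the last which is closed at 1.0.
NETWORK_BINS = (
    (-0.2, -0.1, "[-0.2,-0.1)"),
    (0.2, 0.3, "[0.2,0.3)"),
    (0.3, 0.4, "[0.3,0.4)"),
    (0.4, 0.7, "[0.4,0.7)"),
    (0.7, 1.0, "[0.7,1.0]"),
)

_RIGID_TOL_REL = 1e-8   # eigenvalues below this fraction of the largest are
                        # flagged quasi-rigid (six expected after superposition)


@dataclass(frozen=True)
class QHAResult:
    """Eigen-decomposition of the mass-weighted fluctuation covariance.

    ``eigenvalues`` are sorted descending (amu Å²); ``frequencies_cm``
    ascending, one per mode above the rigid tolerance, so the first
    frequency corresponds to the first (largest) eigenvalue.  ``modes``
    holds the mass-weighted orthonormal eigenvectors as columns, in
    eigenvalue order.
    """

    eigenvalues: np.ndarray          # (3N,), descending
    frequencies_cm: np.ndarray       # (n_nonrigid,), ascending, cm^-1
    modes: np.ndarray                # (3N, 3N), columns = eigenvectors
    mean: np.ndarray                 # (N, 3), iterated mean structure
    masses: np.ndarray               # (N,), amu
    temperature: float
    selection: str
    n_rigid: int                     # modes below the rigid tolerance

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


def quasi_harmonic_modes(
    ensemble: Ensemble,
    selection: Selection,
    temperature: float = 300.0,
    superpose: bool = True,
) -> QHAResult:
    """Quasi-harmonic modes of the selected atoms.

    Frames are superposed onto the iterated mean over the selection
    (``superpose=False`` skips this, for systems without rotational
    freedom such as sampled model oscillators), the mass-weighted
    displacement covariance is formed and diagonalised, and frequencies
    are assigned to all modes above the quasi-rigid tolerance.
    """
    if ensemble.n_frames < 2:
        raise ValueError("QHA needs at least 2 frames")
    idx = selection.indices
    if idx.size == 0:
        raise ValueError("empty selection for QHA")
    n3 = 3 * idx.size
    if ensemble.n_frames < n3:
        warnings.warn(
            f"only {ensemble.n_frames} frames for {n3} modes; "
            "the covariance will be rank deficient",
            stacklevel=2,
        )
    if superpose:
        ref = mean_structure(ensemble, selection)
        fitted, _ = superpose_frames(ensemble.coords, ref, selection)
        delta = fitted[:, idx, :] - ref[idx]
        mean = ref[idx]
    else:
        mean = ensemble.coords[:, idx, :].mean(axis=0)
        delta = ensemble.coords[:, idx, :] - mean
    masses = ensemble.topology.masses[idx]
    weighted = delta * np.sqrt(masses)[None, :, None]
    x = weighted.reshape(ensemble.n_frames, n3)
    cov = x.T @ x / ensemble.n_frames
    total_var = float(np.trace(cov))
    if total_var < 1e-12:
        raise ValueError("near-zero total variance; ensemble is static")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.where(np.abs(evals) < 1e-14, 0.0, evals)
    tol = _RIGID_TOL_REL * evals[0]
    nonrigid = evals > tol
    kbt = KB_KCAL_PER_MOL_K * temperature * KCAL_PER_MOL_TO_AMU_A2_PS2
    omega = np.sqrt(kbt / evals[nonrigid])            # rad/ps, ascending in omega
    freqs = omega / (2.0 * np.pi * C_CM_PER_PS)       # cm^-1
    return QHAResult(
        eigenvalues=evals,
        frequencies_cm=freqs,
        modes=evecs,
        mean=mean,
        masses=masses,
        temperature=temperature,
        selection=selection.expression,
        n_rigid=int(np.sum(~nonrigid)),
    )


def mode_rmsf(
    qha: QHAResult, ensemble: Ensemble, selection: Selection, mode_count: int = 10
) -> FluctuationProfile:
    """Per-residue RMSf restricted to the lowest-frequency modes.

    The lowest-frequency modes are the largest-eigenvalue ones; each
    contributes k_B T / (m_i omega_k^2) |e_{k,i}|^2 = lambda_k |e_{k,i}|^2
    / m_i to atom i's mean-square fluctuation.  Summing over all modes
    recovers the full ensemble RMSf.
    """
    if mode_count < 1:
        raise ValueError("mode_count must be >= 1")
    n_nonrigid = len(qha.frequencies_cm)
    if mode_count > n_nonrigid:
        raise ValueError(
            f"mode_count {mode_count} exceeds {n_nonrigid} non-rigid modes"
        )
    lams = qha.eigenvalues[:mode_count]                 # largest lambda = lowest nu
    vecs = qha.modes[:, :mode_count]                    # (3N, k)
    per_comp = (vecs**2) * lams[None, :]                # (3N, k)
    msf = per_comp.sum(axis=1).reshape(-1, 3).sum(axis=1) / qha.masses
    per_atom = np.sqrt(msf)
    topo = ensemble.topology
    idx = selection.indices
    df = pd.DataFrame(
        {"chain": topo.chain_ids[idx], "res_id": topo.res_ids[idx], "value": per_atom}
    )
    series = df.groupby(["chain", "res_id"], sort=False)["value"].mean()
    window = None
    if ensemble.frame_times is not None:
        window = (float(ensemble.frame_times[0]), float(ensemble.frame_times[-1]))
    return FluctuationProfile(series, qha.selection, window, "rmsf")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Residue-level cross-correlation matrix, block-averaged.

    ``matrix`` is a square DataFrame indexed by residue labels
    ``chain:res_id``; entries lie in [-1, 1] with unit diagonal for
    residues with nonzero variance.
    """

    matrix: pd.DataFrame
    residues: tuple[tuple[str, int, str], ...]
    block_length: float     # ps
    n_blocks: int

    def residue_label(self, chain: str, res_id: int) -> str:
        return f"{chain}:{res_id}"


def _residue_groups(ensemble: Ensemble, selection: Selection):
    topo = ensemble.topology
    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for i in selection.indices:
        key = (str(topo.chain_ids[i]), int(topo.res_ids[i]), str(topo.res_names[i]))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(int(i))
    return order, [np.array(groups[k]) for k in order]


def cross_correlation_matrix(
    ensemble: Ensemble,
    selection: Selection,
    block_length: float = 500.0,
    superpose: bool = True,
) -> CorrelationMatrix:
    """Block-averaged residue cross-correlation matrix.

    The trajectory is cut into consecutive complete blocks of
    ``block_length`` ps (trailing partial block dropped).  Within each
    block, frames are superposed onto the block's iterated mean
    (``superpose=False`` skips the fit, for pre-aligned input) and each
    residue's displacement is that of the centroid of its selected
    (backbone) atoms; C_ij is normalised per block and the final matrix is
    the unweighted block mean.
    """
    ens = ensemble.ensure_times()
    times = ens.frame_times
    t0 = times[0]
    span = times[-1] - t0
    dt = np.median(np.diff(times)) if ens.n_frames > 1 else block_length
    n_blocks = int(np.floor((span + dt) / block_length))
    if n_blocks < 1:
        raise ValueError(
            f"block_length {block_length} ps admits no complete block "
            f"(trajectory spans {span + dt:.0f} ps)"
        )
    block_idx = np.minimum(
        np.floor((times - t0) / block_length).astype(int), n_blocks
    )
    residues, groups = _residue_groups(ens, selection)
    n_res = len(residues)
    acc = np.zeros((n_res, n_res))
    n_used = 0
    for b in range(n_blocks):
        frames = np.flatnonzero(block_idx == b)
        if frames.size < 2:
            continue
        block = ens.subset_frames(frames)
        if superpose:
            ref = mean_structure(block, selection)
            fitted, _ = superpose_frames(block.coords, ref, selection)
        else:
            fitted = block.coords
            ref = fitted.mean(axis=0)
        # residue centroid displacements from the block mean, (F, n_res, 3)
        disp = np.stack(
            [fitted[:, g, :].mean(axis=1) - ref[g].mean(axis=0) for g in groups],
            axis=1,
        )
        inner = np.einsum("fic,fjc->ij", disp, disp) / frames.size
        var = np.diag(inner).copy()
        ok = var > 1e-14
        denom = np.sqrt(np.outer(var, var))
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(np.outer(ok, ok), inner / denom, 0.0)
        np.fill_diagonal(c, np.where(ok, 1.0, np.nan))
        acc += c
        n_used += 1
    if n_used == 0:
        raise ValueError("no block contains at least 2 frames")
    matrix = acc / n_used
    labels = [f"{ch}:{ri}" for ch, ri, _ in residues]
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    return CorrelationMatrix(df, tuple(residues), float(block_length), n_used)


def correlation_network(
    matrix: CorrelationMatrix,
    focus_residues,
    bins=NETWORK_BINS,
) -> pd.DataFrame:
    """Edge list connecting focus residues to partners by correlation class.

    For each focus residue, an edge is emitted to every other residue whose
    C_ij falls inside one of the class bins (half-open, last bin closed at
    its upper edge); values between bins yield no edge.  Returns a
    DataFrame with columns res_i, res_j, cij, class.
    """
    focus = list(focus_residues)
    if not focus:
        raise ValueError("focus residue set is empty")
    labels = list(matrix.matrix.index)
    label_set = set(labels)
    rows = []
    for f in focus:
        f_label = f if isinstance(f, str) else f"{f[0]}:{f[1]}"
        if f_label not in label_set:
            raise KeyError(f"focus residue {f_label!r} not in matrix")
        for other in labels:
            if other == f_label:
                continue
            cij = float(matrix.matrix.loc[f_label, other])
            if np.isnan(cij):
                continue
            for k, (lo, hi, name) in enumerate(bins):
                closed = k == len(bins) - 1
                inside = (lo <= cij < hi) or (closed and lo <= cij <= hi)
                if inside:
                    rows.append((f_label, other, cij, name))
                    break
    return pd.DataFrame(rows, columns=["res_i", "res_j", "cij", "class"])


def network_to_graph(edges: pd.DataFrame):
    """Build a networkx graph from a correlation-network edge list."""
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row.res_i, row.res_j, cij=row.cij, cls=row["class"])
    return g
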