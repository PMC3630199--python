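"""Synthetic conformational ensembles with known ground truth.

These generators emulate the statistical structure that the analysis
modules assume in real trajectories -- near-Gaussian equilibrium
fluctuations, injected low-frequency collective modes, bimodal two-state
side-chain contact switching, and helices of controllable bend and mutual
orientation -- so that every analysis can be validated by parameter
recovery.  They deliberately contain no force-field physics: only the
geometry and statistics that the downstream estimators measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import mass_of
from .trajectory import Ensemble, Topology

__all__ = [
    "HelixSpec",
    "PseudoResidue",
    "ScaffoldSpec",
    "CollectiveMode",
    "GroundTruth",
    "build_ideal_helix",
    "bend_helix_frame",
    "sample_gaussian_ensemble",
    "apply_two_state_switch",
    "build_toy_receptor",
]

# textbook alpha-helix geometry: 1.5 Å rise and 100 deg twist per residue,
# C-alpha atoms on a cylinder of radius 2.3 Å
DEFAULT_RISE = 1.5
DEFAULT_TWIST = 100.0
DEFAULT_HELIX_RADIUS = 2.3


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def _rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking the +z axis onto ``axis`` (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    axis = _unit(axis)
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _calpha_topology(
    n_residues: int, chain: str = "A", first_resid: int = 1, res_name: str = "ALA"
) -> Topology:
    return Topology(
        atom_names=np.array(["CA"] * n_residues, dtype=object),
        elements=np.array(["C"] * n_residues, dtype=object),
        res_names=np.array([res_name] * n_residues, dtype=object),
        res_ids=np.arange(first_resid, first_resid + n_residues),
        chain_ids=np.array([chain] * n_residues, dtype=object),
        masses=np.full(n_residues, mass_of("C")),
    )


def build_ideal_helix(
    n_residues: int,
    rise: float = DEFAULT_RISE,
    twist: float = DEFAULT_TWIST,
    helix_radius: float = DEFAULT_HELIX_RADIUS,
    chain: str = "A",
    first_resid: int = 1,
) -> Ensemble:
    """One-frame C-alpha-only ideal helix along +z.

    Residue ``k`` (0-based) sits at angle ``k * twist`` on a cylinder of the
    given radius, at axial coordinate ``k * rise``; all residues are ALA.
    """
    if n_residues < 4:
        raise ValueError("a helix needs at least 4 residues")
    if rise <= 0 or twist <= 0 or helix_radius <= 0:
        raise ValueError("helix geometry parameters must be positive")
    k = np.arange(n_residues)
    theta = np.deg2rad(twist) * k
    coords = np.column_stack(
        [helix_radius * np.cos(theta), helix_radius * np.sin(theta), rise * k]
    )
    topo = _calpha_topology(n_residues, chain=chain, first_resid=first_resid)
    return Ensemble(topo, coords[None, :, :])


def bend_helix_frame(helix: Ensemble, bend_radius: float) -> Ensemble:
    """Bend a straight (+z axis) helix onto a circular arc of given radius.

    The z axis is mapped isometrically onto an arc in the x-z plane
    (arc length = original axial extent); the cylinder offsets of each
    C-alpha are transported in the local (normal, binormal) frame, so the
    helical geometry around the now-curved axis is preserved.  In the
    large-radius limit the transform is the identity.
    """
    if helix.n_frames != 1:
        raise ValueError("bend_helix_frame expects a single-frame helix")
    coords = helix.coords[0]
    extent = float(coords[:, 2].max() - coords[:, 2].min())
    if bend_radius <= extent / np.pi:
        raise ValueError(
            f"bend_radius {bend_radius} too small for axial extent {extent:.2f} "
            f"(must exceed extent/pi = {extent / np.pi:.2f})"
        )
    s = coords[:, 2]                      # arc-length parameter
    phi = s / bend_radius
    centre_line = np.column_stack(
        [bend_radius * (1.0 - np.cos(phi)), np.zeros_like(phi), bend_radius * np.sin(phi)]
    )
    normal = np.column_stack([np.cos(phi), np.zeros_like(phi), -np.sin(phi)])
    binormal = np.array([0.0, 1.0, 0.0])
    bent = (
        centre_line
        + coords[:, 0:1] * normal
        + coords[:, 1:2] * binormal
    )
    return Ensemble(helix.topology, bent[None, :, :])


@dataclass(frozen=True)
class CollectiveMode:
    """A collective displacement direction with its peak amplitude (Å)."""

    amplitude: float
    vector: np.ndarray     # (n_atoms, 3), unit norm over all 3N components

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("mode amplitude must be >= 0")
        v = np.asarray(self.vector, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("mode vector must be nonzero")
        object.__setattr__(self, "vector", v / n)


@dataclass(frozen=True)
class GroundTruth:
    """Known parameters a synthetic ensemble was generated with.

    Every field is recoverable by the corresponding analysis module:
    sigma by RMSf, modes by QHA / correlation networks, populations by
    distance-window fractions, bend radii by circle fits, and angles by
    helix-axis fits.
    """

    per_atom_sigma: float | np.ndarray = 0.5         # Å, isotropic
    modes: tuple[CollectiveMode, ...] = ()
    state_populations: dict = field(default_factory=dict)   # pair label -> (p_near, p_far)
    bend_radius: dict = field(default_factory=dict)         # helix label -> Å
    interhelix_angles: dict = field(default_factory=dict)   # pair label -> degrees

    def __post_init__(self):
        for label, pops in self.state_populations.items():
            pops = tuple(pops)
            if not all(0.0 <= p <= 1.0 for p in pops) or abs(sum(pops) - 1.0) > 1e-9:
                raise ValueError(f"populations for {label!r} must lie in [0,1] and sum to 1")


def sample_gaussian_ensemble(
    reference: Ensemble,
    ground_truth: GroundTruth,
    n_frames: int,
    seed: int,
    dt: float = 100.0,
) -> Ensemble:
    """Near-Gaussian fluctuations about a reference plus collective modes.

    Frame f = reference + isotropic Gaussian noise (per-atom sigma) +
    sum_m amplitude_m * sin(phase_{f,m}) * mode_vector_m with independent
    uniform phases, so each mode contributes variance amplitude^2/2 along
    its direction both to the covariance (QHA) and to equal-time residue
    correlations.  Reproducible for identical seeds; frames carry uniform
    synthetic times spaced ``dt`` ps.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if reference.n_frames != 1:
        raise ValueError("reference must be a single-frame ensemble")
    rng = np.random.default_rng(seed)
    ref = reference.coords[0]
    n_atoms = ref.shape[0]
    sigma = np.broadcast_to(
        np.asarray(ground_truth.per_atom_sigma, dtype=float), (n_atoms,)
    )
    coords = ref[None] + rng.standard_normal((n_frames, n_atoms, 3)) * sigma[None, :, None]
    for mode in ground_truth.modes:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_frames)
        coords += mode.amplitude * np.sin(phases)[:, None, None] * mode.vector[None]
    times = np.arange(n_frames, dtype=float) * dt
    return Ensemble(reference.topology, coords, frame_times=times)


def apply_two_state_switch(
    ensemble: Ensemble,
    atom_a: int,
    atom_b: int,
    d_near: float,
    d_far: float,
    p_near: float,
    jitter: float,
    seed: int,
) -> Ensemble:
    """Impose bimodal two-state switching on one inter-atomic distance.

    Per frame, atom ``b`` is displaced along the instantaneous a->b
    direction so that its distance to atom ``a`` equals ``d_near`` (with
    probability ``p_near``) or ``d_far``, plus Gaussian jitter on the
    distance.  All other atoms are untouched.
    """
    if atom_a == atom_b:
        raise ValueError("atom_a and atom_b must differ")
    if not 0.0 <= p_near <= 1.0:
        raise ValueError("p_near must lie in [0, 1]")
    if not d_near < d_far:
        raise ValueError("d_near must be smaller than d_far")
    rng = np.random.default_rng(seed)
    coords = ensemble.coords.copy()
    a = coords[:, atom_a, :]
    b = coords[:, atom_b, :]
    direction = b - a
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("atoms a and b coincide in some frame")
    direction = direction / norms
    near = rng.uniform(size=ensemble.n_frames) < p_near
    target = np.where(near, d_near, d_far)
    if jitter > 0:
        target = target + rng.standard_normal(ensemble.n_frames) * jitter
    coords[:, atom_b, :] = a + direction * target[:, None]
    return replace(ensemble, coords=coords)


# ---------------------------------------------------------------------------
# toy receptor scaffold


@dataclass(frozen=True)
class HelixSpec:
    n_residues: int
    start: tuple[float, float, float]
    axis: tuple[float, float, float]      # unit vector
    chain: str = "A"
    first_resid: int = 1

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("helix length must be >= 4 residues")
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("helix axis must be a unit vector")


@dataclass(frozen=True)
class PseudoResidue:
    """Schematic side-chain site: a reference carbon plus its terminal atoms.

    Only inter-atom distances and atom names matter downstream; geometry is
    canonical but not chemically detailed (colinear / planar offsets at
    1.25-1.5 Å bond lengths).
    """

    res_name: str            # ARG, LYS, ASP, GLU
    chain: str
    res_id: int
    position: tuple[float, float, float]     # reference-carbon site
    direction: tuple[float, float, float]    # points toward the partner


# (atom name, element, offset rule) per supported pseudo-residue;
# offsets are built in build_toy_receptor from position + direction
_TERMINAL_SITES = {
    "ARG": [("CZ", "C"), ("NE", "N"), ("NH1", "N"), ("NH2", "N")],
    "LYS": [("CE", "C"), ("NZ", "N")],
    "ASP": [("CG", "C"), ("OD1", "O"), ("OD2", "O")],
    "GLU": [("CD", "C"), ("OE1", "O"), ("OE2", "O")],
}


@dataclass(frozen=True)
class ScaffoldSpec:
    helices: tuple[HelixSpec, ...]
    pseudo_residues: tuple[PseudoResidue, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not self.helices:
            raise ValueError("scaffold needs at least one helix")


def _pseudo_atoms(res: PseudoResidue) -> list[tuple[str, str, np.ndarray]]:
    if res.res_name not in _TERMINAL_SITES:
        raise ValueError(f"unsupported pseudo-residue {res.res_name!r}")
    p = np.asarray(res.position, dtype=float)
    d = _unit(res.direction)
    # any vector orthogonal to d, for planar branching of the two terminal sites
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    perp = _unit(np.cross(d, helper))
    out: list[tuple[str, str, np.ndarray]] = []
    name0, elem0 = _TERMINAL_SITES[res.res_name][0]
    out.append((name0, elem0, p))
    terminals = _TERMINAL_SITES[res.res_name][1:]
    if res.res_name == "LYS":
        out.append(("NZ", "N", p + 1.48 * d))
    elif res.res_name == "ARG":
        out.append(("NE", "N", p - 1.33 * d))
        for name, sign in (("NH1", 1.0), ("NH2", -1.0)):
            offset = 1.33 * (np.cos(np.deg2rad(60)) * d + sign * np.sin(np.deg2rad(60)) * perp)
            out.append((name, "N", p + offset))
    else:  # ASP / GLU carboxylate
        for (name, elem), sign in zip(terminals, (1.0, -1.0)):
            offset = 1.25 * (np.cos(np.deg2rad(30)) * d + sign * np.sin(np.deg2rad(30)) * perp)
            out.append((name, elem, p + offset))
    return out


def build_toy_receptor(spec: ScaffoldSpec) -> Ensemble:
    """Compose helices and pseudo side-chain sites into a one-frame scaffold.

    Atom names follow side-chain conventions (ARG CZ/NE/NH1/NH2, ASP
    CG/OD1/OD2, ...) so that salt-bridge detection and reference-carbon
    distance monitoring run on the scaffold end to end.  Raises if any two
    atoms fall closer than 0.5 Å.
    """
    names, elements, res_names, res_ids, chains, coords = [], [], [], [], [], []
    for hx in spec.helices:
        helix = build_ideal_helix(hx.n_residues, chain=hx.chain, first_resid=hx.first_resid)
        rot = _rotation_from_z(np.asarray(hx.axis, dtype=float))
        placed = helix.coords[0] @ rot.T + np.asarray(hx.start, dtype=float)
        topo = helix.topology
        names.extend(topo.atom_names)
        elements.extend(topo.elements)
        res_names.extend(topo.res_names)
        res_ids.extend(topo.res_ids)
        chains.extend(topo.chain_ids)
        coords.append(placed)
    for res in spec.pseudo_residues:
        for name, elem, pos in _pseudo_atoms(res):
            names.append(name)
            elements.append(elem)
            res_names.append(res.res_name)
            res_ids.append(res.res_id)
            chains.append(res.chain)
            coords.append(pos[None, :])
    xyz = np.concatenate(coords, axis=0)
    from scipy.spatial.distance import pdist

    if len(xyz) > 1 and pdist(xyz).min() < 0.5:
        raise ValueError("scaffold atoms overlap (closer than 0.5 Å)")
    topo = Topology(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_names=np.array(res_names, dtype=object),
        res_ids=np.array(res_ids, dtype=int),
        chain_ids=np.array(chains, dtype=object),
        masses=np.array([mass_of(e) for e in elements]),
    )
    return Ensemble(topo, xyz[None, :, :])
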