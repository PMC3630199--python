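"""Salt-bridge detection and side-chain distance monitoring.

A salt bridge is considered formed in a frame when any side-chain oxygen
of an acidic residue lies within a cutoff (default 3.2 Å) of any side-chain
nitrogen of a basic residue.  Longer-range contact geometry is monitored
through the distance between the side-chain reference carbons (Arg Cζ,
Lys Cε, Glu Cδ, Asp Cγ), summarised as histograms and window populations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .trajectory import Ensemble

__all__ = [
    "SaltBridgeContact",
    "DistanceSeries",
    "reference_carbon",
    "detect_salt_bridges",
    "pair_distance_series",
    "window_populations",
    "donor_angle_formed",
    "ACIDIC_OXYGENS",
    "BASIC_NITROGENS",
]

#: Side-chain acceptor oxygens per acidic residue; SEP (phosphoserine)
#: phosphate oxygens join the set when extended acceptors are enabled.
ACIDIC_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
EXTENDED_ACIDIC = {"SEP": ("O1P", "O2P", "O3P"), "S1P": ("O1P", "O2P", "O3P")}

#: Side-chain donor nitrogens per basic residue (Arg NE included: all
#: side-chain nitrogens count).  His is optional via extended mode.
BASIC_NITROGENS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
EXTENDED_BASIC = {"HIS": ("ND1", "NE2")}

#: Reference side-chain carbon per charged residue, used for
#: distance-distribution monitoring.
REFERENCE_CARBONS = {"ARG": "CZ", "LYS": "CE", "GLU": "CD", "ASP": "CG"}

DEFAULT_SALT_BRIDGE_CUTOFF = 3.2  # Å


def reference_carbon(residue_name: str) -> str:
    """Side-chain reference carbon: ARG->CZ, LYS->CE, GLU->CD, ASP->CG."""
    try:
        return REFERENCE_CARBONS[residue_name]
    except KeyError:
        raise ValueError(
            f"no reference carbon defined for residue {residue_name!r}"
        ) from None


@dataclass(frozen=True)
class SaltBridgeContact:
    """One acidic/basic residue pair with its per-frame minimum N-O distance."""

    acidic: tuple[str, int, str]     # (chain, res_id, res_name)
    basic: tuple[str, int, str]
    min_distance: np.ndarray         # (n_frames,), Å
    formed: np.ndarray               # (n_frames,), bool
    cutoff: float

    @property
    def occupancy(self) -> float:
        """Fraction of frames in which the bridge is formed."""
        return float(np.mean(self.formed))


def _charged_groups(ensemble: Ensemble, table: dict) -> list[tuple[tuple, np.ndarray]]:
    """(chain, res_id, res_name) -> atom indices of the listed side-chain atoms."""
    topo = ensemble.topology
    groups = []
    for res_name, res_id, chain in topo.residues:
        wanted = table.get(res_name)
        if not wanted:
            continue
        idx = topo.residue_atom_indices(chain, res_id)
        idx = idx[np.isin(topo.atom_names[idx], wanted)]
        if idx.size:
            groups.append(((chain, res_id, res_name), idx))
    return groups


def detect_salt_bridges(
    ensemble: Ensemble,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    extended_acceptors: bool = False,
) -> list[SaltBridgeContact]:
    """All acidic/basic residue pairs forming a salt bridge in >= 1 frame.

    For each (acidic residue, basic residue) pair the per-frame minimum
    over all acceptor-O x donor-N distances is taken; a frame is "formed"
    when that minimum is <= cutoff.  Pairs never formed in any frame are
    omitted.  ``extended_acceptors`` adds phosphoserine phosphate oxygens
    and histidine side-chain nitrogens.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    acid_table = dict(ACIDIC_OXYGENS)
    base_table = dict(BASIC_NITROGENS)
    if extended_acceptors:
        acid_table.update(EXTENDED_ACIDIC)
        base_table.update(EXTENDED_BASIC)
    acids = _charged_groups(ensemble, acid_table)
    bases = _charged_groups(ensemble, base_table)
    contacts = []
    coords = ensemble.coords
    for acid_key, o_idx in acids:
        for base_key, n_idx in bases:
            diff = coords[:, o_idx, None, :] - coords[:, None, n_idx, :]
            dist = np.sqrt(np.sum(diff**2, axis=-1))        # (F, nO, nN)
            min_d = dist.reshape(ensemble.n_frames, -1).min(axis=1)
            formed = min_d <= cutoff
            if formed.any():
                contacts.append(
                    SaltBridgeContact(acid_key, base_key, min_d, formed, cutoff)
                )
    return contacts


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame distance between two atoms, with optional histogram/windows."""

    atom_a: int
    atom_b: int
    label: str
    distances: np.ndarray                               # (n_frames,), Å
    bin_edges: np.ndarray | None = None
    counts: np.ndarray | None = None
    windows: tuple[tuple[float, float, float], ...] = ()  # (lo, hi, fraction)


def _resolve_atom(ensemble: Ensemble, residue, atom_rule):
    """Resolve (chain, res_id[, res_name]) plus a rule to one atom index."""
    topo = ensemble.topology
    chain, res_id = residue[0], residue[1]
    idx = topo.residue_atom_indices(chain, res_id)
    if idx.size == 0:
        raise KeyError(f"residue {chain}:{res_id} not in topology")
    res_name = str(topo.res_names[idx[0]])
    if len(residue) > 2 and residue[2] != res_name:
        raise KeyError(
            f"residue {chain}:{res_id} is {res_name}, expected {residue[2]}"
        )
    name = reference_carbon(res_name) if atom_rule == "reference_carbon" else atom_rule
    try:
        return topo.atom_index(chain, res_id, name), res_name
    except KeyError:
        raise KeyError(
            f"atom {name!r} not found in residue {res_name} {chain}:{res_id}"
        ) from None


def pair_distance_series(
    ensemble: Ensemble,
    residue_a,
    residue_b,
    atom_rule="reference_carbon",
) -> DistanceSeries:
    """Euclidean distance per frame between two residues' monitored atoms.

    ``atom_rule`` is either ``"reference_carbon"`` (both sides use the
    side-chain reference carbon of their residue type) or a pair of
    explicit atom names.  Distances are internal coordinates: no
    superposition is applied.
    """
    rule_a, rule_b = (
        (atom_rule, atom_rule)
        if isinstance(atom_rule, str)
        else (atom_rule[0], atom_rule[1])
    )
    ia, name_a = _resolve_atom(ensemble, residue_a, rule_a)
    ib, name_b = _resolve_atom(ensemble, residue_b, rule_b)
    d = np.linalg.norm(ensemble.coords[:, ia, :] - ensemble.coords[:, ib, :], axis=1)
    label = f"{name_a}{residue_a[1]}{residue_a[0]}-{name_b}{residue_b[1]}{residue_b[0]}"
    return DistanceSeries(ia, ib, label, d)


def window_populations(
    series: DistanceSeries,
    bin_width: float = 0.5,
    windows: tuple[tuple[float, float], ...] = (),
) -> DistanceSeries:
    """Histogram a distance series and compute half-open window fractions.

    The histogram spans [min, max] with the stated bin width; each window
    fraction counts frames with lo <= d < hi over the total.  Windows may
    overlap, in which case fractions need not sum to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = series.distances
    if d.size == 0:
        raise ValueError("distance series has no frames")
    lo, hi = float(d.min()), float(d.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width))) if hi > lo else 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)       # last edge inclusive via np.histogram
    counts, edges = np.histogram(d, bins=edges)
    fracs = tuple(
        (float(w_lo), float(w_hi), float(np.mean((d >= w_lo) & (d < w_hi))))
        for w_lo, w_hi in windows
    )
    return replace(series, bin_edges=edges, counts=counts, windows=fracs)


def donor_angle_formed(
    ensemble: Ensemble,
    donor_n: int,
    donor_h: int,
    acceptor_o: int,
    min_angle: float = 120.0,
) -> np.ndarray:
    """Per-frame donor-H-acceptor angle criterion (inclusive threshold).

    The angle at H between the H->N and H->O directions is computed per
    frame; a hydrogen bond counts as formed when angle >= min_angle
    (180 deg = perfectly linear N-H...O).
    """
    if len({donor_n, donor_h, acceptor_o}) != 3:
        raise ValueError("donor_n, donor_h and acceptor_o must be distinct atoms")
    c = ensemble.coords
    v1 = c[:, donor_n, :] - c[:, donor_h, :]
    v2 = c[:, acceptor_o, :] - c[:, donor_h, :]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise ValueError("coincident atoms in angle computation")
    cosang = np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    return angles >= min_angle
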