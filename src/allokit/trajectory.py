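"""Conformational ensembles: topology, coordinates, and multi-model PDB I/O.

An :class:`Ensemble` is an ordered set of coordinate frames (Å) sharing one
:class:`Topology`; it is the universal input of every analysis in this
package.  Multi-model PDB is the canonical interchange format so that all
fixtures remain plain text; parsing and formatting of the fixed-width
records is delegated to :mod:`biotite`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

from .constants import TWO_LETTER_ELEMENTS, mass_of

__all__ = [
    "Topology",
    "Ensemble",
    "PDBFormatError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "discard_equilibration",
]


class PDBFormatError(ValueError):
    """Raised for structurally invalid multi-model PDB input."""


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name (for files lacking column 77-78).

    Leading digits are stripped (e.g. ``1HB``); a two-letter element is
    recognised only when the cleaned name matches a known two-letter symbol
    (FE, ZN, ...), otherwise the first letter wins, which is correct for all
    standard amino-acid atoms (CA is an alpha carbon, not calcium).
    """
    cleaned = atom_name.strip().lstrip("0123456789")
    if not cleaned:
        raise PDBFormatError(f"cannot infer element from atom name {atom_name!r}")
    if cleaned[:2].upper() in TWO_LETTER_ELEMENTS and len(cleaned) >= 2 and cleaned[1].isalpha():
        # Only accept the two-letter reading for names that are *just* the
        # element symbol (metal ions etc.); 'CL1' yes, 'CD' of Glu no --
        # side-chain carbons CD/CE/CG are far more common than Cd/Ce ions
        # in protein work, so single-letter C takes precedence for those.
        if cleaned.upper() in ("CL", "CL1", "BR", "FE", "ZN", "MG", "MN", "NA", "SE"):
            return cleaned[:2].upper()
    return cleaned[0].upper()


@dataclass(frozen=True)
class Topology:
    """Atom-level topology shared by all frames of an ensemble.

    Parallel arrays over atoms; ``(chain, res_id, atom_name)`` must be
    unique and every mass positive.  The residue list is derived: exactly
    the residues referenced by atoms, in order of first appearance.
    """

    atom_names: np.ndarray       # str
    elements: np.ndarray         # str
    res_names: np.ndarray        # str
    res_ids: np.ndarray          # int
    chain_ids: np.ndarray        # str
    masses: np.ndarray           # float, amu

    def __post_init__(self):
        n = len(self.atom_names)
        for name in ("elements", "res_names", "res_ids", "chain_ids", "masses"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology field {name!r} has wrong length")
        if n == 0:
            raise ValueError("topology has no atoms")
        keys = list(zip(self.chain_ids, self.res_ids, self.atom_names))
        if len(set(keys)) != n:
            seen = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom {k} in topology")
                seen.add(k)
        if not np.all(self.masses > 0):
            bad = int(np.argmin(self.masses))
            raise ValueError(
                f"non-positive mass for atom {self.atom_names[bad]} "
                f"({self.chain_ids[bad]}:{self.res_ids[bad]})"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique ``(res_name, res_id, chain_id)`` by first appearance."""
        out, seen = [], set()
        for rn, ri, ch in zip(self.res_names, self.res_ids, self.chain_ids):
            key = (ch, int(ri))
            if key not in seen:
                seen.add(key)
                out.append((str(rn), int(ri), str(ch)))
        return out

    def atom_index(self, chain: str, res_id: int, atom_name: str) -> int:
        """Index of a single atom; raises ``KeyError`` if absent."""
        hits = np.flatnonzero(
            (self.chain_ids == chain)
            & (self.res_ids == res_id)
            & (self.atom_names == atom_name)
        )
        if hits.size == 0:
            raise KeyError(f"no atom {atom_name!r} in residue {chain}:{res_id}")
        return int(hits[0])

    def residue_atom_indices(self, chain: str, res_id: int) -> np.ndarray:
        return np.flatnonzero((self.chain_ids == chain) & (self.res_ids == res_id))


@dataclass
class Ensemble:
    """Ordered coordinate frames (Å) over one topology.

    ``frame_times`` (ps) are optional but required by windowed analyses;
    :meth:`ensure_times` assigns synthetic uniform times when absent.
    """

    topology: Topology
    coords: np.ndarray                       # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None    # (n_frames,), ps, strictly increasing
    b_factors: np.ndarray | None = field(default=None, repr=False)  # (n_atoms,), Å²

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValueError("frame_times length must equal frame count")
            if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
                raise ValueError("frame_times must strictly increase")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def ensure_times(self, dt: float = 100.0) -> "Ensemble":
        """Return an ensemble with times 0, dt, 2dt... if none are present."""
        if self.frame_times is not None:
            return self
        times = np.arange(self.n_frames, dtype=float) * dt
        return replace(self, frame_times=times)

    def subset_frames(self, index: np.ndarray) -> "Ensemble":
        index = np.asarray(index)
        times = self.frame_times[index] if self.frame_times is not None else None
        return Ensemble(self.topology, self.coords[index], times, self.b_factors)


# ---------------------------------------------------------------------------
# multi-model PDB


def _validate_models(path) -> None:
    """Pre-scan a PDB file: consistent atom identity/order across MODELs.

    Raises :class:`PDBFormatError` naming the first offending model, or the
    line number of an unparseable ATOM/HETATM record.
    """
    signatures: list[list[tuple]] = []
    current: list[tuple] | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                if current:
                    signatures.append(current)
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    signatures.append(current)
                current = None
            elif rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PDBFormatError(f"truncated {rec} record at line {lineno}")
                try:
                    name = line[12:16].strip()
                    chain = line[21].strip()
                    res_id = int(line[22:26])
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise PDBFormatError(
                        f"unparseable {rec} record at line {lineno}"
                    ) from None
                if current is None:
                    current = []
                current.append((chain, res_id, name))
    if current:
        signatures.append(current)
    if not signatures:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    ref = signatures[0]
    for m, sig in enumerate(signatures[1:], start=2):
        if len(sig) != len(ref):
            raise PDBFormatError(
                f"model {m} has {len(sig)} atoms, model 1 has {len(ref)}"
            )
        if sig != ref:
            raise PDBFormatError(f"model {m} atom ordering differs from model 1")
    if saw_model and len(signatures) == 0:
        raise PDBFormatError(f"{path}: MODEL records without atoms")


def read_multimodel_pdb(path) -> Ensemble:
    """Read a multi-model PDB into an :class:`Ensemble` (one frame per MODEL).

    Files without MODEL/ENDMDL records yield a single-frame ensemble.
    Elements missing from column 77-78 are inferred from the atom name;
    masses come from the standard atomic-mass table.  B-factors of the
    first model are retained for comparison with computed fluctuations.
    """
    _validate_models(path)
    pdb_file = _pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None, extra_fields=["b_factor"])
    if isinstance(stack, struc.AtomArray):       # single un-modeled set
        stack = struc.stack([stack])
    elements = np.array(
        [
            el if el else infer_element(an)
            for el, an in zip(stack.element, stack.atom_name)
        ],
        dtype=object,
    )
    masses = np.array([mass_of(e) for e in elements])
    topo = Topology(
        atom_names=stack.atom_name.astype(object),
        elements=elements,
        res_names=stack.res_name.astype(object),
        res_ids=stack.res_id.astype(int),
        chain_ids=stack.chain_id.astype(object),
        masses=masses,
    )
    b = np.asarray(stack.b_factor, dtype=float) if stack.b_factor is not None else None
    return Ensemble(topo, np.asarray(stack.coord, dtype=float), b_factors=b)


def write_multimodel_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB (fixed-width, 3 decimals).

    Round-trips through :func:`read_multimodel_pdb` to 0.001 Å.  Raises on
    coordinates that cannot be represented in the 8.3 fixed-width field.
    """
    coords = ensemble.coords
    if coords.max() > 9999.999 or coords.min() < -999.999:
        raise ValueError(
            "coordinates exceed the PDB fixed-width field (-999.999..9999.999 Å)"
        )
    topo = ensemble.topology
    n = topo.n_atoms
    array = struc.AtomArray(n)
    array.atom_name = topo.atom_names.astype("U6")
    array.element = topo.elements.astype("U2")
    array.res_name = topo.res_names.astype("U5")
    array.res_id = topo.res_ids
    array.chain_id = topo.chain_ids.astype("U4")
    array.hetero = np.zeros(n, dtype=bool)
    array.set_annotation(
        "b_factor",
        ensemble.b_factors if ensemble.b_factors is not None else np.zeros(n),
    )
    array.set_annotation("occupancy", np.ones(n))
    stack = struc.from_template(array, coords.astype(np.float32))
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def discard_equilibration(ensemble: Ensemble, t_start: float) -> Ensemble:
    """Drop frames earlier than ``t_start`` ps (equilibration period).

    Requires per-frame times; raises if nothing would remain.
    """
    if ensemble.frame_times is None:
        raise ValueError("ensemble has no frame times; call ensure_times() first")
    if t_start < 0:
        raise ValueError("t_start must be >= 0")
    keep = np.flatnonzero(ensemble.frame_times >= t_start)
    if keep.size == 0:
        raise ValueError(f"t_start={t_start} ps removes every frame")
    return ensemble.subset_frames(keep)
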