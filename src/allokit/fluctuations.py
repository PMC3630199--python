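"""Least-squares superposition, RMSD, per-residue RMSf and the B-factor relation.

The per-atom root-mean-square fluctuation about the ensemble-average
structure is

    RMSf_i = sqrt( (1/T) * sum_t | r_i(t) - r_i^ref |^2 )

with the reference taken as the iterated (two-pass) mean structure after
optimal superposition, and is related to the crystallographic temperature
factor through  B_i = (8 pi^2 / 3) <dr_i^2>.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import B_FACTOR_PREFACTOR
from .selection import Selection, select
from .trajectory import Ensemble

__all__ = [
    "SuperpositionResult",
    "FluctuationProfile",
    "kabsch_superpose",
    "superpose_frames",
    "rmsd_series",
    "mean_structure",
    "rmsf",
    "bfactor_convert",
]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # (3, 3), proper: det = +1
    translation: np.ndarray   # (3,)
    rmsd: float               # Å, over the fitted selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid transform to an (N, 3) coordinate set."""
        return coords @ self.rotation.T + self.translation


def _check_fittable(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError("selected atoms are collinear; rotation is underdetermined")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: Selection | None = None
) -> SuperpositionResult:
    """Optimal proper rotation + translation of ``mobile`` onto ``reference``.

    Both are (N, 3) frames over the same topology; the fit (and the reported
    RMSD) uses the selection's atoms, defaulting to all.  Standard SVD-based
    least-squares solution with the determinant correction that excludes
    reflections.
    """
    idx = selection.indices if selection is not None else slice(None)
    m = np.asarray(mobile, dtype=float)[idx]
    r = np.asarray(reference, dtype=float)[idx]
    if m.shape != r.shape:
        raise ValueError("mobile and reference must have matching selections")
    _check_fittable(r)
    cm, cr = m.mean(axis=0), r.mean(axis=0)
    h = (m - cm).T @ (r - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return SuperpositionResult(rot, trans, rmsd)


def superpose_frames(
    coords: np.ndarray, reference: np.ndarray, selection: Selection | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame of a (F, N, 3) stack onto a reference frame.

    Vectorised Kabsch over the frame axis; returns the transformed full-atom
    stack and the per-frame RMSD (Å) over the fitted selection.
    """
    coords = np.asarray(coords, dtype=float)
    idx = selection.indices if selection is not None else np.arange(coords.shape[1])
    ref = np.asarray(reference, dtype=float)[idx]
    _check_fittable(ref)
    sub = coords[:, idx, :]
    cm = sub.mean(axis=1, keepdims=True)            # (F, 1, 3)
    cr = ref.mean(axis=0)
    h = np.einsum("fni,nj->fij", sub - cm, ref - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fji,fkj->fik", vt, u)))
    corr = np.repeat(np.eye(3)[None], len(coords), axis=0)
    corr[:, 2, 2] = d
    rot = np.einsum("fji,fjk,flk->fil", vt, corr, u)   # V diag(1,1,d) U^T per frame
    trans = cr - np.einsum("fij,fj->fi", rot, cm[:, 0, :])
    fitted = np.einsum("fij,fnj->fni", rot, coords) + trans[:, None, :]
    diff = fitted[:, idx, :] - ref
    rmsds = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    return fitted, rmsds


def rmsd_series(
    ensemble: Ensemble, reference: np.ndarray, selection: Selection | None = None
) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference frame after superposition."""
    _, rmsds = superpose_frames(ensemble.coords, reference, selection)
    return rmsds


def mean_structure(
    ensemble: Ensemble, selection: Selection | None = None
) -> np.ndarray:
    """Ensemble-average structure, iterated once (two-pass).

    Frames are superposed onto the first frame, averaged, then superposed
    once more onto that average and re-averaged; the second pass removes
    the bias of the arbitrary initial alignment reference.
    """
    fitted, _ = superpose_frames(ensemble.coords, ensemble.coords[0], selection)
    avg = fitted.mean(axis=0)
    fitted, _ = superpose_frames(ensemble.coords, avg, selection)
    return fitted.mean(axis=0)


@dataclass(frozen=True)
class FluctuationProfile:
    """Per-residue fluctuation values keyed by (chain, residue number).

    ``quantity`` is ``"rmsf"`` (Å) or ``"bfactor"`` (Å²); the selection
    expression and time window record what the profile was computed over.
    """

    values: pd.Series                 # index: MultiIndex (chain, res_id)
    selection: str
    time_window: tuple[float, float] | None
    quantity: str

    def __post_init__(self):
        if self.quantity not in ("rmsf", "bfactor"):
            raise ValueError("quantity must be 'rmsf' or 'bfactor'")
        if (self.values < 0).any():
            raise ValueError("fluctuation values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = self.values.rename(self.quantity).reset_index()
        df.columns = ["chain", "res_id", self.quantity]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _per_residue(ensemble: Ensemble, idx: np.ndarray, per_atom: np.ndarray) -> pd.Series:
    topo = ensemble.topology
    df = pd.DataFrame(
        {
            "chain": topo.chain_ids[idx],
            "res_id": topo.res_ids[idx],
            "value": per_atom,
        }
    )
    grouped = df.groupby(["chain", "res_id"], sort=False)["value"].mean()
    return grouped


def rmsf(
    ensemble: Ensemble,
    selection: Selection | None = None,
    per_residue: bool = True,
    fit_selection: Selection | None = None,
) -> FluctuationProfile | np.ndarray:
    """Root-mean-square fluctuation about the iterated mean structure.

    Frames are superposed (over ``fit_selection``, defaulting to the
    reported selection) before the fluctuation average; per-residue values
    are unweighted means over each residue's selected atoms.  With
    ``per_residue=False`` the raw per-atom RMSf array is returned instead.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSf needs at least 2 frames")
    if selection is None:
        selection = select(ensemble.topology, "calpha")
    if len(selection) == 0:
        raise ValueError("empty selection for RMSf")
    fit_sel = fit_selection if fit_selection is not None else selection
    ref = mean_structure(ensemble, fit_sel)
    fitted, _ = superpose_frames(ensemble.coords, ref, fit_sel)
    delta = fitted[:, selection.indices, :] - ref[selection.indices]
    per_atom = np.sqrt(np.mean(np.sum(delta**2, axis=2), axis=0))
    if not per_residue:
        return per_atom
    window = None
    if ensemble.frame_times is not None:
        window = (float(ensemble.frame_times[0]), float(ensemble.frame_times[-1]))
    return FluctuationProfile(
        _per_residue(ensemble, selection.indices, per_atom),
        selection.expression,
        window,
        "rmsf",
    )


def bfactor_convert(profile: FluctuationProfile, direction: str) -> FluctuationProfile:
    """Convert between RMSf (Å) and B-factor (Å²): B = (8 pi^2 / 3) RMSf^2."""
    if direction == "to_b":
        if profile.quantity != "rmsf":
            raise ValueError("to_b expects an rmsf profile")
        vals = B_FACTOR_PREFACTOR * profile.values**2
        return replace(profile, values=vals, quantity="bfactor")
    if direction == "to_rmsf":
        if profile.quantity != "bfactor":
            raise ValueError("to_rmsf expects a bfactor profile")
        vals = np.sqrt(profile.values / B_FACTOR_PREFACTOR)
        return replace(profile, values=vals, quantity="rmsf")
    raise ValueError("direction must be 'to_b' or 'to_rmsf'")
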