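"""Ensemble-convergence assessment by reference-structure decomposition.

A cutoff distance d_c (Cα RMSD, default 1.4 Å) is fixed; a reference
structure is picked at random from the trajectory and, together with all
frames within d_c of it, removed.  Iterating until no frames remain gives
a set of mutually well-separated reference structures that covers the
trajectory.  The trajectory is then split into halves by time and every
frame assigned to its nearest reference; a reference whose cluster
contains only itself is a "lone structure".  Few lone structures, and
similar per-half occupancies, indicate that both halves sample the same
conformational basins -- i.e. a converged ensemble with no drift.  The
whole procedure is repeated with different random seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluctuations import superpose_frames
from .selection import Selection, select
from .trajectory import Ensemble

__all__ = ["ReferenceSet", "ConvergenceReport", "build_reference_set", "assess_convergence"]

DEFAULT_CUTOFF = 1.4  # Å Cα RMSD


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered reference frame indices with the cutoff that produced them.

    Invariants: pairwise superposed RMSD between references exceeds d_c,
    and every trajectory frame lies within d_c of at least one reference.
    """

    d_c: float
    reference_indices: tuple[int, ...]
    seed: int
    selection: str


def _rmsd_to_frame(ensemble: Ensemble, frame_idx: int, others: np.ndarray,
                   selection: Selection) -> np.ndarray:
    _, rmsds = superpose_frames(
        ensemble.coords[others], ensemble.coords[frame_idx], selection
    )
    return rmsds


def build_reference_set(
    ensemble: Ensemble,
    d_c: float = DEFAULT_CUTOFF,
    selection: Selection | None = None,
    seed: int = 0,
) -> ReferenceSet:
    """Random pick-and-remove decomposition of a trajectory.

    Repeatedly picks a random remaining frame as a reference and removes
    it together with every remaining frame within d_c (superposed RMSD
    over the selection, default Cα).  Deterministic under a fixed seed.
    """
    if d_c <= 0:
        raise ValueError("d_c must be positive")
    if ensemble.n_frames < 1:
        raise ValueError("empty ensemble")
    if selection is None:
        selection = select(ensemble.topology, "calpha")
    rng = np.random.default_rng(seed)
    remaining = np.arange(ensemble.n_frames)
    refs: list[int] = []
    while remaining.size:
        pick = int(remaining[rng.integers(remaining.size)])
        refs.append(pick)
        rmsds = _rmsd_to_frame(ensemble, pick, remaining, selection)
        remaining = remaining[rmsds > d_c]
    return ReferenceSet(d_c, tuple(refs), seed, selection.expression)


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-half cluster occupancies and lone-structure counts per replicate.

    ``table`` columns: replicate, half (1 or 2), reference (frame index),
    occupancy, lone.  A lone structure is a reference whose cluster
    contains only itself across both halves.
    """

    table: pd.DataFrame
    lone_counts: tuple[int, ...]      # per replicate
    reference_counts: tuple[int, ...]
    n_replicates: int
    seeds: tuple[int, ...]
    d_c: float

    def summary(self) -> str:
        lines = [
            f"replicate {r + 1}: {nref} references, {lone} lone structure(s)"
            for r, (nref, lone) in enumerate(zip(self.reference_counts, self.lone_counts))
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def assess_convergence(
    ensemble: Ensemble,
    d_c: float = DEFAULT_CUTOFF,
    selection: Selection | None = None,
    n_replicates: int = 3,
    seed: int = 0,
) -> ConvergenceReport:
    """Full convergence assessment over several random-seed replicates.

    References are built on the full trajectory; frames are split into
    first/second halves by time order and each frame is assigned to the
    nearest reference within d_c (ties to the lower reference index;
    references belong to their own cluster).
    """
    if ensemble.n_frames < 2:
        raise ValueError("convergence assessment needs at least 2 frames")
    if selection is None:
        selection = select(ensemble.topology, "calpha")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    half = ensemble.n_frames // 2
    halves = (np.arange(half), np.arange(half, ensemble.n_frames))
    rows = []
    lone_counts, ref_counts = [], []
    for rep, rep_seed in enumerate(child_seeds, start=1):
        refset = build_reference_set(ensemble, d_c, selection, int(rep_seed))
        refs = np.array(refset.reference_indices)
        # nearest-reference assignment for every frame
        dists = np.stack(
            [
                _rmsd_to_frame(ensemble, int(r), np.arange(ensemble.n_frames), selection)
                for r in refs
            ],
            axis=1,
        )                                              # (F, n_refs)
        nearest = np.argmin(dists, axis=1)             # ties -> lower index
        totals = np.bincount(nearest, minlength=len(refs))
        lone = totals == 1
        for h, idx in enumerate(halves, start=1):
            occ = np.bincount(nearest[idx], minlength=len(refs))
            for j, r in enumerate(refs):
                rows.append((rep, h, int(r), int(occ[j]), bool(lone[j])))
        lone_counts.append(int(lone.sum()))
        ref_counts.append(len(refs))
    table = pd.DataFrame(
        rows, columns=["replicate", "half", "reference", "occupancy", "lone"]
    )
    return ConvergenceReport(
        table,
        tuple(lone_counts),
        tuple(ref_counts),
        n_replicates,
        tuple(int(s) for s in child_seeds),
        d_c,
    )
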