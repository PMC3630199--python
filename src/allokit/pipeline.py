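"""End-to-end two-ensemble comparison pipeline.

Given two groups of replicate trajectories (e.g. unmodified vs modified
receptor), the pipeline runs every analysis -- convergence assessment,
per-residue RMSf, monitored contact distances with window populations,
helix orientation angles and bend radii, quasi-harmonic modes with
mode-restricted RMSf, and block-averaged correlation matrices -- then
contrasts the per-frame scalar metrics between the groups with
Shapiro-Wilk normality checks and a two-sample t test.  Replicates are
pooled by concatenating their per-frame metric series.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .collective import (
    correlation_network,
    cross_correlation_matrix,
    mode_rmsf,
    quasi_harmonic_modes,
)
from .convergence import assess_convergence
from .fluctuations import rmsf
from .interactions import pair_distance_series, window_populations
from .helices import bend_radius_series, interhelix_angle_series
from .selection import select
from .stats import format_p, shapiro_wilk, students_t
from .trajectory import Ensemble, discard_equilibration, read_multimodel_pdb

__all__ = ["PipelineConfig", "ComparisonReport", "PipelineError", "compare_ensembles"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and inputs."""


@dataclass
class PipelineConfig:
    """Everything the comparison pipeline needs, serialisable to YAML.

    ``helices`` maps helix names to selection expressions; ``helix_pairs``
    and ``bend_helices`` refer to those names.  ``monitored_pairs`` lists
    residue pairs as ((chain, res_id), (chain, res_id)); ``windows`` maps
    a pair's label (built from its residues, e.g. ``"A:62-A:63"``) to
    distance windows in Å.
    """

    label_a: str = "ensemble_a"
    label_b: str = "ensemble_b"
    paths_a: list = field(default_factory=list)
    paths_b: list = field(default_factory=list)
    t_start: float = 0.0            # ps discarded as equilibration
    dt: float = 100.0               # ps between frames when times are absent
    helices: dict = field(default_factory=dict)
    helix_pairs: list = field(default_factory=list)
    bend_helices: list = field(default_factory=list)
    bend_method: str = "enclosing_sphere"
    monitored_pairs: list = field(default_factory=list)
    windows: dict = field(default_factory=dict)
    bin_width: float = 0.5          # Å histogram resolution
    salt_bridge_cutoff: float = 3.2
    d_c: float = 1.4                # Å convergence cutoff (Cα RMSD)
    convergence_replicates: int = 3
    block_length: float = 500.0     # ps for correlation blocks
    analysis_selection: str = "calpha"
    temperature: float = 300.0
    mode_count: int = 10
    t_variant: str = "welch"
    focus_residues: list = field(default_factory=list)
    run_convergence: bool = True
    run_rmsf: bool = True
    run_qha: bool = True
    run_correlations: bool = True
    seed: int = 0

    def validate(self) -> None:
        for field_name, pairs in (("helix_pairs", self.helix_pairs),):
            for pair in pairs:
                for name in pair:
                    if name not in self.helices:
                        raise PipelineError(
                            f"config field {field_name!r} refers to undefined "
                            f"helix {name!r}"
                        )
        for name in self.bend_helices:
            if name not in self.helices:
                raise PipelineError(
                    f"config field 'bend_helices' refers to undefined helix {name!r}"
                )
        if self.bend_method not in ("arc_circle", "enclosing_sphere"):
            raise PipelineError("bend_method must be 'arc_circle' or 'enclosing_sphere'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def pair_label(pair) -> str:
    (ca, ra), (cb, rb) = pair[0], pair[1]
    return f"{ca}:{ra}-{cb}:{rb}"


@dataclass
class ComparisonReport:
    """Per-metric comparison table plus all intermediate analysis tables.

    ``metrics`` has one row per scalar metric (distances, angles, radii)
    with group means +/- sd, Shapiro-Wilk W and p per group, and the
    two-sample t statistic, degrees of freedom and p-value.  ``tables``
    holds the window populations, RMSf profiles, QHA frequencies,
    correlation matrices/networks and convergence tables, keyed by name.
    ``series`` keeps the pooled per-frame metric series per group.
    """

    metrics: pd.DataFrame
    tables: dict
    series: dict
    provenance: dict

    def write(self, out_dir) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.metrics.to_csv(os.path.join(out_dir, "metrics.tsv"), sep="\t", index=False)
        for name, table in self.tables.items():
            table.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t")
        with open(os.path.join(out_dir, "provenance.yaml"), "w") as fh:
            yaml.safe_dump(self.provenance, fh, sort_keys=False)

    def plot_histograms(self, out_dir, bins=40) -> list:
        """Render per-metric histograms of both groups; returns file paths."""
        import os

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        os.makedirs(out_dir, exist_ok=True)
        paths = []
        labels = self.provenance["labels"]
        for metric, groups in self.series.items():
            fig, ax = plt.subplots(figsize=(5, 3.2))
            for label in labels:
                ax.hist(groups[label], bins=bins, alpha=0.55, label=label)
            ax.set_xlabel(metric)
            ax.set_ylabel("frames")
            ax.legend(frameon=False)
            fig.tight_layout()
            path = os.path.join(out_dir, f"hist_{metric.replace(':', '_')}.png")
            fig.savefig(path, dpi=120)
            plt.close(fig)
            paths.append(path)
        return paths


def _load_group(paths, config: PipelineConfig) -> list[Ensemble]:
    group = []
    for path in paths:
        ens = read_multimodel_pdb(path).ensure_times(config.dt)
        group.append(ens)
    return group


def _prepare(group: list[Ensemble], config: PipelineConfig) -> list[Ensemble]:
    out = []
    for ens in group:
        ens = ens.ensure_times(config.dt)
        if config.t_start > 0:
            ens = discard_equilibration(ens, config.t_start)
        out.append(ens)
    return out


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def compare_ensembles(
    config: PipelineConfig,
    ensembles_a: list[Ensemble] | None = None,
    ensembles_b: list[Ensemble] | None = None,
) -> ComparisonReport:
    """Run the full two-ensemble comparison.

    Ensembles may be passed in memory; otherwise they are read from the
    config's path lists.  Identical config and seeds give identical
    reports.
    """
    config.validate()
    with _stage("load"):
        if ensembles_a is None:
            ensembles_a = _load_group(config.paths_a, config)
        if ensembles_b is None:
            ensembles_b = _load_group(config.paths_b, config)
        if not ensembles_a or not ensembles_b:
            raise PipelineError("stage 'load': both groups need at least one ensemble")
        groups = {
            config.label_a: _prepare(ensembles_a, config),
            config.label_b: _prepare(ensembles_b, config),
        }
    labels = list(groups)
    topo = groups[labels[0]][0].topology
    tables: dict[str, pd.DataFrame] = {}
    series: dict[str, dict[str, np.ndarray]] = {}

    with _stage("convergence"):
        if config.run_convergence:
            rows = []
            for label, members in groups.items():
                for rep, ens in enumerate(members, start=1):
                    report = assess_convergence(
                        ens,
                        config.d_c,
                        select(ens.topology, config.analysis_selection),
                        config.convergence_replicates,
                        seed=config.seed + rep,
                    )
                    for nref, lone in zip(report.reference_counts, report.lone_counts):
                        rows.append((label, rep, nref, lone))
            tables["convergence"] = pd.DataFrame(
                rows, columns=["ensemble", "trajectory", "references", "lone_structures"]
            ).set_index(["ensemble", "trajectory"])

    with _stage("rmsf"):
        if config.run_rmsf:
            frames = []
            for label, members in groups.items():
                profiles = [
                    rmsf(ens, select(ens.topology, config.analysis_selection))
                    for ens in members
                ]
                avg = pd.concat([p.values for p in profiles], axis=1).mean(axis=1)
                frames.append(avg.rename(label))
            tables["rmsf"] = pd.concat(frames, axis=1)

    with _stage("distances"):
        pop_rows = []
        for pair in config.monitored_pairs:
            label_p = pair_label(pair)
            series[f"dist:{label_p}"] = {}
            for label, members in groups.items():
                pooled = np.concatenate(
                    [
                        pair_distance_series(
                            ens, tuple(pair[0]), tuple(pair[1])
                        ).distances
                        for ens in members
                    ]
                )
                series[f"dist:{label_p}"][label] = pooled
                windows = [tuple(w) for w in config.windows.get(label_p, [])]
                if windows:
                    ds = pair_distance_series(
                        members[0], tuple(pair[0]), tuple(pair[1])
                    )
                    ds = type(ds)(
                        ds.atom_a, ds.atom_b, ds.label, pooled
                    )
                    ds = window_populations(ds, config.bin_width, tuple(windows))
                    for lo, hi, frac in ds.windows:
                        pop_rows.append((label_p, label, lo, hi, frac))
        if pop_rows:
            tables["window_populations"] = pd.DataFrame(
                pop_rows, columns=["pair", "ensemble", "lo", "hi", "fraction"]
            ).set_index(["pair", "ensemble"])

    with _stage("helices"):
        helix_sel = {
            name: expr for name, expr in config.helices.items()
        }
        for name_a, name_b in config.helix_pairs:
            key = f"angle:{name_a}-{name_b}"
            series[key] = {}
            for label, members in groups.items():
                pooled = np.concatenate(
                    [
                        interhelix_angle_series(
                            ens,
                            select(ens.topology, helix_sel[name_a]),
                            select(ens.topology, helix_sel[name_b]),
                        ).values
                        for ens in members
                    ]
                )
                series[key][label] = pooled
        for name in config.bend_helices:
            key = f"bend:{name}"
            series[key] = {}
            for label, members in groups.items():
                pooled = np.concatenate(
                    [
                        bend_radius_series(
                            ens,
                            select(ens.topology, helix_sel[name]),
                            method=config.bend_method,
                        ).values
                        for ens in members
                    ]
                )
                series[key][label] = pooled

    with _stage("qha"):
        if config.run_qha:
            freq_rows = []
            mode_frames = []
            for label, members in groups.items():
                profiles = []
                for rep, ens in enumerate(members, start=1):
                    sel = select(ens.topology, config.analysis_selection)
                    qha = quasi_harmonic_modes(ens, sel, config.temperature)
                    for k, nu in enumerate(qha.frequencies_cm[:3], start=1):
                        freq_rows.append((label, rep, k, nu))
                    n_modes = min(config.mode_count, len(qha.frequencies_cm))
                    profiles.append(mode_rmsf(qha, ens, sel, n_modes).values)
                avg = pd.concat(profiles, axis=1).mean(axis=1)
                mode_frames.append(avg.rename(label))
            tables["qha_frequencies"] = pd.DataFrame(
                freq_rows, columns=["ensemble", "trajectory", "mode", "frequency_cm"]
            ).set_index(["ensemble", "trajectory", "mode"])
            tables["mode_rmsf"] = pd.concat(mode_frames, axis=1)

    with _stage("correlations"):
        if config.run_correlations:
            for label, members in groups.items():
                mats = [
                    cross_correlation_matrix(
                        ens,
                        select(ens.topology, config.analysis_selection),
                        config.block_length,
                    )
                    for ens in members
                ]
                avg = sum(m.matrix for m in mats) / len(mats)
                tables[f"correlation_{label}"] = avg
                if config.focus_residues:
                    cm = type(mats[0])(
                        avg, mats[0].residues, config.block_length, len(mats)
                    )
                    tables[f"network_{label}"] = correlation_network(
                        cm, config.focus_residues
                    ).set_index(["res_i", "res_j"])

    with _stage("statistics"):
        rows = []
        for metric in sorted(series):
            a = series[metric][labels[0]]
            b = series[metric][labels[1]]
            w_a, p_a = shapiro_wilk(a, seed=config.seed)
            w_b, p_b = shapiro_wilk(b, seed=config.seed)
            t, df, p = students_t(a, b, config.t_variant)
            rows.append(
                {
                    "metric": metric,
                    "n_a": len(a),
                    "mean_a": float(np.mean(a)),
                    "sd_a": float(np.std(a, ddof=1)),
                    "n_b": len(b),
                    "mean_b": float(np.mean(b)),
                    "sd_b": float(np.std(b, ddof=1)),
                    "shapiro_W_a": w_a,
                    "shapiro_p_a": p_a,
                    "shapiro_W_b": w_b,
                    "shapiro_p_b": p_b,
                    "t": t,
                    "df": df,
                    "p": p,
                    "p_formatted": format_p(p),
                }
            )
        metrics = pd.DataFrame(rows)

    provenance = {
        "package_version": _version,
        "labels": labels,
        "seed": config.seed,
        "config": asdict(config),
        "n_frames": {
            label: [ens.n_frames for ens in members]
            for label, members in groups.items()
        },
    }
    return ComparisonReport(metrics, tables, series, provenance)
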