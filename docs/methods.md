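# Methods

`allokit` compares two conformational ensembles of a protein domain and
reports the dynamical signatures through which a local perturbation (the
motivating case is side-chain phosphorylation of a nuclear-receptor
ligand-binding domain) propagates to a distant functional site: salt-bridge
network remodeling, helix bend and orientation changes, local and collective
fluctuation changes, correlation-network changes, and an ensemble-convergence
check. Because suitable public trajectory data are rarely available at test
scale, the package ships a synthetic-ensemble generator whose ground truth
every estimator must recover; all validation rests on that recoverability
plus brute-force oracles and closed-form limits.

## Ensembles and superposition

An ensemble is an ordered stack of coordinate frames (Å) over one topology,
read and written as multi-model PDB so that all fixtures stay plain text.
Frames without time stamps receive synthetic uniform times (default spacing
100 ps) because the windowed analyses need a time axis. Equilibration is
removed by dropping frames before a start time.

Superposition is the standard SVD least-squares (Kabsch) solution with the
determinant correction that excludes reflections; it requires at least three
non-collinear fitted atoms. The reference structure for fluctuation analyses
is the *iterated* (two-pass) mean: frames are aligned to the first frame and
averaged, then aligned to that average and re-averaged. The second pass
removes the bias of the arbitrary initial alignment target.

## Fluctuations

Per-atom RMSf is the root-mean-square deviation from the iterated mean after
superposition; per-residue values are unweighted means over the residue's
selected atoms. The crystallographic relation B = (8π²/3)⟨Δr²⟩ converts
profiles to and from B-factors exactly. For an isotropic Gaussian ensemble
of width σ the per-atom RMSf is √3·σ, slightly shrunk (~2–3% at 40–50
fitted atoms) because superposition absorbs six rigid degrees of freedom;
the 5% test tolerance covers this.

## Salt bridges and contact distances

A salt bridge is formed in a frame when any side-chain oxygen of an acidic
residue (Asp OD1/OD2, Glu OE1/OE2) is within 3.2 Å of any side-chain
nitrogen of a basic residue (Arg NE/NH1/NH2, Lys NZ). An extended mode adds
phosphoserine phosphate oxygens (residue SEP/S1P) and histidine ND1/NE2.
Contact geometry beyond the formation cutoff is monitored via the distance
between side-chain reference carbons (Arg Cζ, Lys Cε, Glu Cδ, Asp Cγ),
histogrammed at 0.5 Å resolution with half-open distance windows \[lo, hi)
so population accounting is unambiguous. The donor–H–acceptor angle check
uses an inclusive threshold (default 120°: an angle of exactly 120° still
counts as formed). Distances are internal coordinates; no superposition is
applied to them.

## Helix geometry

The helix axis is estimated by a geometric least-squares cylinder fit: the
Cα atoms of a regular helix all lie at the cylinder radius from the axis, so
the fit minimises the spread of point-to-axis distances over axis position,
direction and radius. It is initialised from the principal direction of
3-point running means of the Cα positions (which suppress the ~100°/residue
helical wobble) and is exact on ideal helices; under 0.3 Å coordinate noise
on a 20-residue helix the axis direction stays within ~2.2° of truth. Axes
are oriented N→C, so inter-helix angles lie in \[0°, 180°\] with 0 parallel
and 180 antiparallel.

Helix bend is quantified with two conventions, because both are in use:

* **arc-circle radius** — the radius of the circular arc the helix axis
  follows. A plain circle fit through the smoothed axis points is biased
  several percent high on short arcs (the residual wobble does not average
  out over ~60° of arc), so the package refines it with a 3-D circle
  ("torus") fit minimising the spread of Cα-to-circle distances, which is
  exact on noise-free bent constructions. An axis whose line fit explains
  the Cα distances at least as well as the circle is declared straight and
  reported as a cap radius (10⁶ Å) with a flag.
* **enclosing-sphere radius** — the radius of the minimal sphere containing
  the Cα atoms (Welzl's algorithm, exact): a bent helix packs into a
  smaller sphere than an extended helix of the same length. This is the
  default bend metric in the comparison pipeline.

A note on the ideal 22-residue helix: the minimal enclosing sphere has
radius 15.79 Å, *not* the axial construction √((21·1.5/2)² + 2.3²) = 15.92 Å
— the true sphere centre sits slightly off the helix axis. The axial value
is an upper bound within 1%.

## Quasi-harmonic analysis

The mass-weighted covariance of displacements about the iterated mean (after
superposition over the analysis selection) is diagonalised; eigenvalues λ
(amu·Å²) map to frequencies ν = (1/2πc)·√(k_BT/λ) using k_B =
0.001987204 kcal/(mol·K), 1 kcal/mol = 418.4 amu·Å²/ps² and c =
2.99792458·10⁻² cm/ps. Large eigenvalues are the low-frequency collective
modes. Eigenvalues below 10⁻⁸ of the largest are flagged quasi-rigid (six
are expected after superposition) and excluded from frequency lists. Mode-
restricted RMSf sums λ_k|e_{k,i}|²/m_i over the chosen lowest-frequency
modes; over all modes this identity recovers the direct ensemble RMSf
exactly. A `superpose=False` path supports systems without rotational
freedom (e.g. sampled model oscillators, pre-aligned input).

## Cross-correlations

The inter-residue coupling C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩) uses the
displacement of each residue's selected-atom centroid. The trajectory is cut
into consecutive non-overlapping blocks (default 500 ps; trailing partial
block dropped), each block gets its own mean structure and superposition,
and the final matrix is the unweighted block average — this suppresses
spurious correlations from slow drift. Displacements are not mass-weighted.
Correlation networks bin C_ij into one anti-correlated class \[−0.2, −0.1)
and four positive classes \[0.2, 0.3), \[0.3, 0.4), \[0.4, 0.7), \[0.7, 1.0\]
(half-open except the last); values between bins yield no edge.

## Convergence assessment

Following the cutoff-based reference-decomposition approach: with d_c fixed
(default 1.4 Å Cα RMSD), a random remaining frame becomes a reference and
all remaining frames within d_c of it are removed, until none remain.
References are therefore pairwise separated by more than d_c and cover the
trajectory. Frames are then split into first/second halves by time and
assigned to the nearest reference (ties to the lower reference index); a
reference whose cluster holds only itself is a *lone structure*. Few lone
structures and similar per-half occupancies indicate a converged, drift-free
ensemble. The procedure is repeated (default 3 replicates) with seeds
derived deterministically from the master seed. References are built on the
full trajectory, not per half, so both halves are clustered against one
common decomposition.

## Statistics

Metric distributions are checked for normality with the Shapiro–Wilk test
(series longer than 5000 are subsampled with a fixed seed, since the test's
calibration range ends there); group means are compared with a two-sample
t test, Welch's variant by default with the pooled-variance variant
available. p-values below 2.2·10⁻¹⁶ are reported as "< 2.2e-16". No
multiple-testing correction is applied across metrics; the null-calibration
test verifies the per-metric false-positive rate instead.

## The synthetic generator and what it does (not) show

The generator emulates exactly the statistical features the estimators
assume: isotropic Gaussian fluctuations with controllable per-atom σ;
injected sinusoidal collective modes with uniform random phases (variance
amplitude²/2 along the mode, visible to both QHA and equal-time
correlations); two-state switching of one inter-atomic distance with set
populations and Gaussian jitter; ideal helices (rise 1.5 Å, twist 100°,
Cα radius 2.3 Å — textbook values) bent isometrically onto circular arcs;
and a toy receptor scaffold with named pseudo-side-chain atoms (Arg
CZ/NE/NH1/NH2 etc. at schematic 1.25–1.5 Å offsets) so salt-bridge and
reference-carbon analyses run end to end.

The canonical study scenario uses two 20-residue helices crossing at 50°,
a stable Arg/Asp pair at minimum N–O distance 3.0 Å, and a Glu/Arg contact
switching between 4.0 and 6.25 Å whose near-state population drops from
0.998 (baseline) to 0.65 (perturbed) — the only difference between the two
groups. Defaults: three replicate trajectories per group, 200 frames at
10 ps spacing, noise σ = 0.3 Å, collective-mode peak amplitude 12 Å (per-atom
RMS ≈ 1.3 Å after rigid projection, so the mode dominates the background as
a low-frequency collective motion should). The injected mode displaces
residues 1–10 and 31–40 in phase along the dominant axis direction and is
orthogonalised against the Cα rigid-body fields, making it a purely internal
motion that superposition-based estimators can recover without attenuation.

What passing tests show: the estimators are unbiased and correctly scaled on
data satisfying their assumptions, the pipeline flags exactly the perturbed
observable, and the false-positive rate is calibrated. What they do not
show: behaviour under time-correlated dynamics, anharmonicity, conformational
exchange on the analysis timescale, or force-field artefacts — real MD
features the generator deliberately omits. Statistical tests on real
trajectories additionally require attention to frame autocorrelation, which
the i.i.d. generator does not emulate.

## Numerical choices and degenerate inputs

* Superposition requires ≥3 non-collinear atoms; collinear selections raise.
* Welzl's sphere uses a fixed internal shuffle: deterministic output.
* Straightness in the arc-circle metric is decided by comparing line-fit vs
  circle-fit distance spreads (factor 1.05); straight axes report the cap.
* Zero-variance residues get NaN diagonal entries in correlation matrices
  rather than fabricated 1.0 values.
* Two zero-variance groups with equal means give t = 0, p = 1 by convention.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; identical config + seed gives
  byte-identical report tables.

## Problem sizes

Default test and validation sizes — toy scaffold of 54 atoms (40 Cα),
150–200 frames per replicate, three replicates per group, 2000–5000-frame
fixtures for closed-form checks, 20 000 samples for the oscillator — were
chosen so every ground-truth parameter is recoverable at its stated
tolerance with comfortable statistical margin.

## Known limitations

* The selection language covers names, residues, chains and boolean
  composition only (no distance-based or within-style selections).
* Binary trajectory formats (DCD/XTC) are not read; multi-model PDB is the
  interchange format.
* The arc-circle bend metric is undefined (capped) for straight helices by
  construction; compare distributions with the enclosing-sphere metric when
  near-straight conformations are common.
* Replicate pooling concatenates per-frame series; it does not model
  between-replicate variance components.
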