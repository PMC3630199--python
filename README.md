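# allokit

Comparative analysis of protein conformational ensembles.

Allosteric regulation often works without large conformational change: a
local perturbation — the motivating case is phosphorylation of a serine in
a nuclear-receptor ligand-binding domain — subtly redistributes an ensemble
of pre-existing states, remodeling salt-bridge networks, straightening or
re-orienting helices, and shifting low-frequency collective motions at a
functional site tens of Ångströms away. `allokit` is a toolkit for
detecting exactly these signatures when comparing two conformational
ensembles (e.g. unmodified vs modified receptor), aimed at researchers
analysing molecular-dynamics ensembles of signalling proteins.

Given two groups of replicate trajectories sharing one topology, it
computes:

* **salt bridges** — formed when any acidic side-chain O is within 3.2 Å of
  a basic side-chain N; contact distributions monitored between side-chain
  reference carbons (Arg Cζ, Lys Cε, Glu Cδ, Asp Cγ) with window
  populations, plus a donor–H–acceptor angle check;
* **fluctuations** — per-residue RMSf about the iterated mean structure,
  RMSf_i = √(1/T · Σ_t |r_i(t) − r_i^ref|²), and B = (8π²/3)⟨Δr²⟩;
* **helix geometry** — cylinder-fit axes, inter-helix orientation angles,
  and helix bend as either an arc-circle radius or the minimal
  enclosing-sphere radius of the Cα atoms;
* **collective dynamics** — quasi-harmonic modes of the mass-weighted
  covariance, ν_k = (1/2πc)·√(k_B T/λ_k), mode-restricted RMSf, and
  block-averaged cross-correlation maps
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩) with class-binned correlation
  networks;
* **convergence** — random reference-structure decomposition at a Cα-RMSD
  cutoff d_c (default 1.4 Å) with per-half occupancies and lone-structure
  counts;
* **statistics** — Shapiro–Wilk normality and two-sample (Welch) t tests
  per metric, with the "< 2.2e-16" floor convention.

Because suitable trajectories are rarely shareable, the package includes a
synthetic-ensemble generator (Gaussian fluctuations, injected collective
modes, two-state contact switching, bendable ideal helices, a toy receptor
scaffold) whose known ground truth every estimator is validated against.

## Worked example

Generate the canonical synthetic study — a baseline and a perturbed
ensemble of a two-helix scaffold that differ *only* in the near-state
population of one Glu/Arg contact (0.998 → 0.65) — and run the comparison:

```sh
allokit simulate --n-frames 200 --seed 1 --out-dir study
allokit compare --config study/config.yaml --out-dir report
```

which prints (abridged):

```
        metric     mean_a     mean_b          t p_formatted
   angle:H1-H2  50.310356  50.818373  -1.299148       0.194
       bend:H2  14.419983  14.358185   1.062203       0.288
dist:A:60-A:61   4.749467   4.714945   1.436824       0.151
dist:A:62-A:63   4.003665   4.842561 -18.420613   < 2.2e-16
```

Reading: the switched contact (reference-carbon distance of the pair
A:62–A:63) is flagged at the p-value floor, while the inter-helix angle
(~50°, the constructed crossing), the enclosing-sphere radius of helix H2
and the stable salt-bridge distance are statistically indistinguishable —
the pipeline isolates exactly the injected perturbation. `report/`
additionally contains the window populations (99.8% vs ~65% in the
3.5–4.5 Å window), per-residue RMSf and mode-RMSf profiles, the three
lowest quasi-harmonic frequencies per trajectory, averaged correlation
matrices and class-binned networks, and the convergence table (0 lone
structures for these single-basin synthetics).

The same analyses are available per stage (`allokit saltbridges`, `helix`,
`qha`, `correlations`, `converge`) and as a library:

```python
import allokit as ak
ens = ak.read_multimodel_pdb("study/baseline_1.pdb").ensure_times(dt=10.0)
profile = ak.rmsf(ens, ak.select(ens.topology, "calpha"))
```

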