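# thermoenv

Thermodynamic-environment profiling of proteins and proteomes.

Protein sequences can be annotated not only by secondary structure but by the
*local thermodynamics* of each residue: a 4-vector of descriptors
(ΔG, ΔH_apolar, ΔH_polar, TΔS_conf) describing the equilibrium between the
locally folded (native) and locally unfolded (denatured) subensembles at that
position. `thermoenv` coarse-grains these descriptors into an eight-letter
alphabet of **thermodynamic environments (TEs)** per state — ranked TE1
(least stable, least negative mean ΔG) through TE8 (most stable) — and builds
proteome- and protein-level analyses on top of that alphabet. It is aimed at
structural bioinformaticians studying how organisms distribute local protein
stability across their proteomes, and how that distribution tracks growth
temperature, intrinsic disorder and global protein stability.

## What it computes

- **TE assignment.** A residue's descriptor vector is mapped to the TE whose
  cluster center is nearest in *weighted Manhattan distance*:

  TE_j^N = argmin_k [ |ΔḠ_k − ΔG_j| + |ΔH̄_ap,k − ΔH_ap,j| +
  |ΔH̄_pol,k − ΔH_pol,j| + 3·|TΔS̄_conf,k − TΔS_conf,j| ]

  with the conformational-entropy term tripled for the native state and unit
  weights for the denatured state. Ties resolve to the lowest index.
- **Proteome profiles.** Pooled TE frequency vectors T_n/Σ T_n per organism,
  UPGMA clustering (Euclidean distance, newick output), PCA on mean-centered
  frequencies, and OLS regressions of PC scores against organism traits with
  a kingdom × score interaction test.
- **Secondary-structure enrichment.** The 4×8 log-odds matrix
  ln(P(class|TE)/P(class)) over DSSP-derived classes
  (helix = H/G/I, strand = E/B, turn = T/S, coil = rest).
- **Global stability.** An additive model
  ΔG = Σ_i w_i^N·NTE_i + Σ_j w_j^D·DTE_j − L·R·T·ln Z
  (kJ/mol, 298.15 K), fitted by exact linear least squares with optional
  gauge fixing, leave-one-out bootstrapping, and a threshold classifier
  separating structured from intrinsically disordered proteins.
- **Mutation profiles.** Kyte–Doolittle hydropathy windows and positionwise
  TE-delta tracks for wild-type/mutant pairs.
- **Synthetic data.** Generators for every input the pipeline consumes
  (descriptor tables, proteome sets with kingdom structure and planted
  traits, secondary-structure labels with planted enrichments, stability
  records from known parameters), each returning its ground truth.

## Worked example

```python
import numpy as np
from thermoenv import (annotate_protein, proteome_te_frequencies,
                       pca_decompose, regress_pc_vs_trait,
                       StabilityParams, fit_model, loo_bootstrap)
from thermoenv.simulate import (GeneratorConfig, gen_proteome_set,
                                gen_stability_records)

# three kingdoms x 10 organisms, full pipeline: TD tables -> TEs -> profiles
config = GeneratorConfig(seed=42, n_organisms_per_kingdom=10, n_proteins=10)
dataset = gen_proteome_set(config)
profiles = []
for organism in dataset.organisms:
    te_seqs = [annotate_protein(t, dataset.centers) for t in organism.td_tables]
    profiles.append(proteome_te_frequencies(te_seqs, organism.meta))

pca = pca_decompose(profiles)
print("PC1 %.1f%%, PC2 %.1f%% of variance"
      % tuple(100 * pca.explained_variance_ratio[:2]))
reg = regress_pc_vs_trait(pca, profiles, "disorder_fraction", pc_index=1)
print("disorder ~ PC1: r=%.2f, p=%.2g (n=%d)" % (reg.pearson_r, reg.p_value, reg.n))

# stability model: recover Z from synthetic records (mean-zero truth, Z = 20)
k = np.arange(1, 9, dtype=float)
truth = StabilityParams(w_native=-0.45*(k-4.5), w_denatured=-0.30*(k-4.5), z=20.0)
records, _ = gen_stability_records(35, stability_truth=truth, noise_sd=2.0,
                                   config=GeneratorConfig(seed=42))
fit = fit_model(records, gauge_fix=True)
print("fitted Z = %.2f conformations per residue" % fit.params.z)
print("per-residue penalty R*T*ln(Z) = %.2f kJ/mol" % (fit.params.rt * fit.params.ln_z))
```

prints

```
PC1 47.2%, PC2 20.6% of variance
disorder ~ PC1: r=-0.87, p=5.3e-10 (n=30)
fitted Z = 20.13 conformations per residue
per-residue penalty R*T*ln(Z) = 7.44 kJ/mol
```

The first two components carry most of the TE-usage variance (the trailing
eigenvalue is exactly zero because frequencies sum to 1); the planted
disorder trait is recovered on the dominant component; and the fitted
unfolded-state multiplicity Z lands on the generating value of 20
conformations per residue, i.e. a per-residue entropic penalty
R·T·ln 20 ≈ 7.43 kJ/mol.

A `thermoenv` command-line tool exposes the same pipeline
(`simulate`, `assign`, `profile`, `pca`, `regress`, `enrich`,
`fit-stability`, `predict-stability`, `mutprofile`); every stochastic
subcommand takes a seed.

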