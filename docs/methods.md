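# Methods

This note records the models, conventions and design choices behind
`thermoenv`, in the spirit of a statistical package's model documentation.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Thermodynamic descriptors and environments

Each residue position carries two 4-vectors of thermodynamic descriptors
(TDs) — local ΔG, apolar enthalpy ΔH_apolar, polar enthalpy ΔH_polar, and
conformational entropy TΔS_conf — one for the native (locally folded)
subensemble and one for a locally unfolded denatured subensemble. "Local"
means the descriptors report on the folding equilibrium at that position,
not on the residue's contribution to global stability. All energies are
held internally in kJ/mol; center tables supplied in kcal/mol are converted
on load (x4.184).

A residue's thermodynamic environment (TE) is the index (1..8) of the
nearest cluster center under a weighted Manhattan metric. The native metric
weights (ΔG, ΔH_apolar, ΔH_polar, TΔS_conf) as (1, 1, 1, 3) — the tripled
conformational-entropy term is kept exactly as the assignment rule defines
it and is exposed as a configurable weight vector; the denatured metric
uses unit weights. Argmin ties resolve to the lowest environment index; the
minimum itself is silent on ties and a deterministic rule is needed for
reproducibility. Assignment is invariant under a common positive rescaling
of centers and inputs, which is why declared units matter only insofar as
centers and inputs must share them.

Center tables are data, not code: the package ships no empirical center
values. The synthetic default (`gen_center_table`) places centers with all
four coordinates trending monotonically in the stability rank, so native
mean ΔG decreases strictly from TE1 (least stable) to TE8 (most stable) and
the pairwise metric separation grows linearly with rank distance; the
construction guarantees (and verifies exhaustively) a minimum pairwise
separation, 10 kJ/mol by default.

## Proteome profiles, clustering, PCA

A proteome's TE frequency vector is the pooled residue count per
environment divided by the total residue count (long proteins weigh more);
a per-protein mean is available behind a flag since either reading of a
"per-proteome proportion" is defensible. Profiles must sum to 1 within
1e-9.

UPGMA clustering uses Euclidean distance on frequency vectors
(`scipy.cluster.hierarchy`, average linkage). The tree convention places a
node at **half** the average pairwise distance between the joined clusters,
so trees are ultrametric and the cophenetic distance between two leaves
equals the full UPGMA average distance at their join. Newick serialisation
follows this convention.

PCA (scikit-learn, full SVD) runs on mean-centered, *unscaled* frequency
vectors — the common default of the decomposition tooling, and frequencies
already share a scale. Because the 8 frequencies sum to 1 (compositional
closure) their covariance has rank at most 7; the trailing eigenvalue is
zero and is tolerated, never treated as signal, and at most
min(n_features, n_samples − 1) components may be requested. Since PCA signs
are arbitrary, each loading is oriented so its largest-magnitude entry is
positive. A `states="both"` flag concatenates native and denatured
frequencies into 16-vectors before decomposition.

Trait regressions are ordinary least squares of the trait on a single PC
score (slope in trait units per score unit, Pearson r, two-sided p for zero
slope); organisms missing a trait are dropped and counted, never imputed.
The kingdom comparison is an OLS ANCOVA with a full kingdom × score
interaction; the reported p-value is the F-test of the interaction model
against the common-slope model, alongside each kingdom's own slope. The
"most stable fraction" trait defaults to the TE8 frequency with the
environment set configurable (e.g. {7, 8}), since "most stable" is a
presentation choice rather than a defined quantity.

## Secondary-structure log-odds

DSSP codes group as helix (H, G, I), strand (E, B), turn (T, S) and coil
(anything else, applied literally — unassigned residues fall through to
coil). For class j and environment k the score is the pointwise mutual
information ln(N·N_jk / (N_j·N_k)) over the 4×8 joint count table. Cells
with a zero class or environment marginal are undefined (NaN, not zero); a
zero joint count with positive marginals is −inf, which keeps the identity
Σ_k (N_k/N)·exp(score_jk) = 1 exact over defined cells. No pseudocount is
applied by default — at proteome scale zeros are moot — but a Haldane-style
+0.5 flag exists for small samples.

## Additive stability model

Predicted global stability of a protein of length L with native counts
NTE_i and denatured counts DTE_j:

    ΔG = Σ_i w_i^N·NTE_i + Σ_j w_j^D·DTE_j − L·R·T·ln Z

in kJ/mol at T = 298.15 K (configurable but defaulted), R = 0.0083145
kJ/(mol·K). The last term is a uniform per-residue conformational-entropy
penalty with Z the effective number of unfolded-state conformations per
residue; at Z = 20, R·T·ln Z ≈ 7.43 kJ/mol. The sign convention is that
more negative ΔG means more stable, and the classifier calls a protein
disordered when its predicted ΔG exceeds a threshold (default 0).

**Identifiability.** Since Σ_i NTE_i = Σ_j DTE_j = L, the map
w^N → w^N + a, w^D → w^D + b, ln Z → ln Z + (a+b)/(R·T) changes no
prediction: the parameters carry a two-dimensional gauge freedom, and fit
quality must be judged on predictions. The expression is linear in the
weights *and* in ln Z, so fitting is an exact linear least-squares problem.
The fitter therefore solves it directly (`numpy.linalg.lstsq`): the
unconstrained default returns the deterministic minimum-norm solution and
reports the design rank; `gauge_fix=True` pins mean(w^N) = mean(w^D) = 0,
making ln Z identifiable and parameters comparable across fits; `fixed_z`
freezes Z. A generic iterative minimiser was deliberately not used — on a
linear problem with an exact gauge degeneracy it is slower, less accurate,
and its box bounds would bind the unidentifiable directions.

Leave-one-out bootstrapping refits n times, each fold excluding one record,
and averages fold parameters — weights elementwise, Z through its logarithm
(Z enters the model only as ln Z). Held-out predictions and their RMSE are
reported per fold; a failed fold is flagged and excluded from the average.
With 16 count features and n = 35 records the LOO held-out RMSE is expected
to sit moderately above the noise level (roughly σ·sqrt(1 + p/n)).

## Synthetic-data generators

The generators define the study conditions; their defaults are fixed here
and are what the tests and the acceptance script run against.

- **Baseline composition.** Native TE usage peaks at the median-stability
  environments (TE4 0.24, TE5 0.23 — each roughly twice any other
  environment) with the stability extremes TE1 (0.04) and TE8 (0.065)
  rarest.
- **Proteome sets.** 3 kingdoms × 30 organisms, 25 proteins of 60–160
  residues each. An organism's target composition is a Dirichlet draw
  (precision 600) around its kingdom mean: the baseline tilted by ±0.05
  along two unit contrasts, a linear stability gradient and a
  hydrophobicity proxy loading on the stability extremes, with eukaryotes
  tilted apart from bacteria and archaea along both. Residue labels are
  i.i.d. from the target composition; TD vectors add isotropic Gaussian
  scatter (sd 1 kJ/mol against 10 kJ/mol center separation, so assignment
  recovers ≥99% of true labels). Growth temperature (base 34 °C, slope 150
  °C per unit hydrophobicity contrast, noise sd 2 °C) and disorder fraction
  (base 0.18, slope 1.5 per unit stability contrast, noise sd 0.015,
  clipped to [0,1]) are linear in the realised composition; slopes and
  contrasts are recorded as ground truth. An `axis_spread` option replaces
  the Dirichlet scatter with rank-1 variation along the stability gradient,
  the construction under which a noiseless trait is exactly linear in the
  first PC score.
- **Secondary structure.** Classes sample from P(j|k) ∝ base_j·exp(S_jk)
  with a planted 4×8 log-enrichment S (default: helix/strand increasing
  with stability rank, turn/coil decreasing, peak magnitude ln 2). Because
  renormalisation shifts realised marginals, the *population* log-odds of a
  cell generally differs from the planted S; where an exact planted value
  is needed, `planted_cell_conditional` constructs the conditional matrix
  self-consistently so that one cell's realised log-odds equals the target
  (e.g. exactly ln 2) given the TE label distribution.
- **Stability records.** Class-specific compositions tilt the baseline by
  exp(±0.25·(k − 4.5)) (structured toward stable TEs, disordered toward
  unstable; Dirichlet precision 60), and ΔG values come from the recorded
  truth parameters plus Gaussian noise (sd 2 kJ/mol by default). The
  default truth uses Z = 20 with weight gradients −0.45 (native) and −0.30
  (denatured) kJ/mol per rank about a mean of 3.69 kJ/mol; the mean level
  offsets the R·T·ln 20 penalty so structured compositions land clearly
  below the zero classification threshold and disordered ones above it.
  The resulting synthetic ΔG magnitudes (tens of kJ/mol per ~100 residues,
  growing with length) are larger than typical experimental stabilities;
  the generator trades that realism for unambiguous class structure.
  Length-matched structured/disordered pairs are available for
  classification experiments.

All randomness in a generator call flows from one seeded
`numpy.random.Generator`; the same seed reproduces byte-identical outputs.

### What the generators do not emulate

Real descriptor predictions are sequence-driven (tripeptide context), so
neighbouring residues' TDs are correlated and amino-acid composition
constrains TE usage; the generators draw residues independently. Real
proteome compositions reflect phylogeny, not clean Dirichlet kingdoms, and
real traits are not exactly linear in TE frequencies. Experimental
stabilities are bounded (roughly −5 to −60 kJ/mol) rather than
length-proportional. Passing tests therefore demonstrate that the
*pipeline* is correct — assignment, pooling, decomposition, fitting and
classification recover planted structure under the stated noise — not that
the biological conclusions would reproduce on real proteomes.

## Numerical choices and problem sizes

- Assignment ties: lowest index; distances compared exactly (no tolerance).
- Profile normalisation tolerance 1e-9; profile TSVs print 12 decimals so
  round-trips stay within it.
- PCA: full SVD; zero total variance is an error; reconstruction with all
  components is exact to <1e-8.
- Least squares: `lstsq` with default rcond; rank reported; rank deficiency
  beyond the expected gauge freedom warns and falls back to the
  pseudo-inverse solution.
- Window means: centered, odd length, termini shrink symmetrically
  (half-width min(w//2, i, L−1−i)) rather than padding. Note that no
  mean-window scheme preserves the track's sum at shrunken termini; the
  operator is linear and shift-equivariant in the interior, which is what
  the tests assert.
- Substitution effects aggregate signed TE changes over the mutated
  position ±3 residues by default (local stability consequences often land
  on sequence neighbours of the mutated site); population variance (ddof 0)
  is reported.
- Test and acceptance problem sizes: 10^4 vectors for the assignment
  oracle, 10^4 residues for label recovery, 90 organisms for the kingdom
  analysis, 500 replicates of n = 200 for regression calibration, 10^5
  residues for log-odds recovery, 35 training and 50+50 test records for
  the stability model. These sizes give comfortable statistical resolution
  for every check while keeping the full suite and the acceptance script in
  the seconds-to-minutes range.

## Known limitations

- The package does not re-derive TE cluster centers from structural data,
  does not implement the upstream sequence-to-descriptor predictor, and
  ships no empirical center values; real analyses must supply a center
  table transcribed from the published values.
- The unconstrained stability fit's raw parameters are gauge-dependent;
  only the gauge-fixed parameterisation supports cross-fit comparison of
  weights or Z.
- The denatured-state PCA variant concatenates native and denatured
  frequencies into one 16-vector; a separate denatured-only decomposition
  is available by profiling denatured tracks alone.
- Melting temperatures, salt/pH dependence, and abundance/biomass analyses
  are out of scope.
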