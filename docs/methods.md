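# Methods notes

This note documents the models behind `casingsoil`, the choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real casing-soil data.

## Synthetic community generator

The generator emulates the *derived* data of a peat-gradient casing-soil
experiment — an OTU table, a rooted phylogeny and physicochemical
metadata — not sequencing reads. Its default design is 5 peat
proportions (0/20/50/70/100%) x 6 growth stages x 3 replicates
(90 samples) over a 300-taxon regional pool at 20,000 multinomial reads
per sample. Pool size and depth are desk-scale choices that keep >80%
occupancy screens meaningful; they are free parameters, not estimates of
any particular study.

**Environment.** Each sample carries one latent "peat axis"
`e = peat/100 + stage gradient + noise`. The stage gradient is linear and
centred (`stage_amplitude`, default 0.4 axis units across the six
stages); replicate noise is Gaussian (`env_noise_sd`, default 0.05).
The eleven measured physicochemical variables are noisy monotone
transforms of this axis, with endpoint values typical for loam vs pure
peat (e.g. TN 1.32 → 8.45 mg/kg, OM 18.6 → 234.8 mg/kg, bulk density
2.67 → 2.02 g/cm³ falling); nitrate is deliberately flat. Clipping at
zero keeps concentrations physical; it is a monotone transform, so
group-mean trends are exact at zero noise. Collapsing the environment to
one axis makes selection recoverable and Mantel/VPA results
interpretable, at a price discussed under *Limitations*.

**Traits and selection.** Habitat optima evolve by Brownian motion along
the simulated tree (variance rate `trait_signal`, default 0.1 on a tree
rescaled to mean root-tip depth 1; tip optima then have SD ≈ 0.32 around
the root value 0.5). Sampling weights are
`w_i(s) = exp(-selection_strength * (optimum_i - e_s)^2) * m_i(s)`;
`selection_strength` has units of 1/axis², i.e. the niche width is
`1/sqrt(2*selection)` (0.13 axis units at the "strong selection" preset
of 30).

**Dispersal regimes** act through the modulation `m`:

* *neutral* — `m = 1`; with zero selection every taxon is equally likely
  (the uniformity is verified by a chi-square test at depth 1e5).
* *limited* — i.i.d. lognormal weight jitter per sample and taxon
  (`dispersal_sigma`, default 2.0): per-sample abundance idiosyncrasy far
  beyond what reassembly from the shared pool produces.
* *homogenizing* — one shared lognormal abundance profile per group
  (`shared_sigma` 1.5); all samples of a stage carry identical weights.
  Membership of the homogenized pool reorganizes once, right after the
  first growth stage: a fraction `patch_drift` (default 0.3) of taxa flip
  presence state. The early single event is deliberate: it leaves ~71% of
  sample pairs sharing realized membership exactly while keeping drifted
  taxa at intermediate group occupancy — the configuration in which mass
  effects are statistically separable from independent reassembly. A
  naive "shared weights, no drift" regime is *undetectable in principle*:
  i.i.d. multinomial draws from shared weights are exactly reproduced by
  the Raup-Crick null built from those same samples, so RC ≈ 0 for every
  pair.

The three `recovery_design` presets freeze the study conditions for the
parameter-recovery experiment (2 contrasting peat groups x 18 samples,
300 taxa). The selection preset raises `stage_amplitude` to 1.0 so the
within-group environment spans the full niche axis: moderate contrasts
select heavily overlapping clades and βNTI stays below 2, whereas
full-axis contrasts select distinct clades and variable selection
dominates.

## Assembly partitioning

βMNTD is abundance-weighted:
`0.5 * [Σ_i f_i^x min_{j∈y} d_ij + Σ_j f_j^y min_{i∈x} d_ij]` over taxa
present in each community, on patristic distances. The βNTI null
shuffles taxon labels across the tips of the distance matrix
("taxa shuffle"), n_null = 999 by default (199 in the shipped
experiments; two independent 999-draw runs differ by < 0.5 on the
default fixture). The shuffle pool is the *regional* pool — every taxon
observed anywhere in the table — not the group's own taxa: a group pool
is already selection-filtered, and shuffling within it erases precisely
the clade confinement the metric is meant to detect. Null standard
deviations below 1e-12 (e.g. star phylogenies) yield βNTI = 0 with a
warning.

The RC_bray null assembles, per sample, a community with the observed
richness and total reads: membership by a Gumbel top-k draw on
log-odds(occupancy) keys — approximately a conditional Poisson sample
whose inclusion probabilities reproduce pool occupancy (occupancy
clipped to [0.005, 0.995]) — then one read per member and the remainder
multinomial proportional to pool relative abundance. The odds
parameterization matters: weighting taxa *proportionally* to occupancy
excludes even always-present taxa from null assemblies and biases RC to
≈ −1 for data that are themselves i.i.d. draws from the pool; with the
odds keys the same check centres near zero (measured mean −0.14, within
the ±0.2 consistency band we test).

Classification uses strict inequalities (|βNTI| = 2 and |RC| = 0.95 fall
to the stochastic/undominated side), and βNTI/RC are computed within
groups only (18 samples → 153 pairs per group).

**A bound worth knowing.** With deep sequencing, same-environment sample
pairs share nearly all abundant taxa; shared taxa contribute zero to
βMNTD under *any* taxa shuffle, so the homogeneous-selection z-score
saturates around −1 regardless of selection strength, trait signal,
jitter or depth (scanned over selection 30-200, signal 0.1-0.6,
σ 1.5-2.5, depth 2e3-2e4). The package therefore treats "clearly
negative median βNTI within shared environments" as the attainable
clustering signature, while contrasting environments give median βNTI of
+5 to +29.

## Networks

Association is Pearson correlation of log10(relative abundance + 1e-6)
across the group's samples (Spearman available); taxa whose transformed
abundance is constant (sd < 1e-12) are dropped with a warning. Edges at
|r| ≥ St = 0.75, the fixed threshold convention of molecular ecological
network analysis; the RMT threshold scan of the original methodology is
not implemented. Nodes are taxa with at least one retained edge. Modules
come from greedy modularity maximization (deterministic for a given
graph). Average geodesic distance is over connected pairs only, with the
disconnected-pair count reported. Random references are degree-preserving
double-edge-swap randomizations with 10·E swap *attempts* (attempts that
would create loops or duplicate edges are skipped, so the procedure is
well-defined on any graph; complete graphs return the empirical values
with a warning). Robustness removes ⌊f·N⌋ nodes uniformly (default
f = 0.5, 100 repetitions) and then iteratively removes newly isolated
nodes; a flag disables the secondary-extinction cascade. Vulnerability is
`max_i (E - E_{-i}) / E` with E the mean inverse shortest-path length
over ordered pairs (0 for disconnected pairs).

## Statistical tests

PERMANOVA and ANOSIM are delegated to scikit-bio (seeded); MRPP is
implemented here (group-size-weighted mean within-group distance, chance
corrected effect size `A = 1 - δ/E[δ]`). All permutation tests use the
valid-p convention `(1 + exceed)/(1 + n_perm)` and a shared label
permutation null; type-I error for all four (including the partial
Mantel) is verified to sit in [0.03, 0.07] at α = 0.05 over 500 null
simulations. The partial Mantel residualizes the community and focal
distance vectors on the covariate-block distance (first-order partial
correlation), permuting sample labels of the community matrix; a focal
variable fully explained by its covariates returns r = 0. VPA regresses
the positive PCoA axes on each predictor set and their union, combining
adjusted R² by inclusion-exclusion; negative pure fractions are reported
as-is, and collinear predictor sets are handled via the effective rank
with a warning.

Chao1 uses the bias-corrected (F2+1) form everywhere so zero doubletons
need no special case; Shannon is natural-log (evenness then matches
Pielou). Tukey HSD is the single post-hoc procedure.

## Problem sizes in the shipped experiments

The test suite and the acceptance script use: 5 replicate data sets per
regime for recovery (2 groups x 18 samples x 300 taxa, n_null = 199);
500 simulations at n_perm = 199 for test calibration; 999 permutations
for the worked beta-structure analyses; 100 rewired nulls where random
references are compared. These sizes give stable Monte-Carlo estimates
at desk scale.

## Limitations

* The single latent environmental axis means physical and chemical
  variables are collinear by construction: VPA on synthetic data
  attributes almost all explained variance to the *shared* fraction.
  Real casing-soil data, with partially independent physical and
  chemical gradients, will produce informative pure fractions; the
  generative VPA test uses independent predictor sets for exactly that
  reason.
* Axis-driven selection induces dense, low-modularity correlation
  networks (many taxa respond to the same gradient). The network module
  is therefore validated against hand-constructed and atlas graphs with
  brute-force oracles, not against the generator.
* Passing recovery tests show the classifier recovers *these* generating
  mechanisms; real communities mix processes and violate the
  single-axis, fixed-depth, multinomial assumptions in ways the
  generator does not emulate (compositionality artifacts, chimeras,
  taxonomy errors, variable sequencing depth).
* Raw-read processing (quality control, merging, OTU clustering,
  taxonomy), LEfSe, FAPROTAX and NMDS are out of scope.
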