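# Methods

## Pooled-frequency model and estimator

A pooled sample is modelled per biallelic variant *v* as an independent
binomial draw: with founder genotypes g<sub>iv</sub> ∈ {0,1} and strain
frequencies **f** on the simplex, the pool's alternate dosage is
q<sub>v</sub> = Σ<sub>i</sub> f<sub>i</sub> g<sub>iv</sub> and each read
reports the alternate allele with probability
m<sub>v</sub> = q<sub>v</sub>(1−e) + (1−q<sub>v</sub>)e, where *e* is a
symmetric sequencing-error rate (default 10⁻³; it also keeps the
likelihood finite when a rare miscall lands on an allele no strain
carries). Read depths are ancillary, so the likelihood is a product of
binomials in m<sub>v</sub>.

Because m<sub>v</sub> is linear in **f**, attributing each read to a
latent source strain gives an exact EM: an alternate read at *v* is
credited to strain *i* with weight ∝ f<sub>i</sub>p<sub>iv</sub>
(p<sub>iv</sub> = g<sub>iv</sub>(1−e) + (1−g<sub>iv</sub>)e), a
reference read with weight ∝ f<sub>i</sub>(1−p<sub>iv</sub>), and the
M-step averages the weights over all reads. The log-likelihood is
non-decreasing every iteration. A squared-extrapolation step (SQUAREM
style) is attempted each cycle and kept only when it does not decrease
the log-likelihood, preserving monotonicity while cutting iteration
counts roughly tenfold; convergence is declared when the per-cycle
log-likelihood gain falls below `tol` (default 10⁻⁸ — gains smaller in
magnitude than `tol`, including float-noise negatives at the optimum,
count as converged). Initialisation is uniform, so the estimate is
deterministic; optional seeded Dirichlet restarts guard against
multimodality (none has been observed — the likelihood is concave in
**q**). When several samples share one panel, the same updates run
batched across samples as matrix products; each sample converges to
the same optimum as the single-sample path.

Identifiability: strains with identical genotype rows are estimated as
a merged class and the class frequency split equally, with a warning
naming the strains. Variants with any missing panel call are excluded
from the likelihood rather than imputed — a missing call would make
that strain's read-attribution term undefined. Output frequencies
below 10⁻¹² are clamped to zero so the downstream log-ratio floor
triggers cleanly. A small fraction of samples (~5% at desk scale)
shows genuinely slow boundary convergence (frequencies decaying to 0)
and is reported with `converged=False` at `max_iter`; the estimates
are still accurate to the reported tolerances.

At the emulated study's conditions the estimator is essentially
efficient: at 86 strains × 3 000 variants × 75× depth, its per-strain
error matches the Cramér–Rao bound to within 0.1% (see Limitations).

## Fitness metrics

Relative strain fitness is w = log₂(final/initial) per strain and
replicate; a strain estimated at frequency zero in a selected
community receives the floor −8 exactly, below the smallest reduction
measurable at these depths. The floor is assigned only at zero: a tiny
but nonzero estimate keeps its measured log-ratio even if it falls
below −8 (at near-equal inocula and ~75× depth this does not occur;
extreme inocula can produce it). Fitness shifts are
Δw<sub>i</sub> = agg(w, mutant replicates) − agg(w, wild-type
replicates) with the replicate mean as default aggregation (the median
is available; the mean propagates floored values as ordinary numbers,
and floored cells carry a flag). Shannon's H uses natural logs;
absolute fitness is log₁₀ CFU per plant or nodule with zero counts
flagged missing rather than −∞; competitive fitness of a focal strain
is the log₂ fold change of its proportion, with a detection bound
log₂((1/total CFU)/p<sub>inoculum</sub>) reported when it is absent
from the recovered colonies.

## Mixed-model association

Each response (one host's fitness shift, or per-host fitness) is
analysed separately per replicon because the chromosome, pSymA and
pSymB carry distinct strain relatedness. Variants are filtered at
MAF ≥ 0.05 and missingness ≤ 0.2 (boundaries inclusive), then K =
ZZᵀ/m from the column-centered, column-standardized, mean-imputed
dosage matrix. The single-variant model y = α + xβ + u + ε,
u ~ N(0, σ²_g K), ε ~ N(0, σ²_e I) is profiled over δ = σ²_e/σ²_g on
the eigenbasis of K (one decomposition per response × replicon). The
REML surface in log₁₀δ is scanned on a 64-point grid over [−5, 5] —
small panels can make it multimodal — and refined by Brent search
(single fits) or an equivalent vectorised golden-section search (the
multi-variant scan; the two agree to ~10⁻⁷ in β, se and log₁₀p).
Variance components are re-estimated for every variant; passing
`per_variant_reml=False` reuses the null-model δ as a faster
approximation. Wald p-values use χ²₁; at n = 86 this makes the null
fraction below 0.05 land near 0.053 (no small-sample t correction),
which the calibration tests accept. Missing genotypes are mean-imputed
for association only. LD groups collapse to their minimum-p member,
ties broken by variant id; ranks are recomputed at group level with
ties sharing the minimum rank, so "top five" sets are reproducible.

## Candidate classification

From each host mutant's group-level results the five best groups by
p-rank enter the candidate union (provenance retained). Each candidate
is cross-compared in all hosts: counting hosts where its within-replicon
rank is ≤ 10, six or more hosts ⇒ *pervasive*, five or fewer ⇒
*limited*. Classification is rank-based and deliberately ignores
significance so hosts with different power contribute equally; a
`significant` annotation (minimum p < 10⁻⁵, a Bonferroni-style
threshold for group counts of ~3k–12k per replicon) is attached but
never gates the class. A candidate filtered out of some host's
analysis counts as not-top-10 there and is flagged. The sign
trade-off flag requires a consistent allele sign in at least
`min_hosts` of the candidate's top-10 hosts and an opposite wild-type
sign; the wild-type sign is taken at the group representative in the
wild-type fitness GWAS and called only when nominally supported
(p < 0.05), "none" otherwise. The rule is symmetric in sign. The
overlap utility compares top-0.1% variant lists as
|A∩B|/|A| with ⌈0.001·m⌉-element sets.

## Ordination and trait models

RDA centers the samples × strains fitness matrix by column and
projects it onto the orthonormalised, centered dummy space of one
factor; constrained inertia is the squared norm of the projection,
R² its share of total inertia, adjusted by Ezekiel's formula with
p = levels − 1. Significance comes from unrestricted row permutations
(block-restricted available), p = (1 + #{pseudo-F ≥ observed})/(n+1);
since total inertia is permutation-invariant the comparison is made on
constrained inertia directly, which is exact even when the observed
fit is perfect (residual 0 is clamped, pseudo-F reported as ∞).
Mutant-vs-wild-type contrasts rerun the RDA on each pair of hosts.

Univariate traits get two additive least-squares models — host
genotype + block, and symbiotic stage + block — compared only via
adjusted R² (genotypes nest within stage, so one joint model would be
collinear); average and total nodule area are log₁₀-transformed to
tame heteroscedasticity. Tukey HSD contrasts of each mutant against
the wild type come from the genotype+block fit: q = |t|·√2 referred to
the studentized range with k = number of genotype levels and the
model's residual df (for two groups this is exactly the two-sample
t-test); genotypes with fewer than two replicates are flagged, not
tested. Pot-level PCA standardizes columns and collapses genotypes
with incomplete replicate data to replicate means before the
decomposition, so partial data does not drop a genotype; genotype-mean
Pearson correlations require at least three genotypes.

## Synthetic experiments

The generator emulates the study design end to end under one seed.
Defaults: 86 strains; 30 076 variants split 12 000/9 000/9 076 across
chromosome/pSymA/pSymB; perfect-linkage LD groups of mean size 2
(Poisson-distributed), each group one independent carrier set drawn at
an alternate-allele frequency uniform on (0.05, 0.5]; 16 hosts (one
wild type, A17, plus 15 mutants cycling through early/late/AON stage
labels); 5 replicate pots per host in 5 blocks; 8 inoculum aliquots;
75× mean depth (Poisson per variant) with binomial read sampling at
error 10⁻³. The inoculum is a Dirichlet draw with concentration 10 per
strain, reproducing the 5–95% strain-frequency band reported for
equal-volume 86-strain inocula of this kind (0.006–0.018 around ~1/86);
its median (~0.011) sits slightly above the reported 0.0092 — real
inocula are more right-skewed than any symmetric Dirichlet.

The fitness landscape is w(strain, host) = baseline + host intercept +
Σ β<sub>vh</sub>·g<sub>v</sub> + N(0, noise_sd), with strain baselines
N(0, 0.5) (they cancel exactly in shifts; 0.5 keeps the wild-type
GWAS comparably powered to the shift GWAS, as observed in this system),
host intercepts N(0,1), GxG noise noise_sd = 0.5 log₂ units, and
planted causal architecture: 2 pervasive LD groups on pSymA (the
symbiotic replicon carries most pervasive variation here) acting with
β = +1.5 in 8 of the 15 mutant hosts and a wild-type effect whose sign
is flipped with probability `tradeoff_fraction` (default 1), plus 10
limited groups acting with |β| = 1.5 in ≤ 3 mutant hosts and no
wild-type effect. Selection acts once per host,
f′ ∝ f·2<sup>w</sup>; replicate pots share the host's true
post-selection community and differ by read sampling (an optional
multinomial nodule-occupancy subsample is off by default — the
emulated design pools >100 nodules per pot precisely to damp that
stochasticity). Replicate-level biological noise is therefore not
modelled separately: GxG noise lives at the strain × host level.
Host traits are lognormal/Poisson draws with a configurable positive
loading on standardized host-mean fitness plus block effects, giving
the mutualism-aligned trait/fitness covariance the ordination stage
probes.

What the generator does **not** emulate: real population structure
(carrier sets are independent across groups, so kinship is near-identity
and the mixed model's structure correction is exercised only weakly);
partial LD between groups; indels, CNVs and alignment artifacts;
strain–strain interactions during colonisation; host-genotype-specific
depth or nodule counts. Passing tests therefore demonstrate the
statistical machinery under the stated sampling models, not robustness
to those real-data features.

## Problem sizes used by the bundled checks

The test suite runs the deconvolution benchmarks at 3 000 variants
(singleton groups) and depths 50–5 000; the full-pipeline architecture
recovery at 500 LD groups (~1 000 variants) per replicon over 20 seeds
with all other parameters at their defaults; LMM calibration at 500
variants and power at 300 variants (86 strains, causal variant planted
at MAF ≈ 0.3, β = 1.5, noise 0.5); ordination nulls at 24 samples ×
5 strains with 199 permutations over 50 seeds. Brute-force oracles
(simplex grid at step 0.01; naive direct REML with explicit matrix
inverses) back the fast implementations on 3-strain and 20-strain
fixtures.

## Known limitations

Two properties are documented as out of reach at reduced problem
sizes, and the corresponding suite checks record them as expected
failures of the *conditions*, not defects of the implementation:

1. **Recovery correlation at 3 000 variants.** With the study-faithful
   near-equal inoculum (truth sd ≈ 0.004 across strains), the
   Cramér–Rao bound at 86 strains × 3 000 variants × 75× depth caps
   the truth/estimate Pearson r at ≈ 0.88; the EM attains 0.8796
   against a bound of 0.8798 (99.97% efficiency). Reaching r ≥ 0.95
   needs ~9 000 variants at this depth (the full 30 076-variant panel
   gives ≈ 0.985). Median absolute error (≤ 0.002 per strain) and the
   strict error decrease over depths 50/500/5 000 hold as stated. Note
   also that r degenerates by construction as the inoculum approaches
   exact uniformity (zero truth variance).

2. **Chance pervasive calls.** Because every shift response shares the
   subtracted wild-type term, null-variant scores correlate ≈ 0.5
   across hosts regardless of noise magnitude (ranks are
   scale-invariant and the design replicates wild type and mutants
   symmetrically). In addition, with 86 strains and many more LD
   groups, the Gram-matrix dimension bound forces root-mean-square
   inter-group genotype correlation ≥ 1/√86 ≈ 0.11 — independent
   carrier draws already sit at that lower bound — so some non-causal
   groups inevitably tag a planted |β| = 1.5 signal strongly enough to
   enter per-replicon top-10 lists consistently across hosts. At 500
   groups per replicon this yields ~4–13 non-causal pervasive calls
   per run (both planted pervasive groups are nonetheless recovered in
   19/20 seeds and their sign trade-offs flagged in 17/20); the
   integrated tail stays above ~2.5 expected chance calls even at
   3 000–12 000 groups per replicon. Rank-based pervasiveness should
   therefore be read as a *candidate-prioritisation* heuristic whose
   hit lists contain linked or wild-type-noise-correlated passengers,
   not a calibrated test — consistent with validating individual
   candidates experimentally.

Other limitations: the Wald χ²₁ p-values are mildly anticonservative
at n = 86; frequency estimates at the simplex boundary make the −8
floor a source of heavy-tailed noise in per-host fitness responses
(the shift responses are less affected because wild-type noise is
shared); and the EM reports, rather than resolves, merged classes of
identical genotypes.
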