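# Methods

## Model and pipeline

The pipeline infers, for one quantitative trait, (i) QTL regions from a
joint whole-genome marker regression, (ii) a per-animal QTL genotype
class from phased haplotype effects, and (iii) a reduced set of
candidate causative sequence variants whose zygosity agrees with the
inferred QTL status across sequenced animals.

**Deregression.** Input records are EBVs with reliabilities. The
deregressed pseudo-phenotype is `y = PI + (EBV − PI)/r²`, where PI is
the pedigree index (the expectation of the EBV without own-progeny
information) and r² the reliability from progeny information only.
Weights use `w = (1 − h²r²)/(h²(1 − r²))`, which assumes markers explain
all genetic variance. The printed form of that numerator is
typographically ambiguous (`1 − h²r²` vs `(1 − h²)r²`); both parses are
implemented (`weight_form: literal | garrick`), the literal reading is
the default, and the choice is documented rather than silently made.
Deregression weights enter the sampler's residual variance only when
`use_weights` is set, since where (or whether) they enter the original
mixed-model software is not documented; the default is off.

**Bayes C.** `y_i = μ + u_i + Σ_k z_ik a_k + e_i`, spike-and-slab prior
on marker effects (exclusion probability π = 0.99, common slab variance
σ²ₐ), scaled inverse-chi-square priors (ν = 4.2, S² = σ̂²(ν−2)/ν) on all
variances. Gibbs sampling: μ with a flat prior; each (δ_k, a_k) jointly,
the indicator from the marginal likelihood with a_k integrated out and
the effect from its Normal full conditional; variances from their
conjugate conditionals. Residuals are maintained incrementally and can
be checked against a from-scratch recomputation (`return_state=True`);
agreement is ~1e-14 relative. The optional polygenic term u is
single-site Gibbs with a pedigree A-inverse (Henderson's rules, no
inbreeding adjustment), identity A without a pedigree; it is off by
default because the synthetic populations are single-generation.
Prior point values for σ²ₐ/σ²ₑ default to an even split of var(y), the
genetic half spread over the expected (1−π)·Σ 2p_k q_k included-marker
dosage variance; both are config inputs since the original values are
unpublished.

A calibration property used in validation: on data with no
marker-linked signal, the inclusion frequency of a marker equals 1 − π
*only* in the weak-slab regime (z'z·σ²ₐ/σ²ₑ ≪ 1). With a diffuse slab
the marginalized update carries an Occam factor: E[BF] = 1 under the
null, but the posterior-odds transform is concave, so mean inclusion
falls strictly below 1 − π (we measure ≈ 0.006 instead of 0.010 with
the default data-driven prior at z'z·σ²ₐ/σ²ₑ ≈ 10). The null-calibration
benchmark therefore pins σ²ₐ prior at 1e-3 (σ²ₑ = 1), where theory
predicts calibration and the sampler delivers it (0.01005 measured).
This is a property of the model, not an implementation artifact.

**Regions.** Sliding (step-1) windows of L = 40 adjacent markers per
chromosome, ranked by Σp; greedy selection of the top K = 20 windows
sharing no marker, ties broken by (chromosome, start). Sliding windows
are the default because overlap removal only makes sense when candidate
windows overlap; a disjoint-bin mode exists for comparison. Sub-interval
extraction maximizes the contiguous block sum ("adjacent markers with
the highest Σp" read as a max-sum contiguous block, not a top-L′ scatter
by individual p_k); block sums are computed by direct per-block
summation so exact ties resolve to the leftmost block regardless of
cumulative-sum rounding.

**Status inference.** d = |H1 − H2| with H = Σ (alt-allele indicator) ×
â_k over the chosen sub-interval (default: the best 10-marker block —
smaller intervals separate better because fewer independent signals
overlap in them). PAM on the 1-D d values: random distinct initial
medoids, best-improvement swaps to convergence, 10 restarts keeping the
lowest cost (a single random initialization is fragile; restarts are
seeded). k ∈ {2,3,4} by maximal average silhouette, ties to the smaller
k; singleton clusters contribute silhouette 0; with fewer than 4
distinct d values the choice falls back to k = 2 with a warning; if all
d are identical no grouping is attempted and every status is unknown.
With k = 4 both middle clusters are unknown — no merging is attempted.

**Concordance.** An animal enters a variant's comparison iff its status
is hom or het, its genotype is non-missing, and GQ ≥ 20 (a missing GQ
counts as 0 and always fails). "90% of the individuals" is interpreted
as 90% of *compared* individuals — the only denominator available per
variant. Hom-status animals may be homozygous for either allele; no
phase matching is attempted. p_c uses the variant's own compared (n, m).
The p_c threshold is strict (<). `pc_exact` sums the alternating
binomial expansion `2ⁿ Σ_j C(m,j)(−2)ʲ B(n+j+1, n+j+1)` in exact
rational arithmetic up to n+m = 400 and falls back to quadrature beyond;
`pc_quadrature` is an independent adaptive-quadrature route, and the two
agree to ~1e-15 relative over n, m ≤ 40. Missing sequence genotypes
(as opposed to low-GQ ones) are excluded from comparisons.

**LD.** D′ from phased haplotype counts (no EM step — gametic
frequencies are observed): D = f(AB) − f(A)f(B), normalized by
min(f(A)f(b), f(a)f(B)) for D > 0 and min(f(A)f(B), f(a)f(b)) for
D < 0; D = 0 → D′ = 0; monomorphic loci give missing values.

**Pipeline.** One global seed; per-stage seeds derive by SHA-256 hashing
of "seed:stage-name" (stable across runs and platforms, < 2³¹), so any
stage can be rerun in isolation. Every stage persists a TSV/VCF
sufficient to resume downstream stages; reports carry no timestamps, so
identical configs give byte-identical outputs.

## Synthetic populations

The generator emulates the *shape* of a progeny-tested cattle design:
one chromosome of `n_seq_variants` biallelic sequence variants at 6-kb
spacing; a "50K-like" phased panel of every 10th variant; one planted
causative variant off the panel grid (so mapping must work through LD);
EBVs with per-animal reliabilities; and a sequenced subset whose
genotypes are perturbed at `genotype_error_rate` with GQ drawn
independently of the errors (quality scores carry no information about
which genotypes are wrong — the concordance tolerance, not the GQ gate,
must absorb them).

LD has two layers. Founder haplotypes (30 by default) get ancestral LD
from a latent AR(1) Gaussian copula (per-step correlation 0.9998)
thresholded at each site's allele frequency; iid founder alleles would
carry no cross-locus association at all, and mosaics of them produce no
usable population LD. Sample haplotypes are then founder mosaics: at
each locus the tracked founder's allele is copied with probability
`ld_rho` = 0.997, otherwise a fresh allele is drawn from the site
frequency and the tracked founder is re-picked — the
recombination/mutation analogue that breaks blocks up. Mean |D′| decays
from ≈ 0.96 at adjacent panel markers to ≈ 0.7 at lag 10, long-range
block structure in line with the small effective population size of
intensively selected dairy breeds.

Site frequencies are Beta(2, 2) truncated to [0.05, 0.95] —
intermediate-MAF-ascertained, as genotyping-array content is; the
causative site's frequency is pinned (default 0.5) so both status
classes are populated. The trait: true BV = `qtl_effect` × centered QTL
dosage + N(0, `h2_polygenic`) polygenic, in phenotypic-SD units;
defaults (0.65, 0.25) put ≈ 20% of phenotypic variance on the QTL. The
EBV adds noise of variance Var(BV)(1−r²)/r² with r² ~ U(0.70, 0.95) —
the standard accuracy relation for progeny-tested sires. All animals are
founders of a single generation (PI = 0); multi-generation pedigrees,
recombination maps, sex chromosomes and realistic demography are out of
scope.

What passing tests on these populations do **not** show: performance
under imputation errors, phasing errors (phases are generated, not
inferred), multi-QTL interference within one region, or coalescent
site-frequency/haplotype-diversity spectra. The generator produces a
*favourably tagged* QTL; real studies include QTL whose status simply
cannot be called from panel haplotypes (the motivating study could not
infer status for a quarter of its QTL).

## Benchmark problem sizes

The mapping benchmark uses 300 animals, 10,000 sequence variants
(≈ 1,000-marker panel after the MAF ≥ 0.05 filter) and chains of 6,000
sweeps (burn-in 1,000, thinning 5), 10 replicates; posterior summaries
at this scale are stable enough for window ranking. The end-to-end
benchmark runs the full pipeline on the demo condition (300 animals,
1,000 sequence variants, 100 sequenced, 2% genotype error), 10
replicates. The full-scale chain settings (180,000 / 20,000 / 50) remain
the config defaults.

## Known limitations

- End-to-end causative-variant recovery succeeds in ≈ 70% of generator
  realizations: in the remainder, founder-partition flips between the
  causative site and its nearest panel tags leave 8–17% of animals with
  recombinant haplotypes, so the causative variant itself falls below
  the 90% concordance line (PAM was verified to attain the best possible
  1-D threshold, so the loss is informational, not algorithmic). This
  mirrors the real-data failure mode for poorly tagged QTL.
- `pc_exact` values for large (n, m) are far below float-underflow-safe
  magnitudes only past n+m ≈ 1,400; within the supported range the
  rational path is exact by construction.
- The sampler is plain NumPy; a 1,000-marker, 300-animal, 6,000-sweep
  chain takes ~15 s. Full-scale inputs (tens of thousands of markers,
  thousands of animals) would want a compiled inner loop.
- Multi-allelic sequence records are collapsed to zygosity classes, not
  decomposed; BCF/indexed access and genotype-likelihood (PL) handling
  are out of scope.
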