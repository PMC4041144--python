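# Methods

## Consensus and indel coding

Species sequences are majority-rule consensuses over ≥1 sequenced
individuals per species. Columns where individuals disagree are reported,
separating substitution polymorphisms from gap/residue (indel)
polymorphisms; a clean dataset has no indel polymorphism, so the consensus
gap structure is representative of the species. Ties (possible only with an
even number of individuals) take the first-listed individual's state and
flag the column — with the recommended ≥3 individuals this is degenerate
input.

Indel characters follow simple indel coding: every distinct maximal gap
span (identical start and end alignment columns) is one binary character.
A taxon scores 1 when it carries exactly that span, `?` when its own gap
strictly contains the span (the shorter span is unobservable inside the
longer gap), and 0 otherwise — including taxa whose own smaller gap is
nested inside the span, which demonstrably lack *that* span. Leading and
trailing gap runs are missing data, not characters, so per-species lengths
(ungapped nt, aa = nt/3) are driven solely by internal indels; the frame
check requires every span length to be a multiple of three. Region labels
are ordinal (R1, R2, …) along the alignment; a mapping file can override
them when an externally published labelling exists.

## Parsimony event mapping

Each character is mapped by small parsimony on the fixed species tree.
The minimal change count is the Fitch score ('?' taxa contribute both
states); placement uses Sankoff dynamic programming with the root state
anchored to the outgroup's observed state. Anchoring never raises the
score because the outgroup subtends the root directly. Among equally
parsimonious reconstructions, ties in the top-down pass are resolved by
assigning the derived state as close to the root as possible, which puts
the first origin of a gap variant on the branch subtending the largest
clade in which the variant predominates; remaining occurrences become
separate events (parallel origins or reversals). The tie-break is
deterministic (preorder traversal, derived state preferred), so rerunning
with permuted input order yields identical events.

Polarity: with the root anchored to the outgroup, a 0→1 change (gap
gained) is a deletion and 1→0 (residues gained) an insertion. When the
outgroup is itself unobservable for a character its events are reported
with polarity "unresolved", never guessed. A change that truly occurred on
the outgroup's own terminal branch is necessarily mapped to the ingroup
stem with inverted polarity — resolving that would need a second outgroup,
which the design does not assume. Characters whose Fitch score exceeds one
are homoplasious and all their events are flagged; the event summary
enforces unique+homoplasious = insertions+deletions+unresolved =
terminal+internal = total.

## Codon models

The substitution model is the Goldman–Yang 61-sense-codon Markov process:
single-nucleotide changes have rate proportional to the target codon's
equilibrium frequency, times κ for transitions, times ω when
nonsynonymous; multi-nucleotide instantaneous changes are forbidden. Q is
scaled to one expected substitution per codon, so branch lengths are in
expected substitutions per codon. Equilibrium frequencies default to F3x4
(position-specific nucleotide frequencies, a 0.5 pseudocount guards
unobserved nucleotides); F1x4, F61 and uniform are available. Likelihoods
use Felsenstein pruning over compressed site patterns with transition
matrices from the symmetric eigendecomposition available for reversible
chains, cached per (κ, ω).

**M0** maximises the one-ratio likelihood jointly over κ, ω and all branch
lengths (L-BFGS-B on log-transformed parameters, ftol 1e-10; branch
lengths bounded [1e-7, 30], κ [0.05, 60], ω [1e-5, 40]). Its branch
lengths are the phylogenetic distances used by the comparative
regressions.

**Site models** (M1a, M2a, M7, M8, M8a) are proportions-and-ω mixtures
over site classes. The beta models use K equal-probability categories
(default 10) represented by their bin medians. The mixture is normalised
so the proportion-weighted mean rate is one substitution per codon. Branch
lengths are held at the M0 estimates times one free scale factor instead
of being re-optimised per model: this keeps the mixture fits desk-scale
while preserving the nesting relations exactly, because each null's
optimum is reproducible inside its alternative (M1a ⊂ M2a at ω2=1; M7 ⊂ M8
at p0→1; M8a ⊂ M8 at ωs=1). Each fit is multi-started (an M0-informed
start, a randomized start, a near-neutral start, plus warm starts at the
fitted nulls), and the best likelihood is kept; the warm starts make the
nested log-likelihood ordering hold to optimizer tolerance by
construction. LRT statistics are 2ΔlnL clipped at zero against χ² with
df 2 (M1a/M2a, M7/M8) or df 1 (M8a/M8 — conservative; the 50:50 boundary
mixture halves the p-value and can be applied by the caller).

**Positively selected sites** use naive empirical Bayes: the posterior
probability of the ω>1 class per site with all parameters plugged in at
their MLEs. This ignores parameter uncertainty, unlike Bayes empirical
Bayes, and is anticonservative on small datasets — every run log records
the substitution. Sites are reported in both alignment-column and
reference-protein coordinates, since published site labels may use either.

**Branch rates** use a counting estimator rather than a free-ratio ML fit
(the free-ratio model's per-branch ω's are weakly identified at these
sample sizes and dominate runtime): ancestral sequences by per-nucleotide
Fitch parsimony with ambiguities resolved toward the parent state, then
Nei–Gojobori pathway counting per branch. Potential sites are normalised
so each codon contributes exactly N+S = 3 (changes to stop codons excluded
from the opportunity set); observed differences average synonymous and
nonsynonymous steps over the shortest mutational pathways that avoid stop
codons. Proportions are Jukes–Cantor corrected; a proportion ≥ 0.75 is
reported uncorrected and flagged saturated. **Lineage ω** for a tip is
ΣdN/ΣdS along its root-to-tip path, which gives every lineage the same
time depth since the common ancestor and is therefore insensitive to
branch-duration effects; it is flagged undefined when ΣdS = 0.

Counting estimators are downward-biased at high divergence and high ω
(parsimony misses multiple hits; ignoring the transition bias inflates
synonymous counts). In recovery simulations the grand-mean lineage ω over
10 studies is within 10% of truth at both ω = 0.5 and ω = 2, but
individual tips in a single study can deviate by ±35% at ω = 2 because
root-to-tip sums within one tree are strongly correlated — per-tip
accuracy claims should not be read into single datasets.

## Phenotypes and comparative regressions

RTM is observed testes mass over `a·body^b`. The constants are
configuration, defaulting to the rodent testes allometry of Kenagy &
Trombulak (1986), a = 0.031 g, b = 0.77; they are recorded in every
config rather than hard-coded as truth.

Velocity PCA standardises the seven CASA descriptors (z-scores,
correlation-matrix PCA) at species-mean level — chosen so the PCA's n
matches the regression sample; a per-male analysis would need replicate
rows and is out of scope. PC1 is sign-oriented so VCL, VSL and VAP load
positively and is interpreted as overall sperm velocity; descriptor–PC
Pearson correlations are reported so that interpretation is checkable.

PGLS uses residual covariance V(λ): the Brownian tip covariance implied by
the tree's branch lengths with off-diagonals multiplied by Pagel's λ.
λ is profiled by bounded scalar ML on [0, 1] (tolerance 1e-6, endpoint
values checked explicitly) and tested against λ=0 and λ=1 by LR (χ², 1 df;
boundary-conservative). With ordered predictors the per-predictor F tests
use sequential Type-I sums of squares in the whitened space, matching a
design where body mass must enter before testes mass; slope p-values are
two-sided from F(1, df_error). R² is 1 − RSS/TSS around the GLS intercept.
Effect sizes are Fisher-z transforms of r = sqrt(F/(F+df_error)) with 95%
limits ±1.96/√(n−3); these formulas reproduce the internally consistent
published table rows to three decimals. Diagnostics flag species with
|studentized whitened residual| > 3 or leverage > 2(p+1)/n (both
configurable); exclusions are then declared per analysis in the run
configuration, never in code. A non-ultrametric tree is accepted with a
warning; note that at λ=0 the GLS equals OLS exactly only when tip heights
are equal.

Histidine content shifts use exact squared-change parsimony weighted by
branch lengths (a weighted-Laplacian linear system; zero-length branches
floored at 1e-6 of the mean). Branches whose reconstructed parent→child
change exceeds a threshold (default 0.02, i.e. two percentage points —
the scale of clade-level shifts the synthetic planted-shift tests are
built around) are reported largest-first. "Positions containing
histidines" defaults to any-taxon-H at the site, with a strict
reference-species mode.

## The synthetic generator

The generator emulates the study design: a pure-birth 16-species ingroup
(terminal branches extended by 10% of depth — the process otherwise stops
exactly at the n-th split, leaving two zero-divergence sister species),
depth 0.3 expected substitutions/codon root-to-tip, outgroup attached
below the ingroup root at 30% extra depth; 320 codons evolved under the
GY model (default κ=2, ω=0.4; optional site-class mixtures for positive
selection); Poisson(1.0) indel events per branch, 60% deletions, lengths
{1,2,3,4} codons with probabilities {0.5,0.25,0.15,0.1} — always in-frame,
never touching the first or last codon, so flanking regions stay intact;
3 individuals per species with 0–2 substitution-only polymorphisms; the
default event totals and deletion excess are of the same order as the real
exon's. Substitutions are drawn from the exact kernel expm(Qt) per branch,
distributionally identical to event-by-event simulation. The true
alignment is emitted from the simulator's own coordinate bookkeeping —
no realignment — and events that coalesce within one branch are recorded
as the single realized mutation they produce.

Phenotypes: log body mass is Brownian on the tree (mean ln 30 g, sd 0.8);
testes mass is `a·body^b · exp(0.5·u)` where u is a unit-variance deviate
with Pagel-λ structure (λ=0.5) correlated at 0.8 with standardized
negative sequence length; each velocity descriptor declines with length
(−1.5 μm/s per amino acid at VCL scale) on top of a shared species factor
plus independent noise, so PC1 of the seven descriptors carries the
programmed signal.

What the generator does **not** emulate: alignment error (the true
alignment is emitted directly), within-species coalescent structure,
rate variation among branches, indel length distributions with long tails,
or measurement error in phenotypes. Passing tests therefore demonstrate
correctness of the inference machinery under the generating model, not
robustness to misalignment or model violation in real data.

## Problem sizes in the test suite

Recovery and calibration tests run at sizes chosen to exercise the
asymptotics that matter while staying desk-scale: M0 ω recovery at
16 taxa × 300 codons over 10 seeds; LRT type-I error and power at
8 taxa × 150 codons over 20 seeds each (power uses 15% of sites at ω=4);
PGLS slope/λ recovery at n=50 over 20 seeds; parsimony oracle equivalence
on 1000 random characters over trees of 4–8 taxa; codon-likelihood oracle
equivalence on 3 taxa × 20 codons. Site-identification precision is
checked at 8 taxa × 150 codons (at this scale the 0.95 posterior cut
flags few but precise sites; the larger the alignment, the higher the
recall).

## Known limitations

* NEB instead of BEB: anticonservative site posteriors on small data.
* Counting branch rates: downward bias at high divergence/ω; lineage ω
  accuracy statements hold in aggregate, not per tip.
* Site-model branch lengths are scaled M0 lengths; absolute lnL values are
  therefore not comparable to fits that re-optimise all branch lengths
  per model (LRTs within this package remain internally consistent).
* M8a/M8 tested at χ²(1): conservative relative to the boundary mixture.
* Indel characters are identified by span alone; gaps identical in span
  but different in adjacent substitutions are one character.
* PGLS assumes the phenotype covariance follows the molecular branch
  lengths (from M0); a clock-violating gene tree distorts λ and p-values.
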