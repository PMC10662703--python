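# Methods

This note documents the models and procedures mitosel implements, the
choices made where the design was genuinely open, and what the bundled
simulator does and does not emulate.

## Sequence conventions

Input CDSs follow mitochondrial conventions: any ATN codon is accepted as
a start; a coding sequence ends in a complete stop (TAA or TAG under the
invertebrate mitochondrial code) or a truncated stop (a trailing TA or T,
completed by polyadenylation in vivo). `validate_and_trim_cds` strips the
stop — repeatedly for complete stops, so the operation is idempotent —
and reports internal stops without removing them (0-based codon indices
internally; user-facing tables are 1-based). The genetic code defaults to
NCBI translation table 5 (AGA/AGG = Ser, TGA = Trp, ATA = Met), built
from Biopython's table registry, and every codon-level statistic is
driven by the derived family structure rather than hard-coded lists.
Codons containing gaps or N are excluded from codon-level counts, pairwise
for pairwise statistics — the conservative standard when mitogenomes are
incomplete. Genes are concatenated in alphabetical order with 0-based
half-open partition boundaries.

## Codon-usage statistics

RSCU is observed codon count over its equal-usage expectation within the
amino-acid family; families with zero usage are reported as 0 and
flagged. ENC follows Wright: per amino acid with n ≥ 2 observations,
F = (n·Σp² − 1)/(n − 1); each degeneracy class contributes
(amino acids in class)/(mean F of class). For table 5 the classes are
{2-fold: 12, 4-fold: 6, 6-fold: 1 (Leu), 8-fold: 1 (Ser)}, giving the
range [20, 62]. An amino acid with fewer than two observations is dropped
from its class mean; an empty class (or nonpositive mean F) makes ENC
undefined, which is reported as NaN rather than guessed. Because the
finite-sample F correction can push the estimate slightly above the
capacity, ENC is capped at the code's sense-codon capacity and at the
observed codon count. GC3s is computed over third positions of
synonymously variable codons — under table 5 that is every sense codon,
since no family is a singleton — and PR2 uses the third positions of the
six four-fold families (Val, Pro, Thr, Ala, Gly, Arg), the standard
parity-rule-2 convention. The neutrality plot regresses GC12 on GC3s by
OLS; the expected-ENC curve is ENC(s) = 2 + s + 29/(s² + (1−s)²).
Per-species summaries are computed on the concatenated PCGs by default
(per-gene values are also emitted), since a single bias summary per
species is what the downstream plots compare.

## Variation statistics

Site classes use only A/C/G/T states: conserved = one state,
parsimony-informative = at least two states each in at least two
sequences (defined only for ≥ 4 rows), singleton otherwise. π is the mean
over unordered pairs of per-pair difference proportions with pairwise
deletion; sliding windows default to 100 nt with a 25 nt step —
config-exposed, matching common practice for mitogenome scans. Mutation
counts are minimum-change counts (distinct states − 1 per variable site),
i.e. segregating-site style rather than phylogeny-aware counting; each
variable site is classified synonymous/nonsynonymous from the observed
codon pairs differing only at that site, and sites with conflicting or
confounded effects are flagged mixed rather than forced into a class.

## Counting-based selection analysis

Likelihood machinery (codon-model branch/site tests) is deliberately out
of scope; the package provides fully specified counting analogues.

**NG86.** Per sense codon, each of the nine single-nucleotide neighbours
contributes 1/3 of a site, synonymous or nonsynonymous; stop neighbours
contribute to neither class, so s + n = 3 × (non-stop fraction). Observed
differences are averaged with equal weight over the orderings of the
differing positions, excluding orderings that pass through a stop codon.
Proportions use site totals averaged over the two sequences and are
corrected with Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is
flagged saturated and dS = 0 with differences makes ω undefined (flagged)
rather than infinite — downstream means use defined values only.

**Ancestral reconstruction.** Fitch–Sankoff parsimony treats codons as
atomic unit-cost states (optimal internal states therefore lie in the
observed set). All most-parsimonious reconstructions are enumerated up to
a cap of 10,000; beyond it, 10,000 reconstructions are sampled uniformly
with a logged seed. Each changed branch carries one unit of event weight
per reconstruction, split between synonymous and nonsynonymous by the
NG86 pathway fractions when codons differ at several positions, so event
weights sum exactly to the minimum change count at every site. On a
rooted tree the root splits one unrooted edge in two; a change on that
edge appears as two equally weighted placements, which downstream sums
treat correctly. Tips with unreadable codons at a site constrain nothing
at that site.

**SLAC-style site test.** Per codon site, reconstructed synonymous and
nonsynonymous event weights are compared with a binomial null whose
nonsynonymous probability is N/(N+S) from the NG86 site counts averaged
(with multiplicity) over the codons observed at the site. Tail
probabilities use the regularized incomplete beta function, which extends
the binomial tail continuously to fractional event weights. The reporting
threshold defaults to 0.1, the usual SLAC/FEL convention; with the few
events per site typical of real alignments the binomial tail is
conservative, so the realised type-I rate sits well below its nominal
level (the calibration run asserts ≤ 0.08 at α = 0.05).

**Group contrast.** Each terminal branch gets a counting ω: its summed
nonsynonymous event weight over N sites, divided by its summed synonymous
weight over S sites, with S and N from the tip's own codons; zero
synonymous events make the branch undefined (excluded, flagged). The
foreground/background difference in group mean ω is tested against a null
that permutes tip labels preserving group sizes, two-sided,
p = (1 + #{|Δ_perm| ≥ |Δ_obs|})/(n_perm + 1). This is the counting
analogue of a two-ratio branch model; it asks the same question without
estimating branch lengths or codon frequencies by likelihood.

## Comparative layer

PIC follows Felsenstein's recursion exactly (contrast
(x_i − x_j)/√(v_i + v_j), weighted-average node values, parent branch
extended by v_i·v_j/(v_i + v_j)); zero-length branches are inflated by
1e-8 so contrasts stay defined. The contrast regression is forced through
the origin — a statistical requirement, since contrast signs are
arbitrary. The test suite verifies that the contrast coefficients whiten
the Brownian-motion covariance implied by the tree (C·V·Cᵀ = I).

Environment distances z-score each variable (zero-variance variables are
dropped with a warning) before Euclidean distance. The Mantel statistic
is the Pearson correlation of upper triangles; the null jointly permutes
rows and columns of the second matrix; the test is one-sided (upper tail)
with the (+1)/(+1) estimator and n_perm defaults to 9,999 so that p-values
down to 1e-4 are attainable. The ω distance matrix pairs species over
their 13-gene ω vectors (Euclidean), config-exposed.

The GLM screen is forward stepwise selection by AIC over the 19
(z-scored) BIO variables with a variance-inflation cap of 10 — one
concrete reading of "stepwise regression to screen collinear variables",
documented as configuration rather than hidden — followed by a Gaussian
identity-link fit on the retained set. Genes whose sample cannot support
the retained design are refused rather than overfitted.

## Simulator

Sequences evolve site-independently under an MG94×HKY-style rate matrix:
single-nucleotide codon changes at rate
π(target nucleotide) × κ^[transition] × ω^[nonsynonymous], zero for
multi-nucleotide changes and stops. Rates are normalised so branch
lengths are expected substitutions per codon site; the root is drawn from
the F1x4 equilibrium (stop codons renormalised out), which is exactly
stationary for this reversible chain. Evolution is simulated with the
Gillespie algorithm rather than matrix exponentiation so that the
per-branch synonymous/nonsynonymous event log is exact — the ground truth
the counting methods are validated against; replaying the log from the
root reproduces every tip sequence byte for byte.

Defaults emulate the AT-rich chalcidoid mitogenome regime this package
was built around: AT fraction 0.80 (F1x4), κ = 2 (transition/transversion
ratios of such datasets sit near 2), tree depth 0.3 substitutions per
codon site, 29 tips of which a clade of ~11 is foreground, per-gene codon
counts matching the 13 PCG alignment lengths (concatenated 10,995 nt),
foreground altitude 4500 m vs background 200 m (±200 m jitter), and
temperature-type BIO variables decreasing with altitude at the standard
6.5 °C/km lapse rate (WorldClim-style units). Scenario ω values:
neutral 1.0/1.0, purifying 0.2/0.2, foreground_elevated 0.6/0.2,
null_env as purifying with an altitude-independent environment. The
foreground is monophyletic by default (a `scattered_foreground` option
emulates non-monophyletic alpine sets).

What the generator does **not** emulate: indels and alignment error,
among-site rate heterogeneity beyond the two ω classes, base-composition
drift across the tree, translational selection on codon usage, and
tRNA/rRNA genes. Two consequences matter for interpreting green tests.
First, codon bias in the simulator is purely compositional, so simulated
species sit *near* Wright's expected ENC curve: the fixture-bundle check
asserts mean ENC strictly below the curve (a small, consistently negative
deficit of ~0.5–1 ENC units from finite-sample structure), whereas real
mitogenomes showing selection on codon usage fall several units below.
Second, passing recovery tests show the counting estimators work when
their assumptions hold; they do not certify behaviour under alignment
error or saturation.

## Calibration and problem sizes

Validation experiments are sized for a single CPU: ω recovery uses
4-tip trees at depth 0.2 with 500 codons, κ = 1 and uniform frequencies
(20 seeds per ω ∈ {0.1, 0.5, 1.0}; median relative error ≤ 15%) — κ and
frequencies are set to the regime NG86's equal-rate site counting
actually assumes, since with strong transition bias the counting
estimator is known to be biased; contrast power uses 20 tips × 400 codons
at the foreground_elevated ω values (detection = Δ > 0 and permutation
p < 0.05 in ≥ 80% of 20 seeds); the SLAC type-I run uses three neutral
8-tip × 700-codon genes (2,100 sites); the Mantel null calibration uses
1,000 replicates of independent 12-species tables at 99 permutations; and
the qualitative-regime checks run on the full default fixture bundle
(29 tips, 13 genes, AT 0.80, purifying).

## Numerical choices

Jukes–Cantor saturation (p ≥ 3/4), undefined ω (dS = 0), undefined ENC
(empty class), undefined skews/PR2 (zero denominators) and windows with
no comparable site are all reported as flagged NaN, never silently
dropped or clamped. RSCU family sums are exact to 1e-9; distance-matrix
symmetry is enforced to 1e-12. Permutation p-values use the
add-one estimator and are reproducible for a fixed seed; the pipeline
expands its single seed into per-stage child seeds via numpy
`SeedSequence([seed, stage_offset])`, so stages are individually
reproducible and a rerun is byte-identical apart from the run-log
timestamp. MPR enumeration beyond the 10,000 cap switches to seeded
uniform sampling and records that it did.

## Known limitations

Counting methods trade power for transparency: at high divergence NG86
saturates where likelihood methods still estimate; the SLAC-style test is
conservative with few events per site; terminal-branch ω is undefined on
branches without synonymous events (short branches, small genes). The
two-group permutation contrast tests mean terminal-branch ω only — it
does not model episodic selection within branches. PIC assumes Brownian
motion of the trait on the given tree; group-coded (0/1) traits are
accepted as the comparative design of record but violate that assumption
strictly speaking. The GLM screen is one defensible collinearity rule
among several; retained-variable identities (beyond a truly associated
one) should not be over-read when predictors are correlated.
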