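# Methods

## Data model

Expression values are normalized log2(Cy5 sample / Cy3 common genomic-DNA
reference) ratios, one column per hybridization. Normalization is treated
as upstream: the package consumes already-normalized ratios (in-repo, the
synthetic generator stands in for the wet-lab/normalization pipeline). A
matched SNR table defines quantifiability: spots with SNR < `snr_min`
(default 2) are masked, and every downstream statistic — replicate means,
Z scores, phase profiles, pairwise correlations — is computed over
unmasked entries only. Without an SNR table, cells read as `NA` are
masked and everything else is quantifiable. TSV serialization writes
masked cells as `NA` and floats at full `repr` precision, so a
write→read round trip is lossless on the quantifiable entries.

The reference design has 33 samples: mid-exponential profiles for
glucose, xylose, fructose, cellobiose and the glucose+xylose mixture,
plus early- and late-exponential profiles for glucose, xylose and the
mixture — 11 conditions × 3 biological replicates. Array-content
constants (2365 gene sequences used for probe design, 43 with no
acceptable probe, 2322 covered genes, 20 negative-control probes from
random human ORFs) set the synthetic defaults.

## Synthetic generator

Each planted module is a common-factor block: member value =
`shift·1[condition responsive] + a·f + u·ε`, with one standard-normal
factor `f` per module per sample, unit-normal unique noise ε, and
`a² + u² = noise_sd²`. Condition responsiveness is a mean shift (default
2.0 log2 units) applied under the module's responsive conditions, so one
dataset exercises the differential-expression filter and the correlation
network together.

**Correlation calibration.** The deterministic mean pattern is itself
shared variance between members: across the sample axis it contributes
variance `v = shift²·p(1−p)` (p = fraction of responsive columns). The
factor variance is therefore solved from
`(v + a²)/(v + noise_sd²) = r_target`, so the *expected full-axis
pairwise Pearson correlation* of members equals the planted value. When
the mean pattern alone exceeds the target (`r_target < v/(v+noise_sd²)`,
e.g. any target below ≈0.84 for a one-condition 2.0-log2 shift at
noise_sd 0.25) the combination is infeasible and the generator raises a
parameter error rather than silently over-correlating. Hub members get
the boosted share `1 − (1−r)/4`, which raises their correlation to the
rest of the module (≈0.97 when r = 0.95) and hence their degree at any
cutoff inside the module's correlation band.

Background genes are independent Gaussian noise; negative controls are
pure noise with zero mean. SNR dropout is Bernoulli per cell (default
rate 0.02 — the original arrays' spot-failure rate is not published;
this is a repo choice, as is the noise level `noise_sd = 0.25` log2
units, a typical replicate scatter for two-color prokaryotic arrays).

**Study-scale preset.** 2322 genes, the 33-array design, 13 modules with
sizes (138, 70, 65, 60, 55, 50, 45, 40, 35, 25, 15, 10, 6) summing to
614 genes, within-module correlation 0.95, one planted hub per module.
Modules 1–11 each respond to one *distinct* condition of the 11-condition
design; modules 12–13 are constitutive co-expression clusters (factor
only). This is deliberate: with 13 modules over 11 conditions, any two
modules sharing (or overlapping in) a condition signature acquire strong
cross-module correlation through the shared mean pattern (≈0.85 measured
for a fully shared condition), which would merge them in any
correlation-based analysis. The preset mirrors the scale of the real
network, not its actual partition.

**What the generator does not emulate:** dye bias, spatial artifacts,
probe-sequence effects, correlated background (house-keeping trends,
normalization residuals), and heavy-tailed noise. Passing recovery tests
therefore demonstrate the machinery under clean separable conditions;
they do not certify performance on real arrays, where background
correlation is denser and module boundaries are softer.

## Differential expression

Per condition, genes are summarized over unmasked replicates: mean,
sample SD (n−1), and the one-sample Z = mean/(sd/√n). A gene is called
significant when `|mean log2R| ≥ 1.0` and `|Z| ≥ 2.0` and at least two
replicates are quantifiable; no multiple-testing correction is applied
(matching the filter the package reproduces). The exact Z-score recipe of
the original protocol is unpublished; the one-sample replicate Z is this
package's documented choice, and for condition-vs-condition contrasts the
difference of means with a Welch standard error is used. Zero-SD genes
get infinite Z, leaving the decision to the mean cutoff. Peak phase is
the strict argmax of the phase replicate means with tie tolerance 1e-9
(only numerically exact ties are ties on continuous data); genes with
fewer than two quantifiable phases are `undetermined`.

## Correlation and RMT threshold selection

Pairwise-complete Pearson correlation is computed with masked matrix
products; pairs with fewer than `min_pairs = 9` shared quantifiable
samples (~27% of 33) or a zero-variance member are flagged unusable and
never become edges.

For each candidate cutoff τ the weighted thresholded adjacency
(`A_ij = r_ij` where `|r_ij| ≥ τ`, zero diagonal; binarized form
available but not default) restricted to non-isolated genes is
eigendecomposed. Near-degenerate eigenvalues (spacing < 1e-8) are
collapsed first — isolated-node zero multiplicities and block
degeneracies would otherwise pile spacing mass at zero. Unfolding fits a
monotone cubic (PCHIP) interpolant through ~n/20 support points of the
empirical spectral CDF and maps eigenvalues to unit mean spacing; the
spacing histogram on [0, 3] (20 bins, expected probabilities renormalized
to the window so observed and expected totals match, bins with expected
count < 5 merged from the right, dof = bins − 1) is χ²-tested against
`exp(−s)` (Poisson) and the Wigner surmise `(πs/2)·exp(−πs²/4)` (GOE).
Fewer than 100 distinct eigenvalues ⇒ the candidate is unevaluable and
skipped.

**Selection rule.** The selected cutoff is the smallest candidate with
Poisson accepted (p > 0.001) and no *GOE-leaning* rejection at any larger
candidate. The direction qualifier matters: at the top of the grid the
network disintegrates into small fragments whose repeated-motif spectra
reject Poisson toward *clustering* (χ²_GOE ≫ χ²_Poisson); such
breakdowns of the statistic say nothing about modular structure below
and must not veto the stability requirement (unqualified, they would
drive selection to an empty top-of-grid network). A
`transition_bracketed` flag records whether the grid bottom was already
accepted — if so, the Poisson transition lies below the grid and the
selected value only brackets it from above.

**Known limitation (sharp-separation regime).** On the synthetic preset
the within-module and background correlation distributions are separated
by a wide empty band (background |r| over ~2.7M null pairs at n = 33
tops out near 0.79; module pairs sit at 0.95 ± 0.02). Inside that band
the thresholded matrix is *exactly* a superposition of independent
blocks, its spacing statistics are genuinely Poisson, and acceptance
extends all the way down to where background edges become numerous
(τ ≈ 0.57 with an extended grid; the 0.70 grid floor with the default
grid). The selected cutoff therefore sits at the *lower* edge of the
empty band, not at the module/background distribution boundary
(≈ 0.80): the spacing statistic reacts to the bulk of the noise-edge
distribution, not to its extreme-value tail. On real arrays, where the
correlation continuum is dense up to the module band, the two coincide;
on clean synthetic data they do not. Any cutoff inside the band yields
the same module structure, so downstream recovery is unaffected.

The scan runs in `abs` mode (spectral statistics concern magnitude
structure); reported networks are built in `positive` mode (edges are
positive co-expression), both exposed.

## Module detection

Fast-greedy agglomerative modularity maximization on the unweighted
thresholded graph: start from singletons, repeatedly merge the community
pair with the largest ΔQ = l_ab/m − d_a·d_b/(2m²), stop when no gain is
positive. Ties are broken on the communities' canonical labels (smallest
member gene id, lexicographic pair order), making the partition a pure
function of the graph. Q is tracked incrementally and equals the
from-scratch recomputation to 1e-12 (tested, including against
networkx's modularity). Communities with fewer than five members
("more than four genes") are unassigned; module ids are renumbered by
decreasing size, ties by smallest member id — module numbering is
size-ranked, not matched to any reference labelling. Partition quality
against planted truth uses the adjusted Rand index restricted to planted
members.

## Reporting

Percentages are computed to one decimal; the integer display style
rounds the one-decimal value half away from zero (a 138-gene module with
50 members in its top-3 COG categories prints 36.2% → "36%"; its other
54 members print 39.1%). Genes without a COG count toward module size
but not category counts. Module-module interaction requires ≥1 edge
between reported modules; a module with no partner is standalone. Hub
ranking is by degree, ties by gene id, default top 23. The genome-share
denominator defaults to the number of genes on the array and is
configurable. Exports: edge/node TSV, SIF, GML; run reports carry tool
version, seed and a config hash, and are byte-stable across runs except
for the timestamp field.

**Hub recovery at desk scale.** With 3 replicates per condition the
empirical correlations of a whole module rise and fall together with its
shared factor realization, and this between-module luck swamps the
planted hub's loading advantage in a global top-23 list (hubs still top
their own module's degree ranking). The hub demonstration therefore uses
nine replicates per condition, where the hub advantage dominates; this
is a property of sample size, not of the ranking code.

## Problem sizes

The test suite and the acceptance script run the full 2322-gene, 33-array
preset for network reconstruction (a few seconds per run), 20-seed
repetitions of 500×500 GOE and 10×100 block-diagonal spectra for the
spacing-statistics oracle, and small (≤400-gene) datasets for the
differential-expression and hub experiments.
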