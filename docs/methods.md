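# Methods

## Balances and the contrast matrix

A composition x = (x_1, …, x_D) carries only relative information. A
sequential binary partition (SBP) is a hierarchy of D−1 binary splits of
the D parts, encoded as a D × (D−1) sign matrix: each column marks one
group of parts +1, a disjoint group −1, and the rest 0, such that the
supports form the nested (laminar) family of a binary merge tree — exactly
one column spans all parts, and every group of two or more parts created by
a split is itself split by exactly one other column. Validation enforces
precisely these conditions and is insensitive to column order, so
hand-written SBP files are usable as-is.

Column j with r positive and s negative parts defines the balance

    b_j = sqrt(r·s/(r+s)) · ln( g(x over + parts) / g(x over − parts) ),

equivalently the j-th row of the orthonormal contrast matrix Ψ applied to
ln x, with weights +(1/r)·sqrt(rs/(r+s)) and −(1/s)·sqrt(rs/(r+s)). The
square-root coefficient is what makes the rows unit-norm; with it, the
balances are ilr coordinates and the sample-wise balance variances of a
full SBP sum exactly to the total clr variance. `compute_balances` uses
the explicit geometric-mean formula; the test suite independently computes
Ψ·ln x and requires agreement to 1e−12, and enforces the variance identity
to 1e−9 relative on fixtures and random (data, SBP) pairs.

Conventions fixed throughout the package:

* natural logarithms everywhere;
* unbiased sample variance (denominator n−1) — only ratios of variances
  are convention-free, so one choice is fixed and used consistently;
* geometric means as exp(mean(log)), never a product power, so D=500
  count-scale tables cannot overflow;
* components are matched between tables **by label**, never by position
  (positional defaults are generated only when an unlabeled array is
  supplied), preventing silent misalignment between data and SBP.

## Trees and ordering

A merge tree (rooted, strictly binary, uniquely labeled leaves) converts
to an SBP by emitting one column per internal node in preorder (root
first): leaves under the first child get +1, under the second child −1.
Which side is "+" is a pure convention — it flips the sign of a balance,
never its magnitude — so the orientation is deterministic (first child =
"+", matching Newick child order) and a `flip` option exposes the other
choice. The inverse conversion rebuilds the tree from column supports, and
the round trip preserves every bipartition and orientation.

For display, balances are ordered by ascending depth in the SBP hierarchy
(depth = number of columns whose support strictly contains the balance's
support; the root split has depth 0 and always comes first), with ties
broken by descending variance and then original column order. The rule is
well-defined for arbitrary subsets without access to the tree object.

## Zero replacement

Count tables contain zeros that break every log-ratio. `replace_zeros`
performs multiplicative simple replacement on the closed scale: in sample
i with raw total N_i and z_i zeros, each zero becomes
δ_i = f/(N_i + 1) (default label fraction f = 0.65, the standard
count-zero-multiplicative default), and the observed parts, closed to
proportions, are multiplied by (1 − z_i·δ_i). The row sums to exactly 1,
every entry is strictly positive, the ratios among originally non-zero
parts are untouched, and zero-free rows reduce bitwise to plain closure.
Bit-compatibility with any particular external imputation implementation
is not a goal; the contract (positivity, ratio preservation, identity on
zero-free data) is what the tests enforce.

## φ_s and data-driven SBPs

The symmetric proportionality dissimilarity between components j, k with
clr coordinates y_j, y_k is

    φ_s = (1 − ρ)/(1 + ρ),  ρ = 2·cov(y_j, y_k)/(var y_j + var y_k)
        = var(y_j − y_k) / var(y_j + y_k).

φ_s is 0 iff the two components are exactly proportional across samples,
grows without bound as they decouple, and uses the clr of the full
composition as the log-ratio reference (the standard definition of the
symmetric proportionality coefficient). `phi_s` computes both algebraic
forms — the second literally, from per-pair difference/sum variances in
memory-bounded chunks — and insists they agree to 1e−9 as a self-check.
Pairs with a zero-variance denominator (e.g. clr coordinates that are
exactly anti-proportional) are set to the largest finite dissimilarity
observed (at least 1.0) with a warning, so a degenerate component becomes
a late-merging singleton instead of aborting the run. At least 3 samples
are required for the variances to be meaningful.

Agglomerative clustering of the φ_s matrix (scipy linkage; default
**complete**, with average and ward available — the default linkage is a
genuine free choice and results can depend on it, which is why it is a
flag) gives the merge tree, and tree→SBP conversion the partition:
`sbp_from_data` chains imputation → φ_s → clustering → SBP and is fully
deterministic.

## Synthetic data

`simulate_compositions` draws ilr coordinates from independent normals
(one mean and sd per balance of a known SBP, random merge tree by
default), optionally adds a location shift δ on one designated balance for
a fraction of the samples (a two-group design), and inverts through the
contrast matrix: x = closure(exp(coords · Ψ)). This logistic-normal model
is the exact inverse of the analysis pipeline, so recomputing balances
from the simulated table recovers the generating means, sds and group
shift up to sampling error — a sharp end-to-end test (enforced within
normal-theory standard-error bounds: se(mean) = sd/√n, se(median
difference) ≈ 1.2533·sd·√(2/n_group)).

With `sequencing_depth` set, each row is resampled as multinomial counts
at that depth, producing integer tables whose rare parts drop to zero —
the structural-looking sparsity of real sequencing data. Multinomial
rather than Poisson sampling keeps row totals fixed, mirroring how
sequencing depth constrains counts.

What the generator does **not** emulate: real taxon ecology. Correlation
enters only through the SBP basis (independent balances), there is no
overdispersion beyond multinomial noise, no batch effects, and no
taxonomic structure. Passing tests therefore demonstrate correctness of
the transformations and recovery machinery under the stated model, not
performance on real microbiome data.

The default study conditions used by the test suite and the acceptance
script: the use-case scale is D = 500 components with n = 100 samples at
sequencing depth 2000 (deep enough that every sample retains positives,
shallow enough that ~15–20% of entries are zero); parameter recovery uses
n = 200 samples with per-balance sd 0.1 and a group shift of δ = 0.5 on
one balance for half the samples.

## Visualization

`build_plot_spec` produces a renderer-independent data model: contrast
records (balance, component, side, optional component group), distribution
records (balance, sample, score, optional sample group), a per-balance
summary (min, max, median, proportion of total variance — the proportion
always from the **full** D−1 decomposition, even when a subset is shown),
and a single global score scale. Invariants tested on the spec, not on
pixels (rendering backends are not stable test oracles): contrast records
agree with the SBP signs, scores equal the balance table exactly, the
scale is the global extrema, and any subset spec equals the full spec
filtered to the subset. `render` draws the two aligned matplotlib panels;
by default the range is encoded by segment length with variance-width off
(thickness ∝ proportion of variance is an option), and split box plots use
the Tukey convention (quartiles, 1.5·IQR whiskers). Glyphs and palettes
are aesthetics, not contract.

## Numerical and degenerate-input choices

* clr rows are re-centered after the log transform so row sums are exactly
  zero to machine precision.
* Variance decomposition requires ≥ 2 samples and a complete SBP; both are
  checked with specific errors.
* Ranking uses the variance of scores directly (the proportion shares its
  denominator and ranks identically); exact ties keep original column
  order via a stable sort.
* `closure` computes x/Σx·total so that zero replacement on zero-free data
  is bitwise identical to closure.
* Errors are typed (domain / structural / alignment / lookup) and the CLI
  maps each type to a distinct exit code.

## Known limitations

* No additive log-ratio or general (non-SBP) ilr bases; no principal
  balance analysis; no phylogeny-derived SBPs from real trees.
* No hypothesis testing of group differences on balances — the package
  surfaces the scores; testing is left to standard tools.
* φ_s clustering results depend on the linkage choice; only complete,
  average and ward are offered.
* The classical tree-embedded balance dendrogram is deliberately not
  implemented; this package provides its common-scale replacement.
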