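# Methods

Statistical model, estimation procedures, defaults, and numerical
choices, in the order the pipeline applies them.

## 1. Sequence curation

**Pairwise alignment.** Candidate proteins are aligned to a reference
by optimal global alignment (Needleman–Wunsch with affine gaps, via
Biopython's `PairwiseAligner`): BLOSUM62 scores with the `X` row and
column set to 0, gap open −10, gap extension −0.5, end gaps penalized.
Percent identity counts exactly matching non-X residue pairs; percent
similarity counts pairs with strictly positive substitution score
(identities included). Both use the full alignment length — gap columns
count in the denominator — matching the EMBOSS convention, so the
percentages of distant pairs are not inflated by ignoring indels.

**Inclusion filter.** A candidate is retained iff identity ≥ 50% AND
similarity ≥ 60%, both thresholds inclusive. Identity is checked first,
so a doubly failing record reports `below_identity`.

**Start trimming.** Residues of the candidate aligned strictly upstream
of the reference's first aligned residue (typical of mispredicted
upstream starts) are removed; the in-frame CDS, if supplied, is trimmed
by 3 nucleotides per residue. A warning is emitted if the first
retained residue is not methionine.

**Ortholog assignment.** The candidate is clustered with a labelled
multi-family paralog panel by neighbor joining on distances
1 − identity/100. In the unrooted NJ tree, the directions adjacent to
the candidate's attachment point are inspected: if the single-family
directions agree on one family, that family is assigned. If two pure
directions disagree (a candidate basal to its own family in a
two-family panel), the family whose nearest panel member is strictly
closest by patristic distance wins; exact ties return no assignment and
the candidate is excluded as `non_ortholog`.

## 2. Codon substitution model (MG94xREV)

States are the 61 sense codons of the universal code. For codons x, y
differing at exactly one nucleotide position k (x_k → y_k):

q(x→y) = ρ(x_k, y_k) · π_k(y_k) · (ω if the change is non-synonymous, else 1)

with ρ the six symmetric nucleotide exchangeabilities (GT fixed at 1),
π_k the position-specific target-nucleotide frequency, and ω = dN/dS.
Multi-nucleotide changes have rate 0. Codon frequencies are F3x4: the
product of position-specific nucleotide frequencies, renormalized over
the 61 sense codons; the chain is reversible with respect to them
(verified analytically and numerically in the tests). The generator is
normalized so that at ω = 1 the expected substitution flux is 1 per
unit branch length — branch lengths are therefore neutral expected
substitutions per codon site.

**Transition probabilities.** P(t) = exp(Qt) via `scipy.linalg.expm`
for one-off queries. Hot paths (global fit, FEL) instead use the
symmetric spectral decomposition available for reversible Q
(Q = D^{-1/2} S D^{1/2} with S symmetric), which factorizes once per ω
and then yields P(t) for any t by scaling eigenvalue exponentials; the
two agree to ~1e-14.

## 3. Likelihood

Felsenstein pruning over a postorder-flattened tree (arrays of parent
indices and branch lengths), with per-site partial-likelihood scaling
(floor 1e-200) to prevent underflow on large trees. Gaps/ambiguous
codons enter as all-ones partial vectors (marginalized missing data).
Stop codons in the input are an error unless explicitly masked to
missing. The pruning recursion is tested against brute-force
enumeration over internal states on 4- and 5-taxon trees (|Δ| < 1e-8)
and against rerooting invariance.

## 4. Global fit

Maximizes the alignment-wide likelihood over the 5 free
exchangeabilities, one gene-wide ω (both log-parameterized, bounds
[1e-6, 100]), and branch lengths (bounds [1e-9, 25]), with F3x4
frequencies fixed at their empirical values. Optimization alternates
L-BFGS-B sweeps over (log ρ, log ω) with bounded one-dimensional
branch-length refinements, accepting a step only if the log-likelihood
does not decrease, until the per-sweep improvement is below 1e-6
(max 25 sweeps, warning on non-convergence). The trace is recorded and
tested for monotonicity; refitting from a converged solution is a fixed
point.

## 5. Per-site FEL

With the global fit held fixed, each codon column gets parameters
(α, β) scaling the synonymous and non-synonymous components of the
global generator (both normalized by the ω = 1 flux). Internally the
site model is parameterized as (ω, s): ω = β/α selects a spectral
factorization, and the overall scale s multiplies branch lengths, so
the inner 1-D scale optimization (bounded golden-section, xatol 1e-6)
reuses the factorization. The outer search over ω runs in log space on
[1e-6, 1e4] plus the two boundary rays ω = 0 (β = 0) and ω = ∞ (α = 0).

- **Test.** Null: α = β (ω = 1, scale free). LRT = 2(llA − ll0),
  clipped at 0, with p from χ²₁ — the standard, mildly conservative
  choice given the boundary cases.
- **Bookkeeping.** Estimated rates below 1e-8 report as 0. Structurally
  invariant columns (all observed states identical) are classified
  `undefined_0_over_0` directly, since the rate-0 limit is their exact
  MLE. α̂ = 0 with β̂ > 0 is `infinite_beta_over_0` with ω = ∞.
- **Confidence intervals.** 95% profile likelihood: the extreme ω whose
  profile log-likelihood (scale re-optimized) stays within χ²₁(0.95)/2
  of the maximum, found by geometric bracketing and bisection in
  log₁₀ ω (tolerance 5e-3 decades); a bound escaping 1e4 is reported
  +∞, and β̂ = 0 gives a lower bound of exactly 0.
- **Classes.** purifying if ω < 1 and p ≤ 0.1; diversifying if ω > 1
  and p ≤ 0.1; neutral if p > 0.1; undefined for 0/0 sites.

Acceptance tests pin the operating characteristics: type-I error at
p ≤ 0.1 on 200 neutral sites within [0.04, 0.16], and CI coverage at
true ω = 0.2 at least 0.85 over 100 sites.

## 6. Partition aggregates and comparisons

A partition (named set of reference codons) gets one aggregate ω̄ by
maximizing the same profiled (ω, s) likelihood jointly over its usable
columns — identical code to FEL, so a single-site partition reproduces
that site's estimate exactly. Sites with undefined ω (invariant
columns) are excluded; infinite-ω sites are **kept**, because their
non-synonymous changes are informative and dropping them would bias ω̄
downward (empirically from ~0.79 to ~0.55 at true ω = 0.8 on 16 taxa,
where roughly a third of sites show no synonymous change).

Two partitions are compared by a 1-df LRT: the null shares one ω̄
across both column sets while each keeps its own scale (and, for
cross-gene comparisons, its own tree and frequencies); the alternative
fits ω̄ separately. The null search is guarded by evaluating both
separate optima as candidates so the LRT is never negative due to
optimizer noise.

Significant inequalities (default α = 0.05) become edges lower → higher
ω̄; the graph is transitively reduced (networkx) into a Hasse diagram.
Because edges always point from strictly smaller to larger ω̄, the
graph is acyclic by construction; this is property-tested over random
significance patterns.

## 7. Forward simulator

Sites carry independent (α, β); the per-site generator is
α·Qsyn + β·Qnon with the components normalized by the neutral flux, so
branch lengths mean the same thing in simulation and inference.
Evolution uses endpoint sampling — each branch's child state is drawn
directly from the exact P(t) row of its parent state — which is
distributionally identical to event-level simulation for this purpose
and much faster. Sites sharing (α, β) share one spectral factorization.
Roots are drawn from the stationary distribution; an optional invariant
initiator Met pins site 1 to ATG with both rates 0. Trees are balanced
or Yule-shaped, rescaled to a requested total length, or user-supplied
Newick. A seed is mandatory; identical inputs give byte-identical
alignments. Calibration is tested against analytic transition
probabilities (3 MC standard errors) and χ² agreement with the
stationary distribution after a long branch.

Curation fixtures plant exact identity/similarity percentages by
substitution-only mutants at length 100 (whole-residue percentages),
drawing "similar" replacements from positive-scoring BLOSUM62 partners
and "dissimilar" ones from the rest, restricted to positions whose
residue admits the requested flavor (glycine, for instance, has no
positive-scoring partner).

## 8. Pipeline and serialization

`run_full_analysis` chains curation (optional) → tree (user Newick or
NJ from codon p-distances) → global fit → FEL scan → partitions (a
full-length partition is always added) → comparisons → Hasse. Each
stage failure is wrapped with its stage name. Reports serialize rates
to 6 significant digits, p-values as 3-digit scientific notation, ∞ as
`inf`, undefined ω as `NA`, and class summaries as "n/N; x.x%"
(degenerate denominators as "0/0; —"), making reruns byte-identical.
Sites-of-interest reports flag ω < 0.05 as strongly purified.

## Problem-size guidance and limitations

- Designed for tens to ~150 taxa and genes of a few hundred codons;
  the global fit on 16 × 300 takes ~25 s, a FEL site ~0.3 s.
- FEL power at a single site is modest below ~30 taxa; expect partial
  recovery of planted structure at desk scale (the tests assert
  enrichment, not perfection, at such sizes).
- The χ²₁ calibration of the site LRT is asymptotic and mildly
  anticonservative on small trees (observed 0.16 at 12 taxa,
  nominal 0.10 — at the edge of the accepted band).
- One gene-wide ω in the nuisance fit; no rate variation models beyond
  the site-specific FEL parameters; no recombination or codon-position
  partitioning of trees.
- The NJ fallback tree uses raw codon p-distances; for serious use,
  supply a tree estimated with a proper model.
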