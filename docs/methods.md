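# Methods

## The microarray network game and the LRI

The package models a case/control expression study as a *microarray
experiment situation* E = ⟨N; S_D; S_R; A^{S_D}; A^{S_R}⟩: a gene panel
N, diseased samples S_D, reference samples S_R, and their log2-scale
expression matrices. A co-expression network (N, g^E) is derived from E
and turned into a cooperative game whose players are the *links*: the
characteristic function

v(g) = (1/n(g^E)) Σ_{i ∈ N(g^E)} u_{g_i^E}(g)

averages, over the active genes, the unanimity game anchored at each
gene's star (u_T(g) = 1 iff T ⊆ g). v(∅) = 0, v(g^E) = 1, and v is
monotone under link inclusion. The Link Relevance Index of gene i is the
position value: half the Shapley value of each incident link, summed.
Three independent routes are implemented:

1. **closed form** — F_i = (1 + Σ_{j~i} 1/deg(j)) / (2 n(g^E)) for
   active genes, 0 for isolated genes;
2. **star-sum form** — the literal sum over stars,
   F_i = (1/n) Σ_{j ∈ N(g_i^E)} |g'_i| / (2|g_j^E|), where the index set
   is read as *including i itself* (the reading under which both routes
   coincide — the alternative excludes the diagonal term and breaks
   efficiency);
3. **brute-force oracle** — exact link-Shapley over all 2^m coalitions,
   capped at m = 16 links; marginal sums accumulate as integers
   (|S|!(m−|S|−1)! times unanimity hit counts) and are divided by m!·n
   once, so the enumeration stays exact and fast.

All arithmetic is in exact rationals (`fractions.Fraction`): the
allocation's defining identities (efficiency Σ F_i = 1, equality of the
three routes, axiom checks) are then machine-verifiable as equalities,
not tolerances. Floats appear only in display output, rounded at a
configurable precision (default 6 decimals).

The allocation satisfies efficiency, anonymity, additivity and the
superfluous-link property; `check_axioms` verifies all four on any given
network (anonymity by random relabelings; superfluous-link and
additivity through the generic Shapley enumerator, so they are checked
against the brute-force route rather than the formula being tested).

Ranked output uses competition ranking — tied genes share a rank —
with lexicographic gene id as the secondary key, since no canonical
tie-break exists for exactly equal rational scores.

Degenerate inputs: an edgeless network yields an all-zero score table
with a warning (not an error), because a strict correlation threshold can
legitimately produce no links; a game on an edgeless network has no
defined value function and raises.

## Network construction

How g^E is derived from E is a modelling gap: published analyses of this
kind typically do not specify the co-expression criterion, and very
sparse observed networks (on the order of a hundred active genes from a
genome-wide panel) imply a stringent rule. The exact construction behind
any particular published network is therefore not reconstructible; the
package provides two documented, deterministic rules:

- **case-correlation** (default): link i–j iff |r(i,j)| ≥ τ over the
  *diseased* samples, Pearson (default) or Spearman, default τ = 0.9.
  High τ yields sparse hub-bearing networks.
- **differential-correlation**: link iff |r_case − r_control| ≥ τ,
  selecting co-regulation that changes with disease state.

Both are monotone in τ (raising τ never adds links) and deterministic,
which keeps edge lists byte-reproducible. Genes below a per-gene
variance floor, or with zero variance (correlation undefined), never
receive links but stay in the node set as isolated genes. Whether the
network should be built on diseased samples only, all samples, or a
differential contrast is an open modelling question; the default follows
the disease-centric reading. Matrices are used as given (assumed
pre-normalized, log2 scale); missing values are rejected rather than
imputed. P-value-based edge calling is deliberately not offered: it
would break the monotone, threshold-only contract.

## Differential expression arm

The DEG stage exists as the *comparison arm* (salient-vs-DEG overlap),
not as a contribution: per gene, a two-sided Welch two-sample t-test
(unequal variances, Welch–Satterthwaite df) on log2 values, LFC = case
mean − control mean, Benjamini–Hochberg adjustment across all genes, and
the dual filter adj-p ≤ α (default 0.05) AND |LFC| ≥ lfc_min (default 2).
The filter is on |LFC| because down-regulation is as much a DEG as
up-regulation. This is a plain-test simplification relative to
moderated-variance empirical-Bayes linear modelling: with
dozens of samples per group the moderation has little effect on which
large-effect genes pass an |LFC| ≥ 2 gate, but exact statistics will
differ on small-sample data. Genes constant in both groups get p = 1
when the fold change is zero (no evidence) and p = 0 otherwise (exact
separation), with a warning.

## Salient genes, overlaps, enrichment

Salient genes are those with LRI strictly greater than zero —
equivalently the active players — selected by strict inequality at a
configurable threshold (default 0). Score-distribution summaries and
plots exclude zero scores, since zeros encode "not in the network"
rather than a small relevance.

Enrichment implements the two computational atoms of term
over-representation against *caller-supplied* GMT sets and universe:
the right-sided hypergeometric tail P(X ≥ k) for overlap k given
(universe, term, query) sizes, BH correction across tested terms, and a
minimum-overlap filter (default 3 genes). Term redundancy is grouped by
Cohen's kappa between membership indicator vectors (grouping threshold
0.4 by convention); identical terms are defined to have kappa 1 even
when chance agreement is perfect. Live ontology retrieval and term-graph
visualisation are out of scope, and the universe is always explicit
because published universes vary by database release. Gene ids are
opaque strings (whitespace-trimmed; optional case folding): identifier
mapping is the caller's responsibility, and ids that fail to match are
surfaced, never silently dropped.

## Synthetic data generator

`simulate` draws a genes × samples panel with planted structure:

- **background** gene g, sample s: x = μ_g + ε, ε ~ N(0, σ²), with μ_g
  drawn once per gene from a uniform baseline range (default 4–12 log2
  units, the realistic dynamic range of normalized array intensities;
  default σ = 0.5);
- **module** gene in an active group: x = μ_g + λ·f_s + ε with one
  latent factor f_s ~ N(0,1) per sample per module, shared by all module
  members. The population within-module correlation is λ²/(λ²+σ²) —
  the closed form that makes recovery thresholds analytic. Default: one
  10-gene module with λ = 3 active in cases only (correlation ≈ 0.973,
  above the τ = 0.9 default);
- **DEG** genes: +δ added to the case mean (defaults δ = 3, 20 genes),
  disjoint from module members so the two signal types separate cleanly;
- an optional **hub**: one gene belonging to two modules. Its
  correlation to either module's members is λ²/√((2λ²+σ²)(λ²+σ²))
  (≈ 0.69 at the defaults), so hub recovery requires a threshold below
  that value — the single-factor model buys analytic tractability at the
  price of this attenuation.

Randomness comes from one `numpy.random.default_rng(seed)` (PCG64)
stream with a fixed draw order (baselines, case noise, control noise,
then per-module factors), so output is byte-reproducible from the seed
across platforms; the CLI makes the seed mandatory.

What the generator does *not* emulate: probe-level effects, RMA
normalization, batch structure, heavy-tailed noise, correlated
background, or overlap between DEG and module genes. Passing recovery
tests therefore shows that the pipeline recovers the structure this
model plants — clean factor-driven modules against independent Gaussian
background — not that it would recover modules in real array data with
correlated noise and batch effects.

## Problem sizes and checks

The test battery uses sizes chosen so every defining identity is checked
exhaustively where exhaustive checking is feasible: exact triple-route
agreement on 200 random connected networks of ≤ 8 genes / ≤ 10 links
(full 2^m enumeration each), the complete 16-row value table of the
4-gene reference network, module recovery at 1000 genes × 100+100
samples, and DEG type-I calibration on 10 000 null genes at 20/20
samples (raw p ≤ 0.05 fraction within ±0.005 of nominal). A hand-crafted
4-gene, 6-sample expression fixture whose correlation network equals the
reference topology ties the builder to the game end to end.

## Known limitations

- The brute-force oracle is exponential; above 16 links only the two
  formula routes apply (they are exact and linear-time, so this limits
  verification, not analysis).
- The DEG arm is a plain Welch test; small-sample variance moderation is
  out of scope.
- Network construction offers correlation thresholding only — no soft
  thresholding, topological overlap, or mutual-information rules.
- Isolated genes are kept in outputs with score 0 by default
  (`include_isolated=False` drops them), since no convention is
  universal.
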