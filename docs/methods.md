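# Methods

## The model

The analysis treats a drug's transcriptional response as a set of signed
differential-expression calls over lncRNAs.  Expression is handled on the
log2 scale throughout (RMA-style summaries), so a per-instance fold change
is the elementwise difference between a treatment profile and its paired
control.  A lncRNA is differentially expressed (DEL) in an instance iff
|log2FC| strictly exceeds the threshold (default 1.0; 1.5 and 3.0 are the
conventional robustness settings and are exposed through the same
parameter).  Instance-level calls are merged per drug by union; this makes
the association set monotone in the threshold (stricter thresholds give
nested subsets), which the tests verify.

**Sign conflicts.**  When instances disagree on the direction for the same
(drug, lncRNA) pair, the sign is the majority over above-threshold
instances; ties go to the direction with the larger mean |log2FC| and then
to "up".  The reported `mean_log2fc` and `n_supporting_instances` are
computed over the instances supporting the winning sign only, so the
stored sign always matches the sign of the stored mean.

## Projections

The SSN needs no statistics (any shared lncRNA connects two drugs; the
shared count is kept as an edge weight for inspection).  The LLN uses the
upper-tail hypergeometric probability of the observed drug overlap,
computed by summing the feasible terms in log-gamma space (`scipy.special.
gammaln` + `logsumexp`), clamped to [0, 1]; the unit tests cross-check
against `scipy.stats.hypergeom.sf` and the acceptance suite against exact
rational enumeration (≤ 1e−10 relative error for all m ≤ 25).  The
multiple-testing family is the set of lncRNA pairs with non-zero overlap —
pairs with r = 0 have p = 1 by construction and carry no evidence — and m
counts all drugs in the SMLN.  BH-FDR is delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`; both cutoffs
(p < 0.01, q < 0.01) are strict.

## Pharmacological similarity

The permutation statistic is the number of unordered connected drug pairs
whose annotation sets intersect.  Each of the `n_perm` permutations
(default 1000) draws the same number of *distinct* pairs uniformly from all
pairs of annotated drugs in the universe (default: the annotated drugs
incident to connected pairs).  Pair resampling, not degree-preserving
rewiring, is the implemented null; it matches the statistic's exchangeable
construction and calibrates correctly (see below).  Two p-values are
reported: the conservative (r+1)/(N+1) headline and the raw fraction r/N,
which can be 0.  Side-effect sharing is quantified per pair as the Jaccard
ratio |SE_a ∩ SE_b| / |SE_a ∪ SE_b| (pairs with an empty union are
skipped); structural similarity as the Tanimoto coefficient of binary
fingerprints (0 when both are empty).  Both group comparisons
(connected vs all other annotated pairs) use a one-sided Mann–Whitney test:
exact enumeration when both groups have ≤ 8 observations without ties,
otherwise the normal approximation with midranks, tie correction and
continuity correction (scipy's `mannwhitneyu`).

## Modules

Maximal cliques come from Bron–Kerbosch with pivoting (`networkx.
find_cliques`); k-clique percolation uses the standard maximal-clique
acceleration (two k-cliques percolate iff some pair of maximal cliques of
size ≥ k shares ≥ k−1 nodes), as implemented by networkx.  The acceptance
suite proves equivalence to brute-force enumeration of all k-subsets on 200
random graphs.  All outputs are sorted so results are byte-reproducible.
Interface nodes are those in ≥ 2 communities; each is labelled with the
majority ATC class of its drug neighbours (lexicographic tie-break).

## Tissue specificity

The per-tissue score is 1 − √JSD(p, δ_t) with log base 2, where p is the
lncRNA's normalized expression across tissues and δ_t the point mass on
tissue t.  This is the standard expression-specificity score with a
conventional 0.8-type cutoff; since the exact historical formula behind
that cutoff is not fixed by a formula in the literature we follow, a
max-fraction alternative (`method="max_fraction"`) is provided.  The JSD
score is scale-invariant, equals 1 exactly for single-tissue expression,
and is bounded by ≈ 0.442 for a uniform two-tissue profile (decreasing in
the number of tissues), so uniform profiles can never pass the 0.8 cutoff
— the tests assert the analytic bound 0.45 for widths 2–29.

## The synthetic study

The generator emulates the shape of the real inputs, not their content:

- **Instances.**  Each (drug, lncRNA) pair carries a planted effect with
  probability `edge_density` (default 0.2), signed ±`effect_log2fc`
  (default 2.5).  Per instance, control = per-lncRNA baseline (drawn once
  on a dyadic grid so zero-noise fold changes subtract exactly) +
  N(0, noise_sd); treatment = control + effect + N(0, noise_sd).  The
  per-instance log2FC error therefore has sd exactly `noise_sd` (default
  0.3), making the noise parameter directly interpretable on the
  fold-change scale.  Defaults: 60 drugs, 40 lncRNAs, 3 instances/drug.
- **Annotations.**  Integer-labelled vocabularies (100 indications, 150
  targets, 200 side effects, 256 fingerprint bits) with per-item baseline
  probabilities 0.03/0.02/0.10/0.10.  For every drug pair sharing a planted
  lncRNA, a per-item shared injection with probability
  q = (min(1, e·p²) − p²)/(1 − p²) raises the pairwise sharing probability
  to min(1, e·p²), e being `annotation_enrichment`.  At e = 1 no injection
  occurs, so the permutation null is exact.  Because a drug belongs to many
  connected pairs, injections leak into the marginals; in sparse networks
  the empirical sharing odds ratio tracks e with ~10% attenuation (tested),
  while in dense networks (default density 0.2, where ~80% of drug pairs
  are connected) per-pair enrichment is fundamentally unidentifiable — any
  generative model honoring a per-pair sharing odds of e on nearly all
  pairs saturates the drug marginals.  The annotation-sharing study
  therefore uses `edge_density = 0.05` (connected pairs ≈ 10% of all
  pairs), a design constraint of the statistic, with enrichment levels 1
  (null) and 5 (signal) on 60 drugs.
- **Co-expression.**  Five lncRNAs with planted effects each drive 10
  mRNAs: mRNA = ±lncRNA profile + shift + N(0, noise_sd); unlinked mRNAs
  get independent variation (sd 0.5) so null correlations are defined even
  at zero noise.  One enriched gene set per linked lncRNA (its 10 mRNAs
  plus 5 random genes among 15) plus 20 random sets of 15.
- **Tissues.**  Half the lncRNAs are tissue-specific with purity 1.0 by
  default (strictly single-tissue, scoring exactly 1.0); a `purity`
  parameter (e.g. 0.95) spreads the remainder evenly.  Other lncRNAs are
  near-uniform (tight Dirichlet).  Tissues are partitioned round-robin into
  anatomical classes (max(2, min(11, T/2)) classes).

What the generator does **not** model: probe-level microarray noise,
batch/cell-line structure, correlated drug effects (planted effects are
independent across drugs, so the synthetic LLN is empty at the 0.01/0.01
cutoffs and module detection on pipeline output exercises the empty-result
path; module correctness is established on constructed dense-block graphs
instead), realistic chemical fingerprints, or ontology structure in
annotations.  Passing tests therefore validate the algorithms and their
statistics, not biological discovery on real compendia.

## Numerical and design choices

- Strict inequalities at every published cutoff (fold change, p/q, PCC,
  specificity), matching the ">"/"<" conventions of the analysis.
- Hypergeometric terms in log space; exact rational arithmetic only in
  test oracles.
- Power-law fits are OLS on the raw log10–log10 degree distribution
  (slope + R²), not maximum-likelihood exponent estimation, because that
  is the quantity being reported; no binning.
- Giant-component and argmax ties break toward the lexicographically
  smallest identifier; community and clique outputs are sorted.
- One RNG per generator stage, seeded from (config seed, stage offset), so
  stages can be regenerated independently and runs are byte-reproducible.
- Floats are serialized with 17 significant digits and parsed with
  round-trip precision, so write-then-read is exact.

## Problem sizes

The validation suite uses the default study (60 drugs × 40 lncRNAs × 3
instances, 500 mRNAs, 8 tissues), 1000 null replicates / 100 signal
replicates for permutation calibration and power, 200 random graphs (n ≤
15) for clique-percolation equivalence, exhaustive hypergeometric
enumeration up to m = 25, and 20 seeds for co-expression recovery.  These
sizes give tight Monte-Carlo error on every rate being checked while the
whole suite stays fast enough to run routinely.

## Known limitations

- The LLN on default synthetic data is empty (see above); planted
  correlated drug effects would be needed to exercise clique percolation
  end-to-end from expression data.
- Degree-preserving rewiring is not implemented as a permutation mode.
- The enrichment analysis is plain over-representation on user-supplied
  GMT sets; pathway-topology scoring is out of scope.
- The per-pair annotation-enrichment model is approximate in dense
  networks, as documented above.
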