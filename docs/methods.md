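# Methods

## Model and procedure

`reposcan` implements rank-based matching of a disease expression profile
to a compound database. One side is a complete ranked gene list — the
*instance*: all *n* genes from a case/control study ordered by strength of
differential expression, with no significance cutoff. Keeping every gene is
deliberate: compound signatures are short, and truncating the instance
would often leave no overlap to score. The other side is a set of
*signatures*: for each compound, the unordered set of genes it is known to
interact with. Interaction direction (up/down regulation) is ignored by
construction, so databases without regulatory annotation, or with
conflicting annotations, are usable.

For a signature whose genes occupy sorted 1-based instance ranks
V(1) ≤ … ≤ V(t), the signed enrichment score is

    a  = max_j [ j/t − V(j)/n ]      (lead over the uniform expectation)
    b  = max_j [ V(j)/n − (j−1)/t ]  (lag behind it)
    KS = a  if a > b, else −b.

Both running maxima compare the empirical distribution of signature ranks
with the uniform distribution on {1..n}; the signed combination keeps the
side with the larger deviation and makes top-heavy signatures positive. An
exact tie a = b is scored −b: the strict inequality is part of the score's
definition, and the tie is attainable (e.g. n = 10, ranks {3, 7} give
a = b = 0.3, KS = −0.3). Since a and b are rationals with common
denominator t·n, the implementation decides a > b on integer numerators;
deciding it in floating point mis-scores exact ties, which is precisely the
case the rule exists for.

Attainable range: KS ≤ 1 − t/n (first t ranks, when t ≤ n − 2) and
KS ≥ −(n − t + 1)/n (last t ranks). The lower extreme reaches exactly −1
at t = 1, V = n. A signature filling the first n − 1 or all n ranks ties
a = b and scores −1/n.

Significance is assigned by a length-stratified bootstrap. For each
distinct signature length ℓ the engine scores B uniformly random ℓ-gene
subsets of the instance (sets of unique genes, hence sampling without
replacement); all signatures of length ℓ share that null. The p-value is
the proportion of null scores *strictly* exceeding the observed score —
one-sided, so inversely enriched compounds get p near 1. The strict rule
can return p = 0; the `add_one` option switches to (count + 1)/(B + 1),
the standard never-zero estimator, which is also the better-calibrated
choice for type-I-error studies. p-values are Benjamini–Hochberg adjusted
across all scored compounds (via statsmodels).

A screen (`repo`) chains: restrict signatures to the instance (recording
the overlap t, dropping and logging those with t < `min_overlap`), score
each signature, build one null per unique t, convert to p-values, adjust,
and sort by ascending p, ties by descending KS, then compound_id — a total
order, so identical inputs give byte-identical output files.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `B` | 10,000 | bootstrap resamples per signature length; Monte-Carlo SE of a p-value is √(p(1−p)/B) |
| `seed` | required in the API (CLI default 42) | drives all resampling; each length uses the independent substream `default_rng([seed, length])`, so a length's null does not depend on which other lengths are present |
| `min_overlap` | 1 | smallest instance overlap a signature needs to be scored |
| `add_one` | off | never-zero p estimator (count+1)/(B+1) |
| `descending` | off | treat larger instance scores as stronger differential expression (for effect-size-like rankings; default is p-value-like, smaller = stronger) |
| `organism_id` | 9606 | taxon filter in CTD conversion |
| `require_evidence` | on | CTD rows must carry PubMed support |

Instance ingest resolves duplicates (many probes per gene) by keeping the
occurrence with the best score — the strongest evidence — and preserves
input order on score ties; both choices matter because the statistic
depends only on rank positions. Identifier mapping is file-driven (a
two-column alias → Entrez table); no annotation database is bundled, and
aliases missing from the table are dropped with a logged count.

CTD conversion targets the public `chem_gene_ixns` column layout, resolved
by header name (either a plain header row or the commented-header dialect)
so minor dump-version drift is tolerated. The MeSH ChemicalID is the
compound identifier (names collide; accessions do not). All gene forms are
kept: an interaction with a transcript, protein or peptide counts as an
interaction with its gene, and no gene-form exclusion is applied.

## Synthetic data

`synthetic` generates the two inputs with known ground truth. Instances are
n fake genes (`G000001`…) in a seeded random order with ascending
p-value-like pseudo-scores. Null databases draw signatures uniformly
without replacement, with lengths from a constant, a discrete uniform
range, or an explicit discrete law. Planted signatures draw each gene's
rank from a discretised Beta(1, c): weight ∝ (1 − x)^(c−1) at the rank
midpoint x, sampled without replacement. c = 1 is exactly the uniform
null; c → ∞ packs all genes toward rank 1. This model was chosen because
it has a single interpretable strength knob and contains the null as a
special case; nothing about real expression values is simulated — only
rank structure, which is all the statistic sees. Consequently, passing
tests demonstrate the statistical machinery (scoring, null construction,
calibration, FDR, recovery), not robustness to microarray artefacts,
correlated genes, or noisy rank estimates in real data.

Simulated screens default to 2,000 genes, 100 signatures with lengths
uniform on {5..50} (modest, CTD-like set sizes), one planted signature at
concentration 150, and B = 2,000 — sizes at which a 25–50-screen study
completes in minutes on one core while leaving the planted effect
unambiguous.

## Numerical and design notes

- Subset sampling draws a (B, n) uniform matrix and takes each row's ℓ
  smallest entries (argpartition): an exact uniform random subset,
  vectorised; jobs above 2·10⁷ matrix elements are chunked to bound memory.
  ℓ = n short-circuits to the constant score −1/n.
- `empirical_p` requires the null's length to equal the observed t;
  mismatches are contract violations, not warnings.
- BH adjustment returns values in input order, clipped to 1; q is
  non-decreasing in p across a result set, but rowwise q ≥ p is not a
  guarantee of the step-up transform.
- The evaluation module exposes all four hypergeometric counts (N, K,
  n_sig, k_hit) explicitly and tests the upper tail only
  (over-enrichment); percentile rank is 100·rank/total in the
  deterministic output order.
- Degenerate inputs fail loudly: empty instances, empty signatures,
  signatures containing genes absent from the instance, ℓ outside [1, n],
  p-values outside [0, 1], empty databases after filtering.

## Limitations

- The bootstrap null conditions on length only, not on gene identity; gene
  label correlations in real data are invisible to it.
- The strict-> p-value is conservative at small B (p = 0 is reportable);
  use `add_one` when calibrated tails matter.
- CTD conversion trusts the dump's own gene identifiers; it does not
  re-map or validate them against a current annotation.
- Percentile ranks inherit the arbitrary-but-deterministic tie order of
  the result sort.
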