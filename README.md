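# reposcan

Expression-based computational drug repositioning. `reposcan` scores a
complete ranked case/control gene list (an **instance**) against a database
of unordered compound–gene interaction sets (**signatures**) and reports,
for every compound, a signed Kolmogorov–Smirnov enrichment score, a
bootstrap p-value, and a Benjamini–Hochberg FDR. Compounds whose known
interactor genes crowd the top of a disease's differential-expression
ranking are candidates for repositioning against that disease.

The design is deliberately format-agnostic: any differential-expression
tool's ranked output can be the instance (e.g. GEO2R output from a
microarray study, or a ranked RNA-seq table), and any gene-set collection
can be the database — including ones with no directionality information,
such as a converted Comparative Toxicogenomics Database (CTD) dump. The
only requirement is a shared identifier system (typically Entrez Gene IDs)
between the two.

## The statistic

Let *n* be the number of genes in the instance and *t* the number of
signature genes present in it. Let *V*(1) ≤ … ≤ *V*(t) be the sorted
1-based ranks those genes occupy. Then

    a = max_{j=1..t} [ j/t − V(j)/n ]
    b = max_{j=1..t} [ V(j)/n − (j−1)/t ]

    KS = a   if a > b,
    KS = −b  otherwise (including an exact tie a = b).

`a` measures how far the observed rank distribution runs ahead of the
uniform expectation, `b` how far it lags behind; enriched (top-heavy)
signatures score near +1, inversely enriched ones near −1. Because ties
between `a` and `b` are meaningful, the comparison is made in exact integer
arithmetic (both are rationals over *t·n*), never in floating point.

The statistic has no usable analytic null, so significance is assigned by
bootstrap: for each distinct signature length ℓ, the scores of *B* (default
10,000) uniformly random ℓ-gene subsets of the instance form a shared null,
and a signature's p-value is the proportion of null scores strictly
exceeding its observed score (optionally the never-zero estimator
(count+1)/(B+1)). p-values are Benjamini–Hochberg adjusted across all
scored compounds.

## Worked example

`examples/simulated_screen.py` plants one strongly enriched signature among
99 random ones in a 2,000-gene instance and runs the screen:

```
instance: 2000 genes; database: 100 compounds
planted compound: PLANTED_001

top 5 rows (compound, t, KS, p, FDR):
  PLANTED_001   t=34  ks=+0.972  p=0  q=0
  C0045         t=39  ks=+0.244  p=0.01  q=0.5
  C0027         t=12  ks=+0.422  p=0.015  q=0.5
  C0003         t=42  ks=+0.200  p=0.0235  q=0.5875
  C0091         t=42  ks=+0.171  p=0.064  q=0.8893

significant at FDR < 0.05: 1 compounds
planted compound percentile: 1.0 (100 * rank / compounds)
known-therapy enrichment: p = 0.01, expected hits mu = 0.010
```

The planted compound's 34 genes sit near the top of the ranking, so its KS
score (+0.972) towers over the random signatures, none of 2,000 bootstrap
resamples beats it (p = 0, q = 0), and it is the screen's only discovery.
The percentile line is the rank-based summary used to evaluate real
screens, and the hypergeometric p tests whether known therapies are
over-represented among the significant compounds.

Other examples: `score_one_signature.py` (the statistic on a 10-gene toy),
`convert_ctd_dump.py` (raw CTD dump → GMT), `null_calibration.py`
(type-I-error check).

## Command line

```sh
reposcan run --instance ranked.tsv --db signatures.gmt --out results.tsv \
             [--mapping alias2entrez.tsv] [--boots 10000] [--seed 42] \
             [--min-overlap 1] [--add-one] [--descending]
reposcan convert-ctd --in CTD_chem_gene_ixns.tsv[.gz] --out signatures.gmt \
             [--organism 9606] [--no-require-evidence]
reposcan simulate --n-genes 2000 --n-signatures 100 --planted 1 \
             --concentration 150 --seed 42 --out-dir screen/
reposcan evaluate --results results.tsv --known therapies.txt
```

`run` writes a TSV (`compound_id  compound_name  t  ks  p_value  fdr`) plus
a `.meta.json` sidecar recording the bootstrap count, seed, options and
SHA-256 digests of all inputs, so every run is reconstructible.

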