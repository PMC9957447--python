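# trnkit

Network-based annotation of transcription factors from expression data.

Transcription factors (TFs) regulate target genes by binding short DNA
motifs, but for most TFs — even in a well-studied plant like *Arabidopsis
thaliana* — neither the biological processes they control nor the motifs
they recognize are well annotated. `trnkit` implements a purely expression-
driven route to both: infer a genome-scale transcriptional regulatory
network (TRN) from a compendium of expression profiles, treat each TF's
inferred target pool as statistical evidence, and query that pool for
over-represented GO biological-process terms and over-represented k-mer
binding motifs.

It is aimed at computational biologists who have an expression matrix, a TF
list, promoter sequences and a GO corpus, and want candidate TF functions
and binding motifs with calibrated significance — plus a synthetic-data
generator that makes the whole pipeline testable at desk scale.

## The method

**Network inference.** Each gene *j*'s expression Y_j across *m* samples is
modelled as a sparse linear function of the TF expression matrix X:

    minimize (1/2m) ||Y_j − X A_j||² + λ Σ_i |a_ij|

(lasso with a free intercept; a TF's own column is zeroed when fitting its
model, so a_jj = 0). λ is tuned by 10-fold cross-validation; poorly fit
genes (mean CV R² below the 25th percentile) are dropped; the coefficient
matrix is thresholded at |a_ij| ≥ α to give the weighted directed network
G, with positive weights read as up-regulation. `out_i` denotes TF *i*'s
target pool, `in_j` gene *j*'s regulators.

**Function annotation.** For each target pool, every GO biological-process
term annotated to ≥ 2 pool genes is tested with the EASE score — the
upper-tail hypergeometric probability with the observed overlap penalized
by one gene (a conservative variant of Fisher's exact test). The number of
significant terms t(k) for a pool of size k is compared against random
pools: means μ_k and standard deviations σ_k of t over 100 random draws at
sizes ⌊2^1.5⌋ … ⌊2^10⌋ are fitted as linear functions of k, giving a
z-score z = (t(k) − μ̂_k)/σ̂_k per TF; z ≥ 2 marks a significantly annotated
TF. Term specificity (1 / annotated-gene count) and Wang graph-based
semantic similarity support comparison against reference annotations.

**Motif discovery.** All k-mers (k = 6, 7, 8; 86,016 candidates) are
indexed as binary presence per promoter. Enrichment of motif *f* in a pool
uses the upper-tail hypergeometric test, BH-corrected at FDR 5% within each
TF's family of tested motifs. Pair counts are validated against a
size-preserving rewired-network null, and enriched 7-mers are scored
against reference PWMs by a normalized information-content alignment
(ic-score ∈ [0, 1], 1 = the motif matches the PWM's most informative
7-column window exactly).

## Worked example

```python
from trnkit import synthetic, inference, topology, go_annotation as goa

# 1. simulate a compendium with planted sparse linear regulation
expr, model = synthetic.generate_expression(
    n_tf=20, n_genes=500, m=200, density=0.1, noise_sd=0.1, seed=7
)

# 2. fit per-gene lasso models and threshold into a network
A = inference.fit_coefficients(expr, lam=0.01)
net = inference.threshold_network(A, alpha=0.075)

# 3. topology and 4. GO annotation of one TF's target pool
s = topology.summarize(net)
model.go_plants = synthetic.assign_go_plants(model.tf_ids, rho=0.8)
corpus = synthetic.generate_go_corpus(model, model.true_network(), n_terms=60, seed=8)
hits = goa.enrich_pool(set(net.targets("TF0020")), corpus)
```

Output:

```
inferred 1054 edges; precision 0.911, recall 1.000 vs planted truth
mean out-degree 52.7, diameter 4, degree coefficient -0.51
TF0020 pool (k=30): top term GO:P0020 EASE p=2.63e-20, fold enrichment 14.4
```

The inferred network recovers 91% of its edges from the planted truth and
misses none; the planted term for TF0020 tops its enrichment list with an
EASE score of 2.6×10⁻²⁰ and 14-fold enrichment over the background rate.

A negative degree coefficient (here −0.51) means hub TFs attach to
low-degree targets — the disassortative signature typical of regulatory
networks.

## Command line

Every stage is a subcommand of the `trnkit` console script:

```
trnkit simulate --config config.yaml --outdir run/     # synthetic dataset
trnkit infer    --expression expr.tsv --tf-list tfs.txt --seed 1 --outdir run/
trnkit topology --edges run/edges.tsv --expression expr.tsv --tf-list tfs.txt
trnkit annotate --edges run/edges.tsv --obo go.obo --annotations ann.tsv --seed 2
trnkit motifs   --edges run/edges.tsv --promoters promoters.fasta --seed 3
trnkit run      --config config.yaml                   # all stages, one manifest
```

`trnkit run` writes a JSON manifest (full configuration, per-stage timings,
outputs) before any stage executes; a rerun with the same config is
bit-identical.

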