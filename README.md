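# coexpair

Co-expression of chromosomally neighbouring genes: pair classification,
distance-dependent correlation statistics, and a decomposition of local
co-expression into chromatin, shared-promoter and transcriptional-interference
components.

## The problem

In eukaryotic genomes — conspicuously so in the compact genome of
*Arabidopsis thaliana* — adjacent genes are more similar in their expression
than random gene pairs. Three mechanisms can produce this local
co-expression, and they leave different fingerprints in the orientation and
spacing of gene pairs:

1. **Shared chromatin domains.** A region that switches between open and
   closed chromatin modulates all genes inside it, regardless of their
   orientation. Its strength can be read off distant (> 400 bp) divergent
   (`←→`) and convergent (`→←`) neighbours, whose direct transcriptional
   interactions differ completely but whose co-expression is the same.
2. **Shared bi-directional promoters.** Divergent pairs closer than ~400 bp
   can initiate transcription from a single promoter region, which boosts
   their co-expression well above the chromatin baseline.
3. **Transcriptional interference at 3' ends.** In transcription
   termination the polymerase overshoots the poly(A) site; for closely
   spaced pairs where a 3' end flanks the intergenic region (convergent and
   uni-directional pairs) this read-through suppresses the neighbour's
   coordinated expression.

`coexpair` measures these fingerprints from a genome annotation (GFF3) and
a log2 expression matrix (genes × experiments, TSV). With *m* the mean
pairwise Pearson correlation of a group of direct neighbour pairs and *r₀*
the mean correlation of random gene pairs, the decomposition is

```
c   = (m_bd,long + m_cv,long) / 2 − r₀        chromatin effect
pf  = (m_bd,short − c) / m_bd,short           promoter-sharing fraction
if  = (c − m_cv,short) / c                    interference fraction
```

where `bd` = bi-directional (divergent), `cv` = convergent, and short/long
split at 400 bp of intergenic distance (transcript boundary to transcript
boundary). Uni-directional pairs are excluded from `c` because read-through
can couple them even at long range.

Because the full microarray compendium and genome annotation used in the
original analysis are external downloads, the package ships a latent-factor
simulator that generates annotation + expression fixtures embodying exactly
these three mechanisms with known ground truth, and the test suite verifies
that the pipeline recovers the planted parameters end to end.

## Worked example

Simulate a genome of 5,000 genes in two-gene chromatin domains
(chromatin share a = 0.04, promoter share b = 0.11, interference
δ = 0.4 — the defaults), run the pipeline, and decompose:

```python
import coexpair as cx
from coexpair import decomposition

cfg = cx.SimConfig(n_chrom=2500, genes_per_chrom=2, n_experiments=1000, seed=42)
ann, mat, truth = cx.simulate(cfg)
pairs = cx.filter_overlapping_genes(cx.direct_neighbor_pairs(ann), ann)
values, _ = cx.coexpress_pairs(mat, pairs)
joined = cx.join_pairs(pairs, values)
bg = cx.random_background(mat, ann, n_pairs=50_000, seed=43)
groups = cx.group_means(joined, split_bp=400, background=bg)
print(groups.round(4).to_string(index=False))
result = decomposition.decompose(groups, bg)
print(f"chromatin effect      = {result.chromatin_effect:.4f}")
print(f"promoter fraction     = {result.promoter_fraction:.3f}")
print(f"interference fraction = {result.interference_fraction:.3f}")
```

prints

```
   orientation distance_class  mean_r  sem_r   n  p_vs_random
 bidirectional          short  0.1518 0.0016 315          0.0
 bidirectional           long  0.0412 0.0020 295          0.0
unidirectional          short  0.0324 0.0013 670          0.0
unidirectional           long  0.0397 0.0013 600          0.0
    convergent          short  0.0252 0.0019 303          0.0
    convergent           long  0.0411 0.0018 317          0.0
chromatin effect      = 0.0411
promoter fraction     = 0.729
interference fraction = 0.386
```

Close divergent pairs sit at a + b ≈ 0.15, distant divergent and
convergent pairs at the chromatin baseline a ≈ 0.04, and close convergent
pairs at a(1 − δ) ≈ 0.024; the decomposition recovers the planted
(a, b/(a+b), δ) = (0.04, 0.733, 0.40) to within Monte-Carlo error.

The same analysis is available from the shell:

```bash
coexpair simulate --outdir fixture --seed 42
coexpair analyze --config run.yaml          # report.json + TSVs
coexpair decompose --means 0.060 0.050 0.014 0.15 0.024 --rounding printed
```

`analyze` takes a YAML config naming the annotation, matrix and output
directory plus thresholds (split at 400 bp, 100 bp profile bins, E < 0.2
tandem-duplicate filter, 100,000 random background pairs by default), and
writes a single `report.json` with every headline statistic: orientation
counts, per-distance profiles, group means with Wilcoxon rank-sum p-values
against the random background, anti-correlated fractions, opposite-strand
overlap groups (3' overlap / 5' overlap / contained), and the
decomposition.

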