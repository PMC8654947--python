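# dipscan

Analysis pipeline for **domain-insertion profiling**: experiments that
insert a library of polypeptide motifs (donors) between every consecutive
residue pair of a recipient protein — typically an ion channel such as the
inward rectifier Kir2.1 — and read out a phenotype (cell-surface
expression) by two-gate FACS sorting and sequencing. The package takes the
experiment from junction reads to an interpretable biophysical model of
donor/recipient compatibility, and ships a synthetic screen generator so
every stage is testable without any external data.

It is aimed at groups running sort-seq insertional scans (or re-analyzing
published ones) who need a tested, scriptable implementation of the full
chain: insertion calling, enrichment scoring, structure/sequence feature
computation, positional classification, and model interpretation.

## The statistics at the core

**Surface-expression fitness.** For each insertion position *i*, motif
*m*, replicate *r*, counts from the label-high and label-low gates give a
pseudocounted log-ratio enrichment

    E_raw(i,m,r) = ln[ (0.5 + H_i) / Σ_i (0.5 + H_i) ]
                 − ln[ (0.5 + L_i) / Σ_i (0.5 + L_i) ]

computed only where both gates have reads. Scores are z-normalized to an
internal flexible-linker control (AGSAGSA) per sequencing subpool and
collection batch, so 0 means "traffics like a flexible linker". Each
variant gets a Poisson standard error

    SE = sqrt( 1/(H+0.5) + 1/(L+0.5) + 1/(ΣH+0.5) + 1/(ΣL+0.5) )

and replicates are combined by a weighted average with a between-replicate
variance component M estimated per variant by REML Fisher scoring (50
iterations), with weights `sqrt(M + SE_r²) / Σ_r sqrt(M + SE_r²)`. Motifs
observed at ≤80% of positions are dropped.

**Annotation.** Motif profiles are clustered with cosine distance + Ward
linkage; positions are classified by a 2-D UMAP embedding (neighborhood
10) followed by k-means, the cluster number chosen by majority vote of
five validity indices. Class enrichment of annotated sites uses two-sided
Fisher's exact tests; agreement between labelings is Cramér's V.

**Properties and model.** Per-residue features include anisotropic network
model (ANM) stiffness and fluctuations, windowed sums of 14 amino-acid
scales, heavy-atom contact density, φ/ψ, and Shrake–Rupley SASA.
After |ρ| ≥ 0.8 redundancy reduction, a 500-tree regression random forest
(85/15 split) predicts fitness; it is interpreted with drop-and-refit
importance, first- and second-order accumulated local effects (ALE), and
Friedman's H interaction statistic — all implemented in-package.

## Worked example

```python
import dipscan as d
from scipy.stats import spearmanr
import numpy as np

design = d.make_design(seed=1)                     # 50 positions x 40 motifs
truth  = d.simulate_true_fitness(design, seed=2)   # planted class structure
counts = d.simulate_sort_counts(design, truth, d.SortModel(), seed=3)

scorer = d.SortSeqScorer().fit(counts)
fm = scorer.fitness_matrix_all_
est, tru = fm.to_numpy().ravel(), truth.fitness_true.loc[
    fm.index, fm.columns].to_numpy().ravel()
ok = np.isfinite(est)
print(f"observed {ok.mean():.3f} of cells, "
      f"Spearman vs truth {spearmanr(tru[ok], est[ok]).statistic:.3f}")

pc = d.PositionClassifier(random_state=0).fit(
    truth.fitness_true.drop(columns=[design.control_motif_id]))
print("consensus k =", pc.consensus_k_)
```

prints

```
observed 0.922 of cells, Spearman vs truth 0.925
consensus k = 3
```

i.e. at the default screen depth (10⁵ reads/gate, 2 replicates) 92% of
variant cells are scoreable, the combined z-scores rank-correlate with the
planted fitness at ρ ≈ 0.92, and consensus clustering recovers the three
planted positional classes.

A `dipscan` CLI wraps the pipeline stages (`simulate`, `call`, `score`,
`annotate`); run `dipscan --help`.

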