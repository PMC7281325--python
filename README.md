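# phosmark

Marker discovery for acquired drug resistance from paired SILAC
phosphoproteomics and transcriptome profiling.

When a tumor cell line acquires resistance to a targeted drug (the
motivating system is a HER2-positive breast-cancer line made resistant to
trastuzumab), the signaling changes that *cause* resistance are entangled
with the cell's ordinary short-term response to the drug. `phosmark`
implements the analysis that separates the two: a set-algebra
classification of quantified phosphosites across a four-contrast,
label-swapped SILAC design at three time points, combined with selection of
genes whose differential expression is independent of drug exposure, and
integration of both into an annotated network with gene-set enrichment. It
is written for computational proteomics/transcriptomics practitioners who
want the classification logic as a tested, reusable library rather than a
one-off script.

## The classification model

Per time point, four two-channel SILAC mixes quantify four contrasts
(sample vs reference):

* **A** — resistant vs parental, untreated
* **B** — resistant + drug vs parental + drug
* **C** — resistant + drug vs resistant
* **D** — parental + drug vs parental

Raw H/L ratios are re-oriented to the sample/reference scale (inverted when
the light channel carries the sample), mapped to signed fold changes
(r ≥ 1 → +r, r < 1 → −1/r, so ±1 means no change), and thresholded at a
SILAC cutoff of 1.5 (inclusive). Only class-1 phosphosites (localization
probability strictly > 0.75) enter the analysis. A site is a
resistance marker at a time point in direction *d* iff

```
(A ∪ B) ∩ C° \ D     per direction d over regulated-site sets,
```

i.e. A or B regulated in direction *d* (neither opposite), C unchanged,
missing or regulated in the same direction, and D not regulated in
direction *d*; opposite-direction regulation of D is annotated as "de
novo" loss of a sensitivity response. Markers are reported at two
stringency tiers: direction-consistent consensus in ≥ 2 of 3 time points,
and in all 3.

The transcriptome arm selects genes significant (BH-FDR q < 0.05) with
fold change > 2 in **both** the untreated and the treated
resistant-vs-parental contrast with the same sign ("drug-independent"
regulation), using a pooled-variance two-sample t with optional moderation
toward the median gene variance. Gene-set enrichment is an upper-tail
hypergeometric test with BH correction.

A synthetic-data generator (`phosmark.synthetic`) emulates the full study —
planted markers, noise, missingness, localization-probability mixture,
duplicated arrays — with serialized ground truth, so the entire pipeline is
testable end to end without any download.

## Worked example

```sh
phosmark simulate --out-dir demo --seed 3 --n-sites 200 --n-genes 100 \
    --noise-sd 0 --missing-rate 0
phosmark markers --table T1=demo/phospho_T1.tsv --table T2=demo/phospho_T2.tsv \
    --table T3=demo/phospho_T3.tsv --out-dir demo/markers
```

prints

```
{"down_2of3": 2, "down_3of3": 2, "up_2of3": 3, "up_3of3": 3}
```

— the 200-site dataset plants two up- and two down-regulated resistance
sites plus one de-novo-reversal site (here drawn up); at zero noise all
five are recovered, each at full 3-of-3 temporal overlap, and nothing else
is called. `demo/markers/markers.tsv` lists each marker with its
per-time-point signed fold changes for contrasts A–D (planted effects
appear as ±3, the default effect size), its consensus direction, tier and
de-novo flag; `demo/truth.json` carries the generator's ground truth for
comparison. The same stages are callable as a library
(`generate_silac_dataset`, `classify_dataset`, `select_markers`,
`differential_expression`, `select_resistance_genes`, `build_network`,
`hypergeometric_enrichment`), and `phosmark run-all --config config.yaml`
executes the whole pipeline with a manifest.

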