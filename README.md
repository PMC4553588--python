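# tagwinnow

Post-alignment analysis for tag-count RNA-seq against a redundant de novo
transcriptome — built for the kind of study that profiles an immune
response in a non-model insect (e.g. larval *Heliothis virescens*
hemocytes elicited with bacterial or fungal cell-wall components) by
aligning short sequence tags from each treatment to a fragmented
Velvet/Oases assembly.

The pipeline implements four stages:

1. **Annotation grouping** — contigs sharing a top BLAST (NR) accession
   form an annotation group, the putative-transcript unit.
2. **Group-unique read filtering** — only reads aligning within one and
   only one group are retained; group-spanning and unannotated-only reads
   are excluded and tallied by reason.
3. **Correlation winnowing** — within each group, contigs whose
   per-treatment expression profiles correlate at Pearson r ≥ 0.8 are
   recursively collapsed, keeping the member with more hits, until every
   survivor has a distinct combination of annotation and expression.
4. **Fold-change differential expression** — for counts *n* (treatment)
   and *d* (control), the fold change is *n* / max(*d*, 1) (zero-floor
   denominator, 0 when *n* = 0); calls are `up` iff fc ≥ 3, `down` iff
   fc ≤ 1/3 (inclusive), restricted to annotations with e-value < 1e-5.

A ground-truthed simulator (`tagwinnow.simulate`) generates redundant
catalogues, read alignments and overdispersed count matrices with the
statistical structure these stages assume, so the whole pipeline is
testable without any external data. A packaged reference table
(`tagwinnow.reference`) carries 107 published immune-annotated contig
rows whose printed fold changes the arithmetic reproduces.

## Worked example

The analysis scripts run the full study end to end (bulky intermediates
go to `scratch/`, summary tables to `results/`):

```sh
python analysis/01_simulate.py
python analysis/02_filter_and_tally.py
python analysis/03_winnow.py
python analysis/04_differential_expression.py
python analysis/05_reference_fold_checks.py
```

which prints, in order:

```
catalogue: 4649 contigs from 1000 transcripts
lengths: median 398 bp, mean 795 bp
reads: 333506 (66809 span >1 annotation group, 20.0%)
reads: 266697/333506 retained (80.0%); 66809 multi-group, 0 no-group
winnowed 4649 contigs -> 2852 survivors in 1000 groups at r >= 0.8
bacterial_vs_control: 268 up / 386 down (>= 3-fold, e < 1e-5)
fungal_vs_control: 311 up / 393 down (>= 3-fold, e < 1e-5)
fold-change cells agreeing at printed precision: 212/214
```

Reading those numbers: the simulator fragmented 1,000 transcripts into
4,649 contigs; the filter removed exactly the ~20% of reads constructed
to span two annotation groups; winnowing collapsed 1,797 redundant
fragments (groups whose fragment profiles were de-correlated by noise
keep more than one survivor — redundancy removal is conservative by
design); the 3-fold caller then tallied regulated assemblies per
comparison; and recomputing the published tables' arithmetic reproduces
212 of 214 printed fold-change cells, the two exceptions being documented
rounding anomalies in the source tables themselves.

The same stages are available as a CLI (`tagwinnow simulate | filter |
winnow | de | run | report`) for use on real annotation/alignment/count
TSVs (SAM alignments are accepted via pysam).

Library use:

```python
>>> from tagwinnow import rounded_fold_change, classify
>>> rounded_fold_change(1969, 302, 1)   # tags: 302 control, 1969 elicited
6.5
>>> rounded_fold_change(19, 0, 1)       # absent from control: zero-floor
19.0
>>> classify(6.5)
'up'
```

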