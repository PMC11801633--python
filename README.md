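# svensemble

Multi-caller **structural-variant (SV) ensemble analysis** for short-read
call sets: refine raw caller VCFs, combine calls from a panel of callers
under *multiple-agreement* and *union* strategies, and benchmark single
callers and combinations against SV truth sets — plus a statistical
simulator of caller call sets so the whole pipeline runs and can be
validated without any sequencing data.

## Who this is for

No single short-read SV caller detects all types and sizes of variants
well: some callers trade recall for precision, some barely call insertions
at all, and each has its own VCF dialect (paired breakend records, sub-50 bp
calls, non-PASS records). A common remedy is ensemble calling: pool several
callers and either keep only calls seen by two or more of them (higher
precision) or keep everything (higher recall). This package implements that
workflow as a tested library and CLI for anyone comparing SV callers or
building a caller ensemble against a truth set such as the GIAB HG002 or
HGSVC2 benchmarks.

## The method

**Refinement** of each caller VCF, in order: (1) annotate each record's SV
type (DEL, INS, DUP, INV, CTX) and length from `SVTYPE`/`SVLEN`/`END`,
symbolic ALTs, sequence-resolved alleles, or breakend junction orientation;
(2) exclude calls < 50 bp; (3) collapse paired start/end records of one SV
(MATEID, shared EVENT, or `_1`/`_2` ID stems) to the start record;
(4) keep only FILTER == PASS. Records are tagged `caller=<NAME>` in INFO.

**Grouping**: pooled calls on one contig with one SV type are swept left to
right; a call joins the open *neighbor group* iff its start is within
±500 bp of the group's smallest-position member (the *representative*),
otherwise it opens a new group. The representative is emitted as the merged
call. `multiple_agreement` keeps groups supported by ≥ 2 distinct callers;
`union` keeps every group; `direct_merge` concatenates without grouping.
Preset panels: `III` = {Manta, DELLY, GRIDSS}, `V` = III + {LUMPY, SvABA}.

**Benchmarking**: a test call is a true positive when a same-type truth
call on the same contig lies within ±500 bp of its start (one-to-one greedy
nearest-distance assignment). With TP/FP/FN per (dataset, type, call set):

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F1 = 2·precision·recall / (precision + recall)

and across datasets the combined scores are micro-averages over summed
counts: cPr = ΣTP/(ΣTP+ΣFP), cRc = ΣTP/(ΣTP+ΣFN), cF1 their harmonic mean.

**Simulation**: truth sets of DELs and INSs with log-uniform sizes on
[50 bp, 10 kb] and inter-variant spacing > 1 kb; per-caller profiles with
per-type recall, Poisson false-positive loads placed away from truth,
double-geometric breakpoint jitter, and the dialect quirks the refinement
stage must strip. See `docs/methods.md` for every modelling choice.

## Worked example

Recompute benchmark metrics from the packaged reference counts table
(six callers on HG002 and three HGSVC2 genomes):

```sh
$ svensemble tables --out tables/
wrote 5 metric tables to tables/
```

`tables/metrics_HG002.tsv`, DEL rows:

```
callset  total   tp   fp   fn  recall  precision   f1
 DRAGEN   4787 3425 1362 2039    0.63       0.72 0.67
  Manta   3935 2996  939 2468    0.55       0.76 0.64
  DELLY   4142 2620 1522 2844    0.48       0.63 0.55
 GRIDSS   2681 2299  382 3165    0.42       0.86 0.56
  LUMPY   1528  668  860 4796    0.12       0.44 0.19
  SvABA   1910 1526  384 3938    0.28       0.80 0.41
```

Each row is one caller's DEL call set scored against the HG002 truth set:
Manta finds 2,996 of the 5,464 truth deletions (recall 0.55) with 939 false
calls (precision 0.76), F1 0.64.

Run the full synthetic pipeline — simulate four datasets, refine, merge the
III and V panels, benchmark everything, micro-average across datasets:

```sh
$ svensemble run-all --seed 7 --n-truth 500 --n-datasets 4 --out run/
72 evaluations across 4 datasets; reports in run/
```

`run/metrics_combined.tsv`, DEL rows:

```
               callset  total   tp   fp   fn  recall  precision   f1
                 Manta   2469 1067 1402  933    0.53       0.43 0.48
                 DELLY   3187  973 2214 1027    0.49       0.31 0.38
                GRIDSS   1386  832  554 1168    0.42       0.60 0.49
                 LUMPY   1519  250 1269 1750    0.13       0.16 0.14
                 SvABA   1137  566  571 1434    0.28       0.50 0.36
III-multiple agreement    961  915   46 1085    0.46       0.95 0.62
             III-union   5820 1732 4088  268    0.87       0.30 0.44
  V-multiple agreement   1375 1224  151  776    0.61       0.89 0.73
               V-union   7653 1837 5816  163    0.92       0.24 0.38
```

The simulated ensembles reproduce the qualitative trade-off the method is
built around: union strategies dominate every member caller's recall
(0.87–0.92 vs 0.13–0.53) while multiple-agreement strategies dominate on
precision (0.89–0.95), because independent false positives rarely agree
across callers. Individual subcommands (`simulate`, `refine`, `merge`,
`bench`) expose each stage separately; `--window`, `--min-size`,
`--min-support` override the 500 bp / 50 bp / 2-caller defaults.

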