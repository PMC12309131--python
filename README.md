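# icrscan

Genome-wide discovery of **candidate imprinting control regions (ICRs)** by
scanning chromosomal DNA for clusters of composite ZFP57-binding elements.

## The problem and the method

Genomic imprinting — parent-of-origin-specific monoallelic expression — is
governed by ICRs whose allele-specific methylation is protected by the
KRAB zinc-finger protein **ZFP57**. ZFP57 binds the methylated hexamer
**TGC·meC·GC** (TGCCGC at the sequence level). The hexamer alone is far too
common to be informative, but *composite* elements — the hexamer overlapping
a CpG-rich MLL1 morpheme, called **ZFBS-morph overlaps (ZMOs)** — are rare,
and *clusters* of ZMOs mark known ICRs with striking specificity.

`icrscan` implements that discovery pipeline for any FASTA assembly:

1. **Motif construction** — take the ZMO set as an explicit list, or derive
   it by exhaustively overlapping the hexamer with a morpheme lexicon
   (every relative offset at which the two words agree on ≥ *min_overlap*
   shared bases; the composite is the union of the two footprints).
2. **Scanning** — exact-string location of every hexamer and ZMO occurrence
   (overlapping matches included; both strands by default; `N` never matches).
3. **Density profile** — an 850-nt window slides in 6-nt steps, starting at
   nucleotide 6. A window is emitted only when it encompasses **≥ 2 ZMOs**;
   the emitted point records the window midpoint and the ZMO count, shown on
   a 0–5 display scale (raw counts above 5 are kept internally).
4. **Peak calling** — maximal runs of overlapping/abutting qualifying
   windows merge into one candidate-ICR peak. The peak score is the capped
   maximum window count: 5 is more robust than 4, 4 than 3, 3 than 2; peaks
   whose best window holds exactly 2 ZMOs are flagged *low-confidence*.
5. **Track output** — UCSC custom tracks: hexamers (BED6, dense), ZMOs
   (BED6, pack), density (bedGraph or variableStep WIG, full), peaks (BED6,
   maroon) plus a TSV peak report. All coordinates are 0-based half-open in
   BED/bedGraph, deterministic and byte-stable.

A seeded synthetic-genome generator plants ZMO clusters and isolated
singletons on an exactly motif-free background, so the whole pipeline is
testable against known ground truth without downloading a real assembly.

> **Note** — the published ZMO list is not bundled. `examples/motifs.yaml`
> ships an *illustrative* six-string set (the hexamer extended by one base);
> supply your own list to reproduce published scans.

## Worked example

Simulate a 100-kb chromosome with a planted 4-ZMO cluster, a 2-ZMO cluster,
and one isolated ZMO, then run the full pipeline:

```sh
icrscan simulate --motifs examples/motifs.yaml --outdir sim \
    --length 100000 --gc 0.41 --seed 7 \
    --cluster 30000:4:500 --cluster 70000:2:300 --singleton 10000
icrscan all --fasta sim/chrS.fa --motifs examples/motifs.yaml \
    --outdir out --genome-label demo
```

The log reports the stage counts:

```
INFO icrscan.cli: chrS: 7 ZMO occurrences, 260 qualifying windows, 2 peaks
```

and `out/peaks.tsv` contains the candidate ICRs:

```
chrom  start  end    name             score  n_points  max_raw  low_confidence
chrS   29321  31179  ICR_candidate_1  4      169       4        false
chrS   69455  70845  ICR_candidate_2  2      91        2        true
```

Both planted clusters are recovered as single peaks with scores equal to
their planted ZMO counts; the 2-ZMO peak is flagged low-confidence (a
two-ZMO peak can be a true or a false positive), and the isolated singleton
at 10 kb attracts no peak. `out/` also holds `hexamer.bed`, `zmo.bed`,
`density.bedGraph`, and `peaks.bed`, ready for upload as UCSC custom tracks.

The stages compose: running `scan`, `density`, `peaks`, `tracks` separately
produces byte-identical files to one `all` invocation.

## Layout

```
src/icrscan/
  motif_model.py         # hexamer, morphemes, ZMO composite construction
  sequence_io.py         # FASTA read/write + normalization
  scanner.py             # exact occurrence scanning, strand policies
  density_profile.py     # 850-nt / 6-nt sliding-window profile
  peak_caller.py         # candidate-ICR segmentation and scoring
  track_writer.py        # UCSC BED6 / bedGraph / WIG serialization
  synthetic_fixtures.py  # seeded planted-truth genome generator
  cli.py                 # icrscan scan|density|peaks|tracks|simulate|all
```

See `docs/methods.md` for the model, parameter choices, numerical
conventions, and known limitations.
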