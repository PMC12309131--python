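# Methods

## Model

ZFP57 binds the methylated hexamer TGC·meC·GC; its binding maintains
allele-specific methylation at imprinting control regions (ICRs). Because the
unmethylated-sequence scan cannot see methylation, specificity comes from
composition and clustering instead: composite elements (ZMOs) formed by the
hexamer overlapping CpG-rich MLL1 morphemes are individually rare, and ICRs
carry *clusters* of them. The pipeline therefore (i) locates every exact
hexamer/ZMO occurrence, (ii) counts ZMO occurrences in a sliding window, and
(iii) reports maximal runs of qualifying windows as candidate ICRs. No
statistical significance model is attached — the window count itself is the
robustness estimate, exactly as the underlying method defines it.

One orthographic wrinkle in the method's source literature: a single passage
spells the hexamer TGGCGC where every other statement uses TGCCGC. We treat
TGGCGC as a typographical variant of TGCCGC; the hexamer is a configuration
field, so either spelling can be scanned deliberately.

## Composite construction

`build_overlap_composites(hexamer, morpheme, min_overlap)` anchors the
hexamer at offset 0 and places the morpheme at every integer offset in
[-(len(morpheme)-1), len(hexamer)-1]. A placement is admitted when the two
footprints share ≥ `min_overlap` positions and agree at every shared
position; the composite is the union of the two placed words (containment
yields the longer word). The result is the deduplicated set over all
admissible offsets — by construction identical to exhaustive enumeration,
and cross-checked against an independent brute-force oracle in the tests.
`min_overlap` defaults to 1 because the source method says only
"overlapping" with no stated minimum; it is exposed rather than fixed.
Composites are built on the forward orientation of both words only; reverse
orientation is handled at scan time by the strand policy, keeping the motif
set canonical and the strand logic in one place.

The published ZMO list is not bundled; the shipped `examples/motifs.yaml`
set (hexamer ± one flanking base, six strings) is illustrative only.

## Scanning

Exact, possibly overlapping string matching; no mismatches, PWMs, or HMMs —
the method is exact-string by design. Sequences are normalized on input:
uppercased, IUPAC ambiguity codes mapped to N, and N never matches.
Internally all coordinates are 0-based half-open; only track writers convert
(WIG positions are 1-based).

**Strand policy.** Whether the original implementation scanned one or both
strands is not stated. Default is `both_strands` — a double-helical DNA
element is present regardless of the strand it is read from — with
`forward_only` available to reproduce a single-strand dialect. A minus-strand
match is a forward match of the motif's reverse complement, reported at its
forward coordinates. Palindromic motifs would match twice at one locus;
(chrom, start, end, strand) deduplication collapses the duplicate to the `+`
record so counts feeding the density statistic are never inflated.
Overlapping/nested distinct ZMO occurrences are all retained — only
exact-coordinate duplicates collapse.

## Density profile

Parameters (defaults = the method's stated values):

| parameter     | default | meaning                                      |
|---------------|---------|----------------------------------------------|
| window_length | 850 nt  | sliding-window size                          |
| step          | 6 nt    | window advance per iteration                 |
| start_offset  | 5       | first window start, 0-based (= nucleotide 6) |
| min_count     | 2       | minimum ZMOs for a window to be emitted      |
| display_cap   | 5       | browser display scale ceiling                |

The source states the scan "starts at about nucleotide 6"; we fix this
precisely as 0-based 5 (configurable). The stopping rule ("a few bases
before the end") is realized as *the last full window*: windows iterate
while `w + window_length <= chrom_length`. A chromosome shorter than one
window yields an empty profile with a warning.

**Membership rule.** The source counts ZMOs a window "encompassed" without
defining partial-overlap handling. Default: an occurrence belongs to a
window iff its *start* lies in the window — the simplest rule that counts
each occurrence in the same number of windows regardless of motif length.
`membership="contained"` (full containment) is available as an alternative.

Counts above the cap are preserved in `raw_count` and capped only in the
displayed value: the 0–5 axis is a display convention, and peak scoring
should not destroy information. Counting uses `numpy.searchsorted` over the
sorted occurrence starts; the tests verify it equals a naive recount window
by window.

The density track is written as bedGraph (one 1-bp bin per window midpoint)
rather than fixed-step wiggle — qualifying windows are sparse — with a
variableStep WIG writer behind `--wig` for fidelity to full-format density
plots.

## Peak calling

The source defines peaks visually, never operationally. Our rule: maximal
runs of emitted windows whose intervals overlap or abut (successive
window starts differ by ≤ window_length) merge into one peak spanning the
union of contributing windows — one visual peak becomes one interval, and
every counted ZMO falls inside the reported candidate ICR. A `max_gap`
parameter (default 0) can bridge small gaps for sensitivity analysis. The
score is `min(max_raw, display_cap)`; `max_raw` and the number of
contributing windows are reported alongside. `low_confidence` is true iff
the best window held exactly 2 ZMOs. `min_count < 2` is rejected at the CLI
(the 2-ZMO emission rule is definitional); `--expert` lifts this with a loud
warning.

## Synthetic genomes

The generator emulates a chromosome at desk scale: an i.i.d. per-base
background with GC parameter (default 0.41, a typical mammalian genome-wide
GC content), in which every accidental match of any motif or its reverse
complement is destroyed by local resampling, then ZMO clusters (k motifs
evenly spaced across a spread ≤ window) and isolated singletons are planted
at specified coordinates. Junction-created matches are destroyed the same
way, and the result is verified by a full scan: the ZMO occurrence set must
equal the planted set exactly, so recovery tests are sharp. Planted elements
must be separated pairwise by more than twice the window length so truth
labels are unambiguous; motif sets with nested ZMO strings (one inside
another, or inside another's reverse complement) are rejected because their
planted counts would be ambiguous.

What passing these tests does *not* show: behaviour on real assemblies with
repeats, CpG islands, and non-i.i.d. base composition. The background model
deliberately omits dinucleotide structure; accidental-match destruction
makes truth exact at the cost of realism.

Test and acceptance problem sizes — 100-kb chromosomes, 20–50 replicates,
clusters of k = 2…7 — were chosen as the smallest scale at which every
cluster/singleton geometry and the display cap are all exercised.

## External validation recipe (manual, optional)

Reproducing locus-level observations on a real dog assembly requires two
external inputs that cannot be bundled: the canFam2 (Boxer) FASTA from the
UCSC download server and the published ZMO list. Given both:

```sh
icrscan all --fasta canFam2.chr18.fa --motifs published_zmos.yaml \
    --outdir canfam2_chr18 --genome-label canFam2
```

then upload the BED/bedGraph files as custom tracks and inspect the region
upstream of *H19*: the expectation is ZMO occurrences (three in that region)
and several hexamer sites but *no* qualifying density peak, in contrast to
robust peaks inside CpG islands at imprinted loci such as *MEST/PEG1* or
*PLAGL1/ZAC1*. This is a manual recipe, not part of the test suite, because
it depends on an external download.

## Known limitations

- Exact matching only; a single SNP in a ZMO removes the occurrence.
- No CpG-island calling or gene annotation; those are consumed (if at all)
  as external browser tracks.
- Peak robustness is a count, not a calibrated probability; two-ZMO peaks
  are explicitly low-confidence.
- The synthetic background is i.i.d.; false-positive rates measured on it do
  not transfer to real genomes.
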