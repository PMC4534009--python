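# Methods

## The problem and the signal

5'-end sequencing protocols built on template switching (nanoCAGE-style)
read out transcription start sites (TSSs) as clusters of read 5' ends. Two
artifact classes corrupt the read-out: clusters formed by uncapped or
truncated RNAs, and strand-invasion products in which the template-switching
(TS) oligo annealed to internal sequence complementary to its own tail.
The discriminating signal is the *cap signature*: when reverse transcriptase
crosses the 7-methylguanosine cap it adds a cytosine with no template, which
appears in the sequenced read as a 5' guanosine that the genome does not
encode. Reads from capped molecules therefore tend to begin with an
unencoded G; reads from uncapped RNA begin with a genomic base.

## Pipeline

1. **Demultiplexing** (`demux`). Reads begin with the TS-oligo prefix:
   inline barcode (optional), constant linker (optional), and a G-tail
   (default `GGG`). A read is assigned to the barcode with strictly fewest
   Hamming mismatches over the barcode-length prefix, accepted only when
   that count is at most `max_mismatch` (default 3) and the minimum is
   unique; ties are reported as ambiguous, never resolved. N bases count as
   mismatches; no indels are considered. In single (non-barcoded) mode the
   read must begin with the literal tail. The whole prefix is then removed,
   and reads can be truncated at the 3' end (`trim_to`) so libraries
   sequenced at different lengths cluster comparably.

2. **First-base tagging** (`cap_tag.tag_first_base`). Each read's first base
   and its quality are moved into the read identifier as a `|CF=<base>:<q>`
   suffix (whitespace-free, parsed from the right, so it survives the SAM
   qname). This lets a cap-derived G that would otherwise mismatch at the
   read 5' end align cleanly, without discarding the information. Tagging is
   exactly invertible (`untag`); 1-nt reads are rejected and counted.

3. **Alignment intake**. Alignment itself is external; the pipeline consumes
   SAM/BAM of the tagged reads and keeps primary, mapped records, requiring
   `NH == 1` when the tag is present ("uniquely mapped"). The bundled
   simulator emits a ground-truth SAM that fills this role in all tests.

4. **Start-base classification** (`cap_tag.classify_start_base`). The
   removed base is compared to the reference base one step 5' of the mapped
   read start, on the read strand (position − 1 on plus; position + 1,
   complemented, on minus). Equal → *encoded*; different → *unencoded*;
   upstream base unavailable (contig edge) or an N anywhere →
   *indeterminate*. Coordinates are 0-based half-open internally; SAM input
   is converted at the boundary.

5. **Strand-invasion filter** (`invasion`). For each aligned read the nine
   reference bases directly upstream of its 5' end (read strand) are
   compared position-wise to the last nine bases of the TS oligo. A window
   "matches" when at least 2 of the oligo's 3 terminal Gs match and at most
   2 of 9 positions mismatch; the test is repeated at offsets ±1..3 around
   the 5' end (7 windows), and any match flags the read. Both ceilings are
   configurable to support relaxation experiments. Windows that leave the
   contig are non-matches.

6. **Peak calling** (`peaks.call_peaks`). Read 5' ends are clustered per
   (chromosome, strand) by single-linkage: neighbouring occupied positions
   at most `max_gap` nt apart (default 20) join one cluster, and clusters
   with at least `min_reads` members (default 10) become peaks. The original
   peak caller used upstream of cap filtering is not re-implemented here;
   this transparent one-parameter clustering reproduces its "read cluster
   with a 10-read cutoff" semantics, and any results should be reported
   together with the `max_gap` used. The peak *mode* is the most frequent 5'
   position, ties broken toward the 5'-most position on the read strand.

7. **G'-filtering** (`gfilter`). Per peak, `%-Capped` = 100 × (members whose
   removed base is an unencoded G) / (members with a determinate call).
   Unencoded non-G first bases never count toward the numerator;
   indeterminate calls are excluded from both sides (optionally counted as
   encoded). Peaks survive when `%-Capped ≥ min_percent` (default 50,
   inclusive). Only peaks are removed, never reads, so sensitivity can be
   re-balanced after the fact by re-thresholding.

8. **Annotation** (`annotate`). Categories, in precedence order: **TSS**
   (peak interval contains an annotated TSS), **5'UTR/CDS/Intron/3'UTR**
   (gene part containing the peak's 5'-most coordinate; same strand
   required), **Promoter** (within 3000 bp upstream of a TSS), and
   **Intergenic**. The 3'UTR zone is extended 1000 bp downstream of the gene
   end so that near-gene 3' peaks are not called intergenic — the
   category definitions bound Intergenic by both the 3000 bp promoter
   distance and a 1000 bp distance past gene ends, but name no separate
   "downstream" class, so this package folds that zone into 3'UTR.
   Antisense peaks over a gene body fall through to the distance-based
   classes. Quartile distributions split each gene's window (100 bp upstream
   of the TSS to the gene end, read strand) into four equal parts (remainder
   to the 3'-most quartiles; majority ties to the lower quartile index).
   Also computed: the filter-threshold sweep of category distributions, the
   estimated false-negative rate (true-5' peaks — category TSS/5'UTR or
   mode within 500 bp of a TSS — rejected by the filter), position × base
   count matrices around peak modes with the YR summary (pyrimidine fraction
   at −1, purine fraction at +1), and per-library metrics (redundancy =
   uniquely mapped reads / distinct read sequences; % rRNA by 5'-end overlap
   with supplied intervals).

9. **Reproducibility analytics** (`compare`). Peaks of two libraries are
   paired by same-chromosome, same-strand interval overlap and kept only
   when the pairing is one-to-one both ways. Counts are normalized to reads
   per million before Spearman correlation (average ranks on ties; undefined
   below 3 pairs or at zero variance). Mode agreement is summarized by
   median (lower middle on even n — distances are integers), mean, and the
   smallest distance covering 95% of pairs. The saturation curve subsamples
   alignments without replacement (seeded) and reruns peak calling,
   filtering and gene assignment per fraction. `peat_compatible_subset`
   restricts to peaks at TSS/5'UTR or within 500 bp of an annotated TSS for
   comparison against linker-ligation peak sets, which cannot be
   cap-filtered.

## Synthetic data model

`simdata` generates a random genome (default two 60 kb contigs, uniform base
composition), packs non-overlapping, strand-alternating protein-coding genes
(5'UTR 150 nt, two 300 nt CDS exons split by a 120 nt intron, 3'UTR 200 nt),
and draws reads of four classes with full ground truth (raw FASTQ with the
TS-oligo prefix, a truth SAM of where each tagged read aligns, and a per-read
truth table):

* **capped** — 5' end drawn from an initiation pattern with probability 0.2
  exactly at the annotated TSS and otherwise uniform over ±15 nt. This
  two-component shape mirrors real promoters, which show a preferred start
  position inside a read cluster tens of nt wide: the dominant mode makes
  peak modes reproducible across replicates, while the dispersed component
  spreads reads over many distinct positions. The spread matters
  statistically because every read starting at one position shares one
  upstream genomic base, so a peak's %-Capped averages over *positions*, not
  reads. A cap-derived G is prepended with probability 1.0 by default (the
  template-switching reaction anneals to the cap-adjacent cytosine in the
  canonical case; lower values model libraries where the oligo anneals
  directly to the cap-derived cytosine).
* **uncapped_body** — 5' ends uniform over gene bodies, no prepended base.
* **strand_invasion** — 5' ends at loci planted (in a reserved low-coordinate
  zone, > 3 kb from any gene) with an upstream 9-mer exactly equal to the
  oligo tail.
* **rRNA** — 5' ends uniform over a designated rRNA interval (emitted as BED).

Per-gene expression levels are log-normal (σ = 1), a sample property drawn
with the genome so replicate libraries share them — this is what makes
replicate rank correlations meaningful. Class counts default to 2000 capped,
600 uncapped, 30 invasion and 60 rRNA reads: a library dominated by genuine
5' ends with minority artifact classes at the few-percent level. Quality
strings are constant high quality; sequencing error is not modeled. Extra
template-free additions (`extra_c_probability`, default 0) appear in the
FASTQ and as soft-clipped bases in the truth SAM, since exactly one removed
base is tracked.

What the simulator does **not** emulate: alignment error and multi-mapping,
PCR duplication and fragmentation biases, sequencing error, C-rich internal
template-switching without oligo complementarity, and isoform-level TSS
heterogeneity. Passing tests therefore demonstrate the correctness of the
computational procedure under its stated model, not the wet-lab error
profile of any particular library.

## Numerical and design choices

* Tag format `|CF=<base>:<qual>`: compact, whitespace-free, right-parsed.
* Indeterminate start-base calls are excluded from %-Capped on both sides
  (flag `indeterminate_as_encoded` for the conservative alternative).
* %-Capped is written with one decimal place to keep output files
  diff-stable.
* The G'-filter threshold is inclusive (≥), so the 0 row of a threshold
  sweep equals the unfiltered distribution.
* Invasion windows are position-wise (no gaps); offsets are in read-strand
  orientation, making the filter strand-symmetric by construction.
* Peak-mode ties break 5'-most on the read strand; peak intervals are
  [min member position, max member position + 1).
* Even-length median of mode distances takes the lower middle element,
  matching integer medians.
* Quartile windows shorter than 4 nt are skipped and counted.
* Subsampling for saturation curves is per-alignment, without replacement,
  from a seeded generator.
* Defaults everywhere are the documented operating points: barcode ceiling
  3, invasion ceilings 2 mismatches / 2 G-matches over 9 nt at offsets ±3,
  peak cutoff 10 reads, filter threshold 50%, promoter 3000 bp, 3' zone
  1000 bp, TSS window 500 bp, quartile window 100 bp upstream.

## Test and verification scales

The bundled suite runs entirely on simulator output. The default fixture is
two 60 kb contigs, 40 genes, ~2.7 k reads. The cap-signature expectation
(25% of prepended Gs landing on encoded Gs) is measured at 100 000 capped
reads over 200 genes; its sampling error is governed by the ~6 200 distinct
start positions, not the read count. Filter precision/recall are measured on
100-gene, 10 000-read libraries aggregated over four seeds (~380 capped
peaks): precision is 1.0 (uncapped peaks have %-Capped exactly 0 under this
model), recall ≈ 0.96 — structurally below 1 because a peak whose dominant
position sits one base downstream of a genomic G accumulates encoded calls
at that position, the same mechanism that produces the method's estimated
false-negative rate on real data.

## Known limitations

* The single-linkage peak caller is a documented stand-in for the original
  external clustering program; parameterization (`max_gap`) must accompany
  any reported peak sets.
* Gapped alignments are reduced to their aligned span; per-position mismatch
  profiles assume ungapped alignments past position 1.
* "True 5' location" in the false-negative rate (TSS/5'UTR category or mode
  within 500 bp of a TSS) is a documented operational definition.
* Genic categorization requires same-strand genes; antisense transcription
  is not modeled.
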