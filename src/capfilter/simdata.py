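"""Synthetic genomes, annotations and 5'-end reads with ground truth.

The generator emulates the artifact structure of a template-switching
5'-end library so every pipeline stage can be exercised without an aligner
or external data:

* **capped** reads start inside a gene's initiation pattern — a dominant
  mode at the annotated TSS plus dispersed starts over a window of
  ``tss_spread`` nt either side — and, with probability
  ``unencoded_g_probability``, carry a cap-derived G that is not in the
  genome;
* **uncapped_body** reads start uniformly inside gene bodies with no
  prepended base (truncation/recycling background);
* **strand_invasion** reads start at planted loci whose upstream nine bases
  on the read strand equal the TS-oligo tail exactly;
* **rRNA** reads come from a designated rRNA interval.

Every read is emitted three ways, consistently: a raw FASTQ record carrying
the full TS-oligo prefix, a truth SAM record of where the demultiplexed,
first-base-tagged read aligns (template-free extra bases appear as soft
clips), and a truth TSV row with its origin class and true coordinates. All
outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignments import Alignment, write_sam
from .annotate import GeneModel
from .cap_tag import tag_first_base
from .demux import BarcodeSpec, FastqRecord, OligoLayout, write_fastq
from .dna import revcomp
from .genome import ReferenceGenome

BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for one simulated library."""

    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 60000, "chr2": 60000}
    )
    base_probs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # gene structure: 5'UTR, two CDS exons split by one intron, 3'UTR
    n_genes: int = 40
    five_utr_len: int = 150
    cds_exon_len: int = 300
    n_cds_exons: int = 2
    intron_len: int = 120
    three_utr_len: int = 200
    plant_yr: bool = False  # write C at -1 / A at +1 of every TSS
    # artifact loci
    n_invasion_sites: int = 20
    rrna_interval: Tuple[str, int, int] = ("chr2", 500, 1500)
    # per-class read counts
    n_capped: int = 2000
    n_uncapped_body: int = 600
    n_strand_invasion: int = 30
    n_rrna: int = 60
    # cap-signature model
    unencoded_g_probability: float = 1.0
    extra_c_probability: float = 0.0
    # initiation pattern: P(read starts exactly at the TSS) and the uniform
    # half-width of the dispersed remainder
    tss_mode_weight: float = 0.2
    tss_spread: int = 15
    # per-gene expression heterogeneity (log-normal sigma of gene weights)
    expression_sigma: float = 1.0
    read_length: int = 30
    # TS-oligo layout for raw FASTQ emission
    mode: str = "barcoded"
    barcodes: Tuple[Tuple[str, str], ...] = (("S2BPLP", "ATCGTG"),)
    linker: Optional[str] = "GCTATA"
    tail: str = "GGG"

    def __post_init__(self):
        for p in (self.unencoded_g_probability, self.extra_c_probability, self.tss_mode_weight):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.tss_spread < 0:
            raise ValueError("tss_spread must be >= 0")
        for n in (self.n_capped, self.n_uncapped_body, self.n_strand_invasion, self.n_rrna):
            if n < 0:
                raise ValueError("read counts must be >= 0")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")

    @property
    def layout(self) -> OligoLayout:
        if self.mode == "single":
            return OligoLayout(mode="single", tail=self.tail)
        return OligoLayout(
            mode="barcoded",
            barcode_length=len(self.barcodes[0][1]),
            linker=self.linker,
            tail=self.tail,
        )

    @property
    def barcode_specs(self) -> List[BarcodeSpec]:
        return [BarcodeSpec(id=i, sequence=s) for i, s in self.barcodes]

    def oligo_prefix(self, barcode: str = "") -> str:
        if self.mode == "single":
            return self.tail
        return barcode + (self.linker or "") + self.tail

    def oligo_tail9(self, barcode: str = "") -> str:
        return self.oligo_prefix(barcode)[-9:]


@dataclass(frozen=True)
class TruthRecord:
    read_id: str  # tagged qname, as it appears in the truth SAM
    origin: str  # capped | uncapped_body | strand_invasion | rRNA
    gene_id: Optional[str]
    true_tss: Optional[int]
    prepended_unencoded: bool
    chrom: str
    five_prime: int  # 0-based 5' end of the aligned (tagged) read
    strand: str


@dataclass
class SimulatedGenome:
    genome: ReferenceGenome
    genes: List[GeneModel]
    invasion_sites: List[Tuple[str, int, str]]  # (chrom, 5' position, strand)
    rrna_intervals: List[Tuple[str, int, int]]
    config: SimConfig
    # relative expression level per gene (sample property, shared by
    # replicate libraries drawn from this genome)
    gene_weights: List[float] = field(default_factory=list)

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.genome.names:
                fh.write(f">{name}\n")
                seq = self.genome.sequence(name)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.span)):
                lo, hi = g.span
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )
                parts = (
                    [("five_prime_UTR", iv) for iv in g.five_utr]
                    + [("CDS", iv) for iv in g.cds]
                    + [("three_prime_UTR", iv) for iv in g.three_utr]
                )
                for ftype, (s, e) in sorted(parts, key=lambda t: t[1]):
                    fh.write(
                        f"{g.chrom}\tsim\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.{ftype}.{s};Parent={g.gene_id}\n"
                    )

    def write_rrna_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.rrna_intervals:
                fh.write(f"{chrom}\t{s}\t{e}\trRNA\n")


# Reserved low-coordinate region per contig where invasion sites and the
# rRNA locus live; genes are packed after it so artifact reads stay > 3 kb
# from any TSS.
ARTIFACT_ZONE = 4000
EDGE_MARGIN = 200


def simulate_genome(config: SimConfig, seed: int) -> SimulatedGenome:
    """Draw a random genome and pack non-overlapping, strand-balanced genes."""
    rng = np.random.default_rng(seed)
    chroms: Dict[str, list] = {}
    for name, length in config.chrom_lengths.items():
        draws = rng.choice(list(BASES), size=length, p=list(config.base_probs))
        chroms[name] = list(draws)

    span = (
        config.five_utr_len
        + config.n_cds_exons * config.cds_exon_len
        + (config.n_cds_exons - 1) * config.intron_len
        + config.three_utr_len
    )
    names = list(config.chrom_lengths)
    per_chrom = _split_evenly(config.n_genes, len(names))
    genes: List[GeneModel] = []
    gi = 0
    for name, n_here in zip(names, per_chrom):
        usable_start = ARTIFACT_ZONE
        usable_end = config.chrom_lengths[name] - EDGE_MARGIN
        if n_here == 0:
            continue
        slot = (usable_end - usable_start) // n_here
        if slot < span + 2 * EDGE_MARGIN:
            raise ValueError(
                f"infeasible packing: {n_here} genes of span {span} nt do not "
                f"fit on {name} ({usable_end - usable_start} usable nt)"
            )
        for k in range(n_here):
            gi += 1
            slot_start = usable_start + k * slot
            offset = int(rng.integers(EDGE_MARGIN, slot - span - EDGE_MARGIN + 1))
            g0 = slot_start + offset
            strand = "+" if gi % 2 == 1 else "-"
            genes.append(_build_gene(f"gene{gi:04d}", name, strand, g0, span, config))

    if config.plant_yr:
        for g in genes:
            step = 1 if g.strand == "+" else -1
            _set_read_strand_base(chroms[g.chrom], g.tss - step, g.strand, "C")
            _set_read_strand_base(chroms[g.chrom], g.tss, g.strand, "A")

    # plant exact-complement strand-invasion loci inside chr1's artifact zone
    tail9 = config.oligo_tail9(config.barcodes[0][1] if config.mode == "barcoded" else "")
    sites: List[Tuple[str, int, str]] = []
    zone_chrom = names[0]
    lo = EDGE_MARGIN + config.read_length + 10
    hi = ARTIFACT_ZONE - EDGE_MARGIN - config.read_length
    if config.n_invasion_sites > 0:
        if hi <= lo:
            raise ValueError("artifact zone too small for invasion sites")
        positions = np.linspace(lo, hi, config.n_invasion_sites).astype(int)
        for j, p in enumerate(positions):
            p = int(p)
            strand = "+" if j % 2 == 0 else "-"
            seq = chroms[zone_chrom]
            if strand == "+":
                seq[p - 9 : p] = list(tail9)
            else:
                seq[p + 1 : p + 10] = list(revcomp(tail9))
            sites.append((zone_chrom, p, strand))

    genome = ReferenceGenome({name: "".join(seq) for name, seq in chroms.items()})
    weights = list(rng.lognormal(0.0, config.expression_sigma, size=len(genes)))
    return SimulatedGenome(
        genome=genome,
        genes=genes,
        invasion_sites=sites,
        rrna_intervals=[config.rrna_interval],
        config=config,
        gene_weights=weights,
    )


def _split_evenly(n: int, k: int) -> List[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _build_gene(gene_id, chrom, strand, g0, span, config: SimConfig) -> GeneModel:
    """Lay out 5'UTR / CDS exons / introns / 3'UTR inside [g0, g0 + span)."""
    lengths5to3 = [config.five_utr_len]
    for i in range(config.n_cds_exons):
        lengths5to3.append(config.cds_exon_len)
        if i < config.n_cds_exons - 1:
            lengths5to3.append(config.intron_len)
    lengths5to3.append(config.three_utr_len)
    kinds = ["five_utr"] + ["cds", "intron"] * (config.n_cds_exons - 1) + ["cds", "three_utr"]

    if strand == "+":
        tss, gene_end = g0, g0 + span - 1
        cursor = g0
        order = zip(kinds, lengths5to3)
    else:
        tss, gene_end = g0 + span - 1, g0
        cursor = g0
        order = zip(reversed(kinds), reversed(lengths5to3))
    model = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss, gene_end=gene_end)
    for kind, length in order:
        iv = (cursor, cursor + length)
        if kind == "five_utr":
            model.five_utr.append(iv)
        elif kind == "cds":
            model.cds.append(iv)
        elif kind == "three_utr":
            model.three_utr.append(iv)
        cursor += length
    for lst in (model.five_utr, model.cds, model.three_utr):
        lst.sort()
    return model


def _set_read_strand_base(seq: list, pos: int, strand: str, base: str) -> None:
    seq[pos] = base if strand == "+" else revcomp(base)


@dataclass
class SimulatedLibrary:
    fastq: List[FastqRecord]
    truth_alignments: List[Alignment]
    clipped_prefixes: Dict[str, str]
    truth_records: List[TruthRecord]
    config: SimConfig
    barcode_id: Optional[str]

    def write_fastq(self, path: str) -> None:
        with open(path, "w") as fh:
            write_fastq(fh, self.fastq)

    def write_truth_sam(self, path: str, contig_lengths: Dict[str, int]) -> None:
        write_sam(path, self.truth_alignments, contig_lengths, self.clipped_prefixes)

    def write_truth_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "read_id\torigin\tgene_id\ttrue_tss\tprepended_unencoded\t"
                "chrom\tfive_prime\tstrand\n"
            )
            for t in self.truth_records:
                fh.write(
                    f"{t.read_id}\t{t.origin}\t{t.gene_id or 'NA'}\t"
                    f"{'NA' if t.true_tss is None else t.true_tss}\t"
                    f"{int(t.prepended_unencoded)}\t{t.chrom}\t{t.five_prime}\t{t.strand}\n"
                )


def simulate_library(
    sim: SimulatedGenome, config: SimConfig, seed: int
) -> SimulatedLibrary:
    """Draw reads of all configured classes from a simulated genome."""
    rng = np.random.default_rng(seed)
    genome = sim.genome
    rl = config.read_length
    barcode_id, barcode_seq = (None, "")
    if config.mode == "barcoded":
        barcode_id, barcode_seq = config.barcodes[0]
    prefix = config.oligo_prefix(barcode_seq)

    plan: List[Tuple[str, int]] = []
    for origin, n in (
        ("capped", config.n_capped),
        ("uncapped_body", config.n_uncapped_body),
        ("strand_invasion", config.n_strand_invasion),
        ("rRNA", config.n_rrna),
    ):
        plan.extend((origin, i) for i in range(n))

    if config.n_capped + config.n_uncapped_body > 0 and not sim.genes:
        raise ValueError("gene-derived reads requested but the genome has no genes")
    if config.n_strand_invasion > 0 and not sim.invasion_sites:
        raise ValueError("strand-invasion reads requested but no sites were planted")

    fastq: List[FastqRecord] = []
    alns: List[Alignment] = []
    clips: Dict[str, str] = {}
    truth: List[TruthRecord] = []

    gene_p = None
    if sim.genes:
        w = np.asarray(sim.gene_weights if sim.gene_weights else [1.0] * len(sim.genes))
        gene_p = w / w.sum()

    def pick_gene():
        return sim.genes[int(rng.choice(len(sim.genes), p=gene_p))]

    for idx, (origin, _) in enumerate(plan):
        rid = f"r{idx:06d}"
        gene_id = None
        true_tss = None
        prepend = False
        n_extra = 0
        if origin == "capped":
            g = pick_gene()
            gene_id, true_tss = g.gene_id, g.tss
            step = 1 if g.strand == "+" else -1
            if rng.random() < config.tss_mode_weight or config.tss_spread == 0:
                jitter = 0
            else:
                jitter = int(rng.integers(-config.tss_spread, config.tss_spread + 1))
            chrom, five0, strand = g.chrom, g.tss + step * jitter, g.strand
            prepend = bool(rng.random() < config.unencoded_g_probability)
            n_extra = int(rng.random() < config.extra_c_probability)
        elif origin == "uncapped_body":
            g = pick_gene()
            gene_id, true_tss = g.gene_id, g.tss
            lo, hi = g.span
            chrom, strand = g.chrom, g.strand
            five0 = int(rng.integers(lo, hi))
        elif origin == "strand_invasion":
            chrom, five0, strand = sim.invasion_sites[
                int(rng.integers(len(sim.invasion_sites)))
            ]
        else:  # rRNA
            chrom, s, e = config.rrna_interval
            strand = "+" if rng.random() < 0.5 else "-"
            five0 = int(rng.integers(s + rl, e - rl))

        if strand == "+":
            genomic = genome.fetch(chrom, five0, five0 + rl, "+")
        else:
            genomic = genome.fetch(chrom, five0 - rl + 1, five0 + 1, "-")
        if genomic is None:
            raise RuntimeError(f"read at {chrom}:{five0}{strand} leaves the contig")

        raw_seq = prefix + "G" * n_extra + ("G" if prepend else "") + genomic
        fastq.append((rid, raw_seq, "I" * len(raw_seq)))

        trimmed = raw_seq[len(prefix):]
        tagged = tag_first_base((rid, trimmed, "I" * len(trimmed)))
        assert tagged is not None
        n_unencoded_left = max(n_extra + int(prepend) - 1, 0)
        aligned_seq = tagged.sequence[n_unencoded_left:]
        if n_unencoded_left:
            clips[tagged.id] = tagged.sequence[:n_unencoded_left]
        step = 1 if strand == "+" else -1
        five_aligned = five0 if (n_extra + int(prepend)) >= 1 else five0 + step
        start = five_aligned if strand == "+" else five_aligned - len(aligned_seq) + 1
        alns.append(
            Alignment(qname=tagged.id, chrom=chrom, start=start, strand=strand, seq=aligned_seq)
        )
        truth.append(
            TruthRecord(
                read_id=tagged.id,
                origin=origin,
                gene_id=gene_id,
                true_tss=true_tss,
                prepended_unencoded=prepend,
                chrom=chrom,
                five_prime=five_aligned,
                strand=strand,
            )
        )
    return SimulatedLibrary(
        fastq=fastq,
        truth_alignments=alns,
        clipped_prefixes=clips,
        truth_records=truth,
        config=config,
        barcode_id=barcode_id,
    )


def simulate_dataset(config: SimConfig, seed: int, outdir: Optional[str] = None):
    """Genome + one library; optionally write all artifacts and a manifest.

    Seeds for the two stages are derived from ``seed`` so genome and library
    are independently reproducible.
    """
    sim = simulate_genome(config, seed)
    lib = simulate_library(sim, config, seed + 1)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        sim.write_fasta(str(out / "genome.fa"))
        sim.write_gff3(str(out / "annotation.gff3"))
        sim.write_rrna_bed(str(out / "rrna.bed"))
        lib.write_fastq(str(out / "reads.fastq"))
        lib.write_truth_sam(str(out / "truth.sam"), config.chrom_lengths)
        lib.write_truth_tsv(str(out / "truth.tsv"))
        manifest = {
            "seed": seed,
            "config": dataclasses.asdict(config),
            "outputs": [
                "genome.fa", "annotation.gff3", "rrna.bed",
                "reads.fastq", "truth.sam", "truth.tsv",
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return sim, lib
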