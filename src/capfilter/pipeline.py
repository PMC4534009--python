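"""End-to-end pipeline orchestration with a per-stage read ledger.

Stages run in a fixed order — demux, first-base tagging, alignment intake
(an externally produced SAM/BAM of the tagged reads; the bundled simulator's
truth SAM fills this role in tests), start-base classification, strand
invasion filtering, peak calling, G'-filtering, annotation — and every stage
logs how many items went in, came out, and were rejected, so read counts are
conserved from raw FASTQ to final peak table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import annotate as ann
from .alignments import read_sam
from .cap_tag import calls_to_frame, classify_alignments, tag_reads
from .demux import (
    BarcodeSpec,
    OligoLayout,
    demux_reads,
    read_fastq,
    write_demux_report,
    write_fastq,
)
from .genome import ReferenceGenome
from .gfilter import annotate_percent_capped, filtered_peaks_to_frame, g_filter
from .invasion import filter_invasion
from .peaks import call_peaks, five_prime_positions


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the documented operating points."""

    mode: str = "single"
    barcodes: List[List[str]] = field(default_factory=list)  # [[id, seq], ...]
    linker: Optional[str] = None
    tail: str = "GGG"
    max_barcode_mismatch: int = 3
    trim_to: Optional[int] = None
    oligo_tail9: Optional[str] = None  # derived from the layout when None
    invasion_max_mismatch: int = 2
    invasion_min_g_matches: int = 2
    min_reads: int = 10
    max_gap: int = 20
    min_capped_pct: float = 50.0
    promoter_bp: int = 3000
    three_prime_bp: int = 1000
    tss_window: int = 500
    seed: int = 0

    def layout(self) -> OligoLayout:
        if self.mode == "single":
            return OligoLayout(mode="single", tail=self.tail)
        return OligoLayout(
            mode="barcoded",
            barcode_length=len(self.barcodes[0][1]),
            linker=self.linker,
            tail=self.tail,
        )

    def barcode_specs(self) -> List[BarcodeSpec]:
        return [BarcodeSpec(id=i, sequence=s) for i, s in self.barcodes]

    def resolved_tail9(self) -> str:
        if self.oligo_tail9:
            return self.oligo_tail9
        barcode = self.barcodes[0][1] if self.mode == "barcoded" else ""
        return (barcode + (self.linker or "") + self.tail)[-9:]


def run_pipeline(
    config: PipelineConfig,
    fastq_path: str,
    sam_path: str,
    fasta_path: str,
    gff3_path: Optional[str],
    outdir: str,
    rrna_bed: Optional[str] = None,
) -> Dict:
    """Run every stage and write artifacts plus a JSON summary to ``outdir``.

    Inputs are validated before any stage runs; a failing stage raises with
    partial outputs left in place.
    """
    for path, label in (
        (fastq_path, "FASTQ"),
        (sam_path, "SAM/BAM"),
        (fasta_path, "FASTA"),
        (gff3_path, "GFF3"),
        (rrna_bed, "rRNA BED"),
    ):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{label} input not found: {path}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str)
    )
    ledger: List[Dict] = []

    def log(stage: str, n_in: int, n_out: int, detail: Optional[Dict] = None):
        entry = {"stage": stage, "in": n_in, "out": n_out, "rejected": n_in - n_out}
        if detail:
            entry["detail"] = detail
        ledger.append(entry)

    # demux
    with open(fastq_path) as fh:
        raw_reads = read_fastq(fh)
    bins, unassigned, dstats = demux_reads(
        raw_reads,
        config.layout(),
        config.barcode_specs(),
        max_mismatch=config.max_barcode_mismatch,
        trim_to=config.trim_to,
    )
    accepted = [r for reads in bins.values() for r in reads]
    log("demux", len(raw_reads), len(accepted), dict(dstats.per_class))
    write_demux_report(str(out / "demux_report.tsv"), dstats)

    # tag
    tagged, too_short = tag_reads(accepted)
    log("tag", len(accepted), len(tagged), {"too_short": too_short})
    with open(out / "tagged.fastq", "w") as fh:
        write_fastq(fh, [(t.id, t.sequence, t.quality) for t in tagged])

    # alignment intake (external aligner or truth SAM)
    genome = ReferenceGenome.from_fasta(fasta_path)
    alignments = read_sam(sam_path)
    log("align_intake", len(tagged), len(alignments))

    # classification
    calls = classify_alignments(alignments, genome)
    log("classify", len(alignments), len(calls))
    calls_to_frame(calls).to_csv(out / "start_base_calls.tsv", sep="\t", index=False)

    # strand invasion filter
    kept, inv_calls = filter_invasion(
        alignments,
        genome,
        config.resolved_tail9(),
        max_mismatch=config.invasion_max_mismatch,
        min_g_matches=config.invasion_min_g_matches,
    )
    log("invasion_filter", len(alignments), len(kept))

    # peaks + G'-filter
    raw_peaks = call_peaks(five_prime_positions(kept), config.min_reads, config.max_gap)
    with_pct = annotate_percent_capped(raw_peaks, calls)
    filtered = g_filter(with_pct, config.min_capped_pct)
    log("call_peaks", len(kept), len(raw_peaks))
    log("g_filter", len(raw_peaks), len(filtered))
    filtered_peaks_to_frame(with_pct).to_csv(out / "peaks_all.tsv", sep="\t", index=False)
    filtered_peaks_to_frame(filtered).to_csv(out / "peaks_filtered.tsv", sep="\t", index=False)

    # annotation + library metrics
    summary: Dict = {"ledger": ledger}
    categories = []
    if gff3_path:
        genes = ann.load_gene_models(gff3_path)
        categories = ann.categorize_peaks(
            filtered, genes, config.promoter_bp, config.three_prime_bp
        )
        dist = ann.category_distribution(categories)
        quartiles, n_genes_q, _ = ann.quartile_distribution(kept, genes)
        fnr = ann.false_negative_rate(
            with_pct, filtered, genes, config.tss_window,
            config.promoter_bp, config.three_prime_bp,
        )
        matrix, yr, _ = ann.mode_context_matrix(filtered, genome)
        matrix.to_csv(out / "mode_context_matrix.tsv", sep="\t")
        summary["category_distribution"] = dist
        summary["quartile_distribution"] = {str(k): v for k, v in quartiles.items()}
        summary["quartile_genes_counted"] = n_genes_q
        summary["false_negative_rate_pct"] = fnr
        summary["yr"] = yr
    rrna = ann.read_rrna_bed(rrna_bed) if rrna_bed else None
    summary["library_metrics"] = ann.library_metrics(
        len(raw_reads), alignments, categories, rrna
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
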