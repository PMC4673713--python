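"""Genome and annotation model: resolve each gene's 3'UTR cloning locus.

The cloning interval for a gene runs from the first base of its STOP codon
through the annotated 3' end of the longest transcript plus a fixed stretch
of downstream genomic sequence (150 nt by default).  Anchoring the insert at
the STOP codon keeps the cloned 3'UTR in frame with STOP-less ORF clone
collections, and the downstream extension captures 3'-end processing
elements that may lie past the annotated transcript end.

Coordinates are 0-based half-open internally.  GTF/GFF3 input (1-based
closed) is converted on read; BED output is 0-based half-open.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from ._seq import STOP_CODONS, revcomp

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "UtrLocus",
    "DesignFailure",
    "DOWNSTREAM_OFFSET",
    "read_genome",
    "read_annotation",
    "select_longest_transcript",
    "resolve_utr_locus",
    "resolve_utr_loci",
    "extract_interval_sequence",
    "write_loci_bed",
    "write_locus_report",
    "write_failures",
]

#: Default number of genomic bases cloned downstream of the annotated 3' end.
DOWNSTREAM_OFFSET = 150

_VALID_DNA = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: uppercase DNA restricted to the {A,C,G,T,N} alphabet."""

    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptModel:
    """A protein-coding transcript with a resolved CDS end.

    ``cds_end_genomic`` is the boundary of the last CDS base in transcription
    order: on '+' it is the half-open end of the STOP codon, on '-' its
    genomic start.  ``three_prime_end_genomic`` is the transcript's 3'-most
    boundary in the same convention ('+': exon max end, '-': exon min start).
    """

    transcript_id: str
    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_end_genomic: int
    three_prime_end_genomic: int

    @property
    def last_exon(self) -> tuple[int, int]:
        """Exon that is 3'-most in transcription order."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def stop_codon_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.cds_end_genomic - 3, self.cds_end_genomic)
        return (self.cds_end_genomic, self.cds_end_genomic + 3)


@dataclass
class UtrLocus:
    """A gene's resolved cloning interval (STOP codon .. 3' end + offset)."""

    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str
    stop_codon_interval: tuple[int, int]
    last_exon_interval: tuple[int, int]
    insert_interval: tuple[int, int]
    insert_sequence: str

    @property
    def insert_length(self) -> int:
        return self.insert_interval[1] - self.insert_interval[0]

    @property
    def utr_length(self) -> int:
        """Length of the annotated 3'UTR proper (insert minus STOP and offset)."""
        return self.insert_length - 3 - DOWNSTREAM_OFFSET


@dataclass
class DesignFailure:
    """A gene that could not be carried through a pipeline stage.

    Failures are first-class records, never silent skips: every targeted gene
    ends up either in the panel or in a failure sidecar with a reason code.
    """

    gene_id: str
    stage: str
    reason: str
    detail: str = ""


def _open_maybe_gzip(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_genome(path) -> dict[str, GenomeSequence]:
    """Load a FASTA file (plain or gzip) into an indexable contig mapping.

    Sequences are uppercased on load.  Duplicate record IDs and characters
    outside {A,C,G,T,N} are hard errors.
    """
    contigs: dict[str, GenomeSequence] = {}
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in contigs:
                raise ValueError(f"duplicate contig ID {record.id!r} in {path}")
            seq = str(record.seq).upper()
            if not _VALID_DNA.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(
                    f"non-DNA characters {bad} in record {record.id!r}"
                )
            contigs[record.id] = GenomeSequence(record.id, seq)
    return contigs


def extract_interval_sequence(
    genome: dict[str, GenomeSequence], contig_id: str, interval: tuple[int, int],
    strand: str = "+",
) -> str:
    """Sequence of a 0-based half-open interval; '-' returns reverse complement."""
    start, end = interval
    contig = genome[contig_id]
    if start < 0 or end > contig.length or start > end:
        raise ValueError(
            f"interval [{start},{end}) out of bounds for contig "
            f"{contig_id!r} (length {contig.length})"
        )
    seq = contig.sequence[start:end]
    return revcomp(seq) if strand == "-" else seq


def _feature_transcript_id(feature) -> str | None:
    attrs = feature.attributes
    if "transcript_id" in attrs:
        return attrs["transcript_id"][0]
    if "Parent" in attrs:
        return attrs["Parent"][0]
    return None


def _feature_gene_id(feature, db, transcript_parents) -> str | None:
    attrs = feature.attributes
    if "gene_id" in attrs:
        return attrs["gene_id"][0]
    tid = _feature_transcript_id(feature)
    if tid is not None and tid in transcript_parents:
        return transcript_parents[tid]
    return None


def _resolve_stop(strand, cds_intervals, stop_intervals, genome, contig_id):
    """Return (cds_end_genomic, None) or (None, failure_reason)."""
    if stop_intervals:
        if len(stop_intervals) > 1:
            return None, "stop codon split across features"
        s, e = stop_intervals[0]
        if e - s != 3:
            return None, f"stop codon feature of length {e - s}"
        return (e if strand == "+" else s), None
    # No explicit stop_codon feature: derive from the CDS extent.  The last
    # three CDS bases may already be the STOP (GFF3 style) or the STOP may
    # sit just past the CDS (GTF style, stop excluded from CDS).
    contig = genome[contig_id]
    if strand == "+":
        cds_end = max(e for _, e in cds_intervals)
        inside = contig.sequence[cds_end - 3 : cds_end]
        after = contig.sequence[cds_end : cds_end + 3]
        if inside in STOP_CODONS:
            return cds_end, None
        if after in STOP_CODONS:
            return cds_end + 3, None
    else:
        cds_end = min(s for s, _ in cds_intervals)
        inside = revcomp(contig.sequence[cds_end : cds_end + 3])
        before = revcomp(contig.sequence[cds_end - 3 : cds_end])
        if inside in STOP_CODONS:
            return cds_end, None
        if before in STOP_CODONS:
            return cds_end - 3, None
    return None, "unresolvable stop codon"


def read_annotation(
    path_or_text, genome: dict[str, GenomeSequence], *, from_string: bool = False
) -> tuple[list[TranscriptModel], list[DesignFailure]]:
    """Parse GTF or GFF3 into transcript models (one per transcript with CDS).

    1-based closed input coordinates become 0-based half-open.  Transcripts
    with a CDS whose STOP cannot be resolved are returned as design failures,
    not raised.  Features on unknown contigs or out of contig bounds are hard
    errors.
    """
    db = gffutils.create_db(
        str(path_or_text),
        ":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # Map transcript-level features to their gene for GFF3 Parent chains.
    transcript_parents: dict[str, str] = {}
    for ftype in ("transcript", "mRNA"):
        for feat in db.features_of_type(ftype):
            tid = feat.id if "transcript_id" not in feat.attributes else (
                feat.attributes["transcript_id"][0]
            )
            if "gene_id" in feat.attributes:
                transcript_parents[tid] = feat.attributes["gene_id"][0]
            elif "Parent" in feat.attributes:
                transcript_parents[tid] = feat.attributes["Parent"][0]

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    stops: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, contig, strand)

    buckets = {"exon": exons, "CDS": cds, "stop_codon": stops}
    for ftype, bucket in buckets.items():
        for feat in db.features_of_type(ftype):
            tid = _feature_transcript_id(feat)
            if tid is None:
                raise ValueError(f"{ftype} feature without transcript/Parent id")
            gid = _feature_gene_id(feat, db, transcript_parents) or tid
            if feat.seqid not in genome:
                raise ValueError(f"feature on unknown contig {feat.seqid!r}")
            contig_len = genome[feat.seqid].length
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            if start < 0 or end > contig_len:
                raise ValueError(
                    f"feature [{feat.start},{feat.end}] out of bounds on "
                    f"{feat.seqid!r} (length {contig_len})"
                )
            bucket.setdefault(tid, []).append((start, end))
            meta.setdefault(tid, (gid, feat.seqid, feat.strand))

    models: list[TranscriptModel] = []
    failures: list[DesignFailure] = []
    for tid in sorted(cds):  # only transcripts with a CDS
        gid, contig_id, strand = meta[tid]
        exon_list = sorted(exons.get(tid, cds[tid]))
        for (s1, e1), (s2, _) in zip(exon_list, exon_list[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in transcript {tid!r}")
        cds_end, reason = _resolve_stop(
            strand, cds[tid], sorted(stops.get(tid, [])), genome, contig_id
        )
        if cds_end is None:
            failures.append(DesignFailure(gid, "annotation", reason, detail=tid))
            continue
        three_prime = (
            max(e for _, e in exon_list) if strand == "+"
            else min(s for s, _ in exon_list)
        )
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                contig_id=contig_id,
                strand=strand,
                exons=exon_list,
                cds_end_genomic=cds_end,
                three_prime_end_genomic=three_prime,
            )
        )
    return models, failures


def select_longest_transcript(transcripts: list[TranscriptModel]) -> TranscriptModel:
    """Transcript whose 3' end is most distal in the direction of transcription.

    The point of the "longest transcript" rule is to place the downstream
    cloning boundary, so distality of the 3' end (not summed exon length) is
    what is compared.  Ties break on lexicographically smallest transcript_id.
    """
    if not transcripts:
        raise ValueError("no transcripts supplied")
    strand = transcripts[0].strand

    def key(t: TranscriptModel):
        distal = (
            t.three_prime_end_genomic if strand == "+"
            else -t.three_prime_end_genomic
        )
        return (-distal, t.transcript_id)

    return sorted(transcripts, key=key)[0]


def resolve_utr_locus(
    transcripts: list[TranscriptModel],
    genome: dict[str, GenomeSequence],
    downstream_offset: int = DOWNSTREAM_OFFSET,
) -> UtrLocus | DesignFailure:
    """Resolve one gene's cloning locus from its transcripts.

    Chooses the most 3'-distal transcript, requires the STOP codon to lie
    fully within the last exon (genomic PCR needs a contiguous template),
    and extends ``downstream_offset`` bases past the annotated 3' end.
    Failures come back as :class:`DesignFailure` records.
    """
    chosen = select_longest_transcript(transcripts)
    gid = chosen.gene_id
    stop = chosen.stop_codon_interval
    last_exon = chosen.last_exon
    if not (last_exon[0] <= stop[0] and stop[1] <= last_exon[1]):
        return DesignFailure(
            gid, "locus", "stop not in last exon", detail=chosen.transcript_id
        )
    contig = genome[chosen.contig_id]
    if chosen.strand == "+":
        interval = (stop[0], chosen.three_prime_end_genomic + downstream_offset)
        if interval[1] > contig.length:
            return DesignFailure(gid, "locus", "downstream overflow")
    else:
        interval = (chosen.three_prime_end_genomic - downstream_offset, stop[1])
        if interval[0] < 0:
            return DesignFailure(gid, "locus", "downstream overflow")
    seq = extract_interval_sequence(
        genome, chosen.contig_id, interval, chosen.strand
    )
    if seq[:3] not in STOP_CODONS:
        return DesignFailure(
            gid, "locus", f"insert does not begin with a stop codon ({seq[:3]})"
        )
    return UtrLocus(
        gene_id=gid,
        transcript_id=chosen.transcript_id,
        contig_id=chosen.contig_id,
        strand=chosen.strand,
        stop_codon_interval=stop,
        last_exon_interval=last_exon,
        insert_interval=interval,
        insert_sequence=seq,
    )


def resolve_utr_loci(
    models: list[TranscriptModel],
    genome: dict[str, GenomeSequence],
    downstream_offset: int = DOWNSTREAM_OFFSET,
) -> tuple[list[UtrLocus], list[DesignFailure]]:
    """Group transcripts by gene and resolve every gene's locus."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for model in models:
        by_gene.setdefault(model.gene_id, []).append(model)
    loci, failures = [], []
    for gid in sorted(by_gene):
        result = resolve_utr_locus(by_gene[gid], genome, downstream_offset)
        (loci if isinstance(result, UtrLocus) else failures).append(result)
    return loci, failures


def write_loci_bed(loci: list[UtrLocus], path) -> None:
    """BED6: name=gene_id, score=insert_length, strand."""
    with open(path, "w") as out:
        for locus in loci:
            s, e = locus.insert_interval
            out.write(
                f"{locus.contig_id}\t{s}\t{e}\t{locus.gene_id}\t"
                f"{locus.insert_length}\t{locus.strand}\n"
            )


def write_locus_report(loci: list[UtrLocus], path) -> None:
    cols = (
        "gene_id\ttranscript_id\tcontig\tstrand\tinsert_start\tinsert_end\t"
        "insert_length\tutr_length\tstop_start\tstop_end\n"
    )
    with open(path, "w") as out:
        out.write(cols)
        for l in loci:
            out.write(
                f"{l.gene_id}\t{l.transcript_id}\t{l.contig_id}\t{l.strand}\t"
                f"{l.insert_interval[0]}\t{l.insert_interval[1]}\t"
                f"{l.insert_length}\t{l.utr_length}\t"
                f"{l.stop_codon_interval[0]}\t{l.stop_codon_interval[1]}\n"
            )


def write_failures(failures: list[DesignFailure], path) -> None:
    with open(path, "w") as out:
        out.write("gene_id\tstage\treason\tdetail\n")
        for f in failures:
            out.write(f"{f.gene_id}\t{f.stage}\t{f.reason}\t{f.detail}\n")
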