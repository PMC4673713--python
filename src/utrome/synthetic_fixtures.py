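"""Deterministic synthetic fixtures with known truth for the whole pipeline.

Generates mini-genomes whose genes have the anatomy the cloning rules
assume (multi-exon, STOP codon inside the last exon, an annotated 3'UTR,
and intergenic runway downstream of the 3' end), Sanger-like reads off the
expected inserts, and dual-luciferase plate tables with planted repression
ratios.  Every generator is a pure function of its parameters and seed, so
regenerating with the same seed reproduces byte-identical outputs.

These fixtures emulate locus anatomy and assay structure, not human
sequence composition: base composition is uniform, there are no repeats,
no alternative polyadenylation, and noise models are simple (substitution
errors for reads, lognormal multiplicative noise for luminescence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import revcomp
from .genome_model import DOWNSTREAM_OFFSET, GenomeSequence

__all__ = [
    "GeneTruth",
    "GenomeFixture",
    "SangerReadSet",
    "ScreenSim",
    "simulate_genome",
    "mirror_fixture",
    "simulate_sanger_reads",
    "simulate_screen",
    "VECTOR_FLANK_5P",
    "TRIM_FLANK_5P",
    "VECTOR_FLANK_3P",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Synthetic stand-in for the entry-vector context upstream of the cloned
# insert.  The final 30 nt are the published P2rP3 sequencing-primer site;
# the leading spacer is invented.  Reads begin somewhere inside this flank.
VECTOR_FLANK_5P = (
    "CTAGCGTTGAACCAGTCGGCTAAGTTCACCGGTACTTGAC"
    "GCATATGTTGTGTTTTACAGTATTATGTAG"
)
#: Trimming anchor: the part of the 5' flank every read is guaranteed to carry.
TRIM_FLANK_5P = VECTOR_FLANK_5P[-30:]
#: Synthetic downstream vector context (reached only by reads longer than the insert).
VECTOR_FLANK_3P = "GTTAACCTGCAGGACTAGTCCCTTAGGCGCGCCAGTTCGA"

_STOPS = ("TAA", "TAG", "TGA")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@dataclass
class GeneTruth:
    """Generator-side truth for one gene (coordinates 0-based half-open)."""

    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    stop_interval: tuple[int, int]
    three_prime_end: int
    insert_interval: tuple[int, int]
    insert_sequence: str

    @property
    def insert_length(self) -> int:
        return self.insert_interval[1] - self.insert_interval[0]

    @property
    def utr_length(self) -> int:
        return self.insert_length - 3 - DOWNSTREAM_OFFSET


@dataclass
class _Feature:
    ftype: str
    start: int  # 0-based half-open
    end: int
    strand: str
    gene_id: str
    transcript_id: str | None


@dataclass
class GenomeFixture:
    contig_id: str
    genome: dict[str, GenomeSequence]
    truth: list[GeneTruth]
    features: list[_Feature]
    seed: int

    @property
    def fasta_text(self) -> str:
        seq = self.genome[self.contig_id].sequence
        lines = [f">{self.contig_id}"]
        lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
        return "\n".join(lines) + "\n"

    def gtf_text(self, stop_codon_features: bool = True) -> str:
        """Render the annotation as GTF (1-based closed).

        With ``stop_codon_features=False`` the STOP is folded into the CDS
        and no stop_codon lines are emitted, exercising CDS-derived stop
        resolution downstream.
        """
        lines = []
        for f in sorted(self.features, key=lambda f: (f.start, f.end, f.ftype)):
            ftype, start, end = f.ftype, f.start, f.end
            if not stop_codon_features:
                if ftype == "stop_codon":
                    continue
                if ftype == "CDS":
                    # extend the transcription-order last CDS over the STOP
                    stop = next(
                        x for x in self.features
                        if x.ftype == "stop_codon" and x.transcript_id == f.transcript_id
                    )
                    if f.strand == "+" and end == stop.start:
                        end = stop.end
                    elif f.strand == "-" and start == stop.end:
                        start = stop.start
            if f.transcript_id is None:
                attrs = f'gene_id "{f.gene_id}";'
            else:
                attrs = f'gene_id "{f.gene_id}"; transcript_id "{f.transcript_id}";'
            lines.append(
                f"{self.contig_id}\tsim\t{ftype}\t{start + 1}\t{end}\t.\t"
                f"{f.strand}\t.\t{attrs}"
            )
        return "\n".join(lines) + "\n"

    def gff3_text(self) -> str:
        lines = ["##gff-version 3"]
        for f in sorted(self.features, key=lambda f: (f.start, f.end, f.ftype)):
            if f.ftype == "gene":
                attrs = f"ID={f.gene_id}"
            elif f.ftype == "transcript":
                attrs = f"ID={f.transcript_id};Parent={f.gene_id}"
            else:
                attrs = f"Parent={f.transcript_id}"
            ftype = "mRNA" if f.ftype == "transcript" else f.ftype
            lines.append(
                f"{self.contig_id}\tsim\t{ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}"
            )
        return "\n".join(lines) + "\n"

    def write(self, out_dir) -> dict[str, str]:
        import os

        paths = {}
        os.makedirs(out_dir, exist_ok=True)
        for name, text in (
            ("genome.fa", self.fasta_text),
            ("genes.gtf", self.gtf_text()),
            ("genes.gff3", self.gff3_text()),
        ):
            paths[name] = os.path.join(out_dir, name)
            with open(paths[name], "w") as fh:
                fh.write(text)
        truth = pd.DataFrame(
            {
                "gene_id": [t.gene_id for t in self.truth],
                "strand": [t.strand for t in self.truth],
                "insert_start": [t.insert_interval[0] for t in self.truth],
                "insert_end": [t.insert_interval[1] for t in self.truth],
                "insert_length": [t.insert_length for t in self.truth],
                "utr_length": [t.utr_length for t in self.truth],
            }
        )
        paths["truth.tsv"] = os.path.join(out_dir, "truth.tsv")
        truth.to_csv(paths["truth.tsv"], sep="\t", index=False)
        return paths


def simulate_genome(
    n_genes: int = 50,
    seed: int = 0,
    utr_length_range: tuple[int, int] = (150, 3000),
    cds_tail_range: tuple[int, int] = (60, 200),
    first_exon_range: tuple[int, int] = (120, 300),
    intron_range: tuple[int, int] = (80, 200),
    spacer_range: tuple[int, int] = (220, 400),
    minus_strand_fraction: float = 0.5,
    isoform_fraction: float = 0.25,
    contig_id: str = "chrSim",
    max_contig_length: int = 50_000_000,
) -> GenomeFixture:
    """Generate a single-contig mini-genome with annotated genes and truth.

    Each gene has two exons; the last exon carries a coding tail, the STOP
    codon, and the 3'UTR, followed by intergenic runway that always exceeds
    the downstream cloning offset.  ``utr_length_range`` deliberately
    straddles the default 200-2500 nt panel filter so both passing and
    filtered genes exist.  A fraction of genes get a second, 3'-shorter
    isoform so longest-transcript selection is exercised.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if spacer_range[0] <= DOWNSTREAM_OFFSET:
        raise ValueError(
            f"intergenic spacer must exceed the downstream offset ({DOWNSTREAM_OFFSET})"
        )
    rng = np.random.default_rng(seed)
    chunks: list[str] = [_random_dna(rng, 100)]
    offset = 100
    truth: list[GeneTruth] = []
    features: list[_Feature] = []

    for g in range(1, n_genes + 1):
        gid = f"g{g:03d}"
        tid = f"{gid}.t1"
        e1 = int(rng.integers(*first_exon_range))
        i1 = int(rng.integers(*intron_range))
        ct = int(rng.integers(*cds_tail_range))
        utr = int(rng.integers(*utr_length_range))
        stop = _STOPS[rng.integers(0, 3)]
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        with_isoform = rng.random() < isoform_fraction
        utr2 = max(40, utr // 2) if with_isoform else None

        gene_len = e1 + i1 + ct + 3 + utr
        local_seq = (
            _random_dna(rng, e1)
            + _random_dna(rng, i1)
            + _random_dna(rng, ct)
            + stop
            + _random_dna(rng, utr)
        )
        # mRNA-sense downstream runway; placed genomically after a '+' gene
        # and (reverse-complemented) before a '-' gene.
        runway = _random_dna(rng, int(rng.integers(*spacer_range)))
        block = local_seq + runway
        gene_start = offset if strand == "+" else offset + len(runway)

        # mRNA-sense local feature coordinates
        exon1 = (0, e1)
        exon2 = (e1 + i1, gene_len)
        cds1 = (0, e1)
        cds2 = (e1 + i1, e1 + i1 + ct)
        stop_iv = (e1 + i1 + ct, e1 + i1 + ct + 3)

        def put(local_iv, L=gene_len, g0=gene_start):
            s, e = local_iv
            if strand == "+":
                return (g0 + s, g0 + e)
            return (g0 + L - e, g0 + L - s)

        chunks.append(block if strand == "+" else revcomp(block))

        local_feats = [
            ("gene", (0, gene_len), None),
            ("transcript", (0, gene_len), tid),
            ("exon", exon1, tid),
            ("exon", exon2, tid),
            ("CDS", cds1, tid),
            ("CDS", cds2, tid),
            ("stop_codon", stop_iv, tid),
        ]
        if with_isoform:
            tid2 = f"{gid}.t2"
            end2 = e1 + i1 + ct + 3 + utr2
            local_feats += [
                ("transcript", (0, end2), tid2),
                ("exon", exon1, tid2),
                ("exon", (e1 + i1, end2), tid2),
                ("CDS", cds1, tid2),
                ("CDS", cds2, tid2),
                ("stop_codon", stop_iv, tid2),
            ]
        for ftype, iv, t in local_feats:
            s, e = put(iv)
            features.append(_Feature(ftype, s, e, strand, gid, t))

        g_stop = put(stop_iv)
        if strand == "+":
            three_end = gene_start + gene_len
            insert_iv = (g_stop[0], three_end + DOWNSTREAM_OFFSET)
        else:
            three_end = gene_start
            insert_iv = (three_end - DOWNSTREAM_OFFSET, g_stop[1])
        insert_local = local_seq[stop_iv[0] :] + runway[:DOWNSTREAM_OFFSET]
        truth.append(
            GeneTruth(
                gene_id=gid,
                transcript_id=tid,
                contig_id=contig_id,
                strand=strand,
                exons=sorted([put(exon1), put(exon2)]),
                stop_interval=g_stop,
                three_prime_end=three_end,
                insert_interval=insert_iv,
                insert_sequence=insert_local,
            )
        )
        offset += len(block)
        if offset > max_contig_length:
            raise ValueError("infeasible packing: too many genes for contig length")

    sequence = "".join(chunks)
    genome = {contig_id: GenomeSequence(contig_id, sequence)}
    return GenomeFixture(contig_id, genome, truth, features, seed)


def mirror_fixture(fix: GenomeFixture) -> GenomeFixture:
    """Reverse-complement the contig and flip all annotations.

    The mirrored fixture describes the same genes on opposite strands;
    mRNA-sense insert sequences are unchanged, which is the invariant
    strand-aware consumers are tested against.
    """
    length = fix.genome[fix.contig_id].length
    flip_iv = lambda s, e: (length - e, length - s)
    flip_strand = {"+": "-", "-": "+"}
    genome = {
        fix.contig_id: GenomeSequence(
            fix.contig_id, revcomp(fix.genome[fix.contig_id].sequence)
        )
    }
    features = [
        replace(f, start=length - f.end, end=length - f.start,
                strand=flip_strand[f.strand])
        for f in fix.features
    ]
    truth = []
    for t in fix.truth:
        truth.append(
            GeneTruth(
                gene_id=t.gene_id,
                transcript_id=t.transcript_id,
                contig_id=t.contig_id,
                strand=flip_strand[t.strand],
                exons=sorted(flip_iv(*iv) for iv in t.exons),
                stop_interval=flip_iv(*t.stop_interval),
                three_prime_end=length - t.three_prime_end,
                insert_interval=flip_iv(*t.insert_interval),
                insert_sequence=t.insert_sequence,
            )
        )
    return GenomeFixture(fix.contig_id, genome, truth, features, fix.seed)


@dataclass
class SangerReadSet:
    reads: list  # of clone_verification.SangerRead
    manifest: pd.DataFrame  # well, claimed_gene, read_id
    truth: pd.DataFrame  # read_id, true_gene, claimed_gene, swapped, n_errors
    fastq_text: str


def simulate_sanger_reads(
    inserts: dict[str, str],
    seed: int = 0,
    error_rate: float = 0.01,
    read_length: int = 500,
    swap_fraction: float = 0.0,
    reads_per_clone: int = 1,
) -> SangerReadSet:
    """Simulate Sanger-like reads off expected cloned inserts.

    Reads begin at a random offset inside the vector flank, so every read
    carries the trimming anchor followed by the insert 5' end.  Errors are
    iid substitutions at ``error_rate``; positions are recorded in the
    truth table.  ``swap_fraction`` of reads are relabeled to a wrong gene
    (emulating well swaps) and marked in truth.
    """
    from .clone_verification import SangerRead

    if not 0 <= error_rate < 0.2:
        raise ValueError("error_rate must be in [0, 0.2)")
    if read_length < 50:
        raise ValueError("read_length must be >= 50")
    rng = np.random.default_rng(seed)
    genes = sorted(inserts)
    reads: list[SangerRead] = []
    records = []
    fastq_lines = []
    start_span = len(VECTOR_FLANK_5P) - len(TRIM_FLANK_5P)
    idx = 0
    for gene in genes:
        template = VECTOR_FLANK_5P + inserts[gene] + VECTOR_FLANK_3P
        for _ in range(reads_per_clone):
            start = int(rng.integers(0, start_span + 1))
            raw = template[start : start + read_length]
            arr = np.frombuffer(raw.encode(), dtype=np.uint8).copy()
            err_pos = np.nonzero(rng.random(len(arr)) < error_rate)[0]
            for p in err_pos:
                choices = _BASES[_BASES != arr[p]]
                arr[p] = choices[rng.integers(0, len(choices))]
            seq = arr.tobytes().decode()
            idx += 1
            well = f"P{(idx - 1) // 96 + 1:02d}-{chr(65 + ((idx - 1) % 96) // 12)}{(idx - 1) % 12 + 1:02d}"
            read_id = f"read{idx:04d}"
            records.append(
                {
                    "read_id": read_id,
                    "well": well,
                    "true_gene": gene,
                    "claimed_gene": gene,
                    "swapped": False,
                    "n_errors": int(len(err_pos)),
                    "error_positions": ",".join(map(str, err_pos)),
                    "start_offset": start,
                }
            )
            reads.append(SangerRead(well_id=well, claimed_gene_id=gene, sequence=seq))

    n_swaps = int(round(swap_fraction * len(reads)))
    if n_swaps:
        swap_idx = rng.choice(len(reads), size=n_swaps, replace=False)
        for i in swap_idx:
            true = records[i]["true_gene"]
            wrong = genes[(genes.index(true) + 1) % len(genes)]
            if wrong == true:  # single-gene panel: cannot swap
                continue
            records[i]["claimed_gene"] = wrong
            records[i]["swapped"] = True
            reads[i].claimed_gene_id = wrong

    for rec, read in zip(records, reads):
        fastq_lines.append(
            f"@{rec['read_id']}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n"
        )
    truth = pd.DataFrame(records)
    manifest = truth[["well", "claimed_gene", "read_id"]].copy()
    return SangerReadSet(
        reads=reads,
        manifest=manifest,
        truth=truth,
        fastq_text="".join(fastq_lines),
    )


@dataclass
class ScreenSim:
    measurements: pd.DataFrame
    truth: pd.DataFrame  # utr_id, true_ri
    tsv_text: str


def simulate_screen(
    n_utrs: int,
    planted: dict[str, float] | None = None,
    cv: float = 0.10,
    n_replicates: int = 5,
    seed: int = 0,
    query_mirna: str = "miR-sim",
    control_mirna: str = "control",
    baseline_firefly: float = 1.0e5,
    baseline_renilla: float = 2.0e5,
) -> ScreenSim:
    """Simulate a replicate-paired dual-luciferase plate table.

    Query-well firefly signal is baseline x true RI x lognormal noise;
    control wells and all renilla signals are baseline x noise.  The noise
    is multiplicative lognormal with coefficient of variation ``cv`` and
    unit mean, the standard model for luminescence readouts.  UTRs not in
    ``planted`` have true RI 1.0 (null).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if cv <= 0:
        raise ValueError("cv must be positive")
    planted = planted or {}
    if any(ri <= 0 for ri in planted.values()):
        raise ValueError("planted true RI values must be positive")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    mu = -(sigma**2) / 2.0  # unit-mean lognormal

    utr_ids = [f"utr{i + 1:04d}" for i in range(n_utrs)]
    unknown = set(planted) - set(utr_ids)
    if unknown:
        raise ValueError(f"planted UTRs not in screen: {sorted(unknown)}")
    rows = []
    for utr in utr_ids:
        ri = planted.get(utr, 1.0)
        for rep in range(1, n_replicates + 1):
            noise = rng.lognormal(mu, sigma, size=4)
            rows.append(
                {
                    "plate": f"rep{rep}",
                    "well": utr,
                    "utr_id": utr,
                    "mirna_id": query_mirna,
                    "replicate": rep,
                    "firefly": baseline_firefly * ri * noise[0],
                    "renilla": baseline_renilla * noise[1],
                }
            )
            rows.append(
                {
                    "plate": f"rep{rep}",
                    "well": utr,
                    "utr_id": utr,
                    "mirna_id": control_mirna,
                    "replicate": rep,
                    "firefly": baseline_firefly * noise[2],
                    "renilla": baseline_renilla * noise[3],
                }
            )
    measurements = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {"utr_id": utr_ids, "true_ri": [planted.get(u, 1.0) for u in utr_ids]}
    )
    tsv_text = measurements.to_csv(sep="\t", index=False, float_format="%.6f")
    return ScreenSim(measurements=measurements, truth=truth, tsv_text=tsv_text)
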