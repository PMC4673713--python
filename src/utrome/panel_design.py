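"""Gateway-tailed primer panel design for resolved 3'UTR cloning loci.

Forward primer cores are anchored with their 3' terminus on the last base of
the gene's STOP codon and grown 5'-ward (into the coding tail of the last
exon) until the target melting temperature is reached.  Reverse cores have
their outer boundary fixed at the downstream cloning limit (annotated 3' end
+ 150 nt) and grow gene-ward on the opposite strand.  Both cores are then
fused to the fixed Gateway attB2/attB3 recombination tails so the amplicons
can be shuttled into entry vectors.

Melting temperatures use the unified nearest-neighbor thermodynamic model
(50 mM Na+, 500 nM oligo by default) with the Wallace 2(A+T)+4(G+C) rule as
a fallback for very short cores.  Primers whose Tm falls outside the
expected 50-76 degC window are flagged but kept: the touchdown PCR schedule
is designed to accommodate a wide Tm range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from ._seq import revcomp, STOP_CODONS
from .genome_model import (
    DesignFailure,
    GenomeSequence,
    UtrLocus,
    extract_interval_sequence,
)

__all__ = [
    "ATTB2",
    "ATTB3",
    "DesignConfig",
    "PrimerCore",
    "PrimerPair",
    "Panel",
    "melting_temperature",
    "design_primer_cores",
    "attach_gateway_tails",
    "design_panel",
    "write_primer_sheet",
    "write_primer_fasta",
    "PRIMER_SHEET_COLUMNS",
]

#: Gateway attB2 recombination tail prepended to every forward primer (28 nt).
ATTB2 = "GGGGACAGCTTTCTTGTACAAAGTGGAG"
#: Gateway attB3 recombination tail prepended to every reverse primer (26 nt).
ATTB3 = "GGGGACAACTTTGTATAATAAAGTTG"


@dataclass
class DesignConfig:
    """Tunable panel-design parameters.

    target_tm: growth stops at the first core length reaching this Tm.
    tm_window: Tm range outside which a core is flagged (not rejected).
    min_len/max_len: core length bounds in nt.
    downstream_offset: bases cloned past the annotated 3' end.
    panel_length_filter: accepted cloning-insert length range in nt.
    """

    target_tm: float = 60.0
    tm_window: tuple[float, float] = (50.0, 76.0)
    min_len: int = 18
    max_len: int = 35
    downstream_offset: int = 150
    panel_length_filter: tuple[int, int] = (200, 2500)
    tm_model: str = "nearest_neighbor"
    salt_molar: float = 0.05
    oligo_molar: float = 500e-9

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.tm_window[0] >= self.tm_window[1]:
            raise ValueError("tm_window low must be < high")


@dataclass
class PrimerCore:
    """A genome-annealing primer core as synthesized, 5'->3'."""

    sequence_5to3: str
    genomic_interval: tuple[int, int]
    strand_of_annealing: str
    tm_celsius: float

    @property
    def length(self) -> int:
        return len(self.sequence_5to3)


@dataclass
class PrimerPair:
    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str
    forward: PrimerCore
    reverse: PrimerCore
    expected_insert_length: int
    forward_tailed: str | None = None
    reverse_tailed: str | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class Panel:
    pairs: list[PrimerPair]
    failures: list[DesignFailure]


def melting_temperature(
    core: str,
    model: str = "auto",
    salt_molar: float = 0.05,
    oligo_molar: float = 500e-9,
) -> float:
    """Melting temperature of a primer core in degrees Celsius.

    ``model`` is ``nearest_neighbor`` (unified NN parameters with the
    entropic salt correction), ``wallace`` (2(A+T)+4(G+C)), or ``auto``
    which uses nearest-neighbor at length >= 14 and Wallace below.  The two
    strand concentrations are each half of ``oligo_molar`` so the effective
    duplex concentration is the standard C_T/4.
    """
    if len(core) < 2:
        raise ValueError("primer core must be at least 2 nt")
    core = core.upper()
    if "N" in core or set(core) - set("ACGT"):
        raise ValueError(f"primer core contains non-ACGT characters: {core}")
    if model == "auto":
        model = "nearest_neighbor" if len(core) >= 14 else "wallace"
    if model == "wallace":
        return float(_mt.Tm_Wallace(core))
    if model == "nearest_neighbor":
        half_nM = oligo_molar * 1e9 / 2.0
        return float(
            _mt.Tm_NN(
                core,
                nn_table=_mt.DNA_NN3,
                Na=salt_molar * 1e3,
                dnac1=half_nM,
                dnac2=half_nM,
                saltcorr=5,
            )
        )
    raise ValueError(f"unknown Tm model {model!r}")


def _grow_core(
    fetch, max_len: int, min_len: int, config: DesignConfig
) -> tuple[str, float] | str:
    """Grow a core from min_len until Tm >= target; returns (seq, tm) or reason.

    ``fetch(L)`` returns the candidate core of length L as synthesized.
    Growth never extends into an N; an N inside the mandatory min_len window
    is a failure.
    """
    if max_len < min_len:
        return "insufficient runway"
    if "N" in fetch(min_len):
        return "N in primer core"
    best = None
    for length in range(min_len, max_len + 1):
        seq = fetch(length)
        if "N" in seq:
            break  # stop growing before the ambiguity
        tm = melting_temperature(
            seq, "auto" if config.tm_model == "nearest_neighbor" else config.tm_model,
            config.salt_molar, config.oligo_molar,
        )
        best = (seq, tm)
        if tm >= config.target_tm:
            break
    return best


def design_primer_cores(
    locus: UtrLocus, genome: dict[str, GenomeSequence], config: DesignConfig | None = None
) -> PrimerPair | DesignFailure:
    """Design untailed forward/reverse cores for one locus.

    The forward core's 3' terminus is the last base of the STOP codon and
    the core must stay within the last exon.  The reverse core's outer
    boundary is the downstream end of the cloning insert; it grows gene-ward
    along the opposite strand.  Cores with Tm outside the configured window
    are flagged ``low-Tm``/``high-Tm`` but retained.
    """
    config = config or DesignConfig()
    contig, strand = locus.contig_id, locus.strand
    stop = locus.stop_codon_interval
    exon = locus.last_exon_interval
    ins = locus.insert_interval
    flags: list[str] = []

    if strand == "+":
        runway = stop[1] - exon[0]
        fwd_fetch = lambda L: extract_interval_sequence(
            genome, contig, (stop[1] - L, stop[1]), "+"
        )
        rev_fetch = lambda L: extract_interval_sequence(
            genome, contig, (ins[1] - L, ins[1]), "-"
        )
    else:
        runway = exon[1] - stop[0]
        fwd_fetch = lambda L: extract_interval_sequence(
            genome, contig, (stop[0], stop[0] + L), "-"
        )
        rev_fetch = lambda L: extract_interval_sequence(
            genome, contig, (ins[0], ins[0] + L), "+"
        )

    if min(config.max_len, runway) < config.min_len:
        return DesignFailure(
            locus.gene_id, "primer", "stop too close to exon start"
        )
    fwd = _grow_core(fwd_fetch, min(config.max_len, runway), config.min_len, config)
    if isinstance(fwd, str):
        return DesignFailure(locus.gene_id, "primer", fwd, detail="forward")
    rev_cap = min(config.max_len, locus.insert_length)
    rev = _grow_core(rev_fetch, rev_cap, config.min_len, config)
    if isinstance(rev, str):
        return DesignFailure(locus.gene_id, "primer", rev, detail="reverse")

    (fwd_seq, fwd_tm), (rev_seq, rev_tm) = fwd, rev
    assert fwd_seq[-3:] in STOP_CODONS
    lo, hi = config.tm_window
    for name, tm in (("F", fwd_tm), ("R", rev_tm)):
        if tm < lo:
            flags.append(f"low-Tm:{name}")
        elif tm > hi:
            flags.append(f"high-Tm:{name}")

    if strand == "+":
        fwd_iv = (stop[1] - len(fwd_seq), stop[1])
        rev_iv = (ins[1] - len(rev_seq), ins[1])
        fwd_strand, rev_strand = "+", "-"
    else:
        fwd_iv = (stop[0], stop[0] + len(fwd_seq))
        rev_iv = (ins[0], ins[0] + len(rev_seq))
        fwd_strand, rev_strand = "-", "+"

    return PrimerPair(
        gene_id=locus.gene_id,
        transcript_id=locus.transcript_id,
        contig_id=contig,
        strand=strand,
        forward=PrimerCore(fwd_seq, fwd_iv, fwd_strand, fwd_tm),
        reverse=PrimerCore(rev_seq, rev_iv, rev_strand, rev_tm),
        expected_insert_length=locus.insert_length,
        flags=flags,
    )


def attach_gateway_tails(pair: PrimerPair) -> PrimerPair:
    """Fuse the attB2/attB3 recombination tails onto the primer cores."""
    if pair.forward_tailed is not None or pair.reverse_tailed is not None:
        raise ValueError(f"double tailing of pair {pair.gene_id!r}")
    if pair.forward.sequence_5to3.startswith(ATTB2) or (
        pair.reverse.sequence_5to3.startswith(ATTB3)
    ):
        raise ValueError(f"core of pair {pair.gene_id!r} already carries a tail")
    pair.forward_tailed = ATTB2 + pair.forward.sequence_5to3
    pair.reverse_tailed = ATTB3 + pair.reverse.sequence_5to3
    return pair


def design_panel(
    loci: list[UtrLocus],
    genome: dict[str, GenomeSequence],
    config: DesignConfig | None = None,
) -> Panel:
    """Design tailed primer pairs for every locus passing the length filter."""
    if not loci:
        raise ValueError("empty locus set")
    config = config or DesignConfig()
    lo, hi = config.panel_length_filter
    pairs: list[PrimerPair] = []
    failures: list[DesignFailure] = []
    for locus in loci:
        if not (lo <= locus.insert_length <= hi):
            failures.append(
                DesignFailure(
                    locus.gene_id, "panel", "length filter",
                    detail=str(locus.insert_length),
                )
            )
            continue
        result = design_primer_cores(locus, genome, config)
        if isinstance(result, DesignFailure):
            failures.append(result)
            continue
        pairs.append(attach_gateway_tails(result))
    return Panel(pairs=pairs, failures=failures)


PRIMER_SHEET_COLUMNS = [
    "gene_id", "transcript_id", "contig", "strand",
    "forward_tailed", "reverse_tailed", "tm_f", "tm_r",
    "expected_insert_length", "flags",
]


def write_primer_sheet(panel: Panel, path) -> None:
    """Write the panel as a TSV with a stable column order (deterministic)."""
    with open(path, "w") as out:
        out.write("\t".join(PRIMER_SHEET_COLUMNS) + "\n")
        for p in panel.pairs:
            out.write(
                f"{p.gene_id}\t{p.transcript_id}\t{p.contig_id}\t{p.strand}\t"
                f"{p.forward_tailed}\t{p.reverse_tailed}\t"
                f"{p.forward.tm_celsius:.2f}\t{p.reverse.tm_celsius:.2f}\t"
                f"{p.expected_insert_length}\t{';'.join(p.flags)}\n"
            )


def write_primer_fasta(panel: Panel, path) -> None:
    with open(path, "w") as out:
        for p in panel.pairs:
            out.write(f">{p.gene_id}.F\n{p.forward_tailed}\n")
            out.write(f">{p.gene_id}.R\n{p.reverse_tailed}\n")
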