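"""Touchdown PCR schedule, in-silico amplicon prediction, and size screening.

The touchdown program lowers the annealing temperature by a fixed step each
cycle so that stringent early cycles favor specific priming across a panel
whose primer Tms span a wide range, then holds a permissive constant
temperature.  Amplicon prediction finds convergent primer binding sites on
the genome and reports the predicted cloning product: the attB2 tail, the
genomic span from the forward core's 3'-terminal codon through the reverse
core's outer boundary (for designed pairs, exactly the STOP..+150 insert),
and the reverse-complemented attB3 tail, all in mRNA sense.  Size screening
mimics the gel-electrophoresis check of products against expected lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp
from .genome_model import GenomeSequence
from .panel_design import ATTB2, ATTB3, PrimerPair

__all__ = [
    "TouchdownSchedule",
    "AmpliconPrediction",
    "SizeScreenResult",
    "build_touchdown_schedule",
    "find_binding_sites",
    "predict_amplicons",
    "size_screen",
    "DEFAULT_SCHEDULE",
]


@dataclass(frozen=True)
class TouchdownSchedule:
    """Annealing-temperature program: touchdown phase then constant phase."""

    touchdown_phase: tuple[float, ...]
    constant_phase: tuple[float, int]

    @property
    def total_cycles(self) -> int:
        return len(self.touchdown_phase) + self.constant_phase[1]

    def annealing_temperatures(self) -> list[float]:
        temp, cycles = self.constant_phase
        return list(self.touchdown_phase) + [temp] * cycles


def build_touchdown_schedule(
    start_c: float = 66.0,
    floor_c: float = 50.0,
    step_c: float = 1.0,
    constant_c: float = 55.0,
    constant_cycles: int = 15,
) -> TouchdownSchedule:
    """Enumerate the touchdown phase from ``start_c`` down to, but excluding,
    ``floor_c`` in steps of ``step_c``, then append the constant phase.

    The floor-exclusive convention makes a 66->50 degC, 1 degC/cycle program
    span exactly 16 cycles (66..51).
    """
    if step_c <= 0:
        raise ValueError("step_c must be positive")
    if start_c < floor_c:
        raise ValueError("start_c must be >= floor_c")
    temps = []
    t = start_c
    while t > floor_c:
        temps.append(t)
        t -= step_c
    return TouchdownSchedule(tuple(temps), (constant_c, constant_cycles))


DEFAULT_SCHEDULE = build_touchdown_schedule()


@dataclass
class BindingSite:
    contig_id: str
    interval: tuple[int, int]
    extends: str  # '+' rightward (matches sense strand), '-' leftward
    mismatches: int


@dataclass
class AmpliconPrediction:
    gene_id: str
    contig_id: str
    product_interval: tuple[int, int]
    product_sequence: str
    forward_site: BindingSite
    reverse_site: BindingSite
    first_productive_cycle: int | None
    ambiguity: int = 0

    @property
    def product_length(self) -> int:
        return len(self.product_sequence)


@dataclass
class SizeScreenResult:
    gene_id: str
    expected_length: int
    observed_length: int
    relative_error: float
    verdict: str  # 'pass' | 'fail'


def _exact_occurrences(pattern: str, text: str) -> list[int]:
    hits, i = [], text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def _mismatch_occurrences(
    pattern: str, text: str, max_mismatches: int, exact_suffix: slice
) -> list[tuple[int, int]]:
    """Positions where pattern matches text with <= max_mismatches and the
    3'-terminal region (``exact_suffix`` in pattern coordinates) is exact."""
    import numpy as np

    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    L = len(p)
    if len(t) < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    mism = (windows != p).sum(axis=1)
    exact = (windows[:, exact_suffix] != p[exact_suffix]).sum(axis=1) == 0
    pos = np.nonzero((mism <= max_mismatches) & exact)[0]
    return [(int(i), int(mism[i])) for i in pos]


def find_binding_sites(
    core: str, genome: dict[str, GenomeSequence], max_mismatches: int = 0
) -> list[BindingSite]:
    """All genomic sites where a primer core can anneal and extend.

    A site matching the sense strand extends rightward ('+'); a site whose
    reverse complement matches extends leftward ('-').  When internal
    mismatches are allowed, the 5 bases at the primer's 3' terminus must
    still match exactly -- polymerase extension requires a paired 3' end.
    """
    sites: list[BindingSite] = []
    rc = revcomp(core)
    L = len(core)
    for contig_id, contig in genome.items():
        text = contig.sequence
        if max_mismatches <= 0:
            for i in _exact_occurrences(core, text):
                sites.append(BindingSite(contig_id, (i, i + L), "+", 0))
            for i in _exact_occurrences(rc, text):
                sites.append(BindingSite(contig_id, (i, i + L), "-", 0))
        else:
            # 3' terminus: last 5 bases of core => last 5 of '+' pattern,
            # first 5 of the revcomp pattern.
            for i, mm in _mismatch_occurrences(
                core, text, max_mismatches, slice(L - 5, L)
            ):
                sites.append(BindingSite(contig_id, (i, i + L), "+", mm))
            for i, mm in _mismatch_occurrences(
                rc, text, max_mismatches, slice(0, 5)
            ):
                sites.append(BindingSite(contig_id, (i, i + L), "-", mm))
    return sites


def first_productive_cycle(
    tm_forward: float, tm_reverse: float, schedule: TouchdownSchedule
) -> int | None:
    """1-based index of the first cycle whose annealing temperature both
    primer Tms meet or exceed; None if no cycle is productive."""
    tm = min(tm_forward, tm_reverse)
    for i, temp in enumerate(schedule.annealing_temperatures(), start=1):
        if tm >= temp:
            return i
    return None


def predict_amplicons(
    pair: PrimerPair,
    genome: dict[str, GenomeSequence],
    schedule: TouchdownSchedule = DEFAULT_SCHEDULE,
    max_product: int = 5000,
    max_mismatches: int = 0,
) -> list[AmpliconPrediction]:
    """Predict all products of a primer pair against a genome.

    Convergent forward/reverse site pairings within ``max_product`` are
    enumerated; single-primer (F/F or R/R) products are not modeled.  The
    reported product is the cloning insert with both attB tails: it is
    anchored at the forward core's 3'-terminal codon, so its length is
    insert length + 54 for pairs binding uniquely at their design sites.
    """
    f_sites = find_binding_sites(pair.forward.sequence_5to3, genome, max_mismatches)
    r_sites = find_binding_sites(pair.reverse.sequence_5to3, genome, max_mismatches)
    cycle = first_productive_cycle(
        pair.forward.tm_celsius, pair.reverse.tm_celsius, schedule
    )
    products: list[AmpliconPrediction] = []
    for fs in f_sites:
        for rs in r_sites:
            if fs.contig_id != rs.contig_id or fs.extends == rs.extends:
                continue
            right, left = (fs, rs) if fs.extends == "+" else (rs, fs)
            if left.interval[1] <= right.interval[1]:
                continue  # not convergent
            if left.interval[1] - right.interval[0] > max_product:
                continue
            contig_seq = genome[fs.contig_id].sequence
            if fs.extends == "+":
                # '+'-sense product: forward terminal codon .. reverse outer end
                span = (fs.interval[1] - 3, rs.interval[1])
                insert = contig_seq[span[0] : span[1]]
            else:
                # '-'-sense product: reverse outer start .. forward terminal codon
                span = (rs.interval[0], fs.interval[0] + 3)
                insert = revcomp(contig_seq[span[0] : span[1]])
            products.append(
                AmpliconPrediction(
                    gene_id=pair.gene_id,
                    contig_id=fs.contig_id,
                    product_interval=span,
                    product_sequence=ATTB2 + insert + revcomp(ATTB3),
                    forward_site=fs,
                    reverse_site=rs,
                    first_productive_cycle=cycle,
                )
            )
    ambiguity = len(products) - 1
    for p in products:
        p.ambiguity = ambiguity
    return products


def size_screen(
    expected: int, observed: int, tolerance: float = 0.15, gene_id: str = ""
) -> SizeScreenResult:
    """Gel-style size check: pass iff |observed-expected|/expected <= tolerance."""
    if expected <= 0:
        raise ValueError("expected length must be positive")
    if observed < 0:
        raise ValueError("observed length must be non-negative")
    rel = abs(observed - expected) / expected
    return SizeScreenResult(
        gene_id=gene_id,
        expected_length=expected,
        observed_length=observed,
        relative_error=rel,
        verdict="pass" if rel <= tolerance else "fail",
    )
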