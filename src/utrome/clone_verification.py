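"""Sanger-read clone verification by seeded (BLAT-style) local alignment.

Each sequencing read carries a claimed gene identity from its plate well.
After trimming the vector flank, reads are aligned against the panel of
expected insert sequences: shared k-mers nominate candidate references and
the dominant seed diagonal positions a banded affine-gap local alignment
(match +1, mismatch -1, gap open -2, gap extend -1).  A clone is verified
when its best hit is the claimed gene at high identity and coverage with a
clear score margin over the runner-up; a confident best hit on a different
gene is a misassignment (well swap); low-quality alignments are sequence
failures.  Two-pass bookkeeping splits the panel into verified genes and a
re-array list for a second round of cloning.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "SangerRead",
    "AlignmentHit",
    "VerificationCall",
    "VerifyThresholds",
    "PanelIndex",
    "trim_read",
    "seeded_align",
    "verify_clone",
    "pass_bookkeeping",
    "read_fasta_or_fastq_reads",
]

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@dataclass
class SangerRead:
    well_id: str
    claimed_gene_id: str
    sequence: str
    qualities: list[int] | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class AlignmentHit:
    target_gene_id: str
    score: float
    identity: float
    read_coverage: float
    target_span: tuple[int, int]


@dataclass
class VerificationCall:
    well_id: str
    claimed_gene_id: str
    best_hit: AlignmentHit | None
    verdict: str  # verified | misassigned | sequence_fail | no_hit
    evidence: str


@dataclass(frozen=True)
class VerifyThresholds:
    """Acceptance thresholds tuned for Sanger-quality reads."""

    min_identity: float = 0.95
    min_read_coverage: float = 0.90
    min_score_margin: float = 0.10  # (best - second) / best


NEG_INF = np.float32(-1e9)


@njit(cache=False)
def _banded_sw(read, ref, d0, w, match, mismatch, gap_open, gap_ext):
    """Banded local alignment with affine gaps (Gotoh).

    Cells (i=1..n read, j ref) with |(j - i) - d0| <= w are computed.
    Returns (best_score, read_start, read_end, ref_start, ref_end,
    n_match, n_columns) for the best-scoring local path; starts/ends are
    0-based half-open on both sequences.
    """
    n = read.shape[0]
    m = ref.shape[0]
    width = 2 * w + 1
    H = np.full((n + 1, width), NEG_INF, dtype=np.float32)
    E = np.full((n + 1, width), NEG_INF, dtype=np.float32)
    F = np.full((n + 1, width), NEG_INF, dtype=np.float32)
    # H[i, k] is cell (i, j) with j = i + d0 + (k - w)
    for k in range(width):
        j0 = 0 + d0 + (k - w)
        if 0 <= j0 <= m:
            H[0, k] = 0.0
    best = np.float32(0.0)
    bi = 0
    bk = 0
    for i in range(1, n + 1):
        for k in range(width):
            j = i + d0 + (k - w)
            if j < 0 or j > m:
                continue
            h = np.float32(0.0)
            if j >= 1:
                # diagonal: (i-1, j-1) is same k at row i-1
                hd = H[i - 1, k]
                if hd > NEG_INF / 2:
                    s = match if read[i - 1] == ref[j - 1] and read[i - 1] != 4 else mismatch
                    if hd + s > h:
                        h = hd + s
                # E: gap in read (consume ref base, j-1 -> k-1)
                if k >= 1:
                    e1 = E[i, k - 1] - gap_ext
                    e2 = H[i, k - 1] - gap_open
                    e = e1 if e1 > e2 else e2
                    E[i, k] = e
                    if e > h:
                        h = e
            # F: gap in ref (consume read base, from row i-1, k+1)
            if k + 1 < width:
                f1 = F[i - 1, k + 1] - gap_ext
                f2 = H[i - 1, k + 1] - gap_open
                f = f1 if f1 > f2 else f2
                F[i, k] = f
                if f > h:
                    h = f
            H[i, k] = h
            if h > best:
                best = h
                bi = i
                bk = k
    # Traceback from the best cell.
    n_match = 0
    n_cols = 0
    i = bi
    k = bk
    read_end = bi
    ref_end = bi + d0 + (bk - w)
    state = 0  # 0=H, 1=E, 2=F
    while i > 0:
        j = i + d0 + (k - w)
        if state == 0:
            if H[i, k] <= 0.0:
                break
            # which move produced H[i,k]?
            s = match if j >= 1 and read[i - 1] == ref[j - 1] and read[i - 1] != 4 else mismatch
            if j >= 1 and H[i - 1, k] > NEG_INF / 2 and H[i, k] == H[i - 1, k] + s:
                n_cols += 1
                if read[i - 1] == ref[j - 1] and read[i - 1] != 4:
                    n_match += 1
                i -= 1
                continue
            if j >= 1 and k >= 1 and H[i, k] == E[i, k]:
                state = 1
                continue
            state = 2
            continue
        elif state == 1:
            # gap in read: consumed ref base j
            n_cols += 1
            if E[i, k] == H[i, k - 1] - gap_open:
                state = 0
            k -= 1
            continue
        else:
            # gap in ref: consumed read base i
            n_cols += 1
            if F[i, k] == H[i - 1, k + 1] - gap_open:
                state = 0
            i -= 1
            k += 1
            continue
    read_start = i
    ref_start = i + d0 + (k - w)
    return best, read_start, read_end, ref_start, ref_end, n_match, n_cols


class PanelIndex:
    """k-mer index over the panel's expected insert sequences."""

    def __init__(self, references: dict[str, str], k: int = 11):
        if not references:
            raise ValueError("panel is empty")
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.k = k
        self.ids = sorted(references)
        self.seqs = {gid: references[gid].upper() for gid in self.ids}
        self._encoded = {gid: _encode(self.seqs[gid]) for gid in self.ids}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for gid in self.ids:
            seq = self.seqs[gid]
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((gid, pos))


def seeded_align(
    read: str,
    panel: "PanelIndex | dict[str, str]",
    k: int = 11,
    band: int = 32,
    top_candidates: int = 5,
    min_identity: float = 0.5,
) -> list[AlignmentHit]:
    """Rank panel references against a read, BLAT-style.

    Candidate references are nominated by the count of shared k-mers on
    their best diagonal, then re-scored with a banded local alignment
    centered on that diagonal.  Hits below ``min_identity`` over aligned
    columns are discarded.  Ordering is deterministic: score descending,
    then target id.
    """
    if not isinstance(panel, PanelIndex):
        panel = PanelIndex(panel, k=k)
    read = read.upper()
    if len(read) < panel.k:
        return []
    diag_counts: Counter = Counter()
    for pos in range(len(read) - panel.k + 1):
        for gid, ref_pos in panel.index.get(read[pos : pos + panel.k], ()):
            diag_counts[(gid, ref_pos - pos)] += 1
    if not diag_counts:
        return []
    best_diag: dict[str, tuple[int, int]] = {}
    for (gid, diag), count in diag_counts.items():
        if gid not in best_diag or count > best_diag[gid][0]:
            best_diag[gid] = (count, diag)
    candidates = sorted(
        best_diag, key=lambda g: (-best_diag[g][0], g)
    )[:top_candidates]

    read_arr = _encode(read)
    hits: list[AlignmentHit] = []
    for gid in candidates:
        _, d0 = best_diag[gid]
        score, rs, re_, ts, te, n_match, n_cols = _banded_sw(
            read_arr, panel._encoded[gid], d0, band,
            np.float32(1.0), np.float32(-1.0), np.float32(2.0), np.float32(1.0),
        )
        if score <= 0 or n_cols == 0:
            continue
        identity = n_match / n_cols
        coverage = (re_ - rs) / len(read)
        if identity < min_identity:
            continue
        hits.append(
            AlignmentHit(
                target_gene_id=gid,
                score=float(score),
                identity=identity,
                read_coverage=coverage,
                target_span=(int(ts), int(te)),
            )
        )
    hits.sort(key=lambda h: (-h.score, h.target_gene_id))
    return hits


def _find_approx(read: str, flank: str, max_mismatches: int = 2) -> int:
    """Leftmost start of an occurrence of flank in read with <= max_mismatches
    substitutions, or -1."""
    L = len(flank)
    if L == 0 or len(read) < L:
        return -1
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    f = np.frombuffer(flank.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(r, L)
    mism = (windows != f).sum(axis=1)
    pos = np.nonzero(mism <= max_mismatches)[0]
    return int(pos[0]) if pos.size else -1


def trim_read(
    read: SangerRead,
    vector_flank_5p: str,
    vector_flank_3p: str = "",
    quality_floor: int | None = None,
    max_mismatches: int = 2,
) -> SangerRead:
    """Remove leading/trailing vector sequence and low-quality tails.

    The 5' flank is located allowing up to ``max_mismatches`` substitutions
    and removed together with everything before it.  A read without a
    recognizable flank passes through untrimmed with a ``no-flank`` flag.
    """
    seq = read.sequence.upper()
    quals = list(read.qualities) if read.qualities is not None else None
    flags = list(read.flags)
    pos = _find_approx(seq, vector_flank_5p.upper(), max_mismatches)
    if pos >= 0:
        cut = pos + len(vector_flank_5p)
        seq = seq[cut:]
        if quals is not None:
            quals = quals[cut:]
    else:
        flags.append("no-flank")
    if vector_flank_3p:
        pos3 = _find_approx(seq, vector_flank_3p.upper(), max_mismatches)
        if pos3 >= 0:
            seq = seq[:pos3]
            if quals is not None:
                quals = quals[:pos3]
    if quality_floor is not None and quals:
        end = len(quals)
        while end > 0 and quals[end - 1] < quality_floor:
            end -= 1
        seq, quals = seq[:end], quals[:end]
    return replace(read, sequence=seq, qualities=quals, flags=flags)


def verify_clone(
    read: SangerRead,
    claimed_gene_id: str,
    panel: "PanelIndex | dict[str, str]",
    thresholds: VerifyThresholds = VerifyThresholds(),
) -> VerificationCall:
    """Decide verified / misassigned / sequence_fail / no_hit for one read."""
    hits = seeded_align(read.sequence, panel)
    if not hits:
        return VerificationCall(
            read.well_id, claimed_gene_id, None, "no_hit", "no alignment to panel"
        )
    best = hits[0]
    margin_ok = (
        len(hits) == 1
        or (best.score - hits[1].score) / best.score >= thresholds.min_score_margin
    )
    thresholds_met = (
        best.identity >= thresholds.min_identity
        and best.read_coverage >= thresholds.min_read_coverage
        and margin_ok
    )
    if thresholds_met and best.target_gene_id == claimed_gene_id:
        verdict, evidence = "verified", (
            f"best hit {best.target_gene_id} identity {best.identity:.3f} "
            f"coverage {best.read_coverage:.3f}"
        )
    elif thresholds_met:
        verdict, evidence = "misassigned", (
            f"read matches {best.target_gene_id}, not claimed {claimed_gene_id}"
        )
    else:
        verdict, evidence = "sequence_fail", (
            f"best hit {best.target_gene_id} below thresholds "
            f"(identity {best.identity:.3f}, coverage {best.read_coverage:.3f}, "
            f"margin_ok {margin_ok})"
        )
    return VerificationCall(read.well_id, claimed_gene_id, best, verdict, evidence)


@dataclass
class PassBookkeeping:
    verified_genes: set[str]
    second_pass_genes: list[str]
    counts: dict[str, int]


def pass_bookkeeping(
    calls: list[VerificationCall], panel_genes: list[str]
) -> PassBookkeeping:
    """Split the panel into first-pass verified genes and a second-pass list.

    One verified well suffices per gene (a verified call takes precedence
    over any other verdict for the same gene).  The second-pass list keeps
    panel order and names every gene without a verified call.
    """
    counts = Counter(c.verdict for c in calls)
    verified = {
        c.claimed_gene_id for c in calls if c.verdict == "verified"
    }
    second = [g for g in panel_genes if g not in verified]
    return PassBookkeeping(
        verified_genes=verified,
        second_pass_genes=second,
        counts=dict(counts),
    )


def read_fasta_or_fastq_reads(path) -> dict[str, tuple[str, list[int] | None]]:
    """Read sequences (and qualities if FASTQ) keyed by record id."""
    from Bio import SeqIO

    with open(path) as handle:
        first = handle.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    out = {}
    for rec in SeqIO.parse(str(path), fmt):
        quals = rec.letter_annotations.get("phred_quality")
        out[rec.id] = (str(rec.seq), list(quals) if quals else None)
    return out
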