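"""Independent oracles used only by the test suite.

These deliberately re-derive results through a different route than the
package: the melting-temperature oracle is a direct summation of the
published unified nearest-neighbor parameters, and the alignment oracle is
an exhaustive (unseeded, unbanded) local alignment over every
read-reference pair via Biopython's C aligner.
"""

import math

from Bio import Align

# Unified nearest-neighbor parameters: dinucleotide -> (dH kcal/mol, dS cal/mol/K)
NN_PARAMS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Terminal initiation terms per end
NN_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}

GAS_CONSTANT = 1.987  # cal / (K mol)


def nn_tm_oracle(seq: str, na_molar: float = 0.05, total_oligo_molar: float = 500e-9) -> float:
    """Hand-summed unified NN melting temperature with entropic salt correction.

    Tm = 1000*dH / (dS + 0.368*(N-1)*ln[Na+] + R*ln(C_T/4)) - 273.15
    """
    seq = seq.upper()
    dh = NN_INIT[seq[0]][0] + NN_INIT[seq[-1]][0]
    ds = NN_INIT[seq[0]][1] + NN_INIT[seq[-1]][1]
    for a, b in zip(seq, seq[1:]):
        h, s = NN_PARAMS[a + b]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    return 1000.0 * dh / (ds + GAS_CONSTANT * math.log(total_oligo_molar / 4.0)) - 273.15


def make_exhaustive_aligner() -> Align.PairwiseAligner:
    """Full local aligner with the same scoring as the seeded implementation."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def exhaustive_best_target(read: str, references: dict[str, str]) -> str:
    """Best-scoring reference by brute-force alignment of all pairs.

    Ties break on reference id, matching the seeded aligner's ordering.
    """
    aligner = make_exhaustive_aligner()
    scored = sorted(
        ((-aligner.score(ref, read), gid) for gid, ref in references.items())
    )
    return scored[0][1]
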