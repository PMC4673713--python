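"""Small shared sequence helpers."""

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The three canonical translation termination codons (mRNA sense, DNA alphabet).
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_dna(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")
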