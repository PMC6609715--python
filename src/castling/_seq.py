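"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, allow_n: bool = True) -> bool:
    allowed = VALID_BASES if allow_n else VALID_BASES - {"N"}
    return all(c in allowed for c in seq)


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def codons(seq: str):
    """Iterate over complete 3-mers of ``seq``."""
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i : i + 3]


def first_stop_codon(seq: str) -> int | None:
    """Index (codon units) of the first STOP codon in frame 0, or None."""
    for i, codon in enumerate(codons(seq)):
        if codon in STOP_CODONS:
            return i
    return None
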