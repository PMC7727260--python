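"""Small sequence helpers shared across modules.

Reverse complement is implemented with ``str.translate`` because it sits in
the read-generation and alignment hot loops; codon translation goes through
Biopython's standard genetic code (table 1), which is the correct code for
plant mitochondrial protein genes.
"""

from __future__ import annotations

from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate a single codon with the standard genetic code; stop is '*'."""
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    return str(Seq(codon).translate())


def translate_orf(seq: str) -> str:
    """Translate an in-frame sequence (length divisible by 3); stops are '*'."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return str(Seq(seq).translate())
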