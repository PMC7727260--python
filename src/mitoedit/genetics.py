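"""Segregation-ratio testing and ORF point-mutation arithmetic.

Covers the genetics used in mutant identification and allelism testing:
a Pearson chi-square goodness-of-fit test of observed kernel counts against
a Mendelian ratio (1 df, no continuity correction), and codon-level
consequence annotation of single-nucleotide changes within an ORF.
Translation uses the standard genetic code, which plant mitochondrial
protein genes follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from scipy import stats

from ._seq import translate_codon


@dataclass(frozen=True)
class SegregationObservation:
    """Two-class kernel counts with the expected Mendelian ratio."""

    n_class1: int
    n_class2: int
    expected_ratio: Tuple[float, float] = (3.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_class1 < 0 or self.n_class2 < 0:
            raise ValueError("counts must be non-negative")
        if self.n_class1 + self.n_class2 < 1:
            raise ValueError("at least one kernel must be observed")
        r1, r2 = self.expected_ratio
        if r1 <= 0 or r2 <= 0:
            raise ValueError("expected ratio components must be positive")


def segregation_chisq(
    obs: SegregationObservation | int,
    n_class2: Optional[int] = None,
    expected_ratio: Tuple[float, float] = (3.0, 1.0),
) -> Tuple[float, float]:
    """Pearson chi-square test of a two-class segregation ratio.

    One degree of freedom, no Yates continuity correction; the p-value is
    the upper tail of the chi-square distribution.  Accepts either a
    :class:`SegregationObservation` or raw counts, e.g.
    ``segregation_chisq(450, 143, (3, 1))``.

    Returns ``(chi_square, p_value)``.
    """
    if not isinstance(obs, SegregationObservation):
        if n_class2 is None:
            raise ValueError("provide an observation or both counts")
        obs = SegregationObservation(int(obs), int(n_class2), expected_ratio)
    total = obs.n_class1 + obs.n_class2
    r1, r2 = obs.expected_ratio
    e1 = total * r1 / (r1 + r2)
    e2 = total * r2 / (r1 + r2)
    if min(e1, e2) < 1:
        raise ValueError(f"expected counts ({e1:.2f}, {e2:.2f}) below 1; test invalid")
    chi2 = (obs.n_class1 - e1) ** 2 / e1 + (obs.n_class2 - e2) ** 2 / e2
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass(frozen=True)
class MutationRecord:
    """A single-nucleotide substitution inside an ORF.

    The ORF is the sense-strand coding sequence from ATG through the stop
    codon; ``position`` is 1-based within it.
    """

    orf: str
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        orf = self.orf.upper()
        object.__setattr__(self, "orf", orf)
        object.__setattr__(self, "ref_base", self.ref_base.upper())
        object.__setattr__(self, "alt_base", self.alt_base.upper())
        if len(orf) % 3 != 0:
            raise ValueError(f"ORF length {len(orf)} not divisible by 3")
        if not orf.startswith("ATG"):
            raise ValueError("ORF must start with ATG")
        if translate_codon(orf[-3:]) != "*":
            raise ValueError("ORF must end with a stop codon")
        if not 1 <= self.position <= len(orf):
            raise ValueError(f"position {self.position} outside ORF of length {len(orf)}")
        found = orf[self.position - 1]
        if found != self.ref_base:
            raise ValueError(
                f"reference base mismatch at position {self.position}: "
                f"record says {self.ref_base!r}, ORF has {found!r}"
            )
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base equals ref_base")


@dataclass(frozen=True)
class PointMutationEffect:
    codon_index: int
    codon_position: int  # 1-3 within the codon
    ref_codon: str
    alt_codon: str
    aa_ref: str
    aa_alt: str
    effect: str  # "missense" | "synonymous" | "nonsense"
    truncated_length: Optional[int] = None  # peptide length for nonsense


def annotate_point_mutation(rec: MutationRecord) -> PointMutationEffect:
    """Codon-level consequence of a point mutation within an ORF.

    ``codon_index = ceil(position / 3)``; a mutation creating a premature
    stop is *nonsense* with a truncated peptide of ``codon_index − 1``
    residues.
    """
    codon_index = math.ceil(rec.position / 3)
    codon_position = (rec.position - 1) % 3 + 1
    start = 3 * (codon_index - 1)
    ref_codon = rec.orf[start : start + 3]
    alt = list(ref_codon)
    alt[codon_position - 1] = rec.alt_base
    alt_codon = "".join(alt)
    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    if aa_alt == aa_ref:
        effect = "synonymous"
        truncated = None
    elif aa_alt == "*":
        effect = "nonsense"
        truncated = codon_index - 1
    else:
        effect = "missense"
        truncated = None
    return PointMutationEffect(
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        effect=effect,
        truncated_length=truncated,
    )


def orf_protein_length(orf_length_nt: int, includes_stop: bool = True) -> int:
    """Protein length in residues encoded by an ORF of the given length.

    The stop codon, when included in the ORF length, codes for no residue.
    """
    if orf_length_nt < 3:
        raise ValueError("ORF length must be at least one codon")
    if orf_length_nt % 3 != 0:
        raise ValueError(f"ORF length {orf_length_nt} not divisible by 3")
    n_codons = orf_length_nt // 3
    return n_codons - 1 if includes_stop else n_codons
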