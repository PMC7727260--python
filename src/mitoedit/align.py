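"""Gapless seed-and-extend alignment to a small transcript reference set.

Amplicon reads derive from the very transcripts they are mapped back to, so
a gapless aligner with exact k-mer seeding is sufficient: candidate
placements are located by looking up non-overlapping k-mers of the read (in
both orientations) in a k-mer index of the references, then scored by full
mismatch count.  With ``max_mismatch + 1`` disjoint seeds per orientation,
any placement with at most ``max_mismatch`` mismatches is guaranteed to be
found (pigeonhole), so on reads of length >= (max_mismatch + 1) * k the
seeded search is equivalent to exhaustive scoring of every offset of every
reference on both strands.

Coordinates are 1-based inclusive on the sense strand of each reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._seq import revcomp

DEFAULT_K = 20
DEFAULT_MAX_MISMATCH = 5

ALIGNMENT_COLUMNS = ["read_id", "transcript", "start", "strand", "mismatches", "status"]


@dataclass
class Alignment:
    """Placement of one read on the reference set.

    ``sense_sequence`` is the read projected onto the sense strand of the
    reference (i.e. reverse-complemented when the read came from the
    antisense strand); pileup counting reads bases straight off it.
    """

    read_id: str
    transcript_id: Optional[str]
    start: Optional[int]  # 1-based inclusive, sense strand
    strand: Optional[str]  # "sense" | "antisense"
    mismatches: Optional[int]
    status: str  # "unique" | "ambiguous" | "unmapped"
    aligned_length: int = 0
    sense_sequence: Optional[str] = None
    reason: Optional[str] = None

    @property
    def end(self) -> Optional[int]:
        if self.start is None:
            return None
        return self.start + self.aligned_length - 1


def _count_mismatches(a: str, b: str, cap: int) -> int:
    """Mismatch count between equal-length strings, short-circuiting at cap+1."""
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > cap:
                break
    return n


class ReferenceIndex:
    """Exact k-mer index over the sense strands of a reference set."""

    def __init__(self, references: dict[str, str], k: int = DEFAULT_K):
        if not references:
            raise ValueError("references must be non-empty")
        if k < 1:
            raise ValueError("k must be positive")
        self.references = {tid: seq.upper() for tid, seq in references.items()}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid in sorted(self.references):
            seq = self.references[tid]
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((tid, pos))

    def align_read(
        self, read_id: str, seq: str, max_mismatch: int = DEFAULT_MAX_MISMATCH
    ) -> Alignment:
        """Align one read; returns a unique, ambiguous, or unmapped Alignment."""
        seq = seq.upper()
        length = len(seq)
        if length < self.k:
            return Alignment(
                read_id, None, None, None, None, "unmapped",
                aligned_length=length, reason=f"read shorter than seed length {self.k}",
            )

        n_seeds = min(length // self.k, max_mismatch + 1)
        candidates: dict[tuple[str, int, str], str] = {}
        for strand, oriented in (("sense", seq), ("antisense", revcomp(seq))):
            for s in range(n_seeds):
                off = s * self.k
                for tid, pos in self._index.get(oriented[off : off + self.k], ()):
                    start0 = pos - off
                    if start0 < 0 or start0 + length > len(self.references[tid]):
                        continue
                    candidates.setdefault((tid, start0, strand), oriented)

        best_mm = max_mismatch + 1
        best: list[tuple[str, int, str, str]] = []
        for (tid, start0, strand), oriented in sorted(candidates.items()):
            mm = _count_mismatches(
                self.references[tid][start0 : start0 + length], oriented, max_mismatch
            )
            if mm < best_mm:
                best_mm = mm
                best = [(tid, start0, strand, oriented)]
            elif mm == best_mm:
                best.append((tid, start0, strand, oriented))

        if best_mm > max_mismatch or not best:
            return Alignment(
                read_id, None, None, None, None, "unmapped",
                aligned_length=length, reason="no placement within mismatch threshold",
            )
        tid, start0, strand, oriented = best[0]
        status = "unique" if len(best) == 1 else "ambiguous"
        return Alignment(
            read_id=read_id,
            transcript_id=tid,
            start=start0 + 1,
            strand=strand,
            mismatches=best_mm,
            status=status,
            aligned_length=length,
            sense_sequence=oriented if status == "unique" else None,
        )


def align_reads(
    reads: Iterable[tuple[str, str]],
    references: dict[str, str] | ReferenceIndex,
    k: int = DEFAULT_K,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[Alignment]:
    """Align a read set; builds the index once if given raw references."""
    index = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references, k)
    return [index.align_read(rid, seq, max_mismatch) for rid, seq in reads]


def write_alignments_tsv(alignments: Sequence[Alignment], path: str | Path) -> None:
    """Export alignments as a flat table (simpler than SAM by design)."""
    rows = [
        {
            "read_id": a.read_id,
            "transcript": a.transcript_id or ".",
            "start": a.start if a.start is not None else 0,
            "strand": a.strand or ".",
            "mismatches": a.mismatches if a.mismatches is not None else -1,
            "status": a.status,
        }
        for a in alignments
    ]
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)
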