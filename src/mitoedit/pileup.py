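"""Per-site base counting over uniquely placed reads.

Each unique alignment overlapping a site contributes exactly one
strand-normalized base to that site's counts (antisense reads are
complemented by construction of ``Alignment.sense_sequence``).  Bases other
than C or T — sequencing errors at the site — are tallied separately and
excluded from the editing-efficiency denominator, matching the T/(T+C)
statistic.  Ambiguous and unmapped reads contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .align import Alignment
from .sites import EditingSite

PILEUP_COLUMNS = ["site_id", "library", "n_C", "n_T", "n_other"]


@dataclass
class SitePileup:
    """Base counts at one editing site in one library."""

    site_id: str
    library_id: str
    n_C: int = 0
    n_T: int = 0
    n_other: int = 0

    @property
    def depth(self) -> int:
        return self.n_C + self.n_T + self.n_other


def pileup_sites(
    alignments: Iterable[Alignment],
    sites: Sequence[EditingSite],
    library_id: str,
    known_transcripts: Optional[Iterable[str]] = None,
) -> list[SitePileup]:
    """Count strand-normalized bases at every site from unique alignments.

    Non-unique alignments are skipped.  If ``known_transcripts`` is given,
    a site on a transcript outside it raises a ValueError naming the site.
    """
    if known_transcripts is not None:
        known = set(known_transcripts)
        for site in sites:
            if site.transcript_id not in known:
                raise ValueError(
                    f"site {site.site_id} lies on unknown transcript "
                    f"{site.transcript_id!r}"
                )

    by_transcript: dict[str, list[EditingSite]] = {}
    for site in sites:
        by_transcript.setdefault(site.transcript_id, []).append(site)

    pileups = {site.site_id: SitePileup(site.site_id, library_id) for site in sites}
    for aln in alignments:
        if aln.status != "unique" or aln.sense_sequence is None:
            continue
        for site in by_transcript.get(aln.transcript_id, ()):
            offset = site.position - aln.start
            if 0 <= offset < aln.aligned_length:
                base = aln.sense_sequence[offset]
                pile = pileups[site.site_id]
                if base == "C":
                    pile.n_C += 1
                elif base == "T":
                    pile.n_T += 1
                else:
                    pile.n_other += 1
    return [pileups[site.site_id] for site in sites]


def pileups_to_frame(pileups: Iterable[SitePileup]) -> pd.DataFrame:
    """Long-format counts table: site_id, library, n_C, n_T, n_other."""
    rows = [
        {
            "site_id": p.site_id,
            "library": p.library_id,
            "n_C": p.n_C,
            "n_T": p.n_T,
            "n_other": p.n_other,
        }
        for p in pileups
    ]
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def write_pileups_tsv(pileups: Iterable[SitePileup], path: str | Path) -> None:
    pileups_to_frame(pileups).to_csv(path, sep="\t", index=False)


def read_pileups_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup table {path} missing columns: {sorted(missing)}")
    return df
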