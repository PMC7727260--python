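"""Editing-site annotations and their tab-separated exchange format.

A site is one annotated cytidine on the sense strand of a transcript where
C-to-U editing is quantified.  Site ids follow the field convention of
gene id plus CDS-relative coordinate (e.g. ``atp1-1490``); sites in introns
use intron-local coordinates on the intron's own reference entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

SITE_COLUMNS = ["transcript_id", "position", "site_name", "ref_base", "cds_offset"]


@dataclass(frozen=True)
class EditingSite:
    """One annotated C position on a sense-strand transcript.

    Parameters
    ----------
    site_id : str
        Name of the site, conventionally ``<gene>-<CDS position>``.
    transcript_id : str
        Reference entry the site lies on.
    position : int
        1-based coordinate on the sense strand of the transcript.
    ref_base : str
        Unedited base; always ``C`` for C-to-U editing.
    cds_offset : int, optional
        1-based position of the first CDS base on the transcript.  Anchors
        codon arithmetic for consequence annotation; ``None`` for sites on
        non-coding references (e.g. intron entries).
    """

    site_id: str
    transcript_id: str
    position: int
    ref_base: str = "C"
    cds_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site {self.site_id}: position must be >= 1")
        if self.ref_base != "C":
            raise ValueError(
                f"site {self.site_id}: ref_base must be C for C-to-U editing, "
                f"got {self.ref_base!r}"
            )
        if self.cds_offset is not None and self.cds_offset < 1:
            raise ValueError(f"site {self.site_id}: cds_offset must be >= 1")


def validate_sites(sites: Iterable[EditingSite], references: dict[str, str]) -> None:
    """Check every site lies on a known reference within its length."""
    for site in sites:
        ref = references.get(site.transcript_id)
        if ref is None:
            raise ValueError(
                f"site {site.site_id} names unknown transcript {site.transcript_id!r}"
            )
        if site.position > len(ref):
            raise ValueError(
                f"site {site.site_id} position {site.position} exceeds "
                f"{site.transcript_id} length {len(ref)}"
            )


def read_sites_tsv(path: str | Path) -> list[EditingSite]:
    """Read a site table (transcript_id, position, site_name, ref_base, cds_offset)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SITE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns: {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        offset = getattr(row, "cds_offset", None)
        if offset is not None and pd.isna(offset):
            offset = None
        sites.append(
            EditingSite(
                site_id=str(row.site_name),
                transcript_id=str(row.transcript_id),
                position=int(row.position),
                ref_base=str(row.ref_base),
                cds_offset=None if offset is None else int(offset),
            )
        )
    return sites


def write_sites_tsv(sites: Iterable[EditingSite], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": s.transcript_id,
            "position": s.position,
            "site_name": s.site_id,
            "ref_base": s.ref_base,
            "cds_offset": s.cds_offset,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)
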