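"""Editing-efficiency statistics and differential editing-site calling.

The editing efficiency at a site is the percentage of cDNA reads carrying T
among reads carrying C or T, ``100 * T / (T + C)`` — the fraction of
transcript molecules edited at that site.  Differential calling compares
two mutant libraries against two wild-type libraries: a site is *decreased*
when the mutant-minus-WT difference is at most −threshold percentage points
in all four pairwise comparisons, *increased* when it is at least
+threshold in all four (boundaries inclusive), *low_coverage* when any
library lacks the minimum read depth, otherwise *unchanged*.  Requiring
overlap across all four comparisons filters library-specific artefacts
without a formal test.

The caller is exposed as a model/results pair: build
:class:`DifferentialEditing` from pileup counts (or a precomputed
efficiency table), call :meth:`~DifferentialEditing.fit`, and inspect the
returned :class:`DifferentialEditingResults` (``.table``, ``.summary()``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import translate_codon
from .pileup import SitePileup, pileups_to_frame
from .sites import EditingSite

DEFAULT_THRESHOLD = 10.0  # percentage points
DEFAULT_MIN_DEPTH = 10  # reads in the T+C denominator

CALL_DECREASED = "decreased"
CALL_INCREASED = "increased"
CALL_UNCHANGED = "unchanged"
CALL_LOW_COVERAGE = "low_coverage"


def editing_percentage(
    n_T: int, n_C: int, min_depth: int = DEFAULT_MIN_DEPTH
) -> Optional[float]:
    """Editing efficiency 100*T/(T+C) in percent, or None below min_depth.

    ``None`` is a value (insufficient coverage), not an error; bases other
    than C/T never enter the denominator.
    """
    if n_T < 0 or n_C < 0:
        raise ValueError("counts must be non-negative")
    denom = n_T + n_C
    if denom < max(min_depth, 1):
        return None
    return 100.0 * n_T / denom


def strong_reduction(wt_eff: float, mut_eff: float) -> bool:
    """True when the mutant efficiency is more than 50% below the WT one.

    Strict inequality: a mutant at exactly half the WT efficiency is not
    flagged.  A WT efficiency of zero cannot be halved; returns False with
    a warning.
    """
    if wt_eff == 0:
        warnings.warn("WT efficiency is 0; strong-reduction flag undefined, returning False")
        return False
    return mut_eff < 0.5 * wt_eff


@dataclass(frozen=True)
class EditingConsequence:
    """Codon-level consequence of editing a C to U inside a CDS."""

    site_id: str
    coding: bool
    codon_index: Optional[int] = None
    codon_position: Optional[int] = None
    ref_codon: Optional[str] = None
    edited_codon: Optional[str] = None
    aa_before: Optional[str] = None
    aa_after: Optional[str] = None
    creates_stop: bool = False
    synonymous: bool = False


def annotate_editing_consequence(cds_seq: str, site: EditingSite) -> EditingConsequence:
    """Translate the codon containing an editing site before and after C→U.

    ``cds_seq`` starts at the CDS first base; the site position is mapped
    into it via ``site.cds_offset``.  Sites upstream of the CDS (or without
    an anchor) are classified non-coding.
    """
    cds_seq = cds_seq.upper()
    if site.cds_offset is None:
        return EditingConsequence(site_id=site.site_id, coding=False)
    rel = site.position - site.cds_offset + 1  # 1-based within CDS
    if rel < 1 or rel > len(cds_seq):
        return EditingConsequence(site_id=site.site_id, coding=False)
    if cds_seq[rel - 1] != "C":
        raise ValueError(
            f"site {site.site_id}: CDS base at offset {rel} is "
            f"{cds_seq[rel - 1]!r}, expected 'C'"
        )
    codon_index = math.ceil(rel / 3)
    codon_position = (rel - 1) % 3 + 1
    codon_start = 3 * (codon_index - 1)
    ref_codon = cds_seq[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"site {site.site_id}: CDS truncated inside codon {codon_index}")
    edited = list(ref_codon)
    edited[codon_position - 1] = "T"
    edited_codon = "".join(edited)
    aa_before = translate_codon(ref_codon)
    aa_after = translate_codon(edited_codon)
    return EditingConsequence(
        site_id=site.site_id,
        coding=True,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        edited_codon=edited_codon,
        aa_before=aa_before,
        aa_after=aa_after,
        creates_stop=aa_after == "*",
        synonymous=aa_before == aa_after,
    )


# ---------------------------------------------------------------------------
# Differential calling


def classify_deltas(
    deltas: Sequence[float], threshold: float = DEFAULT_THRESHOLD
) -> str:
    """Call one site from its four mutant-minus-WT differences.

    Decreased iff every delta is at most −threshold, increased iff every
    delta is at least +threshold (boundaries inclusive), low_coverage if any
    delta is undefined, otherwise unchanged.  Mixed-direction tuples can
    satisfy neither all-≤ nor all-≥ and are unchanged.
    """
    values = [float(d) for d in deltas]
    if any(math.isnan(v) for v in values):
        return CALL_LOW_COVERAGE
    if all(v <= -threshold for v in values):
        return CALL_DECREASED
    if all(v >= threshold for v in values):
        return CALL_INCREASED
    return CALL_UNCHANGED


def call_differential_sites(
    efficiencies: pd.DataFrame,
    wt_libraries: Sequence[str],
    mutant_libraries: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Apply the threshold/overlap rule to a per-site efficiency table.

    ``efficiencies`` is indexed by site id with one column per library,
    values in percent (NaN = insufficient coverage).  Returns the table
    extended with the four per-comparison differences (mutant − WT,
    percentage points, ordered mut1−wt1, mut1−wt2, mut2−wt1, mut2−wt2),
    the call, and per-mutant strong-reduction flags.
    """
    if len(wt_libraries) != 2 or len(mutant_libraries) != 2:
        raise ValueError("exactly two WT and two mutant libraries are required")
    if efficiencies.index.has_duplicates:
        dupes = efficiencies.index[efficiencies.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated site ids: {dupes}")
    missing = [c for c in (*wt_libraries, *mutant_libraries) if c not in efficiencies]
    if missing:
        raise ValueError(f"efficiency table lacks library columns: {missing}")

    out = efficiencies.copy()
    comparisons = [
        (m, w) for m in mutant_libraries for w in wt_libraries
    ]  # mut1-wt1, mut1-wt2, mut2-wt1, mut2-wt2
    for i, (m, w) in enumerate(comparisons, start=1):
        out[f"delta_{i}"] = out[m] - out[w]

    delta_cols = [f"delta_{i}" for i in range(1, 5)]
    lib_cols = list(wt_libraries) + list(mutant_libraries)

    low = out[lib_cols].isna().any(axis=1)
    out["call"] = [
        CALL_LOW_COVERAGE if is_low else classify_deltas(row, threshold)
        for is_low, row in zip(low, out[delta_cols].itertuples(index=False))
    ]

    wt_mean = out[list(wt_libraries)].mean(axis=1)
    for j, m in enumerate(mutant_libraries, start=1):
        col = f"strong_mut{j}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # wt_mean == 0 handled explicitly
            flag = (out[m] < 0.5 * wt_mean) & (wt_mean > 0)
        out[col] = flag & ~low
    return out


class DifferentialEditing:
    """Four-library differential editing model over per-site base counts.

    Parameters
    ----------
    counts : DataFrame
        Long-format counts with columns ``site_id, library, n_C, n_T``
        (``n_other`` optional, ignored by the statistic).
    wt_libraries, mutant_libraries : pair of str
        The two wild-type and two mutant library ids; the overlap rule is
        defined for exactly this 2+2 design.
    sites : sequence of EditingSite, optional
        Site annotations carried through to the results table.

    Examples
    --------
    >>> model = DifferentialEditing.from_pileups(pileups_by_library)
    >>> res = model.fit(threshold=10, min_depth=10)
    >>> res.n_decreased, res.n_increased
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        wt_libraries: Sequence[str] = ("WT-1", "WT-2"),
        mutant_libraries: Sequence[str] = ("mut-1", "mut-2"),
        sites: Optional[Sequence[EditingSite]] = None,
        _efficiencies: Optional[pd.DataFrame] = None,
    ):
        if len(wt_libraries) != 2 or len(mutant_libraries) != 2:
            raise ValueError("exactly two WT and two mutant libraries are required")
        self.wt_libraries = tuple(wt_libraries)
        self.mutant_libraries = tuple(mutant_libraries)
        self.sites = list(sites) if sites is not None else None
        self._efficiencies = _efficiencies
        self.counts = counts
        if counts is not None:
            required = {"site_id", "library", "n_C", "n_T"}
            missing = required - set(counts.columns)
            if missing:
                raise ValueError(f"counts table missing columns: {sorted(missing)}")
            if counts.duplicated(["site_id", "library"]).any():
                dupes = (
                    counts.loc[counts.duplicated(["site_id", "library"]), "site_id"]
                    .unique()
                    .tolist()
                )
                raise ValueError(f"duplicated site ids in counts: {dupes}")

    @classmethod
    def from_pileups(
        cls,
        pileups: Mapping[str, Iterable[SitePileup]],
        wt_libraries: Sequence[str] = ("WT-1", "WT-2"),
        mutant_libraries: Sequence[str] = ("mut-1", "mut-2"),
        sites: Optional[Sequence[EditingSite]] = None,
    ) -> "DifferentialEditing":
        frames = [pileups_to_frame(p) for p in pileups.values()]
        return cls(
            pd.concat(frames, ignore_index=True),
            wt_libraries=wt_libraries,
            mutant_libraries=mutant_libraries,
            sites=sites,
        )

    @classmethod
    def from_efficiency_table(
        cls,
        efficiencies: pd.DataFrame,
        wt_libraries: Sequence[str] = ("WT-1", "WT-2"),
        mutant_libraries: Sequence[str] = ("mut-1", "mut-2"),
        sites: Optional[Sequence[EditingSite]] = None,
    ) -> "DifferentialEditing":
        """Build from precomputed per-library efficiencies in percent.

        For published per-site tables where raw counts are unavailable;
        the index is the site id, columns are library ids, NaN marks
        low coverage.
        """
        model = cls(
            counts=None,
            wt_libraries=wt_libraries,
            mutant_libraries=mutant_libraries,
            sites=sites,
            _efficiencies=efficiencies,
        )
        return model

    def _efficiency_table(self, min_depth: int) -> pd.DataFrame:
        if self._efficiencies is not None:
            return self._efficiencies.copy()
        libs = list(self.wt_libraries) + list(self.mutant_libraries)
        present = set(self.counts["library"].unique())
        absent = [lib for lib in libs if lib not in present]
        if absent and not self.counts.empty:
            raise ValueError(f"counts table lacks libraries: {absent}")

        def eff(row) -> float:
            value = editing_percentage(int(row.n_T), int(row.n_C), min_depth)
            return np.nan if value is None else value

        site_order = (
            [s.site_id for s in self.sites]
            if self.sites is not None
            else list(dict.fromkeys(self.counts["site_id"]))
        )
        table = pd.DataFrame(index=pd.Index(site_order, name="site_id"), columns=libs, dtype=float)
        for row in self.counts.itertuples(index=False):
            if row.library in libs and row.site_id in table.index:
                table.loc[row.site_id, row.library] = eff(row)
        return table

    def fit(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        min_depth: int = DEFAULT_MIN_DEPTH,
    ) -> "DifferentialEditingResults":
        """Compute efficiencies and apply the threshold/overlap rule."""
        efficiencies = self._efficiency_table(min_depth)
        table = call_differential_sites(
            efficiencies, self.wt_libraries, self.mutant_libraries, threshold
        )
        if self.sites is not None:
            meta = pd.DataFrame(
                {
                    "transcript": {s.site_id: s.transcript_id for s in self.sites},
                    "position": {s.site_id: s.position for s in self.sites},
                }
            )
            table = meta.join(table, how="right")
            table.index.name = "site_id"
        return DifferentialEditingResults(self, table, threshold, min_depth)


class DifferentialEditingResults:
    """Fitted differential-editing call table plus convenience accessors."""

    def __init__(
        self,
        model: DifferentialEditing,
        table: pd.DataFrame,
        threshold: float,
        min_depth: int,
    ):
        self.model = model
        self.table = table
        self.threshold = threshold
        self.min_depth = min_depth

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def _count(self, call: str) -> int:
        return int((self.table["call"] == call).sum())

    @property
    def n_decreased(self) -> int:
        return self._count(CALL_DECREASED)

    @property
    def n_increased(self) -> int:
        return self._count(CALL_INCREASED)

    @property
    def n_unchanged(self) -> int:
        return self._count(CALL_UNCHANGED)

    @property
    def n_low_coverage(self) -> int:
        return self._count(CALL_LOW_COVERAGE)

    @property
    def n_affected(self) -> int:
        return self.n_decreased + self.n_increased

    def affected_sites(self) -> list[str]:
        mask = self.table["call"].isin([CALL_DECREASED, CALL_INCREASED])
        return self.table.index[mask].tolist()

    def to_tsv(self, path: str | Path) -> None:
        """Write the call table; efficiencies and deltas to one decimal place."""
        out = self.table.copy()
        float_cols = out.select_dtypes(include=[float]).columns
        out[float_cols] = out[float_cols].round(1)
        out.to_csv(path, sep="\t", index=True, index_label="site_id")

    def summary(self) -> str:
        lib_line = (
            f"WT: {', '.join(self.model.wt_libraries)}    "
            f"mutant: {', '.join(self.model.mutant_libraries)}"
        )
        lines = [
            "Differential C-to-U editing results",
            "=" * 43,
            lib_line,
            f"threshold: {self.threshold:g} percentage points (all four comparisons)",
            f"min depth (T+C): {self.min_depth}",
            "-" * 43,
            f"sites examined     {len(self.table):6d}",
            f"decreased          {self.n_decreased:6d}",
            f"increased          {self.n_increased:6d}",
            f"unchanged          {self.n_unchanged:6d}",
            f"low coverage       {self.n_low_coverage:6d}",
            "=" * 43,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<DifferentialEditingResults: {len(self.table)} sites, "
            f"{self.n_decreased} decreased, {self.n_increased} increased>"
        )
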