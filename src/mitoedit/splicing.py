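"""Relative qPCR quantification, intron splicing efficiency, and RT-PCR
amplifiability from gene models.

Fold changes follow the comparative-Ct convention: with amplification
efficiency 2 per cycle, fold change = 2^-ddCt where
ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,ctrl - Ct_ref,ctrl).
Within-sample splicing efficiency is the relative abundance of the
spliced-junction amplicon over the intron-retaining (unspliced) amplicon,
each normalised to a reference gene; the reported statistic is the
mutant/WT ratio of those efficiencies (1.0 = unaffected).

Gene models distinguish cis- from trans-spliced group II introns:
a trans intron joins exons transcribed from separate precursor molecules,
so no contiguous unspliced template exists and an exon-to-exon RT-PCR
across it can only amplify the mature spliced transcript.  The maize
mitochondrial *nad1* gene (4 introns: trans, cis, trans, trans) and *nad4*
(3 cis introns) ship as packaged models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import mean, stdev
from typing import Iterable, Optional, Sequence, Tuple, Union

import pandas as pd

MATURE_SPLICED = "mature_spliced"
UNSPLICED_PRECURSOR = "unspliced_precursor"
NO_PRODUCT = "none"

GENE_MODEL_COLUMNS = ["gene", "segment_kind", "index", "length", "splice_mode"]


@dataclass(frozen=True)
class Segment:
    """One exon or intron of a gene model, in genomic order."""

    kind: str  # "exon" | "intron"
    index: int
    length: int
    splice_mode: Optional[str] = None  # "cis" | "trans" for introns

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"segment kind must be exon or intron, got {self.kind!r}")
        if self.index < 1 or self.length < 1:
            raise ValueError("segment index and length must be positive")
        if self.kind == "intron" and self.splice_mode not in ("cis", "trans"):
            raise ValueError(f"intron {self.index}: splice_mode must be cis or trans")
        if self.kind == "exon" and self.splice_mode is not None:
            raise ValueError(f"exon {self.index}: splice_mode must be empty")


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon/intron structure of an organellar gene."""

    gene_id: str
    segments: Tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs or segs[0].kind != "exon" or segs[-1].kind != "exon":
            raise ValueError(f"{self.gene_id}: segments must start and end with an exon")
        for a, b in zip(segs, segs[1:]):
            if a.kind == b.kind:
                raise ValueError(f"{self.gene_id}: segments must alternate exon/intron")
        for kind in ("exon", "intron"):
            indices = [s.index for s in segs if s.kind == kind]
            if indices != list(range(1, len(indices) + 1)):
                raise ValueError(f"{self.gene_id}: {kind} indices must run 1..n in order")

    @property
    def introns(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "intron"]

    @property
    def exons(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "exon"]

    def segment(self, kind: str, index: int) -> Segment:
        for s in self.segments:
            if s.kind == kind and s.index == index:
                return s
        raise KeyError(f"{self.gene_id}: no {kind} {index}")


def nad1_model() -> GeneModel:
    """Packaged *nad1* model: 5 exons, introns trans/cis/trans/trans.

    Segment lengths are synthetic placeholders of realistic magnitude;
    only the exon/intron topology and splice modes carry information.
    """
    return GeneModel(
        "nad1",
        (
            Segment("exon", 1, 387),
            Segment("intron", 1, 1500, "trans"),
            Segment("exon", 2, 86),
            Segment("intron", 2, 1340, "cis"),
            Segment("exon", 3, 192),
            Segment("intron", 3, 2000, "trans"),
            Segment("exon", 4, 59),
            Segment("intron", 4, 1650, "trans"),
            Segment("exon", 5, 254),
        ),
    )


def nad4_model() -> GeneModel:
    """Packaged *nad4* model: 4 exons, three cis-spliced introns.

    Segment lengths are synthetic placeholders of realistic magnitude.
    """
    return GeneModel(
        "nad4",
        (
            Segment("exon", 1, 461),
            Segment("intron", 1, 1600, "cis"),
            Segment("exon", 2, 510),
            Segment("intron", 2, 3000, "cis"),
            Segment("exon", 3, 413),
            Segment("intron", 3, 2000, "cis"),
            Segment("exon", 4, 82),
        ),
    )


def default_gene_models() -> dict[str, GeneModel]:
    models = [nad1_model(), nad4_model()]
    return {m.gene_id: m for m in models}


def read_gene_models_tsv(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models (gene, segment_kind, index, length, splice_mode)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_MODEL_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"gene model table {path} missing columns: {sorted(missing)}")
    models = {}
    for gene, group in df.groupby("gene", sort=False):
        segments = []
        for row in group.to_dict("records"):
            mode = row.get("splice_mode")
            if mode is not None and pd.isna(mode):
                mode = None
            segments.append(
                Segment(str(row["segment_kind"]), int(row["index"]), int(row["length"]), mode)
            )
        models[str(gene)] = GeneModel(str(gene), tuple(segments))
    return models


def write_gene_models_tsv(models: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene": m.gene_id,
            "segment_kind": s.kind,
            "index": s.index,
            "length": s.length,
            "splice_mode": s.splice_mode,
        }
        for m in models
        for s in m.segments
    ]
    pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


def rt_pcr_products(
    model: GeneModel,
    forward_anchor: Tuple[str, int],
    reverse_anchor: Tuple[str, int],
) -> set[str]:
    """Template classes an RT-PCR primer pair can amplify.

    Anchors are segments of the model, forward upstream of reverse.  A pair
    spanning only cis introns (or none) amplifies both the mature spliced
    transcript and the unspliced precursor; spanning any trans intron
    leaves only the mature transcript (no contiguous precursor exists).
    A primer anchored in an intron cannot amplify the mature transcript.
    Returns a subset of {mature_spliced, unspliced_precursor} or {none}.
    """
    fwd = model.segment(*forward_anchor)
    rev = model.segment(*reverse_anchor)
    order = list(model.segments)
    i, j = order.index(fwd), order.index(rev)
    if j < i:
        raise ValueError(
            f"{model.gene_id}: reverse anchor {reverse_anchor} is upstream of "
            f"forward anchor {forward_anchor}"
        )
    span = order[i : j + 1]
    spanned_introns = [s for s in span if s.kind == "intron"]

    products: set[str] = set()
    if fwd.kind == "exon" and rev.kind == "exon":
        products.add(MATURE_SPLICED)
    if not any(s.splice_mode == "trans" for s in spanned_introns):
        products.add(UNSPLICED_PRECURSOR)
    return products or {NO_PRODUCT}


def amplifiability_pattern(model: GeneModel) -> dict[int, bool]:
    """Per intron: can flanking-exon RT-PCR see the unspliced precursor?

    True for cis introns (precursor band visible), False for trans introns
    (precursor-silent).
    """
    pattern = {}
    for intron in model.introns:
        products = rt_pcr_products(
            model, ("exon", intron.index), ("exon", intron.index + 1)
        )
        pattern[intron.index] = UNSPLICED_PRECURSOR in products
    return pattern


# ---------------------------------------------------------------------------
# Ct arithmetic


@dataclass(frozen=True)
class CtRecord:
    """Threshold cycles of one amplicon in one sample (>= 1 replicate)."""

    sample_id: str
    amplicon_id: str
    cts: Tuple[float, ...]
    role: str = "target"  # "target" | "reference"

    def __post_init__(self) -> None:
        cts = tuple(float(c) for c in self.cts)
        object.__setattr__(self, "cts", cts)
        if not cts:
            raise ValueError(f"{self.sample_id}/{self.amplicon_id}: at least one replicate Ct")
        if any(c <= 0 for c in cts):
            raise ValueError(f"{self.sample_id}/{self.amplicon_id}: Ct values must be positive")
        if self.role not in ("target", "reference"):
            raise ValueError(f"role must be target or reference, got {self.role!r}")

    @property
    def mean_ct(self) -> float:
        return mean(self.cts)

    @property
    def sd_ct(self) -> float:
        return stdev(self.cts) if len(self.cts) > 1 else 0.0


CtLike = Union[float, Sequence[float], CtRecord]


def _mean_ct(value: CtLike) -> float:
    if isinstance(value, CtRecord):
        return value.mean_ct
    if isinstance(value, (int, float)):
        return float(value)
    return mean(float(v) for v in value)


def relative_expression(
    ct_target_test: CtLike,
    ct_ref_test: CtLike,
    ct_target_ctrl: CtLike,
    ct_ref_ctrl: CtLike,
    amplification_efficiency: float = 2.0,
) -> float:
    """Comparative-Ct fold change of a target gene in test vs control.

    Replicates are averaged before differencing; fold change is
    ``E**-ddCt`` with per-cycle amplification efficiency ``E`` (default 2).
    """
    ddct = (_mean_ct(ct_target_test) - _mean_ct(ct_ref_test)) - (
        _mean_ct(ct_target_ctrl) - _mean_ct(ct_ref_ctrl)
    )
    return float(amplification_efficiency ** -ddct)


@dataclass(frozen=True)
class SplicingEfficiencyResult:
    """Within-sample splicing efficiencies and their mutant/WT ratio."""

    gene: Optional[str]
    intron: Optional[int]
    efficiency_wt: float
    efficiency_mut: float
    ratio: float


def _record_for(records: Iterable[CtRecord], sample: str, label: str) -> CtRecord:
    for rec in records:
        if rec.sample_id == sample:
            return rec
    raise KeyError(
        f"no {label} amplicon Ct record for sample {sample!r}; for a trans-spliced "
        f"intron no contiguous unspliced template exists - check rt_pcr_products"
    )


def splicing_efficiency(
    spliced: Iterable[CtRecord],
    unspliced: Iterable[CtRecord],
    reference: Iterable[CtRecord],
    mutant_sample: str,
    wt_sample: str,
    amplification_efficiency: float = 2.0,
    gene: Optional[str] = None,
    intron: Optional[int] = None,
) -> SplicingEfficiencyResult:
    """Mutant-relative-to-WT splicing efficiency of one intron.

    Per sample, efficiency = relative abundance of the spliced amplicon over
    the unspliced amplicon, each quantified as ``E**-(Ct - Ct_reference)``;
    the reference gene cancels within the sample but its presence is
    required, keeping the quantities interpretable as relative abundances.
    """
    spliced, unspliced, reference = list(spliced), list(unspliced), list(reference)
    effs = {}
    for sample in (wt_sample, mutant_sample):
        ct_s = _record_for(spliced, sample, "spliced").mean_ct
        ct_u = _record_for(unspliced, sample, "unspliced").mean_ct
        ct_r = _record_for(reference, sample, "reference").mean_ct
        rel_spliced = amplification_efficiency ** -(ct_s - ct_r)
        rel_unspliced = amplification_efficiency ** -(ct_u - ct_r)
        effs[sample] = rel_spliced / rel_unspliced
    return SplicingEfficiencyResult(
        gene=gene,
        intron=intron,
        efficiency_wt=effs[wt_sample],
        efficiency_mut=effs[mutant_sample],
        ratio=effs[mutant_sample] / effs[wt_sample],
    )


# ---------------------------------------------------------------------------
# Ct table I/O (sample, amplicon, role, ct_1..ct_n)


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "amplicon", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table {path} missing columns: {sorted(missing)}")
    if not [c for c in df.columns if c.startswith("ct_")]:
        raise ValueError(f"Ct table {path} has no ct_1..ct_n columns")
    return df


def ct_records_from_frame(df: pd.DataFrame) -> list[CtRecord]:
    ct_cols = [c for c in df.columns if c.startswith("ct_")]
    records = []
    for row in df.itertuples(index=False):
        cts = [getattr(row, c) for c in ct_cols]
        cts = [float(c) for c in cts if pd.notna(c)]
        records.append(
            CtRecord(
                sample_id=str(row.sample),
                amplicon_id=str(row.amplicon),
                cts=tuple(cts),
                role=str(row.role),
            )
        )
    return records
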