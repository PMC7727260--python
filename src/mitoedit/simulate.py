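"""Synthetic data with planted ground truth.

Emulates strand- and transcript-specific amplicon sequencing (STS-PCRseq) of
organellar transcripts: full-length cDNA amplicons are drawn per library,
each molecule is independently edited (C→T) at annotated sites with a
library-specific per-site probability, sheared into 300–500 bp fragments and
sequenced as fixed-length single-end reads from either strand with i.i.d.
substitution errors.  Also generates qPCR Ct tables and Mendelian kernel
segregation counts, so every downstream stage of the pipeline can be tested
against known truth.

Editing events at distinct sites on one molecule are independent Bernoulli
draws — the simplest generative model matching per-site marginal
efficiencies.  The error model is substitution-only, matching the gapless
aligner downstream.  Base qualities are constant Q30 and unused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .sites import EditingSite, validate_sites

QUALITY_CHAR = "?"  # Phred+33 encoding of Q30
_OTHER_BASES = {
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
}

WT_LIBRARIES = ("WT-1", "WT-2")
MUTANT_LIBRARIES = ("mut-1", "mut-2")


@dataclass
class SimConfig:
    """Parameters of one simulated amplicon-sequencing experiment.

    ``efficiencies`` maps ``(library_id, site_id)`` to the true per-molecule
    editing probability; libraries are inferred from its keys.
    ``n_fragments`` molecules are drawn per (library, transcript).
    """

    references: dict[str, str]
    sites: list[EditingSite]
    efficiencies: dict[tuple[str, str], float]
    n_fragments: int
    fragment_length_range: tuple[int, int] = (300, 500)
    read_length: int = 150
    substitution_error_rate: float = 0.001
    strand_fraction_sense: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("references must be non-empty")
        validate_sites(self.sites, self.references)
        site_ids = {s.site_id for s in self.sites}
        for (lib, sid), p in self.efficiencies.items():
            if sid not in site_ids:
                raise ValueError(f"efficiency given for unknown site {sid!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"efficiency for ({lib}, {sid}) outside [0, 1]: {p}")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be positive")
        lo, hi = self.fragment_length_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid fragment_length_range {self.fragment_length_range}")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            raise ValueError("substitution_error_rate outside [0, 1]")
        if not 0.0 <= self.strand_fraction_sense <= 1.0:
            raise ValueError("strand_fraction_sense outside [0, 1]")

    @property
    def libraries(self) -> list[str]:
        return sorted({lib for lib, _ in self.efficiencies})


@dataclass
class SimTruth:
    """Planted truth emitted alongside synthetic reads.

    ``origins`` has one row per emitted read: read_id, library, transcript,
    fragment start (1-based on the sense strand), strand, and the
    comma-joined ids of sites edited on the source molecule.
    """

    efficiencies: dict[tuple[str, str], float]
    origins: pd.DataFrame = field(repr=False)

    def edited_sites_of(self, read_id: str) -> set[str]:
        row = self.origins.loc[self.origins["read_id"] == read_id].iloc[0]
        edited = row["edited_sites"]
        return set(edited.split(",")) if edited else set()


def simulate_editing_reads(
    config: SimConfig,
) -> tuple[dict[str, list[tuple[str, str]]], SimTruth]:
    """Draw reads for every library; returns ({library: [(read_id, seq)]}, truth).

    Deterministic under a fixed ``config.seed``: libraries and transcripts
    are processed in sorted order with a single random stream.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.fragment_length_range
    if config.read_length > hi:
        warnings.warn(
            f"read_length {config.read_length} exceeds maximum fragment length "
            f"{hi}; reads will be truncated at fragment ends",
            stacklevel=2,
        )

    sites_by_transcript: dict[str, list[EditingSite]] = {}
    for site in config.sites:
        sites_by_transcript.setdefault(site.transcript_id, []).append(site)
    for lst in sites_by_transcript.values():
        lst.sort(key=lambda s: s.position)

    reads: dict[str, list[tuple[str, str]]] = {lib: [] for lib in config.libraries}
    origin_rows: list[tuple[str, str, str, int, str, str]] = []

    for lib in config.libraries:
        for tid in sorted(config.references):
            ref = config.references[tid]
            tlen = len(ref)
            tsites = sites_by_transcript.get(tid, [])
            probs = np.array(
                [config.efficiencies.get((lib, s.site_id), 0.0) for s in tsites]
            )
            n = config.n_fragments

            edited = (
                rng.random((n, len(tsites))) < probs
                if tsites
                else np.zeros((n, 0), dtype=bool)
            )
            lengths = np.minimum(rng.integers(lo, hi + 1, size=n), tlen)
            starts = rng.integers(0, tlen - lengths + 1)  # 0-based
            senses = rng.random(n) < config.strand_fraction_sense
            read_lengths = np.minimum(config.read_length, lengths)
            n_errors = (
                rng.binomial(read_lengths, config.substitution_error_rate)
                if config.substitution_error_rate > 0
                else np.zeros(n, dtype=int)
            )

            molecule_cache: dict[bytes, str] = {}
            for i in range(n):
                key = edited[i].tobytes()
                molecule = molecule_cache.get(key)
                if molecule is None:
                    chars = list(ref)
                    for j, site in enumerate(tsites):
                        if edited[i, j]:
                            chars[site.position - 1] = "T"
                    molecule = "".join(chars)
                    molecule_cache[key] = molecule

                s0 = int(starts[i])
                frag = molecule[s0 : s0 + int(lengths[i])]
                if senses[i]:
                    read = frag[: config.read_length]
                    strand = "sense"
                else:
                    read = revcomp(frag)[: config.read_length]
                    strand = "antisense"

                k = int(n_errors[i])
                if k:
                    chars = list(read)
                    for pos in rng.choice(len(read), size=min(k, len(read)), replace=False):
                        alts = _OTHER_BASES.get(chars[pos], "ACG")
                        chars[pos] = alts[rng.integers(len(alts))]
                    read = "".join(chars)

                read_id = f"{lib}|{tid}|{i:06d}"
                reads[lib].append((read_id, read))
                edited_ids = ",".join(
                    s.site_id for j, s in enumerate(tsites) if edited[i, j]
                )
                origin_rows.append((read_id, lib, tid, s0 + 1, strand, edited_ids))

    origins = pd.DataFrame(
        origin_rows,
        columns=["read_id", "library", "transcript", "frag_start", "strand", "edited_sites"],
    )
    return reads, SimTruth(efficiencies=dict(config.efficiencies), origins=origins)


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ with constant Q30 qualities."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{QUALITY_CHAR * len(seq)}\n")


def write_libraries_fastq(
    reads: Mapping[str, Sequence[tuple[str, str]]], outdir: str | Path
) -> dict[str, Path]:
    """Write one ``<library_id>.fastq`` per library; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lib in sorted(reads):
        path = outdir / f"{lib}.fastq"
        write_fastq(reads[lib], path)
        paths[lib] = path
    return paths


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into (read_id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# qPCR and segregation generators


def simulate_qpcr(
    true_relative_abundance: Mapping[tuple[str, str], float],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    baseline_ct: float = 20.0,
    n_replicates: int = 3,
    reference_amplicon: str = "actin",
) -> pd.DataFrame:
    """Generate a Ct table from planted relative template abundances.

    Ct = baseline − log2(abundance) + Gaussian noise, per technical
    replicate.  A reference-gene amplicon (abundance 1 unless specified)
    is included for every sample.  Columns: sample, amplicon, role,
    ct_1..ct_n.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    for key, ab in true_relative_abundance.items():
        if ab <= 0:
            raise ValueError(f"abundance for {key} must be positive, got {ab}")
    rng = np.random.default_rng(seed)

    abundances = dict(true_relative_abundance)
    samples = sorted({s for s, _ in abundances})
    for sample in samples:
        abundances.setdefault((sample, reference_amplicon), 1.0)

    rows = []
    for sample, amplicon in sorted(abundances):
        ab = abundances[(sample, amplicon)]
        cts = baseline_ct - np.log2(ab) + rng.normal(0.0, ct_noise_sd, n_replicates)
        role = "reference" if amplicon == reference_amplicon else "target"
        row = {"sample": sample, "amplicon": amplicon, "role": role}
        row.update({f"ct_{i + 1}": float(c) for i, c in enumerate(cts)})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_segregating_ear(
    n_kernels: int, mutant_fraction: float, seed: int = 0
) -> tuple[int, int]:
    """Draw (n_normal, n_mutant) kernel counts, mutant ~ Binomial(n, fraction)."""
    if n_kernels < 1:
        raise ValueError("n_kernels must be >= 1")
    if not 0.0 <= mutant_fraction <= 1.0:
        raise ValueError("mutant_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_mutant = int(rng.binomial(n_kernels, mutant_fraction))
    return n_kernels - n_mutant, n_mutant


# ---------------------------------------------------------------------------
# Planted four-library designs


def make_planted_dataset(
    n_sites: int = 50,
    n_decreased: int = 24,
    n_increased: int = 7,
    wt_efficiency: float = 0.5,
    delta: float = 0.30,
    depth: int = 1000,
    sites_per_transcript: int = 5,
    transcript_length: int = 200,
    read_length: int = 150,
    substitution_error_rate: float = 0.001,
    seed: int = 0,
) -> tuple[SimConfig, dict[str, str]]:
    """Build a four-library design with a planted differential partition.

    Sites are spaced on short synthetic transcripts inside the window covered
    by every read of either strand, so per-site coverage equals the number
    of fragments drawn (``depth``).  The first ``n_decreased`` sites are
    planted at WT−delta in both mutant libraries, the next ``n_increased``
    at WT+delta, the remainder unchanged.  Returns the config and the
    expected call per site.
    """
    if n_decreased + n_increased > n_sites:
        raise ValueError("planted decreased+increased exceed n_sites")
    if not 0 < wt_efficiency - delta or not wt_efficiency + delta < 1:
        raise ValueError("wt_efficiency ± delta must stay inside (0, 1)")
    window_lo = transcript_length - read_length + 1  # covered by antisense reads
    window_hi = read_length  # covered by sense reads
    if window_hi - window_lo + 1 < sites_per_transcript * 2:
        raise ValueError("transcript/read geometry leaves too small a shared window")

    rng = np.random.default_rng(seed + 1)
    n_transcripts = -(-n_sites // sites_per_transcript)
    positions = np.linspace(window_lo + 5, window_hi - 5, sites_per_transcript).astype(int)

    references: dict[str, str] = {}
    sites: list[EditingSite] = []
    for t in range(n_transcripts):
        tid = f"tx{t + 1:02d}"
        seq = rng.choice(list("ACGT"), size=transcript_length)
        for p in positions:
            seq[p - 1] = "C"
        references[tid] = "".join(seq)
        for j, p in enumerate(positions):
            idx = t * sites_per_transcript + j
            if idx >= n_sites:
                break
            sites.append(EditingSite(site_id=f"{tid}-{p}", transcript_id=tid, position=int(p)))

    efficiencies: dict[tuple[str, str], float] = {}
    expected: dict[str, str] = {}
    for idx, site in enumerate(sites):
        if idx < n_decreased:
            mut_eff, call = wt_efficiency - delta, "decreased"
        elif idx < n_decreased + n_increased:
            mut_eff, call = wt_efficiency + delta, "increased"
        else:
            mut_eff, call = wt_efficiency, "unchanged"
        expected[site.site_id] = call
        for lib in WT_LIBRARIES:
            efficiencies[(lib, site.site_id)] = wt_efficiency
        for lib in MUTANT_LIBRARIES:
            efficiencies[(lib, site.site_id)] = mut_eff

    config = SimConfig(
        references=references,
        sites=sites,
        efficiencies=efficiencies,
        n_fragments=depth,
        read_length=read_length,
        substitution_error_rate=substitution_error_rate,
        seed=seed,
    )
    return config, expected


def planted_splicing_abundances(
    intron_ratios: Mapping[tuple[str, int], float],
    wt_sample: str = "WT",
    mutant_sample: str = "mut",
    wt_efficiency: float = 2.0,
    spliced_suffix: str = "spliced",
    unspliced_suffix: str = "unspliced",
) -> dict[tuple[str, str], float]:
    """Template abundances realising planted mutant/WT splicing-efficiency ratios.

    ``intron_ratios`` maps (gene, intron index) to the target ratio; amplicon
    ids follow the ``<gene>_intron<i>_<spliced|unspliced>`` convention used
    by the splicing report.
    """
    abundances: dict[tuple[str, str], float] = {}
    for (gene, idx), ratio in intron_ratios.items():
        if ratio <= 0:
            raise ValueError(f"ratio for {gene} intron {idx} must be positive")
        spliced = f"{gene}_intron{idx}_{spliced_suffix}"
        unspliced = f"{gene}_intron{idx}_{unspliced_suffix}"
        abundances[(wt_sample, unspliced)] = 1.0
        abundances[(wt_sample, spliced)] = wt_efficiency
        abundances[(mutant_sample, unspliced)] = 1.0
        abundances[(mutant_sample, spliced)] = wt_efficiency * ratio
    return abundances
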