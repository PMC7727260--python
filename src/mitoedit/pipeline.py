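"""End-to-end orchestration: simulate/load reads, align, pile up, call.

A run is described by a flat INI config (sections ``run``, ``simulate`` or
``inputs``, ``libraries``, ``align``, ``call``).  All randomness flows from
the single top-level seed.  Every run writes a manifest recording the
config snapshot, input digests and per-stage record counts; read counts
telescope (reads in = mapped + ambiguous + unmapped) by construction and
are re-checked before the manifest is written.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import align as align_mod
from . import simulate as sim_mod
from .editing import (
    DEFAULT_MIN_DEPTH,
    DEFAULT_THRESHOLD,
    DifferentialEditing,
    DifferentialEditingResults,
)
from .pileup import pileup_sites, pileups_to_frame, write_pileups_tsv
from .sites import EditingSite, read_sites_tsv, write_sites_tsv
from .splicing import (
    GeneModel,
    ct_records_from_frame,
    splicing_efficiency,
)

logger = logging.getLogger("mitoedit")


def default_log_setup(level: int = logging.WARNING) -> None:
    """Route package logging to standard error with a compact format."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


class PipelineError(Exception):
    """Base class; ``exit_code`` drives the CLI exit status."""

    exit_code = 1


class ConfigError(PipelineError):
    exit_code = 2


class InputFormatError(PipelineError):
    exit_code = 3


def read_fasta(path: str | Path) -> dict[str, str]:
    try:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    except (ValueError, FileNotFoundError) as exc:
        raise InputFormatError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise InputFormatError(f"FASTA {path} contains no sequences")
    return records


def write_fasta(references: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=tid, description="") for tid, seq in references.items()]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class PipelineConfig:
    """Resolved configuration of one editing-analysis run."""

    seed: int = 0
    wt_libraries: tuple[str, str] = sim_mod.WT_LIBRARIES
    mutant_libraries: tuple[str, str] = sim_mod.MUTANT_LIBRARIES
    sim: Optional[sim_mod.SimConfig] = None
    references: Optional[dict[str, str]] = None
    sites: Optional[list[EditingSite]] = None
    fastq_paths: dict[str, Path] = field(default_factory=dict)
    input_files: dict[str, Path] = field(default_factory=dict)
    k: int = align_mod.DEFAULT_K
    max_mismatch: int = align_mod.DEFAULT_MAX_MISMATCH
    threshold: float = DEFAULT_THRESHOLD
    min_depth: int = DEFAULT_MIN_DEPTH
    snapshot: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.wt_libraries) != 2 or len(self.mutant_libraries) != 2:
            raise ConfigError(
                "exactly two WT and two mutant libraries are required; the "
                "overlap rule is defined for the four pairwise comparisons"
            )
        if self.sim is None and (self.references is None or self.sites is None):
            raise ConfigError("config must name references and sites, or a simulation block")

    @property
    def libraries(self) -> list[str]:
        return list(self.wt_libraries) + list(self.mutant_libraries)

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        read = parser.read(str(path))
        if not read:
            raise ConfigError(f"config file {path} not found or unreadable")
        base = Path(path).resolve().parent

        def get(section: str, key: str, cast, default):
            try:
                if parser.has_option(section, key):
                    return cast(parser.get(section, key))
            except ValueError as exc:
                raise ConfigError(f"[{section}] {key}: {exc}") from exc
            return default

        seed = get("run", "seed", int, 0)
        wt = tuple(
            s.strip()
            for s in get("libraries", "wt", str, ",".join(sim_mod.WT_LIBRARIES)).split(",")
        )
        mut = tuple(
            s.strip()
            for s in get("libraries", "mutant", str, ",".join(sim_mod.MUTANT_LIBRARIES)).split(",")
        )

        sim = None
        references = None
        sites = None
        fastq_paths: dict[str, Path] = {}
        input_files: dict[str, Path] = {}
        if parser.has_section("simulate"):
            if wt != sim_mod.WT_LIBRARIES or mut != sim_mod.MUTANT_LIBRARIES:
                raise ConfigError("simulation blocks use the built-in library names")
            sim, _ = sim_mod.make_planted_dataset(
                n_sites=get("simulate", "n_sites", int, 50),
                n_decreased=get("simulate", "n_decreased", int, 24),
                n_increased=get("simulate", "n_increased", int, 7),
                wt_efficiency=get("simulate", "wt_efficiency", float, 0.5),
                delta=get("simulate", "delta", float, 0.30),
                depth=get("simulate", "depth", int, 1000),
                read_length=get("simulate", "read_length", int, 150),
                substitution_error_rate=get("simulate", "error_rate", float, 0.001),
                seed=seed,
            )
        elif parser.has_section("inputs"):
            ref_path = base / get("inputs", "references", str, "")
            sites_path = base / get("inputs", "sites", str, "")
            references = read_fasta(ref_path)
            try:
                sites = read_sites_tsv(sites_path)
            except (ValueError, FileNotFoundError) as exc:
                raise InputFormatError(f"cannot read site table {sites_path}: {exc}") from exc
            input_files["references"] = ref_path
            input_files["sites"] = sites_path
            for lib in (*wt, *mut):
                key = f"fastq_{lib}"
                if not parser.has_option("inputs", key):
                    raise ConfigError(f"[inputs] missing {key}")
                fq = base / parser.get("inputs", key)
                fastq_paths[lib] = fq
                input_files[key] = fq
        else:
            raise ConfigError("config needs a [simulate] or [inputs] section")

        return cls(
            seed=seed,
            wt_libraries=wt,  # type: ignore[arg-type]
            mutant_libraries=mut,  # type: ignore[arg-type]
            sim=sim,
            references=references,
            sites=sites,
            fastq_paths=fastq_paths,
            input_files=input_files,
            k=get("align", "k", int, align_mod.DEFAULT_K),
            max_mismatch=get("align", "max_mismatch", int, align_mod.DEFAULT_MAX_MISMATCH),
            threshold=get("call", "threshold", float, DEFAULT_THRESHOLD),
            min_depth=get("call", "min_depth", int, DEFAULT_MIN_DEPTH),
            snapshot={s: dict(parser.items(s)) for s in parser.sections()},
        )


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    seed: int
    config_snapshot: dict
    input_digests: dict[str, str]
    library_counts: dict[str, dict[str, int]]
    sites_quantified: int = 0
    low_coverage: int = 0
    decreased: int = 0
    increased: int = 0

    def validate(self) -> None:
        for lib, counts in self.library_counts.items():
            total = counts["mapped"] + counts["ambiguous"] + counts["unmapped"]
            if counts["reads_in"] != total:
                raise PipelineError(
                    f"manifest counts do not telescope for {lib}: "
                    f"{counts['reads_in']} != {total}"
                )

    def to_json(self, path: str | Path) -> None:
        self.validate()
        payload = {
            "seed": self.seed,
            "config": self.config_snapshot,
            "input_digests": self.input_digests,
            "libraries": self.library_counts,
            "sites": {
                "quantified": self.sites_quantified,
                "low_coverage": self.low_coverage,
                "decreased": self.decreased,
                "increased": self.increased,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_editing_pipeline(
    config: PipelineConfig | str | Path, outdir: str | Path
) -> tuple[DifferentialEditingResults, RunManifest]:
    """Execute simulate (optional) -> align -> pileup -> call; write outputs.

    Writes ``calls.tsv``, ``pileups.tsv`` and ``manifest.json`` to
    ``outdir`` (plus the generated FASTQ, reference, site and truth files
    when simulating).  Deterministic given the config seed.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_ini(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        logger.info("simulating reads for %d libraries", len(config.sim.libraries))
        reads, truth = sim_mod.simulate_editing_reads(config.sim)
        references = config.sim.references
        sites = config.sim.sites
        fastq_paths = sim_mod.write_libraries_fastq(reads, outdir)
        write_fasta(references, outdir / "references.fasta")
        write_sites_tsv(sites, outdir / "sites.tsv")
        truth.origins.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        input_files = dict(fastq_paths)
    else:
        references = config.references
        sites = config.sites
        fastq_paths = config.fastq_paths
        reads = {}
        for lib, path in fastq_paths.items():
            try:
                reads[lib] = sim_mod.read_fastq(path)
            except (ValueError, FileNotFoundError) as exc:
                raise InputFormatError(f"cannot read FASTQ {path}: {exc}") from exc
        input_files = dict(config.input_files)

    missing = [lib for lib in config.libraries if lib not in reads]
    if missing:
        raise ConfigError(f"no reads for libraries: {missing}")

    index = align_mod.ReferenceIndex(references, k=config.k)
    library_counts: dict[str, dict[str, int]] = {}
    pileups_by_library = {}
    for lib in config.libraries:
        alignments = [
            index.align_read(rid, seq, config.max_mismatch) for rid, seq in reads[lib]
        ]
        counts = {
            "reads_in": len(alignments),
            "mapped": sum(a.status == "unique" for a in alignments),
            "ambiguous": sum(a.status == "ambiguous" for a in alignments),
            "unmapped": sum(a.status == "unmapped" for a in alignments),
        }
        library_counts[lib] = counts
        if counts["reads_in"] == 0:
            logger.warning("library %s contributed zero reads", lib)
        pileups_by_library[lib] = pileup_sites(
            alignments, sites, lib, known_transcripts=references
        )
        logger.info(
            "library %s: %d reads, %d mapped, %d ambiguous, %d unmapped",
            lib, counts["reads_in"], counts["mapped"], counts["ambiguous"], counts["unmapped"],
        )

    all_pileups = [p for lib in config.libraries for p in pileups_by_library[lib]]
    write_pileups_tsv(all_pileups, outdir / "pileups.tsv")

    model = DifferentialEditing.from_pileups(
        pileups_by_library,
        wt_libraries=config.wt_libraries,
        mutant_libraries=config.mutant_libraries,
        sites=sites,
    )
    results = model.fit(threshold=config.threshold, min_depth=config.min_depth)
    results.to_tsv(outdir / "calls.tsv")
    if results.n_low_coverage == len(results.table) and len(results.table) > 0:
        logger.warning("every site is low_coverage; check inputs")

    manifest = RunManifest(
        seed=config.seed,
        config_snapshot=config.snapshot,
        input_digests={str(name): _sha256(Path(p)) for name, p in input_files.items()},
        library_counts=library_counts,
        sites_quantified=len(results.table) - results.n_low_coverage,
        low_coverage=results.n_low_coverage,
        decreased=results.n_decreased,
        increased=results.n_increased,
    )
    manifest.to_json(outdir / "manifest.json")
    return results, manifest


# ---------------------------------------------------------------------------
# Splicing report


def run_splicing_report(
    ct_table: pd.DataFrame,
    models: Mapping[str, GeneModel],
    mutant_sample: str = "mut",
    wt_sample: str = "WT",
    reference_amplicon: str = "actin",
    spliced_suffix: str = "spliced",
    unspliced_suffix: str = "unspliced",
) -> pd.DataFrame:
    """Per-intron splicing-efficiency report from a Ct table.

    Amplicons follow the ``<gene>_intron<i>_<spliced|unspliced>`` naming
    convention.  Introns lacking an amplicon in either sample yield a
    flagged row rather than an error.  Columns: gene, intron, splice_mode,
    efficiency_wt, efficiency_mut, ratio, flag.
    """
    columns = ["gene", "intron", "splice_mode", "efficiency_wt", "efficiency_mut", "ratio", "flag"]
    if ct_table.empty:
        warnings.warn("empty Ct table; splicing report is empty")
        return pd.DataFrame(columns=columns)

    records = ct_records_from_frame(ct_table)
    by_amplicon: dict[str, list] = {}
    for rec in records:
        by_amplicon.setdefault(rec.amplicon_id, []).append(rec)
    reference = by_amplicon.get(reference_amplicon)
    if not reference:
        raise InputFormatError(f"Ct table lacks reference amplicon {reference_amplicon!r}")

    rows = []
    for gene in sorted(models):
        model = models[gene]
        for intron in model.introns:
            spliced = by_amplicon.get(f"{gene}_intron{intron.index}_{spliced_suffix}", [])
            unspliced = by_amplicon.get(f"{gene}_intron{intron.index}_{unspliced_suffix}", [])
            row = {
                "gene": gene,
                "intron": intron.index,
                "splice_mode": intron.splice_mode,
                "efficiency_wt": float("nan"),
                "efficiency_mut": float("nan"),
                "ratio": float("nan"),
                "flag": "",
            }
            try:
                result = splicing_efficiency(
                    spliced, unspliced, reference, mutant_sample, wt_sample,
                    gene=gene, intron=intron.index,
                )
            except KeyError as exc:
                row["flag"] = "missing_amplicon"
                logger.warning("%s intron %d: %s", gene, intron.index, exc)
            else:
                row.update(
                    efficiency_wt=result.efficiency_wt,
                    efficiency_mut=result.efficiency_mut,
                    ratio=result.ratio,
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=columns)
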