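"""Shared test utilities: an exhaustive alignment oracle and a pipeline runner.

The oracle is deliberately independent of the package's seeded aligner: it
scores every placement of the read on both strands of every reference by
direct mismatch counting and applies the same unique/ambiguous/unmapped
classification rule.
"""

from __future__ import annotations

from mitoedit._seq import revcomp
from mitoedit.editing import DifferentialEditingResults
from mitoedit.pileup import pileup_sites
from mitoedit.simulate import SimConfig, simulate_editing_reads


def brute_force_align(seq, references, max_mismatch=5):
    """Exhaustively score every placement; returns (status, best_loci, best_mm).

    best_loci is the set of (transcript_id, 1-based start, strand) achieving
    the minimum mismatch count within threshold.
    """
    seq = seq.upper()
    length = len(seq)
    best_mm = max_mismatch + 1
    best = set()
    for strand, oriented in (("sense", seq), ("antisense", revcomp(seq))):
        for tid, ref in references.items():
            ref = ref.upper()
            for start in range(len(ref) - length + 1):
                mm = sum(a != b for a, b in zip(ref[start : start + length], oriented))
                if mm < best_mm:
                    best_mm = mm
                    best = {(tid, start + 1, strand)}
                elif mm == best_mm:
                    best.add((tid, start + 1, strand))
    if best_mm > max_mismatch:
        return "unmapped", set(), None
    return ("unique" if len(best) == 1 else "ambiguous"), best, best_mm


def simulate_align_pileup(config: SimConfig, k=20, max_mismatch=5):
    """Full simulate -> align -> pileup chain; returns (pileups, alignments, truth)."""
    from mitoedit.align import ReferenceIndex

    reads, truth = simulate_editing_reads(config)
    index = ReferenceIndex(config.references, k=k)
    alignments = {
        lib: [index.align_read(rid, seq, max_mismatch) for rid, seq in lib_reads]
        for lib, lib_reads in reads.items()
    }
    pileups = {
        lib: pileup_sites(alns, config.sites, lib) for lib, alns in alignments.items()
    }
    return pileups, alignments, truth


def fit_planted(config: SimConfig) -> DifferentialEditingResults:
    """Run the four-library chain and fit the differential model."""
    from mitoedit.editing import DifferentialEditing

    pileups, _, _ = simulate_align_pileup(config)
    model = DifferentialEditing.from_pileups(pileups, sites=config.sites)
    return model.fit()
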