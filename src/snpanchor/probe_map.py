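"""Place chip probes on a consensus genome and project SNP offsets.

The placement engine uses exact k-mer seeding (both strands) followed by
full-length ungapped extension scored by identity.  This is deterministic
and well suited to short array probes (~50-100 bp); gapped or spliced
placement is out of scope.  Genome N bases never count as a match.

A probe with two or more equally best locations is never resolved
arbitrarily: it is reported as ambiguous and its locus stays uncalled
downstream.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .core_io import ProbeRecord, SeqRecord, revcomp

logger = logging.getLogger(__name__)

Status = Literal["unique", "ambiguous", "unplaced"]

DEFAULT_K = 21
DEFAULT_MIN_IDENTITY = 0.95


@dataclass(frozen=True)
class Placement:
    """Where and how a probe maps on the genome.

    ``start``/``end`` are 0-based half-open genome coordinates of the
    full-length probe footprint; ``identity`` is matches / probe length.
    ``n_best`` counts equally best locations at maximal identity.
    """

    probe_id: str
    target_id: str | None
    start: int | None
    end: int | None
    strand: str | None  # '+' or '-'
    identity: float | None
    n_best: int
    status: Status


@dataclass(frozen=True)
class SnpLocus:
    """A probe's SNP position projected into genome coordinates."""

    probe_id: str
    target_id: str
    snp_pos: int  # 0-based
    strand: str


class GenomeIndex:
    """Exact k-mer index over a set of genome sequences.

    Maps every k-mer to its (sequence index, offset) occurrences.  Built once
    and shared across probes.
    """

    def __init__(self, genome: Sequence[SeqRecord], k: int = DEFAULT_K):
        if not genome:
            raise ValueError("genome is empty")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.records = list(genome)
        self.index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for si, rec in enumerate(self.records):
            seq = rec.sequence
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" not in kmer:
                    self.index[kmer].append((si, off))


def _ungapped_identity(genome_seq: str, start: int, probe_seq: str) -> float | None:
    """Identity of the probe laid ungapped at ``start``; None if out of bounds.

    A genome N never matches, so probes over assembly gaps score low.
    """
    end = start + len(probe_seq)
    if start < 0 or end > len(genome_seq):
        return None
    window = genome_seq[start:end]
    matches = sum(
        1 for g, p in zip(window, probe_seq) if g == p and g != "N"
    )
    return matches / len(probe_seq)


def place_probe(
    probe: ProbeRecord,
    genome: Sequence[SeqRecord] | GenomeIndex,
    k: int = DEFAULT_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> Placement:
    """Place one probe on the genome by k-mer seeding + ungapped extension.

    Candidate locations come from exact k-mer seed hits of the probe (both
    strands); each candidate is extended to the full probe length and scored
    by identity.  The location(s) with maximal identity >= ``min_identity``
    are reported: exactly one maximum -> unique, two or more -> ambiguous,
    none -> unplaced.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, k)
    k = index.k
    if len(probe.sequence) < k:
        raise ValueError(
            f"probe {probe.probe_id!r} shorter ({len(probe.sequence)}) than k={k}"
        )

    plen = len(probe.sequence)
    # candidate (seq_idx, start, strand); for '-' candidates the probe is
    # compared as its reverse complement laid on the plus strand
    candidates: set[tuple[int, int, str]] = set()
    for strand, qseq in (("+", probe.sequence), ("-", revcomp(probe.sequence))):
        for qoff in range(plen - k + 1):
            kmer = qseq[qoff : qoff + k]
            for si, goff in index.index.get(kmer, ()):
                candidates.add((si, goff - qoff, strand))

    best_identity = 0.0
    best: list[tuple[int, int, str]] = []
    for si, start, strand in sorted(candidates):
        qseq = probe.sequence if strand == "+" else revcomp(probe.sequence)
        ident = _ungapped_identity(index.records[si].sequence, start, qseq)
        if ident is None:
            continue
        if ident > best_identity + 1e-12:
            best_identity = ident
            best = [(si, start, strand)]
        elif abs(ident - best_identity) <= 1e-12 and best_identity > 0:
            best.append((si, start, strand))

    if not best or best_identity < min_identity:
        return Placement(probe.probe_id, None, None, None, None, None, 0, "unplaced")
    # a revcomp-palindromic probe hits one location on both strands: count
    # distinct genome locations, preferring '+' at a tied location
    by_location: dict[tuple[int, int], str] = {}
    for si, start, strand in sorted(best):
        by_location.setdefault((si, start), strand)
    best = [(si, start, strand) for (si, start), strand in sorted(by_location.items())]
    if len(best) > 1:
        si, start, strand = min(best)
        return Placement(
            probe.probe_id,
            index.records[si].id,
            start,
            start + plen,
            strand,
            best_identity,
            len(best),
            "ambiguous",
        )
    si, start, strand = best[0]
    return Placement(
        probe.probe_id,
        index.records[si].id,
        start,
        start + plen,
        strand,
        best_identity,
        1,
        "unique",
    )


def project_snp(placement: Placement, probe: ProbeRecord) -> SnpLocus:
    """Project the probe's SNP offset into genome coordinates.

    Plus strand: snp_pos = start + snp_offset.
    Minus strand: the probe reads right-to-left on the genome, so
    snp_pos = end - 1 - snp_offset.
    """
    if placement.status != "unique":
        raise ValueError(
            f"probe {probe.probe_id!r}: cannot project SNP of a "
            f"{placement.status} placement"
        )
    if placement.strand == "+":
        pos = placement.start + probe.snp_offset
    else:
        pos = placement.end - 1 - probe.snp_offset
    return SnpLocus(probe.probe_id, placement.target_id, pos, placement.strand)


def place_all(
    probes: Sequence[ProbeRecord],
    genome: Sequence[SeqRecord] | GenomeIndex,
    k: int = DEFAULT_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[list[Placement], dict[str, int]]:
    """Place every probe; returns placements in input order plus status counts.

    Per-probe errors (e.g. a probe shorter than k) are downgraded to
    unplaced with a logged reason, so one bad probe never aborts the batch.
    """
    if not probes:
        raise ValueError("no probes to place")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, k)
    placements: list[Placement] = []
    counts = {"unique": 0, "ambiguous": 0, "unplaced": 0}
    for probe in probes:
        try:
            pl = place_probe(probe, index, k, min_identity)
        except ValueError as exc:
            logger.warning("probe %s unplaced: %s", probe.probe_id, exc)
            pl = Placement(probe.probe_id, None, None, None, None, None, 0, "unplaced")
        placements.append(pl)
        counts[pl.status] += 1
    return placements, counts


@dataclass(frozen=True)
class UncalledRegion:
    """A run of uncalled loci on one chromosome (positions in bp, 0-based)."""

    chrom: str
    min_pos: int
    max_pos: int
    n_loci: int


def cluster_uncalled(
    positions: Iterable[tuple[str, int]], max_gap: int
) -> list[UncalledRegion]:
    """Group uncalled loci into contiguous genomic regions per chromosome.

    Single linkage: consecutive sorted positions at most ``max_gap`` bp apart
    join the same region.  Used to flag chromosome stretches where calling
    failed systematically (candidate structural variants or coverage gaps).
    """
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in positions:
        by_chrom[chrom].append(pos)
    regions: list[UncalledRegion] = []
    for chrom in sorted(by_chrom):
        pos_sorted = sorted(by_chrom[chrom])
        run_start = 0
        for i in range(1, len(pos_sorted) + 1):
            if i == len(pos_sorted) or pos_sorted[i] - pos_sorted[i - 1] > max_gap:
                run = pos_sorted[run_start:i]
                regions.append(UncalledRegion(chrom, run[0], run[-1], len(run)))
                run_start = i
    return regions


def write_placement_report(placements: Iterable[Placement], path) -> None:
    """TSV placement report (0-based start, half-open end)."""
    with open(path, "w") as fh:
        fh.write("probe_id\ttarget\tstart_0based\tend\tstrand\tidentity\tn_best\tstatus\n")
        for p in placements:
            fh.write(
                "\t".join(
                    [
                        p.probe_id,
                        p.target_id or ".",
                        "." if p.start is None else str(p.start),
                        "." if p.end is None else str(p.end),
                        p.strand or ".",
                        "." if p.identity is None else f"{p.identity:.4f}",
                        str(p.n_best),
                        p.status,
                    ]
                )
                + "\n"
            )
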