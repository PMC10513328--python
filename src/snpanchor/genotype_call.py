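"""Extract genotypes at projected SNP positions and build pseudomolecules.

Every call is expressed in probe (chip) orientation so that sequence-derived
calls and panel chip genotypes are directly comparable: a minus-strand
placement has its genome base complemented before allele validation.

The input genome is a consensus sequence, so every sequence-derived call is
a single letter (homozygous).  A consensus base agreeing with neither chip
allele is treated as missing by default ("allele_mismatch" policy), because
it is more likely a placement or consensus artifact than a true third allele.

The pseudomolecule is a synthetic sequence with one character per panel
locus in the panel's canonical order; loci without a call are N-padded, so
pseudomolecules of different accessions are positionally aligned by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .core_io import GenotypeMatrix, ProbeRecord, SeqRecord, complement_base
from .probe_map import SnpLocus

CallStatus = Literal["called", "missing_base", "allele_mismatch", "uncalled_locus"]


@dataclass(frozen=True)
class GenotypeCall:
    """A single-locus genotype call in chip orientation."""

    probe_id: str
    call: str
    status: CallStatus


@dataclass(frozen=True)
class Pseudomolecule:
    """Concatenated one-character-per-locus genotype string of one accession."""

    accession_id: str
    sequence: str

    def to_seqrecord(self) -> SeqRecord:
        return SeqRecord(self.accession_id, self.sequence)


def extract_call(
    locus: SnpLocus,
    genome: Sequence[SeqRecord] | Mapping[str, SeqRecord],
    probe: ProbeRecord,
    keep_mismatch: bool = False,
) -> GenotypeCall:
    """Read the genome base at the SNP position and validate it.

    Minus-strand loci are complemented into chip orientation.  Genome N ->
    missing_base.  A base outside {allele_a, allele_b, their ambiguity
    letter} -> allele_mismatch, reported as N unless ``keep_mismatch``.
    """
    if isinstance(genome, Mapping):
        by_id = genome
    else:
        by_id = {r.id: r for r in genome}
    try:
        target = by_id[locus.target_id]
    except KeyError:
        raise ValueError(f"locus {locus.probe_id!r}: unknown target {locus.target_id!r}")
    if not (0 <= locus.snp_pos < len(target.sequence)):
        raise ValueError(
            f"locus {locus.probe_id!r}: snp_pos {locus.snp_pos} outside "
            f"{locus.target_id!r} (length {len(target.sequence)})"
        )
    base = target.sequence[locus.snp_pos]
    if locus.strand == "-":
        base = complement_base(base)
    if base == "N":
        return GenotypeCall(locus.probe_id, "N", "missing_base")
    valid = {probe.allele_a, probe.allele_b, probe.het}
    if base not in valid:
        return GenotypeCall(
            locus.probe_id, base if keep_mismatch else "N", "allele_mismatch"
        )
    return GenotypeCall(locus.probe_id, base, "called")


def build_pseudomolecule(
    calls: Iterable[GenotypeCall],
    panel_loci: Sequence[str],
    accession_id: str,
) -> Pseudomolecule:
    """Assemble calls into a pseudomolecule over the panel's locus order.

    Loci without a call get N, so the output length always equals the panel
    locus count.
    """
    locus_set = set(panel_loci)
    by_locus: dict[str, str] = {}
    for call in calls:
        if call.probe_id not in locus_set:
            raise ValueError(f"call for {call.probe_id!r} not among panel loci")
        if call.probe_id in by_locus:
            raise ValueError(f"duplicate call for locus {call.probe_id!r}")
        by_locus[call.probe_id] = call.call
    seq = "".join(by_locus.get(locus, "N") for locus in panel_loci)
    return Pseudomolecule(accession_id, seq)


def call_summary(total_loci: int, uncalled: int) -> tuple[int, float, float]:
    """Called/uncalled counts and percentages (2 decimals, half-up rounding).

    The uncalled percentage is computed as 100 minus the called percentage so
    the two always reconcile to exactly 100.00.
    """
    if total_loci <= 0:
        raise ValueError("total_loci must be positive")
    if not (0 <= uncalled <= total_loci):
        raise ValueError("uncalled must be in [0, total_loci]")
    from decimal import ROUND_HALF_UP, Decimal

    called = total_loci - uncalled
    called_pct = float(
        (Decimal(100 * called) / Decimal(total_loci)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    uncalled_pct = round(100.0 - called_pct, 2)
    return called, called_pct, uncalled_pct


def merge_into_panel(
    pseudo: Pseudomolecule, panel: GenotypeMatrix
) -> GenotypeMatrix:
    """Append the accession's pseudomolecule as the last row of the panel."""
    if len(pseudo.sequence) != len(panel.loci):
        raise ValueError(
            f"pseudomolecule length {len(pseudo.sequence)} != "
            f"panel locus count {len(panel.loci)}"
        )
    if pseudo.accession_id in panel.accessions:
        raise ValueError(f"accession {pseudo.accession_id!r} already in panel")
    calls = np.vstack([panel.calls, np.array(list(pseudo.sequence), dtype="<U1")])
    return GenotypeMatrix(
        panel.accessions + [pseudo.accession_id], list(panel.loci), calls
    )


def write_call_table(
    calls: Sequence[GenotypeCall],
    loci: Mapping[str, SnpLocus],
    path,
) -> None:
    """Per-locus call TSV; positions printed 1-based in a named column."""
    with open(path, "w") as fh:
        fh.write("probe_id\ttarget\tpos_1based\tstrand\tcall\tstatus\n")
        for call in calls:
            locus = loci.get(call.probe_id)
            if locus is None:
                fh.write(f"{call.probe_id}\t.\t.\t.\t{call.call}\t{call.status}\n")
            else:
                fh.write(
                    f"{call.probe_id}\t{locus.target_id}\t{locus.snp_pos + 1}\t"
                    f"{locus.strand}\t{call.call}\t{call.status}\n"
                )
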