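"""Domain types and readers/writers for the formats the pipeline touches.

Genotypes are encoded one IUPAC character per call: homozygotes as the plain
base (A/C/G/T), diploid heterozygotes as the two-allele ambiguity letter
(R = A/G, Y = C/T, ...), missing data as N.  This single-letter encoding is
what makes chip genotypes and sequence-derived calls directly concatenable
into pseudomolecules.

All internal coordinates are 0-based, half-open.  Human-readable reports
print 1-based positions in a clearly named column; BED exports are 0-based
half-open.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: ambiguity letter for each unordered pair of bases (diploid heterozygote)
HET_CODES = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

#: inverse of HET_CODES: ambiguity letter -> the two bases it encodes
HET_ALLELES = {code: tuple(sorted(pair)) for pair, code in HET_CODES.items()}


class FormatError(ValueError):
    """A file or record violates its declared format."""


def het_code(allele_a: str, allele_b: str) -> str:
    """IUPAC ambiguity letter for the heterozygote of two distinct bases."""
    try:
        return HET_CODES[frozenset((allele_a, allele_b))]
    except KeyError:
        raise ValueError(f"no ambiguity code for alleles {allele_a!r}/{allele_b!r}")


def revcomp(sequence: str) -> str:
    """Reverse complement with full IUPAC ambiguity support (R<->Y, N<->N...).

    Raises ``ValueError`` on any character outside the IUPAC nucleotide
    alphabet.
    """
    bad = set(sequence) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC character(s) in sequence: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    """Complement of a single IUPAC base."""
    if base not in IUPAC_ALPHABET:
        raise ValueError(f"non-IUPAC base {base!r}")
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence (e.g. one chromosome of a consensus genome)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"SeqRecord {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"SeqRecord {self.id!r}: non-IUPAC character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProbeRecord:
    """A chip probe: flanking sequence, SNP offset within it, and A/B alleles.

    ``snp_offset`` is a 0-based index into ``sequence``; the probe sequence is
    in chip orientation, so genome hits on the minus strand must be
    complemented before allele comparison.
    """

    probe_id: str
    sequence: str
    snp_offset: int
    allele_a: str
    allele_b: str
    chrom_hint: str | None = None
    pos_hint: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.snp_offset < len(self.sequence)):
            raise ValueError(
                f"probe {self.probe_id!r}: snp_offset {self.snp_offset} outside "
                f"sequence of length {len(self.sequence)}"
            )
        if self.allele_a == self.allele_b:
            raise ValueError(f"probe {self.probe_id!r}: alleles must differ")
        for a in (self.allele_a, self.allele_b):
            if a not in "ACGT":
                raise ValueError(f"probe {self.probe_id!r}: allele {a!r} not in ACGT")
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"probe {self.probe_id!r}: non-IUPAC character(s) {sorted(bad)}"
            )

    @property
    def het(self) -> str:
        """Ambiguity letter of the heterozygous A/B genotype."""
        return het_code(self.allele_a, self.allele_b)


@dataclass
class GenotypeMatrix:
    """Accessions x loci table of single-character IUPAC genotype calls."""

    accessions: list[str]
    loci: list[str]
    calls: np.ndarray  # dtype '<U1', shape (n_accessions, n_loci)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.accessions), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.accessions)}, {len(self.loci)})"
            )
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession ids")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus ids")
        bad = set(self.calls.ravel().tolist()) - IUPAC_ALPHABET
        if bad:
            raise ValueError(f"illegal genotype call character(s): {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def row(self, accession: str) -> np.ndarray:
        return self.calls[self.accessions.index(accession)]

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.loci.index(l) for l in locus_ids]
        return GenotypeMatrix(list(self.accessions), list(locus_ids), self.calls[:, idx])

    def subset_accessions(self, accession_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.accessions.index(a) for a in accession_ids]
        return GenotypeMatrix(list(accession_ids), list(self.loci), self.calls[idx, :])

    def drop_accession(self, accession_id: str) -> "GenotypeMatrix":
        keep = [a for a in self.accessions if a != accession_id]
        if len(keep) == len(self.accessions):
            raise KeyError(accession_id)
        return self.subset_accessions(keep)


@dataclass
class DescriptorTable:
    """Accessions x morphological descriptors, numeric ordinal scores.

    Emulates a CPVO/UPOV descriptor sheet: each column is a standardized
    plant-morphology trait scored on an ordinal scale.
    """

    accessions: list[str]
    descriptors: list[str]
    values: np.ndarray  # float, shape (n_accessions, n_descriptors)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.accessions), len(self.descriptors)):
            raise ValueError("values shape mismatch")
        if len(self.accessions) < 3:
            raise ValueError("need at least 3 accessions")
        if len(self.descriptors) < 2:
            raise ValueError("need at least 2 descriptors")
        if np.isnan(self.values).any():
            raise ValueError("missing cells in descriptor table; impute before PCA")


# ---------------------------------------------------------------------------
# FASTA


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTA file into validated records.

    The header token before the first whitespace becomes the id; sequences
    are uppercased.  Empty files, duplicate ids and non-IUPAC characters are
    reported as :class:`FormatError` naming the offending record.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            bad = set(seq) - IUPAC_ALPHABET
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r} contains non-IUPAC "
                    f"character(s) {sorted(bad)}"
                )
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
            records.append(SeqRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[SeqRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records as wrapped FASTA; round-trips through :func:`read_fasta`."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# genotype tables


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read an accessions x loci CSV of IUPAC calls (header = locus ids).

    Lowercase calls are uppercased.  Ragged rows are reported with their
    1-based row number.
    """
    with _open_text(path) as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file")
        loci = header[1:]
        if not loci:
            raise FormatError(f"{path}: header has no locus columns")
        accessions: list[str] = []
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: row {lineno} has {len(row)} fields, "
                    f"expected {len(header)}"
                )
            accessions.append(row[0])
            rows.append([c.strip().upper() for c in row[1:]])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    calls = np.array(rows, dtype="<U1")
    return GenotypeMatrix(accessions, loci, calls)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the counterpart of :func:`read_genotype_table` (CSV, header row)."""
    with _open_text(path, "wt") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["accession"] + list(matrix.loci))
        for acc, row in zip(matrix.accessions, matrix.calls):
            writer.writerow([acc] + row.tolist())


# ---------------------------------------------------------------------------
# probe tables (CSV is canonical; FASTA + sidecar CSV also accepted)

_PROBE_FIELDS = ["probe_id", "sequence", "snp_offset", "allele_a", "allele_b"]


def read_probe_table(path: str | Path) -> list[ProbeRecord]:
    """Read probes from CSV with columns probe_id, sequence, snp_offset,
    allele_a, allele_b and optional chrom_hint, pos_hint."""
    probes: list[ProbeRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        missing = set(_PROBE_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing probe columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            pid = row["probe_id"]
            if pid in seen:
                raise FormatError(f"{path}: duplicate probe id {pid!r} (row {lineno})")
            seen.add(pid)
            try:
                probes.append(
                    ProbeRecord(
                        probe_id=pid,
                        sequence=row["sequence"].upper(),
                        snp_offset=int(row["snp_offset"]),
                        allele_a=row["allele_a"].upper(),
                        allele_b=row["allele_b"].upper(),
                        chrom_hint=row.get("chrom_hint") or None,
                        pos_hint=int(row["pos_hint"]) if row.get("pos_hint") else None,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {lineno}: {exc}") from exc
    if not probes:
        raise FormatError(f"{path}: no probes")
    return probes


def write_probe_table(probes: Iterable[ProbeRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_PROBE_FIELDS + ["chrom_hint", "pos_hint"])
        for p in probes:
            writer.writerow(
                [
                    p.probe_id,
                    p.sequence,
                    p.snp_offset,
                    p.allele_a,
                    p.allele_b,
                    p.chrom_hint or "",
                    p.pos_hint if p.pos_hint is not None else "",
                ]
            )


def read_probes_fasta(
    fasta_path: str | Path, sidecar_csv: str | Path
) -> list[ProbeRecord]:
    """Read probe sequences from FASTA plus a sidecar CSV of
    probe_id, snp_offset, allele_a, allele_b."""
    seqs = {r.id: r.sequence for r in read_fasta(fasta_path)}
    probes: list[ProbeRecord] = []
    with _open_text(sidecar_csv) as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            pid = row["probe_id"]
            if pid not in seqs:
                raise FormatError(
                    f"{sidecar_csv}: row {lineno}: probe {pid!r} not in FASTA"
                )
            probes.append(
                ProbeRecord(
                    probe_id=pid,
                    sequence=seqs[pid],
                    snp_offset=int(row["snp_offset"]),
                    allele_a=row["allele_a"].upper(),
                    allele_b=row["allele_b"].upper(),
                )
            )
    return probes


# ---------------------------------------------------------------------------
# descriptor tables


def read_descriptor_table(path: str | Path) -> DescriptorTable:
    """Read an accessions x descriptors numeric CSV (header = descriptor names)."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return DescriptorTable(
        accessions=[str(a) for a in df.index],
        descriptors=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_descriptor_table(table: DescriptorTable, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        table.values, index=table.accessions, columns=table.descriptors
    ).to_csv(path, index_label="accession")


# ---------------------------------------------------------------------------
# BED export


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name) intervals as BED (0-based, half-open)."""
    with _open_text(path, "wt") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
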