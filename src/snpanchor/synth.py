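"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator is a pure function of its seed and parameters (one
``numpy.random.default_rng`` per call, no global state), so fixtures are
bit-reproducible across platforms.  Default sizes mirror the real study's
scale at roughly one tenth (~350 loci, 26 accessions) so a full synthetic
pipeline run stays fast.

The truth objects record where every probe was implanted, which allele the
genome carries at each SNP site, the generating allele frequencies of the
panel, the implanted duplicate pairs with their realised homozygous
difference, and the generating covariance of the descriptor table — so
every pipeline stage can be checked against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    DescriptorTable,
    GenotypeMatrix,
    ProbeRecord,
    SeqRecord,
    het_code,
    revcomp,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ProbeTruth:
    """Ground truth for one implanted probe."""

    probe_id: str
    chrom: str
    start: int  # 0-based genome start of the probe footprint
    strand: str
    snp_pos: int  # 0-based genome coordinate of the SNP site
    true_allele: str  # chip-orientation allele written into the genome
    n_mutations: int


@dataclass
class PanelTruth:
    """Ground truth for a simulated genotype panel."""

    allele_pairs: list[tuple[str, str]]
    allele_freqs: np.ndarray
    duplicate_pairs: list[tuple[str, str]]
    divergent_pairs: list[tuple[str, str]] = field(default_factory=list)
    expected_hom_diff: dict[tuple[str, str], float] = field(default_factory=dict)


def make_genome(seed: int, length: int = 50_000, n_chrom: int = 2) -> list[SeqRecord]:
    """Uniform random A/C/G/T chromosomes named chr1..chrN, ``length`` bp each."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)
    return [
        SeqRecord(f"chr{i + 1}", "".join(rng.choice(_BASES, size=length)))
        for i in range(n_chrom)
    ]


def implant_probes(
    genome: list[SeqRecord],
    seed: int,
    n_probes: int = 100,
    probe_len: int = 70,
    mutations_per_probe: int = 0,
    strand_mix: float = 0.5,
) -> tuple[list[SeqRecord], list[ProbeRecord], list[ProbeTruth]]:
    """Write probe footprints into the genome at known positions.

    Each probe is a random sequence carrying its allele A at the SNP offset.
    The genome copy carries a randomly chosen true allele (A or B) at the
    SNP site plus up to ``mutations_per_probe`` substitutions placed away
    from the SNP offset; with probability ``strand_mix`` the reverse
    complement is implanted instead.  Implant sites never overlap.
    """
    rng = np.random.default_rng(seed)
    slot = probe_len + 10  # gap between implants so footprints never touch
    slots_per_chrom = [(len(rec) // slot) for rec in genome]
    total_slots = sum(slots_per_chrom)
    if total_slots < n_probes:
        raise ValueError(
            f"genome too small: {total_slots} non-overlapping slots "
            f"for {n_probes} probes"
        )
    chosen = rng.choice(total_slots, size=n_probes, replace=False)
    chosen.sort()

    seqs = [list(rec.sequence) for rec in genome]
    probes: list[ProbeRecord] = []
    truths: list[ProbeTruth] = []
    bounds = np.cumsum([0] + slots_per_chrom)
    for pi, slot_idx in enumerate(chosen):
        ci = int(np.searchsorted(bounds, slot_idx, side="right") - 1)
        start = int(slot_idx - bounds[ci]) * slot
        probe_seq = rng.choice(_BASES, size=probe_len)
        snp_offset = int(rng.integers(probe_len))
        allele_a, allele_b = rng.choice(_BASES, size=2, replace=False)
        probe_seq[snp_offset] = allele_a
        true_allele = allele_a if rng.random() < 0.5 else allele_b

        implant = probe_seq.copy()
        implant[snp_offset] = true_allele
        if mutations_per_probe > 0:
            non_snp = np.array([i for i in range(probe_len) if i != snp_offset])
            n_mut = int(rng.integers(mutations_per_probe + 1))
            mut_sites = rng.choice(non_snp, size=n_mut, replace=False)
            for m in mut_sites:
                others = [b for b in "ACGT" if b != implant[m]]
                implant[m] = rng.choice(others)
        else:
            n_mut = 0

        strand = "-" if rng.random() < strand_mix else "+"
        implant_str = "".join(implant)
        if strand == "-":
            implant_str = revcomp(implant_str)
        seqs[ci][start : start + probe_len] = list(implant_str)

        if strand == "+":
            snp_pos = start + snp_offset
        else:
            snp_pos = start + probe_len - 1 - snp_offset
        probe_id = f"P{pi:04d}"
        probes.append(
            ProbeRecord(
                probe_id=probe_id,
                sequence="".join(probe_seq),
                snp_offset=snp_offset,
                allele_a=str(allele_a),
                allele_b=str(allele_b),
            )
        )
        truths.append(
            ProbeTruth(
                probe_id=probe_id,
                chrom=genome[ci].id,
                start=start,
                strand=strand,
                snp_pos=snp_pos,
                true_allele=str(true_allele),
                n_mutations=n_mut,
            )
        )
    modified = [
        SeqRecord(rec.id, "".join(chars)) for rec, chars in zip(genome, seqs)
    ]
    return modified, probes, truths


def simulate_panel(
    seed: int,
    n_accessions: int = 26,
    loci: int | list[str] = 350,
    allele_freqs: np.ndarray | None = None,
    het_rate: float = 0.05,
    missing_rate: float = 0.02,
    n_duplicate_pairs: int = 0,
    dup_noise: float = 0.0005,
    n_divergent_pairs: int = 0,
    divergent_noise: float = 0.05,
    hwe_genotypes: bool = False,
) -> tuple[GenotypeMatrix, PanelTruth]:
    """Simulate a chip-genotyped germplasm panel with known structure.

    Per locus two distinct alleles are drawn and each base accession's call
    is heterozygous with probability ``het_rate``, otherwise homozygous for
    allele A with the locus's allele frequency; calls go missing (N) with
    probability ``missing_rate``.  With ``hwe_genotypes`` the three genotype
    classes are instead drawn at Hardy-Weinberg proportions (p^2, 2pq, q^2),
    emulating an outcrossing-like panel whose markers survive a
    Hardy-Weinberg filter.  Duplicate pairs are made by copying a
    base row and flipping an exact round(dup_noise * n_hom) count of its
    homozygous sites to the locus's other allele, so the realised
    homozygous difference deterministically matches the requested fraction.
    Duplicate copies are named after their source with a ``_dup`` suffix;
    divergent pairs are made the same way at ``divergent_noise`` (suffix
    ``_div``) and sit above the duplicate threshold — near-boundary
    negatives for specificity checks.
    """
    for name, rate in (("het_rate", het_rate), ("missing_rate", missing_rate)):
        if not (0 <= rate <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(loci, int):
        locus_ids = [f"L{i:05d}" for i in range(loci)]
    else:
        locus_ids = list(loci)
    n_loci = len(locus_ids)
    if allele_freqs is None:
        allele_freqs = rng.uniform(0.1, 0.9, size=n_loci)
    allele_freqs = np.asarray(allele_freqs, dtype=float)

    pairs = [tuple(rng.choice(_BASES, size=2, replace=False)) for _ in range(n_loci)]
    n_copies = n_duplicate_pairs + n_divergent_pairs
    n_base = n_accessions - n_copies
    if n_base < n_copies:
        raise ValueError("too many copied pairs for the accession count")

    calls = np.empty((n_base, n_loci), dtype="<U1")
    for li in range(n_loci):
        a, b = pairs[li]
        het = het_code(a, b)
        if hwe_genotypes:
            p = allele_freqs[li]
            u = rng.random(n_base)
            col = np.where(u < p * p, a, np.where(u < p * p + 2 * p * (1 - p), het, b))
        else:
            is_het = rng.random(n_base) < het_rate
            is_a = rng.random(n_base) < allele_freqs[li]
            col = np.where(is_het, het, np.where(is_a, a, b))
        col[rng.random(n_base) < missing_rate] = "N"
        calls[:, li] = col

    accessions = [f"ACC{i:03d}" for i in range(n_base)]
    truth = PanelTruth(
        allele_pairs=[(str(a), str(b)) for a, b in pairs],
        allele_freqs=allele_freqs,
        duplicate_pairs=[],
    )

    def _noisy_copy(src: int, noise: float, suffix: str) -> np.ndarray:
        row = calls[src].copy()
        hom_sites = np.where(np.isin(row, _BASES))[0]
        n_flip = int(round(noise * hom_sites.size))
        if n_flip > 0:
            flip = rng.choice(hom_sites, size=n_flip, replace=False)
            for site in flip:
                a, b = pairs[site]
                row[site] = b if row[site] == a else a
        copy_id = f"{accessions[src]}{suffix}"
        pair = (accessions[src], copy_id)
        truth.expected_hom_diff[pair] = (
            n_flip / hom_sites.size if hom_sites.size else float("nan")
        )
        accessions.append(copy_id)
        (truth.duplicate_pairs if suffix == "_dup" else truth.divergent_pairs).append(pair)
        return row

    copy_rows = [
        _noisy_copy(di, dup_noise, "_dup") for di in range(n_duplicate_pairs)
    ] + [
        _noisy_copy(n_duplicate_pairs + vi, divergent_noise, "_div")
        for vi in range(n_divergent_pairs)
    ]
    if copy_rows:
        calls = np.vstack([calls] + [r[None, :] for r in copy_rows])
    return GenotypeMatrix(accessions, locus_ids, calls), truth


def simulate_descriptors(
    seed: int,
    n_accessions: int = 26,
    n_descriptors: int = 24,
    covariance_spec: np.ndarray | list[float] | str = "identity",
    ordinal: bool = False,
) -> tuple[DescriptorTable, np.ndarray]:
    """Multivariate-normal descriptor scores with a controlled covariance.

    ``covariance_spec`` may be a full covariance matrix, a list of
    eigenvalues (rotated by a seeded random orthogonal matrix), or
    "identity".  With ``ordinal`` the draws are shifted and rounded onto a
    1..9 CPVO-like scale.  Returns the table and the generating covariance.
    """
    rng = np.random.default_rng(seed)
    if isinstance(covariance_spec, str):
        if covariance_spec != "identity":
            raise ValueError(f"unknown covariance spec {covariance_spec!r}")
        cov = np.eye(n_descriptors)
    else:
        spec = np.asarray(covariance_spec, dtype=float)
        if spec.ndim == 1:
            if spec.size != n_descriptors:
                raise ValueError("eigenvalue list length != n_descriptors")
            q, _ = np.linalg.qr(rng.standard_normal((n_descriptors, n_descriptors)))
            cov = q @ np.diag(spec) @ q.T
        else:
            cov = spec
    try:
        np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        raise ValueError("covariance specification is not positive definite")
    values = rng.multivariate_normal(np.zeros(n_descriptors), cov, size=n_accessions)
    if ordinal:
        values = np.clip(np.round(values + 5.0), 1, 9)
    table = DescriptorTable(
        accessions=[f"ACC{i:03d}" for i in range(n_accessions)],
        descriptors=[f"D{j + 1:02d}" for j in range(n_descriptors)],
        values=values,
    )
    return table, cov
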