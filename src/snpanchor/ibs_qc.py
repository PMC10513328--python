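"""Identity-by-state duplicate detection with marker/genotype QC filtration.

Re-implements the germplasm duplicate-identification procedure: accessions
with excessive missing data are removed, then markers failing per-marker
heterozygosity or Hardy-Weinberg filters, then markers in high LD are
pruned, and finally accession pairs whose homozygous difference falls below
a small threshold are collapsed into duplicate groups.

Default thresholds: genotype missingness 10%, marker heterozygosity 0.1,
HWE alpha 0.05 (chi-square, 1 df, no multiple-testing correction), LD r-sq
0.8 in a 50-locus window advanced by 5, homozygous difference strictly
below 0.1%.  Stage order is genotype missingness -> het+HWE -> LD pruning
-> duplicate collapsing; a ``filter_order`` switch swaps the two marker
stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core_io import GenotypeMatrix, HET_ALLELES

logger = logging.getLogger(__name__)

_HOM = frozenset("ACGT")


@dataclass
class QCConfig:
    """Thresholds of the duplicate-identification pipeline."""

    max_genotype_missing: float = 0.10
    max_marker_het: float = 0.10
    hwe_alpha: float = 0.05
    ld_r2_max: float = 0.8
    ld_window: int = 50
    ld_step: int = 5
    dup_homdiff_max: float = 0.001
    #: "het_hwe_first" applies het+HWE before LD pruning; "ld_first" swaps
    filter_order: Literal["het_hwe_first", "ld_first"] = "het_hwe_first"
    #: per-marker heterozygosity filter (default) or per-genotype reading
    het_scope: Literal["marker", "genotype"] = "marker"

    def __post_init__(self) -> None:
        for name in (
            "max_genotype_missing",
            "max_marker_het",
            "hwe_alpha",
            "ld_r2_max",
            "dup_homdiff_max",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (self.ld_window >= self.ld_step >= 1):
            raise ValueError("need ld_window >= ld_step >= 1")


@dataclass
class MarkerStats:
    """Per-marker summaries over non-missing calls."""

    locus_id: str
    n_called: int
    het_fraction: float
    maf: float
    hwe_chi2: float
    hwe_p: float
    #: the two most frequent alleles (major, minor); minor may be None
    alleles: tuple[str | None, str | None] = (None, None)


@dataclass
class QCReport:
    """Per-stage retention and the final duplicate partition."""

    retained_after_missingness: list[str]
    removed_accessions: list[str]
    retained_after_het_hwe: list[str]
    retained_after_ld: list[str]
    homdiff: dict[tuple[str, str], float]
    duplicate_groups: list[list[str]]
    representatives: list[str]
    retained_genotypes: list[str]

    def to_json(self, path) -> None:
        payload = {
            "retained_after_missingness": self.retained_after_missingness,
            "removed_accessions": self.removed_accessions,
            "n_markers_after_het_hwe": len(self.retained_after_het_hwe),
            "n_markers_after_ld": len(self.retained_after_ld),
            "duplicate_groups": self.duplicate_groups,
            "representatives": self.representatives,
            "retained_genotypes": self.retained_genotypes,
            "homdiff": {f"{a}|{b}": v for (a, b), v in self.homdiff.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# per-stage operations


def filter_genotypes_by_missingness(
    matrix: GenotypeMatrix, config: QCConfig
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep accessions whose fraction of N calls is <= the threshold."""
    n_missing = (matrix.calls == "N").sum(axis=1)
    frac = n_missing / matrix.calls.shape[1]
    keep = [a for a, f in zip(matrix.accessions, frac) if f <= config.max_genotype_missing]
    removed = [a for a in matrix.accessions if a not in keep]
    return matrix.subset_accessions(keep), removed


def marker_stats(matrix: GenotypeMatrix) -> list[MarkerStats]:
    """Allele/heterozygosity/HWE summaries per locus.

    Allele counts use diploid dosages: a homozygote contributes two copies
    of its base, a heterozygote one copy of each constituent.  Loci with no
    non-missing call are flagged with n_called 0 (callers drop them).
    """
    out: list[MarkerStats] = []
    for li, locus in enumerate(matrix.loci):
        col = matrix.calls[:, li]
        allele_counts: dict[str, int] = {}
        n_called = 0
        n_het = 0
        geno_counts: dict[tuple[str, str], int] = {}
        for call in col:
            if call == "N":
                continue
            if call in _HOM:
                pair = (call, call)
            elif call in HET_ALLELES:
                pair = HET_ALLELES[call]
                n_het += 1
            else:  # three-or-more-base ambiguity: uninterpretable, skip
                continue
            n_called += 1
            for a in pair:
                allele_counts[a] = allele_counts.get(a, 0) + 1
            geno_counts[pair] = geno_counts.get(pair, 0) + 1
        if n_called == 0:
            out.append(MarkerStats(locus, 0, 0.0, 0.0, 0.0, 1.0))
            continue
        ranked = sorted(allele_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        major = ranked[0][0]
        minor = ranked[1][0] if len(ranked) > 1 else None
        minor_count = ranked[1][1] if len(ranked) > 1 else 0
        maf = minor_count / (2 * n_called)
        if minor is None:
            chi2, p = 0.0, 1.0
        else:
            n_AA = geno_counts.get((major, major), 0)
            n_aa = geno_counts.get((minor, minor), 0)
            pair = tuple(sorted((major, minor)))
            n_Aa = geno_counts.get(pair, 0) if major != minor else 0
            chi2, p = hwe_test(n_AA, n_Aa, n_aa)
        out.append(
            MarkerStats(locus, n_called, n_het / n_called, maf, chi2, p, (major, minor))
        )
    return out


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """Chi-square goodness-of-fit test of Hardy-Weinberg proportions (1 df).

    Expected counts are n*p^2, 2n*p*(1-p), n*(1-p)^2 with p estimated from
    the allele counts; cells with zero expectation are skipped.  Monomorphic
    input returns (0, 1).
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = (n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p))
    observed = (n_AA, n_Aa, n_aa)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def filter_markers_het_hwe(
    matrix: GenotypeMatrix, stats_list: Sequence[MarkerStats], config: QCConfig
) -> list[str]:
    """Locus ids surviving the heterozygosity and HWE filters."""
    retained = []
    for st in stats_list:
        if st.n_called == 0:
            continue
        if config.het_scope == "marker" and st.het_fraction > config.max_marker_het:
            continue
        if st.hwe_p < config.hwe_alpha:
            continue
        retained.append(st.locus_id)
    return retained


def dosage_vector(
    col: np.ndarray, major: str | None, minor: str | None
) -> np.ndarray:
    """Minor-allele dosage {0,1,2} per accession; NaN = missing/uninterpretable."""
    out = np.full(col.shape[0], np.nan)
    if major is None:
        return out
    het = None
    if minor is not None:
        pair = frozenset((major, minor))
        for code, alleles in HET_ALLELES.items():
            if frozenset(alleles) == pair:
                het = code
                break
    out[col == major] = 0.0
    if minor is not None:
        out[col == minor] = 2.0
        if het is not None:
            out[col == het] = 1.0
    return out


def ld_r2(dosages_x: np.ndarray, dosages_y: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete entries.

    Zero variance in either vector makes r-sq undefined; callers treat that
    as 1 for pruning safety (an uninformative marker cannot be shown to be
    independent).
    """
    x = np.asarray(dosages_x, dtype=float)
    y = np.asarray(dosages_y, dtype=float)
    valid = ~(np.isnan(x) | np.isnan(y))
    if valid.sum() < 2:
        return float("nan")
    xv, yv = x[valid], y[valid]
    if xv.std() == 0 or yv.std() == 0:
        return float("nan")
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(
    matrix: GenotypeMatrix,
    stats_list: Sequence[MarkerStats],
    config: QCConfig,
) -> list[str]:
    """Sliding-window LD pruning.

    A window of ``ld_window`` loci advances by ``ld_step``; within each
    window, while any retained pair has r-sq above ``ld_r2_max``, the
    member with the lower minor-allele frequency is removed (tie: the later
    locus in order).  Loci keep their input (genome) order, so the result
    is deterministic.  Undefined r-sq (zero variance) prunes as if r-sq = 1.
    """
    stats_by_id = {st.locus_id: st for st in stats_list}
    loci = [l for l in matrix.loci if stats_by_id[l].n_called > 0]
    dosages = {}
    for li, locus in enumerate(matrix.loci):
        if locus in stats_by_id and stats_by_id[locus].n_called > 0:
            st = stats_by_id[locus]
            dosages[locus] = dosage_vector(matrix.calls[:, li], *st.alleles)

    removed: set[str] = set()
    n = len(loci)
    starts = list(range(0, max(n - config.ld_window, 0) + 1, config.ld_step))
    if not starts:
        starts = [0]
    if starts[-1] + config.ld_window < n:
        starts.append(n - config.ld_window)
    for w0 in starts:
        window = loci[w0 : w0 + config.ld_window]
        changed = True
        while changed:
            changed = False
            active = [l for l in window if l not in removed]
            for ai in range(len(active)):
                for bi in range(ai + 1, len(active)):
                    la, lb = active[ai], active[bi]
                    r2 = ld_r2(dosages[la], dosages[lb])
                    if np.isnan(r2):
                        r2 = 1.0
                    if r2 > config.ld_r2_max:
                        maf_a = stats_by_id[la].maf
                        maf_b = stats_by_id[lb].maf
                        # lower-maf member leaves; tie -> later in order (lb)
                        removed.add(la if maf_a < maf_b else lb)
                        changed = True
                        break
                if changed:
                    break
    return [l for l in loci if l not in removed]


def hom_diff(calls_x: np.ndarray, calls_y: np.ndarray) -> float:
    """Fraction of differing calls over sites where both are homozygous.

    Returns NaN when no site is comparably homozygous (callers exclude the
    pair from duplicate calling with a warning).
    """
    x = np.asarray(calls_x, dtype="<U1")
    y = np.asarray(calls_y, dtype="<U1")
    hom_x = np.isin(x, list(_HOM))
    hom_y = np.isin(y, list(_HOM))
    both = hom_x & hom_y
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return float((x[both] != y[both]).sum()) / n


def find_duplicates(matrix: GenotypeMatrix, config: QCConfig) -> QCReport:
    """Collapse accessions into duplicate groups by homozygous difference.

    Pairs with hom_diff strictly below ``dup_homdiff_max`` are edges of a
    graph; duplicate groups are its connected components; the first member
    in input order represents each group.
    """
    n = len(matrix.accessions)
    homdiff: dict[tuple[str, str], float] = {}
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            hd = hom_diff(matrix.calls[i], matrix.calls[j])
            homdiff[(matrix.accessions[i], matrix.accessions[j])] = hd
            if np.isnan(hd):
                logger.warning(
                    "pair (%s, %s) has no comparable homozygous site; "
                    "excluded from duplicate calling",
                    matrix.accessions[i],
                    matrix.accessions[j],
                )
                continue
            if hd < config.dup_homdiff_max:
                parent[find(i)] = find(j)

    groups_by_root: dict[int, list[str]] = {}
    for i, acc in enumerate(matrix.accessions):
        groups_by_root.setdefault(find(i), []).append(acc)
    # groups ordered by first member's input position
    groups = sorted(groups_by_root.values(), key=lambda g: matrix.accessions.index(g[0]))
    representatives = [g[0] for g in groups]
    return QCReport(
        retained_after_missingness=list(matrix.accessions),
        removed_accessions=[],
        retained_after_het_hwe=list(matrix.loci),
        retained_after_ld=list(matrix.loci),
        homdiff=homdiff,
        duplicate_groups=groups,
        representatives=representatives,
        retained_genotypes=representatives,
    )


def run_dedup_pipeline(matrix: GenotypeMatrix, config: QCConfig | None = None) -> QCReport:
    """Full QC chain: missingness -> marker filters -> LD -> duplicates."""
    config = config or QCConfig()
    filtered, removed = filter_genotypes_by_missingness(matrix, config)
    stats_list = marker_stats(filtered)

    if config.filter_order == "het_hwe_first":
        after_first = filter_markers_het_hwe(filtered, stats_list, config)
        m1 = filtered.subset_loci(after_first)
        stats1 = [s for s in stats_list if s.locus_id in set(after_first)]
        after_second = ld_prune(m1, stats1, config)
        retained_het_hwe, retained_ld = after_first, after_second
    else:
        after_first = ld_prune(filtered, stats_list, config)
        m1 = filtered.subset_loci(after_first)
        stats1 = [s for s in stats_list if s.locus_id in set(after_first)]
        after_second = filter_markers_het_hwe(m1, stats1, config)
        retained_ld, retained_het_hwe = after_first, after_second

    final = filtered.subset_loci(after_second)
    report = find_duplicates(final, config)
    report.retained_after_missingness = list(filtered.accessions)
    report.removed_accessions = removed
    report.retained_after_het_hwe = retained_het_hwe
    report.retained_after_ld = retained_ld
    return report


def write_qc_tsv(report: QCReport, path) -> None:
    """QC report as TSV sections (stages, duplicate groups, hom-diff pairs)."""
    with open(path, "w") as fh:
        fh.write("#stage\tn\tids\n")
        fh.write(
            "genotypes_after_missingness\t"
            f"{len(report.retained_after_missingness)}\t"
            + ",".join(report.retained_after_missingness)
            + "\n"
        )
        fh.write(
            f"markers_after_het_hwe\t{len(report.retained_after_het_hwe)}\t-\n"
        )
        fh.write(f"markers_after_ld\t{len(report.retained_after_ld)}\t-\n")
        fh.write(
            "retained_genotypes\t"
            f"{len(report.retained_genotypes)}\t"
            + ",".join(report.retained_genotypes)
            + "\n"
        )
        fh.write("#accession\tgroup\n")
        for gi, group in enumerate(report.duplicate_groups, start=1):
            for acc in group:
                fh.write(f"{acc}\tG{gi}\n")
        fh.write("#pair\thom_diff\n")
        for (a, b), v in report.homdiff.items():
            fh.write(f"{a}|{b}\t{'NA' if np.isnan(v) else f'{v:.6g}'}\n")
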