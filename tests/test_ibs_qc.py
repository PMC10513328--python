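"""QC filters, HWE/LD/hom-diff statistics against brute-force oracles,
duplicate-group collapsing."""

import numpy as np
import pytest
from scipy import stats as sps

from snpanchor import (
    GenotypeMatrix,
    QCConfig,
    find_duplicates,
    hom_diff,
    hwe_test,
    ld_prune,
    ld_r2,
    marker_stats,
    simulate_panel,
)
from snpanchor.ibs_qc import (
    dosage_vector,
    filter_genotypes_by_missingness,
    filter_markers_het_hwe,
    run_dedup_pipeline,
)


def gm(rows, loci=None):
    accs = [f"a{i}" for i in range(len(rows))]
    loci = loci or [f"L{j}" for j in range(len(rows[0]))]
    return GenotypeMatrix(accs, loci, np.array([list(r) for r in rows], dtype="<U1"))


class TestMissingnessFilter:
    def test_threshold_crossing(self):
        m = gm(["A" * 19 + "N", "N" * 3 + "A" * 17])  # 5% vs 15% missing
        kept, removed = filter_genotypes_by_missingness(m, QCConfig())
        assert kept.accessions == ["a0"]
        assert removed == ["a1"]

    def test_matches_brute_force_on_random(self):
        rng = np.random.default_rng(61)
        for seed in range(5):
            panel, _ = simulate_panel(seed, 12, 60, missing_rate=0.1)
            kept, removed = filter_genotypes_by_missingness(panel, QCConfig())
            expected = [
                acc
                for acc, row in zip(panel.accessions, panel.calls)
                if sum(c == "N" for c in row) / len(row) <= 0.10
            ]
            assert kept.accessions == expected

    def test_idempotent(self):
        panel, _ = simulate_panel(3, 12, 60, missing_rate=0.1)
        once, _ = filter_genotypes_by_missingness(panel, QCConfig())
        twice, removed2 = filter_genotypes_by_missingness(once, QCConfig())
        assert twice.accessions == once.accessions and removed2 == []


class TestMarkerStats:
    def test_direct_count_example(self):
        (st,) = marker_stats(gm([["A"], ["A"], ["R"], ["G"]], ["L1"]))
        assert st.n_called == 4
        assert st.het_fraction == 0.25
        assert st.maf == pytest.approx(3 / 8)  # alleles A:5, G:3
        assert st.alleles == ("A", "G")

    def test_monomorphic(self):
        (st,) = marker_stats(gm([["A"], ["A"], ["A"]], ["L1"]))
        assert st.maf == 0.0 and st.het_fraction == 0.0
        assert (st.hwe_chi2, st.hwe_p) == (0.0, 1.0)

    def test_all_missing_flagged(self):
        (st,) = marker_stats(gm([["N"], ["N"]], ["L1"]))
        assert st.n_called == 0

    def test_matches_brute_force(self):
        panel, _ = simulate_panel(17, 20, 50, het_rate=0.2, missing_rate=0.1)
        from snpanchor.core_io import HET_ALLELES

        for st, locus in zip(marker_stats(panel), panel.loci):
            col = panel.calls[:, panel.loci.index(locus)]
            alleles = []
            hets = 0
            for c in col:
                if c in "ACGT":
                    alleles += [c, c]
                elif c in HET_ALLELES:
                    alleles += list(HET_ALLELES[c])
                    hets += 1
            n_called = len(alleles) // 2
            assert st.n_called == n_called
            if n_called:
                assert st.het_fraction == pytest.approx(hets / n_called)
                counts = sorted(
                    [alleles.count(a) for a in set(alleles)], reverse=True
                )
                minor = counts[1] if len(counts) > 1 else 0
                assert st.maf == pytest.approx(minor / (2 * n_called))


class TestHweTest:
    def test_exact_proportions(self):
        assert hwe_test(25, 50, 25) == (0.0, 1.0)

    def test_het_deficit(self):
        chi2, p = hwe_test(30, 40, 30)
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(sps.chi2.sf(4.0, df=1), rel=1e-12)
        assert p == pytest.approx(0.0455, abs=5e-4)

    def test_monomorphic(self):
        assert hwe_test(10, 0, 0) == (0.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 0, 5)


class TestLdR2:
    def test_identical_vectors(self):
        x = np.array([0, 1, 2, 0, 2.0])
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_orthogonal_design(self):
        assert ld_r2(np.array([0, 0, 2, 2.0]), np.array([0, 2, 0, 2.0])) == pytest.approx(0.0)

    def test_zero_variance_undefined(self):
        assert np.isnan(ld_r2(np.array([1.0, 1, 1]), np.array([0.0, 1, 2])))

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(71)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            x = rng.choice([0.0, 1, 2, np.nan], size=n)
            y = rng.choice([0.0, 1, 2, np.nan], size=n)
            mask = ~(np.isnan(x) | np.isnan(y))
            got = ld_r2(x, y)
            if mask.sum() < 2 or x[mask].std() == 0 or y[mask].std() == 0:
                assert np.isnan(got)
            else:
                xm, ym = x[mask] - x[mask].mean(), y[mask] - y[mask].mean()
                r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
                assert got == pytest.approx(r * r, abs=1e-12)


class TestLdPrune:
    def test_duplicated_column_keeps_one(self):
        rng = np.random.default_rng(81)
        col = rng.choice(["A", "G", "R"], size=12)
        calls = np.stack([col, col, rng.choice(["A", "G"], size=12)], axis=1)
        m = GenotypeMatrix([f"a{i}" for i in range(12)], ["L1", "L2", "L3"], calls)
        retained = ld_prune(m, marker_stats(m), QCConfig())
        assert sum(l in retained for l in ("L1", "L2")) == 1

    def test_independent_loci_all_retained(self):
        # orthogonal-ish design with r2 = 0 between the two loci
        calls = np.array(
            [["A", "A"], ["A", "G"], ["G", "A"], ["G", "G"]], dtype="<U1"
        )
        m = GenotypeMatrix(["a", "b", "c", "d"], ["L1", "L2"], calls)
        assert ld_prune(m, marker_stats(m), QCConfig()) == ["L1", "L2"]

    def test_matches_direct_simulation(self):
        """Pruned set equals a brute-force run of the stated window rule."""
        panel, _ = simulate_panel(23, 15, 40, het_rate=0.1, hwe_genotypes=True)
        cfg = QCConfig(ld_window=8, ld_step=3)
        stats_list = marker_stats(panel)
        got = ld_prune(panel, stats_list, cfg)

        stats_by = {s.locus_id: s for s in stats_list}
        dos = {
            l: dosage_vector(panel.calls[:, i], *stats_by[l].alleles)
            for i, l in enumerate(panel.loci)
        }
        loci = [l for l in panel.loci if stats_by[l].n_called > 0]
        removed = set()
        starts = list(range(0, max(len(loci) - cfg.ld_window, 0) + 1, cfg.ld_step))
        if starts[-1] + cfg.ld_window < len(loci):
            starts.append(len(loci) - cfg.ld_window)
        for w0 in starts:
            window = loci[w0 : w0 + cfg.ld_window]
            while True:
                active = [l for l in window if l not in removed]
                offender = None
                for ai in range(len(active)):
                    for bi in range(ai + 1, len(active)):
                        r2 = ld_r2(dos[active[ai]], dos[active[bi]])
                        if np.isnan(r2):
                            r2 = 1.0
                        if r2 > cfg.ld_r2_max:
                            offender = (active[ai], active[bi])
                            break
                    if offender:
                        break
                if not offender:
                    break
                la, lb = offender
                removed.add(la if stats_by[la].maf < stats_by[lb].maf else lb)
        assert got == [l for l in loci if l not in removed]


class TestHomDiff:
    def test_identical_rows(self):
        assert hom_diff(np.array(list("AACG")), np.array(list("AACG"))) == 0.0

    def test_quarter_difference(self):
        assert hom_diff(np.array(list("AACG")), np.array(list("ATCG"))) == 0.25

    def test_het_and_missing_sites_excluded(self):
        x = np.array(list("ARNG"))
        y = np.array(list("AAAG"))
        assert hom_diff(x, y) == 0.0  # only sites 0 and 3 comparable

    def test_no_comparable_site_is_nan(self):
        assert np.isnan(hom_diff(np.array(list("RN")), np.array(list("AA"))))

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(91)
        for _ in range(200):
            n = int(rng.integers(2, 50))
            x = rng.choice(list("ACGTRN"), size=n)
            y = rng.choice(list("ACGTRN"), size=n)
            both = [(a, b) for a, b in zip(x, y) if a in "ACGT" and b in "ACGT"]
            got = hom_diff(x, y)
            if not both:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(
                    sum(a != b for a, b in both) / len(both)
                )


class TestFindDuplicates:
    def test_six_to_four_collapse(self):
        """Two implanted duplicate pairs among six genotypes leave four."""
        panel, truth = simulate_panel(
            101, 6, 350, n_duplicate_pairs=2, dup_noise=0.0005
        )
        report = find_duplicates(panel, QCConfig())
        assert len(report.retained_genotypes) == 4
        multi = {frozenset(g) for g in report.duplicate_groups if len(g) > 1}
        assert multi == {frozenset(p) for p in truth.duplicate_pairs}

    def test_no_pair_under_threshold(self):
        panel, _ = simulate_panel(102, 8, 100)
        report = find_duplicates(panel, QCConfig())
        assert report.retained_genotypes == panel.accessions

    def test_strict_inequality_at_threshold(self):
        # hom_diff exactly 0.001 must NOT collapse
        base = np.array(list("A" * 1000), dtype="<U1")
        other = base.copy()
        other[0] = "G"
        m = GenotypeMatrix(["x", "y"], [f"L{i}" for i in range(1000)], np.stack([base, other]))
        report = find_duplicates(m, QCConfig())
        assert report.homdiff[("x", "y")] == pytest.approx(0.001)
        assert len(report.duplicate_groups) == 2

    def test_components_match_transitive_closure(self):
        panel, _ = simulate_panel(103, 14, 200, n_duplicate_pairs=3, dup_noise=0.0)
        cfg = QCConfig()
        report = find_duplicates(panel, cfg)
        n = len(panel.accessions)
        adj = {a: set() for a in panel.accessions}
        for i in range(n):
            for j in range(i + 1, n):
                hd = hom_diff(panel.calls[i], panel.calls[j])
                if not np.isnan(hd) and hd < cfg.dup_homdiff_max:
                    adj[panel.accessions[i]].add(panel.accessions[j])
                    adj[panel.accessions[j]].add(panel.accessions[i])
        seen, comps = set(), []
        for a in panel.accessions:
            if a in seen:
                continue
            stack, comp = [a], set()
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(adj[v] - comp)
            seen |= comp
            comps.append(comp)
        assert {frozenset(g) for g in report.duplicate_groups} == {
            frozenset(c) for c in comps
        }


class TestPipelineProperties:
    def test_stage_outputs_subset_of_inputs(self):
        panel, _ = simulate_panel(111, 20, 120, het_rate=0.1, hwe_genotypes=True)
        report = run_dedup_pipeline(panel)
        assert set(report.retained_after_missingness) <= set(panel.accessions)
        assert set(report.retained_after_ld) <= set(report.retained_after_het_hwe) <= set(panel.loci)
        flat = [a for g in report.duplicate_groups for a in g]
        assert sorted(flat) == sorted(report.retained_after_missingness)

    def test_raising_threshold_monotone(self):
        panel, _ = simulate_panel(112, 20, 120, missing_rate=0.08)
        kept_strict, _ = filter_genotypes_by_missingness(
            panel, QCConfig(max_genotype_missing=0.05)
        )
        kept_loose, _ = filter_genotypes_by_missingness(
            panel, QCConfig(max_genotype_missing=0.15)
        )
        assert set(kept_strict.accessions) <= set(kept_loose.accessions)

    def test_het_hwe_filter_monotone_in_alpha(self):
        panel, _ = simulate_panel(113, 20, 120, hwe_genotypes=True, het_rate=0)
        st = marker_stats(panel)
        strict = filter_markers_het_hwe(panel, st, QCConfig(hwe_alpha=0.10))
        loose = filter_markers_het_hwe(panel, st, QCConfig(hwe_alpha=0.01))
        assert set(strict) <= set(loose)

    def test_filter_order_switch_runs(self):
        panel, _ = simulate_panel(114, 12, 80, hwe_genotypes=True)
        a = run_dedup_pipeline(panel, QCConfig(filter_order="het_hwe_first"))
        b = run_dedup_pipeline(panel, QCConfig(filter_order="ld_first"))
        assert set(a.retained_after_missingness) == set(b.retained_after_missingness)
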