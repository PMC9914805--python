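"""Peak-gene matching, correlations, cross-tables, permutation association,
direction concordance, Fisher test, and TSS quintile profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lenscape.annotate import PROMOTER_CATEGORIES, annotate_peaks
from lenscape.differential import normalize, size_factors
from lenscape.integrate import (
    chi_squared_independence,
    condition_means,
    cross_table,
    direction_concordance,
    fisher_direction_test,
    gene_level_atac,
    global_correlation,
    match_peaks_to_genes,
    per_gene_correlation_categories,
    permutation_association,
    tss_quintile_profiles,
)
from lenscape.io import CONDITIONS, GeneModel, PeakInterval
from lenscape.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_tss_coverage,
)

# The printed cluster cross-table of the source study (RNA clusters C1..C6 by
# ATAC clusters CA..CF); used as a worked-example input.
TABLE1 = pd.DataFrame(
    [
        [267, 157, 153, 227, 67, 37],
        [300, 163, 129, 198, 107, 66],
        [433, 198, 152, 417, 78, 91],
        [395, 141, 236, 166, 269, 46],
        [296, 96, 106, 124, 152, 36],
        [487, 434, 217, 514, 119, 119],
    ],
    index=[f"C{i}" for i in range(1, 7)],
    columns=list("ABCDEF"),
)


class TestPeakGeneMap:
    def test_peak_at_tss_maps_with_distance_zero(self):
        g = GeneModel("g1", "chr1", "+", 5001, 8000)
        pk = PeakInterval("chr1", 4800, 5200, "p1", summit_offset=200)
        pg = match_peaks_to_genes(annotate_peaks([pk], [g]))
        assert pg.peak_to_gene["p1"] == ("g1", 0)

    def test_equidistant_tie_takes_smaller_gene_id(self):
        ga = GeneModel("ga", "chr1", "+", 10_000, 12_000)
        gb = GeneModel("gb", "chr1", "-", 4_000, 6_000)
        pk = PeakInterval("chr1", 7_800, 8_200, "p", summit_offset=199)
        pg = match_peaks_to_genes(annotate_peaks([pk], [gb, ga]))
        assert pg.gene_of("p") == "ga"

    def test_off_annotation_peaks_counted_not_mapped(self):
        g = GeneModel("g1", "chr1", "+", 5001, 8000)
        pks = [
            PeakInterval("chr1", 4800, 5200, "p1"),
            PeakInterval("chrUn", 100, 500, "p2"),
        ]
        pg = match_peaks_to_genes(annotate_peaks(pks, [g]))
        assert pg.n_unassigned == 1
        assert "p2" not in pg.peak_to_gene

    def test_map_equals_brute_force_nearest_tss(self, small_dataset):
        genes, _, _, peaks, _ = small_dataset
        pg = match_peaks_to_genes(annotate_peaks(peaks, genes))
        for pk in peaks:
            cands = [g for g in genes if g.chrom == pk.chrom]
            best = min(
                cands,
                key=lambda g: (abs(pk.anchor - g.tss0), g.gene_id),
            )
            assert pg.gene_of(pk.peak_id) == best.gene_id


class TestGeneLevelAtac:
    def test_single_peak_gene_row_identical(self):
        g = GeneModel("g1", "chr1", "+", 5001, 8000)
        pk = PeakInterval("chr1", 4800, 5200, "p1", summit_offset=200)
        pg = match_peaks_to_genes(annotate_peaks([pk], [g]))
        mat = pd.DataFrame({"s1": [4.0], "s2": [7.0]}, index=["p1"])
        out = gene_level_atac(mat, pg)
        np.testing.assert_array_equal(out.loc["g1"], [4.0, 7.0])

    def test_two_peaks_averaged(self):
        g = GeneModel("g1", "chr1", "+", 5001, 8000)
        pks = [
            PeakInterval("chr1", 4800, 5200, "p1", summit_offset=200),
            PeakInterval("chr1", 5400, 5800, "p2", summit_offset=200),
        ]
        pg = match_peaks_to_genes(annotate_peaks(pks, [g]))
        mat = pd.DataFrame({"s1": [2.0, 4.0]}, index=["p1", "p2"])
        assert gene_level_atac(mat, pg).loc["g1", "s1"] == 3.0

    def test_matches_brute_force_group_mean(self, small_dataset):
        genes, _, atac, peaks, _ = small_dataset
        anorm = normalize(atac, size_factors(atac))
        pg = match_peaks_to_genes(annotate_peaks(peaks, genes))
        out = gene_level_atac(anorm, pg)
        rng = np.random.default_rng(0)
        for gene in rng.choice(out.index, size=20, replace=False):
            rows = anorm.loc[pg.gene_to_peaks[gene]]
            np.testing.assert_allclose(out.loc[gene], rows.mean(axis=0))


class TestCorrelation:
    def _meta(self, prefix, reps):
        ids, cond, rep = [], [], []
        for c in CONDITIONS:
            for r in range(1, reps + 1):
                ids.append(f"{prefix}_{c}_{r}")
                cond.append(c)
                rep.append(r)
        return pd.DataFrame({"condition": cond, "replicate": rep}, index=ids)

    def test_identical_matrices_r_one(self):
        meta = self._meta("x", 1)
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            rng.uniform(1, 100, size=(10, 6)), columns=meta.index,
            index=[f"g{i}" for i in range(10)],
        )
        r = global_correlation(mat, mat.copy(), meta, meta)
        assert r == pytest.approx(1.0)

    def test_negated_matrix_r_minus_one(self):
        meta = self._meta("x", 1)
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(
            rng.uniform(1, 50, size=(8, 6)), columns=meta.index,
            index=[f"g{i}" for i in range(8)],
        )
        other = -mat + 100.0
        r = global_correlation(mat, other, meta, meta, log2=False)
        assert r == pytest.approx(-1.0)

    def test_planted_global_correlation_recovered(self):
        rs = []
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed, n_genes=400, n_peaks=800,
                chrom_sizes={"chr1": 7_000_000}, rho_planted=0.6,
            )
            genes = simulate_annotation(cfg)
            rna, atac, peaks, _ = simulate_counts(cfg, genes)
            norm = normalize(rna, size_factors(rna))
            anorm = normalize(atac, size_factors(atac))
            prom = [
                r for r in annotate_peaks(peaks, genes)
                if r.category in PROMOTER_CATEGORIES
            ]
            ga = gene_level_atac(anorm, match_peaks_to_genes(prom))
            rs.append(
                global_correlation(norm, ga, rna.sample_meta, atac.sample_meta)
            )
        assert all(abs(r - 0.6) <= 0.1 for r in rs)

    def test_per_gene_constant_accessibility_gives_none(self):
        meta = self._meta("x", 1)
        rna = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6.0]], columns=meta.index, index=["g1"]
        )
        atac = pd.DataFrame(
            [[5, 5, 5, 5, 5, 5.0]], columns=meta.index, index=["g1"]
        )
        rep = per_gene_correlation_categories(rna, atac, meta, meta)
        assert np.isnan(rep.loc["g1", "r"])
        assert rep.loc["g1", "category"] == "none"

    def test_identical_profiles_strong_positive(self):
        meta = self._meta("x", 1)
        rna = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6.0]], columns=meta.index, index=["g1"]
        )
        rep = per_gene_correlation_categories(rna, rna.copy(), meta, meta)
        assert rep.loc["g1", "category"] == "strong_positive"

    def test_planted_correlation_mixture_categories_recovered(self):
        """Planted +0.95 / -0.95 / 0 correlations between expression and
        promoter accessibility are recovered into the right strength category
        for >= 90% of genes that carry condition signal (a correlation
        category is only meaningful for genes whose expression varies)."""
        n = 300
        rho = np.concatenate(
            [np.full(100, 0.95), np.full(100, -0.95), np.full(100, 0.0)]
        )
        correct = 0
        total = 0
        for seed in range(3):
            cfg = SimulationConfig(
                seed=seed, n_genes=n, n_peaks=600,
                chrom_sizes={"chr1": 5_000_000}, rho_planted=rho,
                dispersion=0.01,
            )
            genes = simulate_annotation(cfg)
            rna, atac, peaks, truth = simulate_counts(cfg, genes)
            norm = normalize(rna, size_factors(rna))
            anorm = normalize(atac, size_factors(atac))
            prom = [
                r for r in annotate_peaks(peaks, genes)
                if r.category in PROMOTER_CATEGORIES
            ]
            ga = gene_level_atac(anorm, match_peaks_to_genes(prom))
            rep = per_gene_correlation_categories(
                norm, ga, rna.sample_meta, atac.sample_meta
            )
            want = pd.Series(
                np.where(
                    truth.rho >= 0.9, "strong_positive",
                    np.where(truth.rho <= -0.9, "strong_negative", "none"),
                ),
                index=truth.rho.index,
            )
            signal = truth.rna_cluster[truth.rna_cluster > 0].index
            shared = rep.index.intersection(want.index).intersection(signal)
            correct += (rep.loc[shared, "category"] == want.loc[shared]).sum()
            total += len(shared)
        assert correct / total >= 0.9

    def test_per_gene_r_invariant_to_gene_level_scaling_global_r_not(self):
        """Rescaling each gene's whole profile by gene-specific positive
        constants (in either assay) leaves every per-gene correlation
        unchanged, but moves the pooled global correlation: only the latter
        mixes between-gene magnitude variation into the estimate."""
        meta = self._meta("x", 1)
        rng = np.random.default_rng(2)
        rna = pd.DataFrame(
            rng.uniform(1, 100, (20, 6)), columns=meta.index,
            index=[f"g{i}" for i in range(20)],
        )
        atac = pd.DataFrame(
            rna.to_numpy() + rng.uniform(-5, 5, (20, 6)),
            columns=meta.index, index=rna.index,
        )
        scale = pd.Series(rng.uniform(0.2, 8.0, 20), index=rna.index)
        rna2 = rna.mul(scale, axis=0)
        atac2 = atac.mul(scale.iloc[::-1].to_numpy(), axis=0)
        rep1 = per_gene_correlation_categories(rna, atac, meta, meta, log2=False)
        rep2 = per_gene_correlation_categories(rna2, atac2, meta, meta, log2=False)
        np.testing.assert_allclose(rep1["r"], rep2["r"], rtol=1e-9)
        g1 = global_correlation(rna, atac, meta, meta, log2=False)
        g2 = global_correlation(rna2, atac2, meta, meta, log2=False)
        assert g1 != pytest.approx(g2, abs=1e-6)


class TestCrossTable:
    def test_diagonal_two_by_two(self):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", 20_001 + 20_000 * i, 22_000 + 20_000 * i)
            for i in range(4)
        ]
        peaks = [
            PeakInterval("chr1", max(0, g.tss0 - 200), g.tss0 + 200, f"p{i}",
                         summit_offset=200)
            for i, g in enumerate(genes)
        ]
        pg = match_peaks_to_genes(annotate_peaks(peaks, genes))
        rna = pd.Series([1, 1, 2, 2], index=[f"g{i}" for i in range(4)])
        atac = pd.Series([1, 1, 2, 2], index=[f"p{i}" for i in range(4)])
        tab = cross_table(rna, atac, pg)
        np.testing.assert_array_equal(tab.to_numpy(), [[2, 0], [0, 2]])

    def test_printed_table_row_sum(self):
        assert TABLE1.loc["C1"].sum() == 908
        assert TABLE1.to_numpy().sum() == 7193

    def test_matches_brute_force_tally(self, small_dataset):
        genes, _, _, peaks, truth = small_dataset
        pg = match_peaks_to_genes(annotate_peaks(peaks, genes))
        rna = truth.rna_cluster[truth.rna_cluster > 0]
        atac = truth.atac_cluster[truth.atac_cluster > 0]
        tab = cross_table(rna, atac, pg)
        # brute force: nearest-peak rule over cluster-labeled peaks
        brute = np.zeros((6, 6), dtype=int)
        for gene in rna.index:
            peaks_of = [
                p for p in pg.gene_to_peaks.get(gene, []) if p in atac.index
            ]
            if not peaks_of:
                continue
            nearest = min(
                peaks_of, key=lambda p: (abs(pg.peak_to_gene[p][1]), p)
            )
            brute[rna[gene] - 1, atac[nearest] - 1] += 1
        np.testing.assert_array_equal(tab.to_numpy(), brute)
        # margins are cluster sizes of the tallied genes (conservation)
        assert tab.to_numpy().sum() == brute.sum()


class TestChiSquared:
    def test_proportional_table_statistic_zero(self):
        tab = pd.DataFrame(np.outer([10, 20], [5, 15]) / 10.0)
        stat, df, p = chi_squared_independence(tab)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_computation(self):
        stat, df, p = chi_squared_independence(pd.DataFrame([[10, 0], [0, 10]]))
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_matches_brute_force_on_printed_table(self):
        stat, df, _ = chi_squared_independence(TABLE1)
        arr = TABLE1.to_numpy(dtype=float)
        expect = arr.sum(1, keepdims=True) * arr.sum(0, keepdims=True) / arr.sum()
        brute = ((arr - expect) ** 2 / expect).sum()
        assert stat == pytest.approx(brute, rel=1e-12)
        assert df == 25

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared_independence(pd.DataFrame([[1, 2], [0, 0]]))


def _labels_from_margins(row_margins, col_margins, seed=0):
    rna = np.repeat(np.arange(len(row_margins)), row_margins)
    atac = np.repeat(np.arange(len(col_margins)), col_margins)
    rng = np.random.default_rng(seed)
    rng.shuffle(atac)
    return rna, atac


class TestPermutationAssociation:
    def test_empirical_p_matches_hypergeometric_tail(self):
        """Single-vector permutation null per cell is hypergeometric: every
        cell of random 6x6 tables agrees with the closed-form upper tail
        within Monte-Carlo error (4 SD per cell over 72 dependent cells)."""
        rng = np.random.default_rng(5)
        n_perm = 20_000
        for trial in range(2):
            rows = rng.integers(50, 200, size=6)
            cols_raw = rng.integers(50, 200, size=6)
            # make both label vectors cover the same N
            n = rows.sum()
            cols = np.floor(cols_raw / cols_raw.sum() * n).astype(int)
            cols[0] += n - cols.sum()
            rlab, alab = _labels_from_margins(rows, cols, seed=trial)
            res = permutation_association(rlab, alab, n_perm=n_perm, seed=trial)
            for i in range(6):
                for j in range(6):
                    obs = res.observed.iat[i, j]
                    tail = stats.hypergeom.sf(obs - 1, n, rows[i], cols[j])
                    mc_sd = np.sqrt(max(tail * (1 - tail), 1e-12) / n_perm)
                    assert abs(res.empirical_p.iat[i, j] - tail) <= max(
                        4 * mc_sd, 1e-3
                    )

    def test_maximal_cell_is_associated(self):
        # two clusters perfectly aligned: the (1,1) cell holds its full margin
        rna = np.array([1] * 20 + [2] * 20)
        atac = np.array([1] * 20 + [2] * 20)
        res = permutation_association(rna, atac, n_perm=2000, seed=0)
        assert bool(res.associated.loc[1, 1])
        assert res.empirical_p.loc[1, 1] < 0.05

    def test_margins_conserved_and_expected_counts(self):
        rlab, alab = _labels_from_margins([30, 50, 20], [40, 40, 20], seed=2)
        res = permutation_association(rlab, alab, n_perm=500, seed=1)
        np.testing.assert_array_equal(res.observed.sum(axis=1), [30, 50, 20])
        np.testing.assert_array_equal(res.observed.sum(axis=0), [40, 40, 20])
        expect = np.outer([30, 50, 20], [40, 40, 20]) / 100
        np.testing.assert_allclose(res.expected, expect)

    def test_deterministic_under_seed(self):
        rlab, alab = _labels_from_margins([30, 30], [30, 30], seed=3)
        a = permutation_association(rlab, alab, n_perm=1000, seed=9)
        b = permutation_association(rlab, alab, n_perm=1000, seed=9)
        pd.testing.assert_frame_equal(a.empirical_p, b.empirical_p)

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_association([1, 2], [1, 2], n_perm=0)


class TestDirectionConcordance:
    def _map(self, n):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", 20_001 + 20_000 * i, 22_000 + 20_000 * i)
            for i in range(n)
        ]
        peaks = [
            PeakInterval("chr1", max(0, g.tss0 - 200), g.tss0 + 200, f"p{i}",
                         summit_offset=200)
            for i, g in enumerate(genes)
        ]
        return match_peaks_to_genes(annotate_peaks(peaks, genes))

    def test_all_concordant_up_second_lands_in_corner(self):
        pg = self._map(5)
        tab = direction_concordance(
            rna_up_first=set(), rna_up_second={f"g{i}" for i in range(5)},
            atac_up_first=set(), atac_up_second={f"p{i}" for i in range(5)},
            pg_map=pg,
        )
        assert tab.loc["up_second", "up_second"] == 5
        assert tab.to_numpy().sum() == 5

    def test_printed_day5_table_grand_total(self):
        d5 = np.array([[636, 2434, 915], [1848, 5881, 2580], [593, 2544, 1131]])
        assert d5.sum() == 18_562

    def test_matches_brute_force_tally(self, small_dataset):
        genes, _, _, peaks, _ = small_dataset
        pg = match_peaks_to_genes(annotate_peaks(peaks, genes))
        rng = np.random.default_rng(0)
        gene_ids = [g.gene_id for g in genes]
        peak_ids = list(pg.peak_to_gene)
        r_up1 = set(rng.choice(gene_ids, 40, replace=False))
        r_up2 = set(rng.choice(sorted(set(gene_ids) - r_up1), 40, replace=False))
        a_up1 = set(rng.choice(peak_ids, 100, replace=False))
        a_up2 = set(rng.choice(sorted(set(peak_ids) - a_up1), 100, replace=False))
        tab = direction_concordance(r_up1, r_up2, a_up1, a_up2, pg)
        brute = np.zeros((3, 3), dtype=int)
        for p, (g, _) in pg.peak_to_gene.items():
            ai = 0 if p in a_up1 else (2 if p in a_up2 else 1)
            ri = 0 if g in r_up1 else (2 if g in r_up2 else 1)
            brute[ri, ai] += 1
        np.testing.assert_array_equal(tab.to_numpy(), brute)
        assert tab.to_numpy().sum() == len(pg.peak_to_gene)


def brute_force_fisher(a, b, c, d):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        # P(table with top-left x) under the hypergeometric null
        return comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_direction_test(5, 5, 5, 5) == pytest.approx(1.0)

    def test_epithelial_fiber_direction_table(self):
        # 20 of 30 epithelial-identity genes down / 2 up; 0 fiber genes down /
        # 5 up: association between gene set and direction of regulation
        p = fisher_direction_test(20, 2, 0, 5)
        assert p == pytest.approx(0.0003, abs=5e-5)

    def test_matches_enumeration_for_small_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0 or a + b + c + d > 40:
                continue
            want = brute_force_fisher(int(a), int(b), int(c), int(d))
            got = fisher_direction_test(int(a), int(b), int(c), int(d))
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_direction_test(0, 0, 0, 0)


class TestTssQuintiles:
    @pytest.fixture(scope="class")
    def coverage_setup(self):
        cfg = SimulationConfig(
            seed=21, n_genes=120, n_peaks=120, chrom_sizes={"chr1": 2_000_000},
        )
        genes = simulate_annotation(cfg)
        rna, atac, peaks, truth = simulate_counts(cfg, genes)
        cov, gene_ids = simulate_tss_coverage(cfg, genes, rna)
        norm = normalize(rna, size_factors(rna))
        return cfg, genes, rna, atac, cov, gene_ids, norm

    def test_quintile_profiles_ordered_by_expression(self, coverage_setup):
        cfg, genes, rna, atac, cov, gene_ids, norm = coverage_setup
        prof = tss_quintile_profiles(
            cov, gene_ids, genes, norm, rna.sample_meta, atac.sample_meta
        )
        for cond, mat in prof.items():
            center = mat.shape[1] // 2
            peak_vals = mat.iloc[:, center].to_numpy()
            assert (np.diff(peak_vals) < 0).all(), cond  # quintile 1 highest

    def test_identical_coverage_gives_identical_profiles(self, coverage_setup):
        cfg, genes, rna, atac, cov, gene_ids, norm = coverage_setup
        flat = {s: np.ones_like(a) for s, a in cov.items()}
        prof = tss_quintile_profiles(
            flat, gene_ids, genes, norm, rna.sample_meta, atac.sample_meta
        )
        for mat in prof.values():
            np.testing.assert_allclose(mat.to_numpy(), 1.0)

    def test_input_order_invariance(self, coverage_setup):
        cfg, genes, rna, atac, cov, gene_ids, norm = coverage_setup
        prof1 = tss_quintile_profiles(
            cov, gene_ids, genes, norm, rna.sample_meta, atac.sample_meta
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(gene_ids))
        cov2 = {s: a[perm] for s, a in cov.items()}
        ids2 = [gene_ids[i] for i in perm]
        prof2 = tss_quintile_profiles(
            cov2, ids2, genes, norm, rna.sample_meta, atac.sample_meta
        )
        for cond in prof1:
            np.testing.assert_allclose(
                prof1[cond].to_numpy(), prof2[cond].to_numpy()
            )

    def test_too_few_genes_rejected(self, coverage_setup):
        cfg, genes, rna, atac, cov, gene_ids, norm = coverage_setup
        with pytest.raises(ValueError, match="need >="):
            tss_quintile_profiles(
                {s: a[:3] for s, a in cov.items()}, gene_ids[:3], genes,
                norm, rna.sample_meta, atac.sample_meta,
            )

    def test_minus_strand_rows_are_flipped(self, coverage_setup):
        cfg, genes, rna, atac, cov, gene_ids, norm = coverage_setup
        # make an asymmetric profile: ramp increasing to the right in genome
        # orientation; after flipping, minus-strand genes ramp left
        n_bins = next(iter(cov.values())).shape[1]
        ramp = np.arange(n_bins, dtype=float)
        asym = {s: np.tile(ramp, (len(gene_ids), 1)) for s in cov}
        prof = tss_quintile_profiles(
            asym, gene_ids, genes, norm, rna.sample_meta, atac.sample_meta
        )
        strands = {g.gene_id: g.strand for g in genes}
        frac_minus = np.mean([strands[g] == "-" for g in gene_ids])
        for mat in prof.values():
            # each quintile mixes + (ramp up) and - (ramp down) genes
            expect_left = (1 - frac_minus) * ramp[0] + frac_minus * ramp[-1]
            # quintiles contain different gene mixtures; check the global mean
            got_left = mat.iloc[:, 0].mean()
            got_right = mat.iloc[:, -1].mean()
            assert got_left + got_right == pytest.approx(ramp[0] + ramp[-1])
            assert got_left != pytest.approx(ramp[0])  # flipping happened
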