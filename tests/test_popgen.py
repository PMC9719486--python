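"""f-statistics, weighted block jackknife and PCA projection tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hairline import genotype as gt
from hairline import popgen as pg
from hairline import simulate as sim


@pytest.fixture(scope="module")
def panel_sim():
    return sim.simulate_panel(sim.PanelSimConfig(seed=42, ancient_sources=(1, 1)))


@pytest.fixture(scope="module")
def freqs_blocks(panel_sim):
    freqs, _ = pg.allele_freqs(panel_sim.panel)
    blocks = panel_sim.panel.snp["chromosome"].to_numpy()
    return freqs, blocks


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFreqs:
    def test_single_individual_hom(self):
        snp = pd.DataFrame({"id": ["s1"], "chromosome": [1], "position": [100],
                            "ref": ["A"], "alt": ["G"]})
        ind = pd.DataFrame({"id": ["i1"], "sex": "U", "population": ["P"]})
        panel = gt.GenotypePanel(snp, np.array([[2]], dtype=np.int8), ind)
        freqs, _ = pg.allele_freqs(panel)
        assert freqs.loc["P"].iloc[0] == 1.0

    def test_mixed_genotypes(self):
        snp = pd.DataFrame({"id": ["s1"], "chromosome": [1], "position": [100],
                            "ref": ["A"], "alt": ["G"]})
        ind = pd.DataFrame({"id": ["i1", "i2", "i3"], "sex": "U", "population": ["P"] * 3})
        panel = gt.GenotypePanel(snp, np.array([[0], [1], [2]], dtype=np.int8), ind)
        freqs, _ = pg.allele_freqs(panel)
        assert freqs.loc["P"].iloc[0] == 0.5

    def test_matches_brute_force_recount(self, panel_sim):
        freqs, _ = pg.allele_freqs(panel_sim.panel)
        g = panel_sim.panel.genotypes
        pops = panel_sim.panel.individuals["population"].to_numpy()
        for p in ("Pop0", "Outgroup"):
            rows = g[pops == p].astype(float)
            rows[rows == 9] = np.nan
            want = np.nanmean(rows, axis=0) / 2
            np.testing.assert_allclose(freqs.loc[p].to_numpy(), want, atol=1e-12)

    def test_empty_population_rejected(self, panel_sim):
        with pytest.raises(ValueError):
            pg.allele_freqs(panel_sim.panel, populations=["nope"])


# ---------------------------------------------------------------------------
# f3 / f4
# ---------------------------------------------------------------------------

class TestFStats:
    def test_f3_zero_when_a_equals_outgroup(self, freqs_blocks):
        freqs, blocks = freqs_blocks
        o = freqs.loc["Outgroup"].to_numpy()
        r = pg.f3_outgroup(o, freqs.loc["Pop0"].to_numpy(), o, blocks, min_snps=1)
        assert r.value == 0.0

    def test_f3_self_comparison_nonnegative(self, freqs_blocks):
        freqs, blocks = freqs_blocks
        a = freqs.loc["Pop0"].to_numpy()
        o = freqs.loc["Outgroup"].to_numpy()
        assert pg.f3_outgroup(a, a, o, blocks, min_snps=1).value >= 0

    def test_f3_hand_arithmetic(self):
        a = np.array([1.0, 0.0, 0.5])
        b = np.array([1.0, 0.5, 0.0])
        o = np.zeros(3)
        r = pg.f3_outgroup(a, b, o, np.array([1, 1, 2]), min_snps=1)
        assert r.value == pytest.approx(1 / 3)

    def test_f3_min_snp_floor_enforced(self, freqs_blocks):
        freqs, blocks = freqs_blocks
        a = freqs.loc["Pop0"].to_numpy()[:500]
        o = freqs.loc["Outgroup"].to_numpy()[:500]
        with pytest.raises(ValueError, match="usable SNPs"):
            pg.f3_outgroup(a, a, o, blocks[:500], min_snps=1000)

    def test_f4_zero_when_a_equals_b(self, freqs_blocks):
        freqs, blocks = freqs_blocks
        a = freqs.loc["Pop0"].to_numpy()
        r = pg.f4_stat(a, a, freqs.loc["Pop1"].to_numpy(),
                       freqs.loc["Outgroup"].to_numpy(), blocks)
        assert r.value == 0.0 and r.se == 0.0

    def test_f4_symmetry_identities_exact(self, freqs_blocks):
        freqs, blocks = freqs_blocks
        a, b = freqs.loc["Pop0"].to_numpy(), freqs.loc["Pop1"].to_numpy()
        c, d = freqs.loc["Pop2"].to_numpy(), freqs.loc["Outgroup"].to_numpy()
        base = pg.f4_stat(a, b, c, d, blocks)
        assert pg.f4_stat(b, a, c, d, blocks).value == pytest.approx(-base.value, abs=1e-15)
        assert pg.f4_stat(a, b, d, c, blocks).value == pytest.approx(-base.value, abs=1e-15)
        assert pg.f4_stat(c, d, a, b, blocks).value == pytest.approx(base.value, abs=1e-15)

    def test_missingness_drops_snps(self, freqs_blocks):
        freqs, blocks = freqs_blocks
        a = freqs.loc["Pop0"].to_numpy().copy()
        a[:100] = np.nan
        r = pg.f4_stat(a, freqs.loc["Pop1"].to_numpy(), freqs.loc["Pop2"].to_numpy(),
                       freqs.loc["Outgroup"].to_numpy(), blocks)
        assert r.n_snps == a.size - 100


# ---------------------------------------------------------------------------
# weighted block jackknife
# ---------------------------------------------------------------------------

class TestBlockJackknife:
    def test_constant_contributions_zero_se(self):
        r = pg.block_jackknife(np.full(100, 0.7), np.repeat(np.arange(10), 10))
        assert r.se == pytest.approx(0.0, abs=1e-12)

    def test_equal_blocks_reduce_to_delete_one_formula(self, rng):
        """With equal block sizes the weighted formula equals the classic
        delete-one-block jackknife ((g-1)/g * sum of squared deviations)."""
        x = rng.normal(size=220)
        labels = np.repeat(np.arange(22), 10)
        r = pg.block_jackknife(x, labels)
        minus = np.array([x[labels != k].mean() for k in range(22)])
        want = math.sqrt((22 - 1) / 22 * ((minus - minus.mean()) ** 2).sum())
        assert r.se == pytest.approx(want, rel=1e-10)

    def test_se_of_mean_matches_closed_form(self):
        """Jackknife SE of an i.i.d. mean tracks s/sqrt(n): the mean ratio
        over 50 seeds stays within 15%."""
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(600 + seed)
            x = rng.normal(size=2200)
            r = pg.block_jackknife(x, np.repeat(np.arange(22), 100))
            ratios.append(r.se / (x.std(ddof=1) / math.sqrt(x.size)))
        assert abs(np.mean(ratios) - 1) < 0.15

    def test_unequal_blocks_follow_weighted_formula(self, rng):
        """Direct transcription oracle of the weighted jackknife algebra."""
        sizes = np.array([5, 10, 20, 40])
        x = rng.normal(size=int(sizes.sum()))
        labels = np.repeat(np.arange(4), sizes)
        r = pg.block_jackknife(x, labels)
        n, g = x.size, 4
        theta = x.mean()
        minus = np.array([x[labels != k].mean() for k in range(g)])
        h = n / sizes
        tau = h * theta - (h - 1) * minus
        theta_j = g * theta - np.sum((1 - sizes / n) * minus)
        want = math.sqrt(np.sum((tau - theta_j) ** 2 / (h - 1)) / g)
        assert r.se == pytest.approx(want, rel=1e-12)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            pg.block_jackknife(np.ones(10), np.zeros(10))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _modern_pops(panel):
    return [p for p in pd.unique(panel.individuals["population"]) if p != "Outgroup"]


class TestPCA:
    def test_two_identical_groups_separate_on_pc1(self):
        snp = pd.DataFrame({"id": [f"s{j}" for j in range(8)], "chromosome": 1,
                            "position": np.arange(8) * 100, "ref": "A", "alt": "G"})
        g = np.vstack([np.tile([2, 2, 0, 0, 2, 0, 2, 0], (3, 1)),
                       np.tile([0, 0, 2, 2, 0, 2, 0, 2], (3, 1))]).astype(np.int8)
        ind = pd.DataFrame({"id": [f"i{k}" for k in range(6)], "sex": "U",
                            "population": ["A"] * 3 + ["B"] * 3})
        basis = pg.pca_fit(gt.GenotypePanel(snp, g, ind), n_pcs=4)
        s = basis.scores.to_numpy()
        assert np.sign(s[:3, 0]).std() == 0 and np.sign(s[3:, 0]).std() == 0
        assert np.sign(s[0, 0]) != np.sign(s[3, 0])
        assert np.all(basis.eigenvalues[1:] < 1e-20 * basis.eigenvalues[0] + 1e-12)

    def test_scores_match_dense_eigendecomposition_oracle(self, rng):
        snp = pd.DataFrame({"id": [f"s{j}" for j in range(8)], "chromosome": 1,
                            "position": np.arange(8) * 100, "ref": "A", "alt": "G"})
        g = rng.integers(0, 3, size=(6, 8)).astype(np.int8)
        ind = pd.DataFrame({"id": [f"i{k}" for k in range(6)], "sex": "U",
                            "population": "P"})
        panel = gt.GenotypePanel(snp, g, ind)
        basis = pg.pca_fit(panel)
        # oracle: eigendecomposition of X X^T on the same standardised matrix
        gg = g.astype(float)
        mu = gg.mean(axis=0)
        scale = np.sqrt((mu / 2) * (1 - mu / 2))
        kept = basis.kept
        x = (gg[:, kept] - mu[kept]) / scale[kept]
        vals, vecs = np.linalg.eigh(x @ x.T)
        order = np.argsort(vals)[::-1]
        k = basis.scores.shape[1]
        want = vecs[:, order[:k]] * np.sqrt(np.maximum(vals[order[:k]], 0))
        got = basis.scores.to_numpy()
        for j in range(k):
            assert (np.allclose(got[:, j], want[:, j], atol=1e-8)
                    or np.allclose(got[:, j], -want[:, j], atol=1e-8))

    def test_monomorphic_snps_dropped(self):
        snp = pd.DataFrame({"id": ["s0", "s1", "s2"], "chromosome": 1,
                            "position": [0, 100, 200], "ref": "A", "alt": "G"})
        g = np.array([[2, 2, 0], [2, 0, 2], [2, 0, 0]], dtype=np.int8)  # s0 monomorphic
        ind = pd.DataFrame({"id": ["a", "b", "c"], "sex": "U", "population": "P"})
        basis = pg.pca_fit(gt.GenotypePanel(snp, g, ind))
        assert basis.dropped_monomorphic == 1
        assert 0 not in basis.kept

    def test_projection_self_consistency(self, panel_sim):
        """A panel individual with no missingness projects onto its own
        fitted scores to 1e-8."""
        basis = pg.pca_fit(panel_sim.panel, populations=_modern_pops(panel_sim.panel), n_pcs=4)
        g0 = panel_sim.panel.genotypes[0]
        proj = pg.pca_project(g0, basis, n_pcs=4)
        np.testing.assert_allclose(proj.coordinates,
                                   basis.scores.iloc[0, :4].to_numpy(), atol=1e-8)

    def test_mean_genotype_projects_to_origin(self, panel_sim):
        """A sample sitting exactly at the per-SNP mean standardises to the
        zero vector, so every projected coordinate is 0."""
        basis = pg.pca_fit(panel_sim.panel, populations=_modern_pops(panel_sim.panel), n_pcs=2)
        coef = pg._project(basis.mean, basis, 2, np.arange(basis.kept.size))
        np.testing.assert_allclose(coef, 0.0, atol=1e-8)

    def test_sparse_ancient_lands_near_source_centroid(self, panel_sim):
        """50%-missing pseudo-haploid sample from Pop1 projects within 4
        jackknife SE of the Pop1 centroid."""
        panel = panel_sim.panel
        basis = pg.pca_fit(panel, populations=_modern_pops(panel), n_pcs=2)
        chroms = panel.snp["chromosome"].to_numpy()
        proj = pg.pca_jackknife(panel_sim.ancient_genotypes[0], basis, chroms, n_pcs=2)
        ids = panel.individuals
        pop1 = ids[ids["population"] == "Pop1"]["id"]
        centroid = basis.scores.loc[pop1].mean().to_numpy()[:2]
        assert np.all(np.abs(proj.coordinates - centroid) <= 4 * proj.se)

    def test_requested_pcs_bounded_by_individuals(self, panel_sim):
        with pytest.raises(ValueError):
            pg.pca_fit(panel_sim.panel, populations=_modern_pops(panel_sim.panel), n_pcs=999)


class TestPCAJackknife:
    def test_single_chromosome_sample_rejected(self, panel_sim):
        panel = panel_sim.panel
        basis = pg.pca_fit(panel, populations=_modern_pops(panel), n_pcs=2)
        chroms = panel.snp["chromosome"].to_numpy()
        calls = panel_sim.ancient_genotypes[0].copy()
        calls[chroms != 1] = gt.MISSING
        with pytest.raises(ValueError, match="chromosome"):
            pg.pca_jackknife(calls, basis, chroms, n_pcs=2)

    def test_leave_out_coordinates_match_independent_reprojection(self, panel_sim):
        """Each take-one-chromosome-out coordinate equals a from-scratch
        lstsq reprojection on the remaining SNPs (1e-10)."""
        panel = panel_sim.panel
        basis = pg.pca_fit(panel, populations=_modern_pops(panel), n_pcs=2)
        chroms = panel.snp["chromosome"].to_numpy()
        calls = panel_sim.ancient_genotypes[0]
        proj = pg.pca_jackknife(calls, basis, chroms, n_pcs=2)

        kept_chroms = chroms[basis.kept]
        vals = calls[basis.kept].astype(float)
        nonmiss = calls[basis.kept] != gt.MISSING
        labels = np.unique(kept_chroms[nonmiss])
        minus, sizes = [], []
        for c in labels:
            use = np.flatnonzero(nonmiss & (kept_chroms != c))
            v = basis.loadings[use, :2]
            x = (vals[use] - basis.mean[use]) / basis.scale[use]
            coef, *_ = np.linalg.lstsq(v, x, rcond=None)
            minus.append(coef)
            sizes.append(int((nonmiss & (kept_chroms == c)).sum()))
        minus = np.array(minus)
        se = np.empty(2)
        full = proj.coordinates
        for pc in range(2):
            _, se[pc] = pg.weighted_jackknife(full[pc], minus[:, pc], np.array(sizes))
        np.testing.assert_allclose(se, proj.se, atol=1e-10)

    def test_se_scales_roughly_as_inverse_sqrt_n(self):
        """Doubling the sample's non-missing SNP count shrinks the median
        jackknife SE by ~1/sqrt(2) (+/-25% on the mean ratio, 20 seeds)."""
        ratios = []
        for seed in range(20):
            res = sim.simulate_panel(sim.PanelSimConfig(
                seed=700 + seed, ancient_sources=(1, 1), ancient_missingness=0.5))
            res2 = sim.simulate_panel(sim.PanelSimConfig(
                seed=700 + seed, ancient_sources=(1, 1), ancient_missingness=0.0))
            panel = res.panel
            basis = pg.pca_fit(panel, populations=_modern_pops(panel), n_pcs=2)
            chroms = panel.snp["chromosome"].to_numpy()
            se_half = pg.pca_jackknife(res.ancient_genotypes[0], basis, chroms, 2).se
            se_full = pg.pca_jackknife(res2.ancient_genotypes[0], basis, chroms, 2).se
            ratios.append(np.median(se_full) / np.median(se_half))
        mean_ratio = float(np.mean(ratios))
        assert 0.75 / math.sqrt(2) < mean_ratio < 1.25 / math.sqrt(2)

    def test_full_coverage_panel_individual_has_small_se(self, panel_sim):
        """For a no-missingness panel individual the projection equals its
        scores and the leave-out scatter is far below population spread."""
        panel = panel_sim.panel
        basis = pg.pca_fit(panel, populations=_modern_pops(panel), n_pcs=2)
        chroms = panel.snp["chromosome"].to_numpy()
        proj = pg.pca_jackknife(panel.genotypes[0], basis, chroms, n_pcs=2)
        spread = basis.scores.to_numpy()[:, 0].std()
        assert np.all(proj.se < 0.2 * spread)


# ---------------------------------------------------------------------------
# cladality level and power
# ---------------------------------------------------------------------------

class TestCladality:
    def test_cladal_pair_rarely_significant(self):
        """f4(anc1, anc2; X, Outgroup) for a same-source pseudo-haploid pair:
        |Z| < 3 in >= 95% of 20 seeded replicates."""
        n_ok = 0
        for seed in range(20):
            res = sim.simulate_panel(sim.PanelSimConfig(seed=800 + seed))
            freqs, _ = pg.allele_freqs(res.panel)
            blocks = res.panel.snp["chromosome"].to_numpy()
            r = pg.f4_stat(pg.haploid_freqs(res.ancient_genotypes[0]),
                           pg.haploid_freqs(res.ancient_genotypes[1]),
                           freqs.loc["Pop2"].to_numpy(),
                           freqs.loc["Outgroup"].to_numpy(), blocks)
            n_ok += abs(r.z) < 3
        assert n_ok >= 19

    def test_non_cladal_pair_detected(self):
        """Ancients from two different populations, with the test population
        X sharing one source's drift: |Z| > 3 in >= 80% of 20 replicates.
        Run at drift F = 0.15 where the f4 signal (F * mean p(1-p) ~ 0.027)
        clears the jackknife SE by ~5x."""
        n_sig = 0
        for seed in range(20):
            res = sim.simulate_panel(sim.PanelSimConfig(
                seed=900 + seed, drift=0.15, ancient_sources=(0, 1),
                ancient_missingness=0.0))
            freqs, _ = pg.allele_freqs(res.panel)
            blocks = res.panel.snp["chromosome"].to_numpy()
            r = pg.f4_stat(pg.haploid_freqs(res.ancient_genotypes[0]),
                           pg.haploid_freqs(res.ancient_genotypes[1]),
                           freqs.loc["Pop1"].to_numpy(),
                           freqs.loc["Outgroup"].to_numpy(), blocks)
            n_sig += abs(r.z) > 3
        assert n_sig >= 16


@given(st.lists(st.floats(0, 1), min_size=4, max_size=40))
def test_f4_antisymmetry_property(vals):
    """f4(A,B;C,D) = -f4(B,A;C,D) on arbitrary frequency vectors."""
    x = np.array(vals)
    rng = np.random.default_rng(1)
    a, b = x, rng.permutation(x)
    c, d = rng.permutation(x), rng.permutation(x)
    blocks = np.arange(x.size) % 2
    r1 = pg.f4_stat(a, b, c, d, blocks)
    r2 = pg.f4_stat(b, a, c, d, blocks)
    assert r1.value == pytest.approx(-r2.value, abs=1e-12)
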