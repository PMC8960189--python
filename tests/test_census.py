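import numpy as np
import pytest
from scipy import stats

from nimotif.census import (
    PoissonOutlierDetector,
    density_cdf,
    expected_g_cdf,
    fit_poisson,
    flag_outliers,
    motif_percentages,
    observed_histogram,
    poisson_expected_with_bands,
    x1_composition,
    x1_enrichment,
)
from nimotif.io import BackgroundFrequencies, CANONICAL_AA, aa_frequencies
from nimotif.motifs import MotifHit, MotifScanner
from nimotif.simulate import SyntheticProteomeSpec, gen_proteome


def _hit(x1, st):
    return MotifHit("P", 1, 6, st, x1, (1,), "X-motif")


class TestX1Composition:
    def test_fractions_per_variant(self):
        hits = [_hit("G", "S"), _hit("G", "S"), _hit("A", "S")]
        comp = x1_composition(hits, "S")
        assert comp["G"] == pytest.approx(2 / 3)
        assert comp["A"] == pytest.approx(1 / 3)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_t_variant(self):
        comp = x1_composition([_hit("H", "T")], "T")
        assert comp["H"] == 1.0

    def test_other_variant_excluded(self):
        hits = [_hit("G", "S"), _hit("A", "T")]
        comp = x1_composition(hits, "S")
        assert comp["A"] == 0.0 and comp["G"] == 1.0

    def test_empty_variant_is_error(self):
        with pytest.raises(ValueError, match="empty variant"):
            x1_composition([_hit("G", "S")], "T")


class TestX1Enrichment:
    def _uniform_bg(self):
        return BackgroundFrequencies(
            {aa: 1 / 20 for aa in CANONICAL_AA}, counted_residues=2000
        )

    def test_identity_gives_zero(self):
        bg = self._uniform_bg()
        tab = x1_enrichment({aa: 1 / 20 for aa in CANONICAL_AA}, bg)
        assert tab["score"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_twofold_gives_one(self):
        bg = self._uniform_bg()
        obs = {aa: 0.0 for aa in CANONICAL_AA}
        obs["G"] = 2 / 20
        tab = x1_enrichment(obs, bg)
        assert tab.set_index("residue").loc["G", "score"] == pytest.approx(1.0)

    def test_absent_residue_flagged_with_sentinel(self):
        bg = self._uniform_bg()
        obs = {aa: 0.0 for aa in CANONICAL_AA}
        obs["G"] = 1.0
        tab = x1_enrichment(obs, bg).set_index("residue")
        assert tab.loc["A", "absent"]
        assert tab.loc["A", "score"] == float("-inf")

    def test_zero_background_with_observed_is_error(self):
        bg = BackgroundFrequencies({"A": 1.0}, counted_residues=10)
        with pytest.raises(ValueError):
            x1_enrichment({"G": 1.0}, bg)

    def test_g_spiked_proteome_maximises_glycine(self):
        spec = SyntheticProteomeSpec(
            n_proteins=200, lambda_spike=2.0, spike_pattern="G", seed=3
        )
        records, _ = gen_proteome(spec)
        sc = MotifScanner().fit()
        sc.transform(records)
        obs = x1_composition(sc.hits("X-motif"), "both")
        tab = x1_enrichment(obs, aa_frequencies(records))
        finite = tab[~tab["absent"]].set_index("residue")
        assert finite["score"].idxmax() == "G"
        assert finite.loc["G", "score"] > 0


class TestDensityCDF:
    def test_equal_steps_and_median(self):
        cdf = density_cdf([3.0, 1.0, 2.0])
        assert cdf.evaluate(1.0) == pytest.approx(1 / 3)
        assert cdf.evaluate(2.0) == pytest.approx(2 / 3)
        assert cdf.evaluate(3.0) == 1.0
        assert cdf.median == 2.0

    def test_ties_stack(self):
        cdf = density_cdf([5.0, 5.0, 5.0])
        assert cdf.evaluate(4.99) == 0.0
        assert cdf.evaluate(5.0) == 1.0

    def test_dkw_band_against_known_distribution(self, rng):
        n = 10_000
        draws = rng.exponential(2.0, size=n)
        cdf = density_cdf(draws)
        xs = np.linspace(0.01, 10, 200)
        emp = cdf.evaluate(xs)
        truth = 1 - np.exp(-xs / 2.0)
        # DKW 99% band: eps = sqrt(ln(2/alpha) / (2n))
        eps = np.sqrt(np.log(2 / 0.01) / (2 * n))
        assert np.max(np.abs(emp - truth)) < eps


class TestExpectedGCdf:
    def test_glycine_scaling(self):
        cdf = density_cdf([10.0, 20.0])
        exp = expected_g_cdf(cdf, 0.0707)
        assert exp.densities == pytest.approx([0.707, 1.414])

    def test_identity_at_one(self):
        cdf = density_cdf([1.0, 2.0, 3.0])
        assert expected_g_cdf(cdf, 1.0).densities == pytest.approx(cdf.densities)

    def test_median_scales(self):
        cdf = density_cdf([1.0, 2.0, 3.0])
        assert expected_g_cdf(cdf, 0.5).median == pytest.approx(cdf.median / 2)


class TestFitPoisson:
    def test_degenerate_all_zero(self):
        assert fit_poisson([0, 0, 0]) == 0.0

    def test_plain_mean_without_truncation(self):
        assert fit_poisson([1, 2, 3], min_bin_count=None) == 2.0

    def test_recovers_rate_within_three_se(self, rng):
        draws = rng.poisson(3.0, size=10_000)
        lam = fit_poisson(draws)
        se = np.sqrt(3.0 / 10_000)
        assert abs(lam - 3.0) < 3 * se

    def test_isolated_tail_bin_excluded_from_central_fit(self, rng):
        counts = np.concatenate([rng.poisson(1.0, 2000), np.full(20, 30)])
        lam = fit_poisson(counts)
        assert abs(lam - 1.0) < 0.1

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            fit_poisson([])


class TestPoissonBands:
    def test_lambda_zero_degenerate(self):
        tab = poisson_expected_with_bands(0.0, 100, 3)
        assert tab.loc[0, "expected"] == pytest.approx(100)
        assert tab.loc[1:, "expected"].sum() == 0

    def test_normalisation(self):
        tab = poisson_expected_with_bands(2.0, 500, 60)
        assert tab["expected"].sum() == pytest.approx(500, abs=1e-6)

    def test_bands_bracket_expectation(self):
        tab = poisson_expected_with_bands(2.0, 500, 15)
        assert (tab["band_low"] <= tab["expected"] + 1e-9).all()
        assert (tab["band_high"] >= tab["expected"] - 1e-9).all()

    def test_band_coverage_by_simulation(self):
        # per-bin coverage of exact Poisson bands across replicates
        lam, n = 1.5, 2000
        inside = total = 0
        bands = poisson_expected_with_bands(lam, n, 8)
        for s in range(500):
            counts = np.random.default_rng(s).poisson(lam, n)
            obs = observed_histogram(counts, 8)["observed"].to_numpy()
            lo = bands["band_low"].to_numpy()
            hi = bands["band_high"].to_numpy()
            mask = bands["expected"].to_numpy() > 1  # occupied region
            inside += int(((obs >= lo) & (obs <= hi))[mask].sum())
            total += int(mask.sum())
        assert inside / total >= 0.93


class TestFlagOutliers:
    def test_exact_agreement_flags_nothing(self):
        tab = poisson_expected_with_bands(1.0, 1000, 8)
        obs = tab[["k"]].copy()
        obs["observed"] = np.round(tab["expected"]).astype(int)
        thr, ids = flag_outliers(obs, tab)
        assert thr is None and ids == []

    def test_single_marginal_bin_not_flagged(self):
        tab = poisson_expected_with_bands(1.0, 1000, 10)
        obs = tab[["k"]].copy()
        obs["observed"] = np.round(tab["expected"]).astype(int)
        # final occupied bin exceeds its band by exactly one protein
        obs.loc[obs.index[-1], "observed"] = int(tab["band_high"].iloc[-1]) + 1
        thr, _ = flag_outliers(obs, tab, persistence=2)
        assert thr is None

    def test_planted_block_recovered_exactly(self, rng):
        counts = np.concatenate([rng.poisson(1.0, 2000), np.full(20, 30)])
        ids = [f"BG{i}" for i in range(2000)] + [f"OUT{i}" for i in range(20)]
        det = PoissonOutlierDetector().fit(counts, protein_ids=ids)
        assert det.outlier_threshold_ == 30
        assert set(det.outlier_ids_) == {f"OUT{i}" for i in range(20)}
        labels = det.predict(counts)
        assert (labels == -1).sum() == 20

    def test_null_data_rarely_flagged(self):
        flagged = 0
        for s in range(50):
            counts = np.random.default_rng(900 + s).poisson(0.5, 5000)
            det = PoissonOutlierDetector().fit(counts)
            flagged += det.outlier_threshold_ is not None
        assert flagged <= 5


class TestMotifPercentages:
    def test_matches_direct_counting_on_synthetic(self):
        spec = SyntheticProteomeSpec(n_proteins=150, lambda_spike=0.7, seed=9)
        records, truth = gen_proteome(spec)
        census = MotifScanner().fit().transform(records)
        pct = motif_percentages(census)
        direct_x = 100 * (truth["n_x_scanned"] >= 1).mean()
        direct_g = 100 * (truth["n_g_scanned"] >= 1).mean()
        assert pct["pct_with_x_motif"] == pytest.approx(direct_x)
        assert pct["pct_with_g_motif"] == pytest.approx(direct_g)
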