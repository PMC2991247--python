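import numpy as np
import pytest
from scipy.stats import norm

from intmark import InputError, Region
from intmark.controls import generate_matched_controls
from intmark.core_io import SiteSet
from intmark.supermarker import (SupermarkerModel, composite_density, crossvalidate,
                                 density_correlation, evaluate_model, extract_peaks,
                                 fit_supermarker, kernel_sigma, locus_probability,
                                 make_component, select_threshold)
from intmark import synthetic as syn

from conftest import make_peaks, make_sites


@pytest.fixture(scope="module")
def multi_marker_bundle():
    """3 informative markers (sites planted around each) + 1 pure-noise marker."""
    layout, index = syn.simulate_genome(seed=501)
    markers = [syn.simulate_peakset(layout, 250, 400, seed=510 + i, label=f"m{i}")
               for i in range(3)]
    noise = syn.simulate_peakset(layout, 250, 400, seed=514, label="noise")
    parts = [syn.simulate_integrations(layout, m, 120, 0.9, 400, seed=520 + i,
                                       label=f"s{i}")[0] for i, m in enumerate(markers)]
    sites = SiteSet("sites", layout,
                    np.concatenate([p.chrom_ids for p in parts]),
                    np.concatenate([p.pos for p in parts]))
    controls = generate_matched_controls(sites, index, 5, seed=530)
    return {"layout": layout, "index": index, "markers": markers, "noise": noise,
            "sites": sites, "controls": controls}


def single_peak_model(layout, chrom=0, pos=1_000_000, sigma=400.0):
    return SupermarkerModel(layout, np.array([chrom]), np.array([pos]),
                            np.array([1.0]), sigma, 1, 0.9, 2000, 0.5,
                            ("m",), (0.8,))


class TestMarkerDensity:
    def test_single_peak_mode_value(self, toy_layout):
        big = syn.simulate_genome(seed=1)[0]
        m = make_peaks(big, "m", [(0, 990, 1011, 1000)])
        comp = make_component(m, 0.8, "fixed:400")
        d = comp.density(0, np.array([1000.0]))
        assert d[0] == pytest.approx(1.0 / (400 * np.sqrt(2 * np.pi)), rel=1e-9)

    def test_gaussian_shape_at_one_sigma(self):
        big = syn.simulate_genome(seed=1)[0]
        m = make_peaks(big, "m", [(0, 990, 1011, 1000)])
        comp = make_component(m, 0.8, "fixed:400")
        mode, off = comp.density(0, np.array([1000.0, 1400.0]))
        assert off == pytest.approx(mode * np.exp(-0.5), rel=1e-9)

    def test_two_distant_peaks_split_mass(self):
        layout = syn.simulate_genome(seed=1)[0]
        sigma = 400.0
        m = make_peaks(layout, "m", [(0, 990, 1011, 1000), (0, 4990, 5011, 5000)])
        comp = make_component(m, 0.8, "fixed:400")
        # numeric mass in summit +/- 3 sigma should be ~0.5 * 0.9973 each
        for center in (1000, 5000):
            x = np.arange(center - 3 * sigma, center + 3 * sigma + 1.0)
            mass = comp.density(0, x).sum()
            assert mass == pytest.approx(0.5 * 0.9973, abs=0.002)

    def test_sigma_policies(self, toy_layout):
        m = make_peaks(toy_layout, "m", [(0, 100, 500)])  # width 400
        assert kernel_sigma(m, "width") == 400.0
        assert kernel_sigma(m, "sqrt-width") == pytest.approx(20.0)
        assert kernel_sigma(m, "fixed:123") == 123.0
        with pytest.raises(InputError):
            kernel_sigma(m, "nope")


class TestCompositeDensity:
    def test_single_component_weight_one(self, toy_layout):
        big = syn.simulate_genome(seed=1)[0]
        m = make_peaks(big, "m", [(0, 990, 1011, 1000)])
        dens = composite_density([make_component(m, 0.7, "fixed:300")])
        x = np.array([500.0, 1000.0, 1500.0])
        assert dens.components[0].lam == 1.0
        assert np.allclose(dens.evaluate(0, x), dens.components[0].density(0, x))

    def test_equal_f_equal_weights(self):
        big = syn.simulate_genome(seed=1)[0]
        m1 = make_peaks(big, "a", [(0, 990, 1011, 1000)])
        m2 = make_peaks(big, "b", [(0, 4990, 5011, 5000)])
        dens = composite_density([make_component(m1, 0.6, "fixed:300"),
                                  make_component(m2, 0.6, "fixed:300")])
        assert [c.lam for c in dens.components] == pytest.approx([0.5, 0.5])

    def test_odds_weighting_four_to_one(self):
        big = syn.simulate_genome(seed=1)[0]
        m1 = make_peaks(big, "a", [(0, 990, 1011, 1000)])
        m2 = make_peaks(big, "b", [(0, 4990, 5011, 5000)])
        dens = composite_density([make_component(m1, 0.8, "fixed:300"),
                                  make_component(m2, 0.5, "fixed:300")])
        assert [c.lam for c in dens.components] == pytest.approx([0.8, 0.2])

    def test_f_outside_unit_interval_rejected(self):
        big = syn.simulate_genome(seed=1)[0]
        m = make_peaks(big, "a", [(0, 990, 1011, 1000)])
        with pytest.raises(InputError, match="exclude"):
            composite_density([make_component(m, 1.0, "fixed:300")])


class TestExtractPeaks:
    def test_single_gaussian_single_peak(self):
        layout = syn.simulate_genome(seed=1)[0]
        m = make_peaks(layout, "m", [(0, 990, 1011, 1000)])
        dens = composite_density([make_component(m, 0.7, "fixed:300")])
        peaks = extract_peaks(dens, grid_step=10)
        assert peaks.n == 1
        assert abs(int(peaks.pos[0]) - 1000) <= 10

    def test_coincident_summits_merge_and_superpose(self):
        layout = syn.simulate_genome(seed=1)[0]
        m1 = make_peaks(layout, "a", [(0, 990, 1011, 1000)])
        m2 = make_peaks(layout, "b", [(0, 995, 1006, 1000)])
        dens = composite_density([make_component(m1, 0.6, "fixed:300"),
                                  make_component(m2, 0.6, "fixed:300")])
        peaks = extract_peaks(dens, grid_step=10)
        assert peaks.n == 1
        single = composite_density([make_component(m1, 0.6, "fixed:300")])
        assert peaks.amplitude[0] == pytest.approx(
            single.evaluate(0, np.array([float(peaks.pos[0])]))[0], rel=1e-9)

    def test_amplitudes_match_reevaluation(self, multi_marker_bundle):
        b = multi_marker_bundle
        comps = [make_component(m, 0.7, "width") for m in b["markers"][:2]]
        dens = composite_density(comps)
        peaks = extract_peaks(dens, grid_step=10)
        idx = np.random.default_rng(0).choice(peaks.n, size=20, replace=False)
        for i in idx:
            val = dens.evaluate(int(peaks.chrom_ids[i]),
                                np.array([float(peaks.pos[i])]))[0]
            assert peaks.amplitude[i] == pytest.approx(val, rel=1e-9)


class TestSelectThreshold:
    def test_argmax_contract_and_noise_exclusion(self, multi_marker_bundle):
        b = multi_marker_bundle
        comps = [make_component(m, 0.7, "width") for m in b["markers"]]
        comps.append(make_component(b["noise"], 0.25, "width"))
        dens = composite_density(comps)
        peaks = extract_peaks(dens, grid_step=10)
        k_star, gamma, f_star = select_threshold(peaks, b["sites"], b["controls"], 2000)
        assert gamma.n == k_star and f_star > 0
        # F(k*) >= F at every other evaluated k (re-check a sample directly)
        from intmark.association import build_table, f_score
        for k in [max(k_star // 2, 1), min(k_star * 2, peaks.n), peaks.n]:
            _, _, f_k = f_score(build_table(b["sites"], b["controls"],
                                            peaks.top(k).to_peakset(), 2000))
            assert f_star >= f_k - 1e-12
        # >= 90% of selected peaks lie at planted (informative) summits
        informative = np.concatenate([
            m.summit + b["layout"].offsets[m.chrom_ids] for m in b["markers"]])
        informative.sort()
        gpos = gamma.layout.offsets[gamma.chrom_ids] + gamma.pos
        i = np.searchsorted(informative, gpos)
        near = np.minimum(
            np.abs(gpos - informative[np.clip(i - 1, 0, informative.size - 1)]),
            np.abs(informative[np.clip(i, 0, informative.size - 1)] - gpos))
        assert (near <= 400).mean() >= 0.9

    def test_no_signal_errors(self, multi_marker_bundle):
        b = multi_marker_bundle
        far_sites = make_sites(b["layout"], [(0, 10), (0, 20), (0, 30)])
        comps = [make_component(b["markers"][0], 0.7, "width")]
        peaks = extract_peaks(composite_density(comps), grid_step=10)
        ctrl = generate_matched_controls(far_sites, b["index"], 2, seed=1)
        with pytest.raises(InputError, match="F > 0"):
            select_threshold(peaks, far_sites, ctrl, w=1)


class TestFitSupermarker:
    def test_excludes_noise_and_beats_singletons(self, multi_marker_bundle):
        b = multi_marker_bundle
        fit = fit_supermarker(b["markers"] + [b["noise"]], b["sites"], b["controls"])
        assert "noise" not in fit.model.marker_labels
        singles = {r["markers"][0]: r["f_train"] for r in fit.search
                   if len(r["markers"]) == 1}
        assert fit.model.f_train >= max(singles.values()) - 1e-12
        assert len(fit.search) == 2 ** 4 - 1

    def test_single_candidate_is_thresholded_marker(self, multi_marker_bundle):
        b = multi_marker_bundle
        fit = fit_supermarker([b["markers"][0]], b["sites"], b["controls"])
        assert fit.model.marker_labels == ("m0",)
        assert fit.model.n_peaks == fit.model.k_star

    def test_too_many_candidates(self, multi_marker_bundle):
        b = multi_marker_bundle
        with pytest.raises(InputError, match="pre-filter"):
            fit_supermarker(b["markers"] * 3, b["sites"], b["controls"], max_subset=8)


class TestCrossValidation:
    def test_deterministic_and_partition(self, multi_marker_bundle):
        b = multi_marker_bundle
        r1 = crossvalidate(b["markers"], b["sites"], b["controls"], folds=5, seed=42)
        r2 = crossvalidate(b["markers"], b["sites"], b["controls"], folds=5, seed=42)
        assert np.array_equal(r1.fold_of_site, r2.fold_of_site)
        assert np.allclose(r1.test_f, r2.test_f)
        counts = np.bincount(r1.fold_of_site, minlength=5)
        assert counts.sum() == b["sites"].n and counts.max() - counts.min() <= 1

    def test_heldout_f_tracks_training_f(self, multi_marker_bundle):
        b = multi_marker_bundle
        rep = crossvalidate(b["markers"], b["sites"], b["controls"], folds=5, seed=7)
        assert abs(rep.mean_f - rep.train_f.mean()) < 0.1

    def test_requires_provenance(self, multi_marker_bundle):
        b = multi_marker_bundle
        with pytest.raises(InputError):
            crossvalidate(b["markers"], b["sites"], b["controls"].sites, folds=5, seed=1)


class TestLocusProbability:
    def test_whole_genome_is_one(self, multi_marker_bundle):
        b = multi_marker_bundle
        fit = fit_supermarker(b["markers"][:2], b["sites"], b["controls"])
        total = sum(locus_probability(fit.model,
                                      Region(n, 0, int(l)))
                    for n, l in zip(b["layout"].names, b["layout"].lengths))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_single_peak_three_sigma(self):
        layout = syn.simulate_genome(seed=1)[0]
        model = single_peak_model(layout, sigma=400.0)
        p = locus_probability(model, Region("chr1", 1_000_000 - 1200, 1_000_000 + 1200))
        assert p == pytest.approx(norm.cdf(3) - norm.cdf(-3), abs=1e-4)

    def test_far_region_negligible(self):
        layout = syn.simulate_genome(seed=1)[0]
        model = single_peak_model(layout, sigma=400.0)
        assert locus_probability(model, Region("chr2", 0, 100_000)) < 1e-6

    def test_serialization_roundtrip_preserves_probabilities(self, multi_marker_bundle, tmp_path):
        b = multi_marker_bundle
        fit = fit_supermarker(b["markers"][:2], b["sites"], b["controls"])
        path = tmp_path / "model.json"
        fit.model.to_json(path)
        back = SupermarkerModel.from_json(path)
        rng = np.random.default_rng(11)
        for _ in range(100):
            cid = int(rng.integers(0, 2))
            start = int(rng.integers(0, 4_000_000))
            region = Region(b["layout"].names[cid], start, start + 50_000)
            assert locus_probability(back, region) == pytest.approx(
                locus_probability(fit.model, region), abs=1e-12)


class TestDensityCorrelation:
    def test_sites_from_model_density_correlate(self):
        layout = syn.simulate_genome(seed=61)[0]
        marker = syn.simulate_peakset(layout, 300, 400, seed=61, label="m")
        model = SupermarkerModel(layout, marker.chrom_ids, marker.summit,
                                 np.ones(marker.n), 400.0, marker.n, 0.8, 2000, 0.5,
                                 ("m",), (0.8,))
        rs = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            j = rng.integers(0, marker.n, size=2000)
            pos = marker.summit[j] + rng.normal(0, 400, size=2000).astype(np.int64)
            keep = (pos >= 0) & (pos < layout.lengths[marker.chrom_ids[j]])
            sites = SiteSet("s", layout, marker.chrom_ids[j][keep], pos[keep])
            rs.append(density_correlation(model, sites, 10_000)[0])
        assert min(rs) > 0.7

    def test_uniform_sites_near_zero(self):
        layout = syn.simulate_genome(seed=62)[0]
        marker = syn.simulate_peakset(layout, 100, 400, clustered=True, seed=62)
        model = SupermarkerModel(layout, marker.chrom_ids, marker.summit,
                                 np.ones(marker.n), 400.0, marker.n, 0.8, 2000, 0.5,
                                 ("m",), (0.8,))
        rs = []
        for seed in (4, 5, 6):
            rng = np.random.default_rng(seed)
            g = rng.uniform(0, layout.total, size=2000).astype(np.int64)
            cids = np.searchsorted(layout.offsets, g, side="right") - 1
            sites = SiteSet("s", layout, cids, g - layout.offsets[cids])
            rs.append(abs(density_correlation(model, sites, 10_000)[0]))
        assert max(rs) < 0.1

    def test_too_few_windows(self):
        layout = syn.simulate_genome(seed=1)[0]
        model = single_peak_model(layout)
        with pytest.raises(InputError):
            density_correlation(model, make_sites(layout, [(0, 1)]), 6_000_000)
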