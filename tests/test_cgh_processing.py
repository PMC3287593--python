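import logging
import math

import numpy as np
import pytest
from scipy import stats

from ceqtl.cgh_processing import (
    AUTOSOME_TARGET,
    SEX_TARGET,
    ModeEstimate,
    NoGainDetectedError,
    RetentionTable,
    bin_copy_number,
    call_retention,
    centromere_retention_test,
    concordance_with_legacy,
    fit_bimodal_modes,
    normalize_dosage,
    retention_stats,
    sliding_window_smooth,
)
from ceqtl.matrices import NORMALIZED, SMOOTHED, DosageMatrix
from ceqtl.synthetic_panel import SimulationConfig, simulate_acgh, simulate_fragments

from conftest import build_panel


def make_dosage(values, chrom=None, chrom_class=None, state="raw", spacing=1000):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    chrom = np.array(chrom if chrom is not None else ["chr1"] * n)
    chrom_class = np.array(chrom_class if chrom_class is not None else ["autosome"] * n)
    pos = np.zeros(n, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.arange(idx.size) * spacing
    return DosageMatrix(
        values=values,
        marker_ids=[f"m{i}" for i in range(n)],
        chrom=chrom,
        position=pos,
        chrom_class=chrom_class,
        clone_ids=[f"c{j}" for j in range(values.shape[1])],
        state=state,
    )


class TestSlidingWindowSmooth:
    def test_constant_input_identity(self):
        d = make_dosage(np.full((20, 3), 0.7))
        out = sliding_window_smooth(d, window=10)
        np.testing.assert_allclose(out.values, d.values)
        assert out.state == SMOOTHED

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        d = make_dosage(rng.normal(size=(15, 2)))
        out = sliding_window_smooth(d, window=1)
        np.testing.assert_allclose(out.values, d.values)

    def test_hand_rolling_mean_oracle(self):
        # window 3 centered on [0,0,1,0,0] -> [0, 1/3, 1/3, 1/3, 0]
        d = make_dosage(np.array([[0.0], [0.0], [1.0], [0.0], [0.0]]))
        out = sliding_window_smooth(d, window=3)
        np.testing.assert_allclose(
            out.values.ravel(), [0.0, 1 / 3, 1 / 3, 1 / 3, 0.0]
        )

    def test_truncated_edges_match_brute_force(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(25, 2))
        d = make_dosage(vals)
        out = sliding_window_smooth(d, window=10)
        left, right = 5, 4
        for i in range(25):
            lo, hi = max(0, i - left), min(25, i + right + 1)
            np.testing.assert_allclose(out.values[i], vals[lo:hi].mean(axis=0))

    def test_windows_never_span_chromosomes(self):
        vals = np.concatenate([np.zeros((6, 1)), np.ones((6, 1))])
        d = make_dosage(vals, chrom=["chr1"] * 6 + ["chr2"] * 6)
        out = sliding_window_smooth(d, window=3)
        np.testing.assert_allclose(out.values[:6], 0.0)
        np.testing.assert_allclose(out.values[6:], 1.0)

    def test_window_larger_than_chromosome_falls_back(self, caplog):
        vals = np.arange(8, dtype=float).reshape(4, 2)
        d = make_dosage(vals)
        with caplog.at_level(logging.WARNING):
            out = sliding_window_smooth(d, window=10)
        assert "whole-chromosome mean" in caplog.text
        np.testing.assert_allclose(out.values, np.tile(vals.mean(axis=0), (4, 1)))

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sliding_window_smooth(make_dosage(np.zeros((3, 1))), window=0)

    def test_whole_chromosome_fallback_preserves_mean(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 1))
        d = make_dosage(vals)
        out = sliding_window_smooth(d, window=31)  # > marker count -> fallback
        np.testing.assert_allclose(out.values.mean(), vals.mean(), atol=1e-12)


class TestFitBimodalModes:
    def test_two_point_masses(self):
        v = np.array([0.0] * 500 + [0.176] * 500)
        modes = fit_bimodal_modes(v)
        assert modes.mode1_center == 0.0
        assert modes.mode2_center == 0.176
        assert modes.mode1_p95 == 0.0

    def test_two_gaussian_sample(self):
        rng = np.random.default_rng(3)
        v = np.concatenate(
            [rng.normal(0.05, 0.02, 7000), rng.normal(0.25, 0.02, 3000)]
        )
        modes = fit_bimodal_modes(v)
        assert abs(modes.mode1_center - 0.05) < 0.01
        assert abs(modes.mode2_center - 0.25) < 0.01
        # p95 of the lower component, oracle on the known component
        assert abs(modes.mode1_p95 - np.percentile(v[v <= modes.split], 95)) < 1e-12

    def test_identical_values_error(self):
        with pytest.raises(NoGainDetectedError):
            fit_bimodal_modes(np.full(500, 0.3))

    def test_unimodal_error(self):
        rng = np.random.default_rng(4)
        with pytest.raises(NoGainDetectedError):
            fit_bimodal_modes(rng.normal(0.0, 0.02, 5000))

    def test_tiny_second_mode_below_floor_errors(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(0.0, 0.01, 10_000), rng.normal(0.3, 0.01, 50)])
        with pytest.raises(NoGainDetectedError):
            fit_bimodal_modes(v, weight_floor=0.02)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        v = np.concatenate([rng.normal(0.0, 0.02, 3000), rng.normal(0.2, 0.02, 3000)])
        a, b = fit_bimodal_modes(v), fit_bimodal_modes(v)
        assert a.mode1_center == b.mode1_center
        assert a.mode2_center == b.mode2_center


class TestNormalizeDosage:
    def test_identity_when_already_normalized(self):
        rng = np.random.default_rng(7)
        vals = rng.choice([0.0, AUTOSOME_TARGET], size=(50, 4))
        d = make_dosage(vals, state="smoothed")
        modes = ModeEstimate(0.0, AUTOSOME_TARGET, 0.0, AUTOSOME_TARGET / 2, 0.5, 0.01)
        out = normalize_dosage(d, modes)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)
        assert out.state == NORMALIZED

    def test_affine_formula_autosome(self):
        d = make_dosage(np.array([[0.25]]), state="smoothed")
        modes = ModeEstimate(0.05, 0.25, 0.08, 0.15, 0.5, 0.01)
        out = normalize_dosage(d, modes)
        assert out.values[0, 0] == pytest.approx(math.log10(1.5), abs=1e-12)

    def test_affine_formula_sex(self):
        d = make_dosage(np.array([[0.25]]), chrom_class=["sex"], state="smoothed")
        modes = ModeEstimate(0.05, 0.25, 0.08, 0.15, 0.5, 0.01)
        out = normalize_dosage(d, modes)
        assert out.values[0, 0] == pytest.approx(math.log10(2.0), abs=1e-12)

    def test_degenerate_separation_error(self):
        d = make_dosage(np.array([[0.1]]), state="smoothed")
        with pytest.raises(ValueError, match="separation"):
            normalize_dosage(d, ModeEstimate(0.1, 0.1 + 1e-12, 0.1, 0.1, 0.5, 0.01),
                             epsilon=1e-9)

    def test_idempotent_on_autosomes(self):
        rng = np.random.default_rng(8)
        copy = rng.integers(0, 2, size=(400, 40)).astype(float)
        vals = 0.07 + 0.21 * copy + rng.normal(0, 0.015, size=copy.shape)
        d = make_dosage(vals, state="smoothed")
        once = normalize_dosage(d, fit_bimodal_modes(vals.ravel()))
        again = normalize_dosage(
            once.with_values(once.values, "smoothed"),
            fit_bimodal_modes(once.values.ravel()),
        )
        assert np.max(np.abs(again.values - once.values)) < 1e-6


class TestCallRetention:
    def _panel(self, seed=21, noise=0.0):
        rng = np.random.default_rng(seed)
        copy = rng.integers(0, 2, size=(60, 8)).astype(float)
        vals = copy * AUTOSOME_TARGET + rng.normal(0, noise, size=copy.shape)
        return make_dosage(vals, state="normalized", spacing=1000), copy

    def test_fully_retained_and_lost(self):
        d, copy = self._panel()
        copy_all = copy.copy()
        copy_all[:, 0] = 1  # clone 0 retains everything
        copy_all[:, 1] = 0  # clone 1 lost everything
        d = d.with_values(copy_all * AUTOSOME_TARGET, "normalized")
        modes = ModeEstimate(0.0, AUTOSOME_TARGET, 0.01, AUTOSOME_TARGET / 2, 0.5, 0.01)
        table = call_retention(d, [("chr1", 30_000)], modes=modes, k=10)
        assert table.calls[0, 0] == 1
        assert table.calls[0, 1] == 0

    def test_hand_mixed_case(self):
        # 6 of the 10 nearest markers gained at noiseless separation:
        # mean = 0.6 * target; call = (mean > threshold)
        d, copy = self._panel()
        vals = np.zeros_like(copy)
        vals[28:34, 0] = AUTOSOME_TARGET  # 6 gained markers near position 30500
        d = d.with_values(vals, "normalized")
        threshold = 0.01
        table = call_retention(d, [("chr1", 30_500)], threshold=threshold, k=10)
        # nearest 10 markers to 30500 are rows 26..35; mean = 6/10 * target
        assert (0.6 * AUTOSOME_TARGET > threshold) == bool(table.calls[0, 0])
        assert table.calls[0, 0] == 1

    def test_locus_on_empty_chromosome_errors(self):
        d, _ = self._panel()
        with pytest.raises(ValueError, match="chr7"):
            call_retention(d, [("chr7", 1000)], threshold=0.0)

    def test_affine_invariance_of_calls(self):
        # normalization absorbs any affine transform of the raw data
        rng = np.random.default_rng(22)
        # blocky copy profile so smoothing keeps the distribution bimodal
        copy = np.repeat(rng.integers(0, 2, size=(15, 30)), 20, axis=0).astype(float)
        raw = 0.05 + 0.2 * copy + rng.normal(0, 0.02, size=copy.shape)
        loci = [("chr1", int(p)) for p in (5_000, 100_000, 250_000)]

        def calls(vals):
            d = make_dosage(vals, state="raw", spacing=1000)
            sm = sliding_window_smooth(d, window=10)
            modes = fit_bimodal_modes(sm.values.ravel())
            norm = normalize_dosage(sm, modes)
            norm_modes = fit_bimodal_modes(norm.values.ravel())
            return call_retention(norm, loci, modes=norm_modes, k=10).calls

        np.testing.assert_array_equal(calls(raw), calls(2.0 * raw + 0.3))


class TestRetentionStats:
    def test_all_retained(self):
        table = RetentionTable(
            calls=np.ones((4, 10), dtype=np.int8),
            locus_ids=[f"l{i}" for i in range(4)],
            chrom=np.array(["chr1"] * 4),
            position=np.arange(4) * 1000,
            clone_ids=[f"c{j}" for j in range(10)],
        )
        s = retention_stats(table)
        assert s["genome_wide_mean"] == 1.0
        assert s["representation"] == 10.0

    def test_representation_rounding_convention(self):
        # frequency 0.11 across 79 clones -> representation 8.69 ~ 9
        assert 0.11 * 79 == pytest.approx(8.69)
        assert round(0.11 * 79) == 9

    def test_simulated_panel_near_target(self):
        # genome large enough that the forced selectable-locus fragment
        # (~4 Mb per clone) does not distort the genome-wide mean
        from ceqtl.genome import uniform_genome

        genome = uniform_genome(
            [("chr1", 300_000_000, "autosome"), ("chr2", 300_000_000, "autosome")],
            marker_spacing=50_000,
            n_genes=0,
            seed=23,
        )
        config = SimulationConfig(n_clones=79, seed=23)
        truth = simulate_fragments(genome, config)
        loci = [
            (c, int(p))
            for c, pos in genome.marker_positions.items()
            for p in pos[::20]
        ]
        rows = [genome.nearest_marker_index(c, p) for c, p in loci]
        table = RetentionTable(
            calls=truth.copy_state[rows],
            locus_ids=[f"{c}:{p}" for c, p in loci],
            chrom=np.array([c for c, _ in loci]),
            position=np.array([p for _, p in loci], dtype=np.int64),
            clone_ids=[f"c{j}" for j in range(config.n_clones)],
        )
        s = retention_stats(table)
        assert abs(s["genome_wide_mean"] - 0.114) < 0.02

    def test_called_retention_tracks_truth(self):
        # end-to-end calls: no misses, and the p95 threshold's intrinsic
        # anticonservatism for k-marker means stays below 5% false positives
        from ceqtl.genome import uniform_genome

        genome = uniform_genome(
            [("chr1", 200_000_000, "autosome"), ("chr2", 200_000_000, "autosome")],
            marker_spacing=50_000,
            n_genes=0,
            seed=24,
        )
        config = SimulationConfig(n_clones=79, acgh_noise_sd=0.03, seed=24)
        truth, raw, normalized, _ = build_panel(genome, config)
        loci = [
            (c, int(p))
            for c, pos in genome.marker_positions.items()
            for p in pos[::20]
        ]
        norm_modes = fit_bimodal_modes(normalized.values.ravel())
        table = call_retention(normalized, loci, modes=norm_modes, k=10)
        rows = [genome.nearest_marker_index(c, p) for c, p in loci]
        truth_at = truth.copy_state[rows]
        fn = 1.0 - table.calls[truth_at == 1].mean()
        fp = table.calls[truth_at == 0].mean()
        assert fn < 0.01
        assert fp < 0.05


class TestConcordanceWithLegacy:
    def _table(self, calls):
        n, m = calls.shape
        return RetentionTable(
            calls=calls,
            locus_ids=[f"l{i}" for i in range(n)],
            chrom=np.array(["chr1"] * n),
            position=np.arange(n) * 1000,
            clone_ids=[f"c{j}" for j in range(m)],
        )

    def test_hand_chi_square_oracle(self):
        rng = np.random.default_rng(24)
        calls = rng.integers(0, 2, size=(30, 10)).astype(np.int8)
        legacy = calls.copy()
        flip = rng.random(calls.shape) < 0.2
        legacy[flip] = 1 - legacy[flip]
        table = self._table(calls)
        res = concordance_with_legacy(
            table, legacy, table.locus_ids, table.clone_ids
        )
        # textbook oracle: chi2 = sum (O - E)^2 / E over the 2x2
        obs = res["table"]
        total = obs.sum()
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        chi2_hand = ((obs - exp) ** 2 / exp).sum()
        assert res["chi2"] == pytest.approx(chi2_hand, rel=1e-12)
        assert res["df"] == 1
        assert res["p"] == pytest.approx(stats.chi2.sf(chi2_hand, 1), rel=1e-9)

    def test_identical_tables_zero_loss_gain(self):
        rng = np.random.default_rng(25)
        calls = rng.integers(0, 2, size=(20, 8)).astype(np.int8)
        table = self._table(calls)
        res = concordance_with_legacy(table, calls, table.locus_ids, table.clone_ids)
        assert res["loss_fraction"] == 0.0
        assert res["gain_fraction"] == 0.0

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(26)
        ps = []
        for _ in range(200):
            calls = rng.integers(0, 2, size=(10, 10)).astype(np.int8)
            legacy = rng.integers(0, 2, size=(10, 10)).astype(np.int8)
            table = self._table(calls)
            res = concordance_with_legacy(table, legacy, table.locus_ids, table.clone_ids)
            ps.append(res["p"])
        assert 0.3 < np.mean(ps) < 0.7

    def test_mismatched_sets_error(self):
        calls = np.zeros((3, 2), dtype=np.int8)
        table = self._table(calls)
        with pytest.raises(ValueError, match="extra"):
            concordance_with_legacy(table, calls, ["l0", "l1", "extra"], table.clone_ids)


class TestCentromereRetentionTest:
    def test_welch_formula_oracle(self, small_genome):
        # hand-specified samples through the Welch formula
        a = np.array([0.5, 0.6, 0.7, 0.8, 0.65])
        b = np.array([0.1, 0.15, 0.12, 0.2, 0.18, 0.11])
        calls_pos = list(range(40_000_000, 40_000_000 + 5000, 1000))  # inside cen
        calls_pos += list(range(1_000_000, 1_000_000 + 6000, 1000))  # outside
        n_clones = 20
        calls = np.zeros((11, n_clones), dtype=np.int8)
        for i, f in enumerate(np.concatenate([a, b])):
            calls[i, : int(round(f * n_clones))] = 1
        table = RetentionTable(
            calls=calls,
            locus_ids=[f"l{i}" for i in range(11)],
            chrom=np.array(["chr1"] * 11),
            position=np.array(calls_pos, dtype=np.int64),
            clone_ids=[f"c{j}" for j in range(n_clones)],
        )
        res = centromere_retention_test(table, small_genome)
        fa, fb = table.marker_frequency[:5], table.marker_frequency[5:]
        va, vb = fa.var(ddof=1) / 5, fb.var(ddof=1) / 6
        t_hand = (fa.mean() - fb.mean()) / math.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 5)
        assert res["t"] == pytest.approx(t_hand, rel=1e-10)
        assert res["df"] == pytest.approx(df_hand, rel=1e-10)

    def test_planted_centromere_bias_detected(self, small_genome):
        config = SimulationConfig(
            n_clones=100, centromere_retention_multiplier=8.0, acgh_noise_sd=0.0, seed=27
        )
        truth = simulate_fragments(small_genome, config)
        loci = [
            (c, int(p))
            for c, pos in small_genome.marker_positions.items()
            for p in pos[::3]
        ]
        _, chroms, positions, _ = small_genome.marker_table()
        # build calls directly from copy_state at the chosen loci
        rows = [small_genome.nearest_marker_index(c, p) for c, p in loci]
        table = RetentionTable(
            calls=truth.copy_state[rows],
            locus_ids=[f"{c}:{p}" for c, p in loci],
            chrom=np.array([c for c, _ in loci]),
            position=np.array([p for _, p in loci], dtype=np.int64),
            clone_ids=[f"c{j}" for j in range(config.n_clones)],
        )
        res = centromere_retention_test(table, small_genome)
        assert res["p_one_sided_greater"] < 0.05

    def test_no_centromeres_error(self, small_genome):
        from ceqtl.genome import GenomeDefinition

        bare = GenomeDefinition(
            chromosomes=list(small_genome.chromosomes),
            marker_positions=dict(small_genome.marker_positions),
            genes=list(small_genome.genes),
            selectable_locus=small_genome.selectable_locus,
        )
        table = RetentionTable(
            calls=np.ones((3, 2), dtype=np.int8),
            locus_ids=["a", "b", "c"],
            chrom=np.array(["chr1"] * 3),
            position=np.arange(3),
            clone_ids=["c0", "c1"],
        )
        with pytest.raises(ValueError, match="centromere"):
            centromere_retention_test(table, bare)


class TestBinCopyNumber:
    def test_noiseless_exact_recovery(self):
        copy = np.zeros((60, 2))
        copy[10:25, 0] = 1
        copy[40:55, 0] = 1
        copy[0:30, 1] = 1
        vals = copy * AUTOSOME_TARGET
        d = make_dosage(vals, state="normalized")
        out = bin_copy_number(d)
        np.testing.assert_array_equal(out.values, copy)
        assert out.state == "binned"

    def test_noisy_agreement_99pct(self):
        rng = np.random.default_rng(28)
        copy = np.zeros((500, 5))
        for j in range(5):
            edges = np.sort(rng.choice(np.arange(20, 480), size=6, replace=False))
            for a, b in zip(edges[::2], edges[1::2]):
                copy[a:b, j] = 1
        vals = copy * AUTOSOME_TARGET + rng.normal(0, 0.03, size=copy.shape)
        d = make_dosage(vals, state="normalized")
        out = bin_copy_number(d)
        agreement = (out.values == copy).mean()
        assert agreement >= 0.99

    def test_binned_vs_continuous_alpha_concordance(self, small_genome, noisy_panel):
        # scaled-down concordance property on fitted effect sizes
        from ceqtl.ceqtl_mapping import fit_dosage_model

        _, truth, _, normalized, expr = noisy_panel
        binned = bin_copy_number(normalized)
        a_cont, a_bin = [], []
        for i, g in enumerate(small_genome.genes):
            mid = (g.start + g.end) // 2
            r = small_genome.nearest_marker_index(g.chrom, mid)
            try:
                fc = fit_dosage_model(expr.values[i], normalized.values[r])
                fb = fit_dosage_model(expr.values[i], binned.values[r])
            except ValueError:
                continue
            a_cont.append(fc.alpha)
            a_bin.append(fb.alpha)
        r = np.corrcoef(a_cont, a_bin)[0, 1]
        assert r >= 0.9

    def test_sex_chromosome_target_used(self):
        copy = np.zeros((40, 1))
        copy[10:30, 0] = 1
        vals = copy * SEX_TARGET
        d = make_dosage(vals, chrom_class=["sex"] * 40, state="normalized")
        out = bin_copy_number(d)
        np.testing.assert_array_equal(out.values, copy)
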