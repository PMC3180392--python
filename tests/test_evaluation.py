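"""Benchmark metrics: slopes, null log-ratios, SNR/POT, MAD consistency."""

import numpy as np
import pandas as pd
import pytest

from frozenrma import (
    ModelConfig,
    consistency_mad,
    make_latin_square,
    null_log_ratio_stats,
    run_consistency_experiment,
    signal_detect_slope,
    simulate_spikein,
    simulate_training_set,
    snr_and_pot,
    spikein_report,
)
from frozenrma.evaluation import adjacent_pairs, within_block_pairs


def _toy_spike_tables(expr_fn, n_arrays=12):
    """Nominal concentrations rotating over arrays plus expression built
    from a supplied function of concentration."""
    conc = 2.0 ** np.arange(12)  # 1..2048, all nonzero
    arrays = [f"a{i:02d}" for i in range(n_arrays)]
    nominal = pd.DataFrame(
        {a: np.roll(conc, i) for i, a in enumerate(arrays)},
        index=[f"spk{g:02d}" for g in range(12)],
    )
    expr = nominal.map(expr_fn)
    return expr, nominal


class TestSignalDetectSlope:
    def test_log2_response_gives_unit_slope(self):
        expr, nominal = _toy_spike_tables(lambda c: np.log2(c) + 3.0)
        summary, _ = signal_detect_slope(expr, nominal)
        assert np.allclose(summary["slope"], 1.0)
        assert list(summary.index) == ["low", "medium", "high"]

    def test_constant_expression_gives_zero_slope(self):
        expr, nominal = _toy_spike_tables(lambda c: 5.0)
        summary, _ = signal_detect_slope(expr, nominal)
        assert np.allclose(summary["slope"], 0.0)

    def test_four_point_regression_matches_normal_equations(self):
        conc = np.array([2.0, 4.0, 8.0, 16.0])
        y = np.array([1.0, 1.9, 3.1, 3.9])
        x = np.log2(conc)
        beta = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        nominal = pd.DataFrame([conc], index=["spk00"], columns=list("abcd"))
        expr = pd.DataFrame([y], index=["spk00"], columns=list("abcd"))
        summary, _ = signal_detect_slope(expr, nominal, strata=[conc])
        assert summary.loc["stratum0", "slope"] == pytest.approx(beta, abs=1e-10)


class TestNullLogRatios:
    def test_all_zero_ratios(self):
        expr = pd.DataFrame(np.zeros((100, 4)), columns=list("abcd"))
        sd, q = null_log_ratio_stats(expr, [("a", "b"), ("c", "d")])
        assert sd == 0.0 and q == 0.0

    def test_large_sample_normal_quantiles(self):
        rng = np.random.default_rng(20)
        expr = pd.DataFrame(np.zeros((100_000, 2)), columns=["a", "b"])
        expr["a"] = rng.normal(size=100_000)
        expr["b"] = expr["a"] - rng.normal(size=100_000)  # a-b ~ N(0,1)
        sd, q = null_log_ratio_stats(expr, [("a", "b")])
        assert sd == pytest.approx(1.0, abs=0.01)
        assert q == pytest.approx(2.807, abs=0.03)  # 99.5% of |N(0,1)|

    def test_exactly_half_percent_exceed_threshold(self):
        rng = np.random.default_rng(21)
        n = 100_000
        expr = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        sd, q = null_log_ratio_stats(expr, [("a", "b")])
        ratios = expr["a"] - expr["b"]
        assert np.mean(np.abs(ratios) > q) == pytest.approx(0.005, abs=1e-9)

    def test_too_few_ratios_rejected(self):
        expr = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="200"):
            null_log_ratio_stats(expr, [("a", "b")])


class TestSnrAndPot:
    @pytest.mark.parametrize("slope,null_sd,snr", [
        (0.14, 0.47, 0.30), (0.20, 0.40, 0.50), (0.69, 0.39, 1.77),
        (0.75, 0.34, 2.21), (0.61, 0.33, 1.85), (0.60, 0.28, 2.14),
    ])
    def test_snr_is_slope_over_null_sd(self, slope, null_sd, snr):
        """Arithmetic identity of the metric at printed two-decimal precision."""
        expr, nominal = _toy_spike_tables(lambda c: np.log2(c))
        got, _ = snr_and_pot(slope, null_sd, expr, nominal,
                             [(nominal.columns[0], nominal.columns[2])])
        assert got == pytest.approx(snr, abs=0.005)

    def test_pot_is_one_when_signal_is_noise_free(self):
        expr, nominal = _toy_spike_tables(lambda c: np.log2(c))
        pairs = [(nominal.columns[0], nominal.columns[2])]  # 4-fold pairs exist
        _, pot = snr_and_pot(1.0, 0.3, expr, nominal, pairs)
        assert pot == 1.0

    def test_pot_matches_brute_force_ranking_oracle(self):
        d = make_latin_square(8, base_conc=0.25)
        pm, truth = simulate_spikein(d, n_batches=3, n_null_probesets=120,
                                     probes_per_set=3, seed=22)
        rng = np.random.default_rng(23)
        # stand-in expression: probeset means of the log2 data plus noise
        y = np.log2(pm.intensities)
        rows = [y[sl].mean(axis=0) for _, sl in pm.probeset_slices()]
        expr = pd.DataFrame(rows, index=[p for p, _ in pm.probeset_slices()],
                            columns=pm.array_ids) + rng.normal(0, 0.3, (pm.n_probesets, pm.n_arrays))
        pairs = within_block_pairs(list(pm.array_ids), pm.batch_of)
        _, pot = snr_and_pot(1.0, 0.3, expr, truth.nominal, pairs, list_size=20)
        # oracle: independent rank-and-count
        hits = total = 0
        for a, b in pairs:
            ca, cb = truth.nominal[a], truth.nominal[b]
            ok = (ca > 0) & (cb > 0)
            lfc = np.abs(np.log2(ca.where(ok, 1.0) / cb.where(ok, 1.0)))
            qual = truth.nominal.index[ok & np.isclose(lfc, 2.0)]
            if len(qual) == 0:
                continue
            fc = (expr[a] - expr[b]).abs().sort_values(ascending=False)
            top = set(fc.index[:20])
            hits += sum(ps in top for ps in qual)
            total += len(qual)
        assert total > 0
        assert pot == pytest.approx(hits / total)

    def test_zero_null_sd_rejected(self):
        expr, nominal = _toy_spike_tables(lambda c: np.log2(c))
        with pytest.raises(ValueError, match="null_sd"):
            snr_and_pot(1.0, 0.0, expr, nominal, [("a00", "a01")])


class TestConsistencyMad:
    def test_identical_replicates_give_zero(self):
        s = pd.Series([1.0, 2.0, 3.0], index=["x", "y", "z"])
        rep = consistency_mad([s, s.copy(), s.copy()])
        assert np.all(rep.mads == 0)
        assert rep.median_mad == 0.0 and rep.iqr_mad == 0.0

    def test_recovers_noise_scale(self):
        rng = np.random.default_rng(24)
        truth = pd.Series(rng.uniform(4, 12, 500))
        s = 0.3
        reps = [truth + rng.normal(0, s, 500) for _ in range(100)]
        rep = consistency_mad(reps)
        assert rep.median_mad == pytest.approx(s, rel=0.10)

    def test_invariant_to_adding_constants(self):
        rng = np.random.default_rng(25)
        reps = [pd.Series(rng.normal(size=50)) for _ in range(5)]
        rep1 = consistency_mad(reps)
        rep2 = consistency_mad([r + 7.5 for r in reps])
        assert np.allclose(rep1.mads, rep2.mads)

    def test_report_cell_formats_median_and_iqr(self):
        s = pd.Series([1.0, 2.0])
        rep = consistency_mad([s, s + 0.1, s - 0.1])
        assert rep.cell() == f"{rep.median_mad:.4f} ({rep.iqr_mad:.4f})"

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            consistency_mad([pd.Series([1.0])])

    def test_mismatched_probesets_rejected(self):
        with pytest.raises(ValueError, match="probeset"):
            consistency_mad([pd.Series([1.0], index=["x"]),
                             pd.Series([1.0], index=["y"])])


class TestConsistencyExperiment:
    def test_same_seed_reproduces_reports(self):
        pool, _ = simulate_training_set(30, 4, 8, 5, seed=26)
        test_col = pool.intensities[:, 0]
        pool2 = pool.subset_arrays(list(pool.array_ids[1:]))
        kwargs = dict(designs=[(3, 3)], n_replicates=3, test_array=test_col, seed=5)
        r1 = run_consistency_experiment(pool2, **kwargs)
        r2 = run_consistency_experiment(pool2, **kwargs)
        assert np.array_equal(r1[0].mads.to_numpy(), r2[0].mads.to_numpy())
        assert r1[0].n_batches == 3 and r1[0].batch_size == 3
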