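"""Burst detection, FRET efficiency, sizing, filters, histogram, GaussAmp."""

import numpy as np
import pandas as pd
import pytest

from oligopipe import smfret as sf
from oligopipe.synthetic import BurstSimConfig, simulate_bursts


def _trace(donor, acceptor):
    return pd.DataFrame(
        {
            "bin_index": np.arange(len(donor)),
            "donor_counts": donor,
            "acceptor_counts": acceptor,
        }
    )


def _burst(I_D, I_A, coincident=True, run_length=1, bin=0):
    return sf.Burst(bin=bin, I_D=I_D, I_A=I_A, coincident=coincident,
                    run_length=run_length)


class TestDetectBursts:
    def test_flat_background_trace_has_few_false_positives(self):
        rng = np.random.default_rng(0)
        n = 10_000
        trace = _trace(rng.poisson(4.0, n), rng.poisson(4.0, n))
        params = sf.InstrumentParams(donor_background=4.0, acceptor_background=4.0)
        bursts = sf.detect_bursts(trace, params)
        # 5 sigma on Poisson(4): exceed 14 counts; tail prob ~ 5e-6 per channel
        assert len(bursts) <= 5

    def test_donor_only_spike_is_single_noncoincident_burst(self):
        d = np.zeros(10, dtype=int)
        d[4] = 100
        bursts = sf.detect_bursts(_trace(d, np.zeros(10, dtype=int)),
                                  sf.InstrumentParams())
        assert len(bursts) == 1
        b = bursts[0]
        assert (b.bin, b.coincident, b.run_length) == (4, False, 1)
        assert b.I_D == 100 and b.I_A == 0

    def test_same_bin_spikes_are_coincident(self):
        d = np.zeros(10, dtype=int)
        a = np.zeros(10, dtype=int)
        d[4], a[4] = 80, 60
        (b,) = sf.detect_bursts(_trace(d, a), sf.InstrumentParams())
        assert b.coincident and b.run_length == 1

    def test_consecutive_spikes_merge_into_one_run(self):
        d = np.zeros(10, dtype=int)
        d[3:6] = 50
        (b,) = sf.detect_bursts(_trace(d, np.zeros(10, dtype=int)),
                                sf.InstrumentParams())
        assert b.run_length == 3 and b.I_D == 150

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sf.detect_bursts(_trace(np.array([]), np.array([])),
                             sf.InstrumentParams())


class TestFretEfficiency:
    @pytest.mark.parametrize(
        "I_A, I_D, gamma, expected",
        [
            (50.0, 50.0, 1.0, 0.5),
            (0.0, 80.0, 0.99, 0.0),
            (80.0, 0.0, 0.99, 1.0),
            (65.0, 35.0, 0.99, 0.6523),
        ],
    )
    def test_values(self, I_A, I_D, gamma, expected):
        e = sf.fret_efficiency(_burst(I_D, I_A), gamma)
        assert e == pytest.approx(expected, abs=1e-4)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            sf.fret_efficiency(_burst(0.0, 0.0), 0.99)

    def test_increasing_in_acceptor_intensity(self):
        es = [sf.fret_efficiency(_burst(50.0, ia), 0.99) for ia in (10, 20, 40, 80)]
        assert es == sorted(es)
        assert all(0 <= e <= 1 for e in es)


class TestMonomerBrightness:
    def test_mean_of_donor_only_single_bin_bursts(self):
        bursts = [
            _burst(100.0, 0.0, coincident=False),
            _burst(110.0, 0.0, coincident=False),
            _burst(90.0, 0.0, coincident=False),
            _burst(500.0, 400.0, coincident=True),        # excluded: oligomer
            _burst(80.0, 0.0, coincident=False, run_length=2),  # excluded: multi-bin
        ]
        assert sf.estimate_monomer_brightness(bursts).I_monomer == pytest.approx(100.0)

    def test_all_coincident_rejected(self):
        with pytest.raises(ValueError, match="non-coincident"):
            sf.estimate_monomer_brightness([_burst(10.0, 10.0, coincident=True)])

    def test_simulated_monomers_recovered(self):
        cfg = BurstSimConfig(
            n_bins=50_000, background_mean=2.0, monomer_brightness=100.0,
            monomer_event_rate=0.02, oligomer_mass_fraction=0.0,
            dust_rate=0.0, seed=1,
        )
        trace, truth = simulate_bursts(cfg)
        params = sf.InstrumentParams(donor_background=2.0, acceptor_background=2.0)
        mono = sf.estimate_monomer_brightness(sf.detect_bursts(trace, params))
        sem = 100.0 / np.sqrt(truth.n_monomers)
        assert mono.I_monomer == pytest.approx(100.0, abs=3 * sem + 1.0)


class TestApparentSize:
    def test_dimer_example(self):
        mono = sf.MonomerBrightness(100.0)
        size = sf.apparent_size(_burst(50.0, 49.5), 0.99, mono)
        assert size == pytest.approx(2.0)

    def test_linearity_in_intensity(self):
        mono = sf.MonomerBrightness(100.0)
        s1 = sf.apparent_size(_burst(40.0, 30.0), 0.99, mono)
        s2 = sf.apparent_size(_burst(80.0, 60.0), 0.99, mono)
        assert s2 == pytest.approx(2 * s1)


class TestFilter:
    def test_size_and_run_rules(self):
        mono = sf.MonomerBrightness(2.0)  # size = I_D + I_A/gamma at gamma=1
        bursts = [
            _burst(151.0, 0.0, coincident=True),            # size 151 -> removed
            _burst(150.0, 0.0, coincident=True),            # size 150 -> kept
            _burst(10.0, 0.0, coincident=True, run_length=2),  # dust -> removed
            _burst(10.0, 0.0, coincident=True),             # size 10 -> kept
            _burst(10.0, 0.0, coincident=False),            # monomer -> removed
        ]
        retained, log = sf.filter_oligomer_bursts(bursts, gamma=1.0, mono=mono)
        assert [b.I_D for b in retained] == [150.0, 10.0]
        assert list(log["reason"]) == [
            "too_large", "retained", "multi_bin", "retained", "not_coincident",
        ]


class TestHistogram:
    def test_bin_placement(self):
        hist = sf.fret_histogram(np.array([0.02, 0.07, 0.65]))
        expected = np.zeros(20, dtype=int)
        expected[[0, 1, 13]] = 1
        np.testing.assert_array_equal(hist.counts, expected)

    def test_efficiency_one_lands_in_final_bin(self):
        hist = sf.fret_histogram(np.array([1.0]))
        assert hist.counts[-1] == 1

    def test_empty_input_all_zero(self):
        hist = sf.fret_histogram(np.array([]))
        assert hist.counts.sum() == 0
        assert len(hist.counts) == 20 and len(hist.edges) == 21

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            sf.fret_histogram(np.array([1.2]))

    def test_count_conservation(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=137)
        assert sf.fret_histogram(vals).counts.sum() == 137


class TestGaussAmpFit:
    def test_noiseless_self_consistency(self):
        edges = np.arange(0.0, 1.0001, 0.05)
        centers = (edges[:-1] + edges[1:]) / 2
        y0, A, x_c, w = 0.5, 10.0, 0.65, 0.1
        counts = y0 + A * np.exp(-((centers - x_c) ** 2) / (2 * w**2))
        fit = sf.gaussamp_fit(sf.FretHistogram(edges=edges, counts=counts))
        assert fit.converged
        assert fit.y0 == pytest.approx(0.5, abs=1e-6)
        assert fit.A == pytest.approx(10.0, abs=1e-6)
        assert fit.x_c == pytest.approx(0.65, abs=1e-6)
        assert fit.w == pytest.approx(0.1, abs=1e-6)

    def test_flat_histogram_has_no_amplitude(self):
        edges = np.arange(0.0, 1.0001, 0.05)
        fit = sf.gaussamp_fit(sf.FretHistogram(edges=edges, counts=np.full(20, 7.0)))
        assert (not fit.converged) or fit.A == pytest.approx(0.0, abs=1e-6)

    def test_baseline_shift_equivariance(self):
        edges = np.arange(0.0, 1.0001, 0.05)
        centers = (edges[:-1] + edges[1:]) / 2
        counts = 2.0 + 8.0 * np.exp(-((centers - 0.4) ** 2) / (2 * 0.12**2))
        f1 = sf.gaussamp_fit(sf.FretHistogram(edges=edges, counts=counts))
        f2 = sf.gaussamp_fit(sf.FretHistogram(edges=edges, counts=counts + 5.0))
        assert f2.x_c == pytest.approx(f1.x_c, abs=1e-6)
        assert f2.w == pytest.approx(f1.w, abs=1e-6)
        assert f2.y0 == pytest.approx(f1.y0 + 5.0, abs=1e-6)

    def test_too_sparse_histogram_rejected(self):
        edges = np.arange(0.0, 1.0001, 0.05)
        counts = np.zeros(20)
        counts[5] = 3
        with pytest.raises(ValueError, match="non-zero"):
            sf.gaussamp_fit(sf.FretHistogram(edges=edges, counts=counts))


class TestOligomerFraction:
    def test_no_oligomers_gives_zero(self):
        mono = sf.MonomerBrightness(100.0)
        s = sf.oligomer_fraction([], [_burst(100.0, 0.0, coincident=False)],
                                 0.99, mono)
        assert s.mass_fraction == 0.0

    def test_one_dimer_among_monomers(self):
        mono = sf.MonomerBrightness(100.0)
        dimer = _burst(50.0, 49.5)  # apparent size 2 at gamma 0.99
        monomers = [_burst(100.0, 0.0, coincident=False)] * 98
        s = sf.oligomer_fraction([dimer], monomers, 0.99, mono)
        assert s.mass_fraction == pytest.approx(100 * 2 / 100)
        assert s.mean_apparent_size == pytest.approx(2.0)

    def test_no_bursts_rejected(self):
        with pytest.raises(ValueError, match="no bursts"):
            sf.oligomer_fraction([], [], 0.99, sf.MonomerBrightness(100.0))


class TestEndToEnd:
    def test_analyze_trace_recovers_planted_content(self, burst_trace):
        cfg, trace, truth = burst_trace
        params = sf.InstrumentParams(
            gamma=cfg.gamma,
            donor_background=cfg.background_mean,
            acceptor_background=cfg.background_mean,
        )
        res = sf.analyze_trace(trace, params)
        assert res.mono.I_monomer == pytest.approx(cfg.monomer_brightness, rel=0.05)
        assert res.summary.mass_fraction == pytest.approx(
            truth.mass_fraction(), abs=0.5
        )
        assert res.histogram.counts.sum() == res.summary.n_oligomer_bursts
        if len(res.efficiencies) >= 10:
            assert res.efficiencies.mean() == pytest.approx(cfg.true_E, abs=0.03)
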