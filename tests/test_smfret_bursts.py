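"""Burst detection, correction, oligomer sizing and population estimates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taukinetics import smfret_bursts as smb
from taukinetics.smfret_bursts import (
    BurstEvent,
    InstrumentConfig,
    OligomerEvent,
    PhotonTrace,
)


def make_trace(donor, acceptor, **cfg_kw):
    return PhotonTrace(
        donor_counts=np.asarray(donor, dtype=np.int64),
        acceptor_counts=np.asarray(acceptor, dtype=np.int64),
        config=InstrumentConfig(**cfg_kw),
    )


class TestCorrectTrace:
    def test_identity_without_background_or_crosstalk(self):
        trace = make_trace([5, 20, 0], [1, 7, 0])
        d, a = smb.correct_trace(trace)
        np.testing.assert_array_equal(d, [5, 20, 0])
        np.testing.assert_array_equal(a, [1, 7, 0])

    def test_background_and_crosstalk_arithmetic(self):
        trace = make_trace([20], [5], background_acceptor=1.0, crosstalk_alpha=0.1)
        d, a = smb.correct_trace(trace)
        assert d[0] == 20.0
        assert a[0] == pytest.approx(5 - 1 - 0.1 * 20)  # = 2

    def test_background_only_trace_centers_near_zero(self):
        """Poisson background minus its mean should average ~0 within 3 sigma."""
        rng = np.random.default_rng(11)
        n, bg = 20000, 3.0
        trace = make_trace(
            rng.poisson(bg, n), rng.poisson(bg, n),
            background_donor=bg, background_acceptor=bg,
        )
        d, a = smb.correct_trace(trace)
        # flooring at 0 biases the mean up; compare against the floored model
        raw = rng.poisson(bg, 200000) - bg
        floored_mean = np.clip(raw, 0, None).mean()
        se = 3 * np.sqrt(bg / n)
        assert abs(d.mean() - floored_mean) < se
        assert abs(a.mean() - floored_mean) < se


class TestDetectEvents:
    def test_empty_and_allzero(self):
        assert smb.detect_events(np.array([]), np.array([]), "donor", 10) == []
        z = np.zeros(100)
        assert smb.detect_events(z, z, "donor", 10) == []

    def test_single_bin_threshold_edge(self):
        d = np.zeros(10)
        d[4] = 11
        events = smb.detect_events(d, np.zeros(10), "donor", 10)
        assert len(events) == 1
        assert events[0].duration_bins == 1
        assert events[0].I_D == 11
        # exactly at threshold does not trigger (strictly exceeding)
        d[4] = 10
        assert smb.detect_events(d, np.zeros(10), "donor", 10) == []

    def test_multibin_run_merging_and_both_channel_sums(self):
        d = np.array([0, 12, 15, 11, 0, 20, 0])
        a = np.array([1, 2, 3, 4, 5, 6, 7])
        events = smb.detect_events(d, a, "donor", 10)
        assert [(e.start_bin, e.end_bin) for e in events] == [(1, 3), (5, 5)]
        assert events[0].I_D == 38 and events[0].I_A == 9
        assert events[1].I_A == 6

    def test_counts_k_implanted_bursts(self):
        rng = np.random.default_rng(5)
        n, k = 50000, 40
        d = rng.poisson(1.0, n).astype(float)
        bins = rng.choice(n, size=k, replace=False)
        d[bins] += 100
        events = smb.detect_events(d, np.zeros(n), "donor", 10)
        assert len(events) == k

    @given(scale=st.integers(min_value=2, max_value=7))
    @settings(max_examples=20, deadline=None)
    def test_threshold_scale_exactness(self, scale):
        """Scaling all counts and the threshold by one integer factor
        preserves the event calls exactly."""
        rng = np.random.default_rng(7)
        d = rng.poisson(4.0, 2000).astype(float)
        a = rng.poisson(1.0, 2000).astype(float)
        base = smb.detect_events(d, a, "donor", 6)
        scaled = smb.detect_events(d * scale, a * scale, "donor", 6 * scale)
        assert [(e.start_bin, e.end_bin) for e in base] == [
            (e.start_bin, e.end_bin) for e in scaled
        ]


class TestSizeAndEfficiency:
    def test_donor_only_monomer_mean_event_scores_two(self):
        assert smb.apparent_size(I_D=30.0, I_A=0.0, mean_monomer_I_D=30.0) == 2.0

    def test_equal_channel_case_scores_four(self):
        gamma = 1.7
        assert smb.apparent_size(30.0, gamma * 30.0, 30.0, gamma) == pytest.approx(4.0)

    def test_linear_in_total_intensity(self):
        s1 = smb.apparent_size(10.0, 5.0, 20.0)
        s2 = smb.apparent_size(20.0, 10.0, 20.0)
        assert s2 == pytest.approx(2 * s1)

    def test_reference_must_be_positive(self):
        with pytest.raises(ValueError):
            smb.apparent_size(10.0, 5.0, 0.0)

    @pytest.mark.parametrize(
        "I_D,I_A,gamma,expected",
        [(10.0, 0.0, 1.0, 0.0), (0.0, 10.0, 1.0, 1.0), (10.0, 1.3 * 10.0, 1.3, 0.5)],
    )
    def test_fret_efficiency_anchors(self, I_D, I_A, gamma, expected):
        assert smb.fret_efficiency(I_D, I_A, gamma) == pytest.approx(expected)

    def test_fret_efficiency_zero_total_raises(self):
        with pytest.raises(ValueError):
            smb.fret_efficiency(0.0, 0.0)

    def test_size_unbiased_over_binomial_labels(self):
        """Mean apparent size converges to the true size when labels are
        drawn binomially and only dual-labelled molecules are scored,
        the symmetric truncation leaving the mean at n."""
        rng = np.random.default_rng(23)
        n_true, B, E, gamma = 4, 60.0, 0.4, 1.0
        sizes = []
        for _ in range(4000):
            d = rng.binomial(n_true, 0.5)
            if d == 0 or d == n_true:
                continue  # invisible or no transfer: not an acceptor event
            I_D = d * B * (1 - E)
            I_A = gamma * d * B * E
            sizes.append(smb.apparent_size(I_D, I_A, B, gamma))
        assert np.mean(sizes) == pytest.approx(n_true, rel=0.02)


class TestMonomerIntensity:
    def test_identical_events(self):
        events = [BurstEvent(i, i, 20.0, 0.0) for i in range(60)]
        assert smb.estimate_monomer_intensity(events) == 20.0

    def test_excludes_acceptor_coincident(self):
        events = [BurstEvent(i, i, 20.0, 0.0) for i in range(60)]
        events += [BurstEvent(100 + i, 100 + i, 200.0, 50.0) for i in range(5)]
        est = smb.estimate_monomer_intensity(events, acceptor_threshold=10.0)
        assert est == 20.0

    def test_too_few_events_raises(self):
        with pytest.raises(ValueError):
            smb.estimate_monomer_intensity([])


class TestClassifyOligomers:
    def test_empty(self):
        olig, excl = smb.classify_oligomers([], mean_monomer_I_D=20.0)
        assert olig == [] and excl == []

    def test_fibril_fragment_exclusion(self):
        frag = BurstEvent(0, 49, 5000.0, 5000.0)  # 50 bins, 500x <I_D>
        small = BurstEvent(60, 60, 20.0, 20.0)
        olig, excl = smb.classify_oligomers([frag, small], mean_monomer_I_D=20.0)
        assert excl == [frag]
        assert len(olig) == 1 and olig[0].event is small

    def test_sizes_and_efficiency_populated(self):
        ev = BurstEvent(0, 0, 20.0, 20.0)
        olig, _ = smb.classify_oligomers([ev], mean_monomer_I_D=20.0, gamma=1.0)
        assert olig[0].size_app == pytest.approx(4.0)
        assert olig[0].E == pytest.approx(0.5)


class TestPopulations:
    def test_rate_equal_to_reference(self):
        est = smb.estimate_populations(
            n_donor_events=500, n_oligomer_events=0, duration_s=10.0,
            reference_rate_hz=50.0, reference_conc_uM=2e-5,
        )
        assert est.soluble_uM == pytest.approx(2e-5)
        assert est.oligomer_fraction == 0.0

    def test_fraction_ratio_definition(self):
        est = smb.estimate_populations(
            n_donor_events=2000, n_oligomer_events=2, duration_s=10.0,
            reference_rate_hz=200.0, reference_conc_uM=2e-5,
        )
        assert est.oligomer_fraction == pytest.approx(1e-3)
        assert est.oligomer_uM == pytest.approx(2e-8)

    def test_dilution_mapping(self):
        est = smb.estimate_populations(
            n_donor_events=100, n_oligomer_events=1, duration_s=1.0,
            reference_rate_hz=100.0, reference_conc_uM=2e-4,
        )
        assert est.soluble_reaction_uM == pytest.approx(2e-4 * 50_000)

    def test_zero_events_raises(self):
        with pytest.raises(ValueError):
            smb.estimate_populations(0, 0, 1.0, 10.0, 1.0)


class TestBinEvents:
    @staticmethod
    def _event(size, E):
        return OligomerEvent(event=BurstEvent(0, 0, 1.0, 1.0), size_app=size, E=E)

    def test_empty_histogram(self):
        counts, size_edges, e_edges = smb.bin_events([])
        assert counts.sum() == 0
        assert size_edges[0] == 0.0 and e_edges[0] == 0.0

    def test_single_event_bin_placement(self):
        counts, size_edges, e_edges = smb.bin_events([self._event(2.4, 0.12)])
        i = np.searchsorted(size_edges, 2.4, side="right") - 1
        j = np.searchsorted(e_edges, 0.12, side="right") - 1
        assert (size_edges[i], size_edges[i + 1]) == (2.0, 3.0)
        assert (e_edges[j], e_edges[j + 1]) == pytest.approx((0.10, 0.15))
        assert counts[i, j] == 1 and counts.sum() == 1

    def test_marginal_identity_and_total_conservation(self):
        rng = np.random.default_rng(3)
        events = [
            self._event(s, e)
            for s, e in zip(rng.uniform(0.5, 9, 200), rng.uniform(0, 1, 200))
        ]
        counts, _, _ = smb.bin_events(events)
        assert counts.sum() == 200
        size_hist = counts.sum(axis=1)
        np.testing.assert_array_equal(
            size_hist, np.histogram([e.size_app for e in events],
                                    bins=np.arange(0, len(size_hist) + 1))[0],
        )
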