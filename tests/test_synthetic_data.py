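"""Generators: determinism, noise statistics, trace ground truth."""

import numpy as np
import pytest

from taukinetics import (
    InstrumentConfig,
    ModelConfig,
    RateConstants,
    SpeciesSpec,
    TimecourseSpec,
    TraceSpec,
    generate_study,
    generate_timecourse,
    generate_trace,
    integrate,
)
from taukinetics import smfret_bursts as smb


@pytest.fixture
def tc_spec(generic_params, default_config):
    return TimecourseSpec(
        params=generic_params,
        config=default_config,
        sample_times=tuple(np.linspace(0.25, 8.0, 12)),
        seed=42,
    )


class TestTimecourse:
    def test_zero_noise_equals_integrator(self, tc_spec):
        spec = TimecourseSpec(
            params=tc_spec.params, config=tc_spec.config,
            sample_times=tc_spec.sample_times, noise_sd_m=0.0, noise_sd_x=0.0,
        )
        gen = generate_timecourse(spec)
        grid = np.concatenate([[0.0], spec.sample_times])
        truth = integrate(spec.params, spec.config, grid)
        np.testing.assert_array_equal(gen.dataset.m_obs, truth.m[1:])
        np.testing.assert_array_equal(gen.dataset.x_obs, truth.x[1:])

    def test_seed_determinism(self, tc_spec):
        a = generate_timecourse(tc_spec)
        b = generate_timecourse(tc_spec)
        np.testing.assert_array_equal(a.dataset.m_obs, b.dataset.m_obs)
        c = generate_timecourse(
            TimecourseSpec(
                params=tc_spec.params, config=tc_spec.config,
                sample_times=tc_spec.sample_times, seed=tc_spec.seed + 1,
            )
        )
        assert not np.array_equal(a.dataset.m_obs, c.dataset.m_obs)

    def test_replicate_mean_converges_to_truth(self, generic_params, default_config):
        """Log-normal multiplicative noise: the replicate mean approaches
        the noiseless value (times the small-sd bias factor) within 3 SE."""
        times = (1.0, 2.0, 4.0, 8.0)
        sd = 0.05
        reps = np.array(
            [
                generate_timecourse(
                    TimecourseSpec(
                        params=generic_params, config=default_config,
                        sample_times=times, noise_sd_m=sd, noise_sd_x=0.0,
                        seed=1000 + i,
                    )
                ).dataset.m_obs
                for i in range(200)
            ]
        )
        truth = generate_timecourse(
            TimecourseSpec(
                params=generic_params, config=default_config,
                sample_times=times, noise_sd_m=0.0, noise_sd_x=0.0,
            )
        ).dataset.m_obs
        expected = truth * np.exp(sd**2 / 2)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert (np.abs(reps.mean(axis=0) - expected) < 3 * se).all()

    def test_passes_reader_validation(self, tc_spec, tmp_path):
        from taukinetics.fitting import read_dataset, write_dataset

        gen = generate_timecourse(tc_spec)
        path = tmp_path / "ds.csv"
        write_dataset(gen.dataset, path)
        ds = read_dataset(path)
        np.testing.assert_allclose(ds.m_obs, gen.dataset.m_obs)


class TestTrace:
    def test_background_only_is_poisson(self):
        spec = TraceSpec(
            duration_bins=200_000,
            species=(),
            instrument=InstrumentConfig(background_donor=2.0, background_acceptor=1.0),
            seed=3,
        )
        gen = generate_trace(spec)
        d = gen.trace.donor_counts
        for arr, mean in ((d, 2.0), (gen.trace.acceptor_counts, 1.0)):
            se = np.sqrt(mean / len(arr))
            assert abs(arr.mean() - mean) < 3 * se
            assert abs(arr.var() - mean) < 5 * se * np.sqrt(2 * mean)

    def test_acceptor_only_monomers_invisible(self):
        """Acceptor-labelled monomers are not directly excited: no
        acceptor-channel events beyond the background false-positive rate."""
        spec = TraceSpec(
            duration_bins=100_000,
            species=(
                SpeciesSpec(name="mono-A", rate_per_bin=0.02, size=1,
                            labels="acceptor", brightness=100.0, E=0.0),
            ),
            instrument=InstrumentConfig(background_acceptor=0.5),
            seed=7,
        )
        gen = generate_trace(spec)
        d, a = smb.correct_trace(gen.trace)
        events = smb.detect_events(d, a, "acceptor", 10.0)
        # Poisson(0.5) above 10 counts: ~1e-10 per bin; allow a tiny count
        assert len(events) <= 2

    def test_oligomer_size_recovered_downstream(self):
        """Full round trip: implanted size-4 oligomers are sized ~4 on
        average by the burst pipeline.

        The monomer reference intensity comes from a monomer-only
        calibration trace, as a sample taken at reaction start would
        provide; estimating it from the mixed trace instead would fold
        donor-only oligomers (no FRET, invisible in the acceptor channel)
        into the monomer mean and bias sizes low."""
        inst = InstrumentConfig(background_donor=0.5, background_acceptor=0.5)
        ref = generate_trace(
            TraceSpec(
                duration_bins=100_000,
                species=(SpeciesSpec(name="mono-D", rate_per_bin=0.01, size=1,
                                     labels="donor", brightness=50.0, E=0.0),),
                instrument=inst,
                seed=10,
            )
        )
        ref_result = smb.analyze_trace(ref.trace)
        spec = TraceSpec(
            duration_bins=400_000,
            species=(
                SpeciesSpec(name="mono-D", rate_per_bin=0.01, size=1,
                            labels="donor", brightness=50.0, E=0.0),
                SpeciesSpec(name="tet", rate_per_bin=0.004, size=4,
                            labels="binomial", brightness=50.0, E=0.5),
            ),
            instrument=inst,
            seed=11,
        )
        gen = generate_trace(spec)
        result = smb.analyze_trace(
            gen.trace, mean_monomer_I_D=ref_result["mean_monomer_I_D"]
        )
        sizes = [o.size_app for o in result["oligomers"]]
        assert len(sizes) >= 1000
        assert np.mean(sizes) == pytest.approx(4.0, rel=0.05)

    def test_event_log_matches_poisson_count(self):
        spec = TraceSpec(
            duration_bins=50_000,
            species=(SpeciesSpec(name="m", rate_per_bin=0.01, size=1,
                                 labels="donor", brightness=40.0),),
            seed=19,
        )
        gen = generate_trace(spec)
        n = len(gen.events)
        lam = 0.01 * 50_000
        assert abs(n - lam) < 4 * np.sqrt(lam)


class TestStudy:
    def test_identical_panel_zero_ddg(self, generic_params, default_config):
        panel = {"wt": generic_params, "copy": generic_params}
        study = generate_study(panel, default_config, np.linspace(0.5, 8, 8))
        assert all(abs(v) < 1e-12 for v in study.true_ddg["copy"].values())

    def test_known_ratio_gives_known_ddg(self, generic_params, default_config):
        import dataclasses, math

        mut = dataclasses.replace(generic_params, k_n=generic_params.k_n * math.e**5)
        study = generate_study(
            {"wt": generic_params, "mut": mut}, default_config,
            np.linspace(0.5, 8, 8),
        )
        assert study.true_ddg["mut"]["k_n"] == pytest.approx(-5.0)
        assert study.true_ddg["mut"]["k_plus"] == pytest.approx(0.0)

    def test_requires_two_constructs(self, generic_params, default_config):
        with pytest.raises(ValueError):
            generate_study({"wt": generic_params}, default_config, [0.5, 1, 2, 4])
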