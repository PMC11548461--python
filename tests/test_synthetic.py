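import datetime as dt

import numpy as np
import pandas as pd
import pytest

import herdhmm as hh
from herdhmm import solar
from herdhmm.model import TransitionStructure


class TestSimulateStates:
    def test_absorbing_identity_chain(self, ref_model):
        m = hh.HmmModel(
            n_states=3,
            emissions=ref_model.emissions,
            transitions=TransitionStructure.from_matrix(np.eye(3)),
            pi0=[0.0, 1.0, 0.0],
        )
        st = hh.simulate_states(m, 500, seed=0)
        assert np.all(st == 1)

    def test_uniform_chain_stationary_frequencies(self, ref_model):
        m = hh.HmmModel(
            n_states=3,
            emissions=ref_model.emissions,
            transitions=TransitionStructure.from_matrix(np.full((3, 3), 1 / 3)),
            pi0=np.full(3, 1 / 3),
        )
        st = hh.simulate_states(m, 30_000, seed=1)
        freq = np.bincount(st, minlength=3) / st.size
        assert np.allclose(freq, 1 / 3, atol=0.01)

    def test_two_state_chain_analytic_stationary(self, ref_model):
        # pi Gamma = pi for [[0.9,0.1],[0.5,0.5]] gives pi = (5/6, 1/6)
        m = hh.HmmModel(
            n_states=2,
            emissions=ref_model.emissions[:2],
            transitions=TransitionStructure.from_matrix(
                np.array([[0.9, 0.1], [0.5, 0.5]])
            ),
            pi0=[0.5, 0.5],
        )
        st = hh.simulate_states(m, 50_000, seed=2)
        assert np.mean(st == 0) == pytest.approx(5 / 6, abs=0.01)

    def test_requires_covariates_when_model_has_them(self, ref_model):
        t = TransitionStructure(n_states=3, beta=np.zeros((6, 2)),
                                covariates=("temperature_c",))
        m = hh.HmmModel(n_states=3, emissions=ref_model.emissions,
                        transitions=t, pi0=np.full(3, 1 / 3))
        with pytest.raises(ValueError):
            hh.simulate_states(m, 10, seed=0)


class TestSimulateTrack:
    def test_straight_line_limit(self, ref_model):
        # fixed step, extreme angular concentration at zero turning
        m = hh.HmmModel(
            n_states=1,
            emissions=[hh.EmissionParams(500.0, 1e-4, 0.0, 0.0, 1e7)],
            transitions=TransitionStructure(n_states=1, beta=np.zeros((0, 1))),
            pi0=[1.0],
        )
        lat, lon = hh.simulate_track(m, np.zeros(20, dtype=int), (14.5, -16.5),
                                     seed=3)
        series = hh.compute_steps(pd.DataFrame({"lat": lat, "lon": lon}))
        assert np.allclose(series.steps, 500.0, atol=1.0)
        assert np.nanmax(np.abs(series.angles)) < 0.01

    def test_resting_state_mean_step(self, ref_model):
        n = 10_000
        lat, lon = hh.simulate_track(ref_model, np.zeros(n, dtype=int),
                                     (14.5, -16.5), seed=4)
        series = hh.compute_steps(pd.DataFrame({"lat": lat, "lon": lon}))
        nz = series.steps[series.steps > 0]
        # truncated-normal mean for (mu, sigma) = (13.53, 11.99)
        from scipy import stats
        e = ref_model.emissions[0]
        expected = stats.truncnorm(-e.mu / e.sigma, np.inf, e.mu, e.sigma).mean()
        se = nz.std() / np.sqrt(nz.size)
        assert abs(nz.mean() - expected) < 2 * se

    def test_reversal_state_folds_path(self, ref_model):
        # mu' = pi with high concentration: back-and-forth, tiny net motion
        m = hh.HmmModel(
            n_states=1,
            emissions=[hh.EmissionParams(300.0, 30.0, 0.0, np.pi, 50.0)],
            transitions=TransitionStructure(n_states=1, beta=np.zeros((0, 1))),
            pi0=[1.0],
        )
        lat, lon = hh.simulate_track(m, np.zeros(400, dtype=int), (14.5, -16.5),
                                     seed=5)
        path_len = hh.geo.haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum()
        net = hh.geo.haversine_m(lat[0], lon[0], lat[-1], lon[-1])
        assert net / path_len < 0.05


class TestGpsNoise:
    def test_zero_sd_is_identity(self):
        lat = np.array([14.5, 14.6])
        lon = np.array([-16.5, -16.4])
        la, lo = hh.add_gps_noise(lat, lon, 0.0, seed=1)
        assert np.array_equal(la, lat) and np.array_equal(lo, lon)

    def test_default_sd_hits_95pct_within_10m(self):
        rng = np.random.default_rng(8)
        r = np.hypot(rng.normal(0, hh.GPS_NOISE_SD_M, 50_000),
                     rng.normal(0, hh.GPS_NOISE_SD_M, 50_000))
        assert np.quantile(r, 0.95) == pytest.approx(10.0, rel=0.02)

    def test_stationary_point_angle_signature(self):
        # pure jitter on a fixed point: angles concentrate at the cut +-pi
        n = 4000
        lat = np.full(n, 14.5)
        lon = np.full(n, -16.5)
        la, lo = hh.add_gps_noise(lat, lon, 5.0, seed=9)
        series = hh.compute_steps(pd.DataFrame({"lat": la, "lon": lo}))
        ang = series.angles[np.isfinite(series.angles)]
        R = np.abs(np.mean(np.exp(1j * ang)))
        circ_mean = np.angle(np.mean(np.exp(1j * ang)))
        assert R > 0.1
        assert abs(abs(circ_mean) - np.pi) < 0.2

    def test_stationary_step_mean_scales_as_sd_sqrt_pi(self):
        # distance between two independent isotropic Gaussians has mean
        # sd*sqrt(pi) (Rayleigh with scale sd*sqrt(2))
        n = 20_000
        for sd in (3.0, 5.0):
            la, lo = hh.add_gps_noise(np.full(n, 14.5), np.full(n, -16.5), sd,
                                      seed=int(sd))
            series = hh.compute_steps(pd.DataFrame({"lat": la, "lon": lo}))
            assert series.steps.mean() == pytest.approx(sd * np.sqrt(np.pi),
                                                        rel=0.03)


class TestSimulateSurvey:
    def test_resident_tether_window_is_resting(self, small_survey, ref_model):
        truth = small_survey.truth
        gps = small_survey.gps
        cfg = small_survey.config
        resident = truth[truth["animal_id"] == "A01"].copy()
        assert cfg.herd_types[1] == "resident"
        ts = pd.to_datetime(resident["timestamp_utc"])
        tether = np.zeros(len(ts), dtype=bool)
        for date in sorted(set(ts.dt.date)):
            rise, set_ = solar.sunrise_sunset_utc(date, cfg.home_lat, cfg.home_lon)
            m = ts.dt.date == date
            tether[m.to_numpy()] = (
                (ts[m] < rise - dt.timedelta(hours=1))
                | (ts[m] >= set_ + dt.timedelta(hours=1))
            ).to_numpy()
        night_states = resident["true_state"].to_numpy()[tether]
        assert np.mean(night_states == 0) >= 0.95

    def test_identical_seed_byte_identical(self, ref_model, tmp_path):
        cfg = hh.SimConfig(n_herds=1, n_days=5, seed=13, transhumance_schedule=[])
        for d in ("a", "b"):
            hh.simulate_survey(cfg, ref_model).write(tmp_path / d)
        for name in ("gps.csv", "metadata.csv", "truth.csv",
                     "landuse_fine.geojson", "legend.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_metadata_tiles_span_no_orphans(self, small_survey):
        gps = small_survey.gps
        meta = small_survey.metadata
        ts = pd.to_datetime(gps["timestamp_utc"])
        covered = np.zeros(len(gps), dtype=int)
        for _, row in meta.iterrows():
            start = pd.Timestamp(row["start_utc"])
            end = pd.Timestamp(row["end_utc"])
            m = (gps["collar_id"] == row["collar_id"]) & (ts >= start) & (ts < end)
            covered += m.to_numpy()
        assert np.all(covered == 1)
        assert len(small_survey.truth) == len(gps)

    def test_schedule_outside_span_rejected(self):
        with pytest.raises(ValueError):
            hh.SimConfig(
                n_herds=1, n_days=10,
                herd_types=("transhumant",),
                transhumance_schedule=[
                    hh.synthetic.TranshumancePhase(
                        "pastoral", dt.date(2022, 3, 1) + dt.timedelta(days=50),
                        (40.0, 40.0))
                ],
            )

    def test_gap_rate_validation(self):
        with pytest.raises(ValueError):
            hh.SimConfig(gap_rate=1.0)
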