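import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resteeg.io import Recording
from resteeg.montage import ClusterMap
from resteeg.spectral import (BandScheme, aggregate, band_power,
                              band_power_table, channel_band_powers,
                              logit_transform, relative_power, welch_psd)

TILING = BandScheme(bands={"b1": (1.0, 8.0), "b2": (8.0, 15.0),
                           "b3": (15.0, 22.0), "b4": (22.0, 30.0)},
                    denominator=(1.0, 30.0))


class TestWelch:
    def test_resolution_quarter_hz(self, sine_recording):
        psd = welch_psd(sine_recording)
        assert psd.resolution == pytest.approx(0.25)
        assert np.all(np.diff(psd.freqs) == pytest.approx(0.25))

    def test_sine_peak_and_parseval(self, sine_recording):
        """Unit sinusoid carries A^2/2 = 0.5 units of power at its own bin."""
        psd = welch_psd(sine_recording)
        assert psd.freqs[np.argmax(psd.power[0])] == pytest.approx(10.0)
        p = band_power(psd, (9.0, 11.0))[0]
        assert p == pytest.approx(0.5, rel=0.02)

    def test_white_noise_parseval(self, rng):
        sigma = 3.0
        data = sigma * rng.standard_normal((1, 250 * 360))
        rec = Recording("w", 250.0, ["a"], data)
        psd = welch_psd(rec)
        total = band_power(psd, (0.0, 125.0))[0]
        assert total == pytest.approx(sigma ** 2, rel=0.05)

    def test_constant_signal_is_dc_only(self):
        rec = Recording("c", 250.0, ["a"], 5.0 * np.ones((1, 2500)))
        psd = welch_psd(rec)
        assert psd.power[0, 1:].max() <= 1e-12 * max(psd.power[0, 0], 1.0)

    def test_too_short_rejected(self):
        rec = Recording("s", 250.0, ["a"], np.zeros((1, 500)))
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(rec, window_s=4.0)


class TestBandPower:
    def test_flat_psd_rectangle(self):
        from resteeg.spectral import Psd

        freqs = np.arange(0, 30.25, 0.25)
        psd = Psd(freqs, np.full((1, len(freqs)), 2.0), 0.25, ["a"])
        assert band_power(psd, (4.0, 7.0))[0] == pytest.approx(2.0 * 3.0)

    def test_sine_concentrated_in_own_band(self):
        """An 11 Hz sinusoid (mid alpha-2) puts all its A^2/2 power in the
        10-12 Hz band and nothing in theta."""
        fs = 250.0
        t = np.arange(int(fs * 120)) / fs
        rec = Recording("s11", fs, ["a"], np.sin(2 * np.pi * 11.0 * t)[None])
        psd = welch_psd(rec)
        a2 = band_power(psd, (10.0, 12.0))[0]
        th = band_power(psd, (4.0, 7.0))[0]
        assert a2 == pytest.approx(0.5, rel=0.02)
        assert th < 1e-4 * a2

    def test_band_beyond_signal_support_is_tiny(self, sine_recording):
        psd = welch_psd(sine_recording)
        assert band_power(psd, (31.0, 40.0))[0] < 1e-6  # leakage floor only

    def test_band_outside_grid_rejected(self, sine_recording):
        psd = welch_psd(sine_recording)
        with pytest.raises(ValueError, match="outside"):
            band_power(psd, (100.0, 130.0))


class TestRelativePower:
    def test_ratio(self):
        assert relative_power(2.0, 8.0) == pytest.approx(0.25)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_power(1.0, 0.0)

    def test_sine_alpha2_relative_near_one(self):
        fs = 250.0
        t = np.arange(int(fs * 120)) / fs
        rec = Recording("s11", fs, ["a"], np.sin(2 * np.pi * 11.0 * t)[None])
        psd = welch_psd(rec)
        denom = band_power(psd, (1.0, 30.0))
        rel = relative_power(band_power(psd, (10.0, 12.0)), denom)
        assert rel[0] == pytest.approx(1.0, abs=0.01)

    def test_tiling_bands_sum_to_one(self, small_cohort):
        """Bands that exactly tile the denominator must account for all of
        its power, channel by channel."""
        recs, _ = small_cohort
        for rec in recs[:2]:
            psd = welch_psd(rec)
            denom = band_power(psd, TILING.denominator)
            total = sum(
                relative_power(band_power(psd, b), denom)
                for b in TILING.bands.values())
            np.testing.assert_allclose(total, 1.0, atol=1e-6)

    def test_amplitude_scale_invariance(self, small_cohort):
        recs, _ = small_cohort
        rec = recs[0]
        doubled = Recording(rec.subject_id, rec.fs, list(rec.channels),
                            2.0 * rec.data, rec.group)
        t1 = channel_band_powers(rec)
        t2 = channel_band_powers(doubled)
        np.testing.assert_allclose(t1["relative_power"], t2["relative_power"],
                                   atol=1e-9)


class TestLogit:
    def test_symmetry_point(self):
        assert logit_transform(0.5) == 0.0

    def test_direct_value(self):
        assert logit_transform(0.73) == pytest.approx(np.log(0.73 / 0.27))

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, x):
        assert logit_transform(1 - x) == pytest.approx(-logit_transform(x),
                                                       abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            logit_transform(bad)


class TestAggregate:
    @staticmethod
    def _table(values_by_channel, band="delta"):
        rows = [{"subject_id": "s1", "group": "N", "scope": f"channel:{ch}",
                 "band": band, "relative_power": x,
                 "logit": float(np.log(x / (1 - x)))}
                for ch, x in values_by_channel.items()]
        return pd.DataFrame(rows)

    def test_cluster_mean(self):
        table = self._table({"Fz": 0.2, "AFz": 0.4})
        cmap = ClusterMap({"MF": ["Fz", "AFz"]})
        out = aggregate(table, cmap)
        mf = out[out["scope"] == "cluster:MF"]
        assert mf["relative_power"].iloc[0] == pytest.approx(0.3)

    def test_all_equal_channels_global_identity(self):
        table = self._table({"Fz": 0.25, "Cz": 0.25, "Pz": 0.25})
        cmap = ClusterMap({"MF": ["Fz"], "C": ["Cz"]})
        out = aggregate(table, cmap)
        assert out[out["scope"] == "global"]["relative_power"].iloc[0] == \
            pytest.approx(0.25)

    def test_global_matches_brute_force(self, rng):
        chans = ["Fz", "Cz", "Pz", "Oz", "F3", "F4"]
        vals = dict(zip(chans, rng.uniform(0.05, 0.6, len(chans))))
        table = self._table(vals)
        cmap = ClusterMap({"MF": ["Fz", "F3", "F4"], "C": ["Cz"],
                           "PC": ["Pz"], "OC": ["Oz"]})
        out = aggregate(table, cmap)
        assert out[out["scope"] == "global"]["relative_power"].iloc[0] == \
            pytest.approx(np.mean(list(vals.values())))
        mf = out[out["scope"] == "cluster:MF"]["relative_power"].iloc[0]
        assert mf == pytest.approx(np.mean([vals["Fz"], vals["F3"], vals["F4"]]))

    def test_missing_channel_named_in_error(self):
        table = self._table({"Fz": 0.2})
        cmap = ClusterMap({"MF": ["Fz", "AFz"]})
        with pytest.raises(KeyError, match="AFz"):
            aggregate(table, cmap)

    def test_logit_applied_after_averaging(self):
        table = self._table({"Fz": 0.2, "AFz": 0.4})
        out = aggregate(table, ClusterMap({"MF": ["Fz", "AFz"]}))
        mf = out[out["scope"] == "cluster:MF"].iloc[0]
        assert mf["logit"] == pytest.approx(np.log(0.3 / 0.7))


def test_band_power_table_has_all_scopes(small_cohort):
    recs, _ = small_cohort
    table = band_power_table(recs)
    scopes = set(table["scope"].str.split(":").str[0])
    assert scopes == {"channel", "cluster", "global"}
    assert set(table["band"]) == {"delta", "theta", "alpha1", "alpha2"}
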