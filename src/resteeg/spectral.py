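"""Welch spectra, relative band power, logit transform, and ROI aggregation.

The "slowing of the EEG" arm of the analysis: per-channel Welch power
spectral density (4-s Hamming windows, 50 % overlap, linear detrend), band
power by trapezoidal integration, relative power against a 1-30 Hz
denominator, the logit transform t(x) = log(x / (1 - x)) applied to the
aggregated proportions, and averaging of channel values into anatomical
clusters and a global mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import Recording
from .montage import ClusterMap

#: Canonical band layout: delta, theta and the split alpha band.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "alpha1": (7.5, 9.5),
    "alpha2": (10.0, 12.0),
}


@dataclass(frozen=True)
class BandScheme:
    """Ordered band definitions plus the relative-power denominator range.

    Note the default denominator (1-30 Hz) does not cover delta's 0.5-1 Hz
    portion, so band ratios are not constrained to sum to at most 1; this
    mirrors the analysis convention being reproduced.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    denominator: tuple[float, float] = (1.0, 30.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: need lo < hi, got ({lo}, {hi})")
        if not self.denominator[0] < self.denominator[1]:
            raise ValueError("denominator range must have lo < hi")

    @classmethod
    def from_yaml(cls, path) -> "BandScheme":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        bands = {k: (float(v[0]), float(v[1])) for k, v in raw["bands"].items()}
        den = tuple(float(v) for v in raw.get("denominator", (1.0, 30.0)))
        return cls(bands, den)  # type: ignore[arg-type]


@dataclass
class Psd:
    """Per-channel Welch power spectral density (uV^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray  # channels x freqs
    resolution: float
    channels: list[str]


def welch_psd(rec: Recording, window_s: float = 4.0, overlap: float = 0.5) -> Psd:
    """Welch PSD with Hamming windows and per-segment linear detrend.

    At 250 Hz and a 4-s window the frequency resolution is 0.25 Hz.
    """
    nper = window_s * rec.fs
    if abs(nper - round(nper)) > 1e-9:
        raise ValueError("window length times sampling rate must be an integer")
    nper = int(round(nper))
    if rec.n_samples < nper:
        raise ValueError(
            f"recording of {rec.duration_s:.3g} s shorter than one "
            f"{window_s:.3g} s window")
    freqs, power = signal.welch(
        rec.data, fs=rec.fs, window="hamming", nperseg=nper,
        noverlap=int(round(overlap * nper)), detrend="linear",
        scaling="density", axis=-1,
    )
    return Psd(freqs, power, rec.fs / nper, list(rec.channels))


def band_power(psd: Psd, band: tuple[float, float]) -> np.ndarray:
    """Integral of the PSD over the half-open band ``[lo, hi)``, per channel.

    Rectangle quadrature (bin value times bin width) over the bins whose
    centre lies in ``[lo, hi)``.  Half-open intervals resolve shared band
    edges (e.g. delta/theta at 4 Hz) without double counting, so bands that
    tile the denominator integrate to exactly the denominator power; for a
    flat spectrum the result is exact, otherwise accurate to a one-bin edge
    effect.
    """
    lo, hi = band
    if lo < psd.freqs[0] - 1e-9 or hi > psd.freqs[-1] + psd.resolution:
        raise ValueError(
            f"band ({lo}, {hi}) outside the PSD grid "
            f"[{psd.freqs[0]}, {psd.freqs[-1]}]")
    mask = (psd.freqs >= lo - 1e-12) & (psd.freqs < hi - 1e-12)
    if not mask.any():
        raise ValueError(f"band ({lo}, {hi}) covers no frequency bin")
    return psd.power[:, mask].sum(axis=-1) * psd.resolution


def relative_power(band_powers: np.ndarray, denominator_power: np.ndarray) -> np.ndarray:
    """Ratio of band power to denominator power."""
    band_powers = np.asarray(band_powers, dtype=float)
    denominator_power = np.asarray(denominator_power, dtype=float)
    if np.any(denominator_power <= 0):
        raise ZeroDivisionError("denominator power must be positive")
    return band_powers / denominator_power


def logit_transform(x):
    """t(x) = log(x / (1 - x)); strictly increasing, antisymmetric about 0.5."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("logit transform requires 0 < x < 1")
    out = np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def channel_band_powers(rec: Recording, scheme: BandScheme | None = None,
                        window_s: float = 4.0, overlap: float = 0.5) -> pd.DataFrame:
    """Channel-scope relative band powers for one recording (tidy rows)."""
    scheme = scheme or BandScheme()
    psd = welch_psd(rec, window_s, overlap)
    denom = band_power(psd, scheme.denominator)
    rows = []
    for band_name, band in scheme.bands.items():
        rel = relative_power(band_power(psd, band), denom)
        for ch, x in zip(psd.channels, rel):
            rows.append({
                "subject_id": rec.subject_id, "group": rec.group,
                "scope": f"channel:{ch}", "band": band_name,
                "relative_power": float(x),
                "logit": float(np.log(x / (1 - x))) if 0 < x < 1 else np.nan,
            })
    return pd.DataFrame(rows)


def aggregate(table: pd.DataFrame, clusters: ClusterMap) -> pd.DataFrame:
    """Average channel-scope relative powers into cluster and global rows.

    The mean is taken on the proportion scale; the logit is applied to the
    aggregated value (the transform targets the quantities entering the
    statistics, not the per-channel intermediates).
    """
    chan = table[table["scope"].str.startswith("channel:")].copy()
    if chan.empty:
        raise ValueError("no channel-scope rows to aggregate")
    chan["channel"] = chan["scope"].str.removeprefix("channel:")
    rows = []
    for (sid, band), sub in chan.groupby(["subject_id", "band"], sort=False):
        by_chan = sub.set_index("channel")["relative_power"]
        group = sub["group"].iloc[0]
        for cname, members in clusters.clusters.items():
            missing = [ch for ch in members if ch not in by_chan.index]
            if missing:
                raise KeyError(
                    f"cluster {cname!r} channel {missing[0]!r} missing for "
                    f"subject {sid!r}")
            x = float(by_chan.loc[members].mean())
            rows.append({"subject_id": sid, "group": group,
                         "scope": f"cluster:{cname}", "band": band,
                         "relative_power": x,
                         "logit": float(np.log(x / (1 - x))) if 0 < x < 1 else np.nan})
        g = float(by_chan.mean())
        rows.append({"subject_id": sid, "group": group, "scope": "global",
                     "band": band, "relative_power": g,
                     "logit": float(np.log(g / (1 - g))) if 0 < g < 1 else np.nan})
    return pd.DataFrame(rows)


def band_power_table(recordings, scheme: BandScheme | None = None,
                     clusters: ClusterMap | None = None,
                     window_s: float = 4.0, overlap: float = 0.5) -> pd.DataFrame:
    """Full tidy band-power table (channel + cluster + global scopes)."""
    scheme = scheme or BandScheme()
    chan = pd.concat(
        [channel_band_powers(r, scheme, window_s, overlap) for r in recordings],
        ignore_index=True)
    if clusters is None:
        clusters = ClusterMap.default().restrict(recordings[0].channels)
    agg = aggregate(chan, clusters)
    return pd.concat([chan, agg], ignore_index=True)
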