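"""Multitaper magnitude-squared coherence and FDR-corrected group contrasts.

Coherence is estimated with DPSS (Slepian) tapers on non-overlapping 4-s
segments: cross- and auto-spectra are summed over all segment x taper
estimates and combined as

    MSC(f) = |sum S_xy(f)|^2 / (sum S_xx(f) * sum S_yy(f)),

then averaged over the frequency bins of each band.  MSC lies in [0, 1]
with 1 for perfectly linearly coupled signals; a pure delay leaves it at 1.

Group contrasts are Welch two-sample t-tests per (channel pair, band), with
Benjamini-Hochberg FDR over the whole family of tests within each contrast.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import windows

from .io import Recording
from .spectral import BandScheme

__all__ = ["multitaper_coherence", "coherence_table", "coherence_contrast", "bh_fdr"]


def multitaper_coherence(rec: Recording, pairs: list[tuple[str, str]],
                         bands: BandScheme | None = None,
                         segment_s: float = 4.0,
                         half_bandwidth: float = 1.0) -> pd.DataFrame:
    """Band-averaged MSC for the requested channel pairs of one recording.

    ``half_bandwidth`` W (Hz) sets the taper count: with segment length T,
    K = floor(2 T W) - 1 tapers are used (7 for T=4 s, W=1 Hz).  At least
    two segments are required; a single segment would make MSC degenerate
    at 1 regardless of the signals.
    """
    bands = bands or BandScheme()
    n_per = int(round(segment_s * rec.fs))
    n_seg = rec.n_samples // n_per
    if n_seg < 2:
        raise ValueError(
            f"recording yields {n_seg} segment(s) of {segment_s} s; "
            "coherence needs at least 2")
    nw = segment_s * half_bandwidth
    n_tapers = int(2 * nw) - 1
    if n_tapers < 1:
        raise ValueError(
            f"half-bandwidth {half_bandwidth} Hz gives no usable taper "
            f"(2TW-1 = {2 * nw - 1:.3g})")

    idx = {ch: i for i, ch in enumerate(rec.channels)}
    needed = sorted({ch for p in pairs for ch in p})
    for ch in needed:
        if ch not in idx:
            raise KeyError(f"channel {ch!r} not present in recording "
                           f"{rec.subject_id!r}")

    tapers = windows.dpss(n_per, nw, Kmax=n_tapers)  # (K, n_per)
    freqs = np.fft.rfftfreq(n_per, 1.0 / rec.fs)

    segs = rec.data[[idx[ch] for ch in needed], :n_seg * n_per]
    segs = segs.reshape(len(needed), n_seg, n_per)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    # (ch, seg, taper, freq)
    spectra = np.fft.rfft(segs[:, :, None, :] * tapers[None, None, :, :], axis=-1)
    auto = (spectra * np.conj(spectra)).real.sum(axis=(1, 2))  # (ch, freq)

    pos = {ch: i for i, ch in enumerate(needed)}
    rows = []
    for ch_a, ch_b in pairs:
        a, b = pos[ch_a], pos[ch_b]
        if a == b:
            msc = np.ones_like(freqs)  # MSC of a signal with itself
        else:
            cross = (spectra[a] * np.conj(spectra[b])).sum(axis=(0, 1))
            with np.errstate(invalid="ignore", divide="ignore"):
                msc = np.abs(cross) ** 2 / (auto[a] * auto[b])
            msc = np.nan_to_num(msc, nan=0.0)
        for band_name, (lo, hi) in bands.bands.items():
            mask = (freqs >= lo) & (freqs < hi)
            if not mask.any():
                raise ValueError(f"band {band_name!r} has no frequency bin")
            rows.append({
                "subject_id": rec.subject_id, "group": rec.group,
                "channel_a": ch_a, "channel_b": ch_b, "band": band_name,
                "coherence": float(msc[mask].mean()),
            })
    return pd.DataFrame(rows)


def coherence_table(recordings: list[Recording], pairs: list[tuple[str, str]],
                    bands: BandScheme | None = None, segment_s: float = 4.0,
                    half_bandwidth: float = 1.0) -> pd.DataFrame:
    """Stack :func:`multitaper_coherence` over subjects."""
    return pd.concat(
        [multitaper_coherence(r, pairs, bands, segment_s, half_bandwidth)
         for r in recordings],
        ignore_index=True)


def bh_fdr(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p_raw = np.asarray(p_raw, dtype=float)
    if p_raw.size == 0:
        return p_raw
    return multipletests(p_raw, method="fdr_bh")[1]


def coherence_contrast(table: pd.DataFrame,
                       contrasts: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Welch t-tests per (pair, band) with BH-FDR within each group contrast.

    ``table`` is a tidy coherence table with a ``group`` column.  Default
    contrasts are all unordered pairs of the group labels present.
    """
    groups = sorted(table["group"].dropna().unique(), key=str)
    if contrasts is None:
        contrasts = list(itertools.combinations(groups, 2))
    out = []
    for ga, gb in contrasts:
        rows = []
        for (ch_a, ch_b, band), sub in table.groupby(
                ["channel_a", "channel_b", "band"], sort=False):
            va = sub.loc[sub["group"] == ga, "coherence"].to_numpy()
            vb = sub.loc[sub["group"] == gb, "coherence"].to_numpy()
            if len(va) < 2 or len(vb) < 2:
                raise ValueError(
                    f"contrast {ga} vs {gb}: fewer than 2 subjects per group "
                    f"for pair ({ch_a}, {ch_b}), band {band}")
            t, p = sps.ttest_ind(va, vb, equal_var=False)
            if not np.isfinite(t):  # zero variance in both groups
                t, p = 0.0, 1.0
            rows.append({"group_a": ga, "group_b": gb, "channel_a": ch_a,
                         "channel_b": ch_b, "band": band,
                         "t_stat": float(t), "p_raw": float(p)})
        df = pd.DataFrame(rows)
        df["p_fdr"] = bh_fdr(df["p_raw"].to_numpy())
        out.append(df)
    return pd.concat(out, ignore_index=True)
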