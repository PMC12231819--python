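"""Replicated synthetic-cohort studies for calibration and validation.

These functions run the analysis chain many times on freshly generated data
and report aggregate rates: the type-I error of the assumption-gated
omnibus test on null data, its power against a fixed standardised shift,
and how often the full pipeline recovers the expected direction of the
Alzheimer's-risk contrasts (more delta, less upper-alpha, lower complexity
in double-risk carriers) at the 0.05 level.

Study conditions are fixed here once: cohorts of 25 subjects per group,
four channels (Fz, Cz, Pz, Oz), 60 s of eyes-closed signal at 250 Hz, and
Higuchi FD at k_max = 82 on the whole channel series.  Every replicate
derives its RNG stream from the study seed.
"""

from __future__ import annotations

import numpy as np

from . import spectral
from .hfd import _fd_curves
from .stats import choose_and_run
from .synth import ad_like_groups, gen_resting_eeg

__all__ = ["headline_replicate", "headline_direction_study",
           "null_type1_study", "shift_power_study"]

_MAX_SEED = 2 ** 31 - 1


def _rep_seed(seed: int, rep: int) -> int:
    return (seed * 100003 + rep * 7919 + 17) % _MAX_SEED


def headline_replicate(seed: int, n_per_group: int = 25, n_channels: int = 4,
                       fs: float = 250.0, duration_s: float = 60.0,
                       kmax: int = 82) -> dict[str, bool]:
    """One synthetic cohort: generate, analyse, test the three headline
    contrasts.

    Returns, for global delta relative power, global alpha-2 relative power
    and global HFD, whether the A+P+ vs N post-hoc contrast reached
    p <= 0.05 *and* the group means ordered in the expected direction
    (delta up, alpha-2 down, HFD down in A+P+).
    """
    groups = ad_like_groups(n_per_group, seed=seed)
    recs, _ = gen_resting_eeg(groups, n_channels=n_channels, fs=fs,
                              duration_s=duration_s)
    scheme = spectral.BandScheme()

    subj_group, delta_logit, alpha2_logit, hfd_global = [], [], [], []
    for rec in recs:
        psd = spectral.welch_psd(rec)
        denom = spectral.band_power(psd, scheme.denominator)
        rel_d = spectral.relative_power(
            spectral.band_power(psd, scheme.bands["delta"]), denom).mean()
        rel_a2 = spectral.relative_power(
            spectral.band_power(psd, scheme.bands["alpha2"]), denom).mean()
        fd = _fd_curves(rec.data, kmax, kmax)[:, 0].mean()
        subj_group.append(rec.group)
        delta_logit.append(np.log(rel_d / (1 - rel_d)))
        alpha2_logit.append(np.log(rel_a2 / (1 - rel_a2)))
        hfd_global.append(fd)

    subj_group = np.array(subj_group)
    out = {}
    for name, values, expect_app_low in (
            ("delta", np.array(delta_logit), False),
            ("alpha2", np.array(alpha2_logit), True),
            ("hfd", np.array(hfd_global), True)):
        res = choose_and_run(values, subj_group, outcome=name)
        p_contrast = next(
            (p for pair, p, _ in res.posthoc if set(pair) == {"A+P+", "N"}),
            1.0)
        m_app = values[subj_group == "A+P+"].mean()
        m_n = values[subj_group == "N"].mean()
        direction = m_app < m_n if expect_app_low else m_app > m_n
        out[name] = bool(p_contrast <= 0.05 and direction)
    return out


def headline_direction_study(n_replicates: int = 200, n_per_group: int = 25,
                             seed: int = 0, **kwargs) -> dict[str, float]:
    """Fraction of replicates recovering each headline contrast (percent)."""
    hits = {"delta": 0, "alpha2": 0, "hfd": 0}
    for rep in range(n_replicates):
        res = headline_replicate(_rep_seed(seed, rep), n_per_group, **kwargs)
        for k in hits:
            hits[k] += res[k]
    return {k: 100.0 * v / n_replicates for k, v in hits.items()}


def null_type1_study(n_replicates: int = 1000, n_per_group: int = 25,
                     seed: int = 0) -> float:
    """Type-I error of the assumption-gated omnibus chain on null data.

    Three groups drawn from one normal distribution; returns the fraction
    of replicates with omnibus p <= 0.05 (nominally 0.05).
    """
    rng = np.random.default_rng(seed)
    groups = np.repeat(["N", "A+P-", "A+P+"], n_per_group)
    rejections = 0
    for _ in range(n_replicates):
        values = rng.standard_normal(3 * n_per_group)
        res = choose_and_run(values, groups, run_posthoc=False)
        rejections += res.p <= 0.05
    return rejections / n_replicates


def shift_power_study(n_replicates: int = 200, n_per_group: int = 20,
                      shift_sd: float = 2.0, seed: int = 0) -> float:
    """Power of the chain against one group shifted by ``shift_sd`` pooled
    SDs (percent of replicates with omnibus p <= 0.05)."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["N", "A+P-", "A+P+"], n_per_group)
    hits = 0
    for _ in range(n_replicates):
        values = rng.standard_normal(3 * n_per_group)
        values[groups == "A+P+"] += shift_sd
        res = choose_and_run(values, groups, run_posthoc=False)
        hits += res.p <= 0.05
    return 100.0 * hits / n_replicates
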