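"""Higuchi fractal dimension and plateau-based k_max selection.

The Higuchi estimator measures the fractal dimension of a time-series graph
(1 = smooth curve, 2 = plane-filling; white noise is near 2, fBm with Hurst
index H sits at 2 - H).  For each coarsening scale k it forms k decimated
curve lengths

    L_m(k) = [ sum_{i=1..n} |x(m + i k) - x(m + (i-1) k)| ] * (N - 1) / (n k)
             / k,        n = floor((N - m) / k),  m = 1..k  (1-based),

averages them to L(k), and reads the dimension off the log-log slope:
FD = -slope of the least-squares fit of ln L(k) on ln k over k = 1..k_max.

``select_kmax`` implements a two-stage choice of the tuning parameter:
first the start of the plateau of the grand-average FD-vs-k curve
(consecutive absolute percentage change persistently below a threshold,
default 0.05 %), then, within the plateau, the k maximising the summed
pairwise distance between group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Recording, segment
from .montage import ClusterMap

__all__ = ["HfdEstimate", "KmaxSelection", "PlateauNotFoundError",
           "higuchi_fd", "hfd_table", "hfd_sweep", "select_kmax"]


class PlateauNotFoundError(RuntimeError):
    """No k satisfies the persistent-plateau condition up to search_hi."""


@dataclass
class HfdEstimate:
    kmax: int
    fd: float
    fit_r2: float
    subject_id: str = ""
    scope: str = ""


def _curve_lengths(x: np.ndarray, k_hi: int) -> np.ndarray:
    """L(k) for k = 1..k_hi; rows of ``x`` are independent series.

    For each k the lag-k absolute increments are binned by start offset m by
    zero-padding to a multiple of k and reshaping, so the whole computation
    is O(N * k_hi) in vectorised numpy.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    r, n = x.shape
    out = np.empty((r, k_hi))
    for k in range(1, k_hi + 1):
        d = np.abs(x[:, k:] - x[:, :-k])  # d[:, j] belongs to offset m = j % k
        pad = (-d.shape[1]) % k
        if pad:
            d = np.pad(d, ((0, 0), (0, pad)))
        class_sums = d.reshape(r, -1, k).sum(axis=1)
        m = np.arange(k)
        n_incr = (n - 1 - m) // k
        out[:, k - 1] = (class_sums * (n - 1) / (n_incr * k * k)).mean(axis=1)
    return out


def _fd_r2_from_lengths(lengths: np.ndarray, kmax: int) -> tuple[float, float]:
    k = np.arange(1, kmax + 1)
    mask = lengths[:kmax] > 0
    if mask.sum() < 2:
        raise ValueError("curve lengths vanish: fractal dimension undefined "
                         "(constant or degenerate series)")
    lx, ly = np.log(k[mask]), np.log(lengths[:kmax][mask])
    p = mask.sum()
    sxx = p * (lx ** 2).sum() - lx.sum() ** 2
    sxy = p * (lx * ly).sum() - lx.sum() * ly.sum()
    syy = p * (ly ** 2).sum() - ly.sum() ** 2
    slope = sxy / sxx
    r2 = (sxy ** 2 / (sxx * syy)) if syy > 0 else 1.0
    return -slope, float(r2)


def higuchi_fd(x: np.ndarray, kmax: int) -> HfdEstimate:
    """Higuchi fractal dimension of one series at a fixed ``kmax``.

    Requires ``len(x) >= 3 * kmax`` so every scale has at least two
    increments per offset.
    """
    x = np.asarray(x, dtype=float).ravel()
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if len(x) < 3 * kmax:
        raise ValueError(f"series of length {len(x)} too short for kmax={kmax} "
                         "(need N >= 3 kmax)")
    lengths = _curve_lengths(x, kmax)[0]
    fd, r2 = _fd_r2_from_lengths(lengths, kmax)
    return HfdEstimate(kmax=kmax, fd=float(fd), fit_r2=r2)


def _fd_curves(x: np.ndarray, k_lo: int, k_hi: int) -> np.ndarray:
    """FD at every kmax in [k_lo, k_hi] for each row of ``x`` (prefix OLS)."""
    lengths = _curve_lengths(x, k_hi)
    if np.any(lengths <= 0):
        raise ValueError("curve lengths vanish: fractal dimension undefined")
    lx = np.log(np.arange(1, k_hi + 1))
    ly = np.log(lengths)
    p = np.arange(1, k_hi + 1, dtype=float)
    cx, cxx = np.cumsum(lx), np.cumsum(lx ** 2)
    cy = np.cumsum(ly, axis=1)
    cxy = np.cumsum(lx * ly, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (p * cxy - cx * cy) / (p * cxx - cx ** 2)  # prefix p=1 is nan
    return -slope[:, k_lo - 1:k_hi]


def _subject_channel_series(rec: Recording, epoch_len_s: float | None) -> np.ndarray:
    """Stack of series to analyse: one row per (channel, epoch) or channel."""
    if epoch_len_s is None:
        return rec.data
    eps = segment(rec, epoch_len_s)
    return np.concatenate([e for e in eps.epochs], axis=0)


def hfd_table(recordings: list[Recording], clusters: ClusterMap | None = None,
              kmax: int = 82, epoch_len_s: float | None = 4.0) -> pd.DataFrame:
    """Per-subject HFD at channel, cluster and global scope.

    With ``epoch_len_s`` set, the FD is computed per non-overlapping epoch
    and averaged per channel; with ``None`` it is computed on the whole
    series.  Cluster and global values are means over member channels.
    """
    rows = []
    for rec in recordings:
        series = _subject_channel_series(rec, epoch_len_s)
        n_rep = series.shape[0] // rec.n_channels
        fds = _fd_curves(series, kmax, kmax)[:, 0]
        per_chan = fds.reshape(n_rep, rec.n_channels).mean(axis=0)
        by_chan = dict(zip(rec.channels, per_chan))
        for ch, fd in by_chan.items():
            rows.append({"subject_id": rec.subject_id, "group": rec.group,
                         "scope": f"channel:{ch}", "kmax": kmax, "fd": float(fd)})
        try:
            cmap = (clusters or ClusterMap.default()).restrict(rec.channels)
            cluster_items = list(cmap.clusters.items())
        except ValueError:  # montage shares no channel with the cluster map
            cluster_items = []
        for cname, members in cluster_items:
            rows.append({"subject_id": rec.subject_id, "group": rec.group,
                         "scope": f"cluster:{cname}", "kmax": kmax,
                         "fd": float(np.mean([by_chan[ch] for ch in members]))})
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "scope": "global", "kmax": kmax,
                     "fd": float(per_chan.mean())})
    return pd.DataFrame(rows)


def hfd_sweep(recordings: list[Recording], k_lo: int = 2, k_hi: int = 100,
              epoch_len_s: float | None = 4.0,
              ) -> tuple[dict[str, np.ndarray], np.ndarray, pd.DataFrame]:
    """Global-mean HFD as a function of kmax, per group.

    Returns ``(curves, k_grid, subject_curves)``: per-group mean curves over
    the integer grid ``k_lo..k_hi``, the grid itself, and a tidy per-subject
    table of global FD per k.
    """
    k_grid = np.arange(k_lo, k_hi + 1)
    per_subject: list[dict] = []
    for rec in recordings:
        series = _subject_channel_series(rec, epoch_len_s)
        curves = _fd_curves(series, k_lo, k_hi)
        per_subject.append({"subject_id": rec.subject_id, "group": rec.group,
                            "curve": curves.mean(axis=0)})
    rows = [
        {"subject_id": s["subject_id"], "group": s["group"], "k": int(k),
         "fd": float(v)}
        for s in per_subject for k, v in zip(k_grid, s["curve"])
    ]
    groups = sorted({s["group"] for s in per_subject}, key=str)
    curves = {
        g: np.mean([s["curve"] for s in per_subject if s["group"] == g], axis=0)
        for g in groups
    }
    return curves, k_grid, pd.DataFrame(rows)


@dataclass
class KmaxSelection:
    """Outcome of the two-stage k_max choice."""

    k_grid: np.ndarray
    pct_change: np.ndarray  # aligned with k_grid[1:]
    threshold_pct: float
    first_minimum_k: int
    plateau_start_k: int
    search_hi_k: int
    distance_sum: dict[int, float]
    selected_kmax: int

    def to_dict(self) -> dict:
        return {
            "threshold_pct": self.threshold_pct,
            "first_minimum_k": self.first_minimum_k,
            "plateau_start_k": self.plateau_start_k,
            "search_hi_k": self.search_hi_k,
            "selected_kmax": self.selected_kmax,
            "distance_sum": {int(k): float(v) for k, v in self.distance_sum.items()},
        }


def select_kmax(curves: dict[str, np.ndarray], k_grid: np.ndarray,
                threshold_pct: float = 0.05, search_hi: int = 100,
                group_weights: dict[str, float] | None = None) -> KmaxSelection:
    """Two-stage k_max selection from per-group mean HFD curves.

    Stage 1 (plateau): the grand-average curve g(k) (unweighted mean of the
    group curves unless ``group_weights`` is given) is scanned for the
    smallest k* from which the consecutive absolute percentage change
    ``100 |g(k) - g(k-1)| / |g(k-1)|`` stays below ``threshold_pct`` all the
    way to ``search_hi``.  The first k whose change dips below the threshold
    is also reported (it may be transient and is never used for selection).

    Stage 2 (discrimination): within ``[k*, search_hi]`` the selected k_max
    maximises ``D(k) = sum over unordered group pairs |m_a(k) - m_b(k)|``;
    ties resolve to the smallest k.

    The percentage change is indexed on the curve grid from its second point
    onward (each value needs a predecessor).
    """
    if len(curves) < 2:
        raise ValueError("need at least two group curves")
    k_grid = np.asarray(k_grid)
    if k_grid[-1] < search_hi:
        raise ValueError(f"k grid ends at {k_grid[-1]}, below search_hi={search_hi}")
    lens = {len(c) for c in curves.values()}
    if lens != {len(k_grid)}:
        raise ValueError("all group curves must share the k grid")

    names = sorted(curves, key=str)
    mat = np.vstack([curves[g] for g in names])
    if group_weights is None:
        g = mat.mean(axis=0)
    else:
        w = np.array([group_weights[n] for n in names], dtype=float)
        g = (w[:, None] * mat).sum(axis=0) / w.sum()

    prev = np.abs(g[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(prev > 0, 100.0 * np.abs(np.diff(g)) / prev, np.inf)
    pct_k = k_grid[1:]

    hi_idx = int(np.searchsorted(pct_k, search_hi, side="right")) - 1
    if hi_idx < 0 or pct_k[hi_idx] != search_hi:
        raise ValueError(f"search_hi={search_hi} not on the k grid")

    below = pct[:hi_idx + 1] < threshold_pct
    if not below.any():
        raise PlateauNotFoundError(
            f"no percentage change below {threshold_pct}% up to k={search_hi}")
    first_minimum_k = int(pct_k[int(np.argmax(below))])

    # smallest k* with pct < threshold everywhere on [k*, search_hi]
    ok_suffix = np.flip(np.cumprod(np.flip(below))).astype(bool)
    if not ok_suffix.any():
        raise PlateauNotFoundError(
            f"percentage change re-exceeds {threshold_pct}% at k="
            f"{int(pct_k[hi_idx])}; no persistent plateau up to {search_hi}")
    plateau_start_k = int(pct_k[int(np.argmax(ok_suffix))])

    sel = (k_grid >= plateau_start_k) & (k_grid <= search_hi)
    ks = k_grid[sel]
    sub = mat[:, sel]
    dsum = np.zeros(len(ks))
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            dsum += np.abs(sub[a] - sub[b])
    selected = int(ks[int(np.argmax(dsum))])
    return KmaxSelection(
        k_grid=k_grid, pct_change=pct, threshold_pct=threshold_pct,
        first_minimum_k=first_minimum_k, plateau_start_k=plateau_start_k,
        search_hi_k=search_hi,
        distance_sum={int(k): float(v) for k, v in zip(ks, dsum)},
        selected_kmax=selected,
    )
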