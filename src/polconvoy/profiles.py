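"""Occupancy-profile analytics: normalization, smoothing, extrema, metaplots.

These routines apply equally to simulated occupancy profiles and to
external per-nucleotide polymerase tracks (CRAC- or NET-seq-style 3'-end
densities): read counts are converted to fractions with a pseudocount,
smoothed with a centered Blackman window, local extrema are called with a
configurable neighborhood order, and feature-centered metaplots,
autocorrelation periodicity and randomization controls quantify the
structure of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .observe import Profile

PSEUDOCOUNT = 1e-7


@dataclass
class FeatureSet:
    """Called extrema of one kind (positions strictly increasing)."""

    kind: str  # "peak" | "trough"
    positions: np.ndarray
    order: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        if self.kind not in ("peak", "trough"):
            raise ValueError("kind must be 'peak' or 'trough'")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class Metaplot:
    """Feature-aligned mean signal over offsets -w..+w."""

    offsets: np.ndarray
    mean_signal: np.ndarray
    n_features: int


def normalize_to_fraction(counts: np.ndarray) -> Profile:
    """Fraction-of-reads profile with a 1e-7 pseudocount at every position."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero counts cannot be normalized")
    return Profile(counts / total + PSEUDOCOUNT, normalized=False)


def smooth_blackman(profile: Profile | np.ndarray, window: int = 10) -> Profile:
    """Centered Blackman-weighted moving average with reflection padding."""
    values = profile.values if isinstance(profile, Profile) else np.asarray(profile, float)
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > len(values):
        raise ValueError("window longer than the profile")
    kernel = np.blackman(window)
    kernel = kernel / kernel.sum()
    pad = window  # enough for either parity
    padded = np.pad(values, pad, mode="reflect")
    sm = np.convolve(padded, kernel, mode="same")[pad:-pad]
    return Profile(np.clip(sm, 0.0, None))


def _extrema_positions(values: np.ndarray, order: int, sign: int) -> np.ndarray:
    """Strict local extrema within +/-order, leftmost point of plateaus.

    Comparisons use clipped indices, so sequence boundaries never qualify
    (a boundary position would be compared with itself).  A plateau (run of
    equal values) is reported at its leftmost point iff the run strictly
    dominates every non-run value within the order window of each run
    member.
    """
    v = sign * values
    n = len(v)
    if n == 0:
        return np.array([], dtype=int)
    idx = np.arange(n)
    strict = np.ones(n, dtype=bool)
    for d in range(1, order + 1):
        left = v[np.clip(idx - d, 0, n - 1)]
        right = v[np.clip(idx + d, 0, n - 1)]
        strict &= (v > left) & (v > right)
    out = list(np.nonzero(strict)[0])
    # plateau rule: leftmost of a dominating run of equal values
    cand = np.nonzero(~strict)[0]
    runs_checked = set()
    for i in cand:
        if i in runs_checked:
            continue
        # run of equal values starting at i
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        runs_checked.update(range(i, j + 1))
        if j == i:
            continue
        lo = max(0, i - order)
        hi = min(n - 1, j + order)
        window = np.concatenate([v[lo:i], v[j + 1 : hi + 1]])
        if window.size and np.all(v[i] > window) and i > 0 and j < n - 1:
            out.append(i)
    return np.array(sorted(out), dtype=int)


def call_extrema(
    profile: Profile | np.ndarray, order: int = 35
) -> tuple[FeatureSet, FeatureSet]:
    """Peaks and troughs: strict local extrema within a +/-order window.

    Typical orders: 50 for comparisons between experiments, 35 against
    folding energy, 20 for GC analyses.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    values = profile.values if isinstance(profile, Profile) else np.asarray(profile, float)
    peaks = FeatureSet("peak", _extrema_positions(values, order, +1), order)
    troughs = FeatureSet("trough", _extrema_positions(values, order, -1), order)
    return peaks, troughs


def metaplot(
    signal: np.ndarray | Profile,
    features: FeatureSet | Sequence[int],
    half_window: int = 200,
    per_window_normalize: bool = False,
) -> Metaplot:
    """Mean signal over feature-centered windows, per offset.

    Windows truncated at sequence boundaries contribute only their defined
    offsets.  With ``per_window_normalize`` each window is first converted
    to its fraction-of-window signal (used when absolute levels differ
    between transcripts).  NaN signal values are ignored.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    values = signal.values if isinstance(signal, Profile) else np.asarray(signal, float)
    positions = features.positions if isinstance(features, FeatureSet) else np.asarray(features, int)
    if len(positions) == 0:
        raise ValueError("empty feature set")
    n = len(values)
    width = 2 * half_window + 1
    acc = np.zeros(width)
    cnt = np.zeros(width)
    for p in positions:
        lo = max(0, p - half_window)
        hi = min(n, p + half_window + 1)
        win = values[lo:hi].astype(float)
        if per_window_normalize:
            total = np.nansum(win)
            if total > 0:
                win = win / total
        off = lo - (p - half_window)
        finite = np.isfinite(win)
        acc[off : off + len(win)][finite] += win[finite]
        cnt[off : off + len(win)][finite] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    return Metaplot(
        offsets=np.arange(-half_window, half_window + 1),
        mean_signal=mean,
        n_features=len(positions),
    )


def autocorrelation(
    profile: Profile | np.ndarray, max_lag: int = 400
) -> tuple[np.ndarray, Optional[int]]:
    """Mean-subtracted normalized autocorrelation and dominant spacing.

    Returns the lag curve (lag 0..max_lag, value 1 at lag 0) and the lag of
    the first local maximum at positive lag (None for signals without one).
    Constant profiles have undefined correlation and raise ValueError.
    """
    values = profile.values if isinstance(profile, Profile) else np.asarray(profile, float)
    n = len(values)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the profile length")
    x = values - values.mean()
    denom = np.dot(x, x)
    if denom == 0:
        raise ValueError("constant profile: autocorrelation undefined")
    acf = np.array([np.dot(x[: n - k], x[k:]) / denom for k in range(max_lag + 1)])
    dominant = None
    for k in range(1, max_lag):
        if acf[k] > acf[k - 1] and acf[k] >= acf[k + 1]:
            dominant = k
            break
    return acf, dominant


def bartlett_band(n: int) -> float:
    """White-noise significance band for autocorrelation magnitudes."""
    return 4.0 / np.sqrt(n)


def shuffle_control(counts: np.ndarray, seed: int = 0, smooth_window: int = 10) -> Profile:
    """Randomization control: permute raw read positions, reprocess identically.

    The read multiset is preserved (total count conserved); the permuted
    counts go through the same fraction + smoothing pipeline as the data.
    """
    counts = np.asarray(counts)
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(counts)
    return smooth_blackman(normalize_to_fraction(shuffled), smooth_window)


def spearman(profile_a: Profile | np.ndarray, profile_b: Profile | np.ndarray) -> float:
    """Spearman rank correlation between two profiles."""
    a = profile_a.values if isinstance(profile_a, Profile) else np.asarray(profile_a)
    b = profile_b.values if isinstance(profile_b, Profile) else np.asarray(profile_b)
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def rank_tests(
    x: np.ndarray, y: np.ndarray, kind: str = "rank_sum"
) -> tuple[float, float]:
    """Two-sided tests used throughout the profile comparisons.

    ``rank_sum`` — Wilcoxon rank-sum (Mann-Whitney U; exact enumeration for
    n <= 20 without ties, normal approximation with continuity correction
    otherwise); ``signed_rank`` — Wilcoxon signed-rank on paired samples;
    ``t_two_sided`` — Student's t.  Returns (statistic, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if kind == "rank_sum":
        method = "exact" if max(len(x), len(y)) <= 20 else "asymptotic"
        try:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        except ValueError:  # ties with exact method
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if kind == "signed_rank":
        if len(x) != len(y):
            raise ValueError("signed_rank requires paired samples")
        d = x - y
        if np.all(d == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if kind == "t_two_sided":
        res = stats.ttest_ind(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")
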