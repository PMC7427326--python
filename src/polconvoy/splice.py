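"""De-novo intron prediction and the 3' splice-site window-of-opportunity.

Yeast introns are defined by three short signals: a donor (5'SS) consensus
at the intron start, a branch-point (BP) heptamer, and a minimal acceptor
``AG``.  Prediction proceeds BP-first: every BP hit is extended upstream to
the nearest non-overlapping donor and downstream to the first acceptor at
least ``min_bp_to_3ss`` nt past the BP.  Acceptors upstream of an annotated
3'SS but far enough from it (``min_skip_separation``) are candidate
"predicted but skipped" sites; the folding of the nascent transcript just
downstream of a site (ΔΔG relative to the site) measures how quickly the
polymerase is pushed on, i.e. how short the kinetic window for recognizing
that acceptor is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .energy import EnergyTrack
from .profiles import rank_tests


@dataclass
class SpliceConfig:
    """Consensus motifs and distance rules for intron calling."""

    five_ss_motif: str = "GTATGT"
    bp_motif: str = "TACTAAC"
    acceptor_motif: str = "AG"
    max_intron_len: int = 1000
    min_bp_to_3ss: int = 4
    min_skip_separation: int = 40

    def __post_init__(self) -> None:
        if not (self.five_ss_motif and self.bp_motif and self.acceptor_motif):
            raise ValueError("motifs must be non-empty")
        if self.min_bp_to_3ss < 0:
            raise ValueError("min_bp_to_3ss must be >= 0")


@dataclass
class IntronCall:
    """One predicted intron; coordinates are 0-based motif starts/ends.

    ``three_ss`` is the first nucleotide of the acceptor dinucleotide;
    ``bp_end`` the last nucleotide of the branch-point motif.
    """

    five_ss: int
    bp_start: int
    bp_end: int
    three_ss: int
    skipped_candidates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.five_ss < self.bp_start <= self.bp_end < self.three_ss:
            raise ValueError("intron coordinates out of order")


def _find_all(seq: str, motif: str) -> list[int]:
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(start)
        start = seq.find(motif, start + 1)
    return hits


def predict_introns(seq: str, config: Optional[SpliceConfig] = None) -> list[IntronCall]:
    """BP-first three-step intron prediction.

    For every branch-point hit: the nearest upstream donor that does not
    overlap the BP, then the first acceptor at least ``min_bp_to_3ss`` nt
    downstream of the BP's last nucleotide.  Calls longer than
    ``max_intron_len`` (donor start to acceptor end) are dropped.
    """
    config = config or SpliceConfig()
    s = seq.upper()
    donors = _find_all(s, config.five_ss_motif)
    calls = []
    for bp_start in _find_all(s, config.bp_motif):
        bp_end = bp_start + len(config.bp_motif) - 1
        upstream = [d for d in donors if d + len(config.five_ss_motif) <= bp_start]
        if not upstream:
            continue
        five_ss = max(upstream)
        acc = s.find(config.acceptor_motif, bp_end + config.min_bp_to_3ss)
        if acc == -1:
            continue
        intron_len = acc + len(config.acceptor_motif) - five_ss
        if intron_len > config.max_intron_len:
            continue
        calls.append(IntronCall(five_ss, bp_start, bp_end, acc))
    return calls


def find_skipped_acceptors(
    call: IntronCall, seq: str, config: Optional[SpliceConfig] = None
) -> IntronCall:
    """Record upstream consensus acceptors far enough from the used 3'SS.

    Candidates lie between ``bp_end + min_bp_to_3ss`` and
    ``three_ss - min_skip_separation`` (inclusive of the former bound).
    """
    config = config or SpliceConfig()
    s = seq.upper()
    lo = call.bp_end + config.min_bp_to_3ss
    hi = call.three_ss - config.min_skip_separation
    candidates = [
        a
        for a in _find_all(s, config.acceptor_motif)
        if lo <= a <= hi and a != call.three_ss
    ]
    return replace(call, skipped_candidates=candidates)


def ddg_profile(track: EnergyTrack, ss_pos: int, span: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Folding-energy change relative to a splice site.

    ``ΔΔG(x) = ΔG(ss_pos + x) − ΔG(ss_pos)`` for x in [-span, +span].
    Returns ``(offsets, ddg)``; offsets whose track position is undefined
    or out of bounds carry NaN (truncation is thereby reported).  The track
    must be defined at ``ss_pos`` itself.
    """
    values = track.values
    if not (0 <= ss_pos < len(values)) or np.isnan(values[ss_pos]):
        raise ValueError("track undefined at the splice-site position")
    offsets = np.arange(-span, span + 1)
    ddg = np.full(offsets.shape, np.nan)
    for k, x in enumerate(offsets):
        p = ss_pos + x
        if 0 <= p < len(values):
            ddg[k] = values[p] - values[ss_pos]
    return offsets, ddg


def window_mean_ddg(
    offsets: np.ndarray,
    ddg: np.ndarray,
    window_center: int = 60,
    window_half: int = 10,
) -> float:
    """Mean ΔΔG in the +/-window_half window around ``window_center``."""
    mask = np.abs(offsets - window_center) <= window_half
    vals = ddg[mask]
    if np.all(np.isnan(vals)):
        raise ValueError("window entirely undefined")
    return float(np.nanmean(vals))


def compare_site_classes(
    ddg_curves_a: Sequence[tuple[np.ndarray, np.ndarray]],
    ddg_curves_b: Sequence[tuple[np.ndarray, np.ndarray]],
    window_center: int = 60,
    window_half: int = 10,
) -> tuple[float, float]:
    """Rank-sum test on per-curve mean ΔΔG downstream of two site classes.

    Each class is a list of ``(offsets, ddg)`` curves; the statistic
    compares the per-curve means within +/-``window_half`` nt around
    ``window_center`` nt downstream of the site.
    """
    if len(ddg_curves_a) < 2 or len(ddg_curves_b) < 2:
        raise ValueError("need at least two curves per class")
    means_a = [window_mean_ddg(o, d, window_center, window_half) for o, d in ddg_curves_a]
    means_b = [window_mean_ddg(o, d, window_center, window_half) for o, d in ddg_curves_b]
    return rank_tests(np.array(means_a), np.array(means_b), kind="rank_sum")
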