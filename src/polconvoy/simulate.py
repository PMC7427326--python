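"""Discrete-time stochastic simulation of polymerase convoys.

Each polymerase draws an independent velocity every time step from a
two-component Gaussian mixture (active elongation vs. paused), modified by

* torsional coupling to its neighbours — DNA between two enzymes behaves as
  an elastic rod, so deviations of the current separations from the
  separations recorded at engagement generate restoring velocity terms;
* a low-entrainment region (LER) over the first ~2 kb where polymerases can
  still rotate around the template: torsion engages linearly with position,
  anchors relax toward current geometry, and a small friction penalty
  applies to the intrinsic velocity;
* nascent-RNA elements — strong structure (ΔG at or below a threshold)
  behind the enzyme promotes forward translocation, the RNA:DNA hybrid in
  the bubble opposes it.

The signed velocity sets the probability ``min(1, |V| dt)`` of a 1-nt jump
in the direction of its sign.  Jumps violating the hard-core footprint
exclusion are blocked (forward blocks are logged as collisions); successful
backward jumps are logged as backtrack steps.  Initiation is a stochastic
process gated by clearance of the promoter-proximal initiation region.

:class:`Convoy` is the readable reference implementation of one unit;
:func:`run_replicates` drives a numba-compiled kernel with identical
update rules for production-scale ensembles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .params import ModelParams
from .energy import EnergyTrack


# ---------------------------------------------------------------------------
# landscape

@dataclass
class EnergyLandscape:
    """Per-nucleotide folding and hybrid ΔG tracks for one unit."""

    dg_struct: np.ndarray
    dg_hybrid: np.ndarray

    def __post_init__(self) -> None:
        self.dg_struct = np.asarray(self.dg_struct, dtype=float)
        self.dg_hybrid = np.asarray(self.dg_hybrid, dtype=float)
        if self.dg_struct.shape != self.dg_hybrid.shape:
            raise ValueError("track lengths differ")

    def __len__(self) -> int:
        return len(self.dg_struct)

    @classmethod
    def flat(cls, length: int) -> "EnergyLandscape":
        return cls(np.zeros(length), np.zeros(length))

    @classmethod
    def from_tracks(
        cls, struct: EnergyTrack, hybrid: Optional[EnergyTrack] = None
    ) -> "EnergyLandscape":
        dg_h = hybrid.values if hybrid is not None else np.zeros(len(struct))
        return cls(struct.values, dg_h)

    def copy(self) -> "EnergyLandscape":
        return EnergyLandscape(self.dg_struct.copy(), self.dg_hybrid.copy())


# ---------------------------------------------------------------------------
# elementary terms (unit-testable contracts; the kernel replicates them)

def sample_velocity(
    params: ModelParams,
    rng: np.random.Generator,
    size=None,
    with_labels: bool = False,
):
    """Velocity draw(s) from the paused/elongating Gaussian mixture (nt/s).

    With ``with_labels`` also returns the boolean mask of draws routed to
    the paused component.
    """
    n = 1 if size is None else size
    paused = rng.random(n) < params.p_pause
    v = np.where(
        paused,
        rng.normal(params.v_pause_mean, params.v_pause_sd, n),
        rng.normal(params.v_int, params.sigma_rel * params.v_int, n),
    )
    if size is None:
        return (float(v[0]), bool(paused[0])) if with_labels else float(v[0])
    return (v, paused) if with_labels else v


def torsion_term(
    dxp: Optional[float],
    dxm: Optional[float],
    xp_init: Optional[float],
    xm_init: Optional[float],
    c_eff: float,
    b: float,
    cap: float = math.inf,
) -> float:
    """Torsional velocity contribution from both neighbours (nt/s).

    ``c_eff*(1 - (xp_init-b)/(dxp-b)) - c_eff*(1 - (xm_init-b)/(dxm-b))``;
    a term is zero when the corresponding neighbour is absent (``None``).
    Gaps at or below the bubble length would diverge; the magnitude of each
    term is capped at ``cap``.
    """

    def one_side(dx, x_init):
        if dx is None or x_init is None:
            return 0.0
        gap = dx - b
        if gap <= 0:
            # compressed to (or past) the bubble: the term diverges to -inf
            return -cap if x_init > b else cap
        t = c_eff * (1.0 - (x_init - b) / gap)
        return max(-cap, min(cap, t))

    return one_side(dxp, xp_init) - one_side(dxm, xm_init)


def ler_engagement(pos: float, ler_end: float) -> float:
    """Linear torsional engagement over the low-entrainment region."""
    if ler_end <= 0:
        return 1.0
    return min(1.0, max(0.0, pos) / ler_end)


def rna_element_term(
    dg_struct: float,
    dg_hybrid: float,
    s_struct: float,
    s_hybrid: float,
    dg_threshold: float,
) -> float:
    """Velocity modifier from nascent-RNA elements (nt/s).

    Structure at or below the folding-energy threshold promotes forward
    motion with weight ``s_struct``; the hybrid always opposes it with
    weight ``s_hybrid``.  Magnitudes of ΔG are used; undefined (NaN) track
    values contribute nothing.
    """
    term = 0.0
    if not math.isnan(dg_struct) and dg_struct <= dg_threshold:
        term += s_struct * abs(dg_struct)
    if not math.isnan(dg_hybrid):
        term -= s_hybrid * abs(dg_hybrid)
    return term


def initiation_allowed(positions: Sequence[float], footprint: float) -> bool:
    """Engagement at the promoter requires the initiation region clear."""
    return all(p >= footprint for p in positions)


def _precompute_modifiers(landscape: EnergyLandscape, params: ModelParams):
    """Per-nucleotide forward boost and drag magnitudes (NaN-safe)."""
    dg_s = landscape.dg_struct
    dg_h = landscape.dg_hybrid
    boost = np.where(
        (~np.isnan(dg_s)) & (dg_s <= params.dg_threshold),
        params.s_struct * np.abs(dg_s),
        0.0,
    )
    drag = np.where(~np.isnan(dg_h), params.s_hybrid * np.abs(dg_h), 0.0)
    return boost.astype(np.float64), drag.astype(np.float64)


# ---------------------------------------------------------------------------
# reference implementation

class Convoy:
    """One transcription unit with explicit polymerase state (reference).

    Positions are kept strictly increasing along the template; index 0 is
    the most promoter-proximal enzyme.  ``frozen`` holds positions of
    enzymes immobilized for testing.
    """

    def __init__(
        self,
        landscape: EnergyLandscape,
        params: ModelParams,
        rng: Optional[np.random.Generator] = None,
    ):
        self.landscape = landscape
        self.params = params
        self.rng = rng or np.random.default_rng(params.seed)
        self.pos: list[int] = []
        self.max_pos: list[int] = []
        self.xp_init: list[float] = []  # anchor to downstream neighbour
        self.xm_init: list[float] = []  # anchor to upstream neighbour
        self.frozen: set[int] = set()   # indices that never move (test hook)
        self.events = {
            "backtrack_steps": 0,
            "blocked_collisions": 0,
            "runoff_terminations": 0,
            "premature_terminations": 0,
        }
        self._boost, self._drag = _precompute_modifiers(landscape, params)

    @property
    def n(self) -> int:
        return len(self.pos)

    def place(self, positions: Sequence[int]) -> None:
        """Seed polymerases at given (sorted, non-conflicting) positions."""
        positions = sorted(int(p) for p in positions)
        fp = self.params.footprint
        for a, b in zip(positions, positions[1:]):
            if b - a < fp:
                raise ValueError("placed polymerases violate the footprint")
        self.pos = list(positions)
        self.max_pos = list(positions)
        self.xp_init = [
            float(positions[i + 1] - positions[i]) if i + 1 < len(positions) else math.nan
            for i in range(len(positions))
        ]
        self.xm_init = [
            float(positions[i] - positions[i - 1]) if i > 0 else math.nan
            for i in range(len(positions))
        ]

    def attempt_initiation(self) -> bool:
        """Stochastic engagement at position 0, gated by a clear initiation region."""
        p = self.params
        if self.rng.random() >= p.add_prob * p.dt:
            return False
        if self.pos and self.pos[0] < p.init_region:
            return False
        gap = float(self.pos[0]) if self.pos else math.nan
        self.pos.insert(0, 0)
        self.max_pos.insert(0, 0)
        self.xp_init.insert(0, gap)
        self.xm_init.insert(0, math.nan)
        if self.n > 1:
            self.xm_init[1] = gap
        return True

    def _velocity(self, i: int) -> tuple[float, float, float, float]:
        p = self.params
        pos = self.pos[i]
        eng = ler_engagement(pos, p.ler_end) if p.ler_on else 1.0
        vscale = (1.0 - p.ler_velocity_penalty * eng) if p.ler_on else 1.0
        v_rand = sample_velocity(p, self.rng)
        tors = 0.0
        if p.torsion_on and self.n > 1:
            dxp = float(self.pos[i + 1] - pos) if i + 1 < self.n else None
            dxm = float(pos - self.pos[i - 1]) if i > 0 else None
            xp = self.xp_init[i] if dxp is not None and not math.isnan(self.xp_init[i]) else None
            xm = self.xm_init[i] if dxm is not None and not math.isnan(self.xm_init[i]) else None
            cap = p.torsion_cap_factor * p.v_int
            tors = eng * torsion_term(dxp, dxm, xp, xm, p.c_stiff, p.bubble_b, cap)
        rna = 0.0
        if p.rna_elements_on:
            rna = self._boost[pos] - self._drag[pos]
        return v_rand * vscale + tors + rna, tors, eng, v_rand

    def step(self) -> None:
        """Advance the whole unit by one time step ``dt``."""
        p = self.params
        to_remove: set[int] = set()
        order = self.rng.permutation(self.n) if self.n else []
        for i in order:
            if i in to_remove or self.pos[i] in self.frozen:
                continue
            v, tors, eng, _ = self._velocity(i)
            jump_p = min(1.0, abs(v) * p.dt)
            if self.rng.random() < jump_p:
                if v > 0:
                    nxt = self.pos[i] + 1
                    if i + 1 < self.n and self.pos[i + 1] - nxt < p.footprint:
                        self.events["blocked_collisions"] += 1
                    else:
                        self.pos[i] = nxt
                        self.max_pos[i] = max(self.max_pos[i], nxt)
                        if nxt >= p.unit_length:
                            self.events["runoff_terminations"] += 1
                            to_remove.add(i)
                elif v < 0:
                    nxt = self.pos[i] - 1
                    ok = nxt >= 0 and (i == 0 or nxt - self.pos[i - 1] >= p.footprint)
                    if ok:
                        self.pos[i] = nxt
                        self.events["backtrack_steps"] += 1
            # LER anchor relaxation toward current geometry
            if p.ler_on and p.torsion_on and eng < 1.0 and i not in to_remove:
                w = (1.0 - eng) * p.dt
                if i + 1 < self.n and not math.isnan(self.xp_init[i]):
                    dxp = self.pos[i + 1] - self.pos[i]
                    self.xp_init[i] += (dxp - self.xp_init[i]) * w
                if i > 0 and not math.isnan(self.xm_init[i]):
                    dxm = self.pos[i] - self.pos[i - 1]
                    self.xm_init[i] += (dxm - self.xm_init[i]) * w
            # optional Top1 full-turn relaxation
            if p.p_top1 > 0.0 and i not in to_remove:
                self._top1(i)
            # optional premature termination within the LER
            if p.p_term > 0.0 and self.pos[i] < p.ler_end and i not in to_remove:
                if self.rng.random() < p.p_term * p.dt:
                    self.events["premature_terminations"] += 1
                    to_remove.add(i)
        if to_remove:
            self._remove(sorted(to_remove, reverse=True))
        self.attempt_initiation()

    def _top1(self, i: int) -> None:
        p = self.params
        for attr, neighbour in (("xp_init", i + 1), ("xm_init", i - 1)):
            anchors = getattr(self, attr)
            if math.isnan(anchors[i]) or not (0 <= neighbour < self.n):
                continue
            gap = abs(self.pos[neighbour] - self.pos[i])
            if gap > p.top1_gap and abs(gap - anchors[i]) >= p.bp_per_turn:
                if self.rng.random() < p.p_top1 * p.dt:
                    anchors[i] += math.copysign(p.bp_per_turn, gap - anchors[i])

    def _remove(self, indices: list[int]) -> None:
        for i in indices:
            del self.pos[i], self.max_pos[i], self.xp_init[i], self.xm_init[i]
        # re-record anchors of the now-adjacent neighbours
        for i in range(self.n):
            self.xp_init[i] = (
                float(self.pos[i + 1] - self.pos[i]) if i + 1 < self.n else math.nan
            )
            self.xm_init[i] = (
                float(self.pos[i] - self.pos[i - 1]) if i > 0 else math.nan
            )

    def run(self, seconds: float) -> None:
        for _ in range(int(round(seconds / self.params.dt))):
            self.step()


# ---------------------------------------------------------------------------
# production kernel

@njit(cache=True)
def _simulate_kernel(
    seed,
    n_steps,
    snap_steps,
    L,
    dt,
    p_pause,
    v_pause_mean,
    v_pause_sd,
    v_int,
    sigma_rel,
    add_prob,
    init_region,
    c_stiff,
    bubble_b,
    footprint,
    ler_on,
    ler_end,
    ler_penalty,
    torsion_on,
    rna_on,
    boost,
    drag,
    cap,
    p_term,
    p_top1,
    top1_gap,
    bp_per_turn,
    maxp,
):  # pragma: no cover - exercised via run_replicates
    np.random.seed(seed)
    pos = np.zeros(maxp, dtype=np.int64)
    maxpos = np.zeros(maxp, dtype=np.int64)
    xp = np.full(maxp, np.nan)
    xm = np.full(maxp, np.nan)
    n = 0

    n_snaps = snap_steps.shape[0]
    snap_pos = np.full((n_snaps, maxp), -1, dtype=np.int64)
    snap_max = np.full((n_snaps, maxp), -1, dtype=np.int64)
    snap_n = np.zeros(n_snaps, dtype=np.int64)
    events = np.zeros(4, dtype=np.int64)  # backtrack, blocked, runoff, premature
    mod_sums = np.zeros((3, L))           # |struct|, |hybrid|, |torsion|
    visits = np.zeros(L, dtype=np.int64)
    pol_steps = 0

    order = np.empty(maxp, dtype=np.int64)
    remove = np.zeros(maxp, dtype=np.bool_)
    snap_i = 0

    sig_el = sigma_rel * v_int

    for step in range(n_steps):
        # random update order (Fisher-Yates)
        for i in range(n):
            order[i] = i
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            t = order[i]
            order[i] = order[j]
            order[j] = t
        any_remove = False
        for oi in range(n):
            i = order[oi]
            if remove[i]:
                continue
            pi = pos[i]
            # engagement and velocity scale
            if ler_on:
                eng = pi / ler_end
                if eng > 1.0:
                    eng = 1.0
                vscale = 1.0 - ler_penalty * eng
            else:
                eng = 1.0
                vscale = 1.0
            # mixture draw
            if np.random.random() < p_pause:
                v = np.random.normal(v_pause_mean, v_pause_sd)
            else:
                v = np.random.normal(v_int, sig_el)
            v *= vscale
            tors = 0.0
            if torsion_on:
                if i + 1 < n and not np.isnan(xp[i]):
                    gap = pos[i + 1] - pi - bubble_b
                    if gap <= 0.0:
                        t1 = -cap if xp[i] > bubble_b else cap
                    else:
                        t1 = c_stiff * (1.0 - (xp[i] - bubble_b) / gap)
                        if t1 > cap:
                            t1 = cap
                        elif t1 < -cap:
                            t1 = -cap
                    tors += t1
                if i > 0 and not np.isnan(xm[i]):
                    gap = pi - pos[i - 1] - bubble_b
                    if gap <= 0.0:
                        t2 = -cap if xm[i] > bubble_b else cap
                    else:
                        t2 = c_stiff * (1.0 - (xm[i] - bubble_b) / gap)
                        if t2 > cap:
                            t2 = cap
                        elif t2 < -cap:
                            t2 = -cap
                    tors -= t2
                tors *= eng
                v += tors
            if rna_on:
                v += boost[pi] - drag[pi]
                mod_sums[0, pi] += boost[pi]
                mod_sums[1, pi] += drag[pi]
            mod_sums[2, pi] += abs(tors)
            visits[pi] += 1
            pol_steps += 1
            # translocation attempt
            av = abs(v) * dt
            jp = av if av < 1.0 else 1.0
            if np.random.random() < jp:
                if v > 0.0:
                    nxt = pi + 1
                    if i + 1 < n and pos[i + 1] - nxt < footprint:
                        events[1] += 1
                    else:
                        pos[i] = nxt
                        if nxt > maxpos[i]:
                            maxpos[i] = nxt
                        if nxt >= L:
                            events[2] += 1
                            remove[i] = True
                            any_remove = True
                elif v < 0.0:
                    nxt = pi - 1
                    ok = nxt >= 0
                    if ok and i > 0 and nxt - pos[i - 1] < footprint:
                        ok = False
                    if ok:
                        pos[i] = nxt
                        events[0] += 1
            # LER anchor relaxation
            if ler_on and torsion_on and eng < 1.0 and not remove[i]:
                w = (1.0 - eng) * dt
                if i + 1 < n and not np.isnan(xp[i]):
                    xp[i] += (pos[i + 1] - pos[i] - xp[i]) * w
                if i > 0 and not np.isnan(xm[i]):
                    xm[i] += (pos[i] - pos[i - 1] - xm[i]) * w
            # optional Top1
            if p_top1 > 0.0 and not remove[i]:
                if i + 1 < n and not np.isnan(xp[i]):
                    gap = pos[i + 1] - pos[i]
                    d = gap - xp[i]
                    if gap > top1_gap and abs(d) >= bp_per_turn:
                        if np.random.random() < p_top1 * dt:
                            xp[i] += bp_per_turn if d > 0 else -bp_per_turn
                if i > 0 and not np.isnan(xm[i]):
                    gap = pos[i] - pos[i - 1]
                    d = gap - xm[i]
                    if gap > top1_gap and abs(d) >= bp_per_turn:
                        if np.random.random() < p_top1 * dt:
                            xm[i] += bp_per_turn if d > 0 else -bp_per_turn
            # optional premature termination in the LER
            if p_term > 0.0 and not remove[i] and pos[i] < ler_end:
                if np.random.random() < p_term * dt:
                    events[3] += 1
                    remove[i] = True
                    any_remove = True
        if any_remove:
            k = 0
            for i in range(n):
                if not remove[i]:
                    pos[k] = pos[i]
                    maxpos[k] = maxpos[i]
                    k += 1
                remove[i] = False
            n = k
            for i in range(n):
                xp[i] = pos[i + 1] - pos[i] if i + 1 < n else np.nan
                xm[i] = pos[i] - pos[i - 1] if i > 0 else np.nan
        # initiation
        if np.random.random() < add_prob * dt:
            if (n == 0 or pos[0] >= init_region) and n < maxp:
                for i in range(n, 0, -1):
                    pos[i] = pos[i - 1]
                    maxpos[i] = maxpos[i - 1]
                    xp[i] = xp[i - 1]
                    xm[i] = xm[i - 1]
                pos[0] = 0
                maxpos[0] = 0
                if n > 0:
                    xp[0] = pos[1]
                    xm[1] = pos[1]
                else:
                    xp[0] = np.nan
                xm[0] = np.nan
                n += 1
        # snapshot
        if snap_i < n_snaps and step == snap_steps[snap_i]:
            for i in range(n):
                snap_pos[snap_i, i] = pos[i]
                snap_max[snap_i, i] = maxpos[i]
            snap_n[snap_i] = n
            snap_i += 1

    return snap_pos, snap_max, snap_n, events, mod_sums, visits, pol_steps


# ---------------------------------------------------------------------------
# ensembles

@dataclass
class SimulationEnsemble:
    """Replicate trajectories plus event and modifier logs."""

    params: ModelParams
    snapshot_times: np.ndarray
    snap_pos: list          # per replicate: (n_snapshots, maxp) int64, -1 pad
    snap_max: list
    snap_n: list            # per replicate: (n_snapshots,) engaged counts
    events: dict
    modifier_sums: np.ndarray   # (3, L): |struct|, |hybrid|, |torsion|
    visit_counts: np.ndarray
    pol_steps: int

    @property
    def n_replicates(self) -> int:
        return len(self.snap_pos)

    def post_burn_in(self) -> np.ndarray:
        """Mask of snapshot indices after the burn-in period."""
        return self.snapshot_times >= self.params.burn_in

    def iter_snapshots(self, burn_in: bool = True):
        """Yield (positions, max_positions) per retained snapshot."""
        keep = self.post_burn_in() if burn_in else np.ones(
            len(self.snapshot_times), dtype=bool
        )
        for rep in range(self.n_replicates):
            sn = self.snap_n[rep]
            for s in np.nonzero(keep)[0]:
                k = sn[s]
                yield self.snap_pos[rep][s, :k], self.snap_max[rep][s, :k]

    def engaged_counts(self, burn_in: bool = True) -> np.ndarray:
        keep = self.post_burn_in() if burn_in else slice(None)
        return np.concatenate([sn[keep] for sn in self.snap_n])

    def mean_polymerase_count(self) -> float:
        return float(self.engaged_counts().mean())


def run_replicates(
    landscape: EnergyLandscape,
    params: ModelParams,
    n_replicates: int = 16,
    base_seed: Optional[int] = None,
) -> SimulationEnsemble:
    """Run independently seeded replicates and aggregate their logs."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(landscape) != params.unit_length:
        raise ValueError("landscape length must equal unit_length")
    base_seed = params.seed if base_seed is None else base_seed
    L = params.unit_length
    n_steps = int(round(params.total_time / params.dt))
    snap_steps = np.unique(
        np.round(
            (np.arange(1, params.n_snapshots + 1) / params.n_snapshots) * n_steps
        ).astype(np.int64)
        - 1
    )
    snapshot_times = (snap_steps + 1) * params.dt
    boost, drag = _precompute_modifiers(landscape, params)
    maxp = L // params.footprint + 2

    snap_pos, snap_max, snap_n = [], [], []
    events = np.zeros(4, dtype=np.int64)
    mod_sums = np.zeros((3, L))
    visits = np.zeros(L, dtype=np.int64)
    pol_steps = 0
    for rep in range(n_replicates):
        seed = int((base_seed + rep) % 2**31)
        sp, sm, sn, ev, ms, vi, ps = _simulate_kernel(
            seed,
            n_steps,
            snap_steps,
            L,
            params.dt,
            params.p_pause,
            params.v_pause_mean,
            params.v_pause_sd,
            params.v_int,
            params.sigma_rel,
            params.add_prob,
            params.init_region,
            params.c_stiff,
            params.bubble_b,
            params.footprint,
            params.ler_on,
            params.ler_end,
            params.ler_velocity_penalty,
            params.torsion_on,
            params.rna_elements_on,
            boost,
            drag,
            params.torsion_cap_factor * params.v_int,
            params.p_term,
            params.p_top1,
            params.top1_gap,
            params.bp_per_turn,
            maxp,
        )
        snap_pos.append(sp)
        snap_max.append(sm)
        snap_n.append(sn)
        events += ev
        mod_sums += ms
        visits += vi
        pol_steps += ps
    return SimulationEnsemble(
        params=params,
        snapshot_times=snapshot_times,
        snap_pos=snap_pos,
        snap_max=snap_max,
        snap_n=snap_n,
        events={
            "backtrack_steps": int(events[0]),
            "blocked_collisions": int(events[1]),
            "runoff_terminations": int(events[2]),
            "premature_terminations": int(events[3]),
        },
        modifier_sums=mod_sums,
        visit_counts=visits,
        pol_steps=pol_steps,
    )
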