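"""From simulated ensembles to occupancy profiles and summary statistics.

The experimental signal the model is compared with is a per-nucleotide
density of polymerase active sites (3'-end read counts).  This module
histograms snapshot positions into normalized profiles, applies the smooth
erf cutoff that mimics the detection floor of the measurement, samples
in-silico reads, and computes the backtrack/collision statistics and the
per-nucleotide decomposition of the three velocity modifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import erf

from .simulate import SimulationEnsemble


@dataclass
class Profile:
    """Non-negative per-nucleotide signal, optionally unit-area normalized."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("normalized profile must sum to 1")

    def __len__(self) -> int:
        return len(self.values)

    def normalize(self) -> "Profile":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return Profile(self.values / total, normalized=True)


@dataclass
class CutoffParams:
    """Parameters of the smooth detection cutoff."""

    rho0: float
    sigma_cutoff: float

    def __post_init__(self) -> None:
        if self.sigma_cutoff <= 0:
            raise ValueError("sigma_cutoff must be positive")

    @classmethod
    def from_profile(cls, profile: Profile) -> "CutoffParams":
        """Scale-free default: rho0 at the 20th percentile of positive values."""
        positive = profile.values[profile.values > 0]
        if positive.size == 0:
            raise ValueError("profile has no positive values")
        rho0 = float(np.percentile(positive, 20))
        return cls(rho0=rho0, sigma_cutoff=rho0 / 2 if rho0 > 0 else 1e-12)


def occupancy_profile(ensemble: SimulationEnsemble, burn_in: bool = True) -> Profile:
    """Unit-area histogram of post-burn-in active-site positions."""
    length = ensemble.params.unit_length
    counts = np.zeros(length)
    total = 0
    for positions, _ in ensemble.iter_snapshots(burn_in=burn_in):
        if positions.size:
            counts += np.bincount(positions, minlength=length)[:length]
            total += positions.size
    if total == 0:
        raise ValueError("ensemble contains no snapshot positions")
    return Profile(counts / counts.sum(), normalized=True)


def apply_cutoff(profile: Profile, cutoff: Optional[CutoffParams] = None) -> Profile:
    """Smooth erf cutoff suppressing low-density regions, then renormalize.

    ``value' = value * 0.5 * (1 + erf((value - rho0)/sigma))``.
    """
    if not profile.normalized:
        profile = profile.normalize()
    cutoff = cutoff or CutoffParams.from_profile(profile)
    factor = 0.5 * (1.0 + erf((profile.values - cutoff.rho0) / cutoff.sigma_cutoff))
    damped = profile.values * factor
    return Profile(damped / damped.sum(), normalized=True)


def sample_reads(profile: Profile, n_reads: int, seed: int = 0) -> np.ndarray:
    """Multinomial in-silico read counts from a normalized profile."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not profile.normalized:
        profile = profile.normalize()
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_reads, profile.values)


def contribution_decomposition(ensemble: SimulationEnsemble) -> np.ndarray:
    """Relative contribution (%) of structure/hybrid/torsion per nucleotide.

    For each visited nucleotide the mean magnitude of each of the three
    velocity modifiers is divided by the sum of the three means; positions
    never visited are NaN.  Rows: struct, hybrid, torsion.
    """
    visits = ensemble.visit_counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = ensemble.modifier_sums / visits
        total = means.sum(axis=0)
        shares = 100.0 * means / total
    shares[:, (visits == 0) | ~np.isfinite(total) | (total == 0)] = np.nan
    return shares


def backtrack_collision_stats(
    ensemble: SimulationEnsemble, region: Optional[tuple] = None
) -> dict:
    """Fractions of polymerase-snapshots backtracked or in contact.

    ``backtracked_fraction``: share with the active site behind its
    historical maximum.  ``colliding_fraction``: share whose downstream gap
    equals the footprint (hard contact).  ``blocked_rate`` is the rate of
    blocked forward attempts per polymerase-second.  With ``region`` the
    per-snapshot fractions are restricted to active sites inside
    ``[region[0], region[1])`` — the right scope when only part of the
    landscape was perturbed.
    """
    fp = ensemble.params.footprint
    n_total = 0
    n_back = 0
    n_contact = 0
    for positions, max_positions in ensemble.iter_snapshots():
        contact = np.zeros(positions.size, dtype=bool)
        if positions.size > 1:
            contact[:-1] = np.diff(positions) == fp
        if region is not None:
            keep = (positions >= region[0]) & (positions < region[1])
            positions, max_positions, contact = (
                positions[keep], max_positions[keep], contact[keep],
            )
        n_total += positions.size
        n_back += int(np.sum(positions < max_positions))
        n_contact += int(contact.sum())
    pol_seconds = ensemble.pol_steps * ensemble.params.dt
    return {
        "backtracked_fraction": n_back / n_total if n_total else 0.0,
        "colliding_fraction": n_contact / n_total if n_total else 0.0,
        "blocked_rate": (
            ensemble.events["blocked_collisions"] / pol_seconds if pol_seconds else 0.0
        ),
        "n_polymerase_snapshots": n_total,
    }
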