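"""Model parameters and the desk-scale arithmetic behind them.

The elongation model describes RNA polymerase I molecules transcribing a
~7 kb ribosomal transcription unit as a convoy: each enzyme steps along the
template by a Brownian-ratchet mechanism while the DNA is rotated through
the array of polymerases, so that relative movements of neighbours over- or
under-wind the intervening helix and feed a torsional restoring force back
into the translocation probability.  Nascent-RNA secondary structure behind
the enzyme and the RNA:DNA hybrid inside the transcription bubble further
modify the stepping probability.

Every numeric default in :class:`ModelParams` is either a measured quantity
(intrinsic velocity, pause statistics, footprint, bubble size) or the result
of a short closed-form calibration reproduced by the helper functions in
this module (DNA stiffness constant, time step, initiation rate bounds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterator


@dataclass
class ModelParams:
    """Numeric constants of the elongation model.

    Velocities are nt/s, energies kcal/mol, times seconds, lengths nt.

    Attributes
    ----------
    v_int : intrinsic (pause-free) elongation velocity of RNAPI in vivo.
    sigma_rel : relative SD of the active-elongation velocity component.
    p_pause : probability that a per-step velocity draw comes from the
        paused component of the two-Gaussian velocity mixture.
    v_pause_mean, v_pause_sd : parameters of the paused component.
    dt : time step; 1/120 s so a single step never spans more than 1 nt
        for any velocity the mixture plausibly produces.
    add_prob : stochastic initiation success rate (s^-1); initiation also
        requires the previous polymerase to have cleared the initiation
        region (``init_region``).
    init_region : promoter-proximal region (nt) that must be clear of
        polymerases for a new engagement; the initial separation the
        stall-condition derivation assumes (100 nt).
    c_stiff : DNA torsional stiffness constant (nt/s per unit strain),
        calibrated so 5% overwind stalls a polymerase moving at ``v_int``.
    bubble_b : transcription-bubble length (11 nt for RNAPI).
    footprint : hard-core exclusion distance between active sites (38 nt).
    ler_end : end of the low-entrainment region, within which polymerases
        can still rotate around the template and torsion engages linearly.
    ler_velocity_penalty : maximal fractional velocity loss (friction cost
        of rotation) applied progressively over the LER.
    s_struct : strength coefficient of the nascent-structure term.
    hybrid_ratio : hybrid strength expressed as a ratio to ``s_struct``.
    dg_threshold : folding energies above this threshold (weaker) do not
        contribute a forward-promoting structure term.
    p_term : optional premature-termination rate within the LER (s^-1, off).
    p_top1 : optional topoisomerase-I relaxation rate (s^-1, off).
    top1_gap : minimal neighbour gap for Top1 action (nt).
    bp_per_turn : helical repeat used by the Top1 full-turn relaxation.
    """

    v_int: float = 50.0
    sigma_rel: float = 0.4
    p_pause: float = 0.078
    v_pause_mean: float = 0.9
    v_pause_sd: float = 1.5
    dt: float = 0.008
    add_prob: float = 0.8
    init_region: float = 100.0
    c_stiff: float = 500.0
    bubble_b: float = 11.0
    footprint: int = 38
    ler_end: float = 2000.0
    ler_velocity_penalty: float = 0.2
    s_struct: float = 1.25
    hybrid_ratio: float = 0.48
    dg_threshold: float = -11.0
    unit_length: int = 7000
    total_time: float = 2000.0
    n_snapshots: int = 200
    burn_in: float = 500.0
    p_term: float = 0.0
    p_top1: float = 0.0
    top1_gap: float = 25.0
    bp_per_turn: float = 10.5
    torsion_cap_factor: float = 5.0
    seed: int = 0

    # model-variant switches (full model has both on)
    torsion_on: bool = True
    rna_elements_on: bool = True
    ler_on: bool = True

    @property
    def s_hybrid(self) -> float:
        return self.s_struct * self.hybrid_ratio

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_pause <= 1.0:
            raise ValueError("p_pause must be a probability")
        if self.footprint < self.bubble_b:
            raise ValueError("footprint must be at least the bubble length")
        if self.init_region < self.footprint:
            raise ValueError("init_region cannot be smaller than the footprint")
        if self.ler_end > self.unit_length:
            raise ValueError("ler_end cannot exceed unit_length")
        if not 0.0 <= self.ler_velocity_penalty <= 0.2 + 1e-12:
            raise ValueError("ler_velocity_penalty must be in [0, 0.2]")
        # a step must not plausibly span more than one nucleotide
        vmax = self.v_int * (1.0 + 3.0 * self.sigma_rel)
        if self.dt * vmax >= 1.0 + 1e-9:
            raise ValueError("dt too large for the velocity scale")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    @classmethod
    def variant(cls, name: str, **kwargs) -> "ModelParams":
        """Named model variants used throughout the analyses.

        ``stochastic`` — stochastic initiation + elongation only;
        ``torsion`` — adds DNA torsion (no LER); ``torsion_ler`` — torsion
        engaged progressively over the LER; ``rna_only`` — RNA elements
        without torsion; ``full`` — everything.
        """
        presets = {
            "stochastic": dict(torsion_on=False, rna_elements_on=False, ler_on=False),
            "torsion": dict(torsion_on=True, rna_elements_on=False, ler_on=False),
            "torsion_ler": dict(torsion_on=True, rna_elements_on=False, ler_on=True),
            "rna_only": dict(torsion_on=False, rna_elements_on=True, ler_on=False),
            "full": dict(torsion_on=True, rna_elements_on=True, ler_on=True),
        }
        if name not in presets:
            raise ValueError(f"unknown variant {name!r}")
        merged = dict(presets[name])
        merged.update(kwargs)
        return cls(**merged)


@dataclass(frozen=True)
class TorsionDerivation:
    """Physical constants behind the torque model.

    The torque between neighbouring polymerases follows an elastic-rod
    description of DNA: shear modulus ``mu`` (pN/nm^2), radius ``r_dna``
    (nm), helical repeat ``bp_per_turn``.  A stall torque of ~11 nm.pN and
    the per-bp rotation ``theta`` = 2*pi/10.5 ~ 0.6 rad convert torque to a
    stalling force via F = tau*theta/d with contour length d ~ 0.34 nm/bp.
    """

    mu: float = 300.0
    r_dna: float = 1.0
    bp_per_turn: float = 10.5
    theta: float = 0.6
    d_contour: float = 0.34
    tau_stall: float = 11.0
    sigma_overwind_limit: float = 0.05

    def per_bp_rotation(self) -> float:
        """Angular rotation per bp translocation, 2*pi/bp_per_turn (rad)."""
        return 2.0 * math.pi / self.bp_per_turn

    def stall_force(self) -> float:
        """Force equivalent of the stall torque, tau*theta/d (pN)."""
        return self.tau_stall * self.theta / self.d_contour


def derive_stiffness(v_int: float = 50.0, overwind_percent: float = 5.0) -> float:
    """DNA stiffness constant from the closed-form stall condition.

    Solves for the constant ``c`` that exactly cancels the intrinsic
    velocity when the DNA between three equally loaded polymerases
    (initial separation 100 nt) is overwound by ``overwind_percent``:

        c = -v_int / (100/(100+r) - 100/(100-r))

    At v_int=50 and r=5 this gives 498.75, i.e. c=500 to the nearest
    hundred.
    """
    r = overwind_percent
    if r <= 0 or r >= 100:
        raise ValueError("overwind_percent must be in (0, 100)")
    denom = 100.0 / (100.0 + r) - 100.0 / (100.0 - r)
    return -v_int / denom


def overall_velocity(
    ribosomes_per_generation: float = 200_000.0,
    unit_length: float = 7000.0,
    generation_seconds: float = 6000.0,
    n_polymerases: float = 5500.0,
) -> float:
    """Average RNAPI velocity implied by cellular ribosome output.

    200,000 ribosomes per ~100 min generation, each requiring a 7,000-nt
    pre-rRNA, distributed over the 5,000-6,000 transcribing RNAPI molecules
    give an overall velocity of ~40 nt/s.
    """
    return ribosomes_per_generation * unit_length / (generation_seconds * n_polymerases)


def mean_spacing(unit_length: float = 7000.0, n_polymerases: float = 50.0) -> float:
    """Average centre-to-centre polymerase spacing, unit_length/count (nt)."""
    return unit_length / n_polymerases


def transcripts_per_minute(
    ribosomes_per_minute: float = 2000.0, active_repeats: float = 100.0
) -> float:
    """Completed pre-rRNA transcripts released per gene per minute."""
    return ribosomes_per_minute / active_repeats


def default_time_step(v_max: float = 120.0) -> float:
    """Time step bounding single-step moves to one nucleotide, 1/v_max (s)."""
    return 1.0 / v_max
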