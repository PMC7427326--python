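"""Synthetic inputs with known ground truth.

Every stage of the pipeline can be exercised without any external data:
hairpin-cassette transcription units emulating the highly structured 5'
leader of the pre-rRNA (a ~7,000-nt unit whose 5' region carries ~10 strong
stem-loops with ~80-nt apex spacing), analytic sawtooth ΔG tracks standing
in for computed folding-energy profiles, read-count occupancy profiles with
planted peaks, and intron-containing toy genes with consensus splice motifs
and optional decoy acceptors.

Generators emit DNA (T alphabet); track computations transcribe internally.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .energy import EnergyTrack

_DNA = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_DNA, size=n, p=p))


@dataclass
class SyntheticUnitSpec:
    """Geometry of a hairpin-cassette transcription unit."""

    unit_length: int = 7000
    n_hairpins: int = 10
    stem_length: int = 25
    loop_length: int = 6
    hairpin_spacing: int = 80
    stem_gc_fraction: float = 0.7
    lead_in: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unit_length <= 0:
            raise ValueError("unit_length must be positive")
        if self.n_hairpins < 0:
            raise ValueError("n_hairpins must be non-negative")
        span = 2 * self.stem_length + self.loop_length
        if self.n_hairpins > 0:
            if span > self.hairpin_spacing:
                raise ValueError("hairpins overlap: 2*stem+loop exceeds spacing")
            needed = self.lead_in + (self.n_hairpins - 1) * self.hairpin_spacing + span
            if needed > self.unit_length:
                raise ValueError(
                    f"geometry infeasible: needs {needed} nt, unit is {self.unit_length}"
                )
            if self.n_hairpins * (span + self.hairpin_spacing) > self.unit_length + span:
                raise ValueError("hairpin cassette does not fit the unit")

    @property
    def hairpin_span(self) -> int:
        return 2 * self.stem_length + self.loop_length


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator, for downstream recovery tests."""

    hairpin_apex_positions: list = field(default_factory=list)
    planted_peak_positions: list = field(default_factory=list)
    intron_annotation: Optional[tuple] = None  # (5'SS, bp_start, bp_end, 3'SS, decoy|None)

    def __post_init__(self) -> None:
        if self.intron_annotation is not None:
            five, bps, bpe, three, decoy = self.intron_annotation
            if not five < bps <= bpe < three:
                raise ValueError("intron coordinates out of order")
            if decoy is not None and not decoy < three:
                raise ValueError("decoy acceptor must be upstream of the true 3'SS")


def gen_hairpin_unit(spec: SyntheticUnitSpec) -> tuple[str, PlantedTruth]:
    """Sequence with ``n_hairpins`` perfect inverted repeats at regular spacing.

    Each hairpin is stem + loop + reverse-complement stem; apexes (loop
    centres) form an arithmetic progression with step ``hairpin_spacing``.
    Linker sequence is uniform random DNA.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_dna(rng, spec.unit_length))
    apexes = []
    for k in range(spec.n_hairpins):
        start = spec.lead_in + k * spec.hairpin_spacing
        stem = _random_dna(rng, spec.stem_length, gc=spec.stem_gc_fraction)
        loop = _random_dna(rng, spec.loop_length)
        hp = stem + loop + _revcomp(stem)
        seq[start : start + len(hp)] = list(hp)
        apexes.append(start + spec.stem_length + spec.loop_length // 2)
    return "".join(seq), PlantedTruth(hairpin_apex_positions=apexes)


def gen_sawtooth_dg_track(
    length: int,
    period: int = 80,
    dg_min: float = -20.0,
    dg_apex: float = -2.0,
    phase: int = 0,
) -> EnergyTrack:
    """Analytic piecewise-linear periodic folding-energy track.

    Oscillates between ``dg_min`` (strong structure, at ``phase`` modulo
    ``period``) and ``dg_apex`` (weak, half a period later).  Serves as a
    deterministic stand-in for a computed folding track: its minima mark
    "strong-stem" positions and its maxima "no-structure" positions, with
    amplitude matching the structured 5' leader (apex ~ -2, trough ~ -20
    kcal/mol) so that thresholding at -11 kcal/mol is exercised.
    """
    if length <= 0 or period < 2:
        raise ValueError("length must be positive and period >= 2")
    if not dg_min < dg_apex or dg_apex > 0:
        raise ValueError("need dg_min < dg_apex <= 0")
    i = np.arange(length)
    frac = ((i - phase) % period) / period
    tri = 1.0 - 2.0 * np.abs(frac - 0.5)  # 0 at phase, 1 half a period later
    values = dg_min + (dg_apex - dg_min) * tri
    return EnergyTrack(values, window=1, offset=0, kind="structure")


def gen_profile_with_peaks(
    length: int,
    peak_positions: Sequence[int],
    peak_sd: float = 5.0,
    n_reads: int = 100_000,
    background: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Read counts from a mixture of lattice Gaussians plus uniform background.

    ``background`` is the mixture weight of the uniform component.  Counts
    are a single multinomial draw and therefore sum exactly to ``n_reads``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    peak_positions = list(peak_positions)
    if any(p < 0 or p >= length for p in peak_positions):
        raise ValueError("peaks out of bounds")
    rng = np.random.default_rng(seed)
    weights = np.full(length, background / length)
    if peak_positions:
        x = np.arange(length)
        per_peak = (1.0 - background) / len(peak_positions)
        for p in peak_positions:
            if peak_sd <= 0:
                kernel = np.zeros(length)
                kernel[p] = 1.0
            else:
                kernel = np.exp(-0.5 * ((x - p) / peak_sd) ** 2)
                kernel /= kernel.sum()
            weights += per_peak * kernel
    else:
        weights = np.full(length, 1.0 / length)
    weights /= weights.sum()
    return rng.multinomial(n_reads, weights)


def study_landscape(
    spec: SyntheticUnitSpec | None = None,
    fold_window: int = 65,
    fold_offset: int = 15,
    hybrid_window: int = 8,
):
    """Canonical synthetic study conditions: sequence, truth and landscape.

    Builds the hairpin-cassette unit, a full-length sawtooth folding-energy
    surrogate whose strong minima (-20 kcal/mol) align with the positions
    where a rolling-window folding track would place the planted stems
    (apex + stem + offset), and the RNA:DNA hybrid track computed from the
    sequence.  The sawtooth spans the structured-leader amplitude range
    (apex -2, trough -20 kcal/mol) over the whole unit, so structure
    alternates above and below the -11 kcal/mol threshold with the ~80-nt
    period seen in the hairpin cassette, and the mean velocity budget of
    the full model lands at the overall ~40 nt/s average.

    Returns ``(sequence, truth, landscape)`` where ``landscape`` is an
    :class:`~polconvoy.simulate.EnergyLandscape`.
    """
    from .energy import hybrid_dg_track
    from .simulate import EnergyLandscape

    spec = spec or SyntheticUnitSpec()
    seq, truth = gen_hairpin_unit(spec)
    values = np.zeros(spec.unit_length)
    if truth.hairpin_apex_positions:
        # a stem contributes to the track once fully extruded behind the
        # enzyme: first strong minimum at apex + stem + offset
        first_min = truth.hairpin_apex_positions[0] + spec.stem_length + fold_offset
        phase = first_min % spec.hairpin_spacing
        saw = gen_sawtooth_dg_track(
            spec.unit_length, period=spec.hairpin_spacing, phase=phase
        )
        start = max(0, first_min - spec.hairpin_spacing // 2)
        values[start:] = saw.values[start:]
    hyb = hybrid_dg_track(seq, window=hybrid_window)
    land = EnergyLandscape(values, hyb.values)
    return seq, truth, land


def computed_landscape(
    spec: SyntheticUnitSpec | None = None,
    fold_window: int = 65,
    fold_offset: int = 15,
    hybrid_window: int = 8,
):
    """Study conditions with the folding track computed from the sequence.

    Like :func:`study_landscape` but the structure track is the actual
    rolling-window minimum-free-energy track of the generated unit under
    the builtin backend, mirroring how the experimental folding profile is
    derived from the template sequence.  Slower than the surrogate and with
    the builtin model's stronger-than-measured ΔG scale, but structure is
    present along the entire unit exactly where the sequence supports it.

    Returns ``(sequence, truth, landscape)``.
    """
    from .energy import hybrid_dg_track, rolling_fold_track
    from .simulate import EnergyLandscape

    spec = spec or SyntheticUnitSpec()
    seq, truth = gen_hairpin_unit(spec)
    fold = rolling_fold_track(seq, window=fold_window, offset=fold_offset)
    hyb = hybrid_dg_track(seq, window=hybrid_window)
    return seq, truth, EnergyLandscape(fold.values, hyb.values)


_FIVE_SS = "GTATGT"
_BP = "TACTAAC"
_ACCEPTOR = "AG"


def _scrub(seq: list, rng: np.random.Generator, protected: set,
           motifs: tuple, region_ag: Optional[tuple]) -> None:
    """Mutate accidental motif hits in place, leaving planted spans intact."""
    s = "".join(seq)
    for _ in range(200):
        dirty = []
        for motif in motifs:
            start = s.find(motif)
            while start != -1:
                span = set(range(start, start + len(motif)))
                if not span <= protected:
                    dirty.append((start, len(motif)))
                start = s.find(motif, start + 1)
        if region_ag is not None:
            a, b = region_ag
            for i in range(a, b - 1):
                if s[i : i + 2] == _ACCEPTOR and not {i, i + 1} <= protected:
                    dirty.append((i, 2))
        if not dirty:
            return
        for start, width in dirty:
            candidates = [i for i in range(start, start + width) if i not in protected]
            i = candidates[rng.integers(len(candidates))]
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[rng.integers(3)]
        s = "".join(seq)
    raise RuntimeError("could not scrub accidental consensus motifs")


def gen_intron_gene(
    exon1_len: int = 100,
    intron_len: int = 200,
    bp_to_3ss: int = 20,
    decoy_bp_to_3ss: Optional[int] = None,
    seed: int = 0,
    exon2_len: int = 100,
) -> tuple[str, PlantedTruth]:
    """Toy intron-containing gene with consensus splice motifs.

    The donor ``GTATGT`` starts the intron at ``exon1_len``; the acceptor
    ``AG`` ends it; the branch point ``TACTAAC`` ends ``bp_to_3ss`` nt
    upstream of the acceptor's first nucleotide.  An optional decoy ``AG``
    is planted ``decoy_bp_to_3ss`` nt after the branch point.  Background
    sequence is rejection-sampled so that no accidental donor/branch-point
    motif exists anywhere and no accidental acceptor exists between the
    branch point and the true 3' splice site.
    """
    if bp_to_3ss < 4:
        raise ValueError("bp_to_3ss must be >= 4")
    three_ss = exon1_len + intron_len - 2           # first nt of the acceptor AG
    bp_end = three_ss - bp_to_3ss                   # last nt of TACTAAC
    bp_start = bp_end - len(_BP) + 1
    five_ss = exon1_len
    if bp_start <= five_ss + len(_FIVE_SS):
        raise ValueError("intron too short for the motifs at these offsets")
    decoy = None
    if decoy_bp_to_3ss is not None:
        if decoy_bp_to_3ss < 1 or decoy_bp_to_3ss >= bp_to_3ss - 1:
            raise ValueError("decoy must fall strictly between BP and true 3'SS")
        decoy = bp_end + decoy_bp_to_3ss

    rng = np.random.default_rng(seed)
    total = exon1_len + intron_len + exon2_len
    seq = list(_random_dna(rng, total))
    protected: set = set()

    def plant(motif: str, start: int) -> None:
        seq[start : start + len(motif)] = list(motif)
        protected.update(range(start, start + len(motif)))

    plant(_FIVE_SS, five_ss)
    plant(_BP, bp_start)
    plant(_ACCEPTOR, three_ss)
    if decoy is not None:
        plant(_ACCEPTOR, decoy)

    _scrub(seq, rng, protected, motifs=(_FIVE_SS, _BP),
           region_ag=(bp_end + 1, three_ss + 1))
    truth = PlantedTruth(
        intron_annotation=(five_ss, bp_start, bp_end, three_ss, decoy)
    )
    return "".join(seq), truth
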