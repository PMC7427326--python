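"""Per-nucleotide energy tracks: nascent-RNA folding, RNA:DNA hybrid, GC.

The central objects are :class:`EnergyTrack` (a per-nucleotide ΔG signal
with NaN at positions where the window does not fit) and the pluggable
:class:`FoldingBackend`.  The folding track emulates what a polymerase
"sees": for an active site at template position ``i``, the 65 nt of
transcript extruded behind it — excluding the 15 nt still threaded through
the enzyme — are folded, and the resulting minimum free energy is assigned
to position ``i``.
"""

from __future__ import annotations

import shlex
import subprocess
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import thermo

TRACK_KINDS = ("structure", "hybrid")


@dataclass
class EnergyTrack:
    """Per-nucleotide ΔG values (kcal/mol), NaN where undefined."""

    values: np.ndarray
    window: int
    offset: int = 0
    kind: str = "structure"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"kind must be one of {TRACK_KINDS}")
        defined = self.values[~np.isnan(self.values)]
        if self.kind == "structure" and defined.size and np.any(defined > 1e-9):
            raise ValueError("structure ΔG values must be <= 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with undefined positions replaced by ``fill``."""
        out = self.values.copy()
        out[np.isnan(out)] = fill
        return out

    def copy(self) -> "EnergyTrack":
        return EnergyTrack(self.values.copy(), self.window, self.offset, self.kind)


class FoldingBackend:
    """Contract for minimum-free-energy calculators.

    Implementations must return ΔG <= 0 (0 for unfoldable sequences).
    ``temperature`` is carried for backends that support it; the builtin
    stack table is a fixed published set.
    """

    name = "abstract"

    def __init__(self, temperature: float = 30.0):
        self.temperature = temperature

    def fold_energy(self, seq: str) -> float:
        raise NotImplementedError


class BuiltinBackend(FoldingBackend):
    """Exact stacked-pair nearest-neighbor dynamic program (see thermo)."""

    name = "builtin"

    def fold_energy(self, seq: str) -> float:
        return thermo.mfe_energy(seq)


class ExternalBackend(FoldingBackend):
    """Adapter around any command-line folder printing ``dG = <float>``.

    The command receives the sequence on stdin; the last match of a
    ``dG``-like number in its output is used (works with hybrid-ss-min
    style output and with RNAfold's ``( -12.30 )`` trailer).
    """

    name = "external"
    _FLOAT = re.compile(r"(-?\d+\.?\d*)")

    def __init__(self, command: str, temperature: float = 30.0):
        super().__init__(temperature)
        self.command = command

    def fold_energy(self, seq: str) -> float:
        proc = subprocess.run(
            shlex.split(self.command),
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        matches = self._FLOAT.findall(proc.stdout.splitlines()[-1])
        if not matches:
            raise RuntimeError(f"no ΔG found in output of {self.command!r}")
        return min(0.0, float(matches[-1]))


class PrecomputedBackend(FoldingBackend):
    """Backend that serves a stored per-window table (e.g. reloaded tracks)."""

    name = "precomputed"

    def __init__(self, table: dict, temperature: float = 30.0):
        super().__init__(temperature)
        self.table = dict(table)

    def fold_energy(self, seq: str) -> float:
        key = seq.upper().replace("T", "U")
        return self.table[key]


def get_backend(name: str = "builtin", **kwargs) -> FoldingBackend:
    if name == "builtin":
        return BuiltinBackend(**kwargs)
    if name == "external":
        return ExternalBackend(**kwargs)
    if name == "precomputed":
        return PrecomputedBackend(**kwargs)
    raise ValueError(f"unknown backend {name!r}")


def fold_energy(seq: str, backend: FoldingBackend | None = None) -> float:
    """Minimum free energy (kcal/mol) of the best structure of ``seq``."""
    backend = backend or BuiltinBackend()
    if len(seq) == 0:
        return 0.0
    dg = backend.fold_energy(seq.upper().replace("T", "U"))
    return min(0.0, dg)


def rolling_fold_track(
    seq: str,
    window: int = 65,
    offset: int = 15,
    backend: FoldingBackend | None = None,
) -> EnergyTrack:
    """Folding-energy track of the nascent transcript behind the polymerase.

    ``value(i) = fold_energy(seq[i-offset-window+1 : i-offset+1])`` — the
    ``window`` nucleotides extruded behind an active site at ``i``, skipping
    the ``offset`` nucleotides still inside the enzyme.  Positions with
    ``i < window + offset - 1`` are undefined (NaN).
    """
    if window <= 0 or offset < 0:
        raise ValueError("window must be positive and offset non-negative")
    n = len(seq)
    if n < window + offset:
        raise ValueError("sequence shorter than window + offset")
    backend = backend or BuiltinBackend()
    rna = seq.upper().replace("T", "U")
    values = np.full(n, np.nan)
    first = window + offset - 1
    for i in range(first, n):
        sub = rna[i - offset - window + 1 : i - offset + 1]
        values[i] = min(0.0, backend.fold_energy(sub))
    return EnergyTrack(values, window=window, offset=offset, kind="structure")


def hybrid_dg_track(seq: str, window: int = 8) -> EnergyTrack:
    """RNA:DNA hybrid stability over a rolling window ending at each position.

    ``value(i)`` sums the ``window - 1`` nearest-neighbor hybrid terms of the
    window ``seq[i-window+1 : i+1]``; the first ``window - 1`` positions are
    undefined.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    n = len(seq)
    if n < window:
        raise ValueError("sequence shorter than window")
    rna = seq.upper().replace("T", "U")
    # per-step NN energies, then a cumulative-sum rolling window
    steps = np.array(
        [thermo.HYBRID_DG[rna[i : i + 2]] for i in range(n - 1)], dtype=float
    )
    csum = np.concatenate([[0.0], np.cumsum(steps)])
    values = np.full(n, np.nan)
    for i in range(window - 1, n):
        values[i] = csum[i] - csum[i - window + 1]
    return EnergyTrack(values, window=window, offset=0, kind="hybrid")


GC_MODES = ("up10", "down10", "up10+down10")


def gc_at_features(
    seq: str, positions: Sequence[int], mode: str = "up10", width: int = 10
) -> tuple[np.ndarray, list]:
    """G+C fraction in fixed windows around features.

    ``up10`` is the ``width`` nt ending at (and including) the feature — the
    transcription-bubble side; ``down10`` the ``width`` nt starting just
    after it; ``up10+down10`` both.  Features whose window does not fit are
    skipped and reported in the second return value.

    Returns ``(fractions, skipped_positions)`` with one fraction per
    retained feature, in input order.
    """
    if mode not in GC_MODES:
        raise ValueError(f"mode must be one of {GC_MODES}")
    s = seq.upper()
    n = len(s)
    gc = np.array([1.0 if b in "GC" else 0.0 for b in s])
    fractions = []
    skipped = []
    for p in positions:
        spans = []
        if mode in ("up10", "up10+down10"):
            spans.append((p - width + 1, p + 1))
        if mode in ("down10", "up10+down10"):
            spans.append((p + 1, p + width + 1))
        if any(a < 0 or b > n for a, b in spans):
            skipped.append(p)
            continue
        total = sum(gc[a:b].sum() for a, b in spans)
        length = sum(b - a for a, b in spans)
        fractions.append(total / length)
    return np.asarray(fractions), skipped
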