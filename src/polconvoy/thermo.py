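"""Nearest-neighbor free-energy tables and the builtin RNA folding scorer.

Two published parameter sets are embedded here:

* ``STACK_DG`` — Watson-Crick RNA/RNA helix stacking free energies
  (kcal/mol, 37 C) from Xia et al. 1998, the standard nearest-neighbor
  set for A-form RNA helices.  Ten unique stacks; the rest follow from
  rotational symmetry.
* ``HYBRID_DG`` — RNA/DNA hybrid duplex nearest-neighbor free energies
  (kcal/mol, 37 C) from Sugimoto et al. 1995, keyed by the RNA strand
  dinucleotide read 5'->3'.

The builtin folding backend scores a nested secondary structure as the sum
of stacking terms over consecutive base pairs (i,j),(i+1,j-1); isolated
pairs, loops and bulges contribute nothing.  This keeps every structure
energy <= 0 and makes the minimum-free-energy problem an exact dynamic
program, checkable against exhaustive enumeration on short sequences.
Watson-Crick pairs only, minimum hairpin loop of 3 nt, no pseudoknots.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BASES = "ACGU"
_IDX = {b: i for i, b in enumerate(_BASES)}

# 5'ab3' / 3'dc5' stacks written "ab/dc" (strands antiparallel, d pairs a,
# c pairs b).  Ten unique Watson-Crick stacks, Xia et al. 1998.
_UNIQUE_STACKS = {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
}


def _expand_stacks() -> dict:
    full = {}
    for key, dg in _UNIQUE_STACKS.items():
        ab, dc = key.split("/")
        a, b = ab
        d, c = dc
        full[f"{a}{b}/{d}{c}"] = dg
        # 180-degree rotation: top strand c d, bottom (3'->5') b a
        full[f"{c}{d}/{b}{a}"] = dg
    return full


#: all 16 Watson-Crick stacks, "ab/dc" keyed as above
STACK_DG: dict = _expand_stacks()

#: RNA/DNA hybrid nearest-neighbor free energies, RNA dinucleotide 5'->3'
#: (Sugimoto et al. 1995)
HYBRID_DG: dict = {
    "AA": -1.0, "AC": -2.1, "AG": -1.8, "AU": -0.9,
    "CA": -0.9, "CC": -2.1, "CG": -1.7, "CU": -0.9,
    "GA": -1.3, "GC": -2.7, "GG": -2.9, "GU": -1.1,
    "UA": -0.6, "UC": -1.5, "UG": -1.6, "UU": -0.2,
}

#: minimum unpaired nucleotides closed by a hairpin pair
MIN_HAIRPIN_LOOP = 3


def _stack_array() -> np.ndarray:
    arr = np.zeros((4, 4, 4, 4), dtype=np.float64)
    for key, dg in STACK_DG.items():
        ab, dc = key.split("/")
        arr[_IDX[ab[0]], _IDX[ab[1]], _IDX[dc[0]], _IDX[dc[1]]] = dg
    return arr


_STACKS = _stack_array()

# Watson-Crick pair matrix (A-U, U-A, C-G, G-C)
_WC = np.zeros((4, 4), dtype=np.bool_)
for _x, _y in ("AU", "UA", "CG", "GC"):
    _WC[_IDX[_x], _IDX[_y]] = True


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 indices, transcribing T->U."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(_BASES)
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return np.array([_IDX[b] for b in s], dtype=np.int8)


@njit(cache=True)
def _mfe_dp(enc, wc, stacks, min_loop):  # pragma: no cover - exercised via fold_energy
    n = enc.shape[0]
    if n < min_loop + 2:
        return 0.0
    INF = 1e30
    best = np.zeros((n + 1, n + 1), dtype=np.float64)   # best[i][j] over [i, j)
    bestNP = np.zeros((n + 1, n + 1), dtype=np.float64)  # (i, j-1) not mutually paired
    bestP = np.full((n, n), INF, dtype=np.float64)       # (i, j) paired

    # iterate over closed intervals [i, j] by increasing span
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            # bestP: (i, j) paired
            if wc[enc[i], enc[j]] and j - i - 1 >= min_loop:
                v = bestNP[i + 1, j]  # interval [i+1, j-1], inner ends unpaired to each other
                if (
                    j - 1 - (i + 1) - 1 >= min_loop
                    and wc[enc[i + 1], enc[j - 1]]
                    and bestP[i + 1, j - 1] < INF
                ):
                    w = stacks[enc[i], enc[i + 1], enc[j], enc[j - 1]] + bestP[i + 1, j - 1]
                    if w < v:
                        v = w
                bestP[i, j] = v
            # best / bestNP over [i, j]: decompose on the pairing of j
            b = best[i, j]      # j unpaired: best over [i, j-1] == best[i, j] (half-open)
            bnp = b
            for k in range(i, j - min_loop):
                if wc[enc[k], enc[j]] and bestP[k, j] < INF:
                    left = best[i, k] if k > i else 0.0  # best over [i, k-1]
                    w = left + bestP[k, j]
                    if w < b:
                        b = w
                    if k > i and w < bnp:
                        bnp = w
            best[i, j + 1] = b
            bestNP[i, j + 1] = bnp
        # fill spans shorter than min_loop+1 lazily: best defaults to 0
    return min(0.0, best[0, n])


def mfe_energy(seq: str) -> float:
    """Minimum free energy (kcal/mol) of ``seq`` under the builtin model.

    Returns 0.0 for sequences that cannot form any stabilizing structure.
    """
    enc = encode_rna(seq)
    if enc.shape[0] == 0:
        return 0.0
    return float(_mfe_dp(enc, _WC, _STACKS, MIN_HAIRPIN_LOOP))


def hybrid_window_dg(seq: str) -> float:
    """RNA:DNA hybrid free energy of a window: sum of NN terms (kcal/mol)."""
    s = seq.upper().replace("T", "U")
    if len(s) < 2:
        return 0.0
    total = 0.0
    for i in range(len(s) - 1):
        key = s[i : i + 2]
        if key not in HYBRID_DG:
            raise ValueError(f"invalid dinucleotide {key!r}")
        total += HYBRID_DG[key]
    return total
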