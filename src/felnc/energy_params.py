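"""Nearest-neighbor stacking constants for the gapless duplex energy model.

``WC_STACK`` holds the ten classic Watson-Crick nearest-neighbor free
energies (kcal/mol, 37 C) keyed as ``"XY/ZW"`` meaning the stack

    5'-X Y-3'
    3'-Z W-5'

i.e. X pairs Z and Y pairs W. The remaining six Watson-Crick orientations
are the same duplexes read from the other strand and are resolved by
symmetry at lookup time. Stacks containing G:U wobble pairs use two
documented package constants: a step with exactly one wobble pair
contributes ``ONE_GU_STACK`` and a step with two wobble pairs
``TWO_GU_STACK``. The cis/trans interaction thresholds shipped with the
package are defined relative to this fixed table.
"""

from __future__ import annotations

import numpy as np

WC_STACK: dict[str, float] = {
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

ONE_GU_STACK = -1.20  # step with exactly one G:U pair
TWO_GU_STACK = -0.50  # step with two G:U pairs

# pair codes: 0 = not pairable, 1..6 = AU, UA, GC, CG, GU, UG
_BASES = "ACGU"
_PAIRS = {("A", "U"): 1, ("U", "A"): 2, ("G", "C"): 3, ("C", "G"): 4,
          ("G", "U"): 5, ("U", "G"): 6}
_GU_CODES = {5, 6}


def encode(seq: str) -> np.ndarray:
    """Map an RNA string to integer base codes 0..3 (A, C, G, U)."""
    table = np.full(128, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        table[ord(b)] = i
    codes = table[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted(set(seq) - set(_BASES))
        raise ValueError(f"invalid RNA character(s): {bad}")
    return codes.astype(np.intp)


def _pair_code_matrix() -> np.ndarray:
    m = np.zeros((4, 4), dtype=np.intp)
    for (x, y), code in _PAIRS.items():
        m[_BASES.index(x), _BASES.index(y)] = code
    return m


PAIR_CODE: np.ndarray = _pair_code_matrix()


def _stack_lookup(p1: int, p2: int) -> float:
    """Stack energy for step pair codes (p1 over p2); 0 if either is unpaired."""
    if p1 == 0 or p2 == 0:
        return 0.0
    n_gu = (p1 in _GU_CODES) + (p2 in _GU_CODES)
    if n_gu == 2:
        return TWO_GU_STACK
    if n_gu == 1:
        return ONE_GU_STACK
    decode = {1: ("A", "U"), 2: ("U", "A"), 3: ("G", "C"), 4: ("C", "G")}
    (x, z), (y, w) = decode[p1], decode[p2]
    key = f"{x}{y}/{z}{w}"
    if key in WC_STACK:
        return WC_STACK[key]
    # same duplex read from the opposite strand: 5'-W Z-3' / 3'-Y X-5'
    return WC_STACK[f"{w}{z}/{y}{x}"]


def _stack_matrix() -> np.ndarray:
    m = np.zeros((7, 7))
    for p1 in range(7):
        for p2 in range(7):
            m[p1, p2] = _stack_lookup(p1, p2)
    return m


STACK_ENERGY: np.ndarray = _stack_matrix()
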