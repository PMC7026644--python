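"""Minimal nearest-neighbor energy function for pair-set structures.

The score of a structure is

    E = sum(stack dG37) + 0.45 per AU/GU helix end
        + lone-pair penalty + noncanonical-pair penalty
        - W * sum(Ps(i,j)) / mean(positive Ps)        (optional restraint)

with the Turner 2004 nearest-neighbor stacking free energies (kcal/mol at
37 C, 0.1 kcal granularity) embedded below.  A stack is counted for a pair
(i, j) whenever (i+1, j-1) is also paired and both pairs are canonical
(AU/GC/GU); this adjacency rule stays well-defined when pairs cross, so
helices inside pseudoknots stack normally.  Noncanonical pairs take part in
no stack but pay a penalty, as does any lone pair (one with neither
diagonal neighbor paired).  There are no loop, dangle, or coaxial terms:
the conformational search is meant to be driven by stacking plus the
mutation-derived pairing-score restraint, not by a full folding model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .structures import Structure

# base codes
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# pair-type codes over (5' base, 3' base); -1 = noncanonical
PAIR_TYPES = ["AU", "CG", "GC", "UA", "GU", "UG"]
_PT = {p: k for k, p in enumerate(PAIR_TYPES)}
#: pair types that pay the terminal AU/GU penalty at a helix end
AU_GU_TYPES = frozenset({_PT["AU"], _PT["UA"], _PT["GU"], _PT["UG"]})

#: 4x4 map (base_i, base_j) -> pair-type code
PAIR_TYPE_TABLE = np.full((4, 4), -1, dtype=np.int64)
for _p, _k in _PT.items():
    PAIR_TYPE_TABLE[BASE_INDEX[_p[0]], BASE_INDEX[_p[1]]] = _k

# Turner 2004 nearest-neighbor stacking free energies, kcal/mol at 37 C.
# STACK_DG37[p][q]: pair (i,j) of type p stacked on pair (i+1,j-1) of type q,
# i.e. the 5'-X W-3' / 3'-Y Z-5' motif with XY = p and WZ = q.
_S = {
    ("CG", "CG"): -3.3, ("CG", "GC"): -2.4, ("CG", "AU"): -2.1,
    ("CG", "UA"): -2.1, ("CG", "GU"): -1.4, ("CG", "UG"): -2.1,
    ("GC", "CG"): -3.4, ("GC", "GC"): -3.3, ("GC", "AU"): -2.4,
    ("GC", "UA"): -2.2, ("GC", "GU"): -1.5, ("GC", "UG"): -2.5,
    ("AU", "CG"): -2.2, ("AU", "GC"): -2.1, ("AU", "AU"): -0.9,
    ("AU", "UA"): -1.1, ("AU", "GU"): -0.6, ("AU", "UG"): -1.4,
    ("UA", "CG"): -2.4, ("UA", "GC"): -2.1, ("UA", "AU"): -1.3,
    ("UA", "UA"): -0.9, ("UA", "GU"): -1.0, ("UA", "UG"): -1.3,
    ("GU", "CG"): -2.5, ("GU", "GC"): -2.1, ("GU", "AU"): -1.3,
    ("GU", "UA"): -1.4, ("GU", "GU"): -0.5, ("GU", "UG"): 1.3,
    ("UG", "CG"): -1.5, ("UG", "GC"): -1.4, ("UG", "AU"): -1.0,
    ("UG", "UA"): -0.6, ("UG", "GU"): 0.3, ("UG", "UG"): -0.5,
}
STACK_DG37 = np.zeros((6, 6), dtype=np.float64)
for (_p, _q), _v in _S.items():
    STACK_DG37[_PT[_p], _PT[_q]] = _v

# self-consistency: reading a stack from the other strand gives the same motif
_rev = {"AU": "UA", "UA": "AU", "CG": "GC", "GC": "CG", "GU": "UG", "UG": "GU"}
for (_p, _q), _v in _S.items():
    assert _S[(_rev[_q], _rev[_p])] == _v, (_p, _q)

#: Turner 2004 penalty per helix terminus closed by an AU or GU pair
AU_END_PENALTY = 0.45


def encode_sequence(sequence: str) -> np.ndarray:
    """RNA string -> int codes (A=0, C=1, G=2, U=3)."""
    seq = sequence.upper().replace("T", "U")
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-ACGU base {e.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the pair-set energy function.

    ``lone_penalty`` and ``noncanonical_penalty`` share the single
    adjustable default of 3.0 kcal/mol, chosen so that unrestrained
    annealing produces no lone or noncanonical pair; results are stable for
    values between 2 and 5.  ``min_loop`` is the minimum number of unpaired
    bases inside a hairpin.
    """

    au_end_penalty: float = AU_END_PENALTY
    lone_penalty: float = 3.0
    noncanonical_penalty: float = 3.0
    min_loop: int = 3
    stack_table: np.ndarray = field(default_factory=lambda: STACK_DG37.copy())

    def __post_init__(self):
        if self.lone_penalty <= 0 or self.noncanonical_penalty <= 0:
            raise ValueError("penalties must be positive")
        if not np.all(np.isfinite(self.stack_table)):
            raise ValueError("stack table entries must be finite")


def restraint_matrix(
    ps_map: Mapping[tuple[int, int], float] | None,
    length: int,
    weight: float = 2.0,
    clip_negative: bool = True,
) -> np.ndarray | None:
    """Per-pair bonus ``W * Ps(i,j) / m`` as a symmetric LxL matrix.

    ``m`` is the mean of the positive per-position pairing scores (the raw
    mean can be negative, which would repel high-Ps pairs).  Returns None —
    restraint disabled — if no map or no positive score is supplied.  Pairs
    absent from the map contribute zero, so every base combination stays
    admissible without any score threshold.

    By default negative scores are clipped to zero rather than applied as
    repulsion: a pair covered by only one or two double mutants, none of
    them compensatory, earns a large negative naive-Bayes log score that
    overstates the evidence, and repelling such pairs blocks the stacking
    terms from completing sparsely covered helices — the very gap the
    folding stage exists to fill.  Set ``clip_negative=False`` to apply
    signed scores throughout.
    """
    if ps_map is None:
        return None
    positive = [v for v in ps_map.values() if v > 0]
    if not positive:
        return None
    m = float(np.mean(positive))
    rest = np.zeros((length, length), dtype=np.float64)
    for (i, j), ps in ps_map.items():
        if not (1 <= i <= length and 1 <= j <= length):
            raise ValueError(f"scored pair ({i},{j}) outside [1,{length}]")
        if clip_negative and ps < 0:
            continue
        rest[i - 1, j - 1] = rest[j - 1, i - 1] = weight * ps / m
    return rest


def pair_local_energy(
    partner: np.ndarray,
    seq: np.ndarray,
    i0: int,
    model: EnergyModel,
    rest: np.ndarray | None = None,
) -> float:
    """Energy terms attributed to the pair opening at 0-based position i0.

    Covers this pair's noncanonical and lone penalties, its AU/GU end
    penalty, the stack with its inner neighbor (i0+1, j0-1), and its
    restraint bonus.  Summing over all pairs gives the total energy.
    """
    j0 = partner[i0]
    L = len(partner)
    t = PAIR_TYPE_TABLE[seq[i0], seq[j0]]
    e = 0.0
    inner = i0 + 1 < L and j0 - 1 >= 0 and partner[i0 + 1] == j0 - 1
    outer = i0 - 1 >= 0 and j0 + 1 < L and partner[i0 - 1] == j0 + 1
    if t == -1:
        e += model.noncanonical_penalty
    else:
        if inner:
            t_in = PAIR_TYPE_TABLE[seq[i0 + 1], seq[j0 - 1]]
            if t_in != -1:
                e += model.stack_table[t, t_in]
        if t in AU_GU_TYPES and not (inner and outer):
            e += model.au_end_penalty
    if not inner and not outer:
        e += model.lone_penalty
    if rest is not None:
        e -= rest[i0, j0]
    return e


def energy(
    structure: Structure,
    sequence: str,
    model: EnergyModel | None = None,
    ps_map: Mapping[tuple[int, int], float] | None = None,
    weight: float = 2.0,
) -> float:
    """Total energy (kcal/mol-equivalent) of a structure for a sequence."""
    model = model or EnergyModel()
    seq = encode_sequence(sequence)
    if structure.length != len(seq):
        raise ValueError("structure length does not match sequence")
    structure.validate(min_loop=model.min_loop)
    partner = structure.partner_array
    rest = restraint_matrix(ps_map, len(seq), weight)
    total = 0.0
    for i0 in range(len(seq)):
        if partner[i0] > i0:
            total += pair_local_energy(partner, seq, i0, model, rest)
    return total
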