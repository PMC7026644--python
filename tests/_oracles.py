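"""Brute-force oracles used by the folding tests.

Exhaustive enumeration of pair-set structures (crossings allowed, one
partner per base, hairpin span respected) — independent of the Monte Carlo
search it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from coda.energy import EnergyModel, encode_sequence, energy
from coda.structures import Structure, is_canonical


def candidate_pairs(sequence: str, min_loop: int = 3, canonical_only: bool = True):
    L = len(sequence)
    out = []
    for i in range(1, L + 1):
        for j in range(i + min_loop + 1, L + 1):
            if not canonical_only or is_canonical(sequence[i - 1], sequence[j - 1]):
                out.append((i, j))
    return out


def enumerate_structures(sequence: str, min_loop: int = 3, canonical_only: bool = True):
    """Yield every valid pair set (as a frozen tuple of pairs)."""
    cands = candidate_pairs(sequence, min_loop, canonical_only)
    by_first: dict[int, list[tuple[int, int]]] = {}
    for i, j in cands:
        by_first.setdefault(i, []).append((i, j))
    L = len(sequence)

    def rec(pos: int, used: set, chosen: tuple):
        if pos > L:
            yield chosen
            return
        if pos in used:
            yield from rec(pos + 1, used, chosen)
            return
        # position unpaired
        yield from rec(pos + 1, used, chosen)
        for i, j in by_first.get(pos, ()):
            if j not in used:
                yield from rec(pos + 1, used | {i, j}, chosen + ((i, j),))

    yield from rec(1, set(), ())


def minimum_energy(
    sequence: str, model: EnergyModel | None = None, canonical_only: bool = True
) -> tuple[float, tuple]:
    """Global minimum energy over all valid structures, by enumeration."""
    model = model or EnergyModel()
    best = (0.0, ())
    for pairs in enumerate_structures(sequence, model.min_loop, canonical_only):
        e = energy(Structure(len(sequence), pairs), sequence, model)
        if e < best[0]:
            best = (e, pairs)
    return best


def boltzmann_pair_marginals(
    sequence: str, temperature: float, model: EnergyModel | None = None
) -> dict[tuple[int, int], float]:
    """Exact equilibrium pair probabilities over the full state space,
    noncanonical pairs included."""
    model = model or EnergyModel()
    z = 0.0
    acc: dict[tuple[int, int], float] = {}
    for pairs in enumerate_structures(sequence, model.min_loop, canonical_only=False):
        w = math.exp(-energy(Structure(len(sequence), pairs), sequence, model) / temperature)
        z += w
        for p in pairs:
            acc[p] = acc.get(p, 0.0) + w
    return {p: v / z for p, v in acc.items()}
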