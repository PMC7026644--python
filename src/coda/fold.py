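"""Structure prediction by Metropolis simulated annealing over pair sets.

Each annealing run starts from the empty structure at a high unitless
temperature and cools geometrically while proposing single-pair additions
and removals; crossing (pseudoknotted) pairs are allowed and noncanonical
pairs are penalized rather than forbidden.  Repeating the run with distinct
seeds yields per-pair frequencies ("contact probabilities") from which a
greedy consensus structure is read off.

The mutation-derived pairing scores enter the energy as a per-pair bonus
``-W * Ps(i,j) / mean(positive Ps)``, applied to every scored base pair
with no threshold, which lets the covariation signal recruit pairs —
including pseudoknots and lone pairs — that the stacking terms alone would
never keep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from . import _mc_kernel
from .energy import PAIR_TYPE_TABLE, EnergyModel, encode_sequence, restraint_matrix
from .structures import Structure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule for Metropolis annealing.

    Defaults: start at T=10, multiply by 0.95 after every sweep of 500,000
    steps, stop below T=0.1.  Temperature is unitless with energies in
    kcal/mol.
    """

    t_initial: float = 10.0
    cooling_factor: float = 0.95
    t_final: float = 0.1
    steps_per_temperature: int = 500_000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.cooling_factor < 1:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.t_final >= self.t_initial:
            raise ValueError("t_final must be below t_initial")
        if self.steps_per_temperature < 1:
            raise ValueError("steps_per_temperature must be positive")


@dataclass(frozen=True)
class Move:
    """A proposed elementary move (1-based positions)."""

    kind: Literal["add", "remove", "none"]
    i: int = 0
    j: int = 0


def propose_move(
    structure: Structure, rng: np.random.Generator, min_loop: int = 3
) -> Move:
    """The Monte Carlo proposal: destroy an existing pair or create one.

    A candidate position pair is drawn uniformly from the fixed set of
    geometric candidates (``j - i - 1 >= min_loop``; any base combination,
    canonical or not — noncanonical pairs are penalized by the energy,
    never forbidden by the move set).  If it is currently a pair the move
    removes it; if both bases are unpaired the move adds it; otherwise the
    proposal is a no-op.  Removals are thereby uniform over existing pairs
    and additions uniform over feasible pairs, and — because creation and
    destruction of any given pair are proposed with equal probability —
    plain Metropolis acceptance satisfies detailed balance.
    """
    L = structure.length
    partner = structure.partner_array
    while True:
        i = int(rng.integers(L)) + 1
        j = int(rng.integers(L)) + 1
        if i > j:
            i, j = j, i
        if j - i - 1 >= min_loop:
            break
    if partner[i - 1] == j - 1:
        return Move("remove", i, j)
    if partner[i - 1] == -1 and partner[j - 1] == -1:
        return Move("add", i, j)
    return Move("none")


def _kernel_args(sequence: str, model: EnergyModel, rest: np.ndarray | None):
    seq = encode_sequence(sequence)
    if rest is None:
        rest = np.zeros((len(seq), len(seq)), dtype=np.float64)
    return seq, PAIR_TYPE_TABLE, model.stack_table, float(model.au_end_penalty), float(
        model.lone_penalty
    ), float(model.noncanonical_penalty), rest, int(model.min_loop)


def anneal(
    sequence: str,
    model: EnergyModel | None = None,
    ps_map: Mapping[tuple[int, int], float] | None = None,
    weight: float = 2.0,
    schedule: AnnealSchedule | None = None,
    start: Structure | None = None,
) -> Structure:
    """One simulated-annealing run; reproducible given ``schedule.seed``.

    Returns the lowest-energy structure visited during the run (annealing
    elitism): at the final temperature of 0.1 the chain still fluctuates
    through near-degenerate alternatives, and a last-step snapshot would
    lose an already-found minimum to such a fluctuation.
    """
    model = model or EnergyModel()
    schedule = schedule or AnnealSchedule()
    rest = restraint_matrix(ps_map, len(sequence), weight)
    seq, pt, stack, au, lone, nc, rest_m, min_loop = _kernel_args(sequence, model, rest)
    init = (
        start.partner_array if start is not None else np.full(len(seq), -1, dtype=np.int64)
    )
    partner = _mc_kernel.anneal_kernel(
        seq,
        pt,
        stack,
        au,
        lone,
        nc,
        rest_m,
        min_loop,
        float(schedule.t_initial),
        float(schedule.cooling_factor),
        float(schedule.t_final),
        int(schedule.steps_per_temperature),
        int(schedule.seed) % (2**31),
        init,
    )
    return Structure.from_partner_array(partner)


def sample_at_temperature(
    sequence: str,
    temperature: float,
    model: EnergyModel | None = None,
    ps_map: Mapping[tuple[int, int], float] | None = None,
    weight: float = 2.0,
    n_steps: int = 1_000_000,
    record_every: int = 50,
    seed: int = 0,
) -> dict[tuple[int, int], float]:
    """Equilibrium pair frequencies of a fixed-temperature chain."""
    model = model or EnergyModel()
    rest = restraint_matrix(ps_map, len(sequence), weight)
    seq, pt, stack, au, lone, nc, rest_m, min_loop = _kernel_args(sequence, model, rest)
    occ, n = _mc_kernel.sample_kernel(
        seq, pt, stack, au, lone, nc, rest_m, min_loop,
        float(temperature), int(n_steps), int(record_every), int(seed) % (2**31),
    )
    out = {}
    for i0, j0 in zip(*np.nonzero(occ)):
        out[(int(i0) + 1, int(j0) + 1)] = occ[i0, j0] / n
    return out


@dataclass
class FoldEnsemble:
    """Pair frequencies over repeated annealing runs plus their consensus."""

    n_runs: int
    pair_frequency: dict[tuple[int, int], float]
    consensus: Structure
    structures: list[Structure] = field(default_factory=list)

    def frequency_frame(self) -> pd.DataFrame:
        rows = [
            {"i": i, "j": j, "freq": f}
            for (i, j), f in sorted(self.pair_frequency.items())
        ]
        return pd.DataFrame(rows, columns=["i", "j", "freq"])

    def to_tsv(self, path: str | Path) -> None:
        self.frequency_frame().to_csv(path, sep="\t", index=False)


def consensus_structure(
    pair_frequency: Mapping[tuple[int, int], float],
    length: int,
    threshold: float = 0.5,
) -> Structure:
    """Greedy consensus: sort by frequency (ties by position), keep a pair
    when its frequency reaches the threshold and both bases are free."""
    s = Structure(length)
    taken = set()
    for (i, j), f in sorted(pair_frequency.items(), key=lambda kv: (-kv[1], kv[0])):
        if f >= threshold and i not in taken and j not in taken:
            s.add_pair(i, j)
            taken.update((i, j))
    return s


def fold_ensemble(
    sequence: str,
    model: EnergyModel | None = None,
    ps_map: Mapping[tuple[int, int], float] | None = None,
    weight: float = 2.0,
    schedule: AnnealSchedule | None = None,
    n_runs: int = 100,
    consensus_threshold: float = 0.5,
) -> FoldEnsemble:
    """Repeat annealing with derived seeds and aggregate pair frequencies."""
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    model = model or EnergyModel()
    schedule = schedule or AnnealSchedule()
    run_seeds = np.random.default_rng(schedule.seed).integers(0, 2**31 - 1, size=n_runs)
    counts: dict[tuple[int, int], int] = {}
    structures = []
    for s in run_seeds:
        result = anneal(
            sequence,
            model=model,
            ps_map=ps_map,
            weight=weight,
            schedule=replace(schedule, seed=int(s)),
        )
        structures.append(result)
        for pair in result.pairs():
            counts[pair] = counts.get(pair, 0) + 1
    freq = {pair: c / n_runs for pair, c in counts.items()}
    consensus = consensus_structure(freq, len(sequence), threshold=consensus_threshold)
    return FoldEnsemble(
        n_runs=n_runs, pair_frequency=freq, consensus=consensus, structures=structures
    )
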