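"""Ground-truthed synthetic deep-mutational-scanning benchmarks.

The generator plants a known base-pairing structure in a designed ribozyme
sequence, assigns each library variant a true activity from a multiplicative
structure-determined model with compensatory rescue, and samples cleaved and
total read counts, so that every stage of the inference pipeline can be
exercised against a known answer without any external data.

Activity model.  Each planted pair contributes a factor of 1 while the two
bases remain a canonical (WC or GU) pair in the variant — this is the
compensatory-rescue rule that creates the covariation signal — and a
disruption factor otherwise: ``delta_pair`` for helix pairs, the weaker
``delta_tertiary`` for pseudoknot and lone pairs (edge and tertiary contacts
give weaker covariation in selection experiments).  Each mutated unpaired
position contributes a fixed per-(position, alternate) factor drawn once
from U[0.3, 1.1].  Multiplicative lognormal noise models assay dispersion.

Library model.  Substitutions are drawn per base per error-prone-PCR round
with an elevated rate at A/U positions (epPCR mutates AT-rich regions more
readily than GC-rich ones), read depth per variant is lognormal around a
median, and cleaved counts are binomial in the cleaved fraction implied by
the variant's true activity.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .library import SubKey, Variant, WildType, format_subs
from .structures import ReferenceStructure, is_canonical

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# the default 50-nt benchmark ribozyme
#
# Planted topology: a 5-bp helix, a 6-bp helix, a 2-bp kissing pseudoknot
# between the two hairpin loops, and one lone pair crossing the first stem —
# 14 pairs, all canonical in the wild type.  Loop positions use only A and C
# (which cannot pair with each other), and the tertiary pairs are A-U, so
# that no stackable helix exists outside the planted structure and the
# planted structure is the unique stable ground truth.

BENCHMARK_SEQUENCE = "ACGCGACAACAUAAUCAACGUCGCAAACACGUGCGAAAUCAACGCACGAC"
BENCHMARK_HELIX_PAIRS = [
    (3, 24), (4, 23), (5, 22), (6, 21), (7, 20),        # stem 1 (5 bp)
    (30, 48), (31, 47), (32, 46), (33, 45), (34, 44), (35, 43),  # stem 2 (6 bp)
]
BENCHMARK_TERTIARY_PAIRS = [
    (11, 39), (12, 38),  # kissing pseudoknot between the two loops
    (15, 27),            # lone pair crossing stem 1
]


@dataclass(frozen=True)
class ActivityParams:
    """Parameters of the structure-determined activity model."""

    delta_pair: float = 0.05
    delta_tertiary: float = 0.2
    loop_effect_low: float = 0.3
    loop_effect_high: float = 1.1
    noise_sd: float = 0.1
    p_cleave_wt: float = 0.5

    def __post_init__(self):
        if not 0 < self.delta_pair < 1:
            raise ValueError("delta_pair must be in (0, 1)")
        if not 0 < self.p_cleave_wt < 1:
            raise ValueError("p_cleave_wt must be in (0, 1)")


@dataclass(frozen=True)
class LibraryParams:
    """Parameters of the epPCR library and read-count sampling.

    Defaults give a mean of about two substitutions per variant (2.4% total
    per GC position, 6% per AT position over the rounds) and median depth 50.
    """

    n_variants: int = 30_000
    mutation_rate: float = 0.008
    n_rounds: int = 3
    at_bias: float = 2.5
    depth: int = 50
    depth_dispersion: float = 0.5

    def __post_init__(self):
        for name in ("n_variants", "mutation_rate", "n_rounds", "at_bias", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PlantedRibozyme:
    """A synthetic ribozyme with a known structure and activity model."""

    wild_type: WildType
    structure: ReferenceStructure
    tertiary_pairs: frozenset[tuple[int, int]]
    activity_params: ActivityParams
    seed: int
    loop_effects: dict[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.loop_effects:
            self.loop_effects = _draw_loop_effects(
                self.wild_type, self.structure, self.activity_params, self.seed
            )

    @property
    def canonical_pairs(self) -> set[tuple[int, int]]:
        return set(self.structure.pairs)


def _draw_loop_effects(
    wild_type: WildType,
    structure: ReferenceStructure,
    params: ActivityParams,
    seed: int,
) -> dict[tuple[int, str], float]:
    """Seeded per-(position, alternate) activity factors for unpaired bases."""
    rng = np.random.default_rng([seed, 0xC0DA])
    paired = {p for pair in structure.pairs for p in pair}
    effects = {}
    for pos in range(1, wild_type.length + 1):
        if pos in paired:
            continue
        for alt in "ACGU":
            if alt != wild_type.sequence[pos - 1]:
                effects[(pos, alt)] = float(
                    rng.uniform(params.loop_effect_low, params.loop_effect_high)
                )
    return effects


def make_default_benchmark(
    seed: int = 0, activity_params: ActivityParams | None = None
) -> PlantedRibozyme:
    """The standard 50-nt, 14-pair benchmark ribozyme.

    The sequence and planted topology are fixed; the seed determines the
    unpaired-position activity factors and downstream sampling.
    """
    wt = WildType(id="synthetic-ribozyme-50", sequence=BENCHMARK_SEQUENCE)
    pairs = set(BENCHMARK_HELIX_PAIRS) | set(BENCHMARK_TERTIARY_PAIRS)
    structure = ReferenceStructure(length=wt.length, pairs=pairs)
    for i, j in pairs:
        assert is_canonical(wt.sequence[i - 1], wt.sequence[j - 1])
    return PlantedRibozyme(
        wild_type=wt,
        structure=structure,
        tertiary_pairs=frozenset(BENCHMARK_TERTIARY_PAIRS),
        activity_params=activity_params or ActivityParams(),
        seed=seed,
    )


def simulate_activity(
    ribozyme: PlantedRibozyme,
    substitutions: SubKey,
    rng: np.random.Generator | None = None,
) -> float:
    """True relative activity of a variant under the multiplicative model.

    Without an ``rng`` the value is noiseless; with one, multiplicative
    lognormal noise of sd ``noise_sd`` is applied.
    """
    wt = ribozyme.wild_type
    params = ribozyme.activity_params
    variant_seq = wt.apply(substitutions)
    mutated = {pos for pos, _ in substitutions}
    ra = 1.0
    for i, j in ribozyme.structure.pairs:
        if i in mutated or j in mutated:
            if not is_canonical(variant_seq[i - 1], variant_seq[j - 1]):
                ra *= (
                    params.delta_tertiary
                    if (i, j) in ribozyme.tertiary_pairs
                    else params.delta_pair
                )
    paired = {p for pair in ribozyme.structure.pairs for p in pair}
    for pos, alt in substitutions:
        if pos not in paired:
            ra *= ribozyme.loop_effects[(pos, alt)]
    if rng is not None and params.noise_sd > 0:
        ra *= float(rng.lognormal(0.0, params.noise_sd))
    return ra


def _mutate(
    sequence: str, lib: LibraryParams, rng: np.random.Generator
) -> SubKey:
    """One epPCR pass: per-base per-round substitutions with AT bias."""
    seq = list(sequence)
    wt = sequence
    for _ in range(lib.n_rounds):
        for pos0, base in enumerate(seq):
            # the bias follows the current base, as mutation does in ePCR
            p = lib.mutation_rate * (lib.at_bias if base in "AU" else 1.0)
            if rng.random() < p:
                seq[pos0] = str(rng.choice([b for b in "ACGU" if b != base]))
    return tuple(
        (pos0 + 1, b) for pos0, (a, b) in enumerate(zip(wt, seq)) if a != b
    )


def simulate_library(
    ribozyme: PlantedRibozyme,
    lib_params: LibraryParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[Variant], pd.DataFrame]:
    """Draw a mutant library with read counts and its ground-truth table.

    Returns per-molecule variants (one entry per library molecule; molecules
    sharing a substitution set are aggregated downstream) and a DataFrame
    with columns ``substitutions``, ``ra_true``, ``n_cleaved``, ``n_total``.
    """
    lib = lib_params or LibraryParams()
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng([0 if rng is None else rng, ribozyme.seed])
    wt = ribozyme.wild_type
    params = ribozyme.activity_params
    variants: list[Variant] = []
    rows = []
    log_depth = math.log(lib.depth)
    for _ in range(lib.n_variants):
        subs = _mutate(wt.sequence, lib, rng)
        ra_true = simulate_activity(ribozyme, subs, rng=rng)
        n_total = max(1, int(round(rng.lognormal(log_depth, lib.depth_dispersion))))
        p_cleave = min(params.p_cleave_wt * ra_true, 0.98)
        n_cleaved = int(rng.binomial(n_total, p_cleave))
        variants.append(Variant(substitutions=subs, n_cleaved=n_cleaved, n_total=n_total))
        rows.append(
            {
                "substitutions": format_subs(subs, wt),
                "ra_true": ra_true,
                "n_cleaved": n_cleaved,
                "n_total": n_total,
            }
        )
    return variants, pd.DataFrame(rows)


def aggregate_variants(variants: Iterable[Variant]) -> list[Variant]:
    """Sum counts over molecules sharing the same substitution set."""
    cleaved: Counter = Counter()
    total: Counter = Counter()
    for v in variants:
        cleaved[v.substitutions] += v.n_cleaved
        total[v.substitutions] += v.n_total
    return [
        Variant(substitutions=s, n_cleaved=cleaved[s], n_total=n)
        for s, n in total.items()
    ]


def write_record_tables(
    variants: Iterable[Variant],
    ribozyme: PlantedRibozyme,
    dna_path: str | Path,
    rna_path: str | Path,
    barcode_collision_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> None:
    """Emit raw sequencing-style record TSVs for the preprocessing path.

    Each library molecule gets its own barcode (three DNA-seq reads per
    barcode); the RNA-seq table has one row per read with a cleaved flag.
    ``barcode_collision_rate`` reassigns that fraction of molecules to the
    previous molecule's barcode, exercising the >50% consensus rule.
    """
    rng = rng or np.random.default_rng(ribozyme.seed)
    wt = ribozyme.wild_type
    dna_rows, rna_rows = [], []
    prev_barcode = None
    for k, v in enumerate(variants):
        barcode = f"BC{k:07d}"
        if (
            prev_barcode is not None
            and barcode_collision_rate > 0
            and rng.random() < barcode_collision_rate
        ):
            barcode = prev_barcode
        prev_barcode = barcode
        seq = wt.apply(v.substitutions)
        for _ in range(3):
            dna_rows.append((barcode, seq))
        for r in range(v.n_total):
            rna_rows.append((barcode, 1 if r < v.n_cleaved else 0))
    pd.DataFrame(dna_rows, columns=["barcode", "sequence"]).to_csv(
        dna_path, sep="\t", index=False
    )
    pd.DataFrame(rna_rows, columns=["barcode", "cleaved"]).to_csv(
        rna_path, sep="\t", index=False
    )


def library_to_activity_table(
    ribozyme: PlantedRibozyme,
    variants: Iterable[Variant],
    min_reads: int = 5,
    use_triples: bool = True,
    functional_only: bool = False,
    functional_threshold: float = 0.5,
):
    """Aggregate a simulated library into an :class:`ActivityTable`.

    ``functional_only`` discards variants below ``functional_threshold``
    before any model fitting — the ablation that shows nonfunctional
    variants carry an essential part of the covariation signal.
    """
    from .library import ActivityTable, compute_ra, reduce_triples

    aggregated = aggregate_variants(variants)
    wt_counts = next(
        ((v.n_cleaved, v.n_total) for v in aggregated if not v.substitutions), None
    )
    if wt_counts is None:
        raise ValueError("library contains no wild-type molecules")
    records = compute_ra(aggregated, wt_counts, min_reads=min_reads)
    if functional_only:
        records = [r for r in records if r.ra >= functional_threshold]
    table = ActivityTable.from_records(ribozyme.wild_type, records)
    if use_triples:
        reduce_triples(table)
    return table
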