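"""Variant libraries from self-cleavage selection experiments.

The activity readout of a self-cleaving ribozyme variant is the fraction of
its transcripts found cleaved in sequencing, normalized by the wild type:

    RA(var) = N_cleaved(var) * N_total(wt) / (N_total(var) * N_cleaved(wt))

This module turns sequencing-style records (a DNA-seq-like table mapping
barcodes to full variant sequences, and an RNA-seq-like table of per-read
cleaved/uncleaved flags) into an :class:`ActivityTable` of relative
activities keyed by substitution sets, and implements batch merging and the
reduction of triple mutants to effective double mutants.

Coordinates are 1-based throughout; substitutions are written in the
``A5G`` style (reference base, position, alternate base).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: substitution: (1-based position, alternate base)
Sub = tuple[int, str]
#: canonical key for a substitution set: positions sorted ascending
SubKey = tuple[Sub, ...]


@dataclass(frozen=True)
class WildType:
    """Reference ribozyme sequence (RNA alphabet, 1-based positions)."""

    id: str
    sequence: str
    cleavage_site: int | None = None

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 10:
            raise ValueError("wild-type sequence must be at least 10 nt")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-ACGU characters in wild type: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_fasta(cls, path: str | Path, cleavage_site: int | None = None) -> "WildType":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(id=rec.id, sequence=str(rec.seq), cleavage_site=cleavage_site)

    def apply(self, substitutions: Iterable[Sub]) -> str:
        """Variant sequence with the given substitutions applied."""
        seq = list(self.sequence)
        for pos, alt in substitutions:
            seq[pos - 1] = alt
        return "".join(seq)


@dataclass(frozen=True)
class Variant:
    """A substitution set with aggregated cleaved/total read counts."""

    substitutions: SubKey
    n_cleaved: int = 0
    n_total: int = 0

    def __post_init__(self):
        if self.n_cleaved < 0 or self.n_cleaved > self.n_total:
            raise ValueError("require 0 <= n_cleaved <= n_total")
        positions = [p for p, _ in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate substituted position")

    @property
    def n_mutations(self) -> int:
        return len(self.substitutions)


@dataclass(frozen=True)
class ActivityRecord:
    """Relative activity of one variant (wild type = 1, may exceed 1)."""

    substitutions: SubKey
    ra: float
    n_total: int = 0
    provenance: str = "direct"

    def __post_init__(self):
        if self.ra < 0:
            raise ValueError("relative activity must be nonnegative")


def canonical_subs(substitutions: Iterable[Sub], wild_type: WildType | None = None) -> SubKey:
    """Sort substitutions by position and validate against the wild type."""
    subs = tuple(sorted(((int(p), a) for p, a in substitutions)))
    if wild_type is not None:
        for pos, alt in subs:
            if not 1 <= pos <= wild_type.length:
                raise ValueError(f"position {pos} outside [1,{wild_type.length}]")
            if alt not in RNA_ALPHABET:
                raise ValueError(f"bad alternate base {alt!r}")
            if wild_type.sequence[pos - 1] == alt:
                raise ValueError(f"substitution at {pos} equals the wild-type base")
    return subs


def subs_from_sequence(read: str, wild_type: WildType) -> SubKey | None:
    """Substitution set of a read vs the wild type; None if lengths differ."""
    read = read.upper().replace("T", "U")
    if len(read) != wild_type.length:
        return None
    if set(read) - RNA_ALPHABET:
        raise ValueError("non-ACGU(T) characters in read")
    return tuple(
        (i + 1, b) for i, (a, b) in enumerate(zip(wild_type.sequence, read)) if a != b
    )


def format_subs(substitutions: SubKey, wild_type: WildType) -> str:
    """Encode a substitution set as e.g. ``A5G,C12U`` (``WT`` if empty)."""
    if not substitutions:
        return "WT"
    return ",".join(f"{wild_type.sequence[p - 1]}{p}{a}" for p, a in substitutions)


def parse_subs(text: str, wild_type: WildType) -> SubKey:
    """Inverse of :func:`format_subs`; checks the reference base."""
    text = text.strip()
    if text in ("", "WT", "wt"):
        return ()
    subs = []
    for token in text.split(","):
        token = token.strip()
        ref, pos, alt = token[0], int(token[1:-1]), token[-1]
        ref = "U" if ref == "T" else ref
        alt = "U" if alt == "T" else alt
        if wild_type.sequence[pos - 1] != ref:
            raise ValueError(
                f"{token}: wild-type base at {pos} is {wild_type.sequence[pos - 1]}, not {ref}"
            )
        subs.append((pos, alt))
    return canonical_subs(subs, wild_type)


# ---------------------------------------------------------------------------
# barcode mapping and counting


@dataclass
class BarcodeMap:
    """Barcode -> substitution-set projection built from DNA-seq records."""

    variants: dict[str, SubKey]
    read_tally: dict[str, int]
    n_dropped_no_majority: int = 0
    n_skipped_length: int = 0
    n_skipped_alphabet: int = 0


def build_barcode_map(
    dna_records: Iterable[tuple[str, str]], wild_type: WildType
) -> BarcodeMap:
    """Map barcodes to variants using a strict-majority consensus.

    Reads whose length differs from the wild type are discarded (the variant
    model is substitution-only).  A barcode seen with several distinct
    sequences keeps the majority sequence only when its frequency exceeds
    50%; ties and minority-only barcodes are dropped.
    """
    per_barcode: dict[str, Counter] = defaultdict(Counter)
    n_len = n_alpha = 0
    n_records = 0
    for barcode, read in dna_records:
        n_records += 1
        try:
            subs = subs_from_sequence(read, wild_type)
        except ValueError:
            n_alpha += 1
            continue
        if subs is None:
            n_len += 1
            continue
        per_barcode[barcode][subs] += 1
    if n_records == 0:
        raise ValueError("no DNA-seq records supplied")
    if n_alpha:
        logger.warning("skipped %d reads with non-ACGU(T) characters", n_alpha)
    if n_len:
        logger.info("discarded %d reads with length != wild type", n_len)

    variants: dict[str, SubKey] = {}
    tally: dict[str, int] = {}
    n_dropped = 0
    for barcode, counts in per_barcode.items():
        total = sum(counts.values())
        subs, best = counts.most_common(1)[0]
        if 2 * best > total:  # strict majority
            variants[barcode] = subs
            tally[barcode] = total
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("dropped %d barcodes without a >50%% consensus", n_dropped)
    return BarcodeMap(
        variants=variants,
        read_tally=tally,
        n_dropped_no_majority=n_dropped,
        n_skipped_length=n_len,
        n_skipped_alphabet=n_alpha,
    )


def count_cleavage(
    rna_records: Iterable[tuple[str, bool | int]], barcode_map: BarcodeMap
) -> list[Variant]:
    """Aggregate cleaved/uncleaved read counts per substitution set.

    Counts from different barcodes carrying the same substitution set are
    summed; barcodes absent from the DNA-seq projection are tallied and
    dropped.
    """
    cleaved: Counter = Counter()
    total: Counter = Counter()
    n_unmapped = 0
    n_records = 0
    for barcode, flag in rna_records:
        n_records += 1
        subs = barcode_map.variants.get(barcode)
        if subs is None:
            n_unmapped += 1
            continue
        total[subs] += 1
        if flag:
            cleaved[subs] += 1
    if n_unmapped:
        logger.warning("%d RNA-seq reads had barcodes absent from DNA-seq", n_unmapped)
    if n_records and n_unmapped == n_records:
        logger.warning("every RNA-seq barcode was unmapped")
    return [
        Variant(substitutions=subs, n_cleaved=cleaved[subs], n_total=n)
        for subs, n in total.items()
    ]


def compute_ra(
    variants: Iterable[Variant],
    wild_type_counts: tuple[int, int],
    min_reads: int = 5,
) -> list[ActivityRecord]:
    """Relative activities for variants passing the minimum-read filter.

    ``wild_type_counts`` is ``(n_cleaved_wt, n_total_wt)``.  Variants with
    ``n_total < min_reads`` are omitted.
    """
    c_wt, t_wt = wild_type_counts
    if c_wt <= 0 or t_wt <= 0:
        raise ValueError("wild-type counts must be positive for RA to be defined")
    out = []
    for v in variants:
        if v.n_total < min_reads:
            continue
        ra = (v.n_cleaved * t_wt) / (v.n_total * c_wt)
        out.append(ActivityRecord(substitutions=v.substitutions, ra=ra, n_total=v.n_total))
    return out


# ---------------------------------------------------------------------------
# the activity table


class ActivityTable:
    """Relative activities split by mutation order, keyed for CODA.

    ``singles`` maps ``(pos, alt)`` and ``doubles`` maps the canonical
    ordered key ``((i, alt_i), (j, alt_j))`` with ``i < j`` to
    :class:`ActivityRecord` entries.  Higher-order records are retained in
    ``higher`` (triples feed :func:`reduce_triples`).
    """

    def __init__(self, wild_type: WildType):
        self.wild_type = wild_type
        self.singles: dict[Sub, ActivityRecord] = {}
        self.doubles: dict[SubKey, ActivityRecord] = {}
        self.higher: dict[SubKey, ActivityRecord] = {}

    @classmethod
    def from_records(
        cls, wild_type: WildType, records: Iterable[ActivityRecord]
    ) -> "ActivityTable":
        table = cls(wild_type)
        for rec in records:
            table.add(rec)
        return table

    def add(self, rec: ActivityRecord) -> None:
        subs = canonical_subs(rec.substitutions, self.wild_type)
        rec = ActivityRecord(subs, rec.ra, rec.n_total, rec.provenance)
        n = len(subs)
        if n == 0:
            return  # the wild type itself: RA = 1 by construction
        if n == 1:
            self.singles[subs[0]] = rec
        elif n == 2:
            self.doubles[subs] = rec
        else:
            self.higher[subs] = rec

    def get_double(self, a: Sub, b: Sub) -> ActivityRecord | None:
        """Query a double by its two substitutions in either order."""
        key = tuple(sorted((a, b)))
        return self.doubles.get(key)

    def double_positions(self) -> set[tuple[int, int]]:
        return {(k[0][0], k[1][0]) for k in self.doubles}

    @property
    def single_coverage(self) -> float:
        """Fraction of the 3L possible single substitutions present."""
        return len(self.singles) / (3 * self.wild_type.length)

    @property
    def double_coverage(self) -> float:
        """Fraction of the 9*C(L,2) possible double substitutions present."""
        L = self.wild_type.length
        return len(self.doubles) / (9 * L * (L - 1) / 2)

    def all_records(self) -> list[ActivityRecord]:
        return list(self.singles.values()) + list(self.doubles.values()) + list(self.higher.values())

    # -- persistence --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "substitutions": format_subs(r.substitutions, self.wild_type),
                "ra": r.ra,
                "provenance": r.provenance,
                "n_total": r.n_total,
            }
            for r in self.all_records()
        ]
        return pd.DataFrame(rows, columns=["substitutions", "ra", "provenance", "n_total"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, wild_type: WildType) -> "ActivityTable":
        df = pd.read_csv(path, sep="\t")
        records = [
            ActivityRecord(
                substitutions=parse_subs(row["substitutions"], wild_type),
                ra=float(row["ra"]),
                n_total=int(row.get("n_total", 0)),
                provenance=str(row.get("provenance", "direct")),
            )
            for _, row in df.iterrows()
        ]
        return cls.from_records(wild_type, records)


def read_count_table(path: str | Path, wild_type: WildType) -> list[Variant]:
    """Read a pre-aggregated ``substitutions  n_cleaved  n_total`` TSV."""
    df = pd.read_csv(path, sep="\t")
    return [
        Variant(
            substitutions=parse_subs(row["substitutions"], wild_type),
            n_cleaved=int(row["n_cleaved"]),
            n_total=int(row["n_total"]),
        )
        for _, row in df.iterrows()
    ]


def merge_batches(tables: Sequence[ActivityTable]) -> ActivityTable:
    """Union of several batches; variants present in more than one batch get
    the arithmetic mean of their batch RAs (provenance ``batch_average``)."""
    if not tables:
        raise ValueError("no batches to merge")
    wt = tables[0].wild_type
    for t in tables[1:]:
        if t.wild_type.sequence != wt.sequence:
            raise ValueError("batches disagree on the wild-type sequence")
    grouped: dict[SubKey, list[ActivityRecord]] = defaultdict(list)
    for t in tables:
        for rec in t.all_records():
            grouped[rec.substitutions].append(rec)
    merged = ActivityTable(wt)
    for subs, recs in grouped.items():
        if len(recs) == 1:
            merged.add(recs[0])
        else:
            merged.add(
                ActivityRecord(
                    substitutions=subs,
                    ra=sum(r.ra for r in recs) / len(recs),
                    n_total=sum(r.n_total for r in recs),
                    provenance="batch_average",
                )
            )
    return merged


def reduce_triples(
    table: ActivityTable, ra_threshold: float = 0.5
) -> int:
    """Approximate triples as doubles for position pairs lacking direct data.

    For a triple mutant XYZ with a near-neutral third mutation Z
    (``RA(Z) > ra_threshold``), the double activity is estimated as
    ``RA(XY) = RA(XYZ) / RA(Z)``.  Every qualifying choice of Z contributes;
    several estimates hitting the same double key are averaged.  Position
    pairs that already have any directly measured double are left untouched.
    Returns the number of double entries added.
    """
    covered_positions = table.double_positions()
    estimates: dict[SubKey, list[float]] = defaultdict(list)
    for subs, rec in table.higher.items():
        if len(subs) != 3:
            continue
        for z_idx in range(3):
            z = subs[z_idx]
            single_z = table.singles.get(z)
            if single_z is None or single_z.ra <= ra_threshold:
                continue
            xy = tuple(s for k, s in enumerate(subs) if k != z_idx)
            if (xy[0][0], xy[1][0]) in covered_positions:
                continue
            estimates[xy].append(rec.ra / single_z.ra)
    n_added = 0
    for xy, values in estimates.items():
        if xy in table.doubles:  # direct measurements are never overwritten
            continue
        table.doubles[xy] = ActivityRecord(
            substitutions=xy,
            ra=sum(values) / len(values),
            n_total=0,
            provenance="reduced_triple",
        )
        n_added += 1
    if n_added:
        logger.info("added %d effective doubles from triple reduction", n_added)
    return n_added


def preprocess(
    wild_type: WildType,
    dna_records: Iterable[tuple[str, str]],
    rna_records: Iterable[tuple[str, bool | int]],
    min_reads: int = 5,
    use_triples: bool = True,
    ra_threshold: float = 0.5,
) -> ActivityTable:
    """Full preprocessing: barcode map, counts, RA, triple reduction."""
    bmap = build_barcode_map(dna_records, wild_type)
    variants = count_cleavage(rna_records, bmap)
    wt_counts = next(
        ((v.n_cleaved, v.n_total) for v in variants if not v.substitutions), None
    )
    if wt_counts is None:
        raise ValueError("no wild-type reads found; RA is undefined")
    records = compute_ra(variants, wt_counts, min_reads=min_reads)
    table = ActivityTable.from_records(wild_type, records)
    if use_triples:
        reduce_triples(table, ra_threshold=ra_threshold)
    return table
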