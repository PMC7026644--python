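"""Base-pairing structures and their file formats.

A structure is a partner map over 1-based sequence positions in which every
base pairs with at most one other base.  Crossing (pseudoknotted) pairs are
allowed throughout: the partner-map representation does not privilege nested
helices, so kissing loops and isolated tertiary pairs are first-class.

Supported interchange formats: dot-bracket strings with up to four bracket
layers ``() [] {} <>`` for crossing pairs, CT, bpseq, and a plain
``i  j  [flag]`` pair-list TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

BRACKET_LAYERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]


def is_canonical(base_i: str, base_j: str) -> bool:
    """True for Watson-Crick (AU, GC) and wobble (GU) pairs."""
    return (base_i, base_j) in CANONICAL


class Structure:
    """A set of base pairs over ``L`` positions, one partner per base.

    Internally a partner array ``partner[i] = j`` (0-based, ``-1`` for
    unpaired); the public interface speaks 1-based position pairs ``(i, j)``
    with ``i < j``.
    """

    def __init__(self, length: int, pairs: Iterable[tuple[int, int]] = ()):
        if length < 1:
            raise ValueError("structure length must be positive")
        self.length = int(length)
        self._partner = np.full(self.length, -1, dtype=np.int64)
        for i, j in pairs:
            self.add_pair(i, j)

    @classmethod
    def from_partner_array(cls, partner: np.ndarray) -> "Structure":
        """Build from a 0-based partner array (-1 = unpaired)."""
        s = cls(len(partner))
        for i0, j0 in enumerate(partner):
            if j0 >= 0 and i0 < j0:
                s.add_pair(i0 + 1, j0 + 1)
        return s

    def add_pair(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("a base cannot pair with itself")
        if i > j:
            i, j = j, i
        if not (1 <= i <= self.length and 1 <= j <= self.length):
            raise ValueError(f"pair ({i},{j}) outside [1,{self.length}]")
        if self._partner[i - 1] != -1 or self._partner[j - 1] != -1:
            raise ValueError(f"position {i} or {j} already paired")
        self._partner[i - 1] = j - 1
        self._partner[j - 1] = i - 1

    def remove_pair(self, i: int, j: int) -> None:
        if i > j:
            i, j = j, i
        if self._partner[i - 1] != j - 1:
            raise ValueError(f"({i},{j}) is not a pair")
        self._partner[i - 1] = -1
        self._partner[j - 1] = -1

    def partner_of(self, i: int) -> int | None:
        """1-based partner of position ``i``, or None."""
        p = self._partner[i - 1]
        return int(p) + 1 if p >= 0 else None

    @property
    def partner_array(self) -> np.ndarray:
        """Copy of the 0-based partner array."""
        return self._partner.copy()

    def pairs(self) -> set[tuple[int, int]]:
        """All pairs as 1-based ``(i, j)`` with ``i < j``."""
        out = set()
        for i0, j0 in enumerate(self._partner):
            if j0 > i0:
                out.add((i0 + 1, int(j0) + 1))
        return out

    def __len__(self) -> int:
        return self.length

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Structure)
            and self.length == other.length
            and np.array_equal(self._partner, other._partner)
        )

    def __repr__(self) -> str:
        return f"Structure(L={self.length}, n_pairs={len(self.pairs())})"

    def validate(self, min_loop: int = 0) -> None:
        """Check the involution property and the minimum hairpin span."""
        for i0, j0 in enumerate(self._partner):
            if j0 >= 0:
                if self._partner[j0] != i0:
                    raise ValueError("partner map is not an involution")
                if j0 > i0 and j0 - i0 - 1 < min_loop:
                    raise ValueError(
                        f"pair ({i0 + 1},{j0 + 1}) violates min_loop={min_loop}"
                    )

    def to_dotbracket(self) -> str:
        return pairs_to_dotbracket(self.pairs(), self.length)


@dataclass
class ReferenceStructure:
    """A known (native) structure used only for evaluation.

    ``noncanonical`` flags pairs such as Hoogsteen UA or UU that fall outside
    AU/GC/GU in the reference sequence; both kinds count as positives when
    scoring predictions.
    """

    length: int
    pairs: set[tuple[int, int]] = field(default_factory=set)
    noncanonical: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self):
        self.pairs = {(min(i, j), max(i, j)) for (i, j) in self.pairs}
        self.noncanonical = {(min(i, j), max(i, j)) for (i, j) in self.noncanonical}
        seen: dict[int, tuple[int, int]] = {}
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) outside [1,{self.length}]")
            for k in (i, j):
                if k in seen:
                    raise ValueError(f"position {k} appears in two pairs")
                seen[k] = (i, j)
        if not self.noncanonical <= self.pairs:
            raise ValueError("noncanonical flags must refer to listed pairs")

    def to_structure(self) -> Structure:
        return Structure(self.length, self.pairs)


# ---------------------------------------------------------------------------
# dot-bracket layering


def assign_layers(pairs: Iterable[tuple[int, int]]) -> dict[tuple[int, int], int]:
    """Greedy assignment of bracket layers so no two crossing pairs share one.

    Pairs are taken in order of increasing opening position; each goes to the
    lowest layer where it crosses nothing already placed.
    """
    placed: list[list[tuple[int, int]]] = []
    layers: dict[tuple[int, int], int] = {}
    for i, j in sorted(pairs):
        for k, layer in enumerate(placed):
            if all(not _crosses((i, j), p) for p in layer):
                layer.append((i, j))
                layers[(i, j)] = k
                break
        else:
            if len(placed) >= len(BRACKET_LAYERS):
                raise ValueError("more than 4 mutually crossing layers")
            placed.append([(i, j)])
            layers[(i, j)] = len(placed) - 1
    return layers


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    chars = ["."] * length
    for (i, j), layer in assign_layers(pairs).items():
        op, cl = BRACKET_LAYERS[layer]
        chars[i - 1] = op
        chars[j - 1] = cl
    return "".join(chars)


def parse_dotbracket(db: str) -> set[tuple[int, int]]:
    """Parse a multi-layer dot-bracket string into a pair set."""
    stacks: dict[str, list[int]] = {op: [] for op, _ in BRACKET_LAYERS}
    closer_of = {cl: op for op, cl in BRACKET_LAYERS}
    pairs = set()
    for pos, c in enumerate(db, start=1):
        if c in stacks:
            stacks[c].append(pos)
        elif c in closer_of:
            stack = stacks[closer_of[c]]
            if not stack:
                raise ValueError(f"unbalanced bracket at position {pos}")
            pairs.add((stack.pop(), pos))
        elif c not in ".-:,_~":
            raise ValueError(f"unexpected character {c!r} in dot-bracket")
    for op, stack in stacks.items():
        if stack:
            raise ValueError(f"unclosed {op!r} bracket")
    return pairs


# ---------------------------------------------------------------------------
# file formats


def read_reference(path: str | Path, fmt: str | None = None) -> ReferenceStructure:
    """Read a reference structure; format inferred from the suffix if not given.

    Recognized: ``.ct``, ``.bpseq``, ``.db``/``.dbn`` (dot-bracket),
    ``.tsv``/``.txt`` (pair list).
    """
    path = Path(path)
    if fmt is None:
        fmt = {
            ".ct": "ct",
            ".bpseq": "bpseq",
            ".db": "dotbracket",
            ".dbn": "dotbracket",
            ".tsv": "pairs",
            ".txt": "pairs",
        }.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer structure format from {path.name!r}")
    text = path.read_text()
    if fmt == "ct":
        return _parse_ct(text)
    if fmt == "bpseq":
        return _parse_bpseq(text)
    if fmt == "dotbracket":
        lines = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith(">")]
        db = lines[-1]  # optional sequence line precedes the brackets
        return ReferenceStructure(length=len(db), pairs=parse_dotbracket(db))
    if fmt == "pairs":
        return _parse_pairlist(text)
    raise ValueError(f"unknown structure format {fmt!r}")


def _parse_ct(text: str) -> ReferenceStructure:
    lines = [l for l in text.splitlines() if l.strip()]
    n = int(lines[0].split()[0])
    pairs = set()
    for line in lines[1 : n + 1]:
        f = line.split()
        i, j = int(f[0]), int(f[4])
        if j > i:
            pairs.add((i, j))
    return ReferenceStructure(length=n, pairs=pairs)


def _parse_bpseq(text: str) -> ReferenceStructure:
    pairs = set()
    n = 0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i, _, j = line.split()[:3]
        i, j = int(i), int(j)
        n = max(n, i, j)
        if j > i:
            pairs.add((i, j))
    return ReferenceStructure(length=n, pairs=pairs)


def _parse_pairlist(text: str) -> ReferenceStructure:
    pairs = set()
    noncanon = set()
    n = 0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("i\t"):
            continue
        f = line.split()
        i, j = int(f[0]), int(f[1])
        key = (min(i, j), max(i, j))
        pairs.add(key)
        n = max(n, i, j)
        if len(f) > 2 and f[2].lower().startswith("noncanon"):
            noncanon.add(key)
    return ReferenceStructure(length=n, pairs=pairs, noncanonical=noncanon)


def write_ct(path: str | Path, structure: Structure, sequence: str, name: str = "structure") -> None:
    lines = [f"{structure.length}\t{name}"]
    for i in range(1, structure.length + 1):
        j = structure.partner_of(i) or 0
        lines.append(f"{i}\t{sequence[i - 1]}\t{i - 1}\t{i + 1}\t{j}\t{i}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bpseq(path: str | Path, structure: Structure, sequence: str) -> None:
    lines = [
        f"{i}\t{sequence[i - 1]}\t{structure.partner_of(i) or 0}"
        for i in range(1, structure.length + 1)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_dotbracket(path: str | Path, structure: Structure, sequence: str, name: str = "structure") -> None:
    Path(path).write_text(f">{name}\n{sequence}\n{structure.to_dotbracket()}\n")
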