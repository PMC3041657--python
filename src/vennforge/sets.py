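"""Set algebra: named element sets, region (partial-area) cardinalities,
input readers and a seeded random fixture generator.

A diagram over ``n`` sets partitions the plane into ``2**n - 1`` regions,
one per non-empty subset of set indices.  Region keys are canonicalized as
sorted tuples of 0-based set indices, e.g. ``(0,)`` is the part of set 0
outside every other set and ``(0, 2)`` is the part shared by sets 0 and 2
and no others.
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptyDiagramError, InvalidInputError, UnsupportedSizeError

MAX_SETS = 4

RegionKey = tuple[int, ...]


def all_region_keys(n: int) -> list[RegionKey]:
    """All 2**n - 1 region keys for an n-set diagram, in canonical order
    (by subset size, then lexicographically)."""
    keys: list[RegionKey] = []
    for size in range(1, n + 1):
        keys.extend(itertools.combinations(range(n), size))
    return keys


@dataclass(frozen=True)
class SetCollection:
    """Between one and four named, finite sets of opaque element identifiers.

    Duplicate elements within one input list collapse to a single member;
    identifiers compare by exact equality.
    """

    names: tuple[str, ...]
    members: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        if not 1 <= len(self.names) <= MAX_SETS:
            raise UnsupportedSizeError(
                f"between 1 and {MAX_SETS} sets are supported, got {len(self.names)}"
            )
        if len(set(self.names)) != len(self.names):
            raise InvalidInputError("set labels must be unique")
        if any(not isinstance(name, str) or not name for name in self.names):
            raise InvalidInputError("set labels must be non-empty strings")
        if set(self.names) != set(self.members):
            raise InvalidInputError("members mapping must cover exactly the named sets")

    @classmethod
    def from_dict(cls, sets: Mapping[str, Iterable]) -> "SetCollection":
        names = tuple(sets)
        members = {name: frozenset(elements) for name, elements in sets.items()}
        return cls(names=names, members=members)

    @property
    def n(self) -> int:
        return len(self.names)

    def union(self) -> frozenset:
        out: frozenset = frozenset()
        for name in self.names:
            out |= self.members[name]
        return out


@dataclass(frozen=True)
class RegionCardinalities:
    """Element count for every non-empty subset of set indices.

    All ``2**n - 1`` keys are present with explicit zeros; when derived from
    a :class:`SetCollection` the counts sum to the size of the union.
    """

    n: int
    counts: Mapping[RegionKey, int]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 1 <= self.n <= MAX_SETS:
            raise UnsupportedSizeError(
                f"between 1 and {MAX_SETS} sets are supported, got n={self.n}"
            )
        expected = set(all_region_keys(self.n))
        if set(self.counts) != expected:
            raise InvalidInputError("counts must cover exactly the 2^n - 1 regions")
        if self.labels and len(self.labels) != self.n:
            raise InvalidInputError("labels length must equal n")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(_default_labels(self.n)))

    def __getitem__(self, key: RegionKey) -> int:
        return self.counts[tuple(sorted(key))]

    def set_total(self, i: int) -> int:
        """|set_i|: sum of counts over all regions containing index i."""
        return sum(c for key, c in self.counts.items() if i in key)

    def pair_total(self, i: int, j: int) -> int:
        """|set_i ∩ set_j|: sum over regions containing both indices."""
        return sum(c for key, c in self.counts.items() if i in key and j in key)

    def union_total(self) -> int:
        return sum(self.counts.values())

    def nonzero_pattern(self) -> frozenset:
        """The set of region keys with a strictly positive count."""
        return frozenset(key for key, c in self.counts.items() if c > 0)


def _default_labels(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


def compute_region_cardinalities(sets: SetCollection) -> RegionCardinalities:
    """Tally, for every non-empty subset S of sets, the number of elements
    belonging to exactly the sets in S (the diagram's partial areas)."""
    n = sets.n
    counts: dict[RegionKey, int] = {key: 0 for key in all_region_keys(n)}
    for element in sets.union():
        key = tuple(i for i, name in enumerate(sets.names) if element in sets.members[name])
        counts[key] += 1
    return RegionCardinalities(n=n, counts=counts, labels=sets.names)


def validate_cardinalities(
    n: int,
    counts: Mapping[RegionKey, int],
    labels: Sequence[str] = (),
) -> RegionCardinalities:
    """Validate a user-supplied partial-area table, zero-filling absent keys.

    Raises :class:`UnsupportedSizeError` for n outside 1..4,
    :class:`InvalidInputError` for negative counts or out-of-range keys, and
    :class:`EmptyDiagramError` when every count is zero.
    """
    if not isinstance(n, int) or not 1 <= n <= MAX_SETS:
        raise UnsupportedSizeError(
            f"between 1 and {MAX_SETS} sets are supported, got n={n}"
        )
    full: dict[RegionKey, int] = {key: 0 for key in all_region_keys(n)}
    for raw_key, count in counts.items():
        key = tuple(sorted(raw_key))
        if key not in full:
            raise InvalidInputError(f"region key {raw_key!r} is not a subset of 0..{n - 1}")
        if not isinstance(count, (int, np.integer)) or isinstance(count, bool):
            raise InvalidInputError(f"count for region {raw_key!r} must be an integer")
        if count < 0:
            raise InvalidInputError(f"count for region {raw_key!r} is negative")
        full[key] = int(count)
    if all(c == 0 for c in full.values()):
        raise EmptyDiagramError("all region counts are zero; nothing to draw")
    return RegionCardinalities(n=n, counts=full, labels=tuple(labels))


def generate_random_sets(
    n_sets: int,
    universe_size: int,
    membership_prob: float,
    seed: int,
) -> SetCollection:
    """Random fixture: each of ``universe_size`` elements joins each set
    independently with probability ``membership_prob``.  Deterministic for a
    fixed seed."""
    if not 1 <= n_sets <= MAX_SETS:
        raise UnsupportedSizeError(f"n_sets must be in 1..{MAX_SETS}, got {n_sets}")
    if universe_size < 1:
        raise InvalidInputError("universe_size must be >= 1")
    if not 0.0 <= membership_prob <= 1.0:
        raise InvalidInputError("membership_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((universe_size, n_sets)) < membership_prob
    names = _default_labels(n_sets)
    members = {
        name: frozenset(f"e{j}" for j in range(universe_size) if mask[j, i])
        for i, name in enumerate(names)
    }
    return SetCollection(names=tuple(names), members=members)


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------

def read_set_lists(paths: Sequence[str | Path]) -> SetCollection:
    """One file per set, one element per line (UTF-8); blank lines are
    ignored and the file stem becomes the set name."""
    if not paths:
        raise InvalidInputError("at least one set list file is required")
    if len(paths) > MAX_SETS:
        raise UnsupportedSizeError(
            f"between 1 and {MAX_SETS} sets are supported, got {len(paths)} files"
        )
    sets: dict[str, list[str]] = {}
    for path in paths:
        p = Path(path)
        name = p.stem
        if name in sets:
            raise InvalidInputError(f"duplicate set name {name!r} from {p}")
        lines = p.read_text(encoding="utf-8").splitlines()
        sets[name] = [line.strip() for line in lines if line.strip()]
    return SetCollection.from_dict(sets)


def read_set_table(path: str | Path, delimiter: str | None = None) -> SetCollection:
    """Two-column delimited text with a header row (set_name, element)."""
    text = Path(path).read_text(encoding="utf-8")
    if delimiter is None:
        delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
    if not rows or len(rows[0]) < 2:
        raise InvalidInputError(f"{path}: expected a two-column table with a header")
    sets: dict[str, list[str]] = {}
    for row in rows[1:]:
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) < 2:
            raise InvalidInputError(f"{path}: malformed row {row!r}")
        name, element = row[0].strip(), row[1].strip()
        sets.setdefault(name, []).append(element)
    if len(sets) > MAX_SETS:
        raise UnsupportedSizeError(
            f"between 1 and {MAX_SETS} sets are supported, table defines {len(sets)}"
        )
    return SetCollection.from_dict(sets)


def read_sets_json(path: str | Path) -> SetCollection:
    """JSON object mapping set name to an array of element strings."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict) or not all(isinstance(v, list) for v in data.values()):
        raise InvalidInputError(f"{path}: expected an object mapping name -> array")
    if len(data) > MAX_SETS:
        raise UnsupportedSizeError(
            f"between 1 and {MAX_SETS} sets are supported, JSON defines {len(data)}"
        )
    return SetCollection.from_dict(data)


def parse_region_counts(mapping: Mapping[str, int]) -> RegionCardinalities:
    """Direct partial-area input: keys are set names joined by ``&``
    (e.g. ``"A"``, ``"A&B"``); set order follows first appearance.  Missing
    regions are zero-filled."""
    labels: list[str] = []
    for key in mapping:
        for name in key.split("&"):
            name = name.strip()
            if not name:
                raise InvalidInputError(f"malformed region key {key!r}")
            if name not in labels:
                labels.append(name)
    if len(labels) > MAX_SETS:
        raise UnsupportedSizeError(
            f"between 1 and {MAX_SETS} sets are supported, counts name {len(labels)}"
        )
    if not labels:
        raise InvalidInputError("no regions given")
    index = {name: i for i, name in enumerate(labels)}
    counts: dict[RegionKey, int] = {}
    for key, count in mapping.items():
        region = tuple(sorted(index[name.strip()] for name in key.split("&")))
        if len(set(region)) != len(region):
            raise InvalidInputError(f"region key {key!r} repeats a set name")
        if region in counts:
            raise InvalidInputError(f"region key {key!r} duplicates an earlier region")
        counts[region] = count
    return validate_cardinalities(len(labels), counts, labels)


def read_counts_json(path: str | Path) -> RegionCardinalities:
    """JSON object mapping ``&``-joined set names to region counts."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise InvalidInputError(f"{path}: expected an object mapping region -> count")
    return parse_region_counts(data)
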