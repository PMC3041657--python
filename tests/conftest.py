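import itertools

import pytest

from vennforge.sets import RegionCardinalities, all_region_keys


def card_from_pattern(n: int, pattern, count: int = 7) -> RegionCardinalities:
    """A cardinality table realizing a given zero/nonzero pattern."""
    pattern = {tuple(sorted(k)) for k in pattern}
    return RegionCardinalities(
        n=n, counts={k: (count if k in pattern else 0) for k in all_region_keys(n)}
    )


def all_patterns(n: int, include_empty: bool = False):
    """Every zero/nonzero pattern over the 2**n - 1 regions."""
    keys = all_region_keys(n)
    for bits in itertools.product([0, 1], repeat=len(keys)):
        if not include_empty and not any(bits):
            continue
        yield frozenset(k for k, b in zip(keys, bits) if b)


@pytest.fixture
def venn2_counts():
    from vennforge.sets import parse_region_counts

    return parse_region_counts({"A": 100, "B": 70, "A&B": 30})
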