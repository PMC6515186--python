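"""Shared fixtures: random realizable element-count specs and structures."""

from __future__ import annotations

import numpy as np
import pytest

from aptastruct import PlantedStructureSpec, plant_structure


def random_realizable_spec(rng: np.random.Generator) -> PlantedStructureSpec:
    """Draw element counts satisfying the structural identities."""
    h = int(rng.integers(0, 4))
    if h == 0:
        counts = {"S": 1}
    else:
        m = int(rng.integers(0, max(1, h)))  # needs h >= m + 1
        if m >= h:
            m = h - 1
        i = int(rng.integers(0, 3))
        g = int(rng.integers(0, 3))
        roots = h - m
        s = int(rng.integers(0, roots + 2))
        counts = {"S": s, "H": h, "L": h, "I": i, "G": g, "D": i + g + m, "M": m}
    base = 5 * counts.get("H", 0) + 4 * counts.get("I", 0) + 3 * counts.get("G", 0)
    base += 5 * counts.get("M", 0) + counts.get("S", 0)
    length = max(base, 1) + int(rng.integers(0, 12))
    return PlantedStructureSpec(
        length=length, element_counts=counts, seed=int(rng.integers(0, 2**31))
    )


def random_planted(rng: np.random.Generator):
    spec = random_realizable_spec(rng)
    record, pairs = plant_structure(spec)
    return spec, record, pairs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
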