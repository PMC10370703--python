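"""Craniometric helpers: index classification and Euclidean distance.

Cranial indices are ratios of vault measurements x 100, binned into the
conventional (Martin) categories; Euclidean distance over a shared set of
craniometric measurements is the classical between-group affinity metric.
"""

from __future__ import annotations

import math

import numpy as np

# kind -> ordered (upper_bound_exclusive, category); the last bin is open.
CRANIAL_INDEX_BINS: dict[str, list[tuple[float, str]]] = {
    # breadth / length
    "cranial": [(75.0, "dolichocrany"), (80.0, "mesocrany"),
                (math.inf, "brachycrany")],
    # basion-bregma height / length
    "length-height": [(70.0, "chamaecrany"), (75.0, "orthocrany"),
                      (math.inf, "hypsicrany")],
    # height / breadth
    "breadth-height": [(92.0, "tapeinocrany"), (98.0, "metriocrany"),
                       (math.inf, "acrocrany")],
}


def classify_cranial_index(kind: str, value: float) -> str:
    """Category for an index value of the given kind.

    Bins are closed on the left: e.g. a cranial (length-breadth) index of
    exactly 75.0 is mesocrany, 80.0 brachycrany.
    """
    if kind not in CRANIAL_INDEX_BINS:
        raise ValueError(
            f"unknown index kind {kind!r}; known: {sorted(CRANIAL_INDEX_BINS)}"
        )
    if value <= 0:
        raise ValueError("index value must be positive")
    for upper, category in CRANIAL_INDEX_BINS[kind]:
        if value < upper:
            return category
    raise AssertionError("unreachable")


def euclidean_distance(a, b) -> float:
    """Euclidean distance between two equal-length measurement vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"measurement vectors must be 1-D and equal length, "
            f"got {a.shape} vs {b.shape}"
        )
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("measurement vectors must not contain missing values")
    return float(np.linalg.norm(a - b))
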