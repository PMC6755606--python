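"""Algebra on atom-type holograms.

A hologram is a count vector over atom-type codes, stored sparsely as a
``dict[int, int]`` (absent code means count zero).  Two operations matter
for prediction: the signed entrywise *difference* between an unknown and a
known compound, which drives the library correction, and a count-based
Tanimoto *similarity* used to rank library candidates.
"""

from __future__ import annotations

import json
from typing import Mapping

Hologram = Mapping[int, int]


class SimilarityUndefinedError(ValueError):
    """Similarity of two empty holograms is undefined."""


def difference(unknown: Hologram, known: Hologram) -> dict[int, int]:
    """Signed per-code count difference ``unknown - known``; zeros dropped.

    ``difference(h, h)`` is empty, and the operation is anti-symmetric.
    """
    out: dict[int, int] = {}
    for code in set(unknown) | set(known):
        delta = unknown.get(code, 0) - known.get(code, 0)
        if delta:
            out[code] = delta
    return out


def similarity(h1: Hologram, h2: Hologram, *, per_position_mean: bool = False) -> float:
    """Count-based Tanimoto similarity in [0, 1].

    Over the union of codes, each position contributes its minimum
    occupancy against its maximum occupancy; the default aggregates as
    sum(min)/sum(max), which degenerates to the classical Tanimoto
    coefficient on 0/1 counts.  ``per_position_mean=True`` instead
    averages the per-position min/max ratios (an alternative reading of
    "the value of each position was set to the minimum occupancy divided
    by the maximum occupancy").

    The measure is symmetric, equals 1 exactly on identical holograms and
    0 on disjoint code sets.
    """
    codes = set(h1) | set(h2)
    if not codes:
        raise SimilarityUndefinedError("similarity of two empty holograms")
    if per_position_mean:
        total = 0.0
        for code in codes:
            a, b = h1.get(code, 0), h2.get(code, 0)
            total += min(a, b) / max(a, b)
        return total / len(codes)
    num = sum(min(h1.get(c, 0), h2.get(c, 0)) for c in codes)
    den = sum(max(h1.get(c, 0), h2.get(c, 0)) for c in codes)
    return num / den


def weighted_sum(h: Hologram, coefficients: Mapping[int, float]) -> tuple[float, list[int]]:
    """Dot product of a (difference) hologram with a coefficient table.

    Returns the sum over codes present in ``coefficients`` and the sorted
    list of codes missing from the table (out-of-domain codes).
    """
    total = 0.0
    missing: list[int] = []
    for code, count in h.items():
        coeff = coefficients.get(code)
        if coeff is None:
            missing.append(code)
        else:
            total += coeff * count
    return total, sorted(missing)


# --------------------------------------------------------------------------
# Serialisation ("code:count" text and JSON)
# --------------------------------------------------------------------------

def to_text(h: Hologram) -> str:
    """Render as tab-separated ``code:count`` pairs sorted by code."""
    return "\t".join(f"{code}:{h[code]}" for code in sorted(h))


def from_text(text: str) -> dict[int, int]:
    """Parse the ``code:count`` text format back into a hologram."""
    out: dict[int, int] = {}
    for field in text.split():
        code, _, count = field.partition(":")
        out[int(code)] = int(count)
    return out


def to_json(h: Hologram) -> str:
    return json.dumps({str(code): h[code] for code in sorted(h)})


def from_json(text: str) -> dict[int, int]:
    return {int(code): int(count) for code, count in json.loads(text).items()}
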