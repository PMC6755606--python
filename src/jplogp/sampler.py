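"""Targeted rarest-first diversity sampling for training-set construction.

Training an atom-typer model needs every atom-type represented; plain
random subsampling of a large compound collection loses rare types.  The
targeted sampler instead walks the atom-type occurrence list from rarest
to most common and, for each type, tops up the selection with random
compounds containing it until a per-type quota (the *sampling level*) of
selected compounds is reached.  Types rarer than ``min_occurrence`` total
atom-level occurrences carry too little signal to train on and are not
targeted at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hologram import Hologram

DEFAULT_MIN_OCCURRENCE = 3


def count_occurrences(dataset: Sequence[Hologram]) -> dict[int, int]:
    """Total atom-level occurrences of each code across the dataset."""
    totals: Counter[int] = Counter()
    for h in dataset:
        totals.update(h)
    return dict(totals)


def occurrence_order(table: dict[int, int]) -> list[int]:
    """Codes sorted by ascending occurrence, ties broken by code value."""
    return sorted(table, key=lambda code: (table[code], code))


@dataclass
class SampleManifest:
    """Record of a targeted-sampling run for reproducibility."""

    level: int
    min_occurrence: int
    seed: int
    n_input: int
    n_selected: int
    coverage: dict[int, int] = field(default_factory=dict)  # code -> selected compounds


def targeted_sample(
    dataset: Sequence[Hologram],
    level: int,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
    seed: int = 0,
) -> tuple[list[int], SampleManifest]:
    """Rarest-first selection guaranteeing per-code coverage.

    Iterates codes in ascending total-occurrence order (codes below
    ``min_occurrence`` are not targeted).  For each code, if fewer than
    ``level`` already-selected compounds contain it, additional compounds
    containing it are drawn uniformly at random until the quota is met or
    the pool is exhausted.  Compounds selected for earlier (rarer) codes
    count toward later codes' quotas, so the cumulative selection stays
    compact.  Deterministic for a fixed seed and input order.

    Returns the sorted selected indices and a manifest with the achieved
    per-code coverage.
    """
    if level <= 0:
        raise ValueError("sampling level must be >= 1")

    totals = count_occurrences(dataset)
    members: dict[int, list[int]] = {code: [] for code in totals}
    for i, h in enumerate(dataset):
        for code in h:
            members[code].append(i)

    rng = np.random.default_rng(seed)
    selected: set[int] = set()
    for code in occurrence_order(totals):
        if totals[code] < min_occurrence:
            continue
        pool = members[code]
        have = sum(1 for i in pool if i in selected)
        need = level - have
        if need <= 0:
            continue
        remaining = [i for i in pool if i not in selected]
        if not remaining:
            continue
        take = min(need, len(remaining))
        chosen = rng.choice(len(remaining), size=take, replace=False)
        selected.update(remaining[k] for k in chosen)

    coverage = {
        code: sum(1 for i in members[code] if i in selected)
        for code in totals
        if totals[code] >= min_occurrence
    }
    manifest = SampleManifest(
        level=level,
        min_occurrence=min_occurrence,
        seed=seed,
        n_input=len(dataset),
        n_selected=len(selected),
        coverage=coverage,
    )
    return sorted(selected), manifest
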