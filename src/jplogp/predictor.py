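"""logP prediction in coefficient and library-corrected modes.

Coefficient mode multiplies the query hologram through the trained
coefficient vector.  Library mode instead starts from the experimental
logP of similar known compounds: the signed difference hologram between
the query and each reference is priced with the same coefficients and
added to the reference's measured value, which cancels most of the
least-squares imprecision when the two structures are close.  Multiple
qualifying references are averaged; with no qualifying reference the
prediction falls back to coefficient mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hologram import Hologram, difference, similarity, weighted_sum
from .trainer import CoefficientTable

DEFAULT_MIN_SIMILARITY = 0.75
DEFAULT_MAX_MATCHES = 5

#: Absolute-error bin edges for evaluation summaries (last bin is open).
ERROR_BINS = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass
class LibraryEntry:
    """A reference compound with a measured logP and precomputed hologram."""

    id: str
    structure: str  # SMILES, kept for provenance
    logp: float
    hologram: dict[int, int]


@dataclass
class Match:
    entry_id: str
    similarity: float
    corrected: float
    in_domain: bool
    missing_codes: list[int] = field(default_factory=list)


@dataclass
class PredictionResult:
    value: float
    mode: str  # "coeff" | "library"
    matches: list[Match] = field(default_factory=list)
    in_domain: bool = True
    missing_codes: list[int] = field(default_factory=list)


def predict_coeff(h: Hologram, coeffs: CoefficientTable) -> PredictionResult:
    """Coefficient-only prediction: Σ α_code · count_code.

    Codes absent from the table flag the result out-of-domain; the value
    is then computed over the known codes only.
    """
    if not h:
        raise ValueError("cannot predict from an empty hologram")
    value, missing = weighted_sum(h, coeffs.coefficients)
    return PredictionResult(
        value=value,
        mode="coeff",
        in_domain=not missing,
        missing_codes=missing,
    )


def correct_from_known(
    unknown_h: Hologram, entry: LibraryEntry, coeffs: CoefficientTable
) -> tuple[float, list[int]]:
    """Library correction from one reference compound.

    Returns ``entry.logp + Σ α · (unknown - known)`` and the list of
    out-of-domain codes touched by the difference hologram (empty when the
    correction is fully in domain).  An identical query returns the
    experimental value exactly, since the difference hologram is empty.
    """
    diff = difference(unknown_h, entry.hologram)
    delta, missing = weighted_sum(diff, coeffs.coefficients)
    return entry.logp + delta, missing


def predict_library(
    h: Hologram,
    library: Sequence[LibraryEntry],
    coeffs: CoefficientTable,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    max_matches: int = DEFAULT_MAX_MATCHES,
    *,
    exclude_exact: bool = False,
    weight_by_similarity: bool = False,
) -> PredictionResult:
    """Library-corrected prediction.

    References are ranked by hologram similarity (ties broken by library
    id so results are order independent); those at or above
    ``min_similarity`` are kept, up to ``max_matches``.  The prediction is
    the unweighted mean of the per-reference corrected values (optionally
    similarity-weighted).  References whose difference hologram touches an
    untrained code are excluded from the mean but recorded.  With no
    usable reference the result falls back to coefficient mode.

    ``exclude_exact`` drops references with a hologram identical to the
    query, useful when benchmarking against sets that overlap the library.
    """
    if not library:
        raise ValueError("library is empty")
    if not h:
        raise ValueError("cannot predict from an empty hologram")

    scored = sorted(
        ((similarity(h, e.hologram), e) for e in library),
        key=lambda pair: (-pair[0], pair[1].id),
    )
    matches: list[Match] = []
    for sim, entry in scored:
        if sim < min_similarity:
            break
        if exclude_exact and dict(entry.hologram) == dict(h):
            continue
        corrected, missing = correct_from_known(h, entry, coeffs)
        matches.append(
            Match(
                entry_id=entry.id,
                similarity=sim,
                corrected=corrected,
                in_domain=not missing,
                missing_codes=missing,
            )
        )
        if len(matches) >= max_matches:
            break

    usable = [m for m in matches if m.in_domain]
    if not usable:
        fallback = predict_coeff(h, coeffs)
        fallback.matches = matches
        return fallback

    if weight_by_similarity:
        weights = np.array([m.similarity for m in usable])
        value = float(np.average([m.corrected for m in usable], weights=weights))
    else:
        value = float(np.mean([m.corrected for m in usable]))
    return PredictionResult(value=value, mode="library", matches=matches)


def grid_search(
    library: Sequence[LibraryEntry],
    eval_set: Sequence[tuple[Hologram, float]],
    coeffs: CoefficientTable,
    similarities: Iterable[float] = (0.5, 0.6, 0.7, 0.75, 0.8),
    match_counts: Iterable[int] = range(1, 8),
    *,
    exclude_exact: bool = False,
) -> pd.DataFrame:
    """RMSE of the library prediction per (min_similarity, max_matches) cell.

    ``eval_set`` pairs each query hologram with its measured logP.  Rows
    are match counts, columns similarity thresholds.
    """
    similarities = list(similarities)
    match_counts = list(match_counts)
    table = np.empty((len(match_counts), len(similarities)))
    for i, count in enumerate(match_counts):
        for j, sim in enumerate(similarities):
            preds = [
                predict_library(
                    h,
                    library,
                    coeffs,
                    min_similarity=sim,
                    max_matches=count,
                    exclude_exact=exclude_exact,
                ).value
                for h, _ in eval_set
            ]
            obs = [target for _, target in eval_set]
            table[i, j] = evaluate(preds, obs).rmse
    return pd.DataFrame(table, index=match_counts, columns=similarities)


@dataclass
class EvaluationResult:
    rmse: float
    bin_percentages: list[float]  # |error| in [0,.5), [.5,1), [1,1.5), [1.5,2), [2,inf)
    n: int


def evaluate(
    predictions: Sequence[float], observations: Sequence[float]
) -> EvaluationResult:
    """RMSE and binned absolute-error percentages.

    Bins are half-open [lo, hi) at 0.5-log-unit steps, with the final bin
    catching every error of 2 log units or more.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) == 0:
        raise ValueError("predictions and observations must be equal-length, non-empty")
    err = np.abs(pred - obs)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    edges = list(ERROR_BINS) + [np.inf]
    pcts = [
        float(100.0 * np.mean((err >= lo) & (err < hi)))
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return EvaluationResult(rmse=rmse, bin_percentages=pcts, n=len(pred))
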