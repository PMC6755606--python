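"""Least-squares training of per-atom-type logP coefficients.

The model is purely additive: predicted logP = Σ_n α_n · Count_n over the
atom-type codes of the molecule, with no intercept (the ubiquitous carbon
and hydrogen codes absorb the baseline).  Coefficients are fit by ordinary
least squares on the design matrix of hologram counts.  Rare codes — those
with fewer than ``min_occurrence`` total atom-level occurrences across the
training set — are excluded from the fit to avoid spurious coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .atom_typer import TYPER_VERSION

logger = logging.getLogger(__name__)

DEFAULT_MIN_OCCURRENCE = 3


@dataclass
class TrainingRecord:
    id: str
    hologram: dict[int, int]
    target: float


@dataclass
class TrainingSet:
    """Typed training records plus the ordered code vocabulary."""

    records: list[TrainingRecord]

    @property
    def vocabulary(self) -> list[int]:
        codes: set[int] = set()
        for rec in self.records:
            codes.update(rec.hologram)
        return sorted(codes)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CoefficientTable:
    """Trained mapping code -> logP contribution, with fit provenance."""

    coefficients: dict[int, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [c for c, v in self.coefficients.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite coefficients for codes {bad}")
        self.metadata.setdefault("typer_version", TYPER_VERSION)

    def __len__(self) -> int:
        return len(self.coefficients)

    def get(self, code: int, default=None):
        return self.coefficients.get(code, default)

    def __contains__(self, code: int) -> bool:
        return code in self.coefficients

    def __getitem__(self, code: int) -> float:
        return self.coefficients[code]


def consensus_mean(predictions: list[float]) -> float:
    """Arithmetic mean of several predictors' outputs for one compound.

    The consensus value acts as the training target, distilling the
    knowledge of the constituent models into one number.
    """
    if len(predictions) == 0:
        raise ValueError("consensus_mean of an empty prediction list")
    arr = np.asarray(predictions, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("consensus_mean requires finite predictions")
    return float(arr.mean())


def build_design_matrix(
    ts: TrainingSet,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Dense count matrix (rows = compounds, columns = vocabulary codes).

    Returns ``(X, y, codes)`` where ``X[i, j]`` is the count of
    ``codes[j]`` in compound ``i`` and ``y`` the target vector.  No
    intercept column is added.
    """
    codes = ts.vocabulary
    index = {code: j for j, code in enumerate(codes)}
    X = np.zeros((len(ts.records), len(codes)))
    y = np.empty(len(ts.records))
    for i, rec in enumerate(ts.records):
        for code, count in rec.hologram.items():
            X[i, index[code]] = count
        y[i] = rec.target
    return X, y, codes


def fit_coefficients(
    matrix: np.ndarray,
    targets: np.ndarray,
    codes: list[int] | None = None,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
) -> CoefficientTable:
    """Solve ``matrix @ alpha ~= targets`` by least squares.

    Columns whose total occurrence (column sum of counts) is below
    ``min_occurrence`` are dropped before fitting.  The solver is the
    SVD-based LAPACK least-squares routine, which returns the minimum-norm
    solution when the design is rank deficient (a warning is emitted in
    that case).  Fit R² and training RMSE are stored in the metadata.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design matrix and target vector sizes disagree")
    if codes is None:
        codes = list(range(X.shape[1]))
    if len(codes) != X.shape[1]:
        raise ValueError("code list length does not match matrix columns")

    keep = X.sum(axis=0) >= min_occurrence
    dropped = [codes[j] for j in np.flatnonzero(~keep)]
    if dropped:
        logger.info(
            "dropping %d codes below min_occurrence=%d", len(dropped), min_occurrence
        )
    Xk = X[:, keep]
    kept_codes = [codes[j] for j in np.flatnonzero(keep)]

    if Xk.shape[0] < Xk.shape[1]:
        raise ValueError(
            f"underdetermined system: {Xk.shape[0]} compounds for "
            f"{Xk.shape[1]} atom-type codes"
        )

    alpha, _, rank, _ = np.linalg.lstsq(Xk, y, rcond=None)
    if rank < Xk.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {Xk.shape[1]} columns); "
            "using the minimum-norm solution",
            stacklevel=2,
        )

    r2, rmse = fit_metrics(alpha, Xk, y)
    return CoefficientTable(
        coefficients={code: float(a) for code, a in zip(kept_codes, alpha)},
        metadata={
            "n_compounds": int(X.shape[0]),
            "n_codes": len(kept_codes),
            "n_codes_dropped": len(dropped),
            "min_occurrence": min_occurrence,
            "r2": r2,
            "rmse": rmse,
            "typer_version": TYPER_VERSION,
        },
    )


def fit_metrics(
    coeffs,
    matrix: np.ndarray,
    targets: np.ndarray,
    codes: list[int] | None = None,
) -> tuple[float, float]:
    """R² (about the target mean) and RMSE of ``matrix @ alpha`` vs targets.

    ``coeffs`` may be a coefficient vector aligned with the matrix columns
    or a :class:`CoefficientTable` together with the column ``codes``.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(targets, dtype=float)
    if isinstance(coeffs, CoefficientTable):
        if codes is None:
            raise ValueError("codes required when passing a CoefficientTable")
        alpha = np.array([coeffs.coefficients.get(c, 0.0) for c in codes])
    else:
        alpha = np.asarray(coeffs, dtype=float)
    if X.shape[1] != alpha.shape[0] or X.shape[0] != y.shape[0]:
        raise ValueError("dimension mismatch between matrix, coeffs and targets")

    residuals = y - X @ alpha
    ss_res = float(residuals @ residuals)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R² undefined for zero-variance targets")
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / len(y)))
    return r2, rmse


def train(
    ts: TrainingSet, min_occurrence: int = DEFAULT_MIN_OCCURRENCE
) -> CoefficientTable:
    """Convenience wrapper: design matrix + least squares in one step."""
    X, y, codes = build_design_matrix(ts)
    return fit_coefficients(X, y, codes, min_occurrence=min_occurrence)


def train_test_split(
    records: list, test_fraction: float, seed: int
) -> tuple[list, list]:
    """Seeded random split helper (train, test)."""
    if not 0.0 <= test_fraction <= 1.0:
        raise ValueError("test_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_test = int(round(test_fraction * len(records)))
    test_idx = set(order[:n_test].tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test
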