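"""Analytic hierarchy process (AHP) evaluation.

Implements the comprehensive industry-application evaluation used for
rugosa-rose germplasm: expert judgment matrices on Saaty's 1-9 scale are
aggregated, priority weights are derived (principal eigenvector or row
geometric means), each matrix is screened with the consistency ratio
(CR < 0.1 passes), local weights are composed down a
goal -> criteria -> index hierarchy, and accessions are scored and graded
from a field scoring standard.

A judgment matrix ``A`` is positive and reciprocal (``a_ii = 1``,
``a_ji = 1/a_ij``); ``a_ij`` is the judged importance of item i over item
j. The principal eigenvalue ``lambda_max >= n`` with equality exactly for
consistent matrices, which motivates Saaty's consistency index
``CI = (lambda_max - n)/(n - 1)`` and ratio ``CR = CI/RI(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, RangeError, ValidationError

#: Saaty's random consistency index by matrix order.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45}

#: Grade cutoffs on the final weighted score: I >= 3.6 > II >= 3.1 > III >= 2.7 > IV.
GRADE_CUTOFFS = ((3.6, "I"), (3.1, "II"), (2.7, "III"))


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency screen of one judgment matrix."""

    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    passed: bool


def validate_judgment(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Check that a matrix is square, positive and reciprocal."""
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("judgment matrix must be square")
    if (a <= 0).any():
        raise ValidationError("judgment matrix entries must be > 0")
    if not np.allclose(np.diag(a), 1.0, atol=tol):
        raise ValidationError("judgment matrix diagonal must be all 1")
    if not np.allclose(a * a.T, 1.0, rtol=tol, atol=tol):
        raise ValidationError("judgment matrix must be reciprocal (a_ji = 1/a_ij)")
    return a


def aggregate_judgments(matrices: list[np.ndarray]) -> np.ndarray:
    """Combine expert matrices by the element-wise geometric mean.

    The geometric mean is the canonical aggregator for reciprocal
    matrices: it is the only mean that preserves reciprocity, so the
    combined matrix is again a valid judgment matrix.
    """
    if not matrices:
        raise ValidationError("no judgment matrices to aggregate")
    mats = [validate_judgment(m) for m in matrices]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValidationError("judgment matrices must all have the same dimension")
    log_mean = np.mean([np.log(m) for m in mats], axis=0)
    agg = np.exp(log_mean)
    # enforce exact reciprocity against float round-off
    iu = np.triu_indices(n, 1)
    agg[(iu[1], iu[0])] = 1.0 / agg[iu]
    np.fill_diagonal(agg, 1.0)
    return agg


def _power_iteration(a: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    n = a.shape[0]
    w = np.full(n, 1.0 / n)
    lam = float(n)
    for _ in range(max_iter):
        v = a @ w
        lam = float(v.sum())  # since w sums to 1, a positive-vector Rayleigh estimate
        v_norm = v / v.sum()
        if np.max(np.abs(v_norm - w)) < tol:
            w = v_norm
            break
        w = v_norm
    # refine lambda_max as the mean component-wise eigen-ratio
    lam = float(np.mean((a @ w) / w))
    return w, lam


def derive_weights(
    matrix: np.ndarray, method: str = "eigenvector"
) -> tuple[np.ndarray, ConsistencyReport]:
    """Derive priority weights and the consistency report of one matrix.

    ``method='eigenvector'`` returns the principal right eigenvector
    (power iteration, tolerance 1e-10) normalized to sum 1;
    ``method='geometric_mean'`` returns normalized row geometric means.
    Both coincide exactly on consistent matrices.
    """
    a = validate_judgment(matrix)
    n = a.shape[0]
    if not 2 <= n <= 15:
        raise RangeError(f"judgment matrix order {n} outside the supported range 2-15")
    if method == "eigenvector":
        w, lam = _power_iteration(a)
    elif method == "geometric_mean":
        w = np.exp(np.mean(np.log(a), axis=1))
        w = w / w.sum()
        lam = float(np.mean((a @ w) / w))
    else:
        raise ConfigError(f"unknown weight-derivation method {method!r}")
    return w, consistency(a, lam)


def consistency(matrix: np.ndarray, lambda_max: float) -> ConsistencyReport:
    """Saaty consistency screen: CI = (lambda_max - n)/(n - 1), CR = CI/RI.

    Orders 1 and 2 are consistent by construction (RI = 0, CR defined as
    0). A matrix passes when CR < 0.1 (strict).
    """
    n = int(np.asarray(matrix).shape[0])
    if n not in RANDOM_INDEX:
        raise ConfigError(f"no random consistency index tabulated for order {n}")
    ri = RANDOM_INDEX[n]
    if n <= 2:
        ci, cr = 0.0, 0.0
    else:
        ci = (lambda_max - n) / (n - 1)
        cr = ci / ri
    return ConsistencyReport(n=n, lambda_max=float(lambda_max), ci=ci, ri=ri, cr=cr, passed=cr < 0.1)


# ---------------------------------------------------------------------------
# hierarchy composition and grading


def _check_sums_to_one(weights: np.ndarray, where: str, tol: float = 1e-6) -> None:
    if (weights <= 0).any():
        raise ValidationError(f"local weights must be > 0 ({where})")
    if abs(weights.sum() - 1.0) > tol:
        raise ValidationError(f"local weights at {where} sum to {weights.sum():.8f}, not 1")


def compose_weights(hierarchy: dict) -> pd.DataFrame:
    """Fill global weights down a goal -> criteria -> index hierarchy.

    The global weight of an index leaf is the product of its local weight
    under its criterion and the criterion's weight under the goal; global
    weights over all leaves therefore sum to 1.

    Parameters
    ----------
    hierarchy:
        ``{"goal": str, "criteria": {id: {"name": str, "weight": float,
        "indices": {leaf_id: local_weight}}}}`` (see
        :func:`rosaeval.datasets.example_hierarchy`).

    Returns
    -------
    pandas.DataFrame
        One row per leaf with columns ``index``, ``criterion``,
        ``local_weight``, ``criterion_weight``, ``global_weight``.
    """
    criteria = hierarchy.get("criteria")
    if not criteria:
        raise ValidationError("hierarchy has no criteria")
    crit_weights = np.array([c["weight"] for c in criteria.values()], dtype=float)
    _check_sums_to_one(crit_weights, "the criterion layer", tol=1e-3)
    rows = []
    for crit_id, crit in criteria.items():
        leaves = crit["indices"]
        local = np.array(list(leaves.values()), dtype=float)
        _check_sums_to_one(local, f"criterion {crit_id}")
        for leaf_id, w_local in leaves.items():
            rows.append(
                {
                    "index": leaf_id,
                    "criterion": crit_id,
                    "local_weight": float(w_local),
                    "criterion_weight": float(crit["weight"]),
                    "global_weight": float(w_local) * float(crit["weight"]),
                }
            )
    table = pd.DataFrame(rows)
    table["global_weight"] /= crit_weights.sum()  # renormalize printed-precision criterion weights
    return table


@dataclass(frozen=True)
class ScoringStandard:
    """Field scoring rules: per index, ordered (lower, upper, score) bands.

    Bands are half-open ``[lower, upper)`` except the last band of each
    index, which is closed above, so every declared range is covered
    exactly once. Scores are small integers (typically 1-5); orientation
    (whether large raw values score high or low) is encoded directly in
    the bands.
    """

    rules: dict[str, tuple[tuple[float, float, float], ...]]

    def score(self, index: str, value: float) -> float:
        if index not in self.rules:
            raise ValidationError(f"no scoring rule for index {index!r}")
        bands = self.rules[index]
        for i, (lo, hi, s) in enumerate(bands):
            last = i == len(bands) - 1
            if lo <= value < hi or (last and value == hi):
                return float(s)
        raise RangeError(f"value {value} for index {index!r} outside all scoring bands")


def uniform_standard(indices: list[str], cutpoints: tuple[float, ...], scores: tuple[float, ...]) -> ScoringStandard:
    """Convenience builder: the same score bands for every index."""
    if len(cutpoints) != len(scores) + 1:
        raise ValidationError("need one more cutpoint than scores")
    bands = tuple(
        (float(cutpoints[i]), float(cutpoints[i + 1]), float(scores[i])) for i in range(len(scores))
    )
    return ScoringStandard(rules={ix: bands for ix in indices})


def grade_of(score: float) -> str:
    """Map a final weighted score to grade I-IV (I closed below at 3.6)."""
    for cutoff, grade in GRADE_CUTOFFS:
        if score >= cutoff:
            return grade
    return "IV"


def score_and_grade(
    values: pd.DataFrame, standard: ScoringStandard, hierarchy: dict
) -> pd.DataFrame:
    """Score accessions and assign application grades.

    ``values`` holds one row per accession (``accession_id`` column) and
    one column per index leaf with the raw field measurement or metabolite
    content. Each leaf value is mapped to its band score, the final score
    is the global-weight-weighted sum, and grades follow the fixed
    cutoffs (I >= 3.6, II >= 3.1, III >= 2.7, IV below).
    """
    weights = compose_weights(hierarchy).set_index("index")["global_weight"]
    missing = [ix for ix in weights.index if ix not in values.columns]
    if missing:
        raise ValidationError(f"values table is missing index column(s) {missing}")
    out = []
    for _, row in values.iterrows():
        total = sum(
            w * standard.score(ix, float(row[ix])) for ix, w in weights.items()
        )
        out.append(
            {"accession_id": row["accession_id"], "score": float(total), "grade": grade_of(total)}
        )
    return pd.DataFrame(out)
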