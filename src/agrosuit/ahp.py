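"""Analytic Hierarchy Process: priority weights from pairwise judgments.

A decision maker compares criteria two at a time on Saaty's 1-9 scale
(fractional judgments such as 3/2 are allowed), giving a positive square
matrix ``A`` with ``a_ii = 1`` and ``a_ji = 1/a_ij``.  Priorities are
derived by the column-normalisation / row-average method: each column of
``A`` is divided by its sum and the rows of the normalised matrix are
averaged.  Consistency of the judgments is summarised by

    lambda_max ~ mean_i (A w)_i / w_i
    CI = (lambda_max - n) / (n - 1)
    CR = CI / RI(n)

where ``RI`` is the expected CI of random reciprocal matrices of the same
order.  CR < 0.1 is the conventional acceptability bound.  Multi-level
hierarchies are flattened by multiplying each leaf's local weight by its
parent criterion's weight.

The column-average method is the default because it is the one whose
intermediate tables practitioners publish; a power-iteration principal
eigenvector is available as a cross-check (:func:`eigenvector_weights`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "AhpError",
    "PairwiseMatrix",
    "PriorityResult",
    "HierarchyModel",
    "SAATY_RI",
    "parse_judgment",
    "validate_reciprocal",
    "normalize_columns",
    "priority_weights",
    "lambda_max",
    "consistency",
    "eigenvector_weights",
    "compose_weights",
    "round_half_up",
]

#: Saaty's random consistency index by matrix order.
SAATY_RI: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

RECIPROCITY_RTOL = 1e-9


class AhpError(ValueError):
    """Invalid judgment matrix or hierarchy."""


def parse_judgment(value) -> float:
    """Parse a judgment given as a number or a 'p/q' string.

    Fractions are parsed exactly as rationals before float conversion, so
    '2/3' and its reciprocal '3/2' multiply to 1 without rounding error.
    """
    if isinstance(value, str):
        text = value.strip().rstrip("/")  # tolerate trailing '/' typos
        try:
            return float(Fraction(text))
        except (ValueError, ZeroDivisionError) as exc:
            raise AhpError(f"cannot parse judgment {value!r}") from exc
    x = float(value)
    return x


@dataclass(frozen=True)
class PairwiseMatrix:
    """Validated reciprocal judgment matrix with labelled rows/columns."""

    labels: tuple[str, ...]
    entries: np.ndarray  # n x n, positive, reciprocal, unit diagonal

    @property
    def n(self) -> int:
        return len(self.labels)

    def permuted(self, order: list[int]) -> "PairwiseMatrix":
        idx = np.asarray(order)
        return PairwiseMatrix(
            labels=tuple(self.labels[i] for i in order),
            entries=self.entries[np.ix_(idx, idx)],
        )


@dataclass(frozen=True)
class PriorityResult:
    labels: tuple[str, ...]
    weights: np.ndarray
    lambda_max: float
    ci: float
    cr: float
    ri_used: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.weights)))


@dataclass
class HierarchyModel:
    """Main-criteria matrix plus one sub-criteria matrix per main criterion."""

    main: PairwiseMatrix
    subs: dict[str, PairwiseMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.main.labels) - set(self.subs)
        extra = set(self.subs) - set(self.main.labels)
        if missing or extra:
            raise AhpError(
                f"hierarchy mismatch: main criteria without sub-matrix {sorted(missing)}, "
                f"sub-matrices without main criterion {sorted(extra)}"
            )
        leaves = [l for m in self.main.labels for l in self.subs[m].labels]
        if len(set(leaves)) != len(leaves):
            raise AhpError("a sub-criterion appears under more than one main criterion")

    @property
    def leaf_labels(self) -> list[str]:
        return [l for m in self.main.labels for l in self.subs[m].labels]


def validate_reciprocal(
    entries, labels, *, rtol: float = RECIPROCITY_RTOL, strict: bool = True
) -> PairwiseMatrix:
    """Validate (and if needed complete) a reciprocal judgment matrix.

    ``entries`` is a square nested sequence; cells may be numbers or 'p/q'
    strings, and lower-triangle cells may be ``None`` (or NaN), in which
    case they are completed as ``a_ji = 1/a_ij``.

    With ``strict=False`` a reciprocity violation is downgraded to a
    warning: elicited judgment tables occasionally record the two
    directions of one comparison inconsistently, and when published
    priorities derive from such a table it must be usable verbatim.
    Positivity and the unit diagonal are always enforced.
    """
    labels = tuple(str(l) for l in labels)
    n = len(labels)
    if n < 2:
        raise AhpError("a pairwise matrix needs at least 2 criteria")
    rows = list(entries)
    if len(rows) != n or any(len(list(r)) != n for r in rows):
        raise AhpError(f"matrix must be square with side {n} to match the labels")

    a = np.full((n, n), np.nan)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell is None:
                continue
            x = parse_judgment(cell)
            if np.isnan(x):
                continue
            a[i, j] = x

    # complete a missing lower triangle from the upper one
    for i in range(n):
        for j in range(n):
            if np.isnan(a[i, j]):
                if i > j and not np.isnan(a[j, i]):
                    a[i, j] = 1.0 / a[j, i]
                else:
                    raise AhpError(f"missing judgment at cell ({i}, {j})")

    for i in range(n):
        for j in range(n):
            if not a[i, j] > 0:
                raise AhpError(f"nonpositive judgment {a[i, j]} at cell ({i}, {j})")
    for i in range(n):
        if not np.isclose(a[i, i], 1.0, rtol=rtol):
            raise AhpError(f"diagonal entry at cell ({i}, {i}) is {a[i, i]}, must be 1")
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isclose(a[i, j] * a[j, i], 1.0, rtol=max(rtol, 1e-9), atol=0):
                msg = (
                    f"reciprocity violated at cell ({j}, {i}): "
                    f"{a[j, i]} x {a[i, j]} = {a[j, i] * a[i, j]:.12g} != 1"
                )
                if strict:
                    raise AhpError(msg)
                import warnings

                warnings.warn(msg, stacklevel=2)
    return PairwiseMatrix(labels=labels, entries=a)


def normalize_columns(matrix: PairwiseMatrix) -> np.ndarray:
    """Divide each entry by its column sum; every column then sums to 1."""
    a = matrix.entries
    return a / a.sum(axis=0, keepdims=True)


def priority_weights(matrix: PairwiseMatrix) -> np.ndarray:
    """Row means of the column-normalised matrix; sums to 1."""
    return normalize_columns(matrix).mean(axis=1)


def lambda_max(matrix: PairwiseMatrix, weights: np.ndarray) -> float:
    """Principal-eigenvalue estimate: mean of (A w)_i / w_i over rows."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise AhpError("weights must be strictly positive for lambda_max")
    return float(np.mean(matrix.entries @ w / w))


def consistency(matrix: PairwiseMatrix, *, ri_table: dict[int, float] | None = None) -> PriorityResult:
    """Full priority result: weights, lambda_max, CI, CR.

    ``ri_table`` defaults to Saaty's random index table; it is exposed
    because published CR values occasionally imply a different RI.
    """
    ri_table = SAATY_RI if ri_table is None else ri_table
    n = matrix.n
    if n not in ri_table:
        raise AhpError(f"no random consistency index for a matrix of order {n}")
    w = priority_weights(matrix)
    lm = lambda_max(matrix, w)
    ci = (lm - n) / (n - 1) if n > 1 else 0.0
    ri = ri_table[n]
    cr = ci / ri if ri > 0 else 0.0
    return PriorityResult(
        labels=matrix.labels, weights=w, lambda_max=lm, ci=ci, cr=cr, ri_used=ri
    )


def eigenvector_weights(matrix: PairwiseMatrix, *, tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """Normalised principal eigenvector by power iteration (cross-check only)."""
    a = matrix.entries
    w = np.full(matrix.n, 1.0 / matrix.n)
    for _ in range(max_iter):
        nxt = a @ w
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - w)) < tol:
            return nxt
        w = nxt
    return w


def compose_weights(
    hierarchy: HierarchyModel,
    *,
    cr_threshold: float = 0.1,
    ri_table: dict[int, float] | None = None,
    force: bool = False,
) -> dict[str, float]:
    """Flatten a two-level hierarchy into leaf weights summing to 1.

    Each leaf weight is (main-criterion weight) x (its local sub-weight).
    Any matrix with CR above ``cr_threshold`` aborts the composition by
    name unless ``force`` is set.
    """
    results = {"main": consistency(hierarchy.main, ri_table=ri_table)}
    for name, sub in hierarchy.subs.items():
        results[name] = consistency(sub, ri_table=ri_table)
    if not force:
        for name, res in results.items():
            if res.cr > cr_threshold:
                raise AhpError(
                    f"matrix {name!r} is inconsistent: CR {res.cr:.4f} "
                    f"> threshold {cr_threshold}"
                )
    main_w = results["main"].as_dict()
    flat: dict[str, float] = {}
    for m in hierarchy.main.labels:
        for leaf, w in results[m].as_dict().items():
            flat[leaf] = main_w[m] * w
    return flat


def hierarchy_report(
    hierarchy: HierarchyModel, *, ri_table: dict[int, float] | None = None
) -> dict[str, PriorityResult]:
    """Consistency diagnostics for the main matrix and every sub-matrix."""
    out = {"main": consistency(hierarchy.main, ri_table=ri_table)}
    for name, sub in hierarchy.subs.items():
        out[name] = consistency(sub, ri_table=ri_table)
    return out


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed AHP tables)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
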