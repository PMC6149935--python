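"""Weighted sparse-representation classification (WSRC).

A test vector y is coded as a sparse linear combination of the rows of a
labeled training matrix ("dictionary"): minimize the weighted l1 norm of
the coefficients subject to a reconstruction tolerance,

    min sum_i w_i |alpha_i|   s.t.  || y - alpha X ||_2 <= epsilon,

and the class whose rows reconstruct y with the smallest residual wins.
Locality enters through a Gaussian kernel on the distance from y to each
training row: the coefficient of a nearby row is cheap, that of a distant
row expensive.  The per-class residuals are mapped to a probability-like
score by one of three score functions that all agree on the decision at
their neutral threshold.

Samples are rows throughout (y = alpha X), the transpose of the
column-dictionary convention common in the sparse-coding literature.
The constrained solve is a LARS-lasso homotopy (see :mod:`._homotopy`):
along the lasso path the residual norm decreases monotonically while the
weighted l1 objective increases, so the constrained optimum is the path
point where the residual norm first reaches epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._homotopy import batch_solve, solve_constrained_l1

NON_BINDING, BINDING = 0, 1

#: exponent clip for the locality penalty; beyond it an atom is treated as
#: unreachable (its scaled copy underflows and is never selected)
_EXP_CLIP = 700.0

#: hard cap on homotopy path steps
_MAX_STEPS = 4000


@dataclass
class Dictionary:
    """Labeled training matrix the classifier codes test samples against.

    ``X`` holds one training feature vector per row; ``labels`` are 0/1
    (1 = binding, the minority class).  The Gram matrix of the rows is
    cached after the first batch classification.
    """

    X: np.ndarray
    labels: np.ndarray
    _gram: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] == 0:
            raise ValueError("dictionary X must be a non-empty n x m' matrix")
        if self.labels.shape != (self.X.shape[0],):
            raise ValueError("labels must have one entry per dictionary row")
        if not set(np.unique(self.labels)) <= {NON_BINDING, BINDING}:
            raise ValueError("labels must be 0 (non-binding) or 1 (binding)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def class_counts(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in (NON_BINDING, BINDING)}

    @property
    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = self.X @ self.X.T
        return self._gram


@dataclass(frozen=True)
class WsrcParams:
    """Classifier hyperparameters: Gaussian width sigma, tolerance epsilon,
    and which residual-to-score mapping to use (1, 2 or 3)."""

    sigma: float = 1.5
    epsilon: float = 0.5
    score_type: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.score_type not in (1, 2, 3):
            raise ValueError("score_type must be 1, 2 or 3")


@dataclass
class LocalityWeights:
    """Gaussian similarity lambda_i = exp(-||y - x_i||^2 / (2 sigma^2)).

    lambda_i lies in (0, 1] and equals 1 exactly when y coincides with
    training row i.  The l1 *penalty* applied to coefficient i is the
    inverse similarity exp(+d^2 / (2 sigma^2)), so distant rows are
    penalized more (the locality-weighted-SRC convention).
    """

    lam: np.ndarray

    @property
    def penalties(self) -> np.ndarray:
        """Per-coefficient l1 penalty weights (overflow maps to +inf,
        which disables the atom)."""
        with np.errstate(divide="ignore", over="ignore"):
            return 1.0 / self.lam


@dataclass
class SparseCode:
    """Solution of the weighted-l1 coding problem.

    ``residuals[c]`` is the reconstruction deviation using only class-c
    coefficients; ``objective`` is sum_i w_i |alpha_i|.  ``feasible`` is
    False when epsilon was below the attainable residual, in which case
    ``alpha`` is the path endpoint (minimum-residual boundary solution).
    """

    alpha: np.ndarray
    residuals: dict[int, float] = field(default_factory=dict)
    objective: float = 0.0
    feasible: bool = True


def locality_weights(y: np.ndarray, dictionary: Dictionary, sigma: float) -> LocalityWeights:
    """Gaussian locality weight of every training row relative to y."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y = np.asarray(y, dtype=float)
    d2 = np.sum((dictionary.X - y) ** 2, axis=1)
    return LocalityWeights(lam=np.exp(-d2 / (2.0 * sigma**2)))


def _squared_distances(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """All-pairs squared Euclidean distances, one gemm (clamped at 0)."""
    d2 = (
        np.sum(Y**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * (Y @ X.T)
    )
    return np.maximum(d2, 0.0)


def solve_weighted_l1(
    y: np.ndarray,
    dictionary: Dictionary,
    weights: np.ndarray,
    epsilon: float,
) -> SparseCode:
    """Minimize sum_i w_i |alpha_i| subject to ||y - alpha X||_2 <= epsilon.

    Substituting beta_i = w_i alpha_i reduces the problem to a plain
    l1-minimization over the re-scaled dictionary rows x_i / w_i, traced
    by the homotopy solver; scaling all weights by a positive constant
    leaves the argmin unchanged (weights are normalized by their minimum
    internally for conditioning).
    """
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("y contains NaN or infinite entries")
    if np.any(np.isnan(weights)) or np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if weights.shape != (dictionary.n,):
        raise ValueError("one weight per dictionary row required")
    alpha, _, feasible = solve_constrained_l1(
        dictionary.X, y, weights, epsilon, max_steps=_MAX_STEPS, G0=dictionary.gram
    )
    residuals = class_residuals(y, dictionary, alpha)
    finite = np.isfinite(weights)
    objective = float(np.sum(weights[finite] * np.abs(alpha[finite])))
    return SparseCode(
        alpha=alpha, residuals=residuals, objective=objective, feasible=bool(feasible)
    )


def class_residuals(y: np.ndarray, dictionary: Dictionary, alpha: np.ndarray) -> dict[int, float]:
    """Reconstruction deviation per class, zeroing the other class's coefficients."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (dictionary.n,):
        raise ValueError("alpha must have one coefficient per dictionary row")
    out = {}
    for c in (NON_BINDING, BINDING):
        mask = dictionary.labels == c
        out[c] = float(np.linalg.norm(y - (alpha * mask) @ dictionary.X))
    return out


def score(v_binding: float, v_nonbinding: float, score_type: int = 1) -> float:
    """Map the two class residuals to a probability-like score.

    type 1: 2 - v_b/v_nb            (range (-inf, 2], neutral value 1)
    type 2: 1 - v_b/(v_nb + v_b)    (range [0, 1],    neutral value 0.5)
    type 3: sigmoid(v_nb - v_b)     (range (0, 1),    neutral value 0.5)

    Degenerate conventions: type 1 with v_nb = 0 returns -inf (unless
    v_b = 0 too, a tie, which returns the neutral 1); type 2 with both
    residuals 0 returns 0.5.
    """
    if v_binding < 0 or v_nonbinding < 0:
        raise ValueError("residuals must be non-negative")
    if score_type == 1:
        if v_nonbinding == 0:
            return 1.0 if v_binding == 0 else float("-inf")
        return 2.0 - v_binding / v_nonbinding
    if score_type == 2:
        tot = v_binding + v_nonbinding
        return 0.5 if tot == 0 else 1.0 - v_binding / tot
    if score_type == 3:
        return float(1.0 / (1.0 + np.exp(-(v_nonbinding - v_binding))))
    raise ValueError("score_type must be 1, 2 or 3")


def classify(
    y: np.ndarray,
    dictionary: Dictionary,
    params: WsrcParams = WsrcParams(),
) -> tuple[int, float]:
    """Label y by minimal class residual and return (label, score).

    Ties (equal residuals) go to non-binding, the majority class.
    """
    counts = dictionary.class_counts
    if min(counts.values()) == 0:
        raise ValueError("dictionary must contain both classes")
    lw = locality_weights(y, dictionary, params.sigma)
    code = solve_weighted_l1(y, dictionary, lw.penalties, params.epsilon)
    v_nb, v_b = code.residuals[NON_BINDING], code.residuals[BINDING]
    label = BINDING if v_b < v_nb else NON_BINDING
    return label, score(v_b, v_nb, params.score_type)


def classify_batch(
    Y: np.ndarray,
    dictionary: Dictionary,
    params: WsrcParams = WsrcParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`classify` over the rows of Y.

    Distances come from one gemm; the per-sample homotopy solves run in a
    single compiled loop sharing the dictionary Gram matrix.
    """
    Y = np.ascontiguousarray(np.atleast_2d(np.asarray(Y, dtype=float)))
    if Y.shape[1] != dictionary.X.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: samples have {Y.shape[1]}, "
            f"dictionary has {dictionary.X.shape[1]}"
        )
    d2 = _squared_distances(Y, dictionary.X)
    expo = d2 / (2.0 * params.sigma**2)
    # per-row min-normalized inverse penalties: invW = exp(min - expo)
    invW = np.exp(np.maximum(expo.min(axis=1)[:, None] - expo, -_EXP_CLIP))
    v_nb, v_b, _ = batch_solve(
        dictionary.X,
        dictionary.gram,
        dictionary.labels.astype(np.int64),
        Y,
        invW,
        params.epsilon,
        _MAX_STEPS,
    )
    labels = np.where(v_b < v_nb, BINDING, NON_BINDING)
    scores = np.array(
        [score(b, nb, params.score_type) for b, nb in zip(v_b, v_nb)]
    )
    return labels, scores
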