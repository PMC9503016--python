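"""Conditional random field over a grid of patch labels, with mean-field
marginal inference.

The random field X = {X_1..X_N} assigns each patch in a g x g grid a label
in {background, GM, WM}, conditioned on the patch *embeddings*
I = {I_1..I_N} produced by the classifier.  The Gibbs distribution is

    P(X | I) = exp(-E(X | I)) / Z(I),
    E(X | I) = sum_i psi_u(x_i | I_i) + sum_{i<j} psi_p(x_i, x_j | I_i, I_j),

with the unary potential taken as the negative log-softmax of the
classifier logits and a pairwise potential built from cosine similarity:

    psi_p = H(x_i = x_j) * w_ij * (1 - cos(I_i, I_j)).

With the indicator on label *agreement* (the printed form), agreeing on
dissimilar patches costs w_ij * (1 - cos) while disagreement is free; an
``indicator_mode="different"`` switch flips the indicator so that
*disagreement on similar patches* is what costs (the smoothing-CRF
convention).  The default follows the printed form.

Exact marginals require summing 3^N assignments; :func:`meanfield_infer`
approximates them with the factorized distribution Q(X) = prod_i Q_i(x_i)
that minimizes KL(Q || P) by sequential coordinate updates

    log Q_i(x_i) <- -psi_u(x_i) - sum_{j != i} sum_{x_j} Q_j(x_j) psi_p + c.

Each sequential update is the exact minimizer of the KL objective in its
coordinate, so KL(Q || P) is non-increasing along the sweep — a property
the test-bench verifies against the brute-force enumeration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .nn.autograd import Tensor, stack

NUM_CLASSES = 3

__all__ = ["PatchGridObservation", "MarginalField", "grid_pairwise_weights",
           "unary_potential", "pairwise_potential", "energy",
           "exact_marginals_bruteforce", "meanfield_update",
           "meanfield_infer", "ncrf_loss", "meanfield_marginals_autograd"]


@dataclass
class PatchGridObservation:
    grid_shape: tuple               # (g, g), N = g*g patches row-major
    embeddings: np.ndarray          # (N, d)
    unary_scores: np.ndarray        # (N, 3) classifier logits

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.unary_scores = np.asarray(self.unary_scores, dtype=np.float64)
        n = self.grid_shape[0] * self.grid_shape[1]
        if self.embeddings.shape[0] != n or self.unary_scores.shape != (n, 3):
            raise ValueError("observation sizes inconsistent with grid")
        if not (np.isfinite(self.embeddings).all()
                and np.isfinite(self.unary_scores).all()):
            raise ValueError("non-finite values in observation")

    @property
    def n(self) -> int:
        return self.embeddings.shape[0]


@dataclass
class MarginalField:
    q: np.ndarray                                # (N, 3) rows on the simplex
    iteration_trace: list = field(default_factory=list)   # max row change

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=np.float64)
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("marginal rows must sum to 1")

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.q, axis=1)


def grid_pairwise_weights(grid_shape: tuple, w: float = 1.0) -> np.ndarray:
    """4-neighbor coupling on a row-major grid: w for neighbors, else 0."""
    g_h, g_w = grid_shape
    n = g_h * g_w
    weights = np.zeros((n, n))
    for r in range(g_h):
        for c in range(g_w):
            i = r * g_w + c
            if c + 1 < g_w:
                weights[i, i + 1] = weights[i + 1, i] = w
            if r + 1 < g_h:
                weights[i, i + g_w] = weights[i + g_w, i] = w
    return weights


def _check_weights(weights: np.ndarray, n: int) -> np.ndarray:
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (n, n):
        raise ValueError("pairwise weight matrix has wrong shape")
    if not np.allclose(weights, weights.T):
        raise ValueError("pairwise weights must be symmetric")
    if np.any(np.diag(weights) != 0):
        raise ValueError("pairwise weights must have zero diagonal")
    return weights


def _log_softmax(scores: np.ndarray) -> np.ndarray:
    shift = scores - scores.max(axis=-1, keepdims=True)
    return shift - np.log(np.exp(shift).sum(axis=-1, keepdims=True))


def unary_potential(obs: PatchGridObservation, i: int, x_i: int) -> float:
    """psi_u(x_i | I_i): negative log-softmax of the patch logits (a cost)."""
    if not (0 <= i < obs.n and 0 <= x_i < NUM_CLASSES):
        raise IndexError("patch index or class out of range")
    return float(-_log_softmax(obs.unary_scores[i])[x_i])


def _unary_matrix(obs: PatchGridObservation) -> np.ndarray:
    return -_log_softmax(obs.unary_scores)        # (N, 3) costs


def cosine_distance_matrix(embeddings: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(embeddings, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding: cosine undefined")
    unit = embeddings / norms[:, None]
    return 1.0 - unit @ unit.T


def pairwise_potential(i_emb: np.ndarray, j_emb: np.ndarray, x_i: int,
                       x_j: int, w_ij: float,
                       indicator_mode: str = "same") -> float:
    """psi_p per the cosine form; 0 unless the label indicator fires."""
    if indicator_mode == "same":
        fires = x_i == x_j
    elif indicator_mode == "different":
        fires = x_i != x_j
    else:
        raise ValueError("indicator_mode must be 'same' or 'different'")
    if not fires:
        return 0.0
    ni, nj = np.linalg.norm(i_emb), np.linalg.norm(j_emb)
    if ni == 0 or nj == 0:
        raise ValueError("zero-norm embedding: cosine undefined")
    cos = float(np.dot(i_emb, j_emb) / (ni * nj))
    return float(w_ij * (1.0 - cos))


def energy(assignment, obs: PatchGridObservation, weights: np.ndarray,
           indicator_mode: str = "same") -> float:
    """E(X|I) = sum_i psi_u + sum_{i<j} psi_p."""
    x = np.asarray(assignment, dtype=int)
    if x.shape != (obs.n,):
        raise ValueError("assignment length differs from grid size")
    weights = _check_weights(weights, obs.n)
    unary = _unary_matrix(obs)
    e = float(unary[np.arange(obs.n), x].sum())
    dist = cosine_distance_matrix(obs.embeddings)
    same = x[:, None] == x[None, :]
    fires = same if indicator_mode == "same" else ~same
    pair = weights * dist * fires
    e += float(np.triu(pair, k=1).sum())
    return e


def _pairwise_energy_matrix(obs, weights, indicator_mode) -> np.ndarray:
    """coupling[i, j] = w_ij * (1 - cos(I_i, I_j)); indicator applied later."""
    return _check_weights(weights, obs.n) * cosine_distance_matrix(
        obs.embeddings)


def exact_marginals_bruteforce(obs: PatchGridObservation,
                               weights: np.ndarray,
                               indicator_mode: str = "same",
                               return_joint: bool = False):
    """Enumerate all 3^N assignments of the Gibbs distribution (N <= 9).

    Test oracle only: returns the exact :class:`MarginalField`, and with
    ``return_joint=True`` also the full normalized joint over assignments.
    """
    n = obs.n
    if n > 9:
        raise ValueError("brute-force oracle limited to N <= 9")
    weights = _check_weights(weights, n)
    unary = _unary_matrix(obs)
    coupling = weights * cosine_distance_matrix(obs.embeddings)
    assignments = np.array(list(product(range(NUM_CLASSES), repeat=n)),
                           dtype=int)
    energies = unary[np.arange(n), assignments].sum(axis=1)
    iu, ju = np.triu_indices(n, k=1)
    same = assignments[:, iu] == assignments[:, ju]
    fires = same if indicator_mode == "same" else ~same
    energies = energies + (fires * coupling[iu, ju]).sum(axis=1)
    logp = -energies - np.logaddexp.reduce(-energies)
    p = np.exp(logp)
    q = np.zeros((n, NUM_CLASSES))
    for c in range(NUM_CLASSES):
        q[:, c] = p @ (assignments == c)
    q /= q.sum(axis=1, keepdims=True)
    mf = MarginalField(q=q)
    if return_joint:
        return mf, assignments, p
    return mf


def _update_row(q: np.ndarray, unary: np.ndarray, coupling: np.ndarray,
                i: int, indicator_mode: str) -> np.ndarray:
    """Mean-field coordinate update for row i (returns the new row)."""
    if indicator_mode == "same":
        # sum_j w_ij d_ij Q_j(x): expected pairwise cost of agreeing
        pair_cost = coupling[i] @ q
    else:
        pair_cost = coupling[i] @ (1.0 - q)
    logq = -unary[i] - pair_cost
    logq -= logq.max()
    row = np.exp(logq)
    return row / row.sum()


def meanfield_update(q_field: MarginalField, obs: PatchGridObservation,
                     weights: np.ndarray, i: int,
                     indicator_mode: str = "same") -> MarginalField:
    """Single coordinate update of Q_i; all other rows unchanged."""
    if not (0 <= i < obs.n):
        raise IndexError("patch index out of range")
    coupling = _pairwise_energy_matrix(obs, weights, indicator_mode)
    unary = _unary_matrix(obs)
    q = q_field.q.copy()
    q[i] = _update_row(q, unary, coupling, i, indicator_mode)
    return MarginalField(q=q, iteration_trace=list(q_field.iteration_trace))


def meanfield_infer(obs: PatchGridObservation, weights: np.ndarray,
                    max_sweeps: int = 10, tol: float = 1e-6,
                    indicator_mode: str = "same",
                    schedule: str = "sequential") -> MarginalField:
    """Mean-field marginal inference by coordinate sweeps.

    Q is initialized to the decoupled softmax (exact when all pairwise
    weights vanish).  ``sequential`` updates rows one at a time and carries
    the KL-monotonicity guarantee; ``parallel`` updates all rows from the
    previous sweep's field (faster, no monotonicity claim).
    """
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be >= 1")
    coupling = _pairwise_energy_matrix(obs, weights, indicator_mode)
    unary = _unary_matrix(obs)
    q = np.exp(-unary)
    q /= q.sum(axis=1, keepdims=True)
    trace: list[float] = []
    for _ in range(max_sweeps):
        q_old = q.copy()
        if schedule == "sequential":
            for i in range(obs.n):
                q[i] = _update_row(q, unary, coupling, i, indicator_mode)
        elif schedule == "parallel":
            q = np.stack([_update_row(q_old, unary, coupling, i,
                                      indicator_mode)
                          for i in range(obs.n)])
        else:
            raise ValueError("schedule must be 'sequential' or 'parallel'")
        change = float(np.abs(q - q_old).max())
        trace.append(change)
        if change < tol:
            break
    return MarginalField(q=q, iteration_trace=trace)


def center_marginal(field: MarginalField, grid_shape: tuple) -> np.ndarray:
    """Distribution of the central patch of the grid (g odd)."""
    g_h, g_w = grid_shape
    return field.q[(g_h // 2) * g_w + (g_w // 2)]


def ncrf_loss(q_field: MarginalField, labels) -> float:
    """Mean cross-entropy -log Q_i(true label), floored at 1e-12."""
    labels = np.asarray(labels, dtype=int)
    q = q_field.q
    if labels.shape != (q.shape[0],):
        raise ValueError("label length differs from field size")
    picked = np.clip(q[np.arange(q.shape[0]), labels], 1e-12, None)
    return float(-np.log(picked).mean())


# -- differentiable unrolled mean field ---------------------------------------

def meanfield_marginals_autograd(unary_scores: Tensor,
                                 coupling: np.ndarray,
                                 n_sweeps: int = 5,
                                 indicator_mode: str = "same") -> Tensor:
    """Unrolled sequential mean field as an autograd graph.

    ``unary_scores`` is an (N, 3) leaf tensor of classifier logits;
    ``coupling`` holds the constant w_ij * (1 - cos) factors.  Returns the
    (N, 3) marginal field with gradients flowing back to the logits, so a
    cross-entropy on the marginals trains the unaries end to end.
    """
    n = unary_scores.shape[0]
    unary = -unary_scores.log_softmax(axis=1)           # costs, (N, 3)
    # init: decoupled softmax of -psi_u
    rows = [(-unary[i]).log_softmax().exp() for i in range(n)]
    for _ in range(n_sweeps):
        for i in range(n):
            q_mat = stack(rows)                         # (N, 3)
            if indicator_mode == "same":
                pair_cost = Tensor(coupling[i]) @ q_mat
            else:
                pair_cost = Tensor(coupling[i]) @ (1.0 - q_mat)
            rows[i] = (-unary[i] - pair_cost).log_softmax().exp()
    return stack(rows)


def ncrf_loss_autograd(marginals: Tensor, labels) -> Tensor:
    labels = np.asarray(labels, dtype=int)
    n = marginals.shape[0]
    picked = marginals[np.arange(n), labels]
    floored = Tensor(np.clip(picked.data, 1e-12, None))
    # gradient flows through `picked`; the floor only guards the log's value
    return -(picked + (floored - picked.detach())).log().sum() * (1.0 / n)
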