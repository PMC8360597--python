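"""Task-responsiveness of a vine: Wasserstein statistic + block permutation.

The null hypothesis is that the condition labels produce two groups of
vine-stripped persistence diagrams no more distinct than random labels.
The statistic is the joint within-group cohesion

    S = sum over the two groups of
        mean over unordered within-group pairs (i, j) of W_q(D_i, D_j)^q,

small when diagrams within each condition resemble each other.  W_q is the
q-Wasserstein diagram distance with sup-norm ground metric: unmatched
points pay their distance (death - birth)/2 to the diagonal, so both a
feature's persistence and its sheer presence/absence carry signal -- an
empty diagram at a time index is meaningful, not missing data.

Labels are permuted at the level of whole contiguous task blocks of the
two tested conditions (other conditions stay put), preserving within-block
temporal autocorrelation.  The plus-one estimator
p = (1 + #{S_perm <= S_obs}) / (1 + n_perm) never returns zero and is
valid under Monte-Carlo sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import ValidationError
from .homology import Diagram


@dataclass(frozen=True)
class TaskDesign:
    """Per-time-index condition labels with contiguous block structure.

    ``blocks`` are ``(condition, start, stop)`` half-open runs partitioning
    ``0 .. T-1``; they are derived from the labels.
    """

    labels: tuple[str, ...]
    blocks: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_labels(cls, labels) -> "TaskDesign":
        labels = tuple(labels)
        if not labels:
            raise ValidationError("empty design")
        blocks = []
        start = 0
        for t in range(1, len(labels) + 1):
            if t == len(labels) or labels[t] != labels[start]:
                blocks.append((labels[start], start, t))
                start = t
        return cls(labels=labels, blocks=tuple(blocks))

    @property
    def T(self) -> int:
        return len(self.labels)

    def indices(self, condition: str) -> np.ndarray:
        return np.array([t for t, l in enumerate(self.labels) if l == condition])


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    null_statistics: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    group_labels: tuple[str, str]

    def to_dict(self) -> dict:
        return {
            "observed_statistic": self.observed_statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "group_labels": list(self.group_labels),
            "null_statistics": [float(x) for x in self.null_statistics],
        }


def _diagram_points(diagram, dim: int) -> np.ndarray:
    if isinstance(diagram, Diagram):
        return diagram.points(dim)
    arr = np.asarray(diagram, dtype=float)
    return arr.reshape(-1, 2)


def wasserstein(D1, D2, q: float = 2.0, dim: int = 1) -> float:
    """Exact q-Wasserstein distance between single-dimension diagrams.

    Computed by optimal assignment on the diagonal-augmented cost matrix:
    point-to-point cost is the sup-norm in the (birth, death) plane, and
    every point may instead match its diagonal projection at cost
    (death - birth) / 2.  Truncated deaths are already recorded at r_max.
    Empty vs empty is 0.
    """
    if q < 1:
        raise ValidationError("q must be >= 1")
    P1, P2 = _diagram_points(D1, dim), _diagram_points(D2, dim)
    n, m = len(P1), len(P2)
    if n == 0 and m == 0:
        return 0.0
    diag1 = (P1[:, 1] - P1[:, 0]) / 2.0 if n else np.empty(0)
    diag2 = (P2[:, 1] - P2[:, 0]) / 2.0 if m else np.empty(0)
    size = n + m
    cost = np.zeros((size, size))
    if n and m:
        cost[:n, :m] = np.abs(P1[:, None, :] - P2[None, :, :]).max(axis=2) ** q
    cost[:n, m:] = (diag1 ** q)[:, None]
    cost[n:, :m] = (diag2 ** q)[None, :]
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() ** (1.0 / q))


def _pairwise_qth_power(diagrams, q: float, dim: int) -> np.ndarray:
    pts = [_diagram_points(d, dim) for d in diagrams]
    k = len(pts)
    M = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        M[i, j] = M[j, i] = wasserstein(pts[i], pts[j], q=q, dim=dim) ** q
    return M


def _statistic_from_matrix(M: np.ndarray, groups) -> float:
    s = 0.0
    for idx in groups:
        k = len(idx)
        if k < 2:
            raise ValidationError("each group needs at least 2 diagrams")
        sub = M[np.ix_(idx, idx)]
        s += float(sub.sum()) / (k * (k - 1))  # mean over unordered pairs
    return s


def group_statistic(diagrams_by_t, labels, q: float = 2.0, dim: int = 1) -> float:
    """Within-group mean pairwise q-th-power Wasserstein, summed over groups."""
    labels = list(labels)
    if len(labels) != len(diagrams_by_t):
        raise ValidationError("one label per diagram required")
    conds = sorted(set(labels))
    if len(conds) != 2:
        raise ValidationError(f"exactly two label values required, got {conds}")
    M = _pairwise_qth_power(diagrams_by_t, q, dim)
    groups = [[i for i, l in enumerate(labels) if l == c] for c in conds]
    return _statistic_from_matrix(M, groups)


def permute_labels_blockwise(
    design: TaskDesign, conditions_under_test, rng: np.random.Generator
):
    """Permute the two tested conditions' block labels uniformly at random.

    Whole contiguous blocks swap condition assignments; every time index
    keeps its block membership, and blocks of other conditions are
    untouched.
    """
    a, b = conditions_under_test
    rows = [k for k, (c, _, _) in enumerate(design.blocks) if c in (a, b)]
    if sum(1 for k in rows if design.blocks[k][0] == a) < 2 or sum(
        1 for k in rows if design.blocks[k][0] == b
    ) < 2:
        raise ValidationError("need at least 2 blocks of each tested condition")
    perm = rng.permutation(len(rows))
    new_labels = list(design.labels)
    conds = [design.blocks[k][0] for k in rows]
    for slot, src in zip(rows, perm):
        c = conds[src]
        _, start, stop = design.blocks[slot]
        new_labels[start:stop] = [c] * (stop - start)
    return tuple(new_labels)


def permutation_test(
    diagrams_by_t,
    design: TaskDesign,
    conditions=("encoding", "retrieval"),
    n_perm: int = 4999,
    q: float = 2.0,
    seed: int = 0,
    dim: int = 1,
) -> PermutationResult:
    """Block-permutation test of vine task-responsiveness.

    ``diagrams_by_t`` are the vine-stripped diagrams, one per time index of
    the design (empty diagrams allowed).  Deterministic given ``seed``.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be at least 99")
    if len(diagrams_by_t) != design.T:
        raise ValidationError("need one diagram per design time index")
    a, b = conditions
    used_t = [t for t, l in enumerate(design.labels) if l in (a, b)]
    pos = {t: i for i, t in enumerate(used_t)}
    M = _pairwise_qth_power([diagrams_by_t[t] for t in used_t], q, dim)

    def stat(labels) -> float:
        groups = [
            [pos[t] for t in used_t if labels[t] == c] for c in (a, b)
        ]
        return _statistic_from_matrix(M, groups)

    observed = stat(design.labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = stat(permute_labels_blockwise(design, (a, b), rng))
    p = (1.0 + float(np.sum(null <= observed))) / (1.0 + n_perm)
    return PermutationResult(
        observed_statistic=float(observed),
        null_statistics=null,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        group_labels=(a, b),
    )
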