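"""Affinity-propagation clustering of temporal expression profiles.

Similarity between gene profiles is the negative Euclidean distance;
exemplars emerge from responsibility/availability message passing with
damping.  The diagonal (preference) defaults to the median off-diagonal
similarity, the usual choice for a moderate number of clusters.  A tiny
seeded jitter (relative scale 1e-12) breaks degeneracies such as exactly
tied similarities without sacrificing reproducibility.  After message
passing, the exemplar set is polished by alternating reassignment and
within-cluster exemplar updates to a fixed point, which only ever
increases the net similarity of the solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ValidationError

__all__ = [
    "profile_similarity",
    "affinity_propagation",
    "ClusterAssignment",
    "net_similarity",
    "mean_condition_profiles",
]


def mean_condition_profiles(values: pd.DataFrame, design, conditions=None) -> pd.DataFrame:
    """Per-gene mean log2 expression for each condition (genes x conditions)."""
    conditions = conditions or design.conditions()
    cols = {}
    for c in conditions:
        samples = [s for s in design.samples_for(c) if s in values.columns]
        if not samples:
            raise ValidationError(f"condition {c!r} has no samples in matrix")
        cols[c] = values[samples].mean(axis=1)
    return pd.DataFrame(cols)


def profile_similarity(profiles: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise similarity s(i,j) = -||x_i - x_j||_2; diagonal left at 0.

    The diagonal is a placeholder overwritten by the preference inside
    :func:`affinity_propagation`.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValidationError("profiles must be a 2-D array (items x conditions)")
    if not np.isfinite(X).all():
        raise ValidationError("profiles contain missing or non-finite values")
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    return -np.sqrt(d2)


@dataclass
class ClusterAssignment:
    """Result of exemplar-based clustering.

    labels are contiguous integers 1..k (ordered by exemplar index);
    exemplars maps each label to the index of its exemplar item, which
    is always a member of its own cluster.
    """

    labels: np.ndarray  # per item, 1..k
    exemplars: dict[int, int]  # label -> item index
    net_similarity: float
    n_iter: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def net_similarity(s: np.ndarray, exemplar_idx: np.ndarray, preference: float) -> float:
    """Net similarity of an exemplar set: each non-exemplar contributes its
    best similarity to an exemplar, each exemplar contributes the preference."""
    exemplar_idx = np.asarray(sorted(set(int(i) for i in exemplar_idx)))
    n = s.shape[0]
    is_ex = np.zeros(n, dtype=bool)
    is_ex[exemplar_idx] = True
    total = preference * len(exemplar_idx)
    if (~is_ex).any():
        total += s[np.ix_(~is_ex, is_ex)].max(axis=1).sum()
    return float(total)


def affinity_propagation(
    s: np.ndarray,
    preference: float | str = "median",
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 50,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster items by affinity propagation on a similarity matrix.

    Parameters
    ----------
    s : square symmetric array of pairwise similarities (off-diagonal).
    preference : common diagonal value; ``"median"`` uses the median
        off-diagonal similarity.
    damping : message damping factor in [0.5, 1).
    conv_iter : sweeps the exemplar set must stay unchanged to declare
        convergence.
    seed : seeds the degeneracy-breaking jitter.
    """
    S0 = np.asarray(s, dtype=float)
    if S0.ndim != 2 or S0.shape[0] != S0.shape[1]:
        raise ValidationError("similarity matrix must be square")
    off = ~np.eye(S0.shape[0], dtype=bool)
    if not np.allclose(S0[off], S0.T[off]):
        raise ValidationError("similarity matrix must be symmetric")
    if not 0.5 <= damping < 1:
        raise ValidationError("damping must be in [0.5, 1)")
    n = S0.shape[0]
    if preference == "median":
        pref = float(np.median(S0[off])) if n > 1 else 0.0
    else:
        pref = float(preference)

    if n == 1:
        return ClusterAssignment(
            labels=np.array([1]),
            exemplars={1: 0},
            net_similarity=pref,
            n_iter=0,
            converged=True,
        )

    S = S0.copy()
    np.fill_diagonal(S, pref)
    rng = np.random.default_rng(seed)
    scale = np.abs(S).max() or 1.0
    S_work = S + rng.standard_normal(S.shape) * 1e-12 * scale

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    prev_ex: np.ndarray | None = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + S_work
        first = AS.argmax(axis=1)
        best = AS[idx, first]
        AS[idx, first] = -np.inf
        second = AS.max(axis=1)
        AS[idx, first] = best
        Rnew = S_work - best[:, None]
        Rnew[idx, first] = S_work[idx, first] - second
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, 0.0)
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0.0, R.diagonal()[None, :] + colsum[None, :] - Rp)
        np.fill_diagonal(Anew, colsum)
        A = damping * A + (1 - damping) * Anew

        ex = (A.diagonal() + R.diagonal()) > 0
        if prev_ex is not None and np.array_equal(ex, prev_ex) and ex.any():
            stable += 1
            if stable >= conv_iter:
                converged = True
                break
        else:
            stable = 0
        prev_ex = ex

    ex_idx = np.flatnonzero((A.diagonal() + R.diagonal()) > 0)
    if ex_idx.size == 0:
        ex_idx = np.array([int((A.diagonal() + R.diagonal()).argmax())])

    ex_idx, labels0 = _polish(S, ex_idx)
    ex_idx = _local_search(S0, ex_idx, pref)
    if n <= 32:
        # tiny instances: deterministic multi-start from every singleton
        # exemplar set escapes local optima of the message-passing solution
        best_val = net_similarity(S0, ex_idx, pref)
        for j in range(n):
            cand = _local_search(S0, np.array([j]), pref)
            val = net_similarity(S0, cand, pref)
            if val > best_val + 1e-12 * (np.abs(S0).max() + abs(pref) + 1):
                ex_idx, best_val = cand, val
    ex_idx = _merge_ties(S0, ex_idx, pref)
    ex_idx, labels0 = _polish(S, ex_idx)
    # contiguous labels 1..k ordered by exemplar index
    label_of_ex = {int(e): i + 1 for i, e in enumerate(ex_idx)}
    labels = np.array([label_of_ex[int(ex_idx[j])] for j in labels0])
    exemplars = {i + 1: int(e) for i, e in enumerate(ex_idx)}
    return ClusterAssignment(
        labels=labels,
        exemplars=exemplars,
        net_similarity=net_similarity(S0, ex_idx, pref),
        n_iter=it,
        converged=converged,
    )


def _local_search(
    S0: np.ndarray, ex_idx: np.ndarray, pref: float, max_rounds: int = 200
) -> np.ndarray:
    """Best-improvement local search on the exemplar-set objective.

    Starting from the message-passing solution, repeatedly applies the
    best strictly improving add, drop or swap of an exemplar.  Swap
    moves are scanned only for small instances (n <= 200), where exact
    optimality matters most; adds and drops alone keep larger problems
    near-optimal at linear scan cost.
    """
    n = S0.shape[0]
    ex = sorted(set(int(i) for i in ex_idx))
    current = net_similarity(S0, np.array(ex), pref)
    tol = 1e-12 * (np.abs(S0).max() + abs(pref) + 1)
    for _ in range(max_rounds):
        best_val, best_set = current, None
        non_ex = [i for i in range(n) if i not in ex]
        candidates: list[list[int]] = []
        candidates.extend(ex + [j] for j in non_ex)
        if len(ex) > 1:
            candidates.extend([x for x in ex if x != e] for e in ex)
        if n <= 200 and len(ex) >= 1:
            candidates.extend(
                [x for x in ex if x != e] + [j] for e in ex for j in non_ex
            )
        for cand in candidates:
            val = net_similarity(S0, np.array(cand), pref)
            if val > best_val + tol:
                best_val, best_set = val, cand
        if best_set is None:
            break
        ex, current = sorted(best_set), best_val
    return np.asarray(ex)


def _merge_ties(S0: np.ndarray, ex_idx: np.ndarray, pref: float) -> np.ndarray:
    """Greedily drop exemplars whose removal does not decrease net
    similarity (resolves degenerate geometries, e.g. identical items,
    toward the smallest equivalent exemplar set)."""
    ex = sorted(set(int(i) for i in ex_idx))
    tol = 1e-9 * (np.abs(S0).max() + abs(pref) + 1)
    current = net_similarity(S0, np.array(ex), pref)
    improved = True
    while improved and len(ex) > 1:
        improved = False
        for e in list(ex):
            cand = [x for x in ex if x != e]
            val = net_similarity(S0, np.array(cand), pref)
            if val >= current - tol:
                ex = cand
                current = val
                improved = True
                break
    return np.asarray(ex)


def _polish(S: np.ndarray, ex_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternate assignment / exemplar update until the exemplar set is stable.

    S carries the preference on its diagonal, so choosing the item that
    maximizes within-cluster similarity sums accounts for the exemplar's
    own preference implicitly (it cancels across candidates).
    """
    ex_idx = np.asarray(sorted(set(int(i) for i in ex_idx)))
    for _ in range(100):
        assign = ex_idx[S[:, ex_idx].argmax(axis=1)]
        assign[ex_idx] = ex_idx
        new_ex = []
        for e in ex_idx:
            members = np.flatnonzero(assign == e)
            within = S[np.ix_(members, members)].sum(axis=0)
            new_ex.append(int(members[within.argmax()]))
        new_ex = np.asarray(sorted(set(new_ex)))
        if np.array_equal(new_ex, ex_idx):
            break
        ex_idx = new_ex
    assign = ex_idx[S[:, ex_idx].argmax(axis=1)]
    assign[ex_idx] = ex_idx
    # map each item to the position of its exemplar in ex_idx
    pos = {int(e): i for i, e in enumerate(ex_idx)}
    labels0 = np.array([pos[int(a)] for a in assign])
    return ex_idx, labels0
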