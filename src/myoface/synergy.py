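"""Muscle synergy extraction by non-negative matrix factorization.

The muscles-by-time envelope matrix ``U`` is factorized as ``U ~ Ws @ C``
with ``Ws`` (muscles x s) the synergy matrix and ``C`` (s x time) the
activation coefficients, minimizing the Frobenius reconstruction error with
scikit-learn's coordinate-descent solver over multiple random restarts.

Model order is chosen by the variance-accounted-for rule::

    VAF = 100 * (1 - ||U - Ws C||_F^2 / ||U||_F^2)

with the smallest rank reaching at least 90% selected — the standard
criterion in the muscle-synergy literature.  Columns of ``Ws`` are
normalized to unit Euclidean norm (magnitude carried by ``C``) and sorted
by descending activation energy so that decompositions are comparable
across participants; cross-participant comparison itself always goes
through optimal column matching under cosine similarity.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import NMF

from .core import NEUTRAL, TrialStructure

VAF_THRESHOLD = 90.0
VAF_CURVE_TOL_PP = 0.5  # solver tolerance on monotonicity of the VAF curve


@dataclass
class SynergyDecomposition:
    Ws: np.ndarray                  # muscles x s, unit-norm columns
    C: np.ndarray                   # s x time
    vaf_percent: float
    rank: int
    restart_losses: list[float] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return self.Ws @ self.C


@dataclass
class VafCurve:
    vaf_by_rank: dict[int, float]

    def __getitem__(self, rank: int) -> float:
        return self.vaf_by_rank[rank]


def compute_vaf(U: np.ndarray, Ws: np.ndarray, C: np.ndarray) -> float:
    """Global Frobenius variance accounted for, in percent."""
    U = np.asarray(U, dtype=float)
    total = np.sum(U * U)
    if total == 0:
        raise ValueError("VAF undefined for an all-zero signal")
    resid = U - Ws @ C
    return float(100.0 * (1.0 - np.sum(resid * resid) / total))


def _normalize_columns(Ws: np.ndarray, C: np.ndarray):
    norms = np.linalg.norm(Ws, axis=0)
    norms[norms == 0] = 1.0
    return Ws / norms, C * norms[:, None]


def _sort_by_energy(Ws: np.ndarray, C: np.ndarray):
    energy = np.sum(C * C, axis=1)
    order = np.argsort(-energy)
    return Ws[:, order], C[order]


def fit_nmf(U: np.ndarray, s: int, n_restarts: int = 10, seed: int = 0,
            max_iter: int = 300, tol: float = 1e-5) -> SynergyDecomposition:
    """Best-of-restarts rank-``s`` NMF of a non-negative envelope matrix."""
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("U must be 2-D (muscles x time)")
    if np.any(U < 0):
        raise ValueError("NMF requires non-negative input")
    if not np.any(U > 0):
        raise ValueError("NMF is undefined for an all-zero matrix")
    if not 1 <= s <= U.shape[0]:
        raise ValueError(f"rank {s} outside 1..{U.shape[0]}")
    if n_restarts < 1:
        raise ValueError("need at least one restart")

    X = U.T  # sklearn layout: samples x features = time x muscles
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best = None
    losses = []
    for rs in restart_seeds:
        model = NMF(n_components=s, init="random", solver="cd",
                    beta_loss="frobenius", max_iter=max_iter, tol=tol,
                    random_state=int(rs))
        with warnings.catch_warnings():
            # restarts run on a fixed iteration budget; the best restart is
            # kept by explicit loss comparison, so per-restart convergence
            # warnings are expected and unhelpful
            warnings.simplefilter("ignore", category=UserWarning)
            Ct = model.fit_transform(X)   # time x s
        loss = float(np.linalg.norm(X - Ct @ model.components_, "fro"))
        losses.append(loss)
        if best is None or loss < best[0]:
            best = (loss, model.components_.T.copy(), Ct.T.copy())
    _, Ws, C = best
    Ws, C = _normalize_columns(Ws, C)
    Ws, C = _sort_by_energy(Ws, C)
    return SynergyDecomposition(Ws, C, compute_vaf(U, Ws, C), s, losses)


def select_rank(U: np.ndarray, threshold: float = VAF_THRESHOLD,
                n_restarts: int = 10, seed: int = 0) -> tuple[int, VafCurve]:
    """Smallest rank whose VAF reaches ``threshold``, plus the full curve."""
    if not 0 < threshold <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    U = np.asarray(U, dtype=float)
    n_muscles = U.shape[0]
    curve = {}
    selected = None
    for s in range(1, n_muscles + 1):
        dec = fit_nmf(U, s, n_restarts=n_restarts, seed=seed + s)
        curve[s] = dec.vaf_percent
        if selected is None and dec.vaf_percent >= threshold:
            selected = s
    if selected is None:
        selected = n_muscles  # fallback: full rank
        logging.getLogger("myoface").warning(
            "no rank reached VAF >= %.1f%% (max %.2f%%); falling back to "
            "full rank %d", threshold, max(curve.values()), n_muscles)
    return selected, VafCurve(curve)


def activations_for(Ws: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Non-negative activation coefficients of fixed synergies ``Ws``.

    Solves the per-sample non-negative least-squares problem
    ``min_{c>=0} ||U[:,t] - Ws c||`` exactly for all samples at once by
    enumerating active sets (rank is small), checking primal and dual
    feasibility (KKT conditions) for each support pattern.
    """
    Ws = np.asarray(Ws, dtype=float)
    U = np.asarray(U, dtype=float)
    m, s = Ws.shape
    if U.shape[0] != m:
        raise ValueError("row count of U must match Ws")
    T = U.shape[1]
    C = np.zeros((s, T))
    best_res = np.sum(U * U, axis=0)          # residual of the empty support
    # dual feasibility of the zero solution handled implicitly via residual
    for r in range(1, s + 1):
        for support in itertools.combinations(range(s), r):
            Wsub = Ws[:, support]
            sol, *_ = np.linalg.lstsq(Wsub, U, rcond=None)   # r x T
            feasible = np.all(sol >= -1e-12, axis=0)
            if not np.any(feasible):
                continue
            resid_vec = U - Wsub @ sol
            res = np.sum(resid_vec * resid_vec, axis=0)
            better = feasible & (res < best_res - 1e-15 * (1 + best_res))
            if np.any(better):
                best_res[better] = res[better]
                C[:, better] = 0.0
                C[np.ix_(list(support), np.flatnonzero(better))] = \
                    np.clip(sol[:, better], 0.0, None)
    return C


def match_and_similarity(A: SynergyDecomposition | np.ndarray,
                         B: SynergyDecomposition | np.ndarray,
                         ) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Optimal one-to-one synergy pairing maximizing total cosine similarity.

    Rank is at most the muscle count, so the assignment is solved exactly by
    exhaustive permutation search.  Returns the pairing as (column of A,
    column of B) tuples and the per-pair cosines in pairing order.
    """
    Wa = A.Ws if isinstance(A, SynergyDecomposition) else np.asarray(A, float)
    Wb = B.Ws if isinstance(B, SynergyDecomposition) else np.asarray(B, float)
    if Wa.shape[0] != Wb.shape[0]:
        raise ValueError("muscle counts differ")
    if Wa.shape[1] != Wb.shape[1]:
        raise ValueError("ranks differ; match equal-rank decompositions")
    s = Wa.shape[1]
    na = np.linalg.norm(Wa, axis=0)
    nb = np.linalg.norm(Wb, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    cos = (Wa / na).T @ (Wb / nb)             # s x s cosine table
    best_perm, best_total = None, -np.inf
    for perm in itertools.permutations(range(s)):
        total = sum(cos[i, perm[i]] for i in range(s))
        if total > best_total:
            best_total, best_perm = total, perm
    pairing = [(i, best_perm[i]) for i in range(s)]
    return pairing, np.array([cos[i, j] for i, j in pairing])


def align_to_reference(dec: SynergyDecomposition,
                       ref_Ws: np.ndarray) -> SynergyDecomposition:
    """Permute a decomposition's columns to best match a reference basis.

    Pooling activation features across participants requires column j to
    mean the same synergy everywhere; energy order is not stable across
    datasets, so the optimal cosine pairing defines the permutation.
    """
    pairing, _ = match_and_similarity(ref_Ws, dec.Ws)
    perm = [j for _, j in sorted(pairing)]
    return SynergyDecomposition(dec.Ws[:, perm], dec.C[perm],
                                dec.vaf_percent, dec.rank,
                                dec.restart_losses)


@dataclass
class ExpressionCluster:
    label: str
    centroid: np.ndarray
    hull_vertices: np.ndarray   # indices into the expression's points
    hull_volume: float
    degenerate: bool


def activation_clusters(C: np.ndarray, structure: TrialStructure,
                        fs: float) -> dict[str, ExpressionCluster]:
    """Per-expression centroid and 3-D convex hull in synergy space.

    ``C`` must be a rank-3 activation matrix sampled at ``fs``; each sample
    is labelled by the segment containing it.
    """
    C = np.asarray(C, dtype=float)
    if C.shape[0] != 3:
        raise ValueError("activation clusters are defined for rank-3 data")
    labels = sorted({seg.label for seg in structure})
    out = {}
    for label in labels:
        cols = []
        for seg in structure:
            if seg.label != label:
                continue
            i0 = int(np.ceil(seg.start_s * fs - 1e-9))
            i1 = int(np.ceil(seg.end_s * fs - 1e-9))
            cols.append(C[:, i0:min(i1, C.shape[1])])
        pts = np.concatenate(cols, axis=1).T    # n x 3
        centroid = pts.mean(axis=0)
        try:
            hull = ConvexHull(pts)
            out[label] = ExpressionCluster(label, centroid, hull.vertices,
                                           float(hull.volume), False)
        except (QhullError, ValueError):
            out[label] = ExpressionCluster(label, centroid,
                                           np.empty(0, dtype=int), 0.0, True)
    return out
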