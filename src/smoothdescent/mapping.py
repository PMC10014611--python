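"""Linkage-map estimation: two-point recombination fractions and MDS ordering.

The two-point model is exactly the simulator's meiosis: per parent,
homologues pair uniformly at random into bivalents, each bivalent
transmits one strand that starts on either partner with probability 1/2
and switches partner between the two loci with probability r.  The joint
offspring dosage distribution P(g1, g2 | H, r) follows by convolving the
two parental contribution distributions, and r is estimated per marker
pair by maximum likelihood on a grid with parabolic refinement.

Ordering follows the weighted-MDS convention: Haldane distances from the
pairwise r-hat estimates, LOD^2 weights, a 2-D weighted MDS (SMACOF), and
a principal-curve pass that yields the 1-D order and cM positions as arc
length along the curve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.sparse.csgraph import connected_components

from .containers import DosageMatrix, GeneticMap, HomologueMatrix

__all__ = [
    "RfMatrix",
    "pair_genotype_likelihood",
    "RfEstimator",
    "estimate_rf",
    "estimate_rf_matrix",
    "order_markers",
    "map_length",
    "haldane_cm",
]

R_GRID = np.round(np.arange(0.0, 0.5 + 1e-12, 0.005), 6)
MIN_INFORMATIVE_N = 10
_R_CAP = 0.49  # keeps Haldane distances finite for ordering


def haldane_cm(r: np.ndarray) -> np.ndarray:
    """Haldane map distance (cM) of a recombination fraction."""
    r = np.clip(np.asarray(r, dtype=float), 0.0, _R_CAP)
    return -50.0 * np.log1p(-2.0 * r)


@dataclass
class RfMatrix:
    """Pairwise recombination-fraction estimates with LOD support."""

    r_hat: np.ndarray
    lod: np.ndarray

    @property
    def n_markers(self) -> int:
        return self.r_hat.shape[0]


@lru_cache(maxsize=None)
def _pairings(ploidy: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All perfect matchings of `ploidy` homologues into bivalents."""

    def rec(items: tuple[int, ...]):
        if not items:
            yield ()
            return
        first, rest = items[0], items[1:]
        for k, partner in enumerate(rest):
            pair = (first, partner)
            remaining = rest[:k] + rest[k + 1:]
            for tail in rec(remaining):
                yield (pair,) + tail

    return tuple(rec(tuple(range(ploidy))))


class RfEstimator:
    """Two-point ML estimation with per-pattern likelihood-table caching.

    Tables depend only on the parental phase rows, so one estimator reused
    across correction iterations (the phase never changes) amortises the
    table construction; this caching is what keeps hexaploid runs fast.
    """

    def __init__(self, H: HomologueMatrix, r_grid: np.ndarray = R_GRID):
        self.H = H
        self.r_grid = np.asarray(r_grid, dtype=float)
        self._parent_tables: dict[tuple, np.ndarray] = {}
        self._logp_tables: dict[tuple, np.ndarray] = {}
        p1, p2 = H.ploidy_p1, H.ploidy_p2
        self._u1 = self._encode(H.parent1())
        self._u2 = self._encode(H.parent2())
        self._g_max = (p1 + p2) // 2

    @staticmethod
    def _encode(bits: np.ndarray) -> np.ndarray:
        weights = 1 << np.arange(bits.shape[1])
        return (bits.astype(np.int64) * weights).sum(axis=1)

    @staticmethod
    def _decode(code: int, ploidy: int) -> np.ndarray:
        return (code >> np.arange(ploidy)) & 1

    def _parent_table(self, ploidy: int, u_code: int, v_code: int) -> np.ndarray:
        """Joint dosage-contribution distribution of one parent's gamete at
        two loci: array (m+1, m+1, R)."""
        key = (ploidy, u_code, v_code)
        hit = self._parent_tables.get(key)
        if hit is not None:
            return hit
        swapped = self._parent_tables.get((ploidy, v_code, u_code))
        if swapped is not None:
            out = np.ascontiguousarray(swapped.transpose(1, 0, 2))
            self._parent_tables[key] = out
            return out
        u = self._decode(u_code, ploidy)
        v = self._decode(v_code, ploidy)
        r = self.r_grid
        m = ploidy // 2
        stay = 0.5 * (1.0 - r)
        switch = 0.5 * r
        total = np.zeros((m + 1, m + 1, r.size))
        for pairing in _pairings(ploidy):
            dist = np.ones((1, 1, r.size))
            for a, b in pairing:
                t = np.zeros((2, 2, r.size))
                t[u[a], v[a]] += stay
                t[u[a], v[b]] += switch
                t[u[b], v[b]] += stay
                t[u[b], v[a]] += switch
                new = np.zeros((dist.shape[0] + 1, dist.shape[1] + 1, r.size))
                for h1 in range(2):
                    for h2 in range(2):
                        if t[h1, h2].any():
                            new[h1: h1 + dist.shape[0], h2: h2 + dist.shape[1]] += (
                                dist * t[h1, h2]
                            )
                dist = new
            total += dist
        total /= len(_pairings(ploidy))
        self._parent_tables[key] = total
        return total

    def joint_table(self, i: int, j: int) -> np.ndarray:
        """P(g1, g2 | r) table for marker pair (i, j): (K, K, R)."""
        key = (self._u1[i], self._u1[j], self._u2[i], self._u2[j])
        t1 = self._parent_table(self.H.ploidy_p1, key[0], key[1])
        t2 = self._parent_table(self.H.ploidy_p2, key[2], key[3])
        K = self._g_max + 1
        joint = np.zeros((K, K, self.r_grid.size))
        s1, s2 = t2.shape[0], t2.shape[1]
        for d1 in range(t1.shape[0]):
            for d2 in range(t1.shape[1]):
                sub = t1[d1, d2]
                if sub.any():
                    joint[d1: d1 + s1, d2: d2 + s2] += sub * t2
        return joint

    def _log_joint_table(self, i: int, j: int) -> np.ndarray:
        """log P(g1, g2 | r), floored at 1e-12 so genotype pairs that the
        phase cannot produce (true errors) depress, not void, the
        likelihood."""
        key = (self._u1[i], self._u1[j], self._u2[i], self._u2[j])
        hit = self._logp_tables.get(key)
        if hit is not None:
            return hit
        logp = np.log(np.clip(self.joint_table(i, j), 1e-12, None)).astype(
            np.float32
        )
        self._logp_tables[key] = logp
        return logp

    def _one_hot(self, G: DosageMatrix) -> np.ndarray:
        K = self._g_max + 1
        g = G.as_int(missing=K)  # missing -> extra slot, dropped below
        oh = np.zeros((G.n_markers, G.n_individuals, K + 1))
        m_idx = np.repeat(np.arange(G.n_markers), G.n_individuals)
        n_idx = np.tile(np.arange(G.n_individuals), G.n_markers)
        oh[m_idx, n_idx, g.ravel()] = 1.0
        return oh[:, :, :K]

    def _estimate_from_counts(self, counts: np.ndarray, logp: np.ndarray):
        ll = np.tensordot(counts, logp, axes=([0, 1], [0, 1]))
        k = int(np.argmax(ll))
        if ll[k] - ll.min() < 1e-9:
            return 0.5, 0.0
        step = self.r_grid[1] - self.r_grid[0]
        r_hat = self.r_grid[k]
        if 0 < k < ll.size - 1:
            denom = ll[k - 1] - 2.0 * ll[k] + ll[k + 1]
            if denom < -1e-12:
                r_hat = self.r_grid[k] + 0.5 * step * (ll[k - 1] - ll[k + 1]) / denom
        r_hat = float(np.clip(r_hat, 0.0, 0.5))
        lod = float(max(ll[k] - ll[-1], 0.0) / np.log(10.0))
        return r_hat, lod

    def estimate_pair(self, G: DosageMatrix, i: int, j: int):
        """(r_hat, lod) for one marker pair."""
        if i == j:
            return 0.0, 0.0
        gi = G.values[i]
        gj = G.values[j]
        keep = np.isfinite(gi) & np.isfinite(gj)
        if keep.sum() < MIN_INFORMATIVE_N:
            return 0.5, 0.0
        K = self._g_max + 1
        counts = np.zeros((K, K))
        np.add.at(counts, (gi[keep].astype(int), gj[keep].astype(int)), 1.0)
        return self._estimate_from_counts(counts, self._log_joint_table(i, j))

    def estimate_matrix(self, G: DosageMatrix) -> RfMatrix:
        """Full pairwise r-hat / LOD matrices."""
        M = G.n_markers
        r_hat = np.zeros((M, M))
        lod = np.zeros((M, M))
        oh = self._one_hot(G)
        for i in range(M):
            oh_i = oh[i]
            for j in range(i + 1, M):
                counts = oh_i.T @ oh[j]
                if counts.sum() < MIN_INFORMATIVE_N:
                    r, l = 0.5, 0.0
                else:
                    r, l = self._estimate_from_counts(
                        counts, self._log_joint_table(i, j)
                    )
                r_hat[i, j] = r_hat[j, i] = r
                lod[i, j] = lod[j, i] = l
        return RfMatrix(r_hat=r_hat, lod=lod)


def pair_genotype_likelihood(
    H: HomologueMatrix, i: int, j: int, g1: int, g2: int, r: float
) -> float:
    """P(g1, g2 | phase rows i and j, recombination fraction r)."""
    if not 0.0 <= r <= 0.5:
        raise ValueError("r must lie in [0, 0.5]")
    est = RfEstimator(H, r_grid=np.array([float(r)]))
    return float(est.joint_table(i, j)[g1, g2, 0])


def estimate_rf(
    G: DosageMatrix, H: HomologueMatrix, i: int, j: int
) -> tuple[float, float]:
    """Two-point ML estimate (r_hat, lod) for markers i and j."""
    return RfEstimator(H).estimate_pair(G, i, j)


def estimate_rf_matrix(
    G: DosageMatrix, H: HomologueMatrix, estimator: RfEstimator | None = None
) -> RfMatrix:
    """Pairwise recombination-fraction matrix for a whole linkage group."""
    est = estimator if estimator is not None else RfEstimator(H)
    return est.estimate_matrix(G)


def _classical_mds_2d(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:2]
    comp = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 1e-12))
    return comp


def _smacof(
    d: np.ndarray,
    w: np.ndarray,
    x0: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> np.ndarray:
    """Weighted 2-D SMACOF minimising sum w_ij (||x_i - x_j|| - d_ij)^2."""
    n = d.shape[0]
    v = -w.copy()
    np.fill_diagonal(v, w.sum(axis=1))
    v_pinv = np.linalg.pinv(v + 1.0 / n) - 1.0 / n
    x = x0.copy()
    prev_stress = np.inf
    for _ in range(max_iter):
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(dist, 1.0)
        safe = np.where(dist > 0, dist, 1.0)
        ratio = np.where(dist > 0, w * d / safe, 0.0)
        np.fill_diagonal(ratio, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = v_pinv @ (b @ x)
        np.fill_diagonal(dist, 0.0)
        stress = float((w * (dist - d) ** 2).sum())
        if prev_stress - stress < tol * max(prev_stress, 1e-12):
            break
        prev_stress = stress
    return x


def _project_to_polyline(points: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Arc-length coordinate of each point's nearest location on the curve."""
    seg = np.diff(curve, axis=0)
    seg_len = np.sqrt((seg**2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    d2 = ((points[:, None, :] - curve[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    t = s[nearest].copy()
    for k, (pt, v) in enumerate(zip(points, nearest)):
        for seg_idx in (v - 1, v):
            if 0 <= seg_idx < seg.shape[0] and seg_len[seg_idx] > 0:
                frac = np.dot(pt - curve[seg_idx], seg[seg_idx]) / seg_len[seg_idx] ** 2
                frac = np.clip(frac, 0.0, 1.0)
                cand = curve[seg_idx] + frac * seg[seg_idx]
                if ((pt - cand) ** 2).sum() <= d2[k, v]:
                    d2[k, v] = ((pt - cand) ** 2).sum()
                    t[k] = s[seg_idx] + frac * seg_len[seg_idx]
    return t


def _principal_curve_param(
    x: np.ndarray, n_iter: int = 8, span: float = 0.12
) -> np.ndarray:
    """1-D arc-length parameterisation of a 2-D embedding.

    Alternates between ordering points along the current curve and
    re-smoothing the curve (running mean over the ordered sequence).
    """
    n = x.shape[0]
    window = max(3, int(span * n) | 1)
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    t = xc @ vt[0]
    for _ in range(n_iter):
        idx = np.argsort(t, kind="stable")
        curve = uniform_filter1d(x[idx], size=window, axis=0, mode="nearest")
        t_new = _project_to_polyline(x, curve)
        if np.array_equal(np.argsort(t_new, kind="stable"), idx):
            t = t_new
            break
        t = t_new
    return t


def order_markers(
    rf: RfMatrix,
    prior_positions: np.ndarray | None = None,
    marker_ids: list[str] | None = None,
) -> GeneticMap:
    """Order markers and assign cM positions from pairwise r-hat estimates.

    Distances are the Haldane transform of r-hat; weights are LOD^2, so
    noisy long-range estimates barely constrain the embedding.  A 2-D
    weighted MDS is parameterised by a principal curve whose arc length
    gives the positions.  Orientation is chosen to correlate positively
    with ``prior_positions`` (input row order when absent), keeping maps
    stable across correction iterations.
    """
    m = rf.n_markers
    if m == 1:
        return GeneticMap(np.array([0]), np.array([0.0]), marker_ids or [])
    w = rf.lod**2
    np.fill_diagonal(w, 0.0)
    n_comp, labels = connected_components((w > 0).astype(int), directed=False)
    if n_comp > 1:
        groups = [list(np.nonzero(labels == c)[0]) for c in range(n_comp)]
        raise ValueError(
            f"rf graph is disconnected into {n_comp} components: {groups}"
        )
    d = haldane_cm(rf.r_hat)
    np.fill_diagonal(d, 0.0)
    x0 = _classical_mds_2d(d)
    x = _smacof(d, w, x0)
    t = _principal_curve_param(x)

    prior = (
        np.asarray(prior_positions, dtype=float)
        if prior_positions is not None
        else np.arange(m, dtype=float)
    )
    if np.corrcoef(t, prior)[0, 1] < 0:
        t = -t
    t = t - t.min()
    order = np.argsort(t, kind="stable")
    return GeneticMap(order, t[order], marker_ids or [])


def map_length(genetic_map: GeneticMap) -> float:
    """Map length in cM."""
    return genetic_map.length
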