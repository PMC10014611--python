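"""Error-tolerant IBD prediction by locally weighted averaging.

The predicted IBD at a marker is a convex combination of the observed IBD
at nearby markers, weighted by the probability of *no* recombination over
the separating distance (one minus the inverse map function).  Cells whose
observed IBD sits in the low-informative band — by default [0.3, 0.7] —
are excluded from every window, because they would pull predictions toward
0.5 and mask genuine disagreements.
"""

from __future__ import annotations

import numpy as np

from .containers import IBDTensor

__all__ = [
    "inverse_map_function",
    "MAP_FUNCTIONS",
    "informative_mask",
    "predict_ibd",
]

DEFAULT_BAND = (0.3, 0.7)


def _morgan(d: np.ndarray) -> np.ndarray:
    return np.minimum(d / 100.0, 0.5)


def _haldane(d: np.ndarray) -> np.ndarray:
    return (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0


def _kosambi(d: np.ndarray) -> np.ndarray:
    return 0.5 * np.tanh(2.0 * d / 100.0)


MAP_FUNCTIONS = {"morgan": _morgan, "haldane": _haldane, "kosambi": _kosambi}


def inverse_map_function(d_cm, fn: str = "haldane"):
    """Recombination fraction rho implied by a cM distance.

    Supported map functions: ``morgan`` (linear, capped at 0.5),
    ``haldane`` (no interference), ``kosambi`` (moderate interference).
    """
    if fn not in MAP_FUNCTIONS:
        raise ValueError(f"unknown map function {fn!r}; choose from {sorted(MAP_FUNCTIONS)}")
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    out = MAP_FUNCTIONS[fn](d)
    return float(out) if np.isscalar(d_cm) else out


def informative_mask(values: np.ndarray, band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """True where an observed IBD value is informative.

    Values inside [band[0], band[1]] (inclusive on both ends) and NaNs are
    low-informative and excluded from smoothing windows.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = band
    with np.errstate(invalid="ignore"):
        return (values < lo) | (values > hi)


def predict_ibd(
    I0: IBDTensor,
    positions_cm: np.ndarray,
    window: float = 10.0,
    fn: str = "haldane",
    band: tuple[float, float] = DEFAULT_BAND,
    physical: bool = False,
) -> IBDTensor:
    """Predicted IBD tensor: distance-weighted local average of observed IBD.

    For marker i the window holds markers j != i with |pos_j - pos_i| <
    ``window``; each contributing cell gets weight proportional to
    1 - rho(d_ij) and weights renormalise per cell over the cells that are
    informative.  Cells with an empty window come back NaN (no prediction,
    never an error call).

    With ``physical=True`` the positions are interpreted as base pairs and
    ``window`` as a bp interval; weights fall off linearly with distance
    (Morgan-style relative weighting), since bp separations have no
    absolute recombination-fraction scale.
    """
    positions = np.asarray(positions_cm, dtype=float)
    if positions.shape[0] != I0.n_markers:
        raise ValueError("positions length must match marker count")
    if window <= 0:
        raise ValueError("window must be positive")

    probs = I0.probs
    inf_mask = informative_mask(probs, band)
    obs = np.where(inf_mask, probs, 0.0)

    out = np.full_like(probs, np.nan)
    order = np.argsort(positions, kind="stable")
    pos_sorted = positions[order]

    for rank, m in enumerate(order):
        lo = np.searchsorted(pos_sorted, pos_sorted[rank] - window, side="right")
        hi = np.searchsorted(pos_sorted, pos_sorted[rank] + window, side="left")
        members = order[lo:hi]
        members = members[members != m]
        if members.size == 0:
            continue
        d = np.abs(positions[members] - positions[m])
        if physical:
            base = np.maximum(1.0 - d / window, 0.0)
        else:
            base = 1.0 - inverse_map_function(d, fn)
        num = np.einsum("w,wpn->pn", base, obs[members])
        den = np.einsum("w,wpn->pn", base, inf_mask[members].astype(float))
        with np.errstate(invalid="ignore", divide="ignore"):
            pred = num / den
        out[m] = np.where(den > 0, pred, np.nan)

    return IBDTensor(out, I0.ploidy_p1, I0.ploidy_p2, I0.impossible)
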