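"""Naive (observed) identity-by-descent probabilities.

At a single marker, an offspring of two phased parents must carry one of a
finite set of *inheritance configurations*: a choice of p1/2 homologues from
parent 1 and p2/2 from parent 2.  Without double reduction all
configurations are equally likely a priori, so the IBD probability of a
homologue given an observed dosage g is simply the fraction of
dosage-compatible configurations that contain it.  These marker-by-marker
probabilities are error sensitive — a single wrong dosage can flip them —
which is exactly the property the smoothing step exploits.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import comb

import numpy as np

from .containers import DosageMatrix, HomologueMatrix, IBDTensor

__all__ = [
    "enumerate_configurations",
    "count_configurations_with_double_reduction",
    "configuration_dosage",
    "configuration_dosages",
    "naive_ibd_marker",
    "naive_ibd_population",
]


def _check_even(ploidy_p1: int, ploidy_p2: int) -> None:
    if ploidy_p1 % 2 or ploidy_p2 % 2 or ploidy_p1 < 2 or ploidy_p2 < 2:
        raise ValueError("parental ploidies must be even integers >= 2")


@lru_cache(maxsize=None)
def enumerate_configurations(ploidy_p1: int, ploidy_p2: int) -> np.ndarray:
    """All inheritance configurations without double reduction.

    Returns an (n_config, (p1+p2)/2) array of homologue column indices;
    parent 2's homologues are offset by ``ploidy_p1``.  The count is
    C(p1, p1/2) * C(p2, p2/2): 4 for a diploid cross, 36 for a tetraploid
    cross, 400 for a hexaploid cross.
    """
    _check_even(ploidy_p1, ploidy_p2)
    m1, m2 = ploidy_p1 // 2, ploidy_p2 // 2
    g1 = list(itertools.combinations(range(ploidy_p1), m1))
    g2 = list(
        itertools.combinations(range(ploidy_p1, ploidy_p1 + ploidy_p2), m2)
    )
    configs = [a + b for a in g1 for b in g2]
    out = np.array(configs, dtype=np.int64)
    out.setflags(write=False)
    return out


def _gamete_multisets_with_dr(ploidy: int) -> int:
    """Count transmitted homologue multisets allowing double reduction.

    A double-reduction gamete carries two copies of the same parental
    homologue; no homologue can appear more than twice.  Diploid parents
    cannot produce such gametes (a bivalent transmits one strand).
    """
    m = ploidy // 2
    if ploidy == 2:
        return 2
    count = 0
    for ms in itertools.combinations_with_replacement(range(ploidy), m):
        if max(ms.count(h) for h in set(ms)) <= 2:
            count += 1
    return count


def count_configurations_with_double_reduction(
    ploidy_p1: int, ploidy_p2: int
) -> int:
    """Configuration count when double-reduction gametes are included.

    For a tetraploid x tetraploid cross each parent has C(4,2)=6 ordinary
    gametes plus 4 double-reduction ones, giving 10 x 10 = 100.
    """
    _check_even(ploidy_p1, ploidy_p2)
    return _gamete_multisets_with_dr(ploidy_p1) * _gamete_multisets_with_dr(
        ploidy_p2
    )


def configuration_dosage(h_row: np.ndarray, config: np.ndarray) -> int:
    """Dosage implied by one configuration: sum of its homologues' alleles."""
    h_row = np.asarray(h_row)
    return int(h_row[np.asarray(config)].sum())


def configuration_dosages(
    h_row: np.ndarray, configs: np.ndarray
) -> np.ndarray:
    """Vector of dosages for every configuration at one marker."""
    return np.asarray(h_row)[configs].sum(axis=1)


@lru_cache(maxsize=None)
def _membership_matrix(ploidy_p1: int, ploidy_p2: int) -> np.ndarray:
    """(n_config, p) indicator: does configuration c contain homologue h?"""
    configs = enumerate_configurations(ploidy_p1, ploidy_p2)
    p = ploidy_p1 + ploidy_p2
    ind = np.zeros((configs.shape[0], p), dtype=float)
    rows = np.repeat(np.arange(configs.shape[0]), configs.shape[1])
    ind[rows, configs.ravel()] = 1.0
    ind.setflags(write=False)
    return ind


def _marker_table(
    h_row: tuple[int, ...], ploidy_p1: int, ploidy_p2: int
) -> np.ndarray:
    """Lookup table (g_max+2, p): row g holds p(H_h | g); last row is NaN.

    Row g is all-NaN when no configuration yields dosage g (the
    phase-impossible case).
    """
    configs = enumerate_configurations(ploidy_p1, ploidy_p2)
    ind = _membership_matrix(ploidy_p1, ploidy_p2)
    dosages = configuration_dosages(np.array(h_row), configs)
    p = ploidy_p1 + ploidy_p2
    g_max = p // 2
    table = np.full((g_max + 2, p), np.nan)
    for g in range(g_max + 1):
        mask = dosages == g
        k = int(mask.sum())
        if k:
            table[g] = mask @ ind / k
    return table


@lru_cache(maxsize=None)
def _marker_table_cached(
    h_row: tuple[int, ...], ploidy_p1: int, ploidy_p2: int
) -> np.ndarray:
    out = _marker_table(h_row, ploidy_p1, ploidy_p2)
    out.setflags(write=False)
    return out


def naive_ibd_marker(
    h_row: np.ndarray,
    genotype: float,
    ploidy_p1: int,
    ploidy_p2: int,
) -> tuple[np.ndarray, bool]:
    """Naive IBD probabilities for one marker and one observed dosage.

    Returns ``(probs, impossible)``: a length-p probability vector (NaN
    everywhere when the genotype is missing or phase-impossible) and a flag
    that is True when no configuration reproduces the observed dosage.
    """
    _check_even(ploidy_p1, ploidy_p2)
    p = ploidy_p1 + ploidy_p2
    g_max = p // 2
    table = _marker_table_cached(
        tuple(int(v) for v in np.asarray(h_row)), ploidy_p1, ploidy_p2
    )
    if genotype is None or (isinstance(genotype, float) and np.isnan(genotype)):
        return np.full(p, np.nan), False
    g = int(genotype)
    if g < 0 or g > g_max:
        raise ValueError(f"genotype {g} outside [0, {g_max}]")
    row = table[g]
    impossible = bool(np.isnan(row).all())
    return row.copy(), impossible


def naive_ibd_population(H: HomologueMatrix, G: DosageMatrix) -> IBDTensor:
    """Observed IBD tensor I0 for a whole population.

    Marker rows of ``H`` and ``G`` must be aligned.  Missing dosages give
    all-NaN slices and are never flagged; phase-impossible dosages give
    all-NaN slices *and* set the ``impossible`` flag.
    """
    if H.n_markers != G.n_markers:
        raise ValueError("phase and dosage matrices have different marker counts")
    p = H.p
    g_max = p // 2
    finite = np.isfinite(G.values)
    out_of_range = finite & ((G.values < 0) | (G.values > g_max))
    if out_of_range.any():
        bad = np.argwhere(out_of_range)[0]
        raise ValueError(
            f"dosage out of range [0, {g_max}] at marker row {bad[0]}, "
            f"individual column {bad[1]}"
        )
    g_int = G.as_int(missing=g_max + 1)  # route missing to the NaN row
    probs = np.empty((H.n_markers, p, G.n_individuals))
    impossible = np.zeros((H.n_markers, G.n_individuals), dtype=bool)
    missing = g_int == g_max + 1
    for m in range(H.n_markers):
        table = _marker_table_cached(
            tuple(int(v) for v in H.values[m]), H.ploidy_p1, H.ploidy_p2
        )
        probs[m] = table[g_int[m]].T
        impossible[m] = np.isnan(table[g_int[m]]).all(axis=1) & ~missing[m]
    return IBDTensor(probs, H.ploidy_p1, H.ploidy_p2, impossible)
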