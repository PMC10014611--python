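"""Synthetic F1 populations under a polysomic, bivalent-pairing meiosis model.

Each meiosis pairs a parent's 2m homologues uniformly at random into m
bivalents.  A bivalent transmits a single strand that starts on either
partner with probability 1/2 and switches partner between consecutive loci
with probability equal to the Haldane transform of the interval length (no
crossover interference, no double reduction).  Offspring dosages are the
allele sums over transmitted homologues; the per-homologue inheritance
indicators are retained as the ground-truth IBD tensor.

Error injection replaces selected dosages with a uniform draw over the
other valid dosages, under a uniform rate, per-individual heterogeneous
rates, or a positional spline profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .containers import DosageMatrix, HomologueMatrix, IBDTensor
from .smoothing import inverse_map_function

__all__ = [
    "SimConfig",
    "ErrorProfile",
    "TruthBundle",
    "default_positions",
    "simulate_parents",
    "simulate_gamete",
    "simulate_population",
    "inject_errors",
    "simulate_experiment",
]


@dataclass
class SimConfig:
    """Design of one simulated F1 population (single chromosome)."""

    ploidy_p1: int = 2
    ploidy_p2: int = 2
    n_individuals: int = 100
    n_markers: int = 200
    chrom_length: float = 100.0
    marker_positions: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ploidy_p1 % 2 or self.ploidy_p2 % 2:
            raise ValueError("parental ploidies must be even")
        if self.marker_positions is not None:
            pos = np.asarray(self.marker_positions, dtype=float)
            if pos.size != self.n_markers:
                raise ValueError("marker_positions length must equal n_markers")
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions must be strictly increasing")
            if pos[0] < 0 or pos[-1] > self.chrom_length:
                raise ValueError("positions must lie within [0, chrom_length]")
            self.marker_positions = pos


@dataclass
class ErrorProfile:
    """How genotyping errors are injected.

    ``uniform``: one rate for every cell.  ``per_individual``: a rate per
    offspring column (heterogeneous individuals).  ``positional_spline``: a
    smooth per-marker rate curve through (cM, rate) knots, shared by all
    individuals (heterogeneous markers).
    """

    mode: str = "uniform"
    rate: float = 0.0
    per_individual_rates: np.ndarray | None = None
    spline_knots: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "per_individual", "positional_spline"):
            raise ValueError(f"unknown error mode {self.mode!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")
        if self.per_individual_rates is not None:
            arr = np.asarray(self.per_individual_rates, dtype=float)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("all per-individual rates must be in [0, 1]")
            self.per_individual_rates = arr
        if self.spline_knots is not None:
            if any(not 0 <= r <= 1 for _, r in self.spline_knots):
                raise ValueError("all spline knot rates must be in [0, 1]")

    @classmethod
    def uniform(cls, rate: float) -> "ErrorProfile":
        return cls(mode="uniform", rate=rate)

    @classmethod
    def special_case_a(
        cls, n_individuals: int = 100, low: float = 0.02, high: float = 0.3,
        n_high: int = 20,
    ) -> "ErrorProfile":
        """Heterogeneous individuals: most at a low rate, a minority high.

        Defaults: 80 individuals at 0.02 and 20 at 0.3.
        """
        rates = np.full(n_individuals, low)
        rates[n_individuals - n_high:] = high
        return cls(mode="per_individual", per_individual_rates=rates)

    @classmethod
    def special_case_b(cls, chrom_length: float = 100.0) -> "ErrorProfile":
        """Heterogeneous markers: smooth spline through rates
        (0.02, 0.1, 0.3, 0.02, 0.1) at ~25 cM intervals."""
        xs = np.linspace(0.0, chrom_length, 5)
        ys = (0.02, 0.1, 0.3, 0.02, 0.1)
        return cls(mode="positional_spline", spline_knots=list(zip(xs, ys)))

    def rate_matrix(
        self, n_markers: int, n_individuals: int,
        positions: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-cell error rates (markers x individuals)."""
        if self.mode == "uniform":
            return np.full((n_markers, n_individuals), self.rate)
        if self.mode == "per_individual":
            rates = self.per_individual_rates
            if rates is None or rates.size != n_individuals:
                raise ValueError("per_individual_rates must match individual count")
            return np.broadcast_to(rates, (n_markers, n_individuals)).copy()
        if positions is None:
            raise ValueError("positional_spline profile needs marker positions")
        knots = sorted(self.spline_knots or [])
        xs = np.array([x for x, _ in knots])
        ys = np.array([y for _, y in knots])
        per_marker = np.clip(CubicSpline(xs, ys)(positions), 0.0, 1.0)
        return np.broadcast_to(
            per_marker[:, None], (n_markers, n_individuals)
        ).copy()


@dataclass
class TruthBundle:
    """Ground truth plus the corrupted observations of one simulated run."""

    H: HomologueMatrix
    G_true: DosageMatrix
    I_true: IBDTensor
    positions: np.ndarray
    G_observed: DosageMatrix | None = None
    error_mask: np.ndarray | None = None

    @property
    def realized_error_rate(self) -> float:
        if self.error_mask is None:
            return 0.0
        return float(self.error_mask.mean())


def default_positions(
    n_markers: int, chrom_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Variable-density marker positions: Dirichlet-distributed spacings
    spanning [0, chrom_length]."""
    gaps = rng.dirichlet(np.ones(n_markers - 1)) * chrom_length
    return np.concatenate([[0.0], np.cumsum(gaps)])


def simulate_parents(
    ploidy_p1: int,
    ploidy_p2: int,
    n_markers: int,
    rng: np.random.Generator,
) -> HomologueMatrix:
    """Random phased parents with every marker segregating in the cross.

    Alleles are Bernoulli(1/2) per homologue; rows where both parents are
    internally homozygous (so all offspring would share one dosage) are
    resampled.
    """
    if ploidy_p1 % 2 or ploidy_p2 % 2:
        raise ValueError("parental ploidies must be even")
    if n_markers < 2:
        raise ValueError("need at least 2 markers")
    p = ploidy_p1 + ploidy_p2
    values = rng.integers(0, 2, size=(n_markers, p))
    while True:
        p1 = values[:, :ploidy_p1]
        p2 = values[:, ploidy_p1:]
        mono = ((p1 == p1[:, :1]).all(axis=1)) & ((p2 == p2[:, :1]).all(axis=1))
        if not mono.any():
            break
        values[mono] = rng.integers(0, 2, size=(int(mono.sum()), p))
    return HomologueMatrix(values, ploidy_p1, ploidy_p2)


def simulate_gamete(
    H_parent: np.ndarray,
    positions_cm: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiosis: transmitted homologue indices, (n_markers x m).

    Homologues are paired uniformly at random into bivalents for this
    meiosis; each bivalent's transmitted strand starts on either partner
    with probability 1/2 and switches with the Haldane probability of the
    interval between consecutive loci.
    """
    H_parent = np.asarray(H_parent)
    ploidy = H_parent.shape[1]
    if ploidy % 2:
        raise ValueError("parent ploidy must be even")
    m = ploidy // 2
    n_markers = H_parent.shape[0]
    positions = np.asarray(positions_cm, dtype=float)
    r = inverse_map_function(np.diff(positions), "haldane")

    pairing = rng.permutation(ploidy).reshape(m, 2)
    start = rng.integers(0, 2, size=m)
    switches = rng.random((m, n_markers - 1)) < r[None, :]
    side = (start[:, None] + np.concatenate(
        [np.zeros((m, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
    )) % 2
    chosen = pairing[np.arange(m)[:, None], side]  # (m, n_markers)
    return chosen.T


def simulate_population(
    H: HomologueMatrix, config: SimConfig, rng: np.random.Generator | None = None
) -> TruthBundle:
    """Simulate an F1 population: true dosages and true IBD indicators."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    positions = (
        config.marker_positions
        if config.marker_positions is not None
        else default_positions(config.n_markers, config.chrom_length, rng)
    )
    n_mark, n_ind = H.n_markers, config.n_individuals
    p = H.p
    probs = np.zeros((n_mark, p, n_ind))
    g_true = np.zeros((n_mark, n_ind))
    h1 = H.parent1()
    h2 = H.parent2()
    rows = np.arange(n_mark)
    for i in range(n_ind):
        gam1 = simulate_gamete(h1, positions, rng)
        gam2 = simulate_gamete(h2, positions, rng) + H.ploidy_p1
        chosen = np.concatenate([gam1, gam2], axis=1)  # (n_mark, m1+m2)
        for col in range(chosen.shape[1]):
            probs[rows, chosen[:, col], i] = 1.0
        g_true[:, i] = H.values[rows[:, None], chosen].sum(axis=1)
    G_true = DosageMatrix(g_true, list(H.marker_ids))
    I_true = IBDTensor(probs, H.ploidy_p1, H.ploidy_p2)
    return TruthBundle(H=H, G_true=G_true, I_true=I_true, positions=positions)


def inject_errors(
    G_true: DosageMatrix,
    profile: ErrorProfile,
    ploidy_offspring: int,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
) -> tuple[DosageMatrix, np.ndarray]:
    """Corrupt dosages per the error profile.

    Each selected cell is replaced by a uniform draw over the other valid
    dosages {0..ploidy_offspring} \\ {current}, so a corrupted cell always
    differs from the truth.
    """
    rates = profile.rate_matrix(
        G_true.n_markers, G_true.n_individuals, positions=positions
    )
    mask = rng.random(rates.shape) < rates
    mask &= np.isfinite(G_true.values)  # missing cells cannot be corrupted
    values = G_true.values.copy()
    cur = values[mask].astype(np.int64)
    draw = rng.integers(0, ploidy_offspring, size=cur.size)
    values[mask] = (draw + (draw >= cur)).astype(float)
    return (
        DosageMatrix(values, list(G_true.marker_ids), list(G_true.individual_ids)),
        mask,
    )


def simulate_experiment(
    config: SimConfig, profile: ErrorProfile, seed: int | None = None
) -> TruthBundle:
    """Full pipeline: parents -> population -> corrupted genotypes."""
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    H = simulate_parents(
        config.ploidy_p1, config.ploidy_p2, config.n_markers, rng
    )
    bundle = simulate_population(H, config, rng)
    G_obs, mask = inject_errors(
        bundle.G_true,
        profile,
        H.offspring_ploidy,
        rng,
        positions=bundle.positions,
    )
    bundle.G_observed = G_obs
    bundle.error_mask = mask
    return bundle
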