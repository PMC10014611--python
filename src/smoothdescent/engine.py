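"""Iterative orchestration: correct genotypes, re-map, pick the best round.

Each iteration computes observed (naive) IBD from the current genotypes,
predicts error-tolerant IBD by local weighted averaging along the current
map, flags and re-imputes disagreeing cells, and re-estimates the linkage
map from the corrected genotypes.  Iterations are scored by the R^2 of a
quadratic fit of inter-marker distance on recombination fraction: in a
good map that relationship is tight and monotone, so the round with the
highest R^2 is taken as the final result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .containers import DosageMatrix, GeneticMap, HomologueMatrix
from .correct import (
    ErrorCalls,
    ThresholdSchedule,
    apply_corrections,
    delta_for_iteration,
    detect_errors,
    impute_cells,
)
from .ibd import naive_ibd_population
from .mapping import RfEstimator, RfMatrix, order_markers
from .smoothing import DEFAULT_BAND, predict_ibd

__all__ = [
    "SmoothDescentConfig",
    "IterationResult",
    "EvalMetrics",
    "run_smooth_descent",
    "best_iteration",
    "evaluate",
    "quadratic_fit_r2",
]


@dataclass
class SmoothDescentConfig:
    """Tunables of one run; defaults follow the method's published settings."""

    n_iterations: int = 5
    window: float = 10.0
    map_function: str = "haldane"
    informative_band: tuple[float, float] = DEFAULT_BAND
    schedule: ThresholdSchedule | None = None
    position_type: str = "genetic"  # or "physical"
    remap: bool = True
    r2_pair_max_cm: float = 20.0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.schedule is None:
            self.schedule = ThresholdSchedule(n_iterations=self.n_iterations)
        elif self.schedule.n_iterations != self.n_iterations:
            self.schedule = ThresholdSchedule(
                self.schedule.delta_start,
                self.schedule.delta_end,
                self.n_iterations,
            )
        if self.position_type not in ("genetic", "physical"):
            raise ValueError("position_type must be 'genetic' or 'physical'")
        if self.position_type == "physical":
            self.remap = False


@dataclass
class IterationResult:
    """State after one round (iteration 0 is the preliminary, uncorrected state)."""

    iteration: int
    genotypes: DosageMatrix
    map: GeneticMap | None
    rf: RfMatrix | None
    error_calls: ErrorCalls | None
    r2_score: float | None
    delta: float | None = None

    @property
    def n_flagged(self) -> int:
        return 0 if self.error_calls is None else self.error_calls.n_flagged

    @property
    def map_length(self) -> float:
        return 0.0 if self.map is None else self.map.length


@dataclass
class EvalMetrics:
    """The three simulation-study metrics."""

    genotyping_error: float
    position_correlation: float
    map_length: float


def quadratic_fit_r2(
    genetic_map: GeneticMap, rf: RfMatrix, max_pair_cm: float = 20.0
) -> float | None:
    """R^2 of d = a + b r + c r^2 over close marker pairs.

    Pairs are map-adjacent markers plus any pair within ``max_pair_cm``;
    distant pairs saturate at r = 0.5 and would only dilute the signal.
    Returns None when fewer than 3 pairs are available.
    """
    pos = genetic_map.positions
    order = genetic_map.order
    m = order.size
    ii, jj = np.triu_indices(m, k=1)
    d = pos[jj] - pos[ii]
    close = (d <= max_pair_cm) | (jj == ii + 1)
    ii, jj, d = ii[close], jj[close], d[close]
    if d.size < 3:
        return None
    r = rf.r_hat[order[ii], order[jj]]
    design = np.column_stack([np.ones_like(r), r, r**2])
    coef, *_ = np.linalg.lstsq(design, d, rcond=None)
    resid = d - design @ coef
    ss_tot = float(((d - d.mean()) ** 2).sum())
    if ss_tot <= 0:
        return 1.0
    return float(max(0.0, 1.0 - float((resid**2).sum()) / ss_tot))


def run_smooth_descent(
    G: DosageMatrix,
    H: HomologueMatrix,
    config: SmoothDescentConfig | None = None,
    positions: np.ndarray | None = None,
) -> list[IterationResult]:
    """Run the full iterative correction loop.

    ``positions`` (per input marker row, cM or bp) seeds the first round;
    when absent a preliminary map is estimated de novo from the uncorrected
    genotypes.  Returns one result per round, with the preliminary state at
    index 0.  A mapping failure mid-loop returns the completed rounds.
    """
    config = config or SmoothDescentConfig()
    if G.n_markers != H.n_markers:
        raise ValueError("genotype and phase matrices have different marker counts")

    estimator = RfEstimator(H) if (config.remap or positions is None) else None
    results: list[IterationResult] = []

    if positions is not None:
        current_map = GeneticMap.from_positions(positions, list(G.marker_ids))
        rf0 = None
    else:
        rf0 = estimator.estimate_matrix(G)
        current_map = order_markers(rf0, marker_ids=list(G.marker_ids))
    r2_0 = (
        quadratic_fit_r2(current_map, rf0, config.r2_pair_max_cm)
        if rf0 is not None
        else None
    )
    results.append(
        IterationResult(0, G, current_map, rf0, None, r2_0)
    )
    if config.verbose:
        print(
            f"[iter 0] preliminary map length={current_map.length:.1f} cM"
            + (f" R2={r2_0:.4f}" if r2_0 is not None else "")
        )

    current_G = G
    physical = config.position_type == "physical"
    for k in range(1, config.n_iterations + 1):
        delta = delta_for_iteration(k, config.schedule)
        I_obs = naive_ibd_population(H, current_G)
        I_pred = predict_ibd(
            I_obs,
            current_map.positions_by_marker(),
            window=config.window,
            fn=config.map_function,
            band=config.informative_band,
            physical=physical,
        )
        calls = detect_errors(I_obs, I_pred, delta, config.informative_band)
        imputations = impute_cells(I_pred, H, calls.flags)
        current_G = apply_corrections(current_G, calls, imputations)

        rf_k = None
        if config.remap:
            try:
                rf_k = estimator.estimate_matrix(current_G)
                current_map = order_markers(
                    rf_k,
                    prior_positions=current_map.positions_by_marker(),
                    marker_ids=list(G.marker_ids),
                )
            except ValueError as exc:
                if config.verbose:
                    print(f"[iter {k}] mapping failed: {exc}")
                results.append(
                    IterationResult(k, current_G, None, None, calls, None, delta)
                )
                break
        r2_k = (
            quadratic_fit_r2(current_map, rf_k, config.r2_pair_max_cm)
            if rf_k is not None
            else None
        )
        results.append(
            IterationResult(k, current_G, current_map, rf_k, calls, r2_k, delta)
        )
        if config.verbose:
            print(
                f"[iter {k}] delta={delta:.2f} flags={calls.n_flagged} "
                f"map length={current_map.length:.1f} cM"
                + (f" R2={r2_k:.4f}" if r2_k is not None else "")
            )
    return results


def best_iteration(results: list[IterationResult]) -> int:
    """Index of the correction round with the highest quadratic-fit R^2.

    Only correction rounds (iteration >= 1) compete; ties go to the
    earliest round.  When no round has a valid score (fewer than 3 usable
    pairs, or physical-position mode) the last completed round is returned.
    """
    candidates = [r for r in results if r.iteration >= 1]
    if not candidates:
        raise ValueError("no correction iterations to choose from")
    scored = [r for r in candidates if r.r2_score is not None]
    if not scored:
        return candidates[-1].iteration
    best = max(scored, key=lambda r: (r.r2_score, -r.iteration))
    return best.iteration


def evaluate(
    result: IterationResult,
    G_true: DosageMatrix,
    true_positions: np.ndarray,
) -> EvalMetrics:
    """Simulation-mode metrics against the known truth.

    Genotyping error is the fraction of cells differing from the true
    dosage (missing counts as different); position correlation is the
    absolute Pearson correlation of true vs estimated positions (maps have
    arbitrary orientation); map length is the estimated map's span.
    """
    g = result.genotypes.values
    truth = G_true.values
    mismatch = ~np.isclose(g, truth, equal_nan=True)
    err = float(mismatch.mean())
    if result.map is None:
        corr = float("nan")
        length = float("nan")
    else:
        est = result.map.positions_by_marker()
        corr = float(abs(pearsonr(np.asarray(true_positions, float), est)[0]))
        length = result.map.length
    return EvalMetrics(err, corr, length)
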