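"""Error detection, genotype imputation, and the per-iteration threshold.

A cell (marker, individual) is called an error when, for at least one
homologue, the observed IBD is informative, a prediction exists, and the
two disagree by more than the threshold delta.  Cells whose observed
genotype is impossible under the parental phase are pre-flagged regardless
of the contrast.  Flagged cells are re-genotyped with the dosage of the
configuration that maximises the product of predicted homologue
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DosageMatrix, HomologueMatrix, IBDTensor
from .ibd import configuration_dosages, enumerate_configurations
from .smoothing import DEFAULT_BAND, informative_mask

__all__ = [
    "ErrorCalls",
    "ThresholdSchedule",
    "detect_errors",
    "delta_for_iteration",
    "impute_genotype",
    "impute_cells",
    "apply_corrections",
]

_TIE_RTOL = 1e-9


@dataclass
class ErrorCalls:
    """Boolean error flags plus the per-cell observed/predicted contrast."""

    flags: np.ndarray
    max_contrast: np.ndarray
    delta: float

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    @property
    def per_marker_rate(self) -> np.ndarray:
        return self.flags.mean(axis=1)

    @property
    def per_individual_rate(self) -> np.ndarray:
        return self.flags.mean(axis=0)


@dataclass
class ThresholdSchedule:
    """Linearly decreasing error threshold across iterations (0.9 -> 0.7)."""

    delta_start: float = 0.9
    delta_end: float = 0.7
    n_iterations: int = 5

    def __post_init__(self) -> None:
        if self.delta_end > self.delta_start:
            raise ValueError("schedule must be nonincreasing")
        if self.delta_end < 0.7:
            raise ValueError("error threshold should stay at or above 0.7")


def delta_for_iteration(iter_index: int, schedule: ThresholdSchedule) -> float:
    """Threshold for iteration ``iter_index`` (1-based)."""
    n = schedule.n_iterations
    if not 1 <= iter_index <= n:
        raise ValueError(f"iteration {iter_index} outside [1, {n}]")
    if n == 1:
        return schedule.delta_start
    frac = (iter_index - 1) / (n - 1)
    return schedule.delta_start + frac * (schedule.delta_end - schedule.delta_start)


def detect_errors(
    I0: IBDTensor,
    I0_hat: IBDTensor,
    delta: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> ErrorCalls:
    """Flag cells where observed and predicted IBD disagree by more than delta.

    Low-informative observed values (inside the band) never contribute:
    |i0 - i0_hat| cannot approach 1 when either side is near 0.5, so such
    cells carry no evidence either way.  Phase-impossible cells recorded on
    the observed tensor are always flagged.
    """
    if not 0.5 < delta <= 1.0:
        raise ValueError("delta must lie in (0.5, 1]")
    obs, pred = I0.probs, I0_hat.probs
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted tensors are not aligned")
    usable = informative_mask(obs, band) & np.isfinite(pred)
    with np.errstate(invalid="ignore"):
        contrast = np.where(usable, np.abs(obs - pred), 0.0)
    max_contrast = contrast.max(axis=1)
    flags = (max_contrast > delta) | I0.impossible
    return ErrorCalls(flags=flags, max_contrast=max_contrast, delta=delta)


def _config_scores(pred_cells: np.ndarray, configs: np.ndarray) -> np.ndarray:
    """Product of predicted homologue probabilities per configuration.

    ``pred_cells`` is (n_cells, p); returns (n_cells, n_configs).
    """
    return pred_cells[:, configs].prod(axis=2)


def impute_genotype(
    ihat_slice: np.ndarray,
    h_row: np.ndarray,
    ploidy_p1: int,
    ploidy_p2: int,
) -> float:
    """Most likely dosage for one cell given its predicted IBD slice.

    Every configuration is scored by the product of its homologues'
    predicted probabilities; the dosage of the best-scoring configuration
    is returned.  Score ties among configurations with a common dosage
    resolve to that dosage; ties spanning distinct dosages — and slices
    containing NaNs — yield NaN (no confident imputation).
    """
    ihat_slice = np.asarray(ihat_slice, dtype=float)
    if np.isnan(ihat_slice).any():
        return float("nan")
    configs = enumerate_configurations(ploidy_p1, ploidy_p2)
    scores = _config_scores(ihat_slice[None, :], configs)[0]
    best = scores.max()
    ties = scores >= best * (1.0 - _TIE_RTOL) if best > 0 else np.ones_like(scores, bool)
    dosages = configuration_dosages(np.asarray(h_row), configs)[ties]
    if dosages.min() == dosages.max():
        return float(dosages[0])
    return float("nan")


def impute_cells(
    I_hat: IBDTensor,
    H: HomologueMatrix,
    flags: np.ndarray,
) -> np.ndarray:
    """Vectorised imputation for all flagged cells.

    Returns a (markers x individuals) float matrix that is NaN everywhere
    except flagged cells, which hold the imputed dosage (or NaN when no
    confident dosage exists).
    """
    out = np.full(flags.shape, np.nan)
    rows, cols = np.nonzero(flags)
    if rows.size == 0:
        return out
    configs = enumerate_configurations(H.ploidy_p1, H.ploidy_p2)
    pred = I_hat.probs[rows, :, cols]  # (n_cells, p)
    ok = ~np.isnan(pred).any(axis=1)
    if not ok.any():
        return out
    rows_ok, cols_ok = rows[ok], cols[ok]
    scores = _config_scores(pred[ok], configs)  # (n_cells, n_cfg)
    dosage_by_marker = H.values[rows_ok][:, configs].sum(axis=2)  # (n_cells, n_cfg)
    best = scores.max(axis=1, keepdims=True)
    ties = np.where(best > 0, scores >= best * (1.0 - _TIE_RTOL), True)
    d_masked_lo = np.where(ties, dosage_by_marker, np.iinfo(np.int32).max)
    d_masked_hi = np.where(ties, dosage_by_marker, np.iinfo(np.int32).min)
    dmin = d_masked_lo.min(axis=1)
    dmax = d_masked_hi.max(axis=1)
    unique = dmin == dmax
    out[rows_ok[unique], cols_ok[unique]] = dmin[unique].astype(float)
    return out


def apply_corrections(
    G: DosageMatrix, error_calls: ErrorCalls, imputations: np.ndarray
) -> DosageMatrix:
    """Replace flagged cells with their imputed dosage (NaN when undecided)."""
    if G.values.shape != error_calls.flags.shape:
        raise ValueError("genotype matrix and error calls are not aligned")
    new_values = G.values.copy()
    new_values[error_calls.flags] = imputations[error_calls.flags]
    return DosageMatrix(new_values, list(G.marker_ids), list(G.individual_ids))
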