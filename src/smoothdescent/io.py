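"""Readers and writers for the package's TSV artifacts and the run config.

Conventions: tab-separated, first column holds marker IDs, header row holds
individual IDs (dosage) or homologue labels H1..Hp (phase).  Missing cells
are written as ``NA``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import DosageMatrix, GeneticMap, HomologueMatrix, IBDTensor
from .correct import ThresholdSchedule
from .engine import IterationResult, SmoothDescentConfig

__all__ = [
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phase_tsv",
    "write_phase_tsv",
    "read_map_tsv",
    "write_map_tsv",
    "write_error_report",
    "write_ibd_long_tsv",
    "export_graphical_genotypes",
    "load_run_config",
    "save_run_config",
]

NA = "NA"


def read_dosage_tsv(path, max_dosage: int | None = None) -> DosageMatrix:
    """Read offspring dosages: rows = markers, columns = individuals."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA], dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate marker ID {dup!r} in {path}")
    try:
        values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric dosage cell in {path}: {exc}") from exc
    finite = values[np.isfinite(values)]
    if finite.size and not np.allclose(finite, np.round(finite)):
        raise ValueError(f"non-integer dosage cell in {path}")
    if finite.size and finite.min() < 0:
        raise ValueError(f"negative dosage in {path}")
    if max_dosage is not None and finite.size and finite.max() > max_dosage:
        raise ValueError(
            f"dosage {int(finite.max())} exceeds offspring ploidy {max_dosage} in {path}"
        )
    return DosageMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_dosage_tsv(G: DosageMatrix, path) -> None:
    df = pd.DataFrame(G.values, index=G.marker_ids, columns=G.individual_ids)
    out = df.map(lambda v: NA if np.isnan(v) else str(int(v)))
    out.index.name = "marker"
    out.to_csv(path, sep="\t")


def read_phase_tsv(path, ploidy_p1: int, ploidy_p2: int) -> HomologueMatrix:
    """Read phased parental homologues: columns H1..Hp, parent 1 first."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    p = ploidy_p1 + ploidy_p2
    if df.shape[1] != p:
        raise ValueError(
            f"expected {p} homologue columns for ploidies "
            f"{ploidy_p1}+{ploidy_p2}, found {df.shape[1]} in {path}"
        )
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"non-binary cell in phase file {path}")
    return HomologueMatrix(values, ploidy_p1, ploidy_p2, list(df.index.astype(str)))


def write_phase_tsv(H: HomologueMatrix, path) -> None:
    cols = [f"H{i + 1}" for i in range(H.p)]
    df = pd.DataFrame(H.values, index=H.marker_ids, columns=cols)
    df.index.name = "marker"
    df.to_csv(path, sep="\t")


def read_map_tsv(path) -> pd.DataFrame:
    """Read a map file with columns (marker, position_cM)."""
    df = pd.read_csv(path, sep="\t")
    if "marker" not in df.columns or "position_cM" not in df.columns:
        raise ValueError(f"map file {path} needs 'marker' and 'position_cM' columns")
    return df


def write_map_tsv(genetic_map: GeneticMap, marker_ids: list[str], path) -> None:
    ids = [marker_ids[i] for i in genetic_map.order]
    df = pd.DataFrame({"marker": ids, "position_cM": genetic_map.positions})
    df.to_csv(path, sep="\t", index=False)


def write_error_report(
    results: list[IterationResult], marker_ids, individual_ids, path
) -> None:
    """Long-format change log: one row per corrected cell per iteration."""
    rows = []
    for prev, res in zip(results, results[1:]):
        if res.error_calls is None:
            continue
        flagged = np.argwhere(res.error_calls.flags)
        for m, i in flagged:
            old = prev.genotypes.values[m, i]
            new = res.genotypes.values[m, i]
            rows.append(
                {
                    "marker": marker_ids[m],
                    "individual": individual_ids[i],
                    "iteration": res.iteration,
                    "contrast": res.error_calls.max_contrast[m, i],
                    "old_dosage": NA if np.isnan(old) else int(old),
                    "new_dosage": NA if np.isnan(new) else int(new),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "marker", "individual", "iteration", "contrast",
            "old_dosage", "new_dosage",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_ibd_long_tsv(
    tensor: IBDTensor, marker_ids, individual_ids, path
) -> None:
    """IBD tensor in long format: (marker, homologue, individual, prob)."""
    m_idx, h_idx, i_idx = np.indices(tensor.probs.shape)
    df = pd.DataFrame(
        {
            "marker": np.asarray(marker_ids)[m_idx.ravel()],
            "homologue": [f"H{h + 1}" for h in h_idx.ravel()],
            "individual": np.asarray(individual_ids)[i_idx.ravel()],
            "prob": tensor.probs.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def export_graphical_genotypes(
    tensor: IBDTensor,
    marker_ids,
    individual_ids,
    out_dir,
    heatmaps: bool = False,
) -> list[Path]:
    """Per-individual markers x homologues IBD matrices (the QC artifact).

    One TSV per individual; with ``heatmaps=True`` a PNG rendering of each
    matrix is written alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = [f"H{i + 1}" for i in range(tensor.p)]
    written = []
    for i, ind in enumerate(individual_ids):
        df = pd.DataFrame(tensor.probs[:, :, i], index=marker_ids, columns=cols)
        df.index.name = "marker"
        path = out_dir / f"graphical_genotype_{ind}.tsv"
        df.to_csv(path, sep="\t", na_rep=NA, float_format="%.4g")
        written.append(path)
        if heatmaps:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(4, 6))
            ax.imshow(
                tensor.probs[:, :, i], aspect="auto", cmap="viridis",
                vmin=0, vmax=1, interpolation="nearest",
            )
            ax.set_xlabel("homologue")
            ax.set_ylabel("marker")
            ax.set_title(str(ind))
            fig.tight_layout()
            fig.savefig(out_dir / f"graphical_genotype_{ind}.png", dpi=100)
            plt.close(fig)
    return written


def load_run_config(path) -> SmoothDescentConfig:
    """Load a YAML run config; unspecified keys keep the method defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    schedule = None
    if "delta_start" in raw or "delta_end" in raw:
        schedule = ThresholdSchedule(
            raw.pop("delta_start", 0.9),
            raw.pop("delta_end", 0.7),
            raw.get("n_iterations", 5),
        )
    known = {
        "n_iterations", "window", "map_function", "informative_band",
        "position_type", "remap", "r2_pair_max_cm", "verbose",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "informative_band" in raw:
        raw["informative_band"] = tuple(raw["informative_band"])
    return SmoothDescentConfig(schedule=schedule, **raw)


def save_run_config(config: SmoothDescentConfig, path) -> None:
    data = asdict(config)
    schedule = data.pop("schedule")
    data["delta_start"] = schedule["delta_start"]
    data["delta_end"] = schedule["delta_end"]
    data["informative_band"] = list(data["informative_band"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
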