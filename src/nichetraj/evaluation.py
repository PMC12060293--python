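"""Benchmark utilities: truth correlation, reproducibility, type density.

Because the trajectory direction is arbitrary (s and 1 - s are equivalent
solutions), all correlations here are orientation-invariant by default:
the reported coefficient is the maximum of Spearman's rho over the two
orientations, which equals |rho|.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "spearman_vs_truth",
    "per_lineage_spearman",
    "density_along_nt",
    "reproducibility",
]


def spearman_vs_truth(
    cell_scores: np.ndarray,
    ground_truth: np.ndarray,
    orientation_invariant: bool = True,
) -> float:
    """Spearman rank correlation between NT scores and a reference ordering.

    Raises ``ValueError`` on constant inputs (undefined correlation).
    """
    s = np.asarray(cell_scores, dtype=float)
    t = np.asarray(ground_truth, dtype=float)
    if s.shape != t.shape or s.ndim != 1 or len(s) < 3:
        raise ValueError("need two aligned 1-D vectors of length >= 3")
    if np.ptp(s) == 0.0 or np.ptp(t) == 0.0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho = float(stats.spearmanr(s, t).statistic)
    if orientation_invariant:
        # rho(1 - s, t) = -rho(s, t), so the better orientation gives |rho|
        rho = abs(rho)
    return rho


def per_lineage_spearman(
    cell_scores, ground_truth, lineage_label, orientation_invariant=True
) -> dict:
    """Per-lineage correlation map (lineages with constant truth are skipped)."""
    out = {}
    lineage_label = np.asarray(lineage_label)
    for lineage in np.unique(lineage_label):
        mask = lineage_label == lineage
        try:
            out[str(lineage)] = spearman_vs_truth(
                np.asarray(cell_scores)[mask],
                np.asarray(ground_truth)[mask],
                orientation_invariant,
            )
        except ValueError:
            out[str(lineage)] = float("nan")
    return out


def density_along_nt(
    cell_scores,
    cell_types,
    bandwidth: float | str = "scott",
    grid_size: int = 201,
) -> tuple[np.ndarray, dict]:
    """Per-type Gaussian kernel density of cells along the trajectory.

    Returns the score grid on [0, 1] and a type -> density-curve map; each
    curve is renormalized to integrate to 1 over the grid.  Types with
    fewer than two cells (or zero spread) get a narrow Gaussian bump at
    their score, with a warning.
    """
    scores = np.asarray(cell_scores, dtype=float)
    types = np.asarray(cell_types)
    grid = np.linspace(0.0, 1.0, grid_size)
    curves = {}
    for t in np.unique(types):
        s = scores[types == t]
        if len(s) < 2 or np.ptp(s) == 0.0:
            warnings.warn(
                f"cell type {t!r} has <2 distinct scores; delta-like density",
                stacklevel=2,
            )
            curve = stats.norm.pdf(grid, loc=s.mean(), scale=0.01)
        else:
            curve = stats.gaussian_kde(s, bw_method=bandwidth)(grid)
        curves[str(t)] = curve / np.trapezoid(curve, grid)
    return grid, curves


def reproducibility(scores_runs) -> np.ndarray:
    """Pairwise orientation-invariant Spearman matrix across repeated runs."""
    runs = [np.asarray(r, dtype=float) for r in scores_runs]
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    n = len(runs[0])
    if any(len(r) != n for r in runs):
        raise ValueError("all runs must cover the same cells")
    out = np.eye(len(runs))
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            out[i, j] = out[j, i] = spearman_vs_truth(runs[i], runs[j])
    return out
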