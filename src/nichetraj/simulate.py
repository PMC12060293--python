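"""Synthetic spatial datasets with known trajectory ground truth.

Four benchmark layouts are provided, each pairing a cell table
(``Cell_ID, Sample, Cell_Type, x, y``) with a per-cell ground-truth
trajectory coordinate in [0, 1]:

1. ``circular`` — a lineage of 7 types laid out on concentric circles
   (radius = latent time) plus a second, spatially random lineage of 3
   types filling the unit disk; truth is the radial distance.
2. ``linear`` — a lineage of 6 types ordered along the x-axis plus two
   spatially random lineages; truth is the position along the axis.
3. ``quadratic`` — same lineage structure as (2) but the ordered lineage
   follows the parabola y = a·x²; truth is the normalized arc position
   of each cell's projection onto the curve.
4. ``disconnected`` — two unrelated lineages with disjoint type alphabets
   mapped to mutually exclusive x-ranges (one central, one peripheral);
   truth is the rescaled x-coordinate.

Cell types are assigned from latent times by contiguous equal-width bins,
so the type sequence along each trajectory-bearing lineage is ordered and
non-overlapping.  All generators are deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimulatedDataset",
    "simulate_dataset1",
    "simulate_dataset2_3",
    "simulate_dataset4",
    "simulate",
]

_PATTERNS = ("circular", "linear", "quadratic", "disconnected")


@dataclass
class SimulatedDataset:
    """A simulated cell table plus its ground-truth trajectory coordinate."""

    cells: pd.DataFrame
    ground_truth: np.ndarray
    lineage_label: np.ndarray
    pattern_id: str

    def __post_init__(self) -> None:
        if self.pattern_id not in _PATTERNS:
            raise ValueError(f"unknown pattern_id {self.pattern_id!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def truth_frame(self) -> pd.DataFrame:
        """Ground truth as a two-column table (Cell_ID, truth)."""
        return pd.DataFrame(
            {"Cell_ID": self.cells["Cell_ID"].to_numpy(), "truth": self.ground_truth}
        )

    def write(self, out_dir) -> None:
        """Write ``cells.csv`` and ``ground_truth.csv`` under *out_dir*."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False)
        self.truth_frame().to_csv(out / "ground_truth.csv", index=False)


def _check_n_cells(n_cells: int) -> None:
    if not isinstance(n_cells, (int, np.integer)) or n_cells < 20:
        raise ValueError(f"n_cells must be an integer >= 20, got {n_cells!r}")


def _split_counts(n_cells: int, shares: np.ndarray) -> np.ndarray:
    """Integer lineage sizes proportional to *shares*, summing to n_cells."""
    raw = n_cells * shares / shares.sum()
    counts = np.floor(raw).astype(int)
    # hand out the remainder by largest fractional part, index-stable
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[: n_cells - counts.sum()]] += 1
    return counts


def _types_from_time(t: np.ndarray, alphabet: str) -> np.ndarray:
    """Contiguous equal-width bins of latent time -> categorical labels."""
    n_types = len(alphabet)
    idx = np.minimum((t * n_types).astype(int), n_types - 1)
    return np.array(list(alphabet))[idx]


def _assemble(x, y, types, truth, lineage, pattern_id, sample="sim") -> SimulatedDataset:
    n = len(x)
    cells = pd.DataFrame(
        {
            "Cell_ID": [f"cell_{i}" for i in range(n)],
            "Sample": sample,
            "Cell_Type": types,
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
        }
    )
    truth = np.asarray(truth, dtype=float)
    truth = truth / truth.max()  # max is exactly 1 after rescaling
    return SimulatedDataset(cells, truth, np.asarray(lineage), pattern_id)


def simulate_dataset1(
    n_cells: int = 1000, frac_lineage2: float = 0.3, seed: int = 0
) -> SimulatedDataset:
    """Circular layout: ordered lineage on concentric circles, random filler.

    Lineage-1 cells (types A-G) draw a latent time t ~ U[0,1] and sit at a
    uniform-random angle on the circle of radius t; lineage-2 cells (types
    H-J) are uniform in the unit disk.  The ground truth is the radial
    distance, rescaled so its maximum is exactly 1.
    """
    _check_n_cells(n_cells)
    if not 0.0 < frac_lineage2 < 1.0:
        raise ValueError("frac_lineage2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n2 = int(round(n_cells * frac_lineage2))
    n1 = n_cells - n2

    t1 = rng.uniform(0.0, 1.0, n1)
    t1 /= t1.max()
    theta = rng.uniform(0.0, 2.0 * np.pi, n1)
    x1, y1 = t1 * np.cos(theta), t1 * np.sin(theta)
    types1 = _types_from_time(t1, "ABCDEFG")

    # uniform in the unit disk via sqrt-radius sampling
    r2 = np.sqrt(rng.uniform(0.0, 1.0, n2))
    phi = rng.uniform(0.0, 2.0 * np.pi, n2)
    x2, y2 = r2 * np.cos(phi), r2 * np.sin(phi)
    t2 = rng.uniform(0.0, 1.0, n2)
    types2 = _types_from_time(t2, "HIJ")

    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    truth = np.hypot(x, y)
    lineage = np.concatenate([np.repeat("lineage1", n1), np.repeat("lineage2", n2)])
    return _assemble(x, y, np.concatenate([types1, types2]), truth, lineage, "circular")


def _quadratic_arc_position(x: np.ndarray, a: float, x_max: float) -> np.ndarray:
    """Normalized arc length of the point (x, a x^2) along y = a u^2, u in [0, x_max]."""
    # closed-form arc length of a parabola
    def arc(u):
        w = 2.0 * a * u
        return (u * np.sqrt(1.0 + w * w) + np.arcsinh(w) / (2.0 * a)) / 2.0

    return arc(x) / arc(x_max)


def simulate_dataset2_3(
    n_cells: int = 500,
    pattern: str = "linear",
    seed: int = 0,
    quad_coeff: float = 2.0,
    band_halfwidth: float = 0.25,
) -> SimulatedDataset:
    """Linear or quadratic backbone with two spatially random side lineages.

    Lineage 1 (types A-F) is placed in lineage order along the backbone:
    on the x-axis (``linear``) or on y = quad_coeff * x^2 (``quadratic``).
    Lineages 2 (G-H) and 3 (I-J) get uniform-random coordinates inside the
    bounding region.  The ground truth is the normalized arc position of
    each cell's orthogonal projection onto the backbone curve.
    """
    _check_n_cells(n_cells)
    if pattern not in ("linear", "quadratic"):
        raise ValueError(f"pattern must be 'linear' or 'quadratic', got {pattern!r}")
    rng = np.random.default_rng(seed)
    n1, n2, n3 = _split_counts(n_cells, np.array([6.0, 2.0, 2.0]))

    t1 = rng.uniform(0.0, 1.0, n1)
    t1 /= t1.max()
    types1 = _types_from_time(t1, "ABCDEF")
    types2 = _types_from_time(rng.uniform(0.0, 1.0, n2), "GH")
    types3 = _types_from_time(rng.uniform(0.0, 1.0, n3), "IJ")
    xr = rng.uniform(0.0, 1.0, n2 + n3)

    if pattern == "linear":
        x = np.concatenate([t1, xr])
        y = np.concatenate(
            [np.zeros(n1), rng.uniform(-band_halfwidth, band_halfwidth, n2 + n3)]
        )
        truth = x.copy()  # projection onto the x-axis
    else:
        a = quad_coeff
        yr = rng.uniform(0.0, a, n2 + n3)
        x = np.concatenate([t1, xr])
        y = np.concatenate([a * t1**2, yr])
        # project each cell onto the parabola by dense parametric search
        grid = np.linspace(0.0, 1.0, 2001)
        curve = np.stack([grid, a * grid**2], axis=1)
        d2 = (x[:, None] - curve[None, :, 0]) ** 2 + (y[:, None] - curve[None, :, 1]) ** 2
        proj_x = grid[np.argmin(d2, axis=1)]
        truth = _quadratic_arc_position(proj_x, a, 1.0)
    lineage = np.concatenate(
        [np.repeat("lineage1", n1), np.repeat("lineage2", n2), np.repeat("lineage3", n3)]
    )
    return _assemble(
        x, y, np.concatenate([types1, types2, types3]), truth, lineage, pattern
    )


def simulate_dataset4(
    n_cells: int = 454, seed: int = 0, gap: float = 0.1
) -> SimulatedDataset:
    """Disconnected topology: two unrelated lineages in disjoint x-ranges.

    Lineage 1 (types A-E, earlier latent times) occupies the central band
    x in [0, (1-gap)/2); lineage 2 (types F-J) the peripheral band
    x in ((1+gap)/2, 1].  x is proportional to the latent time within each
    lineage, y is uniform random; ground truth is the rescaled x-coordinate.
    """
    _check_n_cells(n_cells)
    if not 0.0 <= gap < 1.0:
        raise ValueError("gap must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n1, n2 = _split_counts(n_cells, np.array([5.0, 5.0]))
    lo, hi = (1.0 - gap) / 2.0, (1.0 + gap) / 2.0

    t1 = rng.uniform(0.0, 1.0, n1)
    t2 = rng.uniform(0.0, 1.0, n2)
    x1 = t1 * lo * (1.0 - 1e-9)  # strictly below the gap
    x2 = hi + t2 * (1.0 - hi)
    x2[np.argmax(t2)] = 1.0  # pin the endpoint so rescaling is exact
    y = rng.uniform(0.0, 1.0, n1 + n2)

    types = np.concatenate(
        [_types_from_time(t1, "ABCDE"), _types_from_time(t2, "FGHIJ")]
    )
    x = np.concatenate([x1, x2])
    lineage = np.concatenate([np.repeat("lineage1", n1), np.repeat("lineage2", n2)])
    return _assemble(x, y, types, x, lineage, "disconnected")


def simulate(dataset: int, n_cells: int | None = None, seed: int = 0) -> SimulatedDataset:
    """Dispatch by benchmark number (1-4) with the canonical default sizes."""
    if dataset == 1:
        return simulate_dataset1(n_cells or 1000, seed=seed)
    if dataset in (2, 3):
        return simulate_dataset2_3(
            n_cells or 500, pattern="linear" if dataset == 2 else "quadratic", seed=seed
        )
    if dataset == 4:
        return simulate_dataset4(n_cells or 454, seed=seed)
    raise ValueError(f"dataset must be 1, 2, 3 or 4, got {dataset!r}")
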