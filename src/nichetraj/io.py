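"""Cell-table reading/validation and result writers.

The canonical input is a delimited text table with columns ``Cell_ID``,
``Sample``, ``Cell_Type``, ``x``, ``y`` (optional ``z``); unknown columns
are ignored.  Cell types are mapped to a stable, sorted category order
shared across samples.  An AnnData object (obs columns for type/sample,
obsm["spatial"] for coordinates) can also be converted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("Cell_ID", "Sample", "Cell_Type", "x", "y")

__all__ = ["read_cell_table", "validate_cell_table", "write_outputs", "from_anndata"]


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a cell table in place of schema checking."""
    missing = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table is missing required column(s): {missing}")
    keep = [c for c in cells.columns if c in REQUIRED_COLUMNS + ("z",)]
    cells = cells[keep].copy()
    coord_cols = ["x", "y"] + (["z"] if "z" in cells.columns else [])
    cells[coord_cols] = cells[coord_cols].apply(pd.to_numeric, errors="coerce")
    if cells[coord_cols].isna().any().any():
        raise ValueError("missing or non-numeric coordinates")
    if cells[["Cell_ID", "Sample", "Cell_Type"]].isna().any().any():
        raise ValueError("missing Cell_ID, Sample or Cell_Type values")
    dup = cells.duplicated(subset=["Sample", "Cell_ID"])
    if dup.any():
        raise ValueError(
            f"duplicate Cell_ID within a sample: {cells.loc[dup, 'Cell_ID'].iloc[0]!r}"
        )
    if cells["Cell_Type"].nunique() < 2:
        raise ValueError("need at least two distinct cell types")
    return cells.reset_index(drop=True)


def read_cell_table(path) -> pd.DataFrame:
    """Read a CSV/TSV cell table (dialect chosen by file extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return validate_cell_table(pd.read_csv(path, sep=sep, dtype={"Cell_ID": str, "Sample": str}))


def from_anndata(adata, type_key: str = "Cell_Type", sample_key: str = "Sample") -> pd.DataFrame:
    """Convert a single-cell container to the canonical cell table."""
    coords = np.asarray(adata.obsm["spatial"])
    table = pd.DataFrame(
        {
            "Cell_ID": adata.obs_names.astype(str),
            "Sample": adata.obs[sample_key].astype(str).to_numpy()
            if sample_key in adata.obs
            else "sample0",
            "Cell_Type": adata.obs[type_key].astype(str).to_numpy(),
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )
    if coords.shape[1] > 2:
        table["z"] = coords[:, 2]
    return validate_cell_table(table)


def write_outputs(out_dir, estimator, cells: pd.DataFrame) -> dict:
    """Write the five result files of a fitted trajectory model.

    Returns a name -> path map: niche scores, cell scores, soft cluster
    assignments, cluster connectivity (raw and normalized), and the
    cluster ordering.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = np.concatenate([g.cell_ids for g in estimator.niche_graphs_])
    samples = np.concatenate(
        [np.repeat(g.sample, g.n_niches) for g in estimator.niche_graphs_]
    )
    paths = {}

    niche = pd.DataFrame(
        {"Cell_ID": ids, "Sample": samples, "NT_score": estimator.niche_scores_}
    )
    paths["niche_scores"] = out / "niche_NT_scores.csv"
    niche.to_csv(paths["niche_scores"], index=False)

    cell = pd.DataFrame(
        {"Cell_ID": ids, "Sample": samples, "cell_NT_score": estimator.cell_scores_}
    )
    paths["cell_scores"] = out / "cell_NT_scores.csv"
    cell.to_csv(paths["cell_scores"], index=False)

    c = np.vstack(estimator.cluster_assignments_)
    assign = pd.DataFrame(
        c, columns=[f"cluster_{k}" for k in range(c.shape[1])]
    )
    assign.insert(0, "Cell_ID", ids)
    assign.insert(1, "Sample", samples)
    paths["assignments"] = out / "cluster_assignments.csv"
    assign.to_csv(paths["assignments"], index=False)

    paths["connectivity"] = out / "cluster_connectivity.csv"
    k = estimator.connectivity_.E.shape[0]
    conn = pd.DataFrame(
        np.vstack([estimator.connectivity_.E, estimator.connectivity_.E_norm]),
        columns=[f"cluster_{i}" for i in range(k)],
    )
    conn.insert(0, "matrix", ["raw"] * k + ["normalized"] * k)
    conn.to_csv(paths["connectivity"], index=False)

    paths["ordering"] = out / "cluster_ordering.txt"
    paths["ordering"].write_text(
        " -> ".join(str(int(i)) for i in estimator.ordering_) + "\n"
    )
    return paths
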