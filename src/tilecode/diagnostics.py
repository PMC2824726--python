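"""QC analytics: correspondence analysis and position-similarity correlation.

Correspondence analysis ordinates the barcode x tiling-probe signal matrix:
the matrix is scaled to proportions, the chi-square standardized residuals
(P - r c^T) / sqrt(r c^T) are decomposed by SVD, and both barcodes (rows)
and tiling-probe positions (columns) are plotted in symmetric principal
coordinates with the centroid at the origin. A barcode and a probe on the
same side of the centroid are positively associated (that probe's signal is
over-represented for that barcode). The sum of squared singular values is
the total inertia, which times the grand total equals Pearson's chi-square.

The position-correlation diagnostic quantifies how much probe-sequence
overlap drives agreement between tiling positions: squared Pearson
correlations of per-position log2 ratios across constructs, grouped by the
shared-sequence classes of the 7-nt-step design (18 / 11 / 4 / 0 nt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .probe_design import PROBE_LEN, TILING_STEP, probe_pair_overlap

logger = logging.getLogger("tilecode")

TP_POSITIONS = ("TP1", "TP2", "TP3", "TP4", "TP5", "TP6")


@dataclass
class CAResult:
    """Symmetric principal coordinates and inertia decomposition."""

    row_coords: pd.DataFrame    # objects (barcodes) x axes
    col_coords: pd.DataFrame    # tiling positions x axes
    inertia_per_axis: np.ndarray
    total_inertia: float
    row_masses: pd.Series
    col_masses: pd.Series


def correspondence_analysis(matrix: pd.DataFrame) -> CAResult:
    """Standard correspondence analysis of a non-negative matrix.

    Rows/columns that sum to zero are rejected by name: they have no mass
    and would make the chi-square metric undefined.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("correspondence analysis requires a non-negative matrix")
    zero_rows = matrix.index[X.sum(axis=1) == 0]
    if len(zero_rows):
        raise ValueError(f"all-zero row(s): {list(zero_rows[:5])}")
    zero_cols = matrix.columns[X.sum(axis=0) == 0]
    if len(zero_cols):
        raise ValueError(f"all-zero column(s): {list(zero_cols[:5])}")
    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # residual rank: the trivial dimension is already removed by centering
    k = min(len(r), len(c))
    U, sv, Vt = U[:, :k], sv[:k], Vt[:k]
    # symmetric principal coordinates: both clouds scaled by singular values
    rows = (U / np.sqrt(r)[:, None]) * sv
    cols = (Vt.T / np.sqrt(c)[:, None]) * sv
    axes = [f"axis{i + 1}" for i in range(k)]
    return CAResult(
        row_coords=pd.DataFrame(rows, index=matrix.index, columns=axes),
        col_coords=pd.DataFrame(cols, index=matrix.columns, columns=axes),
        inertia_per_axis=sv**2,
        total_inertia=float((sv**2).sum()),
        row_masses=pd.Series(r, index=matrix.index),
        col_masses=pd.Series(c, index=matrix.columns),
    )


def overlap_class(pos_a: str, pos_b: str, step: int = TILING_STEP,
                  probe_len: int = PROBE_LEN) -> int:
    """Shared nucleotides between two TPk positions of the default design."""
    ka = int(pos_a.removeprefix("TP"))
    kb = int(pos_b.removeprefix("TP"))
    return probe_pair_overlap((ka - 1) * step, (kb - 1) * step, probe_len)


@dataclass
class SimilarityCorrelation:
    """Pairwise r-squared of position-wise log2 ratios, grouped by overlap."""

    r2_matrix: pd.DataFrame  # positions x positions
    grouped: pd.DataFrame    # index overlap_nt -> mean_r2, sigma, n_pairs


def position_correlation(
    ratio_wide: pd.DataFrame,
    min_pairs: int = 3,
) -> SimilarityCorrelation:
    """Correlation of per-position log2 ratios across constructs.

    ``ratio_wide`` is constructs x positions (TP1..TP6), NaN where a probe
    was filtered out; correlations are pairwise-complete. Position pairs
    with fewer than ``min_pairs`` joint observations are omitted (logged).
    """
    cols = [c for c in TP_POSITIONS if c in ratio_wide.columns]
    corr = ratio_wide[cols].corr(method="pearson", min_periods=min_pairs)
    r2 = corr**2
    np.fill_diagonal(r2.values, 1.0)
    groups: dict[int, list[float]] = {}
    for a, b in combinations(cols, 2):
        val = r2.loc[a, b]
        if np.isnan(val):
            logger.info("position pair (%s, %s) omitted: fewer than %d joint values",
                        a, b, min_pairs)
            continue
        groups.setdefault(overlap_class(a, b), []).append(float(val))
    rows = []
    for ov in sorted(groups):
        vals = np.array(groups[ov])
        rows.append({
            "overlap_nt": ov,
            "mean_r2": float(vals.mean()),
            "sigma": float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan,
            "n_pairs": len(vals),
        })
    grouped = pd.DataFrame(rows, columns=["overlap_nt", "mean_r2", "sigma", "n_pairs"])
    grouped = grouped.set_index("overlap_nt")
    return SimilarityCorrelation(r2_matrix=r2, grouped=grouped)


def ratio_table_to_wide(kept_ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-construct x position mean log2 ratios from a long ratio table."""
    return (
        kept_ratios.groupby(["construct_id", "position"])["log2_ratio"]
        .mean()
        .unstack("position")
    )


def tzero_position_matrix(table, layout) -> pd.DataFrame:
    """Mean t_zero signal per (construct, position) — input for CA.

    Averages all t_zero replicate features of each tiling probe, matching
    the use of time-point-zero intensity profiles to ordinate barcodes
    against the six tiling positions.
    """
    features = layout.sample_features()
    tiling = features[
        (features["kind"] == "tiling")
        & ~features["construct_id"].isin(layout.negative_construct_ids)
    ]
    zero_cols = table.sample_ids(role="t_zero") or table.sample_ids(role="reference")
    if not zero_cols:
        raise ValueError("no t_zero or reference samples in the table")
    sig = table.values.loc[tiling.index, zero_cols].mean(axis=1)
    mat = sig.groupby([tiling["construct_id"], tiling["position"]]).mean().unstack("position")
    return mat


# ---------------------------------------------------------------------------
# Optional plots (matplotlib imported lazily)


def plot_ca(ca: CAResult, path: str) -> None:
    """Symmetric CA projection: barcodes as dots, positions as squares."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(ca.row_coords["axis1"], ca.row_coords["axis2"],
               s=8, c="black", alpha=0.5, label="barcodes")
    ax.scatter(ca.col_coords["axis1"], ca.col_coords["axis2"],
               s=80, marker="s", c="tab:red", label="tiling probes")
    for name, row in ca.col_coords.iterrows():
        ax.annotate(str(name), (row["axis1"], row["axis2"]), fontsize=8)
    ax.axhline(0, ls="--", lw=0.5, c="gray")
    ax.axvline(0, ls="--", lw=0.5, c="gray")
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ratio_heatmap(ratio_wide: pd.DataFrame, path: str) -> None:
    """Constructs x positions log2-ratio heat map (white = filtered out)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = ratio_wide.mean(axis=1).sort_values().index
    fig, ax = plt.subplots(figsize=(4, 8))
    im = ax.imshow(ratio_wide.loc[order].to_numpy(), aspect="auto",
                   cmap="RdBu_r", interpolation="nearest")
    ax.set_xticks(range(len(ratio_wide.columns)), ratio_wide.columns)
    ax.set_xlabel("tiling probe")
    ax.set_ylabel("constructs (sorted by mean log2 ratio)")
    fig.colorbar(im, ax=ax, label="log2 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
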