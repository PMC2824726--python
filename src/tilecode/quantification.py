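"""The decoding cascade: background, thresholds, normalization, ratios,
filtering and per-construct aggregation.

Order of operations: per-sample median normalization first, then the
median-background estimate from negative-control features, then the
detection threshold (so thresholds are comparable across subarrays);
log2(test/reference) ratios are formed only where the reference feature
passed its threshold, replicate features are collapsed to one ratio per
(probe, experiment), and per-construct abundance is the mean over the
surviving per-probe means. Dilution experiments additionally renormalize
every ratio to the equimolar subpool-0 of the same array.

Thresholds use a strict ">": a signal exactly at k-fold background fails.
Test signals are floored at one raw intensity unit before division so that
empty test pools give finite, very small ratios instead of -inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .probe_design import ArrayLayout, NEG_TILING, TILING, _HH_KINDS
from .synthetic_data import IntensityTable, PoolSpec

logger = logging.getLogger("tilecode")

RATIO_COLUMNS = ["construct_id", "position", "experiment", "log2_ratio", "n_features"]


@dataclass(frozen=True)
class BackgroundEstimate:
    """Per-sample median signal of negative-control features."""

    median_background: pd.Series  # indexed by sample_id
    n_negative_probes: int

    def __post_init__(self) -> None:
        if (self.median_background < 0).any():
            raise ValueError("median background must be non-negative")


def median_background(
    table: IntensityTable, negative_probe_ids: Sequence[str]
) -> BackgroundEstimate:
    """Median background per sample from probes of absent constructs."""
    neg = [p for p in negative_probe_ids if p in table.values.index]
    if not neg:
        raise ValueError("no negative controls present in the intensity table")
    missing = set(negative_probe_ids) - set(neg)
    if missing:
        raise ValueError(f"negative-control probes missing from table: {sorted(missing)[:5]}")
    med = table.values.loc[neg].median(axis=0)
    return BackgroundEstimate(median_background=med, n_negative_probes=len(neg))


def detection_mask(
    table: IntensityTable, background: BackgroundEstimate, k_fold: float
) -> pd.DataFrame:
    """Boolean per feature x sample: signal strictly above k-fold background."""
    if k_fold < 0:
        raise ValueError("k_fold must be >= 0")
    thresh = k_fold * background.median_background
    return table.values.gt(thresh, axis=1)


def sample_medians(table: IntensityTable) -> pd.Series:
    return table.values.median(axis=0)


def normalize_to_array_median(table: IntensityTable) -> IntensityTable:
    """Divide each sample by its own median signal (output medians are 1)."""
    med = sample_medians(table)
    zero = med.index[med <= 0]
    if len(zero):
        raise ValueError(f"zero or negative median signal in sample(s): {list(zero)}")
    return IntensityTable(values=table.values.div(med, axis=1), samples=table.samples)


def probe_log2_ratios(
    test_norm: pd.Series,
    ref_norm: pd.Series,
    ref_mask: pd.Series,
    features: pd.DataFrame,
    experiment: str,
    test_floor: float = 0.0,
) -> pd.DataFrame:
    """One log2(test/reference) ratio per probe for one experiment.

    Replicate features of a probe are averaged within each sample before
    the ratio is formed; only features whose reference signal passed the
    detection threshold contribute. ``test_floor`` (in the same units as
    the signals handed in) is applied per feature before averaging.
    """
    missing = features.index.difference(ref_norm.index)
    if len(missing):
        raise ValueError(f"probes absent from the reference sample: {list(missing[:5])}")
    missing_t = features.index.difference(test_norm.index)
    if len(missing_t):
        raise ValueError(f"probes absent from the test sample: {list(missing_t[:5])}")

    df = features.copy()
    df["ref"] = ref_norm.reindex(features.index)
    df["test"] = test_norm.reindex(features.index).clip(lower=test_floor)
    df["pass"] = ref_mask.reindex(features.index).fillna(False)
    df = df[df["pass"]]
    rows = []
    for (cid, pos), grp in df.groupby(["construct_id", "position"], sort=True):
        mean_ref = grp["ref"].mean()
        mean_test = grp["test"].mean()
        if mean_ref <= 0:
            continue  # cannot form a ratio against a zero reference
        rows.append({
            "construct_id": cid,
            "position": pos,
            "experiment": experiment,
            "log2_ratio": float(np.log2(mean_test / mean_ref)),
            "n_features": int(len(grp)),
        })
    return pd.DataFrame(rows, columns=RATIO_COLUMNS)


def normalize_to_reference_subpool(
    ratios: pd.DataFrame,
    subpool0_ids: Iterable[str],
    stat: str = "mean",
) -> pd.DataFrame:
    """Renormalize linear ratios to the equimolar subpool-0 of each array.

    Every linear ratio of an experiment is divided by the ``stat`` (mean by
    default, median by choice) of the linear ratios of subpool-0 constructs
    on that array; afterwards the subpool-0 mean (resp. median) is exactly 1.
    """
    subpool0 = set(subpool0_ids)
    if not subpool0:
        raise ValueError("subpool-0 construct set is empty")
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown stat {stat!r}")
    out = ratios.copy()
    linear = np.power(2.0, out["log2_ratio"].to_numpy())
    out["_linear"] = linear
    for exp, grp in out.groupby("experiment"):
        anchor = grp.loc[grp["construct_id"].isin(subpool0), "_linear"]
        if anchor.empty:
            raise ValueError(f"no subpool-0 ratios on array {exp!r}")
        factor = anchor.mean() if stat == "mean" else anchor.median()
        out.loc[grp.index, "log2_ratio"] = grp["log2_ratio"] - np.log2(factor)
    return out.drop(columns="_linear")


@dataclass
class AggregationResult:
    """Filtered per-construct abundances plus audit trail."""

    constructs: pd.DataFrame   # indexed by construct_id
    kept_ratios: pd.DataFrame  # surviving (probe, experiment) log2 values
    drop_log: pd.DataFrame     # (level, construct_id, position, reason)


def filter_and_aggregate(
    ratios: pd.DataFrame,
    min_probes: int = 2,
    min_ratio_values: int = 4,
    max_ratio_values: int = 9,
    positions: Sequence[str] = ("TP1", "TP2", "TP3", "TP4", "TP5", "TP6"),
) -> AggregationResult:
    """Probe- and construct-level filtering, then per-construct means.

    A probe survives only when its ratios rest on at least
    ``min_ratio_values`` of the at most ``max_ratio_values`` underlying
    replicate signal ratios (replicate features x experiments); a construct
    is reported only when at least ``min_probes`` of its probes survive.
    Dropped probes/constructs are returned in the drop log, never raised.
    """
    drops = []
    if ratios.empty:
        empty = pd.DataFrame(
            columns=["mean_log2", "n_probes_used", "n_ratio_values", *positions]
        )
        empty.index.name = "construct_id"
        return AggregationResult(
            constructs=empty,
            kept_ratios=ratios.copy(),
            drop_log=pd.DataFrame(columns=["level", "construct_id", "position", "reason"]),
        )

    probe_counts = ratios.groupby(["construct_id", "position"])["n_features"].sum()
    over = probe_counts[probe_counts > max_ratio_values]
    if len(over):
        raise ValueError(
            f"probe(s) with more than {max_ratio_values} underlying ratios: "
            f"{list(over.index[:3])} — experiment pairing is inconsistent"
        )
    keep_probes = set(probe_counts.index[probe_counts >= min_ratio_values])
    for (cid, pos), n in probe_counts.items():
        if (cid, pos) not in keep_probes:
            drops.append({
                "level": "probe", "construct_id": cid, "position": pos,
                "reason": f"{n} of {max_ratio_values} replicate ratios (< {min_ratio_values})",
            })
    kept = ratios[
        ratios.set_index(["construct_id", "position"]).index.isin(keep_probes)
    ].copy()

    rows = []
    for cid in ratios["construct_id"].unique():
        sub = kept[kept["construct_id"] == cid]
        per_probe = sub.groupby("position")["log2_ratio"].mean()
        if len(per_probe) < min_probes:
            drops.append({
                "level": "construct", "construct_id": cid, "position": "",
                "reason": f"{len(per_probe)} surviving probe(s) (< {min_probes})",
            })
            continue
        row = {
            "construct_id": cid,
            "mean_log2": float(per_probe.mean()),
            "n_probes_used": int(len(per_probe)),
            "n_ratio_values": int(sub["n_features"].sum()),
        }
        for pos in positions:
            row[pos] = float(per_probe[pos]) if pos in per_probe.index else np.nan
        rows.append(row)
    constructs = pd.DataFrame(
        rows, columns=["construct_id", "mean_log2", "n_probes_used", "n_ratio_values", *positions]
    ).set_index("construct_id")
    kept = kept[kept["construct_id"].isin(constructs.index)]
    drop_log = pd.DataFrame(drops, columns=["level", "construct_id", "position", "reason"])
    if len(drop_log):
        logger.info("filter_and_aggregate dropped %d probe(s)/construct(s)", len(drop_log))
    return AggregationResult(constructs=constructs, kept_ratios=kept, drop_log=drop_log)


def half_hairpin_filter(
    mask: pd.Series,
    features: pd.DataFrame,
    min_replicates: int = 3,
) -> set[str]:
    """Constructs detected via half-hairpin probes.

    A construct counts as detected when more than two (>= min_replicates)
    of its half-hairpin replicate features pass the detection threshold in
    the reference sample.
    """
    hh = features[features["kind"].isin(_HH_KINDS)]
    passed = mask.reindex(hh.index).fillna(False)
    counts = passed.groupby(hh["construct_id"]).sum()
    return set(counts.index[counts >= min_replicates])


def tiling_detected_constructs(
    mask: pd.Series,
    features: pd.DataFrame,
    min_probes: int = 2,
) -> set[str]:
    """Constructs with more than one tiling probe above the threshold."""
    tiling = features[features["kind"].isin((TILING, NEG_TILING))]
    passed = mask.reindex(tiling.index).fillna(False)
    per_probe = passed.groupby([tiling["construct_id"], tiling["position"]]).any()
    n_probes = per_probe.groupby(level=0).sum()
    return set(n_probes.index[n_probes >= min_probes])


# ---------------------------------------------------------------------------
# Pipelines


@dataclass
class DilutionQuantification:
    """Outputs of the dilution-pool decoding."""

    probe_ratios: pd.DataFrame       # subpool-0 renormalized probe-level ratios
    construct_pools: pd.DataFrame    # one row per (construct, test pool)
    drop_log: pd.DataFrame
    background: BackgroundEstimate


def quantify_dilution(
    table: IntensityTable,
    layout: ArrayLayout,
    pool_spec: PoolSpec,
    k_fold: float = 4.0,
    min_probes: int = 2,
    subpool_stat: str = "mean",
    test_floor: float = 1.0,
    reference_sample: str = "reference",
) -> DilutionQuantification:
    """Decode engineered dilution pools against the equimolar reference.

    Each test pool is one experiment/array: probe ratios against the
    reference, renormalized to subpool-0 of that array, then averaged per
    construct (requiring at least ``min_probes`` probes with a detected
    reference signal). Returns linear (test/reference) ratios per
    (construct, pool).
    """
    raw_med = sample_medians(table)
    norm = normalize_to_array_median(table)
    bg = median_background(norm, layout.negative_probe_ids())
    mask = detection_mask(norm, bg, k_fold)
    features = layout.sample_features()
    tiling = features[
        (features["kind"] == TILING)
        & ~features["construct_id"].isin(layout.negative_construct_ids)
    ]
    parts = []
    for pool in table.sample_ids(role="test"):
        parts.append(probe_log2_ratios(
            norm.values[pool],
            norm.values[reference_sample],
            mask[reference_sample],
            tiling,
            experiment=pool,
            test_floor=test_floor / raw_med[pool],
        ))
    ratios = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=RATIO_COLUMNS)
    ratios = normalize_to_reference_subpool(ratios, pool_spec.subpool0_ids(), stat=subpool_stat)

    rows, drops = [], []
    for (cid, pool), grp in ratios.groupby(["construct_id", "experiment"]):
        if len(grp) < min_probes:
            drops.append({
                "level": "construct", "construct_id": cid, "position": "",
                "reason": f"{len(grp)} detected probe(s) in {pool} (< {min_probes})",
            })
            continue
        mean_log2 = grp["log2_ratio"].mean()
        rows.append({
            "construct_id": cid,
            "pool": pool,
            "ratio": float(np.power(2.0, mean_log2)),
            "mean_log2": float(mean_log2),
            "n_probes": int(len(grp)),
            "dilution_factor": pool_spec.factor_of(pool, cid),
        })
    construct_pools = pd.DataFrame(
        rows, columns=["construct_id", "pool", "ratio", "mean_log2", "n_probes", "dilution_factor"]
    )
    return DilutionQuantification(
        probe_ratios=ratios,
        construct_pools=construct_pools,
        drop_log=pd.DataFrame(drops, columns=["level", "construct_id", "position", "reason"]),
        background=bg,
    )


def dilution_summary(
    construct_pools: pd.DataFrame,
    test: str = "moderated",
) -> pd.DataFrame:
    """Per-dilution-factor summary: mean ratio, sigma, p-value, n.

    The mean and standard deviation are of the linear (test/reference)
    ratios; sigma is left blank (NaN) for factors with fewer than three
    analyzable constructs. The p-value tests the factor group against the
    equimolar (factor 1) group on the log2 scale, by default with the
    moderated (variance-shrunk) two-sample t.
    """
    from .screen_stats import moderated_two_sample_t, welch_two_sample_t

    if test not in ("moderated", "t"):
        raise ValueError(f"unknown test {test!r}")
    groups = {
        f: grp["mean_log2"].to_numpy()
        for f, grp in construct_pools.groupby("dilution_factor")
    }
    if 1.0 not in groups:
        raise ValueError("no equimolar (factor 1) group to test against")
    if test == "moderated":
        pvals = moderated_two_sample_t(groups, reference_key=1.0)
    else:
        pvals = welch_two_sample_t(groups, reference_key=1.0)
    rows = []
    for factor in sorted(groups):
        vals = construct_pools.loc[
            construct_pools["dilution_factor"] == factor, "ratio"
        ]
        n = len(vals)
        rows.append({
            "dilution_factor": factor,
            "mean_ratio": float(vals.mean()),
            "sigma": float(vals.std(ddof=1)) if n >= 3 else np.nan,
            "p_value": pvals.get(factor, np.nan),
            "n": n,
        })
    return pd.DataFrame(rows).set_index("dilution_factor")


def quantify_screen(
    table: IntensityTable,
    layout: ArrayLayout,
    k_fold: float = 10.0,
    min_probes: int = 2,
    min_ratio_values: int = 4,
    test_floor: float = 1.0,
) -> tuple[AggregationResult, BackgroundEstimate]:
    """Decode a paired t_zero/t_end negative-selection screen.

    Replicate r pairs sample t_end_r with t_zero_r; the 10-fold detection
    threshold is applied to the t_zero reference of each replicate. The
    replicate feature count per probe carries through to the
    four-of-nine filter in :func:`filter_and_aggregate`.
    """
    raw_med = sample_medians(table)
    norm = normalize_to_array_median(table)
    bg = median_background(norm, layout.negative_probe_ids())
    mask = detection_mask(norm, bg, k_fold)
    features = layout.sample_features()
    tiling = features[
        (features["kind"] == TILING)
        & ~features["construct_id"].isin(layout.negative_construct_ids)
    ]
    zero_ids = table.sample_ids(role="t_zero")
    end_ids = table.sample_ids(role="t_end")
    by_rep = {table.samples.loc[s, "replicate"]: s for s in zero_ids}
    parts = []
    for end in end_ids:
        rep = table.samples.loc[end, "replicate"]
        if rep not in by_rep:
            raise ValueError(f"t_end sample {end!r} has no matching t_zero replicate")
        zero = by_rep[rep]
        parts.append(probe_log2_ratios(
            norm.values[end],
            norm.values[zero],
            mask[zero],
            tiling,
            experiment=f"rep{rep}",
            test_floor=test_floor / raw_med[end],
        ))
    ratios = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=RATIO_COLUMNS)
    max_values = layout.tiling_reps * len(end_ids)
    agg = filter_and_aggregate(
        ratios,
        min_probes=min_probes,
        min_ratio_values=min_ratio_values,
        max_ratio_values=max_values,
    )
    # conservation: constructs with no detected reference probe at all never
    # reach the ratio table; give them an explicit drop entry
    in_play = set(tiling["construct_id"])
    unseen = in_play - set(ratios["construct_id"]) if len(ratios) else in_play
    if unseen:
        extra = pd.DataFrame([
            {"level": "construct", "construct_id": c, "position": "",
             "reason": f"no reference probe above {k_fold}-fold background"}
            for c in sorted(unseen)
        ])
        agg.drop_log = pd.concat([agg.drop_log, extra], ignore_index=True)
    return agg, bg
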