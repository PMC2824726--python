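"""Ground-truth-annotated hybridization simulation.

Two experiment classes are emulated:

* engineered dilution pools — a reference pool with every construct
  equimolar and test pools in which seven subpools are diluted by known
  factors (subpool-0 always stays equimolar and anchors renormalization);
* paired negative-selection screens — t_zero/t_end sample pairs in which a
  chosen subset of constructs is depleted by a known log2 effect.

The signal model per array feature is

    signal = f(affinity x abundance) x noise + background_residual

with ``f`` the identity, or a Langmuir saturation f(x) = smax x / (smax + x)
when a surface capacity ``smax`` is set. Per-probe affinities are log-normal
(median 1) with scale ``affinity_sigma``; log-affinities of tiling probes
from the same barcode are correlated with coefficient
``overlap_rho x shared_nt / probe_len``, which is what lets probe-sequence
effects propagate into position-wise ratio correlations. Measurement noise
is multiplicative log-normal with unit mean and coefficient of variation
``noise_cv``; the background residual left after the instrument's local
subtraction is a small additive half-normal term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .probe_design import (
    ArrayLayout,
    ConstructRecord,
    PROBE_LEN,
    probe_pair_overlap,
)

logger = logging.getLogger("tilecode")

#: engineered dilution scheme: per test pool, the relative abundance of each
#: subpool (index 0..6); subpool-0 is equimolar (1.0) in every pool and the
#: reference pool keeps every subpool at 1.0.
DILUTION_SCHEME: dict[str, tuple[float, ...]] = {
    "reference": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    "test_pool_1": (1.0, 9e-01, 1e-03, 1e-04, 1e-01, 5e-01, 4e-03),
    "test_pool_2": (1.0, 4e-01, 8e-01, 2e-01, 1e-05, 1e-02, 4e-02),
    "test_pool_3": (1.0, 2e-03, 3e-01, 7e-01, 6e-01, 1e-06, 2e-04),
}

N_SUBPOOLS = 7


@dataclass(frozen=True)
class PoolSpec:
    """Assignment of constructs to subpools plus per-pool dilution factors."""

    subpool_assignment: dict  # construct_id -> subpool index 0..6
    dilution_factors: dict    # (pool_name, subpool) -> relative abundance

    def __post_init__(self) -> None:
        pools = {p for p, _ in self.dilution_factors}
        for pool in pools:
            f0 = self.dilution_factors.get((pool, 0))
            if f0 != 1.0:
                raise ValueError(f"subpool-0 must stay equimolar in pool {pool!r} (got {f0})")
        for cid, sp in self.subpool_assignment.items():
            if not 0 <= sp < N_SUBPOOLS:
                raise ValueError(f"construct {cid!r} assigned to invalid subpool {sp}")

    @property
    def pool_names(self) -> list[str]:
        return sorted({p for p, _ in self.dilution_factors})

    @property
    def test_pool_names(self) -> list[str]:
        return [p for p in self.pool_names if p != "reference"]

    def subpool0_ids(self) -> list[str]:
        return [c for c, s in self.subpool_assignment.items() if s == 0]

    def factor_of(self, pool_name: str, construct_id: str) -> float:
        sp = self.subpool_assignment[construct_id]
        return self.dilution_factors[(pool_name, sp)]

    @classmethod
    def dilution_series(cls, construct_ids: Sequence[str], per_subpool: int = 10) -> "PoolSpec":
        """The engineered dilution design over a given construct list.

        The first ``6 x per_subpool`` constructs populate subpools 1..6
        (``per_subpool`` each); the remainder forms the equimolar subpool-0.
        """
        need = 6 * per_subpool
        if len(construct_ids) <= need:
            raise ValueError(
                f"need more than {need} constructs for {per_subpool} per diluted subpool"
            )
        assignment = {}
        for i, cid in enumerate(construct_ids):
            assignment[cid] = (i // per_subpool) + 1 if i < need else 0
        factors = {
            (pool, sp): f
            for pool, row in DILUTION_SCHEME.items()
            for sp, f in enumerate(row)
        }
        return cls(subpool_assignment=assignment, dilution_factors=factors)


def make_dilution_pools(
    constructs: Sequence[ConstructRecord] | Sequence[str],
    pool_spec: PoolSpec,
) -> dict[str, pd.Series]:
    """Relative abundance vectors, one per pool, from the dilution design."""
    ids = [c.construct_id if isinstance(c, ConstructRecord) else c for c in constructs]
    missing = [c for c in ids if c not in pool_spec.subpool_assignment]
    if missing:
        raise ValueError(f"constructs not assigned to any subpool: {missing[:5]}")
    pools = {}
    for pool in pool_spec.pool_names:
        pools[pool] = pd.Series(
            [pool_spec.factor_of(pool, c) for c in ids], index=ids, name=pool, dtype=float
        )
    return pools


@dataclass
class IntensityTable:
    """Probe x sample matrix of background-subtracted signals.

    ``values`` is indexed by probe_id with one column per sample;
    ``samples`` carries per-sample metadata (role, replicate).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata must match value columns")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensity values must be non-negative")

    def sample_ids(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.samples.index)
        return list(self.samples.index[self.samples["role"] == role])


# ---------------------------------------------------------------------------
# Probe affinities


def _noise_lognormal_params(cv: float) -> tuple[float, float]:
    """(mu, sigma) of a unit-mean log-normal with coefficient of variation cv."""
    s2 = np.log1p(cv * cv)
    return -0.5 * s2, np.sqrt(s2)


def draw_correlated_log_affinities(
    n_barcodes: int,
    offsets: Sequence[int],
    affinity_sigma: float,
    overlap_rho: float,
    probe_len: int = PROBE_LEN,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw (n_barcodes, n_positions) log-affinities with overlap correlation.

    Off-diagonal correlation between positions i, j is
    ``overlap_rho x overlap(i, j) / probe_len``. The triangular overlap
    kernel is positive semi-definite, so the mixture with the identity is a
    valid correlation matrix for any rho in [0, 1].
    """
    if affinity_sigma < 0:
        raise ValueError("affinity_sigma must be >= 0")
    if not 0 <= overlap_rho <= 1:
        raise ValueError("overlap_rho must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    k = len(offsets)
    tri = np.empty((k, k))
    for i, oi in enumerate(offsets):
        for j, oj in enumerate(offsets):
            tri[i, j] = probe_pair_overlap(oi, oj, probe_len) / probe_len
    corr = overlap_rho * tri + (1.0 - overlap_rho) * np.eye(k)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_barcodes, k))
    return affinity_sigma * (z @ chol.T)


def simulate_probe_affinities(
    layout: ArrayLayout,
    affinity_sigma: float,
    overlap_rho: float,
    seed: int | np.random.Generator,
) -> dict[str, float]:
    """Per-probe hybridization affinities, shared by replicate features.

    Affinities are log-normal with median 1 and log-scale ``affinity_sigma``;
    tiling probes of one barcode are correlated according to their sequence
    overlap. Every replicate feature (and every subarray copy) of a probe
    carries the same affinity: affinity is a property of the probe sequence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = layout.frame()
    unique = (
        df.reset_index()[["construct_id", "kind", "offset"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    log_aff: dict[tuple, float] = {}
    tiling = unique[unique["offset"] >= 0]
    for cid, grp in tiling.groupby("construct_id", sort=True):
        offs = sorted(grp["offset"].unique())
        row = draw_correlated_log_affinities(
            1, offs, affinity_sigma, overlap_rho, rng=rng
        )[0]
        for off, la in zip(offs, row):
            for kind in grp.loc[grp["offset"] == off, "kind"]:
                log_aff[(cid, kind, off)] = la
    hh = unique[unique["offset"] < 0].sort_values(["construct_id", "kind"])
    for _, r in hh.iterrows():
        log_aff[(r["construct_id"], r["kind"], r["offset"])] = (
            affinity_sigma * rng.standard_normal()
        )
    keys = list(zip(df["construct_id"], df["kind"], df["offset"]))
    return {pid: float(np.exp(log_aff[k])) for pid, k in zip(df.index, keys)}


# ---------------------------------------------------------------------------
# Hybridization


def simulate_hybridization(
    features: pd.DataFrame,
    abundances: Mapping[str, float] | pd.Series,
    affinities: Mapping[str, float],
    noise_cv: float = 0.0,
    background_level: float = 0.0,
    saturation_smax: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    """Simulate one sample's signals over a feature table.

    ``features`` is a layout feature frame (one subarray); constructs absent
    from ``abundances`` hybridize at abundance 0 (negative controls).
    Returns a non-negative signal per probe_id.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ab = pd.Series(dict(abundances), dtype=float) if not isinstance(abundances, pd.Series) else abundances.astype(float)
    if (ab < 0).any():
        bad = ab.index[ab < 0][0]
        raise ValueError(f"negative abundance for construct {bad!r}")
    x = ab.reindex(features["construct_id"]).fillna(0.0).to_numpy()
    a = np.array([affinities[pid] for pid in features.index])
    expected = a * x
    if saturation_smax is not None:
        smax = float(saturation_smax)
        if smax <= 0:
            raise ValueError("saturation_smax must be positive")
        expected = smax * expected / (smax + expected)
    if noise_cv > 0:
        mu, s = _noise_lognormal_params(noise_cv)
        expected = expected * rng.lognormal(mu, s, size=expected.shape)
    if background_level > 0:
        expected = expected + np.abs(rng.normal(0.0, background_level, size=expected.shape))
    return pd.Series(np.clip(expected, 0.0, None), index=features.index, name="signal")


def simulate_dilution_experiment(
    layout: ArrayLayout,
    pool_spec: PoolSpec,
    affinity_sigma: float = 1.0,
    overlap_rho: float = 0.6,
    noise_cv: float = 0.2,
    background_level: float = 20.0,
    saturation_smax: float | None = None,
    abundance_scale: float = 1e5,
    seed: int = 0,
) -> tuple[IntensityTable, dict[str, float]]:
    """Hybridize the reference and all test pools of a dilution design.

    Each pool occupies one subarray of identical probe content; signals are
    reported over the canonical subarray-1 feature set. Plasmid PCR pools
    are high-input material, so the default full-scale signal of a
    median-affinity probe (1e5) sits far above the post-subtraction
    background residual, giving the dynamic range needed to read 1e-2
    dilutions. Returns the intensity table and the per-probe affinities.
    """
    rng = np.random.default_rng(seed)
    features = layout.sample_features()
    construct_ids = sorted(
        set(features["construct_id"]) - set(layout.negative_construct_ids)
    )
    pools = make_dilution_pools(construct_ids, pool_spec)
    affinities = simulate_probe_affinities(layout, affinity_sigma, overlap_rho, rng)
    cols, meta = {}, []
    for pool in pool_spec.pool_names:
        cols[pool] = simulate_hybridization(
            features,
            pools[pool] * abundance_scale,
            affinities,
            noise_cv=noise_cv,
            background_level=background_level,
            saturation_smax=saturation_smax,
            rng=rng,
        )
        meta.append({
            "sample_id": pool,
            "role": "reference" if pool == "reference" else "test",
            "replicate": 1,
        })
    table = IntensityTable(
        values=pd.DataFrame(cols),
        samples=pd.DataFrame(meta).set_index("sample_id"),
    )
    return table, affinities


# ---------------------------------------------------------------------------
# Negative-selection screens


@dataclass(frozen=True)
class ScreenScenario:
    """Ground-truth specification of a simulated negative-selection screen.

    ``log2_effect`` maps depleted construct IDs to their t_end-vs-t_zero
    log2 change (negative = depletion); all other constructs have effect 0.
    ``abundance_scale`` sets the expected t_zero signal of a median-affinity
    probe in raw intensity units.
    """

    depleted_ids: frozenset = frozenset()
    log2_effect: dict = field(default_factory=dict)
    affinity_sigma: float = 1.0
    overlap_rho: float = 0.6
    noise_cv: float = 0.2
    background_level: float = 20.0
    saturation_smax: float | None = None
    n_replicates: int = 3
    abundance_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "depleted_ids", frozenset(self.depleted_ids))
        stray = {c for c, e in self.log2_effect.items() if e != 0} - self.depleted_ids
        if stray:
            raise ValueError(
                f"non-zero log2_effect for constructs outside depleted_ids: {sorted(stray)[:5]}"
            )

    def effect_of(self, construct_id: str) -> float:
        return float(self.log2_effect.get(construct_id, 0.0))


def simulate_negative_selection(
    layout: ArrayLayout,
    scenario: ScreenScenario,
) -> tuple[IntensityTable, pd.DataFrame]:
    """Paired t_zero/t_end tables across replicates, plus the ground truth.

    Within the whole experiment each probe keeps one affinity (a sequence
    property), so affinity cancels from the t_end/t_zero ratio in the linear
    regime; replicate-to-replicate variation comes from the per-feature
    measurement noise and background residuals.
    """
    rng = np.random.default_rng(scenario.seed)
    features = layout.sample_features()
    construct_ids = sorted(
        set(features["construct_id"]) - set(layout.negative_construct_ids)
    )
    unknown = scenario.depleted_ids - set(construct_ids)
    if unknown:
        raise ValueError(f"depleted_ids not in layout: {sorted(unknown)[:5]}")
    affinities = simulate_probe_affinities(
        layout, scenario.affinity_sigma, scenario.overlap_rho, rng
    )
    ab_zero = pd.Series(scenario.abundance_scale, index=construct_ids, dtype=float)
    ab_end = ab_zero * np.power(2.0, [scenario.effect_of(c) for c in construct_ids])
    cols, meta = {}, []
    for rep in range(1, scenario.n_replicates + 1):
        for role, ab in (("t_zero", ab_zero), ("t_end", ab_end)):
            sid = f"{role}_r{rep}"
            cols[sid] = simulate_hybridization(
                features, ab, affinities,
                noise_cv=scenario.noise_cv,
                background_level=scenario.background_level,
                saturation_smax=scenario.saturation_smax,
                rng=rng,
            )
            meta.append({"sample_id": sid, "role": role, "replicate": rep})
    table = IntensityTable(
        values=pd.DataFrame(cols),
        samples=pd.DataFrame(meta).set_index("sample_id"),
    )
    truth = pd.DataFrame({
        "construct_id": construct_ids,
        "true_log2_effect": [scenario.effect_of(c) for c in construct_ids],
        "depleted": [c in scenario.depleted_ids for c in construct_ids],
    }).set_index("construct_id")
    return table, truth


# ---------------------------------------------------------------------------
# Convenience construct generators (also used by the test fixtures)


def random_constructs(
    n: int,
    seed: int = 0,
    prefix: str = "SH",
    barcode_len: int = 60,
    stem_len: int = 21,
    with_stems: bool = True,
) -> list[ConstructRecord]:
    """Random constructs with unique barcodes (and stems), for simulation."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out = []
    seen = set()
    i = 0
    while len(out) < n:
        bc = "".join(rng.choice(bases, barcode_len))
        if bc in seen:
            continue
        seen.add(bc)
        stem = "".join(rng.choice(bases, stem_len)) if with_stems else ""
        out.append(ConstructRecord(
            construct_id=f"{prefix}{i + 1:04d}",
            barcode_seq=bc,
            hairpin_stem=stem,
            gene_symbol=f"GENE{i // 3 + 1}",
        ))
        i += 1
    return out
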