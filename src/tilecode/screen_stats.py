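"""Depletion significance: empirical-Bayes moderated t, FDR, hit calling.

The limma-style probe-level linear model with a t_end-vs-t_zero contrast
reduces, for paired samples, to a one-sample moderated t on the per-probe
log2(t_end/t_zero) ratios of each construct — that equivalent form is what
is implemented here. Per-construct residual variances s2_g (df_g = n_g - 1)
are shrunk toward a pooled prior: the scaled inverse-chi-square
hyperparameters (df_prior, s2_prior) are fit by method of moments on the
log variances (digamma/trigamma inversion, closed form, no optimization
loop), the posterior variance is

    s2_post = (df_prior * s2_prior + df_g * s2_g) / (df_prior + df_g)

and t_mod = mean / sqrt(s2_post / n_g) is referred to a t distribution
with df_g + df_prior degrees of freedom. Benjamini-Hochberg controls the
FDR across constructs; a hit is a construct with negative mean log2 ratio
and significance below alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tilecode")


def _trigamma(x):
    return special.polygamma(1, x)


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = _trigamma(x) - y
        step = f / special.polygamma(2, x)  # d/dx trigamma < 0
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * x:
            return float(x_new)
        x = x_new
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of (df_prior, s2_prior) on log variances.

    Models s2_g ~ s2_prior * chi2(df_g) scaled, with an inverse-chi-square
    prior of df_prior degrees of freedom; moments of log(s2_g) involve the
    digamma/trigamma functions. Returns df_prior = inf when the observed
    spread of log variances is no larger than expected from sampling alone
    (complete shrinkage to s2_prior).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("degenerate variance: all residual variances are zero")
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise ValueError("need at least two positive variances to pool")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1) - _trigamma(df / 2.0).mean()
    if evar > 0:
        df_prior = 2.0 * trigamma_inverse(evar)
        s2_prior = math.exp(
            emean + special.digamma(df_prior / 2.0) - math.log(df_prior / 2.0)
        )
    else:
        # no excess spread beyond sampling: complete shrinkage to the
        # common variance (its arithmetic mean)
        df_prior = math.inf
        s2_prior = float(s2.mean())
    return df_prior, s2_prior


def posterior_variance(
    s2: np.ndarray, df: np.ndarray, df_prior: float, s2_prior: float
) -> np.ndarray:
    if math.isinf(df_prior):
        return np.full_like(np.asarray(s2, dtype=float), s2_prior)
    return (df_prior * s2_prior + df * s2) / (df_prior + df)


def moderated_one_sample_t(
    values_by_construct: Mapping[str, Sequence[float]],
    df_prior: float | None = None,
    s2_prior: float | None = None,
) -> pd.DataFrame:
    """Moderated one-sample t per construct on its log2 ratios.

    Hyperparameters are estimated across constructs unless ``df_prior`` is
    forced (0 recovers the ordinary one-sample t exactly). Constructs with
    fewer than two values are skipped with a log entry. Returns a frame
    indexed by construct_id with mean_log2, n, s2, t_mod, df_total, p_raw
    and BH-adjusted p_adj; the fitted hyperparameters are in ``.attrs``.
    """
    ids, means, s2s, ns = [], [], [], []
    for cid, vals in values_by_construct.items():
        v = np.asarray(list(vals), dtype=float)
        if len(v) < 2:
            logger.info("construct %s skipped: %d value(s) < 2", cid, len(v))
            continue
        ids.append(cid)
        means.append(v.mean())
        s2s.append(v.var(ddof=1))
        ns.append(len(v))
    if len(ids) < 2 and df_prior is None:
        raise ValueError("need at least two testable constructs to pool variances")
    means = np.array(means)
    s2s = np.array(s2s)
    ns = np.array(ns, dtype=float)
    dfs = ns - 1.0
    if df_prior is None:
        df_prior, s2_prior = fit_variance_prior(s2s, dfs)
    elif df_prior > 0 and s2_prior is None:
        _, s2_prior = fit_variance_prior(s2s, dfs)
    elif df_prior == 0:
        s2_prior = 0.0
        if not (s2s > 0).any():
            raise ValueError("degenerate variance: all residual variances are zero")
    s2_post = posterior_variance(s2s, dfs, df_prior, s2_prior)
    with np.errstate(divide="ignore"):
        t_mod = means / np.sqrt(s2_post / ns)
    if math.isinf(df_prior):
        df_total = np.full_like(dfs, np.inf)
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        df_total = dfs + df_prior
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = pd.DataFrame({
        "mean_log2": means,
        "n": ns.astype(int),
        "s2": s2s,
        "s2_post": s2_post,
        "t_mod": t_mod,
        "df_total": df_total,
        "p_raw": p_raw,
        "p_adj": bh_adjust(p_raw),
    }, index=pd.Index(ids, name="construct_id"))
    out.attrs["df_prior"] = df_prior
    out.attrs["s2_prior"] = s2_prior
    return out


def moderated_two_sample_t(
    groups: Mapping, reference_key
) -> dict:
    """Moderated two-sample test of each group against a reference group.

    Group variances are shrunk with the same scaled inverse-chi-square fit;
    the statistic uses posterior variances with Welch-Satterthwaite degrees
    of freedom augmented by the prior df. The reference tests against
    itself at p = 1.
    """
    keys = [k for k in groups if len(np.asarray(groups[k])) >= 2]
    if reference_key not in keys:
        raise ValueError("reference group needs at least two values")
    s2 = np.array([np.asarray(groups[k], dtype=float).var(ddof=1) for k in keys])
    df = np.array([len(groups[k]) - 1.0 for k in keys])
    df_prior, s2_prior = fit_variance_prior(s2, df)
    post = dict(zip(keys, posterior_variance(s2, df, df_prior, s2_prior)))
    dfs = dict(zip(keys, df))
    ref = np.asarray(groups[reference_key], dtype=float)
    out = {}
    for k in groups:
        if k == reference_key:
            out[k] = 1.0
            continue
        g = np.asarray(groups[k], dtype=float)
        if len(g) < 2 or k not in post:
            out[k] = float("nan")
            continue
        va, vb = post[k] / len(g), post[reference_key] / len(ref)
        se = math.sqrt(va + vb)
        if se == 0:
            out[k] = 1.0 if g.mean() == ref.mean() else 0.0
            continue
        t = (g.mean() - ref.mean()) / se
        prior = 0.0 if math.isinf(df_prior) else df_prior
        df_w = (va + vb) ** 2 / (
            va**2 / (dfs[k] + prior) + vb**2 / (dfs[reference_key] + prior)
        )
        out[k] = float(2.0 * stats.t.sf(abs(t), df_w))
    return out


def welch_two_sample_t(groups: Mapping, reference_key) -> dict:
    """Plain Welch t of each group against the reference group."""
    ref = np.asarray(groups[reference_key], dtype=float)
    out = {}
    for k, v in groups.items():
        if k == reference_key:
            out[k] = 1.0
            continue
        g = np.asarray(v, dtype=float)
        if len(g) < 2 or len(ref) < 2:
            out[k] = float("nan")
            continue
        out[k] = float(stats.ttest_ind(g, ref, equal_var=False).pvalue)
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class HitCalls:
    """Called hits plus volcano-plot coordinates for every construct."""

    hits: pd.DataFrame
    volcano: pd.DataFrame  # columns mean_log2, neg_log10_p
    alpha: float
    use_adjusted: bool


def call_hits(
    results: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    direction: str = "depleted",
) -> HitCalls:
    """Call depleted constructs: negative mean log2 and significance < alpha.

    ``use_adjusted`` selects BH-adjusted (default) versus raw p-values.
    Hits are sorted by mean_log2 ascending (strongest depletion first).
    """
    if direction != "depleted":
        raise ValueError("only depletion calling is supported")
    pcol = "p_adj" if use_adjusted else "p_raw"
    with np.errstate(divide="ignore"):
        volcano = pd.DataFrame({
            "mean_log2": results["mean_log2"],
            "neg_log10_p": -np.log10(results[pcol]),
        }, index=results.index)
    sel = (results["mean_log2"] < 0) & (results[pcol] < alpha)
    hits = results[sel].sort_values("mean_log2")
    return HitCalls(hits=hits, volcano=volcano, alpha=alpha, use_adjusted=use_adjusted)


def screen_results(agg, df_prior: float | None = None) -> pd.DataFrame:
    """Moderated test over an :class:`~tilecode.quantification.AggregationResult`.

    The one-sample moderated t runs on each construct's surviving
    (probe, experiment) log2 ratios; the headline mean_log2 reported next
    to it is the construct abundance from the filtering cascade (mean of
    per-probe means), which is also what hits are called on.
    """
    values = {
        cid: grp["log2_ratio"].to_numpy()
        for cid, grp in agg.kept_ratios.groupby("construct_id")
    }
    res = moderated_one_sample_t(values, df_prior=df_prior)
    attrs = dict(res.attrs)
    res = res.join(agg.constructs[["mean_log2"]].rename(columns={"mean_log2": "mean_log2_agg"}))
    res["mean_log2"] = res["mean_log2_agg"].fillna(res["mean_log2"])
    res = res.drop(columns="mean_log2_agg")
    res.attrs.update(attrs)
    return res
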