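"""Differential methylation calling.

The test statistic is a moderated two-sample t: per-probe pooled variances
are shrunk toward an empirical-Bayes prior (a scaled inverse-chi-square,
estimated by moment matching on the log variances across probes), and
significance comes from a label-permutation null pooled across probes.
Moderation stabilizes variance estimates at the small group sizes typical of
methylation cohorts; pooling the permuted statistics across probes gives
p-value resolution far below 1/B.  A called DML must additionally pass the
biological effect filter |δ| ≥ 0.10 (δ = mean β in IR − mean β in IS) and
carry no exclusion flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .io import BetaMatrix, SampleTable

logger = logging.getLogger(__name__)

#: d0 cap marking the "no residual variance heterogeneity" limit.
D0_CAP = 1e6

#: Minimum probes with usable variance for prior estimation.
MIN_PROBES_FOR_SHRINKAGE = 50

#: Absolute tolerance when counting null exceedances: permuted label
#: arrangements that tie the observed |t| analytically (e.g. the complement
#: arrangement) must count as ties despite last-ulp float noise.
TIE_TOL = 1e-9

FLAG_COLUMNS = ("flag_snp_pattern", "flag_known_snp", "flag_confound_overlap")

ShrinkageMode = Literal["reestimate", "observed", "none"]


@dataclass
class ShrinkageEstimate:
    """Empirical-Bayes variance prior: s² ~ s0²·d0/χ²(d0), β² units.

    ``d0`` is the prior degrees of freedom (``D0_CAP`` marks the effectively
    infinite / homogeneous-variance limit), ``s0_sq`` the prior variance, and
    ``d`` the typical residual degrees of freedom per probe.
    """

    d0: float
    s0_sq: float
    d: float

    @property
    def capped(self) -> bool:
        return self.d0 >= D0_CAP


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def _group_masks(beta: BetaMatrix, groups) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(groups, SampleTable):
        groups = groups.groups
    groups = pd.Series(groups).reindex(beta.sample_ids)
    g_is = (groups == "IS").to_numpy()
    g_ir = (groups == "IR").to_numpy()
    if g_is.sum() < 2 or g_ir.sum() < 2:
        raise ValueError("need at least 2 samples in each of IS and IR")
    return g_is, g_ir


def _masked_stats(M, M2, W, g1, g2):
    """Vectorized per-probe two-group stats with missing values masked out.

    M = values with NaN→0, M2 = M², W = observed indicator; g1/g2 are sample
    indicator vectors.  Returns mean1, mean2, pooled s², d, n1, n2.
    """
    g1 = g1.astype(float)
    g2 = g2.astype(float)
    n1 = W @ g1
    n2 = W @ g2
    with np.errstate(divide="ignore", invalid="ignore"):
        sum1 = M @ g1
        sum2 = M @ g2
        mean1 = sum1 / n1
        mean2 = sum2 / n2
        ss1 = (M2 @ g1) - n1 * mean1**2
        ss2 = (M2 @ g2) - n2 * mean2**2
        d = n1 + n2 - 2.0
        s_sq = (ss1 + ss2) / d
    s_sq = np.where(d > 0, np.maximum(s_sq, 0.0), np.nan)
    return mean1, mean2, s_sq, d, n1, n2


def _prepare_arrays(beta: BetaMatrix):
    vals = beta.values.to_numpy(dtype=float)
    W = (~np.isnan(vals)).astype(float)
    M = np.nan_to_num(vals, nan=0.0)
    return M, M * M, W


def group_stats(beta: BetaMatrix, groups) -> pd.DataFrame:
    """Per-probe IS/IR means, δ = mean_ir − mean_is, pooled variance and df.

    Missing values are excluded probewise; a probe with fewer than two usable
    values in either group is marked unusable (stats NaN) and logged.
    """
    g_is, g_ir = _group_masks(beta, groups)
    M, M2, W = _prepare_arrays(beta)
    mean_is, mean_ir, s_sq, d, n_is, n_ir = _masked_stats(M, M2, W, g_is, g_ir)
    usable = (n_is >= 2) & (n_ir >= 2)
    if not usable.all():
        bad = beta.probe_ids[~usable]
        logger.warning(
            "%d probe(s) with <2 usable values in a group marked unusable (e.g. %s)",
            len(bad), bad[:3].tolist(),
        )
    out = pd.DataFrame(
        {
            "mean_is": np.where(usable, mean_is, np.nan),
            "mean_ir": np.where(usable, mean_ir, np.nan),
            "delta": np.where(usable, mean_ir - mean_is, np.nan),
            "s_sq": np.where(usable, s_sq, np.nan),
            "d": np.where(usable, d, np.nan),
            "n_is": n_is.astype(int),
            "n_ir": n_ir.astype(int),
            "usable": usable,
        },
        index=beta.probe_ids,
    )
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes shrinkage
# ---------------------------------------------------------------------------


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_shrinkage(s_sq, d) -> ShrinkageEstimate:
    """Moment-match a scaled inverse-chi-square prior to per-probe variances.

    Works on log s²: with s²|σ² ~ σ²·χ²(d)/d and σ² ~ s0²·d0/χ²(d0), the
    corrected log variances e = log s² − ψ(d/2) + log(d/2) have mean
    log s0² − ψ(d0/2) + log(d0/2) and excess variance ψ'(d0/2) beyond the
    sampling term ψ'(d/2); inverting the trigamma gives d0.  When the
    observed spread does not exceed the sampling term the prior is flagged
    as effectively infinite (d0 capped) and s0² is set to the plain mean of
    s², which makes the moderated t collapse to the ordinary pooled t.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s_sq.shape)
    ok = np.isfinite(s_sq) & (s_sq > 0) & np.isfinite(d) & (d > 0)
    if int(ok.sum()) < MIN_PROBES_FOR_SHRINKAGE:
        raise ValueError(
            f"need >= {MIN_PROBES_FOR_SHRINKAGE} probes with finite positive "
            f"variance to estimate the prior (got {int(ok.sum())})"
        )
    s_ok = s_sq[ok]
    d_ok = d[ok]
    d_typ = float(np.median(d_ok))
    e = np.log(s_ok) - digamma(d_ok / 2.0) + np.log(d_ok / 2.0)
    e_bar = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(_trigamma(d_ok / 2.0).mean())
    if excess <= 0:
        return ShrinkageEstimate(d0=D0_CAP, s0_sq=float(s_ok.mean()), d=d_typ)
    d0 = 2.0 * _trigamma_inverse(excess)
    if d0 >= D0_CAP:
        return ShrinkageEstimate(d0=D0_CAP, s0_sq=float(s_ok.mean()), d=d_typ)
    s0_sq = float(np.exp(e_bar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ShrinkageEstimate(d0=d0, s0_sq=s0_sq, d=d_typ)


def _moderated_t_arrays(delta, s_sq, d, n1, n2, shrink: ShrinkageEstimate | None):
    if shrink is None:  # ordinary pooled t
        s_tilde = s_sq
    else:
        s_tilde = (shrink.d0 * shrink.s0_sq + d * s_sq) / (shrink.d0 + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s_tilde * (1.0 / n1 + 1.0 / n2))
        t = delta / se
    t = np.where((se == 0) & (delta == 0), 0.0, t)
    return t


def moderated_t(stats: pd.DataFrame, shrink: ShrinkageEstimate | None) -> pd.Series:
    """Moderated t per probe: δ / √(s̃²·(1/n1+1/n2)) with
    s̃² = (d0·s0² + d·s²)/(d0 + d); ``shrink=None`` gives the ordinary t."""
    t = _moderated_t_arrays(
        stats["delta"].to_numpy(),
        stats["s_sq"].to_numpy(),
        stats["d"].to_numpy(),
        stats["n_is"].to_numpy(),
        stats["n_ir"].to_numpy(),
        shrink,
    )
    return pd.Series(t, index=stats.index, name="t_mod")


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def _null_statistics(M, M2, W, masks, mode: ShrinkageMode, observed_shrink):
    """|moderated t| for each label arrangement in ``masks``."""
    out = []
    for g1 in masks:
        g2 = ~g1
        m1, m2_, s_sq, d, n1, n2 = _masked_stats(M, M2, W, g1, g2)
        usable = (n1 >= 2) & (n2 >= 2)
        if mode == "reestimate":
            try:
                shrink = estimate_shrinkage(s_sq[usable], d[usable])
            except ValueError:
                shrink = None
        elif mode == "observed":
            shrink = observed_shrink
        else:
            shrink = None
        t = _moderated_t_arrays(m2_ - m1, s_sq, d, n1, n2, shrink)
        t = np.where(usable, t, np.nan)
        out.append(np.abs(t))
    return np.asarray(out)


def permutation_pvalues(
    beta: BetaMatrix,
    groups,
    B: int | str = 1000,
    seed: int | None = None,
    pool: bool = True,
    shrinkage_mode: ShrinkageMode = "reestimate",
) -> pd.DataFrame:
    """Permutation p- and q-values for the moderated t, per probe.

    For each of ``B`` random relabelings of the samples (or every distinct
    arrangement when ``B="exhaustive"``, allowed up to 10 samples) the whole
    statistic chain — group stats, variance-prior estimation (per
    ``shrinkage_mode``), moderated t — is recomputed, preserving
    exchangeability.  With ``pool=True`` (default) the null is the pooled set
    of all permuted |t| across probes and

        p_j = (1 + #{null ≥ |t_obs,j|}) / (1 + B·P);

    with ``pool=False`` each probe is compared only against its own B
    permuted values (denominator 1 + B).  In exhaustive mode the observed
    arrangement is one of the enumerated ones, so it is counted in the null.
    ``q_perm`` is the permutation FDR: expected null exceedances over
    observed exceedances at each |t| threshold, monotonized.

    Returns a DataFrame with ``t_mod``, ``p_perm``, ``q_perm``.
    """
    g_is, g_ir = _group_masks(beta, groups)
    keep = g_is | g_ir
    if not keep.all():
        beta = beta.subset(samples=beta.sample_ids[keep])
        g_is, g_ir = g_is[keep], g_ir[keep]
    n = len(beta.sample_ids)
    n_is = int(g_is.sum())

    if B == "exhaustive":
        if n > 10:
            raise ValueError("exhaustive enumeration limited to <= 10 samples")
        masks = []
        for combo in combinations(range(n), n_is):
            g = np.zeros(n, dtype=bool)
            g[list(combo)] = True
            masks.append(g)
        n_arrangements = comb(n, n_is)
    else:
        B = int(B)
        if B < 100:
            raise ValueError("B must be >= 100 (or 'exhaustive')")
        if seed is None:
            raise ValueError("seed is required for random permutations")
        rng = np.random.default_rng(seed)
        masks = []
        for _ in range(B):
            perm = rng.permutation(n)
            g = np.zeros(n, dtype=bool)
            g[perm[:n_is]] = True
            masks.append(g)
        n_arrangements = B

    M, M2, W = _prepare_arrays(beta)
    obs = group_stats(beta, pd.Series(np.where(g_is, "IS", "IR"), index=beta.sample_ids))
    usable = obs["usable"].to_numpy()
    observed_shrink = None
    if shrinkage_mode in ("reestimate", "observed"):
        try:
            observed_shrink = estimate_shrinkage(
                obs["s_sq"].to_numpy()[usable], obs["d"].to_numpy()[usable]
            )
        except ValueError:
            logger.info("too few probes for shrinkage; falling back to ordinary t")
            shrinkage_mode = "none"
    obs_shrink_used = observed_shrink if shrinkage_mode in ("reestimate", "observed") else None
    t_obs = moderated_t(obs, obs_shrink_used).to_numpy()

    null_abs = _null_statistics(M, M2, W, masks, shrinkage_mode, observed_shrink)
    abs_obs = np.abs(t_obs)

    p = np.full(len(t_obs), np.nan)
    if pool:
        flat = np.sort(null_abs[:, usable].ravel())
        flat = flat[np.isfinite(flat)]
        denom = flat.size
        counts = denom - np.searchsorted(flat, abs_obs[usable] - TIE_TOL, side="left")
        p[usable] = (1.0 + counts) / (1.0 + denom)
    else:
        ge = np.nansum(null_abs >= (abs_obs - TIE_TOL)[None, :], axis=0)
        p[usable] = (1.0 + ge[usable]) / (1.0 + n_arrangements)

    q = _permutation_fdr(abs_obs, null_abs, usable, n_arrangements)

    return pd.DataFrame(
        {"t_mod": t_obs, "p_perm": p, "q_perm": q}, index=beta.probe_ids
    )


def _permutation_fdr(abs_obs, null_abs, usable, n_arrangements) -> np.ndarray:
    """FDR_j = (mean null exceedances per arrangement) / (observed exceedances)
    at threshold |t_obs,j|, monotonized in |t| and clipped to [0, 1]."""
    q = np.full(abs_obs.shape, np.nan)
    obs_u = abs_obs[usable]
    flat = np.sort(null_abs[:, usable].ravel())
    flat = flat[np.isfinite(flat)]
    sorted_obs = np.sort(obs_u)
    v = (flat.size - np.searchsorted(flat, obs_u - TIE_TOL, side="left")) / n_arrangements
    r = obs_u.size - np.searchsorted(sorted_obs, obs_u, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = v / r
    order = np.argsort(-obs_u)  # largest |t| first
    running = np.minimum.accumulate(raw[order])
    q_u = np.empty_like(raw)
    q_u[order] = running
    q[usable] = np.clip(q_u, 0.0, 1.0)
    return q


# ---------------------------------------------------------------------------
# DML calling
# ---------------------------------------------------------------------------


def dml_table(
    beta: BetaMatrix,
    groups,
    B: int | str = 1000,
    seed: int | None = None,
    pool: bool = True,
    shrinkage_mode: ShrinkageMode = "reestimate",
) -> pd.DataFrame:
    """Full per-probe differential table: group stats + permutation p/q +
    (initially clear) exclusion-flag columns."""
    stats = group_stats(beta, groups)
    perm = permutation_pvalues(
        beta, groups, B=B, seed=seed, pool=pool, shrinkage_mode=shrinkage_mode
    )
    out = stats.join(perm)
    for col in FLAG_COLUMNS:
        out[col] = False
    return out


def call_dmls(
    records: pd.DataFrame,
    p_threshold: float = 0.05,
    delta_threshold: float = 0.10,
) -> tuple[pd.DataFrame, dict]:
    """Apply the significance and effect filters: a probe is a DML iff
    p_perm < p_threshold, |δ| ≥ delta_threshold (boundary inclusive) and no
    exclusion flag is set.  Returns the records with an ``is_dml`` column
    plus a stagewise summary including the hypo/hyper direction split
    (δ < 0 = hypomethylated in IR)."""
    for name, thr in (("p_threshold", p_threshold), ("delta_threshold", delta_threshold)):
        if not (0.0 < thr < 1.0):
            raise ValueError(f"{name} must be in (0, 1)")
    rec = records.copy()
    flags = rec.reindex(columns=list(FLAG_COLUMNS), fill_value=False)[list(FLAG_COLUMNS)]
    flagged = flags.any(axis=1)
    sig = rec["p_perm"] < p_threshold
    big = rec["delta"].abs() >= delta_threshold
    rec["is_dml"] = (sig & big & ~flagged).fillna(False)

    called = rec[rec["is_dml"]]
    summary = {
        "n_tested": int(rec["p_perm"].notna().sum()),
        "n_significant": int(sig.fillna(False).sum()),
        "n_delta_pass": int((sig & big).fillna(False).sum()),
        "n_flag_removed": int((sig & big & flagged).fillna(False).sum()),
        "n_dml": int(len(called)),
        **direction_summary(called["delta"]),
    }
    logger.info(
        "DML calling: %(n_tested)d tested -> %(n_significant)d p<thr -> "
        "%(n_delta_pass)d pass |delta| -> %(n_dml)d DMLs "
        "(%(n_flag_removed)d flag-removed)", summary,
    )
    return rec, summary


def direction_summary(deltas) -> dict:
    """Direction-of-change split for a DML set: counts and percentage of loci
    hypomethylated in IR (δ < 0), percentage rounded to one decimal."""
    d = pd.Series(deltas).dropna()
    n = int(len(d))
    n_hypo = int((d < 0).sum())
    n_hyper = int((d > 0).sum())
    pct = round(100.0 * n_hypo / n, 1) if n else float("nan")
    return {"n_direction": n, "n_hypo_ir": n_hypo, "n_hyper_ir": n_hyper,
            "pct_hypo_ir": pct}
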