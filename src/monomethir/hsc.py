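"""Progenitor (HSC) methylation-state maintenance analysis.

For each DML the group mean β (IS or IR) is compared with the mean β of
hematopoietic stem cells.  A locus *maintains* the HSC state in a group when
|group mean − HSC mean| < 0.10 (strictly inside the band); δ ≥ 0.10 is
*hyper* (hypermethylated vs HSC) and δ ≤ −0.10 *hypo*, with the boundary
assigned to the divergent classes.  A PCA of the DML β values, with HSC
samples included, visualizes whether one group's methylation sits closer to
the progenitor state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import BetaMatrix

MAINTENANCE_THRESHOLD = 0.10

#: Boundary tolerance: β means are reported to a few decimals, so a δ that
#: equals the threshold analytically (e.g. 0.70 − 0.60) must classify as
#: divergent despite float representation error.
_EDGE_TOL = 1e-9

CLASSES = ("hypo", "maintained", "hyper")


def maintenance_classify(group_mean: float, hsc_mean: float,
                         threshold: float = MAINTENANCE_THRESHOLD) -> str:
    """Three-way class for one locus: maintained iff |group − HSC| < threshold,
    hyper iff δ ≥ threshold, hypo iff δ ≤ −threshold."""
    for v in (group_mean, hsc_mean):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"mean β {v!r} outside [0, 1]")
    delta = group_mean - hsc_mean
    if delta >= threshold - _EDGE_TOL:
        return "hyper"
    if delta <= -threshold + _EDGE_TOL:
        return "hypo"
    return "maintained"


def _classify_array(delta: np.ndarray, threshold: float) -> np.ndarray:
    out = np.full(delta.shape, "maintained", dtype=object)
    out[delta >= threshold - _EDGE_TOL] = "hyper"
    out[delta <= -threshold + _EDGE_TOL] = "hypo"
    out[~np.isfinite(delta)] = ""
    return out


def maintenance_table(
    beta: BetaMatrix,
    groups,
    hsc_profile: pd.Series,
    dml_probes,
    threshold: float = MAINTENANCE_THRESHOLD,
) -> pd.DataFrame:
    """Per-DML deltas vs HSC and maintenance classes for both groups.

    ``hsc_profile`` is the probe-indexed mean β of the HSC reference samples.
    """
    groups = pd.Series(groups).reindex(beta.sample_ids)
    probes = pd.Index(dml_probes)
    missing = probes.difference(beta.probe_ids)
    if len(missing):
        raise ValueError(f"DML probes absent from matrix: {missing[:5].tolist()}")
    vals = beta.values.loc[probes]
    mean_is = vals[groups[groups == "IS"].index].mean(axis=1)
    mean_ir = vals[groups[groups == "IR"].index].mean(axis=1)
    hsc = pd.Series(hsc_profile).reindex(probes)
    if hsc.isna().any():
        bad = probes[hsc.isna()][:5].tolist()
        raise ValueError(f"HSC profile missing probes: {bad}")
    d_is = (mean_is - hsc).to_numpy()
    d_ir = (mean_ir - hsc).to_numpy()
    return pd.DataFrame(
        {
            "mean_is": mean_is,
            "mean_ir": mean_ir,
            "hsc_mean": hsc,
            "delta_is_hsc": d_is,
            "delta_ir_hsc": d_ir,
            "class_is": _classify_array(d_is, threshold),
            "class_ir": _classify_array(d_ir, threshold),
        },
        index=probes,
    )


def maintenance_summary(records: pd.DataFrame) -> dict:
    """Counts of DMLs maintaining the HSC state in IR, in IS and in both,
    plus the per-group hypo/maintained/hyper breakdown with fractions."""
    m_ir = records["class_ir"] == "maintained"
    m_is = records["class_is"] == "maintained"
    n = int(len(records))
    out = {
        "n_dml": n,
        "maintained_ir": int(m_ir.sum()),
        "maintained_is": int(m_is.sum()),
        "maintained_both": int((m_ir & m_is).sum()),
    }
    for grp, col in (("ir", "class_ir"), ("is", "class_is")):
        counts = records[col].value_counts()
        for cls in CLASSES:
            c = int(counts.get(cls, 0))
            out[f"{grp}_{cls}"] = c
            out[f"{grp}_{cls}_pct"] = round(100.0 * c / n, 1) if n else float("nan")
    return out


def pca_dmls(
    beta_values: pd.DataFrame,
    center: bool = True,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples in DML-β space (β already on a common [0, 1] scale, so
    centered but not rescaled by default).

    ``beta_values`` is probes × samples (IS + IR + HSC columns together).
    Returns (sample coordinates on the leading components, variance-explained
    fractions).  Sign convention: each component's largest-magnitude probe
    loading is made positive, so results are reproducible.
    """
    if beta_values.shape[0] < 2:
        raise ValueError("need at least 2 probes for PCA")
    if beta_values.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    if beta_values.isna().any().any():
        raise ValueError("missing values must be completed probewise before PCA")
    X = beta_values.to_numpy(dtype=float).T  # samples × probes
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate positive per component
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    total = float((S**2).sum())
    frac = (S**2) / total if total > 0 else np.zeros_like(S)
    k = len(S) if n_components is None else min(n_components, len(S))
    coords = pd.DataFrame(
        U[:, :k] * S[:k],
        index=beta_values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return coords, frac[:k]


def centroid_distances(coords: pd.DataFrame, groups: pd.Series,
                       target: str = "HSC") -> dict[str, float]:
    """Euclidean distance from the ``target`` group centroid to each other
    group centroid in PC space — a qualitative check of which cohort group
    sits nearer the progenitor state."""
    groups = pd.Series(groups).reindex(coords.index)
    cents = coords.groupby(groups).mean()
    if target not in cents.index:
        raise KeyError(f"no samples labeled {target!r}")
    ref = cents.loc[target]
    return {
        str(g): float(np.linalg.norm(cents.loc[g] - ref))
        for g in cents.index
        if g != target
    }
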