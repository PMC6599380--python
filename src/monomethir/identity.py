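"""Reference-based cell-identity panels and purity scoring.

A panel is the set of CpGs whose methylation separates two reference cell
populations (permutation-significant and |δ| above a large threshold, e.g.
0.30 between monocytes and PBMCs).  A sample's identity/purity score is the
Spearman correlation between its β values and a cell type's mean profile at
the panel probes — rank-based, so invariant to monotone distortions of the
sample's values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dml import dml_table
from .io import BetaMatrix

logger = logging.getLogger(__name__)

MIN_PANEL_PROBES_FOR_SCORE = 20


@dataclass
class ReferencePanel:
    """Discriminative CpG set with per-cell-type mean β profiles."""

    probes: list[str]
    profiles: pd.DataFrame  # panel probes × cell types
    builder_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prof = self.profiles.loc[self.probes]
        arr = prof.to_numpy(dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("panel profiles must lie in [0, 1]")
        self.profiles = prof

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)


def build_panel(
    ref_a: BetaMatrix,
    ref_b: BetaMatrix,
    name_a: str,
    name_b: str,
    delta_threshold: float = 0.30,
    p_threshold: float = 0.05,
    B: int | str = 200,
    seed: int | None = None,
    profile_stat: str = "mean",
) -> ReferencePanel:
    """Select probes separating two reference sample sets.

    Runs the same permutation moderated-t procedure as the cohort contrast
    on the pooled reference samples and keeps probes with p < ``p_threshold``
    and |mean difference| strictly greater than ``delta_threshold``.  The
    panel profile per type is the arithmetic mean (or median) across that
    type's reference samples.
    """
    shared = ref_a.probe_ids.intersection(ref_b.probe_ids)
    if len(shared) == 0:
        raise ValueError("reference matrices share no probes")
    a = ref_a.subset(probes=shared)
    b = ref_b.subset(probes=shared)
    combined = BetaMatrix(pd.concat([a.values, b.values], axis=1))
    # reuse the IS/IR two-group machinery with arbitrary type labels
    groups = pd.Series(
        ["IS"] * len(a.sample_ids) + ["IR"] * len(b.sample_ids),
        index=combined.sample_ids,
    )
    rec = dml_table(combined, groups, B=B, seed=seed)
    keep = (rec["p_perm"] < p_threshold) & (rec["delta"].abs() > delta_threshold)
    probes = rec.index[keep.fillna(False)].tolist()
    if not probes:
        raise ValueError(
            f"empty panel at |delta| > {delta_threshold}; lower delta_threshold"
        )
    agg = {"mean": np.mean, "median": np.median}[profile_stat]
    profiles = pd.DataFrame(
        {
            name_a: a.values.loc[probes].apply(agg, axis=1),
            name_b: b.values.loc[probes].apply(agg, axis=1),
        }
    )
    logger.info(
        "panel %s vs %s: %d probes at |delta|>%.2f, p<%.2f",
        name_a, name_b, len(probes), delta_threshold, p_threshold,
    )
    return ReferencePanel(
        probes=probes,
        profiles=profiles,
        builder_params={
            "delta_threshold": delta_threshold,
            "p_threshold": p_threshold,
            "B": B,
            "profile_stat": profile_stat,
        },
    )


def purity_score(
    sample_beta: pd.Series,
    panel: ReferencePanel,
    target_type: str,
    method: str = "spearman",
) -> float:
    """Correlation between a sample and a cell-type profile at panel probes.

    Spearman by default (Pearson behind the flag).  Probes missing from the
    sample are dropped pairwise; fewer than 20 remaining probes, or a
    constant profile, is an error.
    """
    if target_type not in panel.profiles.columns:
        raise KeyError(f"unknown cell type {target_type!r}")
    prof = panel.profiles[target_type]
    sample = pd.Series(sample_beta).reindex(prof.index)
    ok = sample.notna() & prof.notna()
    if int(ok.sum()) < MIN_PANEL_PROBES_FOR_SCORE:
        raise ValueError(
            f"only {int(ok.sum())} panel probes present in sample; "
            f"need >= {MIN_PANEL_PROBES_FOR_SCORE}"
        )
    x = sample[ok].to_numpy()
    y = prof[ok].to_numpy()
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("constant profile or sample: correlation undefined")
    if method == "spearman":
        r = sps.spearmanr(x, y).statistic
    elif method == "pearson":
        r = sps.pearsonr(x, y).statistic
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(r)


def purity_table(
    beta: BetaMatrix,
    panel: ReferencePanel,
    target_type: str,
    method: str = "spearman",
) -> pd.Series:
    """Purity score for every sample in a matrix."""
    return pd.Series(
        {
            s: purity_score(beta.sample(s), panel, target_type, method=method)
            for s in beta.sample_ids
        },
        name=f"purity_{target_type}",
    )


def compare_group_scores(scores: pd.Series, groups) -> tuple[float, float]:
    """Mann-Whitney comparison of per-sample identity scores between IS and IR.

    Returns (U, two-sided p); delegates to :func:`monomethir.stats.mann_whitney`.
    """
    from .stats import mann_whitney  # local import avoids a cycle

    groups = pd.Series(groups).reindex(scores.index)
    x = scores[groups == "IS"].to_numpy()
    y = scores[groups == "IR"].to_numpy()
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need >= 3 scores per group")
    return mann_whitney(x, y)
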