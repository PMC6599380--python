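"""Post-hoc probe exclusions for called DMLs.

Three independent flags, each an independent column so the filters are
idempotent and order-free in the final flag set:

* ``flag_snp_pattern`` — the per-sample β values cluster at ~0 / 0.5 / 1,
  the allelic pattern of a SNP overlapping the probe rather than a true
  methylation difference;
* ``flag_known_snp`` — the manifest annotates the probe as possibly
  harboring a SNP;
* ``flag_confound_overlap`` — the probe also appears in a confounder DML
  list (e.g. an infection-status contrast) and is removed from the primary
  set.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

SNP_MODE_CENTERS = np.array([0.0, 0.5, 1.0])

DEFAULT_TOL = 0.12
DEFAULT_MIN_ASSIGNED = 0.80
DEFAULT_MIN_MODES = 2
MIN_SAMPLES_FOR_PATTERN = 6


def snp_pattern_flag(
    beta_row: Sequence[float] | pd.Series,
    tol: float = DEFAULT_TOL,
    min_assigned: float = DEFAULT_MIN_ASSIGNED,
    min_modes: int = DEFAULT_MIN_MODES,
) -> bool:
    """Flag a probe whose sample β values look like SNP genotype clusters.

    Each sample is assigned to the nearest of {0, 0.5, 1} if within ``tol``;
    the probe is flagged when at least ``min_assigned`` of the samples are
    assigned and at least ``min_modes`` distinct modes are occupied (the
    two-mode minimum avoids flagging constitutively hemimethylated loci).
    Rows with fewer than 6 usable values return False with a log note.
    The rule is invariant to sample order and to the reflection β → 1 − β.
    """
    vals = np.asarray(pd.Series(beta_row).dropna(), dtype=float)
    if vals.size < MIN_SAMPLES_FOR_PATTERN:
        logger.debug("snp_pattern_flag: only %d usable values; returning False", vals.size)
        return False
    dist = np.abs(vals[:, None] - SNP_MODE_CENTERS[None, :])
    nearest = dist.argmin(axis=1)
    assigned = dist.min(axis=1) <= tol
    if assigned.mean() < min_assigned:
        return False
    return len(set(nearest[assigned])) >= min_modes


def snp_pattern_flags(
    beta: BetaMatrix,
    probes: Iterable[str] | None = None,
    tol: float = DEFAULT_TOL,
    min_assigned: float = DEFAULT_MIN_ASSIGNED,
    min_modes: int = DEFAULT_MIN_MODES,
) -> pd.Series:
    """Vectorized :func:`snp_pattern_flag` over (a subset of) the matrix."""
    df = beta.values if probes is None else beta.values.loc[list(probes)]
    arr = df.to_numpy(dtype=float)
    obs = ~np.isnan(arr)
    dist = np.abs(arr[:, :, None] - SNP_MODE_CENTERS[None, None, :])
    nearest = np.nanargmin(np.where(obs[:, :, None], dist, np.inf), axis=2)
    assigned = (np.min(np.where(obs[:, :, None], dist, np.inf), axis=2) <= tol) & obs
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_obs > 0, assigned.sum(axis=1) / n_obs, 0.0)
    modes = np.zeros((arr.shape[0], 3), dtype=bool)
    for m in range(3):
        modes[:, m] = (assigned & (nearest == m)).any(axis=1)
    flags = (
        (n_obs >= MIN_SAMPLES_FOR_PATTERN)
        & (frac >= min_assigned)
        & (modes.sum(axis=1) >= min_modes)
    )
    return pd.Series(flags, index=df.index, name="flag_snp_pattern")


def known_snp_flags(annotation: ProbeAnnotation, probes: Iterable[str] | None = None) -> pd.Series:
    """Manifest known-SNP flag per probe (errors if the column is absent)."""
    table = annotation.table
    if "known_snp" not in table.columns:  # defensive; validated at load
        raise ValueError("annotation has no known_snp column")
    flags = table["known_snp"].astype(bool)
    if probes is not None:
        probes = pd.Index(probes)
        missing = probes.difference(table.index)
        if len(missing):
            raise ValueError(f"probes absent from annotation: {missing[:5].tolist()}")
        flags = flags.loc[probes]
    return flags.rename("flag_known_snp")


def confound_overlap_filter(
    primary_dmls: Iterable[str],
    confounder_dmls: Iterable[str],
) -> tuple[list[str], set[str], int]:
    """Subtract confounder-associated probes from the primary DML list.

    Returns (retained probes in primary order, overlap set, overlap as a
    percentage of the primary list rounded to the nearest whole percent).
    """
    primary = list(dict.fromkeys(primary_dmls))
    confounder = set(confounder_dmls)
    if not primary or not confounder:
        raise ValueError("both probe sets must be nonempty")
    overlap = {p for p in primary if p in confounder}
    retained = [p for p in primary if p not in confounder]
    pct = int(round(100.0 * len(overlap) / len(primary)))
    logger.info(
        "confounder overlap: %d of %d primary DMLs (%d%%) removed, %d retained",
        len(overlap), len(primary), pct, len(retained),
    )
    return retained, overlap, pct


def apply_filters(
    records: pd.DataFrame,
    beta: BetaMatrix | None = None,
    annotation: ProbeAnnotation | None = None,
    confounder_dmls: Iterable[str] | None = None,
    tol: float = DEFAULT_TOL,
    min_assigned: float = DEFAULT_MIN_ASSIGNED,
    min_modes: int = DEFAULT_MIN_MODES,
) -> pd.DataFrame:
    """Populate the exclusion-flag columns on a differential table.

    Each available source sets its own independent flag column; absent
    sources leave the corresponding column untouched.
    """
    rec = records.copy()
    if beta is not None:
        rec["flag_snp_pattern"] = snp_pattern_flags(
            beta, probes=rec.index, tol=tol, min_assigned=min_assigned, min_modes=min_modes
        )
    if annotation is not None:
        rec["flag_known_snp"] = known_snp_flags(annotation, probes=rec.index).to_numpy()
    if confounder_dmls is not None:
        conf = set(confounder_dmls)
        rec["flag_confound_overlap"] = rec.index.isin(conf)
    return rec
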