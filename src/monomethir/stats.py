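"""Cohort-level statistics.

HOMA-IR computation and stratification, nonparametric group comparisons and
associations (Mann-Whitney / Spearman — β values are heteroscedastic, so
rank tests are used throughout), genomic-context enrichment by two-cell
chi-square goodness of fit, Manhattan-distance hierarchical clustering, a
noncentral-t power calculation, and a local Fisher's-exact gene-set test.
"""

from __future__ import annotations

import logging
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io import GENE_REGIONS, HOMA_IR_THRESHOLD, ISLAND_RELATIONS, ProbeAnnotation

logger = logging.getLogger(__name__)

#: mg/dL × µU/mL convention; use 22.5 for SI (mmol/L) glucose.
HOMA_DIVISOR_MASS = 405.0

#: Largest combined sample size for exact Mann-Whitney enumeration.
EXACT_MW_LIMIT = 12

_FAMILIES = {"gene_region": GENE_REGIONS, "island_relation": ISLAND_RELATIONS}


def homa_ir(glucose, insulin, divisor: float = HOMA_DIVISOR_MASS):
    """HOMA-IR index = fasting glucose [mg/dL] × fasting insulin [µU/mL] / 405."""
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    if (g <= 0).any() or (i <= 0).any():
        raise ValueError("glucose and insulin must be positive")
    out = g * i / divisor
    return float(out) if out.ndim == 0 else out


def stratify(index, threshold: float = HOMA_IR_THRESHOLD):
    """IS/IR group from the HOMA-IR index; the boundary value is IR."""
    arr = np.asarray(index, dtype=float)
    out = np.where(arr >= threshold, "IR", "IS")
    return str(out) if out.ndim == 0 else out


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration for combined n ≤ 12 without ties; normal
    approximation with tie correction (and continuity) otherwise.
    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need >= 3 observations per group")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties); constant input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# genomic-context enrichment
# ---------------------------------------------------------------------------


def goodness_of_fit_chi2(observed: float, expected: float, total: float) -> tuple[float, float]:
    """Two-cell chi-square goodness of fit: a category against the sum of all
    other categories, 1 df.

    chi2 = (obs − exp)²/exp + ((total−obs) − (total−exp))²/(total−exp).
    Returns (chi2, p).
    """
    if expected <= 0 or total - expected <= 0:
        raise ValueError("expected counts must be positive in both cells")
    chi2 = (observed - expected) ** 2 / expected + (
        (total - observed) - (total - expected)
    ) ** 2 / (total - expected)
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def region_enrichment(
    dml_probes: Iterable[str],
    annotation: ProbeAnnotation,
    family: str = "gene_region",
) -> pd.DataFrame:
    """Category enrichment of a DML set against the array background.

    For each category in the family (gene region or CpG-island relation),
    the expected count is the array-wide category proportion × n_dml and a
    two-cell chi-square (category vs all others, 1 df) is computed, with
    Bonferroni correction over the family's tested categories.  Categories
    with expected < 1 are skipped with a warning.  Direction is "enriched"
    when observed > expected, "depleted" otherwise.
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {sorted(_FAMILIES)}")
    col = family
    table = annotation.table
    dml_probes = pd.Index(dml_probes)
    missing = dml_probes.difference(table.index)
    if len(missing):
        raise ValueError(f"DML probes absent from annotation: {missing[:5].tolist()}")
    array_counts = table[col].value_counts()
    dml_counts = table.loc[dml_probes, col].value_counts()
    n_dml = len(dml_probes)
    n_array = len(table)

    rows = []
    tested = []
    for cat in _FAMILIES[family]:
        if array_counts.get(cat, 0) == 0:
            continue
        expected = n_dml * array_counts[cat] / n_array
        observed = int(dml_counts.get(cat, 0))
        if expected < 1:
            logger.warning("category %s skipped: expected count %.2f < 1", cat, expected)
            continue
        chi2, p = goodness_of_fit_chi2(observed, expected, n_dml)
        rows.append(
            {
                "category": cat,
                "observed": observed,
                "expected": expected,
                "chi2": chi2,
                "p": p,
                "direction": "enriched" if observed > expected else "depleted",
            }
        )
        tested.append(cat)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonf"] = np.minimum(out["p"] * len(tested), 1.0)
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def manhattan_cluster(
    beta_values: pd.DataFrame,
    method: str = "complete",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of samples by Manhattan (L1) distance over the
    supplied probes (rows), complete linkage by default.

    Columns are processed in sorted sample-id order so ties break
    deterministically.  Returns (scipy linkage matrix, leaf-order sample ids).
    """
    if beta_values.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    if beta_values.isna().any().any():
        raise ValueError("complete missing values probewise before clustering")
    ordered = beta_values[sorted(beta_values.columns)]
    X = ordered.to_numpy(dtype=float).T  # samples × probes
    dist = pdist(X, metric="cityblock")
    Z = linkage(dist, method=method)
    leaf_ids = [ordered.columns[i] for i in leaves_list(Z)]
    return Z, leaf_ids


def two_cluster_purity(Z: np.ndarray, sample_ids: Sequence[str], groups) -> float:
    """Purity of the two-cluster cut against the IS/IR labels (majority vote
    per cluster)."""
    from scipy.cluster.hierarchy import fcluster

    labels = fcluster(Z, t=2, criterion="maxclust")
    groups = pd.Series(groups).reindex(sorted(sample_ids)).to_numpy()
    correct = 0
    for c in np.unique(labels):
        sub = groups[labels == c]
        vals, counts = np.unique(sub, return_counts=True)
        correct += counts.max()
    return correct / len(groups)


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------


def power_sample_size(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_max: int = 100000,
) -> int:
    """Smallest per-group n for a two-sided two-sample t test to reach the
    target power, by noncentral-t iteration.

    ``delta`` is the group mean difference and ``sd`` the common standard
    deviation, both in β units.
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        nc = delta / (sd * np.sqrt(2.0 / n))
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        achieved = 1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
        if achieved >= power:
            return n
    raise ValueError("no n up to n_max reaches the target power")


# ---------------------------------------------------------------------------
# gene-set enrichment (local Fisher's exact over user-supplied sets)
# ---------------------------------------------------------------------------


def gene_set_fisher(
    query_genes: Iterable[str],
    background_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Fisher's exact over-representation test of a query gene list against
    user-supplied gene sets, within a stated background universe."""
    query = set(query_genes)
    background = set(background_genes) | query
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & background
        a = len(query & members)
        b = len(query - members)
        c = len(members - query)
        d = len(background) - a - b - c
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"gene_set": name, "overlap": a, "set_size": len(members), "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
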