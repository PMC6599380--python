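"""Synthetic cohorts and reference methylomes with planted ground truth.

The generator emulates the statistical structure of normalized 450K β-value
data so the whole analysis chain is testable offline:

* per-probe baseline means drawn from a bimodal mixture (most of a methylome
  sits near 0 or 1, a minority midrange);
* per-sample noise from a Beta distribution with common concentration κ,
  which reproduces the heteroscedasticity of β values (variance shrinks
  toward the 0/1 boundaries);
* planted differentially methylated probes that shift the IR group mean by a
  known δ with random sign;
* SNP-like probes whose per-sample values cluster at ~0 / 0.5 / ~1 following
  Hardy–Weinberg genotype frequencies — the pattern the probe filter targets;
* reference panels with cell-type marker probes, and an HSC profile placed
  relative to the realized cohort group means so that maintenance /
  divergence classes are planted exactly.

Every function takes a mandatory integer seed and uses a single
``numpy.random.Generator``; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GENE_REGIONS,
    ISLAND_RELATIONS,
    BetaMatrix,
    ProbeAnnotation,
    SampleTable,
    ValidationError,
)

#: Genotype mode levels for SNP-confounded probes (unmethylated / hemi / full).
SNP_MODES = (0.03, 0.5, 0.97)

# Array-wide category proportions used for the synthetic manifest.  Null
# probes follow the array background; planted DMLs are drawn body/shore-heavy
# to emulate the genomic-context skew of disease-associated loci.
_REGION_BG = {"TSS1500": 0.15, "TSS200": 0.10, "5UTR": 0.10, "1stExon": 0.05,
              "Body": 0.33, "3UTR": 0.04, "Intergenic": 0.23}
_REGION_DML = {"TSS1500": 0.08, "TSS200": 0.05, "5UTR": 0.07, "1stExon": 0.03,
               "Body": 0.54, "3UTR": 0.05, "Intergenic": 0.18}
_ISLAND_BG = {"Island": 0.31, "N_Shore": 0.13, "S_Shore": 0.10, "N_Shelf": 0.05,
              "S_Shelf": 0.04, "OpenSea": 0.37}
_ISLAND_DML = {"Island": 0.15, "N_Shore": 0.22, "S_Shore": 0.12, "N_Shelf": 0.05,
               "S_Shelf": 0.04, "OpenSea": 0.42}


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    beta: BetaMatrix
    samples: SampleTable
    annotation: ProbeAnnotation
    truth: pd.DataFrame

    def __iter__(self):  # allow (beta, samples, truth) unpacking patterns
        return iter((self.beta, self.samples, self.truth))


@dataclass
class ReferenceSet:
    """Bundle returned by :func:`simulate_references`."""

    profiles: pd.DataFrame            # probes × cell types (mean β)
    samples: dict[str, BetaMatrix]    # per-type reference sample matrices
    truth: pd.DataFrame               # probe → marker / maintenance marks
    hsc_profile: pd.Series | None = None
    hsc_samples: BetaMatrix | None = None


def _baseline_means(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal methylome mixture: 45% low, 45% high, 10% midrange."""
    comp = rng.choice(3, size=n, p=(0.45, 0.45, 0.10))
    mu = np.empty(n)
    mu[comp == 0] = rng.beta(0.5, 5.0, size=int((comp == 0).sum()))
    mu[comp == 1] = rng.beta(5.0, 0.5, size=int((comp == 1).sum()))
    mu[comp == 2] = rng.uniform(0.2, 0.8, size=int((comp == 2).sum()))
    return np.clip(mu, 0.005, 0.995)


def _beta_noise(rng: np.random.Generator, mu: np.ndarray, kappa: float) -> np.ndarray:
    return rng.beta(mu * kappa, (1.0 - mu) * kappa)


def _categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    cats = list(probs)
    p = np.asarray([probs[c] for c in cats], dtype=float)
    return rng.choice(np.asarray(cats, dtype=object), size=n, p=p / p.sum())


def simulate_cohort(
    n_is: int = 23,
    n_ir: int = 14,
    n_probes: int = 5000,
    n_dml: int = 200,
    delta: float = 0.15,
    precision: float = 50.0,
    snp_frac: float = 0.01,
    seed: int | None = None,
) -> SimulatedCohort:
    """Simulate an IS/IR cohort β matrix with planted DMLs and SNP-like probes.

    Parameters mirror the study conditions: 23 insulin-sensitive vs 14
    insulin-resistant samples, planted effect size ``delta`` in β units
    (IR − IS, sign random per probe), Beta-noise concentration ``precision``
    (κ), and a fraction ``snp_frac`` of trimodal SNP-like probes disjoint
    from the planted set.  Returns the β matrix, sample metadata whose
    HOMA-IR values stratify back into the group labels, a manifest-like
    probe annotation, and a ground-truth ledger.
    """
    if seed is None:
        raise ValueError("seed is required")
    if not (0.0 <= delta < 1.0):
        raise ValueError("delta must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_snp = int(round(snp_frac * n_probes))
    if n_dml + n_snp > n_probes:
        raise ValueError("n_dml + SNP-like count exceeds n_probes")

    probe_ids = pd.Index([f"cg{i:08d}" for i in range(1, n_probes + 1)], name="probe_id")
    sample_ids = [f"IS{i:02d}" for i in range(1, n_is + 1)] + [
        f"IR{i:02d}" for i in range(1, n_ir + 1)
    ]
    is_ir_sample = np.array([s.startswith("IR") for s in sample_ids])

    special = rng.choice(n_probes, size=n_dml + n_snp, replace=False)
    dml_idx = special[:n_dml]
    snp_idx = special[n_dml:]

    mu_is = _baseline_means(rng, n_probes)
    mu_ir = mu_is.copy()

    # planted effects: base mean midrange so a ±delta shift stays in (0.01, 0.99)
    base = rng.uniform(0.2, 0.8, size=n_dml)
    sign = rng.choice((-1.0, 1.0), size=n_dml)
    shifted = base + sign * delta
    flip = (shifted <= 0.01) | (shifted >= 0.99)
    sign[flip] *= -1.0
    shifted = base + sign * delta
    if ((shifted <= 0.01) | (shifted >= 0.99)).any():
        raise ValueError("delta pushes a planted mean outside (0.01, 0.99)")
    mu_is[dml_idx] = base
    mu_ir[dml_idx] = shifted
    true_delta = np.zeros(n_probes)
    true_delta[dml_idx] = shifted - base

    # per-sample draws
    n = n_is + n_ir
    mu_mat = np.where(is_ir_sample[None, :], mu_ir[:, None], mu_is[:, None])
    values = rng.beta(mu_mat * precision, (1.0 - mu_mat) * precision)

    # SNP-like probes: HWE genotypes at three β modes plus tight Beta noise
    is_snp = np.zeros(n_probes, dtype=bool)
    is_snp[snp_idx] = True
    if n_snp:
        p_allele = rng.uniform(0.2, 0.8, size=n_snp)
        geno_p = np.stack(
            [p_allele**2, 2 * p_allele * (1 - p_allele), (1 - p_allele) ** 2], axis=1
        )
        modes = np.asarray(SNP_MODES)
        for row, gp in zip(snp_idx, geno_p):
            geno = rng.choice(3, size=n, p=gp)
            level = modes[geno]
            values[row] = _beta_noise(rng, level, 800.0)

    beta = BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))

    # sample metadata: HOMA-IR generated so stratification reproduces labels
    homa = np.where(
        is_ir_sample,
        rng.uniform(2.0, 6.0, size=n),
        rng.uniform(0.5, 1.9, size=n),
    )
    glucose = rng.uniform(80.0, 110.0, size=n)
    insulin = homa * 405.0 / glucose
    meta = pd.DataFrame(
        {
            "group": np.where(is_ir_sample, "IR", "IS"),
            "homa_ir": homa,
            "fasting_glucose": glucose,
            "fasting_insulin": insulin,
            "hiv_status": "positive",
            "bmi": rng.normal(27.0, 4.0, size=n).clip(18, 45)
            + np.where(is_ir_sample, 1.5, 0.0),
            "frs": rng.normal(8.0, 4.0, size=n).clip(0, 30)
            + np.where(is_ir_sample, 2.0, 0.0),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    samples = SampleTable(meta)

    annotation = _simulate_annotation(rng, probe_ids, dml_idx, is_snp)

    planted = true_delta != 0.0
    truth = pd.DataFrame(
        {
            "is_planted_dml": planted,
            "true_delta": true_delta,
            "is_snp_like": is_snp,
            "celltype_marker": "",
            "hsc_maintained_in": "",
            "mu_is": mu_is,
            "mu_ir": mu_ir,
        },
        index=probe_ids,
    )
    return SimulatedCohort(beta, samples, annotation, truth)


def _simulate_annotation(
    rng: np.random.Generator,
    probe_ids: pd.Index,
    dml_idx: np.ndarray,
    is_snp: np.ndarray,
) -> ProbeAnnotation:
    n = len(probe_ids)
    region = _categorical(rng, _REGION_BG, n)
    island = _categorical(rng, _ISLAND_BG, n)
    region[dml_idx] = _categorical(rng, _REGION_DML, len(dml_idx))
    island[dml_idx] = _categorical(rng, _ISLAND_DML, len(dml_idx))
    chrom = rng.integers(1, 23, size=n)
    pos = rng.integers(10_000, 200_000_000, size=n)
    gene_id = rng.integers(1, max(2, n // 4), size=n)
    genes = np.where(region == "Intergenic", "", [f"GENE{g:05d}" for g in gene_id])
    # roughly half of SNP-like probes carry a manifest annotation; 1% background
    known = rng.random(n) < 0.01
    known[is_snp] = rng.random(int(is_snp.sum())) < 0.5
    table = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "gene_symbols": genes,
            "gene_region": region,
            "island_relation": island,
            "known_snp": known,
        },
        index=probe_ids,
    )
    return ProbeAnnotation(table)


def simulate_references(
    cell_types: Sequence[str] = ("monocyte", "pbmc"),
    n_markers_per_type: int | Mapping[str, int] = 100,
    marker_delta: float = 0.35,
    n_samples_per_type: int = 6,
    precision: float = 200.0,
    seed: int | None = None,
    probe_ids: Sequence[str] | None = None,
    n_probes: int = 2000,
    cohort: SimulatedCohort | None = None,
    hsc_maintained_ir: int = 0,
    hsc_maintained_is: int = 0,
    hsc_maintained_both: int = 0,
) -> ReferenceSet:
    """Simulate reference methylomes with per-type marker probes.

    Each cell type receives ``n_markers_per_type`` disjoint marker probes at
    which its mean profile differs from every other type by at least
    ``marker_delta`` (≥ 0.10 by precondition); elsewhere profiles coincide.
    Per-type reference samples add Beta noise with concentration
    ``precision``.

    ``n_markers_per_type`` may be a mapping giving a per-type marker count
    (e.g. zero markers for a type whose profile should sit exactly on the
    shared baseline).

    When a ``cohort`` is supplied the shared baseline is the cohort's own
    per-probe baseline mean and markers avoid planted-DML and SNP-like
    probes, so the cohort samples emulate enriched cells of the *first*
    cell type (high rank-correlation with its profile at any panel).  An
    HSC profile is then also emitted on the cohort's probe universe, placed
    relative to the *realized* group means at planted DML probes so that
    maintenance classes are planted exactly:
    ``hsc_maintained_ir`` / ``hsc_maintained_is`` are total counts of planted
    DMLs maintained (|group − HSC| < 0.10) in each group, of which
    ``hsc_maintained_both`` are maintained in both; remaining planted DMLs
    diverge (≥ 0.10) from both groups.
    """
    if seed is None:
        raise ValueError("seed is required")
    if marker_delta < 0.10:
        raise ValueError("marker_delta must be >= 0.10")
    if len(set(cell_types)) != len(cell_types):
        raise ValidationError("duplicate cell-type names")
    rng = np.random.default_rng(seed)

    if cohort is not None and probe_ids is None:
        probe_ids = cohort.beta.probe_ids
    if probe_ids is None:
        probe_ids = pd.Index([f"cg{i:08d}" for i in range(1, n_probes + 1)], name="probe_id")
    else:
        probe_ids = pd.Index(probe_ids, name="probe_id")
    n = len(probe_ids)
    k = len(cell_types)
    if isinstance(n_markers_per_type, Mapping):
        counts = {ct: int(n_markers_per_type.get(ct, 0)) for ct in cell_types}
    else:
        counts = {ct: int(n_markers_per_type) for ct in cell_types}
    n_markers_total = sum(counts.values())

    if cohort is not None:
        mu0 = cohort.truth["mu_is"].to_numpy(dtype=float)
        eligible = np.flatnonzero(
            ~cohort.truth["is_planted_dml"].to_numpy()
            & ~cohort.truth["is_snp_like"].to_numpy()
        )
    else:
        mu0 = _baseline_means(rng, n)
        eligible = np.arange(n)
    if n_markers_total > eligible.size:
        raise ValueError("marker sets exceed the eligible probe universe")
    marker_pool = rng.choice(eligible, size=n_markers_total, replace=False)
    profiles = np.tile(mu0[:, None], (1, k))
    marker_of = np.full(n, "", dtype=object)
    offset = 0
    for t, ct in enumerate(cell_types):
        idx = marker_pool[offset : offset + counts[ct]]
        offset += counts[ct]
        marker_of[idx] = ct
        up = mu0[idx] + marker_delta <= 0.98
        shift = np.where(up, marker_delta, -marker_delta)
        shifted = np.clip(mu0[idx] + shift, 0.02, 0.98)
        profiles[idx, t] = shifted

    prof_df = pd.DataFrame(profiles, index=probe_ids, columns=list(cell_types))
    sample_mats: dict[str, BetaMatrix] = {}
    for t, ct in enumerate(cell_types):
        draws = rng.beta(
            profiles[:, t][:, None] * precision,
            (1.0 - profiles[:, t][:, None]) * precision,
            size=(n, n_samples_per_type),
        )
        cols = [f"{ct}_{i + 1}" for i in range(n_samples_per_type)]
        sample_mats[ct] = BetaMatrix(pd.DataFrame(draws, index=probe_ids, columns=cols))

    truth = pd.DataFrame(
        {"celltype_marker": marker_of, "hsc_maintained_in": ""}, index=probe_ids
    )

    hsc_profile = None
    hsc_samples = None
    want_hsc = hsc_maintained_ir or hsc_maintained_is or hsc_maintained_both
    if want_hsc:
        if cohort is None:
            raise ValueError("HSC maintenance planting requires a cohort")
        hsc_profile, marks = _plant_hsc_profile(
            rng, cohort, hsc_maintained_ir, hsc_maintained_is, hsc_maintained_both
        )
        truth = truth.reindex(hsc_profile.index, fill_value="")
        truth["hsc_maintained_in"] = marks
        draws = rng.beta(
            hsc_profile.to_numpy()[:, None] * 2000.0,
            (1.0 - hsc_profile.to_numpy())[:, None] * 2000.0,
            size=(len(hsc_profile), 3),
        )
        hsc_samples = BetaMatrix(
            pd.DataFrame(draws, index=hsc_profile.index, columns=["HSC_1", "HSC_2", "HSC_3"])
        )

    return ReferenceSet(prof_df, sample_mats, truth, hsc_profile, hsc_samples)


def _plant_hsc_profile(
    rng: np.random.Generator,
    cohort: SimulatedCohort,
    n_ir: int,
    n_is: int,
    n_both: int,
) -> tuple[pd.Series, pd.Series]:
    """Place an HSC mean profile so planted maintenance classes are exact.

    Classes are defined against the cohort's *observed* group means (the
    quantities the downstream classifier uses), so the planted counts are
    reproduced deterministically: maintained-in-IR probes get the IR mean,
    maintained-in-IS the IS mean, maintained-in-both the midpoint (feasible
    only while |δ| < 0.20), and the rest sit ≥ 0.10 away from both groups.
    """
    if n_both > min(n_ir, n_is):
        raise ValueError("hsc_maintained_both exceeds a per-group total")
    groups = cohort.samples.groups
    vals = cohort.beta.values
    mean_is = vals.loc[:, groups[groups == "IS"].index].mean(axis=1)
    mean_ir = vals.loc[:, groups[groups == "IR"].index].mean(axis=1)
    obs_delta = (mean_ir - mean_is).to_numpy()

    planted = cohort.truth["is_planted_dml"].to_numpy()
    planted_idx = np.flatnonzero(planted)
    need = (n_ir - n_both) + (n_is - n_both) + n_both
    if need > planted_idx.size:
        raise ValueError("not enough planted DMLs for the maintenance scenario")

    abs_d = np.abs(obs_delta)
    both_ok = planted_idx[abs_d[planted_idx] < 0.20]
    excl_ok = planted_idx[abs_d[planted_idx] >= 0.10]

    # prefer probes only eligible for 'both' (|δ̂| < 0.10) for the both bucket
    only_both = both_ok[abs_d[both_ok] < 0.10]
    rest_both = both_ok[abs_d[both_ok] >= 0.10]
    rng.shuffle(only_both)
    rng.shuffle(rest_both)
    both_pick = np.concatenate([only_both, rest_both])[:n_both]
    if both_pick.size < n_both:
        raise ValueError("not enough planted DMLs with |observed δ| < 0.20 for 'both'")

    remaining = np.setdiff1d(excl_ok, both_pick)
    rng.shuffle(remaining)
    n_ir_only = n_ir - n_both
    n_is_only = n_is - n_both
    if remaining.size < n_ir_only + n_is_only:
        raise ValueError("not enough planted DMLs with |observed δ| >= 0.10 for exclusives")
    ir_pick = remaining[:n_ir_only]
    is_pick = remaining[n_ir_only : n_ir_only + n_is_only]

    hsc = vals.mean(axis=1).to_numpy()  # background: overall cohort mean
    marks = np.full(len(vals), "", dtype=object)
    hsc[ir_pick] = mean_ir.to_numpy()[ir_pick]
    marks[ir_pick] = "IR"
    hsc[is_pick] = mean_is.to_numpy()[is_pick]
    marks[is_pick] = "IS"
    hsc[both_pick] = 0.5 * (mean_is.to_numpy()[both_pick] + mean_ir.to_numpy()[both_pick])
    marks[both_pick] = "both"
    neither = np.setdiff1d(planted_idx, np.concatenate([ir_pick, is_pick, both_pick]))
    s = np.sign(obs_delta[neither])
    s[s == 0] = 1.0
    # alternate which group the divergent HSC value sits beyond, so these
    # probes do not systematically pull the HSC profile toward one group
    side = rng.random(neither.size) < 0.5
    beyond_is = np.clip(mean_is.to_numpy()[neither] - s * 0.15, 0.01, 0.99)
    beyond_ir = mean_ir.to_numpy()[neither] + s * 0.15
    ir_feasible = (beyond_ir > 0.01) & (beyond_ir < 0.99)
    hsc[neither] = np.where(side | ~ir_feasible, beyond_is, beyond_ir)
    marks[neither] = "neither"

    return (
        pd.Series(np.clip(hsc, 0.0, 1.0), index=vals.index, name="HSC"),
        pd.Series(marks, index=vals.index),
    )


def write_demo_study(
    out_dir,
    seed: int,
    n_probes: int = 2000,
    n_dml: int = 120,
    delta: float = 0.15,
    precision: float = 50.0,
    snp_frac: float = 0.01,
    n_confounder: int = 60,
    maintenance: tuple[int, int, int] = (48, 42, 20),
    B: int = 200,
) -> dict:
    """Write a complete, self-consistent demo study to ``out_dir``.

    Emits the cohort tables (β matrix, sample metadata, annotation, truth),
    monocyte/PBMC reference sample matrices, an HSC profile with planted
    maintenance classes, a confounder DML list, and a ready-to-run
    ``config.yaml`` for :func:`monomethir.pipeline.run_pipeline`.  The
    confounder list mixes a few planted DMLs (the overlap the pipeline
    should subtract) with null probes.  Returns the path map.
    """
    from pathlib import Path

    import yaml

    from .io import (
        write_beta_matrix,
        write_probe_annotation,
        write_probe_list,
        write_sample_table,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    cohort = simulate_cohort(
        n_probes=n_probes, n_dml=n_dml, delta=delta, precision=precision,
        snp_frac=snp_frac, seed=seed,
    )
    m_ir, m_is, m_both = maintenance
    # the cohort emulates enriched monocytes, so the monocyte profile keeps
    # the cohort baseline and only the PBMC profile diverges at the markers
    refs = simulate_references(
        cell_types=("monocyte", "pbmc"),
        n_markers_per_type={"monocyte": 0, "pbmc": 150},
        seed=seed + 1, cohort=cohort,
        hsc_maintained_ir=m_ir, hsc_maintained_is=m_is, hsc_maintained_both=m_both,
    )

    planted = cohort.truth.index[cohort.truth["is_planted_dml"]]
    nulls = cohort.truth.index[
        ~cohort.truth["is_planted_dml"] & ~cohort.truth["is_snp_like"]
    ]
    overlap = rng.choice(planted, size=min(3, len(planted)), replace=False)
    background = rng.choice(nulls, size=n_confounder - len(overlap), replace=False)
    confounder = sorted(map(str, np.concatenate([overlap, background])))

    paths = {
        "beta": out / "beta.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.tsv",
        "reference_a": out / "reference_monocyte.tsv",
        "reference_b": out / "reference_pbmc.tsv",
        "hsc_profile": out / "hsc_profile.tsv",
        "confounder": out / "confounder_dmls.tsv",
        "config": out / "config.yaml",
    }
    write_beta_matrix(cohort.beta, paths["beta"])
    write_sample_table(cohort.samples, paths["samples"])
    write_probe_annotation(cohort.annotation, paths["annotation"])
    truth = cohort.truth.copy()
    truth["hsc_maintained_in"] = refs.truth["hsc_maintained_in"].reindex(truth.index, fill_value="")
    truth.to_csv(paths["truth"], sep="\t", index_label="probe_id")
    write_beta_matrix(refs.samples["monocyte"], paths["reference_a"])
    write_beta_matrix(refs.samples["pbmc"], paths["reference_b"])
    refs.hsc_profile.round(6).to_frame("beta").to_csv(
        paths["hsc_profile"], sep="\t", index_label="probe_id"
    )
    write_probe_list(confounder, paths["confounder"])

    config = {
        "beta": "beta.tsv",
        "samples": "samples.tsv",
        "annotation": "annotation.tsv",
        "confounder_dmls": "confounder_dmls.tsv",
        "reference_a": "reference_monocyte.tsv",
        "reference_b": "reference_pbmc.tsv",
        "hsc_profile": "hsc_profile.tsv",
        "seed": int(seed),
        "B": int(B),
    }
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=True), encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
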