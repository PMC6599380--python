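"""End-to-end pipeline: one YAML config → one output directory.

Stage order follows the analysis narrative: differential test →
confounder-overlap subtraction → SNP flags → final DML call → reference
identity QC → HSC maintenance + PCA → biomarker models → genomic-context
enrichment → clustering.  A JSON report records the parameters and the
row counts in/out of every stage; all randomness flows from the single
config seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dml as dml_mod
from . import filters, hsc, identity, predict
from . import stats as cstats
from .io import (
    BetaMatrix,
    read_beta_matrix,
    read_probe_annotation,
    read_probe_list,
    read_sample_table,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """File inputs, thresholds and the master seed for one run."""

    beta: str
    samples: str
    annotation: str | None = None
    confounder_dmls: str | None = None
    reference_a: str | None = None   # e.g. monocyte reference samples
    reference_b: str | None = None   # e.g. PBMC reference samples
    reference_names: tuple[str, str] = ("monocyte", "pbmc")
    hsc_profile: str | None = None   # two-column TSV: probe_id, beta
    seed: int = 0
    B: int = 1000
    p_threshold: float = 0.05
    delta_threshold: float = 0.10
    panel_delta_threshold: float = 0.30
    maintenance_threshold: float = 0.10
    candidate_q: float = 0.01
    snp_tol: float = filters.DEFAULT_TOL
    snp_min_assigned: float = filters.DEFAULT_MIN_ASSIGNED
    snp_min_modes: int = filters.DEFAULT_MIN_MODES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cfg = cls(**raw)
        base = Path(path).parent
        for attr in ("beta", "samples", "annotation", "confounder_dmls",
                     "reference_a", "reference_b", "hsc_profile"):
            val = getattr(cfg, attr)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, attr, str(base / val))
        return cfg


@dataclass
class PipelineResult:
    out_dir: Path
    report: dict
    dml_records: pd.DataFrame
    files: dict = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="", index_label=index_label)


def run_pipeline(config: PipelineConfig | str | Path, out_dir: str | Path,
                 force: bool = False) -> PipelineResult:
    """Execute the full workflow described by ``config`` into ``out_dir``."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} is not empty (use force=True to overwrite)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    # fail fast on inputs before any stage runs
    for attr in ("beta", "samples", "annotation", "confounder_dmls",
                 "reference_a", "reference_b", "hsc_profile"):
        val = getattr(config, attr)
        if val is not None and not Path(val).exists():
            raise FileNotFoundError(f"config.{attr}: {val} does not exist")

    report: dict = {"parameters": asdict(config), "stages": []}
    files: dict = {}

    def stage(name, **counts):
        entry = {"stage": name, **counts}
        report["stages"].append(entry)
        logger.info("stage %-22s %s", name, counts)

    beta = read_beta_matrix(config.beta)
    samples = read_sample_table(config.samples)
    groups = samples.groups.reindex(beta.sample_ids)
    stage("load", n_probes=beta.shape[0], n_samples=beta.shape[1],
          n_is=int((groups == "IS").sum()), n_ir=int((groups == "IR").sum()))

    annotation = read_probe_annotation(config.annotation) if config.annotation else None

    # --- differential test -------------------------------------------------
    records = dml_mod.dml_table(beta, groups, B=config.B, seed=config.seed)
    n_sig = int((records["p_perm"] < config.p_threshold).sum())
    n_candidate = int(
        (
            (records["p_perm"] < config.p_threshold)
            & (records["delta"].abs() >= config.delta_threshold)
        ).sum()
    )
    stage("differential_test", n_tested=int(records["p_perm"].notna().sum()),
          n_p_significant=n_sig, n_delta_pass=n_candidate)

    candidate_probes = records.index[
        (records["p_perm"] < config.p_threshold)
        & (records["delta"].abs() >= config.delta_threshold)
    ].tolist()

    # --- confounder overlap -------------------------------------------------
    if config.confounder_dmls and candidate_probes:
        confounder = read_probe_list(config.confounder_dmls)
        retained, overlap, pct = filters.confound_overlap_filter(candidate_probes, confounder)
        records = filters.apply_filters(records, confounder_dmls=confounder)
        stage("confounder_overlap", n_in=len(candidate_probes),
              n_overlap=len(overlap), overlap_pct=pct, n_out=len(retained))
        candidate_probes = retained
    else:
        stage("confounder_overlap", skipped=True)

    # --- SNP flags -----------------------------------------------------------
    records = filters.apply_filters(
        records, beta=beta, annotation=annotation,
        tol=config.snp_tol, min_assigned=config.snp_min_assigned,
        min_modes=config.snp_min_modes,
    )
    cand = records.loc[candidate_probes]
    snp_flagged = cand["flag_snp_pattern"] | cand.get("flag_known_snp", False)
    stage("snp_filter", n_in=len(candidate_probes),
          n_pattern=int(cand["flag_snp_pattern"].sum()),
          n_known=int(cand["flag_known_snp"].sum()) if annotation else 0,
          n_out=int((~snp_flagged).sum()))

    # --- final call ----------------------------------------------------------
    records, summary = dml_mod.call_dmls(
        records, p_threshold=config.p_threshold, delta_threshold=config.delta_threshold
    )
    dml_probes = records.index[records["is_dml"]].tolist()
    stage("call_dmls", **summary)
    files["dml"] = out / "dml.tsv"
    _write_tsv(records, files["dml"], "probe_id")

    # --- identity QC ----------------------------------------------------------
    if config.reference_a and config.reference_b:
        ref_a = read_beta_matrix(config.reference_a)
        ref_b = read_beta_matrix(config.reference_b)
        panel = identity.build_panel(
            ref_a, ref_b, *config.reference_names,
            delta_threshold=config.panel_delta_threshold,
            B=min(config.B, 200), seed=config.seed + 1,
        )
        purity = identity.purity_table(beta, panel, config.reference_names[0])
        u, p = identity.compare_group_scores(purity, groups)
        stage("identity_qc", n_panel=len(panel.probes),
              mean_purity=round(float(purity.mean()), 4),
              group_diff_p=round(p, 4))
        files["purity"] = out / "purity.tsv"
        _write_tsv(purity.to_frame(), files["purity"], "sample_id")
    else:
        stage("identity_qc", skipped=True)

    # --- HSC maintenance ------------------------------------------------------
    if config.hsc_profile and dml_probes:
        hsc_prof = pd.read_csv(config.hsc_profile, sep="\t", index_col=0).iloc[:, 0]
        maint = hsc.maintenance_table(
            beta, groups, hsc_prof, dml_probes, threshold=config.maintenance_threshold
        )
        msum = hsc.maintenance_summary(maint)
        stage("hsc_maintenance", **msum)
        files["maintenance"] = out / "maintenance.tsv"
        _write_tsv(maint, files["maintenance"], "probe_id")

        block = beta.values.loc[dml_probes].copy()
        block["HSC"] = hsc_prof.reindex(dml_probes)
        coords, frac = hsc.pca_dmls(block.dropna(axis=0))
        files["pca"] = out / "pca.tsv"
        _write_tsv(coords.iloc[:, :5], files["pca"], "sample_id")
        stage("pca", pc1_var=round(float(frac[0]), 4),
              pc2_var=round(float(frac[1]), 4) if len(frac) > 1 else None)
    else:
        stage("hsc_maintenance", skipped=True)

    # --- biomarker models ------------------------------------------------------
    if dml_probes:
        candidates = predict.select_candidates(
            beta, groups, probes=dml_probes, q_threshold=config.candidate_q
        )
        models = []
        if candidates:
            top = candidates[: min(len(candidates), 8)]
            models = predict.single_cpg_models(beta, groups, top)
        covars = samples.covariates().reindex(beta.sample_ids)
        clin_cols = [c for c in covars.columns if covars[c].notna().all()
                     and covars[c].nunique() > 1]
        if clin_cols:
            y = groups
            for colname in clin_cols:
                models.append(predict.fit_logistic(covars[[colname]], y, name=colname))
        if len(models) >= 2:
            ranked = predict.compare_models(models)
            files["models"] = out / "models.tsv"
            _write_tsv(ranked, files["models"], "rank")
            stage("prediction", n_candidates=len(candidates),
                  n_models=len(models),
                  best_model=str(ranked.iloc[0]["model"]),
                  best_auc=round(float(ranked.iloc[0]["auc"]), 4))
        else:
            stage("prediction", n_candidates=len(candidates), n_models=len(models))
    else:
        stage("prediction", skipped=True)

    # --- enrichment -------------------------------------------------------------
    if annotation is not None and dml_probes:
        enr = []
        for family in ("gene_region", "island_relation"):
            e = cstats.region_enrichment(dml_probes, annotation, family=family)
            e.insert(0, "family", family)
            enr.append(e)
        enr_df = pd.concat(enr, ignore_index=True)
        files["enrichment"] = out / "enrichment.tsv"
        _write_tsv(enr_df, files["enrichment"], "row")
        sig = enr_df[enr_df["p_bonf"] < 0.05]
        stage("enrichment", n_categories=len(enr_df), n_significant=len(sig))
    else:
        stage("enrichment", skipped=True)

    # --- clustering ---------------------------------------------------------------
    if len(dml_probes) >= 2:
        Z, leaves = cstats.manhattan_cluster(beta.values.loc[dml_probes])
        files["cluster"] = out / "cluster_leaves.tsv"
        pd.Series(leaves, name="sample_id").to_frame().to_csv(
            files["cluster"], sep="\t", index_label="leaf_order"
        )
        purity2 = cstats.two_cluster_purity(Z, beta.sample_ids, groups)
        stage("clustering", two_cluster_purity=round(float(purity2), 4))
    else:
        stage("clustering", skipped=True)

    # --- provenance -----------------------------------------------------------------
    files["report"] = out / "pipeline_report.json"
    files["report"].write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )
    files["config"] = out / "config_used.yaml"
    files["config"].write_text(
        yaml.safe_dump(asdict(config), sort_keys=True), encoding="utf-8"
    )
    return PipelineResult(out, report, records, files)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
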