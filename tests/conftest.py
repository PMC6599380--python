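import pytest

import monomethir as mm


@pytest.fixture(scope="session")
def cohort():
    """Study-scale synthetic cohort: 23 IS vs 14 IR, 5000 probes, 200 planted
    DMLs at δ=0.15, κ=50, 1% SNP-like probes."""
    return mm.simulate_cohort(seed=5)


@pytest.fixture(scope="session")
def cohort_records(cohort):
    """Differential table with permutation p-values and filter flags."""
    rec = mm.dml_table(cohort.beta, cohort.samples.groups, B=200, seed=5)
    return mm.apply_filters(rec, beta=cohort.beta, annotation=cohort.annotation)


@pytest.fixture(scope="session")
def references():
    """Standalone two-type reference set: 100 markers per type at δ=0.35."""
    return mm.simulate_references(
        cell_types=("monocyte", "pbmc"), n_markers_per_type=100,
        marker_delta=0.35, seed=3, n_probes=2000,
    )


@pytest.fixture(scope="session")
def panel(references):
    return mm.build_panel(
        references.samples["monocyte"], references.samples["pbmc"],
        "monocyte", "pbmc", delta_threshold=0.30, B=200, seed=3,
    )


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory):
    """Complete on-disk demo study (cohort + references + HSC + config)."""
    out = tmp_path_factory.mktemp("demo_study")
    return mm.write_demo_study(out / "inputs", seed=42)
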