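"""Domain types and TSV readers/writers for 450K-style methylation tables.

All tables are plain TSV (UTF-8, ``.`` decimal separator, empty cell =
missing).  A β value is the per-probe methylation fraction in [0, 1]
(methylated / total signal).  β values are written with six decimals so a
read → write cycle on a file produced here is byte-stable.

The containers are thin dataclasses around :class:`pandas.DataFrame` with
validation at construction; downstream modules operate on the wrapped
frames/arrays directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of gene-region categories (Illumina manifest style).
GENE_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "Intergenic")

#: Closed vocabulary of CpG-island relations.
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

GROUPS = ("IS", "IR")
HIV_STATUSES = ("positive", "seronegative")

#: Decimals used when writing β values.
BETA_DECIMALS = 6

#: HOMA-IR at or above this value defines the insulin-resistant group.
HOMA_IR_THRESHOLD = 2.0


class ValidationError(ValueError):
    """An input table violates a domain invariant."""


def _check_unique(ids: Iterable, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}(s): {dupes}")


def _check_vocab(values: pd.Series, vocab: Sequence[str], column: str) -> None:
    bad = set(values.dropna().unique()) - set(vocab)
    if bad:
        raise ValidationError(
            f"unknown {column} value(s) {sorted(bad)}; allowed: {list(vocab)}"
        )


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes × samples matrix of β values; NaN marks a missing measurement.

    ``values`` is a float DataFrame indexed by probe id with sample-id
    columns.  All non-missing entries must lie in [0, 1] and both axes must
    carry unique identifiers.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("BetaMatrix.values must be a DataFrame")
        _check_unique(df.index, "probe id")
        _check_unique(df.columns, "sample id")
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric beta value: {exc}") from exc
        arr = df.to_numpy()
        bad = ((arr < 0.0) | (arr > 1.0)) & ~np.isnan(arr)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.values = df

    # -- convenience accessors ------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's β values as a probe-indexed Series."""
        return self.values[sample_id]

    def subset(self, probes=None, samples=None) -> "BetaMatrix":
        df = self.values
        if probes is not None:
            missing = pd.Index(probes).difference(df.index)
            if len(missing):
                raise ValidationError(f"unknown probe id(s): {missing[:5].tolist()}")
            df = df.loc[list(probes)]
        if samples is not None:
            missing = pd.Index(samples).difference(df.columns)
            if len(missing):
                raise ValidationError(f"unknown sample id(s): {missing[:5].tolist()}")
            df = df[list(samples)]
        return BetaMatrix(df.copy())


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes × samples β TSV (first column probe ids, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    beta.values.to_csv(
        path,
        sep="\t",
        float_format=f"%.{BETA_DECIMALS}f",
        na_rep="",
        index_label="probe_id",
    )


# ---------------------------------------------------------------------------
# ProbeAnnotation
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ("chrom", "pos", "gene_symbols", "gene_region", "island_relation", "known_snp")


@dataclass
class ProbeAnnotation:
    """Manifest-like probe annotation (hg19, 1-based positions).

    ``table`` is indexed by probe id with columns ``chrom``, ``pos``,
    ``gene_symbols`` (``;``-joined, possibly empty), ``gene_region``,
    ``island_relation`` and boolean ``known_snp``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        _check_unique(df.index, "probe id")
        missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"annotation missing column(s): {sorted(missing)}")
        _check_vocab(df["gene_region"], GENE_REGIONS, "gene_region")
        _check_vocab(df["island_relation"], ISLAND_RELATIONS, "island_relation")
        pos = pd.to_numeric(df["pos"], errors="raise")
        if (pos < 1).any():
            bad = df.index[pos < 1][0]
            raise ValidationError(f"pos must be >= 1 (1-based); probe {bad!r}")
        df = df.copy()
        df["pos"] = pos.astype(int)
        df["known_snp"] = _coerce_bool(df["known_snp"])
        df["gene_symbols"] = df["gene_symbols"].fillna("").astype(str)
        self.table = df

    def gene_list(self, probe_id: str) -> list[str]:
        raw = self.table.at[probe_id, "gene_symbols"]
        return [g for g in raw.split(";") if g]

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


def _coerce_bool(s: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "True": True, "False": False, True: True, False: False, 1: True, 0: False,
    }
    out = s.map(lambda v: mapping.get(v, mapping.get(str(v).strip(), None)))
    if out.isna().any():
        bad = s[out.isna()].iloc[0]
        raise ValidationError(f"known_snp value {bad!r} is not boolean")
    return out.astype(bool)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"gene_symbols": str})
    df.index = df.index.astype(str)
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------

_SAMPLE_CORE = ("group", "homa_ir", "fasting_glucose", "fasting_insulin", "hiv_status")


@dataclass
class SampleTable:
    """Per-sample metadata: group label, HOMA-IR and clinical covariates.

    Units follow clinical convention: fasting glucose mg/dL, fasting insulin
    µU/mL, HOMA-IR unitless.  Any extra numeric column is treated as a
    covariate (BMI, FRS, cholesterol measures, cytokines, ...).  When both
    ``group`` and ``homa_ir`` are present they must agree with the
    stratification rule (IR ⇔ HOMA-IR ≥ 2.0).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        _check_unique(df.index, "sample id")
        for col in _SAMPLE_CORE:
            if col not in df.columns:
                df[col] = np.nan
        _check_vocab(df["group"].replace("", np.nan), GROUPS, "group")
        _check_vocab(df["hiv_status"].replace("", np.nan), HIV_STATUSES, "hiv_status")
        for col in ("homa_ir", "fasting_glucose", "fasting_insulin"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        homa = df["homa_ir"]
        if (homa.dropna() < 0).any():
            bad = df.index[homa < 0][0]
            raise ValidationError(f"homa_ir must be >= 0; sample {bad!r}")
        both = df["group"].notna() & homa.notna()
        if both.any():
            expected = np.where(homa[both] >= HOMA_IR_THRESHOLD, "IR", "IS")
            clash = df.loc[both, "group"].to_numpy() != expected
            if clash.any():
                bad = df.index[both][clash][0]
                raise ValidationError(
                    f"group label inconsistent with HOMA-IR threshold rule "
                    f"(IR iff homa_ir >= {HOMA_IR_THRESHOLD}) for sample {bad!r}"
                )
        self.table = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def groups(self) -> pd.Series:
        """Sample → {IS, IR} labels (NaN when unset)."""
        return self.table["group"]

    def group_sizes(self) -> dict[str, int]:
        counts = self.groups.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def covariates(self) -> pd.DataFrame:
        """All numeric columns beyond the core fields."""
        extra = [c for c in self.table.columns if c not in _SAMPLE_CORE]
        return self.table[extra].apply(pd.to_numeric, errors="coerce")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


# ---------------------------------------------------------------------------
# Probe lists (one id per line) — used for confounder DML subtraction
# ---------------------------------------------------------------------------


def read_probe_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_probe_list(probes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(probes) + "\n", encoding="utf-8")
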