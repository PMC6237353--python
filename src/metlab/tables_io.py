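"""Tabular I/O for every artifact the pipeline consumes or produces.

All artifacts are plain delimited text (comma by default, tab on request).
Decimal point only, never comma. Missing cells are written empty and read
back as missing; literal zeros stay zeros because blank subtraction needs
them. Floats are written with 9 significant digits so write -> read is an
identity on values at that precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

#: Roles a sample can take in an analytical sequence.
ROLES = ("sample", "blank", "cal_standard", "qc_train", "qc_test")

#: The fixed six-database vocabulary for exact-mass library hits.
LIBRARIES = ("BioCyc", "HMDB", "KEGG", "LipidMaps", "PubChem", "SMPDB")

#: Analyte classes of the targeted panel.
ANALYTE_CLASSES = (
    "amino_acid",
    "biogenic_amine",
    "neurotransmitter",
    "nucleobase",
    "carnitine",
    "PC",
    "lysoPC",
    "SM",
    "other",
)

REQUIRED_SHEET_COLUMNS = (
    "sample_id",
    "role",
    "injection_order",
    "batch_id",
    "tissue",
    "replicate_group",
    "dilution_factor",
)

PANEL_COLUMNS = (
    "name",
    "hmdb_id",
    "analyte_class",
    "is_name",
    "conc_is",
    "monoisotopic_mass",
    "n_carbons",
    "n_double_bonds",
    "bond_code",
)

_NA_VALUES = ["", "NA"]
_FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Per-injection metadata: role, order, batch, dilution.

    ``frame`` has one row per injection with at least
    :data:`REQUIRED_SHEET_COLUMNS`; unknown columns ride along untouched.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.frame
        for col in REQUIRED_SHEET_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"sample sheet is missing required column {col!r}")
        if df.empty:
            return
        bad_roles = sorted(set(df["role"]) - set(ROLES))
        if bad_roles:
            raise ValidationError(f"unknown sample roles: {bad_roles}")
        order = pd.to_numeric(df["injection_order"], errors="coerce")
        if order.isna().any() or (order <= 0).any() or (order != order.round()).any():
            raise ValidationError("injection_order must be a positive integer")
        dup = df.duplicated(subset=["batch_id", "injection_order"], keep=False)
        if dup.any():
            offenders = df.loc[dup, ["batch_id", "injection_order"]]
            pairs = sorted(map(tuple, offenders.itertuples(index=False)))
            raise ValidationError(
                f"duplicate (batch_id, injection_order) pairs: {pairs}"
            )
        qc = df["role"].isin(("qc_train", "qc_test"))
        if qc.any() and df.loc[qc, "batch_id"].isna().any():
            raise ValidationError("QC samples must carry a batch_id")
        dil = pd.to_numeric(df["dilution_factor"], errors="coerce")
        if dil.isna().any() or (dil <= 0).any():
            raise ValidationError("dilution_factor must be > 0")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def batches(self) -> list[str]:
        return sorted(self.frame["batch_id"].dropna().unique())

    def ids_with_role(self, *roles: str) -> list[str]:
        mask = self.frame["role"].isin(roles)
        return list(self.frame.loc[mask, "sample_id"])

    def row(self, sample_id: str) -> pd.Series:
        hit = self.frame[self.frame["sample_id"] == sample_id]
        if hit.empty:
            raise KeyError(sample_id)
        return hit.iloc[0]


@dataclass
class TargetPanel:
    """Analyte definitions: IS assignment, IS concentration, lipid C:DB."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("name", "analyte_class", "is_name", "conc_is"):
            if col not in self.frame.columns:
                raise SchemaError(f"target panel is missing required column {col!r}")
        if self.frame["name"].duplicated().any():
            dups = sorted(self.frame.loc[self.frame["name"].duplicated(), "name"])
            raise ValidationError(f"duplicate analytes in panel: {dups}")
        bad = sorted(set(self.frame["analyte_class"]) - set(ANALYTE_CLASSES))
        if bad:
            raise ValidationError(f"unknown analyte classes: {bad}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> list[str]:
        return list(self.frame["name"])

    def analyte(self, name: str) -> pd.Series:
        hit = self.frame[self.frame["name"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]


@dataclass
class AreaMatrix:
    """Samples x analytes peak areas (arbitrary units, >= 0 or missing)."""

    frame: pd.DataFrame  # index: sample_id, columns: analyte names

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("peak areas must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.frame.columns)


@dataclass(frozen=True)
class AnnotationRecord:
    """Spectral-library annotation attached to one feature."""

    best_match_name: str | None
    mzcloud_score: float
    library_hits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.mzcloud_score <= 100.0:
            raise ValidationError(
                f"mzCloud score {self.mzcloud_score} outside [0, 100]"
            )
        unknown = self.library_hits - set(LIBRARIES)
        if unknown:
            raise ValidationError(f"unknown libraries: {sorted(unknown)}")


@dataclass
class FeatureTable:
    """Non-target features: m/z, RT, per-sample intensities, annotations.

    ``frame`` is one row per feature, indexed by feature_id, with columns
    ``mz``, ``rt``, one intensity column per sample and (optionally)
    ``best_match_name``, ``mzcloud_score``, ``library_hits`` (semicolon
    joined database names).
    """

    frame: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("mz", "rt"):
            if col not in self.frame.columns:
                raise SchemaError(f"feature table is missing column {col!r}")
        missing = [s for s in self.sample_ids if s not in self.frame.columns]
        if missing:
            raise SchemaError(f"feature table lacks intensity columns: {missing}")
        if not self.frame.empty:
            if (self.frame["mz"] <= 0).any():
                raise ValidationError("feature m/z must be > 0")
            if (self.frame["rt"] < 0).any():
                raise ValidationError("feature RT must be >= 0")
            inten = self.frame[self.sample_ids].to_numpy(dtype=float)
            if np.nanmin(inten, initial=0.0) < 0:
                raise ValidationError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index)

    def intensities(self) -> pd.DataFrame:
        """Samples x features intensity matrix (transposed view)."""
        return self.frame[self.sample_ids].T.astype(float)

    def has_annotations(self) -> bool:
        return "mzcloud_score" in self.frame.columns

    def annotation(self, feature_id: str) -> AnnotationRecord | None:
        if not self.has_annotations():
            return None
        row = self.frame.loc[feature_id]
        score = row.get("mzcloud_score")
        if pd.isna(score):
            return None
        hits = row.get("library_hits")
        hit_set = (
            frozenset(h for h in str(hits).split(";") if h)
            if isinstance(hits, str) and hits
            else frozenset()
        )
        name = row.get("best_match_name")
        return AnnotationRecord(
            best_match_name=None if pd.isna(name) else str(name),
            mzcloud_score=float(score),
            library_hits=hit_set,
        )


def feature_id_for(mz: float, rt: float) -> str:
    """Canonical synthesized feature id: m/z to 4 decimals @ RT to 2."""
    return f"{mz:.4f}@{rt:.2f}"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_csv(path, delimiter: str = ",") -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=delimiter,
        na_values=_NA_VALUES,
        keep_default_na=False,
        dtype_backend="numpy_nullable",
    )


def read_sample_sheet(path, delimiter: str = ",") -> SampleSheet:
    """Read and validate a sample sheet.

    Raises :class:`SchemaError` when a required column is absent and
    :class:`ValidationError` on duplicate (batch, injection order) pairs.
    """
    df = _read_csv(path, delimiter)
    for col in REQUIRED_SHEET_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"sample sheet is missing required column {col!r}")
    if not df.empty:
        df["injection_order"] = pd.to_numeric(df["injection_order"]).astype(int)
        df["dilution_factor"] = pd.to_numeric(df["dilution_factor"]).astype(float)
        df["sample_id"] = df["sample_id"].astype(str)
        df["batch_id"] = df["batch_id"].astype(str)
    return SampleSheet(df)


def read_target_panel(path, delimiter: str = ",") -> TargetPanel:
    df = _read_csv(path, delimiter)
    for col in ("name", "analyte_class", "is_name", "conc_is"):
        if col not in df.columns:
            raise SchemaError(f"target panel is missing required column {col!r}")
    df["conc_is"] = pd.to_numeric(df["conc_is"]).astype(float)
    for col in ("n_carbons", "n_double_bonds", "monoisotopic_mass"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return TargetPanel(df)


def read_area_matrix(path, delimiter: str = ",") -> AreaMatrix:
    df = _read_csv(path, delimiter)
    if df.columns[0] != "sample_id":
        raise SchemaError("area matrix must have 'sample_id' as its first column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return AreaMatrix(df.astype(float))


def read_feature_table(path, sample_ids: list[str], delimiter: str = ",") -> FeatureTable:
    """Read a feature table (one row per feature).

    Feature ids are synthesized as ``mz@rt`` when the file has no
    ``feature_id`` column. Empty intensity cells stay missing, never zero.
    """
    df = _read_csv(path, delimiter)
    for col in ("mz", "rt"):
        if col not in df.columns:
            raise SchemaError(f"feature table is missing column {col!r}")
    missing = [s for s in sample_ids if s not in df.columns]
    if missing:
        raise SchemaError(f"sample ids absent from feature-table header: {missing}")
    for col in ("mz", "rt"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ParseError(
                f"non-numeric {col} at data row(s) {list(df.index[bad])}"
            )
        df[col] = coerced.astype(float)
    if "feature_id" in df.columns:
        df = df.set_index("feature_id")
    else:
        df.index = pd.Index(
            [feature_id_for(m, r) for m, r in zip(df["mz"], df["rt"])],
            name="feature_id",
        )
    for s in sample_ids:
        df[s] = pd.to_numeric(df[s]).astype(float)
    if "mzcloud_score" in df.columns:
        df["mzcloud_score"] = pd.to_numeric(df["mzcloud_score"]).astype(float)
    if "library_hits" in df.columns:
        df["library_hits"] = df["library_hits"].astype(object).where(
            df["library_hits"].notna(), None
        )
    return FeatureTable(df, sample_ids=list(sample_ids))


def read_report(path, delimiter: str = ",") -> pd.DataFrame:
    return _read_csv(path, delimiter)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _to_frame(report) -> pd.DataFrame:
    if isinstance(report, pd.DataFrame):
        return report
    if hasattr(report, "to_frame"):
        return report.to_frame()
    if hasattr(report, "frame"):
        return report.frame
    raise TypeError(f"cannot serialise object of type {type(report).__name__}")


def write_report(report, path, delimiter: str = ",", index: bool = False) -> None:
    """Write any report deterministically: sorted rows, fixed columns.

    Rows are sorted by every non-numeric (identifier) column, left to
    right; floats carry 9 significant digits; re-reading reproduces the
    values bit-for-bit at that precision. Writing twice gives
    byte-identical files.
    """
    df = _to_frame(report)
    if df.empty and df.columns.empty:
        raise ValidationError("refusing to write an empty report")
    key_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if key_cols:
        df = df.sort_values(key_cols, kind="mergesort")
    df.to_csv(path, sep=delimiter, na_rep="", float_format=_FLOAT_FMT, index=index)


def write_sample_sheet(sheet: SampleSheet, path, delimiter: str = ",") -> None:
    sheet.frame.to_csv(path, sep=delimiter, na_rep="", float_format=_FLOAT_FMT, index=False)


def write_area_matrix(matrix: AreaMatrix, path, delimiter: str = ",") -> None:
    matrix.frame.to_csv(
        path, sep=delimiter, na_rep="", float_format=_FLOAT_FMT, index_label="sample_id"
    )


def write_feature_table(table: FeatureTable, path, delimiter: str = ",") -> None:
    table.frame.to_csv(
        path, sep=delimiter, na_rep="", float_format=_FLOAT_FMT, index_label="feature_id"
    )


def convert_xlsx(xlsx_path, out_path, sheet_name=0, delimiter: str = ",") -> None:
    """One-way conversion of a supplementary xlsx sheet to delimited text."""
    df = pd.read_excel(xlsx_path, sheet_name=sheet_name)
    df.to_csv(out_path, sep=delimiter, na_rep="", float_format=_FLOAT_FMT, index=False)


def load_config(path) -> dict:
    """YAML config (dialect, tolerance defaults); empty file -> {}."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
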