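"""QC-anchored signal-drift and batch correction with an RSD benchmark.

Electrospray response drifts with injection order and jumps between
extraction/analytical batches. Pooled technical-replicate QC injections
(role ``qc_train``) interleaved through the sequence expose the drift;
extraction-replicate QCs (``qc_test``) score how well a correction
generalises. Four base corrections and their combinations are supported:

* ``none`` — passthrough reference,
* ``is_norm`` — divide by the internal-standard signal in the same
  injection, rescaled by the IS grand mean to stay on the raw scale,
* ``linear_sequence`` — per-feature OLS of QC_train intensity on
  injection order; samples are divided by the fitted trend and
  re-anchored at the mean fitted QC level,
* ``batch_anchor`` — within-batch linear sequence correction followed by
  between-batch rescaling so every feature's QC_train mean agrees across
  batches (a QC-anchored stand-in occupying the external batch-tool slot
  of the seven-way comparison).

All corrections are multiplicative (ratio to trend), never subtractive:
drift acts proportionally on ESI signals and corrected intensities must
stay non-negative. Strategies are scored by per-feature RSD over
QC_train and QC_test and the counts of features under 15% / 30% RSD.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .precision_compare import rsd
from .tables_io import AreaMatrix, FeatureTable, SampleSheet

STEPS = ("none", "is_norm", "linear_sequence", "batch_anchor")


def _as_matrix(table) -> pd.DataFrame:
    """Samples x features float frame from any supported container."""
    if isinstance(table, pd.DataFrame):
        return table.astype(float)
    if isinstance(table, AreaMatrix):
        return table.frame.astype(float)
    if isinstance(table, FeatureTable):
        return table.intensities()
    raise TypeError(f"unsupported table type {type(table).__name__}")


@dataclass(frozen=True)
class DriftModel:
    """Per-feature linear trend over injection order, fit on QC_train."""

    slope: float
    intercept: float
    anchor: float  # mean fitted QC level; the level correction re-anchors to
    n_qc_used: int
    fit_ok: bool

    def __post_init__(self) -> None:
        if self.fit_ok and self.n_qc_used < 2:
            raise ValidationError("fit_ok requires >= 2 QC points")
        if self.fit_ok and not self.anchor > 0:
            raise ValidationError("fit_ok requires a positive anchor")

    def trend(self, order) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(order, dtype=float)


@dataclass(frozen=True)
class CorrectionStrategy:
    """An ordered pipeline of correction steps with a display label."""

    steps: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("strategy needs at least one step")
        unknown = set(self.steps) - set(STEPS)
        if unknown:
            raise ValidationError(f"unknown steps: {sorted(unknown)}")
        if len(set(self.steps)) != len(self.steps):
            raise ValidationError("strategy repeats a step")
        if not self.label:
            object.__setattr__(self, "label", "+".join(self.steps))


def default_strategies() -> list[CorrectionStrategy]:
    """The seven-way comparison: four base methods, three combinations."""
    combos = [
        ("none",),
        ("is_norm",),
        ("linear_sequence",),
        ("batch_anchor",),
        ("is_norm", "linear_sequence"),
        ("is_norm", "batch_anchor"),
        ("linear_sequence", "batch_anchor"),
    ]
    return [CorrectionStrategy(steps) for steps in combos]


# ---------------------------------------------------------------------------
# base corrections
# ---------------------------------------------------------------------------


def is_normalize(table, is_map: dict[str, str]):
    """Divide each feature by its IS in the same injection.

    The ratio is rescaled by the IS grand mean so corrected values stay
    on the original intensity scale. Injections where the IS is missing
    or non-positive get missing corrected values and a warning.
    """
    mat = _as_matrix(table)
    out = mat.copy()
    warned: set[str] = set()
    for feat, is_feat in is_map.items():
        if feat not in mat.columns:
            continue
        if is_feat not in mat.columns:
            raise ConfigurationError(f"IS feature {is_feat!r} absent from table")
        is_col = mat[is_feat]
        ok = is_col.notna() & (is_col > 0)
        grand = float(is_col[ok].mean()) if ok.any() else np.nan
        corrected = mat[feat] / is_col * grand
        corrected[~ok] = np.nan
        out[feat] = corrected
        for sid in mat.index[~ok]:
            if sid not in warned:
                _warnings.warn(
                    f"IS {is_feat!r} missing/zero in sample {sid!r}; "
                    "corrected values set missing"
                )
                warned.add(str(sid))
    return out


def fit_linear_sequence(qc_values, orders) -> DriftModel:
    """OLS of one feature's QC_train intensity on injection order."""
    y = np.asarray(qc_values, dtype=float)
    x = np.asarray(orders, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    n = len(y)
    if n < 2:
        return DriftModel(0.0, 0.0, 0.0, n, fit_ok=False)
    design = np.column_stack([np.ones(n), x])
    (b0, b1), *_ = np.linalg.lstsq(design, y, rcond=None)
    anchor = float(b0 + b1 * x.mean())
    if not anchor > 0:
        return DriftModel(float(b1), float(b0), anchor, n, fit_ok=False)
    return DriftModel(float(b1), float(b0), anchor, n, fit_ok=True)


def fit_linear_sequence_all(
    table, sheet: SampleSheet, batch: str | None = None
) -> dict[str, DriftModel]:
    """Fit a DriftModel per feature on the sheet's QC_train injections."""
    mat = _as_matrix(table)
    meta = sheet.frame
    mask = meta["role"] == "qc_train"
    if batch is not None:
        mask &= meta["batch_id"] == batch
    qc_ids = [s for s in meta.loc[mask, "sample_id"] if s in mat.index]
    orders = meta.set_index("sample_id").loc[qc_ids, "injection_order"].to_numpy()
    return {
        feat: fit_linear_sequence(mat.loc[qc_ids, feat].to_numpy(), orders)
        for feat in mat.columns
    }


def apply_drift(table, models: dict[str, DriftModel], sheet: SampleSheet):
    """Divide by the fitted trend, re-anchored at the mean QC level.

    corrected(s) = raw(s) * anchor / (intercept + slope * order(s)).
    Injections where the fitted trend is non-positive become missing
    (with a warning); features whose fit failed pass through unchanged.
    """
    mat = _as_matrix(table)
    order = (
        sheet.frame.set_index("sample_id")["injection_order"]
        .reindex(mat.index)
        .to_numpy(dtype=float)
    )
    out = mat.copy()
    for feat, model in models.items():
        if feat not in mat.columns or not model.fit_ok:
            continue
        trend = model.trend(order)
        bad = trend <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = mat[feat].to_numpy() * model.anchor / trend
        if bad.any():
            vals[bad] = np.nan
            _warnings.warn(
                f"fitted trend non-positive for feature {feat!r} in "
                f"{int(bad.sum())} injection(s); values set missing"
            )
        out[feat] = vals
    return out


def linear_sequence_correct(table, sheet: SampleSheet, per_batch: bool = True):
    """Fit-and-apply linear sequence correction (per batch by default)."""
    mat = _as_matrix(table)
    if not per_batch:
        return apply_drift(mat, fit_linear_sequence_all(mat, sheet), sheet)
    meta = sheet.frame.set_index("sample_id")
    out = mat.copy()
    for batch in sheet.batches:
        ids = [s for s in meta.index[meta["batch_id"] == batch] if s in mat.index]
        if not ids:
            continue
        sub_sheet = SampleSheet(sheet.frame[sheet.frame["batch_id"] == batch])
        models = fit_linear_sequence_all(mat.loc[ids], sub_sheet, batch=batch)
        out.loc[ids] = apply_drift(mat.loc[ids], models, sub_sheet)
    return out


def batch_anchor_correct(table, sheet: SampleSheet):
    """Within-batch linear sequence correction + between-batch anchoring.

    Stage two rescales each feature per batch so its QC_train mean is
    the same in every batch (the grand QC_train mean). Features lacking
    >= 2 usable QC_train injections in a batch are left unscaled there
    and reported back as uncorrectable.
    """
    mat = linear_sequence_correct(table, sheet, per_batch=True)
    meta = sheet.frame.set_index("sample_id")
    qc_ids = [s for s in sheet.ids_with_role("qc_train") if s in mat.index]
    uncorrectable: list[tuple[str, str]] = []
    out = mat.copy()
    grand = mat.loc[qc_ids].mean(axis=0, skipna=True)
    for batch in sheet.batches:
        batch_ids = [s for s in meta.index[meta["batch_id"] == batch] if s in mat.index]
        batch_qc = [s for s in qc_ids if meta.at[s, "batch_id"] == batch]
        for feat in mat.columns:
            vals = mat.loc[batch_qc, feat] if batch_qc else pd.Series(dtype=float)
            n_ok = int(vals.notna().sum())
            m = float(vals.mean()) if n_ok else np.nan
            if n_ok < 2 or not np.isfinite(m) or m <= 0:
                uncorrectable.append((feat, batch))
                continue
            out.loc[batch_ids, feat] = mat.loc[batch_ids, feat] * (grand[feat] / m)
    return out, uncorrectable


# ---------------------------------------------------------------------------
# strategies and benchmark
# ---------------------------------------------------------------------------


@dataclass
class CorrectedTable:
    """A corrected table plus provenance of the applied steps."""

    table: pd.DataFrame
    steps_applied: tuple[str, ...]
    warnings: list = field(default_factory=list)


def run_strategy(
    table,
    sheet: SampleSheet,
    strategy: CorrectionStrategy,
    is_map: dict[str, str] | None = None,
) -> CorrectedTable:
    """Apply the strategy's steps in order; validate applicability first."""
    if "is_norm" in strategy.steps and not is_map:
        raise ConfigurationError(
            f"strategy {strategy.label!r} includes is_norm but no IS map was given"
        )
    mat = _as_matrix(table)
    notes: list = []
    for step in strategy.steps:
        if step == "none":
            continue
        elif step == "is_norm":
            mat = is_normalize(mat, is_map)
        elif step == "linear_sequence":
            mat = linear_sequence_correct(mat, sheet, per_batch=True)
        elif step == "batch_anchor":
            mat, bad = batch_anchor_correct(mat, sheet)
            notes.extend(bad)
    return CorrectedTable(mat, strategy.steps, notes)


@dataclass
class CorrectionBenchmark:
    """Per-strategy RSD tables and threshold counts on both QC sets.

    ``summary`` columns: strategy, qc_set, n_lt_15, n_lt_30, n_total,
    evaluable. ``rsd_tables[(label, qc_set)]`` holds the per-feature RSD
    series behind each summary row.
    """

    summary: pd.DataFrame
    rsd_tables: dict[tuple[str, str], pd.Series]

    def to_frame(self) -> pd.DataFrame:
        return self.summary

    def winner(self, qc_set: str, threshold: int = 30) -> str:
        col = f"n_lt_{threshold}"
        sub = self.summary[self.summary["qc_set"] == qc_set]
        return str(sub.loc[sub[col].idxmax(), "strategy"])

    def metabolite_rsds(self, names: list[str], qc_set: str) -> pd.DataFrame:
        rows = {
            label: series.reindex(names)
            for (label, qs), series in self.rsd_tables.items()
            if qs == qc_set
        }
        return pd.DataFrame(rows)


def qc_rsds(table, sheet: SampleSheet, role: str) -> pd.Series:
    """Per-feature RSD (%) over the injections with the given QC role."""
    mat = _as_matrix(table)
    ids = [s for s in sheet.ids_with_role(role) if s in mat.index]
    sub = mat.loc[ids]
    return sub.apply(lambda col: rsd(col.dropna().to_numpy()), axis=0)


def benchmark_strategies(
    table,
    sheet: SampleSheet,
    strategies: list[CorrectionStrategy] | None = None,
    is_map: dict[str, str] | None = None,
) -> CorrectionBenchmark:
    """Score each strategy by QC_train / QC_test RSD threshold counts."""
    strategies = strategies if strategies is not None else default_strategies()
    for role in ("qc_train", "qc_test"):
        if not sheet.ids_with_role(role):
            raise ConfigurationError(f"benchmark needs {role} samples in the sheet")
    rows = []
    tables: dict[tuple[str, str], pd.Series] = {}
    for strat in strategies:
        corrected = run_strategy(table, sheet, strat, is_map=is_map)
        for role in ("qc_train", "qc_test"):
            ids = [s for s in sheet.ids_with_role(role)]
            evaluable = len(ids) >= 2
            series = qc_rsds(corrected.table, sheet, role)
            tables[(strat.label, role)] = series
            finite = series.dropna()
            rows.append(
                {
                    "strategy": strat.label,
                    "qc_set": role,
                    "n_lt_15": int((finite < 15.0).sum()) if evaluable else 0,
                    "n_lt_30": int((finite < 30.0).sum()) if evaluable else 0,
                    "n_total": int(series.size),
                    "evaluable": evaluable,
                }
            )
    summary = pd.DataFrame(rows)
    bad = summary["n_lt_15"] > summary["n_lt_30"]
    if bad.any():  # impossible by construction; guard the invariant anyway
        raise ValidationError("n_lt_15 exceeded n_lt_30")
    return CorrectionBenchmark(summary, tables)
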