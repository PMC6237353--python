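"""Synthetic fixtures with the statistical structure every stage assumes.

Every generator is deterministic under its seed and returns, next to the
tables themselves, a truth table holding the generating parameters so
tests can assert exact parameter recovery. Noise is multiplicative
lognormal throughout: electrospray intensity noise scales with signal
and signals stay positive.

What is emulated (and what is not): replicate concentration measurements
with proportional noise; lipid-class panels whose M+2 isotope tail
bleeds into the one-fewer-double-bond neighbour; feature tables with
linear injection-order drift, multiplicative batch offsets and a pooled
QC every 10th injection; annotation tables with match scores and
library-hit flags. Not emulated: raw spectra, peak shapes, retention
behaviour, missingness mechanisms or inter-feature correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .isotope_decon import LipidSpecies, overlap_matrix
from .tables_io import LIBRARIES, AreaMatrix, FeatureTable, SampleSheet, TargetPanel

#: 11-level calibration span, µM (346.3 pM to 161.2 µM).
DEFAULT_CAL_RANGE = (3.463e-4, 161.2)


@dataclass(frozen=True)
class DriftSpec:
    """Generative settings for a drifting non-target run.

    ``slope_range`` is the maximum |drift| accumulated over the whole
    sequence, as a fraction of the feature mean (0.3 = up to +/-30% by
    the last injection); per-injection slopes are drawn uniformly and
    scaled down by the sequence length. ``batch_offsets`` multiply whole
    batches; the QC cadence defaults to every 10th injection.
    """

    kind: str = "linear"  # linear | none
    slope_range: float = 0.3
    batch_offsets: tuple[float, ...] = (1.0,)
    noise_cv: float = 0.05
    qc_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "none"):
            raise ValidationError("drift kind must be 'linear' or 'none'")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.qc_every < 2:
            raise ValidationError("qc_every must be >= 2")
        if not self.batch_offsets:
            raise ValidationError("need at least one batch offset")


@dataclass
class TruthTable:
    """Generating parameters, kept for parameter-recovery tests."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __getitem__(self, key: str) -> pd.DataFrame:
        return self.tables[key]

    def __setitem__(self, key: str, value: pd.DataFrame) -> None:
        self.tables[key] = value

    def __contains__(self, key: str) -> bool:
        return key in self.tables


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# targeted run
# ---------------------------------------------------------------------------


def make_targeted_run(
    panel: TargetPanel,
    truth_concs: dict[str, float],
    noise_cv: float = 0.05,
    n_cal_levels: int = 11,
    n_replicates: int = 12,
    n_blanks: int = 3,
    seed: int = 0,
    cal_range: tuple[float, float] = DEFAULT_CAL_RANGE,
    dilution_factor: float = 1.0,
    blank_conc: float = 0.0,
) -> tuple[AreaMatrix, SampleSheet, TruthTable]:
    """Simulate an MRM acquisition of the panel.

    Per-analyte response factors map concentration to area linearly;
    analyte and IS areas get independent lognormal noise. Calibration
    standards sit on a geometric ladder over ``cal_range``, replicates
    carry ``truth_concs``, blanks sit at ``blank_conc``. With zero noise
    the IS quantification pipeline returns the truth exactly.
    """
    rng = np.random.default_rng(seed)
    analytes = [n for n in panel.names if n in truth_concs]
    if not analytes:
        raise ValidationError("no panel analyte has a truth concentration")
    is_names = sorted({str(panel.analyte(a)["is_name"]) for a in analytes})
    levels = np.geomspace(cal_range[0], cal_range[1], n_cal_levels)
    rf = {a: float(rng.uniform(5e4, 5e5)) for a in analytes}
    is_area = {s: float(rng.uniform(1e5, 1e6)) for s in is_names}

    rows = []  # (sample_id, role, replicate_group, conc per analyte)
    for i, level in enumerate(levels, start=1):
        rows.append((f"cal_{i:02d}", "cal_standard", f"cal_{i:02d}", {a: level for a in analytes}))
    for i in range(1, n_blanks + 1):
        rows.append((f"blank_{i:02d}", "blank", "blanks", {a: blank_conc for a in analytes}))
    for i in range(1, n_replicates + 1):
        rows.append((f"rep_{i:02d}", "sample", f"rep_{i:02d}", dict(truth_concs)))

    sheet_rows = []
    area_rows = {}
    for order, (sid, role, group, concs) in enumerate(rows, start=1):
        sheet_rows.append(
            {
                "sample_id": sid,
                "role": role,
                "injection_order": order,
                "batch_id": "B1",
                "tissue": "plasma",
                "replicate_group": group,
                "dilution_factor": dilution_factor,
            }
        )
        areas = {}
        for a in analytes:
            row = panel.analyte(a)
            is_name = str(row["is_name"])
            conc_is = float(row["conc_is"])
            a_is = is_area[is_name]
            # area chosen so Eq-style IS quantification returns truth
            noiseless = concs[a] * a_is / (conc_is * dilution_factor)
            areas[a] = noiseless * float(_lognormal_factor(rng, noise_cv, None))
        for s in is_names:
            areas[s] = is_area[s] * float(_lognormal_factor(rng, noise_cv, None))
        area_rows[sid] = areas

    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    frame = pd.DataFrame.from_dict(area_rows, orient="index")
    frame.index.name = "sample_id"
    matrix = AreaMatrix(frame[analytes + is_names].astype(float))

    truth = TruthTable()
    truth["concs"] = pd.DataFrame(
        {"analyte": analytes, "true_conc": [truth_concs[a] for a in analytes],
         "response_factor": [rf[a] for a in analytes]}
    )
    truth["cal_levels"] = pd.DataFrame({"level": np.arange(1, n_cal_levels + 1), "conc": levels})
    truth["is_areas"] = pd.DataFrame(
        {"is_name": is_names, "area": [is_area[s] for s in is_names]}
    )
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# lipid series with isotope overlap
# ---------------------------------------------------------------------------


def make_lipid_run(
    class_series: list[LipidSpecies],
    truth_areas,
    with_overlap: bool = True,
    seed: int = 0,
    noise_cv: float = 0.0,
    n_samples: int = 1,
) -> AreaMatrix:
    """Forward-simulate observed areas for one class/carbon series.

    ``class_series`` must be in canonical order (descending double
    bonds); observed = M @ truth with the binomial overlap matrix when
    ``with_overlap``, else truth itself, times optional lognormal noise.
    """
    rng = np.random.default_rng(seed)
    truth = np.asarray(truth_areas, dtype=float)
    if truth.shape[0] != len(class_series):
        raise ValidationError("truth_areas length must match the series")
    mat = overlap_matrix(class_series)
    observed = mat @ truth if with_overlap else truth.copy()
    names = [s.name for s in class_series]
    data = np.vstack(
        [observed * _lognormal_factor(rng, noise_cv, len(names)) for _ in range(n_samples)]
    )
    frame = pd.DataFrame(data, columns=names, index=[f"s{i+1:02d}" for i in range(n_samples)])
    frame.index.name = "sample_id"
    return AreaMatrix(frame)


# ---------------------------------------------------------------------------
# drifting feature table
# ---------------------------------------------------------------------------


def make_drift_table(
    n_features: int,
    n_samples: int,
    spec: DriftSpec,
    include_is: bool = False,
) -> tuple[FeatureTable, SampleSheet, TruthTable]:
    """Simulate a non-target sequence with drift, batches and QCs.

    Study samples are split evenly over ``len(spec.batch_offsets)``
    batches. Within each batch a pooled QC_train is injected every
    ``spec.qc_every``-th injection and a QC_test (extraction-replicate
    pool) at the half-cadence offset. Each feature f follows

        intensity = (base_f + slope_f * order) * offset_batch * noise

    with slope_f drawn so the accumulated drift over the sequence is
    uniform in +/- ``slope_range`` of base_f. With ``include_is`` an IS
    feature sharing each injection's drift factor is appended (name
    ``IS_1``), so IS normalisation can cancel the drift.
    """
    rng = np.random.default_rng(spec.seed)
    n_batches = len(spec.batch_offsets)
    base = rng.lognormal(mean=np.log(1e6), sigma=0.4, size=n_features)
    frac = (
        rng.uniform(-spec.slope_range, spec.slope_range, size=n_features)
        if spec.kind == "linear"
        else np.zeros(n_features)
    )

    # build the injection sequence batch by batch
    per_batch = int(np.ceil(n_samples / n_batches))
    sheet_rows = []
    order = 0
    for b in range(n_batches):
        batch_id = f"B{b+1}"
        n_in_batch = min(per_batch, n_samples - b * per_batch)
        placed = qc_i = qt_i = 0
        pos_in_batch = 0
        while placed < n_in_batch:
            pos_in_batch += 1
            order += 1
            half = spec.qc_every // 2
            if pos_in_batch % spec.qc_every == 1:  # leading + every 10th
                qc_i += 1
                sheet_rows.append((f"{batch_id}_qc_train_{qc_i:02d}", "qc_train", order, batch_id, "qc_pool"))
            elif pos_in_batch % spec.qc_every == (half + 1) % spec.qc_every:
                qt_i += 1
                sheet_rows.append((f"{batch_id}_qc_test_{qt_i:02d}", "qc_test", order, batch_id, "qc_test_pool"))
            else:
                placed += 1
                sheet_rows.append((f"{batch_id}_s{placed:03d}", "sample", order, batch_id, f"{batch_id}_s{placed:03d}"))
        # trailing QCs so every batch ends anchored
        order += 1
        qc_i += 1
        sheet_rows.append((f"{batch_id}_qc_train_{qc_i:02d}", "qc_train", order, batch_id, "qc_pool"))
        order += 1
        qt_i += 1
        sheet_rows.append((f"{batch_id}_qc_test_{qt_i:02d}", "qc_test", order, batch_id, "qc_test_pool"))

    sheet = SampleSheet(
        pd.DataFrame(
            [
                {
                    "sample_id": sid,
                    "role": role,
                    "injection_order": order,
                    "batch_id": batch,
                    "tissue": "plasma",
                    "replicate_group": group,
                    "dilution_factor": 1.0,
                }
                for sid, role, order, batch, group in sheet_rows
            ]
        )
    )

    n_inj = len(sheet_rows)
    orders = sheet.frame["injection_order"].to_numpy(dtype=float)
    batch_idx = sheet.frame["batch_id"].str.slice(1).astype(int).to_numpy() - 1
    offsets = np.asarray(spec.batch_offsets, dtype=float)[batch_idx]
    slope = frac * base / n_inj  # per-injection slope
    trend = base[None, :] + slope[None, :] * orders[:, None]  # inj x feat
    noise = _lognormal_factor(rng, spec.noise_cv, trend.shape)
    data = trend * offsets[:, None] * noise

    feat_names = [f"F{i+1:04d}" for i in range(n_features)]
    if include_is:
        # IS drifts with the average relative trend of the run, no extra noise
        rel = trend / base[None, :]
        is_col = 5e5 * rel.mean(axis=1) * offsets
        data = np.column_stack([data, is_col])
        feat_names = feat_names + ["IS_1"]

    sample_ids = [r[0] for r in sheet_rows]
    mz = rng.uniform(80.0, 1000.0, size=len(feat_names))
    rt = rng.uniform(0.5, 12.0, size=len(feat_names))
    frame = pd.DataFrame(data.T, index=feat_names, columns=sample_ids)
    frame.insert(0, "mz", mz)
    frame.insert(1, "rt", rt)
    frame.index.name = "feature_id"
    table = FeatureTable(frame, sample_ids=sample_ids)

    truth = TruthTable()
    truth["features"] = pd.DataFrame(
        {
            "feature_id": feat_names[:n_features],
            "base": base,
            "slope_per_injection": slope,
            "drift_fraction": frac,
        }
    )
    truth["batches"] = pd.DataFrame(
        {"batch_id": [f"B{b+1}" for b in range(n_batches)], "offset": spec.batch_offsets}
    )
    return table, sheet, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def make_annotations(
    n_features: int,
    p_high_score: float,
    p_library_hit: float,
    seed: int = 0,
) -> FeatureTable:
    """Annotated features for exercising the identification filter.

    A feature gets a score above 90 with probability ``p_high_score``
    (uniform on (90, 100]), otherwise uniform on [0, 90]; each of the
    six databases hits independently with probability ``p_library_hit``.
    The expected pass count of the default filter is therefore
    n * p_high_score * (1 - (1 - p_library_hit)^6).
    """
    if not (0 <= p_high_score <= 1 and 0 <= p_library_hit <= 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    high = rng.random(n_features) < p_high_score
    scores = np.where(
        high,
        90.0 + rng.uniform(np.nextafter(0, 1), 10.0, n_features),
        rng.uniform(0.0, 90.0, n_features),
    )
    hits = rng.random((n_features, len(LIBRARIES))) < p_library_hit
    hit_strings = [";".join(lib for lib, h in zip(LIBRARIES, row) if h) for row in hits]
    frame = pd.DataFrame(
        {
            "mz": rng.uniform(80.0, 1000.0, n_features),
            "rt": rng.uniform(0.5, 12.0, n_features),
            "s01": rng.lognormal(np.log(1e6), 0.4, n_features),
            "best_match_name": [f"compound_{i+1}" for i in range(n_features)],
            "mzcloud_score": scores,
            "library_hits": hit_strings,
        },
        index=pd.Index([f"F{i+1:05d}" for i in range(n_features)], name="feature_id"),
    )
    return FeatureTable(frame, sample_ids=["s01"])


def make_demo_panel(n_per_class: int = 3) -> TargetPanel:
    """A small mixed panel usable across examples and tests."""
    rows = []
    aa = ["alanine", "leucine", "valine", "serine", "glycine"][:n_per_class]
    for i, name in enumerate(aa):
        rows.append(
            {
                "name": name,
                "hmdb_id": "",
                "analyte_class": "amino_acid",
                "is_name": "met_13C_d3",
                "conc_is": 0.19,
                "monoisotopic_mass": [89.0477, 131.0946, 117.0790, 105.0426, 75.0320][i],
                "n_carbons": np.nan,
                "n_double_bonds": np.nan,
                "bond_code": "",
            }
        )
    for c, d in [(34, 2), (34, 1), (34, 0)][:n_per_class]:
        rows.append(
            {
                "name": f"PCaaC{c}:{d}",
                "hmdb_id": "",
                "analyte_class": "PC",
                "is_name": "PCaaC25:0",
                "conc_is": 0.21,
                "monoisotopic_mass": 14 * c - 2 * d + 285 + 0.59,
                "n_carbons": c,
                "n_double_bonds": d,
                "bond_code": "aa",
            }
        )
    rows.append(
        {
            "name": "met_13C_d3",
            "hmdb_id": "",
            "analyte_class": "other",
            "is_name": "met_13C_d3",
            "conc_is": 0.19,
            "monoisotopic_mass": np.nan,
            "n_carbons": np.nan,
            "n_double_bonds": np.nan,
            "bond_code": "",
        }
    )
    rows.append(
        {
            "name": "PCaaC25:0",
            "hmdb_id": "",
            "analyte_class": "PC",
            "is_name": "PCaaC25:0",
            "conc_is": 0.21,
            "monoisotopic_mass": 14 * 25 + 285 + 0.59,
            "n_carbons": 25,
            "n_double_bonds": 0,
            "bond_code": "aa",
        }
    )
    return TargetPanel(pd.DataFrame(rows))
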