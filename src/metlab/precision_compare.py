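"""Precision (RSD) and accuracy metrics, and the cross-platform comparison.

RSD is the field's precision currency: sample standard deviation (n-1
denominator, because replicate groups are small) over the absolute mean,
in percent. Three scopes are distinguished:

* technical — repeated injections of one extract (one replicate group),
* within_batch — spread across extraction replicates inside one batch,
* between_batch — spread of the per-batch mean levels.

Accuracy is measured against certified reference concentrations
(measured/reference x 100), with a configurable acceptance band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


def rsd(values) -> float:
    """Relative standard deviation in percent (sample SD / |mean| * 100).

    Returns NaN (not evaluable) for fewer than two finite values or a
    zero mean.
    """
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        return float("nan")
    mean = vals.mean()
    if mean == 0:
        return float("nan")
    return float(vals.std(ddof=1) / abs(mean) * 100.0)


@dataclass
class PrecisionReport:
    """Per-analyte RSDs at each replication scope.

    ``frame`` columns: analyte, scope, n, mean, rsd_pct.
    """

    frame: pd.DataFrame
    skipped: list[tuple[str, str]]  # (analyte, group) with n < 2

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def rsds(self, scope: str) -> pd.Series:
        sub = self.frame[self.frame["scope"] == scope]
        return sub.set_index("analyte")["rsd_pct"]


def precision_report(conc: pd.DataFrame, sheet) -> PrecisionReport:
    """Technical / within-batch / between-batch RSDs per analyte.

    ``conc`` is samples x analytes (concentrations or intensities); only
    rows whose sheet role is ``sample`` enter. Technical RSD is computed
    inside each replicate group and averaged across groups; within-batch
    RSD across the replicate-group means of one batch, averaged across
    batches; between-batch RSD across the per-batch means. Groups with
    fewer than two members are skipped and logged.
    """
    meta = sheet.frame.set_index("sample_id")
    ids = [s for s in conc.index if str(s) in meta.index and meta.at[str(s), "role"] == "sample"]
    if not ids:
        raise ValidationError("no rows with role 'sample' to report on")
    sub = conc.loc[ids]
    groups = meta.loc[[str(s) for s in ids], "replicate_group"]
    batches = meta.loc[[str(s) for s in ids], "batch_id"]

    rows = []
    skipped: list[tuple[str, str]] = []
    for analyte in sub.columns:
        vals = sub[analyte].astype(float)

        tech = []
        n_tech = 0
        for g, idx in groups.groupby(groups).groups.items():
            v = vals.loc[list(idx)].dropna()
            if len(v) < 2:
                skipped.append((analyte, f"replicate_group={g}"))
                continue
            tech.append(rsd(v))
            n_tech += len(v)
        if tech:
            rows.append(
                {
                    "analyte": analyte,
                    "scope": "technical",
                    "n": n_tech,
                    "mean": float(vals.mean()),
                    "rsd_pct": float(np.nanmean(tech)),
                }
            )

        within = []
        n_within = 0
        for b, idx in batches.groupby(batches).groups.items():
            v = vals.loc[list(idx)].dropna()
            group_means = v.groupby(groups.loc[v.index]).mean()
            if len(group_means) < 2:
                skipped.append((analyte, f"batch={b}"))
                continue
            within.append(rsd(group_means))
            n_within += len(group_means)
        if within:
            rows.append(
                {
                    "analyte": analyte,
                    "scope": "within_batch",
                    "n": n_within,
                    "mean": float(vals.mean()),
                    "rsd_pct": float(np.nanmean(within)),
                }
            )

        batch_means = vals.dropna().groupby(batches.loc[vals.dropna().index]).mean()
        if len(batch_means) >= 2:
            rows.append(
                {
                    "analyte": analyte,
                    "scope": "between_batch",
                    "n": len(batch_means),
                    "mean": float(vals.mean()),
                    "rsd_pct": rsd(batch_means),
                }
            )
        else:
            skipped.append((analyte, "between_batch"))

    return PrecisionReport(pd.DataFrame(rows), skipped)


@dataclass
class AccuracyReport:
    """Measured vs certified concentrations.

    ``frame`` columns: analyte, measured_mean, reference_value,
    reference_uncertainty, accuracy_pct, in_band.
    """

    frame: pd.DataFrame
    skipped: list[str]
    band: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return self.frame


def accuracy_vs_reference(
    measured: pd.Series,
    reference: pd.DataFrame,
    band: tuple[float, float] = (50.0, 150.0),
) -> AccuracyReport:
    """accuracy_pct = measured / certified x 100, with band flags.

    ``reference`` must carry ``reference_value`` (and optionally
    ``reference_uncertainty``, the certificate's expanded uncertainty),
    indexed by analyte. Band endpoints are inclusive. Analytes without a
    reference are skipped and listed.
    """
    if "reference_value" not in reference.columns:
        raise ValidationError("reference table needs a 'reference_value' column")
    if (reference["reference_value"] <= 0).any():
        raise ValidationError("reference values must be > 0")
    rows = []
    skipped = []
    for analyte, m in measured.items():
        if analyte not in reference.index:
            skipped.append(str(analyte))
            continue
        ref = reference.loc[analyte]
        acc = float(m) / float(ref["reference_value"]) * 100.0
        rows.append(
            {
                "analyte": analyte,
                "measured_mean": float(m),
                "reference_value": float(ref["reference_value"]),
                "reference_uncertainty": float(ref.get("reference_uncertainty", np.nan)),
                "accuracy_pct": acc,
                "in_band": bool(band[0] <= acc <= band[1]),
            }
        )
    return AccuracyReport(pd.DataFrame(rows), skipped, band)


@dataclass
class PlatformComparison:
    """Matched-compound RSD duel between targeted and non-targeted runs."""

    pairs: pd.DataFrame  # compound, feature, targeted_rsd, nontarget_rsd, winner
    n_matched: int
    n_targeted_better: int
    n_nontarget_better: int
    n_ties: int
    n_excluded: int
    mean_targeted_rsd: float
    mean_nontarget_rsd: float

    def to_frame(self) -> pd.DataFrame:
        return self.pairs


def compare_platforms(
    targeted_rsds,
    nontarget_rsds,
    mapping,
) -> PlatformComparison:
    """Per matched pair, the side with strictly lower RSD wins.

    ``mapping`` is a list of (compound, feature) pairs; a pair missing a
    finite RSD on either side is excluded (counted). Summary means are
    over included pairs only.
    """
    mapping = list(mapping)
    if not mapping:
        raise ValidationError("empty compound-feature mapping")
    t = pd.Series(dict(targeted_rsds), dtype=float)
    nt = pd.Series(dict(nontarget_rsds), dtype=float)
    rows = []
    n_excluded = 0
    for compound, feature in mapping:
        tv = t.get(compound, np.nan)
        nv = nt.get(feature, np.nan)
        if not (np.isfinite(tv) and np.isfinite(nv)):
            n_excluded += 1
            continue
        winner = "tie" if tv == nv else ("targeted" if tv < nv else "nontarget")
        rows.append(
            {
                "compound": compound,
                "feature": feature,
                "targeted_rsd": float(tv),
                "nontarget_rsd": float(nv),
                "winner": winner,
            }
        )
    pairs = pd.DataFrame(rows)
    n_matched = len(pairs)
    wins = pairs["winner"].value_counts() if n_matched else pd.Series(dtype=int)
    return PlatformComparison(
        pairs=pairs,
        n_matched=n_matched,
        n_targeted_better=int(wins.get("targeted", 0)),
        n_nontarget_better=int(wins.get("nontarget", 0)),
        n_ties=int(wins.get("tie", 0)),
        n_excluded=n_excluded,
        mean_targeted_rsd=float(pairs["targeted_rsd"].mean()) if n_matched else float("nan"),
        mean_nontarget_rsd=float(pairs["nontarget_rsd"].mean()) if n_matched else float("nan"),
    )


@dataclass
class FeatureCountSummary:
    """Feature yield per chromatography/polarity combination in a tissue."""

    frame: pd.DataFrame  # tissue, chromatography, polarity, n_features, pct_of_tissue_total
    tissue: str
    pos_vs_neg_pct: float  # sum(+) / sum(-) x 100 ("X% of")
    pos_vs_neg_more_pct: float  # ratio - 100 ("X% more")
    hilic_vs_c18_pct: float
    hilic_vs_c18_more_pct: float

    def to_frame(self) -> pd.DataFrame:
        return self.frame


def feature_count_summary(tables: dict, tissue: str) -> FeatureCountSummary:
    """Count features per (chromatography, polarity) and derive ratios.

    ``tables`` maps (chromatography, polarity) — e.g. ("HILIC", "+") —
    to a FeatureTable or a plain count. Percentages are of the tissue
    total; ratio metrics compare summed positive vs negative mode and
    HILIC vs C18. A zero denominator yields NaN (not evaluable).
    """
    if len(tables) < 2:
        raise ValidationError("need at least two tables to compare")
    counts = {}
    for key, tab in tables.items():
        chrom, pol = key
        counts[(str(chrom), str(pol))] = int(tab if isinstance(tab, (int, np.integer)) else len(tab))
    total = sum(counts.values())
    rows = [
        {
            "tissue": tissue,
            "chromatography": chrom,
            "polarity": pol,
            "n_features": n,
            "pct_of_tissue_total": (n / total * 100.0) if total else float("nan"),
        }
        for (chrom, pol), n in sorted(counts.items())
    ]

    def ratio(num: int, den: int) -> float:
        return num / den * 100.0 if den else float("nan")

    pos = sum(n for (c, p), n in counts.items() if p == "+")
    neg = sum(n for (c, p), n in counts.items() if p == "-")
    hilic = sum(n for (c, p), n in counts.items() if c.upper() == "HILIC")
    c18 = sum(n for (c, p), n in counts.items() if c.upper() == "C18")
    pvn = ratio(pos, neg)
    hvc = ratio(hilic, c18)
    return FeatureCountSummary(
        frame=pd.DataFrame(rows),
        tissue=tissue,
        pos_vs_neg_pct=pvn,
        pos_vs_neg_more_pct=pvn - 100.0 if np.isfinite(pvn) else float("nan"),
        hilic_vs_c18_pct=hvc,
        hilic_vs_c18_more_pct=hvc - 100.0 if np.isfinite(hvc) else float("nan"),
    )
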