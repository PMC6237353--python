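"""Annotation filtering and lipid fragment-parent matching for HRMS features.

Two decision rules sit here. The putative-identification filter accepts
a feature only when its spectral-library match score is strictly above
the threshold (default 90) AND at least ``min_libraries`` exact-mass
databases suggest the same identity — a level-2 putative identification.
The lipid flagger finds features matching a class-diagnostic fragment
m/z (e.g. the 184.0733 phosphocholine head group) and pairs them with
heavier co-eluting features as candidate parents, replacing manual
MS2-to-parent linking. Finally, a wide/narrow mass cross-check flags
targeted detections that only have HRMS support within a sloppy +/-0.5 Da
window — the signature of a targeted false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables_io import FeatureTable, TargetPanel

#: Mass of a proton; protonated mass = monoisotopic + this.
PROTON_MASS = 1.007276

#: Phosphocholine head-group fragment shared by PC, lysoPC and SM.
PC_HEADGROUP_MZ = 184.0733


@dataclass(frozen=True)
class FragmentCatalogEntry:
    """One class-diagnostic fragment ion."""

    lipid_class: str
    fragment_mz: float
    polarity: str = "+"

    def __post_init__(self) -> None:
        if self.fragment_mz <= 0:
            raise ValidationError("fragment m/z must be > 0")
        if self.polarity not in ("+", "-"):
            raise ValidationError("polarity must be '+' or '-'")


def default_fragment_catalog() -> list[FragmentCatalogEntry]:
    """The phosphocholine classes all share the m/z 184 head group."""
    return [
        FragmentCatalogEntry("PC", PC_HEADGROUP_MZ, "+"),
        FragmentCatalogEntry("lysoPC", PC_HEADGROUP_MZ, "+"),
        FragmentCatalogEntry("SM", PC_HEADGROUP_MZ, "+"),
    ]


@dataclass(frozen=True)
class LipidMatch:
    """A fragment feature paired with a candidate parent ion."""

    fragment_feature_id: str
    parent_feature_id: str
    rt_delta: float
    lipid_class: str
    parent_mz: float
    fragment_mz: float

    def __post_init__(self) -> None:
        if self.parent_mz <= self.fragment_mz:
            raise ValidationError("parent m/z must exceed fragment m/z")


@dataclass
class FilterResult:
    """Outcome of the putative-identification filter."""

    passing: FeatureTable
    n_pass: int
    n_fail: int
    n_unannotated: int


def putative_id_filter(
    features: FeatureTable,
    score_threshold: float = 90.0,
    min_libraries: int = 1,
) -> FilterResult:
    """Keep features with score > threshold and enough library support.

    The score comparison is strict (a score of exactly 90 fails the
    default filter). Features without any annotation fail and are
    tallied separately as unannotated.
    """
    n_pass = n_fail = n_unannotated = 0
    keep: list[str] = []
    for fid in features.feature_ids:
        ann = features.annotation(fid)
        if ann is None:
            n_unannotated += 1
            continue
        if ann.mzcloud_score > score_threshold and len(ann.library_hits) >= min_libraries:
            n_pass += 1
            keep.append(fid)
        else:
            n_fail += 1
    passing = FeatureTable(features.frame.loc[keep], sample_ids=list(features.sample_ids))
    return FilterResult(passing, n_pass, n_fail, n_unannotated)


def flag_lipid_parents(
    features: FeatureTable,
    catalog: list[FragmentCatalogEntry] | None = None,
    rt_tol: float = 0.05,
    mz_tol: float = 0.01,
) -> list[LipidMatch]:
    """Pair fragment-mass features with heavier co-eluting parents.

    A feature whose m/z lies within ``mz_tol`` of a catalog fragment is
    treated as that fragment; every feature with retention time within
    ``rt_tol`` minutes and m/z strictly above the fragment's m/z becomes
    a candidate parent. All (fragment, parent) pairs are emitted, sorted
    by |rt delta| then descending mean intensity then ids — never a
    silent best-only pick. Row order of the input is irrelevant.
    """
    if catalog is None:
        catalog = default_fragment_catalog()
    if not catalog or len(features) == 0:
        return []
    frame = features.frame
    mz = frame["mz"].to_numpy(dtype=float)
    rt = frame["rt"].to_numpy(dtype=float)
    if features.sample_ids:
        mean_int = frame[features.sample_ids].mean(axis=1).to_numpy(dtype=float)
    else:
        mean_int = np.zeros(len(frame))
    ids = np.asarray(features.feature_ids)

    matches: list[tuple] = []
    for entry in catalog:
        frag_idx = np.flatnonzero(np.abs(mz - entry.fragment_mz) <= mz_tol)
        for fi in frag_idx:
            parent_idx = np.flatnonzero(
                (np.abs(rt - rt[fi]) <= rt_tol) & (mz > entry.fragment_mz)
            )
            for pi in parent_idx:
                if pi == fi:
                    continue
                delta = float(rt[pi] - rt[fi])
                matches.append(
                    (
                        abs(delta),
                        -float(np.nan_to_num(mean_int[pi])),
                        str(ids[fi]),
                        str(ids[pi]),
                        LipidMatch(
                            fragment_feature_id=str(ids[fi]),
                            parent_feature_id=str(ids[pi]),
                            rt_delta=delta,
                            lipid_class=entry.lipid_class,
                            parent_mz=float(mz[pi]),
                            fragment_mz=float(entry.fragment_mz),
                        ),
                    )
                )
    matches.sort(key=lambda t: t[:4])
    return [m[-1] for m in matches]


def matches_to_frame(matches: list[LipidMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fragment_feature_id": m.fragment_feature_id,
                "parent_feature_id": m.parent_feature_id,
                "rt_delta": m.rt_delta,
                "lipid_class": m.lipid_class,
                "parent_mz": m.parent_mz,
                "fragment_mz": m.fragment_mz,
            }
            for m in matches
        ]
    )


def qqq_cross_check(
    targets: TargetPanel,
    features: FeatureTable,
    mass_tol: float = 0.005,
    wide_tol: float = 0.5,
) -> pd.DataFrame:
    """Confirm targeted detections against the high-resolution run.

    For each target with a monoisotopic mass, looks for a feature within
    ``mass_tol`` of the protonated mass (confirmed). A feature found
    only inside the wide ``wide_tol`` window marks a probable targeted
    false positive (wide_only); no feature in either window is absent.
    Positive-mode protonation is assumed.
    """
    if "monoisotopic_mass" not in targets.frame.columns:
        raise ValidationError("target panel lacks monoisotopic_mass")
    mz = features.frame["mz"].to_numpy(dtype=float) if len(features) else np.empty(0)
    rows = []
    for _, t in targets.frame.iterrows():
        mass = t["monoisotopic_mass"]
        if pd.isna(mass):
            continue
        mh = float(mass) + PROTON_MASS
        diffs = np.abs(mz - mh)
        if diffs.size and diffs.min() <= mass_tol:
            status = "confirmed"
            nearest = float(diffs.min())
        elif diffs.size and diffs.min() <= wide_tol:
            status = "wide_only"
            nearest = float(diffs.min())
        else:
            status = "absent"
            nearest = float(diffs.min()) if diffs.size else float("nan")
        rows.append(
            {
                "name": t["name"],
                "protonated_mass": mh,
                "status": status,
                "nearest_mass_error": nearest,
            }
        )
    return pd.DataFrame(rows)
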