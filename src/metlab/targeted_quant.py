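"""Calibration fitting, internal-standard quantification and detection limits.

The quantification rule is the classic IS ratio:

    conc_analyte = area_analyte / area_IS * conc_IS * dilution_factor

Calibration supports the two response models used on the triple
quadrupole: a straight line with 1/x^2 weighting (weights low standards
up so the low end of an 11-level, ~6-decade range is not swamped by the
top standards under proportional noise), and a quadratic fitted in
log10-log10 space for analytes with bending response. The correlation
coefficient r is Pearson's r between fitted and observed response on the
regression scale, since curve quality is judged on the scale the fit was
performed on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import (
    AmbiguousInversionError,
    FitError,
    InversionError,
    ValidationError,
)

KINDS = ("linear", "quadratic")
WEIGHTINGS = ("inv_x_squared", "log_log", "none")
_MIN_POINTS = {"linear": 5, "quadratic": 6}


def quantify_is(
    area_analyte: float,
    area_is: float,
    conc_is: float,
    dilution_factor: float,
    analyte: str = "",
    sample_id: str = "",
) -> float:
    """IS-ratio concentration in the same units as ``conc_is`` (µM)."""
    if area_is == 0:
        raise ZeroDivisionError(
            f"IS area is zero for analyte={analyte!r} sample={sample_id!r}"
        )
    if area_analyte < 0 or area_is < 0 or conc_is <= 0 or dilution_factor <= 0:
        raise ValidationError(
            "areas must be >= 0 and conc_is/dilution_factor > 0 "
            f"(analyte={analyte!r} sample={sample_id!r})"
        )
    return area_analyte / area_is * conc_is * dilution_factor


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted per-analyte response curve.

    ``coefficients`` are intercept-first on the regression scale: raw
    response for inv_x_squared/none weighting, log10(response) against
    log10(conc) for log_log.
    """

    analyte: str
    kind: str
    weighting: str
    coefficients: tuple[float, ...]
    r: float
    conc_range: tuple[float, float]
    response_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown curve kind {self.kind!r}")
        if self.weighting not in WEIGHTINGS:
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        want = 2 if self.kind == "linear" else 3
        if len(self.coefficients) != want:
            raise ValidationError(
                f"{self.kind} curve needs {want} coefficients, got "
                f"{len(self.coefficients)}"
            )
        if not self.conc_range[0] < self.conc_range[1]:
            raise ValidationError("calibration range must have min < max")
        if not np.isfinite(self.r):
            raise ValidationError("correlation coefficient not finite")

    def predict(self, conc) -> np.ndarray:
        """Forward model: expected response at the given concentration."""
        conc = np.asarray(conc, dtype=float)
        beta = np.asarray(self.coefficients)
        if self.weighting == "log_log":
            x = np.log10(conc)
            y = sum(b * x**k for k, b in enumerate(beta))
            return 10.0**y
        return sum(b * conc**k for k, b in enumerate(beta))


def fit_calibration(
    points,
    kind: str = "linear",
    weighting: str = "inv_x_squared",
    analyte: str = "",
) -> CalibrationModel:
    """Weighted least-squares calibration fit.

    ``points`` is a sequence of (concentration µM, response) pairs; at
    least 5 for a line, 6 for a quadratic. inv_x_squared solves WLS with
    weights 1/conc^2 on the raw scale; log_log fits the polynomial in
    log10-log10 space unweighted (the log transform is itself the
    variance stabiliser); none is plain OLS.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be (conc, response) pairs")
    conc, resp = pts[:, 0], pts[:, 1]
    if kind not in KINDS:
        raise ValidationError(f"unknown curve kind {kind!r}")
    if weighting not in WEIGHTINGS:
        raise ValidationError(f"unknown weighting {weighting!r}")
    need = _MIN_POINTS[kind]
    if len(pts) < need:
        raise FitError(f"{kind} calibration needs >= {need} points, got {len(pts)}")
    if weighting != "none" and np.any(conc <= 0):
        raise ValidationError("concentrations must be > 0 under weighted fits")
    if weighting == "log_log" and np.any(resp <= 0):
        raise ValidationError("responses must be > 0 under log-log fitting")

    degree = 1 if kind == "linear" else 2
    if weighting == "log_log":
        x, y = np.log10(conc), np.log10(resp)
        w = np.ones_like(x)
    else:
        x, y = conc, resp
        w = 1.0 / conc**2 if weighting == "inv_x_squared" else np.ones_like(x)

    design = np.vander(x, degree + 1, increasing=True)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    fitted = design @ beta
    # degenerate flat data: define r = 1 (perfect, trivially)
    if np.ptp(y) == 0 or np.ptp(fitted) == 0:
        r = 1.0 if np.allclose(fitted, y) else 0.0
    else:
        r = float(np.corrcoef(fitted, y)[0, 1])
    return CalibrationModel(
        analyte=analyte,
        kind=kind,
        weighting=weighting,
        coefficients=tuple(float(b) for b in beta),
        r=r,
        conc_range=(float(conc.min()), float(conc.max())),
        response_range=(float(resp.min()), float(resp.max())),
    )


@dataclass(frozen=True)
class InvertedConcentration:
    """Result of reading a concentration off a calibration curve."""

    conc: float
    below_range: bool = False
    extrapolated: bool = False

    @property
    def below_lod(self) -> bool:
        return self.below_range


def invert_calibration(
    response: float,
    model: CalibrationModel,
    dilution_factor: float = 1.0,
) -> InvertedConcentration:
    """Map a response back to concentration through the fitted curve.

    Linear raw-scale curves invert algebraically; everything else is
    bracketed bisection (Brent) on the forward model across the fitted
    concentration range, which is robust on the monotone segments a
    usable calibration has. A response below the curve's bottom end is
    reported as conc 0 with below_range set (the below-LOD convention);
    a response above the top end is extrapolated through the linear
    model, flagged. Two in-range roots raise rather than guess.
    """
    if dilution_factor <= 0:
        raise ValidationError("dilution_factor must be > 0")
    lo, hi = model.conc_range
    ascending = model.predict(hi) >= model.predict(lo)
    f_lo = float(model.predict(lo))
    f_hi = float(model.predict(hi))
    bottom, top = (f_lo, f_hi) if ascending else (f_hi, f_lo)

    if response < bottom:
        return InvertedConcentration(0.0, below_range=True)

    if model.kind == "linear" and model.weighting != "log_log":
        b0, b1 = model.coefficients
        if b1 == 0:
            raise InversionError(f"flat calibration for {model.analyte!r}")
        conc = (response - b0) / b1
        return InvertedConcentration(
            conc * dilution_factor, extrapolated=response > top
        )

    # grid-scan the forward model for sign changes, then Brent per bracket
    grid = (
        np.geomspace(lo, hi, 1025)
        if model.weighting == "log_log" or lo > 0
        else np.linspace(lo, hi, 1025)
    )
    vals = np.asarray(model.predict(grid)) - response
    exact = np.flatnonzero(vals == 0.0)
    roots = [float(grid[i]) for i in exact]
    sign = np.sign(vals)
    flips = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    for i in flips:
        roots.append(
            float(
                brentq(
                    lambda c: float(model.predict(c)) - response,
                    grid[i],
                    grid[i + 1],
                    xtol=1e-15,
                    rtol=1e-14,
                )
            )
        )
    roots = sorted(set(np.round(roots, 12)))
    if len(roots) > 1:
        raise AmbiguousInversionError(
            f"{len(roots)} calibration roots in range for {model.analyte!r}: {roots}"
        )
    if not roots:
        if response > top:
            raise InversionError(
                f"response {response} above calibrated range for {model.analyte!r} "
                "and curve not invertible beyond it"
            )
        raise InversionError(
            f"no calibration root for response {response} ({model.analyte!r})"
        )
    return InvertedConcentration(roots[0] * dilution_factor)


def blank_lod(blank_concs) -> tuple[float, float]:
    """Detection and quantification limit: 10x the mean blank level.

    The flow-injection convention: LOD = LOQ = 10 * mean(blank
    concentrations); all-zero blanks give 0.
    """
    vals = np.asarray(list(blank_concs), dtype=float)
    if vals.size == 0:
        raise ValidationError("blank_lod needs at least one blank value")
    if np.any(vals < 0):
        raise ValidationError("blank concentrations must be >= 0")
    lod = 10.0 * float(vals.mean())
    return lod, lod


def sn_lod(lowest_std_conc: float, snr: float) -> float:
    """S/N-based detection limit for the chromatographic workflow.

    LOD = 3 * (lowest measurable standard concentration / its S/N): the
    concentration at which the analyte would reach S/N = 3.
    """
    if lowest_std_conc <= 0 or snr <= 0:
        raise ValidationError("concentration and S/N must be > 0")
    return 3.0 * lowest_std_conc / snr


@dataclass(frozen=True)
class QuantResult:
    """One quantified analyte in one sample."""

    analyte: str
    sample_id: str
    conc: float
    below_lod: bool
    lod: float

    def __post_init__(self) -> None:
        if self.conc < 0 and not self.below_lod:
            raise ValidationError("negative concentration not flagged below LOD")
        if self.lod < 0:
            raise ValidationError("LOD must be >= 0")


def quantify_run(areas, panel, sheet, lods: dict[str, float] | None = None):
    """Eq-style IS quantification of a whole run.

    For every analyte in ``panel`` with its IS column present in
    ``areas``, computes conc = area/area_IS * conc_IS * dilution per
    sample. Returns a samples x analytes concentration DataFrame plus a
    list of :class:`QuantResult` (flagged against ``lods`` when given).
    Below-LOD values are kept numeric and flagged, never censored.
    """
    import pandas as pd

    lods = lods or {}
    frame = areas.frame
    out = pd.DataFrame(index=frame.index, dtype=float)
    results: list[QuantResult] = []
    for name in panel.names:
        if name not in frame.columns:
            continue
        row = panel.analyte(name)
        is_name = row["is_name"]
        if is_name not in frame.columns:
            raise ValidationError(f"IS column {is_name!r} missing for {name!r}")
        conc_is = float(row["conc_is"])
        concs = []
        for sid in frame.index:
            dilution = float(sheet.row(str(sid))["dilution_factor"])
            conc = quantify_is(
                float(frame.at[sid, name]),
                float(frame.at[sid, is_name]),
                conc_is,
                dilution,
                analyte=name,
                sample_id=str(sid),
            )
            lod = float(lods.get(name, 0.0))
            results.append(
                QuantResult(name, str(sid), conc, below_lod=conc < lod, lod=lod)
            )
            concs.append(conc)
        out[name] = concs
    return out, results
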