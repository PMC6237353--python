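"""Isotopic deconvolution of flow-injection lipid panels.

A triple quadrupole acquiring a whole lipid class in one flow-injection
run cannot chromatographically separate species of the same class and
carbon count that differ by one double bond: they sit 2 Da apart, exactly
where the M+2 (two 13C) isotopologue of the lighter (more unsaturated)
species lands. The monoisotopic signal of each species is therefore
inflated by the M+2 tail of its one-more-double-bond neighbour. This
module models the isotope envelope, builds the resulting lower-triangular
mixing matrix for a class/carbon series, and inverts it by forward
substitution.

The envelope is a carbon-only binomial: each of the n carbons is 13C with
probability 0.0107, so a_k = C(n, k) p^k (1-p)^(n-k). H/N/O/P isotopes
are ignored; at +2 Da the 13C2 contribution dominates for lipids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import binom

from .errors import ParseError, ValidationError

#: Natural abundance of carbon-13.
P_13C = 0.0107

#: Carbons contributed by the class scaffold beyond the chains the name
#: states (choline head group, glycerol, carnitine core...). The SM value
#: excludes the sphingoid base, which the full name carries explicitly.
BACKBONE_CARBONS = {"PC": 8, "lysoPC": 8, "SM": 5, "carnitine": 7}

#: Sphingoid chain length assumed for short-form SM names (e.g. SMC16:0).
DEFAULT_SPHINGOID_CARBONS = 18

# Nominal-mass model: mass = base[class, bond_code] + 14 * chain_carbons
# - 2 * double_bonds. Bases calibrated so real species come out right
# (PCaaC34:0 -> 761, SM(d18:1/C16:0) -> 702, C2:0 -> 203). Only the
# +2 Da neighbour relation is consumed downstream.
_MASS_BASE = {
    ("PC", "aa"): 285,
    ("PC", "ae"): 271,
    ("lysoPC", "a"): 271,
    ("lysoPC", "e"): 257,
    ("SM", "d"): 228,
    ("carnitine", None): 175,
}
_FREE_CARNITINE_MASS = 161


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid of the panel, named class + carbons : double bonds.

    ``chain_carbons`` counts the carbons the name states (both chains for
    diacyl species, sphingoid plus fatty acid for full SM names);
    ``total_carbons`` adds the class backbone and is what the isotope
    envelope uses. The nomenclature deliberately does not resolve
    double-bond positions or the split between side chains.
    """

    name: str
    lipid_class: str  # PC | lysoPC | SM | carnitine
    chain_carbons: int
    n_double_bonds: int
    bond_code: str | None = None  # aa | ae | a | e | d
    sphingoid: tuple[int, int] | None = None  # (carbons, double bonds)
    fatty_acid: tuple[int, int] | None = None

    @property
    def total_carbons(self) -> int:
        extra = BACKBONE_CARBONS[self.lipid_class]
        if self.lipid_class == "SM" and self.sphingoid is None:
            extra += DEFAULT_SPHINGOID_CARBONS
        return self.chain_carbons + extra

    @property
    def nominal_mass(self) -> int:
        if self.lipid_class == "carnitine" and self.chain_carbons == 0:
            return _FREE_CARNITINE_MASS
        key = (self.lipid_class, self.bond_code if self.lipid_class != "SM" else "d")
        if self.lipid_class == "carnitine":
            key = ("carnitine", None)
        base = _MASS_BASE[key]
        return base + 14 * self.chain_carbons - 2 * self.n_double_bonds


_PC_RE = re.compile(r"^PC(aa|ae)C(\d+):(\d+)$")
_LYSO_RE = re.compile(r"^lysoPC(a|e)C(\d+):(\d+)$")
_SM_FULL_RE = re.compile(r"^SM ?\(d(\d+):(\d+)/C(\d+):(\d+)\)$")
_SM_SHORT_RE = re.compile(r"^SMC(\d+):(\d+)$")
_CARN_RE = re.compile(r"^C(\d+)(?::(\d+))?$")


def parse_species(name: str) -> LipidSpecies:
    """Parse a panel lipid name into its species model.

    Grammar: ``PCaaC34:0`` / ``PCaeC36:2`` (diacyl / acyl-alkyl
    phosphatidylcholine), ``lysoPCaC20:2``, ``SM(d18:0/C18:1)`` or the
    fatty-acid-only short form ``SMC16:0``, and carnitines ``C2:0`` or
    bare ``C0``. ``format_species(parse_species(n))`` is canonical.
    """
    if not name or not name.strip():
        raise ParseError("empty species name")
    token = name.strip()

    m = _PC_RE.match(token)
    if m:
        bond, c, d = m.group(1), int(m.group(2)), int(m.group(3))
        return LipidSpecies(f"PC{bond}C{c}:{d}", "PC", c, d, bond_code=bond)
    m = _LYSO_RE.match(token)
    if m:
        bond, c, d = m.group(1), int(m.group(2)), int(m.group(3))
        return LipidSpecies(f"lysoPC{bond}C{c}:{d}", "lysoPC", c, d, bond_code=bond)
    m = _SM_FULL_RE.match(token)
    if m:
        sc, sd, fc, fd = (int(g) for g in m.groups())
        return LipidSpecies(
            f"SM(d{sc}:{sd}/C{fc}:{fd})",
            "SM",
            sc + fc,
            sd + fd,
            bond_code="d",
            sphingoid=(sc, sd),
            fatty_acid=(fc, fd),
        )
    m = _SM_SHORT_RE.match(token)
    if m:
        c, d = int(m.group(1)), int(m.group(2))
        return LipidSpecies(f"SMC{c}:{d}", "SM", c, d, bond_code="d", fatty_acid=(c, d))
    m = _CARN_RE.match(token)
    if m:
        c = int(m.group(1))
        d = int(m.group(2)) if m.group(2) is not None else 0
        canon = "C0" if c == 0 and m.group(2) is None else f"C{c}:{d}"
        return LipidSpecies(canon, "carnitine", c, d)
    raise ParseError(f"cannot parse lipid species name: {name!r}")


def format_species(species: LipidSpecies) -> str:
    """Canonical name (the parser already canonicalises, so: identity)."""
    return species.name


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Relative isotopologue abundances, monoisotopic first, summing to 1."""

    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.abundances):
            raise ValidationError("isotope abundances must be non-negative")
        if abs(sum(self.abundances) - 1.0) > 1e-12:
            raise ValidationError("isotope abundances must sum to 1")

    @property
    def a0(self) -> float:
        return self.abundances[0]

    @property
    def a2(self) -> float:
        return self.abundances[2] if len(self.abundances) > 2 else 0.0

    def __getitem__(self, k: int) -> float:
        return self.abundances[k]


def isotope_envelope(n_carbons: int, n_peaks: int = 3) -> IsotopeEnvelope:
    """Binomial carbon envelope truncated to ``n_peaks`` and renormalised.

    ``n_carbons`` = 0 is the degenerate all-monoisotopic case.
    Renormalisation preserves ratios, so a1/a0 = n p / (1 - p) exactly.
    """
    if n_carbons < 0:
        raise ValidationError("n_carbons must be >= 0")
    if n_peaks < 3:
        raise ValidationError("n_peaks must be >= 3 (M+2 is the point)")
    k = np.arange(n_peaks)
    a = binom.pmf(k, n_carbons, P_13C)
    a = a / a.sum()
    return IsotopeEnvelope(tuple(float(x) for x in a))


def overlap_matrix(
    series: list[LipidSpecies],
    envelopes: list[IsotopeEnvelope] | None = None,
) -> np.ndarray:
    """Mixing matrix M for a same-class, same-carbon series.

    ``series`` must be sorted by descending double bonds (ascending
    mass). M is lower-bidiagonal: M[i, i] = a0 of species i and
    M[i+1, i] = a2 of species i whenever species i+1 sits exactly +2 Da
    above (one fewer double bond). observed = M @ truth.
    """
    if not series:
        raise ValidationError("empty species series")
    names = [s.name for s in series]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate species in series: {names}")
    classes = {s.lipid_class for s in series}
    if len(classes) > 1:
        raise ValidationError(f"series mixes lipid classes: {sorted(classes)}")
    carbons = {s.chain_carbons for s in series}
    if len(carbons) > 1:
        raise ValidationError(f"series mixes carbon counts: {sorted(carbons)}")
    dbs = [s.n_double_bonds for s in series]
    if any(dbs[i] <= dbs[i + 1] for i in range(len(dbs) - 1)):
        raise ValidationError(
            "series must be sorted by strictly descending double bonds"
        )
    if envelopes is None:
        envelopes = [isotope_envelope(s.total_carbons) for s in series]
    n = len(series)
    mat = np.zeros((n, n))
    for i, env in enumerate(envelopes):
        mat[i, i] = env.a0
        if i + 1 < n and series[i + 1].nominal_mass - series[i].nominal_mass == 2:
            mat[i + 1, i] = env.a2
    return mat


def deconvolve_areas(
    observed: np.ndarray, mat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve M x = observed by forward substitution.

    Returns (corrected areas, clipped flags). Negative solutions — noise
    exceeding the predicted isotope contribution — are clipped to zero
    and flagged rather than raised, because downstream RSDs need values.
    """
    observed = np.asarray(observed, dtype=float)
    mat = np.asarray(mat, dtype=float)
    if mat.shape[0] != mat.shape[1] or mat.shape[0] != observed.shape[0]:
        raise ValidationError("matrix/observation dimension mismatch")
    if np.any(np.diag(mat) <= 0):
        raise ValidationError("singular overlap matrix: zero on the diagonal")
    x = solve_triangular(mat, observed, lower=True)
    clipped = x < 0
    return np.where(clipped, 0.0, x), clipped


def series_from_names(names: list[str]) -> list[LipidSpecies]:
    """Parse and canonically sort a series (descending double bonds)."""
    species = [parse_species(n) for n in names]
    return sorted(species, key=lambda s: -s.n_double_bonds)


def deconvolve_matrix(areas, species_names: list[str]):
    """Deconvolve every (class, carbons) series inside an AreaMatrix.

    Columns not parseable as lipids or in a one-species series pass
    through corrected only by their own a0. Returns (AreaMatrix,
    warnings) where warnings lists (sample_id, species) clip events.
    """
    from .tables_io import AreaMatrix

    frame = areas.frame.copy()
    parsed: dict[str, LipidSpecies] = {}
    for name in species_names:
        if name in frame.columns:
            parsed[name] = parse_species(name)
    groups: dict[tuple[str, int], list[str]] = {}
    for name, sp in parsed.items():
        groups.setdefault((sp.lipid_class, sp.chain_carbons), []).append(name)
    warnings: list[tuple[str, str]] = []
    for _, names in sorted(groups.items()):
        cols = sorted(names, key=lambda n: -parsed[n].n_double_bonds)
        series = [parsed[n] for n in cols]
        mat = overlap_matrix(series)
        block = frame[cols].to_numpy(dtype=float)
        out = np.empty_like(block)
        for r in range(block.shape[0]):
            out[r], clipped = deconvolve_areas(block[r], mat)
            for j in np.flatnonzero(clipped):
                warnings.append((str(frame.index[r]), cols[j]))
        frame[cols] = out
    return AreaMatrix(frame), warnings
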