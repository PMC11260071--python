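"""Molecular-formula mass arithmetic and isotope envelopes.

Atomic masses and isotope abundances are pinned in this module (CODATA/
IUPAC-style values) so that every m/z and isotope ratio the package prints
is bit-stable.  Isotope envelopes are computed by convolving per-element
isotopologue distributions and aggregating peaks by total neutron excess —
the centroid picture a unit-resolution instrument reports.  The single-Cl
tag ratio follows directly: (M+2)/M = 0.2424/0.7576 ≈ 0.3200.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ISOTOPES",
    "ELECTRON_MASS",
    "CL_SPACING",
    "ADDUCTS",
    "Adduct",
    "IsotopePattern",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "adduct_mz",
    "isotope_pattern",
]

#: element -> list of (isotope mass in Da, natural abundance, neutron shift).
#: Shifts are relative to the lightest isotope; values pinned for stability.
ISOTOPES: dict[str, list[tuple[float, float, int]]] = {
    "H": [(1.00782503207, 0.999885, 0), (2.01410177785, 0.000115, 1)],
    "C": [(12.0, 0.9893, 0), (13.00335483778, 0.0107, 1)],
    "N": [(14.00307400486, 0.99636, 0), (15.00010889823, 0.00364, 1)],
    "O": [
        (15.99491461956, 0.99757, 0),
        (16.99913170, 0.00038, 1),
        (17.99916107, 0.00205, 2),
    ],
    "S": [
        (31.97207100, 0.9499, 0),
        (32.97145876, 0.0075, 1),
        (33.96786690, 0.0425, 2),
        (35.96708076, 0.0001, 4),
    ],
    "Cl": [(34.96885268, 0.7576, 0), (36.96590259, 0.2424, 2)],
    "Na": [(22.98976928, 1.0, 0)],
    "P": [(30.97376163, 1.0, 0)],
}

#: Mass of the electron (Da), subtracted per positive charge.
ELECTRON_MASS = 0.00054857990907

#: 37Cl - 35Cl mass difference (Da); the chlorine-tag M/M+2 spacing.
CL_SPACING = 1.99705

#: Single-Cl (M+2)/M abundance ratio.
CL_M2_RATIO = ISOTOPES["Cl"][1][1] / ISOTOPES["Cl"][0][1]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Adduct:
    """A singly charged positive adduct: m/z = (M + delta - z*me) / z."""

    name: str
    delta_formula: dict[str, int]
    charge: int = 1

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


ADDUCTS: dict[str, Adduct] = {
    "M+H": Adduct("M+H", {"H": 1}),
    "M+NH4": Adduct("M+NH4", {"N": 1, "H": 4}),
    "M+Na": Adduct("M+Na", {"Na": 1}),
}


@dataclass
class IsotopePattern:
    """Centroided isotope envelope: (mass, abundance) pairs sorted by mass.

    Abundances are fractions of the full distribution (they sum to 1 before
    threshold truncation and are not renormalized afterwards, so peak
    ratios are exact).
    """

    peaks: list[tuple[float, float]]

    @property
    def base_mass(self) -> float:
        return self.peaks[0][0]

    def ratio(self, shift_da: float, tol: float = 0.01) -> float:
        """Abundance of the peak nearest ``base + shift_da`` over the base peak."""
        target = self.base_mass + shift_da
        best = min(self.peaks, key=lambda p: abs(p[0] - target))
        if abs(best[0] - target) > tol:
            return 0.0
        return best[1] / self.peaks[0][1]


def parse_formula(s: str) -> dict[str, int]:
    """Parse e.g. ``"C24H34ClNO7"`` into an element-count map."""
    pos = 0
    out: dict[str, int] = {}
    for m in _FORMULA_RE.finditer(s):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {s!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in ISOTOPES:
            raise ValueError(f"unknown element {el!r} in formula {s!r}")
        out[el] = out.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(s) or not out:
        raise ValueError(f"cannot parse formula {s!r}")
    return out


_HILL_ORDER = ("C", "H")


def formula_to_string(formula: dict[str, int]) -> str:
    """Hill-notation string (C, H, then alphabetical)."""
    rest = sorted(el for el in formula if el not in _HILL_ORDER)
    parts = []
    for el in (*_HILL_ORDER, *rest):
        n = formula.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def _as_formula(formula: dict[str, int] | str) -> dict[str, int]:
    return parse_formula(formula) if isinstance(formula, str) else formula


def monoisotopic_mass(formula: dict[str, int] | str) -> float:
    """Sum of lightest-isotope masses (Da)."""
    f = _as_formula(formula)
    total = 0.0
    for el, n in f.items():
        if el not in ISOTOPES:
            raise ValueError(f"unknown element {el!r}")
        if n < 0:
            raise ValueError(f"negative count for element {el!r}")
        total += n * ISOTOPES[el][0][0]
    return total


def adduct_mz(formula: dict[str, int] | str, adduct: Adduct | str = "M+H") -> float:
    """m/z of an adduct ion: (M + delta - charge*me) / |charge|."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unknown adduct {adduct!r}") from None
    m = monoisotopic_mass(formula) + monoisotopic_mass(adduct.delta_formula)
    return (m - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)


def _single_atom_dist(el: str) -> tuple[np.ndarray, np.ndarray]:
    """(abundance, mean-mass) arrays indexed by neutron shift for one atom."""
    iso = ISOTOPES[el]
    size = max(s for _, _, s in iso) + 1
    ab = np.zeros(size)
    mass = np.zeros(size)
    for m, a, s in iso:
        ab[s] += a
        mass[s] += a * m
    with np.errstate(invalid="ignore", divide="ignore"):
        mass = np.where(ab > 0, mass / np.where(ab > 0, ab, 1.0), 0.0)
    return ab, mass


def _convolve_tracked(
    ab1: np.ndarray, m1: np.ndarray, ab2: np.ndarray, m2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two abundance distributions, tracking abundance-weighted mass."""
    n = len(ab1) + len(ab2) - 1
    ab = np.zeros(n)
    wm = np.zeros(n)  # abundance-weighted mass accumulator
    for i, (a1, mm1) in enumerate(zip(ab1, m1)):
        if a1 == 0.0:
            continue
        for j, (a2, mm2) in enumerate(zip(ab2, m2)):
            if a2 == 0.0:
                continue
            ab[i + j] += a1 * a2
            wm[i + j] += a1 * a2 * (mm1 + mm2)
    mass = np.where(ab > 0, wm / np.where(ab > 0, ab, 1.0), 0.0)
    return ab, mass


def _element_dist(el: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of n atoms of one element (repeated self-convolution)."""
    ab1, m1 = _single_atom_dist(el)
    ab, mass = np.array([1.0]), np.array([0.0])
    base, base_m = ab1, m1
    k = n
    while k:  # exponentiation by squaring keeps large H counts cheap
        if k & 1:
            ab, mass = _convolve_tracked(ab, mass, base, base_m)
        k >>= 1
        if k:
            base, base_m = _convolve_tracked(base, base_m, base, base_m)
    return ab, mass


def isotope_pattern(
    formula: dict[str, int] | str, threshold: float = 1e-3, max_shift: int = 10
) -> IsotopePattern:
    """Centroided isotope envelope of a molecular formula.

    Per-element isotopologue distributions are convolved across elements;
    peaks are aggregated by total neutron excess with abundance-weighted
    centroid masses, truncated at ``max_shift`` neutron units, and peaks
    below ``threshold`` times the maximum abundance are dropped (without
    renormalizing the survivors).
    """
    if not 0.0 < threshold < 0.5:
        raise ValueError("threshold must be in (0, 0.5)")
    f = _as_formula(formula)
    ab, mass = np.array([1.0]), np.array([0.0])
    for el, n in sorted(f.items()):
        if n < 0:
            raise ValueError(f"negative count for element {el!r}")
        if n == 0:
            continue
        eab, emass = _element_dist(el, n)
        ab, mass = _convolve_tracked(ab, mass, eab, emass)
        if len(ab) > max_shift + 1:
            ab, mass = ab[: max_shift + 1], mass[: max_shift + 1]
    keep = ab >= threshold * ab.max()
    peaks = [(float(m), float(a)) for m, a, k in zip(mass, ab, keep) if k]
    peaks.sort(key=lambda p: p[0])
    return IsotopePattern(peaks=peaks)
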