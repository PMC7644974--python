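"""Exact-mass arithmetic for stable-isotope labeling experiments.

Everything downstream of the mass spectrometer rests on four pieces of
arithmetic: the monoisotopic mass of an elemental formula, the m/z of its
deprotonated ion (negative mode), the m/z shift produced by metabolic
labeling with ``13C`` or ``15N``, and the inverse problem — reading an atom
count back off an observed mass shift.  A feature whose m/z moves by
``n * (m13C - m12C)`` in a fully 13C-fed culture contains exactly ``n``
carbon atoms; the same logic with ``m15N - m14N`` counts nitrogens.  That
inversion is what credentials an untargeted feature as biological and
yields its C/N composition without a standard.

A carbon-only binomial model of the natural mass-isotopologue distribution
(MID) is included for comparing unlabeled and labeled isotope envelopes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "ElementalFormula",
    "IsotopeConstants",
    "CONSTANTS",
    "monoisotopic_mass",
    "mz_deprotonated",
    "labeled_mz",
    "natural_mid",
    "infer_atom_count",
    "constants_table_path",
]

_SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "P", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class IsotopeConstants:
    """Physical constants for mass arithmetic, in Da.

    ``delta_13c`` and ``delta_15n`` are the heavy-minus-light isotope mass
    differences that metabolic labeling imprints on m/z; ``electron_mass``
    enters because an [M-H]- ion carries one extra electron.
    """

    monoisotopic: Mapping[str, float] = field(
        default_factory=lambda: {
            "C": 12.0,
            "H": 1.00782503207,
            "N": 14.0030740048,
            "O": 15.99491461956,
            "P": 30.97376163,
            "S": 31.972071,
        }
    )
    delta_13c: float = 1.0033548378
    delta_15n: float = 0.9970349
    electron_mass: float = 0.00054857990907
    natural_13c_abundance: float = 0.0107

    def __post_init__(self) -> None:
        if not 0.0 < self.natural_13c_abundance < 1.0:
            raise ValueError("natural 13C abundance must lie in (0, 1)")
        if any(m <= 0 for m in self.monoisotopic.values()):
            raise ValueError("atomic masses must be positive")


CONSTANTS = IsotopeConstants()

#: Proton mass (H minus one electron); subtracted per charge in negative mode.
PROTON_MASS = CONSTANTS.monoisotopic["H"] - CONSTANTS.electron_mass


class ElementalFormula:
    """Immutable integer atom counts over C, H, N, O, P, S.

    Accepts a Hill-notation string (``"C6H13O9P"``) or a mapping of element
    symbol to count.  At least one atom is required.
    """

    __slots__ = ("_counts",)

    def __init__(self, formula: str | Mapping[str, int]):
        if isinstance(formula, str):
            counts = self._parse(formula)
        else:
            counts = {str(k): int(v) for k, v in formula.items() if int(v) != 0}
        for element, n in counts.items():
            if element not in _SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element symbol: {element!r}")
            if n < 0:
                raise ValueError(f"negative count for {element}: {n}")
        if sum(counts.values()) == 0:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "_counts", dict(counts))

    @staticmethod
    def _parse(formula: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return counts

    def __setattr__(self, name: str, value) -> None:  # pragma: no cover
        raise AttributeError("ElementalFormula is immutable")

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self._counts.items()))

    def __eq__(self, other) -> bool:
        return isinstance(other, ElementalFormula) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(tuple(sorted(self._counts.items())))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self._counts)
        for element, n in other._counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula(merged)

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"

    def hill(self) -> str:
        """Hill-notation string: C first, H second, the rest alphabetical."""
        parts = []
        order = ["C", "H"] + sorted(set(self._counts) - {"C", "H"})
        for element in order:
            n = self._counts.get(element, 0)
            if n:
                parts.append(element + (str(n) if n > 1 else ""))
        return "".join(parts)

    @property
    def n_carbon(self) -> int:
        return self._counts.get("C", 0)

    @property
    def n_nitrogen(self) -> int:
        return self._counts.get("N", 0)


def monoisotopic_mass(
    formula: ElementalFormula | str, constants: IsotopeConstants = CONSTANTS
) -> float:
    """Monoisotopic (lightest-isotope) mass of ``formula`` in Da."""
    if isinstance(formula, str):
        formula = ElementalFormula(formula)
    return sum(n * constants.monoisotopic[el] for el, n in formula)


def mz_deprotonated(
    formula: ElementalFormula | str,
    charge: int = 1,
    constants: IsotopeConstants = CONSTANTS,
) -> float:
    """m/z of the [M-zH]z- ion in negative mode.

    ``(M - z*m_H + z*m_e) / z``; the electron mass term is ~0.5 mDa and is
    kept so that computed values are unambiguous at sub-ppm precision.
    """
    if isinstance(formula, str):
        formula = ElementalFormula(formula)
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    if formula["H"] < charge:
        raise ValueError(
            f"cannot remove {charge} protons from formula with {formula['H']} hydrogens"
        )
    mass = monoisotopic_mass(formula, constants)
    return (mass - charge * PROTON_MASS) / charge


def labeled_mz(
    formula: ElementalFormula | str,
    label: str,
    charge: int = 1,
    constants: IsotopeConstants = CONSTANTS,
) -> tuple[float, bool]:
    """m/z of the fully labeled deprotonated ion.

    ``label`` is ``"13C"`` (every carbon heavy) or ``"15N"`` (every nitrogen
    heavy).  Returns ``(mz, labeled)``; ``labeled`` is False when the formula
    lacks the labeled element, in which case the unlabeled m/z is returned
    unchanged (a 15N label cannot shift a nitrogen-free compound).
    """
    if isinstance(formula, str):
        formula = ElementalFormula(formula)
    base = mz_deprotonated(formula, charge, constants)
    if label == "13C":
        n, delta = formula.n_carbon, constants.delta_13c
    elif label == "15N":
        n, delta = formula.n_nitrogen, constants.delta_15n
    else:
        raise ValueError(f"label must be '13C' or '15N', got {label!r}")
    if n == 0:
        return base, False
    return base + n * delta / charge, True


def natural_mid(
    formula: ElementalFormula | str,
    k: int,
    constants: IsotopeConstants = CONSTANTS,
) -> np.ndarray:
    """Natural-abundance mass-isotopologue distribution M+0 .. M+k.

    Carbon-only binomial model: each of the ``nC`` carbons is independently
    13C with probability ``a`` (natural abundance), so
    ``P(M+i) = C(nC, i) a^i (1-a)^(nC-i)``.  The distribution is truncated
    at ``k`` and renormalized to sum to one.  Heavy isotopes of H/N/O/P/S
    are ignored: for polar metabolites carbon dominates the M+1 peak and
    the envelope is used comparatively, not quantitatively.
    """
    if isinstance(formula, str):
        formula = ElementalFormula(formula)
    if k < 0:
        raise ValueError("k must be >= 0")
    nc = formula.n_carbon
    a = constants.natural_13c_abundance
    pmf = stats.binom.pmf(np.arange(k + 1), nc, a)
    return pmf / pmf.sum()


def infer_atom_count(
    mz_unlabeled: float,
    mz_labeled: float,
    element: str,
    charge: int = 1,
    ppm_tol: float = 10.0,
    constants: IsotopeConstants = CONSTANTS,
) -> int | None:
    """Atom count of ``element`` from a labeling-induced m/z shift.

    Rounds ``charge * (mz_labeled - mz_unlabeled) / delta`` to the nearest
    integer ``n`` and accepts it only if the reconstructed shift
    ``n * delta / charge`` matches the observed one within ``ppm_tol`` ppm
    of the labeled m/z.  Returns ``None`` for a negative shift or a shift
    that is not close to any integer multiple of ``delta``.
    """
    if element == "C":
        delta = constants.delta_13c
    elif element == "N":
        delta = constants.delta_15n
    else:
        raise ValueError(f"element must be 'C' or 'N', got {element!r}")
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    shift = mz_labeled - mz_unlabeled
    if shift < -ppm_tol * 1e-6 * mz_labeled:
        return None
    n = round(charge * shift / delta)
    if n < 0:
        return None
    if abs(shift - n * delta / charge) > ppm_tol * 1e-6 * mz_labeled:
        return None
    return n


def constants_table_path() -> str:
    """Path to the documented plain-text constants table shipped as data."""
    return str(resources.files("isodiel").joinpath("data/isotope_constants.tsv"))
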