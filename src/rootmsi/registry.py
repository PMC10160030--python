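"""Metabolite mass registry.

Parses elemental formulas, computes theoretical monoisotopic masses and
adduct m/z values, and loads the target list used for ion imaging. All
imaging in this package runs in negative ion mode, so the supported adducts
are the deprotonated molecule [M-H]-, the chloride adduct [M+Cl]-, and the
radical anion M-.

Mass conventions: deprotonation subtracts the proton mass (1.00727646 Da),
not the hydrogen-atom mass; the electron mass (~0.00055 Da) is ignored for
the chloride adduct and radical anion. The difference between the two
conventions (~0.0005 Da) is far inside the +-5 ppm extraction windows used
downstream.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "ADDUCTS",
    "MetaboliteRecord",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "load_registry",
    "default_registry",
]

#: Monoisotopic atomic masses (Da) of the elements accepted in formulas.
MONOISOTOPIC_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207069,
    "Cl": 34.96885268,
    "Na": 22.98976928,
    "K": 38.96370649,
}

PROTON_MASS = 1.00727646

#: Supported negative-mode adducts mapped to their neutral-mass offset (Da).
ADDUCTS: Mapping[str, float] = {
    "[M-H]-": -PROTON_MASS,
    "[M+Cl]-": MONOISOTOPIC_MASSES["Cl"],
    "M-": 0.0,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported elemental formulas."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation formula into an element -> count map.

    Only the elements with tabulated monoisotopic masses are accepted
    (C, H, N, O, P, S, Cl, Na, K). Raises :class:`FormulaError` naming the
    position of the first malformed or unrecognized token.
    """
    if not text:
        raise FormulaError("empty formula")
    composition: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, count_str = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASSES:
            raise FormulaError(
                f"unrecognized element {element!r} in {text!r} at position {pos}"
            )
        count = int(count_str) if count_str else 1
        if count <= 0:
            raise FormulaError(f"non-positive count for {element} in {text!r}")
        composition[element] = composition.get(element, 0) + count
        pos = m.end()
    return composition


def monoisotopic_mass(composition: Mapping[str, int]) -> float:
    """Sum of count x monoisotopic atomic mass over the composition (Da)."""
    try:
        return float(
            sum(MONOISOTOPIC_MASSES[el] * n for el, n in composition.items())
        )
    except KeyError as exc:  # pragma: no cover - parse_formula screens these
        raise FormulaError(f"no tabulated mass for element {exc}") from exc


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Theoretical m/z of a singly charged adduct of the neutral molecule."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    try:
        offset = ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        ) from None
    return neutral_mass + offset


@dataclass(frozen=True)
class MetaboliteRecord:
    """A named imaging target with its theoretical adduct m/z."""

    name: str
    formula: Mapping[str, int]
    adduct: str = "[M-H]-"
    verified: bool = True
    theoretical_mz: float = field(init=False)
    nominal_mz: int = field(init=False)

    def __post_init__(self) -> None:
        mz = adduct_mz(monoisotopic_mass(self.formula), self.adduct)
        object.__setattr__(self, "theoretical_mz", mz)
        object.__setattr__(self, "nominal_mz", round(mz))

    @classmethod
    def from_formula(
        cls,
        name: str,
        formula: str,
        adduct: str = "[M-H]-",
        verified: bool = True,
    ) -> "MetaboliteRecord":
        return cls(name=name, formula=parse_formula(formula), adduct=adduct,
                   verified=verified)


def load_registry(path: str | Path) -> list[MetaboliteRecord]:
    """Load a delimited registry (columns: name, formula, adduct[, verified])."""
    records = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            records.append(
                MetaboliteRecord.from_formula(
                    name=row["name"].strip(),
                    formula=row["formula"].strip(),
                    adduct=row.get("adduct", "[M-H]-").strip() or "[M-H]-",
                    verified=row.get("verified", "yes").strip().lower()
                    not in {"no", "false", "0"},
                )
            )
    return records


def default_registry() -> list[MetaboliteRecord]:
    """The registry shipped with the package.

    Covers the detectable TCA-cycle acids plus the other small molecules and
    lipids assigned in negative-mode root imaging. Citrate and isocitrate are
    isobaric isomers and share one entry. Entries whose adduct assignment has
    not been confirmed by fragmentation (the di-hexose and the lipids) are
    flagged ``verified=False``.
    """
    ref = resources.files("rootmsi").joinpath("data/default_registry.csv")
    with resources.as_file(ref) as path:
        return load_registry(path)
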