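"""Exact-mass arithmetic: molecular formulas, monoisotopic masses, adduct registry.

Every mass difference used by the rest of the package is derived here from a
bundled monoisotopic isotope-mass table — never hand-entered as a literal.

The formula dialect is Hill-style element symbols with optional signed counts
(``"NaH-1"`` means one Na gained, one H lost) and bracketed isotope labels
(``"[13C]"``, ``"[107Ag]"``).  Signed counts let a single formula express a net
composition *change*, which is what an adduct is: the composition an adduct ion
carries on top of its protonated parent.
"""

from __future__ import annotations

import csv
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "MolecularFormula",
    "AdductDefinition",
    "AdductRegistry",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "default_registry",
    "load_registry",
    "PROTON_MASS",
    "ELECTRON_MASS",
]

# Monoisotopic masses (Da) of the most abundant isotope of each element, plus
# explicitly labelled isotopes.  CODATA/AME values to >=6 decimals.
ISOTOPE_MASSES: dict[str, float] = {
    "H": 1.0078250,
    "C": 12.0000000,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "Na": 22.9897693,
    "Mg": 23.9850417,
    "Si": 27.9769265,
    "P": 30.9737615,
    "S": 31.9720707,
    "Cl": 34.9688527,
    "K": 38.9637065,
    "Ca": 39.9625909,
    "Fe": 55.9349375,
    "Cu": 62.9295977,
    "Zn": 63.9291420,
    "Br": 78.9183376,
    "Ag": 106.9050916,  # 107Ag, the lighter and more abundant silver isotope
    "I": 126.9044719,
    # bracketed isotope labels
    "2H": 2.0141018,
    "13C": 13.0033548,
    "15N": 15.0001089,
    "18O": 17.9991596,
    "107Ag": 106.9050916,
    "109Ag": 108.9047558,
}

ELECTRON_MASS = 0.0005486
#: Mass added by protonation: an H atom minus the electron carried away.
PROTON_MASS = ISOTOPE_MASSES["H"] - ELECTRON_MASS


class FormulaError(ValueError):
    """Raised for unparseable formula text or unknown element symbols."""


# one token: "[13C]" style isotope or element symbol, optional signed count
_TOKEN = re.compile(r"(\[(?P<iso>\d+[A-Z][a-z]?)\]|(?P<el>[A-Z][a-z]?))(?P<n>-?\d+)?")


@dataclass(frozen=True)
class MolecularFormula:
    """Signed element counts: a neutral composition or a net composition change.

    Counts may be negative (net losses, e.g. ``Na, H:-1`` for a sodium-for-
    proton exchange); a formula standing for an actual neutral molecule must
    have all counts >= 0 (checked by :meth:`require_neutral`).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {s: int(n) for s, n in self.counts.items() if n != 0}
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.counts)
        c.update(other.counts)
        return MolecularFormula(dict(c))

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.counts)
        c.subtract(other.counts)
        return MolecularFormula(dict(c))

    def __mul__(self, k: int) -> "MolecularFormula":
        return MolecularFormula({s: n * k for s, n in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def require_neutral(self) -> "MolecularFormula":
        neg = [s for s, n in self.counts.items() if n < 0]
        if neg:
            raise FormulaError(
                f"negative counts for {neg}: not a valid neutral molecule"
            )
        return self

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __format__(self, spec: str) -> str:
        return format(str(self), spec)

    def __str__(self) -> str:
        return format_formula(self)


def _hill_key(symbol: str) -> tuple:
    # Hill order: C first, H second, then alphabetical; isotope labels sort
    # with their element, heavier after lighter.
    m = re.match(r"(\d*)([A-Z][a-z]?)", symbol)
    nucleon, el = m.group(1), m.group(2)
    rank = {"C": 0, "H": 1}.get(el, 2)
    return (rank, el, int(nucleon) if nucleon else 0)


def format_formula(f: MolecularFormula) -> str:
    """Canonical text for a formula; inverse of :func:`parse_formula`."""
    parts = []
    for sym in sorted(f.counts, key=_hill_key):
        n = f.counts[sym]
        label = f"[{sym}]" if sym[0].isdigit() else sym
        if n == 1:
            parts.append(label)
        else:
            parts.append(f"{label}{n}")
    return "".join(parts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse formula text into signed element counts.

    >>> parse_formula("C7H4O3").counts
    {'C': 7, 'H': 4, 'O': 3}
    >>> parse_formula("NaH-1").counts
    {'Na': 1, 'H': -1}
    """
    text = text.strip()
    counts: Counter = Counter()
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        sym = m.group("iso") or m.group("el")
        if sym not in ISOTOPE_MASSES:
            raise FormulaError(f"unknown element or isotope symbol {sym!r}")
        n = int(m.group("n")) if m.group("n") is not None else 1
        counts[sym] += n
        pos = m.end()
    return MolecularFormula(dict(counts))


def monoisotopic_mass(f: MolecularFormula | str) -> float:
    """Monoisotopic mass in Da: sum of count x most-abundant-isotope mass
    (or the named isotope's mass for bracketed symbols)."""
    if isinstance(f, str):
        f = parse_formula(f)
    total = 0.0
    # canonical summation order so the mass is independent of insertion order
    for sym in sorted(f.counts, key=_hill_key):
        try:
            total += f.counts[sym] * ISOTOPE_MASSES[sym]
        except KeyError:
            raise FormulaError(f"no isotope mass for symbol {sym!r}") from None
    return total


def ion_mz(neutral: MolecularFormula | str, charge: int = 1) -> float:
    """m/z of the protonated ion [M+H]+ of a neutral molecule.

    Only singly charged positive ions are supported; the proton mass is the
    H-atom mass minus the electron mass.
    """
    if charge != 1:
        raise ValueError(f"unsupported charge {charge:+d}: only +1 ions in scope")
    if isinstance(neutral, str):
        neutral = parse_formula(neutral)
    neutral.require_neutral()
    return monoisotopic_mass(neutral) + PROTON_MASS


@dataclass(frozen=True)
class AdductDefinition:
    """A named mass-difference hypothesis.

    ``net_change`` is the composition the adduct ion carries relative to its
    parent ion (both singly charged), so ``delta_mass`` is simply that
    composition's monoisotopic mass — derived, never hand-entered.
    """

    name: str
    net_change: MolecularFormula
    category: str = "custom"  # isotope | alkali | matrix | control | custom

    CATEGORIES = frozenset({"isotope", "alkali", "matrix", "control", "custom"})

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(f"unknown adduct category {self.category!r}")

    @property
    def delta_mass(self) -> float:
        return monoisotopic_mass(self.net_change)


class AdductRegistry:
    """Ordered, name-unique collection of adduct definitions."""

    #: entries closer than this in Δmass trigger a collision warning
    COLLISION_TOL = 1e-4

    def __init__(self, entries: Iterable[AdductDefinition] = (), source: str = "built-in"):
        self._entries: dict[str, AdductDefinition] = {}
        self.source = source
        for e in entries:
            self.add(e)

    def add(self, entry: AdductDefinition) -> None:
        if entry.name in self._entries:
            warnings.warn(f"replacing registry entry {entry.name!r}", stacklevel=2)
        else:
            for other in self._entries.values():
                if abs(other.delta_mass - entry.delta_mass) < self.COLLISION_TOL:
                    warnings.warn(
                        f"adduct {entry.name!r} within {self.COLLISION_TOL} Da of "
                        f"{other.name!r} ({entry.delta_mass:.5f} vs {other.delta_mass:.5f})",
                        stacklevel=2,
                    )
        self._entries[entry.name] = entry

    def __iter__(self) -> Iterator[AdductDefinition]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> AdductDefinition:
        return self._entries[name]

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def subset(self, names: Iterable[str]) -> "AdductRegistry":
        return AdductRegistry((self._entries[n] for n in names), source=self.source)

    def extend(self, other: "AdductRegistry") -> "AdductRegistry":
        merged = AdductRegistry(self, source=self.source)
        for e in other:
            merged.add(e)
        return merged


_DHB = "C7H6O4"  # 2,5-dihydroxybenzoic acid
_DHB_H2O = "C7H4O3"  # DHB after in-source water loss
_CHCA = "C10H7NO3"  # alpha-cyano-4-hydroxycinnamic acid


def _builtin_entries(matrix: str) -> list[AdductDefinition]:
    core = [
        AdductDefinition("13C", parse_formula("[13C]C-1"), "isotope"),
        AdductDefinition("Na-H", parse_formula("NaH-1"), "alkali"),
        AdductDefinition("K-H", parse_formula("KH-1"), "alkali"),
        AdductDefinition("107Ag-H", parse_formula("[107Ag]H-1"), "control"),
    ]
    dhb = [
        AdductDefinition("DHB", parse_formula(_DHB), "matrix"),
        AdductDefinition("DHB-H2O", parse_formula(_DHB_H2O), "matrix"),
        AdductDefinition("2(DHB-H2O)", parse_formula(_DHB_H2O) * 2, "matrix"),
        AdductDefinition("3(DHB-H2O)", parse_formula(_DHB_H2O) * 3, "matrix"),
    ]
    chca = [
        AdductDefinition("CHCA", parse_formula(_CHCA), "matrix"),
        # the printed 212.032 Da implies Na added on top of the whole matrix
        # molecule, not a Na-for-H exchange
        AdductDefinition("CHCA+Na", parse_formula(_CHCA + "Na"), "matrix"),
    ]
    if matrix == "DHB":
        return core + dhb
    if matrix == "CHCA":
        return core + chca
    if matrix == "none":
        return core
    if matrix == "all":
        return core + dhb + chca
    raise ValueError(f"unknown matrix {matrix!r}: expected DHB, CHCA, none or all")


def default_registry(matrix: str = "DHB", include_water_loss: bool = False) -> AdductRegistry:
    """Built-in registry of isotope, alkali, control and matrix adducts.

    Parameters
    ----------
    matrix
        Which matrix-compound entries to include: ``"DHB"``, ``"CHCA"``,
        ``"none"`` (isotope/alkali/control only) or ``"all"``.
    include_water_loss
        Also include the in-source H2O loss (Δmass < 0, so it can never match
        a heavier-minus-lighter pair; useful only for custom workflows).
    """
    entries = _builtin_entries(matrix)
    if include_water_loss:
        entries.append(AdductDefinition("-H2O", parse_formula("H-2O-1"), "custom"))
    return AdductRegistry(entries, source="built-in")


def load_registry(path: str | Path, base: AdductRegistry | None = None) -> AdductRegistry:
    """Load adduct definitions from CSV (columns ``name,formula,category``).

    Lines starting with ``#`` are comments.  If ``base`` is given the loaded
    entries extend it; duplicate names replace with a warning.
    """
    path = Path(path)
    reg = AdductRegistry(base or (), source=str(path))
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise FormulaError(f"{path}: empty registry file (expected a header row)")
    header = [c.strip().lower() for c in rows[0]]
    try:
        i_name, i_formula = header.index("name"), header.index("formula")
    except ValueError:
        raise FormulaError(f"{path}: header must contain 'name' and 'formula' columns")
    i_cat = header.index("category") if "category" in header else None
    for lineno, row in enumerate(rows[1:], start=2):
        try:
            name = row[i_name].strip()
            formula = parse_formula(row[i_formula])
            category = row[i_cat].strip() if i_cat is not None and len(row) > i_cat and row[i_cat].strip() else "custom"
            reg.add(AdductDefinition(name, formula, category))
        except (FormulaError, ValueError, IndexError) as exc:
            raise FormulaError(f"{path}: row {lineno}: {exc}") from exc
    return reg
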