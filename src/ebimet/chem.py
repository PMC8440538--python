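"""Elemental-formula and ion m/z arithmetic for xenobiotic metabolite annotation.

This module carries the mass arithmetic everything else is built on:

* :class:`ElementalFormula` — an element→count map with optional heavy-isotope
  *substitution* counts (``13C``, ``2H``), so an isotopically labeled molecule
  is represented as the unlabeled skeleton plus the number of positions
  carrying the heavy isotope.
* :class:`IonSpecies` — singly charged ion types ([M+H]+, [M−H]−, intact
  cations/anions), with the electron mass handled explicitly so that fragment
  cations such as C9H11ClNO2+ come out at the value a high-resolution
  instrument reports.
* :class:`TransformationRule` — a phase I/II biotransformation (or an
  adduct/isotope spacing) expressed as a signed element-count delta, with the
  monoisotopic mass shift derived from the atomic-mass table rather than
  stored.

Masses are IUPAC monoisotopic masses; all arithmetic is exact summation over
atom counts, so theoretical m/z values are reproducible to well below the
instrument's ppm-level accuracy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "IonSpecies",
    "M_PLUS_H",
    "M_MINUS_H",
    "CATION",
    "ANION",
    "IsotopeLabelSpec",
    "TransformationRule",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "labeled_mz",
    "apply_transformation",
    "enumerate_products",
    "ppm_error",
    "load_rules",
    "default_rules",
]

# IUPAC monoisotopic atomic masses (Da).  Heavy isotopes are keyed by
# mass-number-prefixed symbols ("13C"), light elements by the bare symbol.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "2H": 2.0141017780,
    "C": 12.0,
    "13C": 13.0033548378,
    "N": 14.0030740052,
    "15N": 15.0001088984,
    "O": 15.9949146221,
    "18O": 17.9991604,
    "F": 18.9984032,
    "Na": 22.98976928,
    "Mg": 23.9850417,
    "Si": 27.9769265,
    "P": 30.97376151,
    "S": 31.97207069,
    "34S": 33.96786683,
    "Cl": 34.96885271,
    "K": 38.9637069,
    "Ca": 39.9625912,
    "Fe": 55.9349421,
    "Se": 79.9165218,
    "Br": 78.9183376,
    "I": 126.904468,
}

ELECTRON_MASS = 0.00054857990
#: Mass of a proton: a hydrogen atom minus its electron.  [M+H]+ = M + PROTON_MASS.
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_HEAVY_RE = re.compile(r"^(\d+)([A-Z][a-z]?)$")


def _light_of(symbol: str) -> str:
    """Light-element symbol for a heavy-isotope symbol ("13C" → "C")."""
    m = _HEAVY_RE.match(symbol)
    if m is None:
        return symbol
    return m.group(2)


def _is_heavy(symbol: str) -> bool:
    return _HEAVY_RE.match(symbol) is not None


class FormulaError(ValueError):
    """Raised for unparseable or chemically impossible formulas."""


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition with optional heavy-isotope substitutions.

    ``counts`` holds the *total* number of atoms of each element (labeled
    positions included); ``label_counts`` records how many of those atoms are
    the heavy isotope.  A d3 form of C8H12N4O3 is therefore
    ``counts={C:8,H:12,N:4,O:3}, label_counts={2H:3}`` — substitution, not
    addition.
    """

    counts: Mapping[str, int]
    label_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {e: int(n) for e, n in self.counts.items() if n != 0}
        labels = {i: int(n) for i, n in self.label_counts.items() if n != 0}
        for e, n in counts.items():
            if _is_heavy(e):
                raise FormulaError(
                    f"heavy isotope {e!r} belongs in label_counts, not counts"
                )
            if e not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {e!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {e!r}: {n}")
        for iso, n in labels.items():
            if not _is_heavy(iso) or iso not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown heavy isotope {iso!r}")
            if n < 0:
                raise FormulaError(f"negative label count for {iso!r}: {n}")
            light = _light_of(iso)
            if n > counts.get(light, 0):
                raise FormulaError(
                    f"{n} {iso} substitutions exceed {counts.get(light, 0)} "
                    f"{light} atoms"
                )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "label_counts", labels)

    # -- construction ------------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        return parse_formula(text)

    def with_labels(self, isotope: str, n: int) -> "ElementalFormula":
        """Return a copy with ``n`` atoms substituted by ``isotope``.

        Replaces any existing substitution count for that isotope.
        """
        labels = dict(self.label_counts)
        if n == 0:
            labels.pop(isotope, None)
        else:
            labels[isotope] = n
        return ElementalFormula(dict(self.counts), labels)

    # -- properties --------------------------------------------------------

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def unlabeled(self) -> "ElementalFormula":
        return ElementalFormula(dict(self.counts))

    # -- canonical text form ----------------------------------------------

    def to_string(self) -> str:
        """Hill-order formula with heavy isotopes in bracket notation.

        Labeled atoms are split off their element: C8H12N4O3 with three
        deuteriums is written ``C8H9[2H]3N4O3``.
        """
        symbols = sorted(self.counts)
        if "C" in self.counts:
            ordered = ["C"] + (["H"] if "H" in self.counts else [])
            ordered += [s for s in symbols if s not in ("C", "H")]
        else:
            ordered = symbols
        parts: list[str] = []
        for el in ordered:
            n_heavy = sum(
                n for iso, n in self.label_counts.items() if _light_of(iso) == el
            )
            n_light = self.counts[el] - n_heavy
            if n_light > 0:
                parts.append(el + (str(n_light) if n_light != 1 else ""))
            for iso in sorted(i for i in self.label_counts if _light_of(i) == el):
                n = self.label_counts[iso]
                parts.append(f"[{iso}]" + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return (
            dict(self.counts) == dict(other.counts)
            and dict(self.label_counts) == dict(other.label_counts)
        )

    def __hash__(self) -> int:
        return hash(
            (
                tuple(sorted(self.counts.items())),
                tuple(sorted(self.label_counts.items())),
            )
        )


_TOKEN_RE = re.compile(
    r"\[(?P<iso>\d+[A-Z][a-z]?)\](?P<n_iso>\d*)"
    r"|(?P<el>[A-Z][a-z]?)(?P<n_el>\d*)"
)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula, with heavy isotopes in brackets.

    ``"C8H12N4O3"`` parses to the plain composition; ``"[13C]3"`` marks three
    carbons as 13C substitutions; ``D`` is accepted as shorthand for ``[2H]``.
    Substituted atoms count toward the light element's total, matching the
    substitution semantics of :class:`ElementalFormula`.
    """
    text = text.strip()
    if not text:
        return ElementalFormula({})
    counts: dict[str, int] = {}
    labels: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        pos = m.end()
        if m.group("iso"):
            iso = m.group("iso")
            n = int(m.group("n_iso") or 1)
            if iso not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown heavy isotope {iso!r}")
            labels[iso] = labels.get(iso, 0) + n
            light = _light_of(iso)
            counts[light] = counts.get(light, 0) + n
        else:
            el = m.group("el")
            n = int(m.group("n_el") or 1)
            if el == "D":  # deuterium shorthand
                labels["2H"] = labels.get("2H", 0) + n
                counts["H"] = counts.get("H", 0) + n
                continue
            if el not in MONOISOTOPIC_MASS or _is_heavy(el):
                raise FormulaError(f"unknown element symbol {el!r}")
            counts[el] = counts.get(el, 0) + n
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return ElementalFormula(counts, labels)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass in Da: light-element sum plus substitution deltas."""
    mass = sum(n * MONOISOTOPIC_MASS[e] for e, n in f.counts.items())
    mass += sum(
        n * (MONOISOTOPIC_MASS[iso] - MONOISOTOPIC_MASS[_light_of(iso)])
        for iso, n in f.label_counts.items()
    )
    return mass


# ---------------------------------------------------------------------------
# Ions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged ion type.

    ``proton_delta`` is the number of protons gained (+1 for [M+H]+, −1 for
    [M−H]−, 0 for an intact cation or anion).  For proton-transfer ions the
    electron bookkeeping is already folded into the proton mass; for intact
    ions the electron mass is subtracted (cation) or added (anion) explicitly.
    """

    polarity: int
    proton_delta: int
    label: str

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ValueError("only singly charged ions are supported")

    @classmethod
    def from_label(cls, label: str) -> "IonSpecies":
        key = label.strip().lower().replace(" ", "")
        aliases = {
            "[m+h]+": M_PLUS_H,
            "m+h": M_PLUS_H,
            "[m-h]-": M_MINUS_H,
            "[m−h]−": M_MINUS_H,
            "m-h": M_MINUS_H,
            "cation": CATION,
            "anion": ANION,
        }
        if key not in aliases:
            raise ValueError(f"unsupported ion species {label!r}")
        return aliases[key]


M_PLUS_H = IonSpecies(polarity=+1, proton_delta=+1, label="[M+H]+")
M_MINUS_H = IonSpecies(polarity=-1, proton_delta=-1, label="[M-H]-")
CATION = IonSpecies(polarity=+1, proton_delta=0, label="cation")
ANION = IonSpecies(polarity=-1, proton_delta=0, label="anion")


def ion_mz(f: ElementalFormula, ion: IonSpecies) -> float:
    """Theoretical m/z of the singly charged ion of ``f``.

    [M+H]+ is M + 1.007276 Da; an intact cation is M minus one electron mass
    (the convention needed to reproduce instrument-reported fragment masses).
    """
    mz = monoisotopic_mass(f) + ion.proton_delta * PROTON_MASS
    if ion.proton_delta == 0:
        mz -= ion.polarity * ELECTRON_MASS
    if mz <= 0:
        raise ValueError(f"non-positive m/z for {f.to_string()!r} as {ion.label}")
    return mz


# ---------------------------------------------------------------------------
# Isotope labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopeLabelSpec:
    """A stable-isotope labeling scheme, e.g. 13C3 or d9.

    ``n_labels`` heavy atoms are introduced on the precursor; metabolites may
    retain fewer (deuterium can be lost during biotransformation or exchange).
    """

    light_element: str
    heavy_isotope: str
    n_labels: int

    def __post_init__(self) -> None:
        if self.n_labels < 1:
            raise ValueError("n_labels must be >= 1")
        if _light_of(self.heavy_isotope) != self.light_element:
            raise ValueError(
                f"{self.heavy_isotope} is not an isotope of {self.light_element}"
            )

    @property
    def per_label_delta(self) -> float:
        """Mass added per substitution: mass(heavy) − mass(light), in Da."""
        return (
            MONOISOTOPIC_MASS[self.heavy_isotope]
            - MONOISOTOPIC_MASS[self.light_element]
        )

    @property
    def default_max_label_loss(self) -> int:
        """Labels a metabolite may plausibly lose: 0 for carbon skeletons
        (13C), all for deuterium (metabolic or exchange loss)."""
        return self.n_labels if self.heavy_isotope == "2H" else 0

    @classmethod
    def parse(cls, text: str) -> "IsotopeLabelSpec":
        """Parse "13C:3", "D:9" or "2H:9"."""
        iso, _, n = text.partition(":")
        iso = iso.strip()
        if iso == "D":
            iso = "2H"
        if not n:
            raise ValueError(f"label spec {text!r} needs a count, e.g. '13C:3'")
        return cls(_light_of(iso), iso, int(n))


def labeled_mz(
    f: ElementalFormula,
    ion: IonSpecies,
    label: IsotopeLabelSpec,
    labels_lost: int = 0,
) -> float:
    """m/z of the isotopologue retaining ``n_labels − labels_lost`` labels."""
    if labels_lost < 0 or labels_lost > label.n_labels:
        raise ValueError(
            f"labels_lost={labels_lost} outside [0, {label.n_labels}]"
        )
    retained = label.n_labels - labels_lost
    return ion_mz(f.with_labels(label.heavy_isotope, retained), ion)


# ---------------------------------------------------------------------------
# Biotransformation rules
# ---------------------------------------------------------------------------

_SIGNED_RE = re.compile(r"([+-]?)([^+-]+)")


@dataclass(frozen=True)
class TransformationRule:
    """A named biotransformation as a signed element-count delta.

    ``element_delta`` maps symbols (light elements or heavy isotopes) to
    signed integers; the monoisotopic mass shift is derived.  ``phase`` is
    "I", "II" or "adduct/isotope" (ionization artifacts and isotope spacings,
    kept separate from chemistry for networking).
    """

    name: str
    element_delta: Mapping[str, int]
    phase: str = "I"

    def __post_init__(self) -> None:
        delta = {s: int(n) for s, n in self.element_delta.items() if n != 0}
        for s in delta:
            if s not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown symbol {s!r} in rule {self.name!r}")
        object.__setattr__(self, "element_delta", delta)

    @property
    def mass_delta(self) -> float:
        """Signed monoisotopic mass shift in Da."""
        return sum(n * MONOISOTOPIC_MASS[s] for s, n in self.element_delta.items())

    @classmethod
    def from_delta_string(
        cls, name: str, delta: str, phase: str = "I"
    ) -> "TransformationRule":
        """Build a rule from a signed formula string such as "+O", "-CH2",
        "+C6H8O6" or "+[13C]-C"."""
        delta = delta.strip().replace(" ", "")
        if not delta:
            return cls(name, {}, phase)
        out: dict[str, int] = {}
        pos = 0
        for m in _SIGNED_RE.finditer(delta):
            if m.start() != pos:
                raise FormulaError(f"cannot parse delta {delta!r}")
            pos = m.end()
            sign = -1 if m.group(1) == "-" else 1
            chunk = parse_formula(m.group(2))
            for el, n in chunk.counts.items():
                n_heavy = sum(
                    k for iso, k in chunk.label_counts.items()
                    if _light_of(iso) == el
                )
                if n - n_heavy:
                    out[el] = out.get(el, 0) + sign * (n - n_heavy)
            for iso, n in chunk.label_counts.items():
                out[iso] = out.get(iso, 0) + sign * n
        if pos != len(delta):
            raise FormulaError(f"cannot parse delta {delta!r}")
        return cls(name, out, phase)

    def delta_string(self) -> str:
        """Signed formula string round-tripping through
        :meth:`from_delta_string`."""
        pos_part: dict[str, int] = {}
        neg_part: dict[str, int] = {}
        for s, n in sorted(self.element_delta.items()):
            (pos_part if n > 0 else neg_part)[s] = abs(n)

        def fmt(part: Mapping[str, int]) -> str:
            out = []
            for s, n in part.items():
                sym = f"[{s}]" if _is_heavy(s) else s
                out.append(sym + (str(n) if n != 1 else ""))
            return "".join(out)

        text = ""
        if pos_part:
            text += "+" + fmt(pos_part)
        if neg_part:
            text += "-" + fmt(neg_part)
        return text or "+"


def apply_transformation(
    f: ElementalFormula, rule: TransformationRule
) -> ElementalFormula:
    """Apply a biotransformation delta to a formula.

    Heavy-isotope deltas are substitutions: "+[13C]-C" converts one carbon to
    13C, leaving the atom count unchanged.  Raises :class:`FormulaError` if
    any resulting count would be negative (the transformation is chemically
    impossible for this formula).
    """
    counts = dict(f.counts)
    labels = dict(f.label_counts)
    for sym, d in rule.element_delta.items():
        if _is_heavy(sym):
            labels[sym] = labels.get(sym, 0) + d
            light = _light_of(sym)
            counts[light] = counts.get(light, 0) + d
        else:
            counts[sym] = counts.get(sym, 0) + d
    for e, n in counts.items():
        if n < 0:
            raise FormulaError(
                f"rule {rule.name!r} leaves negative {e} count on "
                f"{f.to_string()!r}"
            )
    for iso, n in labels.items():
        if n < 0 or n > counts.get(_light_of(iso), 0):
            raise FormulaError(
                f"rule {rule.name!r} leaves invalid {iso} substitution on "
                f"{f.to_string()!r}"
            )
    return ElementalFormula(counts, labels)


@dataclass(frozen=True)
class ProductCandidate:
    """A metabolite formula reachable from a parent by a chain of rules."""

    chain: tuple[str, ...]
    formula: ElementalFormula

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


def enumerate_products(
    parent: ElementalFormula,
    rules: Sequence[TransformationRule],
    depth: int = 2,
) -> list[ProductCandidate]:
    """All distinct formulas reachable by up to ``depth`` rule applications.

    Breadth-first over rule chains; chemically impossible branches (negative
    counts) are pruned; products are deduplicated by formula, keeping the
    shortest chain found first.  The parent itself is not a product.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    by_name = {r.name: r for r in rules}
    if len(by_name) != len(rules):
        raise ValueError("rule names must be unique")
    seen: dict[ElementalFormula, tuple[str, ...]] = {}
    frontier: list[tuple[tuple[str, ...], ElementalFormula]] = [((), parent)]
    for _ in range(depth):
        nxt: list[tuple[tuple[str, ...], ElementalFormula]] = []
        for chain, f in frontier:
            for rule in rules:
                try:
                    g = apply_transformation(f, rule)
                except FormulaError:
                    continue
                if g == parent or g in seen:
                    continue
                seen[g] = chain + (rule.name,)
                nxt.append((chain + (rule.name,), g))
        frontier = nxt
    return [ProductCandidate(chain, f) for f, chain in seen.items()]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def within_ppm(observed: float, theoretical: float, tol: float) -> bool:
    return abs(ppm_error(observed, theoretical)) <= tol


# ---------------------------------------------------------------------------
# Rule tables
# ---------------------------------------------------------------------------


def load_rules(
    path=None, phases: Iterable[str] | None = None
) -> list[TransformationRule]:
    """Load a transformation table from a TSV of (name, delta, phase) rows.

    With no path, the packaged default table is used.  ``phases`` optionally
    restricts the result (e.g. ``("I", "II")`` to exclude adduct/isotope
    spacings when enumerating metabolites).
    """
    if path is None:
        text = (
            resources.files("ebimet.data").joinpath("transformations.tsv")
            .read_text()
        )
        lines = text.splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    rules = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "name":
            continue
        if len(fields) != 3:
            raise ValueError(f"malformed rule line: {line!r}")
        name, delta, phase = fields
        rules.append(TransformationRule.from_delta_string(name, delta, phase))
    if phases is not None:
        wanted = set(phases)
        rules = [r for r in rules if r.phase in wanted]
    return rules


def default_rules(phases: Iterable[str] | None = ("I", "II")) -> list[TransformationRule]:
    """The packaged biotransformation table (phase I/II only by default)."""
    return load_rules(None, phases=phases)


def rules_by_name(rules: Sequence[TransformationRule]) -> dict[str, TransformationRule]:
    return {r.name: r for r in rules}
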