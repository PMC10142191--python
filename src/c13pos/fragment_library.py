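"""Registry of GC-EI-MS fragments of TMS-derivatized amino and organic acids.

Each fragment of a trimethylsilyl (TMS) derivative retains a known subset of
the underlying metabolite's carbon backbone.  The registry records, for every
fragment used by the positional-enrichment workflow, its elemental formula,
nominal M0 m/z, the 1-based backbone carbon positions it carries (C1 =
carboxyl carbon, biochemical numbering), and the neutral loss that produces
it.  Two of the published rows are internally inconsistent (their printed
formula does not match the printed m/z); the registry keeps the published
values verbatim for audit and carries a self-consistent "working"
formula/m0 used by all computations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "ElementalFormula",
    "FragmentDefinition",
    "Discrepancy",
    "NOMINAL_MASSES",
    "METABOLITE_CARBONS",
    "parse_formula",
    "format_formula",
    "nominal_mass",
    "load_fragment_table",
    "validate_fragment_table",
    "fragments_for",
    "get_fragment",
    "write_registry_tsv",
    "read_registry_tsv",
]

#: Nominal (integer) atomic masses of the elements that occur in TMS fragments.
NOMINAL_MASSES: dict[str, int] = {"C": 12, "H": 1, "N": 14, "O": 16, "Si": 28}

#: Backbone carbon count of each supported metabolite.
METABOLITE_CARBONS: dict[str, int] = {
    "Alanine": 3,
    "Glycine": 2,
    "Serine": 3,
    "Malate": 4,
    "Glutamate": 5,
    "Proline": 5,
}


class ElementalFormula(dict):
    """Element -> count mapping restricted to C, H, N, O, Si.

    Behaves like a plain dict; construction validates element symbols and
    positivity of counts.
    """

    def __init__(self, counts: dict[str, int]):
        clean: dict[str, int] = {}
        for el, n in counts.items():
            if el not in NOMINAL_MASSES:
                raise ValueError(f"unsupported element {el!r}")
            if not isinstance(n, int) or n <= 0:
                raise ValueError(f"count for {el} must be a positive integer, got {n!r}")
            clean[el] = n
        if not clean:
            raise ValueError("formula must contain at least one atom")
        super().__init__(clean)

    @property
    def n_atoms(self) -> int:
        return sum(self.values())


_TOKEN = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-like formula string into an :class:`ElementalFormula`.

    Both the plain dialect (``"C8H20NO2Si2"``) and the underscore-subscript
    dialect (``"C_8_H_20_NO_2_Si_2"``) are accepted.  An omitted count means 1.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.end() == pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in NOMINAL_MASSES:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


def format_formula(f: ElementalFormula, subscripts: bool = False) -> str:
    """Render a formula in Hill-like order (C, H, then alphabetical)."""
    order = ["C", "H", "N", "O", "Si"]
    parts = []
    for el in order:
        if el in f:
            n = f[el]
            if subscripts:
                parts.append(el if n == 1 else f"{el}_{n}_")
            else:
                parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def nominal_mass(f: ElementalFormula | dict[str, int]) -> int:
    """Nominal mass: sum of counts times integer atomic masses."""
    if not isinstance(f, ElementalFormula):
        f = ElementalFormula(dict(f))
    return sum(NOMINAL_MASSES[el] * n for el, n in f.items())


@dataclass(frozen=True)
class FragmentDefinition:
    """One mass fragment of a TMS derivative.

    ``formula`` and ``m0_mz`` are the working (self-consistent) values used in
    every computation; ``published_formula``/``published_m0`` keep the values
    exactly as published, which differ for two known rows.
    """

    metabolite: str
    derivative: str          # e.g. "Alanine(2TMS)"
    backbone_positions: tuple[int, ...]
    m0_mz: int
    formula: ElementalFormula
    loss: str = ""
    published_formula: str = ""
    published_m0: int = 0
    source: str = "table"    # "table" or "text"

    def __post_init__(self):
        n_c = METABOLITE_CARBONS[self.metabolite]
        if not self.backbone_positions:
            raise ValueError("fragment must carry at least one backbone carbon")
        if any(p < 1 or p > n_c for p in self.backbone_positions):
            raise ValueError(
                f"backbone positions {self.backbone_positions} outside 1..{n_c} "
                f"for {self.metabolite}"
            )
        if len(self.backbone_positions) > self.formula.get("C", 0):
            raise ValueError("more backbone carbons than carbons in the formula")
        if not self.published_formula:
            object.__setattr__(self, "published_formula", format_formula(self.formula))
        if not self.published_m0:
            object.__setattr__(self, "published_m0", self.m0_mz)

    @property
    def n_backbone(self) -> int:
        return len(self.backbone_positions)

    @property
    def positions_label(self) -> str:
        return "".join(f"C{p}" for p in self.backbone_positions)

    @property
    def fragment_id(self) -> str:
        """Registry key, e.g. ``"Glycine_C2_100"``."""
        return f"{self.metabolite}_{self.positions_label}_{self.m0_mz}"

    @property
    def consistent(self) -> bool:
        """True when the published formula reproduces the published m/z."""
        try:
            return nominal_mass(parse_formula(self.published_formula)) == self.published_m0
        except ValueError:
            return False


def _frag(met, deriv, positions, m0, formula, loss, published_formula=None,
          published_m0=None, source="table") -> FragmentDefinition:
    return FragmentDefinition(
        metabolite=met,
        derivative=deriv,
        backbone_positions=tuple(positions),
        m0_mz=m0,
        formula=parse_formula(formula),
        loss=loss,
        published_formula=published_formula or "",
        published_m0=published_m0 or 0,
        source=source,
    )


def load_fragment_table() -> list[FragmentDefinition]:
    """Return the built-in fragment registry.

    Covers every published table row plus the glycine C2 fragment at m/z 174
    ((TMS)2N=CH2+, from TMS-CO2 loss of glycine(3TMS)) that the positional
    workflow also uses.  The proline 142 row is published with formula C7H16N
    (nominal mass 114); its working formula is C7H16NSi, which matches both
    m/z 142 and the stated TMS-CO2 loss from the 259 derivative.  The
    glutamate TMS-CO2-loss row is published at m/z 245 although its formula
    computes to 246; the working M0 is 246 (the "C2-C3-C4-C5_246" fragment).
    """
    A, G, GLY, M, P, S = ("Alanine(2TMS)", "Glutamate(3TMS)", "Glycine(3TMS)",
                          "Malate(3TMS)", "Proline(2TMS)", "Serine(3TMS)")
    return [
        # -- alanine, 3 backbone carbons
        _frag("Alanine", A, (1, 2), 218, "C8H20NO2Si2", "CH3"),
        _frag("Alanine", A, (2, 3), 190, "C7H20NOSi2", "CH3, CO"),
        _frag("Alanine", A, (2, 3), 116, "C5H14NSi", "TMS-CO2"),
        _frag("Alanine", A, (1,), 103, "C4H11OSi", "unknown"),
        # -- glutamate, 5 backbone carbons
        _frag("Glutamate", G, (1, 2, 3, 4, 5), 348, "C13H30NO4Si3", "CH3"),
        _frag("Glutamate", G, (2, 3, 4, 5), 246, "C10H24NO2Si2", "TMS-CO2",
              published_formula="C10H24NO2Si2", published_m0=245),
        _frag("Glutamate", G, (2, 3, 4, 5), 156, "C7H14NOSi", "TMS-CO2, TMS-OH"),
        _frag("Glutamate", G, (1,), 117, "C4H9O2Si", "TMS-NH-C3H5-CO2-TMS"),
        # -- glycine, 2 backbone carbons
        _frag("Glycine", GLY, (1, 2), 276, "C10H26NO2Si3", "CH3"),
        _frag("Glycine", GLY, (2,), 248, "C9H26NOSi3", "CH3, CO"),
        _frag("Glycine", GLY, (2,), 174, "C7H20NSi2", "TMS-CO2", source="text"),
        _frag("Glycine", GLY, (2,), 100, "C4H10NSi", "TMS-CO2, TMS-H"),
        _frag("Glycine", GLY, (2,), 86, "C3H8NSi", "TMS-CO2, TMS-CH3"),
        # -- malate, 4 backbone carbons
        _frag("Malate", M, (1, 2, 3, 4), 335, "C12H27O5Si3", "CH3"),
        _frag("Malate", M, (2,), 265, "C10H29O2Si3", "C3HO3"),
        _frag("Malate", M, (1, 2, 3, 4), 245, "C9H17O4Si2", "TMS-OH, CH3"),
        _frag("Malate", M, (2, 3, 4), 233, "C9H21O3Si2", "TMS-CO2"),
        _frag("Malate", M, (2, 3), 189, "C7H17O2Si2", "TMS-CO2, CH3, COH"),
        _frag("Malate", M, (4,), 117, "C4H9O2Si", "C9H21O3Si2 (233)"),
        # -- proline, 5 backbone carbons
        _frag("Proline", P, (1, 2, 3, 4, 5), 244, "C10H22NO2Si2", "CH3"),
        _frag("Proline", P, (2, 3, 4, 5), 216, "C9H22NOSi2", "CH3, CO"),
        _frag("Proline", P, (2, 3, 4, 5), 142, "C7H16NSi", "TMS-CO2",
              published_formula="C7H16N", published_m0=142),
        # -- serine, 3 backbone carbons
        _frag("Serine", S, (1, 2, 3), 306, "C11H28NO3Si3", "CH3"),
        _frag("Serine", S, (2, 3), 278, "C10H28NO2Si3", "CH3, CO"),
        _frag("Serine", S, (1, 2), 218, "C8H20NO2Si2", "TMS-CH2O"),
        _frag("Serine", S, (2, 3), 204, "C8H22NOSi2", "TMS-CO2"),
        _frag("Serine", S, (2,), 100, "C4H10NSi", "unknown"),
    ]


def registry_index(defs: Iterable[FragmentDefinition] | None = None
                   ) -> dict[str, FragmentDefinition]:
    """Map fragment_id -> FragmentDefinition."""
    defs = load_fragment_table() if defs is None else list(defs)
    idx = {d.fragment_id: d for d in defs}
    if len(idx) != len(list(defs)):
        raise ValueError("duplicate fragment identifiers in registry")
    return idx


def fragments_for(metabolite: str,
                  defs: Iterable[FragmentDefinition] | None = None
                  ) -> list[FragmentDefinition]:
    """All registry fragments of one metabolite."""
    defs = load_fragment_table() if defs is None else list(defs)
    return [d for d in defs if d.metabolite == metabolite]


def get_fragment(fragment_id: str) -> FragmentDefinition:
    """Look one fragment up by its registry key."""
    idx = registry_index()
    try:
        return idx[fragment_id]
    except KeyError:
        raise KeyError(
            f"unknown fragment {fragment_id!r}; known keys include "
            f"{sorted(idx)[:5]} ..."
        ) from None


@dataclass(frozen=True)
class Discrepancy:
    """A registry row whose published formula does not reproduce its m/z."""

    fragment_id: str
    published_formula: str
    published_m0: int
    computed_mass: int


def validate_fragment_table(defs: Iterable[FragmentDefinition] | None = None
                            ) -> list[Discrepancy]:
    """Audit published formula/m0 pairs; report (never fix) mismatches.

    Working values are always self-consistent; this checks the rows as
    published.  Exactly two rows are expected to be discrepant: the proline
    C2-C5 fragment at 142 and the glutamate C2-C5 fragment published at 245.
    """
    defs = load_fragment_table() if defs is None else defs
    out = []
    for d in defs:
        computed = nominal_mass(parse_formula(d.published_formula))
        if computed != d.published_m0:
            out.append(Discrepancy(d.fragment_id, d.published_formula,
                                   d.published_m0, computed))
    return out


_TSV_HEADER = ["fragment_id", "metabolite", "derivative", "loss", "formula",
               "m0_mz", "backbone_positions", "published_formula",
               "published_m0", "source"]


def write_registry_tsv(path: str | Path,
                       defs: Iterable[FragmentDefinition] | None = None) -> None:
    """Serialize the registry as a tab-separated table users can extend."""
    defs = load_fragment_table() if defs is None else defs
    lines = ["\t".join(_TSV_HEADER)]
    for d in defs:
        lines.append("\t".join([
            d.fragment_id, d.metabolite, d.derivative, d.loss,
            format_formula(d.formula), str(d.m0_mz),
            "-".join(str(p) for p in d.backbone_positions),
            d.published_formula, str(d.published_m0), d.source,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_registry_tsv(path: str | Path) -> list[FragmentDefinition]:
    """Read a registry written by :func:`write_registry_tsv`."""
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    if header != _TSV_HEADER:
        raise ValueError(f"unexpected registry header: {header}")
    defs = []
    for line in lines[1:]:
        f = dict(zip(header, line.split("\t")))
        defs.append(FragmentDefinition(
            metabolite=f["metabolite"],
            derivative=f["derivative"],
            backbone_positions=tuple(int(p) for p in f["backbone_positions"].split("-")),
            m0_mz=int(f["m0_mz"]),
            formula=parse_formula(f["formula"]),
            loss=f["loss"],
            published_formula=f["published_formula"],
            published_m0=int(f["published_m0"]),
            source=f["source"],
        ))
    return defs
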