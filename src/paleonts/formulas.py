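"""Molecular-formula parsing and per-molecule descriptors.

Implements the descriptor set used to characterise organic-aerosol
molecules detected by (−)ESI LC-HRMS nontarget screening:

* DBE (double-bond equivalent), with halogens counted together with H;
* the aromaticity equivalent χc, a DBE-based index that discounts
  π-bonded oxygen and sulfur (fractions ``m`` and ``n``, default 0.5 as
  appropriate for carboxylic acids/esters dominating (−)ESI spectra);
  χc ≥ 2.5 flags likely aromatics;
* the average carbon oxidation state OSc = 2·O/C − H/C;
* heteroatom compound classes (CHO, CHNO, CHNOS, CHOS, other);
* Van Krevelen (H/C vs O/C) and Kroll (OSc vs nC) region annotations.

Descriptors are computed for the CHNOS element space; elements beyond
it only enter DBE (halogens) and force class ``other``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "DescriptorConfig",
    "DescriptorRecord",
    "parse_formula",
    "compound_class",
    "dbe",
    "aromaticity_equivalent",
    "carbon_oxidation_state",
    "annotate_regions",
    "compute_descriptors",
    "descriptor_frame",
    "KROLL_REGIONS",
    "COMPOUND_CLASSES",
]

HALOGENS = ("F", "Cl", "Br", "I")

COMPOUND_CLASSES = ("CHO", "CHNO", "CHNOS", "CHOS", "other")

#: Kroll-diagram OSc bands (closed intervals; they overlap by construction).
#: Monoterpene bands cover ozonolysis and OH oxidation products; the
#: hydrocarbon-like band marks barely oxidised reduced material.
KROLL_REGIONS: Mapping[str, tuple[float, float]] = {
    "monoterpene-oxidation": (-1.0, -0.5),
    "isoprene-OH": (-0.8, -0.2),
    "SVOC": (-0.5, 0.0),
    "LVOC": (0.0, 0.9),
    "hydrocarbon-like": (-1.7, -1.6),
}

VK_ALIPHATIC = "aliphatic"
VK_UNSATURATED = "unsaturated/aromatic-leaning"


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid element counts."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a neutral molecular formula.

    Counts are stored for every element present with count > 0; unknown
    element symbols are preserved as given. Instances are hashable and
    compare by composition.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        cleaned = {}
        for sym, n in self.element_counts.items():
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {sym!r} must be a non-negative integer, got {n!r}")
            if n > 0:
                cleaned[sym] = n
        if not cleaned:
            raise FormulaError("formula has no atoms")
        object.__setattr__(self, "element_counts", dict(cleaned))

    def __getitem__(self, symbol: str) -> int:
        return self.element_counts.get(symbol, 0)

    def __hash__(self) -> int:
        return hash(frozenset(self.element_counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return self.element_counts == other.element_counts

    @property
    def C(self) -> int:  # noqa: N802 - element symbols are canonical
        return self["C"]

    @property
    def H(self) -> int:  # noqa: N802
        return self["H"]

    @property
    def N(self) -> int:  # noqa: N802
        return self["N"]

    @property
    def O(self) -> int:  # noqa: N802
        return self["O"]

    @property
    def S(self) -> int:  # noqa: N802
        return self["S"]

    @property
    def halogen_count(self) -> int:
        return sum(self[x] for x in HALOGENS)

    def hill(self) -> str:
        """Serialize in Hill order (C, H, then alphabetical; all
        alphabetical when no carbon)."""
        counts = self.element_counts
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
            order += sorted(s for s in counts if s not in ("C", "H"))
        else:
            order = sorted(counts)
        return "".join(f"{s}{counts[s] if counts[s] != 1 else ''}" for s in order)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style elemental formula string.

    Explicit ``1`` counts are accepted; repeated element tokens are
    summed. Raises :class:`FormulaError` naming the offending position
    on malformed input.
    """
    if text is None or not str(text).strip():
        raise FormulaError("empty formula string")
    s = str(text).strip()
    counts: dict[str, int] = {}
    i = 0
    while i < len(s):
        m = _TOKEN.match(s, i)
        if m is None or m.end() == i:
            raise FormulaError(
                f"malformed formula {s!r}: unexpected character {s[i]!r} at position {i}"
            )
        sym, digits = m.groups()
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        i = m.end()
    return MolecularFormula(counts)


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunables of the aromaticity equivalent.

    ``m_pi_oxygen`` / ``n_pi_sulfur`` are the fractions of O and S atoms
    assumed to sit in π-bonded structures (0.5 suits carboxylic acids
    and esters, the dominant (−)ESI responders); ``aromatic_threshold``
    is the χc value above which a molecule is counted as aromatic.
    """

    m_pi_oxygen: float = 0.5
    n_pi_sulfur: float = 0.5
    aromatic_threshold: float = 2.5

    def __post_init__(self) -> None:
        for name in ("m_pi_oxygen", "n_pi_sulfur"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def compound_class(f: MolecularFormula) -> str:
    """Heteroatom class label: CHO, CHNO, CHNOS, CHOS or other."""
    present = frozenset(f.element_counts)
    if present == {"C", "H", "O"}:
        return "CHO"
    if present == {"C", "H", "N", "O"}:
        return "CHNO"
    if present == {"C", "H", "N", "O", "S"}:
        return "CHNOS"
    if present == {"C", "H", "O", "S"}:
        return "CHOS"
    return "other"


def dbe(f: MolecularFormula) -> float:
    """Double-bond equivalent, DBE = C − (H + halogens)/2 + N/2 + 1.

    Halogens substitute for hydrogen and are counted with it. The value
    is not clamped; exotic inputs may return negative DBE.
    """
    return f.C - (f.H + f.halogen_count) / 2.0 + f.N / 2.0 + 1.0


def aromaticity_equivalent(f: MolecularFormula, cfg: DescriptorConfig | None = None) -> float:
    """Aromaticity equivalent χc = [3·(DBE − m·O − n·S) − 2]/(DBE − m·O − n·S).

    Negative values are clamped to 0; a non-positive discounted DBE
    (degenerate denominator) also returns 0, keeping χc total and ≥ 0.
    """
    cfg = cfg or DescriptorConfig()
    d = dbe(f) - (cfg.m_pi_oxygen * f.O + cfg.n_pi_sulfur * f.S)
    if d <= 0:
        return 0.0
    return max(0.0, (3.0 * d - 2.0) / d)


def carbon_oxidation_state(f: MolecularFormula) -> float:
    """Average carbon oxidation state OSc = 2·O/C − H/C."""
    if f.C == 0:
        raise ValueError(f"carbon oxidation state undefined for carbon-free formula {f}")
    return 2.0 * f.O / f.C - f.H / f.C


@dataclass(frozen=True)
class DescriptorRecord:
    """Derived per-molecule quantities used throughout the pipeline."""

    nC: int
    oc_ratio: float
    hc_ratio: float
    dbe: float
    chi_c: float
    osc: float
    compound_class: str
    vk_region: str = ""
    kroll_regions: frozenset[str] = field(default_factory=frozenset)


def annotate_regions(osc: float, hc_ratio: float) -> tuple[str, frozenset[str]]:
    """Van Krevelen and Kroll region labels for one molecule.

    The Van Krevelen rule splits aliphatic (H/C ≥ 1.5) from
    unsaturated/aromatic-leaning compositions; Kroll membership is the
    set of all OSc bands whose closed interval contains the value.
    """
    vk = VK_ALIPHATIC if hc_ratio >= 1.5 else VK_UNSATURATED
    kroll = frozenset(
        label for label, (lo, hi) in KROLL_REGIONS.items() if lo <= osc <= hi
    )
    return vk, kroll


def compute_descriptors(f: MolecularFormula, cfg: DescriptorConfig | None = None) -> DescriptorRecord:
    """Full descriptor record for a formula with C > 0."""
    if f.C == 0:
        raise ValueError(f"descriptors require at least one carbon atom: {f}")
    cfg = cfg or DescriptorConfig()
    oc = f.O / f.C
    hc = f.H / f.C
    osc = carbon_oxidation_state(f)
    vk, kroll = annotate_regions(osc, hc)
    return DescriptorRecord(
        nC=f.C,
        oc_ratio=oc,
        hc_ratio=hc,
        dbe=dbe(f),
        chi_c=aromaticity_equivalent(f, cfg),
        osc=osc,
        compound_class=compound_class(f),
        vk_region=vk,
        kroll_regions=kroll,
    )


def descriptor_frame(
    formulas: Mapping[str, MolecularFormula] | Iterable[tuple[str, MolecularFormula]],
    cfg: DescriptorConfig | None = None,
) -> pd.DataFrame:
    """Tabulate descriptors, one row per molecule id.

    Columns: id, formula, nC, oc, hc, dbe, chi_c, osc, compound_class,
    vk_region, kroll_regions (semicolon-joined). Values are stored at
    full precision; round only for display.
    """
    items = formulas.items() if isinstance(formulas, Mapping) else formulas
    rows = []
    for mol_id, f in items:
        d = compute_descriptors(f, cfg)
        rows.append(
            {
                "id": mol_id,
                "formula": f.hill(),
                "nC": d.nC,
                "oc": d.oc_ratio,
                "hc": d.hc_ratio,
                "dbe": d.dbe,
                "chi_c": d.chi_c,
                "osc": d.osc,
                "compound_class": d.compound_class,
                "vk_region": d.vk_region,
                "kroll_regions": ";".join(sorted(d.kroll_regions)),
            }
        )
    return pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame(
        columns=[
            "formula", "nC", "oc", "hc", "dbe", "chi_c", "osc",
            "compound_class", "vk_region", "kroll_regions",
        ]
    )
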