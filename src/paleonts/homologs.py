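"""CH2-homolog series detection.

Two formulas are homologs when they differ only by an integer number of
CH2 units, i.e. they share the offset k = H − 2C and every non-CH
element count. A series C_nH_{2n+k}O_o then has constant DBE and
constant compound class; the notation matches the usual series
shorthand (e.g. the dicarboxylic series CnH2n−2O4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formulas import MolecularFormula, compound_class, dbe

__all__ = ["HomologKey", "HomologSeries", "homolog_key", "find_series", "series_frame"]


@dataclass(frozen=True, order=True)
class HomologKey:
    """Identity of a CH2 series: H−2C offset and all non-CH counts."""

    k_offset: int
    o_count: int
    n_count: int
    s_count: int
    #: remaining non-CH elements as a sorted (symbol, count) tuple, so
    #: e.g. a chlorinated formula never keys with its Cl-free analog
    extra: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class HomologSeries:
    """One detected series, members sorted by carbon number."""

    key: HomologKey
    members: tuple[tuple[MolecularFormula, int], ...]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def carbon_numbers(self) -> tuple[int, ...]:
        return tuple(n for _, n in self.members)

    @property
    def dbe(self) -> float:
        return dbe(self.members[0][0])


def homolog_key(f: MolecularFormula) -> HomologKey:
    """Series key of a formula (requires C > 0)."""
    if f.C == 0:
        raise ValueError(f"homolog key requires carbon: {f}")
    extra = tuple(
        sorted((s, c) for s, c in f.element_counts.items() if s not in ("C", "H", "O", "N", "S"))
    )
    return HomologKey(
        k_offset=f.H - 2 * f.C,
        o_count=f.O,
        n_count=f.N,
        s_count=f.S,
        extra=extra,
    )


def find_series(
    formulas: Iterable[MolecularFormula], min_members: int = 3
) -> list[HomologSeries]:
    """Group formulas into CH2-homolog series with ≥ ``min_members``.

    Duplicate formulas count once. Gaps in n are allowed (e.g. an
    unsaturated monocarboxylic series may skip a carbon number). Series
    are returned sorted by member count (descending), then by key.
    """
    if min_members < 2:
        raise ValueError("min_members must be at least 2")
    groups: dict[HomologKey, dict[int, MolecularFormula]] = {}
    for f in formulas:
        key = homolog_key(f)
        groups.setdefault(key, {})[f.C] = f
    out = []
    for key, by_nc in groups.items():
        if len(by_nc) >= min_members:
            members = tuple((by_nc[n], n) for n in sorted(by_nc))
            out.append(HomologSeries(key=key, members=members))
    out.sort(key=lambda s: (-len(s), s.key))
    return out


def series_frame(
    series: Sequence[HomologSeries],
    rt_by_formula: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One row per series member: series_id, key fields, formula, nC, dbe.

    When retention times are supplied (formula string → minutes) an
    ``rt`` column is added as a diagnostic — RT is expected to grow with
    nC within a series, but coherence is reported, never enforced.
    """
    rows = []
    for i, s in enumerate(series, start=1):
        for f, n in s.members:
            row = {
                "series_id": i,
                "k_offset": s.key.k_offset,
                "O": s.key.o_count,
                "N": s.key.n_count,
                "S": s.key.s_count,
                "formula": f.hill(),
                "nC": n,
                "dbe": dbe(f),
                "compound_class": compound_class(f),
            }
            if rt_by_formula is not None:
                row["rt"] = rt_by_formula.get(f.hill(), float("nan"))
            rows.append(row)
    return pd.DataFrame(rows)
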