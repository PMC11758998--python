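"""Identification confidence levels (Schymanski scale, 5 → 1).

Level 5: only m/z known (no formula). Level 4: molecular formula
assigned. Level 3: several plausible library structures. Level 2: an
unambiguous (unique) library spectral match. Level 1: confirmation
against a reference standard, requiring |ΔRT| ≤ 0.1 min between the
feature and the standard of the same formula.

Spectral similarity is a greedy-paired cosine on square-root-scaled
fragment intensities; proprietary vendor match scores present in input
tables are carried through as annotations, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureProfile
from .formulas import MolecularFormula, parse_formula

__all__ = [
    "ReferenceStandard",
    "SpectrumEntry",
    "IdentificationResult",
    "read_standards",
    "read_msp",
    "spectral_match",
    "assign_level",
]


@dataclass(frozen=True)
class ReferenceStandard:
    """In-house standard: compound name, formula and retention time (min)."""

    name: str
    formula: MolecularFormula
    rt: float

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"standard {self.name}: rt must be >= 0")


@dataclass(frozen=True)
class SpectrumEntry:
    """Library fragmentation spectrum; peaks sorted by m/z, intensities
    normalized to a base peak of 100."""

    name: str
    formula: MolecularFormula | None
    peaks: tuple[tuple[float, float], ...]

    @staticmethod
    def from_peaks(
        name: str,
        peaks: Sequence[tuple[float, float]],
        formula: MolecularFormula | None = None,
    ) -> "SpectrumEntry":
        if not peaks:
            raise ValueError(f"spectrum {name}: no peaks")
        top = max(i for _, i in peaks)
        if top <= 0:
            raise ValueError(f"spectrum {name}: all intensities are zero")
        norm = tuple(sorted((float(m), 100.0 * float(i) / top) for m, i in peaks))
        return SpectrumEntry(name=name, formula=formula, peaks=norm)


@dataclass(frozen=True)
class IdentificationResult:
    """Assigned confidence level with scored candidates and rationale."""

    level: int
    candidates: tuple[tuple[str, float], ...] = ()
    evidence: str = ""


def read_standards(path: str | Path) -> list[ReferenceStandard]:
    """Read a delimited standards table (name, formula, rt_min)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"name", "formula", "rt_min"} - set(df.columns)
    if missing:
        raise ValueError(f"standards table {path} missing column(s): {sorted(missing)}")
    return [
        ReferenceStandard(str(r.name), parse_formula(str(r.formula)), float(r.rt_min))
        for r in df.itertuples(index=False)
    ]


def read_msp(path: str | Path) -> list[SpectrumEntry]:
    """Read an MSP-format spectral library via matchms."""
    from matchms.importing import load_from_msp

    entries = []
    for spec in load_from_msp(str(path)):
        if spec is None:
            continue
        meta = spec.metadata
        name = meta.get("compound_name") or meta.get("name") or "unknown"
        ftext = meta.get("formula") or meta.get("molecular_formula")
        formula = parse_formula(ftext) if ftext else None
        peaks = list(zip(spec.peaks.mz.tolist(), spec.peaks.intensities.tolist()))
        if peaks:
            entries.append(SpectrumEntry.from_peaks(str(name), peaks, formula))
    return entries


def spectral_match(
    query: Sequence[tuple[float, float]] | SpectrumEntry,
    entry: Sequence[tuple[float, float]] | SpectrumEntry,
    mz_tol: float = 0.01,
) -> float:
    """Greedy-paired cosine similarity on sqrt-scaled intensities.

    Candidate peak pairs within ``mz_tol`` are matched greedily by
    ascending m/z difference, each peak used at most once; the score is
    the cosine of the matched sqrt-intensity vectors and is symmetric
    in its arguments. Returns a value in [0, 1].
    """
    a = np.asarray(query.peaks if isinstance(query, SpectrumEntry) else list(query), float)
    b = np.asarray(entry.peaks if isinstance(entry, SpectrumEntry) else list(entry), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both spectra must be non-empty")
    sa = np.sqrt(a[:, 1])
    sb = np.sqrt(b[:, 1])
    pairs = [
        (abs(a[i, 0] - b[j, 0]), i, j)
        for i in range(len(a))
        for j in range(len(b))
        if abs(a[i, 0] - b[j, 0]) <= mz_tol
    ]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += sa[i] * sb[j]
    denom = float(np.linalg.norm(sa) * np.linalg.norm(sb))
    if denom == 0:
        return 0.0
    return min(1.0, dot / denom)


def assign_level(
    feature: FeatureProfile,
    refdb: Sequence[ReferenceStandard] = (),
    speclib: Sequence[SpectrumEntry] = (),
    feature_ms2: Sequence[tuple[float, float]] | None = None,
    score_threshold: float = 0.6,
    mz_tol: float = 0.01,
    rt_tol: float = 0.1,
) -> IdentificationResult:
    """Assign a Schymanski confidence level to one feature.

    Evidence is monotone: a matching reference standard (same formula,
    |ΔRT| ≤ ``rt_tol`` minutes) confirms level 1; otherwise a unique
    above-threshold library match gives level 2, several give level 3
    (ambiguous structures), a bare formula level 4 and no formula
    level 5."""
    if feature.formula is None:
        return IdentificationResult(level=5, evidence="no molecular formula; exact mass only")

    std_hits = [
        s
        for s in refdb
        if s.formula == feature.formula and abs(s.rt - feature.rt) <= rt_tol
    ]
    if std_hits:
        best = min(std_hits, key=lambda s: abs(s.rt - feature.rt))
        return IdentificationResult(
            level=1,
            candidates=((best.name, 1.0),),
            evidence=(
                f"reference standard {best.name}: formula {feature.formula.hill()} "
                f"matches, ΔRT = {abs(best.rt - feature.rt):.3f} min <= {rt_tol}"
            ),
        )

    candidates: list[tuple[str, float]] = []
    if feature_ms2 and speclib:
        for entry in speclib:
            score = spectral_match(feature_ms2, entry, mz_tol=mz_tol)
            if score >= score_threshold:
                candidates.append((entry.name, score))
    candidates.sort(key=lambda t: -t[1])

    if len(candidates) == 1:
        return IdentificationResult(
            level=2,
            candidates=tuple(candidates),
            evidence=f"unique library match {candidates[0][0]} (score {candidates[0][1]:.2f})",
        )
    if len(candidates) >= 2:
        return IdentificationResult(
            level=3,
            candidates=tuple(candidates),
            evidence=f"{len(candidates)} library candidates above threshold; structure ambiguous",
        )
    return IdentificationResult(
        level=4,
        evidence=f"formula {feature.formula.hill()} assigned; no spectral or standard evidence",
    )
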