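"""Feature-table and sample-metadata I/O plus the six-predicate QC filter.

A *feature* (molecular profile) is one species detected across the
record: m/z, retention time, an upstream-assigned molecular formula,
per-sample intensities, procedural-blank intensities and vendor QC
fields. Filtering applies, in order: (i) not background, (ii) peak
rating, (iii) group CV, (iv) formula present, (v) maximum intensity,
(vi) sample-to-blank ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formulas import MolecularFormula, parse_formula

__all__ = [
    "FeatureProfile",
    "SampleMeta",
    "FilterConfig",
    "FILTER_PREDICATES",
    "read_sample_table",
    "read_feature_table",
    "write_feature_table",
    "apply_filters",
    "group_cv_from_replicates",
]

log = logging.getLogger(__name__)

FIXED_COLUMNS = ("id", "mz", "rt", "formula", "peak_rating", "group_cv", "is_background")

#: Rejection-tally keys, in the order predicates are evaluated.
FILTER_PREDICATES = (
    "background",
    "peak_rating",
    "group_cv",
    "formula",
    "max_intensity",
    "blank_ratio",
)


@dataclass(frozen=True)
class SampleMeta:
    """One dated ice-core sample."""

    sample_id: str
    depth: float
    year: float
    enrichment_factor: float = 1.0


@dataclass
class FeatureProfile:
    """One molecular profile with its per-sample intensities and QC fields."""

    id: str
    mz: float
    rt: float
    formula: MolecularFormula | None
    intensities: dict[str, float]
    blank_intensities: tuple[float, ...] = ()
    peak_rating: float = 10.0
    group_cv: float = 0.0
    is_background: bool = False

    @property
    def max_intensity(self) -> float:
        return max(self.intensities.values(), default=0.0)

    @property
    def max_blank(self) -> float:
        return max(self.blank_intensities, default=0.0)

    @property
    def sample_blank_ratio(self) -> float:
        """max sample intensity / max blank; +inf for an all-zero blank."""
        if self.max_blank <= 0:
            return math.inf
        return self.max_intensity / self.max_blank


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the six QC predicates (defaults = study settings)."""

    min_peak_rating: float = 7.0
    max_group_cv: float = 15.0
    min_max_intensity: float = 5e6
    min_sample_blank_ratio: float = 3.0
    require_formula: bool = True
    exclude_background: bool = True


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("true", "1", "yes", "t")
    return bool(x)


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata (sample_id, depth_m, year_ce, enrichment_factor)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "depth_m", "year_ce"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table {path} missing column(s): {sorted(missing)}")
    ef = df["enrichment_factor"] if "enrichment_factor" in df.columns else 1.0
    df = df.assign(enrichment_factor=ef)
    return [
        SampleMeta(str(r.sample_id), float(r.depth_m), float(r.year_ce), float(r.enrichment_factor))
        for r in df.itertuples()
    ]


def read_feature_table(path: str | Path, samples: Sequence[SampleMeta]) -> list[FeatureProfile]:
    """Read a delimited feature table into profiles, in file order.

    The header must contain the fixed columns (id, mz, rt, formula,
    peak_rating, group_cv, is_background), optional ``blank_<k>``
    columns, and one intensity column per sample id. Blank formula
    cells yield ``formula=None``; missing intensity cells are read as 0
    (below detection).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"formula": str})
    missing = [c for c in FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} missing mandatory column(s): {missing}")
    sample_ids = [s.sample_id for s in samples]
    blank_cols = [c for c in df.columns if c.startswith("blank_")]
    known = set(FIXED_COLUMNS) | set(blank_cols)
    intensity_cols = [c for c in df.columns if c not in known]
    unmatched = [c for c in intensity_cols if c not in sample_ids]
    if unmatched:
        raise ValueError(
            f"feature table {path} has intensity column(s) without sample metadata: {unmatched}"
        )
    profiles = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        ftext = rec.get("formula")
        formula: MolecularFormula | None
        if ftext is None or (isinstance(ftext, float) and math.isnan(ftext)) or not str(ftext).strip():
            formula = None
        else:
            formula = parse_formula(str(ftext))
        intens = {
            c: float(rec[c]) if not pd.isna(rec[c]) else 0.0 for c in intensity_cols
        }
        blanks = tuple(
            float(rec[c]) if not pd.isna(rec[c]) else 0.0 for c in blank_cols
        )
        profiles.append(
            FeatureProfile(
                id=str(rec["id"]),
                mz=float(rec["mz"]),
                rt=float(rec["rt"]),
                formula=formula,
                intensities=intens,
                blank_intensities=blanks,
                peak_rating=float(rec["peak_rating"]),
                group_cv=float(rec["group_cv"]),
                is_background=_as_bool(rec["is_background"]),
            )
        )
    log.info("read %d profiles x %d samples from %s", len(profiles), len(intensity_cols), path)
    return profiles


def write_feature_table(profiles: Iterable[FeatureProfile], path: str | Path) -> None:
    """Write profiles back to delimited text in the canonical layout."""
    profiles = list(profiles)
    n_blank = max((len(p.blank_intensities) for p in profiles), default=0)
    sample_ids: list[str] = []
    for p in profiles:
        for sid in p.intensities:
            if sid not in sample_ids:
                sample_ids.append(sid)
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "id": p.id,
            "mz": p.mz,
            "rt": p.rt,
            "formula": p.formula.hill() if p.formula is not None else "",
            "peak_rating": p.peak_rating,
            "group_cv": p.group_cv,
            "is_background": p.is_background,
        }
        for k in range(n_blank):
            row[f"blank_{k + 1}"] = p.blank_intensities[k] if k < len(p.blank_intensities) else 0.0
        for sid in sample_ids:
            row[sid] = p.intensities.get(sid, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _first_failure(p: FeatureProfile, cfg: FilterConfig) -> str | None:
    """Name of the first failing predicate in order (i)-(vi), or None."""
    if cfg.exclude_background and p.is_background:
        return "background"
    if p.peak_rating < cfg.min_peak_rating:
        return "peak_rating"
    if p.group_cv > cfg.max_group_cv:
        return "group_cv"
    if cfg.require_formula and p.formula is None:
        return "formula"
    if p.max_intensity < cfg.min_max_intensity:
        return "max_intensity"
    if p.sample_blank_ratio < cfg.min_sample_blank_ratio:
        return "blank_ratio"
    return None


def apply_filters(
    profiles: Iterable[FeatureProfile], cfg: FilterConfig | None = None
) -> tuple[list[FeatureProfile], dict[str, int]]:
    """Keep profiles passing all six predicates; tally rejections.

    A rejected profile is attributed to the *first* failing predicate in
    the order background, peak_rating, group_cv, formula, max_intensity,
    blank_ratio, so kept + sum(tally) equals the input count.
    """
    cfg = cfg or FilterConfig()
    kept: list[FeatureProfile] = []
    tally = dict.fromkeys(FILTER_PREDICATES, 0)
    for p in profiles:
        reason = _first_failure(p, cfg)
        if reason is None:
            kept.append(p)
        else:
            tally[reason] += 1
    log.info("filter kept %d profiles; rejected %s", len(kept), {k: v for k, v in tally.items() if v})
    return kept, tally


def group_cv_from_replicates(replicates: Sequence[float]) -> float:
    """Coefficient of variation (percent) across replicate intensities.

    Helper for tables that ship replicate columns instead of a
    vendor-computed group CV."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2 or x.mean() == 0:
        return 0.0
    return 100.0 * x.std(ddof=1) / x.mean()
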