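"""Synthetic ice-core NTS datasets with known ground truth.

The generator emulates the statistical structure of a 1800–1980 CE
alpine ice-core nontarget-screening record so that every pipeline stage
is testable without any external data:

* 398 molecules split CHO/CHNO/CHNOS/CHOS/other at 75/18/3/2/2 % by
  count, with CHO carrying ~95 % of the record-total intensity;
* a *natural* cluster (2) of stationary-to-slightly-declining series, an
  *anthropogenic* subcluster 1A present throughout but ramping after
  1925, and a purely industrial subcluster 1B absent before its onset
  (1950; 1960 for CHNOS-class members, whose aggregated class record
  steps later);
* class-level step folds (CHNO ×1.4 at 1950, CHNOS ×1.9 at 1960)
  planted exactly in the noiseless construction by solving for the 1B
  intensity budget;
* multiplicative lognormal intensity noise (ESI response varies
  multiplicatively), procedural blanks, vendor-style QC columns, and a
  configurable number of deliberately failing rows to exercise the QC
  filter;
* nitrate/sulfate/ozone/OH proxy series built from the anthropogenic
  cluster mean plus calibrated noise, so the planted proxy correlation
  is known.

Everything planted is emitted in :class:`SyntheticTruth` for recovery
scoring.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureProfile, SampleMeta, write_feature_table
from .formulas import MolecularFormula
from .trends import ProxyRecord, bin_series
from .clustering import zscore

__all__ = ["GeneratorConfig", "SyntheticTruth", "SyntheticDataset", "generate", "write_dataset", "recovery_report"]

_MONOISOTOPIC = {
    "C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221,
    "S": 31.97207069, "P": 30.97376151, "Cl": 34.96885271, "F": 18.99840320,
    "Br": 78.9183376, "I": 126.904468,
}
_PROTON = 1.00727646688

CLASSES = ("CHO", "CHNO", "CHNOS", "CHOS", "other")
CLUSTERS = ("2", "1A", "1B")

#: cluster composition of each class (natural : 1A : 1B), mirroring the
#: composition of a biogenic-dominated record with an industrial overlay
CLASS_CLUSTER_WEIGHTS: Mapping[str, tuple[float, float, float]] = {
    "CHO": (195, 93, 9),
    "CHNO": (24, 27, 21),
    "CHNOS": (4, 0, 7),
    "CHOS": (2, 3, 3),
    "other": (2, 2, 6),
}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic record."""

    n_molecules: int = 398
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"CHO": 0.75, "CHNO": 0.18, "CHNOS": 0.03, "CHOS": 0.02, "other": 0.02}
    )
    class_intensity_shares: dict[str, float] = field(
        default_factory=lambda: {"CHO": 0.95, "CHNO": 0.04, "CHNOS": 0.004, "CHOS": 0.003, "other": 0.003}
    )
    cho_intensity_share_target: float = 0.95
    year_start: int = 1800
    year_end: int = 1980
    n_samples: int = 53
    bin_width: int = 5
    onset_year_1B: int = 1950
    step_year_chnos: int = 1960
    ramp_start_1A: int = 1925
    fold_1A: float = 1.4
    fold_CHNO: float = 1.4
    fold_CHNOS: float = 1.9
    share_1A_pre_target: float = 0.41
    natural_trend_slope: float = -6e-4  # fractional decline per year
    noise_cv: float = 0.15
    blank_level: float = 0.05
    total_intensity_scale: float = 1e13
    proxy_coupling: dict[str, float] = field(
        default_factory=lambda: {"nitrate": 0.70, "sulfate": 0.72, "ozone": 0.66, "OH": 0.30}
    )
    n_reject: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        for k, v in {"fold_1A": self.fold_1A, "fold_CHNO": self.fold_CHNO, "fold_CHNOS": self.fold_CHNOS}.items():
            if v <= 0:
                raise ValueError(f"{k} must be > 0")
        # keep the headline CHO target and the per-class share table consistent
        self.class_intensity_shares = dict(self.class_intensity_shares)
        self.class_intensity_shares["CHO"] = self.cho_intensity_share_target
        rest = 1.0 - self.cho_intensity_share_target
        others = [c for c in CLASSES if c != "CHO"]
        other_sum = sum(self.class_intensity_shares[c] for c in others)
        for c in others:
            self.class_intensity_shares[c] *= rest / other_sum


@dataclass
class SyntheticTruth:
    """Everything planted, for recovery scoring."""

    labels: dict[str, str]
    class_counts: dict[str, int]
    onset_years: dict[str, float]
    folds: dict[str, float]
    proxy_couplings: dict[str, float]
    cho_intensity_share: float
    share_1A_pre: float
    share_1A_post: float
    reject_ids: list[str] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    profiles: list[FeatureProfile]
    samples: list[SampleMeta]
    proxies: dict[str, ProxyRecord]
    truth: SyntheticTruth


def _quota_counts(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` over ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        return [0] * len(w)
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(exact - base))
    base[order[:rem]] += 1
    return base.tolist()


def _sample_formula(rng: np.random.Generator, mol_class: str, cluster: str) -> MolecularFormula:
    """Draw a chemically plausible formula conditioned on class and cluster.

    Cluster 1A skews to higher O/C and OSc and lower nC than the natural
    cluster; 1B is less oxidised with more aromatic compositions. H is
    kept within 1..2C+2+N (so DBE >= 0) with H+N even (integer DBE)."""
    if cluster == "1A":
        nc = 4 + rng.binomial(10, 0.25)
        oc_mu, osc_mu, osc_sd = 0.68, -0.30, 0.25
    elif cluster == "1B":
        nc = 4 + rng.binomial(12, 0.30)
        oc_mu, osc_mu, osc_sd = 0.42, -1.00, 0.40
    else:
        nc = 4 + rng.binomial(16, 0.28)
        oc_mu, osc_mu, osc_sd = 0.55, -0.60, 0.25
    nc = int(min(nc, 20))

    n = 0
    s = 0
    extra: dict[str, int] = {}
    if mol_class == "CHNO":
        n = 1 if rng.random() < 0.7 else 2
    elif mol_class == "CHNOS":
        n, s = 1, 1
    elif mol_class == "CHOS":
        s = 1
    elif mol_class == "other":
        variant = rng.choice(["CHOCl", "CHN", "CHNS", "CHOP"])
        if variant == "CHOCl":
            extra["Cl"] = 1
        elif variant == "CHN":
            n = 1
        elif variant == "CHNS":
            n, s = 1, 1
        elif variant == "CHOP":
            extra["P"] = 1

    # oxygen present except for the CHN / CHNS variants of class "other"
    no_oxygen = mol_class == "other" and (s + n > 0) and not extra
    for _ in range(50):
        oc = float(np.clip(rng.normal(oc_mu, 0.15), 0.12, 1.1))
        o = 0 if no_oxygen else int(np.clip(round(oc * nc), 1, 2 * nc))
        osc_t = rng.normal(osc_mu, osc_sd)
        hc = 2.0 * o / nc - osc_t
        hal = sum(extra.get(x, 0) for x in ("Cl", "F", "Br", "I"))
        h = int(round(hc * nc))
        # parity: DBE integer requires H + halogens + N even
        if (h + hal + n) % 2 == 1:
            h += 1
        h = int(np.clip(h, 1 + ((1 + hal + n) % 2), 2 * nc + 2 + n - hal))
        if (h + hal + n) % 2 == 1:
            h -= 1
        if 1 <= h <= 2 * nc + 2 + n - hal:
            counts = {"C": nc, "H": h}
            if n:
                counts["N"] = n
            if o:
                counts["O"] = o
            if s:
                counts["S"] = s
            counts.update(extra)
            return MolecularFormula(counts)
    # deterministic fallback: a saturated acid-like composition
    counts = {"C": nc, "H": 2 * nc - 2 - (n % 2), "O": max(1, o)}
    if n:
        counts["N"] = n
    if s:
        counts["S"] = s
    counts.update(extra)
    return MolecularFormula(counts)


def _mz_neg_mode(f: MolecularFormula) -> float:
    """[M−H]− mass-to-charge from monoisotopic element masses."""
    m = sum(_MONOISOTOPIC.get(sym, 0.0) * cnt for sym, cnt in f.element_counts.items())
    return m - _PROTON


def _template(cfg: GeneratorConfig, cluster: str, onset: float, years: np.ndarray) -> np.ndarray:
    """Noiseless multiplicative time template of one molecule."""
    y = np.asarray(years, dtype=float)
    if cluster == "2":
        return 1.0 + cfg.natural_trend_slope * (y - cfg.year_start)
    if cluster == "1A":
        ramp = (y - cfg.ramp_start_1A) / (cfg.year_end - cfg.ramp_start_1A)
        return np.where(y < cfg.ramp_start_1A, 1.0, 1.0 + (cfg.fold_1A - 1.0) * ramp)
    if cluster == "1B":
        return np.where(y < onset, 0.0, 1.0)
    raise ValueError(f"unknown cluster {cluster!r}")


def _bin_means(values: np.ndarray, years: np.ndarray, cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    idx = np.floor((years - cfg.year_start) / cfg.bin_width).astype(int)
    n_bins = idx.max() + 1
    bin_years = cfg.year_start + cfg.bin_width * np.arange(n_bins)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = idx == b
        if m.any():
            out[b] = values[m].mean()
    return bin_years, out


def generate(cfg: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate one synthetic record (deterministic under ``cfg.seed``)."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- samples: unevenly spaced dated samples spanning the record ----
    inner = rng.choice(
        np.arange(cfg.year_start + 1, cfg.year_end), size=cfg.n_samples - 2, replace=False
    )
    years = np.sort(np.concatenate([[cfg.year_start], inner, [cfg.year_end]])).astype(float)
    depth = np.interp(years, [cfg.year_start, cfg.year_end], [62.87, 26.55])
    enrich = rng.normal(92.0, 3.0, size=cfg.n_samples)
    samples = [
        SampleMeta(f"S{i + 1:03d}", float(depth[i]), float(years[i]), float(enrich[i]))
        for i in range(cfg.n_samples)
    ]
    sample_ids = [s.sample_id for s in samples]

    # --- molecule roster: quota class counts, quota cluster split ------
    class_counts = dict(
        zip(CLASSES, _quota_counts(cfg.n_molecules, [cfg.class_proportions[c] for c in CLASSES]))
    )
    roster: list[tuple[str, str, str, float]] = []  # (id, class, cluster, onset)
    mol_idx = 0
    for mol_class in CLASSES:
        cluster_n = _quota_counts(class_counts[mol_class], CLASS_CLUSTER_WEIGHTS[mol_class])
        for cluster, n_in in zip(CLUSTERS, cluster_n):
            for _ in range(n_in):
                mol_idx += 1
                onset = float(cfg.step_year_chnos if mol_class == "CHNOS" else cfg.onset_year_1B)
                roster.append((f"M{mol_idx:04d}", mol_class, cluster, onset))

    # --- intensity budgets: noiseless group templates at bin level -----
    group_tpl: dict[tuple[str, str], np.ndarray] = {}
    for mol_class in CLASSES:
        onset = float(cfg.step_year_chnos if mol_class == "CHNOS" else cfg.onset_year_1B)
        for cluster in CLUSTERS:
            _, tb = _bin_means(_template(cfg, cluster, onset, years), years, cfg)
            group_tpl[(mol_class, cluster)] = tb
    bin_years, _ = _bin_means(years, years, cfg)

    def window_means(tb: np.ndarray, split_year: float) -> tuple[float, float]:
        pre = tb[bin_years < split_year]
        post = tb[bin_years >= split_year]
        return float(np.nanmean(pre)), float(np.nanmean(post))

    counts_by_group = {
        (mc, cl): sum(1 for _, c, k, _ in roster if c == mc and k == cl)
        for mc in CLASSES
        for cl in CLUSTERS
    }

    def class_budgets(mol_class: str, a1a_frac: float | None = None) -> dict[str, float]:
        """Relative (2, 1A, 1B) budgets, fold-calibrated where planted."""
        n2 = counts_by_group[(mol_class, "2")]
        n1a = counts_by_group[(mol_class, "1A")]
        n1b = counts_by_group[(mol_class, "1B")]
        if mol_class == "CHO":
            x = a1a_frac if a1a_frac is not None else (n1a / max(1, n1a + n2))
            base = {"2": 1.0 - x, "1A": x, "1B": 0.0}
            if n1b:
                base["1B"] = 0.02  # trace industrial CHO, as in the record
            return base
        fold = {"CHNO": cfg.fold_CHNO, "CHNOS": cfg.fold_CHNOS}.get(mol_class)
        split = float(cfg.step_year_chnos if mol_class == "CHNOS" else cfg.onset_year_1B)
        a = {"2": float(n2), "1A": float(n1a), "1B": 0.3 * n1b}
        if fold is not None and n1b:
            pre = sum(a[cl] * window_means(group_tpl[(mol_class, cl)], split)[0] for cl in ("2", "1A"))
            post = sum(a[cl] * window_means(group_tpl[(mol_class, cl)], split)[1] for cl in ("2", "1A"))
            tb_pre, tb_post = window_means(group_tpl[(mol_class, "1B")], split)
            need = (fold * pre - post) / tb_post
            if need < 0:
                raise ValueError(
                    f"infeasible fold target for {mol_class}: background already exceeds fold {fold}"
                )
            a["1B"] = need
        return a

    def normalise(budgets: dict[str, dict[str, float]]) -> dict[tuple[str, str], float]:
        """Scale each class to its record-total intensity share."""
        out: dict[tuple[str, str], float] = {}
        for mol_class in CLASSES:
            tot = sum(
                budgets[mol_class][cl] * float(np.nanmean(group_tpl[(mol_class, cl)]))
                for cl in CLUSTERS
            )
            scale = cfg.class_intensity_shares[mol_class] / tot if tot > 0 else 0.0
            for cl in CLUSTERS:
                out[(mol_class, cl)] = budgets[mol_class][cl] * scale
        return out

    def share_curve(scaled: dict[tuple[str, str], float]) -> np.ndarray:
        """Per-bin 1A percentage share of the noiseless construction."""
        num = sum(scaled[(mc, "1A")] * group_tpl[(mc, "1A")] for mc in CLASSES)
        den = sum(scaled[(mc, cl)] * group_tpl[(mc, cl)] for mc in CLASSES for cl in CLUSTERS)
        return num / den

    def share_1a_pre(x: float) -> float:
        budgets = {mc: class_budgets(mc, a1a_frac=x if mc == "CHO" else None) for mc in CLASSES}
        shares = share_curve(normalise(budgets))
        return float(np.nanmean(shares[bin_years < cfg.onset_year_1B]))

    from scipy.optimize import brentq

    lo, hi = 1e-3, 1 - 1e-3
    f_lo, f_hi = share_1a_pre(lo) - cfg.share_1A_pre_target, share_1a_pre(hi) - cfg.share_1A_pre_target
    if f_lo * f_hi > 0:
        x_star = counts_by_group[("CHO", "1A")] / max(
            1, counts_by_group[("CHO", "1A")] + counts_by_group[("CHO", "2")]
        )
    else:
        x_star = float(brentq(lambda x: share_1a_pre(x) - cfg.share_1A_pre_target, lo, hi, xtol=1e-6))
    budgets = {mc: class_budgets(mc, a1a_frac=x_star if mc == "CHO" else None) for mc in CLASSES}
    group_budget = normalise(budgets)

    # --- per-molecule base intensities within each (class, cluster) ----
    base: dict[str, float] = {}
    for mol_class in CLASSES:
        for cluster in CLUSTERS:
            ids = [mid for mid, mc, cl, _ in roster if mc == mol_class and cl == cluster]
            if not ids:
                continue
            w = rng.lognormal(mean=0.0, sigma=0.7, size=len(ids))
            w /= w.sum()
            for mid, wi in zip(ids, w):
                # template-scale coefficient: molecule series = base * template
                base[mid] = cfg.total_intensity_scale * group_budget[(mol_class, cluster)] * wi

    # --- noiseless bookkeeping for the truth record --------------------
    def noiseless_matrix() -> dict[str, np.ndarray]:
        out = {}
        for mid, mc, cl, onset in roster:
            out[mid] = base[mid] * _template(cfg, cl, onset, years)
        return out

    clean = noiseless_matrix()
    labels = {mid: cl for mid, _, cl, _ in roster}

    # truth quantities at bin level, exactly as the pipeline measures them
    class_bin = {
        mc: sum(group_budget[(mc, cl)] * group_tpl[(mc, cl)] for cl in CLUSTERS)
        for mc in CLASSES
    }
    grand_tot = sum(float(np.nansum(v)) for v in class_bin.values())
    cho_share = float(np.nansum(class_bin["CHO"])) / grand_tot
    shares_1a = share_curve(group_budget)
    pre_mask_b = bin_years < cfg.onset_year_1B
    share_pre = float(np.nanmean(shares_1a[pre_mask_b]))
    share_post = float(np.nanmean(shares_1a[~pre_mask_b]))

    # --- noisy intensities, blanks, QC columns -------------------------
    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2))
    profiles: list[FeatureProfile] = []
    for mid, mol_class, cluster, onset in roster:
        f = _sample_formula(rng, mol_class, cluster)
        tpl = clean[mid]
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=cfg.n_samples)
        intens = tpl * noise
        peak = float(intens.max()) if intens.max() > 0 else base[mid]
        blanks = tuple(
            float(v)
            for v in peak * cfg.blank_level * rng.lognormal(-0.125, 0.5, size=3)
        )
        profiles.append(
            FeatureProfile(
                id=mid,
                mz=round(_mz_neg_mode(f), 5),
                rt=float(np.clip(1.5 + 0.6 * f.C + rng.normal(0, 0.8), 0.5, 16.0)),
                formula=f,
                intensities={sid: float(v) for sid, v in zip(sample_ids, intens)},
                blank_intensities=blanks,
                peak_rating=float(rng.uniform(7.5, 10.0)),
                group_cv=float(rng.uniform(3.0, 12.0)),
                is_background=False,
            )
        )

    # --- deliberately failing rows to exercise the QC filter -----------
    reject_ids: list[str] = []
    fail_modes = ["background", "peak_rating", "group_cv", "formula", "max_intensity", "blank_ratio"]
    for j in range(cfg.n_reject):
        mode = fail_modes[j % len(fail_modes)]
        rid = f"R{j + 1:03d}"
        reject_ids.append(rid)
        f = _sample_formula(rng, "CHO", "2")
        level = 1e8 * rng.lognormal(0, 0.5)
        intens = level * rng.lognormal(-sigma**2 / 2, sigma, size=cfg.n_samples)
        blanks = [level * 0.02] * 3
        peak_rating, group_cv, is_bg = float(rng.uniform(7.5, 10.0)), float(rng.uniform(3, 12)), False
        formula: MolecularFormula | None = f
        if mode == "background":
            is_bg = True
        elif mode == "peak_rating":
            peak_rating = float(rng.uniform(2.0, 6.9))
        elif mode == "group_cv":
            group_cv = float(rng.uniform(15.5, 60.0))
        elif mode == "formula":
            formula = None
        elif mode == "max_intensity":
            intens = intens * (1e6 / intens.max())
            blanks = [1e4] * 3
        elif mode == "blank_ratio":
            blanks = [intens.max() / 2.0] * 3
        profiles.append(
            FeatureProfile(
                id=rid,
                mz=round(_mz_neg_mode(f), 5),
                rt=float(np.clip(1.5 + 0.6 * f.C + rng.normal(0, 0.8), 0.5, 16.0)),
                formula=formula,
                intensities={sid: float(v) for sid, v in zip(sample_ids, intens)},
                blank_intensities=tuple(float(b) for b in blanks),
                peak_rating=peak_rating,
                group_cv=group_cv,
                is_background=is_bg,
            )
        )

    # --- proxies coupled to the anthropogenic cluster mean z-score -----
    kept = [p for p in profiles if p.id not in set(reject_ids)]
    binned = bin_series(kept, samples, bin_width=cfg.bin_width, anchor_year=cfg.year_start)
    z = zscore(binned)
    anthro_ids = [mid for mid, cl in labels.items() if cl in ("1A", "1B")]
    anthro_rows = z.values.loc[[i for i in anthro_ids if i in z.values.index]]
    sig = anthro_rows.to_numpy(dtype=float).mean(axis=0)
    sig = np.nan_to_num(sig, nan=0.0)
    sig_std = (sig - sig.mean()) / sig.std()
    proxy_scale = {"nitrate": (1.6, 0.9), "sulfate": (2.4, 1.3), "ozone": (32.0, 4.0), "OH": (9.5e5, 6e4)}
    proxies: dict[str, ProxyRecord] = {}
    realized_r: dict[str, float] = {}
    pbin_years = np.asarray(z.values.columns, dtype=float)  # populated bins only
    for name, r_target in cfg.proxy_coupling.items():
        noise_sd = math.sqrt(max(1.0 / r_target**2 - 1.0, 1e-9))
        raw = sig_std + rng.normal(0.0, noise_sd, size=sig_std.size)
        realized_r[name] = float(np.corrcoef(raw, sig_std)[0, 1])
        mu, amp = proxy_scale[name]
        vals = mu + amp * (raw - raw.mean()) / raw.std()
        proxies[name] = ProxyRecord(name, tuple(pbin_years), tuple(float(v) for v in vals))

    truth = SyntheticTruth(
        labels=labels,
        class_counts=class_counts,
        onset_years={
            "cluster_1B": float(cfg.onset_year_1B),
            "class_CHNO": float(cfg.onset_year_1B),
            "class_CHNOS": float(cfg.step_year_chnos),
        },
        folds={"CHNO": cfg.fold_CHNO, "CHNOS": cfg.fold_CHNOS, "cluster_1A_ramp": cfg.fold_1A},
        proxy_couplings=realized_r,
        cho_intensity_share=float(cho_share),
        share_1A_pre=share_pre,
        share_1A_post=share_post,
        reject_ids=reject_ids,
    )
    return SyntheticDataset(profiles=profiles, samples=samples, proxies=proxies, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write features.csv, samples.csv, blanks.csv, proxies/*.csv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["features"] = outdir / "features.csv"
    write_feature_table(ds.profiles, paths["features"])
    paths["samples"] = outdir / "samples.csv"
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in ds.samples],
            "depth_m": [s.depth for s in ds.samples],
            "year_ce": [s.year for s in ds.samples],
            "enrichment_factor": [s.enrichment_factor for s in ds.samples],
        }
    ).to_csv(paths["samples"], index=False)
    paths["blanks"] = outdir / "blanks.csv"
    pd.DataFrame(
        [
            {"id": p.id, **{f"blank_{k + 1}": v for k, v in enumerate(p.blank_intensities)}}
            for p in ds.profiles
        ]
    ).to_csv(paths["blanks"], index=False)
    proxy_dir = outdir / "proxies"
    proxy_dir.mkdir(exist_ok=True)
    for name, rec in ds.proxies.items():
        p = proxy_dir / f"{name}.csv"
        pd.DataFrame({"year": rec.years, "value": rec.values}).to_csv(p, index=False)
        paths[f"proxy_{name}"] = p
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(ds.truth), fh, indent=1)
    return paths


def recovery_report(
    truth: SyntheticTruth,
    labels: Mapping[str, str] | None = None,
    change_points: Mapping[str, float] | None = None,
    folds: Mapping[str, float] | None = None,
    proxy_r: Mapping[str, float] | None = None,
) -> dict:
    """Score pipeline outputs against the planted truth.

    Returns adjusted Rand indices for the full 1A/1B/2 labelling and
    the top-level anthropogenic/natural split, change-point year errors,
    fold-change relative errors and proxy-correlation errors for every
    quantity supplied."""
    from sklearn.metrics import adjusted_rand_score

    report: dict = {}
    if labels is not None:
        common = [m for m in truth.labels if m in labels]
        t = [truth.labels[m] for m in common]
        p = [labels[m] for m in common]
        report["ari"] = float(adjusted_rand_score(t, p))
        top = {"1A": "1", "1B": "1", "2": "2"}
        report["ari_top"] = float(
            adjusted_rand_score([top.get(x, x) for x in t], [top.get(x, x) for x in p])
        )
    if change_points is not None:
        report["change_point_error_years"] = {
            k: abs(change_points[k] - truth.onset_years[k])
            for k in change_points
            if k in truth.onset_years
        }
    if folds is not None:
        report["fold_relative_error"] = {
            k: abs(folds[k] - truth.folds[k]) / truth.folds[k] for k in folds if k in truth.folds
        }
    if proxy_r is not None:
        report["proxy_r_error"] = {
            k: abs(proxy_r[k] - truth.proxy_couplings[k])
            for k in proxy_r
            if k in truth.proxy_couplings
        }
    return report
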