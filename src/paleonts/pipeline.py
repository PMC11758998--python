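"""End-to-end orchestration: simulate/load → filter → descriptors →
homologs → bin → cluster → trends → identify → report.

A run is fully described by a :class:`RunConfig` (serializable to YAML);
re-running with the same config and seed reproduces the report
byte-for-byte. Every stage logs row counts; the report carries a hash
of the configuration it was produced from.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import clustering, homologs, identify, synthdata, trends
from .features import FilterConfig, apply_filters, read_feature_table, read_sample_table
from .formulas import DescriptorConfig, descriptor_frame

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    outdir: str = "nts_run"
    features_path: str | None = None
    samples_path: str | None = None
    proxy_paths: dict[str, str] = field(default_factory=dict)
    standards_path: str | None = None
    library_path: str | None = None
    generator: synthdata.GeneratorConfig | None = field(
        default_factory=synthdata.GeneratorConfig
    )
    filter: FilterConfig = field(default_factory=FilterConfig)
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)
    bin_width: int = 5
    anchor_year: float | None = 1800.0
    homolog_min_members: int = 3
    seed: int = 0
    make_figures: bool = True
    write_tables: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            self.generator = synthdata.GeneratorConfig(**self.generator)
        if isinstance(self.filter, dict):
            self.filter = FilterConfig(**self.filter)
        if isinstance(self.descriptors, dict):
            self.descriptors = DescriptorConfig(**self.descriptors)
        if self.generator is not None:
            self.generator.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and
        rendering switches excluded)."""
        d = self.to_dict()
        for k in ("outdir", "make_figures", "write_tables"):
            d.pop(k, None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _window_stats(years: np.ndarray, values: np.ndarray, split_year: float) -> dict:
    mask = ~np.isnan(values)
    years, values = years[mask], values[mask]
    pre = values[years < split_year]
    post = values[years >= split_year]
    return {
        "split_year": float(split_year),
        "pre_mean": float(pre.mean()) if pre.size else float("nan"),
        "pre_sd": float(pre.std(ddof=1)) if pre.size > 1 else float("nan"),
        "post_mean": float(post.mean()) if post.size else float("nan"),
        "post_sd": float(post.std(ddof=1)) if post.size > 1 else float("nan"),
    }


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    stage = "init"
    truth = None
    try:
        # ------------------------------------------------ inputs ------
        stage = "inputs"
        proxies: dict[str, trends.ProxyRecord] = {}
        if cfg.features_path:
            samples = read_sample_table(cfg.samples_path)
            profiles = read_feature_table(cfg.features_path, samples)
            for name, p in cfg.proxy_paths.items():
                proxies[name] = trends.read_proxy(p, name)
        else:
            if cfg.generator is None:
                raise ValueError("no feature table given and generator disabled")
            ds = synthdata.generate(cfg.generator)
            profiles, samples, proxies, truth = ds.profiles, ds.samples, ds.proxies, ds.truth
            if cfg.write_tables:
                synthdata.write_dataset(ds, outdir / "inputs")
        report["n_input_profiles"] = len(profiles)
        log.info("inputs: %d profiles, %d samples", len(profiles), len(samples))

        # ------------------------------------------------ filter ------
        stage = "filter"
        kept, tally = apply_filters(profiles, cfg.filter)
        report["n_kept"] = len(kept)
        report["filter_tally"] = tally

        # ------------------------------------------- descriptors ------
        stage = "descriptors"
        desc = descriptor_frame({p.id: p.formula for p in kept}, cfg.descriptors)
        counts = desc["compound_class"].value_counts().to_dict()
        report["class_counts"] = {c: int(counts.get(c, 0)) for c in desc["compound_class"].unique()}
        thr = cfg.descriptors.aromatic_threshold
        report["aromatic_fraction_pct"] = float(100.0 * (desc["chi_c"] >= thr).mean())
        report["vk_regions"] = desc["vk_region"].value_counts().to_dict()
        kroll_tally: dict[str, int] = {}
        for labels in desc["kroll_regions"]:
            for lab in filter(None, labels.split(";")):
                kroll_tally[lab] = kroll_tally.get(lab, 0) + 1
        report["kroll_regions"] = kroll_tally

        # ---------------------------------------------- homologs ------
        stage = "homologs"
        series = homologs.find_series(
            [p.formula for p in kept if p.formula is not None], cfg.homolog_min_members
        )
        report["homolog_series"] = [
            {
                "k_offset": s.key.k_offset,
                "O": s.key.o_count,
                "N": s.key.n_count,
                "S": s.key.s_count,
                "n_members": len(s),
                "carbon_numbers": list(s.carbon_numbers),
            }
            for s in series
        ]

        # --------------------------------------------------- bin ------
        stage = "bin"
        binned = trends.bin_series(kept, samples, cfg.bin_width, cfg.anchor_year)

        stage = "class_series"
        sums, bin_shares, total_shares = trends.class_series(binned, desc)
        report["class_total_shares_pct"] = {k: float(v) for k, v in total_shares.items()}
        class_cp: dict[str, dict] = {}
        class_folds: dict[str, float] = {}
        class_trends: dict[str, float] = {}
        for cls in sums.index:
            s = sums.loc[cls]
            try:
                cp = trends.detect_change_point(s)
            except ValueError:
                continue
            class_cp[f"class_{cls}"] = {"year": cp.year, "sse_drop": cp.sse_drop}
            class_folds[f"class_{cls}"] = trends.fold_change(s, cp)
            class_trends[f"class_{cls}"] = trends.trend_test(s)[1]

        # ------------------------------------------------ cluster -----
        stage = "cluster"
        z = clustering.zscore(binned)
        result = clustering.hca(z)
        clustering.summarize_cluster(result, desc)
        report["clusters"] = {
            c: {
                "n": s["n"],
                "class_counts": s["class_counts"],
                "descriptors": {k: list(v) for k, v in s["descriptors"].items()},
            }
            for c, s in result.summaries.items()
        }
        report["n_degenerate_series"] = len(result.degenerate)
        share = clustering.cluster_share(result, binned)

        # ------------------------------------------------- trends -----
        stage = "trends"
        anthro_ids = [m for m, c in result.labels.items() if c in ("1A", "1B")]
        cluster1_mean = z.values.loc[anthro_ids].mean()
        cp1 = trends.detect_change_point(cluster1_mean)
        class_cp["cluster_1"] = {"year": cp1.year, "sse_drop": cp1.sse_drop}
        report["change_points"] = class_cp
        report["fold_changes"] = class_folds
        trend_p = dict(class_trends)
        for c in result.cluster_mean_series.index:
            trend_p[f"cluster_{c}"] = trends.trend_test(result.cluster_mean_series.loc[c])[1]
        report["trend_p_values"] = trend_p

        if "1A" in share.index:
            yrs = np.asarray(share.columns, float)
            report["cluster_1A_share_pct"] = _window_stats(
                yrs, share.loc["1A"].to_numpy(float), cp1.year
            )

        biogenic = [m for m, c in result.labels.items() if c in ("1A", "2")]
        wd_report: dict[str, dict] = {}
        for which in ("oc", "osc", "nC", "dbe", "chi_c"):
            w = trends.weighted_descriptor(binned, desc, which, subset=biogenic, label="1A+2")
            entry: dict[str, Any] = {}
            try:
                cp = trends.detect_change_point(w.as_series().dropna())
                entry.update({"change_point_year": cp.year, "sse_drop": cp.sse_drop})
                entry.update(_window_stats(w.bin_years, w.values, cp.year))
            except ValueError:
                pass
            wd_report[which] = entry
        report["weighted_descriptors"] = wd_report

        proxy_r = {}
        for name, rec in proxies.items():
            try:
                proxy_r[name] = trends.proxy_correlation(cluster1_mean, rec)
            except ValueError:
                proxy_r[name] = float("nan")
        report["proxy_correlations"] = proxy_r

        # ----------------------------------------------- identify -----
        stage = "identify"
        refdb = identify.read_standards(cfg.standards_path) if cfg.standards_path else ()
        speclib = identify.read_msp(cfg.library_path) if cfg.library_path else ()
        level_tally: dict[int, int] = {}
        for p in kept:
            res = identify.assign_level(p, refdb, speclib)
            level_tally[res.level] = level_tally.get(res.level, 0) + 1
        report["identification_levels"] = {str(k): v for k, v in sorted(level_tally.items())}

        # ----------------------------------------------- recovery -----
        if truth is not None:
            stage = "recovery"
            cps = {
                "class_CHNO": class_cp.get("class_CHNO", {}).get("year"),
                "class_CHNOS": class_cp.get("class_CHNOS", {}).get("year"),
                "cluster_1B": class_cp.get("cluster_1", {}).get("year"),
            }
            report["recovery"] = synthdata.recovery_report(
                truth,
                labels=result.labels,
                change_points={k: v for k, v in cps.items() if v is not None},
                folds={k.replace("class_", ""): v for k, v in class_folds.items()},
                proxy_r=proxy_r,
            )
            report["planted"] = {
                "class_counts": truth.class_counts,
                "folds": truth.folds,
                "onset_years": truth.onset_years,
                "proxy_couplings": truth.proxy_couplings,
                "cho_intensity_share_pct": 100.0 * truth.cho_intensity_share,
                "share_1A_pre_pct": 100.0 * truth.share_1A_pre,
                "share_1A_post_pct": 100.0 * truth.share_1A_post,
            }

        # ------------------------------------------------ outputs -----
        stage = "outputs"
        if cfg.write_tables:
            desc.to_csv(outdir / "descriptors.csv")
            homologs.series_frame(series).to_csv(outdir / "homolog_series.csv", index=False)
            pd.Series(result.labels, name="cluster").rename_axis("molecule_id").to_csv(
                outdir / "cluster_labels.csv"
            )
            result.cluster_mean_series.to_csv(outdir / "cluster_mean_series.csv")
        if cfg.make_figures:
            _figures(outdir, desc, z, result)
        report_path = outdir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, allow_nan=True)
        log.info("report written to %s", report_path)
        return report
    except Exception as err:  # preserve partial outputs, name the stage
        partial = outdir / "report_partial.json"
        try:
            with open(partial, "w") as fh:
                json.dump(report, fh, indent=1, sort_keys=True, default=str)
        except Exception:
            pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def _figures(outdir: Path, desc: pd.DataFrame, z, result) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"CHO": "tab:green", "CHNO": "tab:purple", "CHNOS": "gold", "CHOS": "tab:red", "other": "tab:cyan"}
    c = desc["compound_class"].map(colors).fillna("gray")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(desc["oc"], desc["hc"], c=c, s=12, alpha=0.7)
    ax.set_xlabel("O/C")
    ax.set_ylabel("H/C")
    ax.axhline(1.5, ls="--", lw=0.8, color="k")
    ax.set_title("Van Krevelen")
    fig.tight_layout()
    fig.savefig(outdir / "van_krevelen.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(desc["nC"], desc["osc"], c=c, s=12, alpha=0.7)
    ax.set_xlabel("nC")
    ax.set_ylabel("OSc")
    ax.set_title("Kroll diagram")
    fig.tight_layout()
    fig.savefig(outdir / "kroll.png", dpi=120)
    plt.close(fig)

    from scipy.cluster import hierarchy

    order = hierarchy.leaves_list(result.linkage)
    active = z.values.drop(index=result.degenerate)
    mat = active.to_numpy(float)[order]
    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(
        np.clip(np.nan_to_num(mat), -3, 3), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3,
        extent=(float(active.columns[0]), float(active.columns[-1]), mat.shape[0], 0),
    )
    fig.colorbar(im, ax=ax, label="z score")
    ax.set_xlabel("year CE")
    ax.set_ylabel("molecules (tree order)")
    ax.set_title("Clustergram")
    fig.tight_layout()
    fig.savefig(outdir / "clustergram.png", dpi=120)
    plt.close(fig)
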