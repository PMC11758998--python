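"""Generator contracts: determinism, planted structure, feasibility."""

import numpy as np
import pytest

from paleonts import synthdata, trends
from paleonts.clustering import hca, zscore
from paleonts.features import FilterConfig, apply_filters
from paleonts.formulas import compute_descriptors, dbe, parse_formula
from paleonts.synthdata import GeneratorConfig, generate, recovery_report, write_dataset


def test_determinism_byte_identical(tmp_path, default_dataset):
    a = tmp_path / "a"
    b = tmp_path / "b"
    write_dataset(default_dataset, a)
    write_dataset(generate(GeneratorConfig(seed=0)), b)
    for name in ("features.csv", "samples.csv", "blanks.csv", "truth.json"):
        assert (a / name).read_bytes() == (b / name).read_bytes()
    assert (a / "proxies" / "nitrate.csv").read_bytes() == (b / "proxies" / "nitrate.csv").read_bytes()


def test_different_seed_differs(default_dataset):
    other = generate(GeneratorConfig(seed=1))
    a = default_dataset.profiles[0].intensities
    b = other.profiles[0].intensities
    assert list(a.values()) != list(b.values())


def test_class_counts_near_expectation(default_dataset):
    counts = default_dataset.truth.class_counts
    expect = {"CHO": 298, "CHNO": 72, "CHNOS": 12, "CHOS": 8, "other": 8}
    for cls, n in expect.items():
        assert abs(counts[cls] - n) <= 3
    assert sum(counts.values()) == 398


def test_1b_rows_zero_before_onset(default_dataset):
    truth = default_dataset.truth
    year = {s.sample_id: s.year for s in default_dataset.samples}
    earliest_onset = min(truth.onset_years.values())
    seen = 0
    for p in default_dataset.profiles:
        if truth.labels.get(p.id) == "1B":
            seen += 1
            pre = [v for sid, v in p.intensities.items() if year[sid] < earliest_onset]
            assert all(v == 0.0 for v in pre)
    assert seen > 0


def test_generated_formulas_are_valid(default_dataset):
    for p in default_dataset.profiles:
        if p.formula is None:
            continue
        f = p.formula
        assert parse_formula(f.hill()) == f
        d = compute_descriptors(f)
        assert d.dbe >= 0
        assert d.dbe == int(d.dbe)  # parity enforced at generation
        assert f.H <= 2 * f.C + 2 + f.N


def test_samples_span_record(default_dataset):
    years = [s.year for s in default_dataset.samples]
    assert len(years) == 53 and min(years) == 1800 and max(years) == 1980
    assert len(set(years)) == 53


def test_kept_set_is_exactly_the_planted_molecules(default_dataset):
    kept, tally = apply_filters(default_dataset.profiles, FilterConfig())
    truth = default_dataset.truth
    assert {p.id for p in kept} == set(truth.labels)
    assert sum(tally.values()) == len(truth.reject_ids)
    assert all(v == 6 for v in tally.values())  # 36 rejects, 6 per predicate


def test_cho_share_calibrated(default_dataset, kept_profiles):
    from paleonts.formulas import descriptor_frame

    binned = trends.bin_series(kept_profiles, default_dataset.samples, 5, 1800)
    desc = descriptor_frame({p.id: p.formula for p in kept_profiles})
    _, _, total = trends.class_series(binned, desc)
    assert total["CHO"] == pytest.approx(95.0, abs=2.0)
    assert abs(total["CHO"] - 100 * default_dataset.truth.cho_intensity_share) < 1.0


def test_cho_share_converges_at_large_n():
    ds = generate(GeneratorConfig(n_molecules=5000, seed=3, n_reject=0))
    by_class: dict[str, float] = {}
    for p in ds.profiles:
        cls = "CHO" if set(p.formula.element_counts) == {"C", "H", "O"} else "non"
        by_class[cls] = by_class.get(cls, 0.0) + sum(p.intensities.values())
    share = by_class["CHO"] / sum(by_class.values())
    assert share == pytest.approx(0.95, abs=0.02)


def test_infeasible_fold_reported():
    with pytest.raises(ValueError, match="infeasible"):
        generate(GeneratorConfig(fold_CHNO=0.5, seed=0))


def test_noiseless_recovery_is_perfect():
    ds = generate(GeneratorConfig(seed=0, noise_cv=0.0, n_reject=0))
    binned = trends.bin_series(ds.profiles, ds.samples, 5, 1800)
    res = hca(zscore(binned))
    rep = recovery_report(ds.truth, labels=res.labels)
    assert rep["ari_top"] == pytest.approx(1.0)
    mean1 = binned.matrix.loc[[m for m, c in res.labels.items() if c in ("1A", "1B")]]
    cp = trends.detect_change_point(zscore(binned).values.loc[mean1.index].mean())
    assert abs(cp.year - ds.truth.onset_years["cluster_1B"]) <= 5


def test_shuffled_labels_ari_near_zero(default_dataset):
    rng = np.random.default_rng(0)
    truth = default_dataset.truth
    ids = list(truth.labels)
    vals = list(truth.labels.values())
    rng.shuffle(vals)
    rep = recovery_report(truth, labels=dict(zip(ids, vals)))
    assert abs(rep["ari"]) < 0.05


def test_recovery_report_scores_supplied_quantities(default_dataset):
    truth = default_dataset.truth
    rep = recovery_report(
        truth,
        labels=truth.labels,
        change_points={"class_CHNO": 1950.0},
        folds={"CHNO": 1.38},
        proxy_r={"nitrate": truth.proxy_couplings["nitrate"] + 0.02},
    )
    assert rep["ari"] == 1.0
    assert rep["change_point_error_years"]["class_CHNO"] == 0.0
    assert rep["fold_relative_error"]["CHNO"] == pytest.approx(abs(1.38 - 1.4) / 1.4)
    assert rep["proxy_r_error"]["nitrate"] == pytest.approx(0.02)


def test_proxy_records_valid(default_dataset):
    for name, rec in default_dataset.proxies.items():
        years = np.asarray(rec.years)
        assert np.all(np.diff(years) > 0)
        assert len(rec.values) == len(rec.years)
    assert set(default_dataset.proxies) == {"nitrate", "sulfate", "ozone", "OH"}
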