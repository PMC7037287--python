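"""Translocation-factor chains, mobility ratios and their summaries."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vinemetals as vm


def test_ratio_basics_and_undefined_denominator():
    assert vm.ratio(5.0, 5.0) == 1.0
    assert vm.ratio(450.31, 3165.26) == pytest.approx(0.1423, abs=5e-5)
    assert vm.ratio(0.0, 2.0) == 0.0
    with pytest.warns(UserWarning, match="denominator"):
        assert np.isnan(vm.ratio(1.0, 0.0))


def test_summary_of_printed_per_variety_ratios():
    mean, sd, rsd = vm.summarize_transfer([0.411, 0.418, 0.534])
    assert mean == pytest.approx(0.45, abs=0.005)
    assert rsd == pytest.approx(15.25, abs=0.5)


def test_rsd_of_single_nonzero_among_zeros_is_analytic():
    _, _, rsd = vm.summarize_transfer([0.002, 0.0, 0.0])
    assert rsd == pytest.approx(100.0 * np.sqrt(3.0), abs=0.01)
    _, _, flat = vm.summarize_transfer([0.3, 0.3, 0.3])
    assert flat == 0.0
    with pytest.raises(ValueError):
        vm.summarize_transfer([np.nan, np.nan])


@given(st.lists(st.floats(0.001, 100.0), min_size=2, max_size=8),
       st.floats(0.01, 100.0))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_summary_scale_invariance_of_rsd(values, c):
    _, _, rsd = vm.summarize_transfer(values)
    _, _, rsd_scaled = vm.summarize_transfer([v * c for v in values])
    assert rsd_scaled == pytest.approx(rsd, rel=1e-9)


def test_classification_band_and_monotonicity():
    assert vm.classify_mobility(2.90) == "accumulator"
    assert vm.classify_mobility(1.00) == "indicator"
    assert vm.classify_mobility(0.05) == "excluder"
    order = {"excluder": 0, "indicator": 1, "accumulator": 2}
    grades = [order[vm.classify_mobility(m)] for m in np.linspace(0, 3, 40)]
    assert grades == sorted(grades)
    with pytest.raises(ValueError):
        vm.classify_mobility(1.0, band=(2.0, 1.0))


def test_ranking_matches_field_ordering_and_handles_ties():
    means = {"Cr": 2.90, "Co": 2.17, "As": 1.30, "Ni": 0.82, "Hg": 0.60,
             "Cd": 0.58, "Cu": 0.45, "Zn": 0.18, "Pb": 0.05}
    ranking, ties = vm.rank_elements(means)
    assert ranking == "Cr>Co>As>Ni>Hg>Cd>Cu>Zn>Pb"
    assert ties == []
    assert vm.rank_elements({"Cu": 1.0})[0] == "Cu"
    ranking, ties = vm.rank_elements({"Zn": 0.5, "Cu": 0.5})
    assert ranking == "Cu>Zn" and ties == [("Cu", "Zn")]


def test_noise_free_chain_recovers_configuration(noise_free_dataset):
    cfg = vm.default_config(seed=11, cv_noise=0.0)
    for summary in vm.tf_chain(noise_free_dataset, "Cu"):
        key = f"{summary.pair[0]}/{summary.pair[1]}"
        assert summary.mean == pytest.approx(cfg.elements["Cu"].partition[key], rel=1e-12)
        # all three cultivars share the configured ratio
        assert len(set(round(v, 12) for v in summary.per_variety.values())) == 1


def test_single_site_ratios_equal_per_site_ratios(noise_free_dataset):
    one_site = noise_free_dataset[noise_free_dataset["area"] == "Near"]
    full = vm.tf_chain(noise_free_dataset, "Zn")[0]
    single = vm.tf_chain(one_site, "Zn")[0]
    assert single.per_variety == pytest.approx(full.per_variety)


def test_chain_composition_equals_wine_soil_mobility(noise_free_dataset):
    """Product of chain means soil->...->wine equals the wine/soil MR."""
    chain = vm.tf_chain(noise_free_dataset, "Cd",
                        pairs=(("root", "soil"), ("cane", "root"), ("grape", "cane"),
                               ("must", "grape"), ("wine", "must")))
    product = np.prod([s.mean for s in chain])
    mr = vm.tf_chain(noise_free_dataset, "Cd", pairs=(("wine", "soil"),),
                     soil_reference="depth_average")[0]
    assert product == pytest.approx(mr.mean, rel=1e-12)


def test_scale_invariance_of_chain(noise_free_dataset):
    scaled = noise_free_dataset.copy()
    mask = scaled["element"] == "Ni"
    scaled.loc[mask, "value"] *= 37.0
    for orig, new in zip(vm.tf_chain(noise_free_dataset, "Ni"), vm.tf_chain(scaled, "Ni")):
        assert new.mean == pytest.approx(orig.mean, rel=1e-12)


def test_missing_compartment_warns_and_marks_missing(noise_free_dataset):
    without_roots = noise_free_dataset[noise_free_dataset["compartment"] != "root"]
    with pytest.warns(UserWarning, match="missing root"):
        chain = vm.tf_chain(without_roots, "Cu", pairs=(("root", "soil"),))
    assert all(np.isnan(v) for v in chain[0].per_variety.values())
    assert chain[0].classification == "undefined"


def test_soil_reference_choices_differ_with_depth_trend():
    cfg = vm.default_config(seed=4, cv_noise=0.0)
    cfg.elements = {"Cu": cfg.elements["Cu"]}
    cfg.elements["Cu"].depth_slope = 1.3
    df = vm.generate_dataset(cfg)
    top = vm.tf_chain(df, "Cu", pairs=(("root", "soil"),), soil_reference="topsoil_0_20")[0]
    avg = vm.tf_chain(df, "Cu", pairs=(("root", "soil"),), soil_reference="depth_average")[0]
    assert avg.mean == pytest.approx(0.45, rel=1e-12)   # chain keyed to depth average
    assert top.mean > avg.mean                          # topsoil is the smallest layer


def test_recovery_under_noise_smoke():
    """Shortened Monte-Carlo check (full 200-seed run in the acceptance suite)."""
    errs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(20):
            cfg = vm.default_config(seed=seed, cv_noise=0.1)
            cfg.elements = {"Cu": cfg.elements["Cu"]}
            cfg.elements["Cu"].loq = 0.0
            df = vm.generate_dataset(cfg)
            for s in vm.tf_chain(df, "Cu"):
                true = cfg.elements["Cu"].partition[f"{s.pair[0]}/{s.pair[1]}"]
                errs.append(abs(s.mean - true) / true)
    assert np.median(errs) < 0.05


def test_chain_summary_table_layout(noise_free_dataset):
    table = vm.chain_summary_table(noise_free_dataset, vm.MR_PAIRS,
                                   soil_reference="topsoil_0_20")
    assert set(table["pair"]) == {f"{a}/{b}" for a, b in vm.MR_PAIRS}
    root_block = table[table["pair"] == "root/soil"]
    assert list(root_block["row"])[-4:] == ["Average", "STDEV", "RSD %", "Classification"]
    avg = root_block[root_block["row"] == "Average"].iloc[0]
    assert ">" in avg["ranking"]
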