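"""Generator properties: moments, determinism, planted truth consistency."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from strucov.exceptions import ConfigError
from strucov.synthetic_data import (
    DEFAULT_COUPLED_PAIRS,
    GeneratorConfig,
    SUBSCALE_MOMENTS,
    generate_cohort,
    make_fixture_suite,
    preset_config,
    write_truth,
)


def _quiet_generate(cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg)


# -- distributions ----------------------------------------------------------

def test_is_mean_within_3_se_of_target():
    cfg = GeneratorConfig(seed=42)
    cohort, _, _ = _quiet_generate(cfg)
    is_scores = cohort.subscale("insistence_on_sameness")
    se = cfg.is_sd / np.sqrt(cfg.n_subjects)
    assert abs(is_scores.mean() - cfg.is_mean) < 3 * se


def test_subscale_moments_match_targets_in_large_sample():
    cfg = GeneratorConfig(seed=7, n_subjects=20_000, coupled_pairs=(),
                          roi_loadings=(), coupling_slope=0.0,
                          volume_effect_rois=())
    cohort, _, _ = _quiet_generate(cfg)
    for name, (mean, sd) in SUBSCALE_MOMENTS.items():
        s = cohort.subscale(name)
        assert s.mean() == pytest.approx(mean, rel=0.03)
        assert s.std(ddof=1) == pytest.approx(sd, rel=0.03)
        assert np.allclose(s, np.round(s)) and (s >= 0).all()


def test_is_right_skewed_at_defaults():
    cohort, _, _ = _quiet_generate(GeneratorConfig(seed=3, n_subjects=2000))
    assert sps.skew(cohort.subscale("insistence_on_sameness")) > 0


def test_covariates_and_icv_plausible():
    cfg = GeneratorConfig(seed=11, n_subjects=5000)
    cohort, _, _ = _quiet_generate(cfg)
    assert cohort.data["age"].mean() == pytest.approx(cfg.age_mean, abs=0.2)
    assert cohort.data["iq"].std(ddof=1) == pytest.approx(cfg.iq_sd, rel=0.05)
    icv = cohort.data["icv"]
    assert icv.mean() == pytest.approx(cfg.icv_mean, rel=0.02)
    assert (icv > 0).all()


def test_icv_is_a_volume_confounder():
    cohort, vol, _ = _quiet_generate(GeneratorConfig(
        seed=5, n_subjects=400, coupled_pairs=(), roi_loadings=(),
        coupling_slope=0.0, volume_effect_rois=()))
    r = np.corrcoef(cohort.data["icv"], vol.data["thalamus"])[0, 1]
    assert r > 0.3


# -- determinism and truth --------------------------------------------------

def test_generate_cohort_deterministic():
    a = _quiet_generate(GeneratorConfig(seed=9))
    b = _quiet_generate(GeneratorConfig(seed=9))
    assert a[0].data.equals(b[0].data)
    assert a[1].data.equals(b[1].data)
    np.testing.assert_array_equal(a[2].latent_w, b[2].latent_w)
    assert not a[1].data.equals(_quiet_generate(GeneratorConfig(seed=10))[1].data)


def test_truth_w_rederivable_from_is_and_config():
    cfg = GeneratorConfig(seed=13)
    cohort, _, truth = _quiet_generate(cfg)
    is_scores = cohort.subscale("insistence_on_sameness")
    # same association order as the generator: slope * (IS / max IS)
    w = np.sqrt(cfg.coupling_base + cfg.coupling_slope * (is_scores / is_scores.max()))
    np.testing.assert_array_equal(truth.latent_w, w)


def test_truth_pair_effects_are_loading_products():
    cfg = GeneratorConfig(seed=1)
    _, _, truth = _quiet_generate(cfg)
    loadings = dict(cfg.roi_loadings)
    for x, y, effect in truth.coupled_pairs:
        assert effect == pytest.approx(loadings.get(x, 1.0) * loadings.get(y, 1.0))
    assert truth.planted_pairs({"thalamus", "caudate"}) == {("caudate", "thalamus")}


def test_default_pairs_contain_five_subcortical():
    sub = {"thalamus", "caudate", "putamen", "pallidum",
           "hippocampus", "amygdala", "accumbens"}
    intra = [p for p in DEFAULT_COUPLED_PAIRS if set(p) <= sub]
    assert sorted(tuple(sorted(p)) for p in intra) == [
        ("accumbens", "amygdala"), ("accumbens", "pallidum"),
        ("amygdala", "pallidum"), ("caudate", "thalamus"),
        ("hippocampus", "putamen"),
    ]


def test_planted_volume_effect_direction():
    cohort, vol, truth = _quiet_generate(preset_config("planted-volume", 21))
    assert truth.volume_effect_rois == (("thalamus", -100.0),)
    is_scores = cohort.subscale("insistence_on_sameness")
    r = sps.spearmanr(is_scores, vol.data["thalamus"])[0]
    assert r < 0.2  # negative planted slope keeps association non-positive-ish


def test_coupling_visible_in_top_vs_bottom_tertile():
    hits = 0
    for seed in range(10):
        cohort, vol, _ = _quiet_generate(GeneratorConfig(seed=seed))
        is_scores = cohort.subscale("insistence_on_sameness")
        lo, hi = np.quantile(is_scores, [1 / 3, 2 / 3])
        arr = vol.matrix(["amygdala", "pallidum"])
        r_top = np.corrcoef(arr[is_scores >= hi], rowvar=False)[0, 1]
        r_bot = np.corrcoef(arr[is_scores <= lo], rowvar=False)[0, 1]
        hits += r_top > r_bot
    assert hits >= 9


def test_zero_slope_decouples_is():
    """lambda1 = 0: coupling exists but is unrelated to severity."""
    from strucov.continuous_analysis import coupling_association
    from strucov.stats_core import bh_fdr

    ps = []
    for seed in range(5):
        cohort, vol, _ = _quiet_generate(preset_config("null", seed))
        assoc = coupling_association(vol, cohort)
        ps += [a.p for a in assoc]
    reject, _ = bh_fdr(np.array(ps), 0.05)
    assert reject.sum() <= 2


# -- config validation ------------------------------------------------------

def test_non_clique_pairs_rejected():
    with pytest.raises(ConfigError, match="clique"):
        generate_cohort(GeneratorConfig(coupled_pairs=(
            ("amygdala", "pallidum"), ("pallidum", "accumbens"),
        ), roi_loadings=()))


def test_unknown_roi_rejected():
    with pytest.raises(ConfigError, match="not in scheme"):
        generate_cohort(GeneratorConfig(coupled_pairs=(("amygdala", "claustrum"),),
                                        roi_loadings=()))


def test_self_and_duplicate_pairs_rejected():
    with pytest.raises(ConfigError, match="self-pair"):
        generate_cohort(GeneratorConfig(coupled_pairs=(("amygdala", "amygdala"),),
                                        roi_loadings=()))
    with pytest.raises(ConfigError, match="duplicate"):
        generate_cohort(GeneratorConfig(
            coupled_pairs=(("amygdala", "pallidum"), ("pallidum", "amygdala")),
            roi_loadings=()))


def test_negative_coupling_rejected():
    with pytest.raises(ConfigError, match="lambda"):
        generate_cohort(GeneratorConfig(coupling_base=-0.5, coupling_slope=0.2))


def test_unknown_preset_rejected():
    with pytest.raises(ConfigError, match="preset"):
        preset_config("mystery", 0)


# -- fixture suite ----------------------------------------------------------

def test_fixture_suite_byte_identical_reruns(tmp_path):
    out1 = make_fixture_suite(tmp_path / "a", base_seed=1000)
    make_fixture_suite(tmp_path / "b", base_seed=1000)
    for name, paths in out1.items():
        for kind, path in paths.items():
            other = tmp_path / "b" / path.name
            assert path.read_bytes() == other.read_bytes(), (name, kind)
    assert (tmp_path / "a" / "manifest.txt").read_text() == (
        tmp_path / "b" / "manifest.txt").read_text()


def test_fixture_suite_contents(tmp_path):
    from strucov.io import read_phenotypes, read_volume_table

    out = make_fixture_suite(tmp_path, base_seed=1000)
    assert set(out) == {"null", "planted-coupling", "planted-volume", "tiny"}
    cohort = read_phenotypes(out["planted-coupling"]["phenotypes"])
    vol = read_volume_table(out["planted-coupling"]["volumes"])
    assert cohort.n == 55 and vol.n == 55
    assert len(vol.data.columns) == 75
    tiny = read_phenotypes(out["tiny"]["phenotypes"])
    assert tiny.n == 8


def test_write_truth_layout(tmp_path):
    _, _, truth = _quiet_generate(GeneratorConfig(seed=2))
    write_truth(truth, tmp_path / "t.tsv", tmp_path / "l.tsv")
    import pandas as pd

    t = pd.read_csv(tmp_path / "t.tsv", sep="\t")
    assert set(t["kind"]) == {"coupled_pair", "volume_effect"}
    lat = pd.read_csv(tmp_path / "l.tsv", sep="\t")
    assert {"subject_id", "w", "component_1"} <= set(lat.columns)
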