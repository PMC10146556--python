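"""Rank transform, repeated-measures omnibus test, labeled contrasts."""
import math

import numpy as np
import pandas as pd
import pytest

from cardiovar.datatypes import CONDITIONS, CONTRAST_PAIRS, DesignError
from cardiovar.stats import (
    RankConditionANOVA,
    conover_rank_transform,
    descriptive_table,
    mixed_model_ranks,
    null_calibration,
    paired_contrasts,
)


def _study(rng, n_subjects=11, shift=None):
    rows = []
    for s in range(n_subjects):
        base = rng.standard_normal()
        for c in CONDITIONS:
            v = base + rng.standard_normal()
            if shift and c in shift:
                v += shift[c]
            rows.append(dict(subject=f"s{s}", condition=c, value=v))
    return pd.DataFrame(rows)


def test_rank_transform_examples():
    np.testing.assert_array_equal(conover_rank_transform([10, 20, 30]), [1, 2, 3])
    np.testing.assert_array_equal(conover_rank_transform([5, 5, 9]), [1.5, 1.5, 3])


def test_rank_transform_preserves_missing():
    out = conover_rank_transform([3.0, np.nan, 1.0])
    assert math.isnan(out[1])
    np.testing.assert_array_equal(out[[0, 2]], [2, 1])


def test_pipeline_invariant_under_monotone_transform(rng):
    df = _study(rng)
    m1 = RankConditionANOVA().fit(df)
    df2 = df.assign(value=np.exp(df["value"]))      # strictly monotone
    m2 = RankConditionANOVA().fit(df2)
    assert m1.omnibus_p_ == pytest.approx(m2.omnibus_p_, rel=1e-12)
    assert m1.significant_letters_ == m2.significant_letters_


def test_contrast_letters_map_to_condition_pairs():
    assert CONTRAST_PAIRS["a"] == ("ambulatory_normoxia", "ambulatory_hypoxia")
    assert CONTRAST_PAIRS["f"] == ("bedrest_normoxia", "bedrest_hypoxia")
    m = RankConditionANOVA().fit(_study(np.random.default_rng(0)))
    assert list(m.contrasts_.index) == list("abcdef")
    assert m.contrasts_.loc["c", "pair"] == "ambulatory_normoxia vs bedrest_hypoxia"


def test_null_type_one_error_calibrated():
    res = null_calibration(n_subjects=11, n_reps=1000, seed=3)
    assert 0.03 <= res["omnibus_rate"] <= 0.07
    for rate in res["letter_rates"].values():
        assert 0.03 <= rate <= 0.07


def test_power_for_two_sd_shift(rng):
    hits = 0
    for _ in range(50):
        df = _study(rng, shift={"bedrest_hypoxia": 2.0})
        hits += RankConditionANOVA().fit(df).omnibus_p_ < 0.05
    assert hits / 50 > 0.8


def test_shifted_condition_flags_its_contrast_letters(rng):
    df = _study(rng, shift={"bedrest_hypoxia": 3.0})
    m = RankConditionANOVA().fit(df)
    assert set("cef") <= set(m.significant_letters_.split())


def test_identical_values_give_no_letters():
    rows = [dict(subject=f"s{s}", condition=c, value=1.0)
            for s in range(5) for c in CONDITIONS]
    with pytest.warns(UserWarning):
        m = RankConditionANOVA().fit(pd.DataFrame(rows))
    assert math.isnan(m.omnibus_p_)
    assert m.significant_letters_ == ""


def test_mixedlm_agrees_with_closed_form_on_balanced_data(rng):
    df = _study(rng, shift={"bedrest_hypoxia": 1.5})
    p_cf = RankConditionANOVA(method="closed_form").fit(df).omnibus_p_
    p_mm = RankConditionANOVA(method="mixedlm").fit(df).omnibus_p_
    assert p_mm == pytest.approx(p_cf, abs=0.01)


def test_incomplete_design_uses_mixedlm(rng):
    df = _study(rng, shift={"bedrest_hypoxia": 2.0})
    df = df[~((df.subject == "s0") & (df.condition == "ambulatory_hypoxia"))]
    m = RankConditionANOVA().fit(df)
    assert m.method_ == "mixedlm"
    assert m.omnibus_p_ < 0.05


def test_too_few_subjects_raise():
    rows = [dict(subject="s0", condition=c, value=i)
            for i, c in enumerate(CONDITIONS)]
    with pytest.raises(DesignError):
        RankConditionANOVA().fit(pd.DataFrame(rows))


def test_holm_adjustment_is_conservative(rng):
    df = _study(rng, shift={"bedrest_hypoxia": 2.0})
    raw = RankConditionANOVA(holm=False).fit(df).contrasts_["p"]
    adj = RankConditionANOVA(holm=True).fit(df).contrasts_["p"]
    assert (adj >= raw - 1e-12).all()


def test_descriptive_table_layout(rng):
    df = _study(rng).assign(variable="Alpha Index M")
    tab = descriptive_table(df)
    assert "ambulatory_normoxia_mean" in tab.columns
    assert "omnibus_p" in tab.columns and "contrasts" in tab.columns
    assert tab.loc["Alpha Index M", "ambulatory_normoxia_n"] == 11


def test_descriptive_table_single_value_sd_zero():
    rows = [dict(subject="s0", condition=c, value=2.0, variable="x")
            for c in CONDITIONS]
    tab = descriptive_table(pd.DataFrame(rows))
    assert tab.loc["x", "bedrest_hypoxia_sd"] == 0.0
    assert tab.loc["x", "bedrest_hypoxia_n"] == 1


def test_thin_wrappers(rng):
    df = _study(rng)
    assert mixed_model_ranks(df) == RankConditionANOVA().fit(df).omnibus_p_
    assert list(paired_contrasts(df).index) == list("abcdef")
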