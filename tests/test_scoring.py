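"""Scoring equations: hand-derived values, invariants, brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmcq.preprocess import CleanMatrix
from rmcq.schema import FactorSpec
from rmcq.scoring import (
    domain_scores,
    factor_score,
    overall_score,
    score_cohort,
    sum_score,
)

SOCIAL = FactorSpec("Social support", (("companion_labour", 0.85), ("companion_birth", 0.94)))
ABUSE = FactorSpec(
    "Lack of physical & verbal abuse",
    (
        ("slapped_pinched", 0.40),
        ("negative_comments", 0.66),
        ("shouted_items", 0.78),
        ("bribe_request", -0.73),
    ),
)


def _oracle_ss(responses, spec):
    """Naive term-by-term evaluation of the sum-score equation."""
    total, shift, n = 0.0, 0.0, 0
    for iid, w in spec.loadings:
        q = responses.get(iid)
        if q is None or (isinstance(q, float) and np.isnan(q)):
            continue
        n += 1
        total += np.sign(w) * q
        if w < 0:
            shift += 1
    return None if n == 0 else 10.0 * (total / n + shift / n)


def _oracle_fs(responses, spec):
    """Naive term-by-term evaluation of the factor-score equation."""
    num, shift, denom, n = 0.0, 0.0, 0.0, 0
    for iid, w in spec.loadings:
        q = responses.get(iid)
        if q is None or (isinstance(q, float) and np.isnan(q)):
            continue
        n += 1
        num += w * q
        denom += abs(w)
        if w < 0:
            shift += abs(w)
    return None if n == 0 else 10.0 * (num / denom + shift / denom)


def test_sum_score_all_best_positive_loadings_hits_ceiling():
    assert sum_score({"companion_labour": 1.0, "companion_birth": 1.0}, SOCIAL).value == 10.0


def test_sum_score_best_worst_is_midpoint():
    assert sum_score({"companion_labour": 1.0, "companion_birth": 0.0}, SOCIAL).value == 5.0


def test_sum_score_with_negative_loading_all_best():
    r = {iid: 1.0 for iid, _ in ABUSE.loadings}
    assert sum_score(r, ABUSE).value == pytest.approx(7.5)


def test_factor_score_best_worst():
    fs = factor_score({"companion_labour": 1.0, "companion_birth": 0.0}, SOCIAL)
    assert fs.value == pytest.approx(10 * 0.85 / 1.79, abs=5e-4)
    assert fs.value == pytest.approx(4.749, abs=5e-4)


def test_factor_score_with_negative_loading_all_best():
    r = {iid: 1.0 for iid, _ in ABUSE.loadings}
    assert factor_score(r, ABUSE).value == pytest.approx((1.11 + 0.73) / 2.57 * 10, abs=1e-9)
    assert factor_score(r, ABUSE).value == pytest.approx(7.1595, abs=1e-4)


def test_shift_makes_ceiling_attainable_with_negative_loading():
    """Max FS requires the worst (normalized 0) response on the negatively
    keyed item, and equals exactly 10."""
    best = {"slapped_pinched": 1.0, "negative_comments": 1.0, "shouted_items": 1.0,
            "bribe_request": 0.0}
    assert factor_score(best, ABUSE).value == pytest.approx(10.0)
    assert sum_score(best, ABUSE).value == pytest.approx(10.0)


def test_no_answered_items_yields_no_score():
    assert sum_score({}, SOCIAL).value is None
    assert factor_score({"companion_labour": float("nan")}, SOCIAL).value is None


def test_unknown_response_is_ignored():
    ss = sum_score({"companion_labour": 1.0, "other_item": 0.3}, SOCIAL)
    assert ss.n_answered == 1
    assert ss.value == 10.0


def test_overall_score_examples():
    assert overall_score([10, 5]) == pytest.approx(75.0)
    assert overall_score([10] * 6) == pytest.approx(100.0)
    assert overall_score([8, 9, None, 7]) == pytest.approx(80.0)
    assert overall_score([]) is None


def test_domain_scores_with_missing_subscale(grouping):
    scores = {
        "Maintained respect & dignity": 8.0,
        "Lack of physical & verbal abuse": 7.0,
        # privacy absent
        "Communication & supportive care": 10.0,
        "Hospital environment": 10.0,
        "Social support": 10.0,
    }
    resp, respect = domain_scores(scores, grouping)
    assert respect == pytest.approx(75.0)
    assert resp == pytest.approx(100.0)


@st.composite
def spec_and_responses(draw):
    p = draw(st.integers(min_value=1, max_value=8))
    loadings = tuple(
        (
            f"i{j}",
            draw(
                st.floats(min_value=0.05, max_value=1.2).flatmap(
                    lambda x: st.sampled_from([x, -x])
                )
            ),
        )
        for j in range(p)
    )
    responses = {
        f"i{j}": draw(
            st.one_of(st.none(), st.floats(min_value=0.0, max_value=1.0))
        )
        for j in range(p)
    }
    responses = {k: v for k, v in responses.items() if v is not None}
    return FactorSpec("S", loadings), responses


@given(spec_and_responses())
@settings(max_examples=300, deadline=None)
def test_scores_stay_in_range_and_match_oracle(sr):
    """Both scores stay in [0, 10] and agree with the naive term-by-term
    evaluation of the equations to 1e-12, for any signed-loading spec."""
    spec, responses = sr
    ss = sum_score(responses, spec).value
    fs = factor_score(responses, spec).value
    oss, ofs = _oracle_ss(responses, spec), _oracle_fs(responses, spec)
    if not responses:
        assert ss is None and fs is None
        return
    assert -1e-9 <= ss <= 10 + 1e-9
    assert -1e-9 <= fs <= 10 + 1e-9
    assert ss == pytest.approx(oss, abs=1e-12)
    assert fs == pytest.approx(ofs, abs=1e-12)


@given(spec_and_responses())
@settings(max_examples=100, deadline=None)
def test_scores_invariant_to_item_order(sr):
    spec, responses = sr
    if not responses:
        return
    perm = FactorSpec("S", tuple(reversed(spec.loadings)))
    assert sum_score(responses, spec).value == pytest.approx(
        sum_score(responses, perm).value, abs=1e-12
    )
    assert factor_score(responses, spec).value == pytest.approx(
        factor_score(responses, perm).value, abs=1e-12
    )


@given(spec_and_responses())
@settings(max_examples=100, deadline=None)
def test_removing_unanswered_item_changes_nothing(sr):
    spec, responses = sr
    answered = tuple((i, w) for i, w in spec.loadings if i in responses)
    if not answered:
        return
    trimmed = FactorSpec("S", answered)
    assert sum_score(responses, spec).value == pytest.approx(
        sum_score(responses, trimmed).value, abs=1e-12
    )
    assert factor_score(responses, spec).value == pytest.approx(
        factor_score(responses, trimmed).value, abs=1e-12
    )


@given(
    st.integers(min_value=2, max_value=8),
    st.floats(min_value=0.1, max_value=1.0),
    st.lists(st.floats(min_value=0, max_value=1), min_size=8, max_size=8),
)
@settings(max_examples=100, deadline=None)
def test_equal_loadings_make_both_methods_identical(p, w, qs):
    spec = FactorSpec("S", tuple((f"i{j}", w) for j in range(p)))
    responses = {f"i{j}": qs[j] for j in range(p)}
    assert factor_score(responses, spec).value == pytest.approx(
        sum_score(responses, spec).value, abs=1e-12
    )


def _tiny_clean(values, item_ids):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return CleanMatrix(
        respondent_ids=np.array([f"r{i}" for i in range(n)]),
        item_ids=item_ids,
        fa_values=np.nan_to_num(values).astype(int),
        scoring_values=values,
        strata=pd.DataFrame(
            {"country": ["X"] * n, "hospital": ["H"] * n, "round": [1] * n}
        ),
    )


def test_score_cohort_ceiling_and_summary(schema, grouping):
    ids = ["companion_labour", "companion_birth"]
    clean = _tiny_clean(np.ones((5, 2)), ids)
    table, summary = score_cohort(clean, schema, [SOCIAL])
    assert (table["SS:Social support"] == 10.0).all()
    assert summary["subscales"]["Social support"]["ss"]["mean"] == 10.0
    assert summary["subscales"]["Social support"]["ss"]["sd"] == 0.0


def test_score_cohort_single_respondent(schema):
    ids = ["companion_labour", "companion_birth"]
    clean = _tiny_clean(np.array([[1.0, 0.0]]), ids)
    table, summary = score_cohort(clean, schema, [SOCIAL])
    assert summary["subscales"]["Social support"]["ss"]["mean"] == pytest.approx(5.0)
    assert summary["subscales"]["Social support"]["fs"]["mean"] == pytest.approx(
        10 * 0.85 / 1.79
    )


def test_score_cohort_matches_per_respondent_oracle(schema, specs, grouping):
    rng = np.random.default_rng(14)
    ids = [iid for s in specs for iid in s.item_ids]
    ncat = {iid: schema[iid].scale.n_scored_categories for iid in ids}
    codes = np.column_stack([rng.integers(0, ncat[iid], size=60) for iid in ids]).astype(float)
    codes[rng.random(codes.shape) < 0.1] = np.nan
    clean = _tiny_clean(codes, ids)
    table, _ = score_cohort(clean, schema, specs, grouping)
    for i in range(10):
        responses = {
            iid: codes[i, j] / (ncat[iid] - 1)
            for j, iid in enumerate(ids)
            if not np.isnan(codes[i, j])
        }
        for spec in specs:
            exp = _oracle_ss(responses, spec)
            got = table.loc[i, f"SS:{spec.factor_name}"]
            if exp is None:
                assert pd.isna(got)
            else:
                assert got == pytest.approx(exp, abs=1e-12)
            expf = _oracle_fs(responses, spec)
            gotf = table.loc[i, f"FS:{spec.factor_name}"]
            if expf is None:
                assert pd.isna(gotf)
            else:
                assert gotf == pytest.approx(expf, abs=1e-12)


def test_score_cohort_rejects_overlapping_specs(schema):
    clean = _tiny_clean(np.ones((2, 2)), ["companion_labour", "companion_birth"])
    dup = FactorSpec("Other", (("companion_labour", 0.5), ("companion_birth", 0.5)))
    with pytest.raises(ValueError, match="several factor specs"):
        score_cohort(clean, schema, [SOCIAL, dup])
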