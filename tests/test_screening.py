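"""Triplet enumeration, the 8-test battery, BH-FDR and signal selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trioscreen as ts
from trioscreen.screening import BATTERY_LABELS, results_frame, triplet_design


def dose_matrix_from_codes(case_codes, control_codes, columns):
    n = case_codes.shape[0]
    rows = []
    for i in range(n):
        rows.append([i, "case", *case_codes[i]])
        rows.append([i, "control", *control_codes[i]])
    return pd.DataFrame(rows, columns=["pair_id", "role", *columns])


def co_exposure_matrix(n_exposed, n_total, columns=("a", "b", "c", "d")):
    """Cases co-exposed to every drug for the first n_exposed pairs."""
    d = len(columns)
    case = np.zeros((n_total, d), dtype=int)
    case[:n_exposed] = 1
    control = np.zeros_like(case)
    return dose_matrix_from_codes(case, control, columns)


def policy(**kwargs):
    kwargs.setdefault("required_drug_set", {"a"})
    return ts.ScreeningPolicy(**kwargs)


# -------------------------------------------------------------- enumeration

def test_triplet_below_case_count_threshold_is_excluded():
    matrix = co_exposure_matrix(499, 600)
    assert ts.enumerate_triplets(matrix, policy(min_case_count=500)) == []
    matrix = co_exposure_matrix(500, 600)
    got = ts.enumerate_triplets(matrix, policy(min_case_count=500))
    assert len(got) == 3  # the C(4,3)=4 triplets minus (b,c,d), which lacks "a"


def test_triplet_without_required_drug_is_excluded():
    matrix = co_exposure_matrix(50, 60, columns=("a", "b", "c", "d"))
    got = ts.enumerate_triplets(matrix, policy(min_case_count=10))
    assert ("b", "c", "d") not in got
    assert all("a" in trip for trip in got)


def test_four_coexposed_drugs_give_four_candidate_triplets():
    matrix = co_exposure_matrix(30, 30)
    got = ts.enumerate_triplets(
        matrix, ts.ScreeningPolicy(min_case_count=10, required_drug_set={"a", "b", "c", "d"})
    )
    assert got == [("a", "b", "c"), ("a", "b", "d"), ("a", "c", "d"), ("b", "c", "d")]


def test_empty_required_drug_set_is_a_configuration_error():
    matrix = co_exposure_matrix(30, 30)
    with pytest.raises(ts.ConfigurationError):
        ts.enumerate_triplets(matrix, ts.ScreeningPolicy(min_case_count=10))


def test_policy_validation():
    with pytest.raises(ts.ConfigurationError):
        ts.ScreeningPolicy(min_case_count=0)
    with pytest.raises(ts.ConfigurationError):
        ts.ScreeningPolicy(fdr_level=1.5)
    with pytest.raises(ts.ConfigurationError):
        ts.ScreeningPolicy(or_min=0.5)


# ------------------------------------------------------------------ battery

def simulated_fit(beta, n_pairs=4000, seed=0):
    cfg = ts.PairSimConfig(n_pairs=n_pairs, beta=tuple(beta), seed=seed)
    cc, ct = ts.pair_codes(ts.generate_matched_pairs(cfg))
    design = ts.TripletDesign.from_codes(("a", "b", "c"), cc, ct)
    return design, ts.fit_clrm(design)


def test_battery_is_half_when_beta_hat_is_zero():
    design, fit = simulated_fit(np.zeros(7))
    fit.beta = np.zeros(7)
    p = ts.run_battery(design, fit)
    assert set(p) == set(BATTERY_LABELS)
    for value in p.values():
        assert value == pytest.approx(0.5)


def test_battery_composite_matches_highest_dose_contrast_exactly():
    design, fit = simulated_fit([0.2, 0, 0.1, 0, 0, 0, 0.02], seed=3)
    p = ts.run_battery(design, fit)
    direct = ts.wald_contrast(fit, ts.design_row(2, 2, 2))
    assert p["composite_222"] == direct.p_one_sided


def test_battery_matches_mcnemar_style_hand_computation():
    """Single-drug reduction: Wald p from log(b/c), SE sqrt(1/b + 1/c)."""
    from scipy.stats import norm

    b, c = 14, 6  # case-only vs control-only exposed discordant pairs
    z = np.concatenate([np.ones((b, 1)), -np.ones((c, 1))])
    fit = ts.fit_conditional_logit(z)
    res = ts.wald_contrast(fit, np.ones(1))
    z_hand = np.log(b / c) / np.sqrt(1 / b + 1 / c)
    assert res.z == pytest.approx(z_hand, abs=1e-6)
    assert res.p_one_sided == pytest.approx(norm.sf(z_hand), abs=1e-6)


def test_battery_untested_for_separated_fit():
    design, fit = simulated_fit(np.zeros(7), n_pairs=30, seed=1)
    fit.separation_flag = True
    assert ts.run_battery(design, fit) == {"untested": "separation"}


# ----------------------------------------------------------------------- BH

def test_bh_all_ones_stay_one():
    np.testing.assert_allclose(ts.apply_bh([1.0, 1.0, 1.0]), 1.0)


def test_bh_step_up_worked_example():
    q = ts.apply_bh([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_permutation_equivariance():
    rng = np.random.default_rng(0)
    p = rng.random(40)
    perm = rng.permutation(40)
    np.testing.assert_allclose(ts.apply_bh(p)[perm], ts.apply_bh(p[perm]))


def test_bh_matches_statsmodels():
    multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
    rng = np.random.default_rng(1)
    p = rng.random(200) ** 2
    np.testing.assert_allclose(
        ts.apply_bh(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
    )


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_bh_q_values_dominate_p_values(p_values):
    q = ts.apply_bh(p_values)
    assert np.all(q >= np.asarray(p_values) - 1e-15)
    assert np.all(q <= 1.0)


# ------------------------------------------------------------------ signals

def make_result(q_composite=0.01, or_222=2.0, beta=None, q_extra=None):
    fit = ts.TripletFit(
        beta=np.array(beta if beta is not None else [0.1] * 7),
        cov=np.eye(7),
        loglik=-10.0,
        converged=True,
        separation_flag=False,
        n_pairs=100,
        n_discordant=80,
        n_iter=5,
        triplet=("a", "b", "c"),
    )
    q = {lab: 0.5 for lab in BATTERY_LABELS}
    q["composite_222"] = q_composite
    if q_extra:
        q.update(q_extra)
    return ts.ScreeningResult(
        triplet=("a", "b", "c"), fit=fit, p_values=dict(q), q_values=q, or_222=or_222
    )


def test_signal_requires_composite_q_below_fdr():
    res = make_result(q_composite=0.06)
    assert ts.select_signals([res], policy()) == []
    assert "composite_q_above_fdr" in res.reason_codes


def test_signal_requires_or_at_least_floor():
    res = make_result(or_222=1.25)
    assert ts.select_signals([res], policy()) == []
    assert "or_222_below_min" in res.reason_codes


def test_three_positive_main_effects_satisfy_pattern_criterion():
    res = make_result(beta=[0.1, 0.1, 0.1, 0, 0, 0, 0], or_222=float(np.exp(0.6)))
    assert ts.select_signals([res], policy()) == [res]
    assert res.signal and res.reason_codes == []


def test_negative_main_effect_without_interaction_fails_pattern():
    res = make_result(beta=[0.5, -0.1, 0.5, 0, 0, 0, 0])
    assert ts.select_signals([res], policy()) == []
    assert "pattern_drug2" in res.reason_codes


def test_significant_interaction_rescues_negative_main_effect():
    # beta2 < 0 but the x2*x3 interaction clears the FDR level
    res = make_result(
        beta=[0.5, -0.1, 0.5, 0, 0, 0.8, 0], q_extra={"beta6": 0.01}
    )
    assert ts.select_signals([res], policy()) == [res]


# ------------------------------------------------------------- full screen

def screening_matrix(seed=0, beta=(0.5, 0.4, 0.45, 0.05, 0.05, 0.05, 0.03)):
    """Four-drug dose matrix with a planted effect on (a, b, c)."""
    rng = np.random.default_rng(seed)
    n = 800
    cfg = ts.PairSimConfig(n_pairs=n, beta=tuple(beta), seed=seed)
    cc, ct = ts.pair_codes(ts.generate_matched_pairs(cfg))
    extra_case = rng.choice(3, size=(n, 1), p=[0.5, 0.25, 0.25])
    extra_ctrl = rng.choice(3, size=(n, 1), p=[0.5, 0.25, 0.25])
    return dose_matrix_from_codes(
        np.hstack([cc, extra_case]), np.hstack([ct, extra_ctrl]), ("a", "b", "c", "d")
    )


def test_screen_detects_planted_triplet_and_orders_deterministically():
    matrix = screening_matrix()
    pol = policy(min_case_count=20)
    outcome = ts.screen(matrix, pol)
    assert outcome.n_pooled_tests == 8 * len(outcome.results)
    planted = [r for r in outcome.results if r.triplet == ("a", "b", "c")]
    assert planted and planted[0].signal
    # identical input, shuffled rows: identical signal list
    shuffled = matrix.sample(frac=1.0, random_state=1).reset_index(drop=True)
    outcome2 = ts.screen(shuffled, pol)
    assert [r.triplet for r in outcome2.signals] == [r.triplet for r in outcome.signals]


def test_results_frame_has_eight_p_and_q_columns():
    outcome = ts.screen(screening_matrix(), policy(min_case_count=20))
    frame = results_frame(outcome)
    assert sum(c.startswith("p_") for c in frame.columns) == 8
    assert sum(c.startswith("q_") for c in frame.columns) == 8
    assert (frame[[f"q_{lab}" for lab in BATTERY_LABELS]].to_numpy()
            >= frame[[f"p_{lab}" for lab in BATTERY_LABELS]].to_numpy() - 1e-15).all()


def test_triplet_design_requires_paired_rows():
    matrix = screening_matrix().iloc[:-1]  # drop one control row
    with pytest.raises(ts.FitError):
        triplet_design(matrix, ("a", "b", "c"))


# ----------------------------------------------------------------- subgroup

def pairs_with_ages(ages):
    rows = []
    for i, age in enumerate(ages):
        rows.append({"pair_id": i, "role": "case", "age_at_index": age})
        rows.append({"pair_id": i, "role": "control", "age_at_index": age + 1})
    return pd.DataFrame(rows)


def test_subgroup_min_age_zero_is_identity():
    pairs = pairs_with_ages([40, 70, 64])
    pd.testing.assert_frame_equal(ts.subgroup_filter(pairs, 0), pairs)


def test_subgroup_drops_whole_pair_when_case_below_cutoff():
    pairs = pairs_with_ages([64, 65, 80])
    kept = ts.subgroup_filter(pairs, 65)
    assert sorted(kept["pair_id"].unique()) == [1, 2]
    assert len(kept) == 4  # both members of each retained pair
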