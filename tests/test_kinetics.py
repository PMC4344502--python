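"""Remaining fractions, turnover classes, decay fits, kinetic shapes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirturn import (SimConfig, ThresholdConfig, classify_kinetic_shape,
                     classify_turnover, compute_frequencies, fit_single_exponential,
                     fit_two_phase, generate_reference, quantify_reads,
                     turnover_calls)
from mirturn.kinetics import remaining_fractions
from mirturn.synthdata import simulate_timecourse_reads

TH = ThresholdConfig()
T = [0.0, 1.0, 4.0, 12.0]


def _fm(freq_rows, times, reps=3):
    """Tiny FrequencyMatrix stand-in from per-entity per-time replicate values."""
    from mirturn.quantify import FrequencyMatrix
    cols, meta = [], []
    for t in times:
        for r in range(1, reps + 1):
            cols.append(f"t{t:g}h_r{r}")
            meta.append({"sample_id": f"t{t:g}h_r{r}", "time_h": t, "replicate": r})
    data = {}
    for ent, by_time in freq_rows.items():
        vals = []
        for t in times:
            v = by_time[t]
            vals.extend(v if isinstance(v, (list, tuple)) else [v] * reps)
        data[ent] = vals
    freq = pd.DataFrame(data, index=cols).T
    samples = pd.DataFrame(meta).set_index("sample_id", drop=False)
    det = pd.Series(True, index=freq.index)
    return FrequencyMatrix(isoform=freq, isoform_meta=pd.DataFrame(index=freq.index),
                           entity=freq, entity_meta=pd.DataFrame(index=freq.index),
                           samples=samples, detected_isoform=det,
                           detected_entity=det, theta=5e-6)


# ------------------------------------------------------- remaining fractions

def test_constant_frequencies_give_unit_remaining():
    fm = _fm({"x": {0.0: 0.1, 1.0: 0.1, 4.0: 0.1, 12.0: 0.1}}, T)
    rbar, unc = remaining_fractions(fm.entity, fm.samples)
    np.testing.assert_allclose(rbar.loc["x"], 1.0)
    assert not unc["x"]


def test_halving_frequencies_give_halving_remaining():
    fm = _fm({"x": {0.0: 0.4, 1.0: 0.2, 2.0: 0.1}}, [0.0, 1.0, 2.0])
    rbar, _ = remaining_fractions(fm.entity, fm.samples)
    np.testing.assert_allclose(rbar.loc["x"], [1.0, 0.5, 0.25])


def test_remaining_matches_generator_law_noiselessly():
    cfg = SimConfig(n_hairpins=15, nb_dispersion=0.0, depth=1e9,
                    stable_fraction_range=(0.25, 0.25), seed=13)
    ref, _, truth = generate_reference(cfg)
    sim = simulate_timecourse_reads(ref, truth, cfg)
    # frequencies built from exact expectations, not sampled counts
    exp = sim.expected.set_index("sequence")
    counts = exp[list(sim.samples["sample_id"])].round().astype(int)
    fm = compute_frequencies(quantify_reads(counts, ref), sim.samples)
    rbar, _ = remaining_fractions(fm.entity, fm.samples)
    tr = truth.set_index("mature_id")
    # slow species: R = 1 * (total drift correction); fast: plateau law
    fast = [m for m in tr.index[tr["true_class"] == "fast"] if m in rbar.index]
    want = 0.25 + 0.75 * 2.0 ** (-12.0 / cfg.h_fast)
    drift = 1.0 / rbar.loc[tr.index[tr["true_class"] == "slow"], 12.0].mean()
    np.testing.assert_allclose(rbar.loc[fast, 12.0] * drift, want, rtol=1e-5)


def test_zero_baseline_marks_entity_uncomputable():
    fm = _fm({"x": {0.0: 0.0, 4.0: 0.1, 12.0: 0.1}}, [0.0, 4.0, 12.0])
    rbar, unc = remaining_fractions(fm.entity, fm.samples)
    assert unc["x"]
    assert rbar.loc["x"].isna().all()


# ------------------------------------------------------------ classification

@pytest.mark.parametrize("r_end,pvals,expected", [
    (0.20, [0.5, 0.01, 0.5], "fast_lt25"),
    (0.40, [0.5, 0.01, 0.5], "fast_lt50"),
    (1.00, [1.0, 1.0, 1.0], "slow"),
    (0.74, [0.001, 0.001, 0.001], "intermediate"),   # fails both gates
    (0.60, [0.01, 0.01, 0.01], "intermediate"),
    (0.80, [0.01, 0.5, 0.5], "intermediate"),        # significant but stable
    (0.40, [0.5, 0.5, 0.5], "intermediate"),         # low but not significant
])
def test_turnover_class_rules(r_end, pvals, expected):
    assert classify_turnover(r_end, pvals, TH) == expected


def test_identical_replicates_yield_slow_via_unit_pvalues():
    fm = _fm({"x": {0.0: 0.2, 1.0: 0.2, 4.0: 0.2, 12.0: 0.2}}, T)
    calls = turnover_calls(fm, fit=False)
    row = calls.loc["x"]
    assert row["turnover_class"] == "slow"
    assert row["p_0v_end"] == 1.0 and row["p_0v_mid"] == 1.0


def test_single_replicate_groups_are_unclassified():
    fm = _fm({"x": {0.0: 0.2, 4.0: 0.1, 12.0: 0.05}}, [0.0, 4.0, 12.0], reps=1)
    calls = turnover_calls(fm, fit=False)
    assert calls.loc["x", "turnover_class"] == "unclassified"


def test_classification_monotone_in_endpoint_remaining():
    """Lowering R(12) with significant p-values never moves fast -> slow."""
    order = {"fast_lt25": 0, "fast_lt50": 1, "intermediate": 2, "slow": 3}
    pvals = [0.01, 0.01, 0.01]
    prev = None
    for r_end in np.linspace(1.2, 0.01, 40):
        cls = classify_turnover(r_end, pvals, TH)
        if prev is not None:
            assert order[cls] <= order[prev] or cls == prev
        prev = cls


# -------------------------------------------------------------------- fits

def test_single_exponential_closed_forms():
    assert fit_single_exponential([0, 1, 2], [1.0, 0.5, 0.25])["h"] == \
        pytest.approx(1.0)
    assert math.isinf(fit_single_exponential([0, 1, 2], [1, 1, 1])["h"])
    r18 = [2.0 ** (-t / 18.0) for t in T]
    assert fit_single_exponential(T, r18)["h"] == pytest.approx(18.0, abs=1e-6)


def test_single_exponential_excludes_nonpositive_points():
    fit = fit_single_exponential([0, 1, 4, 12], [1.0, 0.5, 0.0, -0.1])
    assert fit["n_used"] == 2
    assert fit["h"] == pytest.approx(1.0)


def test_two_phase_recovers_exact_mixture():
    r = [0.2 + 0.8 * 2.0 ** (-t) for t in T]
    fit = fit_two_phase(T, r)
    assert fit["f_fast"] == pytest.approx(0.8, abs=1e-6)
    assert fit["h_fast"] == pytest.approx(1.0, abs=1e-6)
    assert fit["f_slow"] == pytest.approx(0.2, abs=1e-6)
    assert 1.0 / fit["h_slow"] == pytest.approx(0.0, abs=1e-6)


def test_two_phase_flat_curve_degenerates_to_zero_fast_fraction():
    fit = fit_two_phase(T, [1.0, 1.0, 1.0, 1.0])
    assert fit["f_fast"] == 0.0
    assert math.isinf(fit["h_fast"]) and math.isinf(fit["h_slow"])


@given(st.lists(st.floats(min_value=0.01, max_value=1.2), min_size=3, max_size=3))
def test_two_phase_never_fits_worse_than_single(tail):
    r = [1.0] + tail
    single = fit_single_exponential(T, r)
    two = fit_two_phase(T, r, weights=[3, 3, 3, 3], single_h=single["h"])
    assert two["sse"] <= two["sse_single"] + 1e-12


def test_two_phase_matches_dense_grid_oracle_on_noisy_species():
    """Median recovered fast half-life within 15% of planted, and never a
    worse SSE than a dense brute-force grid search (no refinement)."""
    rng = np.random.default_rng(21)
    hf_o = np.geomspace(0.05, 50.0, 120)
    f_o = np.linspace(0.0, 1.0, 51)
    r_o = np.concatenate([[0.0], np.geomspace(1e-3, 1.0, 15)])
    t = np.array(T)
    recovered = []
    for _ in range(40):
        f_slow = rng.uniform(0.05, 0.4)
        truth_curve = f_slow + (1 - f_slow) * 2.0 ** (-t / 1.0)
        r = truth_curve * (1 + rng.normal(0, 0.05, size=4))
        r[0] = 1.0
        fit = fit_two_phase(t, r, weights=[3, 3, 3, 3])
        lam = math.log(2) / hf_o[None, :, None, None]
        curve = (f_o[:, None, None, None] * np.exp(-lam * t)
                 + (1 - f_o[:, None, None, None])
                 * np.exp(-r_o[None, None, :, None] * lam * t))
        sse = ((curve - r) ** 2).sum(axis=-1)
        assert fit["sse"] <= 3.0 * sse.min() + 1e-9  # fit weights are uniform 3
        recovered.append(fit["h_fast"])
    assert abs(np.median(recovered) - 1.0) <= 0.15


# ------------------------------------------------------------------- shapes

def _shape(rvals, tclass):
    single = fit_single_exponential(T, rvals)
    two = fit_two_phase(T, rvals, weights=[3, 3, 3, 3], single_h=single["h"])
    return classify_kinetic_shape(dict(zip(T, rvals)), tclass, two, TH)


def test_loop_like_collapse_is_ultrafast():
    assert _shape([1.0, 0.05, 0.04, 0.03], "fast_lt25") == "ultrafast"


def test_plateau_curve_is_two_step():
    assert _shape([1.0, 0.55, 0.33, 0.30], "fast_lt50") == "two_step"


def test_slow_entity_is_stable_even_if_fit_wiggles():
    assert _shape([1.0, 0.93, 1.04, 0.97], "slow") == "stable"


def test_fast_entity_without_plateau_is_continuous():
    r = [2.0 ** (-t / 5.0) for t in T]
    assert _shape(r, "fast_lt50") == "continuous"
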