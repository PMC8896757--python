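"""Additive TE stability model: prediction, fitting, LOO, classification."""

import numpy as np
import pytest

from thermoenv import (
    GAS_CONSTANT,
    InvariantError,
    STANDARD_TEMPERATURE,
    StabilityParams,
    StabilityRecord,
    TESequence,
    classify_structured,
    featurize,
    fit_model,
    loo_bootstrap,
    predict_dG,
)
from thermoenv.simulate import GeneratorConfig, gen_stability_records


def random_record(rng, length=100, pid="p"):
    native = rng.multinomial(length, rng.dirichlet(np.ones(8)))
    denatured = rng.multinomial(length, rng.dirichlet(np.ones(8)))
    return StabilityRecord(pid, native, denatured, length)


def random_params(rng):
    return StabilityParams(
        w_native=rng.normal(scale=2.0, size=8),
        w_denatured=rng.normal(scale=2.0, size=8),
        z=float(rng.uniform(2.0, 50.0)),
    )


# ---------------------------------------------------------------------------
# closed forms and prediction

def test_rt_at_standard_temperature():
    assert GAS_CONSTANT * STANDARD_TEMPERATURE == pytest.approx(2.4790, abs=1e-3)


def test_per_residue_entropic_penalty_at_z20():
    rt = GAS_CONSTANT * STANDARD_TEMPERATURE
    assert rt * np.log(20.0) == pytest.approx(7.43, abs=0.01)


def test_zero_weights_unit_z_predicts_zero(rng):
    params = StabilityParams(np.zeros(8), np.zeros(8), z=1.0)
    assert predict_dG(random_record(rng), params) == pytest.approx(0.0)


def test_unit_native_weights_predict_length(rng):
    params = StabilityParams(np.ones(8), np.zeros(8), z=1.0)
    record = random_record(rng, length=73)
    assert predict_dG(record, params) == pytest.approx(73.0)


def test_prediction_matches_seventeen_term_sum(rng):
    record = random_record(rng)
    params = random_params(rng)
    expected = 0.0
    for i in range(8):
        expected += params.w_native[i] * record.native_counts[i]
        expected += params.w_denatured[i] * record.denatured_counts[i]
    expected -= record.length * GAS_CONSTANT * STANDARD_TEMPERATURE * np.log(params.z)
    assert predict_dG(record, params) == pytest.approx(expected, abs=1e-9)


def test_prediction_linear_in_counts(rng):
    params = random_params(rng)
    a, b = random_record(rng, 60, "a"), random_record(rng, 90, "b")
    combined = StabilityRecord(
        "ab", a.native_counts + b.native_counts,
        a.denatured_counts + b.denatured_counts, 150,
    )
    assert predict_dG(combined, params) == pytest.approx(
        predict_dG(a, params) + predict_dG(b, params), abs=1e-9
    )


def test_invalid_z_rejected():
    with pytest.raises(InvariantError):
        StabilityParams(np.zeros(8), np.zeros(8), z=0.0)


# ---------------------------------------------------------------------------
# featurize

def test_featurize_counts_and_conservation():
    seq = TESequence("p", [4, 5], [2, 2])
    record = featurize(seq)
    assert record.native_counts.tolist() == [0, 0, 0, 1, 1, 0, 0, 0]
    assert record.denatured_counts.tolist() == [0, 2, 0, 0, 0, 0, 0, 0]
    assert record.length == 2
    permuted = featurize(TESequence("p", [5, 4], [2, 2]))
    assert np.array_equal(permuted.native_counts, record.native_counts)


# ---------------------------------------------------------------------------
# gauge degeneracy

def test_gauge_transformation_leaves_predictions_invariant(rng):
    """Shifting weights by constants absorbed into ln Z changes nothing."""
    params = random_params(rng)
    a, b = 3.7, -1.2
    rt = params.rt
    shifted = StabilityParams(
        w_native=params.w_native + a,
        w_denatured=params.w_denatured + b,
        z=float(np.exp(params.ln_z + (a + b) / rt)),
    )
    for _ in range(20):
        record = random_record(rng, length=int(rng.integers(30, 300)))
        assert predict_dG(record, shifted) == pytest.approx(
            predict_dG(record, params), abs=1e-9
        )


# ---------------------------------------------------------------------------
# fitting

def test_noiseless_fit_reproduces_training_dG():
    records, _ = gen_stability_records(35, noise_sd=0.0, config=GeneratorConfig(seed=3))
    fit = fit_model(records)
    assert np.max(np.abs(fit.residuals)) < 1e-6


def test_gauge_fixed_fit_recovers_z_from_mean_zero_truth():
    k = np.arange(1, 9, dtype=float)
    truth = StabilityParams(w_native=-0.3 * (k - 4.5), w_denatured=-0.2 * (k - 4.5),
                            z=20.0)
    records, _ = gen_stability_records(
        35, stability_truth=truth, noise_sd=0.0, config=GeneratorConfig(seed=9),
    )
    fit = fit_model(records, gauge_fix=True)
    assert fit.params.z == pytest.approx(20.0, rel=1e-6)
    assert np.abs(fit.params.w_native.mean()) < 1e-9
    assert np.abs(fit.params.w_denatured.mean()) < 1e-9


def test_noisy_fit_heldout_rmse_in_expected_band():
    records, _ = gen_stability_records(35, noise_sd=2.0, config=GeneratorConfig(seed=7))
    result = loo_bootstrap(records)
    assert 1.0 <= result.heldout_rmse <= 4.0  # within [sigma/2, 2*sigma]


def test_too_few_records_rejected():
    records, _ = gen_stability_records(2, config=GeneratorConfig(seed=1))
    with pytest.raises(InvariantError):
        fit_model(records)


def test_fixed_z_fit():
    records, truth = gen_stability_records(20, noise_sd=0.0,
                                           config=GeneratorConfig(seed=13))
    fit = fit_model(records, fixed_z=truth.z)
    assert fit.params.z == pytest.approx(truth.z)
    assert np.max(np.abs(fit.residuals)) < 1e-6


def test_summary_mentions_gauge_freedom():
    records, _ = gen_stability_records(10, config=GeneratorConfig(seed=4))
    fit = fit_model(records)
    text = fit.summary()
    assert "gauge" in text
    assert "Z" in text


# ---------------------------------------------------------------------------
# leave-one-out

def test_loo_bookkeeping_and_z_envelope():
    records, _ = gen_stability_records(12, noise_sd=2.0, config=GeneratorConfig(seed=5))
    result = loo_bootstrap(records)
    assert len(result.fold_results) == 12
    assert not result.failed_folds
    # fold i excludes record i: its training size is n-1
    assert all(f.n_obs == 11 for f in result.fold_results)
    ln_zs = [f.params.ln_z for f in result.fold_results]
    assert min(ln_zs) - 1e-12 <= result.averaged.ln_z <= max(ln_zs) + 1e-12


def test_loo_noiseless_heldout_error_tiny():
    records, _ = gen_stability_records(20, noise_sd=0.0, config=GeneratorConfig(seed=6))
    result = loo_bootstrap(records)
    heldout_err = np.abs(result.heldout_predictions
                         - np.array([r.dG_exp for r in records]))
    assert np.max(heldout_err) < 1e-4


def test_loo_requires_four_records():
    records, _ = gen_stability_records(3, config=GeneratorConfig(seed=8))
    with pytest.raises(InvariantError):
        loo_bootstrap(records)


# ---------------------------------------------------------------------------
# classification

def test_classification_threshold_convention():
    assert classify_structured(-20.0) == "structured"
    assert classify_structured(5.0) == "disordered"
    assert classify_structured(5.0, threshold=10.0) == "structured"


def test_structured_disordered_separation_beats_chance():
    from scipy.stats import binomtest

    config = GeneratorConfig(seed=15)
    train, _ = gen_stability_records(35, noise_sd=2.0, config=config)
    test, _ = gen_stability_records(
        25, noise_sd=2.0, length_matched_pairs=True, config=config,
        rng=np.random.default_rng(16),
    )
    result = loo_bootstrap(train)
    correct = sum(
        classify_structured(predict_dG(r, result.averaged)) == r.class_label
        for r in test
    )
    assert binomtest(correct, len(test), 0.5, alternative="greater").pvalue < 0.01
    # pairs are length-matched by construction
    lengths = [r.length for r in test]
    assert lengths[0::2] == lengths[1::2]
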