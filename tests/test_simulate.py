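import io

import numpy as np
import pandas as pd
import pytest

from exclusim import ScenarioConfig, apply_nonadherence, sample_cohort
from exclusim.simulate import read_cohort, write_cohort
from exclusim.ue import add_ue_columns


def test_same_seed_gives_byte_identical_tables(config):
    a, b = io.StringIO(), io.StringIO()
    write_cohort(sample_cohort(config, seed=3), a)
    write_cohort(sample_cohort(config, seed=3), b)
    assert a.getvalue() == b.getvalue()
    c = io.StringIO()
    write_cohort(sample_cohort(config, seed=4), c)
    assert a.getvalue() != c.getvalue()


def test_csv_round_trip_lossless(config, tmp_path):
    df = sample_cohort(config, seed=9)
    p = tmp_path / "cohort.csv"
    write_cohort(df, p)
    back = read_cohort(p)
    for col in df.columns:
        if df[col].dtype.kind == "f":
            assert np.allclose(back[col], df[col], atol=1e-9, rtol=1e-9)
        else:
            assert (back[col] == df[col]).all()


def test_stratified_allocation_counts(config):
    df = sample_cohort(config, seed=1)
    counts = df["arm"].value_counts()
    assert sorted(counts) == [48, 48, 49]


def test_measured_tee_self_consistent(config):
    df = sample_cohort(config.model_copy(update=dict(nonadherence_fraction=0.3)))
    recon = df["tee_true_end"] * df["rq_bias"] + df["tee_err_end"]
    assert np.allclose(df["tee_measured_end"], recon, atol=1e-9)
    assert (df["weight"] > 0).all() and (df["tee_baseline_true"] > 0).all()
    assert np.allclose(df["bmi"], df["weight"] / (df["height"] / 100) ** 2)


def test_noise_free_cohort_has_zero_unaccounted_energy(config):
    nf = config.noise_free()
    df = add_ue_columns(sample_cohort(nf, seed=2), nf)
    # measured equals true everywhere, so the energy budget closes exactly
    assert np.allclose(df["tee_measured_end"], df["tee_true_end"])
    assert np.allclose(df["ei_measured_end"], df["ei_true_end"])
    assert np.allclose(df["ue"], 0.0, atol=1e-9)


def test_noise_free_dose_response_is_slope_times_four(config):
    nf = config.noise_free()
    df = sample_cohort(nf, seed=2)
    norm = df["effect_prescribed"] * nf.reference_weight_kg / df["weight_postloss"]
    low = norm[df["arm"] == "low"].mean()
    high = norm[df["arm"] == "high"].mean()
    assert low - high == pytest.approx(nf.cim_slope * 4, abs=1e-9)


def test_baseline_tee_marginal_calibrated(config):
    means = [
        sample_cohort(config, seed=10_000 + r)["tee_baseline_measured"].mean()
        for r in range(150)
    ]
    mcse = np.std(means) / np.sqrt(len(means))
    assert abs(np.mean(means) - 3008.0) < 3 * mcse + 5.0


def test_randomization_balance(config):
    """Across replicates, arm-wise standardized differences of baseline
    covariates are centered on zero and small on average."""
    cols = ["weight", "female", "tee_baseline_measured", "runin_loss", "age"]
    diffs = {c: [] for c in cols}
    for r in range(300):
        df = sample_cohort(config, seed=20_000 + r)
        lo = df[df["arm"] == "low"]
        hi = df[df["arm"] == "high"]
        for c in cols:
            sd = df[c].std()
            diffs[c].append((lo[c].mean() - hi[c].mean()) / sd)
    for c in cols:
        assert abs(np.mean(diffs[c])) < 0.05, c


def test_nonadherence_zero_leaves_cohort_unchanged(config):
    df = sample_cohort(config, seed=5)
    out = apply_nonadherence(df, config)
    pd.testing.assert_frame_equal(out, df)
    assert (out["adherent"] == 1).all()


def test_full_drift_moves_everyone_to_40pct_carb(config):
    cfg = config.model_copy(
        update=dict(nonadherence_fraction=1.0, nonadherence_drift=1.0)
    )
    df = sample_cohort(cfg)
    assert (df["adherent"] == 0).all()
    assert np.allclose(df["carb_consumed"], 0.40)
    # consumed-diet effect collapses to the moderate arm's (zero)
    assert np.allclose(df["effect_consumed"], 0.0, atol=1e-9)


def test_nonadherence_count_is_deterministic_rounding(config):
    cfg = config.model_copy(update=dict(nonadherence_fraction=0.5))
    df = sample_cohort(cfg)
    for arm, n_arm in df["arm"].value_counts().items():
        flagged = ((df["arm"] == arm) & (df["adherent"] == 0)).sum()
        assert flagged == round(0.5 * n_arm)


def test_nonadherent_rq_diverges_in_the_expected_direction(config):
    cfg = config.model_copy(update=dict(nonadherence_fraction=0.4))
    df = sample_cohort(cfg)
    non = df[df["adherent"] == 0]
    low = non[non["arm"] == "low"]
    high = non[non["arm"] == "high"]
    # low-carb drifters eat more carbohydrate: true RQ above assumed,
    # apparent TEE inflated; high-carb drifters the reverse
    assert (low["rq_true"] > low["rq_assumed"]).all()
    assert (low["rq_bias"] > 1).all()
    assert (high["rq_true"] < high["rq_assumed"]).all()
    assert (high["rq_bias"] < 1).all()
    assert (df.loc[df["adherent"] == 1, "rq_bias"] == 1.0).all()


def test_missingness_rate(config):
    cfg = config.model_copy(update=dict(missing_rate=0.2, n_participants=500))
    df = sample_cohort(cfg, seed=8)
    frac = df["tee_measured_end"].isna().mean()
    assert 0.1 < frac < 0.3
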