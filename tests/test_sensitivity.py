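import numpy as np
import pytest

from exclusim import (
    add_ue_columns,
    fit_diet_effect,
    nonadherence_sweep,
    sample_cohort,
    symmetric_tail_exclusion,
    tail_depletion_diagnostic,
    tail_exclusion_comparison,
)
from exclusim.effects import fit_group_interaction
from exclusim.simulate import rebuild_measurements


def test_zero_nonadherence_recovers_programmed_effect(config):
    res = nonadherence_sweep(config, fractions=[0.0], replicates=40, seed=1)
    row = res.grid.iloc[0]
    mcse = row["mean_se"] / np.sqrt(40)  # rough scale of the MC error
    assert abs(row["mean_estimate"] - 250.0) < 4 * mcse + 5
    assert row["median_p"] < 0.001


def test_apparent_effect_non_increasing_in_nonadherence(config):
    res = nonadherence_sweep(config, fractions=[0.0, 0.35, 0.7],
                             replicates=40, seed=2)
    est = res.grid["mean_estimate"].to_numpy()
    assert est[0] > est[1] > est[2]
    # with half-drift the fully non-adherent cohort keeps half the effect
    assert est[2] > 100.0


def test_sweep_embeds_provenance_and_validates(config, tmp_path):
    res = nonadherence_sweep(config, fractions=[0.0], replicates=3, seed=3)
    assert res.config_snapshot["n_participants"] == 145
    res.to_json(tmp_path / "s.json")
    res.to_csv(tmp_path / "s.csv")
    with pytest.raises(ValueError):
        nonadherence_sweep(config, fractions=[0.2], replicates=0)
    with pytest.raises(ValueError):
        nonadherence_sweep(config, fractions=[1.5], replicates=2)


def test_symmetric_tail_exclusion_zero_fraction_is_identity(cohort, config):
    att, subset = symmetric_tail_exclusion(cohort, config, 0.0)
    assert att == 0.0 and len(subset) == len(cohort)
    with pytest.raises(ValueError):
        symmetric_tail_exclusion(cohort, config, 0.6)


def test_symmetric_null_one_sided_attenuates(config):
    """Two-tail exclusion of the intake:expenditure ratio leaves the mean
    effect intact; removing the same count from the top of UE attenuates."""
    sym_att, one_att = [], []
    for r in range(80):
        df = add_ue_columns(sample_cohort(config, seed=110_000 + r), config)
        out = tail_exclusion_comparison(df, config, tail_fraction=0.15)
        sym_att.append(out["attenuation_symmetric"])
        one_att.append(out["attenuation_one_sided"])
    sym, one = np.mean(sym_att), np.mean(one_att)
    sym_mcse = np.std(sym_att) / np.sqrt(len(sym_att))
    one_mcse = np.std(one_att) / np.sqrt(len(one_att))
    assert abs(sym) < 3 * sym_mcse  # no attenuation from symmetric tails
    assert one > 3 * one_mcse  # one-sided depletion biases toward null
    assert one - sym > 2 * np.std(np.subtract(one_att, sym_att)) / np.sqrt(80)


def test_depletion_diagnostic_null_under_coin_flip(config):
    rng = np.random.default_rng(5)
    corrs = []
    for r in range(40):
        df = sample_cohort(config, seed=120_000 + r)
        out = tail_depletion_diagnostic(df, rng.random(len(df)) < 0.5)
        corrs.append(out["corr_abs_error"])
    assert abs(np.mean(corrs)) < 3 * np.std(corrs) / np.sqrt(len(corrs))


def test_depletion_diagnostic_positive_under_ue_exclusion(config):
    hits = 0
    for r in range(60):
        df = add_ue_columns(sample_cohort(config, seed=130_000 + r), config)
        out = tail_depletion_diagnostic(df, (df["ue_bin"] <= 18).to_numpy())
        hits += out["corr_abs_error"] > 0
        if r == 0:
            # retained signed error drifts negative as the sweep deepens
            traj = out["retained_error_trajectory"]
            assert len(traj) == 19
    assert hits / 60 >= 0.9


def test_depletion_diagnostic_requires_latent_columns(cohort):
    stripped = cohort.drop(columns=[c for c in cohort.columns if "err" in c])
    with pytest.raises(ValueError, match="latent"):
        tail_depletion_diagnostic(stripped, np.zeros(len(stripped), bool))


def test_interaction_type_one_error_calibrated(config):
    """Same effect in both UE halves: the group-by-diet interaction p is
    null-calibrated (rejection rate ~ alpha)."""
    hits = 0
    n = 150
    for r in range(n):
        df = add_ue_columns(sample_cohort(config, seed=140_000 + r), config)
        _, _, p = fit_group_interaction(df, config)
        hits += p < 0.05
    frac = hits / n
    assert 0.01 <= frac <= 0.11


def test_interaction_power_when_effect_confined_to_low_ue_half(config):
    """Remove the true effect from the high-UE half; the interaction test
    should detect the 250 kcal/d group difference more often than not."""
    hits = 0
    n = 60
    for r in range(n):
        df = add_ue_columns(sample_cohort(config, seed=150_000 + r), config)
        mask = df["ue_group"] == "high"
        for col in ("tee_measured_mid", "tee_measured_end"):
            df.loc[mask, col] -= df.loc[mask, "effect_consumed"] * df.loc[mask, "rq_bias"]
        _, _, p = fit_group_interaction(df, config)
        hits += p < 0.05
    assert hits / n > 0.5
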