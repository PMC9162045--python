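"""Synthetic cohort generator: structure, events, dropout, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cvdtraj.cohort import (
    CLASSES,
    ConfigError,
    GeneratorConfig,
    apply_missingness,
    generate_cohort,
    read_cohort,
    write_cohort,
)

EM_TASKS = [f"em_task{j}" for j in range(1, 6)]


@pytest.fixture(scope="module")
def default_2000():
    cfg = GeneratorConfig(n_subjects=2000, seed=11)
    return cfg, *generate_cohort(cfg)


class TestGenerate:
    def test_mixture_fractions_recovered(self, default_2000):
        _, _, truth = default_2000
        frac = truth["true_class"].value_counts(normalize=True)
        assert frac["accelerated"] == pytest.approx(0.18, abs=0.02)
        assert frac["average"] == pytest.approx(0.60, abs=0.02)
        assert frac["stable"] == pytest.approx(0.22, abs=0.02)

    def test_state_sequences_monotone(self, default_2000):
        _, cohort, _ = default_2000
        order = {"healthy": 0, "AD": 1, "VaD": 1, "dead": 2}
        for _, sub in cohort.groupby("subject_id"):
            codes = sub.sort_values("wave_index")["state"].map(order)
            assert codes.is_monotonic_increasing
            dem = sub.loc[sub["state"].isin(["AD", "VaD"]), "state"]
            assert dem.nunique() <= 1  # no dementia-type switching

    def test_em_composite_is_task_sum_within_range(self, default_2000):
        _, cohort, _ = default_2000
        alive = cohort[cohort["em_composite"].notna()]
        np.testing.assert_allclose(
            alive[EM_TASKS].sum(axis=1), alive["em_composite"], atol=1e-9
        )
        assert (alive["em_composite"] >= 0).all()
        assert (alive["em_composite"] <= 76).all()

    def test_ages_step_by_wave_spacing(self, default_2000):
        _, cohort, _ = default_2000
        diffs = cohort.sort_values(["subject_id", "wave_index"]).groupby(
            "subject_id"
        )["age"].diff().dropna()
        assert (diffs == 5.0).all()

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=150, seed=99)
        a, ta = generate_cohort(cfg)
        b, tb = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(a, pa)
        write_cohort(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_dementia_only_above_age_floor(self, default_2000):
        _, cohort, _ = default_2000
        dem = cohort[cohort["state"].isin(["AD", "VaD"])]
        assert (dem["age"] > 65).all()

    def test_null_generator_events_independent_of_class(self):
        cfg = GeneratorConfig.null(n_subjects=5000, seed=21)
        _, truth = generate_cohort(cfg)
        event = np.where(
            truth["dementia_wave"].notna(), "dementia",
            np.where(truth["death_wave"].notna(), "death", "none"),
        )
        table = pd.crosstab(truth["true_class"], event)
        _, p, *_ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_single_hazard_matches_geometric_incidence(self):
        # one stratum, one cause: cumulative incidence 1-(1-h)^(k-1)
        h = 0.08
        cfg = GeneratorConfig.null(n_subjects=4000, seed=13)
        for name in cfg.hazard_params:
            cfg.hazard_params[name]["base"] = 0.0
        cfg.hazard_params["healthy->AD"]["base"] = h
        _, truth = generate_cohort(cfg)
        for k in (2, 4, 6):
            expect = 1.0 - (1.0 - h) ** (k - 1)
            got = (truth["dementia_wave"] <= k).mean()
            se = np.sqrt(expect * (1 - expect) / len(truth))
            assert got == pytest.approx(expect, abs=4 * se)

    def test_invalid_configs_name_offending_field(self):
        with pytest.raises(ConfigError, match="trajectory_mixture"):
            GeneratorConfig(
                trajectory_mixture={
                    "accelerated": 0.5, "average": 0.6, "stable": 0.2
                }
            ).validate()
        with pytest.raises(ConfigError, match="n_waves"):
            GeneratorConfig(n_waves=1).validate()
        cfg = GeneratorConfig()
        cfg.hazard_params["healthy->AD"]["base"] = 1.5
        with pytest.raises(ConfigError, match="healthy->AD"):
            cfg.validate()


class TestMissingness:
    def test_zero_rates_identity(self):
        cfg = GeneratorConfig(n_subjects=120, seed=3)
        cfg.dropout_hazard = {"per_wave": {}, "outcome_coef": 0.0}
        cfg.missingness_rate = {k: 0.0 for k in cfg.missingness_rate}
        cohort, truth = generate_cohort(cfg)
        obs, _ = apply_missingness(cohort, cfg, truth)
        pd.testing.assert_frame_equal(obs, cohort)

    def test_realized_per_wave_dropout_rates(self, default_2000):
        cfg, cohort, truth = default_2000
        obs, _ = apply_missingness(cohort, cfg, truth)
        wide = obs.pivot(index="subject_id", columns="wave_index", values="state")
        targets = {3: 0.015, 4: 0.06, 5: 0.30, 6: 0.39}
        for w, target in targets.items():
            prev, cur = wide[w - 1], wide[w]
            at_risk = (prev != "dropped") & (cur != "dead")
            new_drop = at_risk & (cur == "dropped")
            rate = new_drop.sum() / at_risk.sum()
            assert rate == pytest.approx(target, abs=0.02)

    def test_dropout_enriched_in_latent_dementia(self):
        cfg = GeneratorConfig(n_subjects=5000, seed=17)
        cohort, truth = generate_cohort(cfg)
        _, truth2 = apply_missingness(cohort, cfg, truth)
        dem = truth2["dementia_wave"].notna()
        never = truth2["dementia_wave"].isna() & truth2["death_wave"].isna()
        p_dem = truth2.loc[dem, "dropout_wave"].notna().mean()
        p_nev = truth2.loc[never, "dropout_wave"].notna().mean()
        count = truth2.loc[dem, "dropout_wave"].notna().sum()
        n = int(dem.sum())
        # one-sided exact test of p_dem <= p_nev
        pval = stats.binomtest(count, n, p_nev, alternative="greater").pvalue
        assert p_dem > p_nev
        assert pval < 0.01

    def test_mar_masking_leaves_truth_untouched(self, default_2000):
        cfg, cohort, truth = default_2000
        before = truth.drop(columns="dropout_wave").copy()
        _, truth2 = apply_missingness(cohort, cfg, truth)
        pd.testing.assert_frame_equal(
            before, truth2.drop(columns="dropout_wave")
        )

    def test_csv_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=80, seed=4)
        cohort, truth = generate_cohort(cfg)
        obs, _ = apply_missingness(cohort, cfg, truth)
        p = tmp_path / "c.csv"
        write_cohort(obs, p)
        back = read_cohort(p)
        assert list(back.columns[: len(obs.columns)]) == list(obs.columns)
        assert back["sbp_mmHg"].isna().sum() == obs["sbp_mmHg"].isna().sum()
        np.testing.assert_allclose(
            back["em_composite"].to_numpy(), obs["em_composite"].to_numpy(),
            atol=1e-9, equal_nan=True,
        )
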