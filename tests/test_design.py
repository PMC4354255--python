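"""Factorial design enumeration, CSV round trips, exclusions and QC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from frmodules import design
from frmodules.design import (
    DayBiasResult,
    SchemaError,
    ValidationError,
    control_survival_qc,
    day_bias_diagnostic,
    enumerate_design,
    filter_replicates,
    read_controls,
    read_records,
    write_controls,
    write_records,
)


class TestEnumerateDesign:
    def test_full_factorial_one_prey(self):
        units = enumerate_design(prey_list=("A_aquaticus",))
        assert len(units) == 224

    def test_full_factorial_three_prey(self):
        assert len(enumerate_design()) == 672

    def test_minimal_design(self):
        units = enumerate_design(
            predator_levels=("G_pulex",),
            parasitism_levels=(False,),
            fish_levels=(False,),
            density_ladder=(5,),
            replicates=1,
            prey_list=("Simulium",),
        )
        assert len(units) == 1

    def test_duplicate_density_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_design(density_ladder=(2, 4, 4))

    def test_binary_factors_balanced(self):
        units = enumerate_design(prey_list=("A_aquaticus",))
        for col in ("parasitised", "fish_present"):
            assert units[col].sum() == len(units) // 2
        assert (units["predator_species"] == "G_pulex").sum() == len(units) // 2

    def test_every_cell_has_replicates(self):
        units = enumerate_design(prey_list=("B_rhodani",), replicates=4)
        cells = units.groupby(
            ["predator_species", "parasitised", "fish_present", "density"]
        ).size()
        assert (cells == 4).all()

    def test_day_schedule_batches(self):
        units = enumerate_design(prey_list=("A_aquaticus",))
        counts = units["day"].value_counts()
        # 224 pots in batches of 22 started every 3 days
        assert sorted(counts.index) == list(range(1, 32, 3))
        assert counts.max() == 22 and counts.sum() == 224

    def test_day_randomisation_only_with_seed(self):
        a = enumerate_design(prey_list=("A_aquaticus",))
        b = enumerate_design(prey_list=("A_aquaticus",))
        assert a.equals(b)
        c = enumerate_design(prey_list=("A_aquaticus",), seed=1)
        d = enumerate_design(prey_list=("A_aquaticus",), seed=1)
        assert c.equals(d)
        assert not a["day"].equals(c["day"])

    def test_unit_key_unique(self):
        units = enumerate_design()
        key_cols = [
            "prey_species", "predator_species", "parasitised", "fish_present",
            "density", "replicate",
        ]
        assert not units.duplicated(subset=key_cols).any()


def _trial_frame(**overrides):
    row = {
        "pot_id": "p1",
        "prey_species": "A_aquaticus",
        "predator_species": "G_pulex",
        "parasitised": False,
        "fish_present": False,
        "density": 4,
        "replicate": 1,
        "day": 1,
        "killed": 2,
        "partially_eaten": 0,
        "moulted": False,
        "infection_stage": "none",
    }
    row.update(overrides)
    return pd.DataFrame([row])


class TestCSVRoundTrip:
    def test_round_trip_identity(self, tmp_path, study_dataset):
        trials, controls = study_dataset
        write_records(trials, tmp_path / "t.csv")
        back = read_records(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(back, trials)
        write_controls(controls, tmp_path / "c.csv")
        pd.testing.assert_frame_equal(read_controls(tmp_path / "c.csv"), controls)

    def test_byte_identical_rewrites(self, tmp_path, study_dataset):
        trials, _ = study_dataset
        write_records(trials, tmp_path / "a.csv")
        write_records(read_records(tmp_path / "a.csv"), tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(design.TRIAL_COLUMNS) + "\n")
        assert len(read_records(path)) == 0

    def test_missing_column_named(self, tmp_path):
        df = _trial_frame().drop(columns=["killed"])
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SchemaError, match="killed"):
            read_records(tmp_path / "bad.csv")

    def test_killed_exceeding_density_rejected_with_row(self, tmp_path):
        df = _trial_frame(killed=5, density=4)
        write_records(df, tmp_path / "bad.csv")
        with pytest.raises(ValidationError, match="row 0"):
            read_records(tmp_path / "bad.csv")

    def test_partial_without_two_kills_rejected(self):
        with pytest.raises(ValidationError, match="partial"):
            design.validate_trials(_trial_frame(killed=1, partially_eaten=1))

    def test_unknown_columns_preserved(self, tmp_path):
        df = _trial_frame()
        df["observer"] = "me"
        write_records(df, tmp_path / "x.csv")
        back = read_records(tmp_path / "x.csv")
        assert list(back["observer"]) == ["me"]


class TestFilterReplicates:
    def test_moulted_excluded(self):
        kept, excluded = filter_replicates(_trial_frame(moulted=True))
        assert len(kept) == 0
        assert list(excluded["exclusion_reason"]) == ["moulted"]

    @pytest.mark.parametrize("stage", ["acanthella", "multiple_cystacanths"])
    def test_early_or_multiple_infection_excluded(self, stage):
        df = _trial_frame(parasitised=True, infection_stage=stage)
        kept, excluded = filter_replicates(df)
        assert len(kept) == 0
        assert list(excluded["exclusion_reason"]) == [stage]

    def test_status_mismatch_configurable(self):
        df = _trial_frame(parasitised=True, infection_stage="none")
        _, excluded = filter_replicates(df)
        assert list(excluded["exclusion_reason"]) == ["parasite_status_mismatch"]
        kept, excluded = filter_replicates(df, exclude_status_mismatch=False)
        assert len(kept) == 1 and len(excluded) == 0

    def test_clean_record_kept_and_partition(self, study_dataset):
        trials, _ = study_dataset
        kept, excluded = filter_replicates(trials)
        assert len(kept) + len(excluded) == len(trials)
        assert set(excluded["exclusion_reason"]) <= set(design.EXCLUSION_REASONS)
        # reasons are reproducible
        kept2, excluded2 = filter_replicates(trials)
        pd.testing.assert_frame_equal(excluded, excluded2)
        clean = _trial_frame(parasitised=True, infection_stage="single_cystacanth")
        kept, excluded = filter_replicates(clean)
        assert len(kept) == 1 and len(excluded) == 0


def _controls(dead_fn):
    rows = []
    for prey in ("A_aquaticus", "Simulium"):
        for fish in (False, True):
            for n0 in (2, 10, 30):
                rows.append(
                    {"prey_species": prey, "density": n0, "fish_present": fish,
                     "dead": dead_fn(n0)}
                )
    return pd.DataFrame(rows)


class TestControlSurvival:
    def test_all_survive(self):
        qc = control_survival_qc(_controls(lambda n0: 0))
        assert qc.overall_survival == 1.0 and qc.passed

    def test_four_percent_mortality_fails_threshold(self):
        # survival 0.96 is below the 0.965 benchmark
        controls = pd.DataFrame(
            [{"prey_species": "A_aquaticus", "density": 100, "fish_present": False,
              "dead": 4}]
        )
        qc = control_survival_qc(controls)
        assert qc.overall_survival == pytest.approx(0.96)
        assert not qc.passed

    def test_total_mortality(self):
        qc = control_survival_qc(_controls(lambda n0: n0))
        assert qc.overall_survival == 0.0 and not qc.passed

    def test_per_stratum_rows(self):
        qc = control_survival_qc(_controls(lambda n0: 0))
        assert len(qc.table) == 4  # 2 prey x 2 fish strata

    def test_empty_controls_error(self):
        with pytest.raises(ValueError, match="empty"):
            control_survival_qc(pd.DataFrame(columns=design.CONTROL_COLUMNS))


def _day_frame(days, kills):
    return pd.DataFrame({"day": days, "killed": kills})


class TestDayBias:
    def test_constant_kills_rho_zero(self):
        res = day_bias_diagnostic(_day_frame([1, 4, 7, 10], [3, 3, 3, 3]))
        assert res.rho == 0.0 and res.p == 1.0

    def test_strict_increase_rho_one(self):
        res = day_bias_diagnostic(_day_frame([1, 4, 7, 10, 13], [1, 2, 3, 4, 5]))
        assert res.rho == pytest.approx(1.0)

    def test_single_day_not_assessable(self):
        res = day_bias_diagnostic(_day_frame([1, 1, 1], [1, 2, 3]))
        assert not res.assessable and res.method == "not_assessable"

    def test_exact_permutation_matches_enumeration(self):
        days = [1, 4, 7, 10, 13]
        kills = [3, 1, 4, 2, 7]
        res = day_bias_diagnostic(_day_frame(days, kills))
        assert res.method == "exact"
        # brute-force oracle over all 5! orderings of the kill vector
        from scipy.stats import rankdata

        xr = rankdata(days)
        yr = rankdata(kills)

        def rho_of(perm):
            y = yr[list(perm)]
            return np.corrcoef(xr, y)[0, 1]

        obs = rho_of(range(5))
        count = sum(
            1
            for perm in itertools.permutations(range(5))
            if abs(rho_of(perm)) >= abs(obs) - 1e-12
        )
        assert res.p == pytest.approx(count / 120)
        assert res.rho == pytest.approx(obs)

    def test_large_sample_uses_asymptotic(self):
        rng = np.random.default_rng(0)
        res = day_bias_diagnostic(
            _day_frame(rng.integers(1, 30, 50), rng.integers(0, 10, 50))
        )
        assert res.method == "asymptotic"
        assert 0 <= res.p <= 1
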