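import numpy as np
import pandas as pd
import pytest

from ccekit.accounting import (
    allocate_allowance,
    allocate_cce,
    allocate_income,
    sharing_coefficient,
    total_cce,
)
from ccekit.errors import (
    DegenerateInstitutionError,
    LedgerError,
    LookupError_,
    UnknownDimensionError,
)
from ccekit.synthetic_data import SimulationConfig, simulate_dataset

from conftest import records_frame


def ledger(institution_id="H0000", ST_INC=0.0, ST_ALL=0.0, S_P_ALL=0.0):
    return pd.DataFrame(
        [dict(institution_id=institution_id, institution_type="general_hospital",
              ST_INC=ST_INC, ST_ALL=ST_ALL, S_P_ALL=S_P_ALL)]
    )


class TestSharingCoefficient:
    @pytest.mark.parametrize(
        "a_i,a,a_p,expected",
        [(100, 1000, 0, 0.10), (0, 1000, 0, 0.0), (50, 1050, 50, 0.05)],
    )
    def test_examples(self, a_i, a, a_p, expected):
        assert sharing_coefficient(a_i, a, a_p) == pytest.approx(expected)

    def test_all_preventive_is_degenerate(self):
        with pytest.raises(DegenerateInstitutionError):
            sharing_coefficient(10, 100, 100)

    def test_coefficients_sum_to_one(self):
        a_i = np.array([3.0, 7.0, 12.5, 0.5])
        assert sum(sharing_coefficient(x, a_i.sum(), 0) for x in a_i) == pytest.approx(1.0)


class TestAllocateIncome:
    def test_proportional_split(self):
        records = records_frame([{"curative_income": 30.0}, {"curative_income": 70.0}])
        out = allocate_income(records, ledger(ST_INC=200.0))
        assert list(out) == pytest.approx([60.0, 140.0])

    def test_single_record_identity(self):
        records = records_frame([{"curative_income": 55.0}])
        out = allocate_income(records, ledger(ST_INC=123.0))
        assert out.iloc[0] == pytest.approx(123.0)

    def test_preventive_share_removed(self):
        # a=100, a_p=20: curative part of ST_INC is 300*(1-0.2)=240
        records = records_frame(
            [
                {"curative_income": 40.0},
                {"curative_income": 40.0},
                {"curative_income": 20.0, "is_preventive": 1},
            ]
        )
        out = allocate_income(records, ledger(ST_INC=300.0))
        assert list(out) == pytest.approx([120.0, 120.0, 0.0])
        assert out.sum() == pytest.approx(300.0 * (1 - 20 / 100))


class TestAllocateAllowance:
    def test_proportional(self):
        records = records_frame([{"curative_income": 25.0}, {"curative_income": 75.0}])
        out = allocate_allowance(records, ledger(ST_ALL=110.0, S_P_ALL=10.0))
        assert list(out) == pytest.approx([25.0, 75.0])

    def test_all_preventive_allowance_leaves_nothing(self):
        records = records_frame([{"curative_income": 10.0}])
        out = allocate_allowance(records, ledger(ST_ALL=50.0, S_P_ALL=50.0))
        assert out.iloc[0] == 0.0

    def test_three_way_split(self):
        records = records_frame(
            [{"curative_income": v} for v in (10.0, 30.0, 60.0)]
        )
        out = allocate_allowance(records, ledger(ST_ALL=500.0, S_P_ALL=100.0))
        assert list(out) == pytest.approx([40.0, 120.0, 240.0])

    def test_preventive_allowance_exceeding_total_is_ledger_error(self):
        records = records_frame([{"curative_income": 10.0}])
        with pytest.raises(LedgerError):
            allocate_allowance(records, ledger(ST_ALL=10.0, S_P_ALL=20.0))


class TestFullAllocation:
    def test_unknown_institution_is_lookup_error(self):
        records = records_frame([{"institution_id": "H9999"}])
        with pytest.raises(LookupError_):
            allocate_cce(records, ledger(ST_INC=10.0))

    def test_cce_is_exact_sum_of_components(self):
        records, ledgers, _ = simulate_dataset(
            SimulationConfig(n_records=300, n_institutions=5, seed=8)
        )
        allocations, _ = allocate_cce(records, ledgers)
        assert (
            allocations["cce"]
            == allocations["allocated_income"] + allocations["allocated_allowance"]
        ).all()

    def test_conservation_per_institution(self):
        records, ledgers, _ = simulate_dataset(
            SimulationConfig(n_records=2000, n_institutions=12, seed=8, preventive_fraction=0.05)
        )
        allocations, unallocated = allocate_cce(records, ledgers)
        assert unallocated.empty
        merged = allocations.merge(records[["record_id", "institution_id", "curative_income",
                                            "is_preventive"]], on="record_id")
        for inst, group in merged.groupby("institution_id"):
            row = ledgers.set_index("institution_id").loc[inst]
            a = group["curative_income"].sum()
            a_p = group.loc[group["is_preventive"] == 1, "curative_income"].sum()
            assert group["allocated_income"].sum() == pytest.approx(
                row["ST_INC"] * (1 - a_p / a), abs=1e-6
            )
            assert group["allocated_allowance"].sum() == pytest.approx(
                row["ST_ALL"] - row["S_P_ALL"], abs=1e-6
            )

    def test_scale_equivariance(self):
        records, ledgers, _ = simulate_dataset(
            SimulationConfig(n_records=200, n_institutions=4, seed=3)
        )
        base, _ = allocate_cce(records, ledgers)
        c = 3.7
        scaled_records = records.assign(curative_income=records["curative_income"] * c)
        scaled_ledgers = ledgers.assign(
            ST_INC=ledgers["ST_INC"] * c, ST_ALL=ledgers["ST_ALL"] * c,
            S_P_ALL=ledgers["S_P_ALL"] * c,
        )
        scaled, _ = allocate_cce(scaled_records, scaled_ledgers)
        np.testing.assert_allclose(scaled["cce"], base["cce"] * c, rtol=1e-12)

    def test_permutation_invariance(self):
        records, ledgers, _ = simulate_dataset(
            SimulationConfig(n_records=200, n_institutions=4, seed=3)
        )
        base, _ = allocate_cce(records, ledgers)
        shuffled = records.sample(frac=1.0, random_state=1).reset_index(drop=True)
        perm, _ = allocate_cce(shuffled, ledgers)
        merged = base.merge(perm, on="record_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["cce_a"], merged["cce_b"], rtol=1e-12)

    def test_degenerate_institution_goes_to_unallocated_bucket(self):
        records = records_frame([{"curative_income": 10.0, "is_preventive": 1}])
        ledgers = ledger(ST_INC=100.0, ST_ALL=50.0, S_P_ALL=10.0)
        allocations, unallocated = allocate_cce(records, ledgers)
        assert allocations.empty
        assert unallocated["unallocated_allowance"].iloc[0] == pytest.approx(40.0)


class TestTotalCce:
    def make(self):
        records = records_frame(
            [
                {"curative_income": 30.0, "setting": "inpatient"},
                {"curative_income": 70.0, "setting": "outpatient", "length_of_stay": 0},
            ]
        )
        ledgers = ledger(ST_INC=200.0, ST_ALL=100.0, S_P_ALL=0.0)
        allocations, _ = allocate_cce(records, ledgers)
        return records, allocations

    def test_constant_grouping_is_grand_total(self):
        records, allocations = self.make()
        records["all"] = "total"
        table = total_cce(allocations, records, by="all")
        assert table["cce"].iloc[0] == pytest.approx(300.0)

    def test_additivity_by_setting(self):
        records, allocations = self.make()
        table = total_cce(allocations, records, by="setting").set_index("setting")
        # income 60/140 plus allowance 30/70, proportional to a_i
        assert table.loc["inpatient", "cce"] == pytest.approx(90.0)
        assert table.loc["outpatient", "cce"] == pytest.approx(210.0)

    def test_matches_brute_force_oracle(self):
        records, ledgers, _ = simulate_dataset(
            SimulationConfig(n_records=600, n_institutions=3, seed=6)
        )
        allocations, _ = allocate_cce(records, ledgers)
        table = total_cce(allocations, records, by="institution_type").set_index("institution_type")
        oracle = (
            allocations.merge(records, on="record_id")
            .groupby("institution_type")["cce"].sum()
        )
        for group, value in oracle.items():
            assert table.loc[group, "cce"] == pytest.approx(value, rel=1e-12)

    def test_unknown_dimension_lists_valid(self):
        records, allocations = self.make()
        with pytest.raises(UnknownDimensionError, match="institution_type"):
            total_cce(allocations, records, by="not_a_dimension")
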