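"""Diagnostic algorithms, severity scores, omega, pooled prevalence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from griefnet._rng import substream
from griefnet.data import CAPS_ITEMS, COPISAC_ITEMS, TGI_ITEMS, ItemResponseMatrix
from griefnet.imputation import ImputationConfig, ImputationStack
from griefnet.scoring import (
    PGD_B_ITEMS,
    PGD_C_ITEMS,
    PGD_E_ITEM,
    diagnose_cptsd,
    diagnose_pgd,
    diagnose_ptsd_icd11,
    mcdonald_omega,
    prevalence_and_comorbidity,
    score_severity,
)


def full_row(tgi=1, caps=0, copisac=0, caps22=1):
    row = {c: float(tgi) for c in TGI_ITEMS}
    row.update({c: float(caps) for c in CAPS_ITEMS})
    row["CAPS_22"] = float(caps22)
    row.update({c: float(copisac) for c in COPISAC_ITEMS})
    return row


# independently coded truth tables (deliberately written as flat boolean
# expressions, not by calling the implementation's helpers)

def oracle_pgd(row, months, bereaved):
    b = row["TGI_03"] >= 4 or row["TGI_01"] >= 4
    c = any(row[f"TGI_{i:02d}"] >= 4 for i in (2, 5, 8, 9, 10, 16, 19, 20, 21, 22))
    return bereaved and b and c and row["TGI_13"] >= 4 and months > 6


def oracle_ptsd(row, trauma):
    return (trauma
            and (row["CAPS_01"] >= 2 or row["CAPS_02"] >= 2)
            and (row["CAPS_06"] >= 2 or row["CAPS_07"] >= 2)
            and (row["CAPS_17"] >= 2 or row["CAPS_18"] >= 2)
            and (row["CAPS_24"] >= 2 or row["CAPS_25"] >= 2)
            and row["CAPS_22"] >= 1)


def oracle_cptsd(row, trauma):
    ptsd = oracle_ptsd(row, trauma)
    c = (ptsd and row["COPISAC_CO1"] >= 2 and row["COPISAC_CO2"] >= 2
         and (row["COPISAC_CO3"] >= 2 or row["CAPS_13"] >= 2)
         and (row["COPISAC_CO4"] >= 2 or row["COPISAC_CO5"] >= 2))
    return c, (ptsd and not c)


class TestSeverity:
    def test_pgd_scale_minimum(self):
        assert score_severity(full_row(tgi=1))["severity_pgd"] == 22

    def test_pgd_scale_maximum(self):
        assert score_severity(full_row(tgi=5))["severity_pgd"] == 110

    def test_ptsd_severity_six_items(self):
        assert score_severity(full_row(caps=4))["severity_ptsd"] == 24

    def test_cptsd_severity_is_ptsd_plus_dso(self):
        sev = score_severity(full_row(caps=3, copisac=2))
        assert sev["severity_cptsd"] == sev["severity_ptsd"] + sev["severity_dso"]

    def test_missing_item_raises_with_name(self):
        row = full_row()
        del row["TGI_07"]
        with pytest.raises(ValueError, match="TGI_07"):
            score_severity(row)


class TestDiagnosisExamples:
    def test_all_maximum_meets_pgd(self):
        assert diagnose_pgd(full_row(tgi=5), months_since_loss=24, bereaved=True)

    def test_accompanying_symptom_gate(self):
        row = full_row(tgi=1)
        row["TGI_01"] = row["TGI_03"] = 5.0
        row["TGI_13"] = 5.0
        for c in PGD_C_ITEMS:
            row[c] = 3.0
        assert not diagnose_pgd(row, 24, True)

    def test_recent_loss_blocks_pgd(self):
        assert not diagnose_pgd(full_row(tgi=5), months_since_loss=5, bereaved=True)

    def test_unknown_months_raises(self):
        with pytest.raises(ValueError, match="months"):
            diagnose_pgd(full_row(tgi=5), months_since_loss=float("nan"), bereaved=True)

    def test_ptsd_all_high(self):
        assert diagnose_ptsd_icd11(full_row(caps=4), trauma_flag=True)

    def test_ptsd_reexperiencing_gate(self):
        row = full_row(caps=4)
        row["CAPS_01"] = row["CAPS_02"] = 1.0
        assert not diagnose_ptsd_icd11(row, trauma_flag=True)

    def test_cptsd_supersedes_ptsd(self):
        assert diagnose_cptsd(full_row(caps=4, copisac=4), True) == (True, False)

    def test_dso_affect_gate_leaves_plain_ptsd(self):
        row = full_row(caps=4, copisac=4)
        row["COPISAC_CO1"] = 1.0
        assert diagnose_cptsd(row, True) == (False, True)


class TestTruthTables:
    def test_pgd_exhaustive_around_threshold(self):
        """All 2^4 x months x bereaved combinations of the four PGD gates
        at ratings {3, 4} match the independent truth table."""
        for b1, c1, e, months, ber in itertools.product((3.0, 4.0), (3.0, 4.0), (3.0, 4.0),
                                                        (5.0, 24.0), (True, False)):
            row = full_row(tgi=1)
            row["TGI_01"] = b1
            row["TGI_08"] = c1
            row["TGI_13"] = e
            assert diagnose_pgd(row, months, ber) == oracle_pgd(row, months, ber)

    def test_ptsd_exhaustive_grid(self):
        """One item per cluster swept over {1, 2} plus the duration gate."""
        for vals in itertools.product((1.0, 2.0), repeat=4):
            for dur in (0.0, 1.0):
                row = full_row(caps=0)
                row["CAPS_01"], row["CAPS_06"], row["CAPS_17"], row["CAPS_24"] = vals
                row["CAPS_22"] = dur
                assert diagnose_ptsd_icd11(row, True) == oracle_ptsd(row, True)

    def test_cptsd_exhaustive_grid(self):
        for vals in itertools.product((1.0, 2.0), repeat=5):
            row = full_row(caps=4)
            (row["COPISAC_CO1"], row["COPISAC_CO2"], row["COPISAC_CO3"],
             row["COPISAC_CO4"], row["CAPS_13"]) = vals
            row["COPISAC_CO5"] = 1.0
            assert diagnose_cptsd(row, True) == oracle_cptsd(row, True)

    def test_random_profiles_match_oracles_and_invariants(self):
        """10^4 random profiles: oracle equality, mutual exclusivity, and
        monotonicity (raising ratings never removes a diagnosis)."""
        rng = substream(77, "truth-table")
        for _ in range(10_000):
            row = {c: float(rng.integers(1, 6)) for c in TGI_ITEMS}
            row.update({c: float(rng.integers(0, 5)) for c in CAPS_ITEMS})
            row["CAPS_22"] = float(rng.integers(0, 2))
            row.update({c: float(rng.integers(0, 5)) for c in COPISAC_ITEMS})
            months = float(rng.choice([3.0, 12.0, 60.0]))
            ber = bool(rng.integers(2))
            trauma = bool(rng.integers(2))

            pgd = diagnose_pgd(row, months, ber)
            cptsd, ptsd_add = diagnose_cptsd(row, trauma)
            assert pgd == oracle_pgd(row, months, ber)
            assert (cptsd, ptsd_add) == oracle_cptsd(row, trauma)
            assert not (cptsd and ptsd_add)  # mutual exclusivity

            # monotonicity: bump one random item to its maximum
            bumped = dict(row)
            col = list(bumped)[rng.integers(len(bumped))]
            bumped[col] = 5.0 if col.startswith("TGI") else (1.0 if col == "CAPS_22" else 4.0)
            if pgd:
                assert diagnose_pgd(bumped, months, ber)
            if cptsd:
                assert diagnose_cptsd(bumped, trauma)[0]


class TestPooledPrevalence:
    @staticmethod
    def _stack_from(frames):
        return ImputationStack([ItemResponseMatrix(f) for f in frames],
                               ImputationConfig(m=len(frames)))

    def test_identical_datasets_equal_single_dataset_counts(self):
        base = pd.DataFrame([full_row(tgi=5, caps=4, copisac=4)] * 4)
        meta = pd.DataFrame({"MONTHS_SINCE_LOSS": [24.0] * 4, "BEREAVED": [1.0] * 4,
                             "TRAUMA_A": [1.0] * 4})
        out = prevalence_and_comorbidity(self._stack_from([base, base]), meta)
        assert out["pooled_counts"]["pgd"] == 4
        assert out["proportions_pct"]["pgd"] == 100.0

    def test_fractional_count_arithmetic(self):
        """Counts (25, 26) over m=2 at N=92 pool to 25.5 -> 27.72%."""
        rows_a = [full_row(tgi=5)] * 25 + [full_row(tgi=1)] * 67
        rows_b = [full_row(tgi=5)] * 26 + [full_row(tgi=1)] * 66
        meta = pd.DataFrame({"MONTHS_SINCE_LOSS": [24.0] * 92, "BEREAVED": [1.0] * 92,
                             "TRAUMA_A": [1.0] * 92})
        out = prevalence_and_comorbidity(
            self._stack_from([pd.DataFrame(rows_a), pd.DataFrame(rows_b)]), meta)
        assert out["pooled_counts"]["pgd"] == pytest.approx(25.5)
        assert out["pooled_n"]["pgd"] == 26  # rounded half-up
        assert out["proportions_pct"]["pgd"] == pytest.approx(100 * 25.5 / 92, abs=0.01)

    def test_zero_cases_give_zero_proportions(self):
        base = pd.DataFrame([full_row(tgi=1, caps=0)] * 5)
        meta = pd.DataFrame({"MONTHS_SINCE_LOSS": [24.0] * 5, "BEREAVED": [1.0] * 5,
                             "TRAUMA_A": [1.0] * 5})
        out = prevalence_and_comorbidity(self._stack_from([base]), meta)
        assert all(v == 0 for v in out["proportions_pct"].values())
        assert all(v == 0 for v in out["conditional_on_pgd_pct"].values())


class TestMcDonaldOmega:
    def test_one_factor_population_closed_form(self):
        """k=10 items with loading 0.8, psi=0.36: omega should approach
        (8)^2 / (8^2 + 3.6)."""
        rng = substream(31, "omega")
        n, k, lam = 5000, 10, 0.8
        f = rng.standard_normal(n)
        X = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, k))
        expected = (k * lam) ** 2 / ((k * lam) ** 2 + k * (1 - lam**2))
        res = mcdonald_omega(pd.DataFrame(X))
        assert abs(res.omega_total - expected) < 0.02

    def test_uncorrelated_items_give_low_omega(self):
        rng = substream(32, "omega")
        X = rng.standard_normal((4000, 8))
        assert mcdonald_omega(pd.DataFrame(X)).omega_total <= 0.1

    def test_two_items_underidentified(self):
        with pytest.raises(ValueError):
            mcdonald_omega(np.random.default_rng(0).normal(size=(100, 2)))
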