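import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pvscreen import datasets
from pvscreen.cohort import (
    CohortPatient,
    classify_recist,
    compare_categorical,
    flag_hypertension_event,
    mann_whitney_u,
    read_patient_table,
    response_rates,
    sbp_change_summary,
    write_patient_table,
)
from pvscreen.errors import DataError
from pvscreen.signal_stats import round_half_up


def make_patient(pid="P1", response="PR", ppi=False, sbp=((0, 130.0), (1, 140.0)), **kw):
    defaults = dict(
        age_years=60.0, sex="M", stage="IV", ps=0, regimen="XELOX",
        antihypertensive_baseline=False,
    )
    defaults.update(kw)
    return CohortPatient(
        patient_id=pid, response=response, ppi_user=ppi, sbp_series=tuple(sbp), **defaults
    )


class TestClassifyRecist:
    @pytest.mark.parametrize(
        "baseline,nadir,current,expected",
        [
            (100, 100, 70, "PR"),  # 30% decrease, inclusive boundary
            (100, 50, 60, "PD"),  # 20% over nadir, inclusive
            (100, 90, 85, "SD"),
            (100, 100, 0, "CR"),
            (100, 100, 120, "PD"),
            (100, 100, 71, "SD"),
            (50, 10, 12, "PD"),  # PD precedence over PR (12 <= 35, 12 >= 12)
        ],
    )
    def test_thresholds(self, baseline, nadir, current, expected):
        assert classify_recist(baseline, nadir, current) == expected

    def test_negative_input_errors(self):
        with pytest.raises(DataError):
            classify_recist(100, -1, 50)

    def test_zero_baseline_errors(self):
        with pytest.raises(DataError):
            classify_recist(0, 10, 10)

    def test_growth_from_zero_nadir_is_pd(self):
        assert classify_recist(100, 0, 5) == "PD"


def reference_patients():
    return datasets.reference_cohort()


class TestResponseRates:
    def test_reference_orr(self):
        cmp = response_rates(reference_patients(), "ppi_user")
        non_ppi, ppi = cmp.arms
        assert round_half_up(100 * non_ppi.orr, 0) == 50
        assert round_half_up(100 * ppi.orr, 0) == 25

    def test_reference_dcr(self):
        cmp = response_rates(reference_patients(), "ppi_user")
        non_ppi, ppi = cmp.arms
        assert round_half_up(100 * non_ppi.dcr, 0) == 90
        assert round_half_up(100 * ppi.dcr, 0) == 69

    def test_reference_pvalues(self):
        # frozen from Fisher's exact on [[21,21],[4,12]] and [[38,4],[11,5]]
        cmp = response_rates(reference_patients(), "ppi_user")
        assert cmp.orr_test == "fisher"
        assert cmp.orr_p == pytest.approx(0.13758558, abs=1e-6)
        assert cmp.dcr_test == "fisher"
        assert cmp.dcr_p == pytest.approx(0.09739393, abs=1e-6)

    def test_counts_sum_to_arm_size(self):
        cmp = response_rates(reference_patients(), "ppi_user")
        for s in cmp.arms:
            assert sum(s.counts.values()) == s.n

    def test_all_cr_arm(self):
        patients = [make_patient(f"A{i}", "CR", ppi=False) for i in range(5)]
        patients += [make_patient(f"B{i}", "PD", ppi=True) for i in range(3)]
        cmp = response_rates(patients, "ppi_user")
        assert cmp.arms[0].orr == 1.0
        assert cmp.arms[0].dcr == 1.0

    def test_orr_le_dcr_always(self):
        cmp = response_rates(reference_patients(), "ppi_user")
        for s in (*cmp.arms, cmp.overall):
            assert 0.0 <= s.orr <= s.dcr <= 1.0

    def test_single_arm_rejected(self):
        patients = [make_patient(f"A{i}") for i in range(5)]
        with pytest.raises(DataError):
            response_rates(patients, "ppi_user")


class TestCompareCategorical:
    def test_fisher_chosen_for_small_cell(self):
        name, _ = compare_categorical([[21, 4], [21, 12]])
        assert name == "fisher"

    def test_chi2_identical_proportions(self):
        name, p = compare_categorical([[20, 20], [20, 20]])
        assert name == "chi2"
        assert p == pytest.approx(1.0)

    def test_fisher_diagonal(self):
        name, p = compare_categorical([[10, 0], [0, 10]])
        assert name == "fisher"
        assert p == pytest.approx(2 / 184756, abs=1e-15)

    def test_degenerate_rejected(self):
        with pytest.raises(DataError):
            compare_categorical([[0, 0], [1, 2]])

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=100, deadline=None)
    def test_2x2_fisher_matches_scipy(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        _, p = compare_categorical([[a, b], [c, d]], rule="fisher")
        assert p == pytest.approx(stats.fisher_exact([[a, b], [c, d]])[1], abs=1e-10)

    def test_rx2_fisher_matches_enumeration(self):
        # independent oracle: direct enumeration of all 3x2 tables with the
        # observed margins via multivariate hypergeometric probabilities
        table = [[2, 4], [5, 1], [3, 3]]
        rows = [6, 6, 6]
        c1 = 10
        p_obs = math.comb(6, 2) * math.comb(6, 5) * math.comb(6, 3)
        kept = total = 0
        for k1, k2 in itertools.product(range(7), range(7)):
            k3 = c1 - k1 - k2
            if not 0 <= k3 <= 6:
                continue
            w = math.comb(6, k1) * math.comb(6, k2) * math.comb(6, k3)
            total += w
            if w <= p_obs:
                kept += w
        _, p = compare_categorical(table, rule="fisher")
        assert p == pytest.approx(kept / total, abs=1e-12)

    def test_auto_uses_fisher_iff_small_cell(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 30, size=(2, 2))
            if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
                continue
            name, _ = compare_categorical(counts.tolist())
            assert name == ("fisher" if counts.min() < 5 else "chi2")


class TestMannWhitney:
    def test_small_exact(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(x, list(x))
        assert u == len(x) ** 2 / 2
        assert p > 0.99

    def test_large_shift_significant(self):
        x = list(range(100, 110))
        y = list(range(10))
        _, p = mann_whitney_u(x, y)
        assert p < 0.001

    def test_empty_sample_errors(self):
        with pytest.raises(DataError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_enumeration(self):
        # oracle: enumerate all rank assignments for small untied samples
        rng = np.random.default_rng(5)
        for _ in range(5):
            pooled = rng.permutation(12).astype(float)
            x, y = pooled[:5], pooled[5:]
            u_obs, p = mann_whitney_u(x, y)
            n1 = len(x)
            ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
            u_stat = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
            n = len(pooled)
            us = []
            for positions in itertools.combinations(range(1, n + 1), n1):
                us.append(sum(positions) - n1 * (n1 + 1) / 2)
            us = np.asarray(us)
            mean_u = n1 * (n - n1) / 2
            extreme = np.abs(us - mean_u) >= abs(u_stat - mean_u) - 1e-12
            assert u_obs == pytest.approx(u_stat)
            assert p == pytest.approx(extreme.mean(), abs=1e-12)

    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=8, unique=True),
           st.lists(st.integers(51, 100), min_size=2, max_size=8, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, x, y):
        _, p1 = mann_whitney_u([float(v) for v in x], [float(v) for v in y])
        # cubing is strictly monotone and exact on small integers
        transform = lambda v: [float(e) ** 3 for e in v]
        _, p2 = mann_whitney_u(transform(x), transform(y))
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestHypertensionFlag:
    def test_delta_rule(self):
        p = make_patient(sbp=((0, 120.0), (1, 145.0)))
        assert flag_hypertension_event(p)

    def test_below_thresholds(self):
        p = make_patient(sbp=((0, 130.0), (1, 139.0)))
        assert not flag_hypertension_event(p, med_change=False)

    def test_absolute_rule(self):
        p = make_patient(sbp=((0, 140.0), (1, 152.0)))
        assert flag_hypertension_event(p)

    def test_med_change_rule(self):
        p = make_patient(sbp=((0, 130.0), (1, 131.0)))
        assert flag_hypertension_event(p, med_change=True)

    def test_missing_baseline_errors(self):
        p = make_patient(sbp=((1, 140.0),))
        with pytest.raises(DataError):
            flag_hypertension_event(p)

    def test_monotone_in_sbp(self):
        for peak in np.linspace(120, 200, 30):
            low = flag_hypertension_event(make_patient(sbp=((0, 120.0), (1, float(peak)))))
            higher = flag_hypertension_event(
                make_patient(sbp=((0, 120.0), (1, float(min(peak + 10, 260)))))
            )
            assert higher >= low

    def test_physiologic_range_enforced(self):
        with pytest.raises(DataError):
            make_patient(sbp=((0, 300.0),))


class TestSbpChange:
    def test_mean_delta(self):
        patients = [
            make_patient("A1", ppi=False, sbp=((0, 130.0), (1, 140.0))),
            make_patient("A2", ppi=False, sbp=((0, 130.0), (1, 150.0))),
            make_patient("B1", ppi=True, sbp=((0, 120.0), (1, 130.0))),
            make_patient("B2", ppi=True, sbp=((0, 120.0), (1, 130.0))),
        ]
        summary = sbp_change_summary(patients)
        assert summary.arms["False"]["delta_mean"] == pytest.approx(15.0)

    def test_zero_deltas(self):
        patients = [
            make_patient(f"A{i}", ppi=False, sbp=((0, 130.0), (1, 130.0))) for i in range(4)
        ] + [make_patient(f"B{i}", ppi=True, sbp=((0, 120.0), (1, 120.0))) for i in range(4)]
        summary = sbp_change_summary(patients)
        assert summary.arms["False"]["delta_mean"] == 0.0
        assert summary.p_between > 0.9

    def test_similar_arms_not_significant(self):
        rng = np.random.default_rng(11)
        patients = []
        for i in range(42):
            delta = rng.normal(13.5, 5)
            patients.append(make_patient(f"A{i}", ppi=False, sbp=((0, 130.0), (1, 130.0 + delta))))
        for i in range(16):
            delta = rng.normal(13.9, 5)
            patients.append(make_patient(f"B{i}", ppi=True, sbp=((0, 120.0), (1, 120.0 + delta))))
        summary = sbp_change_summary(patients)
        assert summary.p_between > 0.05

    def test_unpaired_excluded_with_warning(self, caplog):
        patients = [
            make_patient("A1", ppi=False),
            make_patient("A2", ppi=False, sbp=((0, 130.0),)),  # no on-treatment value
            make_patient("B1", ppi=True),
        ]
        with caplog.at_level("WARNING"):
            summary = sbp_change_summary(patients)
        assert summary.n_excluded == 1


class TestPatientTable:
    def test_round_trip(self, tmp_path):
        patients = reference_patients()
        write_patient_table(patients, tmp_path / "cohort.tsv")
        back = read_patient_table(tmp_path / "cohort.tsv")
        assert back == patients
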