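"""Statistics tests: t test, Pearson chi-square, count reconstruction,
and report assembly."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cmtrial.errors import (
    AmbiguityError,
    DataIntegrityError,
    DegenerateInputError,
    InvalidInputError,
)
from cmtrial.stats import (
    DOSING_VARIABLES,
    PROPORTION_VARIABLES,
    QUALITY_VARIABLES,
    build_report,
    chi_square_test,
    reconstruct_counts,
    t_test_independent,
)


def _pooled_t_oracle(a, b):
    """Closed-form pooled-variance t statistic and two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


class TestTTest:
    def test_identical_samples(self):
        res = t_test_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0]
        res = t_test_independent(a, b)
        t, p = _pooled_t_oracle(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_symmetry(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        ab = t_test_independent(a, b)
        ba = t_test_independent(b, a)
        assert ab.statistic == pytest.approx(-ba.statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_constant_samples_equal_means(self):
        res = t_test_independent([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == 1.0

    def test_constant_samples_unequal_means(self):
        with pytest.raises(DegenerateInputError):
            t_test_independent([5.0, 5.0], [6.0, 6.0])

    def test_tiny_samples_rejected(self):
        with pytest.raises(DegenerateInputError):
            t_test_independent([1.0], [1.0, 2.0])

    def test_welch_option_differs_under_variance_heterogeneity(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 6, 40)
        pooled = t_test_independent(a, b)
        welch = t_test_independent(a, b, welch=True)
        assert pooled.p_value != pytest.approx(welch.p_value, rel=1e-6)


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,printed_p",
        [
            ([[106, 6], [93, 15]], 0.031),  # good-excellent, BW vs LBW
            ([[94, 18], [91, 17]], 0.947),  # optimal window, BW vs LBW
            ([[107, 5], [97, 11]], 0.102),  # diagnostic, BW vs LBW
        ],
    )
    def test_reproduces_published_p_values(self, table, printed_p):
        res = chi_square_test(table)
        assert round(res.p_value, 3) == printed_p

    def test_independence_gives_p_one(self):
        res = chi_square_test([[50, 50], [50, 50]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_marginal_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            chi_square_test([[10, 0], [5, 0]])

    def test_matches_scipy_without_correction(self, rng):
        # independent route: scipy's Pearson chi2 with correction disabled
        for _ in range(25):
            table = rng.integers(1, 30, size=(2, 2))
            res = chi_square_test(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_brute_force_oracle_on_small_tables(self):
        """Sigma (O-E)^2/E evaluated cell by cell equals the implementation
        on a sweep of small 2x2 tables."""
        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            obs = [[a, b], [c, d]]
            n = a + b + c + d
            stat = 0.0
            for i, row in enumerate(obs):
                for j, o in enumerate(row):
                    e = sum(obs[i]) * (obs[0][j] + obs[1][j]) / n
                    stat += (o - e) ** 2 / e
            assert chi_square_test(obs).statistic == pytest.approx(stat, rel=1e-12)

    def test_uniform_padding_never_decreases_p(self):
        """Adding the same count to every cell of a balanced 2x2 dilutes the
        association, so the p-value is non-decreasing in the pad."""
        last = chi_square_test([[12, 4], [4, 12]]).p_value
        for pad in (2, 4, 8, 16):
            table = [[12 + pad, 4 + pad], [4 + pad, 12 + pad]]
            p = chi_square_test(table).p_value
            assert p >= last - 1e-12
            last = p

    def test_padding_the_minority_diagonal_restores_independence(self):
        """On a balanced table whose diagonal holds the minority counts,
        growing the diagonal toward the majority raises p monotonically."""
        last = chi_square_test([[4, 12], [12, 4]]).p_value
        for pad in (2, 4, 8):
            p = chi_square_test([[4 + pad, 12], [12, 4 + pad]]).p_value
            assert p >= last - 1e-12
            last = p

    def test_rxc_degrees_of_freedom(self):
        table = [[10, 12, 8], [9, 14, 7], [11, 10, 12]]
        res = chi_square_test(table)
        ref = sps.chi2_contingency(np.array(table), correction=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "percent,n,expected",
        [
            (94.6, 112, 106),
            (86.1, 108, 93),
            (83.9, 112, 94),
            (84.3, 108, 91),
            (95.5, 112, 107),
            (89.8, 108, 97),
            (100.0, 107, 107),
            (0.0, 50, 0),
        ],
    )
    def test_published_percentages(self, percent, n, expected):
        assert reconstruct_counts(percent, n) == expected

    def test_round_trip(self):
        # every reconstructed count re-prints as its own percentage under
        # the half-away-from-zero convention of the printed tables
        from cmtrial.protocol import round_half_away

        for n in (107, 108, 112):
            for k in range(0, n + 1, 7):
                percent = round_half_away(100.0 * k / n, 1)
                assert reconstruct_counts(percent, n) == k

    def test_no_candidate(self):
        with pytest.raises(InvalidInputError):
            reconstruct_counts(34.4, 16)  # 5/16=31.25, 6/16=37.5

    def test_ambiguous_tie(self):
        # 1000/2001 = 49.975% and 1001/2001 = 50.025% both print as 50.0%
        with pytest.raises(AmbiguityError):
            reconstruct_counts(50.0, 2001)


def _toy_tables(n_per_arm=9, deviants=()):
    rows_q, rows_rx, rows_al = [], [], []
    rng = np.random.default_rng(0)
    for ai, arm in enumerate(("BW", "LBW", "CO")):
        for i in range(n_per_arm):
            pid = f"{arm}{i}"
            hu = float(rng.normal(420 - 10 * ai, 40))
            rows_q.append(
                dict(
                    patient_id=pid,
                    overall_hu=hu,
                    noise=39.0 + rng.normal(0, 2),
                    cnr=14.0 + rng.normal(0, 1),
                    snr=11.0 + rng.normal(0, 1),
                    window="optimal" if 325 <= hu <= 500 else "below",
                    in_window=325 <= hu <= 500,
                    diagnostic=hu >= 325,
                    likert=4 if hu >= 325 else 2,
                )
            )
            flow = float(rng.uniform(3, 7))
            rows_rx.append(
                dict(
                    patient_id=pid,
                    arm=arm,
                    flow_rate=flow,
                    test_bolus_volume=2 * flow,
                    main_bolus_volume=8 * flow,
                    test_duration=2.0,
                    main_duration=8.0,
                    idr=0.3 * flow,
                    til=0.3 * 8 * flow,
                    requires_high_flow_needle=flow > 7,
                )
            )
            rows_al.append(
                dict(
                    patient_id=pid,
                    arm=arm,
                    age_band="50to69",
                    weight_band="70to90",
                    block_index=0,
                    position_in_block=i,
                    seed_fingerprint="t",
                )
            )
    flags = {r["patient_id"]: r["patient_id"] in deviants for r in rows_q}
    return (
        pd.DataFrame(rows_q),
        pd.DataFrame(rows_rx),
        pd.DataFrame(rows_al),
        flags,
    )


class TestBuildReport:
    def test_complete_variable_coverage(self):
        q, rx, al, flags = _toy_tables()
        report = build_report(q, rx, al, population="itt")
        for var in DOSING_VARIABLES + QUALITY_VARIABLES:
            assert set(report.continuous[var]) == {"BW", "LBW", "CO"}
        for var in PROPORTION_VARIABLES:
            assert set(report.proportions[var]) == {"BW", "LBW", "CO"}
        per_var = {}
        for p in report.pairwise:
            per_var.setdefault(p.variable, []).append(p)
        # exactly 3 pairwise comparisons (3 choose 2) per variable
        assert all(len(v) == 3 for v in per_var.items().__iter__().__next__()[1:])
        assert all(len(v) == 3 for v in per_var.values())

    def test_itt_equals_pp_without_deviations(self):
        q, rx, al, flags = _toy_tables()
        itt = build_report(q, rx, al, population="itt", deviation_flags=flags)
        pp = build_report(q, rx, al, population="pp", deviation_flags=flags)
        assert itt.n_per_arm == pp.n_per_arm
        assert itt.continuous == pp.continuous

    def test_pp_excludes_deviants(self):
        q, rx, al, flags = _toy_tables(deviants=("BW0", "LBW3"))
        pp = build_report(q, rx, al, population="pp", deviation_flags=flags)
        assert pp.n_per_arm == {"BW": 8, "LBW": 8, "CO": 9}

    def test_orphan_ids_raise(self):
        q, rx, al, _ = _toy_tables()
        with pytest.raises(DataIntegrityError):
            build_report(q.iloc[:-2], rx, al)

    def test_duplicate_ids_raise(self):
        q, rx, al, _ = _toy_tables()
        q2 = pd.concat([q, q.iloc[[0]]], ignore_index=True)
        with pytest.raises(DataIntegrityError):
            build_report(q2, rx, al)
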