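"""Correlation/test statistics against hand-rank oracles; variance shares."""

import numpy as np
import pytest

from ncrsi.analytics import (
    ConstantInputWarning,
    correlation_matrix,
    kruskal_wallis,
    spearman,
    threshold_sensitivity,
    variance_shares,
    weighting_sensitivity,
)
from ncrsi.cohort import PatientRecord
from ncrsi.scoring import ORIGINAL, SYMMETRIC_3


# --- independent oracles -------------------------------------------------

def midranks(values):
    """Average ranks for ties, built by explicit sorting (oracle helper)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        average = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = average
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Rank both vectors by hand, then plain Pearson on the ranks."""
    rx, ry = np.array(midranks(list(x))), np.array(midranks(list(y)))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def kruskal_oracle(groups):
    """Brute-force rank-sum H with the standard tie correction."""
    pooled = [v for g in groups for v in g]
    ranks = midranks(pooled)
    n_total = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += sum(r) ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n_total**3 - n_total)
    return h / correction


# --- spearman ------------------------------------------------------------

class TestSpearman:
    def test_perfect_inversion_and_identity(self):
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)
        assert spearman([1, 2, 3], [1, 2, 3]).rho == pytest.approx(1.0)

    def test_tied_example(self):
        # hand-ranked Pearson with average ranks: 1.5 / sqrt(3)
        assert spearman([1, 1, 2], [1, 2, 3]).rho == pytest.approx(0.8660, abs=1e-3)

    def test_agrees_with_hand_rank_oracle_under_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 51))
            x = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            y = x * rng.choice([-1, 1]) + rng.integers(0, 5, size=n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y).rho == pytest.approx(spearman_oracle(x, y), abs=1e-9)

    def test_pairwise_complete_missing_handling(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        result = spearman(x, y)
        assert result.n == 3
        assert result.rho == pytest.approx(1.0)

    def test_constant_vector_is_flagged_not_zero(self):
        with pytest.warns(ConstantInputWarning):
            result = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(result.rho)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


# --- kruskal-wallis ------------------------------------------------------

class TestKruskalWallis:
    def test_two_group_example(self):
        # 12/42 * 13.5 by direct evaluation
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[2, 2, 2], [2, 2]])
        assert h == 0.0 and p == 1.0

    def test_three_group_example_matches_oracle(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kruskal_oracle(groups), abs=1e-9)

    def test_agrees_with_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            groups = [
                rng.integers(0, 6, size=int(rng.integers(3, 12))).astype(float).tolist()
                for _ in range(int(rng.integers(2, 5)))
            ]
            pooled = [v for g in groups for v in g]
            if np.ptp(pooled) == 0:
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_oracle(groups), abs=1e-9)

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


# --- variance shares -----------------------------------------------------

class TestVarianceShares:
    def test_symmetric_independent_domains(self):
        rng = np.random.default_rng(0)
        n = rng.integers(0, 4, size=4000)
        c = rng.integers(0, 4, size=4000)
        r = rng.integers(0, 4, size=4000)
        shares = variance_shares(n, c, r)
        assert shares == pytest.approx((1 / 3, 1 / 3, 1 / 3), abs=0.05)

    def test_constant_domain_has_zero_share(self):
        shares = variance_shares([1, 1, 1, 1], [0, 1, 0, 1], [2, 0, 1, 3])
        assert shares[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_correlated_components(self):
        # cov(x, 6x)/var(6x) splits exactly by coefficient: (1/6, 1/6, 4/6)
        shares = variance_shares([0, 1], [0, 1], [0, 4])
        assert shares == pytest.approx((1 / 6, 1 / 6, 4 / 6), abs=1e-12)

    def test_shares_always_sum_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            size = int(rng.integers(2, 40))
            n = rng.integers(0, 4, size=size)
            c = rng.integers(0, 4, size=size)
            r = rng.integers(0, 5, size=size)
            if np.var(n + c + r) == 0:
                continue
            assert sum(variance_shares(n, c, r)) == pytest.approx(1.0, abs=1e-9)

    def test_constant_total_is_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            variance_shares([1, 0], [0, 1], [2, 2])


# --- cohort-level analytics ----------------------------------------------

class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal_bounded(self, default_scores):
        matrix = correlation_matrix(default_scores)
        values = matrix.to_numpy()
        assert np.allclose(values, values.T)
        assert np.allclose(np.diag(values), 1.0)
        assert (np.abs(values) <= 1 + 1e-12).all()


def _record(pid, creatinine, tyg_band_glucose=100.0, triglycerides=None, **kw):
    return PatientRecord(
        patient_id=pid, age=60, sex="male", creatinine=creatinine,
        glucose=tyg_band_glucose, triglycerides=triglycerides or 150.0, **kw,
    )


class TestWeightingSensitivity:
    def test_renal_dominant_cohort_has_largest_renal_share(self, dictionaries):
        # constant neuro/cardio inputs, renal spread across all stages
        records = [
            _record(f"R{i}", creatinine, diagnosis_text="Gonartroza")
            for i, creatinine in enumerate([0.7, 0.9, 1.4, 1.9, 2.8, 5.0, 0.8, 1.5])
        ]
        table = weighting_sensitivity(records, dictionaries, schemes=(ORIGINAL,))
        row = table.loc["original"]
        assert row["share_r"] > row["share_n"]
        assert row["share_r"] > row["share_c"]

    def test_zero_neuro_variance_gives_zero_neuro_share(self, dictionaries):
        records = [
            _record(f"Z{i}", creatinine, diagnosis_text="HTA",
                    triglycerides=float(tg))
            for i, (creatinine, tg) in enumerate([(0.8, 90), (1.2, 150), (2.0, 260), (3.0, 420)])
        ]
        table = weighting_sensitivity(records, dictionaries)
        assert (table["share_n"].abs() < 1e-12).all()

    def test_renal_share_drops_under_symmetric_3(self, default_cohort, dictionaries):
        table = weighting_sensitivity(default_cohort, dictionaries,
                                      schemes=(ORIGINAL, SYMMETRIC_3))
        assert table.loc["symmetric_3", "share_r"] < table.loc["original", "share_r"]


class TestThresholdSensitivity:
    def test_zero_shift_is_identity(self, default_cohort, dictionaries):
        report = threshold_sensitivity(default_cohort, dictionaries, deltas=(0.0,))
        from ncrsi.scoring import score_cohort

        baseline = score_cohort(default_cohort, dictionaries)
        assert report.scores[0.0].drop(columns="scheme").equals(
            baseline.drop(columns="scheme")
        )

    def test_shifts_move_cardiometabolic_points_monotonically(
        self, default_cohort, dictionaries
    ):
        report = threshold_sensitivity(default_cohort, dictionaries)
        base = report.scores[0.0].set_index("patient_id")["c_points"]
        up = report.scores[0.2].set_index("patient_id")["c_points"]
        down = report.scores[-0.2].set_index("patient_id")["c_points"]
        assert (up <= base).all()
        assert (down >= base).all()

    def test_excessive_shift_rejected(self):
        with pytest.raises(ValueError):
            ORIGINAL.with_tyg_shift(0.6)
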