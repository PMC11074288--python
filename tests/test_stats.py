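"""Repeated-measures inference against brute-force and Monte-Carlo oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dcpot import (
    classify_evidence,
    logbf_rm_anova,
    power_rm_anova,
    rm_anova_two_way,
    significance_stars,
    tukey_hsd,
)
from dcpot.stats import MissingCellError, _rm_power


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_rm_anova(y: np.ndarray) -> dict[str, tuple[float, int, int]]:
    """Textbook sums-of-squares partitioning for a (subjects, A, B) array.

    Each within effect is tested against its subject-by-effect interaction.
    Returns {effect: (F, df1, df2)}.
    """
    n, a, b = y.shape
    grand = y.mean()
    A = y.mean(axis=(0, 2))
    B = y.mean(axis=(0, 1))
    S = y.mean(axis=(1, 2))
    AB = y.mean(axis=0)
    AS = y.mean(axis=2)  # (n, a)
    BS = y.mean(axis=1)  # (n, b)
    ss_a = n * b * ((A - grand) ** 2).sum()
    ss_b = n * a * ((B - grand) ** 2).sum()
    ss_ab = n * ((AB - A[:, None] - B[None, :] + grand) ** 2).sum()
    ss_as = b * ((AS - S[:, None] - A[None, :] + grand) ** 2).sum()
    ss_bs = a * ((BS - S[:, None] - B[None, :] + grand) ** 2).sum()
    resid = (
        y
        - AB[None, :, :]
        - AS[:, :, None]
        - BS[:, None, :]
        + A[None, :, None]
        + B[None, None, :]
        + S[:, None, None]
        - grand
    )
    ss_abs = (resid**2).sum()
    out = {}
    out["A"] = (
        (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1))),
        a - 1,
        (a - 1) * (n - 1),
    )
    out["B"] = (
        (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1))),
        b - 1,
        (b - 1) * (n - 1),
    )
    out["A * B"] = (
        (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1))),
        (a - 1) * (b - 1),
        (a - 1) * (b - 1) * (n - 1),
    )
    return out


def long_table(y: np.ndarray) -> pd.DataFrame:
    n, a, b = y.shape
    rows = []
    for i in range(n):
        for j in range(a):
            for k in range(b):
                rows.append(
                    {
                        "subject": f"s{i}",
                        "fa": f"a{j}",
                        "fb": f"b{k}",
                        "value": y[i, j, k],
                    }
                )
    return pd.DataFrame(rows)


def mc_power_oneway_rm(
    f: float, rho: float, n: int, m: int, alpha: float, reps: int, rng
) -> float:
    """Monte-Carlo power of the one-way within-subjects F test under an
    exchangeable-correlation normal model."""
    pattern = np.linspace(-1.0, 1.0, m)
    pattern -= pattern.mean()
    mu = pattern * (f / np.sqrt((pattern**2).mean()))
    b = rng.normal(0.0, np.sqrt(rho), size=(reps, n, 1))
    e = rng.normal(0.0, np.sqrt(1.0 - rho), size=(reps, n, m))
    y = mu[None, None, :] + b + e
    grand = y.mean(axis=(1, 2), keepdims=True)
    mj = y.mean(axis=1, keepdims=True)
    si = y.mean(axis=2, keepdims=True)
    ss_t = n * ((mj - grand) ** 2).sum(axis=(1, 2))
    resid = y - mj - si + grand
    ss_e = (resid**2).sum(axis=(1, 2))
    F = (ss_t / (m - 1)) / (ss_e / ((m - 1) * (n - 1)))
    crit = sps.f.isf(alpha, m - 1, (m - 1) * (n - 1))
    return float((F > crit).mean())


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

class TestRmAnova:
    @pytest.mark.parametrize("shape", [(4, 2, 2), (4, 3, 3), (3, 3, 2)])
    def test_agrees_with_brute_force(self, shape):
        rng = np.random.default_rng(sum(shape))
        y = rng.normal(0, 1, size=shape) + rng.normal(0, 1, size=(shape[0], 1, 1))
        res = rm_anova_two_way(long_table(y), "value", ("fa", "fb"), "subject")
        oracle = brute_force_rm_anova(y)
        for ours_key, oracle_key in [("fa", "A"), ("fb", "B"), ("fa * fb", "A * B")]:
            F, df1, df2 = oracle[oracle_key]
            assert res.effects[ours_key]["F"] == pytest.approx(F, rel=1e-8)
            assert res.effects[ours_key]["df1"] == df1
            assert res.effects[ours_key]["df2"] == df2

    def test_zero_condition_effect_gives_zero_f(self):
        rng = np.random.default_rng(0)
        n, a = 5, 4
        base = rng.normal(0, 1, size=(n, a))
        y = np.stack([base, base], axis=2)  # identical across B levels
        res = rm_anova_two_way(long_table(y), "value", ("fa", "fb"), "subject")
        assert res.effects["fb"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_cell_is_explicit_error(self):
        df = long_table(np.zeros((4, 2, 2))).drop(index=[3])
        with pytest.raises(MissingCellError, match="missing"):
            rm_anova_two_way(df, "value", ("fa", "fb"), "subject")

    def test_too_few_subjects_rejected(self):
        df = long_table(np.random.default_rng(0).normal(size=(2, 2, 2)))
        with pytest.raises(MissingCellError, match="subjects"):
            rm_anova_two_way(df, "value", ("fa", "fb"), "subject")


class TestTukey:
    def test_two_levels_equals_paired_t(self):
        rng = np.random.default_rng(5)
        df = long_table(rng.normal(0, 1, size=(8, 1, 2)) + [[[0.0, 0.8]]])
        res = tukey_hsd(df, "value", "fb", "subject")
        piv = df.pivot_table(index="subject", columns="fb", values="value")
        t_p = sps.ttest_rel(piv["b0"], piv["b1"]).pvalue
        assert res.table["p_tukey"].iloc[0] == pytest.approx(t_p, rel=1e-9)
        assert len(res.table) == 1

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_number_of_contrasts(self, k):
        rng = np.random.default_rng(k)
        df = long_table(rng.normal(size=(5, 1, k)))
        res = tukey_hsd(df, "value", "fb", "subject")
        assert len(res.table) == k * (k - 1) // 2

    def test_null_contrasts_are_conservative(self):
        """Identical level means, noise only: adjusted p is stochastically
        larger than uniform and the familywise error rate stays at alpha."""
        rng = np.random.default_rng(11)
        ps, family_hits = [], 0
        reps = 200
        for _ in range(reps):
            df = long_table(rng.normal(size=(12, 1, 3)))
            p = tukey_hsd(df, "value", "fb", "subject").table["p_tukey"]
            ps.extend(p)
            family_hits += bool((p < 0.05).any())
        assert np.median(ps) > 0.5  # uniform p would have median 0.5
        lo, hi = sps.binom.interval(0.99, reps, 0.05)
        assert lo <= family_hits <= hi

    def test_single_level_rejected(self):
        df = long_table(np.zeros((4, 1, 2)))
        with pytest.raises(MissingCellError):
            tukey_hsd(df[df.fb == "b0"], "value", "fb", "subject")

    def test_star_bands(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.00009) == "****"
        assert significance_stars(0.2) == "ns"


class TestBayes:
    def test_strong_effect_is_decisive(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, size=(6, 5, 2))
        y += np.linspace(0, 4, 5)[None, :, None]  # big session effect
        y[:, 2:, 0] += 2.0  # interaction-style condition effect
        res = logbf_rm_anova(long_table(y), "value", ("fa", "fb"), "subject")
        assert res.logbf10 > 4.6
        assert res.category == "decisive"

    def test_null_data_rarely_exceeds_anecdotal(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(50):
            y = rng.normal(size=(6, 3, 2)) + rng.normal(size=(6, 1, 1))
            vals.append(
                logbf_rm_anova(long_table(y), "value", ("fa", "fb"), "subject").logbf10
            )
        assert np.median(vals) < 1.1


class TestEvidenceBands:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, "anecdotal"),
            (0.5, "anecdotal"),
            (1.0999, "anecdotal"),
            (1.1, "substantial"),
            (2.2999, "substantial"),
            (2.3, "strong"),
            (3.0, "strong"),
            (3.4, "strong"),
            (3.41, "very strong"),
            (4.6, "very strong"),
            (4.61, "decisive"),
            (5.0, "decisive"),
            (16.988, "decisive"),
        ],
    )
    def test_bands_exact_at_edges(self, value, expected):
        assert classify_evidence(value) == expected

    def test_negative_mirrors_magnitude(self):
        assert classify_evidence(-3.0) == "favors null (strong)"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_evidence(float("nan"))


class TestPower:
    def test_monotone_in_n(self):
        powers = [
            power_rm_anova(f=0.3333, m=6, n=n).actual_power for n in range(3, 30)
        ]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_high_rho_saturates_power(self):
        res = power_rm_anova(f=0.3333, m=4, n=10, rho=0.999)
        assert res.actual_power > 0.999

    def test_a_priori_returns_smallest_sufficient_n(self):
        res = power_rm_anova(f=0.3333, m=6, target_power=0.8)
        assert res.actual_power >= 0.8
        below = _rm_power(0.3333, 0.05, 0.5, 1.0, 6, res.n - 1)
        assert below < 0.8

    def test_matches_monte_carlo_oracle(self):
        """Analytic noncentral-F power within +/-0.03 of simulation on a
        small (n, m) grid at the conventional design settings."""
        rng = np.random.default_rng(123)
        for n in (5, 10):
            for m in (3, 6):
                analytic = power_rm_anova(f=0.3333, m=m, n=n).actual_power
                mc = mc_power_oneway_rm(0.3333, 0.5, n, m, 0.05, 4000, rng)
                assert analytic == pytest.approx(mc, abs=0.03)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            power_rm_anova(f=-1.0, m=3, n=5)
        with pytest.raises(ValueError):
            power_rm_anova(f=0.3, m=3, n=5, target_power=0.8)
        with pytest.raises(ValueError):
            power_rm_anova(f=0.3, m=3, rho=1.0, n=5)
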