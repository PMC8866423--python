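import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bgcphylo.association_stats import (
    distance_lm,
    duncan_mrt,
    mantel_test,
    meta_regression,
    per_strain_association,
)
from bgcphylo.records import DistanceMatrix, InhibitionTable, ValidationError


def random_dm(rng, labels):
    n = len(labels)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.uniform(0.1, 1.0, size=len(iu[0]))
    return DistanceMatrix(tuple(labels), m + m.T)


class TestDistanceLM:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        lm = distance_lm(x, 2 * x + 1)
        assert lm.slope == pytest.approx(2.0)
        assert lm.intercept == pytest.approx(1.0)
        assert lm.adjusted_R2 == pytest.approx(1.0)
        assert lm.p_value <= 1e-12
        assert lm.df == (1, 8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = 1.5 * x + rng.normal(size=n)
            lm = distance_lm(x, y)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert lm.slope == pytest.approx(fit.params[1], rel=1e-9)
            assert lm.intercept == pytest.approx(fit.params[0], rel=1e-9)
            assert lm.adjusted_R2 == pytest.approx(fit.rsquared_adj, rel=1e-9, abs=1e-12)
            assert lm.F_statistic == pytest.approx(fit.fvalue, rel=1e-9)
            assert lm.p_value == pytest.approx(fit.f_pvalue, rel=1e-6, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError):
            distance_lm([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_p_uniformish(self, rng):
        ps = []
        for _ in range(200):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            ps.append(distance_lm(x, y).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMantel:
    def test_identical_matrices(self, rng):
        d = random_dm(rng, [f"G{i}" for i in range(8)])
        res = mantel_test(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_p_never_zero(self, rng):
        d1 = random_dm(rng, list("ABCDEF"))
        d2 = random_dm(rng, list("ABCDEF"))
        assert mantel_test(d1, d2, n_perm=99, seed=1).p > 0.0

    def test_label_mismatch_rejected(self, rng):
        d1 = random_dm(rng, list("ABC"))
        d2 = random_dm(rng, list("ABD"))
        with pytest.raises(ValidationError):
            mantel_test(d1, d2)

    def test_label_order_irrelevant(self, rng):
        labels = list("ABCDE")
        d1 = random_dm(rng, labels)
        d2 = random_dm(rng, labels)
        shuffled = d2.reorder(list("EDCBA"))
        a = mantel_test(d1, d2, n_perm=99, seed=3)
        b = mantel_test(d1, shuffled, n_perm=99, seed=3)
        assert a.r == pytest.approx(b.r)

    def test_null_not_anticonservative(self, rng):
        ps = [
            mantel_test(
                random_dm(rng, list("ABCDEFGH")),
                random_dm(rng, list("ABCDEFGH")),
                n_perm=199,
                seed=k,
            ).p
            for k in range(100)
        ]
        assert np.mean(ps) > 0.45  # valid test: p stochastically >= uniform


class TestDuncan:
    def test_identical_groups_share_letter(self):
        letters = duncan_mrt({"g1": [5.0, 5.0, 5.0], "g2": [5.0, 5.0, 5.0]})
        assert letters == {"g1": "a", "g2": "a"}

    def test_outlier_group_separated(self):
        groups = {
            "lo": [-0.05, 0.0, 0.05],
            "mid": [-0.04, 0.01, 0.06],
            "hi": [9.95, 10.0, 10.05],
        }
        letters = duncan_mrt(groups)
        assert letters["hi"] == "a"
        assert letters["mid"] == "b"
        assert letters["lo"] == "b"

    def test_span_two_matches_pooled_t_test(self, rng):
        """With two groups Duncan's decision equals the two-sample
        pooled-variance t test at the same alpha."""
        for _ in range(100):
            n1, n2 = int(rng.integers(3, 10)), int(rng.integers(3, 10))
            g1 = rng.normal(0, 1, size=n1)
            g2 = rng.normal(rng.uniform(0, 1.5), 1, size=n2)
            letters = duncan_mrt({"g1": list(g1), "g2": list(g2)}, alpha=0.05)
            duncan_separates = set(letters["g1"]).isdisjoint(letters["g2"])
            t, p = stats.ttest_ind(g1, g2, equal_var=True)
            assert duncan_separates == (p < 0.05)

    def test_no_shared_letter_implies_large_gap(self, rng):
        """Groups with disjoint letters differ by more than the span-2
        critical range; shared letters form contiguous runs in mean order."""
        for _ in range(25):
            k = int(rng.integers(3, 7))
            groups = {
                f"g{i}": list(rng.normal(rng.uniform(0, 3), 0.5, size=5))
                for i in range(k)
            }
            letters = duncan_mrt(groups)
            means = {g: np.mean(v) for g, v in groups.items()}
            arrays = [np.asarray(v) for v in groups.values()]
            df = sum(len(a) - 1 for a in arrays)
            mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
            r2 = stats.studentized_range.ppf(0.95, 2, df) * np.sqrt(mse / 5)
            ranked = sorted(groups, key=lambda g: -means[g])
            for a in groups:
                for b in groups:
                    if a < b and set(letters[a]).isdisjoint(letters[b]):
                        assert abs(means[a] - means[b]) > r2
            for ch in set("".join(letters.values())):
                pos = [i for i, g in enumerate(ranked) if ch in letters[g]]
                assert pos == list(range(min(pos), max(pos) + 1))

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            duncan_mrt({"g1": [1.0], "g2": [1.0, 2.0]})


class TestPerStrainAssociation:
    def _setup(self, rng, n=6):
        labels = [f"G{i}" for i in range(n)]
        phylo = random_dm(rng, labels)
        bgc = random_dm(rng, labels)
        rows = []
        for a in labels:
            for t in labels:
                if a == t:
                    continue
                for rep in (1, 2, 3):
                    rows.append((a, t, rep, 5 * phylo[a, t] + rng.normal(0, 0.3)))
        table = InhibitionTable(
            pd.DataFrame(rows, columns=["antagonist", "target", "replicate", "zone_mm"])
        )
        counts = {g: int(rng.integers(2, 20)) for g in labels}
        return table, phylo, bgc, counts

    def test_one_row_per_antagonist(self, rng):
        table, phylo, bgc, counts = self._setup(rng)
        summary = per_strain_association(table, phylo, bgc, counts)
        assert list(summary["antagonist"]) == sorted(counts)

    def test_phylo_graded_zones_give_positive_slopes(self, rng):
        table, phylo, bgc, counts = self._setup(rng)
        summary = per_strain_association(table, phylo, bgc, counts)
        assert (summary["slope_phylo"] > 0).all()

    def test_too_few_targets_skipped(self, rng):
        labels = ["A", "B", "C", "D"]
        phylo = random_dm(rng, labels)
        bgc = random_dm(rng, labels)
        rows = [("A", t, r, 1.0 + rng.normal()) for t in ("B", "C") for r in (1, 2)]
        rows += [
            (a, t, r, float(rng.uniform(1, 3)))
            for a in ("B", "C", "D")
            for t in labels
            if t != a
            for r in (1, 2)
        ]
        table = InhibitionTable(
            pd.DataFrame(rows, columns=["antagonist", "target", "replicate", "zone_mm"])
        )
        summary = per_strain_association(table, phylo, bgc, {l: 5 for l in labels})
        assert "A" not in set(summary["antagonist"])


class TestMetaRegression:
    def test_df_structure(self, rng):
        summary = pd.DataFrame(
            {
                "assoc_phylo": rng.uniform(-0.2, 0.8, size=10),
                "assoc_bgc": rng.uniform(-0.2, 0.8, size=10),
                "bgc_count": rng.integers(2, 20, size=10).astype(float),
            }
        )
        lm = meta_regression(summary, "phylo_assoc")
        assert lm.df == (1, 8)

    def test_constant_response_propagates_degeneracy(self):
        summary = pd.DataFrame(
            {
                "assoc_phylo": [0.5, 0.5, 0.5, 0.5],
                "assoc_bgc": [0.5, 0.5, 0.5, 0.5],
                "bgc_count": [2.0, 5.0, 9.0, 14.0],
            }
        )
        with pytest.raises(ValidationError):
            meta_regression(summary, "phylo_assoc")

    def test_too_few_strains(self):
        summary = pd.DataFrame(
            {"assoc_phylo": [0.1, 0.2], "assoc_bgc": [0.1, 0.2], "bgc_count": [2.0, 3.0]}
        )
        with pytest.raises(ValidationError):
            meta_regression(summary, "phylo_assoc")
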