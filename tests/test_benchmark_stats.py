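"""Pose RMSD, success rates, summaries, and rank-based group comparison."""

import numpy as np
import pytest
from scipy import stats as sps

from probedock import (BenchmarkTable, EmptyInputError, PoseRecord,
                       dunn_posthoc, filter_complete, kruskal_wallis, rmsd,
                       success_rate, summarize, symmetry_aware_rmsd)


def reference_dunn(groups):
    """Independent route for Dunn z/p using pandas ranking and statsmodels
    multiplicity adjustment (the implementation uses scipy rankdata and its
    own adjustment loops)."""
    import itertools

    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    pooled = pd.Series(np.concatenate([np.asarray(g, float) for g in groups]))
    ranks = pooled.rank(method="average").to_numpy()
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    w = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
    n = len(pooled)
    counts = pooled.value_counts().to_numpy()
    tie = np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
    zs, ps = [], []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie) * (1 / sizes[i] + 1 / sizes[j]))
        z = 0.0 if se == 0 else (w[i] - w[j]) / se
        zs.append(z)
        ps.append(sps.norm.sf(abs(z)))
    p_bonf = multipletests(ps, method="bonferroni")[1]
    p_holm = multipletests(ps, method="holm")[1]
    return zs, ps, p_bonf, p_holm


class TestRmsd:
    def test_identity_is_zero(self):
        a = np.random.default_rng(0).uniform(-5, 5, (10, 3))
        assert rmsd(a, a) == 0.0

    def test_three_four_five_triangle(self):
        assert rmsd([[0.0, 0, 0]], [[3.0, 4.0, 0]]) == pytest.approx(5.0)

    def test_closed_form_two_atoms(self):
        a = [[0.0, 0, 0], [0.0, 0, 0]]
        b = [[0.0, 0, 0], [2.0, 0, 0]]
        assert rmsd(a, b) == pytest.approx(np.sqrt(2.0))

    def test_symmetric_and_shape_checked(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(-3, 3, (7, 3)), rng.uniform(-3, 3, (7, 3))
        assert rmsd(a, b) == pytest.approx(rmsd(b, a))
        with pytest.raises(ValueError):
            rmsd(a, b[:5])

    def test_symmetry_aware_handles_ring_flip(self):
        """A 180°-flipped benzene ring has huge naive RMSD but 0 under
        automorphism minimization."""
        ang = np.arange(6) * np.pi / 3
        ring = np.column_stack([1.39 * np.cos(ang), 1.39 * np.sin(ang),
                                np.zeros(6)])
        flipped = ring[[0, 5, 4, 3, 2, 1]]
        bonds = [(i, (i + 1) % 6, "ar") for i in range(6)]
        assert rmsd(ring, flipped) > 1.0
        assert symmetry_aware_rmsd(ring, flipped, ["C"] * 6, bonds) == \
            pytest.approx(0.0, abs=1e-12)


class TestSuccessRate:
    def test_strictly_under_cutoff(self):
        assert success_rate([1.9, 2.0, 2.1]) == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("values,expected", [([0.5] * 4, 1.0), ([10.0] * 3, 0.0)])
    def test_extremes(self, values, expected):
        assert success_rate(values) == expected

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 10, 50)
        rates = [success_rate(vals, c) for c in np.linspace(0.1, 12, 25)]
        assert all(a <= b for a, b in zip(rates, rates[1:]))

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            success_rate([])


class TestSummarize:
    def test_closed_form_quartiles(self):
        s = summarize([1, 2, 3, 4])
        assert s["median"] == 2.5 and s["q25"] == 1.75 and s["q75"] == 3.25
        assert s["mean"] == 2.5 and s["count"] == 4

    def test_single_value_convention(self):
        s = summarize([3.3])
        assert all(s[k] == 3.3 for k in ("mean", "min", "q25", "median", "q75", "max"))
        assert s["std"] == 0.0

    def test_sample_std(self):
        assert summarize([0, 10])["std"] == pytest.approx(7.0711, abs=1e-4)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        # rank sums 6 and 15: H = 12/(6*7)*(36/3 + 225/3) - 3*7 = 27/7
        assert h == pytest.approx(27.0 / 7.0, abs=1e-10)
        assert p == pytest.approx(sps.chi2.sf(27.0 / 7.0, 1), abs=1e-12)

    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
        assert h == 0.0 and p == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [np.round(rng.uniform(0, 5, int(rng.integers(3, 12))), 1)
                      for _ in range(k)]
            h, p = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert h == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_larger_separation_larger_h(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        hs = [kruskal_wallis([base, base + shift])[0] for shift in (0.5, 2.0, 6.0)]
        assert hs[0] < hs[1] <= hs[2]


class TestDunn:
    def test_pair_count(self):
        rng = np.random.default_rng(4)
        res = dunn_posthoc([rng.uniform(0, 1, 6) for _ in range(4)])
        assert len(res) == 6    # k(k-1)/2 for k = 4

    def test_identical_constant_groups_convention(self):
        (res,) = dunn_posthoc([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.z == 0.0
        assert res.p == pytest.approx(0.5)
        assert res.p_bonf == pytest.approx(0.5)   # single pair: m = 1

    def test_one_sided_convention_near_zero_z(self):
        """A z of about 0.07 maps to a one-sided p of about 0.47."""
        assert sps.norm.sf(0.069) == pytest.approx(0.4725, abs=1e-4)
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 1, 40)
        res = dunn_posthoc([a, a + rng.normal(0, 1e-3, 40)])
        for r in res:
            assert r.p == pytest.approx(sps.norm.sf(abs(r.z)), abs=1e-12)

    def test_matches_reference_route(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            groups = [np.round(rng.uniform(0, 4, int(rng.integers(3, 15))), 1)
                      for _ in range(k)]
            res = dunn_posthoc(groups)
            zs, ps, p_bonf, p_holm = reference_dunn(groups)
            for r, z, p, pb, ph in zip(res, zs, ps, p_bonf, p_holm):
                assert r.z == pytest.approx(z, abs=1e-10)
                assert r.p == pytest.approx(p, abs=1e-10)
                assert r.p_bonf == pytest.approx(pb, abs=1e-10)
                assert r.p_holm == pytest.approx(ph, abs=1e-10)

    def test_adjustment_ordering(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, 12) for m in (0.0, 0.3, 1.0, 2.0)]
        for r in dunn_posthoc(groups):
            assert r.p <= r.p_holm <= r.p_bonf <= 1.0 + 1e-15


class TestBenchmarkTable:
    def _records(self):
        recs = []
        for cid in ("1abc", "2def", "3ghi"):
            for proto in ("blind", "site"):
                if cid == "3ghi" and proto == "site":
                    continue    # 3ghi failed to dock under "site"
                recs.append(PoseRecord(cid, proto, 1.0))
        return recs

    def test_filter_complete_drops_partial(self):
        table = BenchmarkTable.from_records(self._records())
        filtered = filter_complete(table)
        assert filtered.complexes == ["1abc", "2def"]

    def test_filter_complete_identity_when_all_complete(self):
        recs = [PoseRecord(c, p, 1.0) for c in ("a", "b") for p in ("x", "y")]
        table = BenchmarkTable.from_records(recs)
        assert len(filter_complete(table)) == len(table)

    def test_none_complete_gives_empty_table(self):
        recs = [PoseRecord("a", "x", 1.0), PoseRecord("b", "y", 1.0)]
        assert len(filter_complete(BenchmarkTable.from_records(recs))) == 0

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkTable.from_records(
                [PoseRecord("a", "x", 1.0), PoseRecord("a", "x", 2.0)])

    def test_csv_round_trip(self, tmp_path):
        table = BenchmarkTable.from_records(self._records())
        path = tmp_path / "rmsd.csv"
        table.to_csv(path)
        back = BenchmarkTable.from_csv(path)
        assert back.df.equals(table.df)

    def test_plot_smoke(self, tmp_path):
        from probedock.stats import plot_rmsd_distributions
        rng = np.random.default_rng(7)
        recs = [PoseRecord(f"c{i}", p, float(r))
                for p in ("blind", "site")
                for i, r in enumerate(rng.uniform(0, 20, 20))]
        out = tmp_path / "dist.png"
        plot_rmsd_distributions(BenchmarkTable.from_records(recs), out)
        assert out.stat().st_size > 0
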