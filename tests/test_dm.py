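import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylenr import dm
from methylenr.io import CytosineRecord

from conftest import make_record, two_group_records


def g_test_2x2(m1, u1, m2, u2):
    """Independent oracle: likelihood-ratio (G) test on a pooled 2x2
    methylated/unmethylated table."""
    obs = np.array([[m1, u1], [m2, u2]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2 * terms.sum()
    return g, stats.chi2.sf(g, df=1)


class TestFilterByCoverage:
    def test_min_cov_inclusive(self):
        recs = [make_record(pos=p, meth=t, unmeth=0) for p, t in
                [(1, 9), (2, 10), (3, 11)]]
        kept = dm.filter_by_coverage(recs, min_cov=10, upper_percentile=100)
        assert [r.total for r in kept] == [10, 11]

    def test_extreme_coverage_removed_at_percentile(self):
        rng = np.random.default_rng(0)
        totals = list(rng.integers(10, 100, size=999)) + [10**6]
        recs = [make_record(pos=i + 1, meth=int(t), unmeth=0)
                for i, t in enumerate(totals)]
        kept = dm.filter_by_coverage(recs, min_cov=10, upper_percentile=99.9)
        cutoff = np.percentile(np.array(totals, dtype=float), 99.9)
        expected = [r for r in recs if r.total <= cutoff]
        assert kept == expected
        assert all(r.total < 10**6 for r in kept)

    def test_percentile_100_disables_upper_filter(self):
        recs = [make_record(pos=1, meth=10, unmeth=0),
                make_record(pos=2, meth=10**6, unmeth=0)]
        assert len(dm.filter_by_coverage(recs, upper_percentile=100)) == 2

    def test_empty_input(self):
        assert dm.filter_by_coverage([]) == []


def _records(chrom, positions, meth, total):
    return [CytosineRecord(chrom, p, "+", "CpG", m, t - m)
            for p, m, t in zip(positions, meth, total)]


class TestUnite:
    def _per_sample(self, presence):
        """presence: {sample: [bool per site]} -> records at 20x."""
        per = {}
        for s, mask in presence.items():
            per[s] = [CytosineRecord("chr1", 100 * (i + 1), "+", "CpG", 10, 10)
                      for i, present in enumerate(mask) if present]
        return per

    def test_boundary_three_per_group(self):
        groups = {f"y{i}": "young" for i in range(5)}
        groups |= {f"a{i}": "aged" for i in range(7)}
        presence = {s: [True] for s in groups}
        # site 2: covered in exactly 3 young and 3 aged
        for s in groups:
            presence[s].append(s in {"y0", "y1", "y2", "a0", "a1", "a2"})
        # site 3: only 2 young
        for s in groups:
            presence[s].append(s in {"y0", "y1", "a0", "a1", "a2", "a3"})
        mat = dm.unite(self._per_sample(presence), groups)
        assert mat.n_sites == 2  # sites 1 and 2 retained, site 3 dropped
        assert set(mat.sites["pos"]) == {100, 200}

    def test_all_covered_keeps_all(self):
        groups = {"y0": "g1", "y1": "g1", "y2": "g1",
                  "a0": "g2", "a1": "g2", "a2": "g2"}
        presence = {s: [True, True, True, True] for s in groups}
        mat = dm.unite(self._per_sample(presence), groups)
        assert mat.n_sites == 4

    def test_small_group_is_configuration_error(self):
        groups = {"y0": "g1", "y1": "g1", "a0": "g2", "a1": "g2", "a2": "g2"}
        presence = {s: [True] for s in groups}
        with pytest.raises(dm.ConfigurationError):
            dm.unite(self._per_sample(presence), groups)

    def test_missing_entries_are_absent_not_zero(self):
        groups = {f"s{i}": ("g1" if i < 4 else "g2") for i in range(7)}
        presence = {s: [True] for s in groups}
        presence["s0"].append(False)
        for s in list(groups)[1:]:
            presence[s].append(True)
        mat = dm.unite(self._per_sample(presence), groups)
        col = mat.samples.index("s0")
        row = int(np.flatnonzero(mat.sites["pos"].to_numpy() == 200)[0])
        assert np.isnan(mat.total[row, col])


def _one_sample_matrix(m1, t1, m2, t2, n_sites=1):
    """Matrix with one sample per group (padded to satisfy unite by
    direct construction)."""
    sites = pd.DataFrame({
        "chrom": ["chr1"] * n_sites,
        "pos": np.arange(n_sites) + 1,
        "strand": ["+"] * n_sites,
        "context": ["CpG"] * n_sites,
    })
    meth = np.column_stack([np.full(n_sites, m1, float),
                            np.full(n_sites, m2, float)])
    total = np.column_stack([np.full(n_sites, t1, float),
                             np.full(n_sites, t2, float)])
    return dm.CytosineCountMatrix(sites, meth, total, ["s1", "s2"],
                                  {"s1": "g1", "s2": "g2"})


class TestDiffMeth:
    def test_strong_difference_matches_g_test(self):
        mat = _one_sample_matrix(90, 100, 10, 100)
        res = dm.test_diffmeth(mat, "g1", "g2")
        assert res["meth_diff"].iloc[0] == pytest.approx(-80.0)
        assert res["pvalue"].iloc[0] < 1e-10
        g, p = g_test_2x2(90, 10, 10, 90)
        assert res["pvalue"].iloc[0] == pytest.approx(p, rel=1e-6)
        assert res["statistic"].iloc[0] == pytest.approx(g, rel=1e-6)

    def test_identical_counts_null(self):
        mat = _one_sample_matrix(5, 10, 5, 10)
        res = dm.test_diffmeth(mat, "g1", "g2")
        assert res["meth_diff"].iloc[0] == 0.0
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        sites = pd.DataFrame({"chrom": ["chr1"] * 20, "pos": np.arange(20) + 1,
                              "strand": ["+"] * 20, "context": ["CpG"] * 20})
        total = rng.integers(10, 60, size=(20, 6)).astype(float)
        meth = rng.binomial(total.astype(int), 0.5).astype(float)
        groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        mat = dm.CytosineCountMatrix(sites, meth, total, list(groups), groups)
        fwd = dm.test_diffmeth(mat, "g1", "g2")
        rev = dm.test_diffmeth(mat, "g2", "g1")
        np.testing.assert_allclose(fwd["meth_diff"], -rev["meth_diff"])
        np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"])

    def test_matches_statsmodels_glm_with_replicates(self):
        """The vectorised deviance computation equals an explicit
        per-site binomial GLM likelihood-ratio test."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        total = rng.integers(10, 50, size=(5, 8)).astype(float)
        meth = rng.binomial(total.astype(int),
                            rng.uniform(0.2, 0.8, size=(5, 1))).astype(float)
        sites = pd.DataFrame({"chrom": ["chr1"] * 5, "pos": np.arange(5) + 1,
                              "strand": ["+"] * 5, "context": ["CpG"] * 5})
        groups = {f"s{i}": ("g1" if i < 4 else "g2") for i in range(8)}
        mat = dm.CytosineCountMatrix(sites, meth, total, list(groups), groups)
        res = dm.test_diffmeth(mat, "g1", "g2")
        x = sm.add_constant(np.array([0.0] * 4 + [1.0] * 4))
        for i in range(5):
            endog = np.column_stack([meth[i], total[i] - meth[i]])
            full = sm.GLM(endog, x, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, x[:, :1], family=sm.families.Binomial()).fit()
            lrt = 2 * (full.llf - null.llf)
            p = stats.chi2.sf(lrt, 1)
            assert res["pvalue"].iloc[i] == pytest.approx(p, rel=1e-6, abs=1e-12)


class TestAdjustQvalues:
    def test_bh_equals_slim_when_pi0_is_one(self, monkeypatch):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        monkeypatch.setattr(dm, "estimate_pi0_slim", lambda *a, **k: 1.0)
        np.testing.assert_array_equal(
            dm.adjust_qvalues(p, "slim"), dm.adjust_qvalues(p, "bh")
        )

    def test_single_p_is_conservative(self):
        q = dm.adjust_qvalues(np.array([0.01]), "slim")
        assert 0 < q[0] <= 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dm.adjust_qvalues(np.array([0.5, 1.5]))

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.random(2000), rng.beta(0.1, 5, 500)])
        for method in ("slim", "bh"):
            q = dm.adjust_qvalues(p, method)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(q[order]) >= -1e-12)

    def test_null_pi0_calibration(self):
        """Uniform p-values should give pi0 near 1 in nearly all runs."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pi0 = dm.estimate_pi0_slim(rng.random(10_000))
            hits += 0.9 <= pi0 <= 1.0
        assert hits >= 19


class TestCallDm:
    def _frame(self, q, diff):
        return pd.DataFrame({
            "chrom": ["chr1"], "pos": [1], "strand": ["+"], "context": ["CpG"],
            "meth_diff": [diff], "pvalue": [q], "qvalue": [q],
            "significant": [False], "direction": ["none"],
        })

    def test_q_boundary_strict(self):
        res = dm.call_dm(self._frame(0.001, 50.0))
        assert not res["significant"].iloc[0]

    def test_diff_boundary_strict(self):
        res = dm.call_dm(self._frame(1e-6, 25.0))
        assert not res["significant"].iloc[0]

    def test_direction_assignment(self):
        res = dm.call_dm(self._frame(1e-6, -30.0))
        assert res["significant"].iloc[0]
        assert res["direction"].iloc[0] == "hypo"


class TestCallDmrs:
    def _matrix(self, positions, p_g1, p_g2, coverage=200, seed=0,
                n_per_group=4):
        rng = np.random.default_rng(seed)
        n = len(positions)
        sites = pd.DataFrame({"chrom": ["chr1"] * n, "pos": positions,
                              "strand": ["+"] * n, "context": ["CpG"] * n})
        samples = [f"a{i}" for i in range(n_per_group)] + \
                  [f"b{i}" for i in range(n_per_group)]
        groups = {s: ("g1" if s.startswith("a") else "g2") for s in samples}
        total = np.full((n, 2 * n_per_group), float(coverage))
        levels = np.column_stack(
            [np.repeat(np.asarray(p_g1)[:, None], n_per_group, axis=1),
             np.repeat(np.asarray(p_g2)[:, None], n_per_group, axis=1)])
        meth = rng.binomial(total.astype(int), levels).astype(float)
        return dm.CytosineCountMatrix(sites, meth, total, samples, groups)

    def test_five_shifted_sites_make_one_region(self):
        pos = [100, 300, 500, 700, 900]
        mat = self._matrix(pos, [0.3] * 5, [0.7] * 5)
        regions = dm.call_dmrs(mat, "g1", "g2")
        assert len(regions) == 1
        assert regions[0].n_cytosines == 5
        assert regions[0].mean_diff > 25

    def test_two_sites_do_not_form_a_region(self):
        mat = self._matrix([100, 300], [0.3] * 2, [0.7] * 2)
        assert dm.call_dmrs(mat, "g1", "g2") == []

    def test_distant_sites_split(self):
        pos = [100, 300, 500, 5000, 5200, 5400]
        mat = self._matrix(pos, [0.3] * 6, [0.7] * 6)
        regions = dm.call_dmrs(mat, "g1", "g2")
        assert len(regions) == 2

    def test_null_yields_no_regions(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(100_000, size=500, replace=False)) + 1
        levels = rng.uniform(0.2, 0.8, 500)
        mat = self._matrix(list(pos), levels, levels, coverage=30, seed=8)
        assert dm.call_dmrs(mat, "g1", "g2") == []


class TestGlobalMethylation:
    def test_two_extreme_sites_average_to_half(self):
        per = two_group_records({
            "s1": [(20, 20), (0, 20)],
            "s2": [(15, 15), (0, 30)],
        })
        res = dm.global_methylation(per)
        assert res == {"s1": pytest.approx(50.0), "s2": pytest.approx(50.0)}

    def test_site_below_coverage_anywhere_excluded_everywhere(self):
        per = two_group_records({
            "s1": [(20, 20), (9, 9)],   # second site only 9x in s1
            "s2": [(15, 15), (0, 30)],
        })
        res = dm.global_methylation(per, min_cov=10)
        assert res == {"s1": pytest.approx(100.0), "s2": pytest.approx(100.0)}
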