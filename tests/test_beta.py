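"""Null-model beta diversity, ordination and gradient statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from turbicom import beta
from turbicom.datamodel import ValidationError

from conftest import make_table


class TestRaupCrick:
    def test_identical_maximal_richness_is_half(self):
        """Both samples hold the entire pool: the null always ties -> 0.5."""
        tab = make_table(np.ones((2, 25), dtype=int))
        dm = beta.raup_crick(tab, n_reps=99, seed=0)
        assert dm["s0", "s1"] == pytest.approx(0.5, abs=1e-12)

    def test_disjoint_rich_samples_near_one(self):
        counts = np.zeros((2, 160), dtype=int)
        counts[0, :80] = 1
        counts[1, 80:] = 1
        dm = beta.raup_crick(make_table(counts), n_reps=199, seed=1)
        assert dm["s0", "s1"] > 0.95

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 20, size=(5, 40))
        counts[:, 0] += 1
        d1 = beta.raup_crick(make_table(counts), n_reps=99, seed=3)
        d2 = beta.raup_crick(make_table(counts * 7), n_reps=99, seed=3)
        assert np.allclose(d1.data, d2.data)

    def test_self_calibration_mean_half(self):
        """Pairs drawn from the null itself centre at dissimilarity 0.5."""
        rng = np.random.default_rng(5)
        n_pool, n_samp = 120, 40
        w = rng.lognormal(0, 1.5, n_pool)
        pres = np.zeros((n_samp, n_pool), dtype=int)
        for i in range(n_samp):
            k = int(rng.integers(30, 60))
            keys = np.log(w) + rng.gumbel(size=n_pool)
            pres[i, np.argsort(-keys)[:k]] = 1
        tab = make_table(pres)
        w_kept = w[[int(o[1:]) for o in tab.otu_ids]]
        dm = beta.raup_crick(tab, n_reps=199, seed=6, pool_weights=w_kept)
        iu = np.triu_indices(n_samp, 1)
        assert dm.data[iu].mean() == pytest.approx(0.5, abs=0.06)

    def test_zero_richness_rejected(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValidationError):
            # bypass the constructor's zero-column pruning with a third row
            beta.raup_crick(make_table(np.vstack([counts, [1, 1]])), n_reps=9)

    def test_occurrence_weighting_switch(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 9, size=(4, 30))
        counts[:, 0] += 1
        tab = make_table(counts)
        d = beta.raup_crick(tab, n_reps=49, seed=1, null_weighting="occurrence")
        assert np.all((d.data >= 0) & (d.data <= 1))
        with pytest.raises(ValidationError):
            beta.raup_crick(tab, n_reps=49, null_weighting="nope")


class TestBrayCurtis:
    def test_identical_zero(self):
        tab = make_table([[3, 1], [3, 1]])
        assert beta.bray_curtis(tab)["s0", "s1"] == pytest.approx(0.0)

    def test_disjoint_one(self):
        tab = make_table([[3, 0], [0, 2]])
        assert beta.bray_curtis(tab)["s0", "s1"] == pytest.approx(1.0)

    def test_hand_value(self):
        tab = make_table([[2, 1], [1, 1]])
        assert beta.bray_curtis(tab)["s0", "s1"] == pytest.approx(0.2, abs=1e-9)


class TestNmds:
    def _planar(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        return DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(n)])

    def test_planar_distances_near_zero_stress(self):
        ordn = beta.nmds(self._planar(), k=2, n_restarts=8, seed=1)
        assert ordn.stress < 0.01

    def test_determinism_and_centering(self):
        dm = self._planar(3)
        a = beta.nmds(dm, seed=5)
        b = beta.nmds(dm, seed=5)
        assert np.array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())
        assert np.allclose(a.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_extra_dimension_does_not_hurt(self):
        worse = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            r = rng.uniform(0.1, 1.0, size=(8, 8))
            m = (r + r.T) / 2
            np.fill_diagonal(m, 0)
            dm = DistanceMatrix(m, ids=[f"s{i}" for i in range(8)])
            s2 = beta.nmds(dm, k=2, n_restarts=8, seed=seed).stress
            s3 = beta.nmds(dm, k=3, n_restarts=8, seed=seed).stress
            worse += s3 > s2 + 1e-6
        assert worse <= 1

    def test_rescaled_spread_tracks_magnitude(self):
        dm = self._planar(4)
        big = DistanceMatrix(dm.data * 3.0, ids=dm.ids)
        a = beta.nmds(dm, seed=2)
        b = beta.nmds(big, seed=2)
        spread_a = np.linalg.norm(a.coordinates.to_numpy())
        spread_b = np.linalg.norm(b.coordinates.to_numpy())
        assert spread_b == pytest.approx(3 * spread_a, rel=0.05)

    def test_bad_k(self):
        with pytest.raises(ValidationError):
            beta.nmds(self._planar(), k=6)


class TestAnosim:
    def _blocks(self, within, between, n_per=3, groups=2, seed=0):
        rng = np.random.default_rng(seed)
        n = n_per * groups
        labels = np.repeat([f"g{i}" for i in range(groups)], n_per)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                base = within if labels[i] == labels[j] else between
                m[i, j] = m[j, i] = base + rng.uniform(0, 0.01)
        return DistanceMatrix(m, ids=[f"s{i}" for i in range(n)]), labels

    def test_perfect_separation(self):
        dm, labels = self._blocks(0.1, 0.9)
        r, p = beta.anosim(dm, labels, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p >= 1 / 100

    def test_matches_skbio(self):
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(3)
        m = rng.uniform(0.1, 1, size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix(m, ids=[f"s{i}" for i in range(8)])
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        r, _ = beta.anosim(dm, labels, n_perm=99, seed=0)
        ref = skbio_anosim(dm, grouping=labels, permutations=0)
        assert r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_random_labels_centre_at_zero(self):
        rs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            m = rng.uniform(0.1, 1, size=(10, 10))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            dm = DistanceMatrix(m, ids=[f"s{i}" for i in range(10)])
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            r, _ = beta.anosim(dm, labels, n_perm=0 + 9, seed=seed)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1

    def test_singleton_group_rejected(self):
        dm, _ = self._blocks(0.1, 0.9)
        with pytest.raises(ValidationError):
            beta.anosim(dm, ["a"] + ["b"] * 5, n_perm=9)


class TestEnvfit:
    def _ordn(self, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(12, 2))
        coords -= coords.mean(axis=0)
        return beta.OrdinationResult(
            coordinates=pd.DataFrame(coords, columns=["NMDS1", "NMDS2"]),
            stress=0.05, n_restarts=1, converged=True,
        )

    def test_axis_alignment_r2_one(self):
        ordn = self._ordn()
        env = ordn.coordinates["NMDS1"].to_numpy()
        r2, p = beta.envfit(ordn, env, n_perm=99, seed=1)
        assert r2 == pytest.approx(1.0)
        assert p == pytest.approx(0.01)

    def test_orthogonal_residual_r2_zero(self):
        ordn = self._ordn(2)
        rng = np.random.default_rng(3)
        env = rng.normal(size=12)
        x = ordn.coordinates.to_numpy()
        beta_hat, *_ = np.linalg.lstsq(x, env - env.mean(), rcond=None)
        resid = env - env.mean() - x @ beta_hat
        r2, _ = beta.envfit(ordn, resid, n_perm=9, seed=0)
        assert r2 == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_limit(self):
        ordn = self._ordn(4)
        env = 2.0 * ordn.coordinates["NMDS1"].to_numpy() + 1e-12
        r2, _ = beta.envfit(ordn, env, n_perm=9, seed=0)
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_constant_env_rejected(self):
        with pytest.raises(ValidationError):
            beta.envfit(self._ordn(), np.ones(12), n_perm=9)


class TestConvexHull:
    def test_unit_square(self):
        pts = [[0, 0], [1, 0], [1, 1], [0, 1]]
        assert beta.convex_hull_area(pts) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_zero(self):
        assert beta.convex_hull_area([[0, 0], [1, 1], [2, 2]]) == 0.0

    def test_pentagon_closed_form(self):
        ang = 2 * np.pi * np.arange(5) / 5
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        expected = 2.5 * np.sin(2 * np.pi / 5)
        assert beta.convex_hull_area(pts) == pytest.approx(expected, abs=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            beta.convex_hull_area([[0, np.nan], [1, 1], [2, 0]])


class TestRareAbundantPartition:
    def _tab(self):
        counts = np.zeros((2, 4), dtype=int)
        counts[0] = [996, 2, 2, 0]  # lake 1: o1,o2 at 0.2%
        counts[1] = [500, 0, 1, 499]
        meta = pd.DataFrame(
            {"lake": ["L1", "L2"], "replicate": [1, 1]}, index=["s0", "s1"]
        )
        return make_table(counts, metadata=meta)

    def test_cutoff_strictly_greater(self):
        part = beta.classify_rare_abundant(self._tab(), cutoff=0.001)
        assert "o1" in part.abundant["L1"]  # 0.2% > 0.1%
        assert "o3" not in part.abundant["L1"] and "o3" not in part.rare["L1"]

    def test_uniform_community_all_abundant(self):
        counts = np.full((1, 500), 2)
        meta = pd.DataFrame({"lake": ["L1"], "replicate": [1]}, index=["s0"])
        part = beta.classify_rare_abundant(make_table(counts, metadata=meta), 0.001)
        assert len(part.abundant["L1"]) == 500 and not part.rare["L1"]

    def test_sets_partition_detected(self):
        part = beta.classify_rare_abundant(self._tab(), cutoff=0.001)
        for lake in part.abundant:
            assert not (part.abundant[lake] & part.rare[lake])


class TestSharedAbundantRegression:
    def _partition(self, shared_counts, env):
        abundant = {"ref": {f"o{i}" for i in range(100)}}
        for j, k in enumerate(shared_counts):
            abundant[f"L{j}"] = {f"o{i}" for i in range(k)}
        return beta.AbundanceClassPartition(abundant, {k: set() for k in abundant}, 0.001), {
            f"L{j}": e for j, e in enumerate(env)
        }

    def test_exact_linear(self):
        part, env = self._partition([10, 20, 30, 40], [1, 2, 3, 4])
        r2, sign = beta.shared_abundant_regression(part, "ref", env)
        assert r2 == pytest.approx(1.0) and sign == 1

    def test_constant_zero(self):
        part, env = self._partition([10, 10, 10, 10], [1, 2, 3, 4])
        r2, _ = beta.shared_abundant_regression(part, "ref", env)
        assert r2 == 0.0

    def test_hand_ols(self):
        from scipy.stats import linregress

        part, env = self._partition([2, 4, 5, 9], [1, 2, 3, 4])
        r2, sign = beta.shared_abundant_regression(part, "ref", env)
        ref = linregress([1, 2, 3, 4], [2, 4, 5, 9])
        assert r2 == pytest.approx(ref.rvalue**2, abs=1e-9)
        assert r2 == pytest.approx(121 / 130, abs=1e-9)
        assert sign == 1


class TestRankAbundanceAndRatios:
    def test_rank_abundance_hand(self):
        tab = make_table([[5, 3, 2]])
        curve = beta.rank_abundance(tab)
        assert np.allclose(curve.iloc[0], [0.5, 0.3, 0.2])

    def test_identical_tables_unit_ratio(self):
        from turbicom.datamodel import Taxonomy

        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=(4, 6))
        meta = pd.DataFrame(
            {"lake": ["L1", "L1", "L2", "L2"], "replicate": [1, 2, 1, 2]},
            index=[f"s{i}" for i in range(4)],
        )
        dna = make_table(counts, metadata=meta, fraction="rDNA")
        rna = make_table(counts, metadata=meta, fraction="rRNA")
        tax = Taxonomy(pd.DataFrame(
            {"group": ["G1", "G1", "G2", "G2", "G3", "G3"]},
            index=[f"o{j}" for j in range(6)],
        ))
        ratios = beta.rna_dna_group_ratio(dna, rna, tax)
        assert np.allclose(ratios, 1.0)

    def test_absent_from_rna_is_zero(self):
        from turbicom.datamodel import Taxonomy

        meta = pd.DataFrame({"lake": ["L1"], "replicate": [1]}, index=["s0"])
        dna = make_table([[10, 10]], metadata=meta, fraction="rDNA")
        rna = make_table([[20, 1]], metadata=meta, fraction="rRNA")
        rna.counts.loc["s0", "o1"] = 0
        tax = Taxonomy(pd.DataFrame({"group": ["G1", "G2"]}, index=["o0", "o1"]))
        ratios = beta.rna_dna_group_ratio(dna, rna, tax)
        assert ratios["G2"] == pytest.approx(0.0)


class TestRarityProfile:
    def test_structure_and_boundaries(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, size=(6, 20))
        counts[:, 0] += 1
        tab = make_table(counts)
        prof = beta.rarity_inclusion_profile(
            tab, initial_top=5, step=100, n_reps=49, seed=0, nmds_restarts=2
        )
        sizes = prof.profile["n_otus_included"].tolist()
        assert sizes == [5, tab.n_otus]  # step overshoots -> initial and full only
        assert (prof.profile["hull_area"] >= 0).all()

    def test_requires_more_otus_than_initial(self, small_table):
        with pytest.raises(ValidationError):
            beta.rarity_inclusion_profile(small_table, initial_top=500)

    def test_ranking_ties_broken_by_id(self):
        tab = make_table([[2, 2, 2, 1]])
        assert beta.abundance_ranked_otus(tab) == ["o0", "o1", "o2", "o3"]


class TestRandomSubsample:
    def test_identical_fractions_indistinguishable(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 40, size=(6, 30))
        counts[:, 0] += 5
        meta = pd.DataFrame(
            {"lake": ["L1"] * 3 + ["L2"] * 3, "replicate": [1, 2, 3, 1, 2, 3]},
            index=[f"s{i}" for i in range(6)],
        )
        dna = make_table(counts, metadata=meta, fraction="rDNA")
        rna = make_table(counts, metadata=meta, fraction="rRNA")
        res = beta.random_subsample_ordination(
            dna, rna, n_individuals=int(counts.sum(1).min() // 2),
            n_draws=6, seed=0, rc_reps=49,
        )
        diff = abs(res.loc["rDNA", "mean_R"] - res.loc["rRNA", "mean_R"])
        spread = 2 * max(res["sd_R"].max(), 0.05)
        assert diff <= spread

    def test_determinism(self, small_table):
        n = int(small_table.sample_totals().min() // 2)
        a = beta.random_subsample_ordination(small_table, small_table, n, 2, seed=3, rc_reps=29)
        b = beta.random_subsample_ordination(small_table, small_table, n, 2, seed=3, rc_reps=29)
        pd.testing.assert_frame_equal(a, b)
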