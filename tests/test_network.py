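import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from coexsig import network
from coexsig.io import ExpressionMatrix
from coexsig.synthetic import SimulationParams, generate_dataset


def bicor_reference(x, y):
    """Independent biweight midcorrelation oracle: literal formula with
    explicit loops, no shared code with the implementation."""
    def prepare(v):
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        out = np.empty_like(v, dtype=float)
        for i, vi in enumerate(v):
            u = (vi - med) / (9.0 * mad)
            w = (1.0 - u * u) ** 2 if abs(u) < 1.0 else 0.0
            out[i] = (vi - med) * w
        return out
    a, b = prepare(np.asarray(x, float)), prepare(np.asarray(y, float))
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


class TestBicor:
    def test_self_and_negation(self, rng):
        x = rng.standard_normal(30)
        assert network.bicor(x, x) == pytest.approx(1.0)
        assert network.bicor(x, -x) == pytest.approx(-1.0)

    def test_matches_independent_oracle(self, rng):
        for _ in range(20):
            x = rng.standard_normal(25)
            y = 0.5 * x + rng.standard_normal(25)
            assert network.bicor(x, y) == pytest.approx(bicor_reference(x, y), abs=1e-12)

    def test_outlier_robustness_vs_pearson(self, rng):
        x = np.arange(20.0)
        y = x.copy()
        y[-1] = -100.0  # one gross outlier
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(network.bicor(x, y) - 1.0) < abs(pearson - 1.0)

    def test_equals_pearson_on_tight_symmetric_data(self):
        # no point beyond the weight cutoff and median == mean
        x = np.linspace(-1, 1, 21)
        y = np.linspace(-2, 2, 21)
        assert network.bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-6)

    def test_zero_mad_falls_back_to_pearson(self, rng):
        x = np.zeros(20)
        x[0] = 1.0  # MAD 0, but not constant
        y = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="zero MAD"):
            r = network.bicor(x, y)
        assert np.isfinite(r)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            network.bicor(np.array([1.0, 2.0]), np.array([2.0, 1.0]))


class TestStudentP:
    def test_zero_correlation_is_one(self):
        assert network.correlation_student_p(0.0, 30) == pytest.approx(1.0)

    def test_matches_t_distribution_oracle(self):
        r, n = 0.5, 30
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(t, n - 2)
        assert network.correlation_student_p(r, n) == pytest.approx(expected, abs=1e-10)

    def test_symmetric_in_sign(self):
        assert network.correlation_student_p(0.4, 25) == pytest.approx(
            network.correlation_student_p(-0.4, 25)
        )

    def test_perfect_correlation_returns_zero(self):
        assert network.correlation_student_p(1.0, 10) == 0.0


class TestSoftThreshold:
    def test_exact_power_law_connectivity_fits(self, rng):
        # k drawn from a discrete power law p(k) ~ k^-2
        ks = np.arange(1, 51)
        p = ks ** -2.0
        k = rng.choice(ks, size=3000, p=p / p.sum()).astype(float)
        assert network.scale_free_fit(k) >= 0.95

    def test_default_target_is_point_eight(self):
        assert network.NetworkConfig().scale_free_target == 0.8

    def test_fit_table_covers_candidate_powers(self, small_preprocessed):
        _, log2, *_ = small_preprocessed
        cfg = network.NetworkConfig(candidate_powers=(2, 4, 6))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, table = network.pick_soft_threshold(log2, cfg)
        assert len(table) == 3
        assert beta in (2, 4, 6)
        assert (table["mean_k"].diff().dropna() < 0).all()  # connectivity falls with power

    def test_adjacency_monotone_in_beta(self, rng):
        cor = np.clip(rng.uniform(-1, 1, (10, 10)), -1, 1)
        a_lo = network._adjacency(cor, 4.0, signed=False)
        a_hi = network._adjacency(cor, 8.0, signed=False)
        assert (a_hi <= a_lo + 1e-15).all()


class TestTopologicalOverlap:
    def test_bounded_and_symmetric(self, rng):
        cor = np.corrcoef(rng.standard_normal((15, 40)))
        tom = network.topological_overlap(np.abs(cor) ** 5)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()
        assert np.allclose(tom, tom.T, atol=1e-12)


class TestModuleDetection:
    @pytest.fixture(scope="class")
    def tight_two_block(self):
        """The classical regime: two 150-gene blocks at within-correlation
        0.8, strongly anti-correlated, no background."""
        params = SimulationParams(
            n_samples=200, n_genes=300, module_sizes=(150, 150),
            within_module_cor=0.8, seed=5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expr, _, truth = generate_dataset(params)
        log2 = ExpressionMatrix(
            pd.DataFrame(np.log2(expr.values + 1), index=expr.gene_ids,
                         columns=expr.sample_ids),
            scale="log2",
        )
        return log2, truth

    def test_recovers_planted_two_block_partition(self, tight_two_block):
        log2, truth = tight_two_block
        a = network.detect_modules(log2, network.NetworkConfig())
        assert len(a.module_labels) == 2
        assert adjusted_rand_score(truth.gene_block_labels, a.labels) >= 0.9

    def test_block_below_min_size_goes_grey(self):
        params = SimulationParams(
            n_samples=150, n_genes=200, module_sizes=(40, 120),
            within_module_cor=0.8, seed=3,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expr, _, truth = generate_dataset(params)
            from coexsig.preprocess import filter_missing_transcripts, log2_transform
            log2 = log2_transform(filter_missing_transcripts(expr))
            a = network.detect_modules(log2, network.NetworkConfig(min_module_size=100))
        blocks = pd.Series(truth.gene_block_labels, index=expr.gene_ids).loc[log2.gene_ids]
        small_block = (blocks == 1).to_numpy()
        assert (a.labels[small_block] == 0).all()

    def test_sample_permutation_invariant(self, tight_two_block):
        log2, _ = tight_two_block
        a1 = network.detect_modules(log2, network.NetworkConfig())
        perm = np.random.default_rng(0).permutation(log2.n_samples)
        shuffled = ExpressionMatrix(log2.data.iloc[:, perm], scale="log2")
        a2 = network.detect_modules(shuffled, network.NetworkConfig())
        assert np.array_equal(a1.labels, a2.labels)


class TestEigengenes:
    def test_identical_profiles_give_standardized_common_profile(self):
        profile = np.sin(np.linspace(0, 6, 40))
        em = ExpressionMatrix(
            pd.DataFrame(np.tile(profile, (5, 1)) * np.array([1, 2, 3, 4, 5])[:, None],
                         index=[f"G{i}" for i in range(5)],
                         columns=[f"S{i}" for i in range(40)]),
            scale="log2",
        )
        assignment = network.ModuleAssignment(em.gene_ids, np.ones(5, dtype=int))
        me = network.module_eigengenes(em, assignment)
        expected = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(me.data["M1"].to_numpy(), expected, atol=1e-8)

    def test_variance_explained_matches_eigendecomposition(self, rng):
        X = rng.standard_normal((20, 50)) + 2.0 * rng.standard_normal(50)[None, :]
        em = ExpressionMatrix(
            pd.DataFrame(X, index=[f"G{i}" for i in range(20)],
                         columns=[f"S{i}" for i in range(50)]), scale="log2")
        assignment = network.ModuleAssignment(em.gene_ids, np.ones(20, dtype=int))
        me = network.module_eigengenes(em, assignment)
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        evals = np.linalg.eigvalsh(Xs @ Xs.T)[::-1]
        assert me.variance_explained["M1"] == pytest.approx(evals[0] / evals.sum(), abs=1e-10)

    def test_sign_orientation_makes_gene_flips_unobservable(self, rng):
        X = np.outer(rng.uniform(0.5, 1, 10), rng.standard_normal(30)) \
            + 0.1 * rng.standard_normal((10, 30))
        def me_of(mat):
            em = ExpressionMatrix(
                pd.DataFrame(mat, index=[f"G{i}" for i in range(10)],
                             columns=[f"S{i}" for i in range(30)]), scale="log2")
            a = network.ModuleAssignment(em.gene_ids, np.ones(10, dtype=int))
            return network.module_eigengenes(em, a).data["M1"].to_numpy()
        assert np.allclose(me_of(X), -me_of(-X), atol=1e-8) or np.allclose(
            me_of(X), me_of(-X), atol=1e-8
        )
        # orientation: mean member correlation is positive
        me = me_of(X)
        cors = [np.corrcoef(X[i], me)[0, 1] for i in range(10)]
        assert np.mean(cors) > 0


class TestKmeAndHubs:
    def test_gene_equal_to_eigengene_has_unit_kme(self, small_preprocessed):
        _, log2, *_ = small_preprocessed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = network.detect_modules(log2, network.NetworkConfig(min_module_size=30))
            me = network.module_eigengenes(log2, a)
            spiked = log2.data.copy()
            spiked.iloc[0] = me.data.iloc[:, 0].to_numpy()
            kme = network.kme_table(ExpressionMatrix(spiked, scale="log2"), me)
        assert kme.iloc[0, 0] == pytest.approx(1.0, abs=1e-9)
        assert (kme.abs() <= 1.0 + 1e-12).all().all()

    def test_block_genes_out_kme_background(self, small_preprocessed):
        _, log2, _, _, truth = small_preprocessed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = network.detect_modules(log2, network.NetworkConfig(min_module_size=30))
            me = network.module_eigengenes(log2, a)
            kme = network.kme_table(log2, me)
        labs = pd.Series(truth.gene_block_labels,
                         index=[f"G{i + 1:05d}" for i in range(500)]).loc[log2.gene_ids]
        own = kme.max(axis=1)
        gap = own[labs > 0].median() - own[labs == 0].median()
        assert gap >= 0.3

    @pytest.mark.parametrize("size,expected", [(50, 5), (101, 11), (9, 1)])
    def test_hub_count_is_ceiling_of_top_fraction(self, size, expected, rng):
        genes = [f"G{i:03d}" for i in range(size)]
        kme = pd.DataFrame({"M1": rng.uniform(0.2, 0.9, size)}, index=genes)
        a = network.ModuleAssignment(genes, np.ones(size, dtype=int))
        hubs = network.hub_genes(kme, a)
        assert len(hubs[1]) == expected
        assert set(hubs[1]) <= set(genes)
        top = kme["M1"].sort_values(ascending=False).head(expected)
        assert set(hubs[1]) == set(top.index)


class TestModuleTraitCorrelation:
    def test_me_against_itself(self, small_preprocessed):
        _, log2, _, traits, _ = small_preprocessed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = network.detect_modules(log2, network.NetworkConfig(min_module_size=30))
            me = network.module_eigengenes(log2, a)
            t = traits.copy()
            t["self"] = me.data.iloc[:, 0]
            mt = network.module_trait_correlation(me, t)
        assert mt.bicor.loc[me.module_names[0], "self"] == pytest.approx(1.0, abs=1e-9)
        assert mt.p.loc[me.module_names[0], "self"] == 0.0

    def test_constant_trait_gives_null_cell(self, small_preprocessed):
        _, log2, _, traits, _ = small_preprocessed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = network.detect_modules(log2, network.NetworkConfig(min_module_size=30))
            me = network.module_eigengenes(log2, a)
            t = traits.copy()
            t["flat"] = 1.0
            mt = network.module_trait_correlation(me, t)
        assert mt.bicor["flat"].isna().all()

    def test_eigengenes_track_planted_block_factors(self, small_preprocessed):
        """Each detected eigengene is essentially a combination of its
        block's malignancy and co-regulation factors (high multiple
        correlation), and correlates significantly with the malignancy
        factor alone."""
        _, log2, _, traits, truth = small_preprocessed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = network.detect_modules(log2, network.NetworkConfig(min_module_size=30))
            me = network.module_eigengenes(log2, a)
            keep = np.array([s in set(log2.sample_ids) for s in
                             (f"S{i + 1:04d}" for i in range(160))])
            t = traits.copy()
            t["f1"] = truth.latent_factors[keep, 0]
            mt = network.module_trait_correlation(me, t)
        assert mt.p["f1"].min() < 1e-3
        best = float(mt.bicor["f1"].abs().max())
        # multiple correlation of that ME on the factor pair
        which = mt.bicor["f1"].abs().idxmax()
        y = me.data[which].to_numpy()
        X = np.column_stack([
            np.ones(keep.sum()),
            truth.latent_factors[keep, 0],
            truth.coreg_factors[keep, 0],
            truth.latent_factors[keep, 1],
            truth.coreg_factors[keep, 1],
        ])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r2 = 1 - resid.var() / y.var()
        assert r2 >= 0.8
        assert best >= 0.3


class TestModuleOverlapFisher:
    def test_identical_labelings_diagonal_dominates(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(200)]
        labels = pd.Series(rng.integers(1, 4, 200), index=genes)
        p = network.module_overlap_fisher(labels, labels)
        diag = np.diag(p.to_numpy())
        off = p.to_numpy()[~np.eye(3, dtype=bool)]
        assert diag.max() < off.min()

    def test_two_by_two_oracle(self):
        # universe 20, module A of 5, module B of 5, overlap 3
        genes = [f"G{i}" for i in range(20)]
        a = pd.Series(0, index=genes)
        b = pd.Series(0, index=genes)
        a.iloc[:5] = 1
        b.iloc[2:7] = 1
        p = network.module_overlap_fisher(a, b)
        expected = sum(
            stats.hypergeom.pmf(k, 20, 5, 5) for k in range(3, 6)
        )
        assert p.iloc[0, 0] == pytest.approx(expected, abs=1e-12)  # single cell, BH no-op

    def test_random_labelings_rarely_significant(self):
        genes = [f"G{i}" for i in range(300)]
        passes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = pd.Series(rng.integers(1, 4, 300), index=genes)
            b = pd.Series(rng.permutation(a.to_numpy()), index=genes)
            p = network.module_overlap_fisher(a, b)
            passes += p.to_numpy().min() > 0.01
        assert passes >= 18

    def test_disjoint_universes_rejected(self):
        a = pd.Series([1, 1], index=["G1", "G2"])
        b = pd.Series([1, 1], index=["G3", "G4"])
        with pytest.raises(ValueError, match="universe"):
            network.module_overlap_fisher(a, b)
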