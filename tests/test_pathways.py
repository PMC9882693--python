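import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainscape.matrix import ExpressionMatrix
from brainscape.pathways import (
    GeneSetCollection,
    PathwayScoreMatrix,
    fit_f_dist,
    moderated_t_test,
    read_gmt,
    score_samples,
    shared_regulated,
)


def em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i:04d}" for i in range(values.shape[0])]
    samples = samples or [f"s{j:02d}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), "log2TPM_corrected"
    )


class TestGmt:
    def test_duplicate_genes_collapsed(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\tdesc\tA\tB\tA\n")
        coll = read_gmt(p)
        assert coll.sets == {"S1": ("A", "B")}

    def test_empty_file_empty_collection(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("")
        assert len(read_gmt(p)) == 0

    def test_blank_lines_skipped(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\td\tA\tB\n\n\nS2\td\tC\tD\n")
        assert set(read_gmt(p).sets) == {"S1", "S2"}

    def test_duplicate_set_name_rejected_with_line(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\td\tA\tB\nS1\td\tC\tD\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(p)

    def test_short_line_rejected_with_line(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\td\tA\nS2\tdesc-only\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(p)


class TestScoreSamples:
    def test_top_expressed_set_scores_positive(self, rng):
        x = rng.normal(5, 2, (200, 1))
        m = em(x)
        top = list(m.values.iloc[:, 0].nlargest(10).index)
        coll = GeneSetCollection({"TOP": tuple(top)})
        out = score_samples(m, coll)
        score = out.scores.iloc[0, 0]
        assert 0 < score <= 1

    def test_bottom_expressed_set_scores_negative(self, rng):
        m = em(rng.normal(5, 2, (200, 1)))
        bottom = list(m.values.iloc[:, 0].nsmallest(10).index)
        out = score_samples(m, GeneSetCollection({"BOT": tuple(bottom)}))
        assert -1 <= out.scores.iloc[0, 0] < 0

    def test_rank_symmetric_set_scores_near_zero(self):
        # genes placed symmetrically about the rank median cancel out
        n = 1000
        vals = np.arange(1, n + 1, dtype=float)[:, None]
        m = em(vals)
        genes = m.gene_ids
        sym = tuple(genes[i] for i in (99, n - 100, 299, n - 300, 449, n - 450))
        out = score_samples(m, GeneSetCollection({"SYM": sym}))
        assert abs(out.scores.iloc[0, 0]) < 0.05

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.uniform(1, 9, (150, 4))
        coll = GeneSetCollection(
            {"S": tuple(f"g{i:04d}" for i in range(10, 30))}
        )
        a = score_samples(em(x), coll).scores
        b = score_samples(em(np.exp(x / 2)), coll).scores
        pd.testing.assert_frame_equal(a, b)

    def test_invariant_to_gene_order_permutation(self, rng):
        x = rng.uniform(1, 9, (100, 3))
        m = em(x)
        coll = GeneSetCollection({"S": tuple(m.gene_ids[5:25])})
        perm = rng.permutation(100)
        m2 = ExpressionMatrix(m.values.iloc[perm], "log2TPM_corrected")
        pd.testing.assert_frame_equal(
            score_samples(m, coll).scores, score_samples(m2, coll).scores
        )

    def test_scores_bounded(self, rng):
        x = rng.normal(0, 3, (300, 6))
        sets = {f"S{i}": tuple(
            np.random.default_rng(i).choice([f"g{j:04d}" for j in range(300)],
                                            20, replace=False))
            for i in range(15)}
        out = score_samples(em(x), GeneSetCollection(sets))
        v = out.scores.to_numpy()
        assert v.min() >= -1 and v.max() <= 1

    def test_signature_set_separates_subtypes(self, corrected_small):
        corrected, meta, truth, _ = corrected_small
        name = "astrocytoma"
        coll = GeneSetCollection(
            {"SIG": tuple(truth.signature_genes[name])}
        )
        out = score_samples(corrected, coll)
        scores = out.scores.loc["SIG"]
        own = meta.table["subtype"] == name
        assert scores[own.to_numpy()].mean() > scores[(~own).to_numpy()].mean()

    def test_size_filters_drop_and_log(self, rng):
        m = em(rng.normal(0, 1, (50, 2)))
        coll = GeneSetCollection({
            "SMALL": tuple(m.gene_ids[:3]),
            "OK": tuple(m.gene_ids[:10]),
        })
        out = score_samples(m, coll, min_size=5, max_size=20)
        assert list(out.scores.index) == ["OK"]
        assert "SMALL" in out.dropped_sets

    def test_set_below_two_genes_in_matrix_rejected(self, rng):
        m = em(rng.normal(0, 1, (20, 2)))
        coll = GeneSetCollection({"ONE": (m.gene_ids[0], "absent_gene")})
        with pytest.raises(ValueError, match="< 2 genes"):
            score_samples(m, coll, min_size=1)


def modt_fixture():
    """Seeded heteroscedastic two-group fixture, scaled into [-1, 1].

    The scaling leaves t, p and the prior df invariant, so the frozen
    reference values below (computed with R limma lmFit/eBayes on the
    unscaled fixture) apply directly.
    """
    rng = np.random.default_rng(12345)
    sds = rng.uniform(0.5, 2.0, 50)
    x = rng.normal(0, 1, (50, 12)) * sds[:, None]
    x[:5, 6:] += 1.0
    scores = pd.DataFrame(
        x / 10.0,
        index=[f"S{i:02d}" for i in range(50)],
        columns=[f"a{j}" for j in range(6)] + [f"b{j}" for j in range(6)],
    )
    groups = pd.Series(["A"] * 6 + ["B"] * 6, index=scores.columns)
    return PathwayScoreMatrix(scores, method="rank_ks"), groups


LIMMA_D0 = 3.993397348
LIMMA_S02 = 1.07371931  # on the unscaled fixture; scales by 1/100 here
LIMMA_ROWS = {  # row index -> (moderated t, p)
    "S00": (1.161731228, 0.2647774171),
    "S01": (2.256958145, 0.04052680683),
    "S02": (0.4924034135, 0.6300697098),
    "S24": (-0.7556610554, 0.4623837205),
    "S49": (-0.3950405215, 0.6987690744),
}


class TestModeratedT:
    def test_matches_limma_reference_values(self):
        scores, groups = modt_fixture()
        res = moderated_t_test(scores, groups)
        assert res.attrs["d0"] == pytest.approx(LIMMA_D0, rel=1e-6)
        assert res.attrs["s0_2"] * 100 == pytest.approx(LIMMA_S02, rel=1e-6)
        for name, (t, p) in LIMMA_ROWS.items():
            assert res.loc[name, "moderated_t"] == pytest.approx(t, rel=1e-6)
            assert res.loc[name, "p_value"] == pytest.approx(p, rel=1e-6)

    def test_d0_zero_recovers_pooled_t(self):
        scores, groups = modt_fixture()
        res = moderated_t_test(scores, groups, d0=0.0)
        x = scores.scores
        a = x[groups.index[groups == "A"]].to_numpy()
        b = x[groups.index[groups == "B"]].to_numpy()
        t_ref, _ = stats.ttest_ind(b, a, axis=1)
        np.testing.assert_allclose(res["moderated_t"].to_numpy(), t_ref,
                                   atol=1e-10)

    def test_identical_variances_give_degenerate_prior(self, rng):
        # every set has exactly the same sample variance: s0^2 equals it and
        # the posterior variance equals the observed one for every set
        base = rng.normal(0, 0.1, 12)
        x = np.tile(base, (30, 1))
        x += rng.normal(0, 0.05, (30, 1))  # distinct means, same spread
        scores = PathwayScoreMatrix(
            pd.DataFrame(x, index=[f"S{i}" for i in range(30)],
                         columns=[f"c{j}" for j in range(12)]),
            method="rank_ks")
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=scores.scores.columns)
        res = moderated_t_test(scores, groups)
        s2 = scores.scores.iloc[0][:6].var() * 0 + x[0, :].var(ddof=1)
        assert np.isinf(res.attrs["d0"])
        res0 = moderated_t_test(scores, groups, d0=0.0)
        np.testing.assert_allclose(res["moderated_t"].abs().to_numpy().max(),
                                   res0["moderated_t"].abs().to_numpy().max(),
                                   rtol=0.2)

    def test_large_d0_shrinks_every_variance_to_prior(self):
        scores, groups = modt_fixture()
        res = moderated_t_test(scores, groups, d0=1e8)
        x = scores.scores
        a = x[groups.index[groups == "A"]].to_numpy()
        b = x[groups.index[groups == "B"]].to_numpy()
        diff = b.mean(axis=1) - a.mean(axis=1)
        s0_2 = res.attrs["s0_2"]
        t_expect = diff / np.sqrt(s0_2 * (1 / 6 + 1 / 6))
        np.testing.assert_allclose(res["moderated_t"].to_numpy(), t_expect,
                                   rtol=1e-4)

    def test_bh_adjustment_properties(self):
        scores, groups = modt_fixture()
        res = moderated_t_test(scores, groups).sort_values("p_value")
        assert (res["adj_p_value"] >= res["p_value"] - 1e-15).all()
        assert res["adj_p_value"].iloc[-1] == pytest.approx(
            res["p_value"].iloc[-1])
        assert res["adj_p_value"].is_monotonic_increasing
        assert res["adj_p_value"].between(0, 1).all()

    def test_three_group_labels_rejected(self):
        scores, groups = modt_fixture()
        bad = groups.copy()
        bad.iloc[0] = "C"
        with pytest.raises(ValueError, match="2 group levels"):
            moderated_t_test(scores, bad)

    def test_tiny_group_rejected(self):
        scores, groups = modt_fixture()
        g = groups[groups.index[:7]]  # 6 A, 1 B
        with pytest.raises(ValueError, match="at least 2"):
            moderated_t_test(scores, g)


class TestSharedRegulated:
    def _table(self, names, sig_up=(), sig_down=()):
        rows = []
        for n in names:
            if n in sig_up:
                rows.append((0.5, 4.0, 1e-5, 1e-4, "up"))
            elif n in sig_down:
                rows.append((-0.5, -4.0, 1e-5, 1e-4, "down"))
            else:
                rows.append((0.01, 0.1, 0.9, 0.95, "up"))
        return pd.DataFrame(
            rows, index=names,
            columns=["mean_diff", "moderated_t", "p_value", "adj_p_value",
                     "direction"])

    def test_identical_tables_intersection_is_each(self):
        names = [f"S{i}" for i in range(10)]
        t = self._table(names, sig_up=("S1", "S3"))
        shared, counts = shared_regulated([t, t.copy()], 0.05, "up")
        assert shared == {"S1", "S3"}
        assert counts["intersection"] == 2

    def test_disjoint_significant_sets_empty(self):
        names = [f"S{i}" for i in range(6)]
        a = self._table(names, sig_up=("S0",))
        b = self._table(names, sig_up=("S5",))
        shared, _ = shared_regulated([a, b], 0.05, "up")
        assert shared == set()

    def test_direction_respected(self):
        names = [f"S{i}" for i in range(4)]
        a = self._table(names, sig_down=("S0",))
        b = self._table(names, sig_down=("S0",))
        assert shared_regulated([a, b], 0.05, "down")[0] == {"S0"}
        assert shared_regulated([a, b], 0.05, "up")[0] == set()

    def test_mismatched_collections_rejected(self):
        a = self._table(["S0", "S1"])
        b = self._table(["S0", "S2"])
        with pytest.raises(ValueError, match="different"):
            shared_regulated([a, b])

    def test_single_table_rejected(self):
        with pytest.raises(ValueError, match="two"):
            shared_regulated([self._table(["S0"])])


class TestPlantedRecovery:
    def test_shared_up_pathways_recovered_across_contrasts(self):
        # three contrasts share 30 planted up-regulated sets among 200;
        # the intersection at BH 0.05 recovers nearly all of them
        rng = np.random.default_rng(42)
        names = [f"S{i:03d}" for i in range(200)]
        shared_up = set(names[:30])
        recovered = []
        tables = []
        for c in range(3):
            private_up = set(names[30 + 20 * c: 50 + 20 * c])
            x = rng.normal(0, 0.15, (200, 40))
            for i, nm in enumerate(names):
                if nm in shared_up or nm in private_up:
                    x[i, 20:] += 0.3
            scores = PathwayScoreMatrix(
                pd.DataFrame(x, index=names,
                             columns=[f"c{j:02d}" for j in range(40)]),
                method="rank_ks")
            groups = pd.Series(["A"] * 20 + ["B"] * 20,
                               index=scores.scores.columns)
            tables.append(moderated_t_test(scores, groups))
        got, counts = shared_regulated(tables, 0.05, "up")
        assert len(got & shared_up) >= 28
        assert counts["intersection"] >= 28

    def test_signature_set_separates_in_every_seeded_run(self):
        # across 20 independent simulations the subtype's signature set
        # scores higher in its own subtype every time
        from brainscape import simulate_cohorts
        from brainscape import harmonize as hz
        from conftest import small_config

        wins = 0
        for seed in range(20):
            cfg = small_config(seed=seed, samples_per_cohort_per_subtype=15,
                               n_genes=300)
            mats, meta, _, truth = simulate_cohorts(cfg)
            logged = [hz.log_transform(hz.fpkm_to_tpm(m)) for m in mats]
            combined = logged[0].copy_with(
                pd.concat([m.values for m in logged], axis=1), "log2TPM")
            coll = GeneSetCollection(
                {"SIG": tuple(truth.signature_genes["astrocytoma"])})
            scores = score_samples(combined, coll).scores.loc["SIG"]
            own = (meta.table["subtype"] == "astrocytoma").to_numpy()
            wins += scores[own].mean() > scores[~own].mean()
        assert wins == 20


def test_fit_f_dist_recovers_known_prior():
    # variances drawn from s0^2 * chi2_d / d around a known prior spread
    rng = np.random.default_rng(8)
    d, d0, s02 = 10, 6.0, 2.0
    prior = s02 * d0 / stats.chi2.rvs(d0, size=4000, random_state=rng)
    s2 = prior * stats.chi2.rvs(d, size=4000, random_state=rng) / d
    d0_hat, s02_hat = fit_f_dist(s2, d)
    assert d0_hat == pytest.approx(d0, rel=0.15)
    assert s02_hat == pytest.approx(s02, rel=0.10)
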