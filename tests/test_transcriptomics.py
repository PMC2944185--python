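"""Expression analysis: Ward/1-Pearson clustering vs R hclust, centroid
classifier behavior, moderated t vs Bioconductor limma, DE selection and
hypergeometric enrichment against a rational oracle."""

import subprocess
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from glioprofile.io_formats import GeneSetCollection
from glioprofile.transcriptomics import (build_centroid_classifier,
                                         classify_by_centroid, collapse_to_genes,
                                         filter_de, hypergeometric_enrichment,
                                         moderated_t_test, select_top_genes,
                                         ward_pearson_cluster)


def _rscript(tmp_path, code: str) -> None:
    script = tmp_path / "oracle.R"
    script.write_text(code)
    subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                   capture_output=True, text=True, cwd=tmp_path)


class TestWardPearson:
    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(0)
        e = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        e["d"] = e["b"]
        labels, merges = ward_pearson_cluster(e, 2)
        assert sorted(merges[0][:2]) == [1.0, 3.0]   # b and d
        assert merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_k_equals_n_singletons(self):
        rng = np.random.default_rng(1)
        e = pd.DataFrame(rng.normal(size=(20, 6)))
        labels, _ = ward_pearson_cluster(e, 6)
        assert sorted(labels) == list(range(6))

    def test_zero_variance_sample_rejected(self):
        e = pd.DataFrame(np.ones((10, 3)), columns=["a", "b", "c"])
        e["a"] = np.arange(10)
        with pytest.raises(ValueError, match="b"):
            ward_pearson_cluster(e, 2)

    def test_matches_r_hclust_ward_d(self, tmp_path):
        rng = np.random.default_rng(42)
        n = 12
        centers = np.repeat(np.eye(3), [4, 4, 4], axis=0).T
        X = np.repeat(centers, 10, axis=0) * 2 + rng.normal(size=(30, n))
        expr = pd.DataFrame(X, columns=[f"s{i}" for i in range(n)])
        expr.to_csv(tmp_path / "x.csv")
        _rscript(tmp_path, """
x <- as.matrix(read.csv("x.csv", row.names = 1))
d <- as.dist(1 - cor(x))
h <- hclust(d, method = "ward.D")
write.csv(data.frame(height = h$height), "heights.csv", row.names = FALSE)
write.csv(data.frame(cl = cutree(h, k = 3)), "cut.csv")
""")
        labels, merges = ward_pearson_cluster(expr, 3)
        r_heights = pd.read_csv(tmp_path / "heights.csv")["height"].to_numpy()
        assert np.allclose(np.sort(merges[:, 2]), np.sort(r_heights),
                           atol=1e-8)
        r_cut = pd.read_csv(tmp_path / "cut.csv", index_col=0)["cl"]
        # same partition up to label permutation
        ours = labels.to_numpy()
        theirs = r_cut.loc[labels.index].to_numpy()
        mapping = {}
        for a, b in zip(ours, theirs):
            assert mapping.setdefault(a, b) == b
        assert len(set(mapping.values())) == 3


class TestCentroidClassifier:
    def _archetypes(self, noise=0.0, n_per_class=4, seed=0):
        rng = np.random.default_rng(seed)
        probes = [f"P{i}" for i in range(60)]
        classes = ["c1", "c2", "c3"]
        cols, labels = {}, {}
        base = rng.normal(7, 1, size=60)
        for c, cls in enumerate(classes):
            pattern = base.copy()
            pattern[c * 20:(c + 1) * 20] += 2.0
            for i in range(n_per_class):
                sid = f"{cls}_{i}"
                cols[sid] = pattern + rng.normal(0, noise, 60)
                labels[sid] = cls
        return (pd.DataFrame(cols, index=probes), pd.Series(labels))

    def test_noiseless_self_reclassification_perfect(self):
        expr, labels = self._archetypes(noise=0.0)
        model = build_centroid_classifier(expr, labels)
        pred = classify_by_centroid(model, expr)
        assert (pred["class"] == labels).all()

    def test_accuracy_at_half_effect_noise(self):
        expr, labels = self._archetypes(noise=1.0, n_per_class=10, seed=3)
        model = build_centroid_classifier(expr, labels)
        pred = classify_by_centroid(model, expr)
        assert (pred["class"] == labels).mean() >= 0.90

    def test_probe_permutation_invariance(self):
        expr, labels = self._archetypes(noise=0.3)
        model = build_centroid_classifier(expr, labels)
        rng = np.random.default_rng(1)
        shuffled = expr.iloc[rng.permutation(len(expr))]
        model2 = build_centroid_classifier(shuffled, labels)
        pd.testing.assert_frame_equal(
            model.centroids.sort_index(), model2.centroids.sort_index())

    def test_anticorrelated_cohort_never_keeps_own_class(self):
        # negating the cohort negates its z-scores, so each sample becomes
        # anti-correlated with its own centroid and must switch class
        expr, labels = self._archetypes(noise=0.0)
        model = build_centroid_classifier(expr, labels)
        pred = classify_by_centroid(model, -expr)
        assert (pred["class"] != labels).all()

    def test_small_class_rejected(self):
        expr, labels = self._archetypes()
        labels = labels.copy()
        labels.iloc[0] = "tiny"
        with pytest.raises(ValueError, match="tiny"):
            build_centroid_classifier(expr, labels)

    def test_insufficient_probe_overlap_rejected(self):
        expr, labels = self._archetypes()
        model = build_centroid_classifier(expr, labels)
        with pytest.raises(ValueError, match="50%"):
            classify_by_centroid(model, expr.iloc[:20])


class TestModeratedT:
    def _two_group(self, n_genes=200, n1=6, n2=6, seed=0, effect=None):
        rng = np.random.default_rng(seed)
        cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        X = rng.normal(7, 0.5, size=(n_genes, n1 + n2))
        if effect:
            k, size = effect
            X[:k, :n1] += size
        expr = pd.DataFrame(X, index=[f"G{i:04d}" for i in range(n_genes)],
                            columns=cols)
        groups = pd.Series(["A"] * n1 + ["B"] * n2, index=cols)
        return expr, groups

    def test_equal_means_zero_t_unit_p(self):
        expr, groups = self._two_group(n_genes=10)
        expr.iloc[0] = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], 2)
        res, _ = moderated_t_test(expr, groups)
        row = res.loc["G0000"]
        assert row["t_mod"] == 0.0 and row["p_value"] == 1.0

    def test_label_swap_negates_t(self):
        expr, groups = self._two_group(seed=2)
        r1, _ = moderated_t_test(expr, groups, contrast=("A", "B"))
        r2, _ = moderated_t_test(expr, groups, contrast=("B", "A"))
        r2 = r2.loc[r1.index]
        assert np.allclose(r1["t_mod"], -r2["t_mod"])
        assert np.allclose(r1["p_value"], r2["p_value"])

    def test_gene_order_invariance(self):
        expr, groups = self._two_group(seed=3)
        r1, _ = moderated_t_test(expr, groups)
        r2, _ = moderated_t_test(expr.iloc[::-1], groups)
        pd.testing.assert_frame_equal(r1, r2.loc[r1.index])

    def test_identical_variances_reduce_to_pooled_t(self):
        from scipy import stats as sps
        expr, groups = self._two_group(n_genes=40, seed=4)
        X = expr.to_numpy()
        A, B = X[:, :6], X[:, 6:]
        ss = ((A - A.mean(1, keepdims=True)) ** 2).sum(1) + \
             ((B - B.mean(1, keepdims=True)) ** 2).sum(1)
        X = (X - X.mean(1, keepdims=True)) / np.sqrt(ss / ss[0])[:, None] + 7
        expr2 = pd.DataFrame(X, index=expr.index, columns=expr.columns)
        res, fit = moderated_t_test(expr2, groups)
        assert np.isinf(fit.d0)
        t_ref, _ = sps.ttest_ind(X[:, :6].T, X[:, 6:].T)
        assert np.allclose(res.loc[expr.index, "t_mod"], t_ref, atol=1e-10)

    def test_null_type_one_error_calibrated(self):
        expr, groups = self._two_group(n_genes=2000, n1=10, n2=10, seed=11)
        res, _ = moderated_t_test(expr, groups)
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.04 <= frac <= 0.06

    def test_matches_limma_oracle(self, tmp_path):
        expr, groups = self._two_group(n_genes=150, seed=6,
                                       effect=(20, 1.0))
        expr.to_csv(tmp_path / "x.csv")
        _rscript(tmp_path, """
suppressMessages(library(limma))
x <- as.matrix(read.csv("x.csv", row.names = 1))
group <- c(rep(1, 6), rep(0, 6))
design <- cbind(Intercept = 1, AvsB = group)
fit <- eBayes(lmFit(x, design))
out <- data.frame(t = fit$t[, "AvsB"], p = fit$p.value[, "AvsB"])
write.csv(out, "limma.csv")
cat(fit$df.prior, fit$s2.prior, file = "prior.txt")
""")
        res, fit = moderated_t_test(expr, groups, contrast=("A", "B"))
        limma = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        d0_r, s0_r = map(float, (tmp_path / "prior.txt").read_text().split())
        assert fit.d0 == pytest.approx(d0_r, rel=1e-4)
        assert fit.s0_sq == pytest.approx(s0_r, rel=1e-4)
        merged = res.join(limma, how="inner")
        assert np.allclose(merged["t_mod"], merged["t"], rtol=1e-4)
        assert np.allclose(merged["p_value"], merged["p"], rtol=1e-4)

    def test_small_group_rejected(self):
        expr, groups = self._two_group(n1=1, n2=6)
        with pytest.raises(ValueError, match="at least 2"):
            moderated_t_test(expr, groups)


class TestSelectionAndFilter:
    def _de_frame(self, n_pos, n_neg, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_pos + n_neg):
            delta = 1.0 if i < n_pos else -1.0
            rows.append({"delta": delta, "fc": 2.0 ** delta,
                         "p_value": rng.uniform(),
                         "direction": "up_in_A" if delta > 0 else "up_in_B"})
        return pd.DataFrame(rows, index=[f"P{i:04d}" for i in
                                         range(n_pos + n_neg)])

    def test_full_split_and_disjoint(self):
        de = self._de_frame(500, 500)
        up_a, up_b = select_top_genes(de, 500)
        assert len(up_a) == 500 and len(up_b) == 500
        assert not set(up_a) & set(up_b)

    def test_short_side_returned_with_warning(self):
        de = self._de_frame(300, 600)
        with pytest.warns(UserWarning, match="300"):
            up_a, _ = select_top_genes(de, 500)
        assert len(up_a) == 300

    def test_filter_examples(self):
        de = pd.DataFrame({
            "delta": [0.678, 0.263, -0.8],
            "fc": [1.6, 1.2, 2 ** -0.8],
            "p_value": [0.04, 0.04, 0.01],
            "direction": ["up_in_A", "up_in_A", "up_in_B"],
        }, index=["g1", "g2", "g3"])
        out = filter_de(de, p_max=0.05, fc_min=1.5)
        assert out["lists"]["up_in_A"] == ["g1"]      # g2 fails fold change
        assert out["lists"]["up_in_B"] == ["g3"]      # 1/fc = 1.74 > 1.5
        assert out["counts"] == {"up_in_A": 1, "up_in_B": 1}

    def test_planted_two_fold_power(self):
        rng = np.random.default_rng(8)
        n1 = n2 = 15
        cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        X = rng.normal(7, 0.5, size=(1000, n1 + n2))
        X[:100, :n1] += 1.0   # 100 true 2-fold genes
        expr = pd.DataFrame(X, index=[f"G{i:04d}" for i in range(1000)],
                            columns=cols)
        groups = pd.Series(["A"] * n1 + ["B"] * n2, index=cols)
        res, _ = moderated_t_test(expr, groups, contrast=("A", "B"))
        out = filter_de(res)
        hits = set(out["lists"].get("up_in_A", []))
        assert len(hits & {f"G{i:04d}" for i in range(100)}) >= 90


class TestEnrichment:
    def test_exact_small_example(self):
        sets = GeneSetCollection({"S": frozenset("ABCDE")},
                                 universe=frozenset("ABCDEFGHIJ"))
        table = hypergeometric_enrichment(list("ABCDE"), sets)
        assert table["p_value"].iloc[0] == pytest.approx(1 / 252)

    def test_zero_overlap_and_universe_set(self):
        sets = GeneSetCollection({"S": frozenset("AB"),
                                  "U": frozenset("ABCDEF")},
                                 universe=frozenset("ABCDEF"))
        table = hypergeometric_enrichment(list("CD"), sets).set_index("set")
        assert table.loc["S", "p_value"] == 1.0
        assert table.loc["U", "p_value"] == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(40)]
        sets = GeneSetCollection(
            {f"S{j}": frozenset(rng.choice(universe, size=8, replace=False))
             for j in range(5)},
            universe=frozenset(universe))
        gene_list = list(rng.choice(universe, size=12, replace=False))
        table = hypergeometric_enrichment(gene_list, sets).set_index("set")
        for name, members in sets.sets.items():
            k = len(members & set(gene_list))
            exact = sum(Fraction(comb(8, i) * comb(32, 12 - i), comb(40, 12))
                        for i in range(k, 9))
            assert table.loc[name, "p_value"] == pytest.approx(float(exact),
                                                               rel=1e-12)

    def test_gene_outside_universe_rejected(self):
        sets = GeneSetCollection({"S": frozenset("AB")},
                                 universe=frozenset("ABC"))
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_enrichment(["Z"], sets)

    def test_collapse_picks_highest_variance_probe(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(4, 6)),
                            index=["p1", "p2", "p3", "p4"])
        expr.loc["p2"] *= 5.0
        genes = pd.Series(["gA", "gA", "gB", "gB"], index=expr.index)
        rep = collapse_to_genes(expr, genes)
        assert rep["gA"] == "p2"
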