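"""Cluster assignment and cosine-similarity summaries vs brute force."""

import numpy as np
import pandas as pd
import pytest

from spectraqsar import (
    ClusterAssignment,
    assign_clusters,
    class_composition,
    cosine_similarity,
    similarity_summary,
)


class TestCosine:
    def test_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_analytic_half(self):
        u, v = np.array([1.0, 0.0, 1.0]), np.array([1.0, 1.0, 0.0])
        assert cosine_similarity(u, v) == pytest.approx(0.5)

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestAssign:
    def test_file_passthrough(self, tmp_path):
        path = tmp_path / "labels.csv"
        pd.DataFrame(
            {"compound_id": ["A", "B", "C"], "cluster_id": [1, 1, 2]}
        ).to_csv(path, index=False)
        asg = assign_clusters(pd.DataFrame(), mode="file", label_file=path)
        assert asg.labels == {"A": 1, "B": 1, "C": 2}

    def test_kmeans_recovers_separated_clouds(self, rng):
        a = rng.normal(loc=0.0, scale=0.1, size=(20, 2))
        b = rng.normal(loc=50.0, scale=0.1, size=(20, 2))
        emb = pd.DataFrame(
            np.vstack([a, b]), index=[f"P{i}" for i in range(40)]
        )
        asg = assign_clusters(emb, mode="kmeans", k=2, seed=0)
        first = {asg.labels[f"P{i}"] for i in range(20)}
        second = {asg.labels[f"P{i}"] for i in range(20, 40)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_kmeans_deterministic(self, rng):
        emb = pd.DataFrame(rng.normal(size=(30, 2)), index=[f"P{i}" for i in range(30)])
        a = assign_clusters(emb, mode="kmeans", k=3, seed=7)
        b = assign_clusters(emb, mode="kmeans", k=3, seed=7)
        assert a.labels == b.labels

    def test_k_exceeding_n_errors(self, rng):
        emb = pd.DataFrame(rng.normal(size=(3, 2)), index=list("abc"))
        with pytest.raises(ValueError, match="exceeds"):
            assign_clusters(emb, mode="kmeans", k=5, seed=0)


def brute_force_summary(frame, labels):
    ids = list(frame.index)
    within, cross = {}, {}
    clusters = sorted(set(labels.values()))
    for a in clusters:
        members = [i for i in ids if labels[i] == a]
        vals = [
            cosine_similarity(frame.loc[m1].to_numpy(), frame.loc[m2].to_numpy())
            for x, m1 in enumerate(members)
            for m2 in members[x + 1 :]
        ]
        within[a] = float(np.mean(vals)) if vals else float("nan")
        for b in clusters:
            if b <= a:
                continue
            others = [i for i in ids if labels[i] == b]
            cvals = [
                cosine_similarity(frame.loc[m].to_numpy(), frame.loc[o].to_numpy())
                for m in members
                for o in others
            ]
            cross[(a, b)] = float(np.mean(cvals))
    return within, cross


class TestSummary:
    def test_identical_rows_within_one(self):
        frame = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        asg = ClusterAssignment(labels={"a": 1, "b": 1}, source="file")
        summary = similarity_summary(frame, asg)
        assert summary.within[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(6, 51))
        frame = pd.DataFrame(
            rng.normal(size=(n, 12)), index=[f"c{i}" for i in range(n)]
        )
        labels = {f"c{i}": int(rng.integers(1, 4)) for i in range(n)}
        if len(set(labels.values())) < 2:
            labels["c0"] = 1
            labels["c1"] = 2
        asg = ClusterAssignment(labels=labels, source="file")
        summary = similarity_summary(frame, asg)
        within, cross = brute_force_summary(frame, labels)
        for c, val in within.items():
            if np.isnan(val):
                assert np.isnan(summary.within[c])
            else:
                assert abs(summary.within[c] - val) < 1e-12
        for (a, b), val in cross.items():
            assert abs(summary.between.loc[a, b] - val) < 1e-12
            assert abs(summary.between.loc[b, a] - val) < 1e-12

    def test_permutation_invariance(self, rng):
        frame = pd.DataFrame(
            rng.normal(size=(15, 6)), index=[f"c{i}" for i in range(15)]
        )
        labels = {f"c{i}": 1 + i % 3 for i in range(15)}
        asg = ClusterAssignment(labels=labels, source="file")
        base = similarity_summary(frame, asg)
        perm = frame.sample(frac=1.0, random_state=1)
        shuffled = similarity_summary(perm, asg)
        for c in base.within:
            assert base.within[c] == pytest.approx(shuffled.within[c], abs=1e-12)

    def test_ri_column_excluded(self, rng):
        data = rng.normal(size=(8, 5))
        frame = pd.DataFrame(data, index=[f"c{i}" for i in range(8)],
                             columns=["mz_50", "mz_51", "mz_52", "mz_53", "RI"])
        labels = {f"c{i}": 1 + i % 2 for i in range(8)}
        asg = ClusterAssignment(labels=labels, source="file")
        with_ri = similarity_summary(frame, asg)
        without = similarity_summary(frame.drop(columns=["RI"]), asg)
        for c in with_ri.within:
            assert with_ri.within[c] == pytest.approx(without.within[c], abs=1e-12)

    def test_per_class_within(self, rng):
        frame = pd.DataFrame(rng.normal(size=(10, 4)),
                             index=[f"c{i}" for i in range(10)])
        labels = {f"c{i}": 1 for i in range(10)}
        classes = {f"c{i}": "A" if i < 5 else "B" for i in range(10)}
        asg = ClusterAssignment(labels=labels, source="file")
        summary = similarity_summary(frame, asg, classes)
        assert set(summary.per_class_within) == {"A", "B"}


class TestComposition:
    def test_fractions_and_dominant(self):
        asg = ClusterAssignment(
            labels={"a": 1, "b": 1, "c": 1, "d": 1}, source="file"
        )
        classes = {"a": "Benzenoids", "b": "Benzenoids", "c": "Benzenoids", "d": "Lipids"}
        table = class_composition(asg, classes)
        benz = table[(table.cluster_id == 1) & (table["class"] == "Benzenoids")]
        assert benz.fraction.iloc[0] == pytest.approx(0.75)
        assert bool(benz.dominant.iloc[0])

    def test_unlabeled_cluster_omitted(self):
        asg = ClusterAssignment(labels={"a": 1, "b": 2}, source="file")
        table = class_composition(asg, {"a": "Benzenoids"})
        assert set(table.cluster_id) == {1}

    def test_fractions_sum_to_one_per_cluster(self, small_dataset):
        ids = small_dataset.ids()
        asg = ClusterAssignment(
            labels={cid: 1 + i % 4 for i, cid in enumerate(ids)}, source="file"
        )
        classes = {r.compound_id: r.class_labels["superclass"] for r in small_dataset}
        table = class_composition(asg, classes)
        sums = table.groupby("cluster_id").fraction.sum()
        assert np.allclose(sums, 1.0)


def test_pipeline_within_exceeds_between(small_dataset):
    """Mixed-scaffold corpus: spectra are alike inside map clusters only."""
    from spectraqsar import TSNEConfig, build_analytical_matrix, fit_tsne

    std = build_analytical_matrix(small_dataset, standardize=True)
    res = fit_tsne(std.matrix, TSNEConfig(perplexity=15, n_iter=300, seed=1,
                                          init_mode="pca"))
    emb = pd.DataFrame(res.Y, index=std.compound_ids)
    asg = assign_clusters(emb, mode="kmeans", k=8, seed=1)
    classes = {r.compound_id: r.class_labels["superclass"] for r in small_dataset}
    summary = similarity_summary(std, asg, classes)
    assert summary.mean_within > summary.mean_between


def test_homolog_partition_analytical_vs_molecular_between(ladder):
    """Homolog-adjacent clusters: spectra diverge, fingerprints stay close."""
    from spectraqsar import build_analytical_matrix, build_molecular_matrix

    ks = {r.compound_id: int(r.metadata["Substituents"]) for r in ladder}
    labels = {cid: 1 if k <= 5 else 2 for cid, k in ks.items()}
    asg = ClusterAssignment(labels=labels, source="file")
    std = build_analytical_matrix(ladder, standardize=True)
    spectral = similarity_summary(std, asg)
    fps = build_molecular_matrix(ladder, "ecfp6")
    molecular = similarity_summary(fps.to_frame(), asg)
    assert spectral.between.loc[1, 2] < molecular.between.loc[1, 2]
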