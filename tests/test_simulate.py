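import numpy as np
import pandas as pd
import pytest

from coexdup.expression import preprocess
from coexdup.simulate import (
    AtlasSpec,
    PlantedPairSpec,
    SubgenomeSpec,
    generate_divergence_benchmark,
    generate_duplicate_pairs,
    generate_expression_atlas,
    generate_subgenome_structure,
    generate_linked_dataset,
)


class TestAtlasGenerator:
    def spec(self, **kw):
        base = dict(
            n_genes=14, n_tissues=8, replicates_per_tissue=2, n_modules=2,
            module_sizes=(5, 5), within_module_corr=1.0, noise_sd=0.0, seed=11,
        )
        base.update(kw)
        return AtlasSpec(**base)

    def test_nonnegative_tpm_and_shapes(self):
        atlas, labels = generate_expression_atlas(self.spec())
        assert (atlas.values.values >= 0).all()
        assert atlas.values.shape == (14, 16)
        assert (labels.values[:10] == [0] * 5 + [1] * 5).all()

    def test_zero_noise_perfect_within_module_correlation(self):
        atlas, labels = generate_expression_atlas(self.spec())
        proc, _ = preprocess(atlas)
        x = proc.values.values
        for m in (0, 1):
            idx = np.where(labels.values == m)[0]
            c = np.corrcoef(x[idx])
            assert np.abs(c - 1.0).max() < 1e-12

    def test_determinism(self):
        a1, l1 = generate_expression_atlas(self.spec())
        a2, l2 = generate_expression_atlas(self.spec())
        pd.testing.assert_frame_equal(a1.values, a2.values)
        pd.testing.assert_series_equal(l1, l2)

    def test_high_noise_between_module_correlation_near_zero(self):
        # Monte-Carlo over replicate datasets: noise 10x the unit signal
        means = []
        for seed in range(100):
            spec = self.spec(noise_sd=10.0, seed=seed, n_genes=10, module_sizes=(4, 4))
            atlas, labels = generate_expression_atlas(spec)
            proc, _ = preprocess(atlas)
            x = proc.values.values
            a = np.where(labels.values == 0)[0]
            b = np.where(labels.values == 1)[0]
            c = np.corrcoef(x)[np.ix_(a, b)]
            means.append(c.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-12

    @pytest.mark.parametrize(
        "field,kw",
        [
            ("replicates_per_tissue", {"replicates_per_tissue": 4}),
            ("module_sizes", {"module_sizes": (10, 10)}),
            ("noise_sd", {"noise_sd": -1.0}),
            ("within_module_corr", {"within_module_corr": 1.2}),
        ],
    )
    def test_validation_names_field(self, field, kw):
        with pytest.raises(ValueError, match=field):
            self.spec(**kw)


class TestPairGenerator:
    def labels(self, n_module_genes=4000, n_singletons=22000, module_size=20):
        genes = [f"g{i:06d}" for i in range(n_module_genes + n_singletons)]
        lab = [i // module_size for i in range(n_module_genes)] + [-1] * n_singletons
        return pd.Series(lab, index=genes)

    def test_type_i_pairs_share_module(self):
        spec = PlantedPairSpec(n_pairs=10, divergence_proportions={"I": 1.0})
        pairs = generate_duplicate_pairs(spec, self.labels(200, 10, 10), seed=1)
        lab = self.labels(200, 10, 10)
        assert len(pairs) == 10
        assert all(lab[r.gene1] == lab[r.gene2] >= 0 for r in pairs.itertuples())

    def test_multinomial_type_counts(self):
        spec = PlantedPairSpec(
            n_pairs=1000, type_proportions={"WGD": 0.3, "tandem": 0.2, "inserted": 0.5}
        )
        pairs = generate_duplicate_pairs(spec, self.labels(), seed=2)
        counts = pairs["dup_type"].value_counts()
        for t, p in [("WGD", 0.3), ("tandem", 0.2), ("inserted", 0.5)]:
            se = np.sqrt(1000 * p * (1 - p))
            assert abs(counts[t] - 1000 * p) <= 3 * se

    def test_ds_moments(self):
        mu, sd = 0.5, 0.05
        spec = PlantedPairSpec(
            n_pairs=10000,
            type_proportions={"WGD": 1.0},
            divergence_proportions={"VI": 1.0},
            ds_params={"WGD": (mu, sd)},
        )
        pairs = generate_duplicate_pairs(spec, self.labels(), seed=3)
        ds = pairs["dS"].values
        assert (ds >= 0).all()
        assert abs(ds.mean() - mu) <= 3 * sd / np.sqrt(len(ds))
        assert abs(ds.std(ddof=1) - sd) <= 3 * sd / np.sqrt(2 * len(ds))

    def test_exhausted_genes_error(self):
        spec = PlantedPairSpec(n_pairs=50, divergence_proportions={"VI": 1.0})
        with pytest.raises(ValueError, match="exceed"):
            generate_duplicate_pairs(spec, self.labels(20, 10, 10), seed=4)

    def test_determinism(self):
        spec = PlantedPairSpec(n_pairs=100)
        p1 = generate_duplicate_pairs(spec, self.labels(2000, 2000), seed=5)
        p2 = generate_duplicate_pairs(spec, self.labels(2000, 2000), seed=5)
        pd.testing.assert_frame_equal(p1, p2)


class TestSubgenomeGenerator:
    def test_exact_label_counts(self):
        spec = SubgenomeSpec(n_maize1=150, n_maize2=95, fractionation_rate=0.3, n_pathways=5, seed=6)
        map_df, _, _ = generate_subgenome_structure(spec)
        counts = map_df["subgenome"].value_counts()
        assert counts["maize1"] == 150 and counts["maize2"] == 95

    def test_fractionation_rate_binomial(self):
        spec = SubgenomeSpec(
            n_maize1=1000, n_maize2=820, fractionation_rate=0.2, n_pathways=0, seed=7
        )
        _, homeologs, _ = generate_subgenome_structure(spec)
        n_candidates = len(homeologs)
        lost = int((homeologs["status"] == "lost").sum())
        se = np.sqrt(n_candidates * 0.2 * 0.8)
        assert abs(lost - 0.2 * n_candidates) <= 3 * se

    def test_pathways_have_two_retained_wgd_pairs_and_known_genes(self):
        spec = SubgenomeSpec(n_maize1=300, n_maize2=210, fractionation_rate=0.3, n_pathways=12, seed=8)
        map_df, homeologs, pathways = generate_subgenome_structure(spec)
        retained = homeologs[homeologs["status"] == "retained"]
        pair_set = set(zip(retained["gene1"], retained["gene2"]))
        known = set(map_df["gene_id"])
        assert len(pathways) == 12
        for genes in pathways.values():
            assert set(genes) <= known
            n_pairs = sum(1 for a, b in pair_set if a in set(genes) and b in set(genes))
            assert n_pairs >= 2

    def test_one_label_per_gene(self):
        spec = SubgenomeSpec(n_maize1=120, n_maize2=80, n_ambiguous=15, n_pathways=3, seed=9)
        map_df, _, _ = generate_subgenome_structure(spec)
        assert not map_df["gene_id"].duplicated().any()

    def test_infeasible_pathway_range(self):
        with pytest.raises(ValueError, match="pathway_size_range"):
            SubgenomeSpec(n_maize1=50, n_maize2=40, pathway_size_range=(2, 3))

    def test_determinism(self):
        spec = SubgenomeSpec(n_maize1=100, n_maize2=70, n_pathways=4, seed=10)
        out1 = generate_subgenome_structure(spec)
        out2 = generate_subgenome_structure(spec)
        pd.testing.assert_frame_equal(out1[0], out2[0])
        pd.testing.assert_frame_equal(out1[1], out2[1])
        assert out1[2] == out2[2]


class TestBenchmarkGenerator:
    def test_determinism_and_structure(self):
        a1, p1 = generate_divergence_benchmark(n_pairs=30, seed=21)
        a2, p2 = generate_divergence_benchmark(n_pairs=30, seed=21)
        pd.testing.assert_frame_equal(a1.values, a2.values)
        pd.testing.assert_frame_equal(p1, p2)
        assert len(p1) == 30
        assert set(p1["planted_divergence"]) <= {"I", "II", "III", "IV", "V", "VI", "unclassified"}
        assert (a1.values.values >= 0).all()

    def test_pair_genes_exist_in_atlas(self):
        atlas, pairs = generate_divergence_benchmark(n_pairs=30, seed=22)
        genes = set(atlas.gene_ids)
        assert set(pairs["gene1"]) <= genes and set(pairs["gene2"]) <= genes


class TestLinkedDataset:
    def test_shared_universe_and_consistency(self):
        atlas_spec = AtlasSpec(n_genes=470, n_tissues=16, seed=31, noise_sd=0.05)
        data = generate_linked_dataset(
            atlas_spec,
            PlantedPairSpec(n_pairs=40),
            SubgenomeSpec(n_maize1=250, n_maize2=180, n_ambiguous=40, n_pathways=6, seed=32),
        )
        genes = set(data["atlas"].gene_ids)
        assert set(data["map"]["gene_id"]) == genes
        assert set(data["pairs"]["gene1"]) <= genes
        for members in data["pathways"].values():
            assert set(members) <= genes

    def test_universe_size_mismatch_raises(self):
        with pytest.raises(ValueError, match="n_genes"):
            generate_linked_dataset(
                AtlasSpec(n_genes=100, n_tissues=16, seed=1),
                PlantedPairSpec(n_pairs=5),
                SubgenomeSpec(n_maize1=250, n_maize2=180, n_pathways=2, seed=2),
            )
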