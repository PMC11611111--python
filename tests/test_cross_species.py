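import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gliamine.atlas_io import NormalizedMatrix, normalize_ln10k
from gliamine.cross_species import (
    IntegrationConfig,
    align_orthologs,
    call_intermediates,
    cell_panel_scores,
    conserved_marker_analysis,
    conserved_markers,
    harmonize,
    integrate,
)
from gliamine.panels import default_panels
import gliamine.panels as P
from gliamine.synthetic import planted_markers


def _ortho(rows):
    return pd.DataFrame(rows, columns=["species_a", "gene_a", "species_b",
                                       "gene_b", "homology_type"])


class TestAlignOrthologs:
    def test_identity_map_keeps_all_genes(self):
        table = _ortho([("a", "G1", "b", "G1", "one2one"),
                        ("a", "G2", "b", "G2", "one2one")])
        mapping, dropped = align_orthologs(
            {"a": ["g1", "g2"], "b": ["G1", "G2"]}, table)
        assert list(mapping["symbol"]) == ["G1", "G2"]
        assert dropped.empty

    def test_one2many_record_excludes_gene(self):
        table = _ortho([("a", "G1", "b", "G1", "one2one"),
                        ("a", "G2", "b", "G2", "one2many"),
                        ("a", "G2", "b", "G2B", "one2many")])
        mapping, dropped = align_orthologs(
            {"a": ["G1", "G2"], "b": ["G1", "G2", "G2B"]}, table)
        assert list(mapping["symbol"]) == ["G1"]
        assert "G2" in set(dropped["gene"])

    def test_single_species_passthrough(self):
        mapping, _ = align_orthologs({"a": ["g1", "g2"]}, _ortho([]))
        assert list(mapping["symbol"]) == ["G1", "G2"]

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="no one-to-one"):
            align_orthologs({"a": ["G1"], "b": ["G2"]}, _ortho([]))

    def test_planted_chain_count(self, glia_rich_bundle):
        cfg, per_species, orthologs = glia_rich_bundle
        gene_lists = {s: cm.genes for s, (cm, _) in per_species.items()}
        mapping, _ = align_orthologs(gene_lists, orthologs)
        expected = int(round(cfg.ortholog_one2one_fraction
                             * (cfg.n_genes - cfg.n_private_genes)))
        assert len(mapping) == expected

    def test_species_order_independence(self, glia_rich_bundle):
        _, per_species, orthologs = glia_rich_bundle
        gene_lists = {s: cm.genes for s, (cm, _) in per_species.items()}
        m1, _ = align_orthologs(gene_lists, orthologs)
        reordered = dict(reversed(list(gene_lists.items())))
        m2, _ = align_orthologs(reordered, orthologs)
        assert set(m1["symbol"]) == set(m2["symbol"])


@pytest.fixture(scope="module")
def consensus_run(glia_rich_bundle):
    """Cross-species stage on truth-labeled glia (no extraction noise)."""
    cfg, per_species, orthologs = glia_rich_bundle
    glia_norms, calls = {}, []
    for s, (cm, cells) in per_species.items():
        norm = normalize_ln10k(cm)
        glia = cells[cells["truth_label"].str.startswith("glia")].reset_index(drop=True)
        glia_norms[s] = (norm.subset_cells(list(glia["cell"])), glia)
        calls.append(pd.Series([t.split("_")[1] for t in glia["truth_label"]],
                               index=glia["cell"]))
    mapping, _ = align_orthologs({s: gn[0].genes for s, gn in glia_norms.items()},
                                 orthologs)
    harmonized, combined = harmonize(glia_norms, mapping)
    embedding = integrate(harmonized, combined)
    return cfg, harmonized, combined, embedding, pd.concat(calls)


class TestIntegrate:
    def test_embedding_shape_and_determinism(self, consensus_run):
        _, harmonized, combined, emb, _ = consensus_run
        assert emb.shape == (harmonized.n_cells, 30)
        again = integrate(harmonized, combined)
        np.testing.assert_allclose(emb.to_numpy(), again.to_numpy())

    def test_hvg_clipped_with_warning(self, consensus_run):
        _, harmonized, combined, _, _ = consensus_run
        with pytest.warns(UserWarning, match="clipping"):
            integrate(harmonized, combined,
                      IntegrationConfig(hvg_num=10 ** 6))

    def test_single_species_passthrough(self):
        rng = np.random.default_rng(0)
        vals = rng.random((40, 25))
        norm = NormalizedMatrix(genes=[f"G{i}" for i in range(40)],
                                cells=[f"c{i}" for i in range(25)],
                                values=sp.csr_matrix(vals))
        cells = pd.DataFrame({"cell": norm.cells, "species": "only",
                              "tissue": "lung", "donor": "d1"})
        emb = integrate(norm, cells, IntegrationConfig(n_components=5))
        assert emb.shape == (25, 5)

    def test_subtypes_separate_and_species_mix(self, consensus_run):
        """Clustering the embedding recovers subtypes (ARI >= 0.8) while
        species labels are poorly predictable relative to subtype labels."""
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score
        from sklearn.model_selection import cross_val_score
        from sklearn.neighbors import KNeighborsClassifier

        _, _, combined, emb, calls = consensus_run
        truth = calls.reindex(emb.index).to_numpy()
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(
            emb.to_numpy())
        assert adjusted_rand_score(truth, km) >= 0.8

        X = emb.to_numpy()
        subtype_acc = cross_val_score(KNeighborsClassifier(5), X, truth, cv=3).mean()
        species_acc = cross_val_score(
            KNeighborsClassifier(5), X, combined["species"].to_numpy(), cv=3).mean()
        assert species_acc <= subtype_acc


class TestCallIntermediates:
    def test_margin_and_purity_rules(self):
        emb = pd.DataFrame({"PC1": [0.0, 0.1, 5.0], "PC2": [0.0, 0.1, 5.0]},
                           index=["a", "b", "c"])
        calls = pd.Series(["MG", "MG", "MG"], index=emb.index)
        # cell c has a hybrid panel profile -> margin below delta
        scores = pd.DataFrame({"MG": [2.0, 2.0, 1.0], "NMG": [0.1, 0.1, 0.95]},
                              index=emb.index)
        out = call_intermediates(emb, calls, scores, margin=0.25, n_neighbors=1,
                                 purity_threshold=0.5)
        assert out["a"] == "MG" and out["b"] == "MG"
        assert out["c"] == "intermediate"

    def test_unclassified_cells_become_intermediate(self):
        emb = pd.DataFrame({"PC1": [0.0, 1.0]}, index=["a", "b"])
        calls = pd.Series(["unclassified", "TG"], index=emb.index)
        scores = pd.DataFrame({"MG": [0.0, 0.0], "TG": [2.0, 2.0]}, index=emb.index)
        out = call_intermediates(emb, calls, scores, n_neighbors=0)
        assert out["a"] == "intermediate"

    def test_intermediate_rate_low_without_planted_hybrids(self, consensus_run):
        _, harmonized, _, emb, calls = consensus_run
        scores = cell_panel_scores(harmonized, default_panels().subtypes)
        status = call_intermediates(emb, calls, scores)
        assert (status == "intermediate").mean() <= 0.10


class TestConservedMarkers:
    def test_all_species_rule(self):
        t_pass = pd.DataFrame({"gene": ["A", "B"], "passed": [True, True]})
        t_partial = pd.DataFrame({"gene": ["A", "B"], "passed": [True, False]})
        assert conserved_markers({"s1": t_pass, "s2": t_partial}) == ["A"]
        assert conserved_markers({"s1": t_pass, "s2": t_pass.iloc[:0]}) == []

    def test_planted_consensus_recovered_exactly(self, consensus_run):
        cfg, harmonized, combined, emb, calls = consensus_run
        status = calls.copy()  # truth subtype calls, no demotion noise
        results = conserved_marker_analysis(harmonized, combined, status)
        planted = planted_markers(cfg)
        for subtype in ("MG", "NMG", "TG"):
            assert results[subtype]["status"] == "ok"
            got = set(results[subtype]["conserved"])
            assert got == planted[subtype]
            # conserved set is a subset of every species' own marker set
            for table in results[subtype]["per_species"].values():
                assert got <= set(table.loc[table["passed"], "gene"])

    def test_combined_contrast_recovers_shared_genes(self, consensus_run):
        cfg, harmonized, combined, emb, calls = consensus_run
        results = conserved_marker_analysis(harmonized, combined, calls)
        got = set(results["NMG_TG"]["conserved"])
        assert planted_markers(cfg)["NMG_TG"] <= got
        # never MG-selective, pan-glial, species-private, or null genes
        forbidden = (planted_markers(cfg)["MG"] | planted_markers(cfg)["pan_glial"]
                     | {g for g in harmonized.genes if "PRIV" in g or g.startswith("G0")})
        assert not (got & forbidden)

    def test_species_missing_subtype_is_skipped(self, consensus_run):
        cfg, harmonized, combined, emb, calls = consensus_run
        status = calls.copy()
        one_species = combined.loc[combined["species"] == "mouse", "cell"]
        status.loc[status.index.isin(one_species) & (status == "MG")] = "intermediate"
        results = conserved_marker_analysis(harmonized, combined, status,
                                            contrasts={"MG": ("MG",)})
        assert results["MG"]["status"] == "skipped"
        assert "mouse" in results["MG"]["missing_species"]
        assert results["MG"]["conserved"] == []
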