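import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from gliamine.atlas_io import CountMatrix, GenePanel, NormalizedMatrix, normalize_ln10k
from gliamine.extraction import (
    ClusterLabeling,
    EmptyResultError,
    ExtractionConfig,
    assign_subtypes,
    exclude_tissues,
    extract_glia,
    score_clusters_by_panel,
    screen_cells,
    select_candidate_cluster,
    subcluster,
)
from gliamine.panels import default_panels
from gliamine.synthetic import SimConfig, generate_atlas


def _norm(values, genes):
    values = np.asarray(values, dtype=float)
    cells = [f"c{i}" for i in range(values.shape[1])]
    return NormalizedMatrix(genes=[g.upper() for g in genes], cells=cells,
                            values=sp.csr_matrix(values))


def _cells(ids, tissue="lung", donor="d1"):
    return pd.DataFrame({
        "cell": ids,
        "tissue": tissue if isinstance(tissue, list) else [tissue] * len(ids),
        "species": "mouse",
        "donor": donor if isinstance(donor, list) else [donor] * len(ids),
    })


class TestScoreAndSelect:
    def test_all_zero_cluster_scores_zero(self):
        norm = _norm(np.zeros((2, 3)), ["g1", "g2"])
        lab = ClusterLabeling(norm.cells, [0, 0, 0])
        panel = GenePanel("p", "pan_glial", ("g1", "g2"))
        assert score_clusters_by_panel(norm, lab, panel)[0] == (0.0, 0.0)

    def test_mean_is_panel_by_cell_average(self):
        # cells {g1:1, g2:0} and {g1:0, g2:2} -> mean (1+0+0+2)/4 = 0.75
        norm = _norm([[1.0, 0.0], [0.0, 2.0]], ["g1", "g2"])
        lab = ClusterLabeling(norm.cells, [0, 0])
        panel = GenePanel("p", "pan_glial", ("g1", "g2"))
        mean, frac = score_clusters_by_panel(norm, lab, panel)[0]
        assert mean == pytest.approx(0.75)
        assert frac == 1.0

    def test_missing_panel_genes_warn_and_empty_panel_errors(self):
        norm = _norm([[1.0]], ["g1"])
        lab = ClusterLabeling(norm.cells, [0])
        with pytest.warns(UserWarning, match="missing"):
            score_clusters_by_panel(norm, lab, GenePanel("p", "pan_glial", ("g1", "g9")))
        with pytest.raises(ValueError, match="no genes"):
            score_clusters_by_panel(norm, lab, GenePanel("p", "pan_glial", ("g9",)))

    def test_candidate_selection_rules(self):
        assert select_candidate_cluster({3: (0.4, 0.2)}) == 3
        assert select_candidate_cluster({0: (0.2, 0.5), 1: (0.9, 0.7)}) == 1
        # exact tie on mean -> higher positive fraction wins
        assert select_candidate_cluster({0: (0.5, 0.4), 1: (0.5, 0.6)}) == 1
        # full tie -> lower id
        assert select_candidate_cluster({7: (0.5, 0.4), 2: (0.5, 0.4)}) == 2

    def test_selection_invariant_to_relabeling(self, rng):
        scores = {i: (rng.random(), rng.random()) for i in range(6)}
        winner = select_candidate_cluster(scores)
        perm = rng.permutation(6)
        relabeled = {int(perm[k]): v for k, v in scores.items()}
        assert relabeled[int(perm[winner])] == scores[winner]
        assert select_candidate_cluster(relabeled) == int(perm[winner])

    def test_planted_glial_cluster_has_top_pan_glial_score(
            self, default_atlas, default_normalized, default_extraction):
        _, _, cells = default_atlas
        # recompute every cluster's mean directly from truth labels
        truth_glia = cells["truth_label"].str.startswith("glia")
        retained = set(default_extraction.retained_cells["cell"])
        overlap = cells.loc[truth_glia, "cell"].isin(retained).mean()
        assert overlap > 0.9  # argmax cluster is the planted glial cluster


class TestExcludeTissues:
    def test_empty_blacklist_is_identity(self):
        cells = _cells(["a", "b"])
        pd.testing.assert_frame_equal(exclude_tissues(cells, []), cells)

    def test_cns_funnel_arithmetic(self):
        # 4300 candidate cells of which 3176 from blacklisted CNS tissues
        tissues = ["Brain_Non-Myeloid"] * 2000 + ["Brain_Myeloid"] * 1176 + \
                  ["limb_muscle"] * 1124
        cells = _cells([f"c{i}" for i in range(4300)], tissue=tissues)
        kept = exclude_tissues(cells, ["Brain_Non-Myeloid", "Brain_Myeloid"])
        assert len(cells) == 4300
        assert len(kept) == 1124

    def test_unknown_tissue_warns_not_errors(self):
        with pytest.warns(UserWarning, match="not present"):
            kept = exclude_tissues(_cells(["a"]), ["nonexistent_tissue"])
        assert len(kept) == 1


def _screen_fixture():
    """Toy counts with pan-glial and epithelial contaminant genes."""
    panels = default_panels()
    genes = list(panels.pan_glial.genes) + ["EPCAM", "CDH1", "KRT5", "OTHER"]
    #            glial  epi   zero  manual
    counts = np.zeros((len(genes), 4), dtype=int)
    counts[0:4, 0] = 3          # 4 pan-glial genes detected
    counts[0:2, 1] = 2          # epi cell co-expresses glial genes ...
    counts[6:8, 1] = 5          # ... plus Epcam + Cdh1 -> contaminant rule
    counts[9, 1] = 1
    counts[9, 3] = 2            # manual cell: no glial evidence
    cm = CountMatrix(genes=genes, cells=["glial", "epi", "empty", "manual"],
                     counts=sp.csr_matrix(counts))
    cells = _cells(["glial", "epi", "empty", "manual"])
    return cm, cells


class TestScreenCells:
    def test_rule_application_and_reasons(self):
        cm, cells = _screen_fixture()
        retained, report = screen_cells(cm, cells, ExtractionConfig())
        report = report.set_index("cell")
        assert list(retained["cell"]) == ["glial"]
        assert report.loc["empty", "reason"] == "zero_library"
        assert report.loc["epi", "reason"] == "contaminant_epithelial"
        assert report.loc["manual", "reason"] == "insufficient_glial_evidence"
        # exactly one reason per dropped cell, none for retained
        dropped = report[~report["retained"]]
        assert (dropped["reason"] != "").all()
        assert (report.loc[retained["cell"], "reason"] == "").all()

    def test_manual_overrides_apply_last(self):
        cm, cells = _screen_fixture()
        cfg = ExtractionConfig(manual_include=("manual",), manual_exclude=("glial",))
        retained, report = screen_cells(cm, cells, cfg)
        assert list(retained["cell"]) == ["manual"]
        report = report.set_index("cell")
        assert report.loc["glial", "reason"] == "manual_exclude"
        assert report.loc["manual", "reason"] == "manual_include"

    def test_screen_is_idempotent(self, small_atlas):
        _, counts, cells = small_atlas
        cfg = ExtractionConfig()
        once, _ = screen_cells(counts, cells, cfg)
        twice, _ = screen_cells(counts, once, cfg)
        pd.testing.assert_frame_equal(once, twice)

    def test_activation_rule_drops_single_donor_only(self):
        panels = default_panels()
        genes = list(panels.pan_glial.genes) + ["FOS", "JUN", "IER2"]
        counts = np.zeros((len(genes), 4), dtype=int)
        counts[0:3, :] = 2                   # all cells pass glial evidence
        counts[6:9, 0] = 4                   # activated cells
        counts[6:9, 1] = 4
        cm = CountMatrix(genes=genes, cells=list("abcd"),
                         counts=sp.csr_matrix(counts))
        same_donor = _cells(list("abcd"), donor=["d1", "d1", "d2", "d2"])
        cfg = ExtractionConfig(activation_rule=True)
        retained, report = screen_cells(cm, same_donor, cfg)
        assert list(retained["cell"]) == ["c", "d"]
        assert (report.set_index("cell").loc[["a", "b"], "reason"]
                == "activated_single_donor").all()
        # same activation pattern across two donors -> rule does not fire
        multi_donor = _cells(list("abcd"), donor=["d1", "d2", "d3", "d3"])
        retained, _ = screen_cells(cm, multi_donor, cfg)
        assert len(retained) == 4


class TestSubclusterAndSubtypes:
    def test_single_cell_degenerates(self):
        norm = _norm([[1.0]], ["g1"])
        lab = subcluster(norm, _cells(["c0"]))
        assert list(lab.labels) == [0]

    def test_three_planted_subtypes_recovered(self):
        """Glia-only data with 3 planted subtypes: 3 non-singleton clusters,
        ARI vs truth >= 0.9."""
        cfg = SimConfig(seed=6, n_cells=2_500, glial_fraction=0.2,
                        hybrid_fraction=0.0)
        counts, cells = generate_atlas(cfg)
        glia = cells[cells["truth_label"].str.startswith("glia")].reset_index(drop=True)
        norm = normalize_ln10k(counts)
        lab = subcluster(norm, glia, seed=0)
        nonsingleton = {c for c, n in lab.cluster_sizes().items() if n > 1}
        assert len(nonsingleton) == 3
        truth = glia.set_index("cell")["truth_label"].reindex(lab.cells)
        assert adjusted_rand_score(truth, lab.labels) >= 0.9

    def test_pure_cluster_gets_its_subtype(self):
        full = default_panels().subtypes
        panels = {"MG": full["MG"], "NMG": full["NMG"]}
        genes = list(panels["MG"].genes) + list(panels["NMG"].genes)
        vals = np.zeros((len(genes), 4))
        vals[:5, :2] = 2.0   # two MG cells
        vals[5:, 2:] = 2.0   # two NMG cells
        norm = _norm(vals, genes)
        lab = ClusterLabeling(norm.cells, [0, 0, 1, 1])
        calls = assign_subtypes(norm, lab, panels, margin=0.25)
        assert set(calls[:2]) == {"MG"} and set(calls[2:]) == {"NMG"}

    def test_hybrid_cluster_unclassified(self):
        full = default_panels().subtypes
        panels = {"MG": full["MG"], "NMG": full["NMG"]}
        genes = list(panels["MG"].genes) + list(panels["NMG"].genes)
        vals = np.full((len(genes), 3), 1.0)  # equal MG and NMG scores
        norm = _norm(vals, genes)
        lab = ClusterLabeling(norm.cells, [0, 0, 0])
        calls = assign_subtypes(norm, lab, panels, margin=0.25)
        assert (calls == "unclassified").all()

    def test_singleton_cluster_unclassified(self):
        panels = {"MG": default_panels().subtypes["MG"]}
        genes = list(panels["MG"].genes)
        vals = np.full((len(genes), 3), 2.0)
        norm = _norm(vals, genes)
        lab = ClusterLabeling(norm.cells, [0, 0, 1])
        calls = assign_subtypes(norm, lab, panels, margin=0.25)
        assert calls.iloc[2] == "unclassified"
        assert (calls.iloc[:2] == "MG").all()


class TestExtractGlia:
    def test_empty_after_tissue_exclusion_raises(self, small_atlas):
        _, counts, cells = small_atlas
        cfg = ExtractionConfig(tissue_blacklist=tuple(cells["tissue"].unique()))
        with pytest.raises(EmptyResultError):
            extract_glia(counts, cells, cfg)

    def test_funnel_is_monotone_and_consistent(self, default_extraction):
        f = default_extraction.funnel
        assert (f["atlas"] >= f["candidate_cluster"]
                >= f["after_tissue_exclusion"] >= f["after_screening"]
                >= f["subtyped"])
        assert f["after_screening"] == len(default_extraction.retained_cells)
        assert f["after_screening"] == len(default_extraction.subtype_calls)
        report = default_extraction.screening_report
        dropped = report[~report["retained"]]
        assert (dropped["reason"] != "").all()
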