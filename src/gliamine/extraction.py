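"""Rare-population extraction: find the glia-enriched cluster by panel
scoring, exclude blacklisted (CNS) tissues, screen individual cells against
glial and contaminant panels, re-cluster the survivors, and assign
MG/NMG/TG/unclassified subtypes.

Screening rule order (first rule wins in the per-cell report):

1. ``zero_library`` - the cell has no counts at all;
2. ``insufficient_glial_evidence`` - fewer than ``min_glial_genes_detected``
   pan-glial panel genes with counts at or above ``detection_threshold``;
3. ``contaminant_<lineage>`` - more than ``max_contaminant_genes_detected``
   genes of one contaminant lineage detected (lineages checked in config
   order);
4. optional ``activated_single_donor`` - the cell exceeds the
   immediate-early-gene threshold and every such cell comes from one donor;
5. ``manual_exclude`` / ``manual_include`` overrides, applied last.

Cluster ids are arbitrary; every downstream rule is invariant to relabeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import panels as default_panel_defs
from .atlas_io import CountMatrix, GenePanel, NormalizedMatrix, PanelSet, normalize_ln10k

__all__ = [
    "ClusterLabeling",
    "ExtractionConfig",
    "ExtractionResult",
    "EmptyResultError",
    "cluster_atlas",
    "score_clusters_by_panel",
    "select_candidate_cluster",
    "exclude_tissues",
    "screen_cells",
    "subcluster",
    "assign_subtypes",
    "extract_glia",
]


class EmptyResultError(RuntimeError):
    """A stage produced an empty cell set where downstream work needs cells."""


@dataclass
class ClusterLabeling:
    """Cell id -> cluster id mapping plus the parameters that produced it."""

    cells: list
    labels: np.ndarray
    algorithm: str = "leiden"
    resolution: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.cells) != len(self.labels):
            raise ValueError("every cell must be labeled exactly once")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cells)

    def cluster_sizes(self) -> dict:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def singleton_clusters(self) -> set:
        return {cid for cid, n in self.cluster_sizes().items() if n == 1}


@dataclass
class ExtractionConfig:
    """Thresholds and panels for one extraction run.

    ``detection_threshold`` is the minimum raw UMI count for a gene to count
    as detected in the per-cell screen; the neighbor count and PC number for
    clustering default to k=15 / 30 components (capped at n-1).
    """

    panels: PanelSet = field(default_factory=default_panel_defs.default_panels)
    tissue_blacklist: tuple = default_panel_defs.CNS_TISSUE_BLACKLIST
    detection_threshold: int = 1
    min_glial_genes_detected: int = 2
    max_contaminant_genes_detected: int = 1
    subtype_margin: float = 0.25
    atlas_resolution: float = 0.5
    subcluster_resolution: float = 1.0
    n_neighbors: int = 15
    n_pcs: int = 30
    n_hvg: int = 500
    manual_include: tuple = ()
    manual_exclude: tuple = ()
    activation_rule: bool = False
    activation_panel: tuple = default_panel_defs.ACTIVATION_GENES
    activation_min_genes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detection_threshold < 0 or self.min_glial_genes_detected < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_contaminant_genes_detected < 0 or self.subtype_margin < 0:
            raise ValueError("thresholds must be non-negative")


def _leiden_labels(norm: NormalizedMatrix, resolution: float, n_neighbors: int,
                   n_pcs: int, seed: int, n_hvg: int = 500) -> np.ndarray:
    """HVG -> scaled PCA -> kNN graph -> Leiden community detection (scanpy)."""
    import anndata as ad
    import scanpy as sc

    n = norm.n_cells
    if n < 2:
        return np.zeros(n, dtype=int)
    adata = ad.AnnData(X=norm.values.T.tocsr().astype(np.float32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # standard scRNA-seq preprocessing: highly-variable gene selection and
        # per-gene unit-variance scaling, so a rare population's markers carry
        # weight in the reduction
        if 0 < n_hvg < norm.n_genes and n >= 3:
            sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg)
            adata = adata[:, adata.var.highly_variable].copy()
        sc.pp.scale(adata, max_value=10)
        n_comps = max(1, min(n_pcs, n - 1, adata.shape[1] - 1))
        sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
        sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, n - 1),
                        random_state=seed)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     flavor="igraph", n_iterations=2, directed=False)
    return adata.obs["leiden"].astype(int).to_numpy()


def cluster_atlas(norm: NormalizedMatrix, resolution: float = 1.0,
                  n_neighbors: int = 15, n_pcs: int = 30,
                  seed: int = 0, n_hvg: int = 500) -> ClusterLabeling:
    """Whole-atlas Leiden clustering used to locate the glia-enriched cluster."""
    labels = _leiden_labels(norm, resolution, n_neighbors, n_pcs, seed, n_hvg)
    return ClusterLabeling(list(norm.cells), labels, "leiden", resolution)


def score_clusters_by_panel(norm: NormalizedMatrix, labeling: ClusterLabeling,
                            panel: GenePanel) -> dict:
    """Per cluster: (mean panel expression, fraction of panel-positive cells).

    The mean averages normalized expression over panel genes and cluster
    cells; a cell is panel-positive if at least one panel gene is detected
    (normalized value > 0). Panel genes absent from the matrix are dropped
    with a warning; an empty intersection is an error.
    """
    present = [g for g in panel.genes if g in set(norm.genes)]
    missing = set(panel.genes) - set(present)
    if missing:
        warnings.warn(f"panel {panel.name!r}: genes missing from matrix: {sorted(missing)}")
    if not present:
        raise ValueError(f"panel {panel.name!r} shares no genes with the matrix")
    sub = norm.values[norm.gene_index(present)]
    col_mean = np.asarray(sub.mean(axis=0)).ravel()
    col_pos = np.asarray((sub > 0).sum(axis=0)).ravel() > 0
    labels = labeling.as_series().reindex(norm.cells).to_numpy()
    scores = {}
    for cid in np.unique(labels):
        mask = labels == cid
        scores[int(cid)] = (float(col_mean[mask].mean()), float(col_pos[mask].mean()))
    return scores


def select_candidate_cluster(scores: dict) -> int:
    """Cluster with the highest mean panel expression.

    Ties broken by higher panel-positive fraction, then by lower cluster id;
    invariant under permutation of cluster ids.
    """
    if not scores:
        raise ValueError("no clusters scored")
    return min(scores, key=lambda cid: (-scores[cid][0], -scores[cid][1], cid))


def exclude_tissues(cells: pd.DataFrame, blacklist) -> pd.DataFrame:
    """Drop cells whose tissue is blacklisted (the CNS tissues by default)."""
    blacklist = list(blacklist)
    unknown = set(blacklist) - set(cells["tissue"].unique())
    if unknown:
        warnings.warn(f"blacklisted tissues not present in the table: {sorted(unknown)}")
    kept = cells[~cells["tissue"].isin(blacklist)].reset_index(drop=True)
    return kept


def _detected_gene_counts(counts: CountMatrix, genes, threshold: int) -> np.ndarray:
    """Number of panel genes detected (count >= threshold) per cell."""
    present = [g for g in genes if g in set(counts.genes)]
    if not present:
        return np.zeros(counts.n_cells, dtype=int)
    sub = counts.counts[counts.gene_index(present)]
    return np.asarray((sub >= max(threshold, 1)).sum(axis=0)).ravel()


def screen_cells(counts: CountMatrix, cells: pd.DataFrame,
                 cfg: ExtractionConfig):
    """Per-cell glial-evidence and contaminant screen.

    A cell is retained iff it detects at least ``min_glial_genes_detected``
    pan-glial genes and, for every contaminant lineage, at most
    ``max_contaminant_genes_detected`` lineage genes - subject to the manual
    include/exclude overrides applied last. Returns ``(retained cell table,
    per-cell report)``; the report records the single (first) rule that
    dropped each cell.
    """
    sub = counts.subset_cells(list(cells["cell"]))
    lib = sub.library_sizes()
    glial_det = _detected_gene_counts(sub, cfg.panels.pan_glial.genes,
                                      cfg.detection_threshold)
    contaminant_det = {
        lineage: _detected_gene_counts(sub, panel.genes, cfg.detection_threshold)
        for lineage, panel in cfg.panels.contaminants.items()
    }

    n = len(cells)
    reasons = np.array([""] * n, dtype=object)
    retained = np.ones(n, dtype=bool)
    for i in range(n):
        if lib[i] == 0:
            retained[i], reasons[i] = False, "zero_library"
        elif glial_det[i] < cfg.min_glial_genes_detected:
            retained[i], reasons[i] = False, "insufficient_glial_evidence"
        else:
            for lineage, det in contaminant_det.items():
                if det[i] > cfg.max_contaminant_genes_detected:
                    retained[i], reasons[i] = False, f"contaminant_{lineage}"
                    break

    if cfg.activation_rule:
        act_det = _detected_gene_counts(sub, cfg.activation_panel,
                                        cfg.detection_threshold)
        flagged = retained & (act_det >= cfg.activation_min_genes)
        donors = cells["donor"].to_numpy()
        if flagged.any() and len(set(donors[flagged])) == 1:
            retained[flagged] = False
            reasons[flagged] = "activated_single_donor"

    ids = cells["cell"].to_numpy()
    include = set(cfg.manual_include) & set(ids)
    exclude = set(cfg.manual_exclude) & set(ids)
    for i, cid in enumerate(ids):
        if cid in include and not retained[i]:
            retained[i], reasons[i] = True, "manual_include"
        if cid in exclude:
            retained[i], reasons[i] = False, "manual_exclude"

    report = pd.DataFrame({
        "cell": ids,
        "retained": retained,
        "reason": reasons,
        "n_glial_detected": glial_det,
        **{f"n_{lin}_detected": det for lin, det in contaminant_det.items()},
    })
    retained_cells = cells[retained].reset_index(drop=True)
    return retained_cells, report


def subcluster(norm: NormalizedMatrix, cells: pd.DataFrame,
               resolution: float = 1.0, n_neighbors: int = 15,
               n_pcs: int = 30, seed: int = 0,
               n_hvg: int = 500) -> ClusterLabeling:
    """Leiden re-clustering of the retained cells (low resolution by default).

    The modularity merge tolerance scales with resolution times the product
    of community sizes over the graph size, so the granularity a few hundred
    cells reach at resolution 0.05 needs a higher resolution at the ~100-cell
    scale of the default study condition; the default of 1.0 still separates
    a ~10-cell subtype there. Over-splitting is harmless because subtypes are
    assigned per cluster. Fewer than two cells degenerate to a single cluster
    0. Singleton clusters are treated as outliers downstream (their cells
    stay unclassified).
    """
    ids = list(cells["cell"])
    sub = norm.subset_cells(ids)
    labels = _leiden_labels(sub, resolution, n_neighbors, n_pcs, seed, n_hvg)
    return ClusterLabeling(ids, labels, "leiden", resolution)


def assign_subtypes(norm: NormalizedMatrix, labeling: ClusterLabeling,
                    subtype_panels: dict, margin: float = 0.25) -> pd.Series:
    """Cluster-level subtype calls: MG / NMG / TG / unclassified.

    Each cluster gets the subtype whose panel has the highest mean score,
    provided the top score beats the runner-up by at least ``margin``
    (hybrid clusters stay unclassified); singleton-cluster cells are
    unclassified.
    """
    per_panel = {
        name: score_clusters_by_panel(norm.subset_cells(labeling.cells), labeling, panel)
        for name, panel in subtype_panels.items()
    }
    singletons = labeling.singleton_clusters()
    calls = {}
    for cid in labeling.cluster_sizes():
        if cid in singletons:
            calls[cid] = "unclassified"
            continue
        ranked = sorted(
            ((per_panel[name][cid][0], name) for name in subtype_panels),
            reverse=True,
        )
        if len(ranked) == 1 or ranked[0][0] - ranked[1][0] >= margin:
            calls[cid] = ranked[0][1]
        else:
            calls[cid] = "unclassified"
    return pd.Series(
        [calls[int(l)] for l in labeling.labels], index=labeling.cells, name="subtype"
    )


@dataclass
class ExtractionResult:
    retained_cells: pd.DataFrame
    subtype_calls: pd.Series
    screening_report: pd.DataFrame
    labeling: ClusterLabeling
    candidate_cluster: int
    funnel: dict


def extract_glia(counts: CountMatrix, cells: pd.DataFrame,
                 cfg: ExtractionConfig | None = None,
                 norm: NormalizedMatrix | None = None) -> ExtractionResult:
    """The full extraction chain on one atlas.

    Whole-atlas Leiden clustering -> pan-glial panel scoring -> candidate
    cluster -> CNS-tissue exclusion -> per-cell screen -> low-resolution
    re-clustering -> subtype assignment. The funnel dict records the cell
    count after every stage.
    """
    cfg = cfg or ExtractionConfig()
    if norm is None:
        norm = normalize_ln10k(counts)
    funnel = {"atlas": len(cells)}

    labeling = cluster_atlas(norm, cfg.atlas_resolution, cfg.n_neighbors,
                             cfg.n_pcs, cfg.seed, cfg.n_hvg)
    scores = score_clusters_by_panel(norm, labeling, cfg.panels.pan_glial)
    candidate = select_candidate_cluster(scores)
    in_cluster = labeling.as_series() == candidate
    cluster_cells = cells[cells["cell"].map(in_cluster).fillna(False)].reset_index(drop=True)
    funnel["candidate_cluster"] = len(cluster_cells)

    kept = exclude_tissues(cluster_cells, cfg.tissue_blacklist)
    funnel["after_tissue_exclusion"] = len(kept)
    if kept.empty:
        raise EmptyResultError("no cells remain after tissue exclusion")

    retained, report = screen_cells(counts, kept, cfg)
    funnel["after_screening"] = len(retained)
    if retained.empty:
        raise EmptyResultError("per-cell screening removed every candidate cell")

    sub_labeling = subcluster(norm, retained, cfg.subcluster_resolution,
                              cfg.n_neighbors, cfg.n_pcs, cfg.seed, cfg.n_hvg)
    calls = assign_subtypes(norm, sub_labeling, cfg.panels.subtypes,
                            cfg.subtype_margin)
    funnel["subtyped"] = int((calls != "unclassified").sum())
    return ExtractionResult(retained, calls, report, sub_labeling, candidate, funnel)
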