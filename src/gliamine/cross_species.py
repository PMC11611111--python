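"""Cross-species harmonization and conserved-marker consensus.

Genes are aligned on chains that are one-to-one orthologs across *all*
configured species (any gene touched by a one2many/many2many record is
dropped); the shared axis uses uppercase canonical symbols. Integration is a
pluggable joint-embedding stage whose default is a classical pipeline -
cross-dataset dispersion HVG selection, per-species gene standardization,
joint PCA - which yields the species-mixed embedding the downstream consensus
rules need. A conserved marker for a subtype must pass the marker criteria
(right-tailed rank-sum, Bonferroni < 0.05, 3-fold by default) in every
species, with intermediate cells excluded from foregrounds but kept in the
background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .atlas_io import NormalizedMatrix
from .markers import MarkerCriteria, find_markers

__all__ = [
    "IntegrationConfig",
    "align_orthologs",
    "harmonize",
    "integrate",
    "cell_panel_scores",
    "call_intermediates",
    "conserved_markers",
    "conserved_marker_analysis",
    "CONSERVED_CRITERIA",
]

#: Marker criteria used for cross-species consensus: right-tailed rank-sum,
#: Bonferroni-corrected p < 0.05, and at least a 3-fold linear-scale increase.
CONSERVED_CRITERIA = MarkerCriteria(
    alternative="right_tailed", correction="bonferroni",
    alpha=0.05, min_fold_change=3.0,
)


@dataclass(frozen=True)
class IntegrationConfig:
    """Joint-embedding parameters (dispersion-HVG + per-species z + PCA)."""

    hvg_num: int = 3000
    n_components: int = 30
    seed: int = 0
    method: str = "dispersion_hvg_joint_pca"


def align_orthologs(gene_lists: dict, orthologs: pd.DataFrame):
    """One-to-one ortholog chains across every configured species.

    ``gene_lists`` maps species -> gene identifiers (matched
    case-insensitively against the ortholog table). Returns ``(mapping,
    dropped)``: a DataFrame with a canonical uppercase ``symbol`` column plus
    one column per species, and a report of genes excluded with reasons. The
    retained chain set is a species-order-independent intersection.
    """
    species = list(gene_lists)
    upper_lists = {s: [g.upper() for g in gene_lists[s]] for s in species}
    if len(species) == 1:
        s = species[0]
        mapping = pd.DataFrame({"symbol": upper_lists[s], s: upper_lists[s]})
        return mapping, pd.DataFrame(columns=["species", "gene", "reason"])

    # per species pair: clean one2one map and the set of ambiguous genes
    pair_map: dict = {}
    ambiguous: dict = {s: set() for s in species}
    ot = orthologs.copy()
    ot["gene_a"] = ot["gene_a"].str.upper()
    ot["gene_b"] = ot["gene_b"].str.upper()
    for _, row in ot.iterrows():
        sa, sb = row["species_a"], row["species_b"]
        if sa not in upper_lists or sb not in upper_lists:
            continue
        key = (sa, sb)
        if row["homology_type"] != "one2one":
            ambiguous[sa].add(row["gene_a"])
            ambiguous[sb].add(row["gene_b"])
            continue
        fwd = pair_map.setdefault(key, {})
        if row["gene_a"] in fwd and fwd[row["gene_a"]] != row["gene_b"]:
            ambiguous[sa].add(row["gene_a"])  # duplicated one2one claim
        fwd[row["gene_a"]] = row["gene_b"]

    def lookup(sa: str, sb: str, gene: str):
        if (sa, sb) in pair_map:
            return pair_map[(sa, sb)].get(gene)
        rev = pair_map.get((sb, sa), {})
        hits = [a for a, b in rev.items() if b == gene]
        return hits[0] if len(hits) == 1 else None

    ref = species[0]
    present = {s: set(upper_lists[s]) for s in species}
    rows, dropped = [], []
    for g in upper_lists[ref]:
        if g in ambiguous[ref]:
            dropped.append((ref, g, "non_one2one_record"))
            continue
        chain = {ref: g}
        ok = True
        for s in species[1:]:
            counterpart = lookup(ref, s, g)
            if counterpart is None or counterpart not in present[s]:
                dropped.append((ref, g, f"no_one2one_counterpart_in_{s}"))
                ok = False
                break
            if counterpart in ambiguous[s]:
                dropped.append((ref, g, f"non_one2one_record_in_{s}"))
                ok = False
                break
            chain[s] = counterpart
        if not ok:
            continue
        # cross-check consistency on every non-reference pair that is tabulated
        for i in range(1, len(species)):
            for j in range(i + 1, len(species)):
                si, sj = species[i], species[j]
                if (si, sj) in pair_map or (sj, si) in pair_map:
                    if lookup(si, sj, chain[si]) != chain[sj]:
                        dropped.append((ref, g, f"inconsistent_chain_{si}_{sj}"))
                        ok = False
                if not ok:
                    break
            if not ok:
                break
        if ok:
            rows.append([g] + [chain[s] for s in species])

    mapping = pd.DataFrame(rows, columns=["symbol"] + species)
    if mapping.empty:
        raise ValueError("no one-to-one ortholog chain spans all species")
    dropped_df = pd.DataFrame(dropped, columns=["species", "gene", "reason"])
    return mapping, dropped_df


def harmonize(per_species: dict, mapping: pd.DataFrame):
    """Stack per-species normalized matrices onto the shared ortholog axis.

    ``per_species`` maps species -> (NormalizedMatrix, cell table). Returns a
    :class:`NormalizedMatrix` on the canonical symbol axis plus the
    concatenated cell table (cell count = sum of the per-species counts).
    """
    species = [s for s in mapping.columns if s != "symbol"]
    blocks, tables = [], []
    for s in species:
        norm, cells = per_species[s]
        idx = norm.gene_index(mapping[s])
        blocks.append(norm.values[idx])
        tables.append(cells)
    values = sp.hstack(blocks, format="csr")
    combined = pd.concat(tables, ignore_index=True)
    return NormalizedMatrix(
        genes=list(mapping["symbol"]),
        cells=list(combined["cell"]),
        values=values,
    ), combined


def _dispersion_ranks(dense: np.ndarray) -> np.ndarray:
    mean = dense.mean(axis=1)
    var = dense.var(axis=1)
    disp = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    return disp.argsort().argsort()  # ascending ranks


def integrate(harmonized: NormalizedMatrix, cells: pd.DataFrame,
              cfg: IntegrationConfig | None = None) -> pd.DataFrame:
    """Default joint embedding across species.

    Top ``hvg_num`` genes by cross-dataset dispersion (average of per-species
    dispersion ranks), each gene standardized within its species, then a
    joint principal-component reduction. Deterministic; a single species
    passes through to its own reduction. Returns cells x components.
    """
    cfg = cfg or IntegrationConfig()
    species_col = cells["species"].to_numpy()
    species = list(dict.fromkeys(species_col))
    dense = harmonized.values.toarray().astype(float)

    hvg_num = cfg.hvg_num
    if hvg_num > harmonized.n_genes:
        warnings.warn(
            f"hvg_num={hvg_num} exceeds the {harmonized.n_genes}-gene shared "
            "axis; clipping"
        )
        hvg_num = harmonized.n_genes
    rank_sum = np.zeros(harmonized.n_genes)
    for s in species:
        rank_sum += _dispersion_ranks(dense[:, species_col == s])
    hvg = np.sort(np.argsort(-rank_sum, kind="stable")[:hvg_num])

    X = np.empty((harmonized.n_cells, len(hvg)))
    for s in species:
        mask = species_col == s
        block = dense[np.ix_(hvg, mask)].T
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        sd[sd == 0] = 1.0
        X[mask] = (block - mu) / sd

    X -= X.mean(axis=0)
    n_comp = min(cfg.n_components, X.shape[0] - 1, X.shape[1])
    # full SVD on the (small) glial compartment: deterministic up to sign
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    coords = X @ vt[:n_comp].T
    return pd.DataFrame(
        coords, index=cells["cell"],
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )


def cell_panel_scores(norm: NormalizedMatrix, subtype_panels: dict) -> pd.DataFrame:
    """Per-cell mean normalized expression of each subtype panel."""
    cols = {}
    gene_set = set(norm.genes)
    for name, panel in subtype_panels.items():
        present = [g for g in panel.genes if g in gene_set]
        if not present:
            raise ValueError(f"panel {name!r} shares no genes with the matrix")
        sub = norm.values[norm.gene_index(present)]
        cols[name] = np.asarray(sub.mean(axis=0)).ravel()
    return pd.DataFrame(cols, index=norm.cells)


def call_intermediates(embedding: pd.DataFrame, calls: pd.Series,
                       panel_scores: pd.DataFrame, margin: float = 0.25,
                       n_neighbors: int = 10,
                       purity_threshold: float = 0.6) -> pd.Series:
    """Demote hybrid cells to ``intermediate``.

    A cell is intermediate if its top-two subtype-panel score margin is below
    ``margin``, its embedding neighborhood is subtype-mixed (fewer than
    ``purity_threshold`` of its nearest neighbors share its call), or it was
    already unclassified. Intermediates remain eligible as background cells.
    """
    cells = list(embedding.index)
    calls = calls.reindex(cells)
    scores = panel_scores.reindex(cells)
    ranked = np.sort(scores.to_numpy(), axis=1)
    margins = ranked[:, -1] - ranked[:, -2]

    k = min(n_neighbors, len(cells) - 1)
    labels = calls.to_numpy()
    if k >= 1:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.to_numpy())
        _, idx = nn.kneighbors(embedding.to_numpy())
        same = labels[idx[:, 1:]] == labels[:, None]
        purity = same.mean(axis=1)
    else:
        purity = np.ones(len(cells))

    out = []
    for i, cell in enumerate(cells):
        if labels[i] == "unclassified" or margins[i] < margin or purity[i] < purity_threshold:
            out.append("intermediate")
        else:
            out.append(labels[i])
    return pd.Series(out, index=cells, name="subtype_status")


def conserved_markers(per_species_tables: dict) -> list:
    """Genes whose ``passed`` flag is set in every species' marker table."""
    sets = []
    for table in per_species_tables.values():
        if table.empty:
            return []
        sets.append(set(table.loc[table["passed"], "gene"]))
    conserved = set.intersection(*sets) if sets else set()
    return sorted(conserved)


def conserved_marker_analysis(harmonized: NormalizedMatrix, cells: pd.DataFrame,
                              status: pd.Series,
                              criteria: MarkerCriteria = CONSERVED_CRITERIA,
                              contrasts: dict | None = None,
                              min_group_size: int = 3) -> dict:
    """Per-subtype cross-species consensus on the shared ortholog axis.

    ``status`` holds per-cell subtype calls with hybrids already demoted to
    ``intermediate``. For each contrast the foreground is the subtype's
    non-intermediate cells of one species and the background is that species'
    remaining glia (intermediates included). A species lacking the subtype
    (fewer than ``min_group_size`` foreground cells) marks the contrast
    ``skipped`` rather than silently conserved. The combined ``NMG_TG``
    contrast pools non-myelinating and terminal glia against the rest.
    """
    if contrasts is None:
        contrasts = {
            "MG": ("MG",), "NMG": ("NMG",), "TG": ("TG",),
            "NMG_TG": ("NMG", "TG"),
        }
    status = status.reindex(cells["cell"])
    results = {}
    for name, fg_labels in contrasts.items():
        per_species, skipped = {}, []
        for s in cells["species"].unique():
            in_species = cells["species"].to_numpy() == s
            ids = cells.loc[in_species, "cell"]
            st = status.loc[ids]
            fg = list(st.index[st.isin(fg_labels)])
            bg = list(st.index[~st.isin(fg_labels)])
            if len(fg) < min_group_size or not bg:
                skipped.append(s)
                continue
            per_species[s] = find_markers(harmonized, fg, bg, criteria)
        if skipped:
            results[name] = {
                "status": "skipped", "missing_species": skipped,
                "per_species": per_species, "conserved": [],
            }
        else:
            results[name] = {
                "status": "ok", "missing_species": [],
                "per_species": per_species,
                "conserved": conserved_markers(per_species),
            }
    return results
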