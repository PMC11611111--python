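"""Synthetic multi-tissue, multi-species atlases with a planted rare glial
population.

The generator emulates the setting the pipeline is built for: whole-organism
UMI atlases of tens of thousands of cells in which peripheral glia are a few
tenths of a percent, split into myelinating (MG), non-myelinating (NMG) and
terminal (TG) subtypes with distinct marker programs, surrounded by abundant
epithelial / immune / endothelial / stromal lineages. Counts are negative
binomial with a per-cell lognormal library factor and Bernoulli dropout; each
"species" shares the planted biology on orthologous genes, perturbed by a
per-species multiplicative lognormal gene effect so integration has real
batch structure to remove.

Determinism: one mandatory master seed; per-stage child seeds are derived
with :class:`numpy.random.SeedSequence` (PCG64 streams), so identical
configs give bit-identical atlases across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import panels as P
from .atlas_io import CountMatrix

__all__ = [
    "SimConfig",
    "SimConfigError",
    "generate_atlas",
    "generate_multispecies",
    "plan_composition",
    "empty_ortholog_table",
]

ORTHOLOG_COLUMNS = ["species_a", "gene_a", "species_b", "gene_b", "homology_type"]

NONGLIA_POPULATIONS = ("epithelial", "immune", "endothelial", "stromal")
NONGLIA_PROPORTIONS = (0.40, 0.25, 0.15, 0.20)
GLIA_SUBTYPES = ("MG", "NMG", "TG")
#: Hybrid (intermediate) glia: balanced mixtures of two subtype programs,
#: as the grey "not further classified" cells in real integrated data.
HYBRID_PAIRS = (("MG", "NMG"), ("MG", "TG"), ("NMG", "TG"))

DEFAULT_TISSUES = ("limb_muscle", "heart", "trachea", "fat", "bladder", "lung", "kidney")


class SimConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic atlas (or one per species).

    ``n_cells`` is the per-species total, split evenly across ``tissues``;
    ``species_n_cells`` overrides it per species. ``marker_effect`` is the
    fold elevation of glial panel genes in their target population;
    contaminant lineage genes use the stronger ``contaminant_effect``
    because classic compartment markers (Ptprc, Epcam, ...) are near-binary
    in real atlases, and the per-cell contaminant screen depends on that.
    """

    seed: int
    n_cells: int = 20_000
    tissues: tuple = DEFAULT_TISSUES
    glial_fraction: float = 0.005
    subtype_proportions: tuple = (0.15, 0.55, 0.30)
    hybrid_fraction: float = 0.10
    n_genes: int = 2_000
    marker_effect: float = 8.0
    contaminant_effect: float = 80.0
    program_size: int = 30
    glial_program_size: int = 120
    subtype_program_size: int = 60
    program_effect: float = 5.0
    library_size_mean: float = 4_000.0
    library_size_sigma: float = 0.3
    dispersion: float = 8.0
    dropout_rate: float = 0.05
    species: tuple = ("mouse",)
    species_n_cells: dict | None = None
    species_effect_sigma: float = 0.2
    ortholog_one2one_fraction: float = 0.9
    n_private_genes: int = 50
    n_donors: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimConfigError("seed is mandatory")
        if not (0.0 < self.glial_fraction < 1.0):
            raise SimConfigError("glial_fraction must be in (0, 1)")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise SimConfigError("subtype_proportions must sum to 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise SimConfigError("dropout_rate must be in [0, 1)")
        if not (0.0 <= self.hybrid_fraction < 1.0):
            raise SimConfigError("hybrid_fraction must be in [0, 1)")
        if not (0.0 < self.ortholog_one2one_fraction <= 1.0):
            raise SimConfigError("ortholog_one2one_fraction must be in (0, 1]")
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise SimConfigError("n_cells and n_genes must be positive")
        if self.marker_effect <= 1.0:
            raise SimConfigError("marker_effect must exceed 1")


# -- planted gene architecture ------------------------------------------------

_PANEL_BASE_WEIGHT = 0.2     # glial panel genes outside their target population
_CONTAMINANT_BASE = 0.02     # lineage markers outside their lineage
_PROGRAM_BASE = 0.3          # population program genes outside their population
_ACTIVATION_BASE = 0.5       # immediate-early genes: moderate everywhere


def _special_genes() -> dict:
    """Canonical symbol -> (base weight, {population: extra fold})."""
    roles: dict = {}
    for g in P.PAN_GLIAL_GENES:
        roles[g] = (_PANEL_BASE_WEIGHT, {f"glia_{s}": "marker" for s in GLIA_SUBTYPES})
    for g in P.MG_GENES:
        roles[g] = (_PANEL_BASE_WEIGHT, {"glia_MG": "marker"})
    for g in P.NMG_GENES:
        roles[g] = (_PANEL_BASE_WEIGHT, {"glia_NMG": "marker"})
    for g in P.TG_GENES:
        roles[g] = (_PANEL_BASE_WEIGHT, {"glia_TG": "marker"})
    for g in P.NMG_TG_SHARED_GENES:
        roles[g] = (_PANEL_BASE_WEIGHT, {"glia_NMG": "marker", "glia_TG": "marker"})
    for lineage, genes in P.CONTAMINANT_GENES.items():
        for g in genes:
            roles[g] = (_CONTAMINANT_BASE, {lineage: "contaminant"})
    for g in P.ACTIVATION_GENES:
        roles[g] = (_ACTIVATION_BASE, {})
    return roles


@dataclass
class _Biology:
    """The species-shared expression architecture on canonical symbols."""

    shared_genes: list
    base_weights: np.ndarray           # per shared gene
    population_fold: dict              # population -> per-gene fold vector
    marker_symbols: set                # all planted panel symbols


def _build_biology(cfg: SimConfig, rng: np.random.Generator) -> _Biology:
    special = _special_genes()
    n_shared = cfg.n_genes - cfg.n_private_genes
    # every lineage carries a broad expression program, glia included. The
    # shared Schwann-cell program (``glial_program_size`` genes, elevated in
    # all three subtypes) outweighs the per-subtype programs so rare glia
    # cohere into one atlas-level cluster, while the subtype programs (the
    # myelination program and its counterparts, at full marker strength)
    # let low-resolution re-clustering split the subtypes - mirroring how
    # the real populations behave.
    program_total = (
        len(NONGLIA_POPULATIONS) * cfg.program_size
        + cfg.glial_program_size
        + len(GLIA_SUBTYPES) * cfg.subtype_program_size
    )
    n_background = n_shared - len(special) - program_total
    if n_background <= 0:
        raise SimConfigError("n_genes too small for the planted gene architecture")

    genes = list(special)
    base = [special[g][0] for g in genes]
    program_owner: dict = {}
    for pop in NONGLIA_POPULATIONS:
        for j in range(cfg.program_size):
            name = f"{pop[:3].upper()}PROG{j + 1:03d}"
            program_owner[name] = pop
            genes.append(name)
            base.append(_PROGRAM_BASE)
    for j in range(cfg.glial_program_size):
        name = f"GLIPROG{j + 1:03d}"
        program_owner[name] = "glia"
        genes.append(name)
        base.append(_PROGRAM_BASE)
    for subtype in GLIA_SUBTYPES:
        for j in range(cfg.subtype_program_size):
            name = f"{subtype}SPROG{j + 1:03d}"
            program_owner[name] = f"glia_{subtype}"
            genes.append(name)
            base.append(_PROGRAM_BASE)
    background = [f"G{j + 1:06d}" for j in range(n_background)]
    genes.extend(background)
    base.extend(np.exp(rng.normal(0.0, 0.5, size=n_background)))
    base_weights = np.asarray(base, dtype=float)

    populations = list(NONGLIA_POPULATIONS) + [f"glia_{s}" for s in GLIA_SUBTYPES]
    fold = {pop: np.ones(n_shared) for pop in populations}
    for i, g in enumerate(genes):
        if g in special:
            for pop, kind in special[g][1].items():
                fold[pop][i] = (
                    cfg.marker_effect if kind == "marker" else cfg.contaminant_effect
                )
        elif g in program_owner:
            owner = program_owner[g]
            if owner == "glia":
                for s in GLIA_SUBTYPES:
                    fold[f"glia_{s}"][i] = cfg.program_effect
            elif owner.startswith("glia_"):
                # subtype programs carry full marker strength
                fold[owner][i] = cfg.marker_effect
            else:
                fold[owner][i] = cfg.program_effect

    # hybrid glia sit midway between two subtype programs; they bridge the
    # subtype groups in neighbor graphs the way real intermediate cells do
    for a, b in HYBRID_PAIRS:
        fold[f"glia_{a}x{b}"] = (fold[f"glia_{a}"] + fold[f"glia_{b}"]) / 2.0

    # planted glial markers (panels and glial/subtype programs) are
    # one-to-one orthologs by construction; only non-glial genes may be
    # assigned one2many/many2many homology
    marker_symbols = {
        g for g, (_, targets) in special.items()
        if any(k == "marker" for k in targets.values())
    }
    marker_symbols |= {
        g for g, owner in program_owner.items() if owner.startswith("glia")
    }
    return _Biology(genes, base_weights, fold, marker_symbols)


# -- cell composition ---------------------------------------------------------

def plan_composition(cfg: SimConfig, rng: np.random.Generator,
                     species: str) -> pd.DataFrame:
    """Draw the cell-metadata table (tissue, donor, truth label) for one species.

    Each cell is glial with probability ``glial_fraction`` and, if glial, one
    of MG/NMG/TG by ``subtype_proportions``; non-glia split into the four
    contaminant lineages. Glia carry a non-glial ``prior_annotation``
    (stromal), emulating how rare glia are mis-annotated in real atlases.
    """
    total = (cfg.species_n_cells or {}).get(species, cfg.n_cells)
    per_tissue = [total // len(cfg.tissues)] * len(cfg.tissues)
    for i in range(total - sum(per_tissue)):
        per_tissue[i] += 1

    pops = (
        list(NONGLIA_POPULATIONS)
        + [f"glia_{s}" for s in GLIA_SUBTYPES]
        + [f"glia_{a}x{b}" for a, b in HYBRID_PAIRS]
    )
    props = dict(zip(GLIA_SUBTYPES, cfg.subtype_proportions))
    pair_w = np.array([props[a] * props[b] for a, b in HYBRID_PAIRS])
    pair_w = pair_w / pair_w.sum()
    hf = cfg.hybrid_fraction
    probs = np.array(
        [(1 - cfg.glial_fraction) * p for p in NONGLIA_PROPORTIONS]
        + [cfg.glial_fraction * (1 - hf) * p for p in cfg.subtype_proportions]
        + [cfg.glial_fraction * hf * w for w in pair_w]
    )
    rows = []
    idx = 0
    for tissue, n in zip(cfg.tissues, per_tissue):
        choice = rng.choice(len(pops), size=n, p=probs)
        donors = rng.integers(1, cfg.n_donors + 1, size=n)
        for j in range(n):
            pop = pops[choice[j]]
            rows.append(
                (
                    f"{species}_c{idx:06d}",
                    tissue,
                    species,
                    f"{species}_d{donors[j]}",
                    "stromal" if pop.startswith("glia") else pop,
                    pop,
                )
            )
            idx += 1
    return pd.DataFrame(
        rows,
        columns=["cell", "tissue", "species", "donor", "prior_annotation", "truth_label"],
    )


# -- count generation ---------------------------------------------------------

def _draw_counts(weights_by_pop: dict, cells: pd.DataFrame, cfg: SimConfig,
                 rng: np.random.Generator, n_genes: int) -> sp.csr_matrix:
    """Negative-binomial counts with lognormal library factors and dropout."""
    n_cells = len(cells)
    mu_log = np.log(cfg.library_size_mean) - cfg.library_size_sigma**2 / 2
    libs = np.exp(rng.normal(mu_log, cfg.library_size_sigma, size=n_cells))
    r = cfg.dispersion
    p_by_pop = {pop: w / w.sum() for pop, w in weights_by_pop.items()}
    blocks = []
    chunk = 4000
    truth = cells["truth_label"].to_numpy()
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        mu = np.empty((n_genes, stop - start))
        for j, c in enumerate(range(start, stop)):
            mu[:, j] = libs[c] * p_by_pop[truth[c]]
        counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int32)
        if cfg.dropout_rate > 0:
            counts[rng.random(counts.shape) < cfg.dropout_rate] = 0
        blocks.append(sp.csr_matrix(counts))
    return sp.hstack(blocks, format="csr")


def _species_gene_name(symbol: str, species_index: int) -> str:
    # First species uses mouse-style capitalization; the rest are uppercase.
    return symbol.capitalize() if species_index == 0 else symbol


def empty_ortholog_table() -> pd.DataFrame:
    return pd.DataFrame(columns=ORTHOLOG_COLUMNS)


def planted_markers(cfg: SimConfig) -> dict:
    """Canonical symbols planted as elevated, by role.

    Keys: ``pan_glial`` (panel + shared glial program), each subtype
    (exclusive panel + subtype program), ``NMG_TG`` (genes elevated in both
    non-myelinating and terminal glia but not MG), and
    ``contaminant_<lineage>``. These are the generator's ground truth for
    marker-recovery checks.
    """
    out = {
        "pan_glial": set(P.PAN_GLIAL_GENES)
        | {f"GLIPROG{j + 1:03d}" for j in range(cfg.glial_program_size)},
        "MG": set(P.MG_GENES)
        | {f"MGSPROG{j + 1:03d}" for j in range(cfg.subtype_program_size)},
        "NMG": set(P.NMG_GENES)
        | {f"NMGSPROG{j + 1:03d}" for j in range(cfg.subtype_program_size)},
        "TG": set(P.TG_GENES)
        | {f"TGSPROG{j + 1:03d}" for j in range(cfg.subtype_program_size)},
        "NMG_TG": set(P.NMG_TG_SHARED_GENES),
    }
    for lineage, genes in P.CONTAMINANT_GENES.items():
        out[f"contaminant_{lineage}"] = set(genes)
    return out


def generate_multispecies(cfg: SimConfig):
    """Generate one atlas per configured species plus the ortholog table.

    Returns ``(per_species, orthologs)`` where ``per_species`` maps species
    name to ``(CountMatrix, cell table)``. Shared biology is planted on
    orthologous genes; a configurable fraction of shared genes is one-to-one,
    the remainder one2many (the later species carries a duplicated paralog).
    Planted panel genes are one-to-one by construction. Species-private genes
    are present and absent from the ortholog table.
    """
    seq = np.random.SeedSequence(cfg.seed)
    bio_seed, ortho_seed, *species_seeds = seq.spawn(2 + len(cfg.species))
    biology = _build_biology(cfg, np.random.default_rng(bio_seed))

    shared = biology.shared_genes
    n_shared = len(shared)
    n_one2one = int(round(cfg.ortholog_one2one_fraction * n_shared))
    ortho_rng = np.random.default_rng(ortho_seed)
    candidates = [g for g in shared if g not in biology.marker_symbols]
    n_multi = n_shared - n_one2one
    if n_multi > len(candidates):
        raise SimConfigError("not enough non-marker genes for the one2many quota")
    multi = set(ortho_rng.choice(candidates, size=n_multi, replace=False)) if n_multi else set()

    per_species = {}
    rows = []
    for si, (species, sseed) in enumerate(zip(cfg.species, species_seeds)):
        rng = np.random.default_rng(sseed)
        # per-species multiplicative gene effect on the shared axis
        effect = np.exp(rng.normal(0.0, cfg.species_effect_sigma, size=n_shared))
        names = [_species_gene_name(g, si) for g in shared]
        weights_base = biology.base_weights * effect
        paralog_idx = []
        if si > 0:
            for gi, g in enumerate(shared):
                if g in multi:
                    names.append(f"{g}P2")
                    paralog_idx.append(gi)
        private = [f"{species.upper()}PRIV{j + 1:04d}" for j in range(cfg.n_private_genes)]
        names.extend(private)
        private_w = np.exp(rng.normal(0.0, 0.5, size=cfg.n_private_genes))

        weights_by_pop = {}
        for pop, fold in biology.population_fold.items():
            w = weights_base * fold
            extra = [w[gi] * 0.5 for gi in paralog_idx]
            if paralog_idx:
                w = w.copy()
                w[paralog_idx] *= 0.5
            weights_by_pop[pop] = np.concatenate([w, np.array(extra), private_w])

        cells = plan_composition(cfg, rng, species)
        counts = _draw_counts(weights_by_pop, cells, cfg, rng, len(names))
        cm = CountMatrix(genes=names, cells=list(cells["cell"]), counts=counts,
                         genes_original=names)
        per_species[species] = (cm, cells)

    for ai in range(len(cfg.species)):
        for bi in range(ai + 1, len(cfg.species)):
            sa, sb = cfg.species[ai], cfg.species[bi]
            for gi, g in enumerate(shared):
                ga = _species_gene_name(g, ai)
                gb = _species_gene_name(g, bi)
                if g in multi:
                    target = f"{g}P2"
                    if ai == 0:
                        rows.append((sa, ga, sb, gb, "one2many"))
                        rows.append((sa, ga, sb, target, "one2many"))
                    else:  # both carry paralogs: record as many2many
                        rows.append((sa, ga, sb, gb, "many2many"))
                        rows.append((sa, ga, sb, target, "many2many"))
                        rows.append((sa, f"{g}P2", sb, gb, "many2many"))
                        rows.append((sa, f"{g}P2", sb, target, "many2many"))
                else:
                    rows.append((sa, ga, sb, gb, "one2one"))
    orthologs = pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS) if rows else empty_ortholog_table()
    return per_species, orthologs


def generate_atlas(cfg: SimConfig):
    """Single-species atlas: ``(CountMatrix, cell table with truth_label)``.

    Identical to the first species of :func:`generate_multispecies` under the
    same seed (it is the same code path restricted to one species).
    """
    single = replace(cfg, species=cfg.species[:1])
    per_species, _ = generate_multispecies(single)
    return per_species[single.species[0]]
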