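"""End-to-end orchestration: simulate/load -> extract -> markers -> integrate
-> conserved -> quantify, with a run manifest and a plain-directory layout
(TSV/MTX/JSON only) so every stage is independently inspectable.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .atlas_io import (
    normalize_ln10k,
    read_cell_table,
    read_counts,
    write_cell_table,
    write_counts,
)
from .cross_species import (
    CONSERVED_CRITERIA,
    IntegrationConfig,
    align_orthologs,
    call_intermediates,
    cell_panel_scores,
    conserved_marker_analysis,
    harmonize,
    integrate,
)
from .extraction import ExtractionConfig, extract_glia
from .markers import MarkerCriteria, build_pan_glial_background, find_markers
from .quant import load_count_table, pairwise_tests, proportion_ci
from .synthetic import ORTHOLOG_COLUMNS, SimConfig, empty_ortholog_table, generate_multispecies

__all__ = ["ConfigError", "RunManifest", "run_pipeline"]


class ConfigError(ValueError):
    """The pipeline config violates the documented schema."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    stages: list = field(default_factory=list)

    def record(self, name: str, counts: dict, outputs: dict) -> None:
        self.stages.append({
            "stage": name,
            "counts": counts,
            "outputs": {k: str(v) for k, v in outputs.items()},
        })

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _timestamp() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def _validate_config(config: dict) -> None:
    if "seed" not in config:
        raise ConfigError("config missing required field 'seed'")
    has_sim = "simulate" in config
    has_input = "input" in config
    if has_sim == has_input:
        raise ConfigError("config must contain exactly one of 'simulate' or 'input'")
    if has_input:
        inputs = config["input"]
        species = inputs.get("species", {})
        if not species:
            raise ConfigError("config field 'input.species' must map species to paths")
        for s, paths in species.items():
            for key in ("matrix", "genes", "cells", "cell_table"):
                if key not in paths:
                    raise ConfigError(f"config missing field 'input.species.{s}.{key}'")
        if len(species) > 1 and "ortholog_table" not in inputs:
            raise ConfigError(
                "config missing field 'input.ortholog_table' (required with more "
                "than one species)"
            )


def _load_inputs(config: dict):
    inputs = config["input"]
    per_species = {}
    for s, paths in inputs["species"].items():
        cm = read_counts(paths["matrix"], paths["genes"], paths["cells"])
        cells = read_cell_table(paths["cell_table"])
        per_species[s] = (cm, cells)
    if "ortholog_table" in inputs:
        orthologs = pd.read_csv(inputs["ortholog_table"], sep="\t")
        missing = set(ORTHOLOG_COLUMNS) - set(orthologs.columns)
        if missing:
            raise ConfigError(f"ortholog table missing columns {sorted(missing)}")
    else:
        orthologs = empty_ortholog_table()
    return per_species, orthologs


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Execute the configured stages in order and write the manifest.

    The config is a plain dict (the CLI reads it from JSON): a mandatory
    ``seed``, exactly one of ``simulate`` (SimConfig fields) or ``input``
    (per-species matrix/genes/cells/cell_table paths plus an
    ``ortholog_table`` when more than one species is given), and optional
    ``extraction`` / ``markers`` / ``integration`` / ``quantify`` sections.
    Stages short-circuit with a clear status on empty intermediate results.
    """
    _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seed=int(config["seed"]),
                           started=_timestamp())
    seed = int(config["seed"])

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        sim_kwargs.setdefault("seed", seed)
        for key in ("tissues", "species", "subtype_proportions"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim = SimConfig(**sim_kwargs)
        per_species, orthologs = generate_multispecies(sim)
        outputs = {}
        for s, (cm, cells) in per_species.items():
            sdir = out / "atlas" / s
            outputs.update({f"{s}_{k}": v for k, v in write_counts(cm, sdir).items()})
            write_cell_table(cells, sdir / "cell_table.tsv")
            outputs[f"{s}_cell_table"] = sdir / "cell_table.tsv"
        orthologs.to_csv(out / "orthologs.tsv", sep="\t", index=False)
        outputs["orthologs"] = out / "orthologs.tsv"
        manifest.record(
            "simulate",
            {f"{s}_cells": len(cells) for s, (_, cells) in per_species.items()}
            | {"ortholog_rows": len(orthologs)},
            outputs,
        )
    else:
        per_species, orthologs = _load_inputs(config)
        manifest.record(
            "load",
            {f"{s}_cells": len(cells) for s, (_, cells) in per_species.items()}
            | {"ortholog_rows": len(orthologs)},
            {},
        )

    ext_cfg = ExtractionConfig(seed=seed, **config.get("extraction", {}))
    crit = MarkerCriteria(**config.get("markers", {}))

    extractions, norms = {}, {}
    for s, (cm, cells) in per_species.items():
        norm = normalize_ln10k(cm)
        norms[s] = norm
        result = extract_glia(cm, cells, ext_cfg, norm=norm)
        extractions[s] = result
        sdir = out / "extraction" / s
        sdir.mkdir(parents=True, exist_ok=True)
        write_cell_table(result.retained_cells, sdir / "retained_cells.tsv")
        result.subtype_calls.rename_axis("cell").reset_index().to_csv(
            sdir / "subtype_calls.tsv", sep="\t", index=False)
        result.screening_report.to_csv(sdir / "screening_report.tsv", sep="\t",
                                       index=False)
        manifest.record(f"extract_{s}", result.funnel, {
            "retained": sdir / "retained_cells.tsv",
            "subtypes": sdir / "subtype_calls.tsv",
            "report": sdir / "screening_report.tsv",
        })

    # within-species subtype markers (each subtype vs the remaining glia)
    for s, result in extractions.items():
        sdir = out / "markers" / s
        sdir.mkdir(parents=True, exist_ok=True)
        calls = result.subtype_calls
        counts = {}
        for subtype in sorted(calls.unique()):
            if subtype == "unclassified":
                continue
            fg = list(calls.index[calls == subtype])
            bg = list(calls.index[calls != subtype])
            if len(fg) < 3 or not bg:
                counts[f"{subtype}_status"] = "skipped"
                continue
            table = find_markers(norms[s], fg, bg, crit)
            table.to_csv(sdir / f"{subtype}.tsv", sep="\t", index=False)
            counts[f"{subtype}_passed"] = int(table["passed"].sum())
        manifest.record(f"markers_{s}", counts, {"dir": sdir})

    conserved_out = {}
    if len(per_species) > 1:
        glia_tables = []
        glia_norms = {}
        for s, result in extractions.items():
            ids = list(result.retained_cells["cell"])
            glia_norms[s] = (norms[s].subset_cells(ids), result.retained_cells)
            glia_tables.append(result.retained_cells)
        mapping, dropped = align_orthologs(
            {s: norms[s].genes for s in per_species}, orthologs)
        harmonized, combined = harmonize(glia_norms, mapping)
        int_cfg = IntegrationConfig(seed=seed, **config.get("integration", {}))
        embedding = integrate(harmonized, combined, int_cfg)
        embedding.to_csv(out / "embedding.tsv", sep="\t")
        manifest.record("integrate", {
            "shared_genes": len(mapping), "dropped_genes": len(dropped),
            "cells": len(combined),
        }, {"embedding": out / "embedding.tsv"})

        calls = pd.concat([extractions[s].subtype_calls for s in per_species])
        scores = cell_panel_scores(harmonized, ext_cfg.panels.subtypes)
        status = call_intermediates(embedding, calls, scores,
                                    margin=ext_cfg.subtype_margin)
        results = conserved_marker_analysis(harmonized, combined, status,
                                            CONSERVED_CRITERIA)
        rows = []
        for contrast, res in results.items():
            conserved_out[contrast] = res["conserved"]
            for gene in res["conserved"]:
                row = {"contrast": contrast, "gene": gene}
                for s, table in res["per_species"].items():
                    hit = table[table["gene"] == gene].iloc[0]
                    row[f"{s}_adjusted_p"] = hit["adjusted_pvalue"]
                    row[f"{s}_fold_change"] = hit["fold_change"]
                rows.append(row)
        pd.DataFrame(rows).to_csv(out / "conserved_markers.tsv", sep="\t",
                                  index=False)
        manifest.record(
            "conserved",
            {f"{c}_conserved": len(v) for c, v in conserved_out.items()},
            {"table": out / "conserved_markers.tsv"},
        )

    if "quantify" in config:
        qcfg = config["quantify"]
        table = load_count_table(qcfg["count_table"])
        results = [
            proportion_ci(int(r["k"]), int(r["n"]), label=str(r["label"]))
            for _, r in table.iterrows()
        ]
        props = pd.DataFrame([asdict(r) for r in results])
        props.to_csv(out / "proportions.tsv", sep="\t", index=False)
        outputs = {"proportions": out / "proportions.tsv"}
        counts = {"rows": len(props)}
        if qcfg.get("pairs"):
            pw = pairwise_tests(table, [tuple(p) for p in qcfg["pairs"]])
            pw.to_csv(out / "pairwise.tsv", sep="\t", index=False)
            outputs["pairwise"] = out / "pairwise.tsv"
            counts["pairs"] = len(pw)
        manifest.record("quantify", counts, outputs)

    manifest.finished = _timestamp()
    manifest.write(out / "manifest.json")
    return manifest
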