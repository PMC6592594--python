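"""End-to-end orchestration: simulate -> quantify -> test -> annotate.

Each stage consumes and produces plain files (TSV/GMT/JSON), so any stage
can be rerun in isolation; a manifest records every threshold, seed and
input hash that affects the output. Reruns with the same configuration
produce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexp import (
    ContrastSpec,
    permutation_test,
    select_candidates,
    volcano_plot,
)
from .enrich import enrich, read_gmt, write_chart
from .network import ppi_enrichment, read_network, threshold_edges, write_clusters
from .phenotype import phenotype_hits, read_phenotype_map, write_hits
from .quantify import (
    compute_rpkm,
    compute_tpm,
    filter_expressed,
    read_counts,
    read_expression,
    read_sample_sheet,
    write_expression,
)
from .simulate import (
    SimConfig,
    simulate_annotations,
    simulate_counts,
    simulate_network,
    simulate_phenotypes,
    write_simulation,
)

logger = logging.getLogger("cryodiff")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    simulate: SimConfig | None = None
    days: list[int] | None = None  # default: every day in the sample sheet
    floor: float = 0.4
    floor_scope: str = "any"
    mode: str = "label_within_gene"
    n_permutations: int = 10_000
    p_threshold: float = 0.01
    fold_threshold: float = 2.0
    pseudocount: float = 0.5
    fdr_threshold: float = 0.05
    n_decoy_sets: int = 50
    network_cutoff: float = 0.700
    network_draws: int = 5_000
    intra_set_edge_prob: float = 0.8
    background_edge_prob: float = 0.02
    lethality_terms_only: bool = True
    log_level: str = "INFO"
    # when not simulating, these inputs must exist
    inputs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(outdir=Path(raw.pop("outdir", "cryodiff_run")), **raw)
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            cfg.simulate = SimConfig.from_dict(sim)
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            needed = {"counts", "lengths", "samples"}
            missing = needed - set(self.inputs)
            if missing:
                raise PipelineError("validate", f"missing inputs: {sorted(missing)}")
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise PipelineError("validate", f"input '{key}' not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "expression_floor": config.floor,
            "floor_scope": config.floor_scope,
            "p_threshold": config.p_threshold,
            "fold_threshold": config.fold_threshold,
            "pseudocount": config.pseudocount,
            "fdr_threshold": config.fdr_threshold,
            "network_cutoff": config.network_cutoff,
        },
        "permutation": {"mode": config.mode, "n_permutations": config.n_permutations},
        "network_draws": config.network_draws,
        "inputs": {},
        "days": {},
    }

    # -- simulate ----------------------------------------------------------
    try:
        if config.simulate is not None:
            counts_obj, sheet_obj, truth = simulate_counts(config.simulate)
            annotations = simulate_annotations(
                truth, n_decoy_sets=config.n_decoy_sets, seed=config.seed + 1
            )
            net = simulate_network(
                truth,
                intra_set_edge_prob=config.intra_set_edge_prob,
                background_edge_prob=config.background_edge_prob,
                seed=config.seed + 2,
            )
            phenotypes = simulate_phenotypes(truth, seed=config.seed + 3)
            paths = write_simulation(
                out / "inputs", counts_obj, sheet_obj, truth, annotations, net, phenotypes
            )
            config.inputs = {k: str(p) for k, p in paths.items()}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("simulate", str(exc)) from exc

    manifest["inputs"] = {
        k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in config.inputs.items()
    }

    # -- quantify ----------------------------------------------------------
    try:
        counts = read_counts(config.inputs["counts"], config.inputs["lengths"])
        sheet = read_sample_sheet(config.inputs["samples"])
        days = config.days if config.days is not None else sheet.days
        unknown = [d for d in days if d not in sheet.days]
        if unknown:
            raise ValueError(f"days not present in sample sheet: {unknown}")
        tpm = compute_tpm(counts)
        rpkm = compute_rpkm(counts)
        write_expression(tpm, out / "tpm.tsv")
        write_expression(rpkm, out / "rpkm.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("quantify", str(exc)) from exc

    collection = None
    if "annotations" in config.inputs:
        collection_path = config.inputs["annotations"]
    else:
        collection_path = None
    network_path = config.inputs.get("network")
    pheno_path = config.inputs.get("phenotypes")

    tpm = read_expression(out / "tpm.tsv", "TPM")
    rpkm = read_expression(out / "rpkm.tsv", "RPKM")

    for day in days:
        day_dir = out / f"day{day}"
        day_dir.mkdir(exist_ok=True)
        day_info: dict = {}

        # -- diffexp -------------------------------------------------------
        try:
            day_samples = [
                s
                for c in ("FRSH", "CRYO")
                for s in sheet.samples_for(day, c)
            ]
            expressed = filter_expressed(
                rpkm,
                floor=config.floor,
                scope=config.floor_scope,  # type: ignore[arg-type]
                samples=sheet,
                sample_subset=day_samples,
            )
            contrast = ContrastSpec(
                day=day,
                mode=config.mode,  # type: ignore[arg-type]
                n_permutations=config.n_permutations,
                p_threshold=config.p_threshold,
                fold_threshold=config.fold_threshold,
                pseudocount=config.pseudocount,
                seed=config.seed + 10 + day,
            )
            tpm_day = type(tpm)(tpm.values.loc[sorted(expressed)], "TPM")
            results = permutation_test(tpm_day, sheet, contrast)
            results.to_csv(day_dir / "de_table.tsv", sep="\t")
            volcano_plot(results, day_dir / "volcano.png", title=f"Day {day}")
            up, down = select_candidates(results, contrast)
            (day_dir / "up_candidates.txt").write_text("\n".join(up) + "\n")
            (day_dir / "down_candidates.txt").write_text("\n".join(down) + "\n")
            day_info["n_expressed"] = len(expressed)
            day_info["n_up"] = len(up)
            day_info["n_down"] = len(down)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"diffexp(day {day})", str(exc)) from exc

        # -- enrich (up and down lists separately) -------------------------
        if collection_path is not None:
            try:
                collection = read_gmt(collection_path, universe=expressed)
                for label, genes in (("up", up), ("down", down)):
                    chart = enrich(set(genes), collection, config.fdr_threshold)
                    write_chart(chart, day_dir / f"enrichment_{label}.tsv")
                    day_info[f"n_significant_terms_{label}"] = int(
                        chart["significant"].sum()
                    )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"enrich(day {day})", str(exc)) from exc

        # -- network -------------------------------------------------------
        if network_path is not None:
            try:
                net = threshold_edges(read_network(network_path), config.network_cutoff)
                for label, genes in (("up", up), ("down", down)):
                    report = ppi_enrichment(
                        net,
                        set(genes),
                        n_draws=config.network_draws,
                        seed=config.seed + 20 + day,
                    )
                    report.to_json(day_dir / f"network_{label}.json")
                    write_clusters(report, day_dir / f"clusters_{label}.tsv")
                    day_info[f"ppi_p_{label}"] = report.p_value
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"network(day {day})", str(exc)) from exc

        # -- phenotype (down list, as in the study) ------------------------
        if pheno_path is not None:
            try:
                pmap = read_phenotype_map(pheno_path)
                term_filter = None
                if config.lethality_terms_only:
                    from .simulate import LETHALITY_TERMS

                    term_filter = set(LETHALITY_TERMS)
                hits, freq = phenotype_hits(set(down), pmap, term_filter)
                write_hits(
                    hits, freq, day_dir / "phenotype_hits.tsv", day_dir / "phenotype_terms.json"
                )
                day_info["n_phenotype_hits"] = int(hits["gene"].nunique())
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"phenotype(day {day})", str(exc)) from exc

        manifest["days"][str(day)] = day_info

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %s", out)
    return manifest
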