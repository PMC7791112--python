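"""End-to-end driver: simulate -> preprocess -> call -> enrich -> tfs ->
scan -> network, with a reproducibility manifest.

All randomness flows from one master seed recorded in the manifest; a rerun
with the same configuration and seed produces byte-identical outputs. Each
stage writes its table(s) into the output directory and contributes a row
count to the manifest. A stage failure leaves a ``FAILED`` marker naming the
stage and re-raises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from . import io as pio
from .containers import ExpressionMatrix, GroupDesign
from .degs import DegCallParams, call_degs
from .enrichment import enrich_gene_sets, select_major_tfs
from .errors import ParameterError, PermdegError
from .motifs import PositionFrequencyMatrix, pfm_to_pwm, rank_predicted_tfs, scan_sequence
from .network import build_network, export_network
from .preprocess import filter_expressed, log2_transform, quantile_normalize
from .simulate import (
    SimulationParams,
    simulate_expression,
    simulate_gene_sets,
    simulate_interactions,
    simulate_promoters,
    simulate_tf_map,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "call", "enrich", "tfs", "scan", "network")


def _demo_pfm() -> PositionFrequencyMatrix:
    """A small synthetic 8-column motif used when no PFM file is supplied
    (e.g. fully simulated runs). Synthetic: not taken from any database."""
    counts = np.array(
        [
            [12, 0, 0, 2, 16, 0, 1, 2],
            [2, 17, 0, 1, 1, 1, 14, 2],
            [3, 1, 18, 1, 1, 0, 2, 12],
            [1, 0, 0, 14, 0, 17, 1, 2],
        ],
        dtype=float,
    )
    return PositionFrequencyMatrix("SYN0001", "synthetic_demo_motif", counts)


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run.

    Stages not listed are skipped; input paths not given are produced by the
    simulate stage (which then must be included).
    """

    outdir: str | Path = "permdeg_run"
    seed: int = 0
    stages: Sequence[str] = STAGES
    # file inputs (each optional when the simulate stage provides it)
    matrix: str | None = None
    design: str | None = None
    gmt: str | None = None
    tf_map: str | None = None
    fasta: str | None = None
    pfm: str | None = None
    edges: str | None = None
    # stage parameters
    sim: SimulationParams | None = None
    deg: DegCallParams | None = None
    min_fpkm: float = 1.0
    log2_offset: float = 1.0
    enrich_alpha: float = 0.05
    tf_alpha: float = 0.05
    tf_min_targets: int = 5
    scan_threshold: float = 0.9
    selected_sets: Sequence[str] | None = None
    # simulated ancillary-input sizes
    sim_n_tfs: int = 50
    sim_targets_per_tf: int = 20
    sim_planted_tfs: int = 5
    sim_n_sets: int = 40
    sim_set_size_range: tuple[int, int] = (10, 40)
    sim_planted_sets: int = 5
    sim_n_promoters: int = 5
    sim_promoter_length: int = 500
    sim_n_edges: int = 300
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ParameterError(f"unknown stages {unknown}")
        self.stages = [s for s in STAGES if s in self.stages]
        if self.sim is None:
            self.sim = SimulationParams(seed=self.seed)
        if self.deg is None:
            self.deg = DegCallParams(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimulationParams(**raw["sim"])
        if "deg" in raw and isinstance(raw["deg"], dict):
            raw["deg"] = DegCallParams(**raw["deg"])
        if "sim_set_size_range" in raw:
            raw["sim_set_size_range"] = tuple(raw["sim_set_size_range"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("matrix", "design", "gmt", "tf_map", "fasta", "pfm", "edges"):
            value = getattr(self, name)
            if value is not None and not Path(value).is_file():
                raise ParameterError(f"input file for {name!r} not found: {value}")

    def echo(self) -> dict:
        d = asdict(self)
        d["outdir"] = str(d["outdir"])
        d["stages"] = list(self.stages)
        d["selected_sets"] = (
            list(self.selected_sets) if self.selected_sets is not None else None
        )
        d["sim_set_size_range"] = list(self.sim_set_size_range)
        if d.get("sim"):
            d["sim"]["baseline_log2_range"] = list(
                d["sim"]["baseline_log2_range"]
            )
        return d


class StageError(PermdegError, RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the manifest."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "stages": {},
    }
    state: dict = {}
    current = ""
    try:
        for stage in config.stages:
            current = stage
            logger.info("running stage %s", stage)
            rows = _STAGE_FUNCS[stage](config, state, outdir)
            manifest["stages"][stage] = rows
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current}: {exc}\n")
        pio.write_json(manifest, outdir / "manifest.json")
        raise StageError(current, exc) from exc
    pio.write_json(manifest, outdir / "manifest.json")
    return manifest


# --- stage implementations -------------------------------------------------


def _stage_simulate(config: RunConfig, state: dict, outdir: Path) -> dict:
    study = simulate_expression(config.sim)
    state["study"] = study
    state["matrix"] = study.matrix
    state["design"] = study.design
    pio.write_expression(study.matrix, outdir / "matrix.tsv")
    pio.write_design(study.design, outdir / "design.tsv")
    truth = study.truth_de.to_frame()
    truth["truth_log2_effect"] = study.truth_log2_effect
    truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="gene_id")

    counts = {"n_genes": study.matrix.n_genes, "n_samples": study.matrix.n_samples}
    if "tfs" in config.stages and config.tf_map is None:
        tf_map, planted = simulate_tf_map(
            config.sim_n_tfs,
            config.sim_targets_per_tf,
            config.sim_planted_tfs,
            study.truth_de,
            config.seed,
        )
        state["tf_map"], state["planted_tfs"] = tf_map, planted
        pio.write_tf_map(tf_map, outdir / "tf_map.tsv")
        counts["n_tfs"] = len(tf_map)
    if "enrich" in config.stages and config.gmt is None:
        collection, set_truth = simulate_gene_sets(
            config.sim_n_sets,
            config.sim_set_size_range,
            study.truth_de,
            config.sim_planted_sets,
            config.seed,
        )
        state["gene_sets"], state["set_truth"] = collection, set_truth
        pio.write_gmt(collection, outdir / "gene_sets.gmt")
        counts["n_gene_sets"] = len(collection)
    if "scan" in config.stages and config.fasta is None:
        pfm = state.get("pfm") or _demo_pfm()
        state["pfm"] = pfm
        plants = [
            (i, 60 + 40 * i, "+" if i % 2 == 0 else "-")
            for i in range(min(3, config.sim_n_promoters))
        ]
        sequences, site_truth = simulate_promoters(
            pfm,
            config.sim_n_promoters,
            config.sim_promoter_length,
            plants,
            config.seed,
        )
        state["sequences"], state["site_truth"] = sequences, site_truth
        pio.write_fasta(sequences, outdir / "promoters.fasta")
        pio.write_jaspar([pfm], outdir / "motif.jaspar")
        counts["n_promoters"] = len(sequences)
    if "network" in config.stages and config.edges is None:
        edges = simulate_interactions(
            list(study.truth_de.index[study.truth_de != "silent"]),
            config.sim_n_edges,
            config.seed,
        )
        # bias edges toward DE genes so the network stage has structure
        de = study.de_genes
        if len(de) >= 2:
            extra = simulate_interactions(de, min(config.sim_n_edges, len(de)), config.seed + 1)
            edges = list(dict.fromkeys(edges + extra))
        state["edges"] = edges
        pio.write_edges_tsv(edges, outdir / "interactions.tsv")
        counts["n_edges"] = len(edges)
    return counts


def _require_matrix(config: RunConfig, state: dict) -> ExpressionMatrix:
    if "matrix" not in state:
        if config.matrix is None:
            raise ParameterError("no expression matrix: supply a path or run simulate")
        state["matrix"] = pio.read_expression(config.matrix)
    return state["matrix"]


def _require_design(config: RunConfig, state: dict) -> GroupDesign:
    if "design" not in state:
        if config.design is None:
            raise ParameterError("no design: supply a path or run simulate")
        state["design"] = pio.read_design(config.design)
    return state["design"]


def _stage_preprocess(config: RunConfig, state: dict, outdir: Path) -> dict:
    matrix = _require_matrix(config, state)
    expressed = filter_expressed(matrix, config.min_fpkm)
    processed = quantile_normalize(
        log2_transform(expressed, config.log2_offset)
    )
    state["processed"] = processed
    pio.write_expression(processed, outdir / "processed.tsv")
    return {
        "n_genes_in": matrix.n_genes,
        "n_genes_expressed": processed.n_genes,
    }


def _stage_call(config: RunConfig, state: dict, outdir: Path) -> dict:
    if "processed" not in state:
        _stage_preprocess(config, state, outdir)
    design = _require_design(config, state)
    table, summary, _ = call_degs(state["processed"], design, config.deg)
    state["deg_table"], state["deg_summary"] = table, summary
    table.to_csv(outdir / "deg_table.tsv", sep="\t")
    pio.write_json(summary, outdir / "deg_summary.json")
    return {k: summary[k] for k in ("n_deg", "n_up", "n_down", "cutoff_log2")}


def _degs_and_universe(state: dict) -> tuple[list[str], list[str]]:
    table = state["deg_table"]
    return list(table.index[table["is_deg"]]), list(table.index)


def _stage_enrich(config: RunConfig, state: dict, outdir: Path) -> dict:
    if "deg_table" not in state:
        raise ParameterError("enrich stage needs the call stage")
    collection = state.get("gene_sets")
    if collection is None:
        if config.gmt is None:
            raise ParameterError("no gene sets: supply a GMT or run simulate")
        collection = pio.read_gmt(config.gmt)
    degs, universe = _degs_and_universe(state)
    table = enrich_gene_sets(degs, collection, universe, config.enrich_alpha)
    state["enrichment"] = table
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return {"n_sets_tested": len(table), "n_significant": int(table["significant"].sum())}


def _stage_tfs(config: RunConfig, state: dict, outdir: Path) -> dict:
    if "deg_table" not in state:
        raise ParameterError("tfs stage needs the call stage")
    tf_map = state.get("tf_map")
    if tf_map is None:
        if config.tf_map is None:
            raise ParameterError("no TF map: supply a path or run simulate")
        tf_map = pio.read_tf_map(config.tf_map)
    degs, universe = _degs_and_universe(state)
    table = select_major_tfs(
        tf_map, degs, universe, config.tf_alpha, config.tf_min_targets
    )
    state["major_tfs"] = table
    table.to_csv(outdir / "major_tfs.tsv", sep="\t", index=False)
    return {"n_tfs_tested": len(table), "n_major": int(table["major"].sum())}


def _stage_scan(config: RunConfig, state: dict, outdir: Path) -> dict:
    sequences = state.get("sequences")
    if sequences is None:
        if config.fasta is None:
            raise ParameterError("no sequences: supply a FASTA or run simulate")
        sequences = pio.read_fasta(config.fasta)
    if config.pfm is not None:
        pfms = pio.read_jaspar(config.pfm)
    elif state.get("pfm") is not None:
        pfms = [state["pfm"]]
    else:
        pfms = [_demo_pfm()]
    rows = []
    hits_by_motif: dict[str, list] = {}
    for pfm in pfms:
        pwm = pfm_to_pwm(pfm)
        for seq_id, seq in sequences.items():
            hits = scan_sequence(
                seq, pwm, config.scan_threshold, sequence_id=seq_id
            )
            hits_by_motif.setdefault(pfm.motif_id, []).extend(hits)
            rows.extend(
                {
                    "motif_id": pfm.motif_id,
                    "sequence_id": h.sequence_id,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "raw_score": h.raw_score,
                    "relative_score": h.relative_score,
                }
                for h in hits
            )
    import pandas as pd

    hits_frame = pd.DataFrame(
        rows,
        columns=[
            "motif_id",
            "sequence_id",
            "start",
            "end",
            "strand",
            "raw_score",
            "relative_score",
        ],
    )
    hits_frame.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    ranked = rank_predicted_tfs(hits_by_motif)
    ranked.to_csv(outdir / "predicted_tfs.tsv", sep="\t", index=False)
    state["motif_hits"] = hits_frame
    return {"n_hits": len(hits_frame), "n_motifs_with_hits": len(ranked)}


def _stage_network(config: RunConfig, state: dict, outdir: Path) -> dict:
    if "deg_table" not in state:
        raise ParameterError("network stage needs the call stage")
    edges = state.get("edges")
    if edges is None:
        if config.edges is None:
            raise ParameterError("no interactions: supply a path or run simulate")
        edges = (
            pio.read_sif(config.edges)
            if str(config.edges).endswith(".sif")
            else pio.read_edges_tsv(config.edges)
        )
    selected = None
    if config.selected_sets:
        collection = state.get("gene_sets")
        if collection is None and config.gmt is not None:
            collection = pio.read_gmt(config.gmt)
        if collection is None:
            raise ParameterError("selected_sets given but no gene sets available")
        selected = {
            s: collection[s] for s in config.selected_sets if s in collection
        }
    network = build_network(state["deg_table"], selected, edges)
    for fmt in ("sif", "xml"):
        export_network(network, outdir / "network", fmt)
    state["network"] = network
    return {"n_nodes": len(network.nodes), "n_edges": len(network.edges)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "call": _stage_call,
    "enrich": _stage_enrich,
    "tfs": _stage_tfs,
    "scan": _stage_scan,
    "network": _stage_network,
}
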