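"""End-to-end orchestration: simulate -> filter -> DE x4 -> patterns ->
selection -> motif scan -> enrichment -> peak annotation.

A single config object carries every path and threshold; ``run_all``
executes the stages that have inputs, fails fast on the first error, logs
per-stage summaries to stderr and writes a machine-readable manifest with
SHA-256 hashes of inputs and outputs so deterministic re-runs are
byte-verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import de, enrichment, io, motifs, patterns, peaks, synthetic

logger = logging.getLogger("oxpattern")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the cluster-selection rule for one run.

    All thresholds default to the published analysis: expression filter
    >= 10, q < 0.05, |log2FC| > 1, peak fold > 2, 3 kb promoter scan
    windows, -5 kb..+0.5 kb peak-to-promoter windows.
    """

    # inputs (any may be None; stages without inputs are skipped)
    counts: str | None = None
    metadata: str | None = None
    genome: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    peaks_table: str | None = None
    # simulation (used when counts is None)
    simulate: bool = False
    n_genes: int = 1000
    effect_logfc: float = 3.0
    dispersion: float = 0.05
    baseline_mean: float = 100.0
    pattern_spec: dict[str, float] = field(
        default_factory=lambda: {"1,0,0,-1": 0.05, "-1,0,0,1": 0.05}
    )
    # thresholds
    expression_threshold: float = 10.0
    q_threshold: float = 0.05
    logfc_threshold: float = 1.0
    fold_threshold: float = 2.0
    scan_window: int = 3000
    promoter_upstream: int = 5000
    promoter_downstream: int = 500
    anchor: str = "ATG"
    selection_rule: list[str] | None = None  # explicit code list, else default
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("expression_threshold", "q_threshold", "logfc_threshold",
                     "fold_threshold", "scan_window", "promoter_upstream",
                     "promoter_downstream"):
            if getattr(self, name) is None or getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage with available inputs; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "stages": {},
        "hashes": {},
    }

    def record(stage: str, **info: Any) -> None:
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    def hash_out(path: Path) -> None:
        manifest["hashes"][path.name] = _sha256(path)

    # --- inputs / simulation -------------------------------------------
    if config.counts is None and not config.simulate:
        raise FileNotFoundError("no counts input and simulation disabled")
    for name in ("counts", "metadata", "genome", "annotation", "gene_sets", "peaks_table"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured input {name!r} not found: {p}")

    truth = None
    if config.counts is not None:
        cm = io.read_counts(config.counts, config.metadata)
        manifest["hashes"]["counts_in"] = _sha256(Path(config.counts))
    else:
        spec = {
            patterns.str_to_code(k): v for k, v in config.pattern_spec.items()
        }
        design = synthetic.SimulationDesign(
            n_genes=config.n_genes,
            effect_logfc=config.effect_logfc,
            dispersion=config.dispersion,
            baseline_mean=config.baseline_mean,
            pattern_spec=spec,
            seed=config.seed,
        )
        cm, truth = synthetic.simulate_counts(design)
        io.write_counts(cm, outdir / "counts.tsv", outdir / "metadata.tsv")
        io.write_truth(truth, outdir / "truth.json")
        for f in ("counts.tsv", "metadata.tsv", "truth.json"):
            hash_out(outdir / f)
        record("simulate", n_genes=config.n_genes, seed=config.seed)

    # --- filter + DE ----------------------------------------------------
    filtered = de.filter_expressed(cm, config.expression_threshold)
    record("filter", genes_in=len(cm.gene_ids), genes_out=len(filtered.gene_ids))

    tables = de.run_comparisons(
        filtered,
        q_threshold=config.q_threshold,
        logfc_threshold=config.logfc_threshold,
    )
    for spec_ in de.CANONICAL_COMPARISONS:
        path = outdir / f"de_position{spec_.position}.tsv"
        io.write_de_table(tables[spec_.position], path, comparison=spec_.name)
        hash_out(path)
    record(
        "de",
        **{f"significant_pos{p}": int(t["significant"].sum()) for p, t in tables.items()},
    )

    # --- patterns -------------------------------------------------------
    codes = patterns.assign_patterns(tables)
    cluster_table = patterns.enumerate_clusters(codes)
    rule = config.selection_rule if config.selection_rule else patterns.default_selection_rule
    selected = patterns.select_responsive(cluster_table, rule)
    summary = patterns.selection_summary(selected)
    cluster_table.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    selected.to_csv(outdir / "clusters_selected.tsv", sep="\t", index=False)
    with open(outdir / "pattern_summary.json", "w") as fh:
        json.dump({"n_clusters": int(len(cluster_table)), **summary}, fh, indent=1)
    for f in ("clusters.tsv", "clusters_selected.tsv", "pattern_summary.json"):
        hash_out(outdir / f)
    record("patterns", n_clusters=int(len(cluster_table)),
           **{f"selected_{k}": v for k, v in summary.items()})
    selected_genes = sorted(
        g for row in selected.itertuples(index=False) for g in row.gene_ids.split(";") if g
    )

    # --- motif scan -----------------------------------------------------
    if config.genome is not None and config.annotation is not None:
        import pyfaidx

        genome = pyfaidx.Fasta(config.genome)
        if str(config.annotation).endswith((".bed", ".bed6")):
            anchors = io.anchors_from_bed(config.annotation, anchor=config.anchor)
        else:
            anchors = io.anchors_from_gff3(config.annotation, anchor=config.anchor)
        use = anchors[anchors["gene_id"].isin(selected_genes)] if selected_genes else anchors
        _, seqs = motifs.extract_promoters(use, genome, window_length=config.scan_window)
        hits = motifs.scan_promoters(seqs)
        with open(outdir / "motif_hits.tsv", "w") as fh:
            fh.write("# motif hits; offset_1based is 1-based inclusive from the "
                     "window 5' end in coding orientation\n")
            hits.to_csv(fh, sep="\t", index=False)
        hash_out(outdir / "motif_hits.tsv")
        counts_kn = {
            m.name: "%d/%d" % motifs.genes_with_motif(hits, seqs, m.name)[:2]
            for m in motifs.DEFAULT_MOTIFS
        }
        record("scan", n_promoters=len(seqs), **counts_kn)

    # --- enrichment -----------------------------------------------------
    if config.gene_sets is not None:
        collection = enrichment.read_gmt(config.gene_sets)
        universe = list(filtered.gene_ids)
        query = selected_genes or [g for g, c in codes.items() if any(c)]
        if query:
            res = enrichment.enrich(query, collection, universe)
            res.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            hash_out(outdir / "enrichment.tsv")
            record("enrich", n_sets=len(collection), n_query=len(set(query) & set(universe)))
        else:
            record("enrich", skipped="empty query")

    # --- peaks ----------------------------------------------------------
    if config.peaks_table is not None:
        peak_df = io.read_peaks(config.peaks_table)
        kept = peaks.filter_peaks_fold(peak_df, config.fold_threshold)
        io.write_peaks(kept, outdir / "peaks_filtered.tsv")
        hash_out(outdir / "peaks_filtered.tsv")
        info: dict[str, Any] = {"peaks_in": len(peak_df), "peaks_kept": len(kept)}
        if config.annotation is not None and not str(config.annotation).endswith(".bed"):
            models = io.gene_models_from_gff3(config.annotation)
            genes, assignments = peaks.assign_to_promoters(
                kept, models, config.promoter_upstream, config.promoter_downstream
            )
            classified = peaks.classify_peaks(
                kept, models, config.promoter_upstream, config.promoter_downstream
            )
            assignments.to_csv(outdir / "peak_assignments.tsv", sep="\t", index=False)
            with open(outdir / "peak_classes.json", "w") as fh:
                json.dump(peaks.class_fractions(classified), fh, indent=1)
            hash_out(outdir / "peak_assignments.tsv")
            hash_out(outdir / "peak_classes.json")
            info["promoter_genes"] = len(genes)
        record("peaks", **info)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
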