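"""End-to-end orchestration: generate/load -> estimate -> aggregate ->
normalize -> test -> segment -> enrich, writing a deterministic result
bundle (TSV tables, Venn summary, enrichment table, browser tracks, run
metadata)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import DepletionScenario, ExpressionMatrix, GenomeAnnotation, HybridizationSet, ProbeDesign
from .differential import DepletionModel, DepletionResults
from .enrichment import CategoryTable, enrichment_table
from .io import (
    PipelineConfig,
    export_tracks,
    load_annotation,
    load_hybridizations,
    load_probes,
    write_annotation,
    write_hybridizations,
    write_probes,
)
from .normalize import apply_normalization, fit_normalization, select_least_variant_set
from .probes import aggregate_expression, estimate_probe_profiles
from .segments import Segment, chromosome_median, classify_segment, detect_segments
from .simulate import (
    design_probes,
    make_genome,
    make_random_categories,
    sample_effects,
    simulate_expression,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    annotation: GenomeAnnotation
    design: ProbeDesign
    raw: HybridizationSet
    expression: ExpressionMatrix
    normalized: ExpressionMatrix
    results: DepletionResults
    segments: list[Segment]
    enrichment: pd.DataFrame | None
    outputs: dict = field(default_factory=dict)


def _segments_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "strand": [s.strand for s in segments],
            "label": [s.label_prefix for s in segments],
            "class": [s.klass for s in segments],
            "antisense_to": [",".join(s.antisense_to) for s in segments],
            "anova_F": [s.anova_F for s in segments],
            "anova_p": [s.anova_p for s in segments],
            "n_probes": [len(s.probe_ids) for s in segments],
        },
        index=pd.Index([s.id for s in segments], name="segment"),
    )


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the full analysis; any stage failure aborts with its name.

    With a generator-backed config, inputs are synthesised from
    ``config.seed``; identical configs and seeds give byte-identical
    result bundles.
    """
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        if config.annotation_path:
            annotation = load_annotation(config.annotation_path)
            design = load_probes(config.probes_path, spacing=config.spacing)
            raw = load_hybridizations(config.intensities_prefix)
            categories = None
            if config.categories_path:
                categories = CategoryTable.from_frame(
                    pd.read_csv(config.categories_path, sep="\t")
                )
        else:
            annotation = make_genome(config.generator, seed=config.seed)
            design = design_probes(annotation, spacing=config.spacing)
            effects = sample_effects(
                annotation, seed=config.seed + 1, frac_affected=config.frac_affected
            )
            raw = simulate_expression(
                annotation,
                design,
                effects=effects,
                scenario=DepletionScenario(),
                noise=config.noise,
                seed=config.seed + 2,
                n_replicates=config.n_replicates,
                config=config.generator,
            )
            gene_ids = [f.id for f in annotation.genes]
            categories = CategoryTable(
                make_random_categories(gene_ids, seed=config.seed + 3)
            )

        stage = "estimate"
        profiles = estimate_probe_profiles(raw, design=design)

        stage = "aggregate"
        expression = aggregate_expression(
            profiles, annotation, design, min_probes=config.min_probes
        )

        stage = "normalize"
        gene_ids = [f.id for f in annotation.genes]
        gene_matrix = ExpressionMatrix(
            values=expression.values.loc[
                [g for g in gene_ids if g in expression.values.index]
            ].dropna(),
            samples=expression.samples,
        )
        lv_set = select_least_variant_set(gene_matrix, config.normalization)
        model = fit_normalization(gene_matrix, lv_set, config.normalization)
        normalized_all = apply_normalization(
            ExpressionMatrix(values=expression.values.dropna(), samples=expression.samples),
            model,
        )

        stage = "test"
        fit = DepletionModel(normalized_all, config=config.differential).fit()

        stage = "segments"
        segs = detect_segments(raw, profiles, annotation, design, config.segments)
        med = chromosome_median(raw, design).median()
        for s in segs:
            classify_segment(s, annotation, profiles, design, config.segments, background=float(med))

        stage = "enrich"
        enr = None
        if categories is not None and categories.n_categories:
            enr = enrichment_table(
                fit.table.loc[fit.table.index.intersection(gene_ids)],
                categories,
                alpha=config.enrichment_alpha,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        annotation=annotation,
        design=design,
        raw=raw,
        expression=expression,
        normalized=normalized_all,
        results=fit,
        segments=segs,
        enrichment=enr,
    )

    if write:
        stage = "write"
        write_annotation(annotation, outdir / "annotation.gff3")
        write_probes(design, outdir / "probes.bed")
        write_hybridizations(raw, outdir / "intensities")
        expression.values.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6f")
        normalized_all.values.to_csv(
            outdir / "expression_normalized.tsv", sep="\t", float_format="%.6f"
        )
        fit.supplementary_table().to_csv(
            outdir / "differential.tsv", sep="\t", float_format="%.6g"
        )
        _segments_frame(segs).to_csv(outdir / "segments.tsv", sep="\t", float_format="%.6g")
        if enr is not None:
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", float_format="%.6g")
        venn = fit.venn()
        venn_json = {
            "up": {"+".join(sorted(k)): v for k, v in venn.up.items()},
            "down": {"+".join(sorted(k)): v for k, v in venn.down.items()},
            "mixed": venn.mixed,
            "total_affected": venn.total_affected,
        }
        with (outdir / "venn.json").open("w") as fh:
            json.dump(venn_json, fh, indent=2, sort_keys=True)
        export_tracks(
            profiles,
            design,
            raw.samples,
            outdir / "tracks",
            chromosome_median=float(med),
        )
        run_meta = {
            "seed": config.seed,
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "n_units": int(len(expression.values)),
            "n_segments": len(segs),
        }
        with (outdir / "run.json").open("w") as fh:
            json.dump(run_meta, fh, indent=2, sort_keys=True)
        result.outputs = {"outdir": str(outdir), **run_meta}
        log.info("pipeline complete: %s", outdir)
    return result
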