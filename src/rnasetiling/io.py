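"""Readers and writers for the pipeline's standard formats.

GFF3 for annotations (1-based closed on disk, 0-based half-open in
memory), BED6 for probe designs (score column carries uniqueness 0/1),
TSV for intensity/expression matrices with a sample-metadata sidecar,
bedGraph for genome-browser tracks, YAML for configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    Feature,
    GenomeAnnotation,
    GeneratorConfig,
    HybridizationSet,
    NoiseConfig,
    Probe,
    ProbeDesign,
    RNASES,
)
from .normalize import NormalizationConfig
from .segments import SegmentConfig
from .differential import DifferentialConfig

log = logging.getLogger(__name__)

__all__ = [
    "write_annotation",
    "load_annotation",
    "write_probes",
    "load_probes",
    "write_hybridizations",
    "load_hybridizations",
    "export_tracks",
    "PipelineConfig",
]

_SEQID = "chrom"


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {_SEQID} 1 {annotation.genome_length}\n")
        for f in annotation.features:
            attrs = f"ID={f.id}"
            if f.category_tags:
                attrs += ";category_tags=" + ",".join(f.category_tags)
            fh.write(
                "\t".join(
                    [
                        _SEQID,
                        "rnasetiling",
                        f.kind,
                        str(f.start + 1),  # to 1-based closed
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


class GFFParseError(ValueError):
    pass


def load_annotation(path) -> GenomeAnnotation:
    """Parse GFF3, converting to 0-based half-open coordinates.

    Malformed lines raise :class:`GFFParseError` naming the line number.
    """
    path = Path(path)
    features: list[Feature] = []
    genome_length = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    genome_length = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GFFParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GFFParseError(f"{path}:{lineno}: end {end1} < start {start1}")
            if cols[6] not in ("+", "-"):
                raise GFFParseError(f"{path}:{lineno}: bad strand {cols[6]!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise GFFParseError(f"{path}:{lineno}: missing ID attribute")
            tags = tuple(
                t for t in attrs.get("category_tags", "").split(",") if t
            )
            features.append(
                Feature(
                    id=attrs["ID"],
                    start=start1 - 1,  # to 0-based half-open
                    end=end1,
                    strand=cols[6],
                    kind=cols[2],
                    category_tags=tags,
                )
            )
    if genome_length == 0:
        genome_length = max((f.end for f in features), default=1)
    return GenomeAnnotation(features=features, genome_length=genome_length)


def write_probes(design: ProbeDesign, path) -> None:
    """BED6; the score column carries uniqueness (1 unique, 0 repeated)."""
    with Path(path).open("w") as fh:
        for p in design:
            fh.write(
                f"{_SEQID}\t{p.start}\t{p.end}\t{p.id}\t{1 if p.unique else 0}\t{p.strand}\n"
            )


def load_probes(path, spacing: int = 22) -> ProbeDesign:
    probes = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            probes.append(
                Probe(
                    id=cols[3],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=cols[5],
                    unique=cols[4] not in ("0", "0.0"),
                )
            )
    return ProbeDesign(probes=probes, spacing=spacing)


def write_hybridizations(hyb: HybridizationSet, prefix) -> None:
    """TSV matrix plus a ``<prefix>.samples.tsv`` metadata sidecar."""
    prefix = Path(prefix)
    hyb.intensities.to_csv(f"{prefix}.tsv", sep="\t", float_format="%.6f")
    hyb.samples.to_csv(f"{prefix}.samples.tsv", sep="\t")


def load_hybridizations(prefix) -> HybridizationSet:
    prefix = Path(prefix)
    intensities = pd.read_csv(f"{prefix}.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col=0)
    return HybridizationSet(intensities=intensities, samples=samples)


def _write_bedgraph(path, rows) -> None:
    rows = sorted(rows)
    with Path(path).open("w") as fh:
        for start, end, value in rows:
            fh.write(f"{_SEQID}\t{start}\t{end}\t{value:.4f}\n")


def export_tracks(
    profiles,
    design: ProbeDesign,
    samples: pd.DataFrame,
    outdir,
    chromosome_median: float | None = None,
) -> dict:
    """Per-strand bedGraph tracks of expression and per-RNase log2 ratios.

    Non-unique probes are omitted.  A JSON sidecar records the horizontal
    reference levels (chromosome median and the 5x / 10x thresholds).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pframe = design.to_frame()
    mat = profiles.profiles if hasattr(profiles, "profiles") else profiles
    mat = mat.loc[mat.index.intersection(pframe.index[pframe["unique"]])]

    conds = samples.loc[mat.columns, "condition"]
    iptg = samples.loc[mat.columns, "iptg"]
    mean_of = {}
    for cond in ("wt", "rnc", "rnjA", "rny"):
        cols = [
            c
            for c in mat.columns
            if conds[c] == cond and (cond == "wt" or iptg[c] == "minus")
        ]
        if cols:
            mean_of[cond] = mat[cols].mean(axis=1)

    written = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        ids = [pid for pid in mat.index if pframe.at[pid, "strand"] == strand]
        coords = [(pframe.at[pid, "start"], pframe.at[pid, "end"]) for pid in ids]
        for cond, series in mean_of.items():
            path = outdir / f"expression_{cond}_{tag}.bedGraph"
            _write_bedgraph(
                path, [(s, e, series[pid]) for pid, (s, e) in zip(ids, coords)]
            )
            written.append(path.name)
        if "wt" in mean_of:
            for rnase, cond in zip(RNASES, ("rnc", "rnjA", "rny")):
                if cond not in mean_of:
                    continue
                ratio = mean_of[cond] - mean_of["wt"]
                path = outdir / f"log2ratio_RNase{rnase}_{tag}.bedGraph"
                _write_bedgraph(
                    path, [(s, e, ratio[pid]) for pid, (s, e) in zip(ids, coords)]
                )
                written.append(path.name)

    sidecar = {"tracks": sorted(written)}
    if chromosome_median is not None:
        sidecar["reference_levels"] = {
            "chromosome_median": chromosome_median,
            "5x": chromosome_median + float(np.log2(5)),
            "10x": chromosome_median + float(np.log2(10)),
        }
    with (outdir / "tracks.json").open("w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return sidecar


@dataclass
class PipelineConfig:
    """End-to-end run configuration (generator-backed or file-backed)."""

    seed: int = 0
    outdir: str = "results"
    # file inputs; when None the generator is used
    annotation_path: str | None = None
    probes_path: str | None = None
    intensities_prefix: str | None = None
    categories_path: str | None = None
    # generator settings
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    frac_affected: float = 0.25
    n_replicates: int = 2
    # analysis settings
    spacing: int = 22
    min_probes: int = 3
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    segments: SegmentConfig = field(default_factory=SegmentConfig)
    enrichment_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        for key, sub in (
            ("generator", GeneratorConfig),
            ("noise", NoiseConfig),
            ("normalization", NormalizationConfig),
            ("differential", DifferentialConfig),
            ("segments", SegmentConfig),
        ):
            if key in data and isinstance(data[key], dict):
                if key == "differential" and "fold_changes" in data[key]:
                    data[key]["fold_changes"] = tuple(data[key]["fold_changes"])
                data[key] = sub(**data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
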