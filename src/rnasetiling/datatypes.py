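"""Core data containers shared across the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)``.  File
exporters convert to the 1-based closed convention of GFF3/BED where the
format requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNASES = ("III", "J1", "Y")
#: depletion-strain condition labels, keyed by the RNase they deplete
CONDITION_OF_RNASE = {"III": "rnc", "J1": "rnjA", "Y": "rny"}
RNASE_OF_CONDITION = {v: k for k, v in CONDITION_OF_RNASE.items()}
MAIN_CONDITIONS = ("wt", "rnc", "rnjA", "rny")


@dataclass(frozen=True)
class Feature:
    """One annotated element: a CDS, a known regulatory RNA, or a segment."""

    id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str  # 'CDS', 'misc_RNA' or 'segment'
    category_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id}: strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError(f"feature {self.id}: invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int, strand: str | None = None) -> bool:
        if strand is not None and strand != self.strand:
            return False
        return self.start < end and start < self.end


@dataclass
class GenomeAnnotation:
    features: list[Feature]
    genome_length: int

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("feature ids must be unique")
        for f in self.features:
            if f.end > self.genome_length:
                raise ValueError(
                    f"feature {f.id} extends beyond genome_length={self.genome_length}"
                )

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)

    @property
    def genes(self) -> list[Feature]:
        """Annotated transcription units that block segment discovery."""
        return [f for f in self.features if f.kind in ("CDS", "misc_RNA")]

    @property
    def segments(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "segment"]


@dataclass(frozen=True)
class Probe:
    id: str
    start: int
    end: int
    strand: str
    unique: bool = True


@dataclass
class ProbeDesign:
    """Two-strand tiling design at fixed probe spacing (default 22 nt)."""

    probes: list[Probe]
    spacing: int = 22

    def __post_init__(self) -> None:
        self.probes = sorted(self.probes, key=lambda p: (p.strand, p.start))

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": [p.start for p in self.probes],
                "end": [p.end for p in self.probes],
                "strand": [p.strand for p in self.probes],
                "unique": [p.unique for p in self.probes],
            },
            index=pd.Index([p.id for p in self.probes], name="probe"),
        )


@dataclass(frozen=True)
class SampleMeta:
    condition: str  # 'wt', 'rnc', 'rnjA', 'rny'
    iptg: str  # 'plus', 'minus', 'na'
    replicate: int

    @property
    def name(self) -> str:
        return f"{self.condition}_{self.iptg}_{self.replicate}"


def sample_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": [s.condition for s in samples],
            "iptg": [s.iptg for s in samples],
            "replicate": [s.replicate for s in samples],
        },
        index=pd.Index([s.name for s in samples], name="sample"),
    )


@dataclass
class HybridizationSet:
    """Raw probe x sample log2 intensities with sample metadata.

    ``truth`` (generator output only) holds the noiseless per-probe
    expression, the per-probe affinity vector and the per-sample shift
    vector used to synthesise the intensities.
    """

    intensities: pd.DataFrame  # probes x samples
    samples: pd.DataFrame  # index: sample name; columns condition/iptg/replicate
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.intensities.to_numpy()).all():
            raise ValueError("intensities must be finite")
        missing = set(self.intensities.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")

    @property
    def conditions(self) -> pd.Series:
        return self.samples.loc[self.intensities.columns, "condition"]

    def main_condition_samples(self) -> list[str]:
        """The four main experiments: wt and the three -IPTG depletions."""
        keep = []
        for name in self.intensities.columns:
            cond = self.samples.at[name, "condition"]
            iptg = self.samples.at[name, "iptg"]
            if cond == "wt" or iptg == "minus":
                keep.append(name)
        return keep


@dataclass
class ExpressionMatrix:
    """Aggregated unit (gene/segment) x sample log2 expression values."""

    values: pd.DataFrame  # units x samples
    samples: pd.DataFrame
    n_probes: pd.Series | None = None  # eligible probes per unit
    flagged: frozenset = frozenset()  # units with < min_probes eligible probes

    @property
    def units(self) -> pd.Index:
        return self.values.index

    def condition_of(self, sample: str) -> str:
        return self.samples.at[sample, "condition"]

    def condition_means(self, conditions=MAIN_CONDITIONS) -> pd.DataFrame:
        """Per-unit mean over replicates for each requested condition."""
        cols = {}
        for cond in conditions:
            names = [s for s in self.values.columns if self.samples.at[s, "condition"] == cond]
            if not names:
                raise ValueError(f"no samples for condition {cond!r}")
            cols[cond] = self.values[names].mean(axis=1)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class EffectSpec:
    """A planted depletion effect: gene abundance change under -IPTG."""

    gene_id: str
    rnase: str  # 'III', 'J1' or 'Y'
    delta_log2: float

    def __post_init__(self) -> None:
        if self.rnase not in RNASES:
            raise ValueError(f"unknown RNase {self.rnase!r}")
        if self.delta_log2 == 0:
            raise ValueError("delta_log2 must be non-zero")

    @property
    def direction(self) -> str:
        return "up" if self.delta_log2 > 0 else "down"


@dataclass(frozen=True)
class DepletionScenario:
    """Severity of the IPTG-off depletion: enzyme activity divided by this."""

    fold_reduction: float = 30.0

    def __post_init__(self) -> None:
        if self.fold_reduction < 1:
            raise ValueError("fold_reduction must be >= 1")


@dataclass
class NoiseConfig:
    """Log2-scale Gaussian noise components of the hybridization model."""

    sigma_affinity: float = 0.25  # per-probe offset a_p
    sigma_shift: float = 0.30  # per-hybridization offset s_h
    sigma_resid: float = 0.20  # residual eps
    sigma_background: float = 0.15  # per-probe jitter around the background median


@dataclass
class GeneratorConfig:
    """Shape of the synthetic genome and its expression program.

    Defaults emulate a bacterial chromosome fragment: ~1 kb genes on both
    strands, low-abundance regulatory elements (5'UTRs, antisense RNAs,
    independent small RNAs), and an expression baseline a few log2 units
    above an untranscribed background.
    """

    n_genes: int = 120
    genome_length: int | None = None  # None: sized to fit content
    mean_gene_length: int = 900
    sd_log_gene_length: float = 0.30
    mean_gap: int = 160
    min_gap: int = 30
    frac_plus_strand: float = 0.5
    asRNA_fraction: float = 0.10  # genes carrying an antisense segment
    utr5_fraction: float = 0.10  # genes carrying a 5'UTR segment
    n_indep_segments: int = 0  # free-standing intergenic segments
    segment_length: int = 260
    background_level: float = 6.0  # log2 background median
    baseline_mean: float = 9.5  # log2 level of expressed genes
    baseline_sd: float = 1.0
    segment_level_offset: float = 1.8  # segments sit this far above background
    segment_level_sd: float = 0.6
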