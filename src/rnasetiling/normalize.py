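"""Least-variant-set normalization.

Severe RNase depletion changes the abundance of a large, strongly
up-biased share of the transcriptome, which breaks the distributional
assumptions of quantile-style normalization.  Instead, genes are grouped
into equal-count strata by average expression, the least-variant fraction
of each stratum (variance taken across the four main-condition means) is
pooled into an anchor set, and a per-hybridization loess curve fitted on
that anchor set maps observed values onto a common reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import ExpressionMatrix, MAIN_CONDITIONS

log = logging.getLogger(__name__)

__all__ = [
    "NormalizationConfig",
    "NormalizationModel",
    "select_least_variant_set",
    "fit_normalization",
    "apply_normalization",
]


@dataclass(frozen=True)
class NormalizationConfig:
    n_strata: int = 10
    frac_per_stratum: float = 0.10
    span: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.frac_per_stratum <= 1:
            raise ValueError("frac_per_stratum must be in (0, 1]")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")


@dataclass
class NormalizationModel:
    """Per-sample correction curves anchored on the least-variant set.

    Each curve is stored as sorted (x, offset) support points; evaluation
    is linear interpolation with constant extrapolation beyond the
    observed least-variant range.
    """

    curves: dict[str, tuple[np.ndarray, np.ndarray]]
    lv_set: list[str]
    reference: pd.Series
    config: NormalizationConfig = field(default_factory=NormalizationConfig)

    def correction(self, sample: str, values: np.ndarray) -> np.ndarray:
        if sample not in self.curves:
            raise KeyError(f"sample {sample!r} not covered by the normalization model")
        xs, ys = self.curves[sample]
        return np.interp(values, xs, ys)


def select_least_variant_set(
    matrix: ExpressionMatrix, config: NormalizationConfig = NormalizationConfig()
) -> list[str]:
    """Pick the lowest-variance fraction of each expression stratum.

    Genes are ranked by average expression over all samples and split into
    ``n_strata`` equal-count strata; within each stratum the
    ``floor(frac * size)`` genes with the smallest variance across the
    four main-condition means (replicates averaged first) are retained.
    Ties break lexicographically on gene id; output sorted by gene id.
    """
    values = matrix.values.dropna()
    if len(values) < config.n_strata:
        raise ValueError(
            f"{len(values)} genes cannot be split into {config.n_strata} strata"
        )
    avg = values.mean(axis=1)
    cmeans = ExpressionMatrix(values, matrix.samples).condition_means(MAIN_CONDITIONS)
    variance = cmeans.var(axis=1, ddof=1)

    order = avg.sort_values(kind="mergesort").index
    selected: list[str] = []
    for stratum in np.array_split(np.asarray(order, dtype=object), config.n_strata):
        k = int(np.floor(config.frac_per_stratum * len(stratum)))
        if k == 0:
            continue
        ranked = sorted(stratum, key=lambda g: (variance[g], g))
        selected.extend(ranked[:k])
    return sorted(selected)


def fit_normalization(
    matrix: ExpressionMatrix,
    lv_set: list[str],
    config: NormalizationConfig = NormalizationConfig(),
) -> NormalizationModel:
    """Fit per-sample loess corrections on the least-variant genes.

    For each hybridization, (observed - reference) is regressed on the
    reference (per-gene mean over all samples of the anchor set) with a
    locally weighted linear fit at the configured span.
    """
    missing = set(lv_set) - set(matrix.values.index)
    if missing:
        raise ValueError(f"lv_set genes absent from matrix: {sorted(missing)[:5]} ...")
    lv = matrix.values.loc[list(lv_set)]
    if len(lv) < max(4, int(np.ceil(2 / config.span))):
        raise ValueError("least-variant set too small for the requested span")
    reference = lv.mean(axis=1)
    ref_x = reference.to_numpy(float)

    curves = {}
    for sample in matrix.values.columns:
        resid = lv[sample].to_numpy(float) - ref_x
        fitted = lowess(
            resid, ref_x, frac=config.span, it=2, return_sorted=True
        )
        xs, ys = fitted[:, 0], fitted[:, 1]
        xs, keep = np.unique(xs, return_index=True)
        curves[sample] = (xs, ys[keep])
    log.info("fit_normalization: %d anchor genes, %d samples", len(lv), len(curves))
    return NormalizationModel(curves=curves, lv_set=sorted(lv_set), reference=reference, config=config)


def apply_normalization(matrix: ExpressionMatrix, model: NormalizationModel) -> ExpressionMatrix:
    """Subtract each sample's fitted correction, evaluated at the value.

    Beyond the anchor range the correction is held constant.  Values of
    the least-variant genes move toward the common reference.
    """
    out = matrix.values.copy()
    for sample in out.columns:
        vals = out[sample].to_numpy(float)
        out[sample] = vals - model.correction(sample, vals)
    return ExpressionMatrix(
        values=out,
        samples=matrix.samples,
        n_probes=matrix.n_probes,
        flagged=matrix.flagged,
    )
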