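"""Functional-category composition and Fisher-exact enrichment.

For each hierarchical functional category (levels separated by " * ") the
fraction of member genes called up, unchanged and down under each RNase
depletion is tabulated, and a two-sided Fisher exact test on the 2x2
table (in-category vs rest x flagged vs not) is run separately for the
up and down directions.  Significance flags apply a Bonferroni
correction over the number of categories examined; over/under codes
(+Up, -Up, +Down, -Down) record the direction of the deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import RNASES

log = logging.getLogger(__name__)

__all__ = ["CategoryTable", "category_enrichment", "enrichment_table"]


@dataclass
class CategoryTable:
    """Gene memberships per category; categories may overlap."""

    members: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.members = {c: sorted(set(g)) for c, g in self.members.items()}

    @property
    def n_categories(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members.items())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CategoryTable":
        """Two-column (category, gene) table -> membership map."""
        members: dict[str, list[str]] = {}
        for cat, gene in frame.itertuples(index=False):
            members.setdefault(str(cat), []).append(str(gene))
        return cls(members)

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, g) for c, genes in sorted(self.members.items()) for g in genes]
        return pd.DataFrame(rows, columns=["category", "gene"])


def _fisher_flags(in_cat_flagged, in_cat, total_flagged, total):
    table = np.array(
        [
            [in_cat_flagged, in_cat - in_cat_flagged],
            [total_flagged - in_cat_flagged, (total - in_cat) - (total_flagged - in_cat_flagged)],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def category_enrichment(
    profile: pd.Series,
    categories: CategoryTable,
    direction: str = "up",
    alpha: float = 0.05,
    population: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher screen of one direction of one RNase's profile calls.

    ``profile`` maps gene id -> 'U'/'D'/'-'.  The reference population is
    all genes in ``profile`` (the whole annotated gene set of the run)
    unless ``population`` restricts it.  Empty categories are skipped with
    a warning.  The Bonferroni level is ``alpha / n_categories``.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    code = "U" if direction == "up" else "D"
    genes = pd.Index(population) if population is not None else profile.index
    flags = profile.loc[genes] == code
    total, total_flagged = len(genes), int(flags.sum())
    bonf = alpha / max(categories.n_categories, 1)

    rows = []
    for cat, members in categories:
        in_cat = [g for g in members if g in genes]
        if not in_cat:
            log.warning("category %s has no genes in the population; skipped", cat)
            continue
        sub = profile.loc[in_cat]
        n = len(in_cat)
        n_flagged = int((sub == code).sum())
        odds, p = _fisher_flags(n_flagged, n, total_flagged, total)
        over = n_flagged / n > total_flagged / total
        sig = p <= bonf
        rows.append(
            {
                "category": cat,
                "n_genes": n,
                "pct_up": 100.0 * (sub == "U").mean(),
                "pct_unchanged": 100.0 * (sub == "-").mean(),
                "pct_down": 100.0 * (sub == "D").mean(),
                "odds_ratio": odds,
                "p": p,
                "bonferroni_significant": sig,
                "code": (("+" if over else "-") + direction.capitalize()) if sig else "",
            }
        )
    return pd.DataFrame(rows).set_index("category")


def enrichment_table(
    profiles: pd.DataFrame,
    categories: CategoryTable,
    alpha: float = 0.05,
    fc_tag: str = "2",
) -> pd.DataFrame:
    """Full per-category screen over all three RNases and both directions.

    ``profiles`` holds one ``profile_<RNase>_<tag>`` column per RNase (the
    2-fold, FDR <= 0.1 calls by default).  Output mirrors the published
    layout: per-RNase composition percentages plus p-values and summary
    codes.
    """
    out = None
    for rnase in RNASES:
        col = f"profile_{rnase}_{fc_tag}"
        prof = profiles[col]
        for direction in ("up", "down"):
            tab = category_enrichment(prof, categories, direction=direction, alpha=alpha)
            tab = tab.rename(
                columns={
                    "odds_ratio": f"odds_{direction}_{rnase}",
                    "p": f"p_{direction}_{rnase}",
                    "bonferroni_significant": f"sig_{direction}_{rnase}",
                    "code": f"code_{direction}_{rnase}",
                }
            )
            if out is None:
                out = tab
            else:
                keep = [c for c in tab.columns if c not in out.columns]
                out = out.join(tab[keep])
        out = out.rename(
            columns={
                "pct_up": f"pct_up_{rnase}",
                "pct_unchanged": f"pct_unchanged_{rnase}",
                "pct_down": f"pct_down_{rnase}",
            }
        )
    summaries = []
    for cat in out.index:
        codes = [
            out.at[cat, f"code_{d}_{r}"]
            for r in RNASES
            for d in ("up", "down")
            if out.at[cat, f"code_{d}_{r}"]
        ]
        summaries.append(";".join(codes))
    out["summary"] = summaries
    return out
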