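"""Validation arithmetic for consensomes.

Percentile slicing ("the top 1% of genes"), gene-set frequency and fold
enrichment within a slice relative to the whole consensome, concordance
of top-ranked targets with a literature reference set, and plot-ready
scatter export (rank vs -log10 CPV with percentile guides).

Fold enrichment is reported at full precision; display rounding follows
a two-significant-figure percentage convention. No significance test is
attached to enrichment by default; an upper-tail hypergeometric p can be
requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ContractError, GeneSet

__all__ = [
    "EnrichmentResult",
    "percentile_slice",
    "fold_enrichment",
    "fold_enrichment_from_counts",
    "concordance",
    "scatter_export",
    "format_percent",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts and derived frequencies of an annotation within a slice.

    ``fold_enrichment`` is slice_frequency / universe_frequency, or None
    when the universe carries no annotated gene at all.
    """

    slice_size: int
    slice_hits: int
    universe_size: int
    universe_hits: int
    hypergeom_p: float | None = None

    def __post_init__(self) -> None:
        if self.slice_hits > self.slice_size or self.slice_size > self.universe_size:
            raise ContractError("slice must be contained in the universe")
        if self.slice_hits > self.universe_hits:
            raise ContractError("slice cannot contain more annotated genes than the universe")

    @property
    def slice_frequency(self) -> float:
        return self.slice_hits / self.slice_size if self.slice_size else 0.0

    @property
    def universe_frequency(self) -> float:
        return self.universe_hits / self.universe_size if self.universe_size else 0.0

    @property
    def fold_enrichment(self) -> float | None:
        if self.universe_hits == 0:
            return None
        return self.slice_frequency / self.universe_frequency

    def summary(self) -> dict:
        """JSON-ready summary with full-precision and display-rounded values."""
        return {
            "slice": f"{self.slice_hits}/{self.slice_size}",
            "universe": f"{self.universe_hits}/{self.universe_size}",
            "slice_frequency": self.slice_frequency,
            "universe_frequency": self.universe_frequency,
            "slice_percent": format_percent(100 * self.slice_frequency),
            "universe_percent": format_percent(100 * self.universe_frequency),
            "fold_enrichment": self.fold_enrichment,
            "hypergeom_p": self.hypergeom_p,
        }


def format_percent(value: float) -> str:
    """Display a percentage to two significant figures ('38', '5.7')."""
    return f"{value:.2g}"


def percentile_slice(consensome: pd.DataFrame, cutoff: float) -> GeneSet:
    """Genes at or above a consensome percentile cutoff.

    With the percentile convention 100*(N - rank)/N, cutoff 99 on 1000
    ranked genes returns exactly the top 10.
    """
    if not 0 <= cutoff < 100:
        raise ValueError(f"cutoff must lie in [0, 100), got {cutoff}")
    if "percentile" not in consensome.columns:
        raise ContractError("consensome must be ranked (missing 'percentile' column)")
    members = consensome.loc[consensome["percentile"] >= cutoff, "gene_id"]
    return GeneSet(f"percentile>={cutoff:g}", frozenset(members.astype(str)))


def fold_enrichment(
    universe: GeneSet,
    annotation: GeneSet,
    slice_: GeneSet,
    hypergeometric: bool = False,
) -> EnrichmentResult:
    """Frequency of an annotation inside a slice vs the whole universe.

    ``slice_`` must be a subset of ``universe``; annotation membership is
    intersected with the universe before counting so an over-broad
    annotation file cannot inflate frequencies.
    """
    if not slice_.members <= universe.members:
        raise ContractError("slice genes must all belong to the universe")
    ann = annotation.members & universe.members
    universe_hits = len(ann)
    slice_hits = len(slice_.members & ann)
    result = EnrichmentResult(
        slice_size=len(slice_),
        slice_hits=slice_hits,
        universe_size=len(universe),
        universe_hits=universe_hits,
        hypergeom_p=(
            float(stats.hypergeom.sf(slice_hits - 1, len(universe), universe_hits, len(slice_)))
            if hypergeometric
            else None
        ),
    )
    return result


def fold_enrichment_from_counts(
    slice_size: int,
    slice_hits: int,
    universe_size: int,
    universe_hits: int,
    hypergeometric: bool = False,
) -> EnrichmentResult:
    """Enrichment arithmetic from bare counts (e.g. a published table)."""
    p = (
        float(stats.hypergeom.sf(slice_hits - 1, universe_size, universe_hits, slice_size))
        if hypergeometric
        else None
    )
    return EnrichmentResult(slice_size, slice_hits, universe_size, universe_hits, hypergeom_p=p)


def concordance(top_targets, reference: GeneSet) -> float:
    """Fraction of an ordered top-target list found in a reference set."""
    targets = list(top_targets)
    if not targets:
        raise ContractError("concordance requires a non-empty target list")
    return sum(1 for t in targets if t in reference) / len(targets)


def scatter_export(
    consensome: pd.DataFrame,
    highlight: GeneSet | None = None,
    x: str = "rank",
    guides: tuple[float, ...] = (95.0, 99.0),
) -> tuple[pd.DataFrame, dict[float, float]]:
    """Plot-ready table: x = rank (or any column), y = -log10 CPV.

    Returns the table (gene_id, x, neg_log10_cpv, percentile, highlight)
    and, for each requested percentile guide, the x-value at which that
    cutoff falls (NaN when no gene reaches it). CPV = 1 plots at y = 0;
    a CPV at the p-floor plots finitely large.
    """
    if "cpv" not in consensome.columns:
        raise ContractError("scatter_export requires a 'cpv' column")
    hi = highlight.members if highlight is not None else frozenset()
    table = pd.DataFrame(
        {
            "gene_id": consensome["gene_id"].astype(str),
            x: consensome[x],
            "neg_log10_cpv": -np.log10(consensome["cpv"].to_numpy(dtype=float)),
            "percentile": consensome["percentile"],
            "highlight": consensome["gene_id"].astype(str).isin(hi),
        }
    )
    guide_x: dict[float, float] = {}
    for g in guides:
        above = table.loc[table["percentile"] >= g, x]
        guide_x[g] = float(above.max()) if len(above) else float("nan")
    return table, guide_x
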