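"""Cistromic (ChIP-Seq) consensomes: promoter-window peak-score averages.

Each ChIP-Seq experiment contributes, per gene, the MACS2 score of peaks
falling within +/- `window` bp (default 10 kb) of the gene's TSS; several
peaks in the window are reduced (max by default), several TSSs per gene
take the best-scoring window, and genes with no in-window peak score 0.
Per-gene scores are then averaged arithmetically across every experiment
whose immunoprecipitated node maps to the selected family/biosample, and
genes are ranked by descending mean score with average rank on ties.

The window is symmetric and strand-ignored; overlap is any shared base
between the BED half-open peak interval and the closed window
[tss - window, tss + window] in 1-based coordinates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.base import BaseEstimator

from .io import CistromeExperiment, ContractError, VersionStamp
from .transcriptomic import ConsensomeSelector, rank_and_percentile

__all__ = [
    "assign_peaks_to_genes",
    "build_cistromic_consensome",
    "CistromicConsensome",
]

_REDUCERS = {"max": np.max, "sum": np.sum, "mean": np.mean}


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 10_000,
    reducer: str = "max",
) -> pd.DataFrame:
    """Score every gene by the peaks overlapping its promoter window.

    Parameters
    ----------
    peaks : DataFrame
        Columns chrom/start/end/score, BED 0-based half-open.
    tss : DataFrame
        Columns gene_id/chrom/tss/strand, tss 1-based.
    window : int, default 10000
        Half-width in bp of the closed window [tss - window, tss + window].
    reducer : {"max", "sum", "mean"}, default "max"
        How several in-window peaks combine into one window score; genes
        with several TSSs take their best-scoring window.

    Returns
    -------
    DataFrame with columns gene_id, score — one row for every gene in the
    TSS table, score 0.0 where no peak overlaps any of its windows. Peaks
    on chromosomes absent from the TSS table are skipped with a warning.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if reducer not in _REDUCERS:
        raise ValueError(f"reducer must be one of {sorted(_REDUCERS)}, got {reducer!r}")
    reduce = _REDUCERS[reducer]

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in tss.groupby("chrom"):
        tree = IntervalTree()
        for row in sub.itertuples(index=False):
            # closed window in 1-based coords -> half-open [lo, hi+1)
            tree.addi(row.tss - window, row.tss + window + 1, (row.gene_id, row.tss))
        trees[str(chrom)] = tree

    hits: dict[tuple[str, int], list[float]] = {}
    unknown: set[str] = set()
    for row in peaks.itertuples(index=False):
        tree = trees.get(str(row.chrom))
        if tree is None:
            unknown.add(str(row.chrom))
            continue
        # BED half-open [start, end) covers 1-based bases [start+1, end]
        for iv in tree.overlap(row.start + 1, row.end + 1):
            hits.setdefault(iv.data, []).append(float(row.score))
    if unknown:
        warnings.warn(f"peaks on chromosome(s) {sorted(unknown)} absent from TSS table: skipped", stacklevel=2)

    per_window = {key: float(reduce(scores)) for key, scores in hits.items()}
    gene_score: dict[str, float] = {}
    for (gene_id, _), score in per_window.items():
        if score > gene_score.get(gene_id, -np.inf):
            gene_score[gene_id] = score
    genes = tss["gene_id"].drop_duplicates().sort_values(kind="stable")
    return pd.DataFrame(
        {"gene_id": genes.to_numpy(), "score": [gene_score.get(g, 0.0) for g in genes]}
    ).reset_index(drop=True)


def _select(experiments, selector: ConsensomeSelector) -> list[CistromeExperiment]:
    chosen = []
    for exp in experiments:
        if selector.node_family != "All" and exp.node_family != selector.node_family:
            continue
        if selector.system != "All" and exp.system != selector.system:
            continue
        if selector.organ != "All" and exp.organ != selector.organ:
            continue
        if selector.species != "All" and exp.species != selector.species:
            continue
        chosen.append(exp)
    return sorted(chosen, key=lambda e: e.experiment_id)


class CistromicConsensome(BaseEstimator):
    """Rank genes by mean promoter-window ChIP-Seq peak score.

    Parameters
    ----------
    selector : ConsensomeSelector or None
        Restricts experiments by IP-node family, system, organ, species.
    window : int, default 10000
        Promoter half-window in bp around each TSS.
    reducer : {"max", "sum", "mean"}, default "max"
        Combination of several peaks within one window.
    zero_inclusive : bool, default True
        Average over all selected experiments (a gene with no peak
        contributes 0); if False, average only over experiments where the
        gene has at least one in-window peak.
    version : str, default "1.0"
        Version label for the stamp.

    Attributes
    ----------
    scores_ : DataFrame
        Wide per-gene x per-experiment promoter scores.
    consensome_ : DataFrame
        Ranked table: gene_id, mean_score, n_experiments, rank, percentile.
    stamp_ : VersionStamp
    """

    def __init__(
        self,
        selector: ConsensomeSelector | None = None,
        window: int = 10_000,
        reducer: str = "max",
        zero_inclusive: bool = True,
        version: str = "1.0",
    ):
        self.selector = selector
        self.window = window
        self.reducer = reducer
        self.zero_inclusive = zero_inclusive
        self.version = version

    def fit(self, X, tss: pd.DataFrame = None):
        """Build the cistromic consensome.

        Parameters
        ----------
        X : sequence of CistromeExperiment
        tss : DataFrame
            TSS annotation (gene_id, chrom, tss, strand).
        """
        if tss is None:
            raise ContractError("fit requires a TSS annotation table")
        selector = self.selector or ConsensomeSelector()
        chosen = _select(X, selector)
        self.experiment_ids_ = [e.experiment_id for e in chosen]
        if not chosen:
            warnings.warn(f"no cistromic experiments match selector {selector}", stacklevel=2)
            self.scores_ = pd.DataFrame()
            self.consensome_ = pd.DataFrame(columns=["gene_id", "mean_score", "n_experiments", "rank", "percentile"])
            self.stamp_ = VersionStamp.now(self.version, 0, 0, 0)
            return self
        cols = {}
        for exp in chosen:
            per_gene = assign_peaks_to_genes(exp.peaks, tss, window=self.window, reducer=self.reducer)
            cols[exp.experiment_id] = per_gene.set_index("gene_id")["score"]
        wide = pd.DataFrame(cols)
        self.scores_ = wide
        if self.zero_inclusive:
            mean_score = wide.mean(axis=1)
            n_exp = pd.Series(len(chosen), index=wide.index)
        else:
            nonzero = wide.where(wide > 0)
            mean_score = nonzero.mean(axis=1).fillna(0.0)
            n_exp = nonzero.notna().sum(axis=1)
        rows = pd.DataFrame(
            {
                "gene_id": wide.index.to_numpy(),
                "mean_score": mean_score.to_numpy(),
                "n_experiments": n_exp.to_numpy(dtype=np.int64),
            }
        )
        self.consensome_ = rank_and_percentile(rows, by="mean_score", ascending=False)
        self.stamp_ = VersionStamp.now(
            self.version,
            n_datapoints=int(wide.size),
            n_experiments=len(chosen),
            n_datasets=len({e.dataset_id for e in chosen}),
        )
        return self

    def fit_transform(self, X, tss: pd.DataFrame = None) -> pd.DataFrame:
        """Fit and return the ranked table."""
        return self.fit(X, tss).consensome_


def build_cistromic_consensome(
    experiments,
    tss: pd.DataFrame,
    selector: ConsensomeSelector | None = None,
    window: int = 10_000,
    **kwargs,
) -> tuple[pd.DataFrame, VersionStamp]:
    """Functional wrapper around :class:`CistromicConsensome`."""
    est = CistromicConsensome(selector=selector, window=window, **kwargs)
    est.fit(experiments, tss)
    return est.consensome_, est.stamp_
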