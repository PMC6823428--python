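"""Transcriptomic consensomes: recurrence of significant regulation.

Experiments are binned by signaling-node family, biosample (physiological
system and organ) and species. For each gene the number of experiments
``E_g`` in which its gene-level nominal p-value is <= alpha is counted out
of the ``N_g`` experiments in which the gene is measured at all. The
consensome p-value (CPV) is the upper-tail binomial probability of
observing E_g or more successes in N_g trials at a per-experiment success
rate p0 (default 0.05) — the chance the observed recurrence of
differential expression arises by chance. Direction is deliberately
suppressed: the consensus fold change is the geometric mean of
max(F, 1/F) across experiments, so inductions and repressions both count
as "altered". Genes are ranked by ascending CPV with average rank on
ties, and reported with a percentile 100 * (N - rank) / N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .aggregation import DEFAULT_P_FLOOR, ProbesetAggregator
from .io import (
    ContractError,
    ExperimentTable,
    VersionStamp,
    VocabularyError,
)

__all__ = [
    "ConsensomeSelector",
    "bin_experiments",
    "count_discoveries",
    "consensome_pvalue",
    "consensus_fold_change",
    "rank_and_percentile",
    "build_transcriptomic_consensome",
    "TranscriptomicConsensome",
]


@dataclass(frozen=True)
class ConsensomeSelector:
    """Which slice of the corpus a consensome covers; "All" leaves a facet open.

    Pan-node consensomes (node_family="All" with a concrete system/organ)
    are legal: all experiments mapping to that biosample are combined
    irrespective of the node perturbed.
    """

    node_family: str = "All"
    system: str = "All"
    organ: str = "All"
    species: str = "All"

    def label(self) -> str:
        return f"{self.node_family}-{self.species}-{self.system}/{self.organ}"


def _split_multi(value: str) -> list[str]:
    return [v.strip() for v in str(value).split(";") if v.strip()]


def bin_experiments(
    meta: pd.DataFrame,
    selector: ConsensomeSelector,
    multi_node: str = "all_matching_families",
) -> list[str]:
    """Select the experiment ids matching a consensome selector.

    An experiment matches the family facet if any of its (possibly
    several, ';'-separated) node families equals ``selector.node_family``;
    under ``multi_node="primary_family_only"`` only the first listed
    family counts. System, organ and species facets match by equality
    unless set to "All". Returns ids in lexicographic order.
    """
    if multi_node not in ("all_matching_families", "primary_family_only"):
        raise ValueError(f"unknown multi_node mode {multi_node!r}")
    fam_lists = meta["node_family"].map(_split_multi)
    if multi_node == "primary_family_only":
        fam_lists = fam_lists.map(lambda fams: fams[:1])
    for facet, column in (("node_family", None), ("system", "system"), ("organ", "organ"), ("species", "species")):
        wanted = getattr(selector, facet)
        if wanted == "All":
            continue
        if facet == "node_family":
            vocab = {f for fams in meta["node_family"].map(_split_multi) for f in fams}
        else:
            vocab = set(meta[column].astype(str))
        if wanted not in vocab:
            raise VocabularyError(f"selector {facet}={wanted!r} not in corpus vocabulary {sorted(vocab)}")
    mask = np.ones(len(meta), dtype=bool)
    if selector.node_family != "All":
        mask &= fam_lists.map(lambda fams: selector.node_family in fams).to_numpy()
    for facet in ("system", "organ", "species"):
        wanted = getattr(selector, facet)
        if wanted != "All":
            mask &= (meta[facet].astype(str) == wanted).to_numpy()
    return sorted(meta.loc[mask, "experiment_id"].astype(str))


def count_discoveries(evidence: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene discovery counts over a bin of experiments.

    ``N_g`` counts only experiments where the gene is present in the
    evidence; a discovery is a gene-level p <= alpha (boundary inclusive).
    Returns columns gene_id, n_discoveries, n_experiments, discovery_rate.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    grouped = evidence.groupby("gene_id", sort=True)
    n = grouped.size()
    e = grouped["p"].apply(lambda p: int((p <= alpha).sum()))
    out = pd.DataFrame(
        {
            "gene_id": n.index.to_numpy(),
            "n_discoveries": e.to_numpy(dtype=np.int64),
            "n_experiments": n.to_numpy(dtype=np.int64),
        }
    )
    out["discovery_rate"] = out["n_discoveries"] / out["n_experiments"]
    return out


def consensome_pvalue(n_discoveries, n_experiments, p0: float = 0.05):
    """Upper-tail binomial probability P(X >= E_g | N_g, p0).

    E_g = 0 gives exactly 1.0. Scalar in, scalar out; arrays broadcast.
    """
    E = np.asarray(n_discoveries)
    N = np.asarray(n_experiments)
    if np.any(E < 0) or np.any(N < 0) or np.any(E > N):
        raise ContractError("need 0 <= n_discoveries <= n_experiments")
    cpv = stats.binom.sf(E - 1, N, p0)
    cpv = np.where(E == 0, 1.0, cpv)
    return float(cpv) if cpv.ndim == 0 else cpv


def consensus_fold_change(folds) -> float:
    """Geometric mean of direction-suppressed fold changes max(F, 1/F).

    Computed in log2 space as 2**mean(|log2 F|), which is the same
    quantity and is exactly invariant under F -> 1/F.
    """
    f = np.asarray(folds, dtype=float)
    if f.size == 0:
        raise ContractError("consensus_fold_change requires at least one fold change")
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ContractError("fold changes must be positive and finite")
    return float(np.exp2(np.mean(np.abs(np.log2(f)))))


def rank_and_percentile(rows: pd.DataFrame, by: str = "cpv", ascending: bool = True) -> pd.DataFrame:
    """Rank a consensome and attach percentiles.

    Rank 1 is the best (smallest CPV when ascending); exact ties share the
    arithmetic mean of their positional ranks and may be fractional.
    Percentile = 100 * (N - rank) / N, so the top gene of 10,000 sits at
    99.99. Output rows are ordered by (rank, gene_id) for reproducibility.
    """
    if by not in rows.columns:
        raise ContractError(f"rank_and_percentile: missing column {by!r}")
    out = rows.copy()
    out["rank"] = out[by].rank(method="average", ascending=ascending)
    n = len(out)
    out["percentile"] = 100.0 * (n - out["rank"]) / n
    return out.sort_values(["rank", "gene_id"], kind="stable").reset_index(drop=True)


class TranscriptomicConsensome(BaseEstimator):
    """Consensus ranking of genes by recurrence of significant regulation.

    Fitting aggregates every selected experiment's probeset table to
    gene-level evidence, counts per-gene discoveries at the nominal
    threshold, computes the binomial CPV and consensus fold change, and
    ranks genes by ascending CPV.

    Parameters
    ----------
    selector : ConsensomeSelector or None
        Corpus slice (node family, system, organ, species); None means
        all experiments.
    alpha : float, default 0.05
        Gene-level nominal significance threshold; a discovery is
        p <= alpha (boundary inclusive).
    p0 : float, default 0.05
        Per-experiment chance success rate of the binomial null.
    p_floor : float, default 1e-300
        Clamp for upstream p-values before the quantile transform.
    significant_only_fc : bool, default False
        If True, the consensus fold change averages only the E_g
        significant experiments rather than all N_g.
    min_n_experiments : int, default 1
        Genes measured in fewer experiments are dropped from the table.
    bh_column : bool, default True
        Emit a Benjamini-Hochberg adjusted CPV column (``cpv_bh``); it is
        informational and never used for ranking.
    multi_node : str, default "all_matching_families"
        How experiments whose nodes span several families enter
        family-level bins (see :func:`bin_experiments`).
    version : str, default "1.0"
        Version label recorded in the output stamp.

    Attributes
    ----------
    experiment_ids_ : list of str
        Experiments selected into the bin.
    evidence_ : DataFrame
        Long per-(gene, experiment) evidence table.
    consensome_ : DataFrame
        Ranked consensome rows (gene_id, n_experiments, n_discoveries,
        discovery_rate, cpv, consensus_fc, rank, percentile[, cpv_bh]).
    stamp_ : VersionStamp
        Version, date and corpus counts (data points, experiments,
        datasets) actually used.

    Examples
    --------
    >>> est = TranscriptomicConsensome(alpha=0.05)
    >>> est.fit(tables, meta)                        # doctest: +SKIP
    >>> est.consensome_.head()                       # doctest: +SKIP
    """

    def __init__(
        self,
        selector: ConsensomeSelector | None = None,
        alpha: float = 0.05,
        p0: float = 0.05,
        p_floor: float = DEFAULT_P_FLOOR,
        significant_only_fc: bool = False,
        min_n_experiments: int = 1,
        bh_column: bool = True,
        multi_node: str = "all_matching_families",
        version: str = "1.0",
    ):
        self.selector = selector
        self.alpha = alpha
        self.p0 = p0
        self.p_floor = p_floor
        self.significant_only_fc = significant_only_fc
        self.min_n_experiments = min_n_experiments
        self.bh_column = bh_column
        self.multi_node = multi_node
        self.version = version

    def fit(self, X, meta: pd.DataFrame | None = None):
        """Build the consensome from a corpus.

        Parameters
        ----------
        X : sequence of ExperimentTable
            The probeset-level experiment tables of the corpus.
        meta : DataFrame, optional
            Experiment metadata (one row per experiment_id). Required when
            a selector constrains the corpus; without it every table is
            used and each experiment counts as its own dataset.
        """
        tables = {t.experiment_id: t for t in X}
        selector = self.selector or ConsensomeSelector()
        if meta is not None:
            chosen = bin_experiments(meta, selector, multi_node=self.multi_node)
            chosen = [e for e in chosen if e in tables]
            dataset_of = dict(zip(meta["experiment_id"].astype(str), meta["dataset_id"].astype(str)))
        else:
            if selector != ConsensomeSelector():
                raise ContractError("a constraining selector requires experiment metadata")
            chosen = sorted(tables)
            dataset_of = {e: e for e in chosen}
        self.experiment_ids_ = chosen
        if not chosen:
            warnings.warn(f"no experiments match selector {selector}", stacklevel=2)
            self.evidence_ = pd.DataFrame(columns=["gene_id", "experiment_id", "z", "p", "fold_change_hat", "log2_fc_hat", "n_probesets"])
            self.consensome_ = pd.DataFrame(columns=["gene_id", "n_experiments", "n_discoveries", "discovery_rate", "cpv", "consensus_fc", "rank", "percentile"])
            self.stamp_ = VersionStamp.now(self.version, 0, 0, 0)
            return self
        aggregator = ProbesetAggregator(p_floor=self.p_floor)
        evidence = aggregator.transform([tables[e] for e in chosen])
        self.evidence_ = evidence
        counts = count_discoveries(evidence, alpha=self.alpha)
        counts = counts[counts["n_experiments"] >= self.min_n_experiments].reset_index(drop=True)
        counts["cpv"] = consensome_pvalue(
            counts["n_discoveries"].to_numpy(), counts["n_experiments"].to_numpy(), self.p0
        )
        counts["consensus_fc"] = self._consensus_fc(evidence, counts["gene_id"])
        rows = rank_and_percentile(counts, by="cpv", ascending=True)
        if self.bh_column and len(rows):
            rows["cpv_bh"] = multipletests(rows["cpv"].to_numpy(), method="fdr_bh")[1]
        self.consensome_ = rows
        self.stamp_ = VersionStamp.now(
            self.version,
            n_datapoints=int(len(evidence)),
            n_experiments=len(chosen),
            n_datasets=len({dataset_of[e] for e in chosen}),
        )
        return self

    def _consensus_fc(self, evidence: pd.DataFrame, gene_order: pd.Series) -> np.ndarray:
        ev = evidence
        if self.significant_only_fc:
            ev = ev[ev["p"] <= self.alpha]
        # geometric mean of max(F, 1/F) via mean |log2 F-hat|, exactly
        # symmetric under fold-change inversion
        mean_abs = ev.groupby("gene_id")["log2_fc_hat"].apply(lambda v: np.mean(np.abs(v.to_numpy())))
        fc = np.exp2(mean_abs.reindex(gene_order.to_numpy()).to_numpy())
        return np.where(np.isnan(fc), 1.0, fc)

    def fit_transform(self, X, meta: pd.DataFrame | None = None) -> pd.DataFrame:
        """Fit and return the ranked consensome table."""
        return self.fit(X, meta).consensome_


def build_transcriptomic_consensome(
    tables,
    meta: pd.DataFrame | None = None,
    selector: ConsensomeSelector | None = None,
    alpha: float = 0.05,
    p0: float = 0.05,
    **kwargs,
) -> tuple[pd.DataFrame, VersionStamp]:
    """Functional wrapper around :class:`TranscriptomicConsensome`.

    Returns the ranked consensome rows and the version stamp.
    """
    est = TranscriptomicConsensome(selector=selector, alpha=alpha, p0=p0, **kwargs)
    est.fit(tables, meta)
    return est.consensome_, est.stamp_
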