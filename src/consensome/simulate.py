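"""Synthetic multi-experiment corpora with known ground-truth targets.

The generator emulates the statistical structure the consensome engine
assumes: a handful of true node targets whose per-experiment chance of
significant differential expression (pi_t) is well above the nominal 5%,
against a background of null genes with uniform p-values and fold changes
near 1. True-target effect sizes are log-normal on the fold-change scale;
a configurable fraction of experiments sees a repression rather than an
induction (exercising direction suppression); genes go unmeasured in an
experiment with a configurable missingness rate; and a small fraction of
genes is covered by several correlated probesets, mirroring array
platforms where almost all genes have a single probeset.

Simulation starts at the (fold change, p-value) level the consensome
consumes; no intensity or read-count model is attempted. A single global
seed drives per-experiment substreams, so adding experiments leaves
earlier ones unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CistromeExperiment,
    ExperimentTable,
    GeneSet,
    read_experiment_table,
    read_metadata_table,
    TableDialect,
)

__all__ = [
    "FamilyConfig",
    "SimulationConfig",
    "CistromeSimulationConfig",
    "simulate_transcriptomic_corpus",
    "simulate_cistromic_corpus",
    "invert_corpus",
    "write_transcriptomic_corpus",
    "load_transcriptomic_corpus",
    "write_cistromic_corpus",
]


class ConfigError(ValueError):
    """A simulation configuration violates its own invariants."""


@dataclass(frozen=True)
class FamilyConfig:
    """One node family and the biosample/species its experiments map to."""

    name: str = "FamilyA"
    node_symbols: tuple = ("NodeA1", "NodeA2")
    node_class: str = "ClassA"
    node_category: str = "receptor"
    system: str = "Metabolic"
    organ: str = "Liver"
    species: str = "mouse"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic transcriptomic corpus.

    Defaults describe a modest single-family corpus: 1000 genes of which
    10 are true targets, 20 experiments, per-experiment true-target
    discovery probability 0.8, ~2-fold median effect sizes, 10%
    missingness, a quarter of discoveries repressive, and ~1% of genes
    covered by 2-5 probesets.
    """

    n_genes: int = 1000
    n_true_targets: int = 10
    n_experiments_per_family: int = 20
    experiments_per_dataset: int = 2
    families: tuple = (FamilyConfig(),)
    discovery_prob_true: float = 0.8
    significance_level: float = 0.05
    effect_log2fc_mean: float = 1.0
    effect_log2fc_sd: float = 0.35
    null_log2fc_sd: float = 0.15
    missing_rate: float = 0.1
    multi_probeset_frac: float = 0.01
    max_probesets: int = 5
    probeset_p_jitter: float = 0.15
    probeset_log2fc_jitter: float = 0.05
    sign_flip_prob: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "discovery_prob_true": self.discovery_prob_true,
            "significance_level": self.significance_level,
            "missing_rate": self.missing_rate,
            "multi_probeset_frac": self.multi_probeset_frac,
            "sign_flip_prob": self.sign_flip_prob,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.discovery_prob_true <= self.significance_level:
            raise ConfigError(
                "discovery_prob_true must exceed the nominal significance level "
                f"for a nontrivial simulation (got {self.discovery_prob_true} <= {self.significance_level})"
            )
        if self.n_true_targets > self.n_genes:
            raise ConfigError("more true targets than genes")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")


def _gene_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"Gene{i:0{width}d}" for i in range(1, n + 1)])


def simulate_transcriptomic_corpus(
    config: SimulationConfig,
) -> tuple[list[ExperimentTable], pd.DataFrame, GeneSet]:
    """Generate (experiment tables, metadata, true-target gene set).

    Deterministic given ``config.seed``: corpus-level structure (which
    genes are true targets, probeset counts) comes from one substream and
    each experiment from its own, so the output is reproducible
    experiment by experiment. With ``n_true_targets=0`` (a pure null
    corpus for calibration studies) the truth set is None.
    """
    config.validate()
    structure_rng = np.random.default_rng([config.seed, 0])
    genes = _gene_ids(config.n_genes)
    truth_idx = structure_rng.choice(config.n_genes, size=config.n_true_targets, replace=False)
    is_true = np.zeros(config.n_genes, dtype=bool)
    is_true[truth_idx] = True
    n_probesets = np.ones(config.n_genes, dtype=np.int64)
    multi = structure_rng.random(config.n_genes) < config.multi_probeset_frac
    n_probesets[multi] = structure_rng.integers(2, config.max_probesets + 1, size=int(multi.sum()))

    tables: list[ExperimentTable] = []
    meta_rows: list[dict] = []
    perturbations = ("agonist", "knockout", "overexpression", "knockdown")
    exp_counter = 0
    for fam_idx, fam in enumerate(config.families):
        for e in range(config.n_experiments_per_family):
            exp_id = f"EXP{fam_idx}{e:03d}"
            rng = np.random.default_rng([config.seed, 1 + fam_idx, e])
            table = _simulate_experiment(exp_id, genes, is_true, n_probesets, config, rng)
            tables.append(table)
            meta_rows.append(
                {
                    "experiment_id": exp_id,
                    "dataset_id": f"SYN{fam_idx}{e // config.experiments_per_dataset:03d}",
                    "node_symbols": fam.node_symbols[e % len(fam.node_symbols)],
                    "node_family": fam.name,
                    "node_class": fam.node_class,
                    "node_category": fam.node_category,
                    "species": fam.species,
                    "system": fam.system,
                    "organ": fam.organ,
                    "perturbation_type": perturbations[e % len(perturbations)],
                    "bsm_id": "",
                }
            )
            exp_counter += 1
    meta = pd.DataFrame(meta_rows)
    truth = GeneSet("true_targets", frozenset(genes[truth_idx])) if len(truth_idx) else None
    return tables, meta, truth


def _simulate_experiment(
    exp_id: str,
    genes: np.ndarray,
    is_true: np.ndarray,
    n_probesets: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ExperimentTable:
    n = genes.size
    measured = rng.random(n) >= config.missing_rate
    if not measured.any():  # never emit an empty table
        measured[rng.integers(0, n)] = True
    alpha = config.significance_level
    p = rng.uniform(0.0, 1.0, size=n)
    log2fc = rng.normal(0.0, config.null_log2fc_sd, size=n)
    hit = is_true & (rng.random(n) < config.discovery_prob_true)
    p[hit] = rng.uniform(0.0, alpha, size=int(hit.sum()))
    p[is_true & ~hit] = rng.uniform(alpha, 1.0, size=int((is_true & ~hit).sum()))
    magnitude = np.abs(rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd, size=int(hit.sum())))
    sign = np.where(rng.random(int(hit.sum())) < config.sign_flip_prob, -1.0, 1.0)
    log2fc[hit] = sign * magnitude

    rows_gene, rows_ps, rows_p, rows_l2 = [], [], [], []
    for i in np.flatnonzero(measured):
        k = n_probesets[i]
        if k == 1:
            rows_gene.append(genes[i])
            rows_ps.append(f"{genes[i]}_at")
            rows_p.append(p[i])
            rows_l2.append(log2fc[i])
        else:
            # correlated probesets: shared gene signal, small jitter
            jitter_p = np.clip(p[i] * np.exp2(rng.normal(0.0, config.probeset_p_jitter, size=k)), 1e-300, 1.0)
            jitter_l2 = log2fc[i] + rng.normal(0.0, config.probeset_log2fc_jitter, size=k)
            for j in range(k):
                rows_gene.append(genes[i])
                rows_ps.append(f"{genes[i]}_{j}_at")
                rows_p.append(jitter_p[j])
                rows_l2.append(jitter_l2[j])
    l2 = np.asarray(rows_l2, dtype=float)
    data = pd.DataFrame(
        {
            "probeset_id": rows_ps,
            "gene_id": rows_gene,
            "fold_change": np.exp2(l2),
            "log2_fold_change": l2,
            "p_value": np.asarray(rows_p, dtype=float),
        }
    )
    return ExperimentTable(exp_id, data)


def invert_corpus(tables) -> list[ExperimentTable]:
    """Replace every fold change by its reciprocal (direction flip).

    Uses the exact log2 negation of :meth:`ExperimentTable.invert`, so
    direction-suppressed consensome statistics are bit-identical between
    a corpus and its inversion.
    """
    return [t.invert() for t in tables]


# ---------------------------------------------------------------------------
# cistromic corpus


@dataclass(frozen=True)
class CistromeSimulationConfig:
    """Study conditions of a synthetic ChIP-Seq corpus.

    True targets receive a strong peak inside the +/- window of their TSS
    in each experiment with probability ``peak_prob_true``; background
    peaks fall uniformly on the genome with weaker scores.
    """

    n_genes: int = 200
    n_true_targets: int = 10
    n_experiments: int = 5
    experiments_per_dataset: int = 2
    window: int = 10_000
    peak_prob_true: float = 1.0
    peak_length: int = 400
    true_score_mean: float = 200.0
    true_score_sd: float = 30.0
    n_background_peaks: int = 50
    background_score_mean: float = 40.0
    background_score_sd: float = 15.0
    genome: tuple = (("chr1", 3_000_000), ("chr2", 3_000_000))
    family: FamilyConfig = field(default_factory=FamilyConfig)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.peak_prob_true <= 1.0:
            raise ConfigError(f"peak_prob_true must lie in [0, 1], got {self.peak_prob_true}")
        for chrom, length in self.genome:
            if 2 * self.window + 2 >= length:
                raise ConfigError(f"window {self.window} too large for chromosome {chrom} of length {length}")
        if self.n_true_targets > self.n_genes:
            raise ConfigError("more true targets than genes")
        if min(self._tss_spacing().values()) <= 2 * self.window + self.peak_length:
            raise ConfigError(
                "too many genes for the genome: promoter windows would overlap "
                f"(need spacing > {2 * self.window + self.peak_length} bp)"
            )

    def _tss_spacing(self) -> dict[str, float]:
        n_chrom = len(self.genome)
        per_chrom = {c: self.n_genes // n_chrom + (i < self.n_genes % n_chrom) for i, (c, _) in enumerate(self.genome)}
        return {c: (length - 2 * (self.window + 1)) / max(per_chrom[c], 1) for c, length in self.genome}


def simulate_cistromic_corpus(
    config: CistromeSimulationConfig,
) -> tuple[list[CistromeExperiment], pd.DataFrame, GeneSet]:
    """Generate (cistromic experiments, TSS table, true-target gene set)."""
    config.validate()
    structure_rng = np.random.default_rng([config.seed, 10])
    genes = _gene_ids(config.n_genes)
    chroms = [c for c, _ in config.genome]
    lengths = dict(config.genome)
    # TSSs on a jittered per-chromosome grid whose spacing exceeds the
    # promoter-window diameter, so each window is attributable to one gene
    spacing = config._tss_spacing()
    n_chrom = len(chroms)
    gene_chrom = np.array([chroms[i % n_chrom] for i in range(config.n_genes)])
    slot = np.array([i // n_chrom for i in range(config.n_genes)])
    jitter_span = {c: max(int(spacing[c]) - 2 * config.window - config.peak_length, 1) for c in chroms}
    tss_pos = np.array(
        [
            config.window + 1 + int(s * spacing[c]) + int(structure_rng.integers(0, jitter_span[c]))
            for c, s in zip(gene_chrom, slot)
        ]
    )
    strand = structure_rng.choice(["+", "-"], size=config.n_genes)
    tss = pd.DataFrame({"gene_id": genes, "chrom": gene_chrom, "tss": tss_pos, "strand": strand})
    truth_idx = structure_rng.choice(config.n_genes, size=config.n_true_targets, replace=False)

    experiments: list[CistromeExperiment] = []
    fam = config.family
    for e in range(config.n_experiments):
        rng = np.random.default_rng([config.seed, 11, e])
        rows = []
        for i in truth_idx:
            if rng.random() >= config.peak_prob_true:
                continue
            # peak fully inside the promoter window of the target's TSS
            max_off = config.window - config.peak_length - 1
            center = int(tss_pos[i]) + int(rng.integers(-max_off, max_off + 1))
            start = max(center - config.peak_length // 2, 0)
            rows.append((gene_chrom[i], start, start + config.peak_length, abs(rng.normal(config.true_score_mean, config.true_score_sd))))
        for _ in range(config.n_background_peaks):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, lengths[chrom] - config.peak_length))
            rows.append((chrom, start, start + config.peak_length, abs(rng.normal(config.background_score_mean, config.background_score_sd))))
        peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        experiments.append(
            CistromeExperiment(
                experiment_id=f"SRX{e:04d}",
                dataset_id=f"SRP{e // config.experiments_per_dataset:03d}",
                ip_node=fam.node_symbols[e % len(fam.node_symbols)],
                node_family=fam.name,
                system=fam.system,
                organ=fam.organ,
                species=fam.species,
                peaks=peaks,
            )
        )
    truth = GeneSet("true_targets", frozenset(genes[truth_idx]))
    return experiments, tss, truth


# ---------------------------------------------------------------------------
# on-disk fixtures (exact dialects the readers consume)


def write_transcriptomic_corpus(tables, meta: pd.DataFrame, truth: GeneSet, outdir) -> None:
    """Write a corpus as tables/<exp>.tsv + meta.tsv + truth.txt."""
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    meta = meta.copy()
    meta["path"] = [f"tables/{t.experiment_id}.tsv" for t in tables]
    for table in tables:
        out = table.data.loc[:, ["probeset_id", "gene_id", "fold_change", "p_value"]]
        out.to_csv(outdir / "tables" / f"{table.experiment_id}.tsv", sep="\t", index=False, float_format="%.17g")
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    (outdir / "truth.txt").write_text("\n".join(sorted(truth.members)) + "\n")


def load_transcriptomic_corpus(directory, dialect: TableDialect | None = None) -> tuple[list[ExperimentTable], pd.DataFrame]:
    """Load a corpus written by :func:`write_transcriptomic_corpus`.

    The metadata's ``path`` column locates each experiment table relative
    to the metadata file.
    """
    directory = Path(directory)
    meta = read_metadata_table(directory / "meta.tsv")
    if "path" not in meta.columns:
        raise FileNotFoundError(f"{directory}/meta.tsv has no 'path' column locating experiment tables")
    tables = [
        read_experiment_table(directory / row.path, dialect=dialect, experiment_id=row.experiment_id)
        for row in meta.itertuples(index=False)
    ]
    return tables, meta


def write_cistromic_corpus(experiments, tss: pd.DataFrame, truth: GeneSet, outdir) -> None:
    """Write peaks/<exp>.bed + cistrome_meta.tsv + tss.tsv + truth.txt."""
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    rows = []
    for exp in experiments:
        path = f"peaks/{exp.experiment_id}.bed"
        exp.peaks.to_csv(outdir / path, sep="\t", index=False, header=False, float_format="%.17g")
        rows.append(
            {
                "experiment_id": exp.experiment_id,
                "dataset_id": exp.dataset_id,
                "ip_node": exp.ip_node,
                "node_family": exp.node_family,
                "system": exp.system,
                "organ": exp.organ,
                "species": exp.species,
                "path": path,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "cistrome_meta.tsv", sep="\t", index=False)
    tss.to_csv(outdir / "tss.tsv", sep="\t", index=False)
    (outdir / "truth.txt").write_text("\n".join(sorted(truth.members)) + "\n")
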