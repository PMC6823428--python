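"""Probeset-to-gene aggregation of differential-expression evidence.

Within one experiment, a gene measured by several array probesets gets a
single directional summary. Each probeset's two-tailed p-value ``P_p`` and
linear fold change ``F_p`` is turned into a directional z-score

    Z_p = qnorm(|1 + sign(log2 F_p) - P_p| / 2),    sign(0) = +1

so that induction (F >= 1) maps to the upper tail, qnorm(1 - P_p/2), and
repression to the lower tail, qnorm(P_p/2). The gene-level z is the
arithmetic mean of its probeset z's; the gene-level two-tailed p-value is
P = 2 * (1 - pnorm(|Z|)). The gene-level fold change is the value, at the
mean z, of an ordinary least-squares regression of probeset log2 fold
changes on probeset z's, exponentiated back to a linear ratio.

Single-probeset genes (the overwhelming majority on any array platform)
take a fast path that returns their input (P_p, F_p) exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ContractError, ExperimentTable

__all__ = [
    "directional_z",
    "combine_gene_z",
    "gene_fold_change",
    "aggregate_experiment",
    "ProbesetAggregator",
]

#: Evidence columns produced per (gene, experiment).
EVIDENCE_COLUMNS = [
    "gene_id",
    "experiment_id",
    "z",
    "p",
    "fold_change_hat",
    "log2_fc_hat",
    "n_probesets",
]

DEFAULT_P_FLOOR = 1e-300


def directional_z(fold_change, p_value, p_floor: float = DEFAULT_P_FLOOR):
    """Directional probeset z-score from a fold change and two-tailed p.

    Parameters
    ----------
    fold_change : float or array
        Linear fold-change ratio, strictly positive. Only its direction
        (>= 1 or < 1) enters the score.
    p_value : float or array
        Two-tailed nominal p-value in [0, 1]; clamped to
        [p_floor, 1 - p_floor] before the quantile transform so upstream
        p = 0 cannot produce an infinite z.

    Returns
    -------
    z : float or ndarray
        Positive for induction, negative for repression; zero only at
        p = 1 (with the F >= 1 branch taken at F = 1, since sign(0) = +1).
    """
    fc = np.asarray(fold_change, dtype=float)
    p = np.asarray(p_value, dtype=float)
    if np.any(fc <= 0) or not np.all(np.isfinite(fc)):
        raise ValueError("fold_change must be strictly positive and finite")
    sign = np.where(np.log2(fc) >= 0, 1.0, -1.0)
    z = sign * _z_magnitude(p, p_floor)
    return z if z.ndim else float(z)


def _z_magnitude(p: np.ndarray, p_floor: float) -> np.ndarray:
    """qnorm(1 - p/2): the |z| of a two-tailed p after clamping.

    The signed score sign * qnorm(1 - p/2) equals the branch form
    qnorm(1 - p/2) for induction / qnorm(p/2) for repression, but applying
    the sign to one quantile keeps antisymmetry exact in floating point.
    """
    p = np.clip(p, p_floor, 1.0 - p_floor)
    # = qnorm(1 - p/2) via symmetry, avoiding 1-p cancellation at tiny p;
    # "+ 0.0" normalizes -0.0 at p = 1 so the null case is exactly 0.0
    return -stats.norm.ppf(p / 2.0) + 0.0


def _z_from_log2(log2_fc: np.ndarray, p: np.ndarray, p_floor: float) -> np.ndarray:
    """Vectorized directional z from the canonical log2 representation."""
    sign = np.where(log2_fc >= 0, 1.0, -1.0)
    return sign * _z_magnitude(p, p_floor)


def combine_gene_z(z_values) -> tuple[float, float]:
    """Average probeset z-scores and convert back to a two-tailed p.

    Returns ``(Z, P)`` with Z the arithmetic mean and
    ``P = 2 * (1 - pnorm(|Z|))``, capped at 1.0.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ContractError("combine_gene_z requires at least one z-score")
    Z = float(np.mean(z))
    P = min(2.0 * stats.norm.sf(abs(Z)), 1.0)
    return Z, P


def gene_fold_change(probesets, Z: float) -> float:
    """Gene-level linear fold change from (z, fold_change) probeset pairs.

    For two or more probesets with non-degenerate z-variance this is
    2**(a + b*Z) from the OLS fit of log2(F_p) on Z_p. With a single
    probeset the fold change passes through unchanged; with all z's equal
    (zero regression variance) the geometric mean of the fold changes is
    returned.
    """
    pairs = list(probesets)
    z = np.array([p[0] for p in pairs], dtype=float)
    log2f = np.log2(np.array([p[1] for p in pairs], dtype=float))
    return float(np.exp2(_predict_log2fc(z, log2f, Z)))


def _predict_log2fc(z: np.ndarray, log2f: np.ndarray, Z: float) -> float:
    """OLS prediction of log2 fold change at z = Z, with degenerate fallbacks."""
    n = z.size
    if n == 0:
        raise ContractError("gene_fold_change requires at least one probeset")
    if n == 1:
        return float(log2f[0])
    zbar = np.mean(z)
    dz = z - zbar
    sxx = np.dot(dz, dz)
    if sxx == 0.0:  # all probeset z's identical: regression undefined
        return float(np.mean(log2f))
    ybar = np.mean(log2f)
    bhat = np.dot(dz, log2f - ybar) / sxx
    ahat = ybar - bhat * zbar
    return float(ahat + bhat * Z)


def aggregate_experiment(
    table: ExperimentTable, p_floor: float = DEFAULT_P_FLOOR
) -> pd.DataFrame:
    """Collapse one experiment's probeset rows to per-gene evidence.

    Returns a frame with one row per distinct gene: columns
    ``gene_id, experiment_id, z, p, fold_change_hat, log2_fc_hat,
    n_probesets``. Genes measured by a single probeset keep their input
    p-value and fold change exactly.
    """
    df = table.data
    log2f = df["log2_fold_change"].to_numpy(dtype=float)
    pvals = df["p_value"].to_numpy(dtype=float)
    z = _z_from_log2(log2f, pvals, p_floor)

    genes = df["gene_id"].to_numpy()
    order = np.argsort(genes, kind="stable")
    genes_s, z_s, log2f_s = genes[order], z[order], log2f[order]
    p_s, fc_s = pvals[order], df["fold_change"].to_numpy(dtype=float)[order]

    uniq, starts, counts = np.unique(genes_s, return_index=True, return_counts=True)
    n_genes = uniq.size
    out_z = np.empty(n_genes)
    out_p = np.empty(n_genes)
    out_l2 = np.empty(n_genes)
    for i in range(n_genes):
        s, c = starts[i], counts[i]
        if c == 1:  # fast path: identity on (P_p, F_p)
            out_z[i] = z_s[s]
            out_p[i] = p_s[s]
            out_l2[i] = log2f_s[s]
        else:
            zz = z_s[s : s + c]
            Z = np.mean(zz)
            out_z[i] = Z
            out_p[i] = min(2.0 * stats.norm.sf(abs(Z)), 1.0)
            out_l2[i] = _predict_log2fc(zz, log2f_s[s : s + c], Z)
    out_fc = np.exp2(out_l2)
    single = counts == 1
    out_fc[single] = fc_s[starts[single]]  # exact linear pass-through
    return pd.DataFrame(
        {
            "gene_id": uniq,
            "experiment_id": table.experiment_id,
            "z": out_z,
            "p": out_p,
            "fold_change_hat": out_fc,
            "log2_fc_hat": out_l2,
            "n_probesets": counts.astype(np.int64),
        }
    )


class ProbesetAggregator(TransformerMixin, BaseEstimator):
    """Stateless transformer turning experiment tables into gene evidence.

    Parameters
    ----------
    p_floor : float, default 1e-300
        Clamp applied to p-values before the normal-quantile transform.
    """

    def __init__(self, p_floor: float = DEFAULT_P_FLOOR):
        self.p_floor = p_floor

    def fit(self, X, y=None):
        """No state to learn; present for pipeline compatibility."""
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        """Aggregate one table or a sequence of tables into a long evidence frame."""
        tables = [X] if isinstance(X, ExperimentTable) else list(X)
        frames = [aggregate_experiment(t, p_floor=self.p_floor) for t in tables]
        if not frames:
            return pd.DataFrame(columns=EVIDENCE_COLUMNS)
        return pd.concat(frames, ignore_index=True)
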