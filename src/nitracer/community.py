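"""Community diversity, dissimilarity, ordination and permutation tests.

Implemented from first principles on the count-table container:

* alpha diversity — Chao1 richness (bias-corrected form, defined when no
  doubletons exist; the classical form is an option), Shannon entropy in
  natural-log units, Simpson's index in the dominance form Σp² (lower =
  more even), with the 1−D and 1/D complements also emitted;
* Bray–Curtis dissimilarity;
* principal coordinates analysis (PCoA) by eigendecomposition of the
  double-centred squared-distance matrix;
* the Mantel test (Pearson or Spearman, one-tailed permutation p-value with
  the observed statistic included in the null — the "+1" convention);
* ANOSIM with the statistic R = (r̄_between − r̄_within) / (n(n−1)/4) on
  ranked pairwise distances.

Default permutation count is 999 everywhere.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AlignmentError, DomainError
from .io import CommunityTable, DistanceMatrix

__all__ = [
    "chao1",
    "shannon",
    "simpson",
    "alpha_diversity",
    "bray_curtis",
    "OrdinationResult",
    "pcoa",
    "mantel",
    "anosim",
    "scalar_to_distance",
]

logger = logging.getLogger(__name__)


def _clean_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise DomainError("counts must be a 1-D vector")
    if np.any(c < 0):
        raise DomainError("counts must be non-negative")
    if c.sum() == 0:
        raise DomainError("counts must contain at least one positive value")
    return c


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form S_obs + F1(F1−1) / (2(F2+1)); the classical form
    S_obs + F1²/(2 F2) is available but undefined when F2 = 0.
    """
    c = _clean_counts(counts)
    s_obs = float(np.sum(c > 0))
    f1 = float(np.sum(c == 1))
    f2 = float(np.sum(c == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    if f2 == 0:
        raise DomainError("classical Chao1 undefined without doubletons")
    return s_obs + f1**2 / (2.0 * f2)


def shannon(counts) -> float:
    """Shannon entropy −Σ p ln p over present taxa (natural-log units)."""
    c = _clean_counts(counts)
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Simpson's index in the dominance form Σ p² (1 = single taxon)."""
    c = _clean_counts(counts)
    p = c / c.sum()
    return float((p**2).sum())


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-site diversity table: chao1, shannon, simpson (+ complements).

    Logs a warning when site depths differ by more than 10× — the indices
    are depth-sensitive and no rarefaction is applied here.
    """
    depths = table.counts.sum(axis=1)
    if depths.min() > 0 and depths.max() / depths.min() > 10:
        logger.warning(
            "site depths differ by more than 10x (%d vs %d); diversity "
            "indices are depth-sensitive and no rarefaction is applied",
            depths.min(),
            depths.max(),
        )
    rows = []
    for i, site in enumerate(table.site_ids):
        c = table.counts[i]
        d = simpson(c)
        rows.append(
            {
                "site_id": site,
                "chao1": chao1(c),
                "shannon": shannon(c),
                "simpson": d,
                "simpson_1mD": 1.0 - d,
                "inv_simpson": 1.0 / d,
            }
        )
    return pd.DataFrame(rows)


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity d(a,b) = Σ|a−b| / Σ(a+b) between sites."""
    if table.n_sites < 2:
        raise DomainError("need at least 2 sites")
    X = table.counts.astype(float)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        bad = [table.site_ids[i] for i in np.flatnonzero(totals == 0)]
        raise DomainError(f"site(s) with zero total counts: {bad}")
    n = table.n_sites
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i + 1 :] - X[i]).sum(axis=1)
        summ = (X[i + 1 :] + X[i]).sum(axis=1)
        d[i, i + 1 :] = diff / summ
    d += d.T
    return DistanceMatrix(list(table.site_ids), d)


class OrdinationResult:
    """PCoA coordinates with per-axis proportion of explained variation."""

    def __init__(
        self,
        labels: list[str],
        coordinates: np.ndarray,
        proportion_explained: np.ndarray,
        eigenvalues: np.ndarray,
    ) -> None:
        self.labels = labels
        self.coordinates = coordinates
        self.proportion_explained = proportion_explained
        self.eigenvalues = eigenvalues

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=self.labels,
            columns=[f"PCoA{a + 1}" for a in range(self.coordinates.shape[1])],
        )
        df.index.name = "site_id"
        return df


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates analysis (metric MDS).

    Double-centres −½ D², eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues; proportions explained are
    relative to the sum of positive eigenvalues.  Requests for more axes
    than there are positive eigenvalues are truncated with a warning.
    """
    D2 = d.values**2
    n = d.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-8 * max(abs(evals[0]), 1.0)
    positive = evals > tol
    n_pos = int(positive.sum())
    if n_axes > n_pos:
        logger.warning(
            "requested %d axes but only %d positive eigenvalues; truncating",
            n_axes,
            n_pos,
        )
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    prop = evals[:n_axes] / evals[positive].sum()
    return OrdinationResult(list(d.labels), coords, prop, evals)


def _mantel_r(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise DomainError(f"unknown correlation method {method!r}")
    x = x - x.mean()
    y = y - y.mean()
    return float((x @ y) / np.sqrt((x @ x) * (y @ y)))


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    method: str = "pearson",
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test between two labelled distance matrices.

    r is the correlation of the vectorized upper triangles; the one-tailed
    p-value permutes rows and columns of the second matrix jointly and is
    (1 + #{permuted r ≥ observed}) / (1 + n_perm).
    """
    if d1.n < 4:
        raise DomainError("Mantel test needs at least 4 items")
    d2 = d2.align_to(d1.labels)
    iu = np.triu_indices(d1.n, k=1)
    x = d1.values[iu]
    r_obs = _mantel_r(x, d2.values[iu], method)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(d1.n)
        r_perm = _mantel_r(x, d2.values[np.ix_(perm, perm)][iu], method)
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p


def anosim(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """ANOSIM on ranked pairwise distances.

    R = (mean between-group rank − mean within-group rank) / (n(n−1)/4),
    ranking all M = n(n−1)/2 pairwise distances; the one-tailed p-value
    permutes group labels.
    """
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise AlignmentError("one group label required per distance row")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise DomainError("need at least 2 groups")
    if counts.min() < 2:
        raise DomainError("each group needs at least 2 members")
    iu = np.triu_indices(d.n, k=1)
    ranks = rankdata(d.values[iu])
    denom = d.n * (d.n - 1) / 4.0

    def _stat(g: np.ndarray) -> float:
        within = g[iu[0]] == g[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = _stat(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _stat(rng.permutation(groups)) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p


def scalar_to_distance(labels, values) -> DistanceMatrix:
    """Absolute-difference distance matrix of a scalar site variable.

    The natural transform for Mantel tests of community structure against a
    single environmental variable.
    """
    values = np.asarray(values, dtype=float)
    d = np.abs(values[:, None] - values[None, :])
    return DistanceMatrix(list(labels), d)
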