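"""Microbial community statistics: rarefaction, alpha/beta diversity,
principal-coordinates analysis, Mantel and Procrustes concordance tests,
and a discriminant effect-size screen for indicator taxa.

Count tables carry taxa in rows and samples in columns.  Bray-Curtis is the
beta-diversity metric throughout (it is a semi-metric: the triangle
inequality is not guaranteed and is deliberately not relied upon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "PCoAResult",
    "mantel",
    "procrustes",
    "ProcrustesResult",
    "lda_effect_size",
]


def rarefy(table: pd.DataFrame, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample each sample column to ``depth`` reads without replacement
    (multivariate hypergeometric draw).  Columns shallower than ``depth``
    are dropped with a warning."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    counts = table.to_numpy(dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative integers")
    rng = np.random.default_rng(seed)
    sums = counts.sum(axis=0)
    keep = sums >= depth
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} sample(s) below depth {depth}")
    out = {}
    for j, col in enumerate(table.columns):
        if not keep[j]:
            continue
        out[col] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return pd.DataFrame(out, index=table.index)


def alpha_diversity(column) -> tuple[float, float]:
    """Chao1 richness (bias-corrected) and Shannon entropy (natural log).

    Chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1)) with F1 singletons and F2
    doubletons; Shannon = -sum p ln p over observed taxa.
    """
    x = np.asarray(column, dtype=np.int64)
    if x.size == 0 or x.sum() == 0:
        raise ValueError("empty sample")
    obs = x[x > 0]
    f1 = int(np.sum(obs == 1))
    f2 = int(np.sum(obs == 2))
    chao1 = obs.size + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = obs / obs.sum()
    shannon = float(-np.sum(p * np.log(p)))
    return float(chao1), shannon


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between sample columns,
    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = table.to_numpy(dtype=float).T
    if np.any(x < 0):
        raise ValueError("abundances must be nonnegative")
    zero = x.sum(axis=1) == 0
    if zero.any():
        warnings.warn("all-zero sample(s); their pairwise distances are undefined (NaN)")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    fractions: np.ndarray  # variance fractions of retained (positive) axes
    negative_eigenvalues: np.ndarray


def pcoa(distance: pd.DataFrame) -> PCoAResult:
    """Principal-coordinates analysis (classical MDS).

    Gower-centres -D^2/2, eigendecomposes, and returns coordinates scaled by
    the square roots of the positive eigenvalues.  Negative eigenvalues
    (possible for semi-metrics) are reported but excluded from the variance
    fractions.
    """
    d = np.asarray(distance, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(abs(evals[0]), 1.0)
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    fractions = evals[pos] / evals[pos].sum()
    labels = list(distance.index) if isinstance(distance, pd.DataFrame) else range(n)
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=axes),
        eigenvalues=evals,
        fractions=fractions,
        negative_eigenvalues=evals[evals < -tol],
    )


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel(d1, d2, n_perm: int = 999, seed: int | None = None) -> tuple[float, float]:
    """Mantel test: Pearson correlation of the two upper triangles with a
    one-sided (greater) permutation p-value.

    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm), permuting rows and columns
    of the second matrix jointly.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square with equal shape")
    if a.shape[0] < 4:
        raise ValueError("need at least 4 samples for a meaningful Mantel test")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        if list(d1.index) != list(d2.index):
            raise ValueError("matrices must share sample labels and order")
    va, vb = _upper(a), _upper(b)
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if np.corrcoef(va, _upper(b[np.ix_(idx, idx)]))[0, 1] >= r_obs:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


@dataclass
class ProcrustesResult:
    m_squared: float
    correlation: float
    rotation: np.ndarray
    scale: float


def procrustes(x, y) -> ProcrustesResult:
    """Orthogonal Procrustes superposition of two ordinations.

    Both configurations are centred and scaled to unit sum of squares; the
    optimal rotation comes from the SVD of Y^T X.  m^2 = 1 - (sum sigma)^2
    is the residual after superposition and sqrt(1 - m^2) the Procrustes
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("need at least 2 columns per configuration")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    nx = np.sqrt(np.sum(xc ** 2))
    ny = np.sqrt(np.sum(yc ** 2))
    if nx == 0 or ny == 0:
        raise ValueError("degenerate (zero-variance) configuration")
    xc /= nx
    yc /= ny
    u, s, vt = np.linalg.svd(yc.T @ xc)
    trace = s.sum()
    m2 = max(1.0 - trace ** 2, 0.0)
    return ProcrustesResult(
        m_squared=m2,
        correlation=float(np.sqrt(1.0 - m2)),
        rotation=u @ vt,
        scale=float(trace),
    )


def lda_effect_size(table: pd.DataFrame, groups, kw_alpha: float = 0.05,
                    lda_min: float = 3.0, correction: str = "fdr_bh",
                    group_order=None) -> pd.DataFrame:
    """Discriminant effect-size screen for group-indicator taxa.

    A Kruskal-Wallis test per taxon (multiplicity-corrected) screens for
    group differences; surviving taxa are mapped to a per-sample relative
    scale of 1e6 and scored by the log10 absolute difference of class means
    between the two extreme groups.  A taxon is a significant indicator when
    the corrected KW p < ``kw_alpha`` and the score >= ``lda_min``.

    This is a deliberately reduced effect-size procedure (no subclass
    bootstrapping); scores are on the conventional log10 LDA scale.
    """
    groups = pd.Series(list(groups), index=table.columns)
    order = list(group_order) if group_order is not None else list(dict.fromkeys(groups))
    if len(order) < 2:
        raise ValueError("need at least 2 groups")
    for g in order:
        if (groups == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
    rel = table.div(table.sum(axis=0), axis=1) * 1e6
    lo, hi = order[0], order[-1]
    rows = []
    for taxon, vals in rel.iterrows():
        by_group = [vals[groups == g].to_numpy() for g in order]
        if np.ptp(table.loc[taxon].to_numpy()) == 0:
            rows.append((taxon, np.nan, np.nan, np.nan, None, False, True))
            continue
        kw_p = stats.kruskal(*by_group).pvalue
        mean_lo = vals[groups == lo].mean()
        mean_hi = vals[groups == hi].mean()
        gap = abs(mean_hi - mean_lo)
        score = np.log10(gap) if gap > 0 else -np.inf
        enriched = hi if mean_hi >= mean_lo else lo
        rows.append((taxon, kw_p, np.nan, score, enriched, False, False))
    out = pd.DataFrame(rows, columns=["taxon", "kw_p", "kw_q", "lda_score",
                                      "enriched_group", "significant",
                                      "constant"]).set_index("taxon")
    tested = ~out["kw_p"].isna()
    if tested.any():
        out.loc[tested, "kw_q"] = multipletests(
            out.loc[tested, "kw_p"].to_numpy(), method=correction)[1]
    out["significant"] = (out["kw_q"] < kw_alpha) & (out["lda_score"] >= lda_min)
    return out
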