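"""Flavoromics statistics: scaling, differential abundance, PCA, odor
activity, taste ratios, co-occurrence networks and pathway enrichment.

Operates on rectangular abundance tables with compounds in rows and samples
in columns (nonnegative entries).  Differential testing uses Welch t-tests
on log-transformed abundances with Benjamini-Hochberg correction and a
fold-change gate; co-occurrence networks threshold pairwise Spearman
correlations with family-wise or FDR multiplicity control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "scale_table",
    "differential_test",
    "pca",
    "PCAResult",
    "roav",
    "umami_sweet_ratio",
    "correlation_network",
    "CorrelationNetwork",
    "enrichment_test",
]

_SCALE_MODES = ("pareto", "zscore", "log10p")


def scale_table(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Per-feature scaling of an abundance table (features x samples).

    ``pareto``: (x - mean)/sqrt(SD); ``zscore``: (x - mean)/SD;
    ``log10p``: log10(x + 1).  Constant features cannot be variance-scaled
    and are dropped with a warning.
    """
    if mode not in _SCALE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_SCALE_MODES}")
    if mode == "log10p":
        return np.log10(table + 1.0)
    sd = table.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant feature(s)")
        table = table.loc[~constant]
        sd = sd[~constant]
    centred = table.sub(table.mean(axis=1), axis=0)
    denom = np.sqrt(sd) if mode == "pareto" else sd
    return centred.div(denom, axis=0)


def differential_test(table: pd.DataFrame, group_a, group_b,
                      fc_min: float = 1.0, q_max: float = 0.05) -> pd.DataFrame:
    """Per-feature differential abundance between two sample groups.

    log2FC = log2((mean_B + eps)/(mean_A + eps)) with eps = half the smallest
    nonzero table entry; Welch t-test on the log2(x + eps) scale;
    Benjamini-Hochberg q-values.  A feature is called significant when
    |log2FC| >= ``fc_min`` and q < ``q_max``.
    """
    a = table[list(group_a)].to_numpy(dtype=float)
    b = table[list(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 replicates")
    nonzero = table.to_numpy()[table.to_numpy() > 0]
    eps = 0.5 * nonzero.min() if nonzero.size else 1.0
    log2fc = np.log2((b.mean(axis=1) + eps) / (a.mean(axis=1) + eps))
    with np.errstate(invalid="ignore"):
        tstat, pvals = stats.ttest_ind(np.log2(b + eps), np.log2(a + eps),
                                       axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": tstat,
            "p": pvals,
            "q": qvals,
            "significant": (np.abs(log2fc) >= fc_min) & (qvals < q_max),
        },
        index=table.index,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray


def pca(table: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal-component analysis via SVD of the feature-centred matrix.

    Samples are observations (table columns); explained-variance fractions
    are sigma_i^2 / sum sigma^2.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 features and 2 samples")
    x = table.to_numpy(dtype=float).T  # samples x features
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise ValueError("matrix is constant; PCA undefined")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = n_components or min(xc.shape)
    frac = s ** 2 / np.sum(s ** 2)
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((u * s)[:, :k], index=table.columns, columns=comps)
    loadings = pd.DataFrame(vt[:k].T, index=table.index, columns=comps)
    return PCAResult(scores, loadings, frac[:k])


def roav(concentrations, odor_thresholds):
    """Relative odor-activity values: 100 * (C/OT) / max(C/OT).

    The compound with the largest odor-activity quotient anchors the scale
    at 100; an all-zero concentration vector yields all zeros.
    """
    c = np.asarray(concentrations, dtype=float)
    ot = np.asarray(odor_thresholds, dtype=float)
    if np.any(ot <= 0):
        raise ValueError("odor thresholds must be positive")
    oav = c / ot
    top = oav.max()
    if top == 0:
        return np.zeros_like(oav)
    return 100.0 * oav / top


def umami_sweet_ratio(aa_table: pd.DataFrame, class_map: dict,
                      log_scale: bool = True) -> pd.Series:
    """Per-sample ratio of summed umami to summed sweet amino-acid
    abundances.

    ``class_map`` maps amino-acid name to taste class; ``log_scale`` marks
    tables stored as log10 abundances, which are exponentiated before
    summation.  A zero sweet sum yields ``inf`` with a warning.
    """
    umami = [a for a in aa_table.index if class_map.get(a) == "umami"]
    sweet = [a for a in aa_table.index if class_map.get(a) == "sweet"]
    if not umami or not sweet:
        raise ValueError("both umami and sweet classes must be present")
    values = 10.0 ** aa_table if log_scale else aa_table
    num = values.loc[umami].sum(axis=0)
    den = values.loc[sweet].sum(axis=0)
    if (den == 0).any():
        warnings.warn("zero sweet-class sum; ratio is infinite")
    with np.errstate(divide="ignore"):
        return num / den


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    edges: pd.DataFrame  # feature_i, feature_j, rho, sign, q
    density: float
    clustering_coefficient: float  # global transitivity
    degree: dict = field(repr=False)
    rho_min: float = 0.7
    q_max: float = 0.05


def correlation_network(table: pd.DataFrame, method: str = "spearman",
                        rho_min: float = 0.7, correction: str = "bonferroni",
                        q_max: float = 0.05) -> CorrelationNetwork:
    """Co-occurrence network from pairwise feature correlations over samples.

    Edges keep pairs with |rho| >= ``rho_min`` and corrected p < ``q_max``
    (``correction`` is ``bonferroni`` or ``bh``).  Density is |E| over the
    number of possible pairs; the clustering coefficient is the global
    transitivity 3 x triangles / connected triples.
    """
    if table.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    if method == "spearman":
        rho, p = stats.spearmanr(table.to_numpy(dtype=float), axis=1)
    elif method == "pearson":
        rho = np.corrcoef(table.to_numpy(dtype=float))
        n = table.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    names = list(table.index)
    iu = np.triu_indices(len(names), k=1)
    pv = p[iu]
    if correction == "bonferroni":
        q = np.minimum(pv * pv.size, 1.0)
    elif correction in ("bh", "fdr_bh"):
        q = multipletests(pv, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    rv = rho[iu]
    keep = (np.abs(rv) >= rho_min) & (q < q_max)
    g = nx.Graph()
    g.add_nodes_from(names)
    mean_ab = table.mean(axis=1)
    nx.set_node_attributes(g, mean_ab.to_dict(), "mean_abundance")
    rows = []
    for (i, j, r, qq, k) in zip(iu[0], iu[1], rv, q, keep):
        if k:
            g.add_edge(names[i], names[j], rho=float(r),
                       sign=int(np.sign(r)), q=float(qq))
            rows.append((names[i], names[j], float(r), int(np.sign(r)), float(qq)))
    edges = pd.DataFrame(rows, columns=["feature_i", "feature_j", "rho", "sign", "q"])
    return CorrelationNetwork(
        graph=g,
        edges=edges,
        density=nx.density(g),
        clustering_coefficient=nx.transitivity(g),
        degree=dict(g.degree()),
        rho_min=rho_min,
        q_max=q_max,
    )


def enrichment_test(hit_set, annotation: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation test per pathway.

    ``annotation`` maps feature -> pathway (or iterable of pathways).  The
    one-sided tail probability of drawing at least the observed number of
    pathway members among the hits is corrected by Benjamini-Hochberg.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    hits = set(hit_set)
    if not hits <= universe:
        raise ValueError("hit set must be a subset of the universe")
    pathways: dict[str, set] = {}
    for feat, path in annotation.items():
        if feat not in universe:
            continue
        for pw in ([path] if isinstance(path, str) else path):
            pathways.setdefault(pw, set()).add(feat)
    rows = []
    m_univ, n_hits = len(universe), len(hits)
    for pw, members in sorted(pathways.items()):
        k = len(hits & members)
        size = len(members)
        p = stats.hypergeom.sf(k - 1, m_univ, size, n_hits)
        expected = n_hits * size / m_univ
        fold = k / expected if expected > 0 else np.nan
        rows.append((pw, k, size, fold, p))
    out = pd.DataFrame(rows, columns=["pathway", "count", "pathway_size",
                                      "fold_enrichment", "p"]).set_index("pathway")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] if len(out) else []
    return out
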