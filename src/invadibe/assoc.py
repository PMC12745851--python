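"""Stand-alone statistical tests used around the pairwise-F_ST modelling:

Mantel matrix-correlation test (with exact enumeration for tiny n),
mito-nuclear chi-squared concordance, Kruskal-Wallis with Dunn's post hoc
comparisons (Bonferroni), cluster-climate permutation tests, and the
second-order rate-of-change (Delta K) heuristic for choosing the number of
clusters from STRUCTURE-style log-likelihood tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import spatial, stats

from .genotype_io import GenotypeMatrix


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None


@dataclass(frozen=True)
class DunnComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class DunnResult:
    h: float
    h_p: float
    comparisons: list[DunnComparison]


@dataclass(frozen=True)
class EvannoResult:
    k_values: np.ndarray
    mean_lnp: np.ndarray
    sd_lnp: np.ndarray
    delta_k: np.ndarray      # NaN at the boundary K and where sd == 0
    best_k: int | None


# ---------------------------------------------------------------------------
# Mantel

def _check_square(d: np.ndarray, name: str):
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    return d


def mantel(dA: np.ndarray, dB: np.ndarray, n_perm: int = 10000,
           seed: int = 0, exact: bool = False) -> MantelResult:
    """Mantel test of matrix correlation, one-sided (upper).

    r is the Pearson correlation of the lower-triangle entries; the null is
    generated by simultaneous row/column permutation of the second matrix.
    ``exact=True`` enumerates all n! permutations (n <= 8 recommended) and
    reports the exact one-sided p as the fraction of permutations with
    r_perm >= r_obs.
    """
    dA, dB = _check_square(dA, "dA"), _check_square(dB, "dB")
    if dA.shape != dB.shape:
        raise ValueError("matrix dimensions differ")
    n = dA.shape[0]
    if n < 4:
        raise ValueError("need at least a 4x4 matrix")
    tril = np.tril_indices(n, -1)
    a = dA[tril]
    if np.std(a) == 0 or np.std(dB[tril]) == 0:
        raise ValueError("constant distance matrix: r undefined")

    def corr_with(mat):
        b = mat[tril]
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr_with(dB)
    if exact:
        rs = []
        for perm in permutations(range(n)):
            p = np.asarray(perm)
            rs.append(corr_with(dB[np.ix_(p, p)]))
        rs = np.asarray(rs)
        p_val = float(np.mean(rs >= r_obs - 1e-12))
        return MantelResult(r_obs, p_val, len(rs), None)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr_with(dB[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (1 + count) / (n_perm + 1), n_perm, seed)


def mantel_inputs(G: GenotypeMatrix, meta_frame: pd.DataFrame):
    """(genetic, geographic) distance matrices for the Mantel test.

    Genetic distance is Euclidean on dosage vectors with per-locus mean
    imputation of missing entries; geographic distance is Euclidean on raw
    decimal-degree coordinates (deliberately planar, matching the customary
    adegenet-style usage, unlike the great-circle distances in the pair
    table). ``meta_frame`` must be indexed by sample id with lat/lon columns.
    """
    d = G.dosages.astype(float)
    d = np.where(G.missing, np.nan, d)
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    d = np.where(np.isnan(d), col_mean, d)
    gen = spatial.distance.squareform(spatial.distance.pdist(d))
    coords = meta_frame.loc[G.sample_ids, ["lat", "lon"]].to_numpy(float)
    geo = spatial.distance.squareform(spatial.distance.pdist(coords))
    return gen, geo


# ---------------------------------------------------------------------------
# chi-squared concordance

def chi2_concordance(table: np.ndarray):
    """Pearson chi-squared (no continuity correction) on a 2x2 count table.

    Returns (chi2, df, p). Zero margins raise.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("need a 2x2 table of nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn

def kruskal_dunn(values: Sequence[float], groups: Sequence[str]) -> DunnResult:
    """Kruskal-Wallis H (tie-corrected) plus Dunn's pairwise Z tests with
    Bonferroni adjustment over the observed group pairs."""
    values = np.asarray(values, float)
    groups = np.asarray([str(g) for g in groups])
    labels = sorted(set(groups))
    if len(labels) < 2 or any((groups == l).sum() < 2 for l in labels):
        raise ValueError("need >=2 groups with >=2 values each")
    samples = [values[groups == l] for l in labels]
    if np.all(values == values[0]):
        comps = [DunnComparison(a, b, 0.0, 1.0, 1.0)
                 for a, b in combinations(labels, 2)]
        return DunnResult(0.0, 1.0, comps)
    h, h_p = stats.kruskal(*samples)
    n = values.size
    ranks = stats.rankdata(values)
    # tie correction for the pooled-rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n - 1))
    mean_rank = {l: float(ranks[groups == l].mean()) for l in labels}
    n_g = {l: int((groups == l).sum()) for l in labels}
    m = len(labels) * (len(labels) - 1) // 2
    comps = []
    for a, b in combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / n_g[a] + 1.0 / n_g[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        comps.append(DunnComparison(a, b, float(z), float(p_raw),
                                    float(min(1.0, m * p_raw))))
    return DunnResult(float(h), float(h_p), comps)


# ---------------------------------------------------------------------------
# climate permutation test

def env_perm_test(values: Sequence[float], labels: Sequence[str],
                  n_perm: int = 10000, seed: int = 0):
    """Two-sided permutation test of the between-cluster mean difference.

    Cluster labels are shuffled while values stay fixed;
    p = (1 + #{|diff_perm| >= |diff_obs|}) / (n_perm + 1).
    Returns (observed difference, p).
    """
    values = np.asarray(values, float)
    labels = np.asarray([str(l) for l in labels])
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two clusters, got {uniq}")
    mask = labels == uniq[0]
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("empty cluster")
    obs = float(values[mask].mean() - values[~mask].mean())
    rng = np.random.default_rng(seed)
    n1 = int(mask.sum())
    # vectorised label shuffles
    count = 0
    block = 2000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        idx = np.argsort(rng.random((b, values.size)), axis=1)[:, :n1]
        sums = values[idx].sum(axis=1)
        tot = values.sum()
        m1 = sums / n1
        m2 = (tot - sums) / (values.size - n1)
        count += int(np.sum(np.abs(m1 - m2) >= abs(obs) - 1e-12))
        done += b
    return obs, (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Delta K

def evanno_delta_k(lnpk: pd.DataFrame) -> EvannoResult:
    """Second-order rate of change of the log-likelihood across K.

    ``lnpk`` has columns (K, replicate, lnp) (case-insensitive; "LnP(K)" is
    accepted). Delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| /
    sd(L(K)); undefined at the boundary K values and where sd == 0 (flagged
    NaN). Requires >= 3 consecutive K values with >= 2 replicates each.
    """
    df = lnpk.copy()
    cols = {c.lower().split("(")[0].strip(): c for c in df.columns}
    try:
        kcol, rcol, lcol = cols["k"], cols["replicate"], cols["lnp"]
    except KeyError as exc:
        raise ValueError("lnpk table needs columns K, replicate, LnP") from exc
    grouped = df.groupby(kcol)[lcol]
    ks = np.array(sorted(grouped.groups))
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("need >=3 consecutive K values")
    counts = grouped.count().loc[ks].to_numpy()
    if np.any(counts < 2):
        raise ValueError("need >=2 replicates per K to estimate sd")
    mean = grouped.mean().loc[ks].to_numpy(float)
    sd = grouped.std(ddof=1).loc[ks].to_numpy(float)
    delta = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        if sd[i] > 0:
            delta[i] = abs(mean[i + 1] - 2 * mean[i] + mean[i - 1]) / sd[i]
    best = int(ks[np.nanargmax(delta)]) if np.isfinite(delta).any() else None
    return EvannoResult(ks, mean, sd, delta, best)
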