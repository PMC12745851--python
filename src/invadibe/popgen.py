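"""Diversity and differentiation statistics on SNP dosage matrices.

Implements nucleotide diversity, expected/observed heterozygosity, private
alleles, percent polymorphic loci, the Weir & Cockerham (1984) method-of-
moments F-statistics (multi-locus ratio-of-sums combining), locus-bootstrap
confidence intervals, label-permutation tests, per-individual-pair F_ST, and
P-distance matrices on SNP pseudo-sequences.

Notation for the Weir-Cockerham components at one locus with r populations:
``a`` (among populations), ``b`` (among individuals within populations) and
``c`` (within individuals); theta = sum(a) / sum(a+b+c) over loci, and the
within-population inbreeding coefficient f = 1 - sum(c)/sum(b+c).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotype_io import GenotypeMatrix


@dataclass(frozen=True)
class FstResult:
    """Weir-Cockerham theta with locus-bootstrap CI and permutation p-value."""
    theta: float
    ci95: tuple[float, float]
    perm_p: float | None
    n_loci_used: int


@dataclass(frozen=True)
class DiversityReport:
    group: str
    n: int
    private_alleles: int
    pct_polymorphic: float
    pi: float
    pi_se: float
    he_exp: float
    he_obs: float
    fis: float
    fis_ci95: tuple[float, float]


def _group_arrays(G: GenotypeMatrix, group: Iterable[str]):
    idx = G.sample_index(list(group))
    d = G.dosages[idx].astype(float)
    called = ~G.missing[idx]
    return d, called


def _freqs(d: np.ndarray, called: np.ndarray):
    """Per-locus ALT frequency and allele-copy count over non-missing calls."""
    n = called.sum(axis=0)
    alt = np.where(called, d, 0.0).sum(axis=0)
    copies = 2.0 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
    return p, copies


# ---------------------------------------------------------------------------
# Diversity

def nucleotide_diversity(G: GenotypeMatrix, group: Iterable[str]):
    """Mean per-site nucleotide diversity over variant sites, with SE.

    Per site, pi_l = (n_l/(n_l-1)) * (1 - sum_a p_a^2) with n_l the number of
    non-missing allele copies. The mean is over sites and SE = sd/sqrt(L).
    """
    group = list(group)
    if len(group) < 2:
        raise ValueError("need >=2 samples for nucleotide diversity")
    d, called = _group_arrays(G, group)
    p, copies = _freqs(d, called)
    ok = copies >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = copies / (copies - 1.0) * (1.0 - p ** 2 - (1.0 - p) ** 2)
    pi = pi[ok]
    if pi.size == 0:
        return np.nan, np.nan
    se = float(np.std(pi, ddof=1) / np.sqrt(pi.size)) if pi.size > 1 else np.nan
    return float(np.mean(pi)), se


def heterozygosity(G: GenotypeMatrix, group: Iterable[str]):
    """(mean expected, mean observed) heterozygosity over loci.

    He_exp is Nei's gene diversity 1 - sum p^2 with no small-sample
    correction; He_obs is the fraction of heterozygous calls among
    non-missing genotypes, averaged over loci with at least one call.
    """
    d, called = _group_arrays(G, group)
    p, copies = _freqs(d, called)
    ok = copies > 0
    he_exp = 2.0 * p[ok] * (1.0 - p[ok])
    n_called = called.sum(axis=0)
    het = np.where(called, d == 1, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    return float(np.mean(he_exp)), float(np.nanmean(ho[ok]))


def pct_polymorphic(G: GenotypeMatrix, group: Iterable[str]) -> float:
    """Percent of loci with >=2 alleles observed within the group."""
    d, called = _group_arrays(G, group)
    p, copies = _freqs(d, called)
    ok = copies > 0
    poly = (p > 0) & (p < 1)
    return float(100.0 * poly[ok].sum() / max(ok.sum(), 1))


def private_alleles(G: GenotypeMatrix, groups: Mapping[str, Iterable[str]]):
    """Count alleles observed in exactly one group, per group.

    ``groups`` maps a label to its member sample ids; the groups should
    partition the samples under consideration.
    """
    presence = {}
    for label, members in groups.items():
        d, called = _group_arrays(G, list(members))
        alt_copies = np.where(called, d, 0.0).sum(axis=0)
        ref_copies = np.where(called, 2.0 - d, 0.0).sum(axis=0)
        presence[label] = np.stack([ref_copies > 0, alt_copies > 0])  # (2, L)
    labels = list(groups)
    counts = {}
    total = sum(presence[l].astype(int) for l in labels)
    for l in labels:
        counts[l] = int((presence[l] & (total == 1)).sum())
    return counts


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components

def wc_components(d: np.ndarray, called: np.ndarray, labels: np.ndarray):
    """Per-locus W&C (1984) components a, b, c for diploid genotype data.

    Parameters are the dosage matrix (n_samples x L), the non-missing mask
    and an integer population label per sample. Returns (a, b, c) arrays of
    length L; loci with fewer than 2 populations having data yield NaN.
    """
    pops = np.unique(labels)
    r_max = len(pops)
    onehot = np.stack([labels == u for u in pops]).astype(float)  # (r, n)
    n_i = onehot @ called                                          # (r, L)
    alt_i = onehot @ np.where(called, d, 0.0)
    het_i = onehot @ np.where(called, d == 1.0, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt_i / (2.0 * n_i)
        h_i = het_i / n_i
    present = n_i > 0
    r = present.sum(axis=0).astype(float)                          # pops with data
    n_tot = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_tot / r
        nc = (n_tot - (n_i ** 2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = np.nansum(n_i * p_i, axis=0) / n_tot
        s2 = np.nansum(n_i * (p_i - pbar) ** 2, axis=0) / ((r - 1.0) * nbar)
        hbar = np.nansum(n_i * h_i, axis=0) / n_tot
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    bad = (r < 2) | ~np.isfinite(a)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def _theta_from_components(a, b, c):
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    return num / den if den != 0 else np.nan


def _theta(d, called, labels):
    return _theta_from_components(*wc_components(d, called, labels))


def wc_fst(G: GenotypeMatrix, groupA: Iterable[str], groupB: Iterable[str],
           n_boot: int = 999, n_perm: int = 999,
           seed: int | np.random.Generator = 0) -> FstResult:
    """Weir-Cockerham theta between two groups with bootstrap CI and
    label-permutation test.

    The CI is a percentile bootstrap over loci (``n_boot`` replicates); the
    permutation p-value is (1 + #{theta_perm >= theta_obs}) / (n_perm + 1)
    under random reshuffling of group labels among the pooled samples.
    """
    rng = np.random.default_rng(seed)
    groupA, groupB = list(groupA), list(groupB)
    members = groupA + groupB
    idx = G.sample_index(members)
    d = G.dosages[idx].astype(float)
    called = ~G.missing[idx]
    labels = np.array([0] * len(groupA) + [1] * len(groupB))
    a, b, c = wc_components(d, called, labels)
    usable = np.isfinite(a)
    if not usable.any():
        raise ValueError("no shared informative loci between the groups")
    theta = _theta_from_components(a, b, c)
    a_u, abc_u = a[usable], (a + b + c)[usable]
    lo = hi = np.nan
    if n_boot > 0 and min(len(groupA), len(groupB)) >= 2:
        L = a_u.size
        reps = np.empty(n_boot)
        for k in range(n_boot):
            take = rng.integers(0, L, L)
            den = abc_u[take].sum()
            reps[k] = a_u[take].sum() / den if den != 0 else np.nan
        lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    perm_p = None
    if n_perm > 0:
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if _theta(d, called, perm) >= theta:
                count += 1
        perm_p = (1 + count) / (n_perm + 1)
    return FstResult(float(theta), (float(lo), float(hi)), perm_p,
                     int(usable.sum()))


def fis(G: GenotypeMatrix, group: Iterable[str], n_boot: int = 999,
        seed: int | np.random.Generator = 0):
    """Multilocus W&C inbreeding coefficient f = 1 - sum(c)/sum(b+c).

    Returns (estimate, (lo, hi)) with a percentile locus bootstrap CI.
    All-monomorphic input returns (nan, (nan, nan)).
    """
    rng = np.random.default_rng(seed)
    group = list(group)
    if len(group) < 2:
        raise ValueError("need >=2 samples for F_IS")
    d, called = _group_arrays(G, group)
    labels = np.zeros(len(group), dtype=int)
    b, c = _within_components(d, called)
    ok = np.isfinite(b) & ((b + c) != 0)
    if not ok.any():
        return np.nan, (np.nan, np.nan)
    b_u, c_u = b[ok], c[ok]
    est = 1.0 - c_u.sum() / (b_u + c_u).sum()
    L = b_u.size
    reps = np.empty(n_boot)
    for k in range(n_boot):
        take = rng.integers(0, L, L)
        den = (b_u[take] + c_u[take]).sum()
        reps[k] = 1.0 - c_u[take].sum() / den if den != 0 else np.nan
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return float(est), (float(lo), float(hi))


def _within_components(d: np.ndarray, called: np.ndarray):
    """Single-population W&C components b (among individuals) and c (within).

    The among-population terms vanish at r=1:
    b = n/(n-1) * [p(1-p) - (2n-1)/(4n) * hbar], c = hbar/2.
    """
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, d, 0.0).sum(axis=0) / (2.0 * n)
        hbar = np.where(called, d == 1.0, 0.0).sum(axis=0) / n
        b = n / (n - 1.0) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
    c = hbar / 2.0
    mono = (p <= 0) | (p >= 1)
    b = np.where((n < 2) | mono & (hbar == 0), np.nan, b)
    c = np.where(np.isfinite(b), c, np.nan)
    return b, c


def fis_simple(G: GenotypeMatrix, group: Iterable[str]) -> float:
    """Cross-check estimator 1 - Ho/He over polymorphic loci (not reported)."""
    d, called = _group_arrays(G, group)
    p, copies = _freqs(d, called)
    n_called = called.sum(axis=0)
    het = np.where(called, d == 1, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = het / np.maximum(n_called, 1)
    he = 2 * p * (1 - p)
    ok = (copies > 0) & (he > 0)
    return float(1.0 - ho[ok].sum() / he[ok].sum())


def diversity_report(G: GenotypeMatrix, groups: Mapping[str, Sequence[str]],
                     n_boot: int = 999, seed: int = 0):
    """Per-group diversity table (one :class:`DiversityReport` per group)."""
    priv = private_alleles(G, groups)
    out = []
    for k, (label, members) in enumerate(groups.items()):
        members = list(members)
        pi, se = nucleotide_diversity(G, members)
        he, ho = heterozygosity(G, members)
        f, ci = fis(G, members, n_boot=n_boot, seed=seed + k)
        out.append(DiversityReport(label, len(members), priv[label],
                                   pct_polymorphic(G, members), pi, se, he, ho,
                                   f, ci))
    return out


# ---------------------------------------------------------------------------
# Individual-pair F_ST

def pairwise_individual_fst(G: GenotypeMatrix) -> np.ndarray:
    """Symmetric matrix of Weir-Cockerham theta treating each individual as a
    population of one diploid.

    With n=1 diploid per population the among-individuals component is
    undefined, so the two-level (haplotype-frequency) W&C reduction is used
    on the two allele copies of each individual: per locus
    MSP = (p_i - p_j)^2 * ... reduces to delta^2 with delta=(d_i-d_j)/2, and
    MSG = p_i q_i + p_j q_j; theta = sum(MSP - MSG)/sum(MSP + MSG) over the
    loci called in both individuals. Negative estimates are retained.
    """
    n, L = G.n_samples, G.n_loci
    d = G.dosages.astype(float)
    called = ~G.missing
    g = d * (2.0 - d) / 4.0  # p*q per individual: 0 for hom, 0.25 for het
    out = np.zeros((n, n))
    for i in range(n):
        share = called[i] & called[i + 1:]
        delta2 = ((d[i] - d[i + 1:]) / 2.0) ** 2
        msg = g[i] + g[i + 1:]
        num = np.where(share, delta2 - msg, 0.0).sum(axis=1)
        den = np.where(share, delta2 + msg, 0.0).sum(axis=1)
        n_sh = share.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where((n_sh > 0) & (den != 0), num / np.where(den == 0, 1, den),
                             np.nan)
        out[i, i + 1:] = theta
        out[i + 1:, i] = theta
    if np.isnan(out[~np.eye(n, dtype=bool)]).any():
        import warnings
        warnings.warn("some pairs share no usable loci; NaN entries present")
    return out


# ---------------------------------------------------------------------------
# P-distance

def p_distance_matrix(G: GenotypeMatrix, ambiguous_mode: str = "ignore") -> np.ndarray:
    """Pairwise P-distance on the SNP pseudo-sequences.

    ``ignore``: sites where either call is heterozygous (IUPAC-ambiguous) or
    missing are excluded; the distance is the fraction of remaining sites
    with different homozygous states. ``average``: an ambiguity contributes
    the expected mismatch over its constituent states (het vs hom = 0.5,
    het vs het = 0.5); missing sites are still excluded.
    """
    if ambiguous_mode not in ("ignore", "average"):
        raise ValueError("ambiguous_mode must be 'ignore' or 'average'")
    n = G.n_samples
    d = G.dosages.astype(float)
    called = ~G.missing
    het = d == 1
    out = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1:]
        if ambiguous_mode == "ignore":
            usable = both & ~het[i] & ~het[i + 1:]
            mism = usable & (d[i] != d[i + 1:])
            denom = usable.sum(axis=1)
            num = mism.sum(axis=1).astype(float)
        else:
            usable = both
            any_het = het[i] | het[i + 1:]
            contrib = np.where(any_het, 0.5, (d[i] != d[i + 1:]).astype(float))
            num = np.where(usable, contrib, 0.0).sum(axis=1)
            denom = usable.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(denom > 0, num / np.maximum(denom, 1), np.nan)
        out[i, i + 1:] = dist
        out[i + 1:, i] = dist
    return out
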