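"""Independent brute-force oracles used by the test suite.

These are deliberately naive transcriptions (explicit loops, no shared code
with the package) of the estimators under test.
"""

from __future__ import annotations

import numpy as np


def wc_theta_oracle(dos, miss, labels):
    """Direct per-locus transcription of the Weir & Cockerham (1984)
    variance components a, b, c, combined ratio-of-sums."""
    dos = np.asarray(dos)
    miss = np.asarray(miss)
    labels = list(labels)
    a_sum = b_sum = c_sum = 0.0
    for l in range(dos.shape[1]):
        ns, ps, hs = [], [], []
        for g in sorted(set(labels)):
            idx = [i for i in range(len(labels))
                   if labels[i] == g and not miss[i, l]]
            if not idx:
                continue
            n_i = len(idx)
            ns.append(n_i)
            ps.append(sum(dos[i, l] for i in idx) / (2.0 * n_i))
            hs.append(sum(1 for i in idx if dos[i, l] == 1) / n_i)
        r = len(ns)
        if r < 2:
            continue
        n_tot = sum(ns)
        nbar = n_tot / r
        if nbar <= 1:
            continue
        nc = (n_tot - sum(x * x for x in ns) / n_tot) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / n_tot
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / n_tot
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        if not np.isfinite(a):
            continue
        a_sum += a
        b_sum += b
        c_sum += c
    den = a_sum + b_sum + c_sum
    return a_sum / den if den != 0 else np.nan


def pair_theta_oracle(d_i, d_j, called_i, called_j):
    """Two-level (haplotype-frequency) W&C theta for two single diploids.

    Each individual is a 'population' of two allele copies: MSP and MSG per
    locus, combined as sum(MSP - MSG)/sum(MSP + MSG) (n_c = 2 so the
    denominator weight on MSG is 1).
    """
    num = den = 0.0
    for l in range(len(d_i)):
        if not (called_i[l] and called_j[l]):
            continue
        p1, p2 = d_i[l] / 2.0, d_j[l] / 2.0
        pbar = (p1 + p2) / 2.0
        msp = 2 * (p1 - pbar) ** 2 + 2 * (p2 - pbar) ** 2
        msg = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
        num += msp - msg
        den += msp + msg
    return num / den if den != 0 else np.nan


def filter_oracle(dos, miss, labels, cfg):
    """Per-locus brute-force application of the Stacks-style filters."""
    dos = np.asarray(dos)
    miss = np.asarray(miss)
    labels = np.asarray(labels)
    keep = []
    for l in range(dos.shape[1]):
        called = ~miss[:, l]
        pops_meeting = 0
        for g in set(labels.tolist()):
            sub = called[labels == g]
            if sub.mean() >= cfg.min_samples_per_pop:
                pops_meeting += 1
        n_called = called.sum()
        if n_called > 0:
            alt = dos[called, l].sum()
            copies = 2 * n_called
            p = alt / copies
            maf = min(p, 1 - p)
            mac = min(alt, copies - alt)
            het = (dos[called, l] == 1).mean()
        else:
            maf, mac, het = np.nan, np.nan, np.nan
        ok = (pops_meeting >= cfg.min_populations
              and n_called / len(labels) >= cfg.min_samples_overall
              and maf >= cfg.min_maf and mac >= cfg.min_mac
              and het <= cfg.max_obs_het)
        keep.append(bool(ok))
    return np.asarray(keep)


def dunn_z_oracle(values, groups, pair):
    """Direct transcription of Dunn's rank-sum Z with tie correction."""
    from scipy.stats import rankdata
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    n = values.size
    ranks = rankdata(values)
    a, b = pair
    ra = ranks[groups == a].mean()
    rb = ranks[groups == b].mean()
    na = (groups == a).sum()
    nb = (groups == b).sum()
    _, counts = np.unique(values, return_counts=True)
    ties = np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
    se = np.sqrt((n * (n + 1) / 12.0 - ties) * (1.0 / na + 1.0 / nb))
    return (ra - rb) / se
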