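"""Diversity, frequency-spectrum, LD and differentiation statistics.

All functions operate on integer-coded allele matrices with one row per
haplotype and one column per (candidate) site; allele codes are
non-negative integers and -1 marks a missing/uncalled allele. The caller
chooses the site set (typically 4-fold degenerate positions) and supplies
the site-count denominator L where a per-site quantity is reported.

Statistics: nucleotide diversity pi (Nei's unbiased per-site
heterozygosity), Tajima's D, Kelly's ZnS (mean pairwise r^2), the
log-distance sequence differentiation statistic Kst* of Hudson, Boos &
Kaplan with an individual-level permutation test, and Hudson's
within/between Fst estimator.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, log

import numpy as np

__all__ = [
    "pi",
    "site_heterozygosity",
    "tajimas_d",
    "kellys_zns",
    "pairwise_differences",
    "kst_star",
    "kst_permutation_p",
    "hudson_fst",
]


def _as_matrix(alleles: np.ndarray) -> np.ndarray:
    A = np.asarray(alleles)
    if A.ndim != 2:
        raise ValueError("allele matrix must be 2-D (haplotypes x sites)")
    return A


def site_heterozygosity(alleles: np.ndarray, min_called: int = 4) -> np.ndarray:
    """Unbiased per-site heterozygosity n/(n-1) * (1 - sum p_a^2).

    Sites with fewer than ``min_called`` called alleles are returned as NaN
    and must be excluded from sums by the caller.
    """
    A = _as_matrix(alleles)
    called = A >= 0
    n_c = called.sum(axis=0).astype(float)
    max_code = int(A.max(initial=0))
    sum_sq = np.zeros(A.shape[1])
    for code in range(max_code + 1):
        sum_sq += (A == code).sum(axis=0).astype(float) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        h = n_c / (n_c - 1.0) * (1.0 - sum_sq / n_c**2)
    h[n_c < max(min_called, 2)] = np.nan
    return h

def pi(alleles: np.ndarray, L: int, min_called: int = 4) -> float | None:
    """Nucleotide diversity per site over an L-site region.

    Computed from allele frequencies (phase-free); identical to the mean
    pairwise difference per site on fully called data. ``alleles`` holds
    the variable columns of the region; monomorphic columns contribute 0
    and are accounted for through L. Returns None when L == 0.
    """
    if L == 0:
        return None
    h = site_heterozygosity(alleles, min_called=min_called)
    return float(np.nansum(h) / L)


def segregating_sites(alleles: np.ndarray, min_called: int = 4) -> int:
    A = _as_matrix(alleles)
    count = 0
    for j in range(A.shape[1]):
        col = A[:, j]
        col = col[col >= 0]
        if len(col) >= max(min_called, 2) and len(np.unique(col)) >= 2:
            count += 1
    return count


def tajimas_d(alleles: np.ndarray, min_called: int = 4) -> float | None:
    """Tajima's D from the mean pairwise difference total and S.

    Uses the standard a1, a2, b1, b2, c1, c2, e1, e2 constants for the
    number of haplotype rows. Returns None when no site segregates.
    """
    A = _as_matrix(alleles)
    n = A.shape[0]
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 haplotypes")
    h = site_heterozygosity(A, min_called=min_called)
    S = segregating_sites(A, min_called=min_called)
    if S == 0:
        return None
    total_pi = float(np.nansum(h))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (total_pi - S / a1) / np.sqrt(var)


def kellys_zns(alleles: np.ndarray, min_called: int = 4) -> float | None:
    """Kelly's ZnS: mean r^2 over all unordered pairs of segregating sites.

    r^2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B)), computed on
    haplotypes called at both sites of a pair. Requires phased input and at
    least two segregating biallelic sites; otherwise returns None.
    """
    A = _as_matrix(alleles)
    seg_cols = []
    for j in range(A.shape[1]):
        col = A[:, j]
        vals = np.unique(col[col >= 0])
        if len(vals) == 2 and (col >= 0).sum() >= max(min_called, 2):
            seg_cols.append((j, vals))
    if len(seg_cols) < 2:
        return None
    # binary indicator per segregating site; NaN where uncalled
    B = np.full((A.shape[0], len(seg_cols)), np.nan)
    for k, (j, vals) in enumerate(seg_cols):
        col = A[:, j]
        B[col == vals[1], k] = 1.0
        B[col == vals[0], k] = 0.0
    r2_values = []
    for a, b in combinations(range(B.shape[1]), 2):
        both = ~np.isnan(B[:, a]) & ~np.isnan(B[:, b])
        x, y = B[both, a], B[both, b]
        pa, pb = x.mean(), y.mean()
        denom = pa * (1 - pa) * pb * (1 - pb)
        if denom == 0:
            continue  # pair monomorphic within the jointly called subset
        pab = (x * y).mean()
        r2_values.append((pab - pa * pb) ** 2 / denom)
    if not r2_values:
        return None
    return float(np.mean(r2_values))


def pairwise_differences(alleles: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise difference counts over jointly called sites."""
    A = _as_matrix(alleles)
    n = A.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        ai = A[i]
        diff = (A[i + 1 :] != ai) & (A[i + 1 :] >= 0) & (ai >= 0)
        D[i, i + 1 :] = diff.sum(axis=1)
    return D + D.T


def _kst_from_distances(D: np.ndarray, labels: np.ndarray) -> float | None:
    logd = np.log1p(D)
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    total_pairs = n * (n - 1) // 2
    k_total = logd[iu].sum() / total_pairs
    if k_total == 0:
        return None
    within_sum = 0.0
    within_pairs = 0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = logd[np.ix_(idx, idx)]
        within_sum += sub[np.triu_indices(len(idx), 1)].sum()
        within_pairs += len(idx) * (len(idx) - 1) // 2
    if within_pairs == 0:
        return None
    # pair-count weights make K*_S the pooled within-group mean
    k_s = within_sum / within_pairs
    return 1.0 - k_s / k_total


def kst_star(alleles: np.ndarray, labels) -> float | None:
    """Sequence differentiation Kst* = 1 - K*_S / K*_T.

    Pairwise distances are d_ij = number of differences; each group
    contributes its mean ln(1 + d_ij) over within-group pairs, weighted by
    its pair count; K*_T is the mean over all pairs pooled. Returns None if
    all sequences are identical.
    """
    labels = np.asarray(labels)
    D = pairwise_differences(alleles)
    if len(labels) != D.shape[0]:
        raise ValueError("one label per haplotype required")
    if len(np.unique(labels)) < 2:
        raise ValueError("Kst* requires at least two groups")
    return _kst_from_distances(D, labels)


def kst_permutation_p(
    alleles: np.ndarray,
    hap_individuals,
    individual_labels: dict,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float | None, float | None]:
    """Permutation p-value for Kst* with individuals permuted as units.

    ``hap_individuals`` names the individual of each haplotype row (a
    diploid's two haplotypes stay together) and ``individual_labels`` maps
    individual -> group label (e.g. sex). When the number of distinct label
    arrangements is small (<= n_perm), the full enumeration is used and the
    p-value is exact; otherwise p = (1 + #{K*perm >= K*obs}) / (1 + n_perm).

    Returns (kst_observed, p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    hap_individuals = list(hap_individuals)
    individuals = sorted(set(hap_individuals), key=str)
    base_labels = [individual_labels[ind] for ind in individuals]
    D = pairwise_differences(alleles)

    def hap_labels(ind_labels: dict) -> np.ndarray:
        return np.array([ind_labels[ind] for ind in hap_individuals])

    obs = _kst_from_distances(D, hap_labels(individual_labels))
    if obs is None:
        return None, None

    uniq = sorted(set(base_labels), key=str)
    if len(uniq) == 2:
        n_a = base_labels.count(uniq[0])
        n_arrangements = comb(len(individuals), n_a)
    else:
        n_arrangements = None

    if n_arrangements is not None and n_arrangements <= n_perm:
        hits = 0
        for subset in combinations(range(len(individuals)), base_labels.count(uniq[0])):
            ind_labels = {ind: uniq[1] for ind in individuals}
            for i in subset:
                ind_labels[individuals[i]] = uniq[0]
            k = _kst_from_distances(D, hap_labels(ind_labels))
            if k is not None and k >= obs - 1e-12:
                hits += 1
        return obs, hits / n_arrangements

    rng = np.random.default_rng(seed)
    hits = 0
    perm_labels = list(base_labels)
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        ind_labels = dict(zip(individuals, perm_labels))
        k = _kst_from_distances(D, hap_labels(ind_labels))
        if k is not None and k >= obs - 1e-12:
            hits += 1
    return obs, (1 + hits) / (1 + n_perm)


def hudson_fst(alleles: np.ndarray, labels) -> float | None:
    """Hudson's Fst: 1 - mean(pi_within) / pi_between for two groups.

    pi terms are mean pairwise difference counts (the shared site
    denominator cancels). Returns None when there is no between-group
    divergence.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("hudson_fst requires exactly two groups")
    D = pairwise_differences(alleles)
    idx_a = np.flatnonzero(labels == groups[0])
    idx_b = np.flatnonzero(labels == groups[1])
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least two haplotypes")
    sub_a = D[np.ix_(idx_a, idx_a)]
    sub_b = D[np.ix_(idx_b, idx_b)]
    pw_a = sub_a[np.triu_indices(len(idx_a), 1)].mean()
    pw_b = sub_b[np.triu_indices(len(idx_b), 1)].mean()
    pw_between = D[np.ix_(idx_a, idx_b)].mean()
    if pw_between == 0:
        return None
    return 1.0 - 0.5 * (pw_a + pw_b) / pw_between
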