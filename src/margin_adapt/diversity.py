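"""Per-sample microsatellite diversity statistics and permutation test batteries.

Implements the descriptive genetics of a standard microsatellite survey table:
observed heterozygosity (Ho), Nei's unbiased gene diversity (He), the
Weir–Cockerham within-sample inbreeding estimator f with a permutation test of
panmixia, allelic richness rarefied to a fixed number of gene copies, pairwise
linkage-disequilibrium permutation tests, and Benjamini–Hochberg FDR control
for the resulting test batteries.

Exact Markov-chain tests (as in the GENEPOP program) are deliberately replaced
by seed-reproducible Monte-Carlo permutation tests of the same null, with the
add-one p-value rule p = (1 + #{T_perm >= T_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotype_io import GenotypeMatrix

__all__ = [
    "observed_expected_heterozygosity",
    "fis_with_permutation",
    "allelic_richness",
    "pairwise_ld_test",
    "ld_test_battery",
    "fdr_adjust",
    "diversity_summary",
    "DiversitySummary",
]


class MonomorphicError(ValueError):
    """All loci monomorphic: the requested statistic is undefined."""


def _sample_calls(geno: GenotypeMatrix, sample: str, locus: int) -> np.ndarray:
    """Non-missing diploid calls (k, 2) of one sample at one locus."""
    calls = geno.calls[geno.sample_index(sample), locus, :]
    return calls[(calls != 0).all(axis=1)]


def observed_expected_heterozygosity(
    geno: GenotypeMatrix, sample: str
) -> tuple[dict[str, float], dict[str, float]]:
    """Ho and unbiased He per locus for one sample.

    Ho is the fraction of heterozygous individuals among non-missing calls.
    He is Nei's unbiased gene diversity (2n/(2n-1)) (1 - sum p_u^2) with n the
    number of non-missing diploids.  Loci with fewer than 2 non-missing calls
    are omitted.
    """
    ho: dict[str, float] = {}
    he: dict[str, float] = {}
    for j, locus in enumerate(geno.loci):
        calls = _sample_calls(geno, sample, j)
        n = len(calls)
        if n < 2:
            continue
        ho[locus] = float(np.mean(calls[:, 0] != calls[:, 1]))
        _, counts = np.unique(calls.ravel(), return_counts=True)
        p = counts / (2 * n)
        he[locus] = float((2 * n / (2 * n - 1)) * (1.0 - np.sum(p**2)))
    return ho, he


def _fis_components(calls_by_locus: list[np.ndarray]) -> tuple[float, float]:
    """Summed (b, c) Weir–Cockerham within-sample components over loci/alleles."""
    sum_b = 0.0
    sum_c = 0.0
    for calls in calls_by_locus:
        n = len(calls)
        if n < 2:
            continue
        alleles, counts = np.unique(calls.ravel(), return_counts=True)
        if len(alleles) < 2:
            continue
        p = counts / (2 * n)
        # heterozygote frequency involving each allele
        het = calls[:, 0] != calls[:, 1]
        for u, pu in zip(alleles, p):
            hu = float(np.mean(het & ((calls[:, 0] == u) | (calls[:, 1] == u))))
            b = (n / (n - 1)) * (pu * (1 - pu) - (2 * n - 1) / (4 * n) * hu)
            c = hu / 2.0
            sum_b += b
            sum_c += c
    return sum_b, sum_c


def fis_with_permutation(
    geno: GenotypeMatrix, sample: str, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Weir–Cockerham f (F_IS) for one sample and a permutation p-value.

    f is the multi-locus ratio-of-sums 1 - sum(c)/sum(b+c) over loci and
    alleles.  The null distribution is generated by shuffling the 2n allele
    copies among individuals independently at each locus (i.e. random union of
    gametes within the sample); the two-sided p-value uses |f|.
    """
    calls_by_locus = [_sample_calls(geno, sample, j) for j in range(geno.n_loci)]
    poly = [c for c in calls_by_locus if len(c) >= 2 and len(np.unique(c)) > 1]
    if not poly:
        raise MonomorphicError(f"f undefined: no polymorphic locus in sample {sample!r}")
    sum_b, sum_c = _fis_components(calls_by_locus)
    denom = sum_b + sum_c
    f_obs = 1.0 - sum_c / denom if denom > 0 else 0.0

    if n_perm == 0:
        return float(f_obs), 1.0
    rng = np.random.default_rng(seed)
    sum_b_p = np.zeros(n_perm)
    sum_c_p = np.zeros(n_perm)
    for calls in calls_by_locus:
        n = len(calls)
        if n < 2:
            continue
        alleles, counts = np.unique(calls.ravel(), return_counts=True)
        if len(alleles) < 2:
            continue
        p_u = counts / (2 * n)
        pool = calls.ravel()
        # all permutations at once: random keys -> shuffled allele pools
        order = np.argsort(rng.random((n_perm, 2 * n)), axis=1)
        shuffled = pool[order]
        left, right = shuffled[:, ::2], shuffled[:, 1::2]
        het = left != right
        for u, pu in zip(alleles, p_u):
            hu = np.mean(het & ((left == u) | (right == u)), axis=1)
            sum_b_p += (n / (n - 1)) * (pu * (1 - pu)
                                        - (2 * n - 1) / (4 * n) * hu)
            sum_c_p += hu / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = np.where(sum_b_p + sum_c_p > 0,
                          1.0 - sum_c_p / (sum_b_p + sum_c_p), 0.0)
    hits = int(np.sum(np.abs(f_perm) >= abs(f_obs) - 1e-12))
    p = (1 + hits) / (1 + n_perm)
    return float(f_obs), float(p)


def allelic_richness(geno: GenotypeMatrix, sample: str, g: int) -> dict[str, float]:
    """Allelic richness rarefied to ``g`` gene copies, per locus.

    Hypergeometric rarefaction: Ar(g) = sum_u [1 - C(N-N_u, g)/C(N, g)] with N
    the typed gene copies at the locus and N_u copies of allele u.  Loci with
    N < g are excluded (reported as NaN is avoided; they are simply absent).
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    out: dict[str, float] = {}
    for j, locus in enumerate(geno.loci):
        calls = _sample_calls(geno, sample, j)
        N = 2 * len(calls)
        if N < g or N == 0:
            continue
        _, counts = np.unique(calls.ravel(), return_counts=True)
        denom = math.comb(N, g)
        ar = sum(1.0 - math.comb(N - int(nu), g) / denom for nu in counts)
        out[locus] = float(ar)
    return out


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G for a contingency table (zero cells skipped)."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def _genotype_codes(calls: np.ndarray) -> np.ndarray:
    """Map diploid calls to integer genotype codes (unordered pairs)."""
    lo = np.minimum(calls[:, 0], calls[:, 1]).astype(np.int64)
    hi = np.maximum(calls[:, 0], calls[:, 1]).astype(np.int64)
    combo = lo * 100000 + hi
    _, codes = np.unique(combo, return_inverse=True)
    return codes


def pairwise_ld_test(
    geno: GenotypeMatrix,
    sample: str,
    locus_pair: tuple[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> float | None:
    """Permutation test of genotypic linkage disequilibrium between two loci.

    Builds the two-locus genotype contingency table within the sample and
    computes a G statistic; the null is generated by shuffling one locus's
    genotypes among individuals.  Returns ``None`` (not testable) when fewer
    than 5 individuals carry non-missing calls at both loci or either locus is
    monomorphic among them.
    """
    ja = geno.locus_index(locus_pair[0])
    jb = geno.locus_index(locus_pair[1])
    idx = geno.sample_index(sample)
    a = geno.calls[idx, ja, :]
    b = geno.calls[idx, jb, :]
    keep = (a != 0).all(axis=1) & (b != 0).all(axis=1)
    a, b = a[keep], b[keep]
    if len(a) < 5:
        return None
    ca, cb = _genotype_codes(a), _genotype_codes(b)
    if ca.max() == 0 or cb.max() == 0:
        return None
    na, nb = ca.max() + 1, cb.max() + 1

    def table(x, y):
        t = np.zeros((na, nb))
        np.add.at(t, (x, y), 1)
        return t

    g_obs = _g_statistic(table(ca, cb))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        g = _g_statistic(table(ca, rng.permutation(cb)))
        if g >= g_obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def ld_test_battery(
    geno: GenotypeMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All within-sample locus-pair LD tests with BH-FDR adjusted p-values.

    Returns one row per (sample, locus pair) with columns ``test``, ``p_raw``,
    ``p_fdr`` and ``significant``; non-testable pairs are listed with NaN
    p-values and excluded from the adjustment.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample in geno.sample_names:
        for i in range(geno.n_loci):
            for j in range(i + 1, geno.n_loci):
                pair = (geno.loci[i], geno.loci[j])
                p = pairwise_ld_test(
                    geno, sample, pair, n_perm=n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                )
                rows.append({"test": f"{sample}:{pair[0]}-{pair[1]}", "p_raw": p})
    df = pd.DataFrame(rows)
    testable = df["p_raw"].notna()
    df["p_fdr"] = np.nan
    if testable.any():
        df.loc[testable, "p_fdr"] = fdr_adjust(df.loc[testable, "p_raw"].to_numpy())
    df["significant"] = df["p_fdr"] < alpha
    return df


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


@dataclass
class DiversitySummary:
    """Mean/SD-over-loci diversity table (one row per sample)."""

    table: pd.DataFrame
    g: int
    n_perm: int
    seed: int | None


def diversity_summary(
    geno: GenotypeMatrix,
    g: int | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> DiversitySummary:
    """Per-sample Ho, He, f (with permutation p) and Ar(g), mean and SD over loci.

    ``g`` defaults to twice the smallest per-locus count of typed diploids
    across samples (the largest rarefaction depth every locus supports).
    """
    if g is None:
        mins = []
        for sample in geno.sample_names:
            for j in range(geno.n_loci):
                mins.append(len(_sample_calls(geno, sample, j)))
        g = 2 * min(mins)
    rng = np.random.default_rng(seed)
    rows = []
    for sample in geno.sample_names:
        ho, he = observed_expected_heterozygosity(geno, sample)
        ar = allelic_richness(geno, sample, g)
        f, p = fis_with_permutation(
            geno, sample, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        n_typed = len(geno.sample_index(sample))
        rows.append({
            "sample": sample,
            "n": n_typed,
            "Ho_mean": np.mean(list(ho.values())),
            "Ho_sd": np.std(list(ho.values()), ddof=1),
            "He_mean": np.mean(list(he.values())),
            "He_sd": np.std(list(he.values()), ddof=1),
            "f": f,
            "f_pvalue": p,
            f"Ar{g}_mean": np.mean(list(ar.values())) if ar else np.nan,
            f"Ar{g}_sd": np.std(list(ar.values()), ddof=1) if len(ar) > 1 else np.nan,
        })
    return DiversitySummary(pd.DataFrame(rows), g=g, n_perm=n_perm, seed=seed)
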