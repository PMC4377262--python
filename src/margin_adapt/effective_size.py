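"""Contemporary effective population size from multilocus linkage disequilibrium.

Implements the LD method of Hill (1981) with Waples' (2006) bias correction as
popularised by the LDNe program, under the random-mating model:

1. For every pair of loci and every pair of retained alleles (sample frequency
   >= the screening cutoff, 0.02 by default), the composite Burrows
   disequilibrium Delta is estimated from unphased diploid genotype dosages,
   with Weir's n/(n-1) small-sample factor, and squared into
   r^2 = Delta^2 / (p(1-p) q(1-q)).
2. r^2 values are averaged with weights proportional to each locus pair's
   number of independent allele comparisons, (K_A - 1)(K_B - 1).
3. The pure-sampling expectation of r^2 (for harmonic mean sample size S:
   1/S + 3.19/S^2 when S >= 30, else 0.0018 + 0.907/S + 4.44/S^2) is
   subtracted, and Ne is recovered from the drift component by inverting
   Waples' quadratic.  A non-positive drift component yields a negative
   estimate — the "no drift signal" outcome, reported as-is with an infinite
   upper confidence bound.
4. The 95% CI is a delete-one jackknife over locus pairs on the weighted mean
   r^2, pushed through the same bias correction and inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import math

import numpy as np

from .genotype_io import GenotypeMatrix

__all__ = ["NeEstimate", "burrows_r2", "ldne_estimate"]


class TooSmallSampleError(ValueError):
    """Harmonic-mean sample size below the method's floor."""


@dataclass
class NeEstimate:
    sample: str
    S: float
    r2_mean: float
    r2_drift: float
    ne_hat: float
    ci95: tuple[float, float]
    freq_cutoff: float
    n_locus_pairs: int
    weighting: str


def _dosages(calls: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """(n_alleles, n_ind) matrix of per-individual allele dosages (0/1/2)."""
    return (calls[:, 0][None, :] == alleles[:, None]).astype(float) + \
           (calls[:, 1][None, :] == alleles[:, None]).astype(float)


def burrows_r2(
    geno: GenotypeMatrix,
    sample: str,
    locus_a: str,
    locus_b: str,
    freq_cutoff: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Squared Burrows composite correlations for one locus pair.

    Returns ``(r2_values, weights, n)`` where ``r2_values`` holds one entry per
    retained allele pair (alleles with sample frequency below ``freq_cutoff``
    among the jointly typed individuals are dropped), ``weights`` the per-pair
    aggregation weights (uniform within a locus pair) and ``n`` the number of
    jointly typed individuals.  Empty arrays signal a skipped pair.

    Delta is the covariance of allele dosages / 2 with Weir's n/(n-1) factor;
    r^2 = Delta^2 / (p(1-p) q(1-q)) with unscreened sample frequencies p, q of
    the focal alleles.
    """
    if not (0 <= freq_cutoff < 0.5):
        raise ValueError("freq_cutoff must lie in [0, 0.5)")
    ja, jb = geno.locus_index(locus_a), geno.locus_index(locus_b)
    idx = geno.sample_index(sample)
    a = geno.calls[idx, ja, :]
    b = geno.calls[idx, jb, :]
    keep = (a != 0).all(axis=1) & (b != 0).all(axis=1)
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 10:
        return np.array([]), np.array([]), n

    def retained(calls: np.ndarray) -> np.ndarray:
        al, cnt = np.unique(calls.ravel(), return_counts=True)
        freq = cnt / (2 * n)
        return al[(freq >= freq_cutoff) & (freq <= 1 - freq_cutoff)]

    al_a, al_b = retained(a), retained(b)
    if len(al_a) < 1 or len(al_b) < 1:
        return np.array([]), np.array([]), n

    xa = _dosages(a, al_a)  # (Ka, n)
    xb = _dosages(b, al_b)
    pa = xa.mean(axis=1) / 2.0
    pb = xb.mean(axis=1) / 2.0
    # Delta = cov(x, y)/2 with the n/(n-1) correction
    ca = xa - xa.mean(axis=1, keepdims=True)
    cb = xb - xb.mean(axis=1, keepdims=True)
    delta = (ca @ cb.T) / (2.0 * (n - 1))
    denom = (pa * (1 - pa))[:, None] * (pb * (1 - pb))[None, :]
    r2 = (delta**2 / denom).ravel()
    w = np.full(r2.shape, 1.0 / r2.size)
    return r2, w, n


def _expected_r2(S: float) -> float:
    """Waples' sampling expectation of r^2 under random mating."""
    if S >= 30:
        return 1.0 / S + 3.19 / S**2
    return 0.0018 + 0.907 / S + 4.44 / S**2


def _invert_waples(r2_drift: float, S: float) -> float:
    """Ne from the drift component of r^2 (random-mating model).

    S >= 30:  Ne = (1/3 + sqrt(1/9 - 2.76 r2')) / (2 r2')
    S < 30:   Ne = (0.308 + sqrt(0.308^2 - 2.08 r2')) / (2 r2')
    A negative r2' yields a negative Ne (no drift signal); a discriminant
    below zero (very strong LD) is clamped at zero.
    """
    if r2_drift == 0:
        return math.inf
    if S >= 30:
        disc = max(0.0, 1.0 / 9.0 - 2.76 * r2_drift)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2_drift)
    disc = max(0.0, 0.308**2 - 2.08 * r2_drift)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2_drift)


def ldne_estimate(
    geno: GenotypeMatrix,
    sample: str,
    freq_cutoff: float = 0.02,
    weighted: bool = True,
) -> NeEstimate:
    """LD-based effective population size for one sample.

    ``weighted=True`` (default) weights each locus pair's mean r^2 by its
    number of independent allele comparisons (K_A - 1)(K_B - 1); the harmonic
    mean sample size S uses the same weights.  ``weighted=False`` averages
    locus pairs uniformly (sensitivity check).
    """
    loci = geno.loci
    pair_r2: list[float] = []
    pair_w: list[float] = []
    pair_n: list[int] = []
    for la, lb in combinations(loci, 2):
        r2, _, n = burrows_r2(geno, sample, la, lb, freq_cutoff)
        if r2.size == 0:
            continue
        pair_r2.append(float(r2.mean()))
        pair_n.append(n)
        pair_w.append(float(_independent_comparisons(geno, sample, la, lb, freq_cutoff)))
    if len(pair_r2) < 1:
        raise ValueError("no locus pair survived allele-frequency screening")
    r2_arr = np.array(pair_r2)
    n_arr = np.array(pair_n, dtype=float)
    w = np.array(pair_w) if weighted else np.ones_like(r2_arr)
    w = np.where(w <= 0, 1.0, w)

    S = w.sum() / np.sum(w / n_arr)  # weighted harmonic mean
    if S < 10:
        raise TooSmallSampleError(f"harmonic mean sample size {S:.1f} < 10")
    r2_mean = float(np.sum(w * r2_arr) / w.sum())
    exp_r2 = _expected_r2(S)
    r2_drift = r2_mean - exp_r2
    ne_hat = _invert_waples(r2_drift, S)

    # delete-one jackknife over locus pairs on the weighted mean r^2
    m = len(r2_arr)
    if m >= 2:
        tot_w = w.sum()
        tot_wr = np.sum(w * r2_arr)
        loo = (tot_wr - w * r2_arr) / (tot_w - w)
        jk_mean = loo.mean()
        jk_var = (m - 1) / m * np.sum((loo - jk_mean) ** 2)
        se = math.sqrt(jk_var)
    else:
        se = 0.0
    lo_r2d = r2_mean - 1.96 * se - exp_r2
    hi_r2d = r2_mean + 1.96 * se - exp_r2
    ne_lo = _invert_waples(hi_r2d, S)  # more LD -> smaller Ne
    ne_hi = math.inf if lo_r2d <= 0 else _invert_waples(lo_r2d, S)
    return NeEstimate(
        sample=sample, S=float(S), r2_mean=r2_mean, r2_drift=float(r2_drift),
        ne_hat=float(ne_hat), ci95=(float(ne_lo), ne_hi),
        freq_cutoff=freq_cutoff, n_locus_pairs=m,
        weighting="independent-comparisons" if weighted else "uniform",
    )


def _independent_comparisons(
    geno: GenotypeMatrix, sample: str, locus_a: str, locus_b: str,
    freq_cutoff: float,
) -> int:
    """(K_A - 1)(K_B - 1) over alleles surviving the frequency screen."""
    idx = geno.sample_index(sample)
    ja, jb = geno.locus_index(locus_a), geno.locus_index(locus_b)
    a = geno.calls[idx, ja, :]
    b = geno.calls[idx, jb, :]
    keep = (a != 0).all(axis=1) & (b != 0).all(axis=1)
    a, b = a[keep], b[keep]
    n = len(a)

    def k(calls: np.ndarray) -> int:
        al, cnt = np.unique(calls.ravel(), return_counts=True)
        freq = cnt / (2 * n)
        return int(np.sum((freq >= freq_cutoff) & (freq <= 1 - freq_cutoff)))

    return max(1, (k(a) - 1)) * max(1, (k(b) - 1))
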