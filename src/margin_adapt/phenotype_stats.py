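"""Trait aggregation and permutational ANOVA on Euclidean distances.

For a univariate response the PERMANOVA pseudo-F computed from the Euclidean
distance matrix coincides exactly with the classical ANOVA F on the same
partition of sums of squares; the tests here exploit that identity and work
directly on the response vector, while the null distribution is generated by
permutation (add-one rule), avoiding any normality assumption.

Designs are the study's: a crossed 2x2 fixed-factor design (origin depth x
treatment depth) with interaction for the reciprocal transplants, and a
one-way design (origin depth) for the common garden.  Sums of squares are the
standard balanced-design Type I partition; unbalanced cell counts are refused
rather than silently re-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import PhenotypeTable

__all__ = [
    "PermanovaResult",
    "mean_max_growth",
    "permanova_one_way",
    "permanova_two_way",
    "survival_summary",
]


class UnbalancedDesignError(ValueError):
    """A design cell is empty, too small, or cell sizes are unequal."""


@dataclass
class PermanovaResult:
    """ANOVA-style table: one row per source of variation.

    ``table`` columns: df, SS, MS, pseudo_F, p_perm (NaN where not applicable).
    """

    table: pd.DataFrame
    n_perm: int
    seed: int | None
    degenerate: bool = False


def mean_max_growth(distances, k: int = 10) -> float:
    """Mean of the k greatest calcein-to-periphery distances of a colony.

    With fewer than k measurements the mean is taken over all of them and a
    short-measurement warning is emitted.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("no distances supplied")
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    if d.size < k:
        warnings.warn(
            f"only {d.size} measurements available for k={k}; using all",
            stacklevel=2,
        )
        return float(d.mean())
    return float(np.sort(d)[-k:].mean())


def _extract(pheno: PhenotypeTable | pd.DataFrame, trait: str | None) -> pd.DataFrame:
    df = pheno.df if isinstance(pheno, PhenotypeTable) else pheno
    if trait is not None:
        df = df[df["trait"] == trait]
    if df.empty:
        raise ValueError("no records for the requested trait")
    return df.reset_index(drop=True)


def _perm_pvalue(f_obs: float, f_perm: np.ndarray) -> float:
    return float((1 + np.sum(f_perm >= f_obs - 1e-12)) / (1 + len(f_perm)))


def permanova_one_way(
    pheno: PhenotypeTable | pd.DataFrame,
    factor: str = "origin_depth",
    trait: str | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way univariate PERMANOVA on Euclidean distance.

    Permutes the raw observations among groups; pseudo-F equals the classical
    one-way ANOVA F.  Every factor level must have at least 2 observations.
    """
    df = _extract(pheno, trait)
    y = df["value"].to_numpy(dtype=float)
    groups, gidx = np.unique(df[factor].to_numpy(), return_inverse=True)
    k = len(groups)
    n = len(y)
    if k < 2:
        raise ValueError("factor needs at least 2 levels")
    counts = np.bincount(gidx)
    if (counts < 2).any():
        raise UnbalancedDesignError(
            f"level(s) with fewer than 2 observations: "
            f"{[groups[i] for i in np.flatnonzero(counts < 2)]}"
        )

    def ss_between(Y: np.ndarray) -> np.ndarray:
        # Y: (P, n); group means via indicator multiply
        grand = Y.mean(axis=1, keepdims=True)
        ssb = np.zeros(Y.shape[0])
        for g in range(k):
            mg = Y[:, gidx == g].mean(axis=1, keepdims=True)
            ssb += counts[g] * (mg - grand).ravel() ** 2
        return ssb

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ssb = float(ss_between(y[None, :])[0])
    ssw = ss_tot - ssb
    df_b, df_w = k - 1, n - k
    degenerate = ss_tot == 0 or ssw <= 1e-300
    if ss_tot == 0:
        f_obs, p = 0.0, 1.0
    else:
        msb, msw = ssb / df_b, ssw / df_w
        f_obs = msb / msw if msw > 0 else np.inf
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        Y = y[perms]
        ssb_p = ss_between(Y)
        ssw_p = ss_tot - ssb_p
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ssb_p / df_b) / (ssw_p / df_w)
        f_perm = np.where(np.isfinite(f_perm), f_perm, np.inf)
        p = _perm_pvalue(f_obs, f_perm)
    table = pd.DataFrame(
        {
            "df": [df_b, df_w, n - 1],
            "SS": [ssb, ssw, ss_tot],
            "MS": [ssb / df_b, ssw / df_w if df_w else np.nan, np.nan],
            "pseudo_F": [f_obs, np.nan, np.nan],
            "p_perm": [p, np.nan, np.nan],
        },
        index=[factor, "residual", "total"],
    )
    return PermanovaResult(table, n_perm=n_perm, seed=seed, degenerate=degenerate)


def _two_way_ss(y: np.ndarray, ai: np.ndarray, bi: np.ndarray,
                na: int, nb: int) -> tuple[float, float, float, float, float]:
    """Balanced two-way SS partition (total, A, B, AB, residual)."""
    grand = y.mean()
    ss_tot = float(np.sum((y - grand) ** 2))
    n_a = np.bincount(ai, minlength=na).astype(float)
    n_b = np.bincount(bi, minlength=nb).astype(float)
    mean_a = np.bincount(ai, weights=y, minlength=na) / n_a
    mean_b = np.bincount(bi, weights=y, minlength=nb) / n_b
    ss_a = float(np.sum(n_a * (mean_a - grand) ** 2))
    ss_b = float(np.sum(n_b * (mean_b - grand) ** 2))
    ci = ai * nb + bi
    n_c = np.bincount(ci, minlength=na * nb).astype(float)
    mean_c = np.bincount(ci, weights=y, minlength=na * nb) / n_c
    dev = mean_c - np.repeat(mean_a, nb) - np.tile(mean_b, na) + grand
    ss_ab = float(np.sum(n_c * dev**2))
    ss_res = ss_tot - ss_a - ss_b - ss_ab
    return ss_tot, ss_a, ss_b, ss_ab, ss_res


def permanova_two_way(
    pheno: PhenotypeTable | pd.DataFrame,
    factors: tuple[str, str] = ("origin_depth", "treatment_depth"),
    trait: str | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """Two-factorial univariate PERMANOVA with interaction, Euclidean distance.

    Main-effect p-values permute the raw observations; the interaction
    p-value permutes the residuals of the additive (reduced) model and
    re-fits the full partition on each permutation.  Pseudo-F per term equals
    the classical two-way ANOVA F on a balanced design.
    """
    df = _extract(pheno, trait)
    y = df["value"].to_numpy(dtype=float)
    fa, fb = factors
    la, ai = np.unique(df[fa].to_numpy(), return_inverse=True)
    lb, bi = np.unique(df[fb].to_numpy(), return_inverse=True)
    na, nb = len(la), len(lb)
    if na < 2 or nb < 2:
        raise ValueError("both factors need at least 2 levels")
    cell_counts = np.zeros((na, nb), dtype=int)
    np.add.at(cell_counts, (ai, bi), 1)
    if (cell_counts == 0).any():
        i, j = np.argwhere(cell_counts == 0)[0]
        raise UnbalancedDesignError(f"empty design cell ({la[i]}, {lb[j]})")
    if (cell_counts < 2).any():
        i, j = np.argwhere(cell_counts < 2)[0]
        raise UnbalancedDesignError(
            f"design cell ({la[i]}, {lb[j]}) has fewer than 2 replicates"
        )
    if len(np.unique(cell_counts)) != 1:
        raise UnbalancedDesignError(
            f"unbalanced cell counts {cell_counts.tolist()}; "
            "this analysis requires a balanced design"
        )

    n = len(y)
    ss_tot, ss_a, ss_b, ss_ab, ss_res = _two_way_ss(y, ai, bi, na, nb)
    df_a, df_b_, df_ab = na - 1, nb - 1, (na - 1) * (nb - 1)
    df_res = n - na * nb
    degenerate = ss_tot == 0 or ss_res <= 1e-300

    if ss_tot == 0:
        f = {"a": 0.0, "b": 0.0, "ab": 0.0}
        p = {"a": 1.0, "b": 1.0, "ab": 1.0}
    else:
        ms_res = ss_res / df_res
        with np.errstate(divide="ignore"):
            f = {
                "a": (ss_a / df_a) / ms_res if ms_res > 0 else np.inf,
                "b": (ss_b / df_b_) / ms_res if ms_res > 0 else np.inf,
                "ab": (ss_ab / df_ab) / ms_res if ms_res > 0 else np.inf,
            }
        rng = np.random.default_rng(seed)

        def f_on(yp: np.ndarray) -> tuple[float, float, float]:
            _, sa, sb, sab, sr = _two_way_ss(yp, ai, bi, na, nb)
            mr = sr / df_res
            if mr <= 0:
                return np.inf, np.inf, np.inf
            return (sa / df_a) / mr, (sb / df_b_) / mr, (sab / df_ab) / mr

        fa_p = np.empty(n_perm)
        fb_p = np.empty(n_perm)
        for t in range(n_perm):
            yp = y[rng.permutation(n)]
            fa_p[t], fb_p[t], _ = f_on(yp)
        # interaction: permute residuals of the additive reduced model
        grand = y.mean()
        fitted_red = (np.array([y[ai == i].mean() for i in range(na)])[ai]
                      + np.array([y[bi == j].mean() for j in range(nb)])[bi]
                      - grand)
        resid = y - fitted_red
        fab_p = np.empty(n_perm)
        for t in range(n_perm):
            rp = resid[rng.permutation(n)]
            _, _, fab_p[t] = f_on(fitted_red + rp)
        p = {
            "a": _perm_pvalue(f["a"], fa_p),
            "b": _perm_pvalue(f["b"], fb_p),
            "ab": _perm_pvalue(f["ab"], fab_p),
        }

    table = pd.DataFrame(
        {
            "df": [df_a, df_b_, df_ab, df_res, n - 1],
            "SS": [ss_a, ss_b, ss_ab, ss_res, ss_tot],
            "MS": [ss_a / df_a, ss_b / df_b_, ss_ab / df_ab,
                   ss_res / df_res if df_res else np.nan, np.nan],
            "pseudo_F": [f["a"], f["b"], f["ab"], np.nan, np.nan],
            "p_perm": [p["a"], p["b"], p["ab"], np.nan, np.nan],
        },
        index=[fa, fb, f"{fa} x {fb}", "residual", "total"],
    )
    return PermanovaResult(table, n_perm=n_perm, seed=seed, degenerate=degenerate)


def survival_summary(pheno: PhenotypeTable) -> pd.DataFrame:
    """Per-sample survival and never-necrosed percentages from necrosis series.

    A colony survives when its final necrosis record is below 100%; it counts
    as never-necrosed when every one of its records is 0.  Colonies with no
    records are excluded with a warning.
    """
    df = pheno.df[pheno.df["trait"] == "necrosis_pct"]
    if df.empty:
        raise ValueError("no necrosis records")
    rows = []
    for sample, sub in df.groupby("sample"):
        per_colony = sub.groupby("individual")["value"]
        final = sub.loc[sub.groupby("individual")["time"].idxmax()]
        n = len(final)
        if n == 0:
            warnings.warn(f"sample {sample} has no colonies with records")
            continue
        survived = (final["value"] < 100).sum()
        never = (per_colony.max() == 0).sum()
        rows.append({
            "sample": sample,
            "n_colonies": n,
            "survival_pct": 100.0 * survived / n,
            "never_necrosed_pct": 100.0 * never / n,
        })
    return pd.DataFrame(rows)
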