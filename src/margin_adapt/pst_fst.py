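"""P_ST estimation and comparison with neutral F_ST references.

P_ST is the phenotypic analogue of Q_ST used when breeding designs are
impossible: with sigma2_B and sigma2_W the among- and within-sample variance
components of a trait and r = c/h^2 the assumed ratio between the
across-population additive proportion (c) and the within-population
narrow-sense heritability (h^2),

    P_ST(r) = r * sigma2_B / (r * sigma2_B + 2 * sigma2_W).

The null assumption is r = 1 (equal genetic architecture across populations);
robustness is probed over the conservative range 0 < r <= 1.  A comparison
against a neutral reference F (the upper 95% bound of theta, or an external
allozyme F_ST) is "significant" when the lower 95% percentile-bootstrap bound
of P_ST exceeds F, and (c/h^2)_crit is the smallest r at which that happens;
values of (c/h^2)_crit below 0.2 are flagged as robust inferences.

Bootstrap CIs resample individuals with replacement within each sample
(sample sizes preserved) and recompute the whole P_ST(r) curve per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PstResult",
    "PstFstComparison",
    "variance_components",
    "pst_curve",
    "pst_bootstrap",
    "compare_and_crit",
    "default_r_grid",
]


def default_r_grid(n: int = 200, lo: float = 1e-3) -> np.ndarray:
    """Log-spaced c/h^2 grid on (lo, 1], ending exactly at 1."""
    return np.geomspace(lo, 1.0, n)


@dataclass
class PstResult:
    sigma2_B: float
    sigma2_W: float
    r_grid: np.ndarray
    pst: np.ndarray
    boot_draws: np.ndarray | None  # (n_boot, len(r_grid))
    ci95: np.ndarray | None  # (2, len(r_grid)): lower, upper
    n_boot: int
    seed: int | None
    n_degenerate: int = 0

    def at(self, r: float) -> tuple[float, float, float]:
        """(point, lower, upper) of P_ST at grid value r (must be on grid)."""
        i = int(np.argmin(np.abs(self.r_grid - r)))
        if not np.isclose(self.r_grid[i], r):
            raise ValueError(f"r={r} is not on the grid")
        lo = self.ci95[0, i] if self.ci95 is not None else np.nan
        hi = self.ci95[1, i] if self.ci95 is not None else np.nan
        return float(self.pst[i]), float(lo), float(hi)


@dataclass
class PstFstComparison:
    fst_refs: list[tuple[str, float]]
    significant_at_null: dict[str, bool]
    crit_r: dict[str, float | None]  # None means "none <= 1"
    robust: dict[str, bool] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for label, value in self.fst_refs:
            rows.append({
                "reference": label,
                "fst": value,
                "significant_at_null": self.significant_at_null[label],
                "crit_r": np.nan if self.crit_r[label] is None
                          else self.crit_r[label],
                "robust_below_0.2": self.robust.get(label, False),
            })
        return pd.DataFrame(rows)


def _groups(values, labels) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    return [values[labels == g] for g in pd.unique(labels)]


def variance_components(values, labels) -> tuple[float, float]:
    """Method-of-moments one-way random-effects variance components.

    sigma2_W = MS_within; sigma2_B = max(0, (MS_between - MS_within) / n0)
    with n0 = (N - sum n_i^2 / N) / (k - 1), the standard coefficient for
    (possibly) unbalanced designs.  Requires >= 2 samples with >= 2
    observations each.
    """
    groups = _groups(values, labels)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 samples")
    n_i = np.array([len(g) for g in groups], dtype=float)
    if (n_i < 2).any():
        raise ValueError("every sample needs at least 2 observations")
    N = n_i.sum()
    grand = np.concatenate(groups).mean()
    ss_b = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(n_i, groups)))
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    if ss_b + ss_w == 0:
        return 0.0, 0.0
    ms_b = ss_b / (k - 1)
    ms_w = ss_w / (N - k)
    n0 = (N - np.sum(n_i**2) / N) / (k - 1)
    sigma2_b = max(0.0, (ms_b - ms_w) / n0)
    return float(sigma2_b), float(ms_w)


def pst_curve(sigma2_b: float, sigma2_w: float, r_grid) -> np.ndarray:
    """P_ST(r) = r sigma2_B / (r sigma2_B + 2 sigma2_W) on a grid of r values."""
    r = np.asarray(r_grid, dtype=float)
    if sigma2_b < 0 or sigma2_w < 0:
        raise ValueError("variance components must be nonnegative")
    if sigma2_b == 0 and sigma2_w == 0:
        raise ValueError("P_ST undefined: both variance components are zero")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("c/h^2 values must lie in (0, 1]")
    num = r * sigma2_b
    return num / (num + 2.0 * sigma2_w)


def pst_bootstrap(
    values,
    labels,
    r_grid=None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PstResult:
    """P_ST(r) point curve with 95% percentile bootstrap bands.

    Each replicate resamples individuals with replacement within each sample
    (stratified; sample sizes preserved), recomputes the variance components
    and the full curve.  Replicates in which every sample has zero within
    variance are degenerate (P_ST = 1 at every r); they are counted and a
    warning is emitted when they exceed 1% of replicates.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentile bounds")
    r_grid = default_r_grid() if r_grid is None else np.asarray(r_grid, float)
    groups = _groups(values, labels)
    s2b, s2w = variance_components(values, labels)
    point = pst_curve(s2b, s2w, r_grid) if (s2b + s2w) > 0 else np.zeros_like(r_grid)

    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(r_grid)))
    n_degenerate = 0
    lab = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    for t in range(n_boot):
        res = [g[rng.integers(0, len(g), size=len(g))] for g in groups]
        vals = np.concatenate(res)
        s2b_t, s2w_t = variance_components(vals, lab)
        if s2w_t == 0 and s2b_t == 0:
            draws[t] = 0.0
            n_degenerate += 1
        elif s2w_t == 0:
            draws[t] = 1.0
            n_degenerate += 1
        else:
            draws[t] = pst_curve(s2b_t, s2w_t, r_grid)
    if n_degenerate > 0.01 * n_boot:
        warnings.warn(
            f"{n_degenerate}/{n_boot} bootstrap replicates were degenerate "
            "(zero within-sample variance)", stacklevel=2,
        )
    ci = np.percentile(draws, [2.5, 97.5], axis=0)
    return PstResult(
        sigma2_B=s2b, sigma2_W=s2w, r_grid=r_grid, pst=point,
        boot_draws=draws, ci95=ci, n_boot=n_boot, seed=seed,
        n_degenerate=n_degenerate,
    )


def compare_and_crit(
    pst: PstResult, fst_refs: list[tuple[str, float]],
    robust_threshold: float = 0.2,
) -> PstFstComparison:
    """Significance at the null assumption (r = 1) and (c/h^2)_crit per reference.

    (c/h^2)_crit is the smallest r at which the lower 95% bound of P_ST(r)
    exceeds the reference, linearly interpolated between the bracketing grid
    points; ``None`` means no r <= 1 achieves it.
    """
    if not fst_refs:
        raise ValueError("at least one F_ST reference is required")
    if pst.ci95 is None:
        raise ValueError("PstResult has no bootstrap CI")
    r = pst.r_grid
    if not np.isclose(r[-1], 1.0):
        raise ValueError("r grid must contain r = 1")
    lower = pst.ci95[0]
    sig: dict[str, bool] = {}
    crit: dict[str, float | None] = {}
    robust: dict[str, bool] = {}
    for label, ref in fst_refs:
        sig[label] = bool(lower[-1] > ref)
        above = lower > ref
        if not above.any():
            crit[label] = None
            robust[label] = False
            continue
        i = int(np.argmax(above))  # first grid index exceeding the reference
        if i == 0:
            crit_val = float(r[0])
        else:
            # linear interpolation of the crossing between grid points
            x0, x1 = r[i - 1], r[i]
            y0, y1 = lower[i - 1], lower[i]
            frac = (ref - y0) / (y1 - y0) if y1 != y0 else 1.0
            crit_val = float(x0 + frac * (x1 - x0))
        crit[label] = crit_val
        robust[label] = crit_val < robust_threshold
    return PstFstComparison(
        fst_refs=list(fst_refs), significant_at_null=sig, crit_r=crit,
        robust=robust,
    )
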