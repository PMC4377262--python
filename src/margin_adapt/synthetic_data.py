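"""Synthetic genotype and phenotype generators emulating the study design.

The generators reproduce the statistical structure the analysis assumes — not
the biology.  Genotypes follow a Balding–Nichols island model: ancestral
allele frequencies are drawn from a symmetric Dirichlet, population
frequencies from Dirichlet(p_anc (1-F)/F) so that the expected Wright F_ST
equals the configured ``target_fst``; diploid calls are drawn with optional
inbreeding (probability f of autozygosity) and optional null alleles (a hidden
allele that renders heterozygous carriers apparently homozygous and
double-null calls missing).  A one-generation Wright–Fisher cohort generator
feeds the LD-Ne recovery tests.  Phenotypes follow the study's two designs: a
2x2 origin x treatment transplant layout with configurable cell means and
within-cell variance, and a common-garden necrosis model in which tissue
necrosis accumulates with thermal degree-days above a threshold temperature,
after an origin-specific onset lag and at an origin-specific rate.

Defaults mirror the study's dimensions: four populations (two localities x
two depths) of 42-45 genotyped diploids at 7 microsatellite loci with
differentiation in the 0.02-0.14 range (global target 0.10), ~10 colonies per
transplant cell and 24 colonies per origin in the common garden with a 24 C
necrosis threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PhenotypeTable

__all__ = [
    "GenotypeSimConfig",
    "WrightFisherConfig",
    "RtePhenotypeConfig",
    "CgeNecrosisConfig",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_wf_cohort",
    "simulate_rte_phenotypes",
    "simulate_cge_necrosis",
    "default_temperature_series",
]

STUDY_SAMPLES = ("RI-20", "RI-40", "PZ-20", "PZ-40")
STUDY_SIZES = (43, 43, 42, 45)
STUDY_LOCI = ("Mic13", "Mic20", "Mic22", "Mic24", "Mic26", "Mic27", "COR46bis")


@dataclass
class GenotypeSimConfig:
    """Balding–Nichols island-model genotypes.

    ``target_fst`` may be a single F (classic symmetric island model) or one
    F per population: each population's allele frequencies then drift from
    the shared ancestral pool by its own amount, so pairwise theta between
    populations i and j lands near (F_i + F_j)/2.  The default per-population
    values place the two within-locality comparisons at the weak end and the
    Palazzu samples at the divergent end of the study's 0.02-0.14 pairwise
    range, with global theta near 0.10.
    """

    pop_names: tuple[str, ...] = STUDY_SAMPLES
    n_per_pop: tuple[int, ...] = STUDY_SIZES
    locus_names: tuple[str, ...] = STUDY_LOCI
    alleles_per_locus: int = 10
    target_fst: float | tuple[float, ...] = (0.02, 0.05, 0.17, 0.13)
    inbreeding_f: float = 0.0
    null_allele_rate: float = 0.0
    dirichlet_concentration: float = 1.0

    def fst_per_pop(self) -> tuple[float, ...]:
        if isinstance(self.target_fst, (int, float)):
            return (float(self.target_fst),) * len(self.pop_names)
        return tuple(float(f) for f in self.target_fst)

    def validate(self) -> None:
        if len(self.pop_names) != len(self.n_per_pop):
            raise ValueError("pop_names and n_per_pop lengths differ")
        fs = self.fst_per_pop()
        if len(fs) != len(self.pop_names):
            raise ValueError("target_fst must be scalar or one value per pop")
        if any(not 0 < f < 1 for f in fs):
            raise ValueError("target_fst must lie in (0, 1)")
        if any(n < 1 for n in self.n_per_pop) or self.alleles_per_locus < 2:
            raise ValueError("counts must be positive (>=2 alleles per locus)")
        if not 0 <= self.inbreeding_f <= 1:
            raise ValueError("inbreeding_f must lie in [0, 1]")
        if not 0 <= self.null_allele_rate < 1:
            raise ValueError("null_allele_rate must lie in [0, 1)")


@dataclass
class WrightFisherConfig:
    true_ne: int = 50
    n_offspring: int = 50
    n_loci: int = 30
    alleles_per_locus: int = 8
    pop_name: str = "cohort"
    monomorphic: bool = False  # force single-allele loci (degenerate input)

    def validate(self) -> None:
        if self.true_ne < 10:
            raise ValueError("true_ne must be >= 10")
        if self.n_offspring < 2 or self.n_loci < 1:
            raise ValueError("counts must be positive")


@dataclass
class RtePhenotypeConfig:
    """2x2 transplant design. Cell means are keyed (origin, treatment).

    The default means realise the local-vs-foreign pattern (the local sample
    outgrows the foreign one in each habitat) on a millimetre growth scale
    with within-cell variance matching the residual mean square of a typical
    transplant analysis.
    """

    cell_means: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("shallow", "shallow"): 0.0980,
        ("mesophotic", "shallow"): 0.0635,
        ("shallow", "mesophotic"): 0.0655,
        ("mesophotic", "mesophotic"): 0.0757,
    })
    sigma2_W: float = 4.1e-4
    n_per_cell: int = 10
    sample_labels: dict[str, str] = field(default_factory=lambda: {
        "shallow": "RI-20", "mesophotic": "RI-40",
    })

    def validate(self) -> None:
        if self.sigma2_W < 0:
            raise ValueError("sigma2_W must be >= 0")
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        origins = {k[0] for k in self.cell_means}
        depths = {k[1] for k in self.cell_means}
        if len(self.cell_means) != len(origins) * len(depths):
            raise ValueError("cell_means must cover the full crossed design")


@dataclass
class CgeNecrosisConfig:
    """Threshold necrosis model for the common-garden thermal-stress assay.

    Necrosis stays at 0 until cumulative degree-days above ``threshold_c``
    exceed a colony's onset lag, then grows linearly with the excess at the
    colony's slope, capped at 100%.  Lags and slopes are lognormal around
    origin-specific medians; the mesophotic origin has the shorter lag and
    steeper slope (weaker thermal buffering).
    """

    n_per_origin: int = 24
    threshold_c: float = 24.0
    lag_median: dict[str, float] = field(default_factory=lambda: {
        "shallow": 100.0, "mesophotic": 12.0,  # degree-days
    })
    slope_median: dict[str, float] = field(default_factory=lambda: {
        "shallow": 5.0, "mesophotic": 3.0,  # % necrosis per degree-day
    })
    lognormal_sd: float = 0.6
    n_surveys: int = 10
    sample_labels: dict[str, str] = field(default_factory=lambda: {
        "shallow": "RI-20", "mesophotic": "RI-40",
    })

    def validate(self) -> None:
        if self.n_per_origin < 2 or self.n_surveys < 1:
            raise ValueError("counts must be positive")
        if any(v <= 0 for v in self.slope_median.values()):
            raise ValueError("slopes must be positive")


@dataclass
class SimulationConfig:
    genotypes: GenotypeSimConfig = field(default_factory=GenotypeSimConfig)
    wright_fisher: WrightFisherConfig = field(default_factory=WrightFisherConfig)
    rte: RtePhenotypeConfig = field(default_factory=RtePhenotypeConfig)
    cge: CgeNecrosisConfig = field(default_factory=CgeNecrosisConfig)
    seed: int = 0


def config_as_jsonable(cfg) -> dict:
    """Dataclass config -> JSON-serialisable dict (tuple keys stringified)."""
    import dataclasses

    def conv(v):
        if isinstance(v, dict):
            return {"/".join(k) if isinstance(k, tuple) else str(k): conv(x)
                    for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        return v

    return conv(dataclasses.asdict(cfg))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(
    cfg: GenotypeSimConfig, seed: int | np.random.Generator | None = None
) -> GenotypeMatrix:
    """Balding–Nichols genotypes for the configured populations and loci."""
    cfg.validate()
    rng = _rng(seed)
    K = cfg.alleles_per_locus
    fst = cfg.fst_per_pop()
    names: list[str] = []
    pops: list[str] = []
    calls = np.zeros((sum(cfg.n_per_pop), len(cfg.locus_names), 2), dtype=np.int32)
    for pop, n in zip(cfg.pop_names, cfg.n_per_pop):
        for i in range(n):
            names.append(f"{pop}_{i + 1:03d}")
            pops.append(pop)
    for j, _locus in enumerate(cfg.locus_names):
        p_anc = rng.dirichlet(np.full(K, cfg.dirichlet_concentration))
        row = 0
        for pop, n, F in zip(cfg.pop_names, cfg.n_per_pop, fst):
            p_pop = rng.dirichlet(p_anc * (1.0 - F) / F)
            if cfg.null_allele_rate > 0:
                # visible alleles 1..K, hidden null allele index K
                p_full = np.append(p_pop * (1 - cfg.null_allele_rate),
                                   cfg.null_allele_rate)
            else:
                p_full = p_pop
            k_full = len(p_full)
            ab = rng.choice(k_full, p=p_full, size=(n, 2))
            if cfg.inbreeding_f > 0:
                auto = rng.random(n) < cfg.inbreeding_f
                ab[auto, 1] = ab[auto, 0]
            out = ab + 1
            if cfg.null_allele_rate > 0:
                null_code = K + 1
                a_null = out[:, 0] == null_code
                b_null = out[:, 1] == null_code
                out[a_null & ~b_null, 0] = out[a_null & ~b_null, 1]
                out[b_null & ~a_null, 1] = out[b_null & ~a_null, 0]
                out[a_null & b_null] = 0
            calls[row:row + n, j] = out
            row += n
    return GenotypeMatrix(names, list(cfg.locus_names), pops, calls)


def simulate_wf_cohort(
    cfg: WrightFisherConfig, seed: int | np.random.Generator | None = None
) -> GenotypeMatrix:
    """One-generation Wright–Fisher offspring cohort from a finite parent pool.

    ``true_ne`` diploid parents carry genotypes drawn from flat-Dirichlet
    allele frequencies (independent loci).  Each offspring is produced by a
    random mother-father pair (drawn uniformly, distinct) contributing one
    random allele each per locus — the random-mating model whose drift-induced
    LD the Ne estimator measures.
    """
    cfg.validate()
    rng = _rng(seed)
    K = 1 if cfg.monomorphic else cfg.alleles_per_locus
    parents = np.zeros((cfg.true_ne, cfg.n_loci, 2), dtype=np.int32)
    for j in range(cfg.n_loci):
        p = np.ones(1) if K == 1 else rng.dirichlet(np.ones(K))
        parents[:, j, :] = rng.choice(K, p=p, size=(cfg.true_ne, 2)) + 1
    calls = np.zeros((cfg.n_offspring, cfg.n_loci, 2), dtype=np.int32)
    for i in range(cfg.n_offspring):
        mom = rng.integers(cfg.true_ne)
        dad = rng.integers(cfg.true_ne - 1)
        if dad >= mom:
            dad += 1
        which = rng.integers(2, size=(2, cfg.n_loci))
        calls[i, :, 0] = parents[mom, np.arange(cfg.n_loci), which[0]]
        calls[i, :, 1] = parents[dad, np.arange(cfg.n_loci), which[1]]
    names = [f"{cfg.pop_name}_{i + 1:03d}" for i in range(cfg.n_offspring)]
    loci = [f"L{j + 1:02d}" for j in range(cfg.n_loci)]
    return GenotypeMatrix(names, loci, [cfg.pop_name] * cfg.n_offspring, calls)


def simulate_rte_phenotypes(
    cfg: RtePhenotypeConfig, seed: int | np.random.Generator | None = None
) -> PhenotypeTable:
    """Growth responses for the 2x2 origin x treatment transplant design."""
    cfg.validate()
    rng = _rng(seed)
    sd = float(np.sqrt(cfg.sigma2_W))
    rows = []
    counter = 0
    for (origin, treatment), mu in sorted(cfg.cell_means.items()):
        sample = cfg.sample_labels.get(origin, origin)
        for _ in range(cfg.n_per_cell):
            counter += 1
            rows.append({
                "individual": f"col_{counter:03d}",
                "sample": sample,
                "origin_depth": origin,
                "treatment_depth": treatment,
                "trait": "growth_mm",
                "value": max(0.0, mu + rng.normal(0.0, sd)),
            })
    return PhenotypeTable(pd.DataFrame(rows))


def default_temperature_series(n_days: int = 120, base: float = 19.0,
                               amplitude: float = 7.0) -> np.ndarray:
    """Daily summer temperature profile: half-sine rise to a peak and decline.

    Default peaks at 26 C mid-season, crossing the 24 C necrosis threshold for
    roughly two months — the shape of a strong shallow-water thermal anomaly.
    """
    t = np.arange(n_days)
    return base + amplitude * np.sin(np.pi * t / (n_days - 1))


def simulate_cge_necrosis(
    cfg: CgeNecrosisConfig,
    temperature: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> PhenotypeTable:
    """Necrosis time series for the common-garden thermal-stress experiment.

    Returns a long table with one ``necrosis_pct`` record per colony per
    survey date (times are day indices into the temperature series).
    """
    cfg.validate()
    rng = _rng(seed)
    temp = default_temperature_series() if temperature is None else np.asarray(temperature, float)
    dd = np.cumsum(np.maximum(0.0, temp - cfg.threshold_c))  # degree-days
    survey_days = np.linspace(0, len(temp) - 1, cfg.n_surveys).round().astype(int)
    rows = []
    counter = 0
    for origin in cfg.lag_median:
        sample = cfg.sample_labels.get(origin, origin)
        lags = cfg.lag_median[origin] * np.exp(
            rng.normal(0.0, cfg.lognormal_sd, cfg.n_per_origin))
        slopes = cfg.slope_median[origin] * np.exp(
            rng.normal(0.0, cfg.lognormal_sd, cfg.n_per_origin))
        for i in range(cfg.n_per_origin):
            counter += 1
            nec = np.clip(slopes[i] * np.maximum(0.0, dd - lags[i]), 0.0, 100.0)
            for day in survey_days:
                rows.append({
                    "individual": f"cge_{counter:03d}",
                    "sample": sample,
                    "origin_depth": origin,
                    "treatment_depth": "shallow",
                    "trait": "necrosis_pct",
                    "value": float(nec[day]),
                    "time": int(day),
                })
    return PhenotypeTable(pd.DataFrame(rows))
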