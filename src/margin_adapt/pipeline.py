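"""End-to-end study pipeline: diversity table, differentiation, Ne,
transplant/common-garden ANOVAs and the P_ST-F_ST verdicts from one config.

The pipeline mirrors the order of a depth-transplant population study:

1. genotype input (GENEPOP file, or the Balding–Nichols generator)
2. per-sample diversity table (Ho, He, f, rarefied Ar)
3. global and pairwise Weir–Cockerham theta with loci bootstraps, plus the
   genotypic differentiation permutation test
4. Nei Da distances and a neighbor-joining phenogram
5. LD-based effective population size per sample
6. PERMANOVA of the transplant growth design and the common-garden necrosis
7. P_ST bootstrap curves and (c/h^2)_crit against theta's upper CI bound and
   an external allozyme F_ST reference

One global seed is expanded into independent per-stage child seeds through
``numpy.random.SeedSequence.spawn``, so each stage is individually
reproducible.  Stage failures are recorded and dependent stages are skipped
with a reason instead of aborting the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype_io import (GenotypeMatrix, PhenotypeTable, read_genepop,
                          read_phenotypes, write_genepop, write_phenotypes)
from .diversity import diversity_summary, ld_test_battery
from .differentiation import (genotypic_differentiation_test, nei_da_matrix,
                              neighbor_joining, pairwise_theta_table,
                              weir_cockerham_theta)
from .effective_size import ldne_estimate
from .phenotype_stats import (permanova_one_way, permanova_two_way,
                              survival_summary)
from .pst_fst import compare_and_crit, pst_bootstrap
from .synthetic_data import (SimulationConfig, simulate_cge_necrosis,
                             simulate_genotypes, simulate_rte_phenotypes)

__all__ = ["StudyConfig", "RunReport", "run_study", "write_report"]

_STAGES = ("diversity", "fst", "tree", "ne", "permanova", "pst_fst")


@dataclass
class StudyConfig:
    """Inputs and knobs for one full study run.

    With ``genepop_path``/``rte_path``/``cge_path`` set to ``None`` the
    corresponding inputs are generated by the synthetic-data module from the
    stage seeds (the no-download mode).
    """

    genepop_path: str | None = None
    rte_path: str | None = None
    cge_path: str | None = None
    use_genotypes: bool = True
    use_rte: bool = True
    use_cge: bool = True
    seed: int = 0
    n_perm: int = 999
    n_boot: int = 1000
    ar_genes: int | None = 64
    freq_cutoff: float = 0.02
    allozyme_fst: float = 0.1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**{k: v for k, v in data.items() if k in known})

    def digest(self) -> str:
        from .synthetic_data import config_as_jsonable
        payload = config_as_jsonable(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    stage_status: dict[str, str]
    diversity: pd.DataFrame | None = None
    ld_battery: pd.DataFrame | None = None
    theta_global: dict[str, Any] | None = None
    theta_pairwise: pd.DataFrame | None = None
    differentiation_p: float | None = None
    da_matrix: pd.DataFrame | None = None
    tree_newick: str | None = None
    ne_estimates: pd.DataFrame | None = None
    permanova_rte: pd.DataFrame | None = None
    permanova_cge: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None
    pst_comparisons: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def conv(v):
            if isinstance(v, pd.DataFrame):
                return json.loads(v.to_json(orient="split"))
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        payload = {k: conv(v) for k, v in dataclasses.asdict(self).items()
                   if not isinstance(v, pd.DataFrame)}
        for name in ("diversity", "ld_battery", "theta_pairwise", "da_matrix",
                     "ne_estimates", "permanova_rte", "permanova_cge",
                     "survival", "pst_comparisons"):
            v = getattr(self, name)
            payload[name] = conv(v) if v is not None else None
        return json.dumps(payload, indent=2, sort_keys=True, default=str)

    def to_markdown(self) -> str:
        lines = [f"# Study report (config {self.config_hash}, seed {self.seed})", ""]
        lines.append("## Stage status")
        for stage, status in self.stage_status.items():
            lines.append(f"- {stage}: {status}")
        if self.theta_global:
            tg = self.theta_global
            lines += ["", "## Differentiation",
                      f"Global theta = {tg['theta']:.3f} "
                      f"(95% CI {tg['ci_lo']:.3f}-{tg['ci_hi']:.3f}); "
                      f"genotypic differentiation p = {self.differentiation_p}"]
        for title, df in (("Diversity", self.diversity),
                          ("Pairwise theta", self.theta_pairwise),
                          ("Effective size", self.ne_estimates),
                          ("PERMANOVA (transplants)", self.permanova_rte),
                          ("PERMANOVA (common garden)", self.permanova_cge),
                          ("Survival", self.survival),
                          ("P_ST vs F_ST", self.pst_comparisons)):
            if df is not None:
                lines += ["", f"## {title}", df.to_markdown(index=False)]
        if self.tree_newick:
            lines += ["", "## Phenogram", "```", self.tree_newick, "```"]
        if self.warnings:
            lines += ["", "## Warnings"] + [f"- {w}" for w in self.warnings]
        return "\n".join(lines) + "\n"


def _stage_seeds(seed: int, n: int = 12) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]


def run_study(config: StudyConfig | str | Path) -> RunReport:
    """Execute every stage of the study analysis and collect a report."""
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    seeds = _stage_seeds(config.seed)
    status: dict[str, str] = {}
    warns: list[str] = []
    report = RunReport(config_hash=config.digest(), seed=config.seed,
                       version=__version__, stage_status=status)

    # ---- inputs ----------------------------------------------------------
    geno: GenotypeMatrix | None = None
    rte: PhenotypeTable | None = None
    cge: PhenotypeTable | None = None
    try:
        if not config.use_genotypes:
            status["genotypes"] = "skipped: disabled in config"
        else:
            if config.genepop_path:
                geno = read_genepop(config.genepop_path)
            else:
                geno = simulate_genotypes(config.simulation.genotypes,
                                          seed=seeds[0])
            status["genotypes"] = "ok"
    except Exception as e:  # noqa: BLE001 - recorded, downstream skipped
        status["genotypes"] = f"failed: {e}"
    try:
        if not config.use_rte:
            status["rte_phenotypes"] = "skipped: disabled in config"
        else:
            if config.rte_path:
                rte = read_phenotypes(config.rte_path)
            else:
                rte = simulate_rte_phenotypes(config.simulation.rte,
                                              seed=seeds[1])
            status["rte_phenotypes"] = "ok"
    except Exception as e:  # noqa: BLE001
        status["rte_phenotypes"] = f"failed: {e}"
    try:
        if not config.use_cge:
            status["cge_phenotypes"] = "skipped: disabled in config"
        else:
            if config.cge_path:
                cge = read_phenotypes(config.cge_path)
            else:
                cge = simulate_cge_necrosis(config.simulation.cge,
                                            seed=seeds[2])
            status["cge_phenotypes"] = "ok"
    except Exception as e:  # noqa: BLE001
        status["cge_phenotypes"] = f"failed: {e}"

    # ---- genetic stages --------------------------------------------------
    theta_upper = None
    if geno is None:
        for s in ("diversity", "fst", "tree", "ne"):
            status[s] = "skipped: no genotype input"
    else:
        try:
            summ = diversity_summary(geno, g=config.ar_genes,
                                     n_perm=config.n_perm, seed=seeds[3])
            report.diversity = summ.table
            report.ld_battery = ld_test_battery(geno, n_perm=config.n_perm,
                                                seed=seeds[4])
            status["diversity"] = "ok"
        except Exception as e:  # noqa: BLE001
            status["diversity"] = f"failed: {e}"
        try:
            res = weir_cockerham_theta(geno, n_boot=config.n_boot, seed=seeds[5])
            report.theta_global = {"theta": res.theta,
                                   "ci_lo": res.ci95[0], "ci_hi": res.ci95[1]}
            report.theta_pairwise = pairwise_theta_table(
                geno, n_boot=config.n_boot, seed=seeds[6])
            report.differentiation_p = genotypic_differentiation_test(
                geno, n_perm=config.n_perm, seed=seeds[7])
            status["fst"] = "ok"
        except Exception as e:  # noqa: BLE001
            status["fst"] = f"failed: {e}"
        try:
            da = nei_da_matrix(geno)
            report.da_matrix = pd.DataFrame(da.matrix, index=da.labels,
                                            columns=da.labels)
            if len(da.labels) >= 3:
                report.tree_newick = neighbor_joining(da)
                status["tree"] = "ok"
            else:
                status["tree"] = "skipped: fewer than 3 samples"
        except Exception as e:  # noqa: BLE001
            status["tree"] = f"failed: {e}"
        try:
            rows = []
            for sample in geno.sample_names:
                est = ldne_estimate(geno, sample, freq_cutoff=config.freq_cutoff)
                rows.append({
                    "sample": sample, "ne_hat": est.ne_hat,
                    "ci_lo": est.ci95[0], "ci_hi": est.ci95[1],
                    "S": est.S, "n_locus_pairs": est.n_locus_pairs,
                })
            report.ne_estimates = pd.DataFrame(rows)
            status["ne"] = "ok"
        except Exception as e:  # noqa: BLE001
            status["ne"] = f"failed: {e}"

    # ---- phenotype stages ------------------------------------------------
    if rte is None and cge is None:
        status["permanova"] = "skipped: no phenotype input"
    else:
        try:
            frames = []
            if rte is not None:
                res = permanova_two_way(rte, trait="growth_mm",
                                        n_perm=config.n_perm, seed=seeds[8])
                frames.append(res.table.assign(design="RTE two-way"))
            report.permanova_rte = pd.concat(frames).reset_index(
                names="source") if frames else None
            if cge is not None:
                final = cge.final_time("necrosis_pct")
                res1 = permanova_one_way(final, trait="necrosis_pct",
                                         n_perm=config.n_perm, seed=seeds[9])
                report.permanova_cge = res1.table.reset_index(names="source")
                report.survival = survival_summary(cge)
            status["permanova"] = "ok"
        except Exception as e:  # noqa: BLE001
            status["permanova"] = f"failed: {e}"

    # ---- P_ST-F_ST -------------------------------------------------------
    if rte is None and cge is None:
        status["pst_fst"] = "skipped: no phenotype input"
    else:
        try:
            if report.theta_pairwise is not None and len(report.theta_pairwise):
                theta_upper = float(report.theta_pairwise["ci_hi"].max())
            comps = []
            pst_jobs = []
            if rte is not None:
                for habitat in ("shallow", "mesophotic"):
                    sub = rte.df[(rte.df["trait"] == "growth_mm")
                                 & (rte.df["treatment_depth"] == habitat)]
                    if sub["origin_depth"].nunique() == 2:
                        pst_jobs.append((f"RTE growth, {habitat} habitat",
                                         sub["value"], sub["origin_depth"]))
            if cge is not None:
                final = cge.final_time("necrosis_pct")
                pst_jobs.append(("CGE necrosis", final["value"],
                                 final["origin_depth"]))
            for k, (label, vals, labs) in enumerate(pst_jobs):
                pst = pst_bootstrap(vals, labs, n_boot=config.n_boot,
                                    seed=seeds[10] + k)
                refs = [("allozyme_FST", config.allozyme_fst)]
                if theta_upper is not None:
                    refs.insert(0, ("theta_upper_CI", theta_upper))
                comp = compare_and_crit(pst, refs)
                df = comp.as_frame()
                df.insert(0, "comparison", label)
                point, lo, hi = pst.at(1.0)
                df.insert(1, "pst_at_1", point)
                df.insert(2, "pst_ci_lo", lo)
                df.insert(3, "pst_ci_hi", hi)
                comps.append(df)
            report.pst_comparisons = pd.concat(comps).reset_index(drop=True) \
                if comps else None
            status["pst_fst"] = "ok"
        except Exception as e:  # noqa: BLE001
            status["pst_fst"] = f"failed: {e}"

    report.warnings = warns
    return report


def write_report(report: RunReport, outdir: str | Path,
                 geno: GenotypeMatrix | None = None,
                 phenotypes: dict[str, PhenotypeTable] | None = None) -> None:
    """Write the report (JSON + markdown) and all tables as CSV under outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(report.to_markdown())
    for name in ("diversity", "theta_pairwise", "da_matrix", "ne_estimates",
                 "permanova_rte", "permanova_cge", "survival",
                 "pst_comparisons", "ld_battery"):
        df = getattr(report, name)
        if df is not None:
            df.to_csv(out / f"{name}.csv", index=name == "da_matrix")
    if report.tree_newick:
        (out / "tree.nwk").write_text(report.tree_newick + "\n")
    if geno is not None:
        write_genepop(geno, out / "genotypes.gen")
    for key, table in (phenotypes or {}).items():
        write_phenotypes(table, out / f"{key}_phenotypes.csv")
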