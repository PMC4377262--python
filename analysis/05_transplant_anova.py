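"""Permutational ANOVAs of the field experiments.

Two-factorial univariate PERMANOVA (origin depth x treatment depth, with
interaction) on transplant growth, and a one-way PERMANOVA (origin depth) on
final common-garden necrosis, both on Euclidean distance with 9999
permutations; plus the survival summary of the common garden."""

import argparse
from pathlib import Path

from margin_adapt import (permanova_one_way, permanova_two_way,
                          read_phenotypes, survival_summary)

parser = argparse.ArgumentParser()
parser.add_argument("--rte", default="results/data/rte_growth.csv")
parser.add_argument("--cge", default="results/data/cge_necrosis.csv")
parser.add_argument("--perms", type=int, default=9999)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", default="results")
args = parser.parse_args()

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

rte = read_phenotypes(args.rte)
res2 = permanova_two_way(rte, trait="growth_mm", n_perm=args.perms,
                         seed=args.seed)
print("Reciprocal transplant (growth, 2x2 with interaction):")
print(res2.table.round(5).to_string())
res2.table.to_csv(out / "permanova_rte.csv")

cge = read_phenotypes(args.cge)
final = cge.final_time("necrosis_pct")
res1 = permanova_one_way(final, trait="necrosis_pct", n_perm=args.perms,
                         seed=args.seed + 1)
print("\nCommon garden (final necrosis, one-way):")
print(res1.table.round(5).to_string())
res1.table.to_csv(out / "permanova_cge.csv")

surv = survival_summary(cge)
print("\nCommon-garden survival:")
print(surv.round(1).to_string(index=False))
surv.to_csv(out / "survival.csv", index=False)
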