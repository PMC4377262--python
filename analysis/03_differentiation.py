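"""Global and pairwise theta with bootstrap CIs, the genotypic differentiation
permutation test, Nei's Da distance matrix and the NJ phenogram with
bootstrap-over-loci support."""

import argparse
from pathlib import Path

import pandas as pd

from margin_adapt import (genotypic_differentiation_test, nei_da_matrix,
                          pairwise_theta_table, read_genepop,
                          weir_cockerham_theta)
from margin_adapt.differentiation import nj_bootstrap_support

parser = argparse.ArgumentParser()
parser.add_argument("--genepop", default="results/data/genotypes.gen")
parser.add_argument("--boot", type=int, default=1000)
parser.add_argument("--perms", type=int, default=999)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", default="results")
args = parser.parse_args()

geno = read_genepop(args.genepop)
out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

res = weir_cockerham_theta(geno, n_boot=args.boot, seed=args.seed)
print(f"global theta = {res.theta:.3f} "
      f"(95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f})")

pw = pairwise_theta_table(geno, n_boot=args.boot, seed=args.seed + 1)
pw.to_csv(out / "pairwise_theta.csv", index=False)
print(pw.round(3).to_string(index=False))

p = genotypic_differentiation_test(geno, n_perm=args.perms, seed=args.seed + 2)
print(f"genotypic differentiation (all samples): p = {p:.4g}")

da = nei_da_matrix(geno)
pd.DataFrame(da.matrix, index=da.labels, columns=da.labels).to_csv(
    out / "da_matrix.csv")
nwk, support = nj_bootstrap_support(geno, n_boot=args.boot, seed=args.seed + 3)
(out / "tree.nwk").write_text(nwk + "\n")
print(f"NJ phenogram: {nwk}")
for split, count in support.items():
    print(f"  split {sorted(split)}: {count}/{args.boot} bootstrap support")
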