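"""LD-based contemporary effective population size per sample.

Hill's linkage-disequilibrium method with Waples' bias correction under
random mating, screening alleles below 2% frequency, jackknife CIs over locus
pairs.  A negative estimate with an infinite upper bound means drift leaves
no detectable LD signal at this sample size (effectively large Ne)."""

import argparse
from pathlib import Path

import math
import pandas as pd

from margin_adapt import ldne_estimate, read_genepop

parser = argparse.ArgumentParser()
parser.add_argument("--genepop", default="results/data/genotypes.gen")
parser.add_argument("--cutoff", type=float, default=0.02)
parser.add_argument("--out", default="results")
args = parser.parse_args()

geno = read_genepop(args.genepop)
rows = []
for sample in geno.sample_names:
    est = ldne_estimate(geno, sample, freq_cutoff=args.cutoff)
    hi = "inf" if math.isinf(est.ci95[1]) else f"{est.ci95[1]:.1f}"
    print(f"{sample}: Ne = {est.ne_hat:.1f} (95% CI {est.ci95[0]:.1f}-{hi}), "
          f"S = {est.S:.1f}, {est.n_locus_pairs} locus pairs")
    rows.append({"sample": sample, "ne_hat": est.ne_hat,
                 "ci_lo": est.ci95[0],
                 "ci_hi": est.ci95[1] if math.isfinite(est.ci95[1]) else "inf",
                 "S": est.S, "n_locus_pairs": est.n_locus_pairs,
                 "freq_cutoff": est.freq_cutoff})
out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)
pd.DataFrame(rows).to_csv(out / "effective_size.csv", index=False)
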