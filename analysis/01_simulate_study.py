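#!/usr/bin/env python
"""Generate the study-shaped synthetic GWAS pair used by the later steps.

Emulates the real study's setup: one large exposure GWAS (602,604 samples,
80 candidate instruments) paired with a ~460k-sample outcome GWAS, with
palindromic SNPs, confounder-annotated SNPs, LD-duplicate SNPs, and
moderate pleiotropic outliers planted so that every quality-control rung
downstream has work to do.  Writes exposure/outcome/LD/confounder/truth
tables under results/data/.
"""

import argparse
from pathlib import Path

from mrkit.synthetic import generate, paper_like_config, write_study

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=17)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = paper_like_config(seed=args.seed)
study = generate(cfg)
paths = write_study(study, args.out)

truth = study.truth
print(f"simulated {cfg.n_snps} candidate instruments "
      f"(true causal log-OR {truth.theta}, seed {args.seed})")
print(f"  planted: {int(truth.outlier.sum())} pleiotropic outliers, "
      f"{int(truth.palindromic.sum())} palindromic SNPs, "
      f"{int(truth.confounder.sum())} confounder-annotated SNPs, "
      f"{int((truth.ld_parent >= 0).sum())} LD duplicates")
for name, p in paths.items():
    print(f"  {name}: {p}")
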