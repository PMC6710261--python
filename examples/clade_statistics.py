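"""Clade-level statistics on species-mean PTS indices.

Builds two clades of species means around low/high indices and runs the
analyses used on real measurement tables: one-sample t against 1 (the
no-cam null), one-way ANOVA with pairwise comparisons, and a PGLS
allometric regression against body size on the species tree.
"""

import numpy as np
import pandas as pd

from taluscam import anova_pairwise, one_sample_t, pgls
from taluscam.trees import parse_tree

rng = np.random.default_rng(3)
low = rng.normal(0.85, 0.08, 6)
high = rng.normal(1.45, 0.12, 6)

t, df, p = one_sample_t(high, mu=1.0)
print(f"high clade vs index 1: t = {t:.3f}, df = {df}, p = {p:.2g}")

res = anova_pairwise({"low": low, "high": high})
print(f"ANOVA: F = {res.F:.2f}, df = ({res.df_between}, "
      f"{res.df_within}), p = {res.p:.2g}")

taxa = [f"sp{i}" for i in range(12)]
newick = "(({}):1,({}):1);".format(
    ",".join(f"{t}:1" for t in taxa[:6]), ",".join(f"{t}:1" for t in taxa[6:])
)
tree = parse_tree(newick)
size = pd.Series(rng.normal(3.0, 1.0, 12), index=taxa)  # ln body mass
pts = pd.Series(
    np.concatenate([low, high]) - 0.3 * size.to_numpy(), index=taxa
)
fit = pgls(tree, size, pts)
print(f"PGLS pts ~ size: slope = {fit.slope:.3f} "
      f"(SE {fit.slope_se:.3f}, p = {fit.p_slope:.2g})")
# A negative PGLS slope indicates larger taxa tend to have lower PTS
# indices after accounting for phylogeny.
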