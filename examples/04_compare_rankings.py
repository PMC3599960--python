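"""Compare the ranked gene lists of the three scores with CAT diagnostics.

Builds the logFC-, WAD- and shrinkage-t-ordered lists for one sample and
quantifies their concordance: CAT(r), the p-CAT excess of each alternative
over the t-ordered optimum, and the +/-20-position rank correspondence.
"""

import numpy as np

from somportraits import diffexpr, listcomp, preprocess, synthetic

truth = synthetic.SyntheticTruth(n_modules=2, module_size=60, n_groups=2, seed=9)
raw, conditions, _, truth = synthetic.generate(truth, 2000, 6)
delta, log_expr = preprocess.preprocess(raw, conditions)
scores = diffexpr.score_table(delta, log_expr.values, log_expr.sigma,
                              log_expr.n_replicates)
m = delta.columns[0]
lists = {name: list(diffexpr.rank_genes(scores[name][m]).index)
         for name in ("logFC", "WAD", "t")}
pvals = scores["p"][m]

print(f"sample {m}, N = {len(delta)} genes")
for a, b in (("logFC", "WAD"), ("logFC", "t"), ("WAD", "t")):
    curve = listcomp.cat(lists[a], lists[b], r_max=100)
    rc = listcomp.rank_correspondence(lists[a], lists[b], window=20)
    print(f"{a} vs {b}: CAT(10) = {curve.cat[9]:.2f}, CAT(100) = {curve.cat[99]:.2f} "
          f"(null {curve.null[9]:.3f}/{curve.null[99]:.3f}); "
          f"RC within +/-20 in top 50: {rc[:50].sum()}/50")

for alt in ("logFC", "WAD"):
    dp = listcomp.delta_p_cat(lists[alt], lists["t"], pvals, r_max=100)
    print(f"Delta p-CAT({alt}): at r=10 {dp[9]:.1f}, at r=100 {dp[99]:.1f} "
          "(log10 units above the t-ordered minimum; always >= 0)")
# High CAT values against a tiny r/N null mean the scores agree far beyond
# chance; the Delta p-CAT gap shows how much significance an alternative
# ordering forfeits relative to ranking by the shrinkage-t p-value itself.
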