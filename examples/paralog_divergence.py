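"""Quantify how paralog co-expression decays with synonymous divergence.

Simulates paralog pairs across a Ks range with expression correlation
exp(-lambda * Ks), estimates NG86 Ka/Ks from the simulated CDS, bins
pairs by Ks, and runs the bin-wise statistics: the youngest bin [0, 0.2)
separates from bins >= 0.4 while distant bins do not differ.
"""

import numpy as np

from bahdscape import SimConfig, bin_and_test, ng86_ka_ks, simulate_expression
from bahdscape.expression_divergence import ParalogPair, ks_bin_label
from bahdscape.synthetic_data import simulate_paralog_pair

config = SimConfig(seed=41, decay_lambda=2.5)
rng = np.random.default_rng(41)

targets = np.concatenate([rng.uniform(lo, lo + 0.2, 20)
                          for lo in (0.0, 0.2, 0.4, 0.6, 0.8)])
true_ks = []
est_ks = []
for t in targets:
    a, b, tks, _ = simulate_paralog_pair(config, float(t), 300, rng)
    true_ks.append(tks)
    est_ks.append(ng86_ka_ks(a, b).ks)

_, realized_pcc = simulate_expression(config, true_ks, rng)
pairs = [ParalogPair(gene_a=f"a{i:03d}", gene_b=f"b{i:03d}", pcc=p,
                     ka=0.0, ks=k, ka_ks=0.0, ks_bin=ks_bin_label(k))
         for i, (k, p) in enumerate(zip(est_ks, realized_pcc))]

summary = bin_and_test(pairs)
print(f"NG86 vs true Ks, mean abs error: "
      f"{np.mean(np.abs(np.array(est_ks) - np.array(true_ks))):.4f}")
print(f"PCC ~ Ks: slope {summary.slope:.3f}, R^2 {summary.r_squared:.3f}")
print(f"Kruskal-Wallis across bins: H={summary.kruskal_wallis_H:.2f}, "
      f"p={summary.kruskal_wallis_p:.2e}")
young = summary.pairwise_ks.query("bin_a == '[0.0, 0.2)'")
print(young[["bin_b", "D", "p_adjusted"]].to_string(index=False))
# The negative slope and the small adjusted p-values of the [0.0, 0.2)
# rows show that only the youngest paralogs remain co-expressed; bins
# beyond Ks 0.4 are indistinguishable from each other.
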