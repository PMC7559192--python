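"""Score cancer-cell-intrinsic resistance signatures on expression data.

Builds a simulated log2-TPM cohort whose "RES*" genes track each tumor's
resistant-clone fraction and whose "IMM*" genes (plus GZMA/PRF1) track host
immune pressure. A reference signature (log2 fold changes of a resistant
line vs parental) is scored per sample as the Pearson correlation with
mean-centered expression, then associated with response and with cytolytic
activity.
"""

import numpy as np
import pandas as pd

import clonedyn as cd

sim = cd.simulate_experiment(seed=1)
E, gene_truth = cd.simulate_expression(sim, n_genes=400, seed=1,
                                       return_truth=True)
meta = sim.meta.set_index("sample")

# reference signature for an ICB-resistant line: a pure resistant clone
# over-expresses the intrinsic block in proportion to each gene's effect
# size; null genes are diluted in as in a real differential-expression table
rng = np.random.default_rng(0)
res = gene_truth[gene_truth["block"] == "intrinsic"]
bg_genes = list(gene_truth.index[gene_truth["block"] == "background"][:100])
de = pd.DataFrame({
    "gene": list(res.index) + bg_genes,
    "log2fc": np.r_[0.4 * res["slope"] + rng.normal(0, 0.1, len(res)),
                    rng.normal(0.0, 0.2, len(bg_genes))],
    "padj": np.r_[np.full(len(res), 1e-4),
                  rng.uniform(0.2, 1.0, len(bg_genes))],
})

sig = cd.make_signature(de, top_n=200)
Ep = cd.normalize_expression(E)
scores = cd.score_samples(Ep, sig)

ctrl = meta.loc[meta["arm"] == "IgG", "size_end"]
treated = meta.loc[meta["arm"] != "IgG", "size_end"]
calls = cd.classify_response(treated, ctrl)["label"]
two = calls[calls != "intermediate"]
t_res = cd.associate_scores(scores, two, mode="two_group_t")
print(f"signature score, responders vs non-responders: "
      f"t={t_res['statistic']:+.2f}, p={t_res['pvalue']:.2g} "
      f"({t_res['direction']})")

cyt = cd.cytolytic_score(E)
r_cyt = cd.associate_scores(scores, np.log(cyt), mode="pearson")
print(f"signature score vs log cytolytic activity (GZMA/PRF1): "
      f"r={r_cyt['statistic']:+.2f}, p={r_cyt['pvalue']:.2g}")

grid_scores, consistency = cd.robustness_grid(de, Ep, grid=(200, 400, None))
print(f"robustness grid (top 200/400/all genes): "
      f"score sign consistent for {consistency:.0%} of samples")
print()
print("On-treatment responders score higher for the intrinsic-resistance "
      "signature: immune pressure removed the sensitive clones. The "
      "positive correlation with cytolytic activity shows the same effect "
      "read from the microenvironment side.")
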