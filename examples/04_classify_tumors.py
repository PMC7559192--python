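"""Classify treated tumors as responders / non-responders.

Primary rule: compare end-of-treatment size to the control cohort's log10
median M (responder < 10^(M-0.5), non-responder > 10^(M-0.1)). Alternative
rule: log10 fold change between post- and pre-treatment size.
"""

import clonedyn as cd

sim = cd.simulate_experiment(seed=1)
meta = sim.meta.set_index("sample")
control = meta.loc[meta["arm"] == "IgG", "size_end"]
treated = meta.loc[meta["arm"] != "IgG", "size_end"]

calls = cd.classify_response(treated, control)
print("size-vs-control classification of treated tumors:")
print(calls["label"].value_counts().to_string())
print(f"thresholds: responder < {calls['threshold_responder'].iloc[0]:.4f}, "
      f"non-responder > {calls['threshold_non_responder'].iloc[0]:.4f} mm^3")

sizes = sim.sizes.pivot(index="sample", columns="day", values="size")
pre = sizes.loc[treated.index, sim.config.treat_start_day]
post = sizes.loc[treated.index, sizes.columns.max()]
fc_calls = cd.classify_by_fold_change(pre, post)
print()
print("fold-change classification (post vs treatment-start size):")
print(fc_calls["label"].value_counts().to_string())

both = (calls["label"] != "intermediate") & (fc_calls["label"] != "intermediate")
agree = (calls.loc[both, "label"] == fc_calls.loc[both, "label"]).mean()
print(f"\nagreement where both rules commit: {agree:.0%} of {both.sum()} tumors")
print("Responders are tumors whose host mounted strong immune pressure: "
      "small end sizes and shrinkage after treatment start.")
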