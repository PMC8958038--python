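"""End-to-end pipeline: simulate, build a benchmark, score, evaluate.

Generates a synthetic benchmark with planted signal, applies the
label/overlap filtering rules to produce positives and negatives, scores
every drug x disease combination with NEAT and ANUBIX, and evaluates both
methods with balanced-sample AUROC (all positives plus an equal random
draw of negatives, repeated 100 times with shared draws so the Wilcoxon
comparison is paired). The mu+2*sigma prediction cutoff is then used to
partition above-cutoff pairs into agreed/unique prediction sets.
"""

import numpy as np

from netrepurpose import (
    SyntheticConfig,
    build_benchmark,
    compare_methods,
    evaluate_scores,
    generate_benchmark,
    negative_draws,
    prediction_cutoff,
    prediction_sets,
    score_all_pairs,
)

bench = generate_benchmark(SyntheticConfig(seed=11))
built = build_benchmark(
    bench.network, bench.drug_sets, bench.disease_sets, bench.labels, min_disease_genes=20
)
print("benchmark counts:", built.counts())

labels = built.pairs.set_index(["drug_id", "disease_id"])["binary_label"]
tables = {}
for method, seed in (("neat", 0), ("anubix", 1)):
    tables[method] = score_all_pairs(
        bench.network, built.drugs, built.diseases, method,
        rng=np.random.default_rng(seed),
    )

summaries, draws = {}, None
for method, tab in tables.items():
    keyed = labels.loc[list(zip(tab["drug_id"], tab["disease_id"]))]
    keep = (keyed != "excluded").to_numpy() & np.isfinite(tab["z"]).to_numpy()
    y = (keyed[keep] == "positive").to_numpy().astype(int)
    z = tab["z"].to_numpy()[keep]
    if draws is None:
        draws = negative_draws(int((1 - y).sum()), int(y.sum()), 100, np.random.default_rng(7))
    summaries[method] = evaluate_scores(z, y, draws=draws)
    s = summaries[method]
    print(
        f"{method:7s} AUROC={s.auroc:.3f} balanced={np.mean(s.balanced_aurocs):.3f} "
        f"AUPR={s.aupr:.3f} threshold={s.threshold:.2f} recall={s.recall:.3f}"
    )

p = compare_methods(summaries["neat"].balanced_aurocs, summaries["anubix"].balanced_aurocs)
print(f"paired Wilcoxon signed-rank p (neat vs anubix) = {p:.3g}")

cut = {m: prediction_cutoff(t["z"].dropna()) for m, t in tables.items()}
agreed, u_neat, u_anubix = prediction_sets(
    tables["neat"], tables["anubix"], cut["neat"], cut["anubix"]
)
print(
    f"z cutoffs: neat={cut['neat']:.2f} anubix={cut['anubix']:.2f}; "
    f"predictions agreed={len(agreed)} unique_neat={len(u_neat)} unique_anubix={len(u_anubix)}"
)
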