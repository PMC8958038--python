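"""Drug-drug similarity repurposing: score candidates via approved drugs.

For a disease with approved drugs, each candidate is scored by its
network z against every approved drug's target set (leave-one-out), then
combined: e^(-min z) for proximity, max z for the crosstalk methods. A
candidate whose targets resemble the approved drugs' targets scores high
even if its direct association with the disease genes is weak.
"""

import numpy as np

from netrepurpose import SyntheticConfig, generate_benchmark, similarity_table

bench = generate_benchmark(SyntheticConfig(seed=11))
approved = (
    bench.labels[bench.labels["label"] == "approved"]
    .groupby("disease_id")["drug_id"]
    .apply(list)
    .to_dict()
)
disease = max(approved, key=lambda d: len(approved[d]))
print(f"disease {disease}: approved drugs {approved[disease]}")

tab = similarity_table(
    bench.network,
    bench.drug_sets,
    {disease: approved[disease]},
    "anubix",
    rng=np.random.default_rng(4),
)
truth = bench.truth.set_index(["drug_id", "disease_id"])["planted"]
tab["planted"] = [truth[(d, disease)] for d in tab["drug_id"]]
top = tab.sort_values("similarity", ascending=False).head(8)
print(top[["drug_id", "similarity", "n_references", "planted"]].to_string(index=False))
print("high similarity = candidate shares network neighborhood with approved drugs")
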