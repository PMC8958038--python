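"""Construction of labeled drug–disease benchmark sets.

Raw association labels (approved / off_label / clinical_trial /
contraindicated / unknown) are turned into a binary benchmark with the
following rules, applied in order:

1. restrict drug target sets and disease gene sets to network nodes;
2. drop drugs with no in-network target and diseases with fewer than
   ``min_disease_genes`` in-network genes;
3. approved and off-label pairs become positives; contraindicated and
   clinical-trial pairs are excluded (optionally reassigned to positive
   for sensitivity analysis); unknown pairs become negatives;
4. negatives whose drug targets overlap the disease genes are excluded —
   they may be positives that simply have not been verified yet.

Every (drug, disease) combination is materialized; pairs absent from the
label table default to "unknown". Provenance records counts at each stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .io import LABEL_VALUES
from .network import GeneNetwork

logger = logging.getLogger(__name__)

POSITIVE_SOURCE = {"approved", "off_label"}
EXCLUDED_SOURCE = {"contraindicated", "clinical_trial"}

PAIR_COLUMNS = [
    "drug_id",
    "disease_id",
    "source_label",
    "binary_label",
    "overlap",
    "exclusion_reason",
    "new_positive",
]


class BenchmarkError(ValueError):
    pass


@dataclass
class BenchmarkSet:
    """Labeled drug–disease pairs after filtering, plus provenance.

    ``pairs`` has one row per (drug, disease) combination of the *retained*
    drugs and diseases, with columns drug_id, disease_id, source_label,
    binary_label (positive/negative/excluded), overlap, exclusion_reason,
    new_positive. Pairs of dropped drugs/diseases are kept with
    binary_label = excluded so provenance counts conserve.
    """

    pairs: pd.DataFrame
    drugs: dict[str, set]
    diseases: dict[str, set]
    provenance: dict = field(default_factory=dict)

    @property
    def positives(self) -> pd.DataFrame:
        return self.pairs[self.pairs["binary_label"] == "positive"]

    @property
    def negatives(self) -> pd.DataFrame:
        return self.pairs[self.pairs["binary_label"] == "negative"]

    @property
    def excluded(self) -> pd.DataFrame:
        return self.pairs[self.pairs["binary_label"] == "excluded"]

    def counts(self) -> dict[str, int]:
        c = self.pairs["binary_label"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("positive", "negative", "excluded")}


def overlap_flags(
    net: GeneNetwork,
    drug_sets: Mapping[str, set],
    disease_sets: Mapping[str, set],
) -> pd.DataFrame:
    """Target–gene overlap flag and size for every drug × disease pair.

    Overlap is computed on in-network members only.
    """
    rows = []
    restricted_drugs = {d: set(s) & net.node_set for d, s in drug_sets.items()}
    restricted_dis = {d: set(s) & net.node_set for d, s in disease_sets.items()}
    for did, genes in restricted_dis.items():
        for drug, targets in restricted_drugs.items():
            o = len(targets & genes)
            rows.append(
                {"drug_id": drug, "disease_id": did, "overlap": o > 0, "overlap_size": o}
            )
    return pd.DataFrame(rows)


def build_benchmark(
    net: GeneNetwork,
    drug_sets: Mapping[str, set],
    disease_sets: Mapping[str, set],
    label_table: pd.DataFrame,
    min_disease_genes: int = 20,
    keep_trial_and_contra_as_positive: bool = False,
    dedup_identical_drugs: bool = False,
) -> BenchmarkSet:
    """Apply the inclusion, labeling and overlap-filtering rules.

    ``label_table`` has columns (drug_id, disease_id, label); combinations
    not listed default to "unknown". ``keep_trial_and_contra_as_positive``
    reassigns clinical-trial and contraindicated pairs to the positive
    class (sensitivity analysis) instead of excluding them.
    ``dedup_identical_drugs`` removes drugs whose target set and positive
    disease set both duplicate an earlier drug's.
    """
    bad = set(label_table["label"]) - set(LABEL_VALUES)
    if bad:
        row = label_table[label_table["label"].isin(bad)].iloc[0]
        raise BenchmarkError(
            f"unknown label {row['label']!r} for pair ({row['drug_id']}, {row['disease_id']})"
        )
    if label_table.duplicated(["drug_id", "disease_id"]).any():
        raise BenchmarkError("label table has duplicate (drug_id, disease_id) rows")

    provenance: dict = {
        "min_disease_genes": min_disease_genes,
        "n_drugs_input": len(drug_sets),
        "n_diseases_input": len(disease_sets),
    }

    # stage 1-2: network restriction and size filters
    drugs = {d: set(s) & net.node_set for d, s in drug_sets.items()}
    diseases = {d: set(s) & net.node_set for d, s in disease_sets.items()}
    dropped_drugs = {d for d, s in drugs.items() if not s}
    dropped_dis = {d for d, s in diseases.items() if len(s) < min_disease_genes}
    kept_drugs = {d: s for d, s in drugs.items() if d not in dropped_drugs}
    kept_dis = {d: s for d, s in diseases.items() if d not in dropped_dis}

    if dedup_identical_drugs:
        labels_by_drug = {
            drug: frozenset(
                grp.loc[grp["label"].isin(POSITIVE_SOURCE), "disease_id"]
            )
            for drug, grp in label_table.groupby("drug_id")
        }
        seen: dict[tuple, str] = {}
        for drug in sorted(kept_drugs):
            key = (frozenset(kept_drugs[drug]), labels_by_drug.get(drug, frozenset()))
            if key in seen:
                dropped_drugs.add(drug)
            else:
                seen[key] = drug
        kept_drugs = {d: s for d, s in kept_drugs.items() if d not in dropped_drugs}

    provenance["n_drugs_dropped"] = len(dropped_drugs)
    provenance["n_diseases_dropped"] = len(dropped_dis)
    provenance["n_drugs_kept"] = len(kept_drugs)
    provenance["n_diseases_kept"] = len(kept_dis)

    labels = {
        (r.drug_id, r.disease_id): r.label for r in label_table.itertuples(index=False)
    }

    rows = []
    for did in sorted(set(disease_sets)):
        for drug in sorted(set(drug_sets)):
            source = labels.get((drug, did), "unknown")
            if drug in dropped_drugs or did in dropped_dis:
                reason = "drug_no_targets" if drug in dropped_drugs else "disease_too_small"
                rows.append((drug, did, source, "excluded", False, reason, False))
                continue
            overlap = bool(kept_drugs[drug] & kept_dis[did])
            if source in POSITIVE_SOURCE:
                binary, reason = "positive", None
            elif source in EXCLUDED_SOURCE:
                if keep_trial_and_contra_as_positive:
                    binary, reason = "positive", None
                else:
                    binary, reason = "excluded", source
            else:  # unknown
                if overlap:
                    binary, reason = "excluded", "overlap_negative"
                else:
                    binary, reason = "negative", None
            rows.append((drug, did, source, binary, overlap, reason, False))

    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    counts = pairs["binary_label"].value_counts().to_dict()
    provenance["n_pairs_total"] = len(pairs)
    provenance["n_positive"] = int(counts.get("positive", 0))
    provenance["n_negative"] = int(counts.get("negative", 0))
    provenance["n_excluded"] = int(counts.get("excluded", 0))
    provenance["exclusion_reasons"] = (
        pairs.loc[pairs["binary_label"] == "excluded", "exclusion_reason"]
        .value_counts()
        .to_dict()
    )
    if provenance["n_positive"] == 0:
        logger.warning("build_benchmark: no positive pairs after filtering")
    if provenance["n_negative"] == 0:
        logger.warning("build_benchmark: no negative pairs after filtering")
    return BenchmarkSet(pairs=pairs, drugs=kept_drugs, diseases=kept_dis, provenance=provenance)


def apply_time_stamp(benchmark: BenchmarkSet, new_positive_table: pd.DataFrame) -> BenchmarkSet:
    """Relabel listed negative pairs as positives (time-stamped validation).

    Every listed pair must exist in the benchmark and must not be excluded;
    pairs already positive are left unchanged with a logged notice. The
    relabeled pairs carry the ``new_positive`` flag.
    """
    pairs = benchmark.pairs.copy()
    index = {(r.drug_id, r.disease_id): i for i, r in pairs.iterrows()}
    n_relabeled = 0
    for r in new_positive_table.itertuples(index=False):
        key = (r.drug_id, r.disease_id)
        if key not in index:
            raise BenchmarkError(f"pair {key} not present in the benchmark")
        i = index[key]
        current = pairs.at[i, "binary_label"]
        if current == "excluded":
            raise BenchmarkError(
                f"pair {key} is excluded ({pairs.at[i, 'exclusion_reason']}); cannot relabel"
            )
        if current == "positive":
            logger.info("apply_time_stamp: pair %s already positive; unchanged", key)
            continue
        pairs.at[i, "binary_label"] = "positive"
        pairs.at[i, "new_positive"] = True
        n_relabeled += 1
    provenance = dict(benchmark.provenance)
    provenance["n_new_positives"] = n_relabeled
    counts = pairs["binary_label"].value_counts().to_dict()
    provenance["n_positive"] = int(counts.get("positive", 0))
    provenance["n_negative"] = int(counts.get("negative", 0))
    return BenchmarkSet(
        pairs=pairs,
        drugs=benchmark.drugs,
        diseases=benchmark.diseases,
        provenance=provenance,
    )
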