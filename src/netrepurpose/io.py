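"""Readers and writers for the plain-text formats the pipeline speaks.

Gene sets travel as GMT (``set_id <TAB> description <TAB> member...``, one
set per line), drug–disease labels and score tables as TSV. Everything is
UTF-8; '#'-prefixed lines are comments.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

LABEL_VALUES = ("approved", "off_label", "clinical_trial", "contraindicated", "unknown")

SCORE_COLUMNS = [
    "method",
    "drug_id",
    "disease_id",
    "raw",
    "null_mean",
    "null_sd",
    "z",
    "p",
    "q",
    "direction",
    "n_targets_used",
    "status",
]


class GMTParseError(ValueError):
    pass


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file into an ordered mapping set_id -> member set."""
    sets: dict[str, set] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {line_no}: GMT rows need id, description "
                    f"and at least one member"
                )
            set_id = fields[0]
            if set_id in sets:
                raise GMTParseError(f"{path}: line {line_no}: duplicate set id {set_id!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise GMTParseError(f"{path}: line {line_no}: set {set_id!r} has no members")
            sets[set_id] = members
    return sets


def write_gmt(sets: Mapping[str, set], path, descriptions: Mapping[str, str] | None = None):
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, members in sets.items():
            desc = (descriptions or {}).get(set_id, "na")
            fh.write("\t".join([str(set_id), desc, *sorted(map(str, members))]) + "\n")


def write_network_tsv(net, path):
    """Write a GeneNetwork as (nodeA, nodeB[, confidence]) TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# nodeA\tnodeB\tconfidence\n")
        for u, v, data in sorted(
            net.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))
        ):
            conf = data.get("confidence")
            if conf is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{conf:.6g}\n")


def read_label_table(path) -> pd.DataFrame:
    """TSV of (drug_id, disease_id, label); label must be a known value."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str,
        names=["drug_id", "disease_id", "label"], header=None,
    )
    if not df.empty and list(df.iloc[0]) == ["drug_id", "disease_id", "label"]:
        df = df.iloc[1:].reset_index(drop=True)
    bad = df[~df["label"].isin(LABEL_VALUES)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"{path}: unknown label {row['label']!r} for pair "
            f"({row['drug_id']}, {row['disease_id']})"
        )
    if df.duplicated(["drug_id", "disease_id"]).any():
        raise ValueError(f"{path}: duplicate (drug_id, disease_id) rows")
    return df


def write_label_table(df: pd.DataFrame, path):
    df[["drug_id", "disease_id", "label"]].to_csv(path, sep="\t", index=False, header=False)


def read_pair_table(path) -> pd.DataFrame:
    """TSV of (drug_id, disease_id), e.g. a new-positives relabeling table."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str,
        names=["drug_id", "disease_id"], header=None,
    )
    if not df.empty and list(df.iloc[0]) == ["drug_id", "disease_id"]:
        df = df.iloc[1:].reset_index(drop=True)
    return df


def write_score_table(df: pd.DataFrame, path):
    cols = [c for c in SCORE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
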