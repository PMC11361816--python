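"""Assembly of the per-DDI-type feature table for the confidence model.

Each candidate DDI type becomes one row carrying the evidence the curation
benchmark showed to be informative: the 3did score and z-score of the type's
best-scoring interface, the number of residue-residue contacts of that same
interface, structure counts by chain composition, the DockQ of an AlphaFold
fragment model against the representative resolved structure (ingested,
never computed here), and the interface disorder fraction.  Rows whose Pfam
pair involves a family commonly used in protein engineering (Ankyrin
repeats, immunoglobulin V-set) are excluded: such interfaces are selected in
the laboratory, not by evolution, and teach the model nothing about natural
DDIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConsistencyError, StateError
from .threedid_io import DDIType, best_interface, canonical_pair

__all__ = [
    "FEATURE_COLUMNS",
    "LABELS",
    "DEFAULT_ENGINEERED_FAMILIES",
    "ExclusionPolicy",
    "contact_count",
    "assemble_feature_table",
    "read_feature_table",
    "write_feature_table",
    "read_label_table",
    "apply_exclusion_policy",
]

#: fixed, documented column order of the serialized feature table
FEATURE_COLUMNS = [
    "pfam_a",
    "pfam_b",
    "zscore_3did",
    "score_3did",
    "n_contacts",
    "n_interchain_structures",
    "n_intrachain_structures",
    "af_dockq",
    "iupred_interface",
    "label",
]

LABELS = ("approved", "nonapproved", "unlabeled")

#: Pfam families routinely engineered to bind new targets: Ankyrin repeat
#: (DARPin scaffolds) and the immunoglobulin V-set domain (antibody and
#: nanobody paratopes)
DEFAULT_ENGINEERED_FAMILIES = frozenset({"PF00023", "PF07686"})


@dataclass(frozen=True)
class ExclusionPolicy:
    """Drop any row whose Pfam pair intersects ``families``."""

    families: frozenset[str] = field(default=DEFAULT_ENGINEERED_FAMILIES)

    def __post_init__(self):
        object.__setattr__(self, "families", frozenset(self.families))
        if not self.families:
            raise ValueError(
                "engineered-domain filtering requested with an empty family set"
            )

    def excludes(self, pfam_a: str, pfam_b: str) -> bool:
        return pfam_a in self.families or pfam_b in self.families


def contact_count(t: DDIType) -> int:
    """Residue-residue contact count of the type's highest-3did-score interface."""
    if not t.interfaces:
        raise StateError(f"DDI type {t.pfam_pair} has no interfaces")
    return len(best_interface(t).contacts)


def _structure_counts(t: DDIType) -> tuple[int, int]:
    inter = {i.pdb_id for i in t.interfaces if not i.intrachain}
    intra = {i.pdb_id for i in t.interfaces if i.intrachain}
    return len(inter), len(intra)


def apply_exclusion_policy(
    table: pd.DataFrame, policy: ExclusionPolicy | None
) -> tuple[pd.DataFrame, int]:
    """Drop rows whose pair intersects the policy set; return (table, n_dropped)."""
    if policy is None:
        return table, 0
    mask = table.apply(
        lambda row: policy.excludes(row["pfam_a"], row["pfam_b"]), axis=1
    )
    return table.loc[~mask].reset_index(drop=True), int(mask.sum())


def assemble_feature_table(
    types: list[DDIType],
    annotations: Mapping[tuple[str, str], Mapping[str, float]] | None = None,
    labels: Mapping[tuple[str, str], str] | None = None,
    policy: ExclusionPolicy | None = None,
) -> tuple[pd.DataFrame, int]:
    """One feature row per retained DDI type.

    ``annotations`` supplies per-type ingested features keyed by canonical
    Pfam pair (``af_dockq``, ``iupred_interface``, plus arbitrary
    passthrough columns); missing values stay missing — imputation or
    listwise deletion is the model's decision, not the table's.  ``labels``
    maps pairs to ``approved``/``nonapproved``; a label for a pair absent
    from ``types`` is a consistency error.  Returns the table and the
    number of rows removed by the exclusion policy.
    """
    annotations = annotations or {}
    labels = dict(labels or {})

    known_pairs = {t.pfam_pair for t in types}
    unknown = set(labels) - known_pairs
    if unknown:
        raise ConsistencyError(
            "labels reference unknown DDI types: "
            + ", ".join(f"{a}_{b}" for a, b in sorted(unknown))
        )
    bad = {p: l for p, l in labels.items() if l not in LABELS[:2]}
    if bad:
        raise ConsistencyError(f"unrecognized labels: {bad}")

    rows = []
    passthrough_cols: list[str] = []
    for t in types:
        pair = t.pfam_pair
        iface = best_interface(t)
        n_inter, n_intra = _structure_counts(t)
        ann = dict(annotations.get(pair, {}))
        row = {
            "pfam_a": pair[0],
            "pfam_b": pair[1],
            "zscore_3did": iface.zscore_3did,
            "score_3did": iface.score_3did,
            "n_contacts": len(iface.contacts),
            "n_interchain_structures": n_inter,
            "n_intrachain_structures": n_intra,
            "af_dockq": ann.pop("af_dockq", None),
            "iupred_interface": ann.pop("iupred_interface", None),
            "label": labels.get(pair, "unlabeled"),
        }
        for key, value in ann.items():
            row[key] = value
            if key not in passthrough_cols:
                passthrough_cols.append(key)
        rows.append(row)

    columns = FEATURE_COLUMNS + passthrough_cols
    table = pd.DataFrame(rows, columns=columns)
    return apply_exclusion_policy(table, policy)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ConsistencyError(f"feature table lacks required columns: {missing}")
    return table


def read_label_table(path: str | Path) -> dict[tuple[str, str], str]:
    """Curation labels: TSV pfam_a, pfam_b, label[, reason]; reason is ignored."""
    labels: dict[tuple[str, str], str] = {}
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        labels[canonical_pair(str(row["pfam_a"]), str(row["pfam_b"]))] = str(
            row["label"]
        )
    return labels
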