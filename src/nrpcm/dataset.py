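"""Bioactivity records, EC50 dichotomization, and PCM feature assembly.

Each training atom couples a compound with a receptor target and either a
measured EC50 (half-maximal effective concentration, μM) or a binary
activity label.  EC50 values are dichotomized at 1 μM — the conventional
potency cutoff for calling a nuclear-receptor ligand active — and each
record is featurized into a single vector: the target's panel-similarity
descriptor followed by the compound's ligand descriptor (30 + 187 = 217
dimensions with the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .ligfeat import Compound, DescriptorManifest, descriptor_matrix
from .seqsim import (
    AlignmentParams,
    DEFAULT_PARAMS,
    ProteinSequence,
    ReferencePanel,
    panel_descriptor_matrix,
)

ACTIVE = "active"
INACTIVE = "inactive"

#: EC50 potency cutoff (μM) separating active from inactive ligands.
EC50_THRESHOLD_UM = 1.0

_UNIT_TO_UM = {"um": 1.0, "nm": 1e-3, "mm": 1e3, "m": 1e6, "pm": 1e-6}


class DatasetError(ValueError):
    pass


def label_from_ec50(ec50_um: float, threshold_um: float = EC50_THRESHOLD_UM) -> str:
    """Dichotomize a potency value: active iff EC50 ≤ threshold (boundary inclusive)."""
    if ec50_um is None or not np.isfinite(ec50_um) or ec50_um <= 0:
        raise DatasetError(f"EC50 must be a positive finite value, got {ec50_um!r}")
    return ACTIVE if ec50_um <= threshold_um else INACTIVE


def ec50_to_um(value: float, units: str = "uM") -> float:
    """Convert an EC50 reading to μM."""
    key = units.strip().lower().replace("μ", "u")
    if key not in _UNIT_TO_UM:
        raise DatasetError(f"unknown EC50 units {units!r}")
    return value * _UNIT_TO_UM[key]


@dataclass(frozen=True)
class BioactivityRecord:
    """One (compound, target) measurement: EC50 in μM and/or a binary label."""

    compound_id: str
    target_id: str
    ec50: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.ec50 is None and self.label is None:
            raise DatasetError(
                f"record ({self.compound_id}, {self.target_id}): "
                "needs an EC50 value or a label"
            )
        if self.label is not None and self.label not in (ACTIVE, INACTIVE):
            raise DatasetError(f"label must be {ACTIVE!r} or {INACTIVE!r}, got {self.label!r}")
        if self.ec50 is not None:
            derived = label_from_ec50(self.ec50)
            if self.label is not None and self.label != derived:
                raise DatasetError(
                    f"record ({self.compound_id}, {self.target_id}): label "
                    f"{self.label!r} contradicts EC50 {self.ec50} μM ({derived})"
                )
            if self.label is None:
                object.__setattr__(self, "label", derived)


@dataclass(frozen=True)
class PCMExample:
    """A featurized training example: protein block then ligand block."""

    feature: np.ndarray
    label: str
    compound_id: str
    target_id: str
    origin: Literal["original", "oversampled"] = "original"

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature", np.asarray(self.feature, dtype=float))


@dataclass(frozen=True)
class SplitSpec:
    """Seeded, stratified train/validation split specification."""

    train_fraction: float = 0.85
    seed: int = 42
    stratify_by: Literal["label", "target", "both"] = "both"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise DatasetError("train_fraction must lie strictly between 0 and 1")


def read_bioactivity_csv(path: str | Path) -> tuple[list[BioactivityRecord], list[Compound], list[str]]:
    """Read a bioactivity CSV with columns compound_id, smiles, target_id and
    ec50 (+ optional ec50_units, default μM) and/or label.

    Returns ``(records, compounds, warnings)``; unparseable rows are
    reported, never silently dropped.
    """
    df = pd.read_csv(path)
    required = {"compound_id", "target_id"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetError(f"{path}: missing column(s) {sorted(missing)}")
    records: list[BioactivityRecord] = []
    compounds: dict[str, Compound] = {}
    problems: list[str] = []
    for idx, row in df.iterrows():
        cid = str(row["compound_id"])
        try:
            ec50 = None
            if "ec50" in df.columns and pd.notna(row.get("ec50")):
                units = str(row.get("ec50_units", "uM")) if pd.notna(row.get("ec50_units", "uM")) else "uM"
                ec50 = ec50_to_um(float(row["ec50"]), units)
            label = None
            if "label" in df.columns and pd.notna(row.get("label")):
                label = str(row["label"]).strip().lower()
            records.append(
                BioactivityRecord(cid, str(row["target_id"]), ec50=ec50, label=label)
            )
            if "smiles" in df.columns and cid not in compounds and pd.notna(row.get("smiles")):
                compounds[cid] = Compound(cid, str(row["smiles"]))
        except (DatasetError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if not records:
        raise DatasetError(f"{path}: no usable bioactivity records")
    return records, list(compounds.values()), problems


def write_bioactivity_csv(
    records: Sequence[BioactivityRecord],
    compounds: Sequence[Compound],
    path: str | Path,
) -> None:
    smiles = {c.id: c.smiles for c in compounds}
    rows = [
        {
            "compound_id": r.compound_id,
            "smiles": smiles.get(r.compound_id, ""),
            "target_id": r.target_id,
            "ec50": r.ec50,
            "ec50_units": "uM",
            "label": r.label,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def assemble(
    records: Sequence[BioactivityRecord],
    panel: ReferencePanel,
    compounds: Sequence[Compound],
    manifest: DescriptorManifest,
    params: AlignmentParams = DEFAULT_PARAMS,
    targets: Sequence[ProteinSequence] | None = None,
) -> tuple[list[PCMExample], list[str]]:
    """Featurize records into PCM examples (protein block ⊕ ligand block).

    ``targets`` supplies sequences for target ids absent from the panel;
    panel members themselves are always resolvable.  Unresolvable ids are
    excluded and reported.  Raises if no record survives.
    """
    target_seqs: dict[str, ProteinSequence] = {m.id: m for m in panel.members}
    for t in targets or ():
        target_seqs[t.id] = t
    wanted_targets = {r.target_id for r in records}
    known = [target_seqs[t] for t in sorted(wanted_targets) if t in target_seqs]
    prot = panel_descriptor_matrix(known, panel, params)
    lig = descriptor_matrix(compounds, manifest)

    examples: list[PCMExample] = []
    problems: list[str] = []
    for r in records:
        if r.target_id not in prot:
            problems.append(f"({r.compound_id}, {r.target_id}): unknown target id")
            continue
        if r.compound_id not in lig:
            problems.append(f"({r.compound_id}, {r.target_id}): unknown compound id")
            continue
        feature = np.concatenate([prot[r.target_id], lig[r.compound_id]])
        examples.append(
            PCMExample(feature, r.label, r.compound_id, r.target_id, "original")
        )
    if not examples:
        raise DatasetError("no records could be featurized")
    return examples, problems


def _strata(examples: Sequence[PCMExample], by: str) -> list[str]:
    if by == "label":
        return [e.label for e in examples]
    if by == "target":
        return [e.target_id for e in examples]
    return [f"{e.target_id}|{e.label}" for e in examples]


def split(
    examples: Sequence[PCMExample], spec: SplitSpec
) -> tuple[list[PCMExample], list[PCMExample]]:
    """Disjoint, exhaustive, seeded train/validation partition.

    Stratified by label within target by default so every receptor keeps
    both classes on both sides.  Raises naming any stratum too small to
    appear on both sides.
    """
    strata = _strata(examples, spec.stratify_by)
    counts = pd.Series(strata).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise DatasetError(
            f"stratum too small to split: {small.index[0]!r} "
            f"({int(small.iloc[0])} example(s))"
        )
    idx = np.arange(len(examples))
    train_idx, val_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=strata,
        shuffle=True,
    )
    train = [examples[i] for i in sorted(train_idx)]
    val = [examples[i] for i in sorted(val_idx)]
    return train, val


def split_by_compound(
    examples: Sequence[PCMExample], spec: SplitSpec
) -> tuple[list[PCMExample], list[PCMExample]]:
    """Stricter split: all records of a compound land on the same side."""
    cids = sorted({e.compound_id for e in examples})
    if len(cids) < 2:
        raise DatasetError("need at least two distinct compounds")
    train_c, val_c = train_test_split(
        cids, train_size=spec.train_fraction, random_state=spec.seed, shuffle=True
    )
    train_set = set(train_c)
    train = [e for e in examples if e.compound_id in train_set]
    val = [e for e in examples if e.compound_id not in train_set]
    if not train or not val:
        raise DatasetError("degenerate compound-level split")
    return train, val


def features_labels(examples: Sequence[PCMExample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into (X, y) with y ∈ {0, 1} (1 = active)."""
    X = np.vstack([e.feature for e in examples])
    y = np.array([1 if e.label == ACTIVE else 0 for e in examples])
    return X, y
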