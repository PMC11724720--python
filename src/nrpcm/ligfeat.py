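"""Ligand physicochemical descriptors from a version-pinned manifest.

Compounds are described by a fixed, ordered list of 187 two-dimensional
RDKit descriptors (physicochemical properties, topological indices,
fragment counts).  The manifest — descriptor names plus the toolkit
version — is serialized with every trained model so that feature vectors
can be reproduced exactly.  No 3D descriptors and no hashed fingerprints:
the model relies on interpretable tabular features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import rdkit
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")  # parse failures are reported, not printed

DEFAULT_MANIFEST_SIZE = 187


class CompoundError(ValueError):
    """Raised for unparseable or degenerate compound structures."""


@dataclass(frozen=True)
class Compound:
    """A named molecule stored as canonical SMILES."""

    id: str
    smiles: str
    source: str | None = None

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise CompoundError(f"compound {self.id!r}: unparseable SMILES {self.smiles!r}")
        if mol.GetNumHeavyAtoms() < 1:
            raise CompoundError(f"compound {self.id!r}: no heavy atoms")
        object.__setattr__(self, "smiles", Chem.MolToSmiles(mol))

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass(frozen=True)
class DescriptorManifest:
    """Ordered descriptor names pinned to a toolkit version."""

    names: tuple[str, ...]
    toolkit_version: str = rdkit.__version__

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor manifest contains duplicate names")
        registry = dict(Descriptors._descList)
        unknown = [n for n in self.names if n not in registry]
        if unknown:
            raise ValueError(f"unknown descriptor name(s): {unknown[:5]}")

    def __len__(self) -> int:
        return len(self.names)

    def functions(self):
        registry = dict(Descriptors._descList)
        return [registry[n] for n in self.names]


def default_manifest(size: int = DEFAULT_MANIFEST_SIZE) -> DescriptorManifest:
    """The first ``size`` registry descriptors in alphabetical order.

    Deterministic for a pinned toolkit version; substitute your own list
    via :func:`read_manifest` to pin a different descriptor set.
    """
    names = sorted(n for n, _ in Descriptors._descList)
    if size > len(names):
        raise ValueError(
            f"requested {size} descriptors but the registry defines {len(names)}"
        )
    return DescriptorManifest(tuple(names[:size]))


def read_manifest(path: str | Path) -> DescriptorManifest:
    """Read a manifest file: one descriptor name per line, '#' comments."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    if not names:
        raise ValueError(f"{path}: empty descriptor manifest")
    return DescriptorManifest(tuple(names))


def write_manifest(manifest: DescriptorManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# toolkit version {manifest.toolkit_version}\n")
        for n in manifest.names:
            fh.write(n + "\n")


@dataclass(frozen=True)
class LigandDescriptor:
    """Numeric vector aligned to a manifest; finite entries only."""

    values: np.ndarray
    imputed: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("ligand descriptor contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def ligand_descriptor(
    c: Compound, manifest: DescriptorManifest
) -> LigandDescriptor:
    """Compute the manifest's descriptors for one compound.

    Descriptors that fail or return a non-finite value are imputed as 0
    and listed in ``imputed`` (tree models are insensitive to the sentinel).
    """
    mol = c.mol()
    values = np.zeros(len(manifest), dtype=float)
    imputed: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (name, fn) in enumerate(zip(manifest.names, manifest.functions())):
            try:
                v = float(fn(mol))
            except Exception:
                v = float("nan")
            if np.isfinite(v):
                values[i] = v
            else:
                imputed.append(name)
    if imputed:
        log.debug("compound %s: imputed %d descriptor(s): %s", c.id, len(imputed), imputed)
    return LigandDescriptor(values, tuple(imputed))


def descriptor_matrix(
    compounds: Iterable[Compound], manifest: DescriptorManifest
) -> dict[str, np.ndarray]:
    """Descriptor vectors for many compounds keyed by compound id."""
    return {c.id: ligand_descriptor(c, manifest).values for c in compounds}


def read_compounds(
    path: str | Path,
    format: str = "smiles-list",
    smiles_column: str = "smiles",
    id_column: str = "compound_id",
) -> tuple[list[Compound], list[str]]:
    """Read compounds from a SMILES list, CSV, or SDF.

    Returns ``(compounds, warnings)``: invalid structures are excluded and
    reported (id + reason), never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[tuple[str, str]] = []  # (id, smiles)
    if format == "smiles-list":
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"mol{ln}"
            entries.append((cid, smiles))
    elif format == "csv":
        import pandas as pd

        df = pd.read_csv(path)
        if smiles_column not in df.columns:
            raise ValueError(f"{path}: missing SMILES column {smiles_column!r}")
        ids = (
            df[id_column].astype(str)
            if id_column in df.columns
            else [f"mol{i+1}" for i in range(len(df))]
        )
        entries = list(zip(ids, df[smiles_column].astype(str)))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        problems: list[str] = []
        compounds: list[Compound] = []
        for i, mol in enumerate(supplier):
            if mol is None:
                problems.append(f"record {i + 1}: unparseable molecule")
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            cid = name or f"mol{i + 1}"
            compounds.append(Compound(cid, Chem.MolToSmiles(mol), source=str(path)))
        return compounds, problems
    else:
        raise ValueError(f"unknown compound format {format!r}")

    compounds = []
    problems = []
    for cid, smiles in entries:
        try:
            compounds.append(Compound(cid, smiles, source=str(path)))
        except CompoundError as exc:
            problems.append(str(exc))
    return compounds, problems


def write_smiles(compounds: Iterable[Compound], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in compounds:
            fh.write(f"{c.smiles}\t{c.id}\n")
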