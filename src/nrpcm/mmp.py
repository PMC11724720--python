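"""Matched molecular pairs and the compound chemical-space network.

A matched molecular pair (MMP) is two compounds that become identical
after one localized edit: cutting a single acyclic bond in each yields
the same core fragment with different substituents.  Indexing every
single-cut fragmentation by its canonical core finds all MMPs in a
library in near-linear time.  The MMP relation then defines a
chemical-space network — compounds as nodes, pairs as edges — whose
connected components group compounds sharing a scaffold series; each
node is annotated with the screening argmax target, so bioactive
chemotype clusters for one receptor stand out.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd
from rdkit import Chem

from .ligfeat import Compound

#: Default substituent size limits: at most a third of the parent's heavy
#: atoms and never more than 13 heavy atoms (common MMP practice).
MAX_SUBSTITUENT_FRACTION = 0.33
MAX_SUBSTITUENT_ATOMS = 13


class MMPError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentCut:
    """One single-bond fragmentation: parent = core + substituent."""

    parent_compound_id: str
    core: str  # canonical SMILES with one [*:1] attachment point
    substituent: str
    cut_bond: int

    def __post_init__(self) -> None:
        pass


def _heavy_atoms(frag_smiles: str) -> int:
    mol = Chem.MolFromSmiles(frag_smiles)
    # the dummy attachment atom is not a heavy atom of the fragment
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1 and a.GetAtomicNum() != 0)


def _canonical_fragment(mol: Chem.Mol) -> str:
    # plain [*] attachment marker: no isotope or map-number decoration
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def enumerate_cuts(
    c: Compound,
    max_substituent_fraction: float = MAX_SUBSTITUENT_FRACTION,
    max_substituent_atoms: int = MAX_SUBSTITUENT_ATOMS,
) -> list[FragmentCut]:
    """All single-cut fragmentations of a compound within the size limits.

    Eligible bonds are acyclic single bonds between two heavy atoms.  The
    larger fragment (heavy-atom count; canonical-SMILES order on ties) is
    the core; cuts whose substituent exceeds the size limits are dropped.
    Molecules with no eligible bond (e.g. benzene) return an empty list.
    """
    mol = c.mol()
    parent_heavy = mol.GetNumHeavyAtoms()
    cuts: list[FragmentCut] = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        frag = Chem.FragmentOnBonds(
            mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(1, 1)]
        )
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
        if len(pieces) != 2:
            continue  # cutting a ring bond would leave one piece
        smi = sorted(_canonical_fragment(p) for p in pieces)
        h0, h1 = _heavy_atoms(smi[0]), _heavy_atoms(smi[1])
        if h0 > h1 or (h0 == h1 and smi[0] < smi[1]):
            core, sub, sub_heavy = smi[0], smi[1], h1
        else:
            core, sub, sub_heavy = smi[1], smi[0], h0
        if sub_heavy > max_substituent_atoms:
            continue
        if sub_heavy > max_substituent_fraction * parent_heavy:
            continue
        cuts.append(FragmentCut(c.id, core, sub, bond.GetIdx()))
    return cuts


def reassemble(cut: FragmentCut) -> str:
    """Join core and substituent at their attachment points; canonical SMILES."""
    core = Chem.MolFromSmiles(cut.core)
    sub = Chem.MolFromSmiles(cut.substituent)
    for m in (core, sub):
        for atom in m.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(1)
    joined = Chem.molzip(core, sub)
    Chem.SanitizeMol(joined)
    return Chem.MolToSmiles(joined)


@dataclass(frozen=True)
class MMPair:
    """Two compounds sharing a core under single cuts, differing in substituent."""

    compound_a: str
    compound_b: str
    shared_core: str
    substituent_a: str
    substituent_b: str


def find_mmps(
    compounds: Sequence[Compound],
    max_substituent_fraction: float = MAX_SUBSTITUENT_FRACTION,
    max_substituent_atoms: int = MAX_SUBSTITUENT_ATOMS,
) -> list[MMPair]:
    """All matched molecular pairs in a library by core indexing.

    Every unordered pair of distinct compounds that share a canonical
    core with differing substituents yields exactly one pair per shared
    core.  Output is sorted by (compound_a, compound_b, core), so it is
    invariant under permutation of the input.
    """
    if len(compounds) < 2:
        raise MMPError("need at least two compounds to search for pairs")
    by_core: dict[str, dict[str, set[str]]] = {}
    for c in compounds:
        for cut in enumerate_cuts(c, max_substituent_fraction, max_substituent_atoms):
            by_core.setdefault(cut.core, {}).setdefault(c.id, set()).add(cut.substituent)

    pairs: set[MMPair] = set()
    for core, members in by_core.items():
        ids = sorted(members)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ca, cb = ids[i], ids[j]
                chosen = _differing_substituents(members[ca], members[cb])
                if chosen is not None:
                    pairs.add(MMPair(ca, cb, core, chosen[0], chosen[1]))
    return sorted(pairs, key=lambda p: (p.compound_a, p.compound_b, p.shared_core))


def _differing_substituents(
    subs_a: set[str], subs_b: set[str]
) -> tuple[str, str] | None:
    """Lexicographically smallest pair (x, y), x ∈ subs_a, y ∈ subs_b, x ≠ y."""
    for x in sorted(subs_a):
        for y in sorted(subs_b):
            if x != y:
                return x, y
    return None


def build_network(
    pairs: Sequence[MMPair],
    compounds: Sequence[Compound],
    screening: pd.DataFrame,
) -> nx.Graph:
    """Chemical-space network with per-node argmax-target annotation.

    Nodes are compounds annotated with ``best_target``/``best_score``
    (argmax over the screening table's targets, first-in-order tie-break);
    edges are the MMP relations; each node also carries its connected
    component label.  The screening table must cover every compound.
    """
    screened = set(screening["compound_id"])
    missing = [c.id for c in compounds if c.id not in screened]
    if missing:
        raise MMPError(f"compound(s) missing from the screening table: {missing[:5]}")

    g = nx.Graph()
    for c in compounds:
        grp = screening[screening["compound_id"] == c.id]
        k = grp["score"].to_numpy().argmax()
        g.add_node(
            c.id,
            smiles=c.smiles,
            best_target=str(grp.iloc[k]["target_id"]),
            best_score=float(grp.iloc[k]["score"]),
        )
    for p in pairs:
        g.add_edge(
            p.compound_a,
            p.compound_b,
            core=p.shared_core,
            substituent_a=p.substituent_a,
            substituent_b=p.substituent_b,
        )
    for label, comp in enumerate(sorted(nx.connected_components(g), key=sorted)):
        for node in comp:
            g.nodes[node]["component"] = label
    return g


def write_network(g: nx.Graph, graphml_path: str | Path, edges_csv_path: str | Path | None = None) -> None:
    nx.write_graphml(g, graphml_path)
    if edges_csv_path is not None:
        rows = [
            {
                "compound_a": a,
                "compound_b": b,
                "core": d.get("core", ""),
                "substituent_a": d.get("substituent_a", ""),
                "substituent_b": d.get("substituent_b", ""),
            }
            for a, b, d in g.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(edges_csv_path, index=False)


def write_pairs(pairs: Sequence[MMPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "compound_a": p.compound_a,
                "compound_b": p.compound_b,
                "core": p.shared_core,
                "substituent_a": p.substituent_a,
                "substituent_b": p.substituent_b,
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)
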