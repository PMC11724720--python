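"""Independent brute-force reference implementations used only by tests.

Each oracle is written directly from the mathematical definition and
shares no code path with the package: a three-state dynamic program for
local affine-gap alignment, exhaustive pairwise concordance for ROC-AUC,
an exhaustive threshold scan for the balanced-accuracy cutoff, a
quadratic all-pairs matched-molecular-pair search built on its own bond
deletion routine, and union-find for connected components.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices
from rdkit import Chem

NEG_INF = float("-inf")


def sw_affine_score(a: str, b: str, matrix_name: str = "BLOSUM62",
                    gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Local alignment score by the three-state (match / gap-in-a /
    gap-in-b) dynamic program.  A gap of length k costs
    gap_open + (k - 1) * gap_extend.  Score floor is the empty alignment, 0."""
    mat = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (a advances)
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (b advances)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = prev + s
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def pairwise_auc(labels, scores) -> float:
    """Exhaustive Mann–Whitney concordance: ties count one half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = len(pos) * len(neg)
    if total == 0:
        raise ValueError("both classes required")
    conc = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                conc += 1.0
            elif p == q:
                conc += 0.5
    return conc / total


def best_ba_scan(labels, scores) -> tuple[float, float]:
    """Balanced accuracy maximized over every distinct operating point:
    candidate cutoffs are midpoints of consecutive distinct scores plus
    the endpoints 0 and 1; ties return the smallest cutoff."""
    distinct = sorted(set(scores))
    candidates = [0.0] + [
        (x + y) / 2 for x, y in zip(distinct[:-1], distinct[1:])
    ] + [1.0]
    n_pos = sum(1 for y in labels if y == 1)
    n_neg = len(labels) - n_pos
    best_c, best_ba = 0.0, -1.0
    for c in candidates:
        tp = sum(1 for y, s in zip(labels, scores) if y == 1 and s > c)
        tn = sum(1 for y, s in zip(labels, scores) if y == 0 and s <= c)
        ba = (tp / n_pos + tn / n_neg) / 2
        if ba > best_ba + 1e-12:
            best_c, best_ba = c, ba
    return best_c, best_ba


def _single_cuts(smiles: str, max_frac: float, max_atoms: int):
    """All (core, substituent) single-bond fragmentations via explicit
    RWMol bond deletion (independent of FragmentOnBonds)."""
    mol = Chem.MolFromSmiles(smiles)
    parent_heavy = mol.GetNumHeavyAtoms()
    cuts = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        ai, bi = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        rw = Chem.RWMol(mol)
        rw.RemoveBond(ai, bi)
        for idx in (ai, bi):
            dummy = rw.AddAtom(Chem.Atom(0))
            rw.AddBond(idx, dummy, Chem.BondType.SINGLE)
        pieces = Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=False)
        if len(pieces) != 2:
            continue
        frags = sorted(Chem.MolToSmiles(p) for p in pieces)

        def heavy(smi):
            m = Chem.MolFromSmiles(smi)
            return sum(1 for at in m.GetAtoms() if at.GetAtomicNum() > 0)

        h0, h1 = heavy(frags[0]), heavy(frags[1])
        if h0 > h1 or (h0 == h1 and frags[0] < frags[1]):
            core, sub, sub_h = frags[0], frags[1], h1
        else:
            core, sub, sub_h = frags[1], frags[0], h0
        if sub_h > max_atoms or sub_h > max_frac * parent_heavy:
            continue
        cuts.add((core, sub))
    return cuts


def quadratic_mmps(compounds, max_frac: float = 0.33, max_atoms: int = 13):
    """All-pairs, all-cut-combination MMP search; one (a, b, core) triple
    per shared core with differing substituents."""
    cut_sets = {c.id: _single_cuts(c.smiles, max_frac, max_atoms) for c in compounds}
    found = set()
    for ca, cb in itertools.combinations(sorted(cut_sets), 2):
        for (core_a, sub_a) in cut_sets[ca]:
            for (core_b, sub_b) in cut_sets[cb]:
                if core_a == core_b and sub_a != sub_b:
                    found.add((ca, cb, core_a))
    return found


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[rx] = ry

    def n_components(self):
        return len({self.find(x) for x in self.parent})
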