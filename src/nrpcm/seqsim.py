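"""Protein-similarity descriptors from local sequence alignment.

A query nuclear receptor is described by its normalized Smith-Waterman
similarity against every member of a fixed reference panel (30 receptors by
default), yielding one bounded similarity score per panel member.  Two
receptors with similar ligand-binding domains get similar descriptor
vectors, which is what lets a single proteochemometric model generalize
across the receptor family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity codes that BLOSUM-style matrices define rows for.
AMBIGUITY_AA = set("BZX")


class SequenceError(ValueError):
    """Raised for malformed protein sequences or FASTA records."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence over the canonical 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("protein sequence requires a non-empty id")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - CANONICAL_AA - AMBIGUITY_AA
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains illegal residue(s) "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_ambiguity(self) -> bool:
        return bool(set(self.residues) & AMBIGUITY_AA)


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap local alignment parameters.

    A gap of length ``k`` is penalized ``gap_open + (k - 1) * gap_extend``.
    Defaults follow the EMBOSS ``water`` convention (BLOSUM62, 10 / 0.5).
    ``allow_ambiguity`` maps B/Z/X through the matrix's ambiguity rows
    instead of rejecting them.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    allow_ambiguity: bool = False

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    def matrix(self):
        return substitution_matrices.load(self.substitution_matrix)


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class ReferencePanel:
    """Ordered reference receptor set defining the descriptor axes.

    Member order is part of the model contract: descriptor component ``i``
    always refers to ``members[i]``, and a trained model serializes the
    panel so featurization is reproducible bit-for-bit.
    """

    members: tuple[ProteinSequence, ...]
    name: str = "panel"
    version: str = "0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise SequenceError("reference panel must not be empty")
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate panel member id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def member(self, target_id: str) -> ProteinSequence:
        for m in self.members:
            if m.id == target_id:
                return m
        raise KeyError(f"no panel member with id {target_id!r}")


@dataclass(frozen=True)
class ProteinDescriptor:
    """Normalized similarity of one query against every panel member."""

    values: np.ndarray
    panel_name: str
    member_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("descriptor values must be one-dimensional")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file.

    Record ids are the header up to the first whitespace; residues are
    upper-cased.  Empty files, empty sequences, duplicate ids, and illegal
    residue characters raise :class:`SequenceError` naming the record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            out.append(ProteinSequence(rec.id, str(rec.seq)))
        except SequenceError as exc:
            raise SequenceError(f"{path}: record {rec.id!r}: {exc}") from exc
    return out


def read_panel(
    path: str | Path, name: str | None = None, version: str = "0"
) -> ReferencePanel:
    """Read a FASTA file as an ordered :class:`ReferencePanel`."""
    seqs = read_fasta(path)
    return ReferencePanel(tuple(seqs), name=name or Path(path).stem, version=version)


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = params.matrix()
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_alphabet(seq: ProteinSequence, params: AlignmentParams) -> None:
    if seq.has_ambiguity and not params.allow_ambiguity:
        raise SequenceError(
            f"sequence {seq.id!r} contains ambiguity codes; set "
            "allow_ambiguity=True to score them through the matrix"
        )


def smith_waterman_score(
    a: ProteinSequence, b: ProteinSequence, params: AlignmentParams = DEFAULT_PARAMS
) -> float:
    """Maximum local-alignment score of ``a`` vs ``b`` under affine gaps.

    Symmetric and non-negative; zero exactly when no residue pair scores
    positively under the substitution matrix.
    """
    _check_alphabet(a, params)
    _check_alphabet(b, params)
    aligner = _aligner(params)
    try:
        return float(aligner.score(a.residues, b.residues))
    except ValueError as exc:  # residue outside the matrix alphabet
        raise SequenceError(f"cannot align {a.id!r} vs {b.id!r}: {exc}") from exc


def normalized_similarity(
    a: ProteinSequence, b: ProteinSequence, params: AlignmentParams = DEFAULT_PARAMS
) -> float:
    """Self-score-normalized local-alignment similarity in [0, 1].

    ``SW(a,b) / sqrt(SW(a,a) * SW(b,b))`` — symmetric, 1.0 at identity,
    0.0 when the two sequences share no positively scoring residue pair.
    """
    saa = smith_waterman_score(a, a, params)
    sbb = smith_waterman_score(b, b, params)
    if saa <= 0 or sbb <= 0:
        degenerate = a.id if saa <= 0 else b.id
        raise SequenceError(
            f"sequence {degenerate!r} has non-positive self-score under "
            f"{params.substitution_matrix}; similarity undefined"
        )
    sab = smith_waterman_score(a, b, params)
    return min(1.0, sab / math.sqrt(saa * sbb))


def protein_descriptor(
    query: ProteinSequence,
    panel: ReferencePanel,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> ProteinDescriptor:
    """Normalized similarity of ``query`` against each panel member, in order."""
    values = np.empty(len(panel), dtype=float)
    for i, member in enumerate(panel.members):
        try:
            values[i] = normalized_similarity(query, member, params)
        except SequenceError as exc:
            raise SequenceError(
                f"panel member {member.id!r} (position {i}): {exc}"
            ) from exc
    return ProteinDescriptor(values, panel.name, tuple(panel.ids))


def panel_descriptor_matrix(
    targets: Sequence[ProteinSequence],
    panel: ReferencePanel,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> dict[str, np.ndarray]:
    """Descriptors for many targets keyed by target id (computed once each)."""
    return {t.id: protein_descriptor(t, panel, params).values for t in targets}
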