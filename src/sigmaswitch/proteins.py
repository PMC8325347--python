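"""Detection and classification of the c-di-GMP binding signature in anti-sigma proteins.

The signature is the degenerate pattern ``E(X)3 S(X)2 R(X)3 [Q/H](X)3 D``: five
anchor residues (Glu, Ser, Arg, Gln-or-His, Asp) at fixed spacings on one face of
an alpha-helix, which together coordinate an intercalated c-di-GMP dimer.
Ancestral anti-sigma factors carry one copy of this helix and homodimerise;
derived ones carry two copies on a single chain (an internal duplication) and
act as monomers.  Counting signature copies per protein therefore separates the
two architectural classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InputError

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: zero-based offsets of the five anchors within the 16-residue signature span
ANCHOR_OFFSETS = (0, 4, 7, 11, 15)
MOTIF_SPAN = 16


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence in one-letter code (the 20 standard residues plus X)."""

    id: str
    sequence: str


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of the c-di-GMP binding signature.

    ``start`` is the 1-based position of the Glu anchor; ``anchors`` are the
    1-based positions of E, S, R, Q/H and D; ``variant`` records whether the
    fourth anchor is the canonical glutamine or the histidine replacement.
    """

    protein_id: str
    start: int
    anchors: tuple[int, int, int, int, int]
    variant: str  # "Q" | "H"


@dataclass(frozen=True)
class MotifClass:
    """Architectural class of a protein derived from its signature count."""

    value: str  # none | single | twin | multi
    hit_count: int


def _validate_sequence(record: ProteinRecord) -> None:
    for pos, ch in enumerate(record.sequence, start=1):
        if ch not in AA_ALPHABET:
            raise InputError(
                f"protein {record.id!r}: invalid character {ch!r} at position {pos}"
            )


def scan_cdg_motif(protein: ProteinRecord, allow_his: bool = True) -> list[MotifHit]:
    """Report every placement of the c-di-GMP binding signature in a protein.

    Anchors must match exactly (E, S, R, D strict; the Q position accepts H
    when ``allow_his`` is set, mirroring the frequent Gln->His replacement at
    that anchor).  Wildcard positions accept any residue including X; X at an
    anchor never matches.  Overlapping placements are all reported, sorted by
    start position.
    """
    _validate_sequence(protein)
    seq = protein.sequence
    q_allowed = "QH" if allow_his else "Q"
    hits: list[MotifHit] = []
    for i in range(len(seq) - MOTIF_SPAN + 1):
        if (
            seq[i] == "E"
            and seq[i + 4] == "S"
            and seq[i + 7] == "R"
            and seq[i + 11] in q_allowed
            and seq[i + 15] == "D"
        ):
            start = i + 1
            hits.append(
                MotifHit(
                    protein_id=protein.id,
                    start=start,
                    anchors=tuple(start + off for off in ANCHOR_OFFSETS),
                    variant=seq[i + 11],
                )
            )
    return hits


def classify_by_motif_count(hits: Sequence[MotifHit]) -> MotifClass:
    """Map a protein's signature count onto its architectural class.

    0 -> none, 1 -> single (ancestral homodimer candidate), 2 -> twin
    (derived monomer), >2 -> multi.  All hits must come from one protein.
    """
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise InputError(f"hits from multiple proteins: {sorted(ids)}")
    n = len(hits)
    if n == 0:
        value = "none"
    elif n == 1:
        value = "single"
    elif n == 2:
        value = "twin"
    else:
        value = "multi"
    return MotifClass(value=value, hit_count=n)


def classify_proteins(
    proteins: Iterable[ProteinRecord], allow_his: bool = True
) -> dict[str, MotifClass]:
    """Scan and classify a collection of proteins in one pass."""
    return {
        p.id: classify_by_motif_count(scan_cdg_motif(p, allow_his=allow_his))
        for p in proteins
    }
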