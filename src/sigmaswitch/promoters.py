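"""Two-box promoter scanning for flagellar-type sigma factors.

Flagellar-clade sigma factors (sigma-28/WhiG family) recognise a bipartite
promoter: a -35 box (consensus TAAA) and a -10 box (consensus GCCGATAA)
separated by a spacer.  The scan enumerates, on both strands of intergenic
DNA, every placement of the two boxes with a spacer inside a configured
window and a pooled mismatch budget across both boxes, then links each match
to the nearest co-directional downstream gene and discards matches lying too
far from a start codon.

Coordinates follow the package convention: 1-based inclusive, reported on the
forward strand regardless of match orientation.  For a minus-strand match the
-10 box's 3' end is therefore its *leftmost* forward coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .genome_io import GeneFeature, GenomeRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_BOX35 = "TAAA"
DEFAULT_BOX10 = "GCCGATAA"
DEFAULT_SPACER_MIN = 13
DEFAULT_SPACER_MAX = 17
DEFAULT_MAX_MM = 2
DEFAULT_MAX_DIST = 200


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IntergenicRegion:
    """A maximal gene-free interval of a replicon (1-based inclusive)."""

    replicon_id: str
    start: int
    end: int
    left_gene: str | None
    right_gene: str | None


@dataclass(frozen=True)
class PromoterMatch:
    """One two-box consensus occurrence.

    Box coordinates are forward-strand 1-based inclusive spans; ``spacer`` is
    the nucleotide gap between the boxes on the match strand;
    ``matched_sequence`` reads 5'->3' on the match strand.
    """

    replicon_id: str
    strand: str
    box35_start: int
    box35_end: int
    box10_start: int
    box10_end: int
    spacer: int
    mm35: int
    mm10: int
    mm_total: int
    matched_sequence: str
    downstream_gene: str | None = None
    dist_to_start: int | None = None

    @property
    def box10_three_prime(self) -> int:
        """Forward coordinate of the -10 box's 3'-most base on the match strand."""
        return self.box10_end if self.strand == "+" else self.box10_start

    @property
    def five_prime(self) -> int:
        """Forward coordinate of the match's 5'-most base on the match strand."""
        return self.box35_start if self.strand == "+" else self.box35_end


def count_mismatches(word: str, reference: str) -> int:
    """Hamming distance; an ambiguous N in the word counts as a mismatch."""
    if len(word) != len(reference):
        raise InputError(
            f"length mismatch: word {len(word)} vs reference {len(reference)}"
        )
    return sum(1 for a, b in zip(word, reference) if a != b or a == "N")


def extract_intergenic(
    genes: Sequence[GeneFeature], replicon: GenomeRecord
) -> list[IntergenicRegion]:
    """Maximal intervals of a replicon covered by no gene on either strand."""
    length = len(replicon)
    relevant = sorted(
        (g for g in genes if g.replicon_id == replicon.replicon_id),
        key=lambda g: (g.start, g.end),
    )
    for g in relevant:
        if not (1 <= g.start <= g.end <= length):
            raise InputError(
                f"gene {g.gene_id!r} [{g.start},{g.end}] outside replicon "
                f"{replicon.replicon_id!r} of length {length}"
            )
    regions: list[IntergenicRegion] = []
    cursor = 1  # first uncovered base
    left: str | None = None
    i = 0
    while i < len(relevant):
        # merge a run of overlapping/abutting genes
        g = relevant[i]
        block_start, block_end = g.start, g.end
        last_id = g.gene_id
        i += 1
        while i < len(relevant) and relevant[i].start <= block_end + 1:
            if relevant[i].end >= block_end:
                block_end = relevant[i].end
                last_id = relevant[i].gene_id
            i += 1
        if block_start > cursor:
            regions.append(
                IntergenicRegion(
                    replicon.replicon_id, cursor, block_start - 1, left, g.gene_id
                )
            )
        cursor = max(cursor, block_end + 1)
        left = last_id
    if cursor <= length:
        regions.append(IntergenicRegion(replicon.replicon_id, cursor, length, left, None))
    return regions


def _mismatch_profile(codes: np.ndarray, box: str) -> np.ndarray:
    """mm[i] = mismatches of box against codes[i:i+len(box)] (N always mismatches)."""
    n = len(codes) - len(box) + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    mm = np.zeros(n, dtype=np.int32)
    n_code = ord("N")
    for j, ch in enumerate(box):
        window = codes[j : j + n]
        mm += ((window != ord(ch)) | (window == n_code)).astype(np.int32)
    return mm


def scan_two_box(
    sequence: str,
    box35: str = DEFAULT_BOX35,
    box10: str = DEFAULT_BOX10,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
    max_mm: int = DEFAULT_MAX_MM,
    replicon_id: str = "region",
    offset: int = 1,
    strands: str = "+-",
    dedup: bool = True,
) -> list[PromoterMatch]:
    """Enumerate two-box matches in ``sequence`` (both strands by default).

    ``offset`` is the forward genomic coordinate of ``sequence[0]`` so that
    region scans report replicon coordinates directly.  With ``dedup`` on,
    matches whose -10 placements overlap on the same strand are collapsed to
    one representative (lowest mismatch total, then spacer closest to the
    window midpoint, then leftmost).
    """
    if not box35 or not box10:
        raise InputError("promoter boxes must be non-empty")
    if spacer_min > spacer_max:
        raise InputError(f"spacer_min {spacer_min} > spacer_max {spacer_max}")
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise InputError(f"non-DNA characters in sequence: {sorted(bad)}")

    l35, l10 = len(box35), len(box10)
    length = len(sequence)
    matches: list[PromoterMatch] = []

    for strand in strands:
        if strand not in "+-":
            raise InputError(f"unknown strand {strand!r}")
        seq = sequence if strand == "+" else reverse_complement(sequence)
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        mm35 = _mismatch_profile(codes, box35)
        mm10 = _mismatch_profile(codes, box10)
        for spacer in range(spacer_min, spacer_max + 1):
            window = l35 + spacer + l10
            n = length - window + 1
            if n <= 0:
                continue
            total = mm35[:n] + mm10[l35 + spacer : l35 + spacer + n]
            for i in np.nonzero(total <= max_mm)[0]:
                i = int(i)
                if strand == "+":
                    b35_start = offset + i
                    b10_start = offset + i + l35 + spacer
                else:
                    # index i on the reverse complement maps back to forward
                    # coordinates from the right-hand end of the region
                    b35_start = offset + (length - i - l35)
                    b10_start = offset + (length - i - window)
                matches.append(
                    PromoterMatch(
                        replicon_id=replicon_id,
                        strand=strand,
                        box35_start=b35_start,
                        box35_end=b35_start + l35 - 1,
                        box10_start=b10_start,
                        box10_end=b10_start + l10 - 1,
                        spacer=spacer,
                        mm35=int(mm35[i]),
                        mm10=int(mm10[i + l35 + spacer]),
                        mm_total=int(total[i]),
                        matched_sequence=seq[i : i + window],
                    )
                )
    if dedup:
        matches = dedup_matches(matches, spacer_min, spacer_max)
    matches.sort(key=lambda m: (m.box35_start, m.strand))
    return matches


def dedup_matches(
    matches: Sequence[PromoterMatch], spacer_min: int, spacer_max: int
) -> list[PromoterMatch]:
    """One promoter per site: collapse same-strand matches with overlapping -10 boxes.

    Preference order: lowest mismatch total, then spacer closest to the window
    midpoint, then leftmost -10 box.
    """
    mid = (spacer_min + spacer_max) / 2
    kept: list[PromoterMatch] = []
    ranked = sorted(
        matches,
        key=lambda m: (
            m.mm_total,
            abs(m.spacer - mid),
            m.box10_start,
            m.box35_start,
        ),
    )
    for m in ranked:
        clash = any(
            k.replicon_id == m.replicon_id
            and k.strand == m.strand
            and k.box10_start <= m.box10_end
            and m.box10_start <= k.box10_end
            for k in kept
        )
        if not clash:
            kept.append(m)
    return kept


def attach_downstream_and_filter(
    matches: Sequence[PromoterMatch],
    genes: Sequence[GeneFeature],
    max_dist: int = DEFAULT_MAX_DIST,
    anchor: str = "box10_3p",
) -> list[PromoterMatch]:
    """Link matches to the nearest co-directional downstream gene and filter by distance.

    The downstream gene is the nearest same-strand gene start in the direction
    of transcription with no other gene in between.  Distance is counted from
    the -10 box 3' end (or the match 5' end with ``anchor="match_5p"``) to the
    first codon base so that an immediately adjacent start codon gives 1.
    Matches with no qualifying gene or distance beyond ``max_dist`` are dropped.
    """
    if anchor not in ("box10_3p", "match_5p"):
        raise InputError(f"unknown distance anchor {anchor!r}")
    by_replicon: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_replicon.setdefault(g.replicon_id, []).append(g)
    for gl in by_replicon.values():
        gl.sort(key=lambda g: g.start)

    kept: list[PromoterMatch] = []
    for m in matches:
        gl = by_replicon.get(m.replicon_id, [])
        c = m.box10_three_prime if anchor == "box10_3p" else m.five_prime
        best: GeneFeature | None = None
        dist = None
        if m.strand == "+":
            cands = [g for g in gl if g.strand == "+" and g.start > c]
            if cands:
                best = min(cands, key=lambda g: g.start)
                dist = best.start - c
                lo, hi = c, best.start
        else:
            cands = [g for g in gl if g.strand == "-" and g.end < c]
            if cands:
                best = max(cands, key=lambda g: g.end)
                dist = c - best.end
                lo, hi = best.end, c
        if best is None:
            continue
        intervening = any(
            g is not best and g.start < hi and g.end > lo for g in gl
        )
        if intervening or dist > max_dist:
            continue
        kept.append(replace(m, downstream_gene=best.gene_id, dist_to_start=dist))
    return kept


def predict_promoters(
    genome: GenomeRecord,
    genes: Sequence[GeneFeature],
    box35: str = DEFAULT_BOX35,
    box10: str = DEFAULT_BOX10,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
    max_mm: int = DEFAULT_MAX_MM,
    max_dist: int = DEFAULT_MAX_DIST,
    anchor: str = "box10_3p",
    dedup: bool = True,
) -> list[PromoterMatch]:
    """Full promoter prediction on one replicon.

    Extracts intergenic regions, scans both strands of each for two-box
    matches, then links matches to downstream genes and applies the distance
    filter.  Circular replicons additionally scan the origin-spanning
    concatenation of the terminal intergenic intervals.
    """
    regions = extract_intergenic(genes, genome)
    matches: list[PromoterMatch] = []
    for region in regions:
        seq = genome.sequence[region.start - 1 : region.end]
        matches.extend(
            scan_two_box(
                seq,
                box35=box35,
                box10=box10,
                spacer_min=spacer_min,
                spacer_max=spacer_max,
                max_mm=max_mm,
                replicon_id=genome.replicon_id,
                offset=region.start,
                dedup=False,
            )
        )
    if (
        genome.topology == "circular"
        and len(regions) >= 2
        and regions[0].start == 1
        and regions[-1].end == len(genome)
    ):
        first, last = regions[0], regions[-1]
        joint = (
            genome.sequence[last.start - 1 : last.end]
            + genome.sequence[first.start - 1 : first.end]
        )
        window = len(box35) + spacer_max + len(box10)
        for m in scan_two_box(
            joint,
            box35=box35,
            box10=box10,
            spacer_min=spacer_min,
            spacer_max=spacer_max,
            max_mm=max_mm,
            replicon_id=genome.replicon_id,
            offset=last.start,
            dedup=False,
        ):
            # keep only origin-spanning placements; the rest were already found
            if m.box35_start <= len(genome) < m.box10_end or (
                m.strand == "-" and m.box10_start <= len(genome) < m.box35_end
            ):
                matches.append(_wrap_coordinates(m, len(genome)))
    if dedup:
        matches = dedup_matches(matches, spacer_min, spacer_max)
    matches = attach_downstream_and_filter(matches, genes, max_dist=max_dist, anchor=anchor)
    matches.sort(key=lambda m: (m.box35_start, m.strand))
    return matches


def _wrap_coordinates(m: PromoterMatch, length: int) -> PromoterMatch:
    def wrap(x: int) -> int:
        return ((x - 1) % length) + 1

    return replace(
        m,
        box35_start=wrap(m.box35_start),
        box35_end=wrap(m.box35_end),
        box10_start=wrap(m.box10_start),
        box10_end=wrap(m.box10_end),
    )


def matches_to_dataframe(matches: Iterable[PromoterMatch]) -> pd.DataFrame:
    cols = [
        "replicon_id",
        "strand",
        "box35_start",
        "box35_end",
        "box10_start",
        "box10_end",
        "spacer",
        "mm35",
        "mm10",
        "mm_total",
        "downstream_gene",
        "dist_to_start",
        "matched_sequence",
    ]
    return pd.DataFrame(
        [{c: getattr(m, c) for c in cols} for m in matches], columns=cols
    )
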