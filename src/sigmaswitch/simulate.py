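"""Synthetic genomes, TSS tables, protein sets and toy coordinates with ground truth.

Every generator is fully determined by its seed and writes a machine-readable
ledger of what was planted, so each pipeline stage can be tested for exact
recovery without downloading any real data.  Background DNA is i.i.d. at a
configurable GC fraction (Rubrobacter-like genomes are GC-rich, which raises
the background two-box hit rate); a rejection step rewrites any background
window that happens to satisfy the promoter scan's constraints, so the planted
truth is exhaustive and recovery tests can be exact rather than probabilistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError, InputError
from .genome_io import GeneFeature, GenomeRecord, TSSRecord
from .proteins import ANCHOR_OFFSETS, MOTIF_SPAN, ProteinRecord, scan_cdg_motif
from .promoters import (
    DEFAULT_BOX10,
    DEFAULT_BOX35,
    DEFAULT_MAX_DIST,
    DEFAULT_MAX_MM,
    DEFAULT_SPACER_MAX,
    DEFAULT_SPACER_MIN,
    PromoterMatch,
    extract_intergenic,
    reverse_complement,
    scan_two_box,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PromoterDesign:
    """Design of one planted two-box element.

    ``dist`` is the gap from the -10 box 3' end to the downstream gene's first
    codon base (1 = immediately adjacent); ``kind`` is ``promoter`` for
    elements meant to look real and ``decoy`` for elements planted with three
    or more mismatches.
    """

    mm35: int = 0
    mm10: int = 0
    spacer: int = 15
    dist: int = 50
    strand: str = "+"
    kind: str = "promoter"

    @property
    def mm_total(self) -> int:
        return self.mm35 + self.mm10


@dataclass(frozen=True)
class PlantedElement:
    kind: str  # promoter | decoy | motif | tss
    replicon_id: str
    strand: str
    box35_start: int
    box10_start: int
    box10_end: int
    spacer: int
    mm35: int
    mm10: int
    dist: int
    gene_id: str
    expected_recovery: bool


@dataclass
class PlantedTruth:
    """Ground-truth ledger for one simulated replicon."""

    replicon_id: str
    replicon_length: int
    elements: list[PlantedElement] = field(default_factory=list)

    def promoters(self) -> list[PlantedElement]:
        return [e for e in self.elements if e.kind in ("promoter", "decoy")]

    def expected(self) -> list[PlantedElement]:
        return [e for e in self.elements if e.expected_recovery]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "kind",
            "replicon_id",
            "strand",
            "box35_start",
            "box10_start",
            "box10_end",
            "spacer",
            "mm35",
            "mm10",
            "dist",
            "gene_id",
            "expected_recovery",
        ]
        return pd.DataFrame(
            [{c: getattr(e, c) for c in cols} for e in self.elements], columns=cols
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SimulationSpec:
    """Layout and per-element design of one synthetic replicon.

    Genes of fixed length alternate with intergenic gaps; each promoter design
    is planted in the gap upstream of its own gene, at its designed distance,
    spacer and per-box mismatch counts.  ``scan_*`` record the scan settings
    from which each element's expected-recovery flag is computed.
    """

    seed: int
    replicon_id: str = "sim1"
    gc: float = 0.67
    gene_length: int = 900
    gap_length: int = 400
    n_genes: int | None = None
    promoters: tuple[PromoterDesign, ...] = ()
    box35: str = DEFAULT_BOX35
    box10: str = DEFAULT_BOX10
    scan_spacer_min: int = DEFAULT_SPACER_MIN
    scan_spacer_max: int = DEFAULT_SPACER_MAX
    scan_max_mm: int = DEFAULT_MAX_MM
    scan_max_dist: int = DEFAULT_MAX_DIST

    def expected_recovery(self, design: PromoterDesign) -> bool:
        return (
            design.mm_total <= self.scan_max_mm
            and self.scan_spacer_min <= design.spacer <= self.scan_spacer_max
            and 1 <= design.dist <= self.scan_max_dist
        )


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _mutate_box(rng: np.random.Generator, box: str, n_mm: int) -> str:
    if n_mm > len(box):
        raise GenerationError(f"cannot place {n_mm} mismatches in a {len(box)}-nt box")
    positions = rng.choice(len(box), size=n_mm, replace=False)
    out = list(box)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != box[p]])
    return "".join(out)


def generate_genome(
    spec: SimulationSpec,
) -> tuple[GenomeRecord, list[GeneFeature], PlantedTruth]:
    """Build a replicon with planted promoters/decoys and an exhaustive truth ledger.

    The background is scrubbed so that, within intergenic DNA, every placement
    satisfying the configured scan constraints lies at a planted site (its -10
    box overlaps a planted one on the same strand); after dedup the scan
    therefore emits exactly one match per recoverable planted site.
    """
    rng = np.random.default_rng(spec.seed)
    designs = list(spec.promoters)
    n_genes = spec.n_genes if spec.n_genes is not None else max(len(designs), 1)
    if n_genes < len(designs):
        raise GenerationError(
            f"{len(designs)} promoter designs need at least that many genes, "
            f"got n_genes={n_genes}"
        )
    def extent(d: PromoterDesign) -> int:
        return d.dist + len(spec.box35) + d.spacer + len(spec.box10)

    for d in designs:
        if extent(d) > spec.gap_length:
            raise GenerationError(
                f"design {d} needs {extent(d)} nt of intergenic space, "
                f"gap is {spec.gap_length}"
            )
        if d.kind == "decoy" and d.mm_total < 3:
            raise GenerationError(f"decoy must carry >= 3 mismatches, got {d.mm_total}")
    # a '-' element of gene i and a '+' element of gene i+1 share one gap:
    # their planted windows must not collide
    for i in range(len(designs) - 1):
        left, right = designs[i], designs[i + 1]
        if left.strand == "-" and right.strand == "+":
            if extent(left) + extent(right) > spec.gap_length:
                raise GenerationError(
                    f"designs for genes {i + 1} and {i + 2} collide in their "
                    f"shared {spec.gap_length}-nt gap "
                    f"({extent(left)} + {extent(right)} nt needed)"
                )

    length = n_genes * (spec.gap_length + spec.gene_length) + spec.gap_length
    seq = _random_dna(rng, length, spec.gc)
    genes: list[GeneFeature] = []
    truth = PlantedTruth(replicon_id=spec.replicon_id, replicon_length=length)

    # gene i occupies [gap + i*(gap+gene) + 1 .. + gene_length] (1-based)
    for i in range(n_genes):
        start = spec.gap_length + i * (spec.gap_length + spec.gene_length) + 1
        end = start + spec.gene_length - 1
        design = designs[i] if i < len(designs) else None
        strand = design.strand if design is not None else rng.choice(["+", "-"])
        gene_id = f"g{i + 1:04d}"
        genes.append(
            GeneFeature(
                gene_id=gene_id,
                replicon_id=spec.replicon_id,
                start=start,
                end=end,
                strand=strand,
            )
        )
        if design is None:
            continue
        box35 = _mutate_box(rng, spec.box35, design.mm35)
        box10 = _mutate_box(rng, spec.box10, design.mm10)
        l35, l10 = len(spec.box35), len(spec.box10)
        if design.strand == "+":
            # -10 3' end at gene.start - dist; element extends leftwards
            b10_end = start - design.dist
            b10_start = b10_end - l10 + 1
            b35_start = b10_start - design.spacer - l35
            planted = box35 + _decode(seq[b35_start + l35 - 1 : b10_start - 1]) + box10
            seq[b35_start - 1 : b10_end] = np.frombuffer(
                planted.encode(), dtype=np.uint8
            )
        else:
            # gene on '-': first codon base is gene.end; promoter lies to the right
            b10_start = end + design.dist
            b10_end = b10_start + l10 - 1
            b35_start = b10_end + design.spacer + 1
            fwd = reverse_complement(box10)  # -10 box leftmost on forward strand
            spacer_bases = _decode(seq[b10_end : b35_start - 1])
            planted = fwd + spacer_bases + reverse_complement(box35)
            seq[b10_start - 1 : b35_start + l35 - 1] = np.frombuffer(
                planted.encode(), dtype=np.uint8
            )
        truth.elements.append(
            PlantedElement(
                kind=design.kind,
                replicon_id=spec.replicon_id,
                strand=design.strand,
                box35_start=b35_start,
                box10_start=b10_start,
                box10_end=b10_end,
                spacer=design.spacer,
                mm35=design.mm35,
                mm10=design.mm10,
                dist=design.dist,
                gene_id=gene_id,
                expected_recovery=spec.expected_recovery(design)
                if design.kind == "promoter"
                else False,
            )
        )

    genome = GenomeRecord(spec.replicon_id, _decode(seq))
    if truth.promoters():
        # with nothing planted the replicon is a pure background (null) model
        genome = _scrub_background(genome, genes, truth, spec, rng)
    return genome, genes, truth


def _decode(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


def _is_planted(m: PromoterMatch, truth: PlantedTruth) -> bool:
    return any(
        e.strand == m.strand
        and e.box35_start == m.box35_start
        and e.box10_start == m.box10_start
        for e in truth.promoters()
    )


def overlaps_planted_site(m: PromoterMatch, truth: PlantedTruth) -> bool:
    """True when the match's -10 box overlaps a planted same-strand element's.

    Overlapping placements are one promoter *site*: a planted element may tie
    with a slightly shifted registration of itself within the mismatch budget,
    and the scan's dedup keeps exactly one of them.  Site identity, not exact
    registration, is therefore the recovery criterion.
    """
    return any(
        e.strand == m.strand
        and e.box10_start <= m.box10_end
        and m.box10_start <= e.box10_end
        for e in truth.promoters()
    )


def _protected_variant(
    m: PromoterMatch, truth: PlantedTruth, spec: SimulationSpec
) -> bool:
    """A shifted registration of a planted site whose outcome matches the plan.

    The scan reports slightly shifted registrations of a planted element
    within the mismatch budget, and dedup keeps one per site.  A variant is
    harmless -- and is left alone -- exactly when its own distance to the
    element's gene leads to the same keep/drop decision the element was
    designed for: in-range variants of recoverable sites preserve recovery;
    out-of-range variants of non-recoverable sites are filtered anyway.  Any
    variant that would flip the designed outcome is an offender to scrub.
    """
    for e in truth.elements:
        if e.kind not in ("promoter", "decoy"):
            continue
        if e.strand != m.strand:
            continue
        if not (e.box10_start <= m.box10_end and m.box10_start <= e.box10_end):
            continue
        if e.strand == "+":
            dist_m = (e.box10_end + e.dist) - m.box10_end
        else:
            dist_m = m.box10_start - (e.box10_start - e.dist)
        if (1 <= dist_m <= spec.scan_max_dist) == e.expected_recovery:
            return True
    return False


_COMPLEMENT_CHAR = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _forward_consensus(m: PromoterMatch, p: int, box35: str, box10: str) -> str:
    """Consensus base, on the forward strand, at forward coordinate p of a match."""
    if m.strand == "+":
        if m.box35_start <= p <= m.box35_end:
            return box35[p - m.box35_start]
        return box10[p - m.box10_start]
    if m.box35_start <= p <= m.box35_end:
        return _COMPLEMENT_CHAR[box35[m.box35_end - p]]
    return _COMPLEMENT_CHAR[box10[m.box10_end - p]]


def _scrub_background(
    genome: GenomeRecord,
    genes: Sequence[GeneFeature],
    truth: PlantedTruth,
    spec: SimulationSpec,
    rng: np.random.Generator,
    max_iter: int = 100,
) -> GenomeRecord:
    boxed = set()
    for e in truth.promoters():
        boxed.update(range(e.box35_start, e.box35_start + len(spec.box35)))
        boxed.update(range(e.box10_start, e.box10_end + 1))
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    regions = extract_intergenic(genes, genome)
    for _ in range(max_iter):
        offenders = []
        for region in regions:
            for m in scan_two_box(
                _decode(seq[region.start - 1 : region.end]),
                box35=spec.box35,
                box10=spec.box10,
                spacer_min=spec.scan_spacer_min,
                spacer_max=spec.scan_spacer_max,
                max_mm=spec.scan_max_mm,
                replicon_id=spec.replicon_id,
                offset=region.start,
                dedup=False,
            ):
                if _is_planted(m, truth) or _protected_variant(m, truth, spec):
                    continue
                offenders.append(m)
        if not offenders:
            return GenomeRecord(genome.replicon_id, _decode(seq), genome.topology)
        for m in offenders:
            positions = list(range(m.box35_start, m.box35_end + 1)) + list(
                range(m.box10_start, m.box10_end + 1)
            )
            free = [p for p in positions if p not in boxed]
            if not free:
                raise GenerationError(
                    f"cannot scrub background match at {m.box35_start} without "
                    "touching a planted element"
                )
            p = free[rng.integers(len(free))]
            current = chr(seq[p - 1])
            cons = _forward_consensus(m, p, spec.box35, spec.box10)
            choices = [b for b in "ACGT" if b != current and b != cons]
            seq[p - 1] = ord(rng.choice(choices))
    raise GenerationError(f"background scrub did not converge in {max_iter} iterations")


def generate_tss(
    truth: PlantedTruth,
    in_window_fraction: float,
    spurious_rate: float,
    seed: int,
    offset_min: int = 2,
    offset_max: int = 12,
    exact_fraction: bool = False,
    in_window_genes: Sequence[str] | None = None,
) -> tuple[list[TSSRecord], dict[str, bool]]:
    """Emit a TSS table for a simulated replicon.

    Each planted (non-decoy) promoter receives an in-window TSS with
    probability ``in_window_fraction`` (for an exact rounded count with
    ``exact_fraction``, or for a designated gene set with ``in_window_genes``);
    the rest get an out-of-window TSS or none.  Spurious starts are added at a
    Poisson-distributed count with mean ``spurious_rate`` per kb of replicon.
    Returns the table and a map gene_id -> whether its promoter received an
    in-window TSS.
    """
    if not (0.0 <= in_window_fraction <= 1.0):
        raise InputError(f"in_window_fraction {in_window_fraction} outside [0,1]")
    if not (0.0 <= spurious_rate <= 1.0):
        raise InputError(f"spurious_rate {spurious_rate} outside [0,1]")
    rng = np.random.default_rng(seed)
    promoters = [e for e in truth.elements if e.kind == "promoter"]
    if not promoters:
        raise InputError("truth ledger contains no planted promoters")
    if in_window_genes is not None:
        wanted = set(in_window_genes)
        unknown = wanted - {e.gene_id for e in promoters}
        if unknown:
            raise InputError(f"in_window_genes not in truth ledger: {sorted(unknown)}")
        in_window = [e.gene_id in wanted for e in promoters]
    elif exact_fraction:
        k = int(round(in_window_fraction * len(promoters)))
        chosen = set(rng.permutation(len(promoters))[:k].tolist())
        in_window = [i in chosen for i in range(len(promoters))]
    else:
        in_window = (rng.random(len(promoters)) < in_window_fraction).tolist()

    records: list[TSSRecord] = []
    flags: dict[str, bool] = {}
    for e, flag in zip(promoters, in_window):
        flags[e.gene_id] = bool(flag)
        anchor = e.box10_end if e.strand == "+" else e.box10_start
        if flag:
            off = int(rng.integers(offset_min, offset_max + 1))
        else:
            if rng.random() < 0.5:
                continue  # no TSS at all
            off = int(rng.integers(offset_max + 13, offset_max + 41))
        pos = anchor + off if e.strand == "+" else anchor - off
        if not (1 <= pos <= truth.replicon_length):
            continue
        records.append(
            TSSRecord(
                replicon_id=truth.replicon_id,
                position=pos,
                strand=e.strand,
                read_count=int(rng.integers(5, 100)),
            )
        )
    n_spurious = rng.poisson(spurious_rate * truth.replicon_length / 1000.0)
    for _ in range(n_spurious):
        records.append(
            TSSRecord(
                replicon_id=truth.replicon_id,
                position=int(rng.integers(1, truth.replicon_length + 1)),
                strand=str(rng.choice(["+", "-"])),
                read_count=int(rng.integers(1, 20)),
            )
        )
    records.sort(key=lambda t: t.position)
    return records, flags


def generate_protein_set(
    n: int,
    motif_counts: Sequence[int] | None = None,
    length: int = 150,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Proteins with the c-di-GMP signature planted a designed number of times.

    ``motif_counts`` lists the per-protein copy number (0, 1 or 2, cycled if
    shorter than ``n``); by default a 0/1/2 mixture.  Backgrounds are uniform
    over the 20 standard residues, with a rejection step that rewrites any
    accidental signature so the planted counts are exact.  Returns the records
    and a gene->count truth map.
    """
    rng = np.random.default_rng(seed)
    if motif_counts is None:
        motif_counts = [0, 1, 2]
    counts = [motif_counts[i % len(motif_counts)] for i in range(n)]
    if any(c not in (0, 1, 2) for c in counts):
        raise InputError("motif counts must be 0, 1 or 2")
    if length < MOTIF_SPAN * 2 + 4:
        raise InputError(f"length {length} too short for two non-overlapping motifs")

    records: list[ProteinRecord] = []
    truth: dict[str, int] = {}
    aa = np.array(list(AA20))
    for i, count in enumerate(counts):
        pid = f"prot{i + 1:04d}"
        seq = rng.choice(aa, size=length).tolist()
        # non-overlapping anchor starts in the two halves of the sequence
        if count == 1:
            starts = [int(rng.integers(0, length - MOTIF_SPAN + 1))]
        elif count == 2:
            half = length // 2
            starts = [
                int(rng.integers(0, half - MOTIF_SPAN + 1)),
                int(rng.integers(half, length - MOTIF_SPAN + 1)),
            ]
        else:
            starts = []
        anchor_positions = set()
        for s in starts:
            variant = rng.choice(["Q", "H"])
            for off, res in zip(ANCHOR_OFFSETS, ("E", "S", "R", variant, "D")):
                seq[s + off] = res
                anchor_positions.add(s + off)
        # rejection: break any signature placement that was not designed
        for _ in range(50):
            hits = scan_cdg_motif(ProteinRecord(pid, "".join(seq)))
            extra = [h for h in hits if h.start - 1 not in starts]
            if not extra:
                break
            for h in extra:
                cands = [p - 1 for p in h.anchors if p - 1 not in anchor_positions]
                if not cands:
                    raise GenerationError(
                        f"{pid}: accidental signature at {h.start} shares all anchors "
                        "with planted motifs"
                    )
                p = cands[int(rng.integers(len(cands)))]
                current = seq[p]
                choices = [c for c in AA20 if c not in ("E", "S", "R", "Q", "H", "D", current)]
                seq[p] = str(rng.choice(choices))
        else:
            raise GenerationError(f"{pid}: motif rejection did not converge")
        records.append(ProteinRecord(pid, "".join(seq)))
        truth[pid] = count
    return records, truth


def generate_helix_coordinates(
    n_res: int, rise: float = 1.5, twist: float = 100.0, radius: float = 2.3
) -> np.ndarray:
    """Calpha trace of an ideal alpha-helix along +z (twist in degrees/residue)."""
    if n_res < 4:
        raise InputError(f"need at least 4 residues, got {n_res}")
    i = np.arange(n_res)
    theta = np.deg2rad(twist) * i
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * i]
    )
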