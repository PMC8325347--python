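"""Validation of predicted promoters against mapped transcription start sites.

A predicted two-box promoter is accepted as genuine when a mapped TSS of the
same strand sits a short, configurable distance downstream of its -10 box:
for this promoter class the +1 base typically falls a handful of nucleotides
past the -10 element.  Validated promoters are then tallied per user-defined
gene cluster (e.g. a type IV pilus cluster) to summarise which operons the
sigma factor likely drives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import InputError
from .genome_io import GeneFeature, TSSRecord
from .promoters import PromoterMatch


@dataclass(frozen=True)
class ValidatedPromoter:
    """A promoter prediction paired with its supporting TSS."""

    match: PromoterMatch
    tss: TSSRecord
    offset: int  # nt from -10 box 3' end to the +1 base, on the match strand


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: str
    gene_ids: frozenset[str]
    n_validated_promoters: int
    promoters: tuple[ValidatedPromoter, ...]


def validate_promoters(
    matches: Sequence[PromoterMatch],
    tss_records: Sequence[TSSRecord],
    offset_min: int = 2,
    offset_max: int = 12,
    min_reads: int = 1,
) -> list[ValidatedPromoter]:
    """Pair promoter matches with appropriately positioned TSS.

    A match validates when at least one same-strand TSS with at least
    ``min_reads`` reads lies ``offset_min..offset_max`` nt downstream of its
    -10 box 3' end (downstream = increasing coordinate on '+', decreasing on
    '-').  When several qualify the highest-read TSS is attached; ties break
    to the smallest offset.  Each match validates at most once.
    """
    if offset_min > offset_max:
        raise InputError(f"offset_min {offset_min} > offset_max {offset_max}")
    validated: list[ValidatedPromoter] = []
    for m in matches:
        anchor = m.box10_three_prime
        best: tuple[int, int, TSSRecord] | None = None  # (-reads, offset, tss)
        for t in tss_records:
            if t.replicon_id != m.replicon_id or t.strand != m.strand:
                continue
            if t.read_count < min_reads:
                continue
            offset = t.position - anchor if m.strand == "+" else anchor - t.position
            if offset_min <= offset <= offset_max:
                key = (-t.read_count, offset, t)
                if best is None or key[:2] < best[:2]:
                    best = key
        if best is not None:
            validated.append(ValidatedPromoter(match=m, tss=best[2], offset=best[1]))
    return validated


def summarize_by_cluster(
    validated: Sequence[ValidatedPromoter],
    cluster_defs: Mapping[str, Sequence[str]],
    known_genes: Sequence[GeneFeature] | None = None,
) -> list[ClusterSummary]:
    """Count validated promoters per gene cluster.

    ``cluster_defs`` maps cluster id to the gene ids it contains.  Promoters
    whose downstream gene belongs to no cluster are reported under
    ``unassigned``.  With ``known_genes`` given, cluster definitions naming
    unknown genes raise an input error.
    """
    if known_genes is not None:
        known = {g.gene_id for g in known_genes}
        for cid, gene_ids in cluster_defs.items():
            unknown = set(gene_ids) - known
            if unknown:
                raise InputError(
                    f"cluster {cid!r} names unknown gene ids {sorted(unknown)}"
                )
    assigned: dict[str, list[ValidatedPromoter]] = {cid: [] for cid in cluster_defs}
    unassigned: list[ValidatedPromoter] = []
    membership = {
        gene_id: cid for cid, gene_ids in cluster_defs.items() for gene_id in gene_ids
    }
    for vp in validated:
        cid = membership.get(vp.match.downstream_gene)
        if cid is None:
            unassigned.append(vp)
        else:
            assigned[cid].append(vp)
    summaries = [
        ClusterSummary(
            cluster_id=cid,
            gene_ids=frozenset(cluster_defs[cid]),
            n_validated_promoters=len(assigned[cid]),
            promoters=tuple(assigned[cid]),
        )
        for cid in cluster_defs
    ]
    summaries.append(
        ClusterSummary(
            cluster_id="unassigned",
            gene_ids=frozenset(),
            n_validated_promoters=len(unassigned),
            promoters=tuple(unassigned),
        )
    )
    return summaries


def validated_to_dataframe(validated: Sequence[ValidatedPromoter]) -> pd.DataFrame:
    rows = []
    for vp in validated:
        rows.append(
            {
                "replicon_id": vp.match.replicon_id,
                "strand": vp.match.strand,
                "box35_start": vp.match.box35_start,
                "box10_start": vp.match.box10_start,
                "downstream_gene": vp.match.downstream_gene,
                "dist_to_start": vp.match.dist_to_start,
                "tss_position": vp.tss.position,
                "tss_reads": vp.tss.read_count,
                "offset": vp.offset,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "replicon_id",
            "strand",
            "box35_start",
            "box10_start",
            "downstream_gene",
            "dist_to_start",
            "tss_position",
            "tss_reads",
            "offset",
        ],
    )
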