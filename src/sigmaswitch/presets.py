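"""Ready-made simulation setups emulating the study conditions.

The genome-scale analysis this package reimplements found, in *Rubrobacter
radiotolerans*, 20 intergenic two-box consensus matches within 200 bp of a
start codon, of which 12 sat just upstream of a mapped TSS and 3 fell inside
the type IV pilus gene cluster; a parallel scan of *R. xylanophilus* found 11
matches.  The motif survey classified 135 anti-sigma homologs, 130 with twin
c-di-GMP binding signatures and 5 with a single one.  These presets build
synthetic replicons and protein sets with exactly those planted compositions
so the full pipeline can be exercised end to end, offline, with known truth.
"""

from __future__ import annotations

import numpy as np

from .simulate import PromoterDesign, SimulationSpec

#: number of two-box promoters planted on the R. radiotolerans-like replicon
RR_N_PROMOTERS = 20
#: how many of those receive an in-window TSS
RR_N_VALIDATED = 12
#: how many validated promoters sit in the pil-like gene cluster
RR_N_PIL = 3
#: number of promoters planted on the R. xylanophilus-like replicon
RX_N_PROMOTERS = 11
#: homolog survey composition: twin-signature and single-signature proteins
N_TWIN_MOTIF = 130
N_SINGLE_MOTIF = 5


def _promoter_designs(
    rng: np.random.Generator, n: int, n_decoys: int, n_too_far: int
) -> tuple[PromoterDesign, ...]:
    """n recoverable designs with varied mismatches/spacers/distances, plus
    decoys (>=3 mismatches) and out-of-range plants that must be filtered."""
    designs = []
    for _ in range(n):
        mm35 = int(rng.integers(0, 2))
        mm10 = int(rng.integers(0, 3 - mm35))
        designs.append(
            PromoterDesign(
                mm35=mm35,
                mm10=mm10,
                spacer=int(rng.integers(13, 18)),
                dist=int(rng.integers(20, 200)),
                strand=str(rng.choice(["+", "-"])),
            )
        )
    for _ in range(n_decoys):
        designs.append(
            PromoterDesign(
                mm35=2,
                mm10=2,
                spacer=int(rng.integers(13, 18)),
                dist=int(rng.integers(20, 200)),
                strand=str(rng.choice(["+", "-"])),
                kind="decoy",
            )
        )
    for _ in range(n_too_far):
        designs.append(
            PromoterDesign(
                mm35=0,
                mm10=int(rng.integers(0, 3)),
                spacer=int(rng.integers(13, 18)),
                dist=int(rng.integers(201, 320)),
                strand=str(rng.choice(["+", "-"])),
            )
        )
    return tuple(designs)


def rr_like_spec(seed: int) -> SimulationSpec:
    """R. radiotolerans-like replicon: 20 recoverable promoters plus negatives."""
    rng = np.random.default_rng(seed)
    return SimulationSpec(
        seed=int(rng.integers(2**31)),
        replicon_id="rr_sim",
        gc=0.67,
        n_genes=40,
        gap_length=700,
        promoters=_promoter_designs(rng, RR_N_PROMOTERS, n_decoys=4, n_too_far=3),
    )


def run_study_emulation(seed: int) -> dict:
    """Run the full pipeline on the study-emulating simulations.

    Builds the two Rubrobacter-like replicons and the homolog protein set,
    then predicts promoters, validates them against a simulated TSS table
    (12 of the 20 recoverable promoters carry an in-window start), and tallies
    validated promoters in a pil-like gene cluster containing three of them.
    Returns the computed counts; nothing in the return value is read from the
    planted truth without passing through the pipeline.
    """
    from collections import Counter

    from . import promoters, proteins, simulate, tss

    rng = np.random.default_rng(seed)

    genome, genes, truth = simulate.generate_genome(rr_like_spec(seed))
    matches = promoters.predict_promoters(genome, genes)

    expected_genes = [e.gene_id for e in truth.expected()]
    with_tss = [
        expected_genes[i]
        for i in sorted(rng.permutation(len(expected_genes))[:RR_N_VALIDATED].tolist())
    ]
    tss_records, _flags = simulate.generate_tss(
        truth,
        in_window_fraction=0.0,
        spurious_rate=0.0,
        seed=int(rng.integers(2**31)),
        in_window_genes=with_tss,
    )
    validated = tss.validate_promoters(matches, tss_records)

    # pil-like cluster: the genes behind three of the TSS-supported promoters,
    # padded with their genomic neighbours
    pil_seed_genes = with_tss[:RR_N_PIL]
    order = {g.gene_id: i for i, g in enumerate(genes)}
    pil_genes = set(pil_seed_genes)
    for gid in pil_seed_genes:
        i = order[gid]
        pil_genes.update(
            g.gene_id
            for g in genes[max(0, i - 1) : i + 2]
            if g.gene_id not in with_tss or g.gene_id in pil_seed_genes
        )
    summaries = tss.summarize_by_cluster(
        validated, {"pil": sorted(pil_genes)}, known_genes=genes
    )
    n_pil = next(
        s.n_validated_promoters for s in summaries if s.cluster_id == "pil"
    )

    genome_rx, genes_rx, _truth_rx = simulate.generate_genome(rx_like_spec(seed))
    matches_rx = promoters.predict_promoters(genome_rx, genes_rx)

    records, _truth_map = simulate.generate_protein_set(
        N_TWIN_MOTIF + N_SINGLE_MOTIF,
        motif_counts=[2] * N_TWIN_MOTIF + [1] * N_SINGLE_MOTIF,
        seed=int(rng.integers(2**31)),
    )
    class_counts = Counter(
        c.value for c in proteins.classify_proteins(records).values()
    )

    return {
        "rr_promoter_matches": len(matches),
        "rr_validated_promoters": len(validated),
        "rr_pil_cluster_promoters": n_pil,
        "rx_promoter_matches": len(matches_rx),
        "single_motif_proteins": class_counts["single"],
        "twin_motif_proteins": class_counts["twin"],
        "rr_replicon_bp": len(genome),
        "rx_replicon_bp": len(genome_rx),
    }


def rx_like_spec(seed: int) -> SimulationSpec:
    """R. xylanophilus-like replicon: 11 recoverable promoters plus negatives."""
    rng = np.random.default_rng(seed + 1)
    return SimulationSpec(
        seed=int(rng.integers(2**31)),
        replicon_id="rx_sim",
        gc=0.68,
        n_genes=25,
        gap_length=700,
        promoters=_promoter_designs(rng, RX_N_PROMOTERS, n_decoys=3, n_too_far=2),
    )
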