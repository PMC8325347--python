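"""Tests for intergenic extraction and the two-box promoter scan."""

import numpy as np
import pytest

from sigmaswitch.errors import InputError
from sigmaswitch.genome_io import GeneFeature, GenomeRecord
from sigmaswitch.promoters import (
    DEFAULT_BOX10,
    DEFAULT_BOX35,
    attach_downstream_and_filter,
    count_mismatches,
    extract_intergenic,
    predict_promoters,
    reverse_complement,
    scan_two_box,
)


def brute_force_two_box(
    sequence, box35=DEFAULT_BOX35, box10=DEFAULT_BOX10,
    spacer_min=13, spacer_max=17, max_mm=2,
):
    """Exhaustive enumeration oracle: every strand, placement and spacer.

    Returns tuples (strand, box35_start_fwd, box10_start_fwd, spacer, mm35, mm10)
    in forward 1-based coordinates.
    """
    found = set()
    L = len(sequence)
    for strand in "+-":
        seq = sequence if strand == "+" else reverse_complement(sequence)
        for spacer in range(spacer_min, spacer_max + 1):
            window = len(box35) + spacer + len(box10)
            for i in range(L - window + 1):
                w35 = seq[i : i + len(box35)]
                w10 = seq[i + len(box35) + spacer : i + window]
                mm35 = sum(a != b or a == "N" for a, b in zip(w35, box35))
                mm10 = sum(a != b or a == "N" for a, b in zip(w10, box10))
                if mm35 + mm10 <= max_mm:
                    if strand == "+":
                        b35, b10 = i + 1, i + len(box35) + spacer + 1
                    else:
                        b35 = L - i - len(box35) + 1
                        b10 = L - i - window + 1
                    found.add((strand, b35, b10, spacer, mm35, mm10))
    return found


def coverage_mask_regions(genes, length):
    """Position-mask oracle for intergenic extraction."""
    covered = np.zeros(length + 1, dtype=bool)  # 1-based
    for g in genes:
        covered[g.start : g.end + 1] = True
    regions, start = [], None
    for pos in range(1, length + 1):
        if not covered[pos] and start is None:
            start = pos
        elif covered[pos] and start is not None:
            regions.append((start, pos - 1))
            start = None
    if start is not None:
        regions.append((start, length))
    return regions


# ---------------------------------------------------------------- intergenic


def test_intergenic_basic_layout(small_genome):
    genome, genes = small_genome
    regions = extract_intergenic(genes, genome)
    assert [(r.start, r.end) for r in regions] == [(1, 100), (201, 300), (401, 500)]
    assert regions[0].left_gene is None and regions[0].right_gene == "g1"
    assert regions[1].left_gene == "g1" and regions[1].right_gene == "g2"
    assert regions[2].left_gene == "g2" and regions[2].right_gene is None


def test_intergenic_abutting_genes_leave_no_region():
    genome = GenomeRecord("c", "A" * 500)
    genes = [GeneFeature("a", "c", 1, 250, "+"), GeneFeature("b", "c", 251, 500, "+")]
    assert extract_intergenic(genes, genome) == []


def test_intergenic_gene_outside_replicon_rejected():
    genome = GenomeRecord("c", "A" * 100)
    with pytest.raises(InputError):
        extract_intergenic([GeneFeature("a", "c", 50, 150, "+")], genome)


def test_intergenic_matches_coverage_mask_on_random_layouts(rng):
    length = 2000
    genome = GenomeRecord("c", "A" * length)
    for _ in range(100):
        n = int(rng.integers(0, 12))
        genes = []
        for k in range(n):
            start = int(rng.integers(1, length))
            end = min(length, start + int(rng.integers(0, 400)))
            genes.append(GeneFeature(f"g{k}", "c", start, end, "+"))
        got = [(r.start, r.end) for r in extract_intergenic(genes, genome)]
        assert got == coverage_mask_regions(genes, length)


# ------------------------------------------------------------- mismatches


@pytest.mark.parametrize(
    "word, ref, expected",
    [
        ("TAAA", "TAAA", 0),
        ("TAAA", "TACA", 1),
        ("GCCGATNN", "GCCGATAA", 2),  # N counts as mismatch
        ("NNNN", "TAAA", 4),
    ],
)
def test_count_mismatches(word, ref, expected):
    assert count_mismatches(word, ref) == expected


def test_count_mismatches_length_check():
    with pytest.raises(InputError):
        count_mismatches("TAA", "TAAA")


# ------------------------------------------------------------- two-box scan


def _plant(spacer=15, box35=DEFAULT_BOX35, box10=DEFAULT_BOX10):
    return box35 + "A" * spacer + box10


def test_exact_plant_found_once():
    seq = _plant() + "GGGG"
    matches = scan_two_box(seq, spacer_min=15, spacer_max=15, strands="+")
    assert len(matches) == 1
    m = matches[0]
    assert (m.box35_start, m.box10_start, m.spacer, m.mm_total) == (1, 20, 15, 0)
    assert m.matched_sequence == _plant()


def test_three_mismatches_exceed_budget():
    seq = "TCCA" + "A" * 15 + "GACGATAA"  # 2 mm in -35, 1 in -10
    assert scan_two_box(seq, spacer_min=15, spacer_max=15) == []


def test_budget_boundary_two_mismatches_pass():
    seq = "TCCA" + "A" * 15 + DEFAULT_BOX10
    matches = scan_two_box(seq, spacer_min=15, spacer_max=15, strands="+")
    assert len(matches) == 1
    assert (matches[0].mm35, matches[0].mm10) == (2, 0)


def test_reverse_complement_plant_reported_on_minus_strand():
    seq = reverse_complement(_plant())
    matches = scan_two_box(seq, spacer_min=15, spacer_max=15)
    assert len(matches) == 1
    m = matches[0]
    assert m.strand == "-"
    assert m.matched_sequence == _plant()
    # -10 box occupies the leftmost 8 forward bases; its 3' end is the leftmost
    assert (m.box10_start, m.box10_end, m.box10_three_prime) == (1, 8, 1)


def test_scan_rejects_bad_characters():
    with pytest.raises(InputError):
        scan_two_box("ACGU" * 20)


def test_scan_equals_brute_force_oracle(rng):
    for _ in range(25):
        seq = "".join(rng.choice(list("ACGT"), size=800))
        got = {
            (m.strand, m.box35_start, m.box10_start, m.spacer, m.mm35, m.mm10)
            for m in scan_two_box(seq, dedup=False)
        }
        assert got == brute_force_two_box(seq)


def test_emitted_matches_reverify_mismatch_counts(rng):
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    for m in scan_two_box(seq, dedup=False):
        span = m.matched_sequence
        assert count_mismatches(span[:4], DEFAULT_BOX35) == m.mm35
        assert count_mismatches(span[-8:], DEFAULT_BOX10) == m.mm10
        assert m.mm_total == m.mm35 + m.mm10


def test_budget_nesting_and_spacer_monotonicity(rng):
    seq = "".join(rng.choice(list("ACGT"), size=3000))

    def key_set(**kw):
        return {
            (m.strand, m.box35_start, m.box10_start, m.spacer)
            for m in scan_two_box(seq, dedup=False, **kw)
        }

    assert key_set(max_mm=0) <= key_set(max_mm=1) <= key_set(max_mm=2)
    assert key_set(spacer_min=14, spacer_max=16) <= key_set(spacer_min=13, spacer_max=17)


def test_dedup_keeps_single_best_per_site():
    # two placements share the -10 box: spacers 14 and 15 both fit since the
    # -35 box also matches one base to the left (TAAAA prefix)
    seq = "TAAAA" + "A" * 14 + DEFAULT_BOX10
    raw = scan_two_box(seq, spacer_min=14, spacer_max=15, strands="+", dedup=False)
    assert len(raw) == 2
    kept = scan_two_box(seq, spacer_min=14, spacer_max=15, strands="+")
    assert len(kept) == 1
    assert kept[0].mm_total == min(m.mm_total for m in raw)


# --------------------------------------------- downstream linkage and filter


def _match(box10_end, strand="+", replicon="c"):
    from sigmaswitch.promoters import PromoterMatch

    if strand == "+":
        b10_start = box10_end - 7
        b35_start = b10_start - 15 - 4
        b35_end = b35_start + 3
    else:
        b10_start = box10_end
        b35_start = box10_end + 8 + 15
        b35_end = b35_start + 3
        b10_start, box10_end = box10_end, box10_end + 7
    return PromoterMatch(
        replicon_id=replicon, strand=strand,
        box35_start=b35_start, box35_end=b35_end,
        box10_start=b10_start, box10_end=box10_end,
        spacer=15, mm35=0, mm10=0, mm_total=0, matched_sequence="",
    )


def test_distance_measured_to_first_codon_base():
    genes = [GeneFeature("g1", "c", 151, 400, "+")]
    kept = attach_downstream_and_filter([_match(100)], genes)
    assert kept[0].downstream_gene == "g1"
    assert kept[0].dist_to_start == 51


def test_adjacent_start_codon_gives_distance_one():
    genes = [GeneFeature("g1", "c", 101, 400, "+")]
    kept = attach_downstream_and_filter([_match(100)], genes)
    assert kept[0].dist_to_start == 1


def test_far_gene_removed():
    genes = [GeneFeature("g1", "c", 350, 600, "+")]
    assert attach_downstream_and_filter([_match(100)], genes) == []


def test_opposite_strand_gene_not_linked():
    genes = [GeneFeature("g1", "c", 151, 400, "-")]
    assert attach_downstream_and_filter([_match(100)], genes) == []


def test_minus_strand_distance():
    # minus-strand match with -10 3' end at 500; gene ends at 460
    genes = [GeneFeature("g1", "c", 200, 460, "-")]
    m = _match(500, strand="-")
    kept = attach_downstream_and_filter([m], genes)
    assert kept[0].dist_to_start == 40


def test_intervening_gene_blocks_linkage():
    genes = [
        GeneFeature("mid", "c", 120, 130, "-"),
        GeneFeature("g1", "c", 151, 400, "+"),
    ]
    assert attach_downstream_and_filter([_match(100)], genes) == []


def test_planted_distance_cutoffs(planted_simulation):
    """Distances {50, 150, 199} retained; 201 removed by the 200-bp rule."""
    spec, genome, genes, truth = planted_simulation
    matches = predict_promoters(genome, genes)
    by_gene = {m.downstream_gene for m in matches}
    expected = {e.gene_id for e in truth.expected()}
    assert by_gene == expected
    dists = {e.dist for e in truth.expected()}
    assert dists == {50, 150, 199}
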