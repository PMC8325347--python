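# Methods

## Two-box promoter model

The scan is a literal consensus match, not a weight matrix: flagellar-type
σ-factors are reported with a compact, well-conserved consensus
(−35 `TAAA`, −10 `GCCGATAA`), and the published counts this package
reproduces were produced by mismatch-budget matching. Parameters:

| parameter | default | meaning |
|---|---|---|
| `box35`, `box10` | `TAAA`, `GCCGATAA` | consensus boxes, any lengths |
| `spacer_min..spacer_max` | 13–17 nt | gap between the boxes |
| `max_mm` | 2 | pooled Hamming budget over both boxes; N always mismatches |
| `max_dist` | 200 bp | −10 3′ end → first codon base, on the match strand |

The spacer window is the one genuinely open choice: the source analyses show
a fixed-width promoter alignment without stating the spacer. 13–17 nt
brackets the σ²⁸ literature and is exposed as `--spacer-min/--spacer-max`;
reproducing a published count on a real genome may require narrowing it to
the spacer(s) visible in the published alignment.

Coordinates are 1-based inclusive and always reported on the forward strand;
for a minus-strand match the −10 box 3′ end is its *leftmost* forward
coordinate. The only conversion is at the BED boundary (0-based half-open).
Distance is anchored at the −10 3′ end because both the TSS and the start
codon lie downstream of the −10 element; `--anchor match_5p` measures from
the match 5′ end instead, since "within N bp of a start codon" is ambiguous.
An immediately adjacent start codon gives distance 1.

Overlapping same-strand placements (shared −10 territory) are one promoter
site; dedup keeps the placement with the lowest mismatch total, breaking
ties by spacer closest to the window midpoint, then leftmost. Matches must
be co-directional with their downstream gene, and no other gene may lie
between the promoter and that gene's start. Circular replicons are off by
default; when enabled, the origin-spanning intergenic interval is scanned
as a concatenation of the terminal intervals.

## TSS validation

"Appropriately positioned" is quantified as a TSS 2–12 nt downstream of the
−10 box 3′ end on the match strand, with `min_reads` ≥ 1. Both bounds are
configurable; the defaults bracket typical +1 placement for this σ family
without any coverage filtering. When several TSS qualify, the highest-read
one is attached (ties to the smallest offset). Widening the window or
lowering `min_reads` can only add validations (tested monotonicity).
Cluster membership is user-supplied (gene-id lists), because published
cluster definitions are typically pictorial.

## Anti-σ signature scan

Anchors E/S/R/D are strict; only the Q anchor degenerates to H, matching the
observed conservation pattern. X is accepted at wildcard positions
(unconstrained by definition) and rejected at anchors. All overlapping
placements are reported; classification counts hits per protein
(0/1/2/>2 → none/single/twin/multi) without presupposing non-overlap.

## Structure metrics

* **Superposition** — Kabsch SVD solution restricted to proper rotations
  (the smallest singular direction is flipped when det < 0). Fewer than
  three pairs, or collinear reference points, raise a degeneracy error.
* **SASA** — Shrake–Rupley with van der Waals radii C 1.70, N 1.55, O 1.52,
  S 1.80, P 1.80 Å, probe 1.4 Å, and a deterministic golden-angle spiral of
  960 points per atom (no randomness; doubling the density moves totals by
  < 0.5 % on test structures). Unknown elements require an explicit radius
  override. Only atoms inside the evaluated selection occlude, which is the
  convention the buried-surface difference requires.
* **BSA** — SASA(A) + SASA(B) − SASA(A∪B), reported as the two-sided total
  over both partners (not halved). Heteroatoms (ligands, ions, waters) are
  excluded from protein–protein selections by default and includable per
  selection, because published interface areas may or may not count a bound
  nucleotide. Published areas from lattice tools differ by quadrature and
  radii; agreement within ~10 % is the realistic expectation.
* **Ingest** — PDB/mmCIF via gemmi; first model only; alternate locations
  collapse to the highest-occupancy conformer.

## Synthetic data

The generator emulates the study inputs: a bacterial replicon with annotated
genes and planted two-box promoters, a TSS table with true and spurious
starts, protein sets with planted signatures, and ideal α-helical Cα traces.
Background bases are i.i.d. at a configurable GC fraction (default 0.67,
Rubrobacter-like; GC changes the background hit rate, and the analytic null
631/4¹² per position/strand/spacer holds at GC 0.5). Genes of fixed length
(900 bp) alternate with fixed gaps (400 bp default); each promoter design is
planted in the gap upstream of its own gene with exact per-box mismatch
counts, spacer and distance. A design that does not fit its gap — including
a minus-strand element and the next gene's plus-strand element colliding in
a shared gap — raises a generation error before any output is written.

Two properties make recovery tests exact rather than probabilistic:

1. **Background scrub.** After planting, intergenic DNA is rescanned and any
   placement within the scan constraints that does not sit at a planted site
   is rewritten (one non-planted box base at a time, avoiding the consensus
   base) until none remain. A replicon with nothing planted skips the scrub
   and is a pure background (null) model.
2. **Site semantics.** The scan necessarily reports slightly shifted
   registrations of a planted element within the mismatch budget (the
   `TAAA` box overlaps itself); dedup keeps one per site. Shifted variants
   are left in place only when their own distance to the element's gene
   yields the same keep/drop decision the element was designed for, so the
   designed outcome — recovered or filtered — is invariant to which
   registration wins the tie-break. Ground truth is therefore stated per
   site, and recovery is measured per site.

TSS simulation assigns an in-window start (offset uniform on 2–12 nt) to a
Bernoulli fraction of planted promoters (or an exact count, or a designated
gene set), an out-of-window or absent start to the rest, and Poisson
spurious starts at `spurious_rate` per kb (validated to [0, 1]). Protein
backgrounds are uniform over the 20 standard residues with a rejection step
that breaks accidental signatures, so planted counts are exact.

What the simulations do **not** model: codon structure, dinucleotide or
strand composition bias, operons, overlapping genes, promoter islands, or
read-level TSS noise. Passing recovery tests therefore demonstrates the
correctness of the scanning/filtering logic under the stated constraints,
not calibrated performance on real GC-skewed genomes, where the background
match rate and the intergenic fraction differ.

## Study-emulation presets and problem sizes

The presets plant the published composition — 20 recoverable promoters
(12 with in-window TSS, 3 behind a pil-like cluster) on a 65-kb replicon of
40 genes, 11 on a second 41-kb replicon, plus decoys (≥ 3 mismatches) and
beyond-distance plants, and a 135-protein homolog set (130 twin-, 5
single-signature). Replicon sizes keep the full pipeline and the acceptance
script at a few seconds while leaving realistic intergenic space; all counts
reported by `scripts/acceptance.py` are recomputed by running the pipeline
on these simulations, never read from the truth ledger.

## Known limitations

* The consensus scan has no positional weighting; a one-mismatch match at a
  critical position scores the same as one at a peripheral position.
* Reproducing published match counts on real genomes depends on the exact
  spacer window and on whether the annotation's `gene` or `CDS` rows defined
  intergenic space (`--feature-type` switches this).
* SASA ignores hydrogens and treats all occupancies as full after altloc
  selection.
* The origin-spanning scan on circular replicons reports wrapped coordinates
  but does not wrap downstream-gene linkage across the origin.
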