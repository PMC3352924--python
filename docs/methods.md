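# Methods

This note documents the models and procedures implemented in `nbsarch`,
the parameters that matter, and what the synthetic benchmarks do and do not
demonstrate.

## Gene models and coordinates

External coordinates are GFF3 (1-based, inclusive); every internal CDS or
protein offset is 0-based half-open. Alternative transcripts are collapsed
to the longest-CDS mRNA per gene, since the survey counts genes. The GFF3
phase column is ignored: intron phase is recomputed from CDS segment
lengths on the spliced CDS, which makes it strand-free and independently
testable. Codons containing ambiguity letters translate to `X` and never
count as stops; a gene is flagged as a pseudogene when a stop codon occurs
before the final position of its conceptual translation.

## NBS detection

Each of the eight NBS motifs (P-loop … MHDV) is a fixed-width PSSM built
from a packaged block of aligned exemplar peptides: log-odds in bits against
a uniform background with a Laplace pseudocount, floored at −1 bit per cell
so one substitution cannot veto an otherwise strong window. The motifs
conserved across all classes (P-loop, Kinase-2, GLPL, RNBS-D) have tight
blocks; the class-variable motifs (RNBS-A/B/C, MHDV) looser ones.

Per-profile acceptance thresholds are calibrated empirically: the maximum
score of 1,000 random uniform windows plus a one-bit margin, from a fixed
internal seed. An **NBS call** requires the three anchors {P-loop,
Kinase-2, GLPL} present with strictly increasing starts in canonical order;
RNBS-D is scored but not required, because C-terminal truncations lose it.
The annotation spans the first to last motif of the accepted chain.

The proteome **search runs in two rounds**, reflecting the query-refinement
needed when a standard NB-ARC query is too divergent for a distant lineage:
round 1 scans with the packaged profiles; the motif windows of the
best-scoring hit are folded back into the blocks (weight 3) and the
remaining proteins are rescanned, the result being the union of both rounds
(so refinement can only add genes). Acceptance uses an empirical
expectation value: the null is the best-per-anchor score sum over shuffled
proteome sequences (composition-preserving), and the expectation of a score
is its null exceedance probability scaled by proteome size. The default
threshold of 1.0 expected hits filters spurious matches; decoy genes are
additionally excluded by the ordered-anchor requirement.

## N-terminal typing, coiled coils, LRRs

The region N-terminal of the NBS is scored with wide PSSMs for TIR, PK and
α/β-hydrolase (each built from a packaged domain template plus two
10%-divergent variants); the kind with the largest margin above its
calibrated threshold wins. If none qualifies, a coiled-coil heuristic
decides CC vs NONE: per-window (28 residues) mean log-propensity over
heptad positions, maximized across the seven register offsets and mapped to
[0, 1] by a fixed logistic; windows at probability ≥ 0.9 form the call.
The 28-residue window (four heptads) and the propensity table are package
choices; the 0.9 threshold matches standard coiled-coil screening practice.
LRRs are counted as non-overlapping matches to LxxLxLxx (L ∈ {L, I, V, F})
in the region C-terminal of the NBS; ≥ 3 matches within a 200-residue
window constitute a domain. Redundant sequences are collapsed by
single-linkage clustering at 97% global nucleotide identity (gaps count as
mismatches), the longest member representing each cluster; the threshold
separates alleles/sequencing error from paralogs and is configurable.

## Intron signatures

`cds_offset` is the spliced-CDS offset of the first base after an intron;
phase is `offset mod 3`, protein position `offset // 3`. Region labels give
domain membership priority, then boundary zones: the inter-domain gap
widened by a 10-residue slack on each side (no numeric tolerance exists for
"between domains"; 10 residues is configurable). When no N-terminal domain
is detected, the zone within the slack of the NBS start still labels
NTERM_NBS_BOUNDARY, so truncated genes can be fingerprinted.

Signatures: TNL requires (NTERM_NBS_BOUNDARY, phase 2) and
(NBS_LRR_BOUNDARY, 0); PNL the same with boundary phase 0; HNL adds
(WITHIN_NTERM, 0); CNL requires the *absence* of boundary introns. A
signature matches when every required (region, phase) pair is present.
Because HNL's required set strictly contains PNL's, the intron channel
prefers the most specific matching signature. Conserved locations across a
family are found by single-linkage clustering of introns on NBS-relative
protein positions (±5 residues, equal phase), reported at ≥ 80% family
support — tolerant of truncation forms, and independent of alignment
quality because all surveyed introns sit near NBS-relative landmarks.

## Classification cascade

1. **ARCHITECTURE** — a typed N-terminal domain fixes the class
   (TIR→TNL, PK→PNL, hydrolase→HNL, CC→CNL).
2. **NBS_SIMILARITY** — otherwise the NBS domain is globally aligned
   (BLOSUM62, gap open 10 / extend 1) to every reference — the NBS domains
   of the architecture-classified genes, capped at five per class — and
   takes the best class at identity ≥ 0.40. Exact ties are never guessed.
3. **INTRON_SIGNATURE** — otherwise a uniquely (most-specifically) matching
   intron fingerprint decides.
4. **UNCLASSIFIED** — reported separately and excluded from class totals so
   the survey table stays well defined.

The 0.40 identity threshold mirrors the convention that > 40% amino-acid
identity marks moderate homology; it is configurable. Pseudogenes are
classified from their conceptual translation with stops as wildcards, and
flagged rather than dropped.

## Phylogeny

The survey's phylogenetic claims are clade-membership statements, so the
package deliberately uses distance methods rather than likelihood:
progressive alignment (UPGMA guide tree on 3-mer distances; profile–profile
Gotoh alignment with BLOSUM62, gap open 10 / extend 1; deterministic for a
fixed input order), p-distances with pairwise gap deletion, and
neighbor joining (scikit-bio; negative branch lengths clamped to zero).
Bootstrap support resamples alignment columns with replacement and tallies
bipartitions over replicates. A filter drops sequences covering < 50% of
columns or with mean p-distance > 0.8 — the reproducible analogue of
excluding sequences "too short or too divergent in a fine alignment". A
codon back-translation utility maps protein alignments onto coding
sequences; amino-acid distances are the default input to tree building.

## Synthetic benchmark genomes

The generator assembles each gene from fixed, versioned templates: leader
(6 aa) + N-terminal domain + linker (8 aa) + NBS + linker + LRR + tail.
Class founders diverge the NBS template at 30% per site outside the anchor
motifs (anchors are conserved across real classes too — that is what makes
them anchors), giving the between-class signal the similarity channel and
the phylogeny rely on; family members then diverge from the founder at the
requested within-family rate (default 0.2, protein level, start residue
preserved). Proteins are reverse-translated with uniformly random
synonymous codons (no codon-usage model — irrelevant to every downstream
statistic computed here). Signature introns sit at fixed template offsets
with the class phases; CNL genes receive one non-boundary intron inside the
NBS; intron sequences are random 80–300 nt flanked by GT…AG (splice-site
realism beyond the dinucleotides is not modelled). Half of the genes go on
the minus strand; a chosen fraction (rounded count, deterministic choice)
gets one internal stop in the linker after the NBS; decoys are
composition-matched order-0 random proteins. Default family compositions
mirror the published bryophyte surveys: 9 TNL / 45 PNL / 11 CNL moss-style
genes across intact and truncated forms, and 36 liverwort-style HNL genes.

**What passing the benchmarks shows** — that the pipeline recovers classes,
forms, phases and conserved intron locations under substitution divergence,
truncation, pseudogenization, strand mixing and decoy background, at the
stated rates. **What it does not show** — robustness to indels and
misannotated gene models, to domain architectures outside the template
grammar, or to real lineage-specific motif variants beyond what two-round
refinement captures; real-genome counts also depend on annotation version
and search calibration, which is why the whole-genome check is run on the
synthetic composition rather than a download.

## Numerical and scale choices

All randomness flows through seeded NumPy generators; profile calibration
uses a fixed internal seed so thresholds are stable package constants.
Score ties break by leftmost start, then lexical gene id. Benchmark sizes
(106-gene mixtures, 20-taxon trees, 100 bootstrap replicates, 1,000
calibration windows and null shuffles) were chosen as the smallest problems
that exercise every code path with clear statistical margins; the full test
suite runs in about a minute.

## Known limitations

* Fixed-width block scoring, not full profile HMMs: no insert/delete states,
  so motif hits do not tolerate indels within a motif window.
* The coiled-coil propensity table is a compact heuristic, not a published
  matrix; only the 0.9 decision threshold is treated as authoritative.
* Neighbor joining redistributes negative branch lengths by clamping to
  zero without transferring the deficit to the sister edge.
* The intron channel cannot separate PNL from HNL for genes lacking both an
  N-terminal domain and a WITHIN_NTERM intron; such genes are expected to
  resolve in the similarity channel.
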