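# Methods

## Problem and model

`pepgraph` enumerates the non-canonical peptides that a sample's genomic
and transcriptomic variation can place in a mass-spectrometry search
space: peptides carrying combinations of small variants (SNVs, indels,
RNA-editing events), products of alternative splicing, novel ORFs on
transcripts annotated as noncoding, chimeric peptides of gene fusions,
and rolling-translation products of circular RNAs.  Enumerating these by
applying every compatible variant combination to every transcript is
exponential in the variant count; the package instead builds a sequence
graph per transcript in which combinations share structure, so run time
grows linearly with the number of variants while the emitted peptide set
is exactly the exhaustive one (validated continuously against a
brute-force oracle; see below).

## The three graph stages

**Transcript variant graph (TVG).**  Three linear root nodes hold the
transcript sequence offset by 0, 1 or 2 nt from the 5' end — one
subgraph per reading frame, with frame `k`'s codon grid at transcript
positions ≡ k (mod 3).  A variant is spliced in by breaking the
reference chain at its span and attaching a node with the alternative
sequence.  An in-frame variant closes back into the same subgraph; a
frameshifting variant closes into subgraph `(k + S_ref − S_alt) mod 3`,
which is exactly codon-phase bookkeeping: if a path's codon grid is
aligned at the variant start, it is aligned again at the variant end in
the target subgraph.  Transcripts with an annotated ORF incorporate
variants into the canonical frame's subgraph plus any subgraph already
entered by an upstream frameshift; unknown-ORF transcripts use all
three.  Alternative-splicing insertions and substitutions become depth-1
subgraphs of reference-typed nodes that can carry their own nested small
variants.

**Variant bubbles.**  Variants closer than five reference nucleotides
(the minimum connection-node length) are clustered into bubbles.  Within
a bubble, every path — every pairwise-compatible variant choice, with
compatibility encoded structurally as span-disjointness and
nested-variant containment — is merged into a single member node.
Member boundaries are then snapped to codon grids by taking nucleotides
from the anchors: the upstream boundary snaps down to the incoming
frame's grid and each member's downstream boundary snaps up to its own
outgoing frame's grid, which makes every member a whole number of codons
regardless of net frameshift.  Because anchors are at least five
nucleotides and total donation is at most four, anchors never vanish
between bubbles.  The aligned result is a three-chain lattice:
`anchor(k, j) → members(cluster j+1 entered in frame k) → anchor(k', j+1)`.
Unknown-ORF graphs enter all three chains; known-ORF graphs enter only
the canonical chain at the ORF start, and the other chains are reachable
only through frameshift members (unreachable regions are pruned).

**Peptide variant graph and cleavage graph.**  Each aligned node is
translated codon-wise (PVG); because every node is whole-codon on its
grid, no codon straddles a node boundary and stop codons are detected
node-locally.  The PVG is converted into the peptide cleavage graph
(PCG) by a stage-and-call forward pass in topological order.  The pass
carries, per path state: the open peptide segment since the last
cleavage site, two residues of context for cut decisions (enough for
every supported protease rule, including trypsin's K/P suppression and
WK/P override across node boundaries), ORF state, and carried
annotations (upstream frameshifts, cleavage-gain context).  Segments
close at cleavage sites and at stop codons; every PCG edge is then a
cleavage site and node interiors contain none.  States are merged by
(context, open-segment content), which bounds the state count: after a
cut inside a shared anchor, paths that differ only in upstream variant
choices converge to one state whose source annotations are unioned.  An
open segment that grows past the maximum peptide length is replaced by
an oversized sentinel — every peptide contains each of its cleavage
segments entirely, so such a segment can never be emitted or extended —
which both prunes dead work and merges states in long cleavage-free
stretches; the segment still resets normally at the next cleavage site.

**Peptide calling.**  PCG nodes are zero-miscleavage peptides;
miscleaved peptides are concatenations across up to the permitted number
of cleavage edges along graph paths.  For unknown-ORF graphs every
methionine in every frame subgraph opens a candidate ORF: peptides are
attributed to the 5'-most compatible start ("minimum ORF order"), and a
methionine inside an open reading produces its own N-terminal peptide
segment (its downstream peptides coincide with the enclosing ORF's and
are not duplicated; the threads provably re-synchronise at the next
cleavage site because every ORF begins with M, which no supported rule
cuts around context-dependently).  Paths that reach the transcript end
without a stop codon close with an *open* C-terminus that is never
emitted — translation terminates at the last complete peptide when stop
codons are unknown.  Final filters enforce length bounds (default 7–25
residues), drop peptides containing `X` (from `N` bases) and remove any
sequence the canonical proteome digest can produce under the same
enzyme/miscleavage/length settings.

## Edge-case rules

Applied before graph construction, identically in the graph pipeline and
the brute-force oracle:

* variants overlapping the annotated start codon are excluded
  (translation-start uncertainty), as are variants wholly 5' of the ORF
  or 3' of the annotated stop codon;
* stop-codon-destroying variants are kept; translation continues to the
  next in-frame stop or to the transcript end (open C-terminus rule);
* splice-site-altering variants are excluded via VEP consequence strings
  when present; geometrically, the genomic parsers only admit variants
  whose footprint is fully exonic for the transcript at hand, which
  removes anything touching the intronic splice dinucleotides;
* selenocysteine: a TGA codon whose first base originates from an
  annotated selenocysteine position reads as `U`; the override is
  origin-tracked, so an upstream frameshift that moves the codon grid
  off the annotated position disables it, and edited bases never carry
  an origin.

## Fusion and circular backbones

A fusion backbone is donor prefix + acceptor suffix, instantiated for
every donor x acceptor transcript pair of the fused genes.  Intronic
breakpoints retain the intron sequence up to (donor) or from (acceptor)
the breakpoint, in transcript direction and strand-aware, and variants
inside the retained span are mappable into backbone coordinates.
Variants overlapping a breakpoint are dropped with a warning.  The donor
ORF start is used if the donor is coding and its start lies 5' of the
junction; otherwise the backbone is called as noncoding.

A circular RNA is linearized as **three** concatenated copies of the
circle: a non-triplet circle shifts frame at each back-splice passage
and returns to the original frame after three traversals, after which
the amino-acid sequence repeats.  (The alternative convention of a
fourth copy guarantees that every junction-spanning peptide window
exists linearly even on very short circles, but it can also emit
peptides that no three-traversal reading produces; three copies keep the
graph consistent with the rolling-translation bound and with the
brute-force oracle's definition.)  Circle variants are replicated into
each copy as independent records; traversals in which a variant appears
in one loop passage but not another are therefore included — a
deliberate superset appropriate for database generation.  Calling treats
every circle as noncoding (three-frame methionine scan).

## Protease model

Cut sites are inter-residue positions decidable from at most two
residues before and one residue after the site: trypsin (C-side of K/R,
suppressed before P, WK/P override), Lys-C (K), Lys-N (N-side of K),
Arg-C (R), Glu-C (E), Asp-N (N-side of D), chymotrypsin (F/W/Y,
suppressed before P; the low-specificity L/M variant is not included).
Default miscleavage allowances: 2 (trypsin, Lys-C, Lys-N, Arg-C), 3
(Glu-C, Asp-N), 4 (chymotrypsin).  `U` and `X` are ordinary non-cutting
residues.

## Pop-and-collapse

Hypermutated bubbles can blow up the aligned member count.  When a
bubble exceeds a configurable cutoff (default 32 members), the last `x`
residues (default 5) of each member are split off and identical suffixes
are merged, unioning variant annotations.  Prefix and suffix concatenate
to the original member along the only path through them, so the callable
peptide multiset is unchanged (property-tested).  The traversal's
state merging provides the same protection dynamically at anchors.

## Validation: fuzz testing against a brute-force oracle

The package carries its validation engine.  `simulate_case` draws a
transcript (random sequence 60–600 nt, 1–3 exons, either strand,
embedded in a synthetic genome so that sequence extraction and
coordinate mapping are exercised), optionally coding (ATG written at the
chosen start; annotated stop located; 15% of coding cases carry an
annotated selenocysteine TGA), and 1–12 variants (70% SNV / 20% indel of
1–9 nt / 10% RNA-editing SNVs; alternative-splicing, fusion and circRNA
configurations add their event types).  Variants are placed at
transcript positions ≥ 3: a variant starting at position 0–2 is not
representable in a frame subgraph rooted downstream of it (the roots
trim the *reference* 5' end), and such cap-proximal variants are
declared out of scope.

`brute_force_peptides` iterates over all variant subsets, keeps those
whose members are pairwise span-disjoint (nested variants additionally
require their parent), applies each subset by plain string editing with
per-base origin tracking, translates (annotated ORF, or every ATG of the
edited sequence for noncoding/circular backbones), digests and filters.
The two engines share only declared semantics — the compatibility
notion, the edge-case pre-filter, the enzyme rule table, backbone
metadata and the bounds; graph construction/traversal and string
enumeration are independent code paths.  Agreement is exact sequence-set
equality per case.  The brute force also defines the enumeration
baseline whose subset count doubles per added variant, against which the
pipeline's linear runtime is demonstrated.

What the simulator does not emulate: real exon/intron length
distributions, splice-site sequence motifs, homopolymer/repeat-induced
indel ambiguity beyond VCF left-anchoring, multi-transcript genes in
linear cases, and sequencing artifacts.  Passing fuzz validation
therefore demonstrates algorithmic correctness of the enumeration, not
robustness to upstream caller noise.

## FDR formulas

Peptide-level FDR for a sample/tier is `(D + 1) / (T + D)` over decoy
and target PSM counts, clipped to 1 (the formula exceeds 1 when T = 0).
The post hoc cohort-level cutoff finds, per sample, the target hit with
the highest FDR value strictly below the per-sample threshold (FDR_i),
counts decoy and all hits with FDR ≤ FDR_i, and divides summed decoys by
summed hits across the cohort.  Samples with no sub-threshold target
contribute nothing.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; GTF (1-based
  inclusive) and VEP/REDItools positions are converted on ingestion.
* CDS bounds exclude the stop codon; translation discovers stops from
  sequence, which makes stop-destroying variants behave uniformly.
* Indels are stored left-anchored against the transcript with one
  retained anchor base, as in VCF.
* Two zero-length insertions at the same point are mutually exclusive;
  an insertion point on the boundary of another variant's span is
  compatible with it.  Same-start edits apply insertion-before-base.
* Bubble member enumeration and subset enumeration visit variants in
  (start, end) order; ties are resolved identically in both engines.
* The connection-node criterion ("first common downstream reference
  node of ≥ 5 nt") is implemented with a sink fallback: the transcript
  end terminates the search and acts as the terminal connection node.
* Mixed-tier peptides take the highest-priority tier in the order
  Variant > Noncoding > NoncodingVariant > CircularRNA > AltTranslation.
* W>F substitutants are emitted one site at a time by default; a flag
  enables the all-sites variant.  Selenocysteine-termination products
  are emitted per Sec position with a certain (stop-derived) C-terminus.
* FASTA headers are space-joined source blocks
  `gene|backbone|variant ids|ORF start|kind`, lossless, so databases can
  be merged and re-tiered from their FASTA form alone.

## Problem sizes used in the checks

The validation suite runs about a thousand fuzz cases spread over the
six configurations, with the default study conditions above; the
runtime-scaling analysis uses coding transcripts with 10–200
well-separated SNVs (20 replicates per count) for the linear fit and
1–12 variants for the brute-force doubling baseline; protease rules are
checked against an independent positional scanner on 1,000 random
sequences per enzyme; pop-and-collapse is checked on 100 random
hypermutated bubbles; circular backbones are checked on random circles
of 9–60 nt in both length classes (≡ 0 and ≢ 0 mod 3).

## Known limitations

* Variants at transcript positions 0–2 of unknown-ORF transcripts are
  not representable in all frame subgraphs and are out of scope.
* Source annotation is a documented superset: peptides carry the
  variants of the bubble members and carried frameshifts on their path,
  which can over-attribute in-frame co-resident variants of the same
  member; state merging at anchors can union source classes.  Sequence
  content is never affected.
* No recursive alternative-splicing subgraphs (an event nested inside
  another event's insertion), no structural variants beyond the listed
  classes, no semi-specific or chemical cleavage, no decoy generation
  and no transcript-abundance filtering.
* 5' UTR start-gain modeling on coding transcripts is not performed;
  novel ORF discovery is restricted to unknown-ORF backbones.
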