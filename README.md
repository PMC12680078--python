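# pepgraph

Graph-based enumeration of non-canonical peptides for proteogenomic
database searches.

Sample-specific proteogenomics detects peptides that are absent from the
canonical reference proteome — products of germline and somatic SNVs and
indels, RNA editing, alternative splicing, novel ORFs on transcripts
annotated as noncoding, gene fusions and circular RNAs.  Building the
search database requires enumerating the peptides of **every compatible
combination** of such events on each transcript, which is exponential if
done by exhaustive editing.  `pepgraph` builds a *transcript variant
graph* instead: three reading-frame subgraphs over the transcript
sequence with variant nodes spliced in, frameshifts routed between
subgraphs by

    outgoing frame = (incoming + S_ref − S_alt) mod 3,

overlapping variants aligned into codon-snapped *variant bubbles*, the
graph translated node-wise and converted into a *peptide cleavage graph*
whose edges are exactly the enzymatic cleavage sites.  Peptides with up
to the permitted number of miscleavages are read off the graph in one
topological pass, so run time grows linearly with variant count while
the output equals the exhaustive enumeration — an equivalence the
package itself verifies continuously with a built-in brute-force oracle
and fuzz-testing engine.

Intended users: proteogenomics groups generating custom FASTA databases
from DNA/RNA sequencing of the samples they search by mass spectrometry.

## Worked example

A one-gene genome with a missense SNV, from VEP output to a tiered
database:

```bash
pepgraph parseVEP --vep variants.vep.txt --genome genome.fa \
    --annotation ann.gtf --source sSNV -o variants.gvf
# wrote 1 records to variants.gvf
cat variants.gvf
# ##fileformat=GVF
# ##parser=parseVEP
# ##annotation=.
# #CHROM  POS  ID    REF  ALT  QUAL  FILTER  INFO
# G1      16   snv1  A    G    .     .       TRANSCRIPT=T1;TYPE=SNV;SOURCE=sSNV
```

The genomic SNV (chr1:26 A>G) has been re-expressed gene-centrically in
transcript coordinates (position 16, 1-based, on transcript T1).  Calling
variant peptides against the canonical proteome:

```bash
pepgraph callVariant --gvf variants.gvf --genome genome.fa \
    --annotation ann.gtf --proteome proteome.fa --min-length 4 -o db.fasta
# called 4 unique peptides from 1 transcripts, 0 fusions, 0 circRNAs -> db.fasta
cat db.fasta
# >G1|T1|snv1|CDS|coding_tx
# DVELK
# >G1|T1|snv1|CDS|coding_tx
# DVELKGF
# >G1|T1|snv1|CDS|coding_tx
# MAAKDVELK
# >G1|T1|snv1|CDS|coding_tx
# MAAKDVELKGF
```

The reference protein is `MAAKDIELKGF`; the SNV turns I into V, and the
four peptides are the tryptic products (0–2 miscleavages, length ≥ 4
here) that cover the variant and are **not** producible from the
canonical proteome — `MAAK`, for instance, is canonical and is excluded.
Each FASTA header documents every source of the peptide: gene, backbone,
variant ids, ORF and backbone class.  Finally:

```bash
pepgraph splitDB db.fasta -o tiers
# Variant: 4 peptides -> tiers.Variant.fasta
```

partitions the database into the five search tiers (Variant, Noncoding,
NoncodingVariant, CircularRNA, AltTranslation), each searched with
independent FDR control.

The same pipeline is available as a library:

```python
from pepgraph import CallParams, call_transcript

peptides = call_transcript(tx_seq, variants, CallParams(),
                           coding=True, cds_start=10,
                           canonical_set=canonical_digest)
```

Other entry points: `parseFusion` / `parseAltSplice` / `parseRNAEditing`
/ `parseCircRNA` for the remaining upstream callers, `callNovelORF` for
noncoding transcripts, `callAltTranslation` for selenocysteine-
termination and W>F substitutant peptides, `mergeDB` for plex-level
merging, `fuzz` for the validation engine and `fdr` for the target-decoy
formulas.

## Validation

`pepgraph fuzz --n 1000 --seed 1` simulates transcripts (coding status,
strand, exon structure, selenocysteine positions) paired with random
variants of all supported types and compares the graph pipeline's
peptides against a brute-force algorithm that iterates over all variant
combinations by string editing.  Disagreements are reported per case and
can be serialized as replayable fixtures; the shipped configuration
passes with exact agreement.  See `docs/methods.md` for the model, the
edge-case rules, the study conditions the simulator emulates, and known
limitations.

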