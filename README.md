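# unsense

Analytics for the genetic code's single-nucleotide substitution space, plus
an evidence-driven classifier and auditor for coding variants that look
synonymous at codon level.

The toolkit does three things:

1. **Substitution-space analytics** — enumerates every ordered single-base
   change of every codon (64 × 9 = 576 records for the standard code),
   classifies each as synonymous / missense / nonsense / stop-loss /
   stop-to-stop and transition / transversion, and summarises counts,
   percentages and wobble-group structure.
2. **Classification** — assigns a final label from the codon-level category
   plus experimental evidence records: `missense`, `nonsense`, `unsense`
   (codon-synonymous but with splicing / splicing-regulation / miRNA-binding
   evidence), `synonymous_with_effect` (effect at DNA, protein, or
   mRNA-stability level), `verified_synonymous` (no-effect evidence), or
   `unverified_synonymous_predicted` (no evidence at all). Frame and
   decay-escape rules (in-frame iff affected length mod 3 = 0; premature stops
   escape decay in the last exon or within a configurable window of the
   penultimate exon's 3' end, default 50 nt) are available for splice events.
3. **Audit** — checks externally claimed labels against computed ones and
   flags evidence-free "synonymous" claims as `overclaimed_synonymous`.

A seeded fixture generator produces toy transcripts, CDS sequences, variant
sets, claimed labels and planted evidence, so everything is testable offline.

Note on published figures: the widely quoted tallies of 141 synonymous /
137 coding-synonymous substitutions and 7 fully degenerate codon groups do
not survive brute-force recomputation under directed counting (an odd
directed count is impossible by symmetry). The enumeration here, verified
against an independent per-amino-acid pair-listing oracle, yields 138
(incl. 4 stop-to-stop), 134, and 8 respectively; the verifiable printed
counts (576 total, 4 stop-to-stop, 8 off-wobble synonymous, all at codon
position 1, 1.4 % of the space) are reproduced exactly.

## CLI

```bash
# substitution-space summary (JSON or TSV)
unsense space --table standard --out summary.json
unsense space --fold-stop-to-stop --format tsv --out summary.tsv

# generate a seeded fixture bundle
unsense fixtures --seed 1 --n-variants 200 --out bundle/

# annotate a transcript-coordinate VCF with UNS_* INFO keys
unsense classify --vcf bundle/variants.vcf \
    --transcripts bundle/transcripts.json \
    --sequences bundle/cds_sequences.fasta \
    --evidence bundle/evidence.tsv \
    --out annotated.vcf

# audit claimed labels against evidence
unsense audit --claims bundle/claims.tsv \
    --evidence bundle/evidence.tsv \
    --sequences bundle/cds_sequences.fasta \
    --out audit.tsv        # JSON summary lands next to it
```

`--table` accepts `standard` or a two-column TSV (codon, amino_acid);
`--nmd-window` overrides the 50-nt decay-escape window.

## File formats

- **Transcript models**: JSON (`transcript_id`, `exon_lengths`, `cds_start`,
  `cds_end`, `strand`; 1-based inclusive transcript coordinates) or a GFF3
  subset (exon + CDS rows sharing a `Parent` transcript ID; both strands).
- **Evidence TSV**: `variant_id, assay, mechanism, effect, level`.
- **Claims TSV**: `variant_id, transcript_id, cds_pos, ref_base, alt_base,
  claimed_label`.
- **HGVS**: the coding-substitution subset (`[ACC:]c.<pos><ref>><alt>`) plus
  length-bearing `del`/`ins`; intronic offsets are an explicit out-of-scope
  error.
- **VCF**: CHROM = transcript ID, POS = transcript position; annotation adds
  only INFO keys (`UNS_CAT`, `UNS_LABEL`, `UNS_MECH`, `UNS_EVID`) and leaves
  CHROM..FILTER byte-identical.

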