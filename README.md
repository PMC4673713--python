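# utrome

A toolkit for building and using genome-scale 3'UTR clone libraries.

3'UTRs — the mRNA segments downstream of the STOP codon — are where
miRNAs and RNA-binding proteins dock to control translation, stability,
and localization, yet clone collections of full-length 3'UTRs are rare
compared to ORF collections. `utrome` implements the computational side of
producing and exploiting such a library:

* **Locus resolution** (`genome_model`) — from a genome (FASTA, optionally
  gzip) and annotation (GTF/GFF3), resolve each gene's cloning insert:
  the STOP codon of the most 3'-distal transcript through the annotated
  3' end plus 150 nt of downstream sequence, with design failures
  (unresolvable STOP, overflow) recorded, never skipped.
* **Panel design** (`panel_design`) — grow forward primer cores 5'-ward
  from the STOP and reverse cores gene-ward from the +150 boundary until
  a 60 degC nearest-neighbor melting temperature, then fuse Gateway
  attB2/attB3 recombination tails; inserts outside 200–2,500 nt are
  filtered.
* **In-silico PCR** (`insilico_pcr`) — touchdown schedules (16 cycles,
  66→51 degC, then 15 at 55 degC by default), amplicon prediction with a
  3'-anchored binding model, and gel-style size screening.
* **Clone verification** (`clone_verification`) — BLAT-style seeded local
  alignment of Sanger reads against the expected-insert panel, verdicts
  (`verified` / `misassigned` / `sequence_fail` / `no_hit`), and two-pass
  re-array bookkeeping.
* **Screen analysis** (`life_screen`) — dual-luciferase repression
  indices `RI_i = (F/R)_query,i / (F/R)_control,i`, replicate-paired, with
  hits called at mean RI < 0.8 and one-sample t-test on log2 RI at
  p < 0.05; plate planning and miRNA control-construct design included.
* **QC reporting** (`qc_report`) — length distributions and medians,
  per-chromosome coverage, ORF-collection overlap, cloning success by
  length bin.
* **Synthetic fixtures** (`synthetic_fixtures`) — deterministic
  mini-genomes, Sanger-like reads, and plate tables with known truth, so
  the entire pipeline is testable without downloads.

See `docs/methods.md` for the models, conventions, and their rationale.

## Worked example

Everything below runs offline on a generated mini-genome:

```bash
utrome fixtures genome --n-genes 12 --seed 42 --out fix
utrome design --genome fix/genome.fa --annotation fix/genes.gtf --out panel
utrome pcr --panel panel/panel.tsv --genome fix/genome.fa --out amplicons.tsv
utrome fixtures screen --n-utrs 24 --seed 42 --out screenin
utrome screen --plates screenin/plates.tsv --query-mirna miR-sim \
    --control-mirna control --out screenout
```

which prints:

```text
wrote genes.gff3, genes.gtf, genome.fa, truth.tsv to fix
10 primer pairs designed, 2 failures
10 predicted amplicons written to amplicons.tsv
plate table for 24 3'UTRs written to screenin
0 repressed hits of 24 3'UTRs
```

Two of the twelve genes were excluded by the 200–2,500 nt insert filter
(`panel/failures.tsv` lists them with reason `length filter` and their
lengths, 2,955 and 2,802 nt). The amplicon table shows one unambiguous
product per designed pair whose length is the insert plus 54 nt of attB
tails, and the first touchdown cycle at which both primers anneal:

```text
gene_id  contig  product_start  product_end  product_length  first_productive_cycle  ambiguity
g001     chrSim  644            967          377             6                       0
g002     chrSim  1295           3071         1830            7                       0
```

The screen table reports, per 3'UTR, the mean repression index over five
replicates and its p-value; this simulated plate set has no planted
effect, so no UTR passes the RI < 0.8, p < 0.05 hit rule:

```text
utr_id   mirna_id  mean_ri             p_value              n_replicates  verdict
utr0011  miR-sim   0.9145870101902307  0.2766120056261651   5             none
utr0012  miR-sim   0.9170373295454699  0.06377499165557643  5             none
```

The same operations are available as library calls
(`utrome.genome_model.resolve_utr_loci`, `utrome.panel_design.design_panel`,
`utrome.life_screen.analyze_screen`, ...), which is how the test suite and
acceptance script drive them.

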