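# spottcr

Spatially resolved TCR-beta repertoire analysis for 10x Visium
targeted-amplicon libraries.

## The problem

Standard Visium spatial gene-expression captures polyadenylated mRNA on
barcoded spots, but the hypervariable CDR3 region that defines a T cell
clone sits kilobases away from the 3' end and is essentially never covered.
A targeted protocol solves this by re-amplifying the Visium cDNA with a pool
of 45 TRBV-specific primers (equimolar, e.g. 10 uM total ≈ 0.22 uM each)
carrying partial read-2 adapters, so that paired-end sequencing yields:

- **read 1** — the 16-nt spatial barcode and the 12-nt UMI (hence read 1
  must be at least 28 cycles), and
- **read 2** — the TCR-beta amplicon spanning the V 3' region, the CDR3
  junction (conserved V cysteine → conserved J phenylalanine of the FGXG
  motif), the J segment and the start of the constant region.

`spottcr` implements the computational half of this assay end to end:

1. **Clonotype calling** (`spottcr.clonotype`) — ungapped V assignment from
   the 5' primer-anchored window of read 2, J assignment 3' of the V hit,
   CDR3 extraction between the anchor codons, and assembly into clonotypes
   keyed by the exact (V gene, J gene, CDR3 nucleotide) triple. A
   MiXCR-format import adapter (`import_mixcr`) accepts an external clone
   table plus per-clone `reads_clnN.fastq.gz` files as an alternative
   front-end.
2. **Spatial linkage** (`spottcr.spatial`) — pair each clone-supporting read
   with its read 1 by name, extract barcode and UMI, match the barcode
   against the Space Ranger tissue positions list (exact by default,
   optional unique 1-mismatch rescue), deduplicate so each (barcode, UMI)
   combination counts once, and build the spot x clone UMI matrix.
3. **Repertoire statistics** (`spottcr.repstats`) — per-sample totals,
   Shannon diversity H = -Σ pᵢ ln pᵢ over clone UMI frequencies, sequencing
   saturation 1 − UMIs/reads, UMIs per in-tissue spot, the fraction of reads
   under tissue, and a chain filter flagging non-TRB (e.g. IGKV cross-primed
   BCR) clones.
4. **Simulation** (`spottcr.simulate`) — a full synthetic-data generator
   (segment reference with valid CDR3 anchors, primer pool, tissue
   positions, clone placements, PCR duplication, sequencing error,
   off-tissue and BCR-like contamination) with complete ground truth, so the
   whole pipeline is testable without any sequencing data.

## Worked example

Simulate a small tissue section and run the full pipeline:

```
$ spottcr simulate --out-dir demo --seed 7
simulated 5996 read pairs -> demo

$ spottcr all --r1 demo/reads_R1.fastq.gz --r2 demo/reads_R2.fastq.gz \
    --positions demo/tissue_positions_list.csv \
    --reference demo/segments.fasta --anchors demo/segment_anchors.tsv \
    --primers demo/primer_pool.tsv --out-dir demo/out
20 clones, 2000 in-tissue UMIs, Shannon 2.030, saturation 0.666
```

The simulated section has 50 spots (40 under tissue) and 20 clones with
geometrically skewed sizes placed on 5 spots each — 2,000 distinct
molecules, each sequenced on average 3 times (PCR duplication), giving 5,996
read pairs. The pipeline recovers all 20 clonotypes, deduplicates the reads
back to exactly 2,000 UMIs (saturation 1 − 2000/5996 ≈ 0.666), and reports
Shannon diversity 2.03 (between 0 for a monoclonal repertoire and
ln 20 ≈ 3.0 for 20 equal clones — the skew lowers it). `demo/out/` then
contains:

```
spot_clone_matrix.tsv        # rows = in-tissue spot barcodes, cols = clones,
                             # cells = deduplicated UMI counts
spot_clone_matrix.tsv.off_tissue.tsv
clones.tsv                   # cloneId, readCount, V/J, CDR3 nt+aa, productive
link_log.tsv                 # in-tissue / off-tissue / unmatched read counts
repertoire_stats.tsv (+.json)
```

For example the first matrix rows:

```
barcode           clone1  clone2  ...
TTGAGCACTGTTAGGA  0       0       ...  (33 UMIs of clone5, 14 of clone7, ...)
CAATACTCCCTTTCCA  0       0       ...  (23 UMIs of clone6, ...)
```

The matrix is a plain TSV ready for joining onto a Seurat or scanpy spatial
object as per-spot metadata.

Each stage is also available separately (`call-clones`, `import-mixcr`,
`link`, `stats`), and everything can be driven from Python via
`spottcr.simulate`, `spottcr.clonotype`, `spottcr.spatial` and
`spottcr.repstats`.

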