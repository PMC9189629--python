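# Methods

## Assay model

The package models a targeted spatial TCR-beta assay built on 10x Visium.
Each capture spot carries a 16-nt spatial barcode; reverse transcription
adds a 12-nt UMI per molecule. A pool of 45 TRBV-specific primers (equimolar;
at 10 uM total each primer is at 10/45 ≈ 0.22 uM), each carrying a partial
read-2 adapter at its 5' end, re-amplifies the cDNA so that read 2 runs:

```
[read-2 tail][TRBV primer region][V 3' region][CDR3][J segment][constant...]
```

and read 1 covers barcode + UMI (positions 0–16 and 16–28; read 1 shorter
than 28 nt is a hard error, mirroring the sequencing requirement of at least
28 cycles). The CDR3 is defined anchor-to-anchor: from the first base of the
conserved V-segment cysteine codon through the last base of the conserved
J-segment phenylalanine codon (the F of the FGXG motif), inclusive.

## Clonotype calling

**V assignment.** Because every amplicon begins at a V primer, V identity is
read from the 5' window of read 2. For each primer the query is the read-2
tail plus the V segment from the primer's annealing position, truncated to
60 nt. Queries are scanned ungapped (match +1, mismatch −1) at read offsets
0–10; a call requires mismatch fraction ≤ 0.1 over the compared span (≥ 20
nt). Ties on score break to the lexicographically smallest segment name,
then the smallest offset. The reported alignment covers the V-segment
portion only, in V-segment coordinates, so anchor positions can be projected
onto the read.

**J assignment.** Each J segment is scanned ungapped at every offset 3' of
the V alignment end; a hit needs ≤ 2 mismatches over ≥ 20 aligned nt (the
span may be truncated by the read end). Same tie rules.

**CDR3 extraction.** Anchor read positions are projected through the
ungapped alignments (`read_start + (anchor − ref_start)`); if either anchor
codon falls outside the read the read is discarded and counted in the drop
log. A CDR3 whose length is not a multiple of three gets an empty
amino-acid string; `productive` requires in-frame translation with no stop,
starting with C and ending with F.

**Assembly.** The clone key is the exact (V gene, J gene, CDR3 nucleotide
sequence) triple — no fuzzy clustering, matching the granularity a targeted
amplicon supports. Clones are numbered 1..K by descending read support,
ties by first appearance. Nonproductive clonotypes are retained and flagged,
never silently dropped. Alignment is ungapped throughout: the chemistry
produces no structural indels and the simulator emits none; reads with
sequencing indels fail the mismatch thresholds and land in the drop log
rather than being rescued.

An import adapter accepts MiXCR-style clone tables plus per-clone
`reads_clnN.fastq.gz` files (column names and the table's clone-numbering
base are configurable, since header sets differ between caller versions);
the package's own per-clone export uses 0-based file numbering to match that
convention while keeping 1-based clone ids in tables.

## Spatial linkage and deduplication

Read pairs are matched by read name (not file order — per-clone exports
reorder reads). Barcodes are matched against the tissue positions whitelist
exactly by default; the protocol's published analysis shows no evidence of
barcode error correction, so 1-mismatch rescue is opt-in and accepts a
candidate only when it is unique at Hamming distance 1. Barcodes containing
N never match. Gem-group suffixes ("-1") are stripped from the positions
file by default because raw read barcodes carry none; both the headerless
and the headered Space Ranger CSV dialects are auto-detected.

Deduplication enforces "one count per (barcode, UMI)": duplicates within a
clone collapse; when several clones claim the same pair, the clone with the
most supporting reads in that pair wins and exact ties discard the pair
entirely (the conservative choice — a tie carries no evidence either way).
UMIs are compared exactly; no directional/network UMI collapsing is applied.
The matrix has one row per in-tissue barcode (zero rows kept, file order)
and one column per clone with ≥ 1 in-tissue UMI, ordered by clone id.
Off-tissue hits are never silently dropped: they are tallied separately as a
permeabilization/diffusion diagnostic.

## Statistics

- Shannon diversity H = −Σ pᵢ ln pᵢ over clone UMI frequencies (natural
  log; H = 0 for a monoclonal repertoire, H ≤ ln K; log base configurable).
- Sequencing saturation = 1 − UMIs / clone-supporting barcode-matched
  reads, the standard 10x-style definition; the denominator is pre-dedup.
- UMIs per spot = in-tissue UMIs / number of in-tissue spots.
- Fraction of reads in tissue = in-tissue / (in-tissue + off-tissue +
  unmatched) clone-supporting reads.
- Chain filter: clones whose V gene is not TRBV-prefixed (typically
  cross-primed immunoglobulin light chains such as IGKV) are flagged and
  reported, to be excluded from the spatial matrix.
- Clone overlap with an external clone set (e.g. scRNA-seq V(D)J calls) is
  UMI-weighted by default — the fraction of deduplicated UMIs whose clone
  key appears in the reference set — with clone-weighted and
  amino-acid-key modes available.

## Simulator

The generator is first-class, tested code and defines the conditions every
claim is tested under. Defaults describe one small tissue section:

| parameter | default | meaning |
|---|---|---|
| n_spots / frac_in_tissue | 50 / 0.8 | whitelist size; 40 spots under tissue |
| n_clones | 20 | TRB clonotypes |
| clone_abundance | geometric(0.7) | clone sizes wᵢ ∝ 0.7^i, apportioned by largest remainder (min 1) |
| spots_per_clone | 5 | random in-tissue spots per clone |
| umis_per_clone_spot | 20 | sets the total molecule budget (20·5·20 = 2,000) |
| pcr_duplication_mean | 3.0 | reads per molecule = 1 + Poisson(mean − 1) |
| seq_error_rate | 0.0 | i.i.d. per-base substitutions on both mates |
| frac_background_reads | 0.0 | random non-TCR read 2 sequence |
| frac_off_tissue | 0.0 | molecules assigned to in_tissue = 0 whitelist barcodes |
| frac_bcr_like | 0.0 | share of molecules from decoy (70%-identity, IGKV-named) segments |
| r1_len / r2_len | 30 / 300 | read lengths (read 2 truncates the amplicon) |

V segments are 250–300 nt ending within 10 nt of the recorded TGT anchor; J
segments are 45–60 nt with TTT/TTC followed by a GGN-XXX-GGN spacing
(FGXG). Codons that would enter the CDR3 in frame adjacent to the anchors
are redrawn if they are stop codons, so every V/J combination can yield a
productive junction. All generated clones are productive (C...F, in frame,
no stop); nonproductive paths are exercised by constructed test inputs.
UMIs are drawn without replacement per barcode so the truth matrix is the
count of distinct (barcode, UMI, clone) triples. All randomness flows from
one seed; gzip output is written with mtime 0 so identical configs produce
byte-identical files.

What the simulator does **not** emulate: real human TRBV/TRBJ sequences and
their cross-homology (segments are random, so V discrimination is easier
than on the real locus), sequencing indels, quality-score profiles,
position-dependent error, barcode synthesis errors, UMI errors, ambient
diffusion structure, and overdispersed PCR. Passing tests therefore
demonstrate the correctness of the bookkeeping (pairing, matching, dedup,
counting, statistics) and robustness to uniform substitution noise — not
calling accuracy on real repertoires.

## Numerical and design choices

- Published per-sample results from the original assay derive from deposited
  sequencing data and are not reproducible at desk scale; verification is
  property-based on simulations plus analytic values (e.g. monoclonal H = 0,
  uniform two-clone H = ln 2, 10/45 uM primer concentration).
- Clone numbering differs between the generator (abundance order) and the
  caller (read-support order); truth comparisons map ids through the exact
  clone key (`TruthSet.clone_id_map`).
- The saturation denominator counts barcode-matched clone-supporting reads;
  with zero such reads the statistic is reported as missing, not 0.
- Problem sizes in the test suite and acceptance script (2,000 molecules at
  duplication 3; 10,000 reads for the noise-tolerance check) are chosen as
  the smallest scales at which the binomial error bars are tight enough to
  be meaningful.
- Reads with an N in the UMI keep the N as a literal symbol for dedup;
  an N in the barcode makes the read unmatched.

## Known limitations

- Ungapped alignment cannot rescue reads with sequencing indels.
- Exact-match clonotype keys split clones when the CDR3 itself carries a
  sequencing error surviving both V and J thresholds; at realistic error
  rates and with UMI dedup this inflates singleton clones slightly.
- Whitelist matching scans linearly for Hamming-1 rescue; adequate for
  Visium-scale whitelists (~5k spots), not optimized for million-barcode
  chemistry.
- TCR-alpha and full immunoglobulin calling are out of scope; non-TRB
  segments are detected only to be flagged.
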