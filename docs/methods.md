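# Methods

## The separation model

`blobsep` treats a host+symbiont sequencing sample as a low-complexity
metagenome. The central assumption is that each genome in the mixture is
internally homogeneous in two aggregate properties — base composition (GC
fraction) and effective molarity (read depth) — while differing from the
other genomes in at least one of them, and that sequence similarity to known
taxa can label enough contigs to identify which cluster is which. None of
these signals is used probabilistically; the method is deliberately a chain
of deterministic filters so that every contig's fate is auditable.

The pipeline stages and their contracts:

1. **Read QC** (`sequence_qc`). 3′-terminal bases with Phred quality < 20
   are removed as one maximal run (a literal, deterministic reading — not a
   BWA-style partial-sum heuristic); pairs with either mate shorter than 35
   bases are dropped; long-insert mate-pair reads may additionally be
   truncated to 50 bases *after* quality trimming, since the truncation
   exists to limit junction chimerism, not quality. Reads that become empty
   are kept as zero-length records until the pair filter so the two rules
   stay orthogonal and independently testable. The Phred offset is a
   parameter (default 33).
2. **Assembly statistics** (`contig_stats`). GC counts G/C over the full
   length, so N and other ambiguity codes dilute GC rather than being
   excluded; soft-masked lowercase counts as its uppercase base. N50 scans
   from the largest contig and returns the first length at which the
   cumulative span reaches half the total — on ties this is deterministic
   and always a member of the length set.
3. **Coverage profiling** (`coverage_profile`). Mean depth is total aligned
   reference bases (CIGAR M/=/X of primary alignments) over contig length,
   which equals the per-base pileup mean — the pileup is retained as the
   test oracle, the cheap form as the implementation. "Mapped best" means
   the highest alignment score (AS tag, falling back to MAPQ); primary
   records outrank secondary/supplementary ones, and score ties keep the
   first record seen, a declared convention since upstream mappers do not
   define one. Insert size is the median and MAD of proper-pair outer
   distances (both mates on one contig, opposite strands); an even count
   takes the mean of the central pair. Robust statistics are used because
   junction-spanning and mismapped pairs make the outer-distance
   distribution heavy-tailed.
4. **Taxonomic annotation** (`taxonomy_annotation`). A seeded uniform
   subsample of contigs (default 10,000) keeps the database search
   affordable and still estimates cluster density. Hits above the E-value
   cutoff (default 1e-10) are discarded; the best survivor per contig is the
   maximal bit score, ties broken by lower E-value, then first encountered.
   The hit's taxid is walked up an NCBI-taxdump-style tree to the first
   ancestor at the requested rank; the rank is an explicit parameter (order
   for two-party mixtures, class for messier samples) with no hard-wired
   default beyond `order` in the CLI. Taxids that cannot be resolved map to
   `unresolved` — never silently dropped — and an optional merged-taxid
   table handles retired IDs.
5. **Blob plot** (`blobplot`). A taxon earns a colour iff it annotates at
   least 10% (inclusive) of the contigs with a *real* hit; `no-hit` contigs
   carry no taxon to match and are excluded from the denominator. Coverage
   is drawn on a log axis — the clusters of interest differ by ~an order of
   magnitude and are unreadable on a linear one — with zero-depth contigs
   pinned at a pseudo-depth floor (default 0.01) so they stay visible.
   Every plot writes a companion TSV holding exactly the plotted rows, so
   figures are reproducible from data alone. Colours come from the
   Okabe–Ito colour-blind-safe palette, assigned by sorted taxon name.
6. **Binning** (`binning`). The four-way rule is described in the README.
   One written rule conflates two distinct thresholds — a 50-bit floor below
   which a hit is noise, and a 50-bit margin needed to win an ambiguous
   contig — so both are independent parameters defaulting to 50. The
   coverage floor applied to `BOTH`/`NEITHER` contigs is a required explicit
   parameter; `suggest_coverage_floor` proposes 0.25 × the median depth of
   `TARGET` contigs, reproducing the judgment of picking ~250× under a
   >1000× cluster. The floor applies to `BOTH` and `NEITHER` jointly.
   Multiple counter databases are combined by per-contig maximum — the
   conservative choice, since any strong counter evidence should block a
   contig. A symmetric host-side bin (`COUNTER` plus the low-coverage
   remainder) is emitted from the same pass.
7. **Read extraction** (`read_extraction`). A pair is selected iff at least
   one mate's best placement is a bin contig; unmapped mates never veto.
   Pair identity strips `/1`, `/2` and whitespace-tag mate designators.
   Extraction is two-pass and streaming: memory scales with the selected-ID
   set, not the FASTQ size.
8. **Reassembly parameters** (`reassembly_params`). Read coverage of the bin
   is its median contig depth (robust to collapsed repeats); expected k-mer
   coverage uses C·(L−k+1)/L at the top of the k scan range (41–63 by
   default, clipped below the read length and forced odd per De Bruijn
   convention), the k an optimizer tends to pick at high coverage. The
   minimum-coverage cutoff automates manual histogram inspection: the depth
   histogram (64 bins over [0, 1.2×expected]) is split at half the expected
   coverage; the dominant bin above is the main mode, the dominant bin below
   the noise mode, and the emptiest bin strictly between them is the valley.
   With no interior valley the suggestion falls back to expected/2. The
   heuristic is this package's automation of a judgment call, not a claim
   about how any particular analyst chose their cutoff, and it is always
   overridable.

## Synthetic mixtures

The generator emulates the study conditions the method was designed for: a
host-like genome at moderate depth and low GC and a symbiont-like genome at
>6× the host's depth with overlapping GC (defaults: 400 kb / 60× / GC 0.25
vs 50 kb / 400× / GC 0.32, 100-base pairs, insert 340 ± 30 bp), so depth
separates what composition cannot. A second preset adds six bacterial
co-bionts from six further taxonomic orders (seven orders total) at depths
from 15× to 900×, emulating an unexpectedly dirty sample. Genome sizes are
scale-reduced from real projects to keep generation and analysis within a
few minutes on one CPU; depth ratios, GC overlap and hit-accuracy levels are
preserved, which is what the binning logic actually sees.

Genomes are i.i.d. base strings at a target GC; contigs are a non-overlapping
tiling with noisy lengths (min 200 bp, emulating an assembler's minimum
contig length); read pairs are uniform fragments with a normal insert,
perfect quality and no errors by default (an optional uniform substitution
rate exists for robustness checks). True alignments are emitted directly as
SAM — reads spanning a contig junction are unmapped, reproducing the real
phenomenon of assembly-edge coverage loss (~(L−1)/contig-length of reads).
Mock BLAST hits give a contig its true taxon with probability
`hit_accuracy` (default 0.95) and strong, length-scaled bit scores;
otherwise a decoy taxon or no hit; taxon-restricted databases give
non-member contigs only occasional weak (25–80 bit) spurious hits. The toy
taxonomy is a fixed 3-level tree with nine orders and one species leaf per
order.

What the generator does *not* model — and hence what passing tests do not
show: realistic error and quality profiles, repeat structure and collapsed
repeats, chimeric contigs, lateral-gene-transfer fragments shared between
genomes, and database incompleteness beyond a uniform miss rate. Results on
real data depend on exactly these effects; the synthetic results validate
the plumbing and the rule logic, not biological performance.

All randomness flows from a single integer seed through one generator in a
fixed order, and gzip members are written with mtime 0, so a bundle
regenerates byte-identically.

## Numerical and design choices

* Depth/score/length tables join on contig IDs; duplicate IDs in a FASTA are
  a hard error rather than a warning because every downstream join would
  silently mis-assign.
* Zero proper pairs is an estimation error, not a zero estimate.
* `exhaustive_rule_check` exists so the four-branch classifier can be
  verified against an independent oracle over a full score lattice,
  including the `absent` value and both limit margins.
* The end-to-end suite measures separation quality against generated truth:
  with 95% hit accuracy the symbiont bin captures ≥95% of symbiont contigs
  with ≤1% host contamination and the extracted pairs are ≥99%
  symbiont-origin. These bars are the package's own acceptance conditions
  under the default synthetic mixture.
* Problem sizes in the default test run (450 kb of genome, 220k read pairs,
  ~230 contigs) were chosen so the whole suite completes in a few minutes on
  a single CPU; full project scale is explicitly not a test target.

## Known limitations

* The binning rule is sharp-thresholded; contigs near the margin flip with
  small score changes. The blob plot exists precisely to let an analyst see
  such borderline structure.
* Best-placement ties are resolved by input order; a different record order
  can reassign a tied read (documented, deterministic under a stable input).
* The valley heuristic assumes a roughly bimodal depth histogram; heavily
  multimodal bins (mixed-copy plasmids, collapsed repeats) need a manual
  cutoff.
* `lineage_at_rank` assumes parent links reach the root; cycles are guarded
  against but malformed taxonomies may still resolve surprisingly.
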