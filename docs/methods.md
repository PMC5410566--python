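# Methods

## Identification and the completeness filter

Candidates are proteins with at least one J-domain (PF00226) hit below the
e-value threshold (default 10⁻⁵). Hits arrive either from an external
profile search as a whitespace-separated per-domain table (target, domain,
i-E-value, hmm span, alignment span, profile length) or from the bundled
internal scanner. Profile coverage is `(hmm_to − hmm_from + 1) / hmm_length`.

"Complete J-domain" has no published operational criterion; this package
defines it as **profile coverage ≥ 0.8** (`cov_complete`, configurable).
This separates truncated hits from full-length domains without inventing
sequence-level rules. Candidates with only sub-threshold-coverage hits are
removed; everything else proceeds to classification.

The internal scanner is an ungapped per-column log-odds profile (no
insert/delete states). The bundled J-domain profile is built from a
63-residue idealised consensus (helix II/III core with the HPD tripeptide
at its centre), emitting the consensus residue with probability 0.6 per
column against a uniform background; a placement scores the sum of column
log₂-odds and is reported at ≥ 0 bits. Random 20-letter background scores
≈ −63 ± 8 bits per window, so the false-positive rate on 200-residue random
sequences is far below 1% (asserted by simulation in the tests), while a
consensus plant with 5% substitutions scores ≈ +200 bits. Reported
"e-values" are the naive transform 2^(−score) — adequate for thresholding
synthetic data, not calibrated statistics; real-data users should supply an
external hit table instead.

## Classification

Group assignment is a fixed decision order on three architecture flags:

1. no HPD inside a retained J-domain span → **E** (J-like), regardless of
   other domains — this precedence matches the published placement of
   zinc-finger-bearing J-like proteins;
2. zinc finger + C-terminal region → **A**;
3. zinc finger only → **D**;
4. C-terminal region only → **B**;
5. otherwise → **C**.

A zinc-finger *domain* requires ≥ 2 `CxxCxGxG` repeats (`zf_min_repeats`,
configurable); type-I proteins carry a repeat pair. A distinct C-terminal
region requires ≥ 40 residues downstream of the last retained J-domain end
(`cterm_min`) — a package convention, since no published rule exists. The
G/F-rich region that older three-group schemes use is deliberately not
detected: the five-group scheme implemented here never references it.

Names are assigned by sorting placed genes on (numeric chromosome, start)
and appending unplaced genes in lexicographic locus order; rank is
zero-padded to at least two digits.

## Physicochemical properties

Molecular weight is the sum of average residue masses (ExPASy table) plus
one water; B/Z/U/X are rejected with an error rather than approximated.
Net charge at a given pH is the Henderson–Hasselbalch sum over basic groups
(H, K, R, N-terminus) and acidic groups (C, D, E, Y, C-terminus) with
Bjellqvist-lineage pKa values; both tables are plain data, so EMBOSS-style
alternatives drop in. The charge curve is strictly decreasing in pH, so the
isoelectric point is the unique root in [0, 14], found by bisection to
1 × 10⁻³ pH units (tests compare against an independent 10⁻⁴-step grid
scan). Because the published catalog's MW/pI columns contain internal
copy errors and the underlying sequences are not printed, numeric agreement
with those columns is not asserted anywhere; catalog statistics are
computed from the fixture as data.

## Tandem duplication

Candidates are same-chromosome pairs whose **interval gap** (end of the
upstream gene to start of the downstream gene, 0 when overlapping) is
≤ 100 kb, with at most one other family member between them (non-family
genes are invisible to the pipeline; the limit is configurable or can be
disabled). Start-to-start distance would reproduce the same single
catalog pair; the gap convention is robust to long genes. Calls then
require alignment coverage of the longer sequence > 0.70 **and** identity
of the aligned region > 0.70, both strict inequalities.

Alignment is global Needleman–Wunsch with a linear gap penalty (defaults
match +1 / mismatch −1 / gap −2; a substitution table can be supplied for
proteins). Coverage counts the longer sequence's residues that sit in
residue–residue columns; identity is identical columns over residue–residue
columns. Protein sequences are aligned by default (the criteria's
gene-vs-protein basis is ambiguous in the literature); a nucleotide mode is
a matter of passing nucleotide strings. The DP score is property-tested
against an exhaustive memoized recursion (pairs ≤ 12) and against an
independent pairwise-aligner implementation.

## Promoters and cis-elements

Promoters are the `upstream_bp` (default 1 500) bases immediately upstream
of the gene start, excluding the start base itself: `[start−1500, start−1]`
for plus-strand genes and the reverse complement of `[end+1, end+1500]` for
minus-strand genes, truncated (and flagged) at contig edges. Scanning
matches IUPAC degenerate motifs at every position on both strands,
counting overlapping occurrences, with reverse-strand hits reported in
forward coordinates.

The bundled element table carries the classical heat-shock element core
`AAAAAATTTC` plus canonical published consensi for nine stress/hormone
elements (TC-rich, LTR, MBS; TCA, TGA, GARE, CGTCA, ABRE, ERE). The
cis-element discovery services used in genome surveys hold larger internal
motif libraries, so absolute element tallies depend entirely on the motif
table; the table is user-replaceable data and published per-element counts
from any specific service are not reproduction targets.

## Expression and qPCR

The expression matrix is genes × tissues of non-negative RPKM-like
abundances (no unit conversion is attempted). Pattern calls use two
conventions: a tissue counts as expressed at RPKM ≥ 1 (`expr_min`), and
"tissue-specific" allows at most 2 expressed tissues (`specific_max`);
barely-expressed rows have none, constitutive rows all, everything else is
"other". Clustering is average-linkage on Euclidean distances between
log₂(RPKM+1) rows; rows are pre-sorted by gene name so the tree is a
deterministic function of the data and invariant to input order. The
dendrogram exports to Newick; the heat map is purely presentational (SVG
output is byte-deterministic).

2^(−ΔΔCt): replicate Ct values are averaged per (gene, condition); ΔCt is
target minus reference within condition; ΔΔCt is treatment minus control;
fold = 2^(−ΔΔCt) with amplification efficiency fixed at 2. A per-replicate
pairing mode is available. The replicate SD is propagated from the target
gene's Ct spread (√(sd²_ctrl + sd²_trt), cycles). Up/down thresholds
(2.0 / 0.5) are conventions — only the 3-fold strong-induction flag has a
published anchor. Fold changes are invariant to plate-wide Ct offsets
within a condition (tested).

## The simulator

`synthetic_data.simulate` emulates the statistical structure the pipeline
assumes, with defaults mirroring the surveyed family: 76 family genes over
12 chromosomes in group proportions 9/8/53/1/5, 9 decoys whose J-domain
evidence covers only 31/63 profile columns, one tandem pair placed 4 kb
apart at 85% protein identity (substitutions only, so true identity and
coverage are exact by construction), promoter windows with
Poisson-planted motif copies, expression archetypes in proportions
29/10/3/34 (barely/constitutive/specific/other), and Ct tables with true
log₂ folds ~ U(−3, 3) at replicate noise sd 0.2 cycles (n = 3).

Design choices that make truth exact rather than approximate:

- proteins are rejected and regenerated until chance zinc-finger or HPD
  matches equal the planted count (background hit probability is small, so
  rejection is cheap);
- promoter backgrounds are scrubbed — chance motif hits outside planted
  spans are mutated away until a scan returns exactly the planted set
  (verified: no bundled motif can occur strictly inside another, so a
  mutable base always exists except across plant junctions, which trigger
  regeneration);
- non-tandem neighbours are spaced 150 kb apart, beyond the 100 kb
  criterion, so planted pairs are the only distance candidates.

What the simulator does **not** model: coding sequences consistent with
the planted proteins, intron length distributions, indel evolution between
duplicates, genome-scale base composition, or dropout/efficiency artefacts
in qPCR. Passing tests therefore demonstrate correctness of the pipeline's
logic and arithmetic under its stated assumptions, not performance on real
genomes with gapped homology, fragmented assemblies or noisy annotations.

One qPCR subtlety: the generated Ct table shares one set of reference-gene
wells per plate (as real plates do), so the realized reference noise is a
common offset across all genes of one bundle. The log₂-fold recovery
property (median |error| < 0.25 at sd 0.2) assumes independent reference
measurements, so its test constructs a 500-gene table with per-gene
reference wells; recovery on generator bundles is asserted with a looser
per-gene bound that includes the shared offset.

## Problem sizes and determinism

All randomness flows from a single seed through one numpy Generator; the
bundle is byte-identical across runs at a fixed seed. The test suite runs
the full study-scale design (85 genes, 12 chromosomes, ~15 Mb genome) once
as a session fixture plus twenty reduced designs (8 genes, 2 chromosomes)
for duplication-recovery statistics; oracle-equivalence suites use
sequence lengths where exhaustive enumeration is exact (alignment ≤ 12,
clustering ≤ 10 rows). These sizes are the package's own test design and
complete in well under a minute.

## Known limitations

- The internal profile scanner is ungapped; real J-domains with insertions
  need an external gapped search.
- BED export is BED6-flavoured and promoter-relative for motif hits.
- Segmental duplications are ingested, never discovered.
- The bundled catalog preserves the published table verbatim, including
  its internal inconsistencies (duplicated MW/pI values between two rows,
  and several text-vs-table disagreements); statistics derived from it are
  statistics of the table, not corrections of it.
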