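# Methods

This note records the models and procedures mitodyn implements, the
defaults that matter, the design choices that were genuinely open, and
what the synthetic cohorts do and do not establish about real data.

## Coordinate and annotation model

Internally all coordinates are 0-based half-open; the GenBank convention
applies only at the file boundary. Features are typed as `core_pcg`,
`rrna`, `trna`, `un_orf`, `heg` or `intron`; gene labels are folded
through an explicit, versioned synonym table (e.g. `ATP6`, `atpase 6` →
`atp6`; `ND1` → `nad1`; `cytb` → `cob`). Introns are taken from explicit
`intron` features when present and otherwise inferred from the gaps of
`join()` CDS locations; when both exist and disagree, the explicit
annotation wins with a warning. Circular records whose features span the
origin are linearized by rotating the sequence so that no feature wraps.
Ambiguity codes other than N are rejected under `strict` parsing and
mapped to N otherwise.

## Component decomposition

Every genome position is assigned to exactly one of five exclusive
categories by the priority core-gene exon > RNA (rRNA exon + tRNA) >
intron > un_ORF > intergenic, so the five lengths always sum to the
genome length. HEGs are measured as an *overlay* (positions inside
homing-endonuclease ORFs, which live inside introns or free-standing
ORFs) and are never subtracted from the host category. This resolves the
tension between a five-fraction stacked view and a six-component
correlation analysis without double counting: `rps3` nested inside `rnl`
is attributed to `rps3` by the same priority rule.

## Repeat detection

Two deliberately simplified detectors stand in for full repeat-finding
suites, and their acceptance is property-based (planted repeats must be
recovered) rather than count-matching:

- *Tandem*: the sequence is compared against itself shifted by each
  candidate unit length p (default 10–200 nt); runs where positions match
  their p-shifted partner at ≥ 0.8 identity and span ≥ 0.9 units beyond
  the first are reported with copy number (run+p)/p (threshold 1.9
  copies). Extension starts only at a streak of 8 consecutive matches and
  stops after a long mismatch run, keeping the scan near-linear; the
  p-multiple echoes of an array are suppressed in favour of the smallest
  period.
- *Dispersed / synteny blocks*: exact 12-mer seeds are extended gaplessly
  with +1/−2 scoring and an x-drop of 12, on both strands; the trivial
  self-diagonal and mirrored duplicates are excluded. Dispersed repeats
  default to ≥ 35 nt at ≥ 0.76 identity; synteny blocks to ≥ 500 nt at
  ≥ 0.7, with a minus-strand winner reported as an inverted block. There
  is no e-value model; the length and identity thresholds are the
  documented deviation from alignment-statistics-based search.

## Codon usage

Codon counts aggregate all core-gene codons of one genome, including the
start codon and the terminal stop; stops are excluded from RSCU.
Synonymous families follow genetic code 4 strictly — the Trp family is
{TGA, TGG} (k = 2) — and single-codon families get RSCU 1 by convention;
families with zero total are undefined (NaN). Within any non-empty
family the mean RSCU is exactly 1, which the tests assert exactly.
Codons containing N are excluded. un_ORFs are not included in RSCU.

## Pairwise rates

Coding sequences of the same gene are aligned globally at the protein
level (BLOSUM62, gap open 10, extend 1) and back-mapped to codons;
columns with gaps or N are discarded. Alignment replaces an external
multiple-aligner binary deliberately: at within-genus divergences the
core-gene alignments are unambiguous, and an in-process deterministic
aligner keeps the pipeline dependency-free.

- K2P: d = −½ ln(1−2P−Q) − ¼ ln(1−2Q) with P and Q the transition and
  transversion proportions; the distance is undefined (NaN, with a
  diagnostic) outside the log domain, and undefined pairs are dropped
  from per-gene medians with a logged count.
- Ka/Ks: Nei–Gojobori (1986). Synonymous site counts per codon are the
  mean synonymous fraction over the three positions, with changes to stop
  codons counted as nonsynonymous, so S + N = 3 × codons exactly.
  Observed differences average over all mutational pathways between the
  two codons; pathways through stop codons are excluded, and if every
  pathway is blocked the average falls back to all pathways. pS and pN
  are Jukes–Cantor corrected (d = −¾ ln(1−4p/3), undefined at p ≥ 3/4).
  The exact variant used by interactive desktop tools is not published;
  NG86 + JC is pinned here by its own oracle tests.
- Neighbor joining runs on the matrix of mean K2P over genes; negative
  branch lengths are clamped to zero with a warning. The NJ tree is a
  lightweight distance-based summary, not a substitute for model-based
  phylogenetic inference, which is out of scope.

Both the 15-gene and a 14-gene set (without `rps3`) are supported, since
`rps3` is variably treated as a core gene in this field.

## Intron position sets

An intron's position is its `local_pos`: the number of host-gene coding
nucleotides 5′ of the intron, taken from the exon offsets of the spliced
gene. Phase is `local_pos mod 3` with 0 meaning between codons; rRNA
hosts have undefined phase. Positions are projected onto a configurable
reference species through the codon-aware protein alignment (nucleotide
alignment for rRNA hosts): the projected position is the number of
reference nucleotides aligned strictly 5′ of the insertion point, and an
insertion inside a reference gap maps to the nearest 5′ reference
nucleotide. When the reference lacks the host gene, positions map via
the alphabetically first species carrying it and are flagged `indirect`.

Clustering is per-gene single linkage: adjacent projected positions at
most `tolerance` nt apart (default 3) join one IPS. The published rule
states only the pairwise "within three" criterion; single linkage is the
documented interpretation, so a chain 100–103–106 forms one set even
though its span exceeds 3 nt. The representative coordinate is the
reference species' own position when present, else the cluster minimum;
IPS ids are `gene-position`. An IPS in ≥ 2 species is "shared", and the
full n-species sharing spectrum is reported so that stricter readings
(e.g. shared-by-all) are derivable without re-clustering. Flank profiles
tabulate per-position base frequencies over ±15 exonic nt around the
insertion site (truncated flanks are N-padded and excluded per
position), a majority/IUPAC consensus, and the tally of intron 5′
dinucleotides.

## Gene order and size correlations

The 17 markers (15 core genes + rnl + rns) are read off the linearized
circle by start coordinate (a nested `rps3` ordered by its own start)
and rotated to `cox1`. Breakpoint distance counts circular adjacencies
of one order absent from the other, as unordered strand-aware pairs; in
the usual all-one-strand case this is plain adjacency comparison, and
records with markers on both strands trigger a warning and a signed
comparison. Size correlations are simple OLS of genome length on each
component length; R² is the squared Pearson correlation and the p-value
comes from the slope t-statistic with n−2 degrees of freedom (identical
to the Pearson test for simple regression). Components with zero
variance across the cohort yield NaN rather than a spurious fit.

## Synthetic cohorts

The generator builds one ancestral genome — core genes of realistic
lengths with ATG starts and TAA/TAG stops, rnl/rns, 25–27 tRNAs,
free-standing un_ORFs, intergenic spacers — and evolves it along a
newick tree. Defaults emulate the observed study conditions for this
genome family: AT-rich base frequencies (A 0.38, T 0.35, G 0.145,
C 0.125) giving GC ≈ 27% with positive AT and GC skews; a 2× codon
preference for TTA reproducing the strong UUA (Leu) usage bias of these
genomes; log-normal intron lengths with median 1.4 kb (σ = 0.25, clipped
to 0.5–4 kb) so lengths concentrate in the 1–2 kb bin; 60% of introns
carry a HEG ORF; intron gains at 8 per host gene per unit branch length
with losses at 2 and 6 ancestral introns, yielding ~15–20 introns per
leaf and 40–100 kb genomes on the default 7-leaf tree; insertion phases
drawn with probabilities (0.5, 0.25, 0.25) to reproduce the observed
phase-0 excess.

Substitutions follow the exact K2P transition-probability matrix per
branch (κ = 2 by default, branch lengths in expected substitutions per
site). Coding sequences use the same proposals plus an acceptance
filter: nonsynonymous changes are accepted with probability ω (default
0.2), stop-creating changes and changes to the start/stop codons are
always rejected. This is a deliberate, simple stand-in for codon models:
it produces Ka/Ks well below 1 under purifying settings, but it also
means realized coding distances sit slightly below the nominal branch
length — measured ≈ 4% low at d = 0.1 — because of the stop-codon
rejections. The estimator-recovery checks therefore run with ω = 1,
where only the stop exclusion remains, and accept a 5% band on the mean.

Intron gains pick a host gene uniformly, a position uniformly among
codons (with the phase weights above), and are recorded in an event log;
losses remove whole introns. Gained positions keep a minimum spacing of
8 nt within a gene so that distinct lineages remain separable at the
clustering tolerances under study. Intron sequences start with GT, are
generated once at gain and inherited unchanged — position turnover, not
intron-sequence divergence, is the object of study. Indels are not
simulated, so ancestral coordinates persist in every leaf and the
tolerance-0 clustering of an indel-free cohort must reproduce the
simulator's shared-lineage matrix exactly; the `transposed` fixture
exercises gene-order analysis via per-species order overrides, and the
`intron_rich`/`intron_poor` fixtures build independent genomes with
varying RNA/un_ORF/intergenic content for the size regressions.

What passing these tests shows — and does not. The simulator gives exact
ground truth for component lengths, intron sharing, gene order and
substitution processes, so it validates the analysis algorithms
end-to-end. It does not model indels (real position mapping must absorb
alignment gaps; that path is exercised by constructed insertion cases),
tRNA/rRNA secondary structure, recombination, intron sequence homology
between lineages, or annotation noise in real GenBank submissions.

## Problem sizes and determinism

The shipped fixtures use 3–7 genomes of 30–55 kb; estimator-recovery
checks use 50 two-leaf replicates at d = 0.1 over ~14 kb of coding
sequence, and the acceptance script uses 20 replicates per estimator
plus one 7-genome cohort — sizes chosen so the whole suite completes in
well under a minute of compute while keeping Monte-Carlo error far
inside the asserted bands. All randomness flows from explicit integer
seeds (package default 1729); identical configurations produce
byte-identical GenBank output, and pipeline reruns produce
byte-identical tables and manifests.
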