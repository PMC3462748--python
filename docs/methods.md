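# Methods

`barnapep` reimplements, as a tested desk-scale pipeline, the in-silico
workflow used to catalogue neuropeptides and peptide hormones in the
barnacle *Balanus amphitrite* and to relate them to larval settlement:
translated homology mining of a transcriptome, screening of candidate
precursors, prediction of prohormone processing and post-translational
modifications, family annotation of the mature peptides, and the two
statistical analyses that accompany such a catalog (2^-ΔΔCt developmental
expression profiling and an arcsine/ANOVA settlement bioassay).

## Homology mining

The original screen used tBLASTn with an E-value cutoff of 0.01, keeping the
top three hits per query. We reproduce the *semantics* of that screen
without the word-seeding heuristic: each reference peptide is aligned by
exact affine-gap Smith–Waterman (Bio.Align.PairwiseAligner) against all six
conceptual frame translations of every transcript. Frame translations are
segmented at stop codons before alignment, so an alignment can never cross a
stop — the defining behaviour of a translated search. Segments too short to
reach the score that the E threshold implies (score bound: segment length ×
the largest diagonal entry of the matrix) are skipped; this is a pure
pruning step and cannot change the result.

Alignment significance uses the explicit Karlin–Altschul formula
E = K·m·n·e^(−λS) with the published gapped-BLOSUM62 constants λ = 0.267,
K = 0.041, where m is the query length and n the total number of translated
residues in the database. Because NCBI BLAST applies edge-effect and
composition corrections, absolute E-values differ from BLAST output;
ordering and thresholding behave identically, which is what the screen
needs. Defaults follow BLAST protein conventions: BLOSUM62, gap open 11,
gap extend 1, with a gap of length L costing `open + (L−1)·extend`. The
original report's per-family E-values/scores are products of a specific NCBI
build and database size and are not reproduced.

Per query, at most `top_k` (default 3) transcripts are reported, each by its
best alignment, all below the E threshold (default 0.01), sorted by
ascending E-value with deterministic tie-breaking (raw score, subject start,
query start, frame order, transcript id) — so mining is invariant under
shuffling of the input transcript list.

## ORF selection and precursor screening

For each candidate transcript the precursor ORF is the maximal stop-to-stop
stretch in the hit's frame containing the hit span, trimmed to the first Met
at or upstream of the hit (no Met ⇒ the stretch boundary, flagged). The
classical three-criterion screen is then applied: a predicted signal
peptide, at least one accepted processing site downstream of it, and length
strictly under 300 residues (the 299/300 boundary is tested).

Signal-peptide prediction is deliberately a transparent von-Heijne-style
heuristic, not a re-implementation of a neural-network predictor: the
original workflow delegated this step to an external server, and the
pipeline needs an auditable, dependency-free stand-in. A signal is called
when (i) some 8-residue window beginning within positions 2–23 contains at
least 6 residues from {A,I,L,M,F,V,W,C}, and (ii) a cleavage position c in
10–40 with c ≥ core end + 3 satisfies the (−3,−1) rule (residues c and c−2
in {A,G,S,C,T,V}). The core is taken as the **last** maximal-scoring
window and the cleavage point as the **earliest** qualifying c; the
three-residue offset models the minimal c-region between the hydrophobic
core and the cleavage site. Without the offset and the last-window rule,
A/V-rich cores (which are simultaneously "hydrophobic" and "small") would
pull the predicted cleavage into the core. A consequence worth knowing:
long poly-Ala stretches downstream of a real signal can postpone the
predicted cleavage; the synthetic generator avoids A/V/C in planted cores
so planted cleavage points are recovered exactly.

## Prohormone processing rules

Cleavage prediction is an operational reading of the classical
proprotein-convertase site statistics, each sub-rule toggleable in
`PipelineConfig`:

* maximal runs of K/R are classified atomically: runs of ≥3 are one
  multibasic site (position = last residue), runs of 2 are dibasic sites
  (KR and RR accepted by default; RK and KK off by default), single R is a
  monobasic candidate;
* a monobasic R is accepted only with another basic residue at −4, −6 or
  −8 — and, by default, only when that supporting residue is **not** inside
  an accepted site or the signal peptide. The guard reflects processing
  order: the convertase products are trimmed by carboxypeptidase before a
  monobasic context exists, so a basic residue that is itself removed cannot
  support cleavage. Without the guard, any Arg 4–9 residues after a dibasic
  site would be cleaved — which would, for example, split the canonical
  orcokinin N-terminus NFDEIDR (Arg7) after every copy;
* any otherwise-accepted site immediately followed by Pro is rejected.

Excision takes the maximal stretches strictly between the signal end,
accepted-site residues and the precursor end; the basic residues themselves
are excluded, and signal + sites + segments always reconstruct the
precursor exactly (property-tested on random sequences).

PTMs follow the canonical rules: a C-terminal Gly is removed and the
preceding residue amidated; an N-terminal Gln (optionally Glu) is flagged
as pyroglutamate; a Tyr is flagged as sulfated when ≥2 Asp/Glu fall within
±5 residues (window and count configurable). Flags never move stored
coordinates; reports render them as a `pQ` prefix and `-NH2` suffix in a
display field only.

## Family motifs and alignment

Mature peptides are assigned to families by short terminal signatures held
as data (`data/family_patterns.tsv`; literal residues, `X`, `[AB]`,
`X(n)`, trailing `a` = requires amidation; first match in file order wins).
The shipped set generalises the canonical arthropod signatures just enough
to admit the barnacle variants: ASTC `SXWKQCXFNAVSCFa` (Ser7 variant),
sulfakinin `[YF]G[HMF][MLF][RK]Fa` (Lys8, Met6/Phe6 variants), ASTA
`[YF]XFG[LIV]a`, ASTB `WX(6)Wa`, SIFamide `SIFa`, TRP `FX(1)GX(1)Ra`, NPF
`RX(1)RFa`, orcokinin N-terminal `NFDEIDR`. Large disulfide-bonded hormones
(bursicons, EH, IRP, ITP, CLDH) have no useful terminal motif; their
precursors are identified by homology (the family of the best supporting
reference hit), which is also how the pipeline reports precursor-level
family in discovery runs.

Pairwise alignment is exact global affine-gap Needleman–Wunsch (end gaps
penalised, same gap convention as the local aligner); the multiple
alignment is a deterministic centre-star progressive scheme (centre = the
sequence with the highest summed pairwise score; once a gap, always a
gap). Removing the gaps of row i always reproduces input i. No guide tree
is built and figure-level alignment layouts are out of scope.

## Quantification statistics

`ddct` implements textbook relative quantification: ΔCt pairs each target
measurement with the reference-gene measurement of the same (stage, batch,
replicate) cell (configurable to stage-mean pairing; the pairing choice is
not dictated by the emulated protocol), ΔΔCt subtracts the calibrator-stage
mean, and fold = 2^(−ΔΔCt). The ANOVA runs on per-replicate −ΔΔCt (log2
fold), which is Gaussian under Gaussian Ct noise, giving variance
homogeneity; the reported point fold is 2^(−mean ΔΔCt), so the calibrator
fold is exactly 1. Amplification-efficiency correction is out of scope (the
emulated protocol used plain 2^-ΔΔCt). One-way ANOVA comes from
scipy.stats.f_oneway and Tukey HSD from statsmodels'
`pairwise_tukeyhsd` (studentized-range distribution); the test suite
cross-checks both against hand-derived sums-of-squares F statistics and
direct `studentized_range.sf` evaluations on a fixed fixture.

The settlement analysis transforms per-well metamorphosis proportions by
arcsin√p, then runs the same ANOVA/Tukey machinery across the five
treatment groups (seawater control, DMSO vehicle control, 1, 10,
100 µmol/L inhibitor) within each timepoint, reporting contrasts against
the seawater control with significance tiers (* p<0.05, ** p<0.01,
*** p<0.001).

## Synthetic data

The raw study data (transcriptome reads, Ct values, settlement counts) are
not published, so every pipeline input has a generator with known ground
truth; generators are pure functions of (spec, seed) and every generated
precursor is self-validated on emission — the annotation rules must
reproduce the planted signal end, site positions and peptide
(sequence, amidated, pyroglu) triples exactly, so a ground-truth object can
never drift from its FASTA.

* **Precursors** follow the tripartite architecture: synthetic signal
  (Met + Lys n-region + 8–14 residue hydrophobic core from {L,I,F,M,W} + a
  c-region ending S·A), optional propeptide spacer (alphabet excludes
  basics, Pro, Gly, Gln so spacers cannot create or veto sites or fake
  PTMs), and mature payloads joined by basic sites, with a Gly appended to
  amidated payloads.
* **Transcriptomes** back-translate precursors with uniformly chosen
  synonymous codons (codon bias is immaterial to protein-space mining),
  flank them with in-frame stops and random UTRs of 30–90 nt, flip strands
  with probability ½, and add i.i.d.-nucleotide decoys with matched length
  distribution and target GC. No sequencing error, assembly artefacts or
  isotig redundancy are simulated, so a planted-recovery pass demonstrates
  rule correctness, not robustness to fragmented or erroneous assemblies.
* **Mining queries** are "related-species homologs": 60-residue windows of
  the planted precursors with conservative (BLOSUM62-nonnegative)
  substitutions at rate 0.2. The original screen used full-length arthropod
  precursors; a 60-residue window at 80% identity already clears the
  E < 0.01 threshold by many orders of magnitude and keeps the all-vs-all
  Smith–Waterman fast at the 500-decoy study size used throughout
  (the published assembly's size statement is internally inconsistent, and
  the desk-scale study size is the package's own choice).
* **Ct tables** put the reference gene at mean Ct 18 and each target at
  reference + 3 − log2(fold), with independent Gaussian noise (default sd
  0.3 cycles) on every measurement; 3 batches × 3 replicates per stage. The
  default fold profile encodes the reported qualitative pattern (SIFamide
  ≈6-fold and PDH ≈4-fold up in cyprids, ASTB ≈3-fold, TRP high in nauplius
  VI and adult, most genes down in adults) relative to the juvenile
  calibrator.
* **Settlement counts** are Binomial(20, p) per well, 3 wells × 3 batches
  per group and timepoint, counts independent between timepoints. The
  default scenario is (24 h, 48 h) metamorphosis probabilities
  AFSW (0.70, 0.85), DMSO (0.70, 0.85), 1 µM (0.67, 0.85),
  10 µM (0.20, 0.83), 100 µM (0.08, 0.82): strong inhibition at ≥10 µM
  after 24 h, a 1 µM effect too small to reach Tukey significance at this
  design size, and recovery by 48 h — the reported qualitative outcome.
  The effect sizes were calibrated by simulating the generator itself so
  that this qualitative contract holds in well over 90% of simulated
  experiments, the design requirement the default conditions must satisfy;
  no quantitative bioassay data exist to fit against.

## The synthetic catalog

The published supplementary precursor tables are not machine-readable, so
`catalog.py` carries a synthetic reconstruction pinned to every printed
fact: 16 families/subfamilies on 17 precursors (the two calcitonin-like DH
isoforms share one family), 64 mature peptides in total, 10 ASTB isoforms,
4 distinct TRP copies, 14-residue orcokinins, the exact PDH
(NSELINSLLGLPKIMNEAamide) and ASTC (SYWKQCSFNAVSCFamide) matures,
pyroglutamate sulfakinin-1 and acidic (sulfated) Tyr in all sulfakinins,
and ≥9 numbered ASTA isoforms. The remaining apportionment (ASTA 26
instances over 9 isoforms, orcokinin 6 copies, IRP B/C/A chains, singles
elsewhere) and all hormone-domain sequences are invented; catalog
precursors are deliberately spacer-free so that every processed segment is
a mature peptide and the catalog count is exact. Counting is per instance
(copies of identical peptides count separately), with a config flag to
deduplicate.

## Numerical and design notes

* Coordinates are 1-based inclusive everywhere a user sees them; frame
  translations carry an offset map back to forward-strand nucleotide
  coordinates.
* Local/global alignment tracebacks use the aligner's deterministic first
  alignment; only scores are contract-guaranteed, and the test oracles
  (plain-Python Gotoh DP, a literal codon table) share no code with the
  implementation paths they check.
* A zero-variance ANOVA input yields a flagged degenerate result (F = NaN),
  never an exception; Tukey α=0.01 flags are a subset of α=0.05 flags by
  construction.
* RACE/cloning confirmation is an input metadata flag on candidates, never
  computed. Disulfide pairing, phylogenetic interpretation, live database
  queries and 454 assembly are out of scope.

## Problem sizes

The shipped study conditions are: 16 planted precursors + 500 decoy
transcripts for discovery; 200 simulated experiments for the ΔΔCt recovery
and settlement-contract rates; 500 random pairs (≤20 aa) for the alignment
oracles and 1,000 random precursors for the excision-conservation property.
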