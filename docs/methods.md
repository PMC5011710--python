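# Methods

## Model and scope

`prfmap` treats a +1 programmed ribosomal frameshift (PRF) event as a
single-nucleotide skip at a "shifty stop".  A transcript is read in
frame 0 from its first base; the first in-frame stop codon either
terminates the ORF or, when the codon immediately 5′ of it matches a
slippery-motif pre-codon (and at least one complete codon follows the
skip), licenses a junction: translation resumes at `skip_pos + 1`,
i.e. in the +1 frame, at the codon that shares the stop codon's last
two bases.  Up to three junctions per gene are supported (serial
shifts 0 → 1 → 2 are observed in *Euplotes*); the terminal segment
ends at its first in-frame stop or the sequence end.  Coordinates are
0-based, intervals half-open; `skip_pos` names the skipped nucleotide
itself (the "U" of `AAA-UAA`).

Decoding uses the Euplotid nuclear genetic code (NCBI translation
table 10, via Biopython): UGA encodes cysteine and only UAA/UAG
terminate.  This is applied globally to conceptual translation;
selenocysteine insertion at UGA is not modeled.  DNA input is
normalized to RNA; ambiguity codes are rejected rather than rendered
as X because downstream mass arithmetic is undefined for X.

The motif catalog contains the classical `AAA-UAA`/`AAA-UAG` pair plus
ten novel slippery sequences reported for this organism
(`UUU-UAG`, `UUU-UAA`, `AUU-UAA`, `AUU-UAG`, `AAG-UAA`, `ACC-UAA`,
`AGA-UAG`, `UAU-UAG`, `CUU-UAA`, `AAU-UAA`).  Scanning is frame-aware
by default — only a stop that actually terminates the tracked ORF can
be a site, which is what distinguishes a junction from the ordinary
terminal stop of a non-PRF gene.  A naive any-position scan is
available (`frame_tracking=False`) for exploration.  Sites whose
7-mer windows overlap a previously accepted site are rejected with a
warning; stops in the +1 frame upstream of a junction are never
consulted (overlapping-ORF genes), because segment termination only
ever looks downstream of the skip.

## Digestion and masses

Fully specific digestion with protein termini as boundaries, up to 2
missed cleavages (configurable), peptide length 6–50 by default.
Protease dialects follow common search-engine defaults and are
declared, not inferred: trypsin cuts after K/R except before P; GluC
cuts after E only (the ammonium-bicarbonate dialect; after-D/E
available as `gluc_de`); chymotrypsin cuts after F/W/Y/L except before
P (after-M optional).  Fixed carbamidomethyl-C (+57.021464 Da) and
variable oxidation-M (+15.994915 Da, ≤ 2 sites per peptide to bound
the combinatorics).  Monoisotopic residue masses come from pyteomics;
peptide mass = Σ residues + water + Σ modification deltas; m/z =
(M + z·1.007276)/z.  I and L are kept as distinct letters with equal
mass.  The test suite cross-checks every mass against an independent
oracle that composes residues from elemental formulas and atomic
masses, and digestion against an exhaustive substring enumeration.

## Spectrum matching and FDR

The scorer is deliberately minimal: the fraction of theoretical
singly-charged b/y ions found within 0.1 Da in the observed peak list
(each observed peak may support at most one ion; the closest wins).
Commercial probabilistic scores are intentionally not reproduced: the
biological conclusions rest on peptide identity and accurate precursor
mass (20 ppm), not on a score scale.  Precursor charges 2–3 are
considered; fragments are singly charged.  Decoys are full-sequence
reversals (pseudo-reversal available); FDR is controlled at q = 0.01
first at peptide level (best score per sequence), then at protein
level (best surviving peptide per protein), each by the loosest score
threshold with #decoys/#targets ≤ q.  A single best match is reported
per spectrum, ties broken by smaller precursor error then
lexicographic sequence, making all outputs deterministic.

## Evidence classes and direction calls

Accepted peptides are mapped back to models by coordinates; peptides
whose sequence occurs in more than one model are excluded (unique
peptide accounting).  A peptide *spans* junction *j* iff it covers
residues *j* and *j + 1*; a peptide ending exactly at *j* is upstream.
Classes: **a** — any junction spanned (junctions are counted, not
peptides, so a two-junction gene with two spanning peptides is one
class-a protein); **b** — no spanning but coverage on both sides of
the first junction; **c** — downstream-only; **d** — upstream-only.
For multi-junction models we considered requiring every junction to be
flanked for class b, but that rule is not total — a model covered on
both sides of junction 1 with an unflanked junction 2 would fit no
class — so the first-junction rule is used; it is the unique choice
that keeps the classes a partition of the evidenced models.  Models
without junctions are never classified (class `none`) and enter the
summary only through the denominator.

A spanning peptide localizes the site (the junction's slippery site
and skipped nucleotide) and confirms the +1 direction when the
junction residue pair matches the pre-codon and the post-skip codon.
The −2 alternative at the same stop re-reads the codon starting two
bases before it and therefore inserts exactly one extra residue; at
every `AAA-UAR` context that codon is AAU (Asn, 114.043 Da), so the
two conceptual products differ by far more than the 20 ppm envelope
and a single precursor mass decides the direction.  Calls are `+1`,
`-2`, or `ambiguous` (unreachable at classical sites).

## Synthetic data: what it emulates, and what it does not

The generator draws genes with uniform codon usage over the 61
non-stop codons (an AT-rich preset is deliberately not the default, to
keep chance-motif rates predictable).  Study-condition defaults:
11.4% PRF genes; junctions per PRF gene 1/2/3 with probabilities
0.85/0.12/0.03; 94.2% of junctions classical (within classical, UAA
is used 9:1 over UAG, as UAA dominates reported sites), the rest
uniform over the ten novel motifs; mean gene length 150 codons
(desk-scale; segments are Dirichlet-split with a 25-codon floor so
peptides exist on both sides of every junction).  Genes end at their
terminal stop with no 3′ trailer, so a chance pre-codon before a
terminal stop can never satisfy the scanner's downstream-continuation
requirement — scanning the synthetic transcriptome therefore recovers
the planted sites with perfect recall *and* precision, a property the
tests assert.  Chance motifs in untracked frames remain as hard
negatives.

Protein abundance is log-normal (μ = 0, σ = 2 on the natural-log
scale); PRF proteins' abundance is multiplied by 0.4, encoding the
documented observation that frameshifted proteins are mostly
low-abundance.  Each theoretical peptide is detected independently
with probability `0.9·A/(A + 75)`; with ~100–150 detectable peptides
per protein this yields protein-level detection around 60–80% for
ordinary genes and visibly less for PRF genes, so the *detected* PRF
fraction falls below the planted 11.4% — the same direction and
rough size of bias as the real survey's ~8% vs ~11.4% gap.  Spectra
carry Gaussian precursor error (σ = 5 ppm), Gaussian fragment error
(σ = 0.01 Da), 10 uniform noise peaks in 300–1800 m/z, and charge 2
with probability 0.7 (else 3).  One spectrum per detected peptide.

Passing tests on these data show the pipeline's bookkeeping and
statistics are correct under the stated generative model; they do not
certify performance on real spectra, which have correlated noise,
co-eluting precursors, intensity structure and non-uniform codon
usage that the generator does not attempt.

## Numerical and reproducibility choices

All randomness flows from one integer seed through
`numpy.random.default_rng((seed, stage))`; identical configs give
byte-identical FASTA/MGF/TSV/JSON outputs.  Fragment complementarity
(b_i + y_{n−i} = M + 2·proton) is asserted to 1e−6; mass agreement
with the elemental oracle to 1e−6 Da; FDR thresholds use exact
rational comparisons on counts.  Degenerate inputs fail loudly:
empty proteins, `*` in digestion input, invalid residues, frames out
of range, malformed MGF blocks (missing PEPMASS) and inconsistent
slippery sites all raise with named offenders.

Problem sizes used by the checked-in studies — 1,000 genes for the
noiseless closure run and 10 × 300 genes for noisy parameter
recovery — are the package's chosen desk-scale defaults; they keep
each study in the tens of seconds while leaving hundreds of detected
proteins per run, enough for the binomial-interval recovery check to
be meaningful.

## Known limitations

- No stimulatory-element modeling (no Shine–Dalgarno or pseudoknot
  search) and no tRNA-level mechanism; motif context is the only
  signal, as in the underlying survey design.
- No homology triage for nominating novel-motif candidates; the
  scanner reports any cataloged motif whose stop terminates the ORF.
- Semi-specific/non-specific digestion, fragment charges > 1,
  isotope envelopes, retention time and quantification are out of
  scope.
- The minimum downstream ORF length after a junction defaults to one
  codon and is configurable; real surveys may have used longer,
  unstated thresholds.
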