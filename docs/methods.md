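# Methods

## Scope and model

The package models, at single-base resolution, the life of a self-integrating
cassette (SIC): design of the encoding microarray oligo, its in-vitro
conversion into a linear cassette, its genomic integration by homologous
recombination, and the sequencing-based quantification of the resulting
pooled clone library. All sequence operations are exact string operations on
A/C/G/T; biochemistry enters only as rules (overlap fidelity, restriction
cutting, arm matching, frame checking), not as kinetics.

## Coordinates and genome model

Coordinates are 0-based, half-open and genome-forward internally; GFF3 I/O
converts from the 1-based closed convention. `stop_codon_start` is the
leftmost genomic base of the STOP codon interval on either strand, so for a
minus-strand ORF it equals `cds_start`. For intron-containing ORFs only the
terminal exon is carried (C-terminal tagging touches nothing else); the STOP
location and total CDS length are derived from all exons. ORFs violating the
invariants (CDS length not a multiple of 3, annotated end not a STOP codon,
out-of-bounds intervals) are excluded at load time with a logged reason
rather than failing the whole genome. `N` bases are allowed in chromosomes,
but any candidate target or homology arm overlapping an `N` is discarded —
undefined bases can be neither synthesized nor matched.

## Target discovery

Candidates are every occurrence, on either genomic strand, of a PAM matching
TTV (V ∈ {A,C,G}) or TYN (Y ∈ {C,T}) immediately 5′ of a 20-nt protospacer
whose extent overlaps the terminus window (STOP codon ± 30 bp by default).
PAM classes TTC/TTG/TTA take precedence over the TYN catch-all where both
patterns match. Filters:

* **T-run** — spacers containing > 5 consecutive T are removed; such runs
  act as premature Pol III terminators within the crRNA gene. The 7×T
  terminator placed downstream of the spacer on the oligo is exempt by
  construction: the filter applies to the spacer only.
* **Off-target** — the estimator counts genomic sites (both strands) where
  any configured PAM is immediately adjacent to a perfect match of the 10
  PAM-proximal spacer bases; candidates above a configurable hit cap
  (default 10) are removed, and a perfect duplicate of the full
  PAM+protospacer anywhere else forbids the candidate outright. This
  seed-based surrogate is deliberately simple and fully configurable
  (seed length, hit cap); it is a conservative stand-in for more elaborate
  genome-wide specificity scores.
* **Destruction** — a candidate is "destroyed by insertion" when the
  contiguous PAM+protospacer string no longer occurs (either strand) in the
  locus after inserting the cassette payload at the insertion point. Targets
  that survive insertion allow recurrent cleavage and are penalized (or
  removed when `require_destruction` is set). The pre-hoc check and the
  post-hoc flag computed on the actually edited locus agree by construction
  and are tested for agreement.

Scoring is multiplicative over the features reported to matter:
w_pam = 3.0/2.0/1.5/1.0 for TTC/TTG/TTA/TYN, ×2.5 for a PAM-proximal CG/CC/GG
dinucleotide, ×3.5 for a destroyed target, ×1.5 for targeting the
non-transcribed strand. These defaults are qualitative calibrations — the
midpoints of the observed 2–3× and 3–4× fold ranges — not fitted values, and
all are configurable. Ranking is by descending score, then absolute distance
to the insertion point, then genomic coordinate and strand: a deterministic
total order invariant under input order. A global array-size cap is applied
as a seeded uniform draw over all surviving candidates, mirroring a random
fill of a fixed-size microarray. Nucleosome occupancy is deliberately not a
feature (no significant effect reported).

## Oligo layout and recombineering

Oligo segment order is `overlap_A | spacer | terminator | ha_down | BstXI |
ha_up | overlap_B`, where the overlaps (25 nt each) are identical copies of
the two cassette ends and double as the constant PCR priming sites. With the
fixed segments (25+20+7+12+25 = 89 nt) the two arms are balanced to hit the
midpoint of the 160–170 nt budget: 38 + 38 nt, comfortably above the 29-nt
floor. `ha_up` ends immediately 5′ of the STOP codon (automatically a codon
boundary); `ha_down` starts at the native STOP, which is therefore retained
downstream of the cassette, preserving 3′ regulatory sequence. Designs whose
arms would cross a chromosome end or an `N`, or that contain an accidental
second BstXI site, are rejected individually; pool design then falls back to
the next-ranked candidate of that ORF.

Circularization requires exact overlap matches — any substitution aborts
assembly, mirroring the junction-fidelity selection of overlap-assembly
chemistry. RCA is modelled as plain repetition of the circle; cutting the
concatemer at every BstXI site (`CCANNNNNNTGG`, a self-reverse-complementary
pattern, cut modelled at the site centre) yields n−1 identical SICs plus two
discarded terminal fragments. The 6-nt residual half-sites at the SIC ends
are retained in the sequence and ignored during recombination, a
sequence-level stand-in for the 3′-overhang chemistry and end resection. A
circle with zero or more than one site is an error (the latter is the
chimera guard). The cassette carries no endonuclease gene.

## Integration simulation

Both homology arms are located in the target chromosome by approximate
matching (edlib, ≤ 3 edits per arm, unique best location required); the
genomic span between the matches is replaced by the SIC core. Crucially the
SIC sequence — including any synthesis errors in its arms — is copied into
the genome, which is exactly how faulty oligos create frameshifted "dark"
clones. `in_frame` holds when the edited locus translates from the native
START to the tag's own STOP with the tag CDS at frame offset 0 and no
premature STOP; a 1-nt arm deletion shifts the offset and fails
deterministically. Arms that match nowhere, ambiguously, or not as a
colinear pair produce `success=False` with a reason (failed/ectopic
integration). The returned edited genome shifts downstream ORF coordinates
and drops ORFs overlapping the replaced span.

## Synthetic data

The generators encode the study conditions rather than idealized data:

* **Oligo pools** — per-base substitution and deletion probabilities
  linearly interpolated along the molecule, substitutions rising toward the
  3′ end (synthesized first; 0.001→0.005) and deletions toward the 5′ end
  (0.004→0.001), giving ≈ 40% error-free full-length molecules at 165 nt.
  Abundance is log-normal (σ = 1), the standard surrogate for the strongly
  skewed copy-number distributions such pools show.
* **Libraries** — clone classes drawn at the reported rates: off-target
  0.2%, contaminant (a design foreign to the experiment at its own cognate
  locus) 1.6%, dark clones 5% (within the observed 2–8% range of
  non-fluorescent cells), double uptake 0.5%.
* **Junction reads** — mate 1 starts at the constant cassette region and
  reads across spacer, terminator and 3′ arm into genomic sequence; mate 2
  is adapter-side (`barcode | UMI | constant anchor | genomic`). PCR
  duplication emits an exact number of copies per molecule so the
  duplication factor is itself checkable. Sequencing errors are uniform
  substitutions only — junction counting and UMI logic are what is under
  test, not basecalling. UMIs are drawn without replacement within a
  (sample, genotype): an idealized UMI space without birthday collisions,
  which keeps the molecule table exactly recoverable and makes the
  end-to-end identity a sharp test. Real UMI data would add a small
  collision loss at high depth; nothing downstream depends on its absence.
* **FACS bins** — eight gates at the published sorted fractions
  (5/20/20/20/25/5/5/1%, renormalized). Measured intensity is the
  genotype's true log-intensity plus Gaussian noise (σ = 0.5 against a
  between-genotype spread of σ = 1.5); gate boundaries are empirical
  quantiles of the pooled measured intensities at the cumulative fractions,
  and per-bin read counts are multinomial in the bin's genotype cell
  counts. The generator does not model optics, spillover or sorter drift,
  so recovery results speak to the estimator, not to cytometer physics.

All generators are deterministic under their seeds (byte-identical FASTQ
across runs) and emit annotation tables linking every molecule, clone and
read to its ground truth.

## Quantification

Junction references are `cassette anchor (30 nt) + spacer + terminator +
600 bp proximal genomic sequence`; the SIC-derived prefix (anchor + spacer +
terminator + 3′ arm) is the "homology span". A pair counts for design g iff
both mates match reference g, mate 1 starts at reference position 0, and the
inferred insert size exceeds the homology span — so free, unintegrated
cassettes can never count as genomic insertions. The internal matcher is
exact-20-mer seed plus mismatch-counting extension (≤ 4 mismatches, several
seed offsets per read so one error cannot mask a molecule); the second mate
is placed concordantly on the first mate's reference, as a paired-end
aligner would, because neighbouring loci can share genomic sequence between
references. Pairs whose mates disagree are rejected, not split. An external
SAM stream can substitute for the matcher; the counting rules only need
(reference, start) per mate.

UMI deduplication is the directional rule: visiting UMIs in descending count
order, v merges into an accepted representative u when Hamming(u,v) = 1 and
count(u) ≥ 2·count(v) − 1. Barcode demultiplexing assigns the unique barcode
within Levenshtein distance 1 and requires the barcode set itself to be
pairwise distance ≥ 3. Molecule classification assigns each observed
sequence to the design minimizing global edit distance (ties unassigned;
distance 0 = error-free) — the design set is always known here, so
model-based denoising is unnecessary.

## Statistics

Bin fractions are renormalized to sum to 1; bins with zero total reads are
dropped with a warning before the distribution is formed. The intensity
estimate uses raw bin indices (1..8), matching the estimator's definition;
mapping to log-intensity midpoints is a caller-side transform, deliberately
not applied by default. Copy-number normalization divides by the per-sample
median over detected designs; fold changes and the fraction beyond 2-fold
follow from the normalized values, with designs absent from one sample
reported as lost/gained rather than given a fold change. Fisher's exact test
(two-sided, via scipy's hypergeometric computation, cross-checked in the
tests against full enumeration) reports raw p-values with Benjamini–Hochberg
values alongside; odds ratios use the Haldane +0.5 correction only when a
cell is zero. Enrichment uses a 0.5-read pseudocount. The co-integrand model
draws two independent uptakes per double transformant; the heterozygous
fraction is 2q(1−q) — one half at equimolar ratio, which is why doubling the
observed heterozygote count estimates all co-integrands.

## Problem sizes and numerical choices

The bundled analyses run on genomes of 10–60 ORFs (9–48 kb), libraries of
60–200 clones, read sets of a few thousand pairs and FACS simulations of
500 genotypes × 10⁵ cells — sizes at which every oracle comparison is
exhaustive and the full suite runs in well under a minute per module. Ties
in candidate ranking, UMI ordering and molecule assignment are broken
deterministically (score, then distance, then coordinate; count, then
lexicographic; ties unassigned). Degenerate inputs — empty annotation,
all-zero bin distributions, zero-median samples, sub-minimum arms — return
flagged values or typed errors rather than silent results.

## Known limitations

The off-target estimator is a seed-count surrogate, not a specificity model;
no thermodynamic or learned on-target activity model is included. RCA
branching, chew-back kinetics and transformation efficiency are outside the
sequence-level model, as are basecalling error profiles and long-read signal
characteristics. Integration assumes a single nuclear genome copy and no
chromatin effects. The synthetic FACS model knows nothing of autofluorescence
or gate spillover; recovery correlations above 0.99 on synthetic data are an
upper bound, not a field expectation.
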