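# Methods

This note documents the models, conventions, parameter choices and
known limitations behind `carpamp`. It describes what the code does and
why; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Coordinate conventions and the haplotype key

Variant tables use 1-based, inclusive, gene-relative coordinates
(`cytb:117` is the 117th base of the cytochrome-*b* gene). Full gene
lengths default to 1141 nt for cyt*b* and 1551 nt for COI; the key's
highest positions (cytb 1066, COI 595) exceed the fragment lengths
typically Sanger-sequenced for such surveys, so fragment-relative
numbering is ruled out and whole-gene numbering is the only consistent
reading. Lengths are configurable for other loci.

The key's first row is the reference haplotype and must be fully
spelled out; other rows use `.` for "same as reference". A row that
spells out the reference allele explicitly is normalised to the
sentinel, so `parse → reconstruct → re-derive` is exactly the identity
(a property test).

The bundled silver carp key has 8 haplotypes (A–H) over 58 variant
positions (47 cyt*b*, 11 COI). Substitution counts per row against the
reference A are B=1, C=1, D=5, E=5, F=9, G=9, H=48. The closest silver
carp haplotype to the divergent, introgression-derived H is G at 45 nt
(F is at 47 nt); both values were verified with an independent counting
script before being frozen into tests.

## The diagnostic window and primer placement

The 135 nt amplified region is interpreted as the *between-primer
insert* occupying cyt*b* positions 114–248 inclusive (the primers bind
outside it). This is the only reading consistent with the key's
annotation that assay-discernable variants span 117–228: all ten of
those positions fall inside 114–248, and the first/last ones sit close
to but inside the boundaries. The alternative reading — the 135 nt
including a primer — would put discernable variants under a primer foot
and is rejected.

Within this window the haplotypes partition into six classes —
A/C, B, D, E, F/G, H — because C's only substitution (cytb 864) and the
F/G distinguishing sites lie outside the window. Class names join
member labels with `/` in alphabetical order. Two properties are
enforced by tests: windowed distance never exceeds full-length
distance, and growing a window can only split classes, never merge
them.

**One deliberate mismatch.** Synthetic backbones place the forward
primer immediately 5′ of position 114 and the reverse primer
immediately 3′ of position 248. The reverse-primer footprint then
covers position 258, where the primer pattern has a literal G but the
reference allele is A (haplotype H carries G there — the real template
under a primer can be polymorphic). The backbone keeps the reference
allele, so in-silico PCR (`extract_insert`) tolerates one mismatch by
default (`max_mismatch=1`). On reconstructed panels this is the only
mismatch that occurs; H's site is exact.

## In-silico PCR

IUPAC matching is asymmetric: primer codes are degenerate, template
bases must be concrete A/C/G/T; a template N fails every comparison.
Primer degeneracies (forward 48 = 2·2·2·2·3, reverse 16 = 2⁴) are
cross-checked against exhaustive expansion enumeration. A reference on
which a primer binds more than once is an error rather than
multi-amplicon output — the assay is single-locus. A
reverse-complemented reference is handled: the insert comes back
reverse-complemented at mirrored coordinates.

## Read model and verification

Reads are modelled as `spacer + primer + template` on both mates
(2×150 nt, substitution-only errors, no indels — consistent with the
fixed-length assay). Checks, in order:

1. **Spacer, exact.** Spacers are the index-hop sentinel; any
   tolerance would defeat that purpose. A hopped read keeps its origin
   library's spacers and therefore always fails the destination
   library's check (spacer pairs are unique per library).
2. **Primer, ≤ 2 IUPAC-aware mismatches** (configurable), then
   trimmed.
3. **Length.** A mate that reads through into the opposite primer
   exposes the template's true length, which must be within ±10 nt of
   the expected 135; primer dimers (short concatemers) fail here. The
   merged template is checked against the same band.
4. **Ambiguity.** Templates containing N are rejected under a separate
   ledger category (`ambiguous_base`), keeping ASV sequences strictly
   ACGT.

The per-sample ledger satisfies exact conservation:
`raw = verified + spacer_mismatch + missing_primer + bad_length +
ambiguous_base` and `verified = merged + no_overlap + excess_mismatch +
wrong_length`; a property test asserts this on simulated runs with all
artifact classes active.

## Merging

Mates are aligned by best ungapped overlap (scored by fewest
mismatches, ties to the longer overlap), requiring ≥ 20 nt overlap and
≤ 10 % mismatches within it. At disagreements the higher-quality base
wins (first mate wins exact ties); agreements keep the higher quality.
With 2×150 reads over a 135 nt insert plus 4–8 nt spacers, the overlap
is ≈ 100 nt, so merging is unambiguous in practice.

A consequence worth knowing: consensus corrects single-mate errors in
the overlap but not in the two single-coverage flanks (the first
≈ 13–16 and last ≈ 13–16 insert bases, depending on spacer lengths).
Surviving errors therefore concentrate at the insert's ends, and
multi-error reads whose other errors are corrected collapse onto exact
1-off sequences — error pileups at flank positions are *larger* than a
naive independent-error estimate. The denoiser handles them as long as
its error-rate parameter reflects the platform rate (below).

## Denoising

For a minor ASV at Hamming distance *d* from a more abundant parent
with *N* total reads, the expected number of parent reads miscalled
into exactly the minor's sequence is

    λ = N · (e/3)^d · (1 − e)^(L − d)

— the per-read probability of the exact *d*-substitution path, with
substitutions independent at rate *e* and the three alternative bases
equally likely. The minor is absorbed (counts added to the parent, so
totals are conserved) when the Poisson upper tail P(X ≥ count | λ)
exceeds α. Defaults: e = 0.001, α = 1e−6. Passes repeat to a fixed
point, so the operation is idempotent; ASV counts never increase.

Set `denoise_error_rate` to the platform's error rate. The λ above is
deliberately conservative for merged reads (consensus lowers the
effective per-base rate in the overlap while flank errors occur at the
raw rate); an *e* matching the raw platform rate absorbs flank pileups
correctly, while an *e* far below it leaves real error pileups in the
table as unassigned junk. Exact parity with error-rate-learning
denoisers is a non-goal; the parameters are exposed instead.

Only equal-length ASVs participate (fixed-length assay; no indel
model). Decisions use total counts across samples; per-sample counts
move with the ASV.

## Chimera removal

An ASV is removed as a bimera when some breakpoint splits it into a
prefix matching one parent exactly and a suffix matching another, with
both parents ≥ 2× (configurable) more abundant. Removed reads are
recorded in the ledger, not reassigned. The implementation is checked
against exhaustive breakpoint enumeration on small random tables.

## Calibration and controls

Positive controls contain an equal mixture of 10 mock species whose
inserts are ≥ 30 nt from every panel insert (emulating control taxa
absent from the study area). Any control ASV not exactly matching an
expected sequence is erroneous; the run's cutoff is the **largest
single erroneous-ASV fraction** across that run's controls (0 if none).
A sample ASV below the cutoff fraction is not trusted on abundance;
the boundary case (exactly at the cutoff) is retained.

No-template controls pass when their *verified* read count is ≤ 0
(configurable): raw reads that fail verification (hops into the NTC,
dimers) do not count against it. A failing NTC marks the whole run's
reports invalid while leaving the evidence inspectable.

## Assignment and the divergence flag

ASVs are assigned by Hamming distance against the panel's insert
sequences: distance 0 → `known` (class of the matched haplotype);
0 < d ≤ 2 with a unique best species → `novel`; an exact inter-species
tie → `ambiguous` (reported, never silently resolved); otherwise
`unassigned`. `novel_max = 2` reflects that newly observed wild
haplotypes tend to sit 1 nt from known ones, while species in this
group are ≥ 14 nt apart at this locus. Assignment is deterministic and
invariant to panel ordering (property test). Length-mismatched ASVs are
unassigned outright.

A below-cutoff ASV is normally removed, but is **flagged**
(`below_cutoff_flagged`, requiring confirmation) when it (i) assigns to
a panel species and (ii) differs from every retained ASV in its sample
by more than 10 % of the insert length (> 13.5 nt for 135 nt, i.e.
≥ 14). Such an ASV cannot be an error derivative of anything retained —
the motivating case is a bighead carp haplotype at 0.07 % of reads,
14–15 nt from the retained silver carp haplotypes. All positive panel
detections carry `requires_confirmation`: a detection stands only after
re-sequencing on an independent run, which is outside this package's
scope.

Detection summaries count only `known`/`novel` rows as species
detections; retained ASVs that are unassigned or ambiguous appear in
the per-ASV rows but never as a detected species. Fractions are
computed over the sample's merged-read total and reported to 4
decimals.

## Synthetic data

The simulator is the package's study-condition generator, not a
convenience fixture:

- **Backbones** are seeded pseudorandom sequences with reference
  alleles installed at all variant positions and concrete primer
  expansions at the binding sites (degenerate positions keep a
  compatible random draw; the position-258 rule above applies).
  Identical seeds give byte-identical output, through to FASTQ.
- **Reads** carry spacer + primer oligo + template; errors are
  injected per base at rate *e* with Q35 at correct bases and Q15 at
  error bases, making merge tie-breaking exercisable.
- **Artifacts**: index hops (read emitted into another library,
  keeping origin spacers), primer dimers (0–40 nt junk templates),
  bimeric templates (uniform breakpoint). NTC libraries emit only
  dimers plus whatever hops into them. Every read gets a truth-table
  row (origin, library, template, artifact class); artifact counts
  match binomial expectations within 3σ over 20 replicates (test).
- **Bighead panel**: real bighead reference sequences are not bundled;
  synthetic stand-ins place haplotype L exactly 14 nt from silver A
  and 15 nt from silver B inside the window — the documented
  assay-scale separations — with I–K 1–3 nt from L. They are labelled
  synthetic wherever they appear.
- **Mock control species** are random inserts ≥ 30 nt from all panel
  inserts.

Because templates are drawn multinomially, the generator itself
contributes sampling noise to composition checks: at 5,000 reads the
per-class standard deviation is ≈ 0.6–0.7 pp, so a ±3 pp recovery band
is ≈ 4–5σ of generator noise plus pipeline effects.

What passing simulation tests do **not** show: performance on real
instrument error profiles (quality-by-cycle decay, indels, context-
dependent errors), real index-hopping mechanisms, PCR amplification
bias, or taxa outside the curated panel.

## Problem sizes used

Desk-scale runs use 400–5,000 reads per sample (real runs of this assay
produce ~10⁵ reads per sample; all pipeline rules are per-read or
per-fraction and scale-free). The composition-recovery and recall study
uses 20 seeded replicates at 5,000 reads per sample and e = 0.005;
oracle comparisons for the denoiser and chimera remover use randomized
tables of ≤ 10 ASVs, where exhaustive enumeration is exact.

## Known limitations

- No indel handling anywhere (fixed-length locus assumption).
- Demultiplexing is assumed done upstream; the manifest maps one FASTQ
  pair per library.
- The Poisson denoiser ignores quality scores and position-dependent
  error rates.
- Hamming assignment against a curated panel replaces database search;
  taxa not in the panel come back `unassigned` rather than receiving a
  nearest-species guess.
- Abundance fractions are not biomass estimates.
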