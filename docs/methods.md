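# Methods

## The measurement model

A PEM-seq library is a set of molecules, each reporting the fate of one
target allele. Every molecule is modelled as

```
[bait: primer → junction] + [untemplated insertion] + [prey: junction → sonication end]
```

with a random molecular barcode (RMB, 14 nt) attached during adapter
ligation. R1 (150 bp) reads from the bait primer across the junction into
the prey; R2 reads the RMB followed by the reverse complement of the
sonication end of the fragment. Two molecules from the same biological
clone share the junction nucleotide and orientation but have independent
RMBs and sonication ends; PCR duplicates of one molecule share all three.
That asymmetry is the entire basis of the dedup and expansion analysis.

## Toy reference

Analyses run against a deterministic desk-scale reference: two 2 Mb random
chromosomes, the SpCas9 protospacer + AGG PAM embedded so the blunt cut
(3 bp 5' of the PAM) lands at chr1:1,000,000, and a fabricated 2.8 kb
retroviral vector of 400 bp LTR + 2 kb payload + identical 400 bp LTR. The
2 Mb scale is the smallest at which the 500 kb small/large-deletion and
translocation bounds operate verbatim with room on both sides; the vector
sequence itself is arbitrary (the real vector sequence is not public), but
the LTR direct-repeat structure — which creates genuinely ambiguous
integration junctions — is preserved. A gene/exon model (a three-exon
Myc-like gene whose first intron holds the cut, plus ten fixed genes) backs
hotspot annotation and coding-impact scoring. Coordinates are 0-based
half-open everywhere; only report text is 1-based.

## Simulator

Outcome classes are drawn i.i.d. from a configurable mixture. Defaults are
the study conditions of the activated-T-cell preset: perfect 5%, insertion
20%, small deletion 55%, large deletion 15%, translocation 1%, vector
integration 4%.

- **Insertions**: 1-bp T with weight 0.73; the remainder geometric over
  2–20 bp with random sequence.
- **Small deletions**: geometric (p = 0.03), truncated to 1–100 bp,
  giving the declining near-cut profile.
- **Large deletions**: log-uniform over (100 bp, 500 kb] — scale-free
  between the two bounds; the true law is unknown, and nothing downstream
  depends on it beyond spanning both boundaries.
- **Translocations**: uniform over the genome excluding ±500 kb of the cut
  (and an 800 bp chromosome-end margin so fragments fit), random strand.
- **Vector integrations**: positions weighted 3× inside either LTR (a
  modest enrichment parameter, configurable), random strand; junctions
  closer to a vector end than ~70 bp of readable prey are not drawn — they
  would be physically unrecoverable from a 150 bp read.
- **Clonal expansion**: founders drawn from the translocation class (class
  mix configurable), copy numbers log-series (p = 0.98) conditioned on
  5–1000 copies. The lower bound matches the hotspot cutoff: a clone below
  5 copies is undetectable by definition, and reported clone sizes range
  from 5 to tens of thousands with a heavy tail. Each copy gets a fresh
  RMB and fragment length.
- **Fragments**: truncated normal, mean 300 bp, sd 50, size-selected to
  [300, 700] (sonication to ~300 bp followed by gel selection), clipped
  where the prey runs off the reference.
- **PCR duplication**: 1 + Poisson(rate) read pairs per molecule; the rate
  (default 1) is a free parameter of library amplification.

Presets: `activated` (above, no expansion) and `inflammatory` (12–17
expanded translocation founders, background translocations halved to 0.5%,
otherwise identical chemistry).

The generator emulates the statistical structure the analysis relies on; it
does **not** model indel-containing alignments, chimeric 3+-segment reads,
base-quality variation, resection on the bait side of the cut, or real
integrase site preference. Passing tests therefore certify the analysis
logic under the stated model, not performance on production sequencing.

## Junction extraction

R1 must begin with the 20 bp bait primer (≤2 mismatches). The bait is
extended from the primer along the reference; extension tolerates an
isolated substitution only when followed by 12 further matches, so interior
sequencing errors do not truncate the bait but running into the prey
(expected to match ~¼ of positions) stops it. A full-length match is a
perfect/uncut read.

The remaining suffix is seeded with exact 20-mers (2-bit-packed,
binary-searched against a sorted index of genome + vector; reverse-strand
hits via the seed's reverse complement) and every candidate diagonal is
extended over the whole read; the highest-matching diagonal wins. Ties are
resolved to the vector first (this is what maps LTR-internal junctions),
then to the lexicographically smallest locus, and are flagged `ambiguous`.
Suffixes shorter than `min_prey_match` (20 bp) are dropped and counted.

**Breakpoint resolution.** With bait end `e_bait` (maximal) and prey start
`s_prey` (maximal leftward extension of the prey alignment):

- overlap (`e_bait ≥ s_prey`) → microhomology of that length, assigned to
  the bait side: the reported prey coordinate is advanced past the shared
  bases. This makes the prey-side nucleotide the stable unit that hotspot
  binning aggregates.
- gap → scored like an aligner scores it: an untemplated base costs 2, a
  substitution against either flanking frame costs 3; the cheapest
  interpretation wins and ties stay insertions. Concretely a gap of m bases
  with h mismatches against the prey (or bait) frame is absorbed into that
  side when 3h < 2m; absorbing into the bait re-extends it exactly through
  any microhomology. A 1 bp gap is always an insertion (h ≥ 1 ⇒ 3 ≥ 2), so
  the dominant +1 T product is never rewritten; a single error adjacent to
  the junction no longer shifts the breakpoint.

One consequence is canonicalisation of templated insertions: an inserted
base that copies adjacent reference is indistinguishable from a tandem
duplication, and the convention reports it as prey resuming *behind* the
bait end (a negative deletion d, with |d| the insertion length). The
classifier maps small negative d back to the insertion class, so allele
identity and length are preserved. The truth tables written by the
simulator are compared to extraction output after applying this same
convention (`canonical_junctions`), which is exact on error-free reads.

Junctions aligned wholly inside an LTR are intrinsically ambiguous between
the two identical copies; they are reported under the 5' copy (the
tie-break above) and flagged. Fragment length is recovered by locating the
reverse-complemented post-RMB part of R2 inside the reconstructed fragment
template; for LTR-canonical junctions the mirrored 3'LTR frame is tried as
a fallback, since only there can the fragment continue into the payload.

## Deduplication and expansion diagnostics

Reads collapse on (junction signature, fragment length); within a key,
RMBs merge by directional network: a barcode absorbs a neighbour within 1
mismatch when its read count is ≥ 2× the neighbour's − 1 (the standard
UMI-error rule). The merge iterates to a fixpoint, which makes
deduplication idempotent — a one-pass merge is not, because absorbed counts
can newly qualify a founder. Keying on fragment length is the default
(both features are independent evidence); a flag drops it for the
RMB-only variant.

Per prey site (1 bp, stranded), the diagnostics compare reads, molecules,
distinct RMBs and distinct fragment lengths: ≥5 molecules with ≥90% RMB
diversity → `expanded`; a ≥5-read pileup on a single RMB →
`pcr_artifact`; otherwise `singleton`. The thresholds are configuration;
5 mirrors the hotspot cutoff. The diagnostics are meaningful per junction
class — deletion endpoints legitimately recur near the cut, so expansion
verdicts are read off the translocation (or other single-class) track.

## Classification

Rules apply in order: vector prey → `viral_integration`; other chromosome,
orientation-inconsistent (inversion-like, flagged — the taxonomy has no
inversion bin and deletions imply sense continuity), or |prey − cut| >
500 kb → `translocation`; same-chromosome sense junctions by signed offset
d = prey − bait_end: 1–100 → `small_deletion` (boundary inclusive),
>100 → `large_deletion`; d = 0 with insertion → `insertion`, without →
`perfect`; small negative d → `insertion` (tandem duplication, see above),
large negative d → `translocation`. Editing efficiency is 1 −
perfect/total; class frequencies are quoted among editing events (the
perfect class is excluded from the denominator). "Events" are always
deduplicated molecules, never reads. Coding impact scores a deletion by
its span, anything else by a point disruption at the cut, and a
translocation by the bait-side interval only (the partner locus is
reported but not counted).

## Normalization and hotspot calling

Samples are normalized to the smallest sample's editing-event count by
seeded uniform subsampling without replacement — the simplest reading of
"normalized to the same editing events"; junction counts then scale
hypergeometrically. Published per-figure normalization targets are not
recoverable from printed totals, so no attempt is made to match them
beyond the procedure itself.

Hotspots are threshold runs on the per-nucleotide junction-count track of
deduplicated translocation molecules: maximal runs of consecutive positions
with count ≥ 5 and run length ≥ 1 bp, exactly the bdgpeakcall `-l 1 -c 5`
semantics. No p-values or multiple-testing machinery — the published method
is a fixed-count cutoff, and fidelity to it is the point. Strands are
pooled for calling; orientation uniformity (max(plus, minus)/total) is
annotated on the call, 1.0 being the clonal signature. Gene overlap is
annotated from the BED model.

## Numerical and formatting choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; per-sample streams derive as `[seed, i]`.
Sorting is always explicit (site, then barcode; ties in allele and
proportion tables break lexicographically), so every table is reproducible
byte for byte; report floats use 6 significant digits. Degenerate inputs
are contracts: empty event tables raise, an all-perfect sample reports
zero frequencies with a flag rather than NaN, an empty FASTQ aborts the
pipeline naming the file.

## Problem sizes

The shipped presets default to 150 000 molecules — the scale of a real
library — which the vectorised simulator handles in ~1 s; read-level
stages (emission, extraction) are exercised at 8 000–20 000 molecules,
where the full FASTQ round trip completes in tens of seconds while
exercising every outcome class including the LTR-ambiguous corner.

## Known limitations

- The prey aligner is exact-seed + gapless extension: a true indel inside
  the prey segment, or more than ~1 error per 20 bp preventing any clean
  seed, loses the read. Production data would want an indel-aware aligner;
  the module boundary (`extract_junctions`) is where one would slot in.
- Dedup assumes RMBs of one length and at most the directional-network
  error structure; no quality-aware consensus is built.
- The ±500 kb bound classifies same-chromosome junctions by distance only;
  a biological translocation landing inside the window is counted as a
  large deletion, exactly as the operational definition dictates.
- Site sharing across samples is exact-position (binnable); it does not
  model near-miss junction scatter.
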