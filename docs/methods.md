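# Methods

This note documents the models, conventions and numerical choices behind
the package, what the simulator does and does not emulate, and the
limitations a user should know before trusting a number.

## Coordinates and formats

All internal coordinates are 0-based half-open; AGP (1-based inclusive)
and VCF (1-based, left-anchored indels) are converted at the parser
boundary and back on write. Assembly–assembly alignments travel as PAF
with a typed `rc:A:R|N` tag carrying the best-hit reciprocity class, and
an optional `cg:Z:` CIGAR that refines a block into co-linear ungapped
segments; a block without a CIGAR is a single ungapped segment. On
minus-strand blocks the target offset decreases as the query offset
increases; projection is strand-aware linear interpolation within the
containing segment, and positions inside query-only (insertion) regions
are "unprojectable" — a data condition, not an error.

## Collapse/expansion classification

Per-base labels come from segment-resolution coverage (envelope counting
would bleed labels across indels inside a block): covered by reciprocal
and nonreciprocal best hits → collapsed; nonreciprocal only → expanded;
reciprocal only → unique; none → unaligned. Candidate regions are maximal
inter-gap segments, using AGP gap rows as separators (N-runs ≥ 10 bp as a
fallback when no AGP is given), kept iff their non-N fraction strictly
exceeds 0.5. Regions touching sequence ends are not treated specially.
Top-k interval lists sort by length with ties broken by (sequence, start).

## Read movement

* Unchanged regions are computed purely from AGP provenance: per
  component accession.version present in both assemblies, the intersection
  of component coordinates mapped into both object coordinate systems;
  orientation mismatches are excluded, and duplicate placement of one
  component span within one assembly is an error.
* "Uniquely mapped" is operationalized as primary + MAPQ ≥ 20
  (configurable). The threshold matches the MAPQ filter used in the
  pileup and coverage analyses, giving one uniqueness notion throughout.
* A pair moves if **either** mate's primary B-placement midpoint lies on a
  different component accession.version than its A placement (a version
  bump counts as changed: a re-finished component is new sequence). The
  midpoint decides component assignment when a read straddles two AGP
  rows. Per-read categories are then assigned only to the mates whose own
  component changed.
* Centromere overlap for the ONCEN/OFFCEN/UNCEN categories means any
  overlap of the aligned span with a centromere BED interval; a scaffold
  is centromere-associated if the BED carries any interval on it.
  Same-chromosome identity is by sequence name, which the two assemblies
  share.
* Rescue fractions are read-level, and 0/0 is reported as undefined
  (`None`), never as 0.

## Base validation

Pileup tallies count primary alignments with MAPQ ≥ 20; secondary and
supplementary records are excluded. SNV sites count the aligned base,
with a spanning deletion recorded as a distinct `del` allele (which
triggers the unexpected-allele review flag). Indel sites count presence
or absence of the left-anchored event at the anchor: a read is assessable
only if it aligns through the junction (for deletions, across the whole
deleted span), so reads ending at the anchor are not counted toward either
allele.

Classification anchors on the majority allele — required so homozygous-
alternate sites are detectable at all — with homozygosity at fraction
≥ 0.90 for SNVs and ≥ 0.70 for indels; the boundary counts as homozygous.
Review triggers: >2 alleles at an SNV, or any observed allele outside the
expected ref/alt pair. The indel cutoff is applied to the majority allele
(the alternate-specific reading is indistinguishable for biallelic tallies
with presence/absence alleles). Decisions are a pure function of the
classification: homozygous-alternate → apply; homozygous-reference →
retain (candidate refuted); heterozygous in a source-library component →
retain (the allele is real in that haplotype); heterozygous elsewhere,
any review/no-data, and every non-homozygous-alternate indel → manual
review.

Mini-contig validation aligns the contig to its reference window with an
end-free affine alignment (match 1, mismatch −2, gap open −4, gap extend
−1, free end gaps on both sequences) — a scheme that favors the
single-edit interpretation the check asserts. Indel differences are
left-normalized before comparison so homopolymer placement ambiguity
cannot produce spurious failures; a contig aligning with < 80% of its
length inside the window is unalignable.

## Coverage and remap transitions

A site is covered iff ≥ 1 primary MAPQ-≥20 alignment overlaps its
position. Remapping projects the anchor base through every containing
block, deduplicating placements at exact (sequence, position, strand) —
the conservative choice absent any published fuzz radius; a site is
ambiguous with ≥ 2 distinct placements on primary-assembly sequences,
alternate-loci placements being reported but not counted. The
gained/lost protocol follows each site's *unique reciprocal-best*
placement — the behavior of a default remap, which prefers first-pass
reciprocal alignments — while the ambiguity flag continues to consider
all placements; this separation mirrors the two distinct analyses the
method comprises. Region groups merge sites by single linkage within
100 kb (configurable; the grouping radius is a reporting convention, not
an inference).

## The simulator

The simulator is the study's ground-truth generator: a donor genome (the
biological truth), assemblies A (old) and B (curated) derived from it by
implanted events, sample reads, and candidate sites.

**Donor.** i.i.d. bases at GC 0.41; one alpha-satellite-like tandem array
per chromosome (171-bp monomer, 5% per-copy divergence — enough variation
that per-copy alignment is nontrivial while the array remains a coherent
read sink); segmental-duplication pairs at ~98% identity placed in
opposite chromosome arms. All randomness flows from one integer seed
through named generator streams, making every output byte-reproducible.

**Events.** False duplication (near-identical extra copy in one assembly),
collapse (one donor segdup copy absent from A), gap closure (A carries a
50,000-bp N gap — the reference convention for unsized gaps, which
deliberately overestimates the real insertion, 6 kb by default), inversion,
single-base error (component version bump), retiling (new accessions, same
sequence), centromere model (satellite array in B, N gap in A), and
alternate locus (diverged extra scaffold in B's full assembly only).
Truth labels are computed from the event list analytically — expanded =
duplicate copies, collapsed = their homologous primary spans — so classifier
tests against them are not circular.

**Aligner model.** Truth placements use a deliberately minimal model:
MAPQ 60 for a uniquely resolvable placement; MAPQ 0 for reads whose span
lies inside a window with a zero-divergence duplicate copy elsewhere in
the same assembly, with such reads deterministically placed at the
duplicate copy (the tie-break). Reads are placed only when their span is
contained in a contiguous donor-backed run (boundary-straddling reads are
truth-unmapped, standing in for soft-clipped alignments). Reads from a
collapsed (removed) segdup copy map onto the kept partner copy at MAPQ 60
with mismatches, which is both what a real aligner does and the mechanism
behind collapse-driven movement. This binary MAPQ model realizes the
coverage-loss and read-movement phenomena exactly and reproducibly; it
does not model intermediate MAPQ values, soft clips, chimeric alignments,
or error-dependent mapping noise.

**Reads.** Pair counts are Poisson per source at half depth per haplotype;
inserts are normal (mean 400, SD 50), truncated at the read length
(150 bp); per-base substitution errors optional (0 by default — the truth
checks are exact only for error-free reads). The sample comprises two
donor haplotypes (differing at planted candidate sites), one source per
alternate-locus haplotype, and optionally a novel sequence absent from
both assemblies (so the full-assembly rescue fraction has a nontrivial
denominator).

**Candidate sites** are planted on unchanged, donor-backed A sequence,
spaced beyond two read lengths so pileups do not interact, with exact
type/genotype counts by largest-remainder apportionment. The calibration
panels (`site_panel`/`simulate_site_reads`) use *exact* per-site depth so
the heterozygous-call-rate has a closed form: at depth 30 and cutoff 0.90,
P(HET) = P(4 ≤ Binomial(30, ½) ≤ 26).

**What passing tests show — and do not.** Exact truth recovery on these
fixtures demonstrates the *bookkeeping* is correct: definitions, coordinate
arithmetic, filters, and decision rules. It does not demonstrate
robustness to real aligner behavior (MAPQ landscapes, clipping, duplicate
reads), real satellite structure, sequencing error profiles, or
genome-scale repeat content — all of which the simulator idealizes.

## Pipeline

Stages run in dependency order (simulate → collapse/expand → read
movement → base validation → variant transition); each stage is a pure
function of files under the working directory, so re-running one stage
from cached upstream outputs is bit-identical to a full run, and a fixed
config + seed gives a byte-identical bundle. The summary JSON records
every resolved default and a truth-versus-called concordance section. The
bundled 10-Mb fixture (4 × 2.5 Mb, ~50k pairs at 1.5×) exercises the full
event suite; note that at 1.5× coverage the per-site analyses are
depth-starved by design — their concordance is reported honestly rather
than tuned — while the movement and label analyses remain exact. The
problem sizes throughout (hundreds of kilobases to ten megabases, 4,000–
10,000-site panels) were chosen as the smallest scales at which every
mechanism appears with comfortable counting statistics.

## Known limitations

* Unchanged-region detection trusts AGP provenance; it cannot see
  sequence-identical components relabeled under new accessions (they count
  as changed, by design).
* Movement categories assume the two assemblies share chromosome naming.
* The remap ambiguity radius is exact-coordinate; real duplicated
  placements that differ by a few bases would need a fuzz radius.
* `decide_update` routes heterozygous candidates outside source-library
  components to manual review; an automated population-frequency check is
  out of scope.
* The simulator's alternate-locus scaffolds carry no truth alignment to
  the primary assembly, so alt-aware remapping is exercised only through
  constructed blocks in tests.
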