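# Methods

This note documents the models, conventions and numerical choices behind
`haplomite`, and what the synthetic-data generator does and does not
emulate.

## Sequence model and conventions

All coordinates are 0-based, half-open. Sequences are uppercase IUPAC DNA
(`ACGT`, ambiguity codes, `N`, and `-` for alignment gaps). The genetic
code defaults to NCBI translation table 5 (invertebrate mitochondrial:
`TGA` = Trp, `AGA`/`AGG` = Ser, stops `TAA`/`TAG`); both the table and the
reading-frame offset are configuration, and `infer_frame` estimates the
frame as the one minimizing in-frame stops over a reference panel (ties
resolved toward frame 0, with a warning when no panel member is stop-free
in any frame).

Trimming a ragged multi-study alignment follows two policies: keep the
maximal contiguous column window whose coverage (fraction of rows with
data) meets a threshold and drop rows still missing data inside it, or
keep the full span and drop rows with missing flanks. Which characters
count as "missing" is itself a convention: merged multi-study alignments
pad non-overlapping flanks with `N`, so the default treats both `N` and
`-` as absent; the end-to-end pipeline instead treats only `N` as missing,
because in a curated alignment an internal `-` is a real indel — notably
the frameshifting deletion of a pseudogene lineage, which must survive to
the screening stage rather than truncate the analysis window. Haplotype
collapsing excludes (and logs) rows containing ambiguity codes, mirroring
the field practice of discarding unreliable double-peak reads; the
pipeline keeps gapped rows for the same reason as above, while the
function default excludes them.

## Diversity statistics

Haplotype diversity uses Nei's small-sample-corrected estimator
`Hd = n(1 − Σ pᵢ²)/(n − 1)`, which equals the probability that two
individuals drawn without replacement carry different haplotypes (this
identity is the test oracle). Segregating sites are counted per farm over
the haplotypes present; gaps are a fifth state excluded from S by default
(configurable). Farm profiles follow the three-way classification used for
this mite: a single typical haplogroup; two or three typical haplogroups
including C (flagged as the high-S/h pattern — deep intergroup divergence
adds many segregating sites per haplotype without proportionally raising
Hd); or any atypical (unassignable) haplotypes present.

## Minimum spanning network

With ε = 0 the MSN is the union of all minimum spanning trees of the
haplotype Hamming-distance graph. The implementation processes edge-weight
classes in increasing order (Kruskal over classes): an edge is kept iff it
joins two components that were distinct before its class was processed,
and it is additionally marked `in_every_MST` iff it is a bridge of its
class subgraph after contracting previously connected components (parallel
class edges between the same component pair demote both). Tests verify
this against two independent characterizations: exhaustive spanning-tree
enumeration (≤7 haplotypes) and the forced-edge/removed-edge MST weight
test. Gaps count as a fifth state in the Hamming distance, so a
one-base deletion is one mutation step.

The star score operationalizes the founder-expansion pattern: the modal
haplotype's frequency share times the fraction of the remaining haplotypes
within ≤2 mutations of it. A monomorphic sample scores 1 by convention
(degenerate star). High scores mark expansion; low scores mark the
balanced, scattered pattern characteristic of co-amplified pseudogene
swarms. The threshold separating the two (0.5) belongs to the screening
configuration, not to the statistic.

## Haplogroup assignment

Queries are assigned to the nearest reference by p-distance (computed over
positions where both sequences are unambiguous). The unassignability
threshold τ = 0.03 sits between the within-star scale (≤2 mutations,
~0.004 on 471 bp) and the intergroup scale (≈0.05–0.09), so every member
of a typical star lands on its haplogroup while pseudogene lineages
(≈0.10+ from every reference) are reported `atypical_unassigned`. The
bundled synonymy table maps each study's identifiers to canonical labels
with a status (typical / cryptic / numt); unknown identifiers raise — the
mapping never guesses.

## Trees and the resolution-retention diagnostic

Trees are neighbor-joining over p, Jukes–Cantor or Kimura-2-parameter
distances (saturated pairs fall back to p with a warning), with support
from B column-resampling bootstrap replicates; the support of a group is
the percentage of replicates containing the bipartition separating it from
everything else, and its stem length is that bipartition's branch length
in the point tree (0 if absent). A distance method is used deliberately:
the diagnostic depends on the *differential* signal between position sets,
not on likelihood machinery, and it keeps the whole analysis fast and
deterministic.

The diagnostic itself: in a functional coding fragment most fixed
differences are synonymous third-position changes, so restricting the
alignment to first codon positions collapses the resolution of genuine
haplogroups, while a pseudogene lineage — evolving position-uniformly —
keeps a long, well-supported first-position stem. A group "retains
resolution" when

* its pos-1 bootstrap support ≥ τ_support (default 70),
* its pos-1 stem ≥ τ_stem × its all-positions stem (default 0.5), and
* its pos-1 stem ≥ 0.015 substitutions/site in absolute terms.

The absolute floor encodes "long branch": 0.015 on a 157-column
first-position alignment corresponds to at least three independent
first-position steps. One or two first-position changes arise routinely in
functional groups (sporadic nonsynonymous polymorphism — with ~12
substitutions per haplogroup stem and a 5% per-substitution chance of
landing on position 1, two or more occur in ~10% of groups), whereas a
relaxed-selection lineage at ~10% divergence carries a dozen. Groups
spanning all taxa or a single taxon are degenerate and flagged as such.

## NUMT screening

Five warnings are evaluated per candidate group (the haplotypes of one
assigned label within one building):

* **W1** — amino-acid segregating differences against the reference panel
  ≥ 3 ("several", configurable), counted as alignment positions where some
  group member shows a residue absent from every reference; and/or a
  retained first-position resolution per the diagnostic above. Stop codons
  are recorded separately. The retention branch matters because the
  absence of stop codons is not evidence of functionality.
* **W2** — tree discordance: the minimal bipartition side containing all
  typical references plus the whole group also contains an outgroup taxon.
  This fires for a lineage placed among the congeneric outgroups while a
  cryptic sister lineage to the typical clade (the L1/D pattern) does not.
  Requires ≥2 outgroup taxa; an unresolvable placement is reported
  indeterminate, not fired.
* **W3** — balanced multiplicity: within-building Hd > 0.70 among the
  group's members with a star score < 0.5. Samples under ~20 individuals
  per henhouse are flagged low-n (the pattern needs intensive sampling).
* **W4** — chromatogram proxy: more than 10% of the building's raw
  (pre-exclusion) sequences exceed a 2% per-sequence ambiguity-code
  fraction, the in-silico signature of mito+NUMT co-amplification double
  peaks. No chromatogram parsing is attempted; the consensus-with-IUPAC
  representation is the supported proxy.
* **W5** — nuclear corroboration: a mitochondrially divergent group whose
  carriers share nuclear (Tpm) alleles with carriers of typical
  haplogroups cannot be a reproductively isolated species.

Verdict rule (an explicit codification, since qualitative advice to
"consider several criteria" must become a decision procedure): any
in-frame stop codon ⇒ `numt_suspect`; else ≥2 of W1–W4 ⇒ `numt_suspect`;
else a divergent group with private nuclear alleles ⇒ `cryptic_candidate`
(also when nuclear data are absent, with an explicit flag), with shared
alleles ⇒ `numt_suspect`; else `typical`, with a manual-review flag when
exactly one warning fired. Adding a stop codon can only move a verdict
toward `numt_suspect` (a tested monotonicity invariant).

## Heterozygote phasing (indel-shift decoding)

A heterozygote whose two intron alleles differ by one fixed-length indel
(3–7 bp in this intron) yields a superimposed trace in which, downstream of
the indel at position p, every consensus column i shows
`{X[i]} ∪ {Y[i]} = S[i]` with `Y[i] = X[i+L]` except at substitution
sites (X the long allele, Y the short). Positions of X congruent mod L
therefore form independent chains, and each chain is decoded exactly by a
Viterbi-style dynamic program minimizing the number of implied
substitutions. Hypotheses (p, L) are scanned — p near the first ambiguous
column, L up to 7 — and ranked by explained ambiguity, then by total
mutational events (substitutions + 1 for the indel), so a lone double peak
is read as a substitution rather than a spurious deletion. A
branch-and-bound cap (seeded by the no-indel reading) keeps the scan fast.
Failure is declared when the winning overlay leaves >10% of ambiguous
columns to be absorbed by substitutions — the signature of multiple indels
or unusable trace quality.

Two identifiability limits are inherent to the method, not to this
implementation: the phase of heterozygous sites *upstream* of the indel is
not determined by a single trace (both assignments produce the same
overlay), and occasional overlay coincidences downstream admit a tied or
more parsimonious alternative reading. Such outputs are returned with low
confidence; the intended workflow resolves them against the homozygote
allele catalog (`match_against_catalog`), which never merges novel alleles
silently.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the biochemistry of sequencing:

* A 471 bp in-frame CDS (157 codons, frame 0), stop-free by construction.
* A genus-level genealogy: species ancestor and outgroup stem each 4% from
  the root; two outgroup taxa at ~10–12% from the species; haplogroup
  centroids around the species ancestor at pairwise distance
  `intergroup_divergence` (default 5%), placed on disjoint sites so the
  target is met exactly up to rounding.
* Functional substitutions land on third positions with probability
  q3 = 0.9, never create stops, and take a synonymous alternative when one
  exists with probability 0.95 (purifying selection); the 10% leak to
  positions 1–2 is what produces occasional amino-acid polymorphism in
  typical groups.
* Star demography is sampled directly as the resulting pattern — a hub
  plus Binomial(n−1, 0.15) distinct satellites at 1–2 mutations — rather
  than through coalescent machinery; the claims under test concern the
  pattern, not its generative process.
* The NUMT centroid branches halfway along one outgroup's stem and
  accumulates 8% position-uniform substitutions. This "ancient
  integration" design makes the pseudogene lineage fall genuinely inside
  the congeneric radiation of a distance tree — the placement reported for
  deep NUMT haplogroups — rather than relying on a distance method to
  reproduce long-branch attraction. Farm NUMT swarms descend from a
  farm founder (2–4 further uniform mutations), split into 3–5 variants at
  balanced copy numbers (an as-even-as-possible split keeps the max/min
  count ratio ≤ 3, the operationalization of "relatively balanced"), and
  optionally carry a 1 bp deletion verified to create a downstream
  in-frame stop. Co-amplified mode emits the IUPAC overlay of the
  mitochondrial hub and the NUMT template, N-padded to alignment length.
* The Tpm intron pool derives alleles from a 350 bp ancestor by one
  fixed-length deletion (3–7 bp, in the first third) and/or private
  substitutions placed downstream of the indel zone — within reach of the
  shift decoder, per the identifiability limits above. Emitted indel
  heterozygotes are restricted to pairs whose overlay determines the
  allele pair as the unique maximum-parsimony decode; non-identifiable
  pairs (which also occur in real data) are exactly those requiring
  catalog comparison and are left out of the emitted mix. Cryptic-species
  farms draw from a private allele sub-pool; all other farms share a
  common pool, which is what W5 consumes.

What passing tests on this generator do **not** show: performance on real
chromatograms (quality trimming, base-calling errors and heteroplasmy are
not simulated), behaviour under alignment error (input is pre-aligned by
contract), recombination or selection on the nuclear marker, and the
geographic/temporal structure of real surveys. The generator's defaults
are the study conditions for all benchmarks and are not tuned per test.

## Benchmark problem sizes and determinism

The acceptance benchmarks use 20 replicate panels at bootstrap B = 100 for
the retention operating point (≤10% of typical groups, ≥90% of NUMT groups
flagged), 13 replicate studies at B = 50 for classifier parameter recovery
(≥50 candidate groups per class), 500 heterozygotes for the phasing round
trip, 200 random instances for the MSN oracle and 30 random additive
matrices (≤8 leaves) for NJ. All randomness flows from explicit seeds;
identical seed and configuration give byte-identical outputs (no
timestamps, sorted keys, fixed float formatting), which the determinism
check asserts end-to-end.

## Known limitations

* Nearest-reference assignment presumes the panel spans the typical
  groups; a novel *functional* haplogroup beyond τ = 0.03 would surface as
  `atypical_unassigned` and, with private nuclear alleles, be reported
  `cryptic_candidate` — the correct conservative behaviour, but only
  nuclear data distinguish it from a stop-free NUMT.
* W2 needs a rooted perspective supplied by ≥2 outgroup taxa in the panel.
* The phasing decoder assumes at most one heterozygous indel; multi-indel
  genotypes fail with a diagnostic rather than phasing partially.
* The MSN is the strict ε = 0 network; median-joining/TCS-style inferred
  median vectors are out of scope.
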