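# Methods

## The multiplexing model

A scheme is a three-level design: libraries → multiplexed groups → fixed
inner barcode pairs. Each *sample* is one fixed (i5, i7) pair inside one
group; each group is one outer-index combination on a lane; each library is
one lane. Libraries come in two preparation types: **A** (each sample
amplified individually before pooling — only sequencing-stage artifacts can
recombine samples) and **B** (samples pooled per group before the indexing
PCR — PCR chimeras can additionally form *within* a group's pool).

The built-in reference design has 9 global fixed pairs and 75 groups across
7 libraries (4×A with group sizes 8×9+8+6; 3×B with 8×9+3×8, plus one extra
group of 4 in B-1 and of 3 in B-2), 639 samples in total. A group of *n*
samples uses the first *n* of the 9 pairs. Derived counts — 56 groups where
only type-I chimeras are observable, 19 where type IV is detectable, 81
combinations per full group of which 88.9 % are chimeric, 675 possible vs 36
identifiable type-IV (group, pair) cases — follow from the structure alone.
The actual tag sequences are synthetic stand-ins produced by this package's
own designer (`design_tag_set`, seed 20220627) under the published
constraints; no derived count depends on them.

## Classification rules

For an observed combination in group *g*: genuine iff it is one of *g*'s
pairs; type I iff both tags are used in *g* but not as this pairing; type II
iff exactly one tag is used in *g*; otherwise type IV if the combination is
a fixed pair used in some *other* group, else type III. Detectability is
emergent: a group using every global pair can only ever produce genuine and
type-I calls, with no special-casing.

A "case" for the estimator is a (group *g*, pair *p*) with *p* used in at
least one other group. Cases with *p* ∈ *g* are counted in `pos_chimIV`
(hops of *p* into *g* are real type-IV events, misassigned as genuine);
the identifiable subset (`total_chimIV`) are cases classified TYPE_IV in
*g*. Whether cases should be weighted by source-group read depth is not
settled; the unweighted count is used, matching the estimator's role as a
detectability correction.

## The type-IV extrapolation

`est_chimIV = (obs/total_mg_reads) · total_reads · (pos/total_chimIV)`.
Under a uniform-hopping model the estimator is exact when every case is
identifiable and receives equal expected landings (then `obs` *is* the hop
count and both correction factors are 1). In designs dominated by full
groups the two factors both scale the observation upward and the result
behaves as an upper-bound-style extrapolation — consistent with its use to
say what the type-IV load could be *at most* had the design exposed it. The
acceptance-level recovery check therefore uses a scheme of small groups with
disjoint pair sets, where every inter-group hop is identifiable and the
estimate must reproduce the injected hop count; the upward bias in unequal
designs is deliberate and documented rather than corrected.

## The synthetic-read generator

Reads are `[8-nt tag][4-nt VBBN][restriction remnant][uniform random
insert]` on both mates (SbfI remnant TGCAG on mate 1, MseI remnant TAA on
mate 2), 150 nt, constant Phred 37 with an optional low-quality tail.
Inserts are i.i.d. uniform DNA of length ≥ read length: all detection
operates on barcodes, so genomic realism (and 3′ read-through) is out of
scope. VBBN draws follow the IUPAC degeneracies (V=ACG, B=CGT, N=ACGT).

Per template, exactly one event is drawn (categorical at the configured
rates; remaining mass is genuine):

* **pcr_chimera** (type B only): mate-2 identity (tag, VBBN, insert) taken
  from a different sample of the *same group* — the pool that is amplified
  together is the group, so PCR recombination surfaces as type I.
* **seq_chimera**: mate-2 identity from any template of the same library
  (one lane), emulating cluster-stage chimera formation.
* **index_hop**: the intact pair is emitted in a uniformly chosen other
  group of the same library; it lands genuine-looking or as type IV.
* **junk**: both mates are arbitrary DNA — adapter dimers and contaminant
  clusters whose "tag" regions are not barcodes.

Duplication is applied independently on top (probability `dup_rate` of one
extra copy of the emitted molecule, sharing template and both VBBNs,
receiving fresh sequencing errors). Sequencing errors substitute each base
to a different base at `error_rate` and overwrite with N at
`uncalled_rate`. Everything is driven by one `numpy` generator seeded from
`SimParams.seed`; identical parameters give byte-identical output.

Defaults (per read): duplicates 0.10, PCR chimeras 0.005, sequencing
chimeras 0.005, index hops 0.002, junk 0.001, per-base error 0.001. These
are plausible magnitudes for a patterned-flow-cell run of a pooled RAD
library — chimera/hop rates of a few per mille reproduce overall chimeric
fractions of ~0.5–2 % as observed in practice, and junk at 0.1 % represents
the residue of artifact clusters that survives the chastity filter.

What the generator does **not** emulate: fragment-length/size-selection
effects, PCR-cycle-resolved amplification (duplicates are single extra
copies), indel sequencing errors, quality-dependent error profiles,
reference-genome structure (hence no intra-sample chimeras — which barcodes
cannot detect anyway), or chimera junctions *inside* the tag region.
Passing tests therefore validate the accounting and detection logic under a
clean artifact model, not the messiness of any particular instrument run.

## Demultiplexing and filtering

Clone removal precedes demultiplexing and keys on the *full* mate-1 + mate-2
sequences (template plus both VBBN tags); only exact copies are removed, so
error-bearing duplicates are missed in proportion to the per-read error
probability — the same behaviour as degenerate-tag clone filtering in
practice.

Tag rescue is Hamming distance, not Levenshtein: inline tags are
fixed-position and fixed-length, and this matches the semantics of the
standard demultiplexers. N counts as a mismatch. A read is assigned to the
unique tag at minimal distance d ≤ k; ties at the minimal distance are
discarded as ambiguous, never guessed. Retention is therefore monotone in k
by construction, and with pairwise tag distance ≥ 4 a single-substitution
read can never be reassigned to the wrong tag at k ≤ 1 (verified
exhaustively over all neighbourhoods).

Quality filtering fails a pair on (in order): chastity flag, any N in the
payload after tag+VBBN removal, any sliding window (length 0.15 × payload,
the common demultiplexer default, configurable) with mean Phred < 10. The
N-check excludes the tag region — otherwise rescue of reads with uncalled
tag bases would be impossible. Retained reads are stripped of tag+VBBN
(12 nt), keep the restriction remnant (which demultiplexers verify and
keep), and are truncated to 136 nt — exactly reachable from 150-nt reads
(150 − 12 = 138). Remnant verification (≤1 mismatch) sits behind an
off-by-default flag. Accounting is exact: retained + per-reason discards =
input, per group and per level.

Because tag distances and quality outcomes do not depend on k, the
multi-level sweep computes one assignment per group and slices all rescue
levels from it (`demultiplex_group_levels`); this is bit-identical to
running each level independently (tested) and what keeps the 20-replicate
sweep check cheap.

## Why the rescue-sweep crossover needs junk clusters

The sweep reports, per increment of k, the newly retained genuine and
chimeric reads, and the smallest k where chimeric newcomers outnumber
genuine ones. With a pure substitution-error model at rate *e* per base the
expected fraction of reads first rescued at level k is ≈ 2·C(8,k)·eᵏ — at
e = 0.01 that is ~1.4×10⁻¹ at k = 1 but ~10⁻⁶ at k = 4, and those reads
split genuine/chimeric like the underlying population, so no crossover can
occur. What drives the late-k chimera flood in real data is reads whose tag
regions are not barcodes at all: a random 8-mer sits within distance 3 of a
9-tag side with probability ≈ 0.2 but within distance 4 with probability
≈ 0.66, so junk clusters enter the count table almost entirely at k = 3–4
and scatter near-uniformly over the combination space, ~89 % of which is
chimeric. The generator's `junk_rate` default of 0.001 places the expected
increments in the regime (roughly 10⁻⁵ < junk < 2×10⁻³ at e = 0.01) where
newly recruited junk overtakes genuine rescue exactly at k = 4, the
inter-tag design distance — with margins of ≈ 2 σ at k = 3 for runs of
~2×10⁵ reads, which is why the replicate check uses 300 reads/sample on the
reference scheme (≈ 1.9×10⁵ reads per replicate).

## Statistics

Group-level chimera percentages are computed on retained reads after clone
removal and quality filtering (the pipeline's denominators); a group with
zero retained reads reports its percentage as missing, not 0. A-vs-B
comparisons use the two-sided Mann–Whitney U; across libraries or rescue
levels, Kruskal–Wallis; pairwise follow-ups use Dunn's rank test with the
tie-corrected pooled variance and Holm adjustment (configurable, including
"none" — the adjustment choice is a convention, not derivable from the
protocol). Dunn's statistic is validated against the two-group identity
z² = H with scipy's Kruskal–Wallis as the independent implementation.

## Numerical and interface choices

* Ordered combinations: i5-side and i7-side tags are physically distinct
  adapters; "used in a group" is evaluated per side.
* Barcode designer: greedy filtered search over seeded random candidates,
  default budget 10⁶; self-complementarity means reverse complement equal
  to self; GC bounds are compared exactly as rationals.
* Flank contexts for restriction-site reconstruction default to the
  overhang remnants adjacent to the tag (TGCAGG / TAA).
* Scheme, pipeline configs: YAML; count tables: TSV; reports: JSON + text.
  Seeds are mandatory in pipeline configs (no wall-clock seeding).
* Outer barcodes are labels only; groups arrive pre-split by outer
  combination (as delivered by a sequencing centre), so index hopping is
  modelled as group reassignment of an intact pair.

## Known limitations

The estimator's behaviour in unequal designs is an extrapolation, not an
unbiased count (see above). The clone filter is exact-match only. Junk
reads are uniform random DNA rather than structured contaminants. The
per-read truth labels record one event per read; compound events (e.g. a
hopped chimera) are not modelled. Mate-level chimera identity switches at
the whole-mate level; junctions inside a tag (which would produce hybrid
barcodes rescued at intermediate k) are not simulated.
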