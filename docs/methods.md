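# Methods

This note documents the models, conventions and numerical choices behind
`neochrom`, what the synthetic-data generators do and do not emulate, and
the known limitations of each component.

## Coordinates and sequence model

All positions are 0-based, half-open, stored on the forward strand.
Circular molecules keep their origin at index 0; insertion points and site
searches wrap modulo length, and features are stored non-wrapping (the
concatenation origin falls between the backbone and the first fragment, so
no feature spans it by construction). Translation uses the standard nuclear
genetic code throughout.

## Design editing

**Concatenation.** Fragments are ordered by decreasing length (ties broken
lexicographically by id) and the centromeric backbone is appended last; the
result is circular. Each ORF's translation is recorded at this point so
every later edit can be audited against it.

**Stop-codon recoding.** Exactly the terminal codon of each ORF is
inspected on the ORF's strand; TAG becomes TAA, while TAA and TGA are left
untouched and non-stop terminal codons are reported rather than silently
accepted. Internal TAG codons are not recoded: the rule targets stop
codons only, matching the Sc2.0 convention of freeing the TAG codon at ORF
ends without touching coding sense positions.

**loxPsym insertion.** The 34-bp site (its own reverse complement, so
recombination is orientation-independent) is placed starting exactly 3 bp
downstream of the stop codon in ORF orientation: at `end + 3` for `+` ORFs
and ending at `start − 3` for `−` ORFs. Insertions are applied in
descending coordinate order so pending coordinates stay valid; an
insertion point falling strictly inside another feature is skipped and
reported (configurable to a hard error). The default selection is every
high-confidence ORF; because published selections are typically curated,
the selection is an explicit, serializable input (a list of ORF ids or a
predicate) — the study-scale runs select 63 sites.

**Watermarks.** Within a window of 12 codons starting at codon 10 (both
configurable), each codon with at least one synonym carries one payload
bit: bit 0 keeps the original codon; bit 1 swaps to the synonym at maximal
nucleotide Hamming distance, ties resolved to the lexicographically
smallest. Swaps that would mint a loxPsym, PmeI or NotI occurrence within
±40 bp are skipped and the bit moves to the next degenerate codon, so the
design stays restriction-clean. Decoding compares current codons with the
recorded originals; an unwatermarked ORF decodes to the empty payload,
distinct from an error. Translations are preserved by construction and
re-proved by `validate_design`.

**Edit log.** Every edit records (operation, position, removed, inserted);
replaying the log on the concatenated input must reproduce the design
byte-identically, and validation re-executes that replay.

## Chunking and assembly

Chunk *i* consists of a body (one arc of the design) plus a 200-bp right
overhang duplicating the start of chunk *i+1*'s body, so adjacent
synthesized fragments share exactly one 200-bp homology window and the
bodies alone concatenate to the design. Boundaries start at even spacing
(`n = round(L / target)`, target 10 kb) and shift locally — at most 1 kb,
capped at 10% of the spacing — until the overlap window is unique in the
design (exact search, both copies of the doubled circle) and free of
PmeI/NotI; an inadmissible region raises an error naming it. The chunk
count is therefore an output of the algorithm, not an input constant.

In-silico homologous recombination joins pieces wherever one piece's
terminal 200 bp equals another's initial 200 bp, exactly; ambiguous
(one tail, two matching heads) or missing overlaps are errors listing the
termini. Joined length obeys Σ lengths − overlap × joins.

The assembly planner opens with rounds of 2 then 3 chunks (the historical
build schedule) and then packs up to 4 chunks per round; *URA3* and *LEU2*
alternate strictly, and the final step swaps the last marker for a BFP
expression cassette. Selection/counter-selection marker chemistry is
modeled as plain `replace_region` edits — no selection biology is
simulated.

Junction confirmation primers (18–25 nt, Tm 58–62 °C, product 400–1000 bp,
aiming near 600 bp) are found by scanning outward from each junction;
melting temperatures use nearest-neighbor thermodynamics with the unified
SantaLucia parameter set at 50 mM monovalent salt and 500 nM primer, and
uniqueness is verified by exact search of both strands.

## Linearization

Telomerator-style linearization is a deterministic transformation: rotate
the circle to open at the cut locus, drop the counter-selected cassette
marker from the annotation, and append telomere seeds — by default 30
copies of TG on the right end and its complement on the left (the seed is
configurable; real telomerator cassettes leave a defined remnant whose
sequence is not modeled here). Cutting inside a feature requires an
explicit override, which drops the feature with a report. Stripping both
seeds and rotating recovers the parent circle exactly, and variants cut at
different loci differ only in gene arrangement relative to the new ends.

## SCRaMbLE simulation and SV calling

A circular design with *n* loxPsym sites is represented as a signed
circular sequence of its *n* site-delimited segments. Events draw a type
(defaults DEL 0.45 / INV 0.45 / DUP 0.10; event count fixed or
Poisson(λ = 2) — all configurable) and a uniform pair of current site
indices. INV reverse-complements the spanned segments (length and site
count unchanged — loxPsym symmetry keeps the flanking sites intact); DEL
excises one arc plus one boundary site, always choosing the arc that
spares every designated essential segment (the backbone/centromere
segment in the pipeline); DUP tandem-duplicates the span plus one site.
The truth log is replayable and seeded runs are bit-reproducible.

The caller re-locates loxPsym sites in an observed sequence, matches each
intervening segment to the original vocabulary by exact full-length
sequence in either orientation (order-preserving assignment for duplicated
identical segments — a documented limitation for repeat-rich designs), and
reports copy numbers, orientations and a minimal event history. Tandem
duplications are collapsed first; deletions are maximal runs of absent
segments; inversions are found by iterative-deepening DFS over
breakpoint-bounded reversals (a reversal removes at most two breakpoints,
which prunes the tree), considering both arcs of the circle. Because
deletions and inversions commute when their arcs do not interact, the
search first tries the deletions-then-inversions decomposition and only
falls back to a node-budgeted interleaved search when a strictly shorter
(crossing-event) history exists. Structures no bounded history explains
are returned flagged, never raised.

**Identifiability.** Parsimony is a genuine ceiling, not an implementation
artifact: two deletions whose arcs become adjacent leave a molecule
byte-identical to one merged deletion, and the extent of an inversion into
a subsequently deleted arc leaves no trace. Under uniform site-pair
sampling (mean arc ≈ n/3 segments) such interactions are common, so exact
truth-history recovery over multi-event simulations plateaus around 80%
even though every call replays to the observed molecule; single-event
histories are recovered exactly. Distance-biased site pairing would raise
the exact-recovery rate but is deliberately not the default.

Copy number is reported as `depth(element) / mean(depth of contigs longer
than 200 kb)`, so a gained element reads > 1. The per-contig mean is an
unweighted mean over qualifying contigs, mirroring coverage-summary
practice.

## Phenotype statistics

`U = ln(x/x₀)/t` is computed exactly; the maximum specific growth rate is
the maximum over sliding windows (default 5 points) of the least-squares
slope of ln(OD) against time. Maximum curve height *A* is the peak of a
5-point centered rolling median (`min_periods = 1` at the edges), which
suppresses isolated spikes; the smoothing window is explicit and
configurable because phenotype-microarray packages differ here.
Classification excludes a well when either strain's *A* fails to reach its
negative control plus 50 units (inclusive: `A ≥ neg + 50` passes) or when
either plate's positive control falls below 100 units; surviving wells are
increased / decreased / unchanged by `log2(A_test/A_ref)` against
symmetric ±1 thresholds, and excluded wells carry no ratio.

Mitotic stability assumes independent per-generation loss:
`R(g) = (1 − p)^g`. Retention tables report per-generation replicate
proportions, their mean and sample (n−1) standard deviation in percent,
and exact Clopper–Pearson 95% intervals per replicate. The loss-rate
estimator inverts the geometric model, `p̂ = 1 − R^{1/g}`; R = 0 leaves
the rate unidentifiable (only a lower bound exists) and raises.

## Synthetic-data generators

All generators take explicit seeds and return their ground truth; a single
master seed fans out to substreams via `SeedSequence` spawning (values
kept below 2³¹).

- **Fragments**: 17 fragments by default, log-uniform 1.1–60.3 kb, i.i.d.
  nucleotides at GC 0.38, non-overlapping ORFs planted on random strands at
  0.35 ORFs/kb (lengths 300–1500 bp, ATG start, stop-free interior, random
  stop, ~80% flagged high-confidence). Fragments are synthesis-aware:
  PmeI/NotI/loxPsym motifs are scrubbed (synonymously inside ORFs), and
  terminal-TAG contexts whose TAG→TAA recoded image would mint a PmeI site
  are switched to TGA at generation time. Not emulated: real codon usage,
  repeats, GC heterogeneity, gene synteny — so passing tests demonstrate
  algorithmic correctness, not robustness to genomic repeat structure.
- **Kinetic plates**: 4-parameter logistic mean curves (baseline 2 units,
  plateau 150–300 for reference compound wells, midpoint 6–10 h,
  steepness 0.6–1.2/h) sampled 97 times over 24 h with multiplicative
  lognormal noise (CV 0.05 default); a well with effect *f* has a test
  plateau *f* × the reference plateau; negative controls plateau at 10–30
  units, positive at 240–280, blanks at 5–20 (always below negative + 50).
  A planted effect of exactly 2.0 sits on the log2 = 1 decision boundary,
  where recovery is ~50% by symmetry — recovery properties are therefore
  tested at effects clearly inside a class.
- **Growth curves**: logistic with inoculum OD 0.01, plateau 1.4, 20-min
  sampling over 24 h. With the 5-point windowed estimator the
  finite-inoculum bias is ≈ r·(OD₀/K)·⟨e^{rt}⟩ ≈ 0.005 h⁻¹ at
  r = 0.53 h⁻¹, well inside a 0.01 tolerance; at 1% multiplicative noise
  the median relative error is ≈ 0.8%.
- **Passaging**: resistant counts ~ Binomial(96, (1 − p)^g) per replicate
  (3 replicates; sampling at generations 25 and 50), verified against the
  binomial by chi-square goodness of fit.
- **Coverage**: per-contig mean depth as Poisson(L·depth)/L (or exact when
  noiseless), element scaled by the true ratio; default contig panel has
  three contigs > 200 kb, one below the cutoff, and a 211-kb element.

## Problem sizes

The default test-suite and acceptance runs use: one study-scale design
(17 fragments, ~200–400 kb realized, 63 loxPsym sites, 36 watermarks);
one 211,409-bp random circle for the assembly round trip; 200 SCRaMbLE
simulations of 1–3 events; 200 seeds for growth-rate and loss-rate
recovery; 100 seeds for copy-number and plateau recovery; 1,000 random
plates for the classifier oracle; 50 small fragment sets for proteome
preservation. These sizes give sub-percent Monte-Carlo error on every
reported rate while keeping a full run in well under a minute per
component.

## Known limitations

- Segment matching is exact full-length identity; point mutations inside a
  segment make it "foreign" (flagged) rather than fuzzily matched.
- The SV caller's histories are minimal by design; see Identifiability.
- No vendor synthesis screens beyond restriction sites (repeats, hairpins,
  homopolymers are out of scope), no read-level simulation (coverage is
  modeled at the per-contig summary level), and no selection/induction
  biology (5-FOA, galactose, estradiol) — those appear only as their net
  sequence-level effects.
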