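# Methods

## The problem and the model system

Plant cells carry three genomes, and DNA moves among them: organellar
segments integrate into nuclear chromosomes (numts from the mitogenome,
nupts from the plastome), plastid segments integrate into the mitogenome
(mtpts), and nuclear sequence — mostly repeats — accumulates in the
mitogenome.  After an allopolyploidy event the merged nucleus carries both
parental subgenomes, and the fate of previously acquired insertions can be
asymmetric between the mitochondrial- and plastid-derived classes.
`igtscan` implements the full measurement chain for this phenomenon:
homology detection, gene-level state calling, junction analysis, donor-side
hotspot profiling, network reconciliation and expression quantification,
together with a generator of synthetic study systems in which every one of
these measurements has a known right answer.

## Homology search

Detection is seed-and-extend: all exact k-mer matches (default k = 12)
between donor and recipient, on both donor strands, are extended without
gaps under an x-drop rule (drop 20) with match +1 and mismatch −2.  The
ambiguous base N never matches, so scoring is deterministic.  Gap penalties
(−5 open, −2 extend) are part of the parameter surface but the default
engine does not open gaps: the decay model is substitution-only (below), and
on such data an ungapped extension recovers the planted alignment exactly.
Seeds landing on the diagonal of an already-extended hit are skipped;
duplicate extensions collapse by coordinates.  Circular donors are seeded
with a (k−1)-base wrap and extended over a doubled copy, capped at one full
turn; a hit crossing the origin reports `donor_end > length`.

Significance uses the ungapped Karlin–Altschul expectation
E = κ·m·n·exp(−λ·S) with λ = 1.33 and κ = 0.621, the conventional
constants for +1/−2 nucleotide scoring; both are configurable.  `search`
itself applies only a loose E ≤ 10⁻³ report ceiling; analysis thresholds
live in two presets: `norg` (length ≥ 100 bp, identity ≥ 0.95, E ≤ 10⁻⁵ —
the organelle-to-nucleus filter, with the 95 % bound read as inclusive) and
`mtpt` (length ≥ 50 bp, identity strictly > 0.95, donor/query coverage
strictly > 0.90).  Coverage is attached to the donor element because the
mtpt workflow queries each plastid gene separately (`detect_mtpt`).
Hits overlapping or within 500 bp on the recipient merge into insertion
segments; opposite orientations never merge, since orientation is a
reported property of each transfer.  Direction totals are unions of
recipient intervals (no double counting), reported in kb per species per
direction, with ratio and percent-of-genome helpers rounding to two
decimals for reports.

## Synthetic genomes

The generator emulates a four-species allopolyploid system on the network
root → (A lineage → A2, D lineage → D5) with a hybrid node AD → AD1, AD2.
Defaults (all configurable) are scaled for desk-sized experiments:

* nuclear: 2 chromosomes per species on 150-kb i.i.d.-uniform backgrounds;
* mitogenome: one shared circular molecule, 250-kb background, carrying 36
  of the 42 panel genes (six ribosomal-protein genes are deleted in all
  species, emulating shared ancestral loss), eight plastid tRNA-like
  insertions (the mtpts), two longer plastid segments, ten nuclear segments
  and a 7-class repeat library planted at 5 % divergence;
* plastome: one shared circular quadripartite molecule (~160 kb; LSC and
  SSC gene regions, 25-kb inverted repeats with IRb the exact reverse
  complement of IRa) carrying all 78 panel genes plus the eight tRNAs.

Organelle genomes are identical across the four species — at the timescale
modelled they are nearly invariant in real systems — which is what makes
mtpt junctions fully shared across species.  Background transfers per
species and direction (30 mt→nu, 50 cp→nu by default) have uniform lengths
200–2000 bp, divergence ages 1–3 %, random orientation (probability 0.5 of
reverse) and 4-bp junction microhomologies planted by copying the terminal
bases of the donor flanks into the recipient flanks immediately outside the
insertion, so donor and recipient share those bases at the fusion point.
30 % of mt→nu sources are drawn from a single 10-kb annotation-free window
of the mitogenome (the planted source hotspot).  Gene-anchored transfers
follow a simulated single-gain history over the network with per-node loss
and decay probabilities chosen to produce the qualitative study conditions:
numts gained in roughly half the panel with heavy polyploid loss, nupts
gained nearly universally with light loss, yielding diploid numt counts two
to three times the polyploid counts and a strong nupt-vs-numt retention
contrast.  Pseudogenization is either a planted in-frame premature stop
(≤ 2 substitutions) or truncation to 40–70 % of gene length.

Decay is substitution-only: each site mutates independently with
probability equal to the planted age, to a uniformly chosen different base.
This keeps identity and coverage arithmetic exact for truth tests.  An
`indel_rate` hook exists but only the value 0 is supported; non-zero rates
raise rather than silently degrading the ungapped engine.  Intact
gene copies are mutated under a resampling loop that rejects draws creating
internal stops, so the planted state matrix is exact.  mt→nu sources keep a
600-bp margin from planted mitogenome inserts so that backwards homology
(nuclear copies matching the mitogenome) cannot merge into genuine nu→mt
insertions; all other sources keep a 20-bp margin.  One global seed is
forked into independent streams keyed by stable string labels, so output is
byte-identical under a fixed seed and changing one planting count does not
perturb unrelated draws.

What the generator does not model — and hence what passing tests do not
show about real data: repetitive nuclear backgrounds (detection precision
on i.i.d. background is easier than on a 70 %-repeat cotton genome), indel
decay, nested/fragmented transposable elements, organelle recombination,
RNA editing, and realistic base-quality error profiles.

### Cross-compartment homology

Because homology is symmetric, a nuclear numt also matches the mitogenome
when the nucleus is used as the donor, and a plastid segment that reached
the mitogenome matches the plastome everywhere it also reached the nucleus.
The recovery evaluator therefore scores a detected segment as a true
positive only against planted truth of its own direction, tallies
detections explained by planted homology of another direction as
cross-talk, and counts as false positives only calls on clean background.
The hotspot computation in the acceptance script handles the same effect
the way an analyst would: it masks the (detected) plastid-homologous and
repeat regions of the mitogenome before attributing mt→nu source midpoints.

## Gene transfer states

Each panel gene is searched as the query against the species' nuclear
records; merged donor-side coverage decides full-length status with a
default intact threshold of 0.99 ("full length" made quantitative; reported
with every matrix).  Protein genes additionally require a stop-free
translation of the best hit's recipient copy in the frame inherited from
the donor through the alignment (standard genetic code by default, which
plant organelles use; bacterial table selectable).  tRNA/rRNA genes are
decided on coverage alone.  Ties among nuclear copies break by score, then
lower recipient coordinate.  The donor-side call (`lost_from_organelle`)
asks whether the organelle genome itself still carries the panel reference
at full-length coverage.

## Junctions

Flanks are extracted 5'→3' on the insertion's strand: recipient flanks
immediately outside the insertion, donor flanks immediately outside the
source interval, with donor flanks reverse-complemented and swapped for
reverse-orientation insertions.  Microhomology is the fusion-point-anchored
maximal exact match (suffix match upstream, prefix match downstream), not a
best match anywhere in the window; offsets are not allowed, and N never
matches.  The default window is 10 bp (configurable to 50).  The
cross-species shared flank is the anchored run identical across all
contexts of a homologous insertion; it is anti-monotone in the species set
and, on i.i.d. flanks, P(shared ≥ L over s species) = 4^(−L(s−1)) — the
null used in the test suite.

## Hotspots and plastome regions

Insertions are summarised by donor midpoints, floor((start+end)/2), modulo
the genome length on circular donors, and binned at a fixed width
(default 10 kb; argmax ties break to the lowest coordinate; an empty
profile has no argmax).  Binning rather than kernel density keeps
tie-breaking exact; a per-bp density accessor supports plotting.  Plastome
hits are assigned to LSC/IRa/SSC/IRb by midpoint (boundaries left-closed),
IRa and IRb pooled by default, and relative rates normalised to LSC = 1
(flagged when LSC is empty); per-kb rates are also emitted because raw
counts and per-length rates answer different questions.

## Repeats

Repeat classification is nucleotide homology against a labelled library
with looser thresholds (identity ≥ 0.80, length ≥ 50 bp) than the transfer
presets, because repeats diverge faster than recent insertions.  Bases are
claimed by the highest-scoring hit, with ties broken by the fixed class
priority copia > gypsy > LTR_retro_unclassified > TE > simple_repeat >
low_complexity > unspecified; per-class totals are claimed-base counts and
therefore sum exactly to the union length.  The maximal-exact-repeat finder
anchors on min-length k-mers and extends each candidate pair to maximality
in both directions, de-duplicating to the set of maximal pairs; its entire
correctness surface is an O(n²) brute-force oracle run on sequences up to
2 kb, including palindromic (reverse-complement) pairs and the tandem
filter (period ≤ length).  The regression helper is ordinary least squares
with R² = 1 − SS_res/SS_tot.

## Network reconciliation

The species network is a rooted DAG whose hybrid node has two parents and
inherits presence from either (union inheritance).  Reconciliation is
Dollo: one gain per gene, absences below the gain explained by losses.
Loss and decay events are counted per node rather than per incoming edge:
losing a gene from the merged allopolyploid genome is one event even though
the hybrid has two incoming edges.  The reconstruction enumerates
presence assignments of the internal nodes below each candidate gain
(networks here have ≤ 4 internal nodes) and minimises the event count; gain
ties break rootward (the oldest-gain reading of shared presences) and decay
ties break leafward (decay as late as possible, implemented as maximising
the number of intact internal nodes among minimal solutions).  An
independent brute-force oracle enumerating every (gain, loss-subset) pair
verifies minimality over all presence vectors, and replaying each history
forward over the network must reproduce the observed leaves exactly.
Retention asymmetry reports, per polyploid leaf and direction, the fraction
of the diploid-union gene set still present, the nupt-minus-numt contrast,
and the diploid/polyploid count-ratio range.  Parental-origin assignment of
retained polyploid copies is out of scope.

## Expression

Gene pairs are equal-length aligned copies; diagnostic sites are exactly
their mismatch offsets.  Read mapping is pigeonhole-seeded (max_mismatches+1
non-overlapping exact seeds) with full Hamming verification, guaranteed to
find every placement within the mismatch budget on both strands; a
sliding-window oracle checks this on references up to 5 kb.  A read is
assigned to a copy only if it overlaps at least one diagnostic site and
carries that copy's allele at every overlapped site; site-free reads are
removed as ambiguous, mixed-allele reads are excluded as conflicting, and
the three classes partition the overlapping reads exactly.  Mates of a pair
are assigned independently and reconciled conservatively (agreement, or one
ambiguous mate).  RPKM uses the experiment-wide mapped-read total as the
denominator (the standard definition).  OE = NOE − NE is floored at zero
with a flag, since subtraction of noisy quantities can go negative.

## Problem sizes and determinism

The bundled study (four species; per species ~430 kb of nuclear sequence,
a 300-kb mitogenome and a 160-kb plastome; ~680 planted truth records) runs
the full simulate-detect-reconcile cycle in about two minutes and the test
suite in under a minute.  The acceptance script reruns everything from
scratch at these sizes.  All randomness flows from the single run seed
through labelled sub-streams; identical seeds give byte-identical genomes,
truth tables and hit lists.
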