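# Methods

## Classification model

`ltrsort` treats TE classification as evidence aggregation over conserved
protein domains. The hierarchy is class → order → superfamily → clade; a
profile-HMM database supplies one model per (lineage, domain) pair, with the
domain vocabulary normalised to the five LTR-RT polyprotein domains — GAG
(capsid), AP (aspartic proteinase; GyDB's "PROT" is treated as an alias),
INT (integrase), RT (reverse transcriptase), RH (RNase H) — plus `other`
for anything else. Lineage metadata comes from a sidecar TSV
(`profile_name, class, order, superfamily, clade, domain_label`); parsing
the profile name with the `order[/superfamily[/clade]]:DOMAIN` grammar is
the fallback. The sidecar is authoritative because real domain databases
use incompatible naming schemes, and a table isolates that dialect problem
from the engine.

### Pass 1: domain search

Each sequence is translated in all six frames. Two deliberate conventions:
any codon containing a non-ACGT base translates to `X` (scored neutrally by
the engine), and internal stops are kept as `*` rather than splitting ORFs —
the profile-HMM engine handles them, and splitting would penalise elements
with nonsense mutations. The genetic code defaults to the standard table
(table 1) and is configurable.

Translated frames are scanned with the pyhmmer plan7 pipeline (an external
`hmmscan --domtblout` table is accepted as an alternative backend through
the same filter path). Per-domain hits are filtered by:

* **model coverage** `(hmm_to − hmm_from + 1) / model_length ≥ 0.20` — the
  denominator is the profile's match-state count, not the query, because
  coverage here judges how much of the *domain model* was seen;
* **independent per-domain E-value ≤ 10⁻³** — the per-domain statistic, not
  the full-sequence one, because filtering operates on domains.

Both thresholds keep boundary values (the discard rule is the strict
`coverage < 20% or E-value > 10⁻³`) and both are configurable.

Overlapping hits compete in nucleotide space: hits whose intervals overlap
by more than 50% of the shorter interval form a conflict, resolved greedily
in rank order (score desc, E-value asc, profile name asc). This keeps
genuinely repeated (tandem) domain copies, which a per-label deduplication
would erase.

### Lineage call and completeness

The element lineage is the level-by-level summed-bit-score majority with a
strict > 50% descent rule: at each level, the candidate value with the
largest summed score wins, and the walk descends only while the winner holds
a majority of the total summed score among hits consistent with the chosen
prefix. Cross-superfamily conflicts therefore stop at `LTR` rather than
forcing an arbitrary superfamily; exact ties also stop. The strand is the
summed-score majority strand.

Completeness (Copia/Gypsy only) requires the five domains exactly once
each after best-hit resolution, on a single strand, in the canonical 5′→3′
order — Copia GAG-AP-INT-RT-RH, Gypsy GAG-AP-RT-RH-INT (configuration
data, per the standard TE classification hierarchy). Minus-strand elements
are order-checked after strand normalisation (descending forward
coordinates).

### Pass 2: 80-80-80 rescue

Elements with no surviving domain evidence are aligned against the
pass-1-classified elements on both strands. The best hit per query (highest
score, ties by identity then subject id) rescues the query iff alignment
length ≥ 80 bp, identity ≥ 80% and **query** coverage ≥ 80% (all
inclusive). Design choices made here:

* *Coverage side*: the rule's purpose is to ensure the unknown element is
  substantially explained by a known one, so coverage is measured on the
  query; it remains configurable.
* *Coverage basis*: the union of all HSP query intervals against the best
  subject (fragmented non-autonomous derivatives), while the length and
  identity tests apply to the single best HSP.
* *Depth*: rescued lineages are truncated to superfamily — sequence-level
  similarity is too weak for clade calls, and the pipeline asserts on every
  run that no pass-2 classification carries a clade.
* *One round only*: rescued elements are never recycled as subjects;
  transitive rescue risks label drift.

The internal backend is the Biopython pairwise aligner in local mode with
blastn-like scoring (match +2, mismatch −3, gap open −5, extend −2), which
reports one HSP per strand; the external backend shells out to `blastn`
(outfmt 6) and the same tabular parser computes the HSP-union coverage.

## Synthetic fixtures

The generator emulates a curated LTR-RT library at desk scale. Per clade
and domain, an ancestor protein is drawn by mutating a shared per-
superfamily root at 15% of positions (clades within a superfamily ≈ 72–85%
pairwise identity, well above the 60% floor; superfamilies are independent
random proteins, ≈ 5% identity). Profiles are built from 6-row alignments
of ancestors noised at 4% per position; the builder seed and the embedded
HMM timestamp are pinned so databases are byte-identical across runs.

Elements are assembled as `pad + polyprotein + pad`: domains
reverse-translated with a fixed most-frequent-codon table (so sibling
elements share high nucleotide identity and rescue is deterministic),
joined by short in-frame linkers, in the canonical superfamily order, on a
random strand, with 300 bp random flanks. Default domain lengths: GAG 150,
AP 120, INT 280, RT 250, RH 150 aa — round figures matching typical
LTR-RT domain sizes. Degradation knobs, all rates per element in [0, 1]:
point substitutions (per-base), a single-base indel (frameshift), per-domain
loss, and a non-autonomous fraction. Non-autonomous derivatives are
contiguous copies of a sibling's 5′ flank (a solo-LTR-like remnant) at
≥ 85% identity: contiguity is what a single-HSP aligner can cover at ≥ 80%,
mirroring how real non-autonomous elements are rescued via their intact
flanks. Truth completeness is structural (all five domains retained);
substitutions and frameshifts do not remove a domain.

The reference study conditions — and the generator defaults — are seed 42,
4 Copia + 4 Gypsy clades, 10 elements per clade, all mutation rates zero.
What passing on these fixtures shows: the coordinate bookkeeping, filters,
aggregation, completeness and rescue logic are exact. What it does not
show: robustness to real-world divergence depths, nested insertions, LTR
structure (no LTRs, PBS or TSDs are simulated), or database curation
quality.

## Benchmarking

Per category at a chosen level: tp (predicted = truth = category), fp
(predicted category, truth differs), fn (truth category, predicted differs
or absent). Unclassified or too-shallow predictions count only against
sensitivity, never as false positives — the usual treatment of abstentions.
Elements whose truth label does not reach the requested level are excluded;
scoring with no truth at the level is an error.

## Determinism and problem sizes

The pipeline proper has no randomness; the only seed is the fixture
generator's. Thread count only parallelises the profile-HMM scan, whose
results are thread-invariant, and all outputs are canonicalised by element
id, so outputs are byte-identical across reruns and thread counts. The test
suite and acceptance script use the reference conditions above (80
elements, 40 profiles) plus smaller two-clade libraries for the degradation
sweep (six elements per clade, five seeds per substitution rate, rescue
disabled there since it cannot affect clade-level sensitivity) — sizes
chosen to exercise every code path at desk scale.

## Known limitations

* The > 50% descent rule for conflicting lineages is this package's own
  aggregate; other tools may label cross-superfamily chimeras differently.
* The internal rescue aligner reports one HSP per strand; multi-HSP query
  coverage is only available through the external tabular backend.
* Completeness is domain-order-based only; it does not check LTR boundaries
  or target-site duplications, which are structural-annotation concerns
  outside sequence classification.
* E-values from the embedded engine depend on the database size used as the
  search space; with very small fixture databases they are conservative.
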