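# Methods

## The model

The package treats PCR quantification bias as a composition of two maps.
First, an in-silico PCR operator assigns each (primer pair, taxon group) a
coverage c ∈ [0, 1]: the fraction of the group's reference sequences on which
both primers find a binding site and delimit a product inside the allowed
size window. Second, a measurement model attenuates the true copy number:
`measured(pair, g) = c(pair, g) × A(g)`, where A(g) is the group's true 16S
gene copies/mL. Every downstream statistic — relative abundance, percentage
dissimilarity, ANOVA — is a function of these measurements.

This deliberately ignores PCR efficiency, template competition, chimeras and
copy-number variation between genomes: coverage is the single bias channel
modeled, because it is the one a primer choice controls directly.

## Primer matching

Degenerate primers use the 15 IUPAC nucleotide codes; U is normalized to T
and matching is case-insensitive. A primer position matches a reference base
when the base belongs to the code's set; reference ambiguity codes are
matched literally (a reference N matches nothing except a primer N, which
matches anything) so results are deterministic on dirty references. A site
is accepted when the total mismatch count is ≤ `max_mismatches` and no
mismatch falls within `protected_3prime_len` bases of the primer's 3'
terminus — the elongation-critical end. When the reverse primer is scanned
as its reverse complement along the stored strand, its biological 3' end
corresponds to the *start* of the oriented string, and the protected zone is
applied there.

Defaults: `max_mismatches = 0`, `protected_3prime_len = 0`, product window
50–2000 bp. Exact matching is the most conservative choice, and the
synthetic databases plant sites so that planted coverages are invariant to
these settings (see below); the parameters exist because real primer
evaluation services expose them.

Only the forward strand of each reference record is scanned, with the
(forward, reverse-complemented reverse) orientation: rRNA reference
databases store genes 5'→3'. A property test verifies strand consistency:
reverse-complementing every record and swapping primer roles leaves coverage
unchanged.

**Eligibility.** Coverage denominators exclude partial-length records: a
record counts as eligible when it yields an amplicon, or is at least long
enough to host both primers and — when the pair carries positional labels —
long enough to reach the reverse locus. This mirrors how database coverage
tools exclude sequences truncated at a primer site rather than scoring them
as misses. A group with zero eligible records has *undefined* coverage
(flagged), not zero.

## Positional names and the primer registry

Universal pairs are named by E. coli 16S positions (`1055f-1392r`), so the
implied product length is `reverse − forward`. The packaged registry
transcribes the eight universal pairs with their published regions, product
sizes and literature hit counts. Positional length agrees with the published
length for seven of the eight pairs; `519f-907r` publishes 391 bp against a
positional 388 bp, so positional lengths are advisory (a warning is raised on
disagreement) and the published value is authoritative where present. Primer
nucleotide sequences are not published alongside the names, so the registry
schema carries optional sequence columns and all coverage computations in the
tests use synthetic primers with known sequences; the engine accepts any
registry TSV with sequences filled in.

## Synthetic reference databases

`generate_reference_db` is the ground-truth substitute for a curated 16S
database. For each group, n random background sequences are drawn and, per
primer pair, a forward site and a reverse-complemented reverse site are
written at fixed non-overlapping offsets (default inter-primer spacing 80 nt,
so planted products are ~120 nt for 20-nt primers). Each planted site is a
uniformly drawn concrete realization of the degenerate primer, so degenerate
matching is genuinely exercised. Exactly `round(f·n)` members per group keep
intact sites for a pair with target coverage f; the remainder are ablated by
`k = 2` substitutions inside the 3'-terminal 3 positions of each primer, one
of them always at the terminal base, each substitution chosen outside the
primer's IUPAC set at that position. Consequently an ablated site fails under
exact matching and under any tolerance that protects at least one 3' base,
making the planted coverage invariant to the match parameters used in tests.
Fully degenerate (N) positions cannot be disrupted; site ablation requires
enough non-N positions in the 3' zone and fails loudly otherwise. Generators
are pure functions of (spec, seed).

What this emulates — and what it does not: the generator reproduces the
*combinatorics* of coverage (which fraction of a group amplifies) with exact
truth, but not the phylogenetic structure, length heterogeneity, alignment
ambiguity or annotation errors of a real database. Passing tests therefore
demonstrate that the engine measures coverage correctly, not that any
specific published coverage percentage is reproducible; published SILVA132
coverages are carried as fixed input tables (`silva132_coverage_table`) and
are never targets for the engine, because they depend on the database
release and on unreported matching settings.

## qPCR simulation

Replicate measurements are `coverage × abundance × ε`, with ε lognormal with
unit mean and coefficient of variation `cv` (σ² = ln(1 + cv²), μ = −σ²/2):
copy-number error is multiplicative on the log scale. Defaults follow
technical-triplicate practice (`replicates = 3`, `cv = 0.1`); `cv = 0`
reduces exactly to the theoretical measurement, which is the anchor for the
end-to-end identity test (generate → coverage → theoretical abundance equals
truth × community exactly under exact matching).

## Statistics

**Percentage dissimilarity** is Bray–Curtis × 100 over replicate vectors.
A similarity-percentage (SIMPER) breakdown of a two-sample comparison sums
to exactly this quantity, so the two-sample total is implemented directly;
per-taxon contribution decomposition is out of scope. Two all-zero vectors
make the quotient undefined and raise, rather than returning 0 or 100.
Implemented as the explicit formula (the scipy implementation is the
cross-check in tests).

**Two-way ANOVA without replication** uses the classical randomized-block
decomposition (SS_row, SS_col, residual with df (a−1), (b−1), (a−1)(b−1));
with one observation per cell no interaction is estimable. It is computed
directly rather than through an OLS fit so the perfectly additive table is
exact: zero residual SS yields F = 0, p = 1 for a zero-SS effect and F = ∞,
p = 0 otherwise, instead of a 0/0 floating-point artifact. statsmodels'
`anova_lm` serves as the independent oracle in the tests. Values enter on
the raw (untransformed) scale, and the worked example's significance
statement uses the minimum of the two main-effect p-values, the weakest
reading when the effect in question is not pinned down.

**One-way ANOVA** wraps `scipy.stats.f_oneway`, with the zero-within-variance
degenerate cases handled explicitly (identical constant groups → F = NaN,
p = 1; distinct constant groups → F = ∞, p = 0).

## Advisor

The study-design decision tree is shipped as a JSON rule table, not code
branches, so its wiring can be diffed and audited. The engine applies:
quantification mode → method (absolute → qPCR, relative → 16S amplicon
sequencing); intent → primer guidance (cross-study comparison → reuse the
reference study's pairs; dynamics → in-silico coverage evaluation and
interpretation against a same-reactor reference sample); gel-electrophoresis
product verification is required except for degenerate primers; an in-silico
coverage analysis is always required; and requesting normalization to total
EUB always emits a warning. The ecological question (presence / richness /
evenness) selects no additional guidance — those branches are left empty in
the rule table rather than guessed. The objective space is finite
(3×2×2×2×2 = 48) and exhaustively tested.

## Problem sizes and numerical choices

Synthetic acceptance runs use n = 200 sequences per group for the planted
coverage grid (f ∈ {0, 0.25, 0.8, 1.0}), 40 per group for the three-pair
end-to-end loop, 50 random instances for engine-vs-oracle equivalence, and
10,000 replicates for the noisy-recovery check (mean within 3 standard
errors per cell). These sizes give exact or well-separated outcomes at
desk scale. Coordinates are 0-based half-open throughout. Hit-count ties in
survey rankings break alphabetically for stable output.

## Known limitations

- Coverage is binary per sequence; partial amplification efficiency,
  primer–template thermodynamics and multi-template competition are not
  modeled.
- The engine scans one strand under the stored-orientation convention;
  records stored reverse-complemented would need pre-normalization.
- Survey computations operate on packaged or synthetic study-record tables;
  no literature retrieval is performed.
- Real-database coverage percentages are inputs, not outputs: reproducing
  them would require the specific database release and matching settings of
  the original evaluation service.
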