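# Methods

## Model and assumptions

The tool answers a qualitative question: *could* a given genomic source
have produced a given compound. A source is a set of KO identifiers; its
producible-compound closure is the union of right-hand-side compounds over
all KEGG reactions linked to those KOs. Three assumptions follow directly
from what KEGG records can support:

1. **Direction.** KEGG reaction files do not annotate reversibility, so
   the primary direction is taken to be left-to-right and products are the
   right-hand side of each equation. Consequently a compound that only ever
   appears on left-hand sides is never called producible. The
   `--bidirectional-reversible` flag relaxes this by also counting
   substrates of `<=>` reactions as products; it is off by default because
   the left-to-right rule is the method's stated convention and turning it
   on roughly doubles the closure.
2. **Presence, not flux.** The inference is set-valued: a KO in the list is
   treated as a functional enzyme regardless of abundance or expression.
   No gap-filling, stoichiometric balancing or metabolic modelling is
   attempted — the output is an annotation aid, not a flux estimate.
3. **Single-step.** Only compounds one reaction step away from the supplied
   KOs are reported. Host–microbe co-metabolism chains (e.g. microbial
   trimethylamine oxidised to TMAO by the host) are *not* chained: each
   step appears under its own source, and deciphering the chain is left to
   the user via the KEGG Mapper visualisation.

A compound on *both* sides of one equation (catalytic cycling, polymer
`(n+1) A <=> n A + B` growth) counts as a product: right-hand-side
membership is the rule.

## Input handling

- KO / compound lists: plain text, one id per line, `#` comments and
  blanks ignored; non-matching lines are counted and warned about, never
  fatal. Duplicates collapse (all downstream logic is set-based and
  order-invariant).
- KEGG flat files: the classic dialect (12-character label column, `///`
  terminators). Reactions without an `EQUATION` field are kept in the
  database but excluded from inference, with a warning — nothing is
  silently dropped, and dangling cross-references are counted per link
  kind. Glycan ids (`G#####`) pass through product inference exactly like
  compounds. Pathway ids from any namespace (`ko00650`, `hsa00650`) are
  normalised to `map00650` so KO-linked and compound-linked references
  join in one key space.
- Symbolic stoichiometry (`n`, `(n+1)`) is preserved verbatim in the
  parsed equation and treated as presence (coefficient 1), since the
  inference never uses coefficients quantitatively.
- REST client: batches of 10 ids per `/get/` request, at most one request
  per second, 3 retries with exponential backoff, responses cached on disk
  keyed by (kind, id). The throttle is deliberately conservative; the
  public API's exact limits are not documented. A warm cache makes repeat
  runs network-free and bit-identical.

## Origin classification

The origin table covers the union of all sources' producible sets plus all
detected compounds. Detected compounds that no source can produce — or
that are not even in the database — are retained as `neither` with an
`in_database` flag rather than dropped: the unexplained fraction of a
metabolome (environmental, dietary, or products of unannotated genes) is a
result, not noise. With exactly one producing source the category is
`<label>_only`; with two producers out of two sources, `both`; with more
than two sources, the `+`-joined subset of producing labels. The
two-source categories are a partition by construction, which the tests
verify against per-compound brute-force enumeration.

An optional exclusion list (e.g. currency metabolites: water, ATP, H+) can
be supplied; nothing is filtered by default because any default list would
be an undocumented judgement call baked into results.

## Enrichment

- Universe (background) choice is genuinely open; the default is every
  database compound annotated to at least one pathway, because it is the
  largest background that can actually join against pathway membership —
  compounds no pathway contains can only dilute $N$ without ever being
  countable in $K$. `--universe all` and `--universe detected` expose the
  alternatives rather than hiding the ambiguity.
- One enrichment table is produced per origin category among detected
  compounds (`microbiome_only`, `host_only`, `both`); the `neither`
  category is skipped because those compounds carry no origin signal to
  interpret. When no metabolome is supplied, each source's full producible
  set is tested instead.
- The survival function is the exact hypergeometric tail
  (`scipy.stats.hypergeom.sf`, log-space combinatorials), never a normal or
  chi-square approximation: enrichment decisions live at small $k$, where
  approximations are worst. BH adjustment
  (`statsmodels.multipletests(method="fdr_bh")`) spans exactly the emitted
  rows — pathways with $k = 0$ are not tested and therefore not counted in
  $m$. Only upper-tail enrichment is computed; depletion is out of scope.
- Rows are sorted by raw p ascending, ties broken by pathway id, so output
  is byte-deterministic.

## Reports

- KEGG Mapper color file: defined for the two-source case only (the
  coloring semantics are a two-source convention); more sources fall back
  to the tabular outputs. Default palette: first source blue, second
  yellow, both green, detected foreground orange; all overridable.
  `neither`-category compounds are omitted — there is no origin to color.
- Venn summary: region counts are computed by exact set algebra and always
  written as a text table; the figure (matplotlib circle patches, 2–3
  sets) is decoration, and with more than three sets only the counts are
  emitted. Region counts biject with origin-category counts restricted to
  the same sets, which is tested.
- The bundle manifest records inputs, database provenance, package
  version, seed and flags, and the exact file list, so a run is auditable.

## Synthetic data generator

The generator emulates the *structure* of KEGG that the pipeline depends
on: KOs linked to reactions, reactions with directed equations over a
compound pool, compounds grouped into pathways, and a gene→KO link table.
Defaults (30 KOs, 40 reactions, 60 compounds, 8 pathways, 50% reversible,
20% reaction-less KOs) give a network where a KO reaches 1–3 reactions and
equations carry 1–3 substrates/products with coefficients 1–2 — small but
covering every grammar branch, including one symbolic-`n` equation.
Structural edge cases exist by construction: an orphan (reaction-less) KO,
a substrate-only compound, reversible and forward arrows, and one compound
produced by reactions of two different KOs. The `planted_enrichment`
option adds a dedicated source KO whose reactions produce exactly one
pathway's compounds, kept exclusive to that pathway, so the planted
pathway must rank first.

What the generator does **not** emulate: KEGG's degree distribution (hub
currency metabolites), biochemical plausibility of equations, multi-step
pathway topology, or realistic KO/reaction counts (real KEGG has ~11,000
reactions). Passing tests therefore demonstrate correctness of parsing,
closure, classification, statistics and reporting — not that real-KEGG
runs will show any particular biology. Ground truth is recorded as JSON
next to the flat files and every oracle in the test suite reads the
generator's bookkeeping, never the parser's output.

## Numerical and determinism choices

- All pipeline logic is deterministic; the only randomness is the fixture
  generator, seeded from configuration. Tables are sorted (compounds
  lexicographically, enrichment by p then id), so identical runs produce
  byte-identical TSVs.
- Domain violations (hypergeometric constraints, p outside [0,1]) raise
  errors naming the violated inequality rather than clamping.
- Unknown ids raise a defined error on lookup; bulk operations skip and
  count unknowns instead of failing, because upstream KO predictions
  routinely contain ids absent from any given KEGG snapshot (in the
  motivating use case, only about a third of predicted microbiome KOs have
  reactions at all — the per-stage counts logged at INFO exist to make
  that data loss visible).
- BH is *not* idempotent on its own output (a monotone, capped q-vector
  can change under re-adjustment); the tests assert the properties that do
  hold — agreement with the literal step-up formula, permutation
  invariance, constant fixed points — rather than idempotence.

## Problem sizes used in verification

The acceptance script uses 20 generator seeds for closure checks, 100
random KO-set pairs for additivity, 200 random hypergeometric instances
with $N \le 12$ against exhaustive subset enumeration (the test suite
additionally sweeps *all* valid instances at $N \le 12$), 500 random
p-vectors ($m \le 50$) for BH, and 50 randomized two-source trials for
partition/Venn conservation. These sizes make every check exact or
enumeration-backed while keeping the whole verification run under a few
seconds.

## Known limitations

- Origin calls are hypotheses for follow-up (authentic standards, MS/MS,
  gnotobiotic designs), not evidence of production in vivo.
- Everything inherits KEGG's annotation gaps: unannotated genes,
  collapsed lipid species, and compound ids assigned by mass alone will
  propagate into origin calls.
- No co-metabolism chaining, no quantitative turnover scoring, no
  depletion testing, no KGML map rendering.
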