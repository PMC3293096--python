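# Methods

## The model

`cellvocab` treats an experiment vocabulary as a forest of *term nodes*
organized like nested folders. Four root terms — `study`, `assay`, `cell`,
`instrument` — anchor the forest; everything more specific hangs beneath
them, and the parent–child relation deliberately carries no name: the only
semantics asserted are "this term is organized under that one". This keeps
the structure open-ended (any user can append terms at any level, and root
labels may recur deeper in the tree) while still giving federated sites
fixed intersection points: two vocabularies grown independently under the
same roots can be merged by unifying nodes with equal normalized paths.

A path from a root to a node, joined with `:`, is the node's *phrase*
(`cell:history:maintenance_culture:passaging:plating_density`). Phrases are
the keys of every metadata record and every query.

### Term normalization

Two labels denote the same term when they differ only in case, whitespace,
dashes, underscores, parentheses/punctuation, or stop words. The canonical
key is computed by lower-casing, splitting on every non-alphanumeric
character, dropping stop-word tokens, and concatenating the rest. The
default stop-word list is `{of, the, a, an, and, in, for}`; only a couple
of stop words are conventional in this setting, so the list is a package
choice and is configurable per call. Two guard rails keep the map total
and idempotent on non-empty labels:

- a label consisting *only* of stop words (`"of"`) keeps its words rather
  than normalizing to the empty string;
- stop words are removed as whole tokens only, so `offer` is untouched.

Normalization never equates labels whose residual alphanumeric content
differs.

### The layered store

Instrument output is immutable — any processed result (e.g. a segmentation
mask) is a new file — whereas metadata tables must stay editable and
shareable. The two layers meet only through filenames, so filenames carry
the burden of being unambiguous. The OURI grammar is

```
<code>_<user region>_<unique id>_s<series><ext>
```

with `_` as the part delimiter, `_`→`-` escaping inside the user region,
unique IDs of the form `SITE` + ≥6-digit zero-padded counter, and the
extension carried verbatim. The content-code registry defaults to
`I` (image), `P` (protocol text), `R` (reference/benchmark), `D` (derived
data); the four kinds are fixed by the file types the catalog handles, but
the letter assignments and the delimiter are this package's declaration —
an implementation has to pick *some* concrete grammar, and the choice is
recorded here rather than inherited. The registry is extensible.

The catalog persists as three CSV linkage tables joined on the series
name (series metadata, image files, protocol files) plus the vocabulary
table. A relational engine would work equally well; CSV keeps the store
diffable and mirrors how the tables are actually exchanged. Free-form
protocol text never becomes a metadata value — it lives in separate
`P`-files linked through the protocol table.

Mask files are linked as image-role files with content code `D` on a
dedicated per-cell-type derived-data series carrying
`assay:datatype = derived`. Per-mask ↔ per-parent-image correspondence is
not modeled: only series-level linkage is specified, and inventing a
finer-grained link would overcommit the schema.

### Queries and comparison

A query is a conjunction of (phrase, predicate) selections; predicates are
equality, set membership, or wildcard (term present). OR is expressed as
membership within one selection — the interaction model being mirrored is
drill-down through a visual folder tree, which only ever narrows. Values
are opaque strings compared exactly after whitespace trimming
(`800 cells/cm2` is never parsed as a number). A wildcard selection on an
interior phrase matches any series holding any key at or beneath that
folder; value predicates apply to the value stored at the exact phrase.

`compare` reports one verdict per phrase: `equal`, `differs`, `missing_A`
or `missing_B`. A requested interior phrase expands to every key beneath
it in either series, so whole folders (`instrument`) can be compared in
one call. A phrase held by neither series is reported `equal` with both
values absent, which keeps the report symmetric under swapping the two
series.

### Merging

`merge_trees` enumerates every node path of every input, rewrites labels
through the (optional, explicit) synonym map, and inserts the paths into a
fresh tree. The merged normalized path set is therefore exactly the union
of the inputs' — merging is total, idempotent, commutative and associative
at the path-set level, and never deletes anything. Conflicting example
values under a unified token are concatenated with `[siteN]` provenance
tags rather than overwritten. Alignment happens only on full normalized
paths from the root: aligning shared interior terms with different root
ancestry would require semantics the folder model does not assert.

### Exports

The RDF export emits one `narrowerTerm` triple per parent→child edge in a
configurable project namespace (default `http://example.org/cellvocab/`),
plus an `rdfs:label` per node; since the hierarchy is unnamed, a single
SKOS-like predicate is the strongest claim the export can honestly make.
Node IRIs are slash-joined normalized paths, so triple count =
node count − root count, and the graph round-trips back to the exact
normalized path set. The XSD export nests one `xs:element` per node
(leaves string-typed); labels that are not valid XML names are emitted via
their normalized key with the raw label preserved in an `xs:annotation`.

## The synthetic study generator

`fixtures.StudyDesign` encodes the emulated study: two cell types (rat A10
vascular smooth muscle cells seeded at 800 cells/cm2, mouse NIH3T3
fibroblasts at 1200 cells/cm2), 3 replicate wells per type, 50 fields per
well, 5 Texas Red imaging conditions (exposure/filter variants), one DAPI
and one phase pass per field, 100 manually segmented masks per type, and
1 spatial + 4 intensity + 2 resolution instrument benchmarks. The closed
forms are

- Texas Red per type: fields × conditions × wells = 50 × 5 × 3 = 750,
- per extra channel per type: fields × wells = 150,
- total images: 2 × (750 + 150 + 150 + 100) + 7 = 2307.

One metadata series is generated per (cell type, well); the imaging
conditions are recorded inside each series as per-condition terms
(`…:imaging condition:c1` … `c5`) since how the original study distributed
them across records is not documented — folder-level selection makes the
convention queryable either way. Masks get one derived-data series per
cell type, benchmarks one dedicated instrument series; every series links
exactly one protocol file.

The fixture vocabulary is this package's own wording of a realistic
cell-imaging term list; it reproduces the *structure and size* of the term
list of the prototype database it emulates — 163 terms under the four
roots at the default design — not its exact contents, which are not
reproduced in any source available to this package. The `seed` jitters
only free-text values (passage numbers, exposure descriptions); the
manifest arithmetic and filenames are seed-independent, and the same seed
reproduces the fixture byte-identically.

What the fixture does **not** emulate: pixel data (manifests are
filename-level only; optional protocol stubs are the only files written),
acquisition timestamps, per-mask parentage, and any of the segmentation
study's accuracy results. Tests passing on the fixture therefore show that
the metadata machinery is sound, not that any image-analysis claim holds.

## Numerical and design choices

- Children are stored and rendered sorted by normalized key; ordering is
  unspecified in the folder model, and determinism is chosen for
  testability (renders and saves are byte-stable).
- Synonym collisions (two sibling labels with one normalized key) are a
  hard error on `add_term`, but configurable warn-or-fail on bulk
  `build_tree`, since legacy spreadsheets must be importable.
- Catalog persistence writes series and metadata rows sorted, file rows in
  registration order (insertion order is part of the record); save → load
  → save is byte-identical.
- `evaluate` is defined to agree with a brute-force linear scan of all
  series; the implementation compiles selections to normalized paths but
  the scan remains the semantic reference (and the test oracle).
- Degenerate inputs: empty tables build empty trees; the empty query is
  universal; zero-count designs produce empty (but valid) manifests;
  empty user regions are legal OURI parts.

## Problem sizes

The default test suite exercises the full default design (2307-file
manifest, 163-term tree) once per session and uses scaled-down designs
(2 wells × 3 fields × 2 conditions) for persistence and CLI round trips;
property suites run 25–300 randomized examples per invariant and 100
randomized catalogs for the query/scan agreement. The whole suite
completes in a few seconds.

## Known limitations

- No fuzzy matching beyond the normalization rule; synonym resolution is
  entirely manual (explicit maps).
- No OWL semantics, reasoning, or SPARQL service over the RDF export.
- Single-user, in-memory catalog; no transactions or concurrent writers.
- OURIs are not resolved to URLs and carry no content checksums.
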