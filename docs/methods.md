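# Methods

## The data model and its two modes

The atomic observation of an ethnomedicinal survey is the use report —
one informant citing one species for one ailment. Published surveys,
however, rarely release per-informant data; they print aggregates: the
frequency of citation FC per species, the use-mention count UM for a
species' principal purpose, and per-category taxon/use-report totals
(Nt, Nur). The `SurveyDataset` container therefore runs in two modes:

- **raw** — use reports present; FC, UM, Nt and Nur are derived by
  counting. A stored FC that disagrees with the recomputed
  distinct-informant count is a validation error.
- **aggregate** — only the published counts are stored; the indices are
  computed from them directly.

`aggregate_survey` collapses a raw dataset to aggregate form, and the test
suite asserts that indices computed either way agree exactly — the
aggregate path is a cached version of the raw path, not a second method.

One deliberate asymmetry: per-category Nt counts the taxa a category's
*reports* cite in raw mode (which guarantees Nt ≤ Nur, as the consensus
ratio requires), but counts ailment listings in aggregate mode, where
reports do not exist. With complete citation the two coincide.

## The packaged Kohistan dataset

The reference dataset transcribes a published five-group survey: 20
villages with per-village informant counts (N = 281), 96 species records
(taxonomy, local names with language tags, habit, parts, preparations,
routes, ailments, voucher, FC), and twelve ICPC-2 disease categories with
their (Nt, Nur) totals and highest-fidelity exemplar species. Since the
per-informant reports were never published, the dataset is aggregate-mode,
and all printed index values — all 12 category ICFs and all 12 exemplar
FLs — reproduce exactly under half-up rounding at 2 decimals.

Transcription choices worth knowing about:

- **Group membership.** Local-name language tags under-report sharing, so
  cross-cultural membership uses explicit per-species group columns: the
  35 taxa the source narrative lists as unique to one group (13 Shina, 10
  Kohistani, 8 Bateri, 2 Pushto, 2 Gujjari) carry that single group, and
  the remaining 61 carry all five — consistent with the narrative's count
  of 61 taxa shared by every group.
- **Ailment vocabulary.** Every ailment term maps to exactly one category
  (ties are validation errors). Where the source's own per-row category
  labels conflict (e.g. "backache" appears under both musculoskeletal and
  "others"), the majority assignment wins and the printed per-category
  totals are stored as aggregates rather than re-derived; re-categorising
  the transcription yields slightly different Nt values (44 vs 40 for the
  digestive category), an internal inconsistency of the printed tables
  that the package records rather than adjudicates.
- **Known printed-value conflicts.** One exemplar row prints FC 14 where
  the species table prints FC 15; the exemplar's own (UM, FC) pair is used
  for its fidelity value, as printed. One exemplar species does not occur
  in the species table at all and is kept as an exemplar-only row. The
  printed life-form percentages (71.8/16.6/10.4) differ by ~2 points from
  a recount of the printed habit column; summaries are checked within ±3
  points. The families Compositae/Leguminosae are kept as printed unless
  `canonicalize_families=True`.
- **Prior literature.** No machine-readable comparison table exists, so
  `literature_stub.csv` is a curated stub: one row per previously reported
  taxon with a recorded use. It supports taxon-level novelty flagging (the
  ten first-report taxa) but is not a bibliography.

## Indices and numerical choices

- RFC = FC/N is computed at full precision. The definition's strict bound
  0 < RFC < 1 is treated as a data-quality warning (`BoundaryWarning`),
  not an error: fc = 0 (an uncited listed species) and fc = N are legal.
- ICF = (Nur − Nt)/(Nur − 1) returns an explicit `None` at Nur = 1
  (zero denominator); tables carry it as NaN. It is never coerced to 0
  or 1.
- FL = 100·Ip/Iu. In raw mode the principal purpose is the modal ailment
  of the species' reports (alphabetical tie-break); in aggregate mode the
  stored UM is used.
- Display rounding is half-up via `decimal` (`0.005 → 0.01`); Python's
  built-in banker's rounding would disagree with conventionally printed
  tables on ties. Full precision is retained in every machine-readable
  export (`*_rounded` columns sit beside the exact ones).
- Frequency-summary denominators: habit and family are one-per-species
  (denominator = species count); part/preparation/route admit several
  terms per species, so the denominator is the count of species-term
  incidences.
- Ranking is descending with alphabetical tie-break by default (a
  "stable" rule preserves input order); tied rows are flagged.

## Cross-cultural partition

`venn_partition` assigns each quoted item to the subset of groups quoting
it — an exact partition, verified in the tests against a brute-force
per-item membership enumeration over randomized instances (≤ 5 groups,
≤ 200 items) on every one of the 2^k − 1 regions. Overlap percentages
divide by the union of quoted items of that kind, and region percentages
sum to 100 before display rounding.

Use units default to (species, ailment-term) pairs; a coarser
(species, category) granularity is available. The source survey's
use-level Venn counts (109 uses, 1.83 % vs "12" shared across all groups)
are internally inconsistent and were computed from unpublished data, so
they are not reproduction targets; the use-level machinery is validated on
synthetic data instead.

## Synthetic-survey generator

The generator emulates the structure the analysis assumes, nothing more:

- *k* groups of stated sizes; the species pool splits into a shared core,
  group-unique blocks, and a mixed class accessible to a random proper,
  non-singleton subset of groups (so that the designed core and unique
  sets are exactly recoverable under certain citation; a mixed class
  therefore needs ≥ 3 groups).
- Independent Bernoulli citation: informant *i* of group *g* cites an
  accessible species *s* with probability p(g, class(s)); each citation
  yields one use report whose ailment is the species' principal purpose
  with probability `purpose_concentration` and otherwise uniform over the
  rest of the repertoire.

Under this model E[FC(s)] = Σ_g n_g · p(g, class(s)) and the FL of a
multi-purpose species estimates 100 · purpose_concentration, which is what
`recovery_check` verifies (exact set recovery under certain citation; FL
within 3 binomial standard errors at FC ≥ 30; ICF = 1 for single-taxon
categories with ≥ 2 reports).

Defaults are the reference survey's conditions: groups of 101/88/35/29/28
informants, 96 species with a 61-species core and 10/13/8/2/2 unique
blocks, and citation probabilities calibrated so expected FC falls in the
observed 9–18 band (0.05 for core species, which all 281 informants can
cite; group-specific 0.14–0.50 for unique species, inverse to group size).
`purpose_concentration` defaults to 0.7, the centre of the observed
fidelity range (41.67–94.44 %). Ages are drawn uniformly on 20–80.

What the generator deliberately does **not** model: informant-level
heterogeneity beyond group membership, age/gender knowledge gradients,
correlated citation (social transmission), or seasonal/village structure.
Passing recovery tests therefore show the *pipeline* is correct under the
stated model, not that real surveys satisfy the model.

Randomness: one root seed feeds a fixed spawn order of six independent
streams (structure, accessibility, repertoires, demographics, citations,
purposes), so adding a configuration field cannot silently reshuffle
earlier draws, and equal seeds give byte-identical exports.

Statistical tests in the suite use 200 replicates of a 40–100 species,
75-informant configuration — large enough for 3-standard-error bands to
be meaningful, small enough that the whole suite runs in seconds.

## Command-line interface

`ethnosurvey` exposes `analyze`, `indices`, `venn`, `simulate` and
`validate` subcommands. Outputs are CSV tables plus one plain-text
summary whose every number also appears in a table; logging goes to
stderr (`-q` silences below warnings); strict-mode validation failures
exit nonzero and remove partial outputs. Venn *figures* are not rendered —
the region table is the analytical artifact; the set sizes it contains can
be fed to any drawing tool.

## Known limitations

- Aggregate mode cannot reconstruct per-purpose fidelity for species
  without a stored UM; such species simply have no fidelity row.
- The ailment vocabulary is survey-specific; applying the packaged one to
  other datasets will bin unknown terms under "Others" (lenient) or fail
  (strict) by design.
- Name normalisation strips authorities by position (first two epithets
  plus an infraspecific qualifier); it is not a nomenclatural resolver and
  does not consult any taxonomic backbone.
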