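# Methods

## The problem

Dispersed sporomorphs — fossil spores and pollen grains found loose in
sediment — are described under form-genus names because the plant that
produced them is not directly observable. Palaeoenvironmental interpretation
of a sporomorph assemblage therefore needs two inferences layered on top of
the counts: (1) a botanical affinity, linking each sporomorph genus to its
most likely parent plant at phylum, order or family level, and (2) an
Eco-Plant classification of that parent plant by its climatic tolerance — a
humidity group (EPH: hydrophytes, hygrophytes, mesophytes, xerophytes,
euryphytes) and a temperature group (EPT: megathermic, mesothermic,
microthermic, eurythermic). Shifts in the relative abundance of these groups
through a stratigraphic section track relative humidity and temperature
change. The approach is applicable to Triassic and Jurassic assemblages of
bryophyte, pteridophyte and gymnosperm sporomorphs; angiosperm pollen and
Paleozoic taxa are not covered by the ecogroup assignments and resolve to
Uncertain.

## The procedure

The pipeline is a relational join followed by a compositional normalisation:

1. **Annotate.** Each observation (sample, genus, abundance) is joined on
   the genus name to one of two reference tables: the taxonomy table
   (genus → kingdom/phylum/class/order/family) for the rank modes, or the
   ecogroup table (genus → EPH, EPT) for the ecogroup modes. A genus absent
   from the relevant table, or present with the requested field blank, is
   assigned the sink category **Uncertain**. Absence is a value, not an
   error: unresolved affinity is a routine outcome and must stay visible in
   the result.
2. **Group.** Abundances are summed by (sample, category). Duplicate
   (sample, genus) rows are legal and simply add.
3. **Normalise.** Each sum is divided by the sample's *total* uploaded
   abundance — Uncertain mass included in the denominator — and multiplied
   by 100. This holds whether the input column carries raw grain counts or
   pre-computed percentages: a percentage column that totals 100.2 is
   renormalised against 100.2, so a category with raw value 34 reports
   33.9, not 34.0. Keeping Uncertain in the denominator means the published
   single Uncertain row and the interpretable categories together always
   account for exactly 100% of the counted material.

Categories are presented alphabetically (case-insensitive) with Uncertain
forced last, samples in first-appearance order. An all-zero Uncertain
column is dropped rather than printed as a row of zeros; other categories
are materialised as 0 in every sample where they do not occur, so all
samples share one column set.

An off-by-default `linked_only` toggle renormalises against linked
(non-Uncertain) mass only, for users who want percentages of the
interpretable fraction; it drops the Uncertain column entirely.

## Numerical choices

Abundances are parsed from their decimal text into exact rationals
(`fractions.Fraction`), and the whole aggregation runs in rational
arithmetic. Consequences:

- each sample's output row sums to exactly 100 (an identity, not a
  tolerance);
- multiplying a sample's abundances by any positive rational leaves its
  output row bit-for-bit unchanged — the counts-versus-percent equivalence
  the input format promises is exact;
- floats appear only at the display, plotting and DataFrame boundary.

Display rounding is half-away-from-zero to 1 decimal by default, with
trailing zeros trimmed (so whole percentages print as `25`, `2`, `0`). The
stored values keep full precision and the rounding is re-derivable at any
`decimals` setting. No printed cell in the worked example discriminates
half-even from half-up rounding, so tests compare printed cells within
±0.05 — the display-rounding ambiguity — while internal comparisons are
exact.

Degenerate inputs: a sample whose abundances total zero has undefined
percentages and is rejected by name; negative, blank or non-numeric
abundance cells are rejected with their file row number; thousands
separators are rejected rather than guessed at (a comma inside a number in
a comma-separated file is almost always a column error). Genus matching is
whitespace-trimmed and case-insensitive, with original spellings preserved
for display; duplicate genera within one reference table are a load error.

## Reference tables

The bundled taxonomy (17 genera) and ecogroup (16 genera) CSVs are the
published excerpts of a much larger curated dataset; they are exactly what
is needed to reproduce the worked example and are not extended beyond it.
Both loaders accept drop-in replacements of the same schema, and
`merge_reference` overlays a correction table over a base (last writer
wins), so a revised affinity — e.g. reassigning *Annulispora* from
Notothyladaceae to Sphagnaceae — is a two-line CSV, not a code change.
EPH/EPT values are validated against the closed five- and four-member
group sets; "halophytes", which Mesozoic usage folds into xerophytes, is
deliberately rejected rather than silently remapped. Empty rank cells are
stored as absent: a genus linked at order level only returns Uncertain in
family mode, because inventing a family the reference does not assert
would be worse than admitting ignorance. Kingdom and class are stored but
are not analysis modes.

## Diagrams

Rendering follows pollen-diagram convention: one panel per category, panels
sharing a single vertical sample axis, one horizontal bar (default) or
silhouette per sample per panel, percentages on the horizontal axes.
Horizontal axes are scaled per panel to the panel maximum rounded up to the
next multiple of 5, or fixed via `scale_max` (e.g. 100 for full-scale
panels). Samples follow input order, or depth order (shallowest on top)
when every sample carries a depth; depth never enters the aggregation
itself. The Uncertain panel is drawn last on a grey field so unlinked mass
is visible but separated from the interpretable signal. Output formats are
PDF (default), SVG and PNG. Draw-curve mode plots a user-supplied wide
matrix verbatim — no lookup, no renormalisation, no Uncertain row — for
users who edited or combined result tables by hand.

## Synthetic data

`random_assemblage` emulates counted sporomorph samples for property
testing: per sample, community proportions are drawn from a symmetric
Dirichlet over the genus pool (default: all genera of the reference
taxonomy, so the linked share is fully linkable in every mode), a
configurable expected fraction of abundance is routed to invented genera
absent from every reference table, and grain counts are multinomial
(default 300 grains/sample, a realistic palynological counting effort; a
"percent" mode emits the proportions scaled to 100 instead). The generator
reproduces exactly under its seed. It does **not** model taphonomy,
differential pollen productivity, transport bias, or correlated
stratigraphic structure between samples — so passing tests demonstrate the
arithmetic and bookkeeping of the method on realistic-looking tables, not
ecological realism of the communities themselves.

Test problem sizes: the conservation sweep uses 200 seeded assemblages
(2 samples × 200 grains) across all five modes; scale invariance uses 50
assemblages × three factors {0.01, 3, 1000}; the brute-force oracle sweep
enumerates all 18,563 multisets of up to 6 rows over a 4-genus pool with
abundances in {1, 2, 3} and checks exact agreement with an explicit-loop
rational recomputation.

## Known limitations

- The bundled references are excerpts; real studies must supply fuller
  tables via `--taxonomy`/`--ecogroup` or `merge_reference`.
- No synonym resolution: users must supply advisable genus names; a broad
  collective name simply resolves to whatever the reference asserts for it,
  or to Uncertain.
- No downstream statistics (climate indices, ordination, zonation,
  confidence intervals on percentages): the method stops at grouped
  percentages, which the researcher interprets.
- Ecogroup modes display only observed groups; a humidity group absent
  from both the assemblage and the Uncertain sink is not materialised as a
  zero row.
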