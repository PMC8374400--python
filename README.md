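# ecoplant

Eco-Plant analysis of dispersed sporomorph assemblages: link fossil spore
and pollen counts to parent-plant taxonomy and Eco-Plant ecogroups, compute
per-sample percentage abundances with an *Uncertain* sink, and draw
stratigraphic pollen diagrams.

## Who this is for

Palynologists reconstructing Triassic–Jurassic palaeoenvironments from
dispersed sporomorph counts. Sporomorph genera are form taxa, so the
producing plant must be inferred: a genus-keyed **taxonomy** table supplies
the parent plant's phylum/order/family, and a genus-keyed **ecogroup**
table supplies its Eco-Plant humidity group (EPH: hydrophytes, hygrophytes,
mesophytes, xerophytes, euryphytes) and temperature group (EPT:
megathermic, mesothermic, microthermic, eurythermic). Relative abundances
of these groups through a section track relative humidity and temperature
change.

## The computation

For an assemblage of observations (sample *s*, genus *g*, abundance
*a(s,g)*) and an analysis mode *m* ∈ {PHYLUM, ORDER, FAMILY, EPH, EPT},
each genus resolves to a category *c(g)* by joining on the genus name
(genera absent from the relevant table resolve to *Uncertain*), and

```
P(s, C) = 100 · Σ_{g : c(g)=C} a(s,g) / Σ_g a(s,g)
```

The denominator is the sample's **total** uploaded abundance, Uncertain
included, so each sample's percentages sum to exactly 100 and the input may
be raw grain counts or pre-computed percentages interchangeably. All
arithmetic is exact (rational); rounding happens only at display time.

## Worked example

The package bundles a two-sample Triassic assemblage (samples HJG 01 and
HJG 02, 29 rows) plus taxonomy and ecogroup excerpts. Export them and run
the order-level vegetation analysis:

```sh
ecoplant fixtures --out example
ecoplant vegetation --rank order example/assemblage.csv -o order.csv --pdf order.pdf
```

`order.csv` contains:

```
Sample,HJG 01,HJG 02
Bennettitales,33.8,8.9
Corystospermales,25,33.9
Cyatheales,6.6,4.7
Equisetales,0,2
Ginkgoales,4.4,7.5
Gleicheniales,13.2,7.7
Isoetales,7.4,2.4
Lycopodiales,0,8.4
Marattiales,0,11.3
Notothyladales,5.9,0.7
Osmundales,0.7,0
Peltaspermales,0,1.3
Pinales,1.5,9.8
Uncertain,1.5,1.5
```

Reading the numbers: in HJG 01, 33.8% of all counted grains came from
Bennettitales producers (the sporomorph genera *Bharadwajipollenites*,
30.9, and *Huabeisporites*, 2.9, over a sample total of 100.0).
HJG 02's Corystospermales cell is **33.9**, not the raw 34 in the input:
that sample's abundance column totals 100.2, and every sample is
renormalised against its own column total. *Quadraeculina* has no accepted
parent plant, so its 1.5 sits in the Uncertain row — still counted in the
denominator, never silently dropped. `order.pdf` is the same matrix as a
14-panel pollen diagram, one horizontal track per sample, Uncertain panel
last and greyed.

The ecogroup modes work the same way through the ecogroup table:

```sh
ecoplant eph example/assemblage.csv -o eph.csv
```

gives HJG 01 the humidity split hydrophytes 7.4, hygrophytes 16.1,
mesophytes 42.6, xerophytes 1.5, Uncertain 32.4 — a mesophyte-dominated
flora, with about a third of the grains from genera the ecogroup excerpt
does not cover (the run log lists them to stderr).

`ecoplant draw-curve matrix.csv --pdf fig.pdf` plots an already-wide
percentage matrix (first column `Sample`, one column per category) exactly
as given — no lookup, no renormalisation — for hand-combined or edited
result tables. The same pipeline is available as a library:

```python
import ecoplant as ep

refs = ep.default_reference()          # or load_taxonomy / load_ecogroup
asm = ep.example_table("assemblage")
matrix = ep.run_analysis(asm, "order", refs)
print(ep.write_matrix(matrix, decimals=1))
```

Larger reference tables drop in by path (`--taxonomy`, `--ecogroup`) or by
overlaying corrections with `ep.merge_reference`; the bundled CSVs are
excerpts sized to the worked example.

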