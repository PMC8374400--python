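"""Grouped percentage abundances with an Uncertain sink.

The analysis pipeline is: annotate every observation with a category by joining
on the genus name, group by (sample, category), and normalise each sample to
percentages of its *total* uploaded abundance — unlinked (Uncertain) mass
included in the denominator.  That denominator choice is what the method's
published example demonstrates: a sample whose percentage column totals 100.2
yields 34/100.2*100 = 33.9 for its largest category, not 34.0, so even
percentage input is renormalised against the per-sample column total.

All arithmetic is exact (Fraction), so each sample's output row sums to 100
identically and scaling a sample's abundances by any positive rational leaves
its percentages bit-for-bit unchanged — the counts-versus-percent equivalence
the input contract promises.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .assemblage_io import AbundanceMatrix, AssemblageTable, Observation
from .errors import ValidationError
from .reference import UNCERTAIN, ReferenceSet, lookup_category

__all__ = [
    "AnalysisMode",
    "AnnotatedObservation",
    "annotate",
    "aggregate_percent",
    "format_matrix",
    "run_analysis",
]


class AnalysisMode(enum.Enum):
    """Grouping field for an analysis run.

    PHYLUM/ORDER/FAMILY group by parent-plant rank via the taxonomy table;
    EPH/EPT group by Eco-Plant humidity/temperature class via the ecogroup
    table.  Kingdom and class are stored in the taxonomy but are not analysis
    modes.
    """

    PHYLUM = "phylum"
    ORDER = "order"
    FAMILY = "family"
    EPH = "eph"
    EPT = "ept"

    @classmethod
    def _missing_(cls, value):
        if isinstance(value, str):
            try:
                return cls[value.strip().upper()]
            except KeyError:
                return None
        return None

    @property
    def uses_taxonomy(self) -> bool:
        return self in (AnalysisMode.PHYLUM, AnalysisMode.ORDER, AnalysisMode.FAMILY)

    @property
    def rank_field(self) -> str:
        """Attribute name on the reference record holding this mode's value."""
        return self.value


@dataclass(frozen=True)
class AnnotatedObservation:
    """An observation plus the category its genus resolved to."""

    observation: Observation
    category: str


def annotate(
    assemblage: AssemblageTable, mode: AnalysisMode, refs: ReferenceSet
) -> list[AnnotatedObservation]:
    """Attach a category to every observation, preserving row order.

    Genera missing from the relevant reference table (or with the requested
    rank blank) carry the ``Uncertain`` sink category.
    """
    mode = AnalysisMode(mode)
    cache: dict[str, str] = {}
    out: list[AnnotatedObservation] = []
    for obs in assemblage.observations:
        key = obs.genus.casefold()
        if key not in cache:
            cache[key] = lookup_category(obs.genus, mode, refs)
        out.append(AnnotatedObservation(obs, cache[key]))
    return out


def aggregate_percent(
    annotated: Sequence[AnnotatedObservation],
    *,
    mode: AnalysisMode | None = None,
    linked_only: bool = False,
) -> AbundanceMatrix:
    """Group annotated rows by (sample, category) and normalise to percent.

    value(sample, category) = 100 * sum(abundance of that category in that
    sample) / sum(abundance of all rows of that sample).  Categories absent
    from a sample are materialised as 0 wherever the category occurs in any
    sample, and Uncertain mass stays in the denominator, so every sample row
    sums to exactly 100.

    ``linked_only=True`` switches to percentages of the linked (non-Uncertain)
    mass only; this is an off-by-default convenience and drops the Uncertain
    column entirely.
    """
    sums: dict[str, dict[str, Fraction]] = {}
    totals: dict[str, Fraction] = {}
    categories: dict[str, None] = {}
    depths: dict[str, float] = {}
    for ann in annotated:
        obs = ann.observation
        sample_sums = sums.setdefault(obs.sample, {})
        sample_sums[ann.category] = (
            sample_sums.get(ann.category, Fraction(0)) + obs.abundance
        )
        totals[obs.sample] = totals.get(obs.sample, Fraction(0)) + obs.abundance
        categories.setdefault(ann.category)
        if obs.depth is not None and obs.sample not in depths:
            depths[obs.sample] = obs.depth

    if linked_only:
        categories.pop(UNCERTAIN, None)
        totals = {
            s: sum(
                (v for c, v in by_cat.items() if c != UNCERTAIN), start=Fraction(0)
            )
            for s, by_cat in sums.items()
        }

    for sample, total in totals.items():
        if total == 0:
            raise ValidationError(f"sample {sample!r} has total abundance 0")

    samples = list(sums)
    cats = list(categories)
    exact: dict[tuple[str, str], Fraction] = {}
    rows: list[list[float]] = []
    for sample in samples:
        row: list[float] = []
        for cat in cats:
            share = 100 * sums[sample].get(cat, Fraction(0)) / totals[sample]
            exact[(sample, cat)] = share
            row.append(float(share))
        rows.append(row)

    data = pd.DataFrame(rows, index=samples, columns=cats, dtype=float)
    return AbundanceMatrix(data=data, mode=mode, depths=depths, exact=exact)


def format_matrix(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Presentation ordering: categories alphabetical, Uncertain forced last.

    Sample order (first appearance) and cell values are untouched.  An
    Uncertain column whose mass is zero everywhere is dropped rather than
    printed as a row of zeros.
    """
    if matrix.mode is None:
        raise ValidationError("draw-curve matrices are plotted as given, not formatted")
    cats = [c for c in matrix.categories if c != UNCERTAIN]
    cats.sort(key=str.casefold)
    if UNCERTAIN in matrix.categories and float(matrix.data[UNCERTAIN].sum()) > 0:
        cats.append(UNCERTAIN)
    data = matrix.data.loc[:, cats]
    exact = None
    if matrix.exact is not None:
        exact = {
            (s, c): v for (s, c), v in matrix.exact.items() if c in set(cats)
        }
    return AbundanceMatrix(
        data=data, mode=matrix.mode, depths=dict(matrix.depths), exact=exact
    )


def run_analysis(
    assemblage: AssemblageTable,
    mode: AnalysisMode,
    refs: ReferenceSet,
    *,
    linked_only: bool = False,
) -> AbundanceMatrix:
    """annotate -> aggregate -> format in one call; the usual entry point."""
    mode = AnalysisMode(mode)
    annotated = annotate(assemblage, mode, refs)
    matrix = aggregate_percent(annotated, mode=mode, linked_only=linked_only)
    return format_matrix(matrix)
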