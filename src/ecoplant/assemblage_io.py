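"""CSV dialects for sporomorph count data.

Two user-facing shapes exist:

* the **long** assemblage table — one row per (sample, genus) observation with
  columns Sample, Genus, Abundance and optionally Depth.  Abundance may be raw
  grain counts or pre-computed percentages; the analysis renormalises either
  way, so the distinction never matters downstream.
* the **wide** matrix — first column Sample, remaining columns category
  percentages.  This shape feeds the draw-curve mode (plotting exactly the
  numbers supplied, no reference lookup, no renormalisation) and is also what
  an analysis run writes out.

Abundances are parsed into exact rationals (`fractions.Fraction`) straight
from their decimal text, so every later percentage is an exact arithmetic
identity; floats are produced only at the display/plot boundary.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from fractions import Fraction
from pathlib import Path
from typing import IO, Sequence, Union

import pandas as pd

from .errors import InputFormatError, ValidationError

__all__ = [
    "Observation",
    "AssemblageTable",
    "AbundanceMatrix",
    "read_long_assemblage",
    "read_wide_matrix",
    "write_long_assemblage",
    "write_matrix",
]

Source = Union[str, Path, IO[str]]
Number = Union[int, float, str, Fraction, Decimal]


def as_fraction(value: Number) -> Fraction:
    """Convert a CSV cell or numeric literal to an exact Fraction.

    Decimal strings convert losslessly ("0.7" -> 7/10).  Thousands separators
    are rejected rather than guessed at: a comma inside a number in a
    comma-separated file is almost always a column error.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, (int, float, Decimal)):
        return Fraction(value)
    text = value.strip()
    if "," in text:
        raise ValueError(f"thousands separators are not accepted: {value!r}")
    try:
        return Fraction(Decimal(text))
    except InvalidOperation:
        raise ValueError(f"not a number: {value!r}") from None


def fraction_to_str(x: Fraction) -> str:
    """Render a Fraction as plain decimal text when exact, else as a float."""
    num, den = x.numerator, x.denominator
    if den == 1:
        return str(num)
    # Exact decimal expansion exists iff the denominator is 2^a * 5^b.
    d = den
    for p in (2, 5):
        while d % p == 0:
            d //= p
    if d == 1:
        return str(Decimal(num) / Decimal(den))
    return repr(float(x))


@dataclass(frozen=True)
class Observation:
    """One counted (or percentage) occurrence of a genus in a sample."""

    sample: str
    genus: str
    abundance: Fraction
    depth: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample", self.sample.strip())
        object.__setattr__(self, "genus", self.genus.strip())
        object.__setattr__(self, "abundance", as_fraction(self.abundance))
        if not self.sample:
            raise ValidationError("empty sample label")
        if not self.genus:
            raise ValidationError("empty genus name")
        if self.abundance < 0:
            raise ValidationError(
                f"negative abundance {self.abundance} for {self.genus!r}"
            )


@dataclass(frozen=True)
class AssemblageTable:
    """Ordered long-format observations; row order is preserved from source."""

    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))

    @property
    def sample_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for obs in self.observations:
            seen.setdefault(obs.sample)
        return list(seen)

    def totals(self) -> dict[str, Fraction]:
        out: dict[str, Fraction] = {}
        for obs in self.observations:
            out[obs.sample] = out.get(obs.sample, Fraction(0)) + obs.abundance
        return out

    def depths(self) -> dict[str, float]:
        """First non-missing depth per sample (samples without depth omitted)."""
        out: dict[str, float] = {}
        for obs in self.observations:
            if obs.depth is not None and obs.sample not in out:
                out[obs.sample] = obs.depth
        return out

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class AbundanceMatrix:
    """Samples x categories percentage matrix.

    ``data`` is a float DataFrame (samples as index, categories as columns).
    For analysis output (``mode`` set) ``exact`` carries the same cells as
    Fractions, where each sample row sums to exactly 100; for draw-curve input
    (``mode is None``) values are taken verbatim from the file and ``exact``
    is absent.
    """

    data: pd.DataFrame
    mode: object | None = None  # AnalysisMode for analysis output, None for raw
    depths: dict[str, float] = field(default_factory=dict)
    exact: dict[tuple[str, str], Fraction] | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def categories(self) -> list[str]:
        return list(self.data.columns)

    def value(self, sample: str, category: str) -> float:
        return float(self.data.at[sample, category])

    def exact_value(self, sample: str, category: str) -> Fraction:
        if self.exact is None:
            raise ValueError("matrix has no exact values (raw draw-curve input)")
        return self.exact.get((sample, category), Fraction(0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _read_table(source: Source) -> pd.DataFrame:
    try:
        return pd.read_csv(
            source, dtype=str, keep_default_na=False, encoding="utf-8-sig", sep=","
        )
    except pd.errors.EmptyDataError:
        raise InputFormatError("file is empty (no header row)") from None


def read_long_assemblage(source: Source) -> AssemblageTable:
    """Read a long-format assemblage CSV (Sample, Genus, Abundance[, Depth]).

    Header matching is case-insensitive and extra columns are ignored.
    Duplicate (sample, genus) rows are legal and are summed at aggregation
    time.  Rows with blank, non-numeric or negative abundance are rejected
    with their file row number, and a sample whose abundances total zero is a
    validation error (its percentages would be undefined).
    """
    df = _read_table(source)
    cols = {str(c).strip().casefold(): c for c in reversed(df.columns)}
    for required in ("sample", "genus", "abundance"):
        if required not in cols:
            raise InputFormatError(
                f"assemblage file has no {required.capitalize()!r} column"
            )
    has_depth = "depth" in cols

    observations: list[Observation] = []
    for i, (_, row) in enumerate(df.iterrows()):
        rownum = i + 2
        depth: float | None = None
        if has_depth:
            raw_depth = str(row[cols["depth"]]).strip()
            if raw_depth:
                try:
                    depth = float(as_fraction(raw_depth))
                except ValueError as exc:
                    raise ValidationError(f"bad depth: {exc}", row=rownum) from None
        try:
            abundance = as_fraction(str(row[cols["abundance"]]))
        except ValueError as exc:
            raise ValidationError(str(exc), row=rownum) from None
        try:
            observations.append(
                Observation(
                    sample=str(row[cols["sample"]]),
                    genus=str(row[cols["genus"]]),
                    abundance=abundance,
                    depth=depth,
                )
            )
        except ValidationError as exc:
            raise ValidationError(str(exc), row=rownum) from None

    table = AssemblageTable(tuple(observations))
    for sample, total in table.totals().items():
        if total == 0:
            raise ValidationError(f"sample {sample!r} has total abundance 0")
    return table


def write_long_assemblage(table: AssemblageTable, sink: Source | None = None) -> str:
    """Serialise an assemblage back to the long CSV dialect."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    any_depth = any(obs.depth is not None for obs in table.observations)
    header = (["Depth"] if any_depth else []) + ["Sample", "Genus", "Abundance"]
    w.writerow(header)
    for obs in table.observations:
        row = []
        if any_depth:
            row.append("" if obs.depth is None else _trim_float(obs.depth))
        row += [obs.sample, obs.genus, fraction_to_str(obs.abundance)]
        w.writerow(row)
    return _deliver(buf.getvalue(), sink)


def read_wide_matrix(source: Source) -> AbundanceMatrix:
    """Read a wide matrix CSV: first column Sample, then category percentages.

    Used by draw-curve mode; values are plotted exactly as supplied, so no
    renormalisation or reference lookup happens here.  The first header cell
    must be Sample (any letter-case).
    """
    df = _read_table(source)
    if len(df.columns) == 0 or str(df.columns[0]).strip().casefold() != "sample":
        first = str(df.columns[0]).strip() if len(df.columns) else "<none>"
        raise InputFormatError(
            f"first column of a wide matrix must be 'Sample', found {first!r}"
        )
    categories = [str(c).strip() for c in df.columns[1:]]
    if len(set(categories)) != len(categories):
        raise InputFormatError("duplicate category columns in wide matrix")

    samples: list[str] = []
    values: list[list[float]] = []
    for i, (_, row) in enumerate(df.iterrows()):
        rownum = i + 2
        sample = str(row.iloc[0]).strip()
        if not sample:
            raise ValidationError("empty sample label", row=rownum)
        if sample in samples:
            raise ValidationError(f"duplicate sample {sample!r}", row=rownum)
        cells: list[float] = []
        for cat, raw in zip(categories, row.iloc[1:]):
            try:
                v = as_fraction(str(raw))
            except ValueError as exc:
                raise ValidationError(f"column {cat!r}: {exc}", row=rownum) from None
            if v < 0:
                raise ValidationError(
                    f"column {cat!r}: negative abundance {raw}", row=rownum
                )
            cells.append(float(v))
        samples.append(sample)
        values.append(cells)

    data = pd.DataFrame(values, index=samples, columns=categories, dtype=float)
    return AbundanceMatrix(data=data, mode=None)


def format_percent(value: Fraction | float, decimals: int) -> str:
    """Display-round a percentage half-away-from-zero and trim zero padding.

    ``25`` prints as "25" and ``2.0`` as "2", mirroring how result tables are
    conventionally printed; the stored value keeps full precision.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    x = value if isinstance(value, Fraction) else Fraction(Decimal(repr(float(value))))
    scale = 10**decimals
    scaled = x * scale
    sign = -1 if scaled < 0 else 1
    # floor(|x| + 1/2) implements round-half-away-from-zero exactly.
    n = (abs(scaled) + Fraction(1, 2)).__floor__() * sign
    text = str(Decimal(n) / Decimal(scale)) if decimals else str(n)
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text


def write_matrix(
    matrix: AbundanceMatrix,
    sink: Source | None = None,
    *,
    layout: str = "samples_as_columns",
    decimals: int = 1,
) -> str:
    """Write a percentage matrix to CSV; returns the CSV text.

    ``samples_as_columns`` reproduces the conventional result-table shape:
    first column holds category names under the header cell "Sample", one
    column per sample, the Uncertain row (if any) last.  ``tidy`` emits
    (Sample, Category, Percent) triples.  Rounding is display-only.
    """
    if layout not in ("samples_as_columns", "tidy"):
        raise ValueError(f"unknown layout {layout!r}")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")

    def cell(sample: str, category: str) -> str:
        if matrix.exact is not None:
            return format_percent(matrix.exact_value(sample, category), decimals)
        return format_percent(matrix.value(sample, category), decimals)

    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    if layout == "samples_as_columns":
        w.writerow(["Sample"] + matrix.samples)
        for category in matrix.categories:
            w.writerow([category] + [cell(s, category) for s in matrix.samples])
    else:
        w.writerow(["Sample", "Category", "Percent"])
        for sample in matrix.samples:
            for category in matrix.categories:
                w.writerow([sample, category, cell(sample, category)])
    return _deliver(buf.getvalue(), sink)


def _trim_float(x: float) -> str:
    text = repr(x)
    return text[:-2] if text.endswith(".0") else text


def _deliver(text: str, sink: Source | None) -> str:
    if sink is None:
        return text
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)
    return text
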