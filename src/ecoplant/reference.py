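"""Genus-keyed reference tables: parent-plant taxonomy and Eco-Plant ecogroups.

Dispersed sporomorph genera are form taxa: the plant that produced them must be
inferred.  Two small relational tables carry that inference.  The *taxonomy*
table maps a sporomorph genus to the ranks of its most likely parent plant
(kingdom down to family); the *ecogroup* table maps a genus to its Eco-Plant
humidity group (EPH: hydrophytes, hygrophytes, mesophytes, xerophytes,
euryphytes) and temperature group (EPT: megathermic, mesothermic, microthermic,
eurythermic).  Both tables are keyed by the genus name, which is how they join
to an uploaded assemblage.

A genus that is absent from the relevant table — or present but with the
requested rank left blank — resolves to the ``Uncertain`` sink category rather
than raising: unresolved affinity is a routine outcome in palynology, not an
error.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Union

import pandas as pd

from .errors import DuplicateGenusError, InputFormatError, ValidationError

__all__ = [
    "UNCERTAIN",
    "EPH_GROUPS",
    "EPT_GROUPS",
    "TaxonRecord",
    "EcogroupRecord",
    "ReferenceSet",
    "load_taxonomy",
    "load_ecogroup",
    "write_taxonomy",
    "write_ecogroup",
    "lookup_category",
    "merge_reference",
    "list_unlinked",
    "canonical_genus",
]

#: Sink category for genera whose affinity is unknown under the active mode.
UNCERTAIN = "Uncertain"

#: Closed set of Eco-Plant humidity groups, from wettest to driest habit
#: (euryphytes tolerate a wide humidity range).
EPH_GROUPS = ("hydrophytes", "hygrophytes", "mesophytes", "xerophytes", "euryphytes")

#: Closed set of Eco-Plant temperature groups (eurythermic = wide tolerance).
EPT_GROUPS = ("megathermic", "mesothermic", "microthermic", "eurythermic")

Source = Union[str, Path, IO[str]]


def canonical_genus(name: str) -> str:
    """Matching key for a genus name: inner whitespace collapsed, casefolded."""
    return " ".join(name.split()).casefold()


def _clean(cell: str | None) -> str | None:
    if cell is None:
        return None
    cell = cell.strip()
    return cell or None


@dataclass(frozen=True)
class TaxonRecord:
    """Parent-plant ranks for one sporomorph genus.

    At least one of ``phylum``/``order``/``family`` must be present: a record
    carrying no analysable rank holds no information and is rejected at load
    time.  Kingdom and class are stored for completeness but no analysis mode
    groups by them.
    """

    genus: str
    kingdom: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genus", self.genus.strip())
        if not self.genus:
            raise ValidationError("genus name is empty")
        for f in ("kingdom", "phylum", "class_", "order", "family"):
            object.__setattr__(self, f, _clean(getattr(self, f)))
        if self.phylum is None and self.order is None and self.family is None:
            raise ValidationError(
                f"taxon record for {self.genus!r} has no phylum, order or family"
            )


@dataclass(frozen=True)
class EcogroupRecord:
    """Eco-Plant humidity (EPH) and temperature (EPT) group for one genus.

    Group names are validated against the closed five-member EPH and
    four-member EPT sets and normalised to lowercase.
    """

    genus: str
    eph: str
    ept: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "genus", self.genus.strip())
        if not self.genus:
            raise ValidationError("genus name is empty")
        eph = self.eph.strip().lower()
        ept = self.ept.strip().lower()
        if eph not in EPH_GROUPS:
            raise ValidationError(
                f"unknown EPH group {self.eph!r} for genus {self.genus!r}; "
                f"expected one of {', '.join(EPH_GROUPS)}"
            )
        if ept not in EPT_GROUPS:
            raise ValidationError(
                f"unknown EPT group {self.ept!r} for genus {self.genus!r}; "
                f"expected one of {', '.join(EPT_GROUPS)}"
            )
        object.__setattr__(self, "eph", eph)
        object.__setattr__(self, "ept", ept)


class GenusMap(Mapping[str, object]):
    """Mapping genus -> record with case-insensitive, whitespace-trimmed keys.

    Original spellings are preserved for display; lookups accept any
    capitalisation.  Iteration follows insertion (file) order.
    """

    def __init__(self, records: Iterable[TaxonRecord | EcogroupRecord] = ()):
        self._by_key: dict[str, TaxonRecord | EcogroupRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: TaxonRecord | EcogroupRecord, *, row: int | None = None) -> None:
        key = canonical_genus(rec.genus)
        if key in self._by_key:
            raise DuplicateGenusError(f"duplicate genus {rec.genus!r}", row=row)
        self._by_key[key] = rec

    def __getitem__(self, genus: str):
        return self._by_key[canonical_genus(genus)]

    def __contains__(self, genus: object) -> bool:
        return isinstance(genus, str) and canonical_genus(genus) in self._by_key

    def __iter__(self) -> Iterator[str]:
        return (rec.genus for rec in self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)

    def get(self, genus: str, default=None):
        return self._by_key.get(canonical_genus(genus), default)

    def records(self):
        return list(self._by_key.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenusMap):
            return NotImplemented
        return self._by_key == other._by_key

    def __repr__(self) -> str:
        return f"GenusMap({len(self)} genera)"


@dataclass(frozen=True)
class ReferenceSet:
    """The pair of reference tables an analysis run consults.

    The two tables are independent excerpts: the ecogroup table need not cover
    every genus of the taxonomy table nor vice versa.
    """

    taxonomy: GenusMap
    ecogroup: GenusMap


def _read_table(source: Source) -> pd.DataFrame:
    """Read a reference/assemblage CSV as strings, tolerating a UTF-8 BOM."""
    try:
        return pd.read_csv(
            source, dtype=str, keep_default_na=False, encoding="utf-8-sig", sep=","
        )
    except pd.errors.EmptyDataError:
        raise InputFormatError("file is empty (no header row)") from None


def _header_map(df: pd.DataFrame) -> dict[str, str]:
    """Case-insensitive column lookup: canonical lowercase name -> real name."""
    out: dict[str, str] = {}
    for col in df.columns:
        out.setdefault(str(col).strip().casefold(), col)
    return out


def load_taxonomy(source: Source) -> GenusMap:
    """Load a taxonomy CSV (header Kingdom,Phylum,Class,Order,Family,Genus).

    Headers match in any letter-case; extra columns are ignored; empty rank
    cells are stored as absent.  Duplicate genera and rank-less records are
    load errors.
    """
    df = _read_table(source)
    cols = _header_map(df)
    if "genus" not in cols:
        raise InputFormatError("taxonomy file has no 'Genus' column")

    def cell(row, name: str) -> str | None:
        return str(row[cols[name]]) if name in cols else None

    table = GenusMap()
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            rec = TaxonRecord(
                genus=str(row[cols["genus"]]),
                kingdom=cell(row, "kingdom"),
                phylum=cell(row, "phylum"),
                class_=cell(row, "class"),
                order=cell(row, "order"),
                family=cell(row, "family"),
            )
            table.add(rec, row=i + 2)  # +2: header line + 1-based
        except DuplicateGenusError:
            raise
        except ValidationError as exc:
            raise ValidationError(str(exc), row=i + 2) from None
    return table


def load_ecogroup(source: Source) -> GenusMap:
    """Load an ecogroup CSV (header Genus,EPH,EPT, any letter-case).

    EPH/EPT values are matched case-insensitively against the closed group
    sets; anything outside them (e.g. "halophytes", which Mesozoic usage folds
    into xerophytes) is a validation error citing the row.
    """
    df = _read_table(source)
    cols = _header_map(df)
    for required in ("genus", "eph", "ept"):
        if required not in cols:
            raise InputFormatError(f"ecogroup file has no {required.upper()!r} column")

    table = GenusMap()
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            rec = EcogroupRecord(
                genus=str(row[cols["genus"]]),
                eph=str(row[cols["eph"]]),
                ept=str(row[cols["ept"]]),
            )
            table.add(rec, row=i + 2)
        except DuplicateGenusError:
            raise
        except ValidationError as exc:
            raise ValidationError(str(exc), row=i + 2) from None
    return table


def write_taxonomy(table: GenusMap, sink: Source | None = None) -> str:
    """Serialise a taxonomy table back to CSV; returns the CSV text."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["Kingdom", "Phylum", "Class", "Order", "Family", "Genus"])
    for rec in table.records():
        w.writerow(
            [
                rec.kingdom or "",
                rec.phylum or "",
                rec.class_ or "",
                rec.order or "",
                rec.family or "",
                rec.genus,
            ]
        )
    return _deliver(buf.getvalue(), sink)


def write_ecogroup(table: GenusMap, sink: Source | None = None) -> str:
    """Serialise an ecogroup table back to CSV; returns the CSV text."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["Genus", "EPH", "EPT"])
    for rec in table.records():
        w.writerow([rec.genus, rec.eph, rec.ept])
    return _deliver(buf.getvalue(), sink)


def _deliver(text: str, sink: Source | None) -> str:
    if sink is None:
        return text
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)
    return text


def lookup_category(genus: str, mode, refs: ReferenceSet) -> str:
    """Resolve one genus to its category under an analysis mode.

    Returns the rank value (PHYLUM/ORDER/FAMILY modes, via the taxonomy table)
    or ecogroup name (EPH/EPT modes, via the ecogroup table), or ``UNCERTAIN``
    when the genus is missing from the relevant table or the requested field is
    blank.  Absence is a value, never an error.
    """
    from .aggregate import AnalysisMode  # local import: avoid cycle

    mode = AnalysisMode(mode)
    if mode.uses_taxonomy:
        rec = refs.taxonomy.get(genus)
        value = getattr(rec, mode.rank_field) if rec is not None else None
    else:
        rec = refs.ecogroup.get(genus)
        value = getattr(rec, mode.rank_field) if rec is not None else None
    return value if value else UNCERTAIN


def merge_reference(base: ReferenceSet, overlay: ReferenceSet) -> ReferenceSet:
    """Overlay one reference set on another; overlay wins on shared genera.

    This is the update path for revised affinities: ship a small CSV with the
    corrected rows and merge it over the bundled tables.
    """

    def merged(a: GenusMap, b: GenusMap) -> GenusMap:
        out = GenusMap()
        keep = [rec for rec in a.records() if rec.genus not in b]
        for rec in keep + b.records():
            out.add(rec)
        return out

    return ReferenceSet(
        taxonomy=merged(base.taxonomy, overlay.taxonomy),
        ecogroup=merged(base.ecogroup, overlay.ecogroup),
    )


def list_unlinked(assemblage, mode, refs: ReferenceSet) -> list[str]:
    """Genera of an assemblage that resolve to Uncertain, first-appearance order.

    Too many unlinked genera dilute the Uncertain sink and make the percentage
    signal uninterpretable, so callers surface this list as a quality warning.
    """
    seen: set[str] = set()
    out: list[str] = []
    for obs in assemblage.observations:
        key = canonical_genus(obs.genus)
        if key in seen:
            continue
        seen.add(key)
        if lookup_category(obs.genus, mode, refs) == UNCERTAIN:
            out.append(obs.genus)
    return out
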