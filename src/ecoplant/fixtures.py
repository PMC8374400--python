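"""Bundled example tables and a synthetic-assemblage generator.

The bundled CSVs are the published excerpts of the curated reference datasets
(17 taxonomy rows, 16 ecogroup rows) together with the worked-example inputs:
a two-sample Triassic assemblage (samples HJG 01 and HJG 02) and an
eight-sample wide percentage matrix for draw-curve mode.  They are excerpts by
construction — the full curated dataset (859 genera reviewed, 484 linked) is
not redistributable here — and the loaders accept drop-in replacements of the
same schema.

`random_assemblage` emulates counted sporomorph data for property testing: per
sample, community proportions are drawn from a symmetric Dirichlet and grains
from a multinomial, with a configurable fraction of the abundance assigned to
invented genera absent from the reference (the "unlinked" share that ends up
in the Uncertain sink).  It makes no attempt to model taphonomy, pollen
productivity or transport bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib.resources import files
from typing import Sequence

import numpy as np

from .assemblage_io import (
    AbundanceMatrix,
    AssemblageTable,
    Observation,
    read_long_assemblage,
    read_wide_matrix,
)
from .reference import GenusMap, ReferenceSet, load_ecogroup, load_taxonomy

__all__ = [
    "example_table",
    "default_reference",
    "SyntheticSpec",
    "random_assemblage",
]

_DATA = files("ecoplant") / "data"

_LOADERS = {
    "taxonomy": ("taxonomy.csv", load_taxonomy),
    "ecogroup": ("ecogroup.csv", load_ecogroup),
    "assemblage": ("assemblage.csv", read_long_assemblage),
    "wide_matrix": ("wide_matrix.csv", read_wide_matrix),
}


def example_table(name: str):
    """Return a bundled example table, parsed through the public loaders.

    ``name`` is one of "taxonomy" (genus -> parent-plant ranks), "ecogroup"
    (genus -> EPH/EPT), "assemblage" (long-format input example) or
    "wide_matrix" (draw-curve input example).  Repeated calls re-read the same
    bundled bytes, so the result is stable across calls.
    """
    try:
        filename, loader = _LOADERS[name]
    except KeyError:
        raise ValueError(
            f"unknown example table {name!r}; expected one of {sorted(_LOADERS)}"
        ) from None
    with (_DATA / filename).open("r", encoding="utf-8") as fh:
        return loader(fh)


def fixture_path(name: str) -> str:
    """Filesystem path of a bundled example CSV (for CLI export and docs)."""
    filename = _LOADERS[name][0]
    return str(_DATA / filename)


def default_reference() -> ReferenceSet:
    """The bundled taxonomy + ecogroup excerpts as a ReferenceSet."""
    return ReferenceSet(
        taxonomy=example_table("taxonomy"), ecogroup=example_table("ecogroup")
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for one synthetic assemblage.

    total_per_sample: grain count per sample (multinomial total), or the
        string "percent" to emit Dirichlet proportions scaled to 100 instead
        of counts.
    unlinked_fraction: expected share of each sample's abundance assigned to
        invented genera that no reference table contains.
    """

    seed: int
    n_samples: int = 3
    genus_pool: tuple[str, ...] = ()
    total_per_sample: int | str = 300
    unlinked_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.unlinked_fraction <= 1.0:
            raise ValueError("unlinked_fraction must lie in [0, 1]")
        if isinstance(self.total_per_sample, str):
            if self.total_per_sample != "percent":
                raise ValueError("total_per_sample must be an int or 'percent'")
        elif self.total_per_sample < 1:
            raise ValueError("total_per_sample must be >= 1")
        object.__setattr__(self, "genus_pool", tuple(self.genus_pool))


#: Invented names used for the unlinked share; deliberately form-genus-like
#: but absent from every bundled table.
_UNLINKED_NAMES = ("Ignotisporites", "Dubiopollenites", "Incertaespora")


def random_assemblage(
    spec: SyntheticSpec, refs: ReferenceSet | None = None
) -> AssemblageTable:
    """Generate a reproducible synthetic assemblage.

    Genera come from ``spec.genus_pool`` (default: every genus of ``refs``'
    taxonomy table, so the linked share is fully linkable in every rank mode).
    Per sample, proportions are symmetric-Dirichlet within the linked and
    unlinked pools, scaled to (1 - unlinked_fraction) and unlinked_fraction
    respectively, then counts are multinomial.  The same spec always yields
    the identical table.
    """
    pool: Sequence[str] = spec.genus_pool
    if not pool:
        if refs is None:
            raise ValueError("genus_pool is empty and no reference set was given")
        pool = list(refs.taxonomy)
    if not pool:
        raise ValueError("genus pool is empty")

    f = spec.unlinked_fraction
    unlinked = list(_UNLINKED_NAMES) if f > 0 else []
    names = list(pool) + unlinked

    rng = np.random.default_rng(spec.seed)
    observations: list[Observation] = []
    for i in range(spec.n_samples):
        p_linked = rng.dirichlet(np.ones(len(pool))) * (1.0 - f)
        p = list(p_linked)
        if unlinked:
            p += list(rng.dirichlet(np.ones(len(unlinked))) * f)
        p = np.asarray(p)
        p = p / p.sum()

        sample = f"SYN {i + 1:02d}"
        depth = float(i + 1)
        if spec.total_per_sample == "percent":
            for genus, prop in zip(names, p):
                ab = Fraction(float(prop)).limit_denominator(10**9) * 100
                if ab > 0:
                    observations.append(Observation(sample, genus, ab, depth))
        else:
            counts = rng.multinomial(int(spec.total_per_sample), p)
            for genus, count in zip(names, counts):
                if count > 0:
                    observations.append(
                        Observation(sample, genus, Fraction(int(count)), depth)
                    )
        # A sample must carry some abundance; with total >= 1 the multinomial
        # guarantees it, and the percent branch always emits positive mass.
    return AssemblageTable(tuple(observations))
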