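"""Shared fixtures: bundled example tables and hand-frozen expected matrices."""

from fractions import Fraction

import pytest

import ecoplant as ep

# Expected order-mode percentage matrix for the bundled two-sample example,
# as conventionally printed (1 decimal, half away from zero).  Frozen from
# hand summation of the example assemblage joined to the taxonomy excerpt:
# e.g. Bennettitales HJG 01 = (30.9 + 2.9) / 100.0 * 100 = 33.8 and
# Corystospermales HJG 02 = 34 / 100.2 * 100 = 33.932... -> 33.9.
ORDER_EXPECTED = {
    "Bennettitales": (33.8, 8.9),
    "Corystospermales": (25.0, 33.9),
    "Cyatheales": (6.6, 4.7),
    "Equisetales": (0.0, 2.0),
    "Ginkgoales": (4.4, 7.5),
    "Gleicheniales": (13.2, 7.7),
    "Isoetales": (7.4, 2.4),
    "Lycopodiales": (0.0, 8.4),
    "Marattiales": (0.0, 11.3),
    "Notothyladales": (5.9, 0.7),
    "Osmundales": (0.7, 0.0),
    "Peltaspermales": (0.0, 1.3),
    "Pinales": (1.5, 9.8),
    "Uncertain": (1.5, 1.5),
}

# Hand summation of the example assemblage joined to the ecogroup excerpt;
# HJG 01 splits 7.4 / 16.1 / 42.6 / 1.5 with 30.9 + 1.5 = 32.4 Uncertain
# (Bharadwajipollenites and Quadraeculina are absent from the excerpt).
EPH_EXPECTED = {
    "hydrophytes": (7.4, 2.4),
    "hygrophytes": (16.1, 28.8),
    "mesophytes": (42.6, 49.8),
    "xerophytes": (1.5, 10.4),
    "Uncertain": (32.4, 8.6),
}

SAMPLES = ("HJG 01", "HJG 02")

# Per-sample input column totals of the example assemblage (hand-summed).
TOTALS = {"HJG 01": Fraction(100), "HJG 02": Fraction("100.2")}


@pytest.fixture(scope="session")
def refs() -> ep.ReferenceSet:
    return ep.default_reference()


@pytest.fixture(scope="session")
def assemblage() -> ep.AssemblageTable:
    return ep.example_table("assemblage")


@pytest.fixture(scope="session")
def order_matrix(assemblage, refs) -> ep.AbundanceMatrix:
    return ep.run_analysis(assemblage, "order", refs)


@pytest.fixture(scope="session")
def wide_matrix() -> ep.AbundanceMatrix:
    return ep.example_table("wide_matrix")
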