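"""Shared fixtures: small hand-built datasets exercising the count schema."""

from __future__ import annotations

import pytest

from drillcore import CoreDataset, Group, Increment, TaxonIncrementCount


def make_increment(increment_id, top, bottom, age=None, core_id="c1"):
    return Increment(
        core_id=core_id,
        increment_id=increment_id,
        top_depth_cm=top,
        bottom_depth_cm=bottom,
        age_estimate=age,
    )


def bivalve_row(increment_id, taxon="Varicorbula gibba", core_id="c1", **counts):
    return TaxonIncrementCount(
        core_id=core_id,
        increment_id=increment_id,
        taxon=taxon,
        group=Group.BIVALVE,
        **counts,
    )


def gastropod_row(
    increment_id,
    taxon="Tritia varicosa",
    core_id="c1",
    is_predator=False,
    **counts,
):
    return TaxonIncrementCount(
        core_id=core_id,
        increment_id=increment_id,
        taxon=taxon,
        group=Group.GASTROPOD,
        is_predator=is_predator,
        **counts,
    )


@pytest.fixture
def mixed_increment_dataset():
    """One increment: bivalves DV=3 RV=10 LV=10 A=5 plus 10 gastropod
    shells of which 2 drilled — assemblage DF 5/25 = 0.20."""
    increments = [make_increment("i0", 0.0, 2.0, age=2000.0)]
    counts = [
        bivalve_row("i0", n_articulated=5, n_left=10, n_right=10, n_drilled=3),
        gastropod_row("i0", n_whole=10, n_drilled=2),
    ]
    return CoreDataset(increments=increments, counts=counts)


@pytest.fixture
def two_increment_dataset():
    increments = [
        make_increment("i0", 0.0, 2.0, age=2005.0),
        make_increment("i1", 2.0, 4.0, age=1995.0),
    ]
    counts = [
        gastropod_row("i0", n_whole=30, n_drilled=6),
        gastropod_row("i1", n_whole=40, n_drilled=8),
        bivalve_row("i1", n_articulated=10, n_left=4, n_right=6, n_drilled=5),
    ]
    return CoreDataset(increments=increments, counts=counts)
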