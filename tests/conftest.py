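"""Shared fixtures: the default parameter table and one simulated study.

The session-scoped synthetic genome uses the generator defaults (three
100 kb chromosomes, GC 0.38, six planted flexibility tracts per chromosome
plus one telomeric and one rDNA tract) so that every co-localization and
statistics test runs against the same ground truth.
"""

from __future__ import annotations

import numpy as np
import pytest

from dnaflex import SynthSpec, default_step_table, run_pipeline, simulate_genome


@pytest.fixture(scope="session")
def table():
    return default_step_table()


@pytest.fixture(scope="session")
def sim():
    """(genomes, manifest) for the default synthetic study, seed 7."""
    return simulate_genome(SynthSpec(seed=7))


@pytest.fixture(scope="session")
def pipeline_result(sim):
    genomes, manifest = sim
    return run_pipeline(
        genomes,
        manifest.features,
        utrs=manifest.utr_records,
        sites=[s.site for s in manifest.sites],
        halflife=manifest.halflife_records,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
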