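import dataclasses

import numpy as np
import pytest

from forestsignal import (
    PollenRecord,
    Region,
    Sample,
    SiteMetadata,
    scenario_library,
    simulate_pollen_record,
    synthetic_pfg_map,
)


@pytest.fixture
def site_meta():
    return SiteMetadata(
        site_id="TEST01",
        site_name="Test Lake",
        region=Region.NEOTROPICS,
        zone="Los Llanos",
        latitude=5.0,
        longitude=-70.0,
        elevation=150.0,
        biome="tropical savanna",
        contact_year=1520.0,
    )


@pytest.fixture
def toy_record(site_meta):
    """Three samples, two taxa, 50 yr/cm deposition."""
    return PollenRecord(
        metadata=site_meta,
        samples=(
            Sample(depth=10.0, age=1900.0, counts={"Moraceae": 40, "Poaceae": 10}),
            Sample(depth=20.0, age=1400.0, counts={"Moraceae": 30, "Poaceae": 20}),
            Sample(depth=30.0, age=900.0, counts={"Moraceae": 20, "Poaceae": 30}),
        ),
    )


@pytest.fixture(scope="session")
def pfg_map():
    return synthetic_pfg_map()


@pytest.fixture(scope="session")
def library():
    return scenario_library()


def make_record(name: str, seed: int, **overrides) -> PollenRecord:
    spec = dataclasses.replace(scenario_library()[name], seed=seed, **overrides)
    return simulate_pollen_record(spec)


def random_record(rng: np.random.Generator, site_meta=None) -> PollenRecord:
    """Small random but valid pollen record for round-trip/property tests."""
    n = int(rng.integers(2, 8))
    depths = np.sort(rng.uniform(0, 100, n))
    while np.any(np.diff(depths) <= 0):  # pragma: no cover - vanishing chance
        depths = np.sort(rng.uniform(0, 100, n))
    ages = np.sort(rng.uniform(0, 1950, n))[::-1]
    taxa = [f"Taxon{i}" for i in range(int(rng.integers(1, 6)))]
    meta = site_meta or SiteMetadata(
        site_id="RND", site_name="Random", region=Region.NEOTROPICS, zone="z",
        latitude=0.0, longitude=0.0, elevation=0.0, biome="tropical",
        contact_year=1520.0,
    )
    samples = tuple(
        Sample(
            depth=float(d), age=float(a),
            counts={t: int(rng.integers(0, 200)) for t in taxa},
        )
        for d, a in zip(depths, ages)
    )
    return PollenRecord(metadata=meta, samples=samples)
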