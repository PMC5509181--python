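"""Shared fixtures: tiny handcrafted datasets on the Y23 panel."""

from typing import Dict, List, Sequence

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ystrkit import (
    PANEL_Y23,
    PopulationDataset,
    SampleRecord,
    make_haplotype,
)

#: a complete, clean default haplotype covering every Y23 locus
BASE_VALUES: Dict[str, object] = {
    "DYS576": 17, "DYS389I": 13, "DYS448": 19, "DYS389II": 17, "DYS19": 14,
    "DYS391": 10, "DYS481": 22, "DYS549": 12, "DYS533": 11, "DYS438": 10,
    "DYS437": 14, "DYS570": 17, "DYS635": 21, "DYS390": 24, "DYS439": 12,
    "DYS392": 13, "DYS643": 10, "DYS393": 12, "DYS458": 16, "DYS456": 15,
    "YGATAH4": 12, "DYS385": (13, 17),
}


def hap(**overrides):
    """Full Y23 haplotype from BASE_VALUES with per-locus overrides."""
    values = dict(BASE_VALUES)
    values.update(overrides)
    return make_haplotype(values)


def make_dataset(rows: Sequence[tuple]) -> PopulationDataset:
    """Dataset from ``(sample_id, population, overrides_dict)`` rows."""
    records: List[SampleRecord] = []
    for sample_id, population, overrides in rows:
        records.append(
            SampleRecord(
                sample_id=sample_id,
                population=population,
                haplotype=hap(**overrides),
            )
        )
    return PopulationDataset(records, PANEL_Y23)


@pytest.fixture
def toy_dataset() -> PopulationDataset:
    """Four clean samples in two populations, two shared haplotypes."""
    return make_dataset(
        [
            ("s1", "north", {}),
            ("s2", "north", {"DYS19": 15}),
            ("s3", "south", {}),
            ("s4", "south", {"DYS385": (13, 18)}),
        ]
    )
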