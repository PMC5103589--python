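"""Shared fixtures: small generated datasets, in memory and on disk."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from phenotab.synthetic_data import (
    basic_gwas,
    field_multiyear,
    generate,
    greenhouse_hts,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def schema_transcription() -> dict:
    """Frozen hand-transcription of the default Study-file schemas."""
    with (DATA_DIR / "study_schema_transcription.json").open() as fh:
        return json.load(fh)


@pytest.fixture()
def tiny_basic():
    """Basic profile at desk scale: 5 accessions x 2 reps, 4 variables."""
    return generate(basic_gwas(sources=5, reps=2, vars=4, seed=7))


@pytest.fixture()
def small_field():
    """Field profile at desk scale: 4 lines + 2 parents, 2 years."""
    return generate(field_multiyear(lines=4, parents=2, years=2,
                                    pheno_vars=3, env_vars=2, seed=11))


@pytest.fixture()
def small_greenhouse():
    return generate(greenhouse_hts(plants=8, pheno_vars=3, seed=5))


@pytest.fixture()
def field_dir(tmp_path):
    """A small field dataset written to disk."""
    out = tmp_path / "field_ds"
    generate(field_multiyear(lines=4, parents=2, years=2,
                             pheno_vars=3, env_vars=2, seed=11), out)
    return out
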