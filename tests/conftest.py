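from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from fireladder.graph_core import OntDagCollection, build_ontdag
from fireladder.rrf_io import SourceConfig, read_mrconso, read_mrrel
from fireladder.synth_fixtures import (
    FixtureSpec,
    GroundTruth,
    fig3_fixture,
    generate_fixture,
)

FIG3_SABS = ["HPO", "NCI", "SNOMEDCT_US"]


@dataclass
class LoadedFixture:
    conso: Path
    rel: Path
    ground_truth: GroundTruth
    config: SourceConfig
    atoms: list
    rels: list
    dags: OntDagCollection


def load_fixture_dir(conso, rel, gt, sabs, **config_kwargs) -> LoadedFixture:
    config = SourceConfig(included_sabs=list(sabs), **config_kwargs)
    atoms = read_mrconso(conso, config)
    rels = read_mrrel(rel, config)
    dags = build_ontdag(atoms, rels, config)
    return LoadedFixture(
        conso=conso, rel=rel, ground_truth=gt, config=config,
        atoms=atoms, rels=rels, dags=dags,
    )


@pytest.fixture(scope="session")
def fig3(tmp_path_factory) -> LoadedFixture:
    d = tmp_path_factory.mktemp("fig3")
    conso, rel, gt = fig3_fixture(d)
    return load_fixture_dir(conso, rel, gt, FIG3_SABS)


@pytest.fixture
def make_synth(tmp_path):
    """Factory: build and load a synthetic fixture for a FixtureSpec."""
    counter = {"n": 0}

    def _make(spec: FixtureSpec, **config_kwargs) -> LoadedFixture:
        counter["n"] += 1
        d = tmp_path / f"synth{counter['n']}"
        conso, rel, gt = generate_fixture(spec, d)
        return load_fixture_dir(conso, rel, gt, spec.sabs, **config_kwargs)

    return _make
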