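"""Shared fixtures: simulated datasets and pipeline runs reused across tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import settings

from spottcr import clonotype as ct
from spottcr import simulate as sim
from spottcr import spatial as sp

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@dataclass
class PipelineRun:
    """One simulated dataset pushed through call -> link -> dedup -> matrix."""

    config: sim.SimConfig
    reference: object
    primer_pool: object
    spot_map: object
    truth: sim.TruthSet
    r1: object
    r2: object
    clones: list
    read_to_clone: dict
    call_log: dict
    records: list
    link_log: object
    deduped: list
    matrix: object


def run_pipeline(config: sim.SimConfig, out_dir) -> PipelineRun:
    res = sim.simulate_dataset(config, out_dir)
    clones, read_to_clone, call_log = ct.call_clones(
        res["r2"], res["reference"], res["primer_pool"]
    )
    records, link_log = sp.link_files(
        res["r1"], res["r2"], read_to_clone, res["spot_map"]
    )
    deduped = sp.deduplicate(records)
    matrix = sp.build_matrix(deduped, res["spot_map"])
    return PipelineRun(
        config=config,
        reference=res["reference"],
        primer_pool=res["primer_pool"],
        spot_map=res["spot_map"],
        truth=res["truth"],
        r1=res["r1"],
        r2=res["r2"],
        clones=clones,
        read_to_clone=read_to_clone,
        call_log=call_log,
        records=records,
        link_log=link_log,
        deduped=deduped,
        matrix=matrix,
    )


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> PipelineRun:
    """The standard study conditions: 50 spots (80% in tissue), 20 clones,
    2,000 molecules, PCR duplication mean 3, no sequencing error."""
    config = sim.SimConfig(seed=7)
    return run_pipeline(config, tmp_path_factory.mktemp("default_run"))


@pytest.fixture(scope="session")
def noisy_dataset(tmp_path_factory):
    """~10,000 read pairs at per-base substitution error 0.001 (fixed seed)."""
    config = sim.SimConfig(
        seed=11, seq_error_rate=0.001, umis_per_clone_spot=34,
        pcr_duplication_mean=3.0,
    )
    return sim.simulate_dataset(config, tmp_path_factory.mktemp("noisy")), config


@pytest.fixture(scope="session")
def tiny_reference():
    return sim.make_reference(3, 2, seed=5)


@pytest.fixture(scope="session")
def tiny_pool(tiny_reference):
    return sim.make_primer_pool(tiny_reference, seed=5)
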