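"""Shared fixtures: one small synthetic assembly pair and one pipeline run.

Everything is generated programmatically at test time; session scope keeps
the simulation cost paid once.
"""

import json
import os

import pytest

from asmeval import pipeline as pl
from asmeval import simulate as sim

SMALL_SIM = dict(
    n_chromosomes=2,
    chromosome_length=300_000,
    segdup_count=2,
    segdup_length=8_000,
    satellite_copy_count=50,
    depth=8.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    return sim.SimConfig(**SMALL_SIM)


@pytest.fixture(scope="session")
def small_donor(small_config) -> sim.Donor:
    return sim.build_donor(small_config)


@pytest.fixture(scope="session")
def small_pair(small_donor) -> sim.AssemblyPair:
    suite = sim.standard_event_suite(
        small_donor, dup_length=4_000, attractor_length=1_500, alt_length=4_000
    )
    return sim.derive_assembly_pair(small_donor, suite.events, suite.scaffolds)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A complete pipeline run over the small fixture: workdir + summary +
    truth manifest."""
    workdir = str(tmp_path_factory.mktemp("bundle"))
    cfg = pl.PipelineConfig(
        seed=11,
        outdir=workdir,
        simulate=dict(
            {k: v for k, v in SMALL_SIM.items() if k != "seed"},
            novel_length=5_000,
            n_candidate_sites=24,
        ),
    )
    summary = pl.run(cfg)
    manifest = json.load(
        open(os.path.join(workdir, "sim", "truth_manifest.json"))
    )
    return {"workdir": workdir, "summary": summary, "manifest": manifest}
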