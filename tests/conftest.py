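"""Shared fixtures.

The full-scale study run (2.6 Mb reference, 20x case and control cohorts)
takes under a minute and is shared session-wide; unit tests use small
purpose-built inputs instead.
"""

from __future__ import annotations

import pytest

from svdissect.pipeline import RunConfig, run_all

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Summary and in-memory objects of one full default-parameter run."""
    outdir = tmp_path_factory.mktemp("study_run")
    summary, objects = run_all(
        RunConfig(seed=STUDY_SEED, write_reads=False), outdir, keep_objects=True
    )
    objects["summary"] = summary
    objects["outdir"] = outdir
    return objects


@pytest.fixture(scope="session")
def ref(study):
    return study["ref"]


@pytest.fixture(scope="session")
def plan(study):
    return study["plan"]


@pytest.fixture(scope="session")
def truth(study):
    return study["truth"]
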