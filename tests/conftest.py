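"""Shared fixtures: synthetic studies at tiny and full scale.

Everything is generated programmatically with fixed seeds; the full-scale
study is session-scoped because several recovery suites share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from dmrscape.calling import CallerConfig
from dmrscape.model import DifferentialMethylation
from dmrscape.setlogic import ComparisonResult
from dmrscape.simulate import (
    default_study_config,
    generate_truth,
    simulate_study,
)

TINY_SEED = 7
STUDY_SEED = 11


@pytest.fixture(scope="session")
def tiny_truth():
    return generate_truth(default_study_config(seed=TINY_SEED, scale="tiny"))


@pytest.fixture(scope="session")
def tiny_study(tiny_truth):
    return simulate_study(tiny_truth)


@pytest.fixture(scope="session")
def study_truth():
    return generate_truth(default_study_config(seed=STUDY_SEED, scale="default"))


@pytest.fixture(scope="session")
def study_samples(study_truth):
    return simulate_study(study_truth)


@pytest.fixture(scope="session")
def study_results(study_truth, study_samples):
    """Fitted tumor-vs-control comparisons for every tumor genotype."""
    out = {}
    for genotype in ("wt", "ko", "ci"):
        res = DifferentialMethylation.from_samples(
            study_samples["control"], study_samples[genotype], CallerConfig()
        ).fit()
        out[genotype] = ComparisonResult(f"{genotype}_vs_control", res.dmrs, res.dmcs)
    return out


def overlaps_truth(region_interval, dmr) -> bool:
    return (
        dmr.chrom == region_interval.chrom
        and dmr.interval.start < region_interval.end
        and dmr.interval.end > region_interval.start
    )
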