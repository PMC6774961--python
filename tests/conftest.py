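from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from hetspec.pipeline import analyze_sites
from hetspec.simulate import (
    discordant_config,
    recovery_config,
    simulate,
    smoke_config,
    write_fixture_bundle,
)

SMOKE_SEED = 11
RECOVERY_SEED = 7
DISCORDANT_SEED = 13


@pytest.fixture(scope="session")
def smoke_dataset():
    """In-memory smoke-scale synthetic dataset (≈400 focal variants)."""
    return simulate(smoke_config(SMOKE_SEED))


@pytest.fixture(scope="session")
def smoke_bundle(tmp_path_factory):
    """On-disk smoke fixture bundle (FASTA + VCF + panel + truth)."""
    outdir = tmp_path_factory.mktemp("smoke_bundle")
    paths = write_fixture_bundle(smoke_config(SMOKE_SEED), outdir, overwrite=True)
    return paths


@pytest.fixture(scope="session")
def smoke_analysis(smoke_dataset):
    return analyze_sites(
        smoke_dataset.sites, smoke_dataset.panel, smoke_dataset.reference
    )


@pytest.fixture(scope="session")
def recovery_run():
    """Full-scale parameter-recovery run: 10^6 focal variants with known
    per-class slopes, analysed with copies pooled. Shared across tests
    because it is the expensive fixture."""
    config = recovery_config(RECOVERY_SEED)
    dataset = simulate(config)
    result = analyze_sites(
        dataset.sites, dataset.panel, dataset.reference, copy_numbers=[None]
    )
    return config, dataset, result


@pytest.fixture(scope="session")
def discordant_run():
    """Smaller run with one region's slope vector replaced by independent
    noise — the concordance negative control."""
    config = discordant_config(DISCORDANT_SEED)
    dataset = simulate(config)
    result = analyze_sites(
        dataset.sites, dataset.panel, dataset.reference, copy_numbers=[None]
    )
    return config, dataset, result


def recovered_vs_true_slopes(config, result) -> pd.DataFrame:
    """Per-class estimated slope (mean across regions, copies pooled)
    joined against the generating slope vector."""
    from hetspec.classes import enumerate_classes

    frame = result.results.frame
    ok = frame[(frame["status"] == "ok") & (frame["copy_number"] == -1)]
    est = ok.groupby("class")["slope"].mean()
    truth = pd.Series(
        np.asarray(config.class_het_slopes),
        index=[c.label for c in enumerate_classes()],
        name="true",
    )
    return pd.concat([est.rename("est"), truth], axis=1).dropna()
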