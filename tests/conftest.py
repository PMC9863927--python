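"""Shared fixtures: a small, fast synthetic data set used across the suite."""

from __future__ import annotations

from types import SimpleNamespace

import pytest
from hypothesis import settings

from nucleograv import (
    SimulationConfig,
    generate_deg_series,
    generate_scaffold_and_models,
    map_genes_to_beads,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def small_config(**overrides) -> SimulationConfig:
    """A five-chromosome, ~1200-gene configuration that generates in seconds."""
    base = dict(
        seed=7,
        chrom_lengths_mb={"chr1": 100, "chr2": 80, "chr3": 60, "chr4": 50, "chr17": 30},
        n_beads=300,
        genes_per_bead_mean=4.0,
        n_models=20,
        comparisons=("t1", "t2", "t3"),
        deg_counts=((60, 50), (90, 80), (70, 60)),
        discordant_counts=(0, 4, 6),
        skew_chromosomes=("chr17",),
        skew_odds=4.0,
        n_persistent_up=10,
        n_persistent_down=5,
        persistence_rho=0.6,
        samples_per_group=4,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim():
    """One small simulation shared by read-only tests."""
    cfg = small_config()
    annotation, ensemble = generate_scaffold_and_models(cfg)
    assignment = map_genes_to_beads(annotation, ensemble)
    series = generate_deg_series(cfg, annotation, ensemble, assignment)
    return SimpleNamespace(
        config=cfg,
        annotation=annotation,
        ensemble=ensemble,
        assignment=assignment,
        tables=series.tables,
        truth=series.truth,
    )
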