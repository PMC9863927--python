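"""Bead-model I/O, gene->bead mapping, and radial distribution statistics."""

from __future__ import annotations

import numpy as np
import pytest

from nucleograv.deg_io import GeneAnnotation
from nucleograv.nucleus_models import (
    Bead,
    NucleusModel,
    NucleusModelEnsemble,
    actual_radial_stats,
    expected_radial_profile,
    map_genes_to_beads,
    radial_deviation,
    read_bead_models,
    write_bead_models,
    write_cmm_models,
)
from nucleograv.synthetic import generate_scaffold_and_models

from conftest import small_config


def tiny_ensemble(coords_per_model, beads=None, radius=5.0):
    beads = beads or [
        Bead("chr1", 0, 1000, False, 0),
        Bead("chr1", 1000, 2000, True, 1),
        Bead("chr2", 0, 1500, False, 2),
        Bead("chr2", 1500, 4000, False, 3),
    ]
    models = [
        NucleusModel(model_id=i, nuclear_radius=radius, coordinates=np.array(c, dtype=float))
        for i, c in enumerate(coords_per_model)
    ]
    return NucleusModelEnsemble(scaffold=beads, models=models)


class TestBeadModelIO:
    def test_tsv_round_trip(self, tmp_path):
        ens = tiny_ensemble(
            [
                [(1, 0, 0), (0, 2, 0), (0, 0, 3), (1, 1, 1)],
                [(0.5, 0.5, 0), (2, 0, 0), (0, 3, 0), (1, 0, 1)],
            ]
        )
        p = tmp_path / "beads.tsv"
        write_bead_models(ens, p)
        back = read_bead_models(p, format="tsv")
        assert back.n_models == 2 and back.n_beads == 4
        assert back.scaffold == ens.scaffold
        np.testing.assert_allclose(back.coordinates(), ens.coordinates())

    def test_cmm_round_trip_exact(self, tmp_path):
        cfg = small_config(n_models=3, n_beads=40)
        _, ens = generate_scaffold_and_models(cfg)
        write_cmm_models(ens, tmp_path / "cmm")
        back = read_bead_models(tmp_path / "cmm", format="cmm")
        assert back.scaffold == ens.scaffold
        np.testing.assert_allclose(back.coordinates(), ens.coordinates(), atol=1e-9)

    def test_cmm_without_unit_declaration_is_rescaled(self, tmp_path):
        ens = tiny_ensemble([[(10, 0, 0), (0, 20, 0), (0, 0, 30), (10, 10, 10)]])
        d = tmp_path / "cmm"
        write_cmm_models(ens, d)
        # strip the unit declaration to emulate arbitrary-unit output
        for f in d.glob("*.cmm"):
            f.write_text(f.read_text().replace(' units="um"', ""))
        back = read_bead_models(d, format="cmm", nuclear_radius=5.0)
        assert np.isclose(back.radii().max(), 5.0)

    def test_invalid_span_is_a_parse_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "model_id\tchrom\tstart\tend\tx_um\ty_um\tz_um\tis_lad\n"
            "0\tchr1\t100\t100\t1\t1\t1\t0\n"
        )
        with pytest.raises(ValueError, match=":2"):
            read_bead_models(p, format="tsv")

    def test_inconsistent_scaffolds_rejected(self, tmp_path):
        p = tmp_path / "mismatch.tsv"
        p.write_text(
            "model_id\tchrom\tstart\tend\tx_um\ty_um\tz_um\tis_lad\n"
            "0\tchr1\t0\t100\t1\t0\t0\t0\n"
            "1\tchr1\t0\t200\t1\t0\t0\t0\n"
        )
        with pytest.raises(ValueError, match="scaffold"):
            read_bead_models(p, format="tsv")

    def test_bead_outside_nucleus_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            tiny_ensemble([[(9, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)]]).validate()


class TestGeneBeadMapping:
    def test_midpoint_containment_and_boundary(self):
        ens = tiny_ensemble([[(1, 0, 0), (0, 2, 0), (0, 0, 3), (1, 1, 1)]])
        genes = [
            GeneAnnotation("inside", "chr1", 100, 200),       # mid 150 -> bead 0
            GeneAnnotation("boundary", "chr1", 500, 1500),    # mid 1000 -> bead 1 (half-open)
            GeneAnnotation("other", "chr2", 2000, 3000),      # mid 2500 -> bead 3
            GeneAnnotation("nochrom", "chr9", 0, 100),
            GeneAnnotation("gap", "chr2", 3900, 4300),        # mid 4100 beyond last bead
        ]
        asg = map_genes_to_beads(genes, ens)
        assert asg.mapping == {"inside": 0, "boundary": 1, "other": 3}
        assert set(asg.unmapped) == {"nochrom", "gap"}

    def test_matches_brute_force_interval_scan(self):
        cfg = small_config(n_models=1)
        annotation, ens = generate_scaffold_and_models(cfg)
        rng = np.random.default_rng(11)
        # 1000 random genes, some deliberately off-scaffold
        genes = []
        for i in range(1000):
            chrom = rng.choice(["chr1", "chr2", "chr3", "chr4", "chr17", "chrZ"])
            length_bp = cfg.chrom_lengths_mb.get(chrom, 10) * 1_000_000
            start = int(rng.integers(0, int(length_bp * 1.05)))
            genes.append(GeneAnnotation(f"R{i}", chrom, start, start + 1000))
        asg = map_genes_to_beads(genes, ens)
        for g in genes:
            mid = g.midpoint
            hit = [
                b.index for b in ens.scaffold
                if b.chrom == g.chrom and b.start <= mid < b.end
            ]
            if hit:
                assert asg.mapping[g.gene_id] == hit[0]
            else:
                assert g.gene_id in asg.unmapped

    def test_duplicate_gene_rejected(self):
        ens = tiny_ensemble([[(1, 0, 0), (0, 2, 0), (0, 0, 3), (1, 1, 1)]])
        genes = [GeneAnnotation("A", "chr1", 0, 10), GeneAnnotation("A", "chr1", 20, 40)]
        with pytest.raises(ValueError, match="duplicate"):
            map_genes_to_beads(genes, ens)


class TestRadialStatistics:
    def test_degenerate_geometry_all_beads_at_same_radius(self):
        coords = [[(2, 0, 0), (0, 2, 0), (0, 0, 2), (-2, 0, 0)]] * 3
        ens = tiny_ensemble(coords)
        genes = [
            GeneAnnotation("A", "chr1", 0, 100),
            GeneAnnotation("B", "chr1", 1200, 1400),
            GeneAnnotation("C", "chr2", 0, 100),
        ]
        asg = map_genes_to_beads(genes, ens)
        for n in (1, 2, 50):
            exp = expected_radial_profile(asg, ens, n)
            assert exp.mean == pytest.approx(2.0)

    def test_single_model_mean_is_arithmetic_mean(self):
        ens = tiny_ensemble([[(1, 0, 0), (0, 2, 0), (0, 0, 3), (4, 0, 0)]])
        genes = [
            GeneAnnotation("A", "chr1", 0, 100),
            GeneAnnotation("B", "chr1", 1100, 1300),
            GeneAnnotation("C", "chr2", 0, 100),
        ]
        asg = map_genes_to_beads(genes, ens)
        stats = actual_radial_stats({"A", "B", "C"}, asg, ens)
        assert stats.mean == pytest.approx(2.0)  # (1 + 2 + 3) / 3

    def test_exhaustive_set_equals_expectation(self, sim):
        mapped = set(sim.assignment.mapped_genes)
        actual = actual_radial_stats(mapped, sim.assignment, sim.ensemble)
        expected = expected_radial_profile(sim.assignment, sim.ensemble, len(mapped))
        assert actual.mean == pytest.approx(expected.mean, abs=1e-12)
        np.testing.assert_allclose(actual.cdf, expected.cdf, atol=1e-9)

    def test_expectation_direction_independent(self, sim):
        # same universe -> identical expectation for up and down
        up = expected_radial_profile(sim.assignment, sim.ensemble, 60)
        down = expected_radial_profile(sim.assignment, sim.ensemble, 60)
        assert abs(up.mean - down.mean) < 1e-12

    def test_expectation_matches_monte_carlo_subset_means(self, sim):
        """Random DEG drawing: average subset mean converges to the expectation."""
        exp = expected_radial_profile(sim.assignment, sim.ensemble, 50)
        genes = np.array(sim.assignment.mapped_genes)
        rng = np.random.default_rng(5)
        r_bar = {
            g: sim.ensemble.radii()[:, b].mean() for g, b in sim.assignment.mapping.items()
        }
        means = [
            np.mean([r_bar[g] for g in rng.choice(genes, size=50, replace=False)])
            for _ in range(2000)
        ]
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - exp.mean) < 3 * se

    def test_cdfs_monotone_and_end_at_n_genes(self, sim):
        exp = expected_radial_profile(sim.assignment, sim.ensemble, 37)
        assert (np.diff(exp.cdf) >= -1e-12).all()
        assert exp.cdf[-1] == pytest.approx(37)
        some = set(sim.assignment.mapped_genes[:25])
        act = actual_radial_stats(some, sim.assignment, sim.ensemble)
        assert (np.diff(act.cdf) >= -1e-12).all()
        assert act.cdf[-1] == pytest.approx(act.n_genes)

    def test_model_order_invariance(self, sim):
        ens = sim.ensemble
        shuffled = NucleusModelEnsemble(
            scaffold=ens.scaffold, models=list(reversed(ens.models))
        )
        genes = set(sim.assignment.mapped_genes[:40])
        a = actual_radial_stats(genes, sim.assignment, ens)
        b = actual_radial_stats(genes, sim.assignment, shuffled)
        assert a.mean == pytest.approx(b.mean, abs=1e-12)
        np.testing.assert_allclose(sorted(a.per_model_means), sorted(b.per_model_means))

    def test_empty_deg_set_flagged_not_zero(self, sim):
        stats = actual_radial_stats({"not_a_gene"}, sim.assignment, sim.ensemble)
        assert not stats.defined
        assert np.isnan(stats.mean)
        assert stats.n_dropped == 1

    def test_lad_beads_sit_more_peripherally(self):
        """Outward LAD bias: LAD beads' mean radius exceeds non-LAD across seeds."""
        from scipy import stats as sps

        diffs = []
        for seed in (0, 1, 2):
            cfg = small_config(seed=seed, n_models=10)
            _, ens = generate_scaffold_and_models(cfg)
            lad = np.array([b.is_lad for b in ens.scaffold])
            r = ens.radii().mean(axis=0)
            t, p = sps.ttest_ind(r[lad], r[~lad], alternative="greater")
            diffs.append(p)
        assert all(p < 0.01 for p in diffs)


class TestRadialDeviation:
    def test_identity_and_errors(self):
        assert radial_deviation(2.19, 2.19) == 0.0
        with pytest.raises(ValueError):
            radial_deviation(float("nan"), 1.0)

    def test_center_and_periphery_shifts(self):
        assert radial_deviation(1.81, 2.19) == pytest.approx(-0.38)
        assert radial_deviation(2.59, 2.19) == pytest.approx(0.40)
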