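"""Coherence, transition flows, persistent DEGs, and splice discordance."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nucleograv.deg_io import DEGStatusMap, DEResultTable, classify_degs
from nucleograv.timecourse import (
    coherence,
    coherence_matrix,
    persistent_degs,
    persistent_fc_tests,
    splice_discordance,
    transition_flows,
)


def table_from_status(status: dict[str, str], comparison: str, track="regular"):
    """Build a DE table whose classification reproduces ``status``."""
    rows = []
    for g, s in status.items():
        if s == "up":
            rows.append((g, 1.0, 0.01))
        elif s == "down":
            rows.append((g, -1.0, 0.01))
        else:
            rows.append((g, 0.1, 0.5))
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])
    return DEResultTable(comparison=comparison, track=track, data=df)


class TestCoherence:
    def test_self_coherence(self):
        a = {f"g{i}" for i in range(100)}
        res = coherence(a, set(a), universe_size=10_000)
        assert res.actual_ratio == 1.0
        assert res.expected_ratio == pytest.approx(0.01)
        assert res.coherence == pytest.approx(100.0)
        assert res.percent == pytest.approx(100.0)

    def test_disjoint_sets_give_zero(self):
        a = {f"a{i}" for i in range(50)}
        b = {f"b{i}" for i in range(80)}
        assert coherence(a, b, 1000).coherence == 0.0

    def test_empty_smaller_set_is_undefined(self):
        res = coherence(set(), {"g1", "g2"}, 100)
        assert not res.defined
        assert math.isnan(res.coherence)

    @given(
        seed=st.integers(0, 1000),
        na=st.integers(1, 60),
        nb=st.integers(1, 60),
    )
    def test_symmetric_under_argument_swap(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(200)]
        a = set(rng.choice(pool, size=na, replace=False))
        b = set(rng.choice(pool, size=nb, replace=False))
        r1 = coherence(a, b, 200)
        r2 = coherence(b, a, 200)
        assert r1.overlap == r2.overlap
        if r1.defined and r2.defined:
            assert r1.coherence == pytest.approx(r2.coherence)

    def test_null_mean_one_and_variance_shrinks(self):
        """Independent random sets: mean coherence ~ 1; larger sets, less noise."""
        rng = np.random.default_rng(3)

        def sample(set_size, universe, reps=150):
            vals = []
            for _ in range(reps):
                a = set(rng.choice(universe, set_size, replace=False))
                b = set(rng.choice(universe, set_size, replace=False))
                vals.append(coherence(a, b, universe).coherence)
            return np.array(vals)

        small = sample(50, 5000)
        large = sample(500, 5000)
        se = small.std(ddof=1) / np.sqrt(len(small))
        assert abs(small.mean() - 1.0) < 3 * se
        assert large.std(ddof=1) < small.std(ddof=1)


class TestCoherenceMatrix:
    def test_reference_identical_series(self):
        status = {f"g{i}": "up" if i < 20 else ("down" if i < 35 else "ns") for i in range(200)}
        tables = [table_from_status(status, c) for c in ("a", "b", "c")]
        df = coherence_matrix(tables, references=["a"])
        up = df[(df.direction == "up")]
        # identical sets: coherence = universe / |set|
        assert np.allclose(up["coherence"], 200 / 20)

    def test_sign_flipped_copy_has_zero_coherence(self):
        status = {f"g{i}": "up" if i < 30 else ("down" if i < 60 else "ns") for i in range(300)}
        flipped = {g: {"up": "down", "down": "up", "ns": "ns"}[s] for g, s in status.items()}
        tables = [table_from_status(status, "ref"), table_from_status(flipped, "inv")]
        df = coherence_matrix(tables, references=["ref"])
        assert (df["coherence"] == 0).all()

    def test_cross_direction_detects_inversion(self):
        status = {f"g{i}": "up" if i < 30 else ("down" if i < 60 else "ns") for i in range(300)}
        flipped = {g: {"up": "down", "down": "up", "ns": "ns"}[s] for g, s in status.items()}
        tables = [table_from_status(status, "ref"), table_from_status(flipped, "inv")]
        df = coherence_matrix(tables, references=["ref"], cross_direction=True)
        inv = df[df.direction == "up_vs_down"]
        assert (inv["coherence"] > 1).all()

    def test_missing_reference_errors(self):
        tables = [table_from_status({"g1": "up"}, "a")]
        with pytest.raises(ValueError, match="reference"):
            coherence_matrix(tables, references=["zzz"])

    def test_planted_persistence_decays_with_distance(self, sim):
        """With persistence probability < 1, coherence to the first comparison
        decreases (weakly, on average) with temporal distance."""
        df = coherence_matrix(sim.tables["regular"], references=[sim.config.comparisons[0]])
        up = df[df.direction == "up"].set_index("comparison")["coherence"]
        assert up[sim.config.comparisons[1]] > 1.0  # coherent with reference
        assert up[sim.config.comparisons[1]] >= up[sim.config.comparisons[2]]


class TestTransitionFlows:
    def test_identical_maps_are_diagonal(self):
        status = {f"g{i}": s for i, s in enumerate(["up"] * 5 + ["down"] * 3 + ["ns"] * 7)}
        maps = [DEGStatusMap("a", "regular", dict(status)), DEGStatusMap("b", "regular", dict(status))]
        flow = transition_flows(maps)[0]
        assert flow.counts.loc["up", "up"] == 5
        assert flow.counts.loc["down", "down"] == 3
        assert flow.counts.loc["ns", "ns"] == 7
        off = flow.counts.to_numpy().sum() - np.trace(flow.counts.to_numpy())
        assert off == 0

    def test_total_inversion_fills_single_cell(self):
        a = DEGStatusMap("a", "regular", {f"g{i}": "up" for i in range(10)})
        b = DEGStatusMap("b", "regular", {f"g{i}": "down" for i in range(10)})
        flow = transition_flows([a, b])[0]
        assert flow.counts.loc["up", "down"] == 10
        assert flow.total == 10

    def test_matches_brute_force_tally_and_conserves(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(400)]
        maps = [
            DEGStatusMap(
                f"c{k}", "regular",
                {g: ["up", "down", "ns"][rng.integers(3)] for g in genes},
            )
            for k in range(3)
        ]
        flows = transition_flows(maps)
        for (a, b), flow in zip(itertools.pairwise(maps), flows):
            brute = {(s, t): 0 for s in ("up", "down", "ns") for t in ("up", "down", "ns")}
            for g in genes:
                brute[(a.status[g], b.status[g])] += 1
            for (s, t), n in brute.items():
                assert flow.counts.loc[s, t] == n
            # conservation: row sums equal source state sizes
            for s in ("up", "down", "ns"):
                assert flow.counts.loc[s].sum() == len(a.genes(s))
            assert flow.total == len(genes)

    def test_universe_mismatch_restricts_to_intersection(self):
        a = DEGStatusMap("a", "regular", {"g1": "up", "g2": "down"})
        b = DEGStatusMap("b", "regular", {"g2": "ns", "g3": "up"})
        flow = transition_flows([a, b])[0]
        assert flow.total == 1
        assert flow.counts.loc["down", "ns"] == 1


class TestPersistentDegs:
    def _series(self, spec: dict[str, list[tuple[float, float]]], comparisons):
        tables = []
        for k, comp in enumerate(comparisons):
            rows = [(g, vals[k][0], vals[k][1]) for g, vals in spec.items()]
            df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])
            tables.append(DEResultTable(comparison=comp, track="regular", data=df))
        return tables

    def test_selection_rules(self):
        comps = ("a", "b", "c")
        spec = {
            "always_up": [(1.0, 0.01), (2.0, 0.02), (0.5, 0.001)],
            "sign_flip": [(1.0, 0.01), (-1.0, 0.01), (1.0, 0.01)],
            "loses_significance": [(1.0, 0.01), (1.0, 0.2), (1.0, 0.01)],
            "always_down": [(-0.5, 0.04), (-2.0, 0.001), (-0.1, 0.049)],
        }
        pers = persistent_degs(self._series(spec, comps))
        assert pers.always_up == ["always_up"]
        assert pers.always_down == ["always_down"]
        assert list(pers.fc_matrix.index) == ["always_up", "always_down"]
        assert list(pers.fc_matrix.columns) == list(comps)

    def test_members_subset_of_every_comparisons_degs(self, sim):
        pers = persistent_degs(sim.tables["regular"])
        for t in sim.tables["regular"]:
            st_map = classify_degs(t)
            assert set(pers.always_up) <= st_map.up
            assert set(pers.always_down) <= st_map.down

    def test_planted_persistent_recovered_exactly(self, sim):
        pers = persistent_degs(sim.tables["regular"])
        assert pers.always_up == sim.truth.persistent_up
        assert pers.always_down == sim.truth.persistent_down


class TestPersistentFcTests:
    def test_reference_vs_itself_copy(self):
        rng = np.random.default_rng(0)
        fc = pd.DataFrame(
            {"ref": rng.normal(1, 0.2, 30), "same": 0.0, "shift": 0.0}
        )
        fc["same"] = fc["ref"]
        fc["shift"] = fc["ref"] + 1.0
        out = persistent_fc_tests(fc, reference="ref").set_index("comparison")
        assert out.loc["same", "t"] == 0.0
        assert out.loc["same", "padj"] == pytest.approx(1.0)
        assert out.loc["same", "stars"] == "ns"
        # constant +1 shift across 30 genes: overwhelmingly significant
        assert out.loc["shift", "padj"] < 0.01
        assert out.loc["shift", "stars"] == "**"

    def test_too_few_genes_flagged(self):
        fc = pd.DataFrame({"ref": [1.0], "b": [2.0]})
        out = persistent_fc_tests(fc, reference="ref")
        assert not out["defined"].any()


class TestSpliceDiscordance:
    def test_planted_discordance_recovered_exactly(self, sim):
        for i, comp in enumerate(sim.config.comparisons):
            d = splice_discordance(
                sim.tables["spliced"][i],
                sim.tables["unspliced"][i],
                sim.tables["regular"][i],
            )
            assert d.discordant == sim.truth.discordant[comp]
            assert set(d.regular_subset) <= set(d.discordant)

    def test_same_direction_gene_excluded_and_empty_fraction_nan(self):
        status_s = {"g1": "up", "g2": "ns"}
        status_u = {"g1": "up", "g2": "ns"}
        status_r = {"g1": "up", "g2": "ns"}
        d = splice_discordance(
            table_from_status(status_s, "c", "spliced"),
            table_from_status(status_u, "c", "unspliced"),
            table_from_status(status_r, "c", "regular"),
        )
        assert d.discordant == []
        assert math.isnan(d.fraction_regular)
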