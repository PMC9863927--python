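"""End-to-end orchestration: run every statistic and emit summary reports.

``run_all`` executes the stages — classify DEGs per comparison and track,
radial profiles over the bead-model ensemble, coherence against the
reference comparisons, transition flows, persistent DEGs with fold-change
tests, splice discordance, per-chromosome distribution — and writes a tidy
summary TSV (one row per comparison x track) with a JSON mirror, plus
per-comparison chromosome tables and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .chrom_enrichment import chromosome_distribution
from .deg_io import DEResultTable, GeneAnnotation, classify_degs
from .nucleus_models import NucleusModelEnsemble, map_genes_to_beads, radial_profile
from .timecourse import (
    coherence,
    persistent_degs,
    persistent_fc_tests,
    splice_discordance,
    transition_flows,
)

__all__ = ["RunManifest", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int | None
    package_version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    status: str = "running"

    def record(self, stage: str, seconds: float, records: int) -> None:
        self.stages.append(
            {"stage": stage, "seconds": round(seconds, 3), "records": records}
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    tables: dict[str, list[DEResultTable]],
    annotation: list[GeneAnnotation],
    ensemble: NucleusModelEnsemble | None,
    outdir: str | Path,
    references: tuple[str, ...] = ("hypg20s", "hypg60"),
    alpha: float = 0.05,
    seed: int | None = None,
    input_paths: dict[str, Path] | None = None,
    config_repr: str = "",
) -> pd.DataFrame:
    """Run every downstream statistic and write the report bundle.

    ``tables`` maps track name -> ordered DE tables (one per comparison);
    the regular track drives flows, persistence and chromosome reports.
    Returns the summary frame (one row per comparison x track). Blank
    (undefined) cells stay NaN — an empty DEG set never reports 0.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_repr.encode()).hexdigest(),
        seed=seed,
        package_version=__version__,
    )
    for name, p in (input_paths or {}).items():
        manifest.input_digests[name] = _digest(Path(p))
    manifest_path = outdir / "manifest.json"
    try:
        summary = _run_stages(
            tables, annotation, ensemble, outdir, references, alpha, manifest
        )
    except Exception as exc:
        manifest.status = f"failed: {type(exc).__name__}: {exc}"
        manifest.write(manifest_path)
        # remove partial report outputs, keep the failed manifest
        for p in outdir.glob("summary.*"):
            p.unlink()
        raise
    manifest.status = "ok"
    manifest.write(manifest_path)
    return summary


def _run_stages(tables, annotation, ensemble, outdir, references, alpha, manifest):
    tracks = list(tables)
    if "regular" not in tracks:
        raise ValueError("a 'regular' track is required")
    comparisons = [t.comparison for t in tables["regular"]]
    for track, tabs in tables.items():
        if [t.comparison for t in tabs] != comparisons:
            raise ValueError(f"track {track!r} comparisons differ from the regular track")

    t0 = time.perf_counter()
    status = {
        (track, t.comparison): classify_degs(t, alpha=alpha)
        for track, tabs in tables.items()
        for t in tabs
    }
    manifest.record("classify", time.perf_counter() - t0, len(status))

    assignment = None
    if ensemble is not None:
        t0 = time.perf_counter()
        assignment = map_genes_to_beads(annotation, ensemble)
        manifest.record("map_genes", time.perf_counter() - t0, len(assignment))

    # summary rows: comparison x track
    rows = []
    t0 = time.perf_counter()
    valid_refs = [r for r in references if r in comparisons]
    for r in references:
        if r not in comparisons:
            logger.warning("reference %s absent from comparisons, skipped", r)
    for track in tracks:
        for tab in tables[track]:
            st = status[(track, tab.comparison)]
            row: dict = {
                "comparison": tab.comparison,
                "track": track,
                "n_up": len(st.up),
                "n_down": len(st.down),
                "n_total_deg": len(st.up) + len(st.down),
            }
            for ref in valid_refs:
                ref_st = status[(track, ref)]
                shared = st.universe & ref_st.universe
                for d in ("up", "down"):
                    if tab.comparison == ref:
                        row[f"coherence_{d}_{ref}"] = math.nan
                        continue
                    res = coherence(
                        st.genes(d) & shared, ref_st.genes(d) & shared, len(shared), d
                    )
                    row[f"coherence_{d}_{ref}"] = (
                        res.coherence if res.defined else math.nan
                    )
            if assignment is not None:
                for d in ("up", "down"):
                    prof = radial_profile(d, st.genes(d), assignment, ensemble)
                    row[f"radial_dev_{d}"] = prof.deviation if prof.defined else math.nan
            rows.append(row)
    summary = pd.DataFrame(rows)
    manifest.record("summary", time.perf_counter() - t0, len(summary))

    # transition flows (regular track)
    t0 = time.perf_counter()
    flows = transition_flows([status[("regular", c)] for c in comparisons])
    flow_rows = []
    for f in flows:
        for src in f.counts.index:
            for dst in f.counts.columns:
                flow_rows.append(
                    {
                        "source": f.source,
                        "target": f.target,
                        "from_state": src,
                        "to_state": dst,
                        "count": int(f.counts.loc[src, dst]),
                    }
                )
    pd.DataFrame(flow_rows).to_csv(outdir / "flows.tsv", sep="\t", index=False)
    manifest.record("flows", time.perf_counter() - t0, len(flow_rows))

    # persistent DEGs + fold-change tests (regular track)
    t0 = time.perf_counter()
    pers = persistent_degs(tables["regular"], alpha=alpha)
    pers_payload = {
        "always_up": pers.always_up,
        "always_down": pers.always_down,
    }
    if pers.n_up + pers.n_down >= 2:
        tests = persistent_fc_tests(pers.fc_matrix, reference=comparisons[0])
        pers_payload["fc_tests"] = tests.to_dict(orient="records")
    with open(outdir / "persistent.json", "w") as fh:
        json.dump(pers_payload, fh, indent=2)
    manifest.record("persistent", time.perf_counter() - t0, pers.n_up + pers.n_down)

    # splice discordance per comparison (needs all three tracks)
    if {"spliced", "unspliced"} <= set(tracks):
        t0 = time.perf_counter()
        disc_rows = []
        for i, comp in enumerate(comparisons):
            d = splice_discordance(
                tables["spliced"][i], tables["unspliced"][i], tables["regular"][i],
                alpha=alpha,
            )
            disc_rows.append(
                {
                    "comparison": comp,
                    "n_discordant": d.n_discordant,
                    "n_regular_deg": len(d.regular_subset),
                    "fraction_regular": d.fraction_regular,
                }
            )
        pd.DataFrame(disc_rows).to_csv(outdir / "discordance.tsv", sep="\t", index=False)
        manifest.record("discordance", time.perf_counter() - t0, len(disc_rows))

    # per-chromosome distribution per comparison (regular track)
    t0 = time.perf_counter()
    rho_rows = []
    for comp in comparisons:
        dist = chromosome_distribution(status[("regular", comp)], annotation, alpha=alpha)
        dist.table.to_csv(outdir / f"chrom_{comp}.tsv", sep="\t", index=False)
        rho_rows.append(
            {"comparison": comp, "rho_total": dist.rho_total, "rho_up": dist.rho_up}
        )
    pd.DataFrame(rho_rows).to_csv(outdir / "chrom_rho.tsv", sep="\t", index=False)
    manifest.record("chromosomes", time.perf_counter() - t0, len(rho_rows))

    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(json.loads(summary.to_json(orient="records")), fh, indent=2)
    return summary
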