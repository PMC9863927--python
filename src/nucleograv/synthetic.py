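"""Synthetic inputs with controllable planted structure.

Generates everything the downstream statistics consume — a gene annotation,
a 3D bead-model ensemble, DESeq2-style DE tables for the regular / spliced /
unspliced tracks across an ordered time course, and a transcript-level count
matrix — so every statistic can be exercised and calibrated without real
sequencing data.

Planted structure, each independently switchable:

* LAD beads drawn with an outward radial bias (lamina-associated chromatin
  sits peripherally);
* up-/downregulated gene sets with a target radial deviation (``delta_up``
  toward the center, ``delta_down`` toward the periphery), calibrated by
  tilted sampling with rejection so the planted shift is recoverable;
* chromosomal skew: an odds multiplier favouring upregulation on a chosen
  chromosome set (emulating the small gene-dense chromosomes);
* temporal persistence: DEG labels carry over to the next comparison with
  probability ``persistence_rho``, plus an explicit always-up / always-down
  persistent gene set;
* spliced/unspliced discordance: a per-comparison quota of genes planted as
  unspliced-up and spliced-down;
* biotype composition: negative-binomial transcript counts with per-group
  multiplicative shifts on chosen biotypes.

Synthetic adjusted p-values are generated consistently with the planted
labels (padj < 0.05 iff labelled) rather than via simulated count testing:
the downstream statistics consume only labels and fold changes, and DE
testing itself is out of scope here.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deg_io import DEResultTable, GeneAnnotation, write_annotation, write_de_table
from .nucleus_models import (
    Bead,
    GeneBeadAssignment,
    NucleusModel,
    NucleusModelEnsemble,
    map_genes_to_beads,
    write_bead_models,
    write_cmm_models,
)

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "DEGSeries",
    "generate_scaffold_and_models",
    "generate_deg_series",
    "generate_transcript_counts",
    "write_simulation",
]

#: approximate human chromosome lengths in Mb, karyotype order
HUMAN_CHROM_MB = {
    "chr1": 249, "chr2": 243, "chr3": 198, "chr4": 190, "chr5": 182,
    "chr6": 171, "chr7": 159, "chr8": 146, "chr9": 141, "chr10": 136,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 64,
    "chr21": 47, "chr22": 51, "chrX": 156, "chrY": 57,
}

DEFAULT_COMPARISONS = (
    "hypg20s", "hypg75s", "hypg3", "hypg5", "hypg7", "hypg9", "hypg15", "hypg60",
)
# per-comparison DEG counts for the regular track (up, down)
DEFAULT_DEG_COUNTS = (
    (962, 753), (2096, 1830), (3001, 3442), (896, 535),
    (1021, 1018), (1470, 1164), (4191, 4537), (3704, 3295),
)

DEFAULT_BIOTYPE_WEIGHTS = {
    "protein_coding": 0.55,
    "retained_intron": 0.15,
    "nonsense_mediated_decay": 0.12,
    "processed_transcript": 0.10,
    "processed_pseudogene": 0.08,
}
# expression scale per biotype: protein-coding dominates total counts
DEFAULT_BIOTYPE_MEAN_SCALE = {
    "protein_coding": 60.0,
    "retained_intron": 4.0,
    "nonsense_mediated_decay": 2.0,
    "processed_transcript": 1.5,
    "processed_pseudogene": 1.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study-like conditions."""

    seed: int = 0
    # genome / scaffold
    chrom_lengths_mb: dict[str, int] = field(default_factory=lambda: dict(HUMAN_CHROM_MB))
    n_beads: int = 3000
    genes_per_bead_mean: float = 6.7
    nuclear_radius: float = 5.0
    lad_fraction: float = 0.35
    lad_outward_bias: float = 3.0
    bead_position_concentration: float = 30.0
    n_models: int = 100
    # DEG time course
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS
    deg_counts: tuple[tuple[int, int], ...] = DEFAULT_DEG_COUNTS
    delta_up: float = -0.4
    delta_down: float = 0.4
    radial_tolerance: float = 0.02
    skew_chromosomes: tuple[str, ...] = (
        "chr16", "chr17", "chr18", "chr19", "chr20", "chr21", "chr22",
    )
    skew_odds: float = 3.0
    persistence_rho: float = 0.5
    n_persistent_up: int = 214
    n_persistent_down: int = 87
    # spliced / unspliced derivation
    discordant_counts: tuple[int, ...] = (0, 0, 2, 8, 15, 25, 60, 120)
    discordant_regular_fraction: float = 0.5
    spliced_keep: tuple[float, float] = (0.4, 0.9)  # (up, down)
    unspliced_keep: tuple[float, float] = (0.9, 0.3)
    # transcript counts
    biotype_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_WEIGHTS)
    )
    biotype_mean_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_MEAN_SCALE)
    )
    extra_transcripts_mean: float = 0.8  # Poisson mean beyond the first transcript
    nb_mean: float = 200.0
    nb_dispersion: float = 0.1
    samples_per_group: int = 6
    control_group: str = "Ctrl"
    biotype_shifts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "hypg3": {"retained_intron": 1.6},
            "hypg15": {"retained_intron": 1.5, "protein_coding": 0.92},
            "hypg60": {"retained_intron": 1.6, "protein_coding": 0.9},
        }
    )

    def __post_init__(self) -> None:
        for p in (self.lad_fraction, self.persistence_rho, self.discordant_regular_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if len(self.deg_counts) != len(self.comparisons):
            raise ValueError("deg_counts must match comparisons")
        if len(self.discordant_counts) != len(self.comparisons):
            raise ValueError("discordant_counts must match comparisons")
        r = self.nuclear_radius
        for d in (self.delta_up, self.delta_down):
            if not -r < d < r:
                raise ValueError(f"planted radial shift {d} outside (-{r}, {r})")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        w = sum(self.biotype_weights.values())
        if not math.isclose(w, 1.0, rel_tol=1e-6):
            raise ValueError(f"biotype weights must sum to 1, got {w}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["deg_counts"] = [list(x) for x in self.deg_counts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("comparisons", "skew_chromosomes", "discordant_counts",
                    "spliced_keep", "unspliced_keep"):
            if key in d:
                d[key] = tuple(d[key])
        if "deg_counts" in d:
            d["deg_counts"] = tuple(tuple(x) for x in d["deg_counts"])
        return cls(**d)


# ---------------------------------------------------------------------------
# scaffold + models


def generate_scaffold_and_models(
    config: SimulationConfig,
) -> tuple[list[GeneAnnotation], NucleusModelEnsemble]:
    """Generate a gene annotation and a bead-model ensemble.

    Beads tile each chromosome (allocation proportional to length); each
    bead carries a Poisson number of genes tiled within its span.

    Bead positions emulate a constraint-satisfying model ensemble: each bead
    has a persistent radial preference drawn once per scaffold from
    ``Beta(3 + bias * is_lad, 1)`` — bias 0 reproduces the uniform-in-sphere
    radial law (density 3u^2), and a positive ``lad_outward_bias`` pushes
    LAD beads toward the envelope — and per model the bead's radius jitters
    around that preference (Beta with concentration
    ``bead_position_concentration``) with an isotropic direction. Positional
    preferences persisting across the ensemble are what make radial DEG
    statistics informative; fully exchangeable positions would average every
    gene to the same radius. Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_lengths_mb)
    lengths = np.array([config.chrom_lengths_mb[c] for c in chroms], dtype=float)
    alloc = np.maximum(1, np.round(config.n_beads * lengths / lengths.sum()).astype(int))

    scaffold: list[Bead] = []
    genes: list[GeneAnnotation] = []
    index = 0
    gene_no = 0
    for c, mb, k in zip(chroms, lengths, alloc):
        length_bp = int(mb * 1e6)
        bounds = np.linspace(0, length_bp, k + 1).astype(int)
        n_genes_per_bead = rng.poisson(config.genes_per_bead_mean, size=k)
        is_lad = rng.random(k) < config.lad_fraction
        for j in range(k):
            start, end = int(bounds[j]), int(bounds[j + 1])
            scaffold.append(Bead(chrom=c, start=start, end=end, is_lad=bool(is_lad[j]), index=index))
            ng = int(n_genes_per_bead[j])
            span = end - start
            if ng > span:
                raise ValueError(f"infeasible config: {ng} genes in a {span} bp bead")
            if ng:
                step = span // ng
                for g in range(ng):
                    gs = start + g * step
                    ge = gs + max(1, step // 2)
                    biotypes = list(config.biotype_weights)
                    bt = biotypes[
                        rng.choice(len(biotypes), p=list(config.biotype_weights.values()))
                    ]
                    genes.append(
                        GeneAnnotation(
                            gene_id=f"G{gene_no:05d}",
                            chrom=c,
                            start=gs,
                            end=ge,
                            strand="+" if rng.random() < 0.5 else "-",
                            biotype=bt,
                        )
                    )
                    gene_no += 1
            index += 1

    n_beads = len(scaffold)
    lad_mask = np.array([b.is_lad for b in scaffold])
    a = np.where(lad_mask, 3.0 + config.lad_outward_bias, 3.0)
    # persistent per-bead radial preference, jittered per model
    u_pref = np.clip(rng.beta(a, 1.0), 0.02, 0.98)
    kappa = config.bead_position_concentration
    models = []
    for m in range(config.n_models):
        u = rng.beta(kappa * u_pref, kappa * (1.0 - u_pref))
        r = config.nuclear_radius * u
        # isotropic directions
        v = rng.normal(size=(n_beads, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        models.append(
            NucleusModel(
                model_id=m,
                nuclear_radius=config.nuclear_radius,
                coordinates=v * r[:, None],
            )
        )
    ensemble = NucleusModelEnsemble(scaffold=scaffold, models=models)
    ensemble.validate()
    return genes, ensemble


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure, for recovery checks."""

    persistent_up: list[str]
    persistent_down: list[str]
    discordant: dict[str, list[str]]  # comparison -> planted discordant genes


@dataclass
class DEGSeries:
    """Generated DE tables per track plus the planted ground truth."""

    tables: dict[str, list[DEResultTable]]
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# calibrated DEG label drawing


def _calibrated_draw(
    rng: np.random.Generator,
    r: np.ndarray,
    base_weight: np.ndarray,
    available: np.ndarray,
    n_draw: int,
    target_mean: float | None,
    tol: float,
    max_tries: int = 80,
) -> np.ndarray:
    """Draw ``n_draw`` distinct gene indices from ``available``.

    With ``target_mean`` set, sampling probabilities are exponentially
    tilted in the radial coordinate and the tilt strength is adapted until a
    drawn set's mean radius lands within ``tol`` of the target (rejection on
    candidate label sets). Without a target, a plain weighted draw.
    """
    avail_idx = np.flatnonzero(available)
    if n_draw > avail_idx.size:
        raise ValueError(f"requested {n_draw} genes but only {avail_idx.size} available")
    if n_draw == 0:
        return np.empty(0, dtype=int)
    w0 = base_weight[avail_idx].astype(float)
    if target_mean is None:
        p = w0 / w0.sum()
        return rng.choice(avail_idx, size=n_draw, replace=False, p=p)
    ra = r[avail_idx]
    sd = ra.std()
    if sd == 0:
        p = w0 / w0.sum()
        return rng.choice(avail_idx, size=n_draw, replace=False, p=p)
    z = (ra - ra.mean()) / sd
    # initial tilt from the with-replacement weighted mean
    beta = 0.0
    lo, hi = -30.0, 30.0
    for _ in range(60):
        beta = 0.5 * (lo + hi)
        w = w0 * np.exp(np.clip(beta * z, -700, 700))
        m = float((w * ra).sum() / w.sum())
        if m < target_mean:
            lo = beta
        else:
            hi = beta
    best: np.ndarray | None = None
    best_err = math.inf
    for _ in range(max_tries):
        w = w0 * np.exp(np.clip(beta * z, -700, 700))
        p = w / w.sum()
        draw = rng.choice(avail_idx, size=n_draw, replace=False, p=p)
        err = float(r[draw].mean()) - target_mean
        if abs(err) < best_err:
            best, best_err = draw, abs(err)
        if abs(err) <= tol:
            return draw
        beta -= err / sd  # feedback: d(mean)/d(beta) ~ weighted variance / sd
    return best  # closest candidate after max_tries


def _synth_columns(
    rng: np.random.Generator, gene_ids: list[str], up: set[str], down: set[str]
) -> pd.DataFrame:
    """Synthesize baseMean / log2fc / pvalue / padj consistent with labels."""
    n = len(gene_ids)
    padj = rng.uniform(0.05, 1.0, size=n)
    lfc = rng.normal(0.0, 0.25, size=n)
    ids = np.array(gene_ids)
    up_mask = np.isin(ids, list(up))
    down_mask = np.isin(ids, list(down))
    n_up, n_down = int(up_mask.sum()), int(down_mask.sum())
    padj[up_mask] = rng.uniform(1e-8, 0.05 - 1e-4, size=n_up)
    padj[down_mask] = rng.uniform(1e-8, 0.05 - 1e-4, size=n_down)
    lfc[up_mask] = np.abs(rng.normal(1.0, 0.5, size=n_up)) + 0.05
    lfc[down_mask] = -(np.abs(rng.normal(1.0, 0.5, size=n_down)) + 0.05)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": rng.lognormal(5.0, 1.0, size=n),
            "log2fc": lfc,
            "pvalue": padj * rng.uniform(0.3, 1.0, size=n),
            "padj": padj,
        }
    )


def generate_deg_series(
    config: SimulationConfig,
    annotation: list[GeneAnnotation],
    ensemble: NucleusModelEnsemble,
    assignment: GeneBeadAssignment | None = None,
) -> DEGSeries:
    """Generate regular / spliced / unspliced DE tables for the time course.

    Upregulated labels are drawn with probability tilted toward the nuclear
    center so the realized ensemble radial deviation is ``delta_up`` (within
    ``radial_tolerance``); downregulated labels are tilted toward the
    periphery analogously. Genes on ``skew_chromosomes`` receive an odds
    multiplier for upregulation. Labels persist to the next comparison with
    probability ``persistence_rho``; the designated persistent genes stay
    labelled throughout and no other gene keeps one sign across all
    comparisons. Spliced and unspliced tracks are derived from the regular
    labels without direction flips, plus the planted discordant quota
    (unspliced-up and spliced-down), so the discordant sets are exactly the
    planted ones.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if assignment is None:
        assignment = map_genes_to_beads(annotation, ensemble)
    gene_ids = [g.gene_id for g in annotation]
    n_genes = len(gene_ids)
    id_index = {g: i for i, g in enumerate(gene_ids)}
    chrom = np.array([g.chrom for g in annotation])

    # ensemble-mean radius per gene; unmapped genes (none by construction)
    # fall back to the global mean so they carry no tilt
    radii = ensemble.radii()
    r_gene = np.empty(n_genes)
    mapped_mask = np.zeros(n_genes, dtype=bool)
    for g, bead_idx in assignment.mapping.items():
        i = id_index[g]
        r_gene[i] = radii[:, bead_idx].mean()
        mapped_mask[i] = True
    global_mean = r_gene[mapped_mask].mean()
    r_gene[~mapped_mask] = global_mean

    up_weight = np.where(np.isin(chrom, config.skew_chromosomes), config.skew_odds, 1.0)
    down_weight = np.ones(n_genes)

    max_deg = max(u + d for u, d in config.deg_counts)
    if max_deg + config.n_persistent_up + config.n_persistent_down > n_genes:
        raise ValueError("requested DEG counts exceed the gene universe")

    target_up = global_mean + config.delta_up
    target_down = global_mean + config.delta_down

    # persistent gene sets, drawn with the same tilts they must carry
    avail = np.ones(n_genes, dtype=bool)
    pers_up = _calibrated_draw(
        rng, r_gene, up_weight, avail, config.n_persistent_up,
        target_up, config.radial_tolerance,
    )
    avail[pers_up] = False
    pers_down = _calibrated_draw(
        rng, r_gene, down_weight, avail, config.n_persistent_down,
        target_down, config.radial_tolerance,
    )
    pers_up_set, pers_down_set = set(pers_up), set(pers_down)

    up_sets: list[set[int]] = []
    down_sets: list[set[int]] = []
    prev_up: set[int] = set()
    prev_down: set[int] = set()
    for (n_up, n_down) in config.deg_counts:
        if n_up < config.n_persistent_up or n_down < config.n_persistent_down:
            raise ValueError(
                "per-comparison DEG counts must be at least the persistent set sizes"
            )
        carried_up = {
            i for i in sorted(prev_up - pers_up_set - pers_down_set)
            if rng.random() < config.persistence_rho
        }
        forced_up = pers_up_set | set(sorted(carried_up)[: max(0, n_up - config.n_persistent_up)])
        avail = np.ones(n_genes, dtype=bool)
        avail[list(forced_up)] = False
        avail[list(pers_down_set)] = False
        n_new = n_up - len(forced_up)
        forced_arr = np.fromiter(forced_up, dtype=int)
        target_new = (
            (n_up * target_up - r_gene[forced_arr].sum()) / n_new if n_new > 0 else None
        )
        new_up = (
            _calibrated_draw(
                rng, r_gene, up_weight, avail, n_new, target_new,
                config.radial_tolerance * n_up / max(n_new, 1),
            )
            if n_new > 0 else np.empty(0, dtype=int)
        )
        up = forced_up | set(int(i) for i in new_up)

        carried_down = {
            i for i in sorted(prev_down - pers_down_set - pers_up_set - up)
            if rng.random() < config.persistence_rho
        }
        forced_down = pers_down_set | set(
            sorted(carried_down)[: max(0, n_down - config.n_persistent_down)]
        )
        avail = np.ones(n_genes, dtype=bool)
        avail[list(forced_down)] = False
        avail[list(up)] = False
        avail[list(pers_up_set)] = False
        n_new = n_down - len(forced_down)
        forced_arr = np.fromiter(forced_down, dtype=int)
        target_new = (
            (n_down * target_down - r_gene[forced_arr].sum()) / n_new if n_new > 0 else None
        )
        new_down = (
            _calibrated_draw(
                rng, r_gene, down_weight, avail, n_new, target_new,
                config.radial_tolerance * n_down / max(n_new, 1),
            )
            if n_new > 0 else np.empty(0, dtype=int)
        )
        down = forced_down | set(int(i) for i in new_down)

        up_sets.append(up)
        down_sets.append(down)
        prev_up, prev_down = up, down

    # demote accidental persistents so the planted sets are recovered exactly
    def _demote(sets: list[set[int]], planted: set[int]) -> None:
        if len(sets) < 2:
            return
        accidental = set.intersection(*sets) - planted
        if not accidental:
            return
        last = sets[-1]
        other = sets[0]
        free = [
            i for i in range(n_genes)
            if i not in last and i not in down_sets[-1] and i not in up_sets[-1]
            and i not in other
        ]
        rng.shuffle(free)
        for i, g in enumerate(sorted(accidental)):
            last.discard(g)
            if i < len(free):
                last.add(free[i])

    # at rho = 1 full persistence is the requested behaviour, not an accident
    if config.persistence_rho < 1.0:
        _demote(up_sets, pers_up_set)
        _demote(down_sets, pers_down_set)

    # derive track label sets and synthesize tables
    def to_ids(idx: set[int]) -> set[str]:
        return {gene_ids[i] for i in idx}

    tables: dict[str, list[DEResultTable]] = {"regular": [], "spliced": [], "unspliced": []}
    discordant_truth: dict[str, list[str]] = {}
    for k, comp in enumerate(config.comparisons):
        up = up_sets[k]
        down = down_sets[k]
        # planted discordant genes: part regular DEGs, part unlabelled
        n_disc = config.discordant_counts[k]
        n_from_deg = int(round(n_disc * config.discordant_regular_fraction))
        deg_pool = sorted(up | down)
        ns_pool = sorted(set(range(n_genes)) - up - down)
        n_from_deg = min(n_from_deg, len(deg_pool))
        disc = set()
        if n_from_deg:
            disc |= set(rng.choice(deg_pool, size=n_from_deg, replace=False).tolist())
        n_from_ns = n_disc - len(disc)
        if n_from_ns:
            disc |= set(rng.choice(ns_pool, size=n_from_ns, replace=False).tolist())
        discordant_truth[comp] = sorted(gene_ids[i] for i in disc)

        keep_su, keep_sd = config.spliced_keep
        keep_uu, keep_ud = config.unspliced_keep
        up_nd = np.array(sorted(up - disc), dtype=int)
        down_nd = np.array(sorted(down - disc), dtype=int)
        spl_up = set(up_nd[rng.random(up_nd.size) < keep_su].tolist())
        spl_down = set(down_nd[rng.random(down_nd.size) < keep_sd].tolist()) | disc
        uns_up = set(up_nd[rng.random(up_nd.size) < keep_uu].tolist()) | disc
        uns_down = set(down_nd[rng.random(down_nd.size) < keep_ud].tolist())

        for track, (u, d) in (
            ("regular", (up, down)),
            ("spliced", (spl_up, spl_down)),
            ("unspliced", (uns_up, uns_down)),
        ):
            df = _synth_columns(rng, gene_ids, to_ids(u), to_ids(d))
            tables[track].append(DEResultTable(comparison=comp, track=track, data=df))
    truth = PlantedTruth(
        persistent_up=sorted(gene_ids[i] for i in pers_up_set),
        persistent_down=sorted(gene_ids[i] for i in pers_down_set),
        discordant=discordant_truth,
    )
    return DEGSeries(tables=tables, truth=truth)


# ---------------------------------------------------------------------------
# transcript counts


def generate_transcript_counts(
    config: SimulationConfig, annotation: list[GeneAnnotation]
) -> "TranscriptCounts":
    """Negative-binomial transcript counts with planted per-group shifts.

    Each gene carries one transcript of its own biotype plus a Poisson
    number of extra transcripts with biotypes drawn from the mixture
    weights. Per-transcript base expression is log-normal scaled by the
    biotype's mean scale; counts are NB(mean, dispersion) with the group's
    multiplicative shift applied to the mean for shifted biotypes.
    Deterministic given the config seed.
    """
    from .biotype_stats import TranscriptCounts

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    biotypes = list(config.biotype_weights)
    weights = np.array(list(config.biotype_weights.values()))

    t_ids: list[str] = []
    t_gene: dict[str, str] = {}
    t_bt: dict[str, str] = {}
    for g in annotation:
        n_extra = rng.poisson(config.extra_transcripts_mean)
        bts = [g.biotype] + [
            biotypes[i] for i in rng.choice(len(biotypes), size=n_extra, p=weights)
        ]
        for j, bt in enumerate(bts):
            tid = f"{g.gene_id}.t{j}"
            t_ids.append(tid)
            t_gene[tid] = g.gene_id
            t_bt[tid] = bt

    groups = [config.control_group] + list(config.comparisons)
    samples = [f"{g}_{i + 1}" for g in groups for i in range(config.samples_per_group)]
    sample_groups = {s: s.rsplit("_", 1)[0] for s in samples}

    scale = np.array([config.biotype_mean_scale.get(t_bt[t], 1.0) for t in t_ids])
    base = rng.lognormal(0.0, 1.0, size=len(t_ids)) * scale
    base *= config.nb_mean / base.mean()
    n_param = 1.0 / config.nb_dispersion

    mat = np.empty((len(t_ids), len(samples)), dtype=np.int64)
    bt_arr = np.array([t_bt[t] for t in t_ids])
    for j, s in enumerate(samples):
        grp = sample_groups[s]
        mu = base.copy()
        for bt, factor in config.biotype_shifts.get(grp, {}).items():
            mu[bt_arr == bt] *= factor
        p = n_param / (n_param + mu)
        mat[:, j] = rng.negative_binomial(n_param, p)
    counts = pd.DataFrame(mat, index=pd.Index(t_ids, name="transcript_id"), columns=samples)
    return TranscriptCounts(
        counts=counts,
        sample_groups=sample_groups,
        transcript_gene=t_gene,
        transcript_biotype=t_bt,
    )


# ---------------------------------------------------------------------------
# file output


def write_simulation(
    config: SimulationConfig,
    outdir: str | Path,
    cmm: bool = False,
    transcript_counts: bool = True,
) -> dict[str, object]:
    """Generate a full synthetic data set and write it to ``outdir``.

    Writes genes.gtf, beads.tsv (and a cmm/ directory when requested), one
    DE table per track and comparison (``de_<track>_<comparison>.tsv``),
    counts.tsv + t2g.tsv + t2b.tsv + samples.tsv, and config.json. Returns
    the in-memory objects keyed by name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, ensemble = generate_scaffold_and_models(config)
    write_annotation(annotation, outdir / "genes.gtf", format="gtf")
    write_bead_models(ensemble, outdir / "beads.tsv")
    if cmm:
        write_cmm_models(ensemble, outdir / "cmm")
    series = generate_deg_series(config, annotation, ensemble)
    for track, tabs in series.tables.items():
        for t in tabs:
            write_de_table(t, outdir / f"de_{track}_{t.comparison}.tsv")
    with open(outdir / "planted.json", "w") as fh:
        json.dump(
            {
                "persistent_up": series.truth.persistent_up,
                "persistent_down": series.truth.persistent_down,
                "discordant": series.truth.discordant,
            },
            fh,
            indent=2,
        )
    out: dict[str, object] = {
        "annotation": annotation,
        "ensemble": ensemble,
        "tables": series.tables,
        "truth": series.truth,
        "config": config,
    }
    if transcript_counts:
        tc = generate_transcript_counts(config, annotation)
        tc.counts.reset_index().to_csv(outdir / "counts.tsv", sep="\t", index=False)
        pd.DataFrame(tc.transcript_gene.items()).to_csv(
            outdir / "t2g.tsv", sep="\t", index=False, header=False
        )
        pd.DataFrame(tc.transcript_biotype.items()).to_csv(
            outdir / "t2b.tsv", sep="\t", index=False, header=False
        )
        pd.DataFrame(
            {"sample": list(tc.sample_groups), "group": list(tc.sample_groups.values())}
        ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
        out["transcript_counts"] = tc
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    return out
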