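"""3D chromatin bead-model ensembles and radial DEG-distribution statistics.

A nucleus model represents chromatin as a chain of beads, each covering a
genomic span (a TAD or an inter-TAD region, possibly carrying several genes).
An ensemble is a set of independent 3D configurations sharing one genomic
bead scaffold; many alternative configurations satisfying the same contact
and lamina constraints stand in for the unknown true conformation.

The radial statistics ask whether a set of differentially expressed genes
sits closer to the nuclear center (or periphery) than expected when genes
are drawn at random from all mapped genes. Distances are to the nuclear
center, in micrometres, evaluated at the center of the bead carrying each
gene; per-model statistics are averaged over the ensemble.
"""

from __future__ import annotations

import logging
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deg_io import GeneAnnotation

__all__ = [
    "Bead",
    "NucleusModel",
    "NucleusModelEnsemble",
    "GeneBeadAssignment",
    "RadialExpectation",
    "RadialStats",
    "RadialProfile",
    "read_bead_models",
    "write_bead_models",
    "map_genes_to_beads",
    "expected_radial_profile",
    "actual_radial_stats",
    "radial_deviation",
    "radial_profile",
]

logger = logging.getLogger(__name__)

#: tolerance on the bead-containment invariant (fraction of nuclear radius)
CONTAINMENT_TOL = 1e-6


@dataclass(frozen=True)
class Bead:
    """One scaffold bead: genomic span (0-based half-open) plus LAD flag."""

    chrom: str
    start: int
    end: int
    is_lad: bool = False
    index: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"bead {self.chrom}:{self.start}-{self.end}: start must be < end"
            )


@dataclass
class NucleusModel:
    """One 3D configuration: (x, y, z) in µm per scaffold bead."""

    model_id: int
    nuclear_radius: float
    coordinates: np.ndarray  # (n_beads, 3) µm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_beads, 3)")

    @property
    def radii(self) -> np.ndarray:
        """Euclidean distance of each bead center from the nuclear center."""
        return np.linalg.norm(self.coordinates, axis=1)

    def validate(self) -> None:
        limit = self.nuclear_radius * (1.0 + CONTAINMENT_TOL)
        r = self.radii
        if (r > limit).any():
            worst = float(r.max())
            raise ValueError(
                f"model {self.model_id}: bead at radius {worst:.6g} µm exceeds "
                f"nuclear radius {self.nuclear_radius} µm"
            )


@dataclass
class NucleusModelEnsemble:
    """N independent configurations over one shared bead scaffold."""

    scaffold: list[Bead]
    models: list[NucleusModel]
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        n = len(self.scaffold)
        for m in self.models:
            if m.coordinates.shape[0] != n:
                raise ValueError(
                    f"model {m.model_id}: {m.coordinates.shape[0]} coordinates "
                    f"for a {n}-bead scaffold"
                )
        # per-chromosome beads must be sorted and non-overlapping
        by_chrom: dict[str, list[Bead]] = {}
        for b in self.scaffold:
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, beads in by_chrom.items():
            for a, b in zip(beads, beads[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"scaffold beads on {chrom} overlap or are unsorted: "
                        f"[{a.start},{a.end}) then [{b.start},{b.end})"
                    )

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_beads(self) -> int:
        return len(self.scaffold)

    @property
    def nuclear_radius(self) -> float:
        return self.models[0].nuclear_radius

    def coordinates(self) -> np.ndarray:
        """All coordinates stacked: shape (n_models, n_beads, 3)."""
        if self._coords is None or self._coords.shape[0] != self.n_models:
            self._coords = np.stack([m.coordinates for m in self.models])
        return self._coords

    def radii(self) -> np.ndarray:
        """Bead radial distances, shape (n_models, n_beads)."""
        return np.linalg.norm(self.coordinates(), axis=2)

    def validate(self) -> None:
        for m in self.models:
            m.validate()


@dataclass
class GeneBeadAssignment:
    """gene_id -> scaffold bead index; genes with no containing bead listed."""

    mapping: dict[str, int]
    unmapped: list[str]

    @property
    def mapped_genes(self) -> list[str]:
        return list(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# I/O


BEAD_TSV_HEADER = ["model_id", "chrom", "start", "end", "x_um", "y_um", "z_um", "is_lad"]


def write_bead_models(ensemble: NucleusModelEnsemble, path: str | Path) -> None:
    """Write an ensemble in the flat bead TSV dialect (one row per bead/model)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(BEAD_TSV_HEADER) + "\n")
        for m in ensemble.models:
            for b, (x, y, z) in zip(ensemble.scaffold, m.coordinates):
                fh.write(
                    f"{m.model_id}\t{b.chrom}\t{b.start}\t{b.end}\t"
                    f"{float(x)!r}\t{float(y)!r}\t{float(z)!r}\t{int(b.is_lad)}\n"
                )


def write_cmm_models(ensemble: NucleusModelEnsemble, outdir: str | Path) -> list[Path]:
    """Write one CMM XML file per model (marker id encodes chrom:start-end).

    Files declare ``units="um"`` on the marker_set element so they round-trip
    without rescaling.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in ensemble.models:
        root = ET.Element("marker_set", name=f"model_{m.model_id}", units="um")
        for b, (x, y, z) in zip(ensemble.scaffold, m.coordinates):
            ET.SubElement(
                root,
                "marker",
                id=f"{b.chrom}:{b.start}-{b.end}",
                x=repr(float(x)),
                y=repr(float(y)),
                z=repr(float(z)),
                lad=str(int(b.is_lad)),
            )
        p = outdir / f"model_{m.model_id:05d}.cmm"
        ET.ElementTree(root).write(p, xml_declaration=True, encoding="unicode")
        paths.append(p)
    return paths


def _read_bead_tsv(path: Path, nuclear_radius: float | None) -> NucleusModelEnsemble:
    header: list[str] | None = None
    per_model: dict[int, list[tuple[Bead, tuple[float, float, float]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                if header != BEAD_TSV_HEADER:
                    raise ValueError(
                        f"{path}:1: bead TSV header must be {BEAD_TSV_HEADER}, got {header}"
                    )
                continue
            if len(fields) != len(BEAD_TSV_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(BEAD_TSV_HEADER)} fields")
            try:
                model_id = int(fields[0])
                chrom = fields[1]
                start, end = int(fields[2]), int(fields[3])
                xyz = (float(fields[4]), float(fields[5]), float(fields[6]))
                is_lad = bool(int(fields[7]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bead row: {exc}") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: bead end ({end}) must be > start ({start})")
            bead = Bead(chrom=chrom, start=start, end=end, is_lad=is_lad)
            per_model.setdefault(model_id, []).append((bead, xyz))
    if not per_model:
        raise ValueError(f"{path}: no bead rows found")
    return _assemble(per_model, nuclear_radius, rescale=False)


_CMM_ID = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _read_cmm_dir(path: Path, nuclear_radius: float | None) -> NucleusModelEnsemble:
    files = sorted(path.glob("*.cmm"))
    if not files:
        raise ValueError(f"{path}: no .cmm files found")
    per_model: dict[int, list[tuple[Bead, tuple[float, float, float]]]] = {}
    declared_um = True
    for model_id, f in enumerate(files):
        try:
            root = ET.parse(f).getroot()
        except ET.ParseError as exc:
            raise ValueError(f"{f}: XML parse error: {exc}") from exc
        if root.get("units") != "um":
            declared_um = False
        rows = []
        for marker in root.iter("marker"):
            mid = marker.get("id", "")
            m = _CMM_ID.match(mid)
            if m is None:
                raise ValueError(f"{f}: marker id {mid!r} does not encode chrom:start-end")
            start, end = int(m.group("start")), int(m.group("end"))
            if start >= end:
                raise ValueError(f"{f}: marker {mid!r}: end must be > start")
            bead = Bead(
                chrom=m.group("chrom"),
                start=start,
                end=end,
                is_lad=bool(int(marker.get("lad", "0"))),
            )
            try:
                xyz = (float(marker.get("x")), float(marker.get("y")), float(marker.get("z")))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{f}: marker {mid!r}: missing/malformed x/y/z") from exc
            rows.append((bead, xyz))
        per_model[model_id] = rows
    return _assemble(per_model, nuclear_radius, rescale=not declared_um)


def _assemble(
    per_model: dict[int, list[tuple[Bead, tuple[float, float, float]]]],
    nuclear_radius: float | None,
    rescale: bool,
) -> NucleusModelEnsemble:
    model_ids = sorted(per_model)
    ref_beads = [b for b, _ in per_model[model_ids[0]]]
    scaffold = [
        Bead(chrom=b.chrom, start=b.start, end=b.end, is_lad=b.is_lad, index=i)
        for i, b in enumerate(ref_beads)
    ]
    key = [(b.chrom, b.start, b.end, b.is_lad) for b in ref_beads]
    models = []
    for mid in model_ids:
        rows = per_model[mid]
        if [(b.chrom, b.start, b.end, b.is_lad) for b, _ in rows] != key:
            raise ValueError(f"model {mid}: bead scaffold differs from model {model_ids[0]}")
        coords = np.array([xyz for _, xyz in rows], dtype=float)
        models.append(NucleusModel(model_id=mid, nuclear_radius=math.nan, coordinates=coords))
    max_r = max(float(np.linalg.norm(m.coordinates, axis=1).max()) for m in models)
    if rescale:
        # arbitrary units: scale so the outermost bead sits on the envelope
        radius = nuclear_radius if nuclear_radius is not None else 5.0
        scale = radius / max_r if max_r > 0 else 1.0
        for m in models:
            m.coordinates = m.coordinates * scale
    else:
        radius = nuclear_radius if nuclear_radius is not None else max_r
    for m in models:
        m.nuclear_radius = radius
    ens = NucleusModelEnsemble(scaffold=scaffold, models=models)
    ens.validate()
    return ens


def read_bead_models(
    path: str | Path,
    format: str = "tsv",
    nuclear_radius: float | None = None,
) -> NucleusModelEnsemble:
    """Read a bead-model ensemble.

    ``format='tsv'``: one flat tab-separated file with columns
    model_id, chrom, start, end, x_um, y_um, z_um, is_lad (coordinates in µm).

    ``format='cmm'``: a directory of Chrom3D-style CMM XML files, one per
    model, with ``<marker>`` elements carrying x/y/z attributes and an id
    encoding ``chrom:start-end``. Files without a ``units="um"`` declaration
    are treated as arbitrary units and rescaled so the outermost bead lies at
    ``nuclear_radius`` (default 5 µm).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_bead_tsv(path, nuclear_radius)
    if format == "cmm":
        return _read_cmm_dir(path, nuclear_radius)
    raise ValueError(f"unknown bead-model format: {format!r}")


# ---------------------------------------------------------------------------
# Gene -> bead mapping


def map_genes_to_beads(
    annotation: list[GeneAnnotation], ensemble: NucleusModelEnsemble
) -> GeneBeadAssignment:
    """Assign each gene to the bead whose span contains the gene midpoint.

    Bead spans are half-open, so a midpoint landing exactly on a boundary
    belongs to the bead that starts there. Genes whose midpoint falls in no
    bead (or on a chromosome absent from the scaffold) are listed unmapped.
    """
    if not ensemble.scaffold:
        raise ValueError("ensemble has an empty scaffold")
    seen: set[str] = set()
    for g in annotation:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id in annotation: {g.gene_id}")
        seen.add(g.gene_id)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[Bead]] = {}
    for b in ensemble.scaffold:
        tmp.setdefault(b.chrom, []).append(b)
    for chrom, beads in tmp.items():
        starts = np.array([b.start for b in beads])
        ends = np.array([b.end for b in beads])
        idx = np.array([b.index for b in beads])
        by_chrom[chrom] = (starts, ends, idx)
    mapping: dict[str, int] = {}
    unmapped: list[str] = []
    for g in annotation:
        entry = by_chrom.get(g.chrom)
        if entry is None:
            unmapped.append(g.gene_id)
            continue
        starts, ends, idx = entry
        mid = g.midpoint
        i = int(np.searchsorted(starts, mid, side="right")) - 1
        if i >= 0 and mid < ends[i]:
            mapping[g.gene_id] = int(idx[i])
        else:
            unmapped.append(g.gene_id)
    return GeneBeadAssignment(mapping=mapping, unmapped=unmapped)


# ---------------------------------------------------------------------------
# Radial statistics


@dataclass
class RadialExpectation:
    """Expected radial distribution when DEG labels are drawn at random.

    ``cdf`` is ``n_genes`` times the empirical CDF of all mapped genes'
    radial distances, averaged over models, evaluated on ``grid``.
    """

    mean: float
    grid: np.ndarray
    cdf: np.ndarray
    n_genes: int


@dataclass
class RadialStats:
    """Ensemble-averaged radial distribution of an actual DEG set."""

    mean: float
    grid: np.ndarray
    cdf: np.ndarray
    per_model_means: np.ndarray
    n_genes: int
    n_dropped: int = 0

    @property
    def defined(self) -> bool:
        return self.n_genes > 0


@dataclass
class RadialProfile:
    """Actual vs expected radial distribution for one DEG direction."""

    direction: str
    n_genes: int
    expected_mean: float
    actual_mean: float
    deviation: float
    expected_cdf: tuple[np.ndarray, np.ndarray]
    actual_cdf: tuple[np.ndarray, np.ndarray]
    per_model_actual_means: np.ndarray
    defined: bool = True


def _gene_radii(
    assignment: GeneBeadAssignment, ensemble: NucleusModelEnsemble, genes: list[str]
) -> np.ndarray:
    """Radial distance per (model, gene): shape (n_models, n_genes)."""
    idx = np.array([assignment.mapping[g] for g in genes], dtype=int)
    return ensemble.radii()[:, idx]


def _mean_cdf(radii: np.ndarray, grid: np.ndarray, n_genes: int) -> np.ndarray:
    """Cumulative gene count vs radius, averaged over models.

    ``radii`` has one row per model; every row has the same gene count, so
    pooling across models and averaging per-model ECDFs coincide.
    """
    n_models, n = radii.shape
    s = np.sort(radii, axis=1)
    counts = np.stack([np.searchsorted(row, grid, side="right") for row in s])
    return n_genes * counts.mean(axis=0) / n


def expected_radial_profile(
    assignment: GeneBeadAssignment,
    ensemble: NucleusModelEnsemble,
    n_genes: int,
    grid_size: int = 256,
) -> RadialExpectation:
    """Expected radial distribution of ``n_genes`` randomly drawn genes.

    Drawing genes uniformly from all mapped genes and averaging makes the
    expected mean the (per-model, then ensemble) average of every mapped
    gene's bead radius; multi-gene beads weigh in once per gene. The result
    is independent of the DEG direction, so up- and downregulated sets share
    one expectation.
    """
    if n_genes <= 0:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if not assignment.mapping:
        raise ValueError("assignment maps no genes")
    radii = _gene_radii(assignment, ensemble, assignment.mapped_genes)
    grid = np.linspace(0.0, ensemble.nuclear_radius, grid_size)
    cdf = _mean_cdf(radii, grid, n_genes)
    return RadialExpectation(
        mean=float(radii.mean()), grid=grid, cdf=cdf, n_genes=n_genes
    )


def actual_radial_stats(
    deg_genes: set[str],
    assignment: GeneBeadAssignment,
    ensemble: NucleusModelEnsemble,
    grid_size: int = 256,
) -> RadialStats:
    """Ensemble-averaged mean radial distance of an actual DEG set.

    Per model, the mean bead radius over the DEG genes; the headline value
    averages the per-model means with equal weight. DEG members with no
    bead assignment are dropped (count logged and reported).
    """
    genes = sorted(g for g in deg_genes if g in assignment.mapping)
    n_dropped = len(deg_genes) - len(genes)
    if n_dropped:
        logger.info("actual_radial_stats: dropped %d unmapped DEG genes", n_dropped)
    grid = np.linspace(0.0, ensemble.nuclear_radius, grid_size)
    if not genes:
        return RadialStats(
            mean=math.nan,
            grid=grid,
            cdf=np.zeros_like(grid),
            per_model_means=np.full(ensemble.n_models, math.nan),
            n_genes=0,
            n_dropped=n_dropped,
        )
    radii = _gene_radii(assignment, ensemble, genes)
    per_model = radii.mean(axis=1)
    cdf = _mean_cdf(radii, grid, len(genes))
    return RadialStats(
        mean=float(per_model.mean()),
        grid=grid,
        cdf=cdf,
        per_model_means=per_model,
        n_genes=len(genes),
        n_dropped=n_dropped,
    )


def radial_deviation(actual_mean: float, expected_mean: float) -> float:
    """Actual minus expected mean radial distance (µm).

    Negative values mean the gene set sits closer to the nuclear center
    than random drawing predicts; positive values mean a peripheral shift.
    """
    if not (math.isfinite(actual_mean) and math.isfinite(expected_mean)):
        raise ValueError("radial_deviation requires finite means")
    return actual_mean - expected_mean


def radial_profile(
    direction: str,
    deg_genes: set[str],
    assignment: GeneBeadAssignment,
    ensemble: NucleusModelEnsemble,
    grid_size: int = 256,
) -> RadialProfile:
    """Convenience wrapper combining expectation, actual stats and deviation."""
    actual = actual_radial_stats(deg_genes, assignment, ensemble, grid_size=grid_size)
    if not actual.defined:
        grid = actual.grid
        return RadialProfile(
            direction=direction,
            n_genes=0,
            expected_mean=math.nan,
            actual_mean=math.nan,
            deviation=math.nan,
            expected_cdf=(grid, np.zeros_like(grid)),
            actual_cdf=(grid, actual.cdf),
            per_model_actual_means=actual.per_model_means,
            defined=False,
        )
    expected = expected_radial_profile(
        assignment, ensemble, actual.n_genes, grid_size=grid_size
    )
    return RadialProfile(
        direction=direction,
        n_genes=actual.n_genes,
        expected_mean=expected.mean,
        actual_mean=actual.mean,
        deviation=radial_deviation(actual.mean, expected.mean),
        expected_cdf=(expected.grid, expected.cdf),
        actual_cdf=(actual.grid, actual.cdf),
        per_model_actual_means=actual.per_model_means,
        defined=True,
    )
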