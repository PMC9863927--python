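"""Transcript-biotype count aggregation and group tests.

Works at transcript resolution: a counts matrix (transcripts x samples) with
transcript-to-gene and transcript-to-biotype maps and a sample-to-group
sheet. Counts are summed per biotype and sample (no internal normalisation),
the most abundant biotypes are retained, and each treatment group is tested
against a control group with a Student's t test per biotype, BH-adjusted
with four-level star codes.

Also provides per-gene biotype composition (counts and fractions of one
gene's transcripts by biotype) and the centrifuge spin-down exposure
fraction used to bound how much of a centrifugation run the deceleration
phase represents.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mtc import FOUR_LEVEL, bh_adjust, star_code

__all__ = [
    "TranscriptCounts",
    "BiotypeAggregate",
    "read_transcript_counts",
    "aggregate_biotypes",
    "biotype_group_tests",
    "gene_transcript_composition",
    "exposure_fraction",
]

logger = logging.getLogger(__name__)


@dataclass
class TranscriptCounts:
    """Transcript x sample count matrix plus grouping and identity maps."""

    counts: pd.DataFrame = field(repr=False)  # index: transcript_id, columns: samples
    sample_groups: dict[str, str]
    transcript_gene: dict[str, str]
    transcript_biotype: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing_group = [s for s in self.counts.columns if s not in self.sample_groups]
        if missing_group:
            raise ValueError(f"samples without group label: {missing_group}")
        missing_bt = [t for t in self.counts.index if t not in self.transcript_biotype]
        if missing_bt:
            raise ValueError(f"transcripts without biotype: {missing_bt[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    def gene_transcripts(self, gene_id: str) -> list[str]:
        return [t for t in self.counts.index if self.transcript_gene.get(t) == gene_id]


def read_transcript_counts(
    counts_path: str | Path,
    t2g_path: str | Path,
    t2b_path: str | Path,
    samples_path: str | Path,
) -> TranscriptCounts:
    """Read a counts TSV plus two-column maps and a sample sheet.

    The counts file has a ``transcript_id`` column followed by one column
    per sample; the maps are headerless two-column TSVs (transcript, gene)
    and (transcript, biotype); the sample sheet has columns sample, group.
    """
    counts = pd.read_csv(counts_path, sep="\t").set_index("transcript_id")
    t2g = dict(pd.read_csv(t2g_path, sep="\t", header=None).itertuples(index=False, name=None))
    t2b = dict(pd.read_csv(t2b_path, sep="\t", header=None).itertuples(index=False, name=None))
    sheet = pd.read_csv(samples_path, sep="\t")
    groups = dict(zip(sheet["sample"].astype(str), sheet["group"].astype(str)))
    return TranscriptCounts(
        counts=counts, sample_groups=groups, transcript_gene=t2g, transcript_biotype=t2b
    )


@dataclass
class BiotypeAggregate:
    """Summed counts per biotype and sample for the top-k biotypes."""

    per_sample: pd.DataFrame = field(repr=False)  # index: biotype, columns: samples
    sample_groups: dict[str, str] = field(repr=False, default_factory=dict)
    biotype_rank: list[str] = field(default_factory=list)

    @property
    def group_means(self) -> pd.DataFrame:
        groups = pd.Series(self.sample_groups)[self.per_sample.columns]
        return self.per_sample.T.groupby(groups).mean().T


def aggregate_biotypes(counts: TranscriptCounts, top_k: int = 5) -> BiotypeAggregate:
    """Sum counts per (biotype, sample) and keep the top-k biotypes by total.

    When fewer than ``top_k`` biotypes exist, all are used (warning logged).
    """
    bt = pd.Series({t: counts.transcript_biotype[t] for t in counts.counts.index})
    sums = counts.counts.groupby(bt).sum()
    rank = sums.sum(axis=1).sort_values(ascending=False)
    if top_k > len(rank):
        logger.warning(
            "aggregate_biotypes: top_k=%d exceeds %d available biotypes; using all",
            top_k, len(rank),
        )
        top_k = len(rank)
    keep = list(rank.index[:top_k])
    return BiotypeAggregate(
        per_sample=sums.loc[keep],
        sample_groups=dict(counts.sample_groups),
        biotype_rank=keep,
    )


def biotype_group_tests(
    agg: BiotypeAggregate, control_group: str, equal_var: bool = True
) -> pd.DataFrame:
    """Student's t test of each group against the control, per biotype.

    p-values are BH-adjusted across the treatment groups within each
    biotype; stars follow the four-level convention (* <0.05 .. **** <0.0001).
    Groups with fewer than two samples are flagged undefined.
    """
    groups = pd.Series(agg.sample_groups)[agg.per_sample.columns]
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} not among samples")
    ctrl_samples = groups.index[groups == control_group]
    if len(ctrl_samples) < 2:
        raise ValueError(f"control group {control_group!r} has < 2 samples")
    others = [g for g in dict.fromkeys(groups) if g != control_group]
    rows = []
    for biotype in agg.per_sample.index:
        ctrl = agg.per_sample.loc[biotype, ctrl_samples].to_numpy(dtype=float)
        for g in others:
            samp = groups.index[groups == g]
            defined = len(samp) >= 2
            if not defined:
                logger.warning("biotype_group_tests: group %s has < 2 samples", g)
                t = p = math.nan
            else:
                x = agg.per_sample.loc[biotype, samp].to_numpy(dtype=float)
                if np.allclose(x, x[0]) and np.allclose(ctrl, ctrl[0]) and np.isclose(x[0], ctrl[0]):
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(x, ctrl, equal_var=equal_var)
            rows.append(
                {"biotype": biotype, "group": g, "t": float(t), "pvalue": float(p),
                 "defined": defined}
            )
    out = pd.DataFrame(rows)
    out["padj"] = np.nan
    for biotype in agg.per_sample.index:
        mask = out["biotype"] == biotype
        out.loc[mask, "padj"] = bh_adjust(out.loc[mask, "pvalue"])
    out["stars"] = [star_code(p, FOUR_LEVEL) for p in out["padj"]]
    return out


def gene_transcript_composition(
    counts: TranscriptCounts, gene_id: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biotype composition of one gene's transcripts.

    Returns ``(sums, fractions)``: per-sample counts of the gene's
    transcripts summed by biotype, and the same as fractions of the gene's
    per-sample total (NaN where the total is 0).
    """
    transcripts = counts.gene_transcripts(gene_id)
    if not transcripts:
        raise KeyError(f"gene {gene_id!r} has no transcripts in the count matrix")
    sub = counts.counts.loc[transcripts]
    bt = pd.Series({t: counts.transcript_biotype[t] for t in transcripts})
    sums = sub.groupby(bt).sum()
    totals = sums.sum(axis=0)
    fractions = sums.divide(totals.where(totals > 0), axis=1)
    return sums, fractions


def exposure_fraction(stop_time: float, exposure_time: float) -> float:
    """Spin-down time as a percentage of the total centrifugation time.

    Quantifies how much of a hypergravity exposure the centrifuge's
    deceleration phase represents (e.g. a 1.08 s stop against a 20 s spin
    is 5.4%). Both times are in seconds and must be positive.
    """
    if stop_time <= 0 or exposure_time <= 0:
        raise ValueError("stop_time and exposure_time must be positive")
    return 100.0 * stop_time / exposure_time
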