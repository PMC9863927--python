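"""Per-chromosome distribution of differentially expressed genes.

Compares the observed number of DEGs (and the up/down split) on each
chromosome against a uniform random-drawing expectation: every detected gene
is equally likely to be differentially expressed, so a chromosome's expected
DEG count is the genome-wide DEG fraction times its detected-gene count, and
the expected down-share among its DEGs is the genome-wide down-share.

Departures are tested per chromosome with Fisher's exact test (a binomial
alternative is available), BH-adjusted separately for the total-count and
skew families, and summarised globally by the Spearman rank correlation
between expected and observed counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .deg_io import DEGStatusMap, GeneAnnotation
from .mtc import bh_adjust, star_code

__all__ = [
    "ChromosomeDistribution",
    "chromosome_distribution",
    "expectation_correlation",
    "karyotype_order",
]

logger = logging.getLogger(__name__)


def karyotype_order(chroms: set[str]) -> list[str]:
    """Sort chromosome names in karyotype order (chr1..chr22, chrX, chrY)."""

    def key(c: str):
        name = c[3:] if c.lower().startswith("chr") else c
        if name.isdigit():
            return (0, int(name), name)
        return (1, {"X": 0, "Y": 1, "M": 2, "MT": 2}.get(name.upper(), 9), name)

    return sorted(chroms, key=key)


@dataclass
class ChromosomeDistribution:
    """Per-chromosome observed/expected DEG counts with tests and correlations."""

    comparison: str
    table: pd.DataFrame = field(repr=False)
    rho_total: float = math.nan
    rho_up: float = math.nan
    alpha: float = 0.05
    second_threshold: float = 0.01


def expectation_correlation(expected, observed) -> float:
    """Spearman rank correlation between expected and observed counts.

    1 means the observation follows the expectation's ordering exactly.
    Undefined (NaN) for constant vectors; requires at least 3 chromosomes.
    """
    expected = np.asarray(expected, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if expected.shape != observed.shape or expected.size < 3:
        raise ValueError("need >= 3 paired chromosome counts")
    if np.all(expected == expected[0]) or np.all(observed == observed[0]):
        logger.warning("expectation_correlation: constant vector, rho undefined")
        return math.nan
    rho = stats.spearmanr(expected, observed).statistic
    return float(rho)


def chromosome_distribution(
    status: DEGStatusMap,
    annotation: list[GeneAnnotation],
    alpha: float = 0.05,
    second_threshold: float = 0.01,
    test: str = "fisher",
) -> ChromosomeDistribution:
    """Observed vs expected DEG distribution across chromosomes.

    Two test families per chromosome, each BH-adjusted across chromosomes:

    * total: is the chromosome's DEG count compatible with uniform drawing?
      Fisher's exact test on [DEG on c, non-DEG on c; DEG elsewhere,
      non-DEG elsewhere].
    * skew: is the up/down split on the chromosome compatible with the
      genome-wide split? Fisher's exact test on [up on c, down on c;
      up elsewhere, down elsewhere].

    Stars mark padj < ``alpha`` (*) and < ``second_threshold`` (**).
    Chromosomes with no detected genes are excluded (logged). Genes in the
    status map must carry a chromosome in the annotation.
    """
    if test not in ("fisher", "binomial"):
        raise ValueError(f"unknown test {test!r}")
    chrom_of = {g.gene_id: g.chrom for g in annotation}
    missing = [g for g in status.universe if g not in chrom_of]
    if missing:
        raise ValueError(
            f"{len(missing)} genes in the status map lack an annotation "
            f"(e.g. {sorted(missing)[:3]})"
        )
    df = pd.DataFrame(
        {
            "gene_id": list(status.universe),
            "status": [status.status[g] for g in status.universe],
        }
    )
    df["chrom"] = df["gene_id"].map(chrom_of)
    chroms = karyotype_order(set(df["chrom"]))

    total_detected = len(df)
    total_up = int((df["status"] == "up").sum())
    total_down = int((df["status"] == "down").sum())
    total_deg = total_up + total_down
    deg_rate = total_deg / total_detected if total_detected else math.nan
    down_share = total_down / total_deg if total_deg else math.nan
    up_share_detected = total_up / total_detected if total_detected else math.nan

    rows = []
    for c in chroms:
        sub = df[df["chrom"] == c]
        detected = len(sub)
        if detected == 0:
            logger.info("chromosome_distribution: %s has no detected genes, excluded", c)
            continue
        obs_up = int((sub["status"] == "up").sum())
        obs_down = int((sub["status"] == "down").sum())
        obs_deg = obs_up + obs_down
        exp_total = deg_rate * detected
        exp_up = up_share_detected * detected
        exp_down_of_deg = down_share * obs_deg if total_deg else math.nan
        # total family
        if test == "fisher":
            p_total = stats.fisher_exact(
                [[obs_deg, detected - obs_deg],
                 [total_deg - obs_deg, (total_detected - detected) - (total_deg - obs_deg)]]
            ).pvalue
        else:
            p_total = stats.binomtest(obs_deg, detected, deg_rate).pvalue
        # skew family: up vs down composition
        if total_deg and obs_deg:
            if test == "fisher":
                p_skew = stats.fisher_exact(
                    [[obs_up, obs_down], [total_up - obs_up, total_down - obs_down]]
                ).pvalue
            else:
                p_skew = stats.binomtest(obs_up, obs_deg, 1.0 - down_share).pvalue
        else:
            p_skew = math.nan
        rows.append(
            {
                "chrom": c,
                "detected_genes": detected,
                "observed_up": obs_up,
                "observed_down": obs_down,
                "observed_total": obs_deg,
                "expected_total_deg": exp_total,
                "expected_up": exp_up,
                "expected_down_of_deg": exp_down_of_deg,
                "p_total": float(p_total),
                "p_skew": float(p_skew) if not math.isnan(p_skew) else math.nan,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no chromosome has detected genes")
    table["padj_total"] = bh_adjust(table["p_total"])
    table["padj_skew"] = bh_adjust(table["p_skew"])
    thresholds = (alpha, second_threshold)
    table["stars_total"] = [star_code(p, thresholds) for p in table["padj_total"]]
    table["stars_skew"] = [star_code(p, thresholds) for p in table["padj_skew"]]

    rho_total = (
        expectation_correlation(table["expected_total_deg"], table["observed_total"])
        if len(table) >= 3 else math.nan
    )
    rho_up = (
        expectation_correlation(table["expected_up"], table["observed_up"])
        if len(table) >= 3 else math.nan
    )
    return ChromosomeDistribution(
        comparison=status.comparison,
        table=table,
        rho_total=rho_total,
        rho_up=rho_up,
        alpha=alpha,
        second_threshold=second_threshold,
    )
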