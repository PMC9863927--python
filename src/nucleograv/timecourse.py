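"""Temporal statistics over ordered differential-expression comparisons.

Covers four analyses of a DEG time course:

* **coherence** — for two DEG sets of the same direction, the overlap
  fraction of the smaller set divided by its random-drawing expectation;
  1 means random overlap, >> 1 strong coherence, ~ 0 inverted coherence;
* **transition flows** — 3x3 tabulation of per-gene state changes
  (up / down / ns) between consecutive comparisons, the numbers behind a
  Sankey diagram;
* **persistent DEGs** — genes significant with a constant fold-change sign
  in every comparison, with paired t tests of their fold changes against a
  reference comparison;
* **splice discordance** — genes upregulated on the unspliced (nascent)
  track while downregulated on the spliced (mature) track.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .deg_io import DEGStatusMap, DEResultTable, classify_degs
from .mtc import TWO_LEVEL, bh_adjust, star_code

__all__ = [
    "CoherenceResult",
    "TransitionFlow",
    "PersistentDEGSet",
    "SpliceDiscordance",
    "coherence",
    "coherence_matrix",
    "transition_flows",
    "persistent_degs",
    "persistent_fc_tests",
    "splice_discordance",
]

logger = logging.getLogger(__name__)

STATES = ("up", "down", "ns")


@dataclass
class CoherenceResult:
    """Coherence of two same-direction DEG sets over a shared universe."""

    direction: str
    size_small: int
    size_large: int
    overlap: int
    actual_ratio: float
    expected_ratio: float
    coherence: float
    defined: bool = True

    @property
    def percent(self) -> float:
        """The overlap fraction of the smaller set, as a percentage."""
        return 100.0 * self.actual_ratio


def coherence(
    set_a: set[str], set_b: set[str], universe_size: int, direction: str = ""
) -> CoherenceResult:
    """Coherence statistic for two DEG sets of the same direction.

    The overlap is counted against the smaller set (ties: the first
    argument): ``actual = |A ∩ B| / |smaller|``. Under independent random
    labelling the expected value of this ratio is ``|larger| / universe``,
    so ``coherence = actual / expected`` is 1 for random overlap.

    An empty smaller set leaves the statistic undefined (``defined=False``),
    mirroring blank report cells rather than reporting 0.
    """
    if universe_size < 1:
        raise ValueError(f"universe_size must be >= 1, got {universe_size}")
    if len(set_a) <= len(set_b):
        small, large = set_a, set_b
    else:
        small, large = set_b, set_a
    if not small:
        return CoherenceResult(
            direction=direction,
            size_small=0,
            size_large=len(large),
            overlap=0,
            actual_ratio=math.nan,
            expected_ratio=len(large) / universe_size,
            coherence=math.nan,
            defined=False,
        )
    overlap = len(small & large)
    actual = overlap / len(small)
    expected = len(large) / universe_size
    return CoherenceResult(
        direction=direction,
        size_small=len(small),
        size_large=len(large),
        overlap=overlap,
        actual_ratio=actual,
        expected_ratio=expected,
        coherence=actual / expected if expected > 0 else math.nan,
        defined=expected > 0,
    )


def coherence_matrix(
    tables: list[DEResultTable],
    references: list[str],
    alpha: float = 0.05,
    lfc_cutoff: float = 0.0,
    cross_direction: bool = False,
) -> pd.DataFrame:
    """Coherence of every non-reference comparison against each reference.

    The shared universe for each pair is the intersection of the two tables'
    tested genes. Returns a tidy frame with one row per (comparison,
    reference, direction): set sizes, overlap, actual and expected ratios,
    the coherence quotient, and the overlap percentage.

    With ``cross_direction=True``, additional rows compare up-in-comparison
    against down-in-reference (and vice versa) as a diagnostic for inverted
    responses; these carry directions ``up_vs_down`` / ``down_vs_up``.
    """
    labels = [t.comparison for t in tables]
    for ref in references:
        if ref not in labels:
            raise ValueError(f"reference comparison {ref!r} not among tables {labels}")
    by_label = {t.comparison: t for t in tables}
    status = {t.comparison: classify_degs(t, alpha=alpha, lfc_cutoff=lfc_cutoff) for t in tables}
    rows = []
    for comp in labels:
        for ref in references:
            if comp == ref:
                continue
            shared = by_label[comp].universe & by_label[ref].universe
            n = len(shared)
            pairs = [("up", "up"), ("down", "down")]
            if cross_direction:
                pairs += [("up", "down"), ("down", "up")]
            for d_comp, d_ref in pairs:
                a = status[comp].genes(d_comp) & shared
                b = status[ref].genes(d_ref) & shared
                direction = d_comp if d_comp == d_ref else f"{d_comp}_vs_{d_ref}"
                res = coherence(a, b, n, direction=direction)
                rows.append(
                    {
                        "comparison": comp,
                        "reference": ref,
                        "direction": direction,
                        "universe_size": n,
                        "size_small": res.size_small,
                        "size_large": res.size_large,
                        "overlap": res.overlap,
                        "actual_ratio": res.actual_ratio,
                        "expected_ratio": res.expected_ratio,
                        "coherence": res.coherence,
                        "percent": res.percent,
                        "defined": res.defined,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class TransitionFlow:
    """3x3 gene-count flow between the states of two consecutive comparisons."""

    source: str
    target: str
    counts: pd.DataFrame  # index: source state, columns: target state

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(index=STATES, columns=STATES, fill_value=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def transition_flows(status_maps: list[DEGStatusMap]) -> list[TransitionFlow]:
    """Tabulate up/down/ns state transitions between consecutive comparisons.

    Maps with differing universes are restricted to their intersection
    (dropped counts logged). Row sums of each flow equal the source
    comparison's state sizes on the shared universe.
    """
    if len(status_maps) < 2:
        raise ValueError("need at least two status maps")
    flows = []
    for a, b in zip(status_maps, status_maps[1:]):
        shared = a.universe & b.universe
        dropped = len(a.universe | b.universe) - len(shared)
        if dropped:
            logger.info(
                "transition_flows %s->%s: %d genes outside the shared universe dropped",
                a.comparison, b.comparison, dropped,
            )
        counts = pd.DataFrame(0, index=list(STATES), columns=list(STATES))
        for g in shared:
            counts.loc[a.status[g], b.status[g]] += 1
        flows.append(TransitionFlow(source=a.comparison, target=b.comparison, counts=counts))
    return flows


@dataclass
class PersistentDEGSet:
    """Genes significant with constant fold-change sign in every comparison."""

    always_up: list[str]
    always_down: list[str]
    fc_matrix: pd.DataFrame = field(repr=False)  # genes x comparisons, log2fc
    alpha: float = 0.05

    @property
    def n_up(self) -> int:
        return len(self.always_up)

    @property
    def n_down(self) -> int:
        return len(self.always_down)


def persistent_degs(tables: list[DEResultTable], alpha: float = 0.05) -> PersistentDEGSet:
    """Select genes that stay significant with one sign across the series.

    A gene qualifies as always-up when padj < alpha and log2fc > 0 in every
    comparison (always-down analogously with log2fc < 0). The returned
    fold-change matrix is restricted to the qualifying genes, rows ordered
    always_up then always_down.
    """
    if len(tables) < 2:
        raise ValueError("need at least two comparisons")
    shared = set.intersection(*(t.universe for t in tables))
    frames = []
    for t in tables:
        df = t.data.set_index("gene_id").loc[sorted(shared)]
        frames.append(df[["log2fc", "padj"]].rename(
            columns={"log2fc": f"lfc_{t.comparison}", "padj": f"padj_{t.comparison}"}
        ))
    wide = pd.concat(frames, axis=1)
    lfc_cols = [f"lfc_{t.comparison}" for t in tables]
    padj_cols = [f"padj_{t.comparison}" for t in tables]
    lfc = wide[lfc_cols].to_numpy(dtype=float)
    padj = wide[padj_cols].to_numpy(dtype=float)
    sig_all = (~np.isnan(padj) & (padj < alpha)).all(axis=1)
    up = sig_all & (lfc > 0).all(axis=1)
    down = sig_all & (lfc < 0).all(axis=1)
    always_up = list(wide.index[up])
    always_down = list(wide.index[down])
    fc = pd.DataFrame(
        lfc[up | down],
        index=list(wide.index[up]) + list(wide.index[down]),
        columns=[t.comparison for t in tables],
    )
    # preserve up-before-down row order
    fc = fc.loc[always_up + always_down]
    return PersistentDEGSet(
        always_up=always_up, always_down=always_down, fc_matrix=fc, alpha=alpha
    )


def persistent_fc_tests(
    fc_matrix: pd.DataFrame, reference: str, paired: bool = True
) -> pd.DataFrame:
    """Test each comparison's fold changes against a reference comparison.

    The same genes appear in every column, so the default is a paired t test
    (pairing by gene); an unpaired two-sample variant is available. p-values
    are BH-adjusted across the non-reference comparisons; stars mark
    padj < 0.05 (*) and < 0.01 (**).
    """
    if reference not in fc_matrix.columns:
        raise ValueError(f"reference {reference!r} not among comparisons")
    if len(fc_matrix) < 2:
        return pd.DataFrame(
            {
                "comparison": [c for c in fc_matrix.columns if c != reference],
                "t": math.nan,
                "pvalue": math.nan,
                "padj": math.nan,
                "stars": "",
                "defined": False,
            }
        )
    ref = fc_matrix[reference].to_numpy(dtype=float)
    rows = []
    for comp in fc_matrix.columns:
        if comp == reference:
            continue
        x = fc_matrix[comp].to_numpy(dtype=float)
        if np.allclose(x, ref):
            t, p = 0.0, 1.0
        elif paired:
            t, p = stats.ttest_rel(x, ref)
        else:
            t, p = stats.ttest_ind(x, ref)
        rows.append({"comparison": comp, "t": float(t), "pvalue": float(p)})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pvalue"])
    out["stars"] = [star_code(p, TWO_LEVEL) for p in out["padj"]]
    out["defined"] = True
    return out


@dataclass
class SpliceDiscordance:
    """Genes upregulated on the unspliced track but down on the spliced one."""

    comparison: str
    discordant: list[str]
    regular_subset: list[str]
    fraction_regular: float  # NaN when no discordant genes

    @property
    def n_discordant(self) -> int:
        return len(self.discordant)


def splice_discordance(
    spliced: DEResultTable,
    unspliced: DEResultTable,
    regular: DEResultTable,
    alpha: float = 0.05,
) -> SpliceDiscordance:
    """Find "unspliced up, spliced down" genes for one comparison.

    Returns the discordant gene set, its intersection with the regular
    track's DEGs (either direction), and that subset's fraction of the
    discordant set (undefined when the set is empty).
    """
    s_status = classify_degs(spliced, alpha=alpha)
    u_status = classify_degs(unspliced, alpha=alpha)
    r_status = classify_degs(regular, alpha=alpha)
    discordant = sorted(u_status.up & s_status.down)
    regular_deg = r_status.up | r_status.down
    subset = sorted(set(discordant) & regular_deg)
    frac = len(subset) / len(discordant) if discordant else math.nan
    return SpliceDiscordance(
        comparison=regular.comparison,
        discordant=discordant,
        regular_subset=subset,
        fraction_regular=frac,
    )
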