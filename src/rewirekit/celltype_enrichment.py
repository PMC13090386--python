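"""Cell-type enrichment of variant-affected genes and network summaries.

A transcript is "altered" in a cell type when its promoter participates in
a concordant rewiring event, the transcript is expressed in that cell type,
and at least one transcription factor whose binding the event's variant
perturbs is expressed there too. Altered-gene proportions are compared
between cohorts per cell type, separately for promoter events (test 1) and
enhancer events (test 2, run for concordant and discordant classes), and
stratified by minor allele frequency:

* MAFa (rare)            [0, 2%)
* MAFb (moderately rare) [2%, 4%)
* MAFc (common)          [4%, 10%)  — the upstream cohort filter caps at 10%

Each (stratum, component, class) family is BH-corrected across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .allelic_imbalance import bh_fdr
from .core_model import Cohort
from .rewiring_engine import ContingencyTable2x2, RewiringEvent, fisher_two_tailed


@dataclass(eq=False)
class ExpressionProfile:
    """Mean expression per gene x cell type, with optional DE flags."""

    mean: pd.DataFrame  # genes x cell types, non-negative
    de_flags: pd.DataFrame | None = None  # same shape, boolean

    def __post_init__(self) -> None:
        if (self.mean.values < 0).any():
            raise ValueError("expression must be non-negative")
        if self.de_flags is not None:
            if not self.de_flags.index.equals(self.mean.index) or not self.de_flags.columns.equals(
                self.mean.columns
            ):
                raise ValueError("de_flags must be defined for every (gene, cell type)")

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean.columns)

    def expressed(self, cell_type: str, floor: float = 0.0) -> set[str]:
        col = self.mean[cell_type]
        keep = col > floor
        if self.de_flags is not None:
            keep &= self.de_flags[cell_type]
        return set(col.index[keep])


@dataclass(frozen=True)
class MafStratum:
    label: str
    low: float   # inclusive
    high: float  # exclusive


DEFAULT_STRATA = (
    MafStratum("MAFa", 0.0, 0.02),
    MafStratum("MAFb", 0.02, 0.04),
    MafStratum("MAFc", 0.04, 0.10),
)


def stratify_by_maf(
    events: Sequence[RewiringEvent], strata: Sequence[MafStratum] = DEFAULT_STRATA
) -> dict[str, list[RewiringEvent]]:
    """Bin events into half-open MAF strata; every event lands in exactly one."""
    out: dict[str, list[RewiringEvent]] = {s.label: [] for s in strata}
    top = max(s.high for s in strata)
    for e in events:
        maf = e.variant.maf
        if maf >= top:
            raise ValueError(f"variant MAF {maf} >= {top}: violates the upstream cohort filter")
        for s in strata:
            if s.low <= maf < s.high:
                out[s.label].append(e)
                break
        else:
            raise ValueError(f"MAF {maf} falls in no stratum")
    return out


def flag_de_genes(
    cells: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene differential expression flags, one cell type vs all others.

    ``cells`` maps cell type -> genes x cells expression matrix. Each gene is
    tested with a two-sided Wilcoxon rank-sum test against the pooled other
    cell types; the flag requires BH q < alpha within the cell type and a
    higher in-group median. Constant genes are unflagged.
    """
    cell_types = list(cells)
    if len(cell_types) < 2:
        raise ValueError("need at least two cell types")
    genes = cells[cell_types[0]].index
    flags = pd.DataFrame(False, index=genes, columns=cell_types)
    mats = {ct: cells[ct].loc[genes].to_numpy() for ct in cell_types}
    for ct in cell_types:
        x = mats[ct]
        y = np.hstack([mats[o] for o in cell_types if o != ct])
        constant = (np.ptp(x, axis=1) == 0) & (np.ptp(y, axis=1) == 0) & (
            x[:, :1] == y[:, :1]
        ).ravel()
        with np.errstate(all="ignore"):
            _, p = mannwhitneyu(x, y, axis=1, alternative="two-sided")
        p = np.where(constant, 1.0, p)
        q = np.asarray(bh_fdr(p))
        higher = np.median(x, axis=1) > np.median(y, axis=1)
        flags[ct] = (q < alpha) & higher
    return flags


def altered_transcripts(
    events: Sequence[RewiringEvent],
    expression: ExpressionProfile,
    tf_map: Mapping[str, Sequence[str]],
    cell_type: str,
    *,
    expression_floor: float = 0.0,
    counters: dict | None = None,
) -> set[str]:
    """Genes altered in one cell type by concordant events.

    ``tf_map`` maps a variant key to the TF genes whose motifs it perturbs.
    A gene qualifies iff it belongs to a concordant event's promoter anchor,
    is expressed above the floor (and DE-flagged when flags are present),
    and at least one perturbed TF of the event is expressed there. Events
    lacking motif annotation are excluded and counted.
    """
    if counters is None:
        counters = {}
    counters.setdefault("events_without_motif_annotation", 0)
    expressed = expression.expressed(cell_type, expression_floor)
    # TF expression ignores DE flags: the TF merely needs to be present
    tf_expressed = set(
        expression.mean.index[expression.mean[cell_type] > expression_floor]
    )
    out: set[str] = set()
    for e in events:
        if e.concordance != "concordant":
            continue
        tfs = tf_map.get(e.variant.key)
        if not tfs:
            counters["events_without_motif_annotation"] += 1
            continue
        if not any(tf in tf_expressed for tf in tfs):
            continue
        out.update(g for g in e.genes if g in expressed)
    return out


@dataclass
class EnrichmentResult:
    cell_type: str
    stratum: str
    component: str
    concordance: str
    table: ContingencyTable2x2
    odds_ratio: float
    p: float
    q: float


def _enrichment(
    events: Sequence[RewiringEvent],
    expression: ExpressionProfile,
    tf_map: Mapping[str, Sequence[str]],
    cohort: Cohort,
    component: str,
    concordance_class: str,
    strata: Sequence[MafStratum],
    expression_floor: float,
) -> list[EnrichmentResult]:
    subset = [e for e in events if e.component == component and e.concordance == concordance_class]
    case_events = [e for e in subset if e.cohort == "case_specific"]
    control_events = [e for e in subset if e.cohort == "control_specific"]
    results: list[EnrichmentResult] = []
    for stratum_label, case_s in stratify_by_maf(case_events, strata).items():
        control_s = stratify_by_maf(control_events, strata)[stratum_label]
        fam: list[EnrichmentResult] = []
        for ct in expression.cell_types:
            expressed = expression.expressed(ct, expression_floor)
            if not expressed:
                continue
            # altered_transcripts keys on concordant events; for the
            # discordant class the same expression/TF gating is applied here
            case_alt = _altered(case_s, expression, tf_map, ct, expression_floor)
            control_alt = _altered(control_s, expression, tf_map, ct, expression_floor)
            tab = ContingencyTable2x2(
                len(case_alt), len(expressed - case_alt),
                len(control_alt), len(expressed - control_alt),
            )
            try:
                oddsratio, p = fisher_two_tailed(tab)
            except ValueError:
                oddsratio, p = float("nan"), 1.0
            fam.append(
                EnrichmentResult(ct, stratum_label, component, concordance_class, tab, oddsratio, p, 1.0)
            )
        for r, q in zip(fam, bh_fdr([r.p for r in fam])):
            r.q = q
        results.extend(fam)
    return results


def _altered(events, expression, tf_map, cell_type, floor) -> set[str]:
    expressed = expression.expressed(cell_type, floor)
    tf_expressed = set(expression.mean.index[expression.mean[cell_type] > floor])
    out: set[str] = set()
    for e in events:
        tfs = tf_map.get(e.variant.key)
        if not tfs or not any(tf in tf_expressed for tf in tfs):
            continue
        out.update(g for g in e.genes if g in expressed)
    return out


def enrichment_test1(
    events: Sequence[RewiringEvent],
    expression: ExpressionProfile,
    tf_map: Mapping[str, Sequence[str]],
    cohort: Cohort,
    strata: Sequence[MafStratum] = DEFAULT_STRATA,
    *,
    expression_floor: float = 0.0,
) -> list[EnrichmentResult]:
    """Promoter-event enrichment: altered-gene proportions, case vs control.

    Per cell type and MAF stratum, a two-tailed Fisher exact test on
    [altered case genes, expressed-not-altered; same for controls], BH
    across cell types within the stratum.
    """
    return _enrichment(
        events, expression, tf_map, cohort, "promoter", "concordant", strata, expression_floor
    )


def enrichment_test2(
    events: Sequence[RewiringEvent],
    expression: ExpressionProfile,
    tf_map: Mapping[str, Sequence[str]],
    cohort: Cohort,
    strata: Sequence[MafStratum] = DEFAULT_STRATA,
    *,
    expression_floor: float = 0.0,
) -> list[EnrichmentResult]:
    """Enhancer-event enrichment, run separately per concordance class."""
    out = []
    for cls in ("concordant", "discordant"):
        out.extend(
            _enrichment(events, expression, tf_map, cohort, "enhancer", cls, strata, expression_floor)
        )
    return out


def network_degree_stats(
    nodes: Sequence[str], edges: Iterable[tuple[str, str]]
) -> tuple[int, int, float]:
    """(n_nodes, n_edges, average degree) with average = 2|E|/|V| to 2 d.p.

    Duplicate edges are deduplicated as unordered pairs; self-loops and
    edges naming unlisted nodes are rejected.
    """
    node_set = set(nodes)
    if not node_set:
        raise ValueError("empty node list")
    dedup = set()
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop at {u}")
        if u not in node_set or v not in node_set:
            raise ValueError(f"edge ({u}, {v}) references unlisted node")
        dedup.add((u, v) if u <= v else (v, u))
    n, m = len(node_set), len(dedup)
    return n, m, round(2 * m / n, 2)
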