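"""Post-calling interaction filters and cohort-level interaction summaries.

Interaction calls come pre-filtered for statistical significance by the
capture Hi-C caller; this module applies the downstream quality filters —
supporting-pair count, adjusted p, trans removal, long-range removal and
fragment-length caps — and summarises what each cohort retains.

Boundary semantics follow the filter definitions exactly: support uses
">= keep", adjusted p uses "< keep", distance and fragment length use
">= drop".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .core_model import Cohort, Interaction

RULE_ORDER = ("support", "p", "trans", "distance", "fragment")


@dataclass
class QcThresholds:
    """Interaction QC thresholds.

    Defaults: >= 5 supporting pairs, Bonferroni-adjusted p < 0.05, cis only,
    midpoint distance < 5 Mb, both fragments < 7500 bp.
    """

    min_support: int = 5
    max_adj_p: float = 0.05
    max_distance: int = 5_000_000
    max_fragment_len: int = 7_500

    def __post_init__(self) -> None:
        for f in ("min_support", "max_adj_p", "max_distance", "max_fragment_len"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")


def _first_failing_rule(i: Interaction, t: QcThresholds) -> str | None:
    if i.support_pairs < t.min_support:
        return "support"
    if not (i.adj_p < t.max_adj_p):
        return "p"
    if i.trans:
        return "trans"
    if i.distance is not None and i.distance >= t.max_distance:
        return "distance"
    if i.promoter.fragment_len >= t.max_fragment_len or i.pir.fragment_len >= t.max_fragment_len:
        return "fragment"
    return None


def filter_interactions(
    interactions: list[Interaction], thresholds: QcThresholds | None = None
) -> tuple[list[Interaction], dict[str, int]]:
    """Apply all QC rules; return kept interactions and per-rule drop counts.

    Dropped interactions are attributed to the first failing rule in the
    fixed order support, p, trans, distance, fragment, so the counts
    partition the removed set.
    """
    t = thresholds or QcThresholds()
    kept: list[Interaction] = []
    drops: Counter[str] = Counter({r: 0 for r in RULE_ORDER})
    for i in interactions:
        rule = _first_failing_rule(i, t)
        if rule is None:
            kept.append(i)
        else:
            drops[rule] += 1
    return kept, dict(drops)


@dataclass
class CohortInteractionSummary:
    case_specific_interactions: int
    control_specific_interactions: int
    shared_interactions: int
    case_specific_genes: int
    control_specific_genes: int
    case_specific_enhancers: int
    control_specific_enhancers: int
    case_control_ratio: float | None  # specific-interaction ratio, 1 d.p.; None if undefined


def interaction_ratio(n_case: int, n_control: int) -> float:
    """Case:control interaction-count ratio reported to one decimal."""
    if n_control == 0:
        raise ZeroDivisionError("control count is zero; ratio undefined")
    return round(n_case / n_control, 1)


def cohort_interaction_summary(
    kept: list[Interaction], cohort: Cohort
) -> CohortInteractionSummary:
    """Per-group unique interaction/gene/enhancer counts after QC.

    Uniqueness key is the (promoter region, PIR region) pair; an interaction
    is group-specific when observed only in patients of that group. Genes are
    taken from the promoter anchors of group-specific interactions and
    enhancers from their PIR anchors.
    """
    cases, controls = cohort.cases, cohort.controls
    by_key: dict[tuple, set[str]] = {}
    promoters: dict[tuple, Interaction] = {}
    for i in kept:
        by_key.setdefault(i.key, set()).add(i.patient)
        promoters.setdefault(i.key, i)

    def specific(group: set[str]) -> set[tuple]:
        return {k for k, pats in by_key.items() if pats and pats <= group}

    case_keys = specific(cases)
    control_keys = specific(controls)
    shared = set(by_key) - case_keys - control_keys

    def genes(keys):
        return {g for k in keys for g in promoters[k].promoter.gene_ids}

    def enhancers(keys):
        return {promoters[k].pir.key for k in keys}

    if case_keys and control_keys:
        ratio = interaction_ratio(len(case_keys), len(control_keys))
    else:
        ratio = None
    return CohortInteractionSummary(
        case_specific_interactions=len(case_keys),
        control_specific_interactions=len(control_keys),
        shared_interactions=len(shared),
        case_specific_genes=len(genes(case_keys)),
        control_specific_genes=len(genes(control_keys)),
        case_specific_enhancers=len(enhancers(case_keys)),
        control_specific_enhancers=len(enhancers(control_keys)),
        case_control_ratio=ratio,
    )
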