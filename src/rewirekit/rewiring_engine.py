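"""Rewiring event classification and cohort summary statistics.

A rare variant splits the cohort into carriers (alt dosage >= 1) and
non-carriers. For each promoter-enhancer interaction whose promoter or PIR
anchor overlaps the variant, the set of patients in whom the interaction
passed QC ("presence") is compared with the carrier set:

* presence within carriers only      -> gain-of-interaction, concordant
* presence within non-carriers only  -> loss-of-interaction, concordant
* presence spanning both classes     -> discordant (direction by the
  majority presence rate; ties go to gain-of-interaction)

Concordance uses subset semantics — the interaction is rewired exclusively
in one genotype class — with strict equality (presence == carriers or
== non-carriers) available behind ``concordance="equality"``.

Cohort specificity of an event follows its carrier set: entirely within
cases, entirely within controls, or shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from scipy.stats import fisher_exact

from .core_model import (
    Cohort,
    GeneAnnotation,
    Interaction,
    RegulatoryRegion,
    Variant,
    overlap_variants_regions,
)

Direction = Literal["GoI", "LoI"]
Concordance = Literal["concordant", "discordant"]
Specificity = Literal["case_specific", "control_specific", "shared"]


@dataclass
class RewiringEvent:
    variant: Variant
    interaction_key: tuple
    component: Literal["promoter", "enhancer"]
    direction: Direction
    concordance: Concordance
    cohort: Specificity
    carriers: frozenset[str]
    presence: frozenset[str]
    genes: tuple[str, ...]


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in 2x2 table")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty 2x2 table")


def classify_event(
    carriers: set[str],
    presence: set[str],
    all_patients: set[str],
    *,
    concordance: Literal["subset", "equality"] = "subset",
) -> tuple[Direction, Concordance] | None:
    """Classify one (variant, interaction) pair; None if uninformative.

    Requires a genotype contrast: an empty carrier set or carriers covering
    every patient yields no event.
    """
    if not carriers or carriers >= all_patients:
        return None
    if not presence or not presence <= all_patients:
        raise ValueError("presence must be a non-empty subset of the cohort")
    noncarriers = all_patients - carriers
    in_c = presence & carriers
    in_n = presence & noncarriers
    if not in_n:
        if concordance == "equality" and presence != carriers:
            return ("GoI", "discordant")
        return ("GoI", "concordant")
    if not in_c:
        if concordance == "equality" and presence != noncarriers:
            return ("LoI", "discordant")
        return ("LoI", "concordant")
    # presence spans both genotype classes: discordant, direction by majority rate
    rate_c = len(in_c) / len(carriers)
    rate_n = len(in_n) / len(noncarriers)
    return ("GoI" if rate_c >= rate_n else "LoI", "discordant")


def assign_cohort_specificity(carriers: set[str], cohort: Cohort) -> Specificity:
    if not carriers:
        raise ValueError("carriers must be non-empty")
    if carriers <= cohort.cases:
        return "case_specific"
    if carriers <= cohort.controls:
        return "control_specific"
    return "shared"


def enumerate_events(
    variants: Sequence[Variant],
    kept_interactions: Sequence[Interaction],
    regions: Sequence[RegulatoryRegion],
    cohort: Cohort,
    *,
    concordance: Literal["subset", "equality"] = "subset",
) -> list[RewiringEvent]:
    """One event per (variant, interaction pair) whose anchor the variant hits.

    ``regions`` supplies the gene annotation of promoter anchors; anchors are
    matched to regions by exact coordinates. ``presence`` is the set of
    patients in whom the interaction passed QC. A variant overlapping both
    anchors of the same pair yields one event per component.
    """
    all_patients = set(cohort.patients)
    region_by_key = {r.key: r for r in regions}

    # presence sets and one representative interaction per unique pair
    presence: dict[tuple, set[str]] = {}
    rep: dict[tuple, Interaction] = {}
    for i in kept_interactions:
        presence.setdefault(i.key, set()).add(i.patient)
        rep.setdefault(i.key, i)

    # anchors indexed by the region coordinate key they occupy
    anchors: dict[tuple, list[tuple[tuple, str]]] = {}
    for k, i in rep.items():
        anchors.setdefault(i.promoter.key, []).append((k, "promoter"))
        anchors.setdefault(i.pir.key, []).append((k, "enhancer"))

    anchor_regions = [region_by_key.get(rk) or _bare_region(rk) for rk in anchors]
    hits = overlap_variants_regions(variants, anchor_regions)

    events: list[RewiringEvent] = []
    for v in variants:
        if v not in hits:
            continue
        carriers = v.carriers()
        if not carriers or carriers >= all_patients:
            continue
        seen: set[tuple] = set()
        for region, _role in hits[v]:
            for key, component in anchors[region.key]:
                if (key, component) in seen:
                    continue
                seen.add((key, component))
                label = classify_event(carriers, presence[key], all_patients, concordance=concordance)
                if label is None:
                    continue
                direction, conc = label
                prom_key = rep[key].promoter.key
                prom_region = region_by_key.get(prom_key)
                genes = prom_region.gene_ids if prom_region is not None else ()
                events.append(
                    RewiringEvent(
                        variant=v,
                        interaction_key=key,
                        component=component,
                        direction=direction,
                        concordance=conc,
                        cohort=assign_cohort_specificity(carriers, cohort),
                        carriers=frozenset(carriers),
                        presence=frozenset(presence[key]),
                        genes=tuple(genes),
                    )
                )
    return events


def _bare_region(key: tuple) -> RegulatoryRegion:
    chrom, start, end = key
    return RegulatoryRegion(chrom, start, end, "enhancer")


# ---------------------------------------------------------------------------
# Fisher tests and the cohort summary


def fisher_two_tailed(table: ContingencyTable2x2) -> tuple[float, float]:
    """Sample cross-product odds ratio and two-sided Fisher exact p.

    OR = (a*d)/(b*c); +inf when b*c == 0 with a*d > 0; 0/0 raises. The p
    follows the hypergeometric point-probability rule.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        if a * d == 0:
            raise ValueError("odds ratio undefined (0/0 table)")
        oddsratio = math.inf
    else:
        oddsratio = (a * d) / (b * c)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return oddsratio, float(p)


def rate_ratio(table: ContingencyTable2x2) -> float:
    """Prevalence fold change (a/b) / (c/d) between the two rows."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if b == 0 or c == 0 or d == 0:
        raise ValueError("rate ratio undefined with a zero denominator")
    return (a / b) / (c / d)


def share_percent(part: int, total: int, ndigits: int = 2) -> float:
    """Percentage share rounded to ``ndigits`` decimals; 0.00 for empty part."""
    if total == 0:
        raise ValueError("empty total")
    return round(100 * part / total, ndigits)


@dataclass
class Table1Summary:
    """Cohort-level numerical overview of the event filtering."""

    # counts[(specificity, component, concordance)] -> n events
    counts: dict[tuple, int]
    # per-specificity LoI/GoI counts among concordant events
    loi_goi: dict[str, tuple[int, int]]
    # per-specificity concordant LoI share, percent to 2 d.p.
    loi_share: dict[str, float]
    goi_share_concordant: float | None
    tier_vs_housekeeping: dict[str, dict] = field(default_factory=dict)


def loi_goi_shares(loi: int, goi: int) -> tuple[float, float]:
    """(LoI share %, GoI share %) of concordant events, 2 d.p."""
    total = loi + goi
    return share_percent(loi, total), share_percent(goi, total)


def goi_share_of_concordant(
    case_loi: int, case_goi: int, control_loi: int, control_goi: int
) -> float:
    """GoI percentage among all concordant events of both cohorts, 1 d.p."""
    goi = case_goi + control_goi
    total = case_loi + case_goi + control_loi + control_goi
    return share_percent(goi, total, ndigits=1)


def table1_summary(
    events: Sequence[RewiringEvent],
    gene_annotation: Mapping[str, GeneAnnotation] | None = None,
) -> Table1Summary:
    """Event counts per cohort-specificity, component and concordance,
    LoI/GoI breakdown of concordant events, and tier-vs-housekeeping
    enrichment (Fisher) for the concordant and discordant sets."""
    counts: dict[tuple, int] = {}
    loi_goi: dict[str, list[int]] = {}
    for e in events:
        k = (e.cohort, e.component, e.concordance)
        counts[k] = counts.get(k, 0) + 1
        if e.concordance == "concordant":
            lg = loi_goi.setdefault(e.cohort, [0, 0])
            lg[0 if e.direction == "LoI" else 1] += 1

    loi_share = {
        spc: share_percent(lg[0], lg[0] + lg[1]) for spc, lg in loi_goi.items() if sum(lg)
    }
    specs = ("case_specific", "control_specific")
    if all(s in loi_goi for s in specs):
        goi_share = goi_share_of_concordant(
            loi_goi["case_specific"][0], loi_goi["case_specific"][1],
            loi_goi["control_specific"][0], loi_goi["control_specific"][1],
        )
    else:
        goi_share = None

    tier_vs_hk: dict[str, dict] = {}
    if gene_annotation is not None:
        for conc in ("concordant", "discordant"):
            tab = _tier_housekeeping_table(events, gene_annotation, conc)
            if tab is not None:
                oddsratio, p = fisher_two_tailed(tab)
                tier_vs_hk[conc] = {
                    "table": (tab.a, tab.b, tab.c, tab.d),
                    "odds_ratio": oddsratio,
                    "p": p,
                    "rate_ratio": rate_ratio(tab),
                }

    return Table1Summary(
        counts=counts,
        loi_goi={k: tuple(v) for k, v in loi_goi.items()},
        loi_share=loi_share,
        goi_share_concordant=goi_share,
        tier_vs_housekeeping=tier_vs_hk,
    )


def _tier_housekeeping_table(
    events: Sequence[RewiringEvent],
    annotation: Mapping[str, GeneAnnotation],
    concordance: str,
) -> ContingencyTable2x2 | None:
    """Rows case/control, columns tier1-2 vs housekeeping event gene counts."""
    cells = {("case_specific", True): 0, ("case_specific", False): 0,
             ("control_specific", True): 0, ("control_specific", False): 0}
    for e in events:
        if e.concordance != concordance or e.cohort == "shared":
            continue
        for g in e.genes:
            ann = annotation.get(g)
            if ann is None:
                continue
            if ann.tier in ("tier1", "tier2"):
                cells[(e.cohort, True)] += 1
            elif ann.housekeeping:
                cells[(e.cohort, False)] += 1
    a = cells[("case_specific", True)]
    b = cells[("case_specific", False)]
    c = cells[("control_specific", True)]
    d = cells[("control_specific", False)]
    if a + b + c + d == 0:
        return None
    return ContingencyTable2x2(a, b, c, d)
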