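"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: two patient
groups (8 cases / 8 controls by default), heterozygous rare variants with
configurable minor-allele-frequency strata, patient-specific promoter-
enhancer interaction sets with planted concordant gain/loss-of-interaction
events, overdispersed allelic read counts with planted imbalance, and
single-cell style expression with planted differential expression and a
planted cell-type burden.

The genome is an abstract single chromosome. Promoters and enhancers are
disjoint intervals; planted events get dedicated promoter/enhancer pairs
that background interactions never touch, so in the noiseless setting the
planted labels are recoverable exactly and no chance concordant event can
arise (background interactions are present in every patient, which always
classifies as discordant).

A single root seed drives independent per-stage substreams, so any stage
can be regenerated in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .celltype_enrichment import ExpressionProfile
from .core_model import (
    AllelicCount,
    Cohort,
    GeneAnnotation,
    Interaction,
    RegulatoryRegion,
    Variant,
    write_allelic_counts,
    write_gene_table,
    write_interactions_tsv,
    write_regions_bed,
    write_variants_vcf,
)

CHROM = "chr1"
_PROM_SPACING, _PROM_LEN = 2000, 800
_ENH_SPACING, _ENH_LEN = 1500, 600

MAF_RANGES = {"MAFa": (0.0, 0.02), "MAFb": (0.02, 0.04), "MAFc": (0.04, 0.10)}


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the emulated design: 8 + 8 patients, rare heterozygous
    variants spread over the three MAF strata, concordant events planted as
    carrier-defined interaction presence, beta-binomial allelic counts and
    log-normal expression with a case-specific cell-type burden.
    """

    n_case: int = 8
    n_control: int = 8
    n_genes: int = 500
    n_promoters: int | None = None  # one per gene when None
    n_enhancers: int = 1500
    n_variants: int = 2000
    maf_stratum_props: dict = field(
        default_factory=lambda: {"MAFa": 0.5, "MAFb": 0.3, "MAFc": 0.2}
    )
    n_planted_goi: int = 50
    n_planted_loi: int = 20
    n_planted_discordant: int = 30
    interaction_background_rate: float = 0.2  # per promoter x candidate enhancer
    presence_noise: float = 0.0  # per-patient presence flip rate on planted events
    # allelic imbalance stage
    n_imbalanced_genes: int = 5
    n_ase_null_genes: int = 200
    ase_alt_fraction: float = 0.8
    ase_rho: float = 0.1
    ase_snvs_per_gene: int = 5
    ase_patients_per_gene: int = 4
    ase_mean_depth: float = 60.0
    # expression stage
    n_cell_types: int = 5
    cells_per_type: int = 100
    de_effect_size: float = 2.0
    n_de_per_type: int = 20
    # planted cell-type burden (enrichment stage); odds 1 = null. The
    # default is strong enough that the planted burden is recoverable by
    # construction at the default event counts (case event genes are
    # expressed in the target cell type with probability ~1).
    target_cell_type: str = "CT1"
    burden_odds: float = 10.0
    base_expression_prob: float = 0.3
    # motif stage
    n_tfs: int = 20
    n_tf_families: int = 5
    motif_burden_family: str | None = "FAM1"
    motif_burden_odds: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_promoters is None:
            self.n_promoters = self.n_genes
        if min(self.n_case, self.n_control) < 1:
            raise ValueError("both groups must be non-empty")
        n_planted = self.n_planted_goi + self.n_planted_loi + self.n_planted_discordant
        if n_planted > min(self.n_promoters, self.n_enhancers):
            raise ValueError(
                "more planted events than dedicated promoter/enhancer slots"
            )
        if n_planted > self.n_variants:
            raise ValueError("more planted events than variants")
        if not math.isclose(sum(self.maf_stratum_props.values()), 1.0, rel_tol=1e-6):
            raise ValueError("maf_stratum_props must sum to 1")


@dataclass
class SimBundle:
    """In-memory output of one simulation, writable as the text dialects."""

    config: SimConfig
    cohort: Cohort
    variants: list[Variant]
    interactions: list[Interaction]
    regions: list[RegulatoryRegion]
    gene_table: list[GeneAnnotation]
    counts: list[AllelicCount]
    expression: ExpressionProfile
    cell_matrices: dict[str, pd.DataFrame]
    impacts: pd.DataFrame  # variant, pwm, tf, family, call, group
    tf_map: dict[str, list[str]]
    truth_events: pd.DataFrame
    truth_ase: pd.DataFrame
    truth_de: pd.DataFrame
    truth_burden: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_variants_vcf(self.variants, out / "variants.vcf", self.cohort)
        write_interactions_tsv(self.interactions, out / "interactions.tsv")
        write_regions_bed(self.regions, out / "regions.bed")
        write_gene_table(self.gene_table, out / "genes.tsv")
        write_allelic_counts(self.counts, out / "counts.tsv")
        self.expression.mean.to_csv(out / "expression_mean.tsv", sep="\t")
        self.impacts.to_csv(out / "impacts.tsv", sep="\t", index=False)
        self.truth_events.to_csv(out / "truth_events.tsv", sep="\t", index=False)
        self.truth_ase.to_csv(out / "truth_ase.tsv", sep="\t", index=False)
        self.truth_de.to_csv(out / "truth_de.tsv", sep="\t", index=False)
        with open(out / "truth_burden.json", "w") as fh:
            json.dump(self.truth_burden, fh, indent=2)
        with open(out / "cohort.json", "w") as fh:
            json.dump({"patients": self.cohort.patients, "group": self.cohort.group}, fh, indent=2)
        with open(out / "sim_config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)


def _promoter(i: int, gene: str) -> RegulatoryRegion:
    start = i * _PROM_SPACING
    return RegulatoryRegion(CHROM, start, start + _PROM_LEN, "promoter",
                            name=f"prom{i:05d}", gene_ids=(gene,))


def _enhancer(j: int, offset: int) -> RegulatoryRegion:
    start = offset + j * _ENH_SPACING
    return RegulatoryRegion(CHROM, start, start + _ENH_LEN, "enhancer", name=f"enh{j:05d}")


def _sample_maf(rng: np.random.Generator, props: dict) -> float:
    labels = sorted(props)
    stratum = labels[rng.choice(len(labels), p=[props[l] for l in labels])]
    lo, hi = MAF_RANGES[stratum]
    return float(rng.uniform(lo, hi))


def _majority_direction(carriers: set, presence: set, all_patients: set) -> str:
    noncarriers = all_patients - carriers
    in_c, in_n = presence & carriers, presence & noncarriers
    if not in_n:
        return "GoI"
    if not in_c:
        return "LoI"
    return "GoI" if len(in_c) / len(carriers) >= len(in_n) / len(noncarriers) else "LoI"


def simulate_cohort(config: SimConfig) -> SimBundle:
    """Generate the full bundle; deterministic given ``config.seed``."""
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_events, rng_var, rng_bg, rng_ase, rng_expr, rng_motif = (
        np.random.default_rng(s) for s in streams
    )

    cases = [f"BAV{i+1:02d}" for i in range(cfg.n_case)]
    controls = [f"TAV{i+1:02d}" for i in range(cfg.n_control)]
    cohort = Cohort(
        patients=cases + controls,
        group={**{p: "case" for p in cases}, **{p: "control" for p in controls}},
    )
    all_patients = set(cohort.patients)

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    tfs = [f"TF{i:03d}" for i in range(cfg.n_tfs)]
    families = {tf: f"FAM{i % cfg.n_tf_families + 1}" for i, tf in enumerate(tfs)}
    gene_table = _make_gene_table(genes, tfs, rng_bg)

    promoters = [_promoter(i, genes[i % cfg.n_genes]) for i in range(cfg.n_promoters)]
    enh_offset = cfg.n_promoters * _PROM_SPACING + 10_000
    enhancers = [_enhancer(j, enh_offset) for j in range(cfg.n_enhancers)]
    regions = promoters + enhancers

    # --- planted events: dedicated promoter/enhancer pairs, never reused ---
    n_planted = cfg.n_planted_goi + cfg.n_planted_loi + cfg.n_planted_discordant
    prom_idx = rng_events.permutation(cfg.n_promoters)
    enh_idx = rng_events.permutation(cfg.n_enhancers)
    planted_proms = prom_idx[:n_planted]
    planted_enhs = enh_idx[:n_planted]
    free_proms = prom_idx[n_planted:]
    free_enhs = enh_idx[n_planted:]

    kinds = (["GoI_concordant"] * cfg.n_planted_goi
             + ["LoI_concordant"] * cfg.n_planted_loi
             + ["discordant"] * cfg.n_planted_discordant)

    variants: list[Variant] = []
    interactions: list[Interaction] = []
    truth_rows = []
    tf_map: dict[str, list[str]] = {}
    impact_rows = []

    for k, kind in enumerate(kinds):
        prom = promoters[planted_proms[k]]
        enh = enhancers[planted_enhs[k]]
        component = "promoter" if k % 2 == 0 else "enhancer"
        anchor = prom if component == "promoter" else enh
        group = cases if (k // 2) % 2 == 0 else controls
        n_carriers = int(rng_events.integers(1, 4))
        carriers = set(rng_events.choice(group, size=n_carriers, replace=False))

        if kind == "GoI_concordant":
            presence = set(carriers)
        elif kind == "LoI_concordant":
            presence = all_patients - carriers
        else:
            noncar = sorted(all_patients - carriers)
            presence = {sorted(carriers)[0], noncar[int(rng_events.integers(len(noncar)))]}
        if cfg.presence_noise > 0:
            flip = rng_events.random(len(cohort.patients)) < cfg.presence_noise
            for p, f in zip(cohort.patients, flip):
                if f:
                    presence.symmetric_difference_update({p})
            presence = presence or set(carriers)

        pos = int(rng_events.integers(anchor.start, anchor.end))
        genotypes = {p: (1 if p in carriers else 0) for p in cohort.patients}
        v = Variant(
            chrom=CHROM, pos=pos, end=pos + 1,
            ref="A", alt="G",
            maf=_sample_maf(rng_events, cfg.maf_stratum_props),
            genotypes=genotypes,
        )
        variants.append(v)
        for p in sorted(presence):
            interactions.append(_interaction(p, prom, enh, rng_events))

        direction = (
            "GoI" if kind == "GoI_concordant"
            else "LoI" if kind == "LoI_concordant"
            else _majority_direction(carriers, presence, all_patients)
        )
        concordance = "discordant" if kind == "discordant" else "concordant"
        specificity = "case_specific" if group is cases else "control_specific"
        tf = tfs[k % cfg.n_tfs]
        tf_map[v.key] = [tf]
        impact_rows.append(
            {"variant": v.key, "pwm": f"{tf}_PWM", "tf": tf, "family": families[tf],
             "call": "GoM" if direction == "GoI" else "LoM",
             "group": "case" if specificity == "case_specific" else "control"}
        )
        truth_rows.append(
            {
                "variant": v.key,
                "prom_chrom": prom.chrom, "prom_start": prom.start, "prom_end": prom.end,
                "enh_chrom": enh.chrom, "enh_start": enh.start, "enh_end": enh.end,
                "component": component, "direction": direction,
                "concordance": concordance, "cohort": specificity,
                "gene": prom.gene_ids[0], "tf": tf,
                "carriers": ",".join(sorted(carriers)),
            }
        )

    truth_events = pd.DataFrame(truth_rows)

    # --- background interactions: present in every patient ---
    bg_pairs = []
    n_cand = min(5, len(free_enhs))
    for pi in free_proms:
        cand = rng_bg.choice(free_enhs, size=n_cand, replace=False)
        for ej in cand:
            if rng_bg.random() < cfg.interaction_background_rate:
                bg_pairs.append((pi, ej))
    for pi, ej in bg_pairs:
        for p in cohort.patients:
            interactions.append(_interaction(p, promoters[pi], enhancers[ej], rng_bg))

    # --- background variants: in background anchors or in gaps ---
    n_background_variants = cfg.n_variants - n_planted
    gap_lo = cfg.n_promoters * _PROM_SPACING + 1000
    gap_hi = gap_lo + 8000
    bg_anchor_regions = [promoters[pi] for pi, _ in bg_pairs] + [
        enhancers[ej] for _, ej in bg_pairs
    ]
    used_pos = {v.pos for v in variants}
    for k in range(n_background_variants):
        for _attempt in range(200):  # variant keys stay unique
            if bg_anchor_regions and k % 2 == 0:
                r = bg_anchor_regions[int(rng_var.integers(len(bg_anchor_regions)))]
                pos = int(rng_var.integers(r.start, r.end))
            else:
                pos = int(rng_var.integers(gap_lo, gap_hi))
            if pos not in used_pos:
                break
        used_pos.add(pos)
        n_car = int(rng_var.integers(1, 5))
        carriers = set(rng_var.choice(cohort.patients, size=n_car, replace=False))
        v = Variant(
            chrom=CHROM, pos=pos, end=pos + 1, ref="C", alt="T",
            maf=_sample_maf(rng_var, cfg.maf_stratum_props),
            genotypes={p: (1 if p in carriers else 0) for p in cohort.patients},
        )
        variants.append(v)

    # --- motif annotation for background variants ---
    for v in variants[n_planted:]:
        if rng_motif.random() < 0.5:
            continue
        group = "case" if v.carriers() <= set(cases) else (
            "control" if v.carriers() <= set(controls) else "shared"
        )
        if group == "case" and cfg.motif_burden_family is not None:
            fam_tfs = [t for t in tfs if families[t] == cfg.motif_burden_family]
            other = [t for t in tfs if families[t] != cfg.motif_burden_family]
            w = cfg.motif_burden_odds
            if rng_motif.random() < w * len(fam_tfs) / (w * len(fam_tfs) + len(other)):
                tf = fam_tfs[int(rng_motif.integers(len(fam_tfs)))]
            else:
                tf = other[int(rng_motif.integers(len(other)))]
        else:
            tf = tfs[int(rng_motif.integers(len(tfs)))]
        tf_map[v.key] = [tf]
        if group in ("case", "control"):
            impact_rows.append(
                {"variant": v.key, "pwm": f"{tf}_PWM", "tf": tf, "family": families[tf],
                 "call": "GoM" if rng_motif.random() < 0.5 else "LoM", "group": group}
            )
    impacts = pd.DataFrame(impact_rows)

    # --- allelic counts ---
    counts, truth_ase = _simulate_ase(cfg, cohort, genes, rng_ase)

    # --- expression with planted DE and planted cell-type burden ---
    expression, cell_matrices, truth_de, truth_burden = _simulate_expression(
        cfg, genes, tfs, truth_events, rng_expr
    )

    return SimBundle(
        config=cfg,
        cohort=cohort,
        variants=variants,
        interactions=interactions,
        regions=regions,
        gene_table=gene_table,
        counts=counts,
        expression=expression,
        cell_matrices=cell_matrices,
        impacts=impacts,
        tf_map=tf_map,
        truth_events=truth_events,
        truth_ase=truth_ase,
        truth_de=truth_de,
        truth_burden=truth_burden,
    )


def _interaction(patient, prom, enh, rng) -> Interaction:
    support = int(rng.integers(5, 40))
    adj_p = float(rng.uniform(0, 0.049))
    return Interaction(
        patient=patient, promoter=prom, pir=enh,
        support_pairs=support, adj_p=adj_p,
        distance=abs(enh.midpoint - prom.midpoint), trans=False,
    )


def _make_gene_table(genes, tfs, rng) -> list[GeneAnnotation]:
    table = []
    for i, g in enumerate(genes):
        tier = "tier1" if i % 20 == 0 else ("tier2" if i % 20 == 1 else "none")
        table.append(
            GeneAnnotation(
                gene_id=g, tier=tier,
                housekeeping=(tier == "none" and i % 3 == 0),
                endothelial_specific=(i % 10 == 2),
            )
        )
    table.extend(GeneAnnotation(gene_id=tf) for tf in tfs)
    return table


def _betabinom_draw(rng, n, mu, rho):
    if rho == 0:
        return rng.binomial(n, mu)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return rng.binomial(n, rng.beta(a, b))


def _simulate_ase(cfg, cohort, genes, rng):
    n_ase = min(cfg.n_imbalanced_genes + cfg.n_ase_null_genes, len(genes))
    ase_genes = list(rng.choice(genes, size=n_ase, replace=False))
    planted = set(ase_genes[: cfg.n_imbalanced_genes])
    counts: list[AllelicCount] = []
    truth_rows = []
    for g in ase_genes:
        mu = cfg.ase_alt_fraction if g in planted else 0.5
        patients = rng.choice(cohort.patients, size=cfg.ase_patients_per_gene, replace=False)
        for s in range(cfg.ase_snvs_per_gene):
            snv = f"{g}_snv{s}"
            for p in patients:
                n = max(10, int(rng.poisson(cfg.ase_mean_depth)))
                alt = int(_betabinom_draw(rng, n, mu, cfg.ase_rho))
                counts.append(
                    AllelicCount(variant=snv, patient=str(p), ref_n=n - alt, alt_n=alt,
                                 gq=99.0, dp=n)
                )
        truth_rows.append({"gene": g, "planted": g in planted, "alt_fraction": mu})
    return counts, pd.DataFrame(truth_rows)


def _simulate_expression(cfg, genes, tfs, truth_events, rng):
    cell_types = [f"CT{i+1}" for i in range(cfg.n_cell_types)]
    if cfg.target_cell_type not in cell_types:
        raise ValueError(f"target cell type {cfg.target_cell_type} not among {cell_types}")
    all_ids = genes + tfs

    def _event_genes(specificity: str) -> set:
        if not len(truth_events):
            return set()
        sel = (truth_events["cohort"] == specificity) & (truth_events["concordance"] == "concordant")
        return set(truth_events.loc[sel, "gene"])

    case_genes = _event_genes("case_specific")
    control_genes = _event_genes("control_specific")

    # planted burden: in the target cell type, case event genes are expressed
    # with up-weighted odds and control event genes with down-weighted odds,
    # so the planted cohort contrast is an expression odds of ~burden_odds^2
    p_lo = cfg.base_expression_prob
    p_hi = min(1.0, p_lo * cfg.burden_odds)
    p_depressed = p_lo / cfg.burden_odds

    mean = pd.DataFrame(0.0, index=all_ids, columns=cell_types)
    on = pd.DataFrame(False, index=all_ids, columns=cell_types)
    for ct in cell_types:
        prob = np.full(len(all_ids), p_lo)
        if ct == cfg.target_cell_type:
            for i, g in enumerate(all_ids):
                if g in case_genes:
                    prob[i] = p_hi
                elif g in control_genes:
                    prob[i] = p_depressed
        prob[len(genes):] = 0.9  # TFs broadly expressed
        mask = rng.random(len(all_ids)) < prob
        on[ct] = mask
        base = rng.lognormal(mean=0.0, sigma=0.5, size=len(all_ids))
        mean[ct] = np.where(mask, base, 0.0)

    # planted DE genes: effect multiplier in one cell type, per-cell matrices
    de = pd.DataFrame(False, index=all_ids, columns=cell_types)
    n_de = min(cfg.n_de_per_type, len(genes) // max(1, cfg.n_cell_types))
    pool = list(rng.permutation(genes))
    for ct in cell_types:
        for g in pool[:n_de]:
            de.loc[g, ct] = True
            if not on.loc[g, ct]:
                on.loc[g, ct] = True
                mean.loc[g, ct] = float(rng.lognormal(0.0, 0.5))
            mean.loc[g, ct] *= cfg.de_effect_size
        pool = pool[n_de:]

    cell_matrices = {}
    for ct in cell_types:
        mu = mean[ct].to_numpy()[:, None]
        noise = rng.lognormal(0.0, 0.3, size=(len(all_ids), cfg.cells_per_type))
        cell_matrices[ct] = pd.DataFrame(
            mu * noise, index=all_ids,
            columns=[f"{ct}_c{j}" for j in range(cfg.cells_per_type)],
        )

    truth_de = de.reset_index(names="gene").melt(
        id_vars="gene", var_name="cell_type", value_name="planted_de"
    )
    truth_burden = {
        "target_cell_type": cfg.target_cell_type,
        "burden_odds": cfg.burden_odds,
        "case_event_genes": sorted(case_genes),
    }
    return ExpressionProfile(mean=mean), cell_matrices, truth_de, truth_burden


# ---------------------------------------------------------------------------
# recovery evaluation


def evaluate_recovery(
    bundle: SimBundle,
    events: Sequence,
    gene_imbalance: Sequence | None = None,
    enrichment: Sequence | None = None,
) -> dict:
    """Compare pipeline outputs against the planted truth.

    Returns per-stage metrics: event sensitivity/specificity and label
    accuracy, the AUC of planted-vs-null allelic-imbalance gene ranking, and
    whether the planted burden cell type attains the minimum enrichment q.
    """
    truth = {
        (r.variant, ((r.prom_chrom, r.prom_start, r.prom_end),
                     (r.enh_chrom, r.enh_start, r.enh_end)), r.component):
        (r.direction, r.concordance)
        for r in bundle.truth_events.itertuples(index=False)
    }
    found: dict[tuple, tuple] = {}
    n_extra_concordant = 0
    n_nonplanted = 0
    for e in events:
        k = (e.variant.key, e.interaction_key, e.component)
        if k in truth:
            found[k] = (e.direction, e.concordance)
        else:
            n_nonplanted += 1
            if e.concordance == "concordant":
                n_extra_concordant += 1
    n_truth = len(truth)
    correct = sum(1 for k, lab in found.items() if truth[k] == lab)
    report: dict = {
        "n_planted": n_truth,
        "n_recovered": len(found),
        "n_label_correct": correct,
        "event_sensitivity": correct / n_truth if n_truth else float("nan"),
        "event_specificity": (
            1.0 - n_extra_concordant / n_nonplanted if n_nonplanted else 1.0
        ),
    }
    if gene_imbalance is not None:
        report["ase_auc"] = _ranking_auc(bundle.truth_ase, gene_imbalance)
    if enrichment is not None and len(enrichment):
        best = min(enrichment, key=lambda r: (r.q, r.p))
        report["burden_target_hit"] = best.cell_type == bundle.truth_burden["target_cell_type"]
        report["burden_best_cell_type"] = best.cell_type
    return report


def _ranking_auc(truth_ase: pd.DataFrame, gene_imbalance) -> float:
    """AUC for planted imbalanced genes ranked by ascending combined p."""
    pvals = {g.gene_id: g.p for g in gene_imbalance}
    planted = [pvals[g] for g, pl in zip(truth_ase["gene"], truth_ase["planted"]) if pl and g in pvals]
    nulls = [pvals[g] for g, pl in zip(truth_ase["gene"], truth_ase["planted"]) if not pl and g in pvals]
    if not planted or not nulls:
        raise ValueError("need both planted and null genes with results")
    wins = sum(
        (1.0 if p < q else 0.5 if p == q else 0.0) for p in planted for q in nulls
    )
    return wins / (len(planted) * len(nulls))
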