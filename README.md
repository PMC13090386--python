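# rewirekit

Rare non-coding variants can rewire promoter–enhancer chromatin contacts in
a patient-specific way. Given per-patient promoter-anchored interaction
calls (promoter capture Hi-C), per-patient germline variant calls, and
supporting annotation, `rewirekit` classifies **rewiring events**, annotates
variants with transcription-factor **motif impact**, tests **allele-specific
contact imbalance**, and runs MAF-stratified **cell-type enrichment** of
affected genes. It targets a case/control cohort design (e.g. bicuspid vs
tricuspid aortic valve patients, 8 + 8 individuals) and ships a synthetic
cohort generator with planted ground truth, so the whole pipeline is
testable without controlled-access patient data.

## The model

For a rare variant *v* with carrier set *C* (patients with alt dosage ≥ 1)
and an interaction observed in patient set *P* (after QC), the event
classifier is a set predicate:

* *P* ⊆ *C* — **gain of interaction (GoI), concordant**: the contact exists
  only in carriers;
* *P* ⊆ *N* (non-carriers) — **loss of interaction (LoI), concordant**;
* *P* meets both *C* and *N* — **discordant**, direction by the majority
  presence rate (|P∩C|/|C| vs |P∩N|/|N|, ties to GoI).

Events are labelled case-/control-specific/shared by their carrier set and
summarised with two-tailed Fisher exact tests on 2×2 tables using the
sample cross-product odds ratio OR = ad/bc.

Motif impact scores a variant against a PWM as
log₂(p_ref / p_alt), where each p is the best motif-hit p-value over all
placements and strands covering the variant, computed *exactly* by dynamic
programming over the discretized background score distribution. Hits with
p ≤ 5·10⁻⁴ and ≥ 4-fold p-value change are called gain/loss of motif.

Allelic imbalance at a heterozygous site with counts (ref, alt) is tested
conditional on n = ref + alt under beta-binomial(n, ½, ρ); the minimal
one-tailed p is doubled (capped at 1). Gene-level p-values combine SNVs per
individual, then individuals, with the Mudholkar–George logit method
(T = −Σ logit(pᵢ) against a scaled t with 5k+4 df), followed by
Benjamini–Hochberg FDR across genes.

Cell-type enrichment calls a transcript *altered* in a cell type when its
promoter joins a concordant event, the transcript is expressed there, and
an affected TF is expressed there; altered-gene proportions are compared
between cohorts per cell type and MAF stratum (MAFa [0, 2%), MAFb [2%, 4%),
MAFc [4%, 10%)) with Fisher tests and per-family BH correction.

## Worked example

```python
from rewirekit import (SimConfig, simulate_cohort, filter_interactions,
                       enumerate_events, table1_summary, evaluate_recovery,
                       enrichment_test1)

cfg = SimConfig(seed=11)              # 8+8 patients, 2000 variants,
bundle = simulate_cohort(cfg)         # 50 GoI + 20 LoI + 30 discordant planted
kept, drops = filter_interactions(bundle.interactions)
events = enumerate_events(bundle.variants, kept, bundle.regions, bundle.cohort)
summary = table1_summary(events, {g.gene_id: g for g in bundle.gene_table})
enr = enrichment_test1(events, bundle.expression, bundle.tf_map, bundle.cohort)
report = evaluate_recovery(bundle, events, enrichment=enr)
```

This prints (via the field accessors shown in `tests/` and the CLI):

```
interactions kept: 6778 (drops: 0)
events: 1537
concordant LoI/GoI per cohort: {'case_specific': (10, 26), 'control_specific': (10, 24)}
LoI share (%): {'case_specific': 27.78, 'control_specific': 29.41}
GoI share of concordant events: 71.4%
event recovery: sensitivity=1.0, specificity=1.0
burden cell type recovered: CT1
```

All 6778 generated interactions pass QC (the generator plants clean calls);
1537 events are enumerated, of which the 100 planted ones are recovered
with their exact direction/concordance labels (sensitivity = specificity
= 1), and the planted cell-type burden is located in CT1. The LoI/GoI
shares reflect the planted 50:20 concordant mix plus cohort assignment.

The same stages are exposed as a CLI over the documented text formats:

```bash
rewirekit simulate --seed 11 --out data/
rewirekit qc --interactions data/interactions.tsv --cohort data/cohort.json \
             --out kept.tsv --report qc.json
rewirekit events --variants data/variants.vcf --interactions kept.tsv \
                 --regions data/regions.bed --genes data/genes.tsv \
                 --cohort data/cohort.json --out events.tsv --summary table.json
```

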