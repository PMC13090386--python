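"""Allele-specific imbalance testing and gene-level p-value aggregation.

Heterozygous SNVs covered by interaction-spanning reads should show equal
read support for both alleles; a consistent excess of one allele indicates
allele-specific chromatin contact. Conditional on the total read count n at
a site, the alt count is modelled beta-binomial(n, mean 1/2, overdispersion
rho): rho = 0 recovers the exact binomial test, rho > 0 absorbs the extra
variance of capture sequencing. One-tailed p-values (toward ref / toward
alt) include the observed point mass; the minimal one is doubled (capped at
1) to mimic a two-tailed test.

Gene-level significance combines SNV p-values annotated to a gene with the
Mudholkar-George logit method per individual, re-combines the per-individual
gene p-values across individuals with the same method, and controls FDR over
genes by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_model import AllelicCount

logger = logging.getLogger(__name__)

_EPS = 1e-300


def qc_counts(
    counts: Iterable[AllelicCount],
    min_gq: float = 50,
    min_dp: int = 10,
    min_allele: int = 5,
) -> list[AllelicCount]:
    """Keep sites with gq >= 50, dp >= 10 and >= 5 reads per allele (defaults).

    All boundaries inclusive.
    """
    return [
        c
        for c in counts
        if c.gq >= min_gq and c.dp >= min_dp and c.ref_n >= min_allele and c.alt_n >= min_allele
    ]


@dataclass
class ImbalanceResult:
    p_toward_ref: float
    p_toward_alt: float
    p_two: float
    effect: float  # alt fraction


def _null_dist(n: int, rho: float):
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if rho == 0:
        return stats.binom(n, 0.5)
    ab = (1 / rho - 1) / 2  # symmetric beta-binomial with rho = 1/(a+b+1)
    return stats.betabinom(n, ab, ab)


def imbalance_test(ref_n: int, alt_n: int, rho: float = 0.0) -> ImbalanceResult:
    """Two-tailed-by-doubling beta-binomial test of allelic balance.

    ``p_toward_alt`` = Pr(X >= alt_n), ``p_toward_ref`` = Pr(X <= alt_n),
    both including the observed outcome; ``p_two = min(1, 2 min(...))``.
    """
    if min(ref_n, alt_n) < 0:
        raise ValueError("negative counts")
    n = ref_n + alt_n
    if n == 0:
        raise ValueError("no reads")
    dist = _null_dist(n, rho)
    p_alt = float(dist.sf(alt_n - 1))
    p_ref = float(dist.cdf(alt_n))
    return ImbalanceResult(
        p_toward_ref=min(p_ref, 1.0),
        p_toward_alt=min(p_alt, 1.0),
        p_two=min(1.0, 2 * min(p_ref, p_alt)),
        effect=alt_n / n,
    )


def estimate_overdispersion(counts: Sequence[AllelicCount], min_sites: int = 20) -> float:
    """Method-of-moments overdispersion from alt fractions across het sites.

    Under beta-binomial(n, 1/2, rho), Var(alt/n) = (1 + (n-1) rho) / (4n);
    rho is solved from the mean squared deviation of alt fractions from 1/2,
    clipped to [0, 0.5]. Fewer than ``min_sites`` sites returns 0 with a
    warning.
    """
    if len(counts) < min_sites:
        logger.warning("only %d sites; overdispersion set to 0", len(counts))
        return 0.0
    n = np.array([c.ref_n + c.alt_n for c in counts], dtype=float)
    f = np.array([c.alt_n for c in counts], dtype=float) / n
    msd = np.mean((f - 0.5) ** 2)
    base = np.mean(0.25 / n)  # binomial part
    slope = np.mean(0.25 * (n - 1) / n)
    rho = (msd - base) / slope
    return float(np.clip(rho, 0.0, 0.5))


def combine_pvalues_logit(ps: Sequence[float]) -> float:
    """Mudholkar-George logit combination of independent p-values.

    T = -sum logit(p_i) referred to a scaled t distribution with 5k+4
    degrees of freedom. A single p-value is returned unchanged.

    Degenerate inputs are clamped into the open interval with a warning:
    p = 0 to 1e-300, and p = 1 to 1 - 1e-4. The upper clamp is deliberately
    mild: a doubled-and-capped discrete p-value of exactly 1 has a large
    point mass under the null (any near-balanced site), so its null-evidence
    is bounded; clamping at the float boundary (logit ~ 36.7) would let a
    single balanced site cancel several strongly imbalanced ones.
    """
    if len(ps) == 0:
        raise ValueError("no p-values")
    clean = []
    n_degenerate = 0
    for p in ps:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0 or p == 1:
            n_degenerate += 1
            p = min(max(p, _EPS), 1 - 1e-4)
        clean.append(p)
    if n_degenerate:
        logger.warning("%d degenerate p-value(s) clamped into (0, 1)", n_degenerate)
    k = len(clean)
    if k == 1:
        return clean[0]
    t_stat = -sum(math.log(p / (1 - p)) for p in clean)
    nu = 5 * k + 4
    scale = math.sqrt(k * math.pi**2 * (nu - 2) / (3 * nu))
    return float(stats.t.sf(t_stat / scale, nu))


def bh_fdr(ps: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values."""
    ps = np.asarray(ps, dtype=float)
    if len(ps) == 0:
        return []
    if not np.isfinite(ps).all() or (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must be finite in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(ps, method="fdr_bh")[1].tolist()


@dataclass
class GeneImbalance:
    gene_id: str
    per_patient_p: dict[str, float]
    p: float  # cross-individual combined
    q: float
    n_snvs: int


def gene_level_imbalance(
    results: Mapping[tuple[str, str], ImbalanceResult],
    snv_to_genes: Mapping[str, Sequence[str]],
) -> list[GeneImbalance]:
    """Two-stage logit combination of per-SNV imbalance p-values.

    ``results`` is keyed by (variant, patient). Per gene and individual the
    doubled p-values of its SNVs are combined; the per-individual gene
    p-values are then re-combined across individuals, and BH is applied
    across genes. Output sorted by gene ID.
    """
    per_gene: dict[str, dict[str, list[float]]] = {}
    for (variant, patient), res in results.items():
        for gene in snv_to_genes.get(variant, ()):
            per_gene.setdefault(gene, {}).setdefault(patient, []).append(res.p_two)
    genes = sorted(per_gene)
    rows = []
    for gene in genes:
        per_patient = {
            patient: combine_pvalues_logit(ps)
            for patient, ps in sorted(per_gene[gene].items())
        }
        p = combine_pvalues_logit(list(per_patient.values()))
        n_snvs = sum(len(v) for v in per_gene[gene].values())
        rows.append((gene, per_patient, p, n_snvs))
    qs = bh_fdr([r[2] for r in rows])
    return [
        GeneImbalance(gene_id=g, per_patient_p=pp, p=p, q=q, n_snvs=n)
        for (g, pp, p, n), q in zip(rows, qs)
    ]
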