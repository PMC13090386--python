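"""Domain types, coordinate conventions and file I/O.

All internal coordinates are 0-based half-open. VCF input (1-based) is
converted on read; BED-family input is native. Overlap of an indel is by
its reference footprint ``[pos, pos + len(ref))``.

The file dialects handled here:

* variants — VCF 4.x with GT genotypes, or a TSV with columns
  ``chrom, pos, ref, alt, maf`` (``pos`` 1-based, VCF-like; ``maf`` may be
  empty) followed by one dosage column per patient;
* interactions — BEDPE-like TSV with columns
  ``chrom1, start1, end1, chrom2, start2, end2, patient, support_pairs, adj_p``;
* regions — BED6 plus two extra columns ``role`` and ``gene_ids``
  (comma-separated, empty for enhancers);
* gene table — TSV ``gene_id, tier, housekeeping, endothelial_specific``;
* allelic counts — TSV ``variant, patient, ref_n, alt_n, gq, dp``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

Group = Literal["case", "control"]
Role = Literal["promoter", "enhancer"]


@dataclass
class Cohort:
    """Patient IDs with case/control labels.

    Two non-empty groups; IDs unique.
    """

    patients: list[str]
    group: dict[str, Group]

    def __post_init__(self) -> None:
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate patient IDs")
        if set(self.group) != set(self.patients):
            raise ValueError("group labels must cover exactly the cohort patients")
        labels = set(self.group.values())
        if labels != {"case", "control"}:
            raise ValueError(f"need both 'case' and 'control' groups, got {labels}")

    @property
    def cases(self) -> set[str]:
        return {p for p in self.patients if self.group[p] == "case"}

    @property
    def controls(self) -> set[str]:
        return {p for p in self.patients if self.group[p] == "control"}


@dataclass(eq=False)
class Variant:
    """A short germline variant (SNV or indel), left-anchored.

    ``pos``/``end`` are the 0-based half-open reference footprint, so
    ``end - pos == len(ref)``. ``genotypes`` maps every cohort patient to an
    alt-allele dosage in {0, 1, 2}; dosage >= 1 defines a carrier.
    """

    chrom: str
    pos: int
    end: int
    ref: str
    alt: str
    maf: float
    genotypes: dict[str, int]
    kind: Literal["snv", "indel"] | None = None  # derived when omitted

    def __post_init__(self) -> None:
        if self.end - self.pos != len(self.ref):
            raise ValueError("end - pos must equal len(ref)")
        if not 0 <= self.maf < 1:
            raise ValueError("maf must be in [0, 1)")
        if self.kind is None:
            self.kind = "snv" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def carriers(self) -> set[str]:
        return {p for p, d in self.genotypes.items() if d >= 1}


@dataclass(eq=False)
class RegulatoryRegion:
    """A promoter or a promoter-interacting region (PIR, called enhancer)."""

    chrom: str
    start: int
    end: int
    role: Role
    name: str = ""
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def fragment_len(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(eq=False)
class Interaction:
    """One promoter-anchored promoter-PIR pair observed in one patient.

    ``distance`` is the absolute midpoint distance for cis pairs and None
    (undefined) for trans pairs.
    """

    patient: str
    promoter: RegulatoryRegion
    pir: RegulatoryRegion
    support_pairs: int
    adj_p: float
    distance: float | None
    trans: bool

    @property
    def key(self) -> tuple[tuple[str, int, int], tuple[str, int, int]]:
        """Patient-independent identity of the promoter-PIR pair."""
        return (self.promoter.key, self.pir.key)


@dataclass
class GeneAnnotation:
    gene_id: str
    tier: Literal["tier1", "tier2", "none"] = "none"
    housekeeping: bool = False
    endothelial_specific: bool = False


@dataclass
class AllelicCount:
    """Per-SNV per-patient allelic read counts with genotype QC fields."""

    variant: str
    patient: str
    ref_n: int
    alt_n: int
    gq: float
    dp: int

    def __post_init__(self) -> None:
        if min(self.ref_n, self.alt_n) < 0:
            raise ValueError("negative read count")
        if self.dp < max(self.ref_n, self.alt_n):
            raise ValueError("dp must be >= max(ref_n, alt_n)")


# ---------------------------------------------------------------------------
# variants


def _dosage(gt: str) -> int:
    """Parse a diploid GT string ('0/1', '1|1', ...) to alt dosage."""
    alleles = gt.replace("|", "/").split("/")
    if len(alleles) != 2 or not all(a in ("0", "1") for a in alleles):
        raise ValueError(f"malformed genotype {gt!r}")
    return sum(a == "1" for a in alleles)


def compute_maf(genotypes: Mapping[str, int]) -> float:
    """Minor-allele frequency as alt-allele count over 2N diploid alleles."""
    n = len(genotypes)
    if n == 0:
        raise ValueError("no genotypes")
    ac = sum(genotypes.values())
    f = ac / (2 * n)
    return min(f, 1 - f)


def read_variants(
    path: str | Path,
    cohort: Cohort,
    *,
    multiallelic: Literal["reject", "split"] = "reject",
    stats: dict | None = None,
) -> list[Variant]:
    """Read variants from VCF (via cyvcf2) or the TSV dialect.

    Multi-allelic records are rejected (skip counter in ``stats``) or split
    per ``multiallelic``. MAF is taken from INFO/MAF when present, else
    computed from cohort genotypes. A sample column missing for any cohort
    patient is a hard error; a malformed genotype skips the record and is
    counted.
    """
    path = Path(path)
    if stats is None:
        stats = {}
    stats.setdefault("skipped_multiallelic", 0)
    stats.setdefault("skipped_malformed", 0)
    if path.suffix in (".tsv", ".txt", ".csv"):
        return _read_variants_tsv(path, cohort, stats=stats)
    return _read_variants_vcf(path, cohort, multiallelic=multiallelic, stats=stats)


def _variant_kind(ref: str, alt: str) -> str:
    return "snv" if len(ref) == 1 and len(alt) == 1 else "indel"


def _read_variants_vcf(path, cohort, *, multiallelic, stats) -> list[Variant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    missing = set(cohort.patients) - set(vcf.samples)
    if missing:
        raise ValueError(f"cohort patients missing from VCF samples: {sorted(missing)}")
    col = {s: i for i, s in enumerate(vcf.samples)}
    out: list[Variant] = []
    for rec in vcf:
        alts = rec.ALT
        if len(alts) > 1 and multiallelic == "reject":
            stats["skipped_multiallelic"] += 1
            continue
        try:
            gts = rec.genotypes  # [allele_a, allele_b, phased]
            dosages_all = []
            for alt_index in range(1, len(alts) + 1):
                dosages_all.append(
                    {
                        p: _dosage_from_alleles(gts[col[p]][:2], alt_index)
                        for p in cohort.patients
                    }
                )
        except ValueError:
            stats["skipped_malformed"] += 1
            logger.warning("malformed genotype at %s:%s, record skipped", rec.CHROM, rec.POS)
            continue
        maf_info = rec.INFO.get("MAF")
        for alt, genotypes in zip(alts, dosages_all):
            maf = float(maf_info) if maf_info is not None else compute_maf(genotypes)
            out.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS - 1,
                    end=rec.POS - 1 + len(rec.REF),
                    ref=rec.REF,
                    alt=alt,
                    maf=maf,
                    genotypes=genotypes,
                    kind=_variant_kind(rec.REF, alt),
                )
            )
    return out


def _dosage_from_alleles(alleles: Sequence[int], alt_index: int) -> int:
    if any(a < 0 for a in alleles):
        raise ValueError("missing genotype")
    return sum(a == alt_index for a in alleles)


def _read_variants_tsv(path, cohort, *, stats) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["chrom", "pos", "ref", "alt", "maf"]
    missing_cols = set(fixed) - set(df.columns)
    if missing_cols:
        raise ValueError(f"variant TSV missing columns {sorted(missing_cols)}")
    missing = set(cohort.patients) - set(df.columns)
    if missing:
        raise ValueError(f"cohort patients missing from TSV columns: {sorted(missing)}")
    out: list[Variant] = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        try:
            genotypes = {p: int(rec[p]) for p in cohort.patients}
            if any(d not in (0, 1, 2) for d in genotypes.values()):
                raise ValueError("dosage outside {0,1,2}")
        except (ValueError, TypeError):
            stats["skipped_malformed"] += 1
            logger.warning("malformed genotype row at %s:%s skipped", rec["chrom"], rec["pos"])
            continue
        maf = rec["maf"]
        maf = compute_maf(genotypes) if pd.isna(maf) else float(maf)
        ref, alt = str(rec["ref"]), str(rec["alt"])
        pos0 = int(rec["pos"]) - 1
        out.append(
            Variant(
                chrom=str(rec["chrom"]),
                pos=pos0,
                end=pos0 + len(ref),
                ref=ref,
                alt=alt,
                maf=maf,
                genotypes=genotypes,
                kind=_variant_kind(ref, alt),
            )
        )
    return out


def write_variants_tsv(variants: Iterable[Variant], path: str | Path, cohort: Cohort) -> None:
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos + 1,
            "ref": v.ref,
            "alt": v.alt,
            "maf": v.maf,
        }
        row.update({p: v.genotypes[p] for p in cohort.patients})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_variants_vcf(variants: Iterable[Variant], path: str | Path, cohort: Cohort) -> None:
    """Write a minimal VCF 4.2 with GT genotypes and INFO/MAF."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    variants = list(variants)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted({v.chrom for v in variants}):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.patients) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            gts = "\t".join(gt[v.genotypes[p]] for p in cohort.patients)
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tMAF={v.maf:.6g}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# interactions

_INTERACTION_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "patient", "support_pairs", "adj_p",
]


def read_interactions(path: str | Path, cohort: Cohort) -> list[Interaction]:
    """Read the BEDPE-like interaction TSV.

    Anchor 1 is the promoter, anchor 2 the PIR. ``trans`` is set when the
    chromosomes differ; cis distance is the absolute midpoint distance.
    An unknown patient ID is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str, "patient": str})
    missing_cols = set(_INTERACTION_COLS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"interaction TSV missing columns {sorted(missing_cols)}")
    unknown = set(df["patient"]) - set(cohort.patients)
    if unknown:
        raise ValueError(f"unknown patient IDs in interaction table: {sorted(unknown)}")
    out: list[Interaction] = []
    # regions of identical coordinates are shared so Interaction.key compares
    region_cache: dict[tuple, RegulatoryRegion] = {}

    def region(chrom, start, end, role):
        k = (chrom, int(start), int(end), role)
        if k not in region_cache:
            region_cache[k] = RegulatoryRegion(chrom, int(start), int(end), role)
        return region_cache[k]

    for row in df.itertuples(index=False):
        trans = row.chrom1 != row.chrom2
        prom = region(row.chrom1, row.start1, row.end1, "promoter")
        pir = region(row.chrom2, row.start2, row.end2, "enhancer")
        dist = None if trans else abs(pir.midpoint - prom.midpoint)
        out.append(
            Interaction(
                patient=row.patient,
                promoter=prom,
                pir=pir,
                support_pairs=int(row.support_pairs),
                adj_p=float(row.adj_p),
                distance=dist,
                trans=trans,
            )
        )
    return out


def write_interactions_tsv(interactions: Iterable[Interaction], path: str | Path) -> None:
    rows = [
        {
            "chrom1": i.promoter.chrom, "start1": i.promoter.start, "end1": i.promoter.end,
            "chrom2": i.pir.chrom, "start2": i.pir.start, "end2": i.pir.end,
            "patient": i.patient, "support_pairs": i.support_pairs, "adj_p": i.adj_p,
        }
        for i in interactions
    ]
    pd.DataFrame(rows, columns=_INTERACTION_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# regions and gene annotation


def read_regions_bed(path: str | Path) -> list[RegulatoryRegion]:
    """BED6+2: chrom, start, end, name, score, strand, role, gene_ids."""
    cols = ["chrom", "start", "end", "name", "score", "strand", "role", "gene_ids"]
    df = pd.read_csv(path, sep="\t", names=cols, dtype={"chrom": str}, comment="#")
    out = []
    for row in df.itertuples(index=False):
        genes = tuple(g for g in str(row.gene_ids).split(",") if g and g != "nan")
        if row.role == "promoter" and not genes:
            raise ValueError(f"promoter region {row.name} carries no gene IDs")
        if row.role == "enhancer" and genes:
            raise ValueError(f"enhancer region {row.name} carries gene IDs at load time")
        out.append(
            RegulatoryRegion(
                chrom=row.chrom, start=int(row.start), end=int(row.end),
                role=row.role, name=str(row.name), gene_ids=genes,
            )
        )
    return out


def write_regions_bed(regions: Iterable[RegulatoryRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            genes = ",".join(r.gene_ids)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t.\t{r.role}\t{genes}\n")


def read_gene_table(path: str | Path) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tier": str})
    out = {}
    for row in df.itertuples(index=False):
        out[row.gene_id] = GeneAnnotation(
            gene_id=row.gene_id,
            tier=row.tier,
            housekeeping=bool(row.housekeeping),
            endothelial_specific=bool(row.endothelial_specific),
        )
    return out


def write_gene_table(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id, "tier": g.tier,
                "housekeeping": g.housekeeping,
                "endothelial_specific": g.endothelial_specific,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allelic counts


def read_allelic_counts(path: str | Path) -> list[AllelicCount]:
    df = pd.read_csv(path, sep="\t", dtype={"variant": str, "patient": str})
    return [
        AllelicCount(
            variant=r.variant, patient=r.patient,
            ref_n=int(r.ref_n), alt_n=int(r.alt_n),
            gq=float(r.gq), dp=int(r.dp),
        )
        for r in df.itertuples(index=False)
    ]


def write_allelic_counts(counts: Iterable[AllelicCount], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "variant": c.variant, "patient": c.patient,
                "ref_n": c.ref_n, "alt_n": c.alt_n, "gq": c.gq, "dp": c.dp,
            }
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval overlap


def overlap_variants_regions(
    variants: Sequence[Variant], regions: Sequence[RegulatoryRegion]
) -> dict[Variant, list[tuple[RegulatoryRegion, Role]]]:
    """Half-open interval intersection of variant footprints with regions.

    A variant may map to both a promoter and an enhancer; each yields one
    entry. Result order is deterministic given input order.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, (idx, r))
    out: dict[Variant, list[tuple[RegulatoryRegion, Role]]] = {}
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(v.pos, v.end), key=lambda iv: iv.data[0])
        if hits:
            out[v] = [(iv.data[1], iv.data[1].role) for iv in hits]
    return out
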