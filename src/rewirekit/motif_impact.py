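"""PWM scoring, exact motif p-values and variant motif-impact calls.

A motif hit p-value is the probability that a random background word scores
at least as high as the observed word under the PWM's additive log-odds
model. It is computed exactly by dynamic programming over the discretized
score distribution: weights are fixed to a 1e-4 grid and per-position score
distributions are convolved with exact integer offsets, so p-values do not
depend on floating-point summation order.

A variant's impact on a motif is the log2 fold change of the best-hit
p-value between the reference and alternative alleles over all motif
placements (and both strands) covering the variant. Calls:

* gain-of-motif (GoM): the alt allele is a valid hit (p_alt <= 0.0005 by
  default) and the p-value drops at least 4-fold (log2 fc >= 2);
* loss-of-motif (LoM): symmetric, for the reference allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .allelic_imbalance import bh_fdr
from .rewiring_engine import ContingencyTable2x2, fisher_two_tailed

logger = logging.getLogger(__name__)

RESOLUTION = 1e-4
ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

StrandPolicy = Literal["both", "forward"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(eq=False)
class PWM:
    """Position weight matrix with additive log-odds scores.

    ``weights`` is L x 4 (columns A, C, G, T); scores are evaluated on a
    fixed-point grid of step 1e-4. ``background`` is a strictly positive
    mononucleotide distribution summing to 1.
    """

    name: str
    weights: np.ndarray
    background: np.ndarray | None = None
    quality: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4 or self.weights.shape[0] < 1:
            raise ValueError("weights must be an L x 4 matrix with L >= 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or (self.background <= 0).any() or not math.isclose(
            self.background.sum(), 1.0, rel_tol=1e-9
        ):
            raise ValueError("background must be a strictly positive length-4 distribution")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @cached_property
    def int_weights(self) -> np.ndarray:
        """Weights on the fixed-point grid (integer units of RESOLUTION)."""
        return np.rint(self.weights / RESOLUTION).astype(np.int64)

    @cached_property
    def _score_distribution(self) -> tuple[int, np.ndarray]:
        """(min integer score, survival array) of the background score law.

        survival[i] = Pr(integer score >= min + i); survival[0] == 1.
        """
        iw = self.int_weights
        probs = np.ones(1)
        cur_min = 0
        for pos in range(self.length):
            offs = iw[pos]
            new_min = cur_min + int(offs.min())
            new_max = cur_min + int(offs.max()) + len(probs) - 1
            new = np.zeros(new_max - new_min + 1)
            for letter in range(4):
                start = cur_min + int(offs[letter]) - new_min
                new[start : start + len(probs)] += probs * self.background[letter]
            probs, cur_min = new, new_min
        sf = np.cumsum(probs[::-1])[::-1]
        return cur_min, sf

    @cached_property
    def max_score(self) -> float:
        return float(self.int_weights.max(axis=1).sum()) * RESOLUTION

    def score(self, word: str) -> float:
        """Additive score of a length-L word over {A,C,G,T}."""
        if len(word) != self.length:
            raise ValueError(f"word length {len(word)} != motif length {self.length}")
        try:
            idx = [_IDX[c] for c in word.upper()]
        except KeyError as err:
            raise ValueError(f"non-ACGT letter in word {word!r}") from err
        return int(self.int_weights[np.arange(self.length), idx].sum()) * RESOLUTION

    def pvalue(self, score: float) -> float:
        """Pr(background word scores >= score); in (0, 1], non-increasing."""
        if not math.isfinite(score):
            raise ValueError("score must be finite")
        cur_min, sf = self._score_distribution
        qi = int(round(score / RESOLUTION)) - cur_min
        if qi <= 0:
            return 1.0
        if qi >= len(sf):
            qi = len(sf) - 1  # above max achievable: clamp to the top word mass
        return float(sf[qi])


def pwm_score(pwm: PWM, word: str) -> float:
    return pwm.score(word)


def pwm_pvalue(pwm: PWM, score: float) -> float:
    return pwm.pvalue(score)


def best_hit_pvalue(
    pwm: PWM, sequence: str, strand_policy: StrandPolicy = "both"
) -> float:
    """Minimum motif p-value over all placements covering the central base.

    ``sequence`` is a window of length 2L-1 centered on the variant position
    (shorter flanks are tolerated; only fully contained placements are
    scanned). Placements containing non-ACGT letters are skipped; if every
    placement is skipped the p-value is 1 with a warning.
    """
    seq = sequence.upper()
    L = pwm.length
    center = len(seq) // 2
    lo = max(0, center - L + 1)
    hi = min(len(seq) - L, center)
    best = None
    for i in range(lo, hi + 1):
        for word in _strand_words(seq[i : i + L], strand_policy):
            try:
                p = pwm.pvalue(pwm.score(word))
            except ValueError:
                continue
            best = p if best is None else min(best, p)
    if best is None:
        logger.warning("no scannable placement in window %r for %s", sequence, pwm.name)
        return 1.0
    return best


def _strand_words(word: str, strand_policy: StrandPolicy) -> Iterable[str]:
    yield word
    if strand_policy == "both":
        yield revcomp(word)


@dataclass
class MotifImpact:
    variant: str
    pwm: str
    p_ref: float
    p_alt: float
    impact: float  # log2(p_ref / p_alt)
    call: Literal["GoM", "LoM", "none"]


def motif_impact(
    pwm: PWM,
    ref_window: str,
    alt_window: str,
    *,
    hit_threshold: float = 0.0005,
    fc_min: float = 2.0,
    strand_policy: StrandPolicy = "both",
    variant_span: tuple[int, int] | None = None,
    variant_id: str = "",
) -> MotifImpact:
    """Score a variant's effect on one motif from ref/alt sequence windows.

    Windows must be identical outside the variant footprint (the central
    base unless ``variant_span`` gives the edited [start, end) range).
    """
    if len(ref_window) != len(alt_window):
        raise ValueError("ref and alt windows must have equal length (indels need flanked windows)")
    center = len(ref_window) // 2
    span = variant_span if variant_span is not None else (center, center + 1)
    for i, (r, a) in enumerate(zip(ref_window.upper(), alt_window.upper())):
        if r != a and not (span[0] <= i < span[1]):
            raise ValueError(f"windows differ at position {i}, outside the variant footprint {span}")
    p_ref = best_hit_pvalue(pwm, ref_window, strand_policy)
    p_alt = best_hit_pvalue(pwm, alt_window, strand_policy)
    impact = math.log2(p_ref / p_alt)
    call = "none"
    if p_alt <= hit_threshold and impact >= fc_min:
        call = "GoM"
    elif p_ref <= hit_threshold and -impact >= fc_min:
        call = "LoM"
    return MotifImpact(
        variant=variant_id, pwm=pwm.name, p_ref=p_ref, p_alt=p_alt, impact=impact, call=call
    )


# ---------------------------------------------------------------------------
# TF family burden


def tf_family_burden(
    hits: Iterable[tuple[str, str]],
    family_map: Mapping[str, str],
) -> list[dict]:
    """Per-TF-family motif-hit burden between cohorts.

    ``hits`` are (pwm_name, group) records for every GoM/LoM call, group in
    {case, control}. Each family with at least one hit yields a 2x2 table
    (family vs all other hits, case vs control) with Fisher OR/p and a BH q
    across families. Sorted by q then family name.
    """
    case_by_family: dict[str, int] = {}
    control_by_family: dict[str, int] = {}
    n_case = n_control = 0
    for pwm_name, group in hits:
        fam = family_map.get(pwm_name)
        if fam is None:
            continue
        if group == "case":
            case_by_family[fam] = case_by_family.get(fam, 0) + 1
            n_case += 1
        elif group == "control":
            control_by_family[fam] = control_by_family.get(fam, 0) + 1
            n_control += 1
        else:
            raise ValueError(f"unknown group {group!r}")
    families = sorted(set(case_by_family) | set(control_by_family))
    rows = []
    for fam in families:
        a = case_by_family.get(fam, 0)
        c = control_by_family.get(fam, 0)
        tab = ContingencyTable2x2(a, n_case - a, c, n_control - c)
        try:
            oddsratio, p = fisher_two_tailed(tab)
        except ValueError:  # 0/0 cross-product
            oddsratio, p = math.nan, 1.0
        rows.append({"family": fam, "case_hits": a, "control_hits": c,
                     "odds_ratio": oddsratio, "p": p})
    qs = bh_fdr([r["p"] for r in rows])
    for r, q in zip(rows, qs):
        r["q"] = q
    rows.sort(key=lambda r: (r["q"], r["family"]))
    return rows


# ---------------------------------------------------------------------------
# HOCOMOCO-style plain-text matrix files


def read_pwm_file(
    path: str | Path,
    *,
    kind: Literal["auto", "pwm", "pcm"] = "auto",
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> list[PWM]:
    """Read plain-text matrices: ``>NAME [quality]`` header, L rows of 4.

    ``kind='pcm'`` converts count matrices to log-odds with the given
    pseudocount distributed by background frequency; ``'auto'`` treats an
    all-non-negative matrix with row sums > 2 as counts.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    pwms: list[PWM] = []
    name, quality, rows = None, "", []

    def flush():
        if name is None:
            return
        mat = np.array(rows, dtype=float)
        k = kind
        if k == "auto":
            k = "pcm" if (mat >= 0).all() and (mat.sum(axis=1) > 2).all() else "pwm"
        if k == "pcm":
            mat = pcm_to_pwm(mat, bg, pseudocount)
        pwms.append(PWM(name=name, weights=mat, background=bg.copy(), quality=quality))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                name = parts[0]
                quality = parts[1] if len(parts) > 1 else ""
                rows = []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"matrix row with {len(vals)} columns in {path}")
                rows.append(vals)
    flush()
    return pwms


def pcm_to_pwm(counts: np.ndarray, background: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Counts to additive log-odds: ln((c + pc*bg) / ((N + pc) * bg))."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    p = (counts + pseudocount * background) / (totals + pseudocount)
    return np.log(p / background)
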