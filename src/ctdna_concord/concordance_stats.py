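"""Per-pair mutation matching, fractional TP/FP/FN/TN allocation and
aggregate concordance statistics.

Tumor tissue is the reference standard. A mutation found in both
compartments of a pair is a true positive; plasma-only mutations are false
positives, tumor-only mutations false negatives, and a pair with no
mutations at all in either compartment is one true negative. A pair with
several mutations still contributes exactly one pair-equivalent of weight:
each of its T mutations carries weight 1/T toward its group, so a pair
with three plasma-only and two tumor-only mutations contributes
FP = 3/5 = 0.6 and FN = 2/5 = 0.4.

Weights are kept as exact rationals so per-pair conservation
(tp + fp + fn + tn = 1) holds identically, not merely to tolerance.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from ctdna_concord.core_io import SamplePair, VariantCall

MutationKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class MutationMatch:
    """Mutation keys of one pair split by compartment membership."""

    concordant: frozenset[MutationKey]
    tdna_only: frozenset[MutationKey]
    ctdna_only: frozenset[MutationKey]

    def __post_init__(self) -> None:
        if (
            self.concordant & self.tdna_only
            or self.concordant & self.ctdna_only
            or self.tdna_only & self.ctdna_only
        ):
            raise ValueError("match sets must be pairwise disjoint")

    @property
    def total(self) -> int:
        return len(self.concordant) + len(self.tdna_only) + len(self.ctdna_only)


class PairCategory(str, enum.Enum):
    """Bookkeeping category of one sample pair."""

    CONCORDANT_ONLY = "concordant_only"
    CONCORDANT_PLUS_DISCORDANT = "concordant_plus_discordant"
    TDNA_ONLY = "tdna_only"
    CTDNA_ONLY = "ctdna_only"
    DISCORDANT_BOTH = "discordant_both"
    NONE = "none"


@dataclass(frozen=True)
class FractionalCounts:
    """Per-pair TP/FP/FN/TN weights in pair-equivalents (exact rationals)."""

    tp: Fraction = Fraction(0)
    fp: Fraction = Fraction(0)
    fn: Fraction = Fraction(0)
    tn: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("fractional counts must be >= 0")

    def __add__(self, other: "FractionalCounts") -> "FractionalCounts":
        return FractionalCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    @property
    def total(self) -> Fraction:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ConcordanceSummary:
    """Aggregate metrics over a cohort of pairs.

    A metric whose denominator is zero is ``None`` (undefined), never 0;
    its interval is likewise ``None``.
    """

    n_pairs: int
    totals: FractionalCounts
    concordance_rate: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    concordance_ci: tuple[float, float] | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    ppv_ci: tuple[float, float] | None
    ci_method: str

    def to_dict(self) -> dict:
        t = self.totals
        return {
            "n_pairs": self.n_pairs,
            "totals": {
                "tp": float(t.tp), "fp": float(t.fp),
                "fn": float(t.fn), "tn": float(t.tn),
            },
            "concordance_rate": self.concordance_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "concordance_ci": self.concordance_ci,
            "sensitivity_ci": self.sensitivity_ci,
            "specificity_ci": self.specificity_ci,
            "ppv_ci": self.ppv_ci,
            "ci_method": self.ci_method,
        }


def match_mutations(
    tumor_calls: Iterable[VariantCall], plasma_calls: Iterable[VariantCall]
) -> MutationMatch:
    """Compare post-filter call sets by normalized (chrom, pos, ref, alt).

    VAFs play no role in matching. Duplicate keys within one compartment
    (e.g. the same mutation spelled twice) collapse to one with a warning.
    """
    tumor_keys = _collapse_keys(tumor_calls, "tumor")
    plasma_keys = _collapse_keys(plasma_calls, "plasma")
    return MutationMatch(
        concordant=frozenset(tumor_keys & plasma_keys),
        tdna_only=frozenset(tumor_keys - plasma_keys),
        ctdna_only=frozenset(plasma_keys - tumor_keys),
    )


def _collapse_keys(calls: Iterable[VariantCall], label: str) -> set[MutationKey]:
    keys: list[MutationKey] = [c.key for c in calls]
    unique = set(keys)
    if len(keys) != len(unique):
        warnings.warn(
            f"duplicate mutation keys in {label} calls collapsed", stacklevel=3
        )
    return unique


def classify_pair(match: MutationMatch) -> PairCategory:
    """Assign the single bookkeeping category of a pair (total function)."""
    has_c = bool(match.concordant)
    has_t = bool(match.tdna_only)
    has_p = bool(match.ctdna_only)
    if not (has_c or has_t or has_p):
        return PairCategory.NONE
    if has_c:
        if has_t or has_p:
            return PairCategory.CONCORDANT_PLUS_DISCORDANT
        return PairCategory.CONCORDANT_ONLY
    if has_t and has_p:
        return PairCategory.DISCORDANT_BOTH
    return PairCategory.TDNA_ONLY if has_t else PairCategory.CTDNA_ONLY


def allocate_fractions(match: MutationMatch) -> FractionalCounts:
    """Allocate one pair-equivalent across TP/FP/FN (or TN) for one pair.

    With C concordant, Fp plasma-only and Fn tumor-only mutations and
    T = C + Fp + Fn > 0, each mutation carries weight 1/T, giving
    tp = C/T, fp = Fp/T, fn = Fn/T. A mutation-free pair is one true
    negative. Either way the pair's weights sum to exactly 1, keeping the
    cohort total equal to the number of pairs.
    """
    c, fp, fn = len(match.concordant), len(match.ctdna_only), len(match.tdna_only)
    t = c + fp + fn
    if t == 0:
        return FractionalCounts(tn=Fraction(1))
    w = Fraction(1, t)
    return FractionalCounts(tp=w * c, fp=w * fp, fn=w * fn)


def proportion_ci(
    numerator: float,
    denominator: float,
    method: str = "wilson",
    level: float = 0.95,
) -> tuple[float, float] | None:
    """Confidence interval for a proportion with fractional effective counts.

    ``wilson`` (default) and ``wald`` accept non-integer numerator and
    denominator, as produced by the fractional allocation;
    ``clopper-pearson`` rounds both to the nearest integer first (the
    exact beta interval needs integer counts). Returns ``None`` when the
    denominator is zero.
    """
    if denominator == 0:
        return None
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    z = float(stats.norm.ppf(0.5 + level / 2))
    p = numerator / denominator
    n = denominator
    if method == "wilson":
        center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (
            z
            * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
            / (1 + z**2 / n)
        )
        return (max(0.0, center - half), min(1.0, center + half))
    if method == "wald":
        half = z * math.sqrt(p * (1 - p) / n)
        return (max(0.0, p - half), min(1.0, p + half))
    if method == "clopper-pearson":
        k, m = round(numerator), round(denominator)
        alpha = 1 - level
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, m - k + 1))
        hi = 1.0 if k == m else float(stats.beta.ppf(1 - alpha / 2, k + 1, m - k))
        return (lo, hi)
    raise ValueError(f"unknown CI method {method!r}")


def _metric(
    num: Fraction, den: Fraction, ci_method: str
) -> tuple[float | None, tuple[float, float] | None]:
    if den == 0:
        return None, None
    return float(num / den), proportion_ci(float(num), float(den), ci_method)


def aggregate_concordance(
    counts: Sequence[FractionalCounts], ci_method: str = "wilson"
) -> ConcordanceSummary:
    """Sum per-pair fractional counts and derive the cohort metrics.

    concordance = (tp + tn)/n, sensitivity = tp/(tp + fn),
    specificity = tn/(tn + fp), PPV = tp/(tp + fp); a metric is undefined
    (``None``) exactly when its denominator is zero.
    """
    if not counts:
        raise ValueError("aggregate_concordance needs at least one pair")
    totals = FractionalCounts()
    for c in counts:
        totals = totals + c
    n = Fraction(len(counts))
    concordance, concordance_ci = _metric(totals.tp + totals.tn, n, ci_method)
    sensitivity, sensitivity_ci = _metric(
        totals.tp, totals.tp + totals.fn, ci_method
    )
    specificity, specificity_ci = _metric(
        totals.tn, totals.tn + totals.fp, ci_method
    )
    ppv, ppv_ci = _metric(totals.tp, totals.tp + totals.fp, ci_method)
    return ConcordanceSummary(
        n_pairs=len(counts),
        totals=totals,
        concordance_rate=concordance,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        concordance_ci=concordance_ci,
        sensitivity_ci=sensitivity_ci,
        specificity_ci=specificity_ci,
        ppv_ci=ppv_ci,
        ci_method=ci_method,
    )


def concordance_from_pairs(
    pairs: Iterable[SamplePair], ci_method: str = "wilson"
) -> tuple[ConcordanceSummary, pd.DataFrame]:
    """Match, classify and allocate every filtered pair, then aggregate.

    Returns the cohort summary and a per-pair table (category plus the
    four weights as floats).
    """
    rows = []
    counts = []
    for pair in pairs:
        match = match_mutations(pair.tumor, pair.plasma)
        category = classify_pair(match)
        frac = allocate_fractions(match)
        counts.append(frac)
        rows.append(
            {
                "patient_id": pair.patient_id,
                "n_concordant": len(match.concordant),
                "n_tdna_only": len(match.tdna_only),
                "n_ctdna_only": len(match.ctdna_only),
                "category": category.value,
                "tp": float(frac.tp),
                "fp": float(frac.fp),
                "fn": float(frac.fn),
                "tn": float(frac.tn),
            }
        )
    summary = aggregate_concordance(counts, ci_method)
    return summary, pd.DataFrame(rows)


def distinct_mutation_summary(
    n_tdna: int, n_ctdna: int, n_concordant: int, n_positive_pairs: int
) -> dict[str, float]:
    """Reconcile compartment mutation totals into distinct-mutation counts.

    A concordant mutation appears in both compartment tallies, so the
    number of distinct mutations is ``n_tdna + n_ctdna - n_concordant``;
    dividing by the number of mutation-positive pairs gives the average
    mutation burden per positive pair. Both the distinct count and the
    double-counted grand total are reported.
    """
    distinct = n_tdna + n_ctdna - n_concordant
    return {
        "distinct_mutations": distinct,
        "grand_total_double_counted": n_tdna + n_ctdna,
        "mean_per_positive_pair": (
            distinct / n_positive_pairs if n_positive_pairs else math.nan
        ),
    }


def mutation_spectrum(pairs: Sequence[SamplePair]) -> dict:
    """Per-gene and per-class mutation spectrum of a filtered cohort.

    Reports, per compartment: the fraction of samples carrying a mutation
    in each gene (calls without a gene label fall in ``unannotated``) and
    the SNP/MNP/Indel proportions among mutations. Also reconciles
    distinct-mutation totals (each concordant mutation counted once) and
    the average burden per mutation-positive pair.
    """
    n = len(pairs)
    gene_samples: dict[str, dict[str, set[str]]] = {"tumor": {}, "plasma": {}}
    class_counts: dict[str, dict[str, int]] = {"tumor": {}, "plasma": {}}
    n_tdna = n_ctdna = n_concordant = n_positive = 0
    for pair in pairs:
        match = match_mutations(pair.tumor, pair.plasma)
        n_tdna += len(match.concordant) + len(match.tdna_only)
        n_ctdna += len(match.concordant) + len(match.ctdna_only)
        n_concordant += len(match.concordant)
        if match.total > 0:
            n_positive += 1
        for comp, callset in (("tumor", pair.tumor), ("plasma", pair.plasma)):
            seen: set[MutationKey] = set()
            for call in callset:
                if call.key in seen:
                    continue
                seen.add(call.key)
                gene = call.gene or "unannotated"
                gene_samples[comp].setdefault(gene, set()).add(pair.patient_id)
                cls = call.variant_class.value
                class_counts[comp][cls] = class_counts[comp].get(cls, 0) + 1
    gene_rates = {
        comp: {
            gene: len(samples) / n if n else math.nan
            for gene, samples in sorted(d.items())
        }
        for comp, d in gene_samples.items()
    }
    class_props = {}
    for comp, d in class_counts.items():
        total = sum(d.values())
        class_props[comp] = {
            cls: cnt / total for cls, cnt in sorted(d.items())
        } if total else {}
    return {
        "n_pairs": n,
        "gene_sample_rates": gene_rates,
        "class_proportions": class_props,
        **distinct_mutation_summary(n_tdna, n_ctdna, n_concordant, n_positive),
        "n_tdna_mutations": n_tdna,
        "n_ctdna_mutations": n_ctdna,
        "n_concordant_mutations": n_concordant,
        "n_positive_pairs": n_positive,
    }


def pairs_from_listing(listing: pd.DataFrame) -> list[MutationMatch]:
    """Build per-pair matches from a long-format per-mutation listing.

    Expected columns: ``patient_id``, ``compartment`` (``tumor``/``plasma``/
    ``both``), ``chrom``, ``pos``, ``ref``, ``alt``. This is the encoder
    for externally curated per-pair mutation lists (e.g. transcribed
    supplementary tables): one row per mutation per pair, ``both`` marking
    concordant mutations. Patients listed with no mutation rows are
    represented by a row with empty ``chrom``.
    """
    required = {"patient_id", "compartment", "chrom", "pos", "ref", "alt"}
    missing = required - set(listing.columns)
    if missing:
        raise ValueError(f"listing missing columns: {sorted(missing)}")
    matches = []
    for _, group in listing.groupby("patient_id", sort=True):
        tumor: set[MutationKey] = set()
        plasma: set[MutationKey] = set()
        for row in group.itertuples(index=False):
            if not isinstance(row.chrom, str) or not row.chrom:
                continue
            key = (row.chrom, int(row.pos), str(row.ref), str(row.alt))
            comp = str(row.compartment)
            if comp in ("tumor", "both"):
                tumor.add(key)
            if comp in ("plasma", "both"):
                plasma.add(key)
            if comp not in ("tumor", "plasma", "both"):
                raise ValueError(f"unknown compartment {comp!r}")
        matches.append(
            MutationMatch(
                concordant=frozenset(tumor & plasma),
                tdna_only=frozenset(tumor - plasma),
                ctdna_only=frozenset(plasma - tumor),
            )
        )
    return matches
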