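"""Reference-standard validation: assay accuracy and limit of detection.

A dilution series of a mutant plasmid into wild type (nominal fractions
0-1%) is sequenced in replicate; each replicate is "called" with the
plasma per-variant thresholds, and the per-fraction detection rates give
the limit of detection under an explicit, configurable rule. Accuracy is
the fraction of negative (0%) replicates with no call anywhere on the
control panel.

Standards bypass germline subtraction and hotspot filtering: the control
loci are the whole universe of sites, and plasmid context has no
germline. The sample-level mean-depth QC bound is likewise skipped — each
site carries its own simulated depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from ctdna_concord.synthetic_cohort import PanelSite, ReadEvidence, StandardRun
from ctdna_concord.variant_filtering import (
    PLASMA_PROFILE,
    FilterProfile,
    variant_pvalue,
)

DETECTION_RULES = ("majority", "all", "any")


@dataclass(frozen=True)
class LodEstimate:
    """Detection rates per (fraction, site), accuracy, and the LoD.

    ``lod`` is the lowest tested non-zero fraction whose mean per-site
    detection rate satisfies the rule, or ``None`` ("not reached").
    ``accuracy`` is ``None`` when no zero-fraction runs were provided.
    """

    detection_rates: pd.DataFrame  # columns: fraction, site, rate, n_replicates
    accuracy: float | None
    lod: float | None
    rule: str
    threshold: float

    def mean_rate(self, fraction: float) -> float:
        sub = self.detection_rates[self.detection_rates["fraction"] == fraction]
        return float(sub["rate"].mean())


def _passes(ev: ReadEvidence, profile: FilterProfile) -> bool:
    if not ev.alt_reads > profile.min_alt_reads:
        return False
    if ev.depth == 0 or not ev.alt_reads / ev.depth > profile.min_vaf:
        return False
    return variant_pvalue(ev.alt_reads, ev.depth, profile.error_rate) < profile.max_p


def call_standard_run(
    run: StandardRun, profile: FilterProfile = PLASMA_PROFILE
) -> set[PanelSite]:
    """Sites of one replicate whose evidence passes the per-variant
    thresholds (alt reads, VAF and binomial p-value; all strict)."""
    return {site for site, ev in run.sites if _passes(ev, profile)}


def estimate_lod(
    runs: Sequence[StandardRun],
    profile: FilterProfile = PLASMA_PROFILE,
    rule: str = "majority",
    threshold: float | None = None,
) -> LodEstimate:
    """Estimate accuracy and the limit of detection from replicate runs.

    ``rule`` sets the per-fraction criterion on the mean per-site
    detection rate: ``majority`` (>= 0.5, the default), ``all`` (every
    replicate detects every site) or ``any`` (at least one detection);
    ``threshold`` overrides the rate cut directly.
    """
    if rule not in DETECTION_RULES:
        raise ValueError(f"rule must be one of {DETECTION_RULES}")
    if threshold is None:
        threshold = {"majority": 0.5, "all": 1.0, "any": 0.0}[rule]

    by_fraction: dict[float, list[StandardRun]] = {}
    for run in runs:
        by_fraction.setdefault(run.nominal_fraction, []).append(run)

    rows = []
    for frac in sorted(by_fraction):
        reps = by_fraction[frac]
        site_hits: dict[PanelSite, int] = {}
        for run in reps:
            detected = call_standard_run(run, profile)
            for site, _ in run.sites:
                site_hits[site] = site_hits.get(site, 0) + (site in detected)
        for site, hits in site_hits.items():
            rows.append(
                {
                    "fraction": frac,
                    "site": f"{site.gene}:{site.chrom}:{site.pos}",
                    "rate": hits / len(reps),
                    "n_replicates": len(reps),
                }
            )
    rates = pd.DataFrame(
        rows, columns=["fraction", "site", "rate", "n_replicates"]
    )

    if 0.0 in by_fraction:
        negatives = by_fraction[0.0]
        clean = sum(
            1 for run in negatives if not call_standard_run(run, profile)
        )
        accuracy = clean / len(negatives)
    else:
        warnings.warn("no zero-fraction runs: accuracy undefined", stacklevel=2)
        accuracy = None

    lod = None
    for frac in sorted(f for f in by_fraction if f > 0):
        sub = rates[rates["fraction"] == frac]
        mean_rate = float(sub["rate"].mean()) if len(sub) else 0.0
        if rule == "any":
            ok = mean_rate > 0.0
        else:
            ok = mean_rate >= threshold
        if ok:
            lod = frac
            break

    return LodEstimate(
        detection_rates=rates,
        accuracy=accuracy,
        lod=lod,
        rule=rule,
        threshold=threshold,
    )


def detection_probability(
    fraction: float,
    depth: int,
    error_rate: float = 0.0,
    profile: FilterProfile = PLASMA_PROFILE,
) -> float:
    """Closed-form probability that one site passes the thresholds.

    With ``X ~ Binomial(depth, q)``, ``q = fraction + (1 - fraction) *
    error_rate``, the pass region in the alt-read count is an upper set
    (every criterion is monotone in X), so the probability is the
    binomial upper tail above the smallest passing count.
    """
    q = fraction + (1.0 - fraction) * error_rate
    k_min = None
    for k in range(depth + 1):
        if (
            k > profile.min_alt_reads
            and k / depth > profile.min_vaf
            and variant_pvalue(k, depth, profile.error_rate) < profile.max_p
        ):
            k_min = k
            break
    if k_min is None:
        return 0.0
    return float(stats.binom.sf(k_min - 1, depth, q))
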