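"""Three-step somatic variant filtering for tissue and plasma call sets.

Step one applies the published numeric thresholds (sample-level mean depth,
per-variant coverage, VAF and caller p-value, all strict inequalities
exactly as printed: tissue mean depth >1000, variant coverage >20, VAF >5%,
p < 0.01; plasma mean depth >10000, coverage >10, VAF >0.1%, p < 0.01).
Step two removes strand-specific errors with a two-sided Fisher exact test
on the ref/alt-by-strand table — an automated stand-in for the manual IGV
review such pipelines traditionally use. Step three restricts calls to the
hotspot panel. Germline variants are then subtracted against the matched
white-blood-cell call set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from ctdna_concord.core_io import (
    HotspotRegions,
    SampleCallSet,
    SamplePair,
    SampleType,
    VariantCall,
)


class Disposition(str, enum.Enum):
    """Which pipeline step removed a call (or ``kept``)."""

    KEPT = "kept"
    MEAN_DEPTH = "mean_depth"
    ALT_READS = "alt_reads"
    VAF = "vaf"
    P_VALUE = "p_value"
    STRAND_BIAS = "strand_bias"
    HOTSPOT = "hotspot"
    GERMLINE = "germline"


@dataclass(frozen=True)
class FilterProfile:
    """Numeric thresholds for one compartment; comparisons are strict.

    ``error_rate`` is the per-base substitution error against which a
    binomial p-value is computed when a call carries none of its own.
    """

    name: str
    min_mean_depth: float
    min_alt_reads: int
    min_vaf: float
    max_p: float
    strand_bias_alpha: float = 1e-3
    apply_hotspot: bool = True
    error_rate: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.min_mean_depth, self.min_alt_reads, self.min_vaf) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 < self.strand_bias_alpha < 1:
            raise ValueError("strand_bias_alpha must be in (0, 1)")


TISSUE_PROFILE = FilterProfile(
    name="tissue", min_mean_depth=1000, min_alt_reads=20, min_vaf=0.05, max_p=0.01
)
PLASMA_PROFILE = FilterProfile(
    name="plasma", min_mean_depth=10000, min_alt_reads=10, min_vaf=0.001, max_p=0.01
)


@dataclass
class FilterTrace:
    """Per-call audit record: exactly one disposition per input call."""

    records: list[tuple[VariantCall, Disposition]] = field(default_factory=list)

    def add(self, call: VariantCall, disposition: Disposition) -> None:
        self.records.append((call, disposition))

    def extend(self, other: "FilterTrace") -> None:
        self.records.extend(other.records)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, d in self.records:
            out[d.value] = out.get(d.value, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": c.sample_id,
                "sample_type": c.sample_type.value,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "depth": c.depth,
                "alt_reads": c.alt_reads,
                "disposition": d.value,
            }
            for c, d in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id", "sample_type", "chrom", "pos", "ref", "alt",
                "depth", "alt_reads", "disposition",
            ],
        )

    def __len__(self) -> int:
        return len(self.records)


def variant_pvalue(alt_reads: int, depth: int, error_rate: float) -> float:
    """Upper-tail binomial probability of >= ``alt_reads`` error reads.

    ``P[X >= alt_reads]`` for ``X ~ Binomial(depth, error_rate)``, the
    probability that sequencing error alone produces at least the observed
    alternate support. Evaluated through the regularized incomplete beta
    function, which is exact (to float precision) at any depth.

    Limiting cases: ``alt_reads == 0`` gives 1 (the whole sample space);
    ``error_rate == 0`` with ``alt_reads > 0`` gives 0.
    """
    if not 0 <= alt_reads <= depth:
        raise ValueError("need 0 <= alt_reads <= depth")
    if not 0 <= error_rate < 1:
        raise ValueError("need 0 <= error_rate < 1")
    if alt_reads == 0:
        return 1.0
    return float(stats.binom.sf(alt_reads - 1, depth, error_rate))


def call_pvalue(call: VariantCall, profile: FilterProfile) -> float:
    """The call's own p-value, or the binomial stand-in when absent."""
    if call.p_value is not None:
        return call.p_value
    return variant_pvalue(call.alt_reads, call.depth, profile.error_rate)


def apply_threshold_filter(
    callset: SampleCallSet, profile: FilterProfile
) -> tuple[SampleCallSet, FilterTrace]:
    """Step one: sample-level mean-depth QC plus per-call thresholds.

    A failing sample-level mean depth removes every call with disposition
    ``mean_depth`` (QC semantics, not an error). Otherwise a call survives
    iff ``alt_reads > min_alt_reads`` and ``VAF > min_vaf`` and
    ``p < max_p``, all strict. A zero-depth call has undefined VAF and is
    removed with disposition ``vaf``.
    """
    trace = FilterTrace()
    if not callset.mean_depth > profile.min_mean_depth:
        for call in callset:
            trace.add(call, Disposition.MEAN_DEPTH)
        return callset.with_calls(()), trace
    kept = []
    for call in callset:
        if call.depth == 0:
            trace.add(call, Disposition.VAF)  # VAF undefined == fail
        elif not call.alt_reads > profile.min_alt_reads:
            trace.add(call, Disposition.ALT_READS)
        elif not call.vaf > profile.min_vaf:
            trace.add(call, Disposition.VAF)
        elif not call_pvalue(call, profile) < profile.max_p:
            trace.add(call, Disposition.P_VALUE)
        else:
            trace.add(call, Disposition.KEPT)
            kept.append(call)
    return callset.with_calls(kept), trace


def strand_bias_pvalue(call: VariantCall) -> float:
    """Two-sided Fisher exact p on [[ref_fwd, ref_rev], [alt_fwd, alt_rev]]."""
    table = [[call.ref_fwd, call.ref_rev], [call.alt_fwd, call.alt_rev]]
    if sum(table[0]) + sum(table[1]) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def strand_bias_filter(call: VariantCall, alpha: float = 1e-3) -> bool:
    """Step two: keep unless the strand distribution of alt vs ref reads
    departs from independence at level ``alpha`` (Fisher exact, two-sided).

    Degenerate all-zero tables carry no evidence and are kept.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return strand_bias_pvalue(call) >= alpha


def apply_strand_bias_filter(
    callset: SampleCallSet, alpha: float = 1e-3
) -> tuple[SampleCallSet, FilterTrace]:
    trace = FilterTrace()
    kept = []
    for call in callset:
        if strand_bias_filter(call, alpha):
            trace.add(call, Disposition.KEPT)
            kept.append(call)
        else:
            trace.add(call, Disposition.STRAND_BIAS)
    return callset.with_calls(kept), trace


def hotspot_filter(
    callset: SampleCallSet, regions: HotspotRegions
) -> tuple[SampleCallSet, FilterTrace]:
    """Step three: keep only calls whose position lies in a hotspot region."""
    trace = FilterTrace()
    kept = []
    for call in callset:
        if regions.contains(call.chrom, call.pos):
            trace.add(call, Disposition.KEPT)
            kept.append(call)
        else:
            trace.add(call, Disposition.HOTSPOT)
    return callset.with_calls(kept), trace


def subtract_germline(
    callset: SampleCallSet, wbc: SampleCallSet
) -> tuple[SampleCallSet, FilterTrace]:
    """Remove calls whose mutation key also appears in the WBC call set.

    Variants carried by white blood cells are germline by definition; an
    empty WBC set leaves the input unchanged.
    """
    germline_keys = wbc.keys()
    trace = FilterTrace()
    kept = []
    for call in callset:
        if call.key in germline_keys:
            trace.add(call, Disposition.GERMLINE)
        else:
            trace.add(call, Disposition.KEPT)
            kept.append(call)
    return callset.with_calls(kept), trace


def _filter_compartment(
    callset: SampleCallSet,
    profile: FilterProfile,
    regions: HotspotRegions | None,
) -> tuple[SampleCallSet, FilterTrace]:
    """threshold -> strand bias -> hotspot; final dispositions only.

    Each step is a pure predicate on the call, so the surviving set does
    not depend on stage order — only the attributed dispositions do.
    """
    trace = FilterTrace()
    out, t1 = apply_threshold_filter(callset, profile)
    trace.records.extend(r for r in t1.records if r[1] is not Disposition.KEPT)
    out, t2 = apply_strand_bias_filter(out, profile.strand_bias_alpha)
    trace.records.extend(r for r in t2.records if r[1] is not Disposition.KEPT)
    if profile.apply_hotspot and regions is not None:
        out, t3 = hotspot_filter(out, regions)
        trace.records.extend(
            r for r in t3.records if r[1] is not Disposition.KEPT
        )
    for call in out:
        trace.add(call, Disposition.KEPT)
    return out, trace


def run_filter_pipeline(
    pair: SamplePair,
    tissue_profile: FilterProfile = TISSUE_PROFILE,
    plasma_profile: FilterProfile = PLASMA_PROFILE,
    regions: HotspotRegions | None = None,
    wbc_profile: FilterProfile | None = None,
) -> tuple[SamplePair, dict[str, FilterTrace]]:
    """Filter a patient's tumor/plasma/WBC call sets end to end.

    Tumor and plasma go through threshold, strand-bias and hotspot steps
    and then germline subtraction against the (threshold-filtered) WBC
    set. WBC calls pass only threshold filtering, since they serve as the
    germline reference rather than a somatic profile. Returns the filtered
    pair and one trace per compartment (germline-subtraction dispositions
    overwrite the final ``kept`` rows of the somatic traces).
    """
    wbc_profile = wbc_profile or tissue_profile
    wbc_filtered, wbc_trace = apply_threshold_filter(pair.wbc, wbc_profile)

    traces: dict[str, FilterTrace] = {"wbc": wbc_trace}
    filtered = {}
    for name, callset, profile in (
        ("tumor", pair.tumor, tissue_profile),
        ("plasma", pair.plasma, plasma_profile),
    ):
        out, trace = _filter_compartment(callset, profile, regions)
        out, gl_trace = subtract_germline(out, wbc_filtered)
        surviving = {id(r[0]) for r in gl_trace.records}
        trace.records = [
            r for r in trace.records
            if not (r[1] is Disposition.KEPT and id(r[0]) in surviving)
        ]
        trace.records.extend(gl_trace.records)
        traces[name] = trace
        filtered[name] = out

    return (
        SamplePair(
            patient_id=pair.patient_id,
            tumor=filtered["tumor"],
            plasma=filtered["plasma"],
            wbc=wbc_filtered,
        ),
        traces,
    )


def filter_cohort(
    pairs: Iterable[SamplePair],
    tissue_profile: FilterProfile = TISSUE_PROFILE,
    plasma_profile: FilterProfile = PLASMA_PROFILE,
    regions: HotspotRegions | None = None,
) -> tuple[list[SamplePair], list[dict[str, FilterTrace]]]:
    """Apply :func:`run_filter_pipeline` to every pair of a cohort."""
    filtered, traces = [], []
    for pair in pairs:
        fp, tr = run_filter_pipeline(
            pair, tissue_profile, plasma_profile, regions
        )
        filtered.append(fp)
        traces.append(tr)
    return filtered, traces
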