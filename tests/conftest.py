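import pytest

from ctdna_concord.core_io import SampleCallSet, SampleType, VariantCall
from ctdna_concord.synthetic_cohort import (
    CohortConfig,
    build_panel,
    simulate_cohort,
)


def make_call(
    chrom="chr7",
    pos=55_241_705,
    ref="C",
    alt="T",
    depth=10_000,
    alt_reads=100,
    sample_id="S1",
    sample_type=SampleType.PLASMA,
    balanced_strands=True,
    **kwargs,
):
    """A plausible variant call with evenly split strands by default."""
    if balanced_strands:
        kwargs.setdefault("alt_fwd", alt_reads // 2)
        kwargs.setdefault("alt_rev", alt_reads - alt_reads // 2)
        ref_reads = depth - alt_reads
        kwargs.setdefault("ref_fwd", ref_reads // 2)
        kwargs.setdefault("ref_rev", ref_reads - ref_reads // 2)
    kwargs.setdefault("p_value", 1e-6)
    return VariantCall(
        sample_id=sample_id,
        sample_type=sample_type,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        depth=depth,
        alt_reads=alt_reads,
        **kwargs,
    )


def make_callset(calls, sample_type=SampleType.PLASMA, mean_depth=12_000,
                 sample_id="S1"):
    return SampleCallSet(
        sample_id=sample_id,
        sample_type=sample_type,
        mean_depth=mean_depth,
        calls=tuple(calls),
    )


@pytest.fixture(scope="session")
def panel():
    return build_panel()


@pytest.fixture(scope="session")
def default_cohort():
    """The full 58-patient cohort under default study conditions."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(
        n_patients=10,
        stage_counts={"IA": 5, "IB": 3, "IIA": 2},
        histology_counts={"AC": 9, "SCC": 1},
        seed=7,
    )
    return simulate_cohort(cfg)
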