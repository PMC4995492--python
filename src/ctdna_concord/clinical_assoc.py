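"""cfDNA-concentration associations with clinical features, and the
cfDNA-versus-serum-tumor-marker detection comparison.

Each clinical feature induces a two-group split of the cohort (age
dichotomized at 65, stage I vs II, GGO-dominant vs solid-dominant, etc.)
and group cfDNA concentrations are compared with the Mann-Whitney U test.
Group summaries report mean +/- SD alongside median/IQR, since skewed
cfDNA distributions are better described by the latter.

Serum markers are called positive at or above the standard clinical
cut-offs (negativity is defined by strict '<'): CA125 35 U/ml, CA19-9
39 U/ml, CEA 4.7 ng/ml, CYFRA21-1 3.3 ng/ml, NSE 16.3 ng/ml. In an
all-cancer cohort the "positive predictive value" of a test reduces to
its detection rate, and the comparison report labels it as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ctdna_concord.core_io import (
    ClinicalRecord,
    Histology,
    MARKER_NAMES,
    Sex,
)

#: Serum marker cut-offs; a sample is negative strictly below the cut-off.
MARKER_CUTOFFS: Mapping[str, float] = {
    "CA125": 35.0,      # U/ml
    "CA19_9": 39.0,     # U/ml
    "CEA": 4.7,         # ng/ml
    "CYFRA21_1": 3.3,   # ng/ml
    "NSE": 16.3,        # ng/ml
}

AGE_CUT = 65.0


@dataclass(frozen=True)
class AssociationRow:
    """One clinical feature's two-group cfDNA comparison."""

    feature: str
    groups: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]
    median: tuple[float, float]
    iqr: tuple[tuple[float, float], tuple[float, float]]
    u_statistic: float | None
    p_value: float | None

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "groups": list(self.groups),
            "n": list(self.n),
            "mean": list(self.mean),
            "sd": list(self.sd),
            "median": list(self.median),
            "iqr": [list(q) for q in self.iqr],
            "U": self.u_statistic,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class MarkerResult:
    """Per-patient marker panel and cfDNA positivity."""

    patient_id: str
    positive: Mapping[str, bool]
    any_positive: bool
    cfdna_positive: bool


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U (for ``x``) with a two-sided p-value.

    U is computed from midranks, so ties contribute half-wins. The
    p-value is exact (full enumeration) for small untied samples and a
    tie-corrected, continuity-corrected normal approximation otherwise.
    Two samples whose pooled values are all identical carry no ordering
    information and return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return u, 1.0
    method = "exact" if (len(x) + len(y) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return u, min(p, 1.0)


#: Default feature splits; each maps a record to a group index (0/1) and
#: carries the two group labels.
FeatureSplit = tuple[str, tuple[str, str], Callable[[ClinicalRecord], int]]

DEFAULT_FEATURES: tuple[FeatureSplit, ...] = (
    ("age", ("<65", ">=65"), lambda r: int(r.age >= AGE_CUT)),
    ("sex", ("F", "M"), lambda r: int(r.sex is Sex.M)),
    ("ggo", ("solid-dominant", "GGO-dominant"), lambda r: int(r.ggo_dominant)),
    (
        "differentiation",
        ("median_or_high", "poor"),
        lambda r: int(r.differentiation.value == "poor"),
    ),
    ("vascular_invasion", ("N", "Y"), lambda r: int(r.vascular_invasion)),
    ("vpi", ("N", "Y"), lambda r: int(r.vpi)),
    ("histology", ("SCC", "AC"), lambda r: int(r.histology is Histology.AC)),
    ("stage", ("I", "II"), lambda r: int(r.stage.numeric == 2)),
)


def _summary(values: np.ndarray) -> tuple[float, float, float, tuple[float, float]]:
    if len(values) == 0:
        nan = float("nan")
        return nan, nan, nan, (nan, nan)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    median = float(np.median(values))
    q1, q3 = (float(q) for q in np.percentile(values, [25, 75]))
    return mean, sd, median, (q1, q3)


def cfdna_feature_table(
    records: Sequence[ClinicalRecord],
    features: Sequence[FeatureSplit] = DEFAULT_FEATURES,
) -> list[AssociationRow]:
    """One two-group cfDNA-concentration comparison per clinical feature.

    A feature with an empty group still yields a row, with undefined U
    and p (and a warning) rather than an error.
    """
    rows = []
    for name, labels, splitter in features:
        groups: tuple[list[float], list[float]] = ([], [])
        for r in records:
            groups[splitter(r)].append(r.cfdna_conc)
        g0, g1 = (np.asarray(g, dtype=float) for g in groups)
        m0, s0, med0, iqr0 = _summary(g0)
        m1, s1, med1, iqr1 = _summary(g1)
        if len(g0) == 0 or len(g1) == 0:
            warnings.warn(f"feature {name}: empty group, p undefined",
                          stacklevel=2)
            u = p = None
        else:
            u, p = mann_whitney_u(g0, g1)
        rows.append(
            AssociationRow(
                feature=name,
                groups=labels,
                n=(len(g0), len(g1)),
                mean=(m0, m1),
                sd=(s0, s1),
                median=(med0, med1),
                iqr=(iqr0, iqr1),
                u_statistic=u,
                p_value=p,
            )
        )
    return rows


def marker_positivity(
    record: ClinicalRecord,
    cutoffs: Mapping[str, float] = MARKER_CUTOFFS,
    cfdna_floor: float = 0.0,
) -> MarkerResult:
    """Classify one patient's marker panel and cfDNA detectability.

    A marker is positive at or above its cut-off; a missing value counts
    as not positive (with a warning). cfDNA is positive when the
    concentration exceeds the quantification floor (default 0 ng/ml).
    Negative marker values are physically impossible and raise.
    """
    positive: dict[str, bool] = {}
    for name in MARKER_NAMES:
        value = record.markers.get(name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            warnings.warn(
                f"patient {record.patient_id}: marker {name} missing, "
                "treated as not positive",
                stacklevel=2,
            )
            positive[name] = False
            continue
        if value < 0:
            raise ValueError(
                f"patient {record.patient_id}: negative {name} value {value}"
            )
        positive[name] = value >= cutoffs[name]
    return MarkerResult(
        patient_id=record.patient_id,
        positive=positive,
        any_positive=any(positive.values()),
        cfdna_positive=record.cfdna_conc > cfdna_floor,
    )


def detection_comparison(
    records: Iterable[ClinicalRecord],
    cutoffs: Mapping[str, float] = MARKER_CUTOFFS,
    cfdna_floor: float = 0.0,
) -> dict:
    """Compare serum-marker and cfDNA detection over a confirmed-cancer
    cohort.

    Reports per-marker positive counts, the union ("any marker") count
    and rate, and the cfDNA-positive count and rate. All patients being
    diseased, each rate is a detection rate (what a same-design study
    would call the test's positive predictive value).
    """
    results = [marker_positivity(r, cutoffs, cfdna_floor) for r in records]
    n = len(results)
    per_marker = {
        name: sum(r.positive[name] for r in results) for name in MARKER_NAMES
    }
    any_pos = sum(r.any_positive for r in results)
    cfdna_pos = sum(r.cfdna_positive for r in results)
    return {
        "n": n,
        "per_marker_positive": per_marker,
        "any_marker_positive": any_pos,
        "any_marker_detection_rate": any_pos / n if n else None,
        "cfdna_positive": cfdna_pos,
        "cfdna_detection_rate": cfdna_pos / n if n else None,
        "note": (
            "all patients are confirmed cancer cases, so each detection "
            "rate is also the test's positive predictive value in this "
            "cohort"
        ),
    }
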