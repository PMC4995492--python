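"""Domain types and readers/writers for the formats the pipeline touches.

Conventions, fixed here and nowhere else:

* variant positions are 1-based (VCF convention);
* hotspot regions are 0-based half-open intervals (BED convention);
* the single conversion rule lives in :func:`position_in_region`;
* mutation identity is ``(chrom, pos, ref, alt)`` after trimming shared
  allele prefix/suffix (:func:`normalize_variant`), never gene labels.
"""

from __future__ import annotations

import enum
import math
import re
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

MARKER_NAMES = ("CA125", "CA19_9", "CEA", "CYFRA21_1", "NSE")


class SampleType(str, enum.Enum):
    TUMOR = "tumor"
    PLASMA = "plasma"
    WBC = "wbc"


class VariantClass(str, enum.Enum):
    SNP = "SNP"
    MNP = "MNP"
    INDEL = "Indel"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Histology(str, enum.Enum):
    AC = "AC"
    SCC = "SCC"


class Stage(str, enum.Enum):
    IA = "IA"
    IB = "IB"
    IIA = "IIA"

    @property
    def numeric(self) -> int:
        """Stage group: 1 for IA/IB, 2 for IIA."""
        return 2 if self is Stage.IIA else 1


class Differentiation(str, enum.Enum):
    MEDIAN_OR_HIGH = "median_or_high"
    POOR = "poor"


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared allele suffix then prefix, adjusting the 1-based position.

    This is reference-free left-trimming: it makes the common redundant
    indel spellings (``GGT>GG`` vs ``GT>G``) compare equal, which is all
    the pipeline needs since identity is positional, not annotated.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def classify_variant(ref: str, alt: str) -> VariantClass:
    """SNP if both alleles are single bases, MNP if equal length >1, else Indel."""
    _, ref, alt = normalize_variant(1, ref, alt)
    if len(ref) == len(alt):
        return VariantClass.SNP if len(ref) == 1 else VariantClass.MNP
    return VariantClass.INDEL


def position_in_region(pos: int, start: int, end: int) -> bool:
    """Is 1-based ``pos`` inside the 0-based half-open ``[start, end)``?

    Equivalent to ``start < pos <= end`` on the 1-based scale.
    """
    return start <= pos - 1 < end


@dataclass(frozen=True)
class VariantCall:
    """One called variant with its read evidence.

    ``alt_fwd``/``alt_rev`` (and ``ref_fwd``/``ref_rev``) are read-orientation
    counts as emitted by the caller; no reference-strand normalization is
    attempted. ``p_value`` is the caller's confidence that the variant is not
    a sequencing error (smaller = more confident).
    """

    sample_id: str
    sample_type: SampleType
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    alt_fwd: int = 0
    alt_rev: int = 0
    ref_fwd: int = 0
    ref_rev: int = 0
    p_value: float | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} exceeds depth {self.depth} "
                f"at {self.chrom}:{self.pos}"
            )
        if self.alt_fwd + self.alt_rev not in (0, self.alt_reads):
            raise ValueError(
                f"strand counts {self.alt_fwd}+{self.alt_rev} do not sum to "
                f"alt_reads {self.alt_reads} at {self.chrom}:{self.pos}"
            )
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def vaf(self) -> float:
        """Variant allele frequency alt_reads/depth; NaN at zero depth."""
        return self.alt_reads / self.depth if self.depth > 0 else math.nan

    @property
    def variant_class(self) -> VariantClass:
        return classify_variant(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized mutation identity (chrom, pos, ref, alt)."""
        pos, ref, alt = normalize_variant(self.pos, self.ref, self.alt)
        return (self.chrom, pos, ref, alt)


@dataclass(frozen=True)
class SampleCallSet:
    """All calls for one sample plus its panel-wide average coverage depth."""

    sample_id: str
    sample_type: SampleType
    mean_depth: float
    calls: tuple[VariantCall, ...]

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        for c in self.calls:
            if c.sample_id != self.sample_id or c.sample_type != self.sample_type:
                raise ValueError(
                    f"call {c.chrom}:{c.pos} sample {c.sample_id}/{c.sample_type} "
                    f"does not match set {self.sample_id}/{self.sample_type}"
                )

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    def with_calls(self, calls: Iterable[VariantCall]) -> "SampleCallSet":
        return replace(self, calls=tuple(calls))

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {c.key for c in self.calls}


@dataclass(frozen=True)
class SamplePair:
    """One patient's tumor, plasma and (possibly empty) WBC call sets."""

    patient_id: str
    tumor: SampleCallSet
    plasma: SampleCallSet
    wbc: SampleCallSet

    def __post_init__(self) -> None:
        expected = {
            "tumor": SampleType.TUMOR,
            "plasma": SampleType.PLASMA,
            "wbc": SampleType.WBC,
        }
        for attr, want in expected.items():
            got = getattr(self, attr).sample_type
            if got != want:
                raise ValueError(f"{attr} call set has sample_type {got}")


@dataclass
class HotspotRegions:
    """Hotspot panel intervals, 0-based half-open, kept in file order.

    Intervals may overlap; no merging is performed.
    """

    regions: list[tuple[str, int, int, str | None]] = field(default_factory=list)
    _trees: dict[str, IntervalTree] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for chrom, start, end, _ in self.regions:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.regions)

    def _tree(self, chrom: str) -> IntervalTree | None:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for c, s, e, _ in self.regions:
                trees.setdefault(c, IntervalTree()).addi(s, e)
            object.__setattr__(self, "_trees", trees)
        return self._trees.get(chrom)

    def contains(self, chrom: str, pos: int) -> bool:
        """Does the 1-based position fall inside any region?"""
        tree = self._tree(chrom)
        return bool(tree is not None and tree[pos - 1])


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical covariates, cfDNA concentration and serum marker panel.

    ``cfdna_conc`` is in ng per ml plasma; marker units are U/ml for CA125
    and CA19-9, ng/ml for CEA, CYFRA21-1 and NSE.
    """

    patient_id: str
    age: float
    sex: Sex
    histology: Histology
    stage: Stage
    smoker: bool
    ggo_proportion: float
    differentiation: Differentiation
    vascular_invasion: bool
    vpi: bool
    cfdna_conc: float
    markers: Mapping[str, float]

    def __post_init__(self) -> None:
        # accept plain strings for the enum fields
        for name, cls in (
            ("sex", Sex), ("histology", Histology), ("stage", Stage),
            ("differentiation", Differentiation),
        ):
            value = getattr(self, name)
            if not isinstance(value, cls):
                object.__setattr__(self, name, _parse_enum(cls, value, name))
        if not 0.0 <= self.ggo_proportion <= 1.0:
            raise ValueError("ggo_proportion outside [0, 1]")
        if self.cfdna_conc < 0:
            raise ValueError("cfdna_conc must be >= 0")

    @property
    def ggo_dominant(self) -> bool:
        """Ground-glass-opacity proportion strictly above 50%."""
        return self.ggo_proportion > 0.5


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

#: INFO keys used by the minimal VCF dialect (Torrent-caller style strand keys).
VCF_FIELDS = {
    "depth": "DP",
    "alt_reads": "AO",
    "alt_fwd": "SAF",
    "alt_rev": "SAR",
    "ref_fwd": "SRF",
    "ref_rev": "SRR",
    "p_value": "PVAL",
    "gene": "GENE",
}

_VCF_HEADER_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observations">',
    '##INFO=<ID=SAF,Number=A,Type=Integer,Description="Alt observations on forward strand">',
    '##INFO=<ID=SAR,Number=A,Type=Integer,Description="Alt observations on reverse strand">',
    '##INFO=<ID=SRF,Number=1,Type=Integer,Description="Ref observations on forward strand">',
    '##INFO=<ID=SRR,Number=1,Type=Integer,Description="Ref observations on reverse strand">',
    '##INFO=<ID=PVAL,Number=A,Type=Float,Description="Caller variant p-value">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
]


def _info_scalar(value, idx: int):
    """INFO values may be scalars or per-ALT tuples after multi-allelic split."""
    if isinstance(value, (tuple, list)):
        return value[idx]
    return value


def read_vcf_calls(
    path: str | Path,
    sample_id: str,
    sample_type: SampleType | str,
    fields: Mapping[str, str] = VCF_FIELDS,
    mean_depth: float | None = None,
) -> SampleCallSet:
    """Read a VCF into a :class:`SampleCallSet`, one call per ALT allele.

    Depth/alt-read/strand counts are taken from the INFO keys named in
    ``fields`` (defaults cover the dialect written by
    :func:`write_vcf_calls`). Multi-allelic records are split. The set's
    ``mean_depth`` is, in order of precedence: the ``mean_depth``
    argument, a ``mean_depth=`` annotation in a header ``##source`` line
    (the panel-wide average, as written by :func:`write_vcf_calls`), or
    the arithmetic mean of DP over the called records.

    Raises :class:`ValueError` naming the record when DP or AO is missing.
    """
    sample_type = SampleType(sample_type)
    calls: list[VariantCall] = []
    depths: list[int] = []
    with pysam.VariantFile(str(path)) as vcf:
        if mean_depth is None:
            m = re.search(r"mean_depth=([0-9.eE+-]+)", str(vcf.header))
            if m:
                mean_depth = float(m.group(1))
        for rec in vcf:
            info = dict(rec.info)
            if fields["depth"] not in info or fields["alt_reads"] not in info:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} lacks required "
                    f"{fields['depth']}/{fields['alt_reads']} INFO fields"
                )
            depth = int(info[fields["depth"]])
            depths.append(depth)
            for i, alt in enumerate(rec.alts or ()):
                def get(name: str, default=None):
                    key = fields.get(name)
                    if key is None or key not in info:
                        return default
                    return _info_scalar(info[key], i)

                pval = get("p_value")
                gene = get("gene")
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        sample_type=sample_type,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        depth=depth,
                        alt_reads=int(get("alt_reads")),
                        alt_fwd=int(get("alt_fwd", 0)),
                        alt_rev=int(get("alt_rev", 0)),
                        ref_fwd=int(get("ref_fwd", 0)),
                        ref_rev=int(get("ref_rev", 0)),
                        p_value=float(pval) if pval is not None else None,
                        gene=str(gene) if gene is not None else None,
                    )
                )
    if mean_depth is None:
        mean_depth = statistics.fmean(depths) if depths else 0.0
    return SampleCallSet(
        sample_id=sample_id,
        sample_type=sample_type,
        mean_depth=mean_depth,
        calls=tuple(calls),
    )


def write_vcf_calls(callset: SampleCallSet, path: str | Path) -> None:
    """Write a minimal self-contained VCF v4.2 (one record per call)."""
    contigs = sorted({c.chrom for c in callset.calls})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=ctdna-concord;sample={callset.sample_id};"
                 f"type={callset.sample_type.value};"
                 f"mean_depth={callset.mean_depth:g}\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(callset.calls, key=lambda c: (c.chrom, c.pos, c.alt)):
            info = (
                f"DP={c.depth};AO={c.alt_reads};SAF={c.alt_fwd};SAR={c.alt_rev};"
                f"SRF={c.ref_fwd};SRR={c.ref_rev}"
            )
            if c.p_value is not None:
                info += f";PVAL={c.p_value:.6g}"
            if c.gene:
                info += f";GENE={c.gene}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed_regions(path: str | Path) -> HotspotRegions:
    """Read a 3+ column BED (0-based half-open) preserving file order."""
    regions: list[tuple[str, int, int, str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"line {lineno}: start {start} >= end {end}"
                )
            label = parts[3] if len(parts) > 3 else None
            regions.append((chrom, start, end, label))
    return HotspotRegions(regions=regions)


def write_bed_regions(regions: HotspotRegions, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in regions.regions:
            row = f"{chrom}\t{start}\t{end}"
            if label is not None:
                row += f"\t{label}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "patient_id", "age", "sex", "histology", "stage", "smoker",
    "ggo_proportion", "differentiation", "vascular_invasion", "vpi",
    "cfdna_conc", *MARKER_NAMES,
]

_BOOL_COLUMNS = ("smoker", "vascular_invasion", "vpi")


def _parse_enum(cls, value, column: str):
    try:
        return cls(str(value))
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValueError(
            f"column {column}: unknown value {value!r} (allowed: {allowed})"
        ) from None


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read the tab-separated clinical table, one record per row.

    Expected columns: ``patient_id age sex histology stage smoker
    ggo_proportion differentiation vascular_invasion vpi cfdna_conc
    CA125 CA19_9 CEA CYFRA21_1 NSE`` (booleans as 0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ClinicalRecord(
                patient_id=row.patient_id,
                age=float(row.age),
                sex=_parse_enum(Sex, row.sex, "sex"),
                histology=_parse_enum(Histology, row.histology, "histology"),
                stage=_parse_enum(Stage, row.stage, "stage"),
                smoker=bool(int(row.smoker)),
                ggo_proportion=float(row.ggo_proportion),
                differentiation=_parse_enum(
                    Differentiation, row.differentiation, "differentiation"
                ),
                vascular_invasion=bool(int(row.vascular_invasion)),
                vpi=bool(int(row.vpi)),
                cfdna_conc=float(row.cfdna_conc),
                markers={m: float(getattr(row, m)) for m in MARKER_NAMES},
            )
        )
    return records


def write_clinical_table(
    records: Sequence[ClinicalRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex.value,
            "histology": r.histology.value,
            "stage": r.stage.value,
            "smoker": int(r.smoker),
            "ggo_proportion": r.ggo_proportion,
            "differentiation": r.differentiation.value,
            "vascular_invasion": int(r.vascular_invasion),
            "vpi": int(r.vpi),
            "cfdna_conc": r.cfdna_conc,
        }
        row.update({m: r.markers.get(m, float("nan")) for m in MARKER_NAMES})
        rows.append(row)
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
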