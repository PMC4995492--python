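"""Synthetic cohorts and reference-standard runs.

The generator emulates a prospective early-stage NSCLC liquid-biopsy
cohort: 58 patients (stage IA/IB/IIA, adenocarcinoma-dominated), a
50-gene / 739-site hotspot panel, tumor-tissue sequencing at roughly
2,000x and plasma at roughly 12,000x, tumor VAFs of 5-60%, plasma VAFs
log-normally distributed around a ~0.9% median, partial shedding of tumor
mutations into plasma plus plasma-private mutations, germline variants
present in all three compartments, sequencing-noise and strand-artifact
and off-target calls for the filters to remove, and cfDNA concentrations
with multiplicative stage-II and GGO-dominance effects. Serum tumor
markers are drawn log-normally with scales calibrated to the positivity
rates such cohorts show at the standard cut-offs.

Every random draw flows from one master seed through per-patient
substreams, so outputs are reproducible independent of iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ctdna_concord.core_io import (
    ClinicalRecord,
    Differentiation,
    Histology,
    HotspotRegions,
    SampleCallSet,
    SamplePair,
    SampleType,
    Sex,
    Stage,
    VariantCall,
    write_bed_regions,
    write_clinical_table,
    write_vcf_calls,
)
from ctdna_concord.variant_filtering import variant_pvalue

# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

#: 50 cancer genes of a hotspot amplicon panel.
PANEL_GENES = (
    "ABL1", "AKT1", "ALK", "APC", "ATM", "BRAF", "CDH1", "CDKN2A", "CSF1R",
    "CTNNB1", "EGFR", "ERBB2", "ERBB4", "EZH2", "FBXW7", "FGFR1", "FGFR2",
    "FGFR3", "FLT3", "GNA11", "GNAQ", "GNAS", "HNF1A", "HRAS", "IDH1",
    "IDH2", "JAK2", "JAK3", "KDR", "KIT", "KRAS", "MET", "MLH1", "MPL",
    "NOTCH1", "NPM1", "NRAS", "PDGFRA", "PIK3CA", "PTEN", "PTPN11", "RB1",
    "RET", "SMAD4", "SMARCB1", "SMO", "SRC", "STK11", "TP53", "VHL",
)

N_HOTSPOTS = 739

#: Relative probability that a somatic mutation lands in each gene; genes
#: not listed share the remainder equally. EGFR-dominated, as in NSCLC.
GENE_WEIGHTS = {"EGFR": 0.28, "TP53": 0.16, "PIK3CA": 0.12, "KRAS": 0.10,
                "BRAF": 0.04, "MET": 0.03, "STK11": 0.03}

_BASES = "ACGT"


@dataclass(frozen=True)
class PanelSite:
    """One mutational hotspot with its catalogued alternate allele."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    weight: float


def build_panel(
    n_sites: int = N_HOTSPOTS, genes: Sequence[str] = PANEL_GENES
) -> tuple[HotspotRegions, list[PanelSite]]:
    """Deterministically lay out the hotspot panel and mutation catalogue.

    Sites are apportioned across genes (hotspot-rich genes get more),
    placed at synthetic coordinates, and given one catalogued alternate
    allele each: SNVs everywhere except a block of 15-bp deletions in EGFR
    and dinucleotide MNVs in KRAS, mirroring the variant-class structure
    of lung-cancer hotspot panels. Regions are single-base BED intervals,
    one per hotspot.
    """
    rich = {"EGFR": 75, "TP53": 70, "PIK3CA": 40, "KRAS": 25, "BRAF": 20}
    other = [g for g in genes if g not in rich]
    remainder = n_sites - sum(rich.get(g, 0) for g in genes)
    per = remainder // len(other) if other else 0
    extra = remainder - per * len(other)
    counts = {}
    for g in genes:
        if g in rich:
            counts[g] = rich[g]
        else:
            counts[g] = per + (1 if other.index(g) < extra else 0)

    base_weight = GENE_WEIGHTS
    rest = max(0.0, 1.0 - sum(base_weight.values()))
    flat = rest / max(1, len(genes) - len(base_weight))

    regions: list[tuple[str, int, int, str | None]] = []
    sites: list[PanelSite] = []
    for gi, gene in enumerate(genes):
        chrom = f"chr{(gi % 22) + 1}"
        start = 1_000_000 * (gi + 1)
        gweight = base_weight.get(gene, flat)
        n_gene = counts[gene]
        for j in range(n_gene):
            pos = start + 50 * j + 1  # 1-based
            ref_base = _BASES[(gi + j) % 4]
            alt_base = _BASES[(gi + j + 1) % 4]
            if gene == "EGFR" and j >= n_gene - 15:
                # 15-bp in-frame deletions (exon-19-del-like)
                ref = ref_base + "".join(
                    _BASES[(gi + j + k) % 4] for k in range(1, 15)
                )
                alt = ref_base
            elif gene == "KRAS" and j >= n_gene - 3:
                ref = ref_base + _BASES[(gi + j + 1) % 4]
                alt = _BASES[(gi + j + 2) % 4] + _BASES[(gi + j + 3) % 4]
            else:
                ref, alt = ref_base, alt_base
            sites.append(
                PanelSite(chrom, pos, ref, alt, gene, gweight / n_gene)
            )
            regions.append((chrom, pos - 1, pos, gene))
    return HotspotRegions(regions=regions), sites


#: Control loci of the positive reference-standard plasmid: six canonical
#: driver mutations (GRCh37 coordinates).
CONTROL_SITES = (
    PanelSite("chr12", 25398285, "C", "A", "KRAS", 0.0),        # p.G12C
    PanelSite("chr3", 178936091, "G", "A", "PIK3CA", 0.0),      # p.E545K
    PanelSite("chr3", 178952085, "A", "G", "PIK3CA", 0.0),      # p.H1047R
    PanelSite("chr7", 140453136, "A", "T", "BRAF", 0.0),        # p.V600E
    PanelSite("chr7", 55259515, "T", "G", "EGFR", 0.0),         # p.L858R
    PanelSite("chr7", 55242464, "GGAATTAAGAGAAGCA", "G", "EGFR", 0.0),
    # p.E746_A750delELREA
)


# ---------------------------------------------------------------------------
# Read evidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadEvidence:
    """Simulated coverage at one site."""

    depth: int
    alt_reads: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth or self.alt_fwd + self.alt_rev != self.alt_reads:
            raise ValueError("inconsistent read evidence")


def simulate_read_evidence(
    true_vaf: float,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
    strand_bias: float = 0.5,
) -> ReadEvidence:
    """Draw alt support at one site.

    ``alt_reads ~ Binomial(depth, true_vaf + (1 - true_vaf) * error_rate)``
    — the mutant fraction plus error substitutions on wild-type molecules —
    and the forward-strand share of alt reads is Binomial(alt, strand_bias).
    """
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError("true_vaf outside [0, 1]")
    q = true_vaf + (1.0 - true_vaf) * error_rate
    alt = int(rng.binomial(depth, q)) if depth > 0 else 0
    fwd = int(rng.binomial(alt, strand_bias)) if alt > 0 else 0
    return ReadEvidence(depth=depth, alt_reads=alt, alt_fwd=fwd, alt_rev=alt - fwd)


@dataclass(frozen=True)
class StandardRun:
    """One sequencing replicate of a reference-standard mixture."""

    replicate_id: str
    nominal_fraction: float
    sites: tuple[tuple[PanelSite, ReadEvidence], ...]


def simulate_reference_standards(
    fractions: Sequence[float],
    replicates: int,
    depth: int = 10_000,
    sites: Sequence[PanelSite] = CONTROL_SITES,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[StandardRun]:
    """Simulate dilution-series replicates of the control plasmid mix.

    Each of ``len(fractions) * replicates`` runs carries read evidence at
    every control site with true VAF equal to the nominal mutant fraction;
    the wild-type plasmid contributes only error reads.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    runs = []
    for frac in fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction {frac} outside [0, 1]")
        for rep in range(replicates):
            evidence = tuple(
                (site, simulate_read_evidence(frac, depth, error_rate, rng))
                for site in sites
            )
            runs.append(
                StandardRun(
                    replicate_id=f"f{frac:g}_r{rep + 1}",
                    nominal_fraction=frac,
                    sites=evidence,
                )
            )
    return runs


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Parameters of the simulated study cohort.

    Defaults mirror the marginal structure of an early-stage NSCLC
    surgical cohort of 58 patients: stage mix 30/16/12 (IA/IB/IIA), 51
    adenocarcinomas vs 7 squamous carcinomas, 22 smokers, 8 GGO-dominant
    tumors; about one somatic panel mutation per tumor, 58% of which shed
    into plasma, plus ~0.7 plasma-private mutations per patient; plasma
    VAFs log-normal with median 0.9% (≈95% of draws in 0.1-16%); cfDNA
    concentration log-normal around 5.5 ng/ml with a 3x stage-II and a
    0.1x GGO-dominance effect and coefficient of variation 1.5.
    """

    n_patients: int = 58
    stage_counts: Mapping[str, int] = field(
        default_factory=lambda: {"IA": 30, "IB": 16, "IIA": 12}
    )
    histology_counts: Mapping[str, int] = field(
        default_factory=lambda: {"AC": 51, "SCC": 7}
    )
    smoker_fraction: float = 22 / 58
    ggo_dominant_fraction: float = 8 / 58
    poor_differentiation_fraction: float = 14 / 58
    vascular_invasion_fraction: float = 7 / 58
    vpi_fraction: float = 10 / 58
    age_mean: float = 64.5
    age_sd: float = 9.3

    tumor_depth_mean: float = 2_000
    plasma_depth_mean: float = 12_000
    wbc_depth_mean: float = 2_000
    tumor_mutation_rate: float = 59 / 58
    tumor_vaf_range: tuple[float, float] = (0.05, 0.60)
    plasma_vaf_log_params: tuple[float, float] = (math.log(0.009), 1.25)
    shed_probability: float = 0.58
    plasma_private_rate: float = 0.72
    plasma_private_vaf_multiplier: float = 2.0
    n_germline_per_patient: int = 2
    seq_error_rate: float = 1e-3
    noise_calls_per_sample: float = 3.0
    strand_artifact_rate: float = 0.3
    off_target_rate: float = 0.3

    cfdna_base_mean: float = 5.5
    cfdna_stage2_multiplier: float = 3.0
    cfdna_ggo_multiplier: float = 0.1
    cfdna_cv: float = 1.5
    #: per-marker (median, log-scale sigma); scales calibrated so the
    #: cohort shows realistic positivity at the standard cut-offs
    marker_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CA125": (10.0, 0.50),
            "CA19_9": (10.0, 0.75),
            "CEA": (2.0, 0.78),
            "CYFRA21_1": (2.0, 0.84),
            "NSE": (9.0, 0.40),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if sum(self.stage_counts.values()) != self.n_patients:
            raise ValueError("stage_counts must sum to n_patients")
        if sum(self.histology_counts.values()) != self.n_patients:
            raise ValueError("histology_counts must sum to n_patients")
        for name in (
            "smoker_fraction", "ggo_dominant_fraction", "shed_probability",
            "poor_differentiation_fraction", "vascular_invasion_fraction",
            "vpi_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if min(self.cfdna_stage2_multiplier, self.cfdna_ggo_multiplier) <= 0:
            raise ValueError("cfDNA multipliers must be > 0")


def _exact_labels(rng: np.random.Generator, counts: Mapping[str, int]) -> list[str]:
    labels = [k for k, v in counts.items() for _ in range(v)]
    rng.shuffle(labels)
    return labels


def _exact_bools(rng: np.random.Generator, n: int, fraction: float) -> list[bool]:
    k = round(n * fraction)
    flags = [True] * k + [False] * (n - k)
    rng.shuffle(flags)
    return flags


def _lognormal_with_mean(
    rng: np.random.Generator, mean: float, cv: float
) -> float:
    """Log-normal draw with the given arithmetic mean and CV (exact at cv=0)."""
    if cv == 0:
        return mean
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _make_call(
    sample_id: str,
    sample_type: SampleType,
    site_chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: str | None,
    true_vaf: float,
    depth_mean: float,
    error_rate: float,
    rng: np.random.Generator,
    strand_bias: float = 0.5,
) -> VariantCall | None:
    depth = int(rng.poisson(depth_mean))
    ev = simulate_read_evidence(true_vaf, depth, error_rate, rng, strand_bias)
    if ev.alt_reads == 0:
        return None  # a caller emits nothing without alt support
    ref_reads = depth - ev.alt_reads
    ref_fwd = int(rng.binomial(ref_reads, 0.5)) if ref_reads > 0 else 0
    return VariantCall(
        sample_id=sample_id,
        sample_type=sample_type,
        chrom=site_chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        depth=depth,
        alt_reads=ev.alt_reads,
        alt_fwd=ev.alt_fwd,
        alt_rev=ev.alt_rev,
        ref_fwd=ref_fwd,
        ref_rev=ref_reads - ref_fwd,
        p_value=variant_pvalue(ev.alt_reads, depth, error_rate)
        if error_rate > 0
        else (0.0 if ev.alt_reads else 1.0),
    )


def simulate_cohort(
    config: CohortConfig | None = None,
    panel: tuple[HotspotRegions, list[PanelSite]] | None = None,
) -> tuple[list[SamplePair], list[ClinicalRecord], pd.DataFrame]:
    """Simulate a full cohort: call sets, clinical records, truth table.

    Per patient: clinical covariates are drawn with exact cohort marginals
    (stage/histology counts, smoker/GGO/differentiation fractions); tumor
    mutations are drawn from the panel catalogue at uniform tissue VAFs;
    each sheds into plasma with ``shed_probability`` at a log-normally
    drawn plasma VAF; plasma-private mutations are added at
    ``plasma_private_rate``; germline variants appear identically in
    tumor, plasma and WBC; noise, strand-artifact and off-target calls
    give the downstream filters something to remove. The truth table
    records every planted variant, its compartments and true VAFs.
    """
    config = config or CohortConfig()
    config.validate()
    regions, catalogue = panel or build_panel()
    weights = np.array([s.weight for s in catalogue])
    weights = weights / weights.sum()

    master = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(master)
    patient_seeds = master.spawn(config.n_patients)

    n = config.n_patients
    stages = _exact_labels(cohort_rng, config.stage_counts)
    histologies = _exact_labels(cohort_rng, config.histology_counts)
    smokers = _exact_bools(cohort_rng, n, config.smoker_fraction)
    ggo_dominant = _exact_bools(cohort_rng, n, config.ggo_dominant_fraction)
    poor_diff = _exact_bools(cohort_rng, n, config.poor_differentiation_fraction)
    vasc = _exact_bools(cohort_rng, n, config.vascular_invasion_fraction)
    vpi = _exact_bools(cohort_rng, n, config.vpi_fraction)
    sexes = _exact_bools(cohort_rng, n, 33 / 58)  # True = male

    # germline catalogue: common SNPs inside the panel footprint so that
    # germline subtraction, not the hotspot filter, must remove them
    germline_sites = [catalogue[i] for i in range(0, len(catalogue), 7)]

    pairs: list[SamplePair] = []
    records: list[ClinicalRecord] = []
    truth_rows: list[dict] = []
    mu_p, sigma_p = config.plasma_vaf_log_params

    for i in range(n):
        rng = np.random.default_rng(patient_seeds[i])
        pid = f"P{i + 1:03d}"
        stage = Stage(stages[i])

        # --- planted variants -------------------------------------------
        n_som = rng.poisson(config.tumor_mutation_rate)
        som_idx = rng.choice(
            len(catalogue), size=min(n_som, len(catalogue)),
            replace=False, p=weights,
        )
        somatic: list[tuple[PanelSite, float, float]] = []
        for idx in som_idx:
            site = catalogue[int(idx)]
            t_vaf = float(rng.uniform(*config.tumor_vaf_range))
            if rng.random() < config.shed_probability:
                p_vaf = min(0.5, float(rng.lognormal(mu_p, sigma_p)))
            else:
                p_vaf = 0.0
            somatic.append((site, t_vaf, p_vaf))

        taken = {s.pos for s, _, _ in somatic}
        n_priv = rng.poisson(config.plasma_private_rate)
        free = [s for s in catalogue if s.pos not in taken]
        if n_priv > 0 and free:
            w_free = np.array([s.weight for s in free])
            w_free = w_free / w_free.sum()
            priv_idx = rng.choice(
                len(free), size=min(n_priv, len(free)), replace=False, p=w_free
            )
            for idx in priv_idx:
                site = free[int(idx)]
                p_vaf = min(
                    0.5,
                    float(rng.lognormal(mu_p, sigma_p))
                    * config.plasma_private_vaf_multiplier,
                )
                somatic.append((site, 0.0, p_vaf))

        g_idx = rng.choice(
            len(germline_sites),
            size=min(config.n_germline_per_patient, len(germline_sites)),
            replace=False,
        )
        germline = [
            (germline_sites[int(j)], 1.0 if rng.random() < 0.25 else 0.5)
            for j in g_idx
        ]

        # --- read evidence per compartment ------------------------------
        tumor_calls: list[VariantCall] = []
        plasma_calls: list[VariantCall] = []
        wbc_calls: list[VariantCall] = []

        def emit(bucket, sid, stype, site, vaf, depth_mean, strand_bias=0.5):
            call = _make_call(
                sid, stype, site.chrom, site.pos, site.ref, site.alt,
                site.gene, vaf, depth_mean, config.seq_error_rate, rng,
                strand_bias,
            )
            if call is not None:
                bucket.append(call)
            return call

        for site, t_vaf, p_vaf in somatic:
            t_call = (
                emit(tumor_calls, f"{pid}-T", SampleType.TUMOR, site, t_vaf,
                     config.tumor_depth_mean)
                if t_vaf > 0 else None
            )
            p_call = (
                emit(plasma_calls, f"{pid}-P", SampleType.PLASMA, site, p_vaf,
                     config.plasma_depth_mean)
                if p_vaf > 0 else None
            )
            truth_rows.append(
                {
                    "patient_id": pid, "chrom": site.chrom, "pos": site.pos,
                    "ref": site.ref, "alt": site.alt, "gene": site.gene,
                    "origin": "somatic",
                    "true_tumor_vaf": t_vaf, "true_plasma_vaf": p_vaf,
                    "tumor_called": t_call is not None,
                    "plasma_called": p_call is not None,
                }
            )

        for site, g_vaf in germline:
            emit(tumor_calls, f"{pid}-T", SampleType.TUMOR, site, g_vaf,
                 config.tumor_depth_mean)
            emit(plasma_calls, f"{pid}-P", SampleType.PLASMA, site, g_vaf,
                 config.plasma_depth_mean)
            emit(wbc_calls, f"{pid}-W", SampleType.WBC, site, g_vaf,
                 config.wbc_depth_mean)
            truth_rows.append(
                {
                    "patient_id": pid, "chrom": site.chrom, "pos": site.pos,
                    "ref": site.ref, "alt": site.alt, "gene": site.gene,
                    "origin": "germline",
                    "true_tumor_vaf": g_vaf, "true_plasma_vaf": g_vaf,
                    "tumor_called": True, "plasma_called": True,
                }
            )

        # noise: error-level evidence at unmutated panel sites
        planted = {s.pos for s, _, _ in somatic} | {s.pos for s, _ in germline}
        open_sites = [s for s in catalogue if s.pos not in planted]
        for bucket, sid, stype, depth_mean in (
            (tumor_calls, f"{pid}-T", SampleType.TUMOR, config.tumor_depth_mean),
            (plasma_calls, f"{pid}-P", SampleType.PLASMA, config.plasma_depth_mean),
        ):
            n_noise = rng.poisson(config.noise_calls_per_sample)
            if n_noise and open_sites:
                for j in rng.choice(
                    len(open_sites), size=min(n_noise, len(open_sites)),
                    replace=False,
                ):
                    emit(bucket, sid, stype, open_sites[int(j)], 0.0, depth_mean)

        # strand-specific artifacts in plasma (all alt reads one strand)
        for _ in range(rng.poisson(config.strand_artifact_rate)):
            if open_sites:
                site = open_sites[int(rng.integers(len(open_sites)))]
                emit(plasma_calls, f"{pid}-P", SampleType.PLASMA, site, 0.005,
                     config.plasma_depth_mean, strand_bias=1.0)

        # off-target calls outside the hotspot footprint
        for _ in range(rng.poisson(config.off_target_rate)):
            off = PanelSite("chrX", int(rng.integers(1, 10_000_000)),
                            "A", "G", None, 0.0)
            emit(plasma_calls, f"{pid}-P", SampleType.PLASMA, off, 0.01,
                 config.plasma_depth_mean)

        pairs.append(
            SamplePair(
                patient_id=pid,
                tumor=SampleCallSet(
                    f"{pid}-T", SampleType.TUMOR,
                    config.tumor_depth_mean, tuple(tumor_calls),
                ),
                plasma=SampleCallSet(
                    f"{pid}-P", SampleType.PLASMA,
                    config.plasma_depth_mean, tuple(plasma_calls),
                ),
                wbc=SampleCallSet(
                    f"{pid}-W", SampleType.WBC,
                    config.wbc_depth_mean, tuple(wbc_calls),
                ),
            )
        )

        # --- clinical record --------------------------------------------
        cfdna_mean = config.cfdna_base_mean
        if stage.numeric == 2:
            cfdna_mean *= config.cfdna_stage2_multiplier
        if ggo_dominant[i]:
            cfdna_mean *= config.cfdna_ggo_multiplier
        markers = {
            name: float(rng.lognormal(math.log(median), sigma))
            for name, (median, sigma) in config.marker_model.items()
        }
        records.append(
            ClinicalRecord(
                patient_id=pid,
                age=float(np.clip(rng.normal(config.age_mean, config.age_sd), 40, 84)),
                sex=Sex.M if sexes[i] else Sex.F,
                histology=Histology(histologies[i]),
                stage=stage,
                smoker=smokers[i],
                ggo_proportion=float(
                    rng.uniform(0.55, 1.0) if ggo_dominant[i]
                    else rng.uniform(0.0, 0.45)
                ),
                differentiation=(
                    Differentiation.POOR if poor_diff[i]
                    else Differentiation.MEDIAN_OR_HIGH
                ),
                vascular_invasion=vasc[i],
                vpi=vpi[i],
                cfdna_conc=_lognormal_with_mean(rng, cfdna_mean, config.cfdna_cv),
                markers=markers,
            )
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id", "chrom", "pos", "ref", "alt", "gene", "origin",
            "true_tumor_vaf", "true_plasma_vaf", "tumor_called",
            "plasma_called",
        ],
    )
    return pairs, records, truth


def write_cohort_fixtures(
    pairs: Sequence[SamplePair],
    records: Sequence[ClinicalRecord],
    regions: HotspotRegions,
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the cohort as VCFs + clinical TSV + hotspot BED + truth TSV.

    Returns the manifest of written paths; a ``manifest.tsv`` listing the
    per-patient VCF triples is written alongside for the CLI stages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for pair in pairs:
        paths = {}
        for name, callset in (
            ("tumor", pair.tumor), ("plasma", pair.plasma), ("wbc", pair.wbc)
        ):
            p = outdir / f"{pair.patient_id}_{name}.vcf"
            write_vcf_calls(callset, p)
            paths[name] = p
        manifest_rows.append(
            {
                "patient_id": pair.patient_id,
                "tumor_vcf": paths["tumor"].name,
                "plasma_vcf": paths["plasma"].name,
                "wbc_vcf": paths["wbc"].name,
            }
        )
    out = {
        "clinical": outdir / "clinical.tsv",
        "hotspots": outdir / "hotspots.bed",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.tsv",
    }
    write_clinical_table(records, out["clinical"])
    write_bed_regions(regions, out["hotspots"])
    truth.to_csv(out["truth"], sep="\t", index=False)
    pd.DataFrame(manifest_rows).to_csv(out["manifest"], sep="\t", index=False)
    return out
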