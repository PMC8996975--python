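"""Synthetic two-cohort microarray data with known planted truth.

The generator emulates the input structure of a dual-normalization
probe-level study: each gene is measured by several probes; log2
intensities are Gaussian around a baseline (i.e. log-normal intensities,
the standard microarray noise approximation); the linear track is
derived from the log2 track as 2^x times multiplicative noise with unit
median, so the two tracks describe the same underlying RNA.  Planted
gene sets shift their member genes' log2 mean in the disease class by a
known effect size, and a configurable subset of genes is planted in both
cohorts — the ground-truth shared panel that the downstream pipeline
should recover.  Decoy gene sets of matched sizes are drawn from
unplanted genes so that permutation FDR estimates are meaningful.

qPCR Ct tables and right-censored survival tables with known generative
parameters are provided for the validation modules.

All randomness flows from the design seed through
``numpy.random.SeedSequence`` spawning, so identical designs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection, ProbeAnnotation
from .survival import SurvivalRecord
from .validation import QpcrMeasurement

__all__ = [
    "PlantedSet",
    "SyntheticDesign",
    "SyntheticTruth",
    "CohortData",
    "generate_cohort",
    "generate_two_cohorts",
    "generate_qpcr_fixture",
    "generate_survival_fixture",
    "default_design",
]


@dataclass
class PlantedSet:
    name: str
    genes: tuple[str, ...]
    delta_log2: float
    direction: str  # up | down

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up or down, got {self.direction!r}")
        if not np.isfinite(self.delta_log2):
            raise ValueError("delta_log2 must be finite")
        if self.delta_log2 == 0:
            raise ValueError("delta_log2 = 0 with a direction set makes the truth unidentifiable")
        if self.delta_log2 < 0:
            raise ValueError("delta_log2 must be positive; use direction for the sign")

    @property
    def signed_delta(self) -> float:
        return self.delta_log2 if self.direction == "up" else -self.delta_log2


@dataclass
class SyntheticDesign:
    """Parameters of one simulated disease-vs-control cohort.

    Defaults mirror a small severe-asthma-sized study: 20 disease vs 20
    control arrays, 300 genes each measured by 3 probes, baseline log2
    intensity 7.0 ± 1.0 (linear mean ≈ 128, log2-scale CV ≈ 14%, so
    typical probes survive the nonspecific filter exactly as real
    above-background variant probes do).
    """

    n_genes: int = 300
    probes_per_gene: int = 3
    n_disease: int = 20
    n_control: int = 20
    planted_sets: list[PlantedSet] = field(default_factory=list)
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    linear_noise_sd: float = 0.1  # log2 units of multiplicative noise
    n_decoy_sets: int = 30
    decoy_set_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("n_genes", self.n_genes), ("probes_per_gene", self.probes_per_gene),
            ("n_disease", self.n_disease), ("n_control", self.n_control),
        ):
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.baseline_log2_sd <= 0:
            raise ValueError("baseline_log2_sd must be positive")
        universe = set(self.gene_universe())
        for ps in self.planted_sets:
            unknown = set(ps.genes) - universe
            if unknown:
                raise ValueError(f"planted set {ps.name!r} names unknown genes {sorted(unknown)[:5]}")
        # a gene planted in two sets of one cohort must move one way
        self.planted_effects()

    def gene_universe(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def planted_effects(self) -> dict[str, float]:
        """gene → signed log2 shift; rejects contradictory directions."""
        effects: dict[str, float] = {}
        for ps in self.planted_sets:
            for g in ps.genes:
                prev = effects.get(g)
                if prev is not None and np.sign(prev) != np.sign(ps.signed_delta):
                    raise ValueError(f"gene {g!r} planted in opposite directions")
                effects[g] = ps.signed_delta if prev is None else prev
        return effects


@dataclass
class SyntheticTruth:
    enriched_sets: list[str]
    up_genes: list[str]
    down_genes: list[str]
    shared_panel: list[str] = field(default_factory=list)


@dataclass
class CohortData:
    linear: ExpressionMatrix
    log2: ExpressionMatrix
    annotation: ProbeAnnotation
    gene_sets: GeneSetCollection
    truth: SyntheticTruth


def _cohort_rng(design: SyntheticDesign, cohort_id: str) -> np.random.Generator:
    tag = zlib.crc32(cohort_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([design.seed, tag]))


def generate_cohort(design: SyntheticDesign, cohort_id: str = "A") -> CohortData:
    """Simulate one cohort: paired linear/log2 matrices, probe annotation,
    a gene-set collection (planted + decoys), and the truth record."""
    rng = _cohort_rng(design, cohort_id)
    genes = design.gene_universe()
    effects = design.planted_effects()

    probes, probe_gene = [], {}
    for g in genes:
        for j in range(1, design.probes_per_gene + 1):
            pid = f"{g}_p{j}"
            probes.append(pid)
            probe_gene[pid] = g
    n_probes = len(probes)
    n_samples = design.n_disease + design.n_control
    samples = [f"{cohort_id}_dis{i:02d}" for i in range(1, design.n_disease + 1)] + [
        f"{cohort_id}_ctl{i:02d}" for i in range(1, design.n_control + 1)
    ]
    phenotype = pd.Series(
        ["disease"] * design.n_disease + ["control"] * design.n_control, index=samples
    )

    log2_vals = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd,
                           size=(n_probes, n_samples))
    shift = np.array([effects.get(probe_gene[p], 0.0) for p in probes])
    log2_vals[:, : design.n_disease] += shift[:, None]

    lin_noise = 2.0 ** rng.normal(0.0, design.linear_noise_sd, size=(n_probes, n_samples))
    linear_vals = (2.0 ** log2_vals) * lin_noise

    log2_df = pd.DataFrame(log2_vals, index=probes, columns=samples)
    linear_df = pd.DataFrame(linear_vals, index=probes, columns=samples)
    classes = ("disease", "control")
    log2_m = ExpressionMatrix(log2_df, "log2", phenotype, classes)
    linear_m = ExpressionMatrix(linear_df, "linear", phenotype, classes)

    # gene sets: planted + size-matched decoys from unplanted genes
    sets = [GeneSet(ps.name, f"planted {ps.direction}", tuple(ps.genes))
            for ps in design.planted_sets]
    unplanted = [g for g in genes if g not in effects]
    planted_sizes = [len(ps.genes) for ps in design.planted_sets]
    for d in range(design.n_decoy_sets):
        size = planted_sizes[d % len(planted_sizes)] if planted_sizes else design.decoy_set_size
        size = min(size, len(unplanted))
        if size == 0:
            break
        members = tuple(sorted(rng.choice(unplanted, size=size, replace=False)))
        sets.append(GeneSet(f"DECOY_{d + 1:03d}", "decoy", members))

    truth = SyntheticTruth(
        enriched_sets=[ps.name for ps in design.planted_sets],
        up_genes=sorted(g for g, e in effects.items() if e > 0),
        down_genes=sorted(g for g, e in effects.items() if e < 0),
    )
    return CohortData(linear_m, log2_m, ProbeAnnotation(probe_gene),
                      GeneSetCollection(sets), truth)


def generate_two_cohorts(
    design_a: SyntheticDesign,
    design_b: SyntheticDesign,
    shared_genes: list[str] | None = None,
) -> tuple[CohortData, CohortData, SyntheticTruth]:
    """Two cohorts over the same gene universe with independent noise.

    The joint truth's shared panel is the set of genes planted in both
    designs (validated against *shared_genes* when supplied); a gene
    planted up in one cohort and down in the other is rejected.
    """
    if design_a.n_genes != design_b.n_genes or design_a.probes_per_gene != design_b.probes_per_gene:
        raise ValueError("cohorts must share the gene universe and probe layout")
    eff_a, eff_b = design_a.planted_effects(), design_b.planted_effects()
    common = sorted(set(eff_a) & set(eff_b))
    for g in common:
        if np.sign(eff_a[g]) != np.sign(eff_b[g]):
            raise ValueError(f"shared gene {g!r} planted with inconsistent direction")
    if shared_genes is not None:
        missing = sorted(set(shared_genes) - set(common))
        if missing:
            raise ValueError(f"declared shared genes not planted in both cohorts: {missing}")
        common = sorted(shared_genes)

    cohort_a = generate_cohort(design_a, "A")
    cohort_b = generate_cohort(design_b, "B")
    joint = SyntheticTruth(
        enriched_sets=sorted(set(cohort_a.truth.enriched_sets) | set(cohort_b.truth.enriched_sets)),
        up_genes=sorted(set(cohort_a.truth.up_genes) | set(cohort_b.truth.up_genes)),
        down_genes=sorted(set(cohort_a.truth.down_genes) | set(cohort_b.truth.down_genes)),
        shared_panel=common,
    )
    return cohort_a, cohort_b, joint


def default_design(
    seed: int,
    shared_genes: tuple[str, ...] = tuple(f"G{i:04d}" for i in range(1, 8)),
    n_planted_sets: int = 3,
    set_size: int = 20,
    delta_log2: float = 2.0,
    filler_start: int = 101,
    **overrides,
) -> SyntheticDesign:
    """A study-sized design: each planted set carries the shared genes
    plus distinct filler genes, so shared genes recur across leading
    edges while fillers appear once — the frequency-score contrast the
    panel stage exploits."""
    planted = []
    nxt = filler_start
    n_fill = set_size - len(shared_genes)
    for k in range(n_planted_sets):
        fillers = tuple(f"G{i:04d}" for i in range(nxt, nxt + n_fill))
        nxt += n_fill
        planted.append(PlantedSet(f"PLANTED_{k + 1}", shared_genes + fillers, delta_log2, "up"))
    return SyntheticDesign(planted_sets=planted, seed=seed, **overrides)


def generate_qpcr_fixture(
    groups: list[str],
    n_per_group: int,
    planted_log2_shift: float,
    seed: int,
    gene: str = "TARGET",
    replicate_sd: float = 0.15,
    sample_sd: float = 0.2,
) -> list[QpcrMeasurement]:
    """Ct triplicates (target + 18S-style reference) for several groups.

    The first group is the calibrator baseline; every other group's
    target Ct mean is lowered by *planted_log2_shift* cycles, so the
    expected ddCt relative to the calibrator is −shift and the expected
    relative expression is 2^shift.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x71DC]))
    base_gene_ct, base_ref_ct = 25.0, 15.0
    out = []
    for gi, grp in enumerate(groups):
        shift = planted_log2_shift if gi > 0 else 0.0
        for s in range(1, n_per_group + 1):
            gene_level = base_gene_ct - shift + rng.normal(0, sample_sd)
            ref_level = base_ref_ct + rng.normal(0, sample_sd)
            ct_gene = tuple(gene_level + rng.normal(0, replicate_sd, 3))
            ct_ref = tuple(ref_level + rng.normal(0, replicate_sd, 3))
            out.append(QpcrMeasurement(f"{grp}_{s:02d}", grp, gene, ct_gene, ct_ref))
    return out


def generate_survival_fixture(
    n: int,
    hazard_ratio: float,
    censor_rate: float,
    seed: int,
    base_hazard: float = 0.02,
) -> list[SurvivalRecord]:
    """Right-censored cohort where marker-high subjects (expression above
    the sample median) carry *hazard_ratio* times the baseline hazard.

    Event times are exponential; censoring is independent exponential
    with rate base_hazard · censor_rate/(1 − censor_rate), which gives a
    censored fraction near *censor_rate* in the baseline group.  With
    censor_rate = 0 every event is observed.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5AFE]))
    expression = rng.normal(5.0, 1.0, size=n)
    high = expression > np.median(expression)
    rates = base_hazard * np.where(high, hazard_ratio, 1.0)
    event_times = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        c_rate = base_hazard * censor_rate / (1.0 - censor_rate)
        censor_times = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_times = np.full(n, np.inf)
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    return [
        SurvivalRecord(f"subj{i:04d}", float(times[i]), int(events[i]), float(expression[i]))
        for i in range(n)
    ]
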