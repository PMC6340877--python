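"""Synthetic tumor-cohort generator with known subclonal architecture.

Every downstream stage of the pipeline is exercised against cohorts
whose truth is known by construction.  A sample is a mixture of
subclones: each mutation draws a cancer-cell fraction (CCF) from the
archetype's mixture, its expected VAF in the sequenced specimen is
``purity * CCF / 2`` (diploid, copy-neutral), and the observed alt read
count is Binomial(depth, VAF).  Around this signal the generator plants
the nuisance structure the filter chain must remove: PolyPhen-benign
decoy mutations, low-depth mutations, and copy-altered genome segments
(mutations falling there must be excluded downstream).  Survival times
are exponential with an archetype-dependent hazard multiplier and
independent exponential censoring.

The five default archetypes are calibrated so that a filtered cohort
reproduces the canonical per-cluster medians of (m_peak, m_count,
m_math):

====  ======  =======  ======  =========================================
arch  m_peak  m_count  m_math  architecture
====  ======  =======  ======  =========================================
1     0.376   6.794    0.186   many mutations, mostly clonal
2     0.229   6.119    0.320   many mutations, subclone-heavy
3     0.424   4.000    0.133   few mutations, tight clonal
4     0.271   3.807    0.251   few mutations, one selected mid-CCF clone
5     0.140   3.807    0.473   few mutations, dispersed low-CCF mixture
====  ======  =======  ======  =========================================

Everything is driven by a single ``numpy`` Generator, so a cohort is a
pure function of its spec and seed, and written files are byte-identical
across reruns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .io_formats import (
    ClinicalRecord,
    CNVSegment,
    MutationRecord,
    write_clinical,
    write_mutations,
    write_segments,
)
from .cohort_stats import SPECTRUM_CLASSES

__all__ = [
    "ArchetypeSpec",
    "CohortSpec",
    "SimulatedCohort",
    "default_archetype_specs",
    "default_cohort_spec",
    "simulate_sample",
    "simulate_cohort",
    "write_cohort",
]

GENOME_LENGTH = 10_000_000  # one abstract chromosome; only overlap matters
N_SEGMENTS = 10

_GENE_POOL = (
    "PIK3CA TP53 CTNNB1 BRAF IDH1 KRAS EGFR PTEN ARID1A APC "
    "NRAS RB1 CDKN2A SMAD4 FBXW7 ATM NF1 KMT2D BRCA2 SETD2 "
    "STK11 VHL NFE2L2 POLE CDH1 GATA3 MAP3K1 CTCF KEAP1 ERBB2"
).split()

#: Purine-strand representation used for half the emitted records so the
#: spectrum collapse is exercised: class -> (ref, alt) on the purine strand.
_PURINE_EQUIVALENT = {
    "C>A": ("G", "T"), "C>G": ("G", "C"), "C>T": ("G", "A"),
    "T>A": ("A", "T"), "T>C": ("A", "G"), "T>G": ("A", "C"),
}
_PYRIMIDINE = {c: tuple(c.split(">")) for c in SPECTRUM_CLASSES}


@dataclass
class ArchetypeSpec:
    """Generator parameters for one VAF-distribution archetype.

    ``subclones`` is a list of (CCF, weight) pairs, weights summing to 1;
    ``ccf_sd`` adds Gaussian spread around each subclone's CCF (clipped
    to (0.02, 1]).  ``n_mutations_median`` / ``n_mutations_sigma``
    parametrise a log-normal for the total emitted mutation count.
    """

    label: int
    n_mutations_median: float
    subclones: list[tuple[float, float]]
    n_mutations_sigma: float = 0.35
    ccf_sd: float = 0.04
    purity_range: tuple[float, float] = (0.5, 0.9)
    depth_mean: float = 120.0
    benign_fraction: float = 0.15
    low_depth_fraction: float = 0.02
    cnv_altered_fraction: float = 0.1
    spectrum: tuple[float, ...] = (0.2, 0.1, 0.3, 0.1, 0.2, 0.1)

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.subclones)
        if not np.isclose(total, 1.0):
            raise ValueError(f"subclone weights must sum to 1, got {total}")
        if not all(0 < ccf <= 1 for ccf, _ in self.subclones):
            raise ValueError("subclone CCFs must lie in (0, 1]")
        if not np.isclose(sum(self.spectrum), 1.0):
            raise ValueError("spectrum probabilities must sum to 1")
        if not (0 <= self.benign_fraction < 1):
            raise ValueError("benign_fraction must lie in [0, 1)")


@dataclass
class CohortSpec:
    """A full cohort: archetype mixture, survival model, covariates."""

    archetypes: list[ArchetypeSpec]
    proportions: list[float]
    n_samples: int = 500
    cancer_type: str = "SYNTH"
    baseline_hazard: float = 1.0 / 1500.0  # per day
    hazard_multipliers: tuple[float, ...] = (1.5, 1.0, 2.0, 2.5, 1.6)
    censoring_hazard: float = 1.0 / 1500.0
    age_mean: float = 63.0
    age_sd: float = 11.0
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.archetypes) != len(self.proportions):
            raise ValueError("one proportion per archetype required")
        if not np.isclose(sum(self.proportions), 1.0):
            raise ValueError("proportions must sum to 1")
        if len(self.hazard_multipliers) != len(self.archetypes):
            raise ValueError("one hazard multiplier per archetype required")


@dataclass
class SimulatedCohort:
    """Generated input bundle plus the ground truth behind it."""

    mutations: list[MutationRecord]
    segments: list[CNVSegment]
    clinical: list[ClinicalRecord]
    truth: dict[str, int]  # sample_id -> archetype label
    spec: CohortSpec


def default_archetype_specs() -> list[ArchetypeSpec]:
    """The five calibrated archetypes (see module docstring for targets).

    Subclone CCFs are placed at twice the target m_peak (adjusted VAF of
    a CCF-c clone is c/2 under the diploid copy-neutral model); mixture
    weights and CCF spread are tuned so the filtered cohort's median
    m_math lands on target given binomial read noise at the default
    depth and purity.  Emitted mutation counts for the high-burden
    archetypes are inflated for the expected loss to decoys and altered
    segments, so the *filtered* MF count matches the m_count target;
    archetype 3's median stays at the nominal 2^4 = 16.
    """
    return [
        ArchetypeSpec(
            label=1,
            n_mutations_median=135.0,  # ~2^6.794 after filter losses
            subclones=[(0.752, 0.85), (0.52, 0.15)],
            ccf_sd=0.05,
            spectrum=(0.15, 0.05, 0.50, 0.05, 0.15, 0.10),  # C>T-rich trunk
        ),
        ArchetypeSpec(
            label=2,
            n_mutations_median=88.0,  # ~2^6.119 after filter losses
            subclones=[(0.46, 0.62), (0.70, 0.16), (0.30, 0.22)],
            ccf_sd=0.05,
            cnv_altered_fraction=0.2,  # highest genomic instability
        ),
        ArchetypeSpec(
            label=3,
            n_mutations_median=16.0,  # 2^4.000
            subclones=[(0.848, 1.0)],
            ccf_sd=0.04,
        ),
        ArchetypeSpec(
            label=4,
            n_mutations_median=17.0,  # ~2^3.807 after filter losses
            subclones=[(0.542, 0.75), (0.90, 0.25)],
            ccf_sd=0.05,
        ),
        ArchetypeSpec(
            label=5,
            n_mutations_median=17.0,  # ~2^3.807 after filter losses
            subclones=[(0.28, 0.50), (0.16, 0.25), (0.46, 0.25)],
            ccf_sd=0.05,
        ),
    ]


def default_cohort_spec(n_samples: int = 500, seed: int = 1) -> CohortSpec:
    """Equal-proportion five-archetype cohort with cluster-dependent
    hazards (archetype 2 carries the lowest hazard)."""
    return CohortSpec(
        archetypes=default_archetype_specs(),
        proportions=[0.2] * 5,
        n_samples=n_samples,
        seed=seed,
    )


def _make_segments(
    sample_id: str, spec: ArchetypeSpec, rng: np.random.Generator
) -> list[CNVSegment]:
    """Tile the abstract genome into equal segments; a deterministic count
    of them (matching cnv_altered_fraction) gets a non-neutral mean."""
    block = GENOME_LENGTH // N_SEGMENTS
    n_altered = int(round(spec.cnv_altered_fraction * N_SEGMENTS))
    altered_idx = set(rng.choice(N_SEGMENTS, size=n_altered, replace=False).tolist())
    segments = []
    for i in range(N_SEGMENTS):
        if i in altered_idx:
            mean = float(rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0]))
        else:
            mean = float(np.clip(rng.normal(0.0, 0.05), -0.18, 0.18))
        segments.append(
            CNVSegment(
                sample_id=sample_id,
                chrom="1",
                start=i * block + 1,
                end=(i + 1) * block,
                num_probes=int(rng.integers(20, 200)),
                segment_mean=round(mean, 4),
            )
        )
    return segments


def simulate_sample(
    spec: ArchetypeSpec,
    rng: np.random.Generator | int,
    sample_id: str = "S0",
) -> tuple[list[MutationRecord], list[CNVSegment], float]:
    """Generate one sample's mutations, segments and purity.

    Expected raw VAF of a mutation with CCF c is ``purity * c / 2``;
    observed alt reads are Binomial(depth, VAF).  ``benign_fraction`` of
    mutations carry a benign PolyPhen class, ``low_depth_fraction`` get
    a sub-threshold depth, and positions are uniform over the genome, so
    mutations landing in altered segments exist in the output and must be
    filtered out by the consumer.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    purity = float(rng.uniform(*spec.purity_range))
    segments = _make_segments(sample_id, spec, rng)

    n_mut = max(2, int(round(rng.lognormal(
        np.log(spec.n_mutations_median), spec.n_mutations_sigma))))
    ccfs_centers = np.array([c for c, _ in spec.subclones])
    weights = np.array([w for _, w in spec.subclones])
    which = rng.choice(len(ccfs_centers), size=n_mut, p=weights)
    ccfs = np.clip(
        ccfs_centers[which] + rng.normal(0.0, spec.ccf_sd, size=n_mut), 0.02, 1.0
    )
    true_vafs = purity * ccfs / 2.0

    depths = rng.poisson(spec.depth_mean, size=n_mut)
    depths = np.maximum(depths, 20)
    low = rng.random(n_mut) < spec.low_depth_fraction
    depths[low] = rng.integers(5, 20, size=int(low.sum()))
    alt_counts = rng.binomial(depths, true_vafs)

    benign = rng.random(n_mut) < spec.benign_fraction
    classes = np.where(
        benign,
        "benign",
        np.where(rng.random(n_mut) < 0.5, "probably_damaging", "possibly_damaging"),
    )
    spectrum_class = rng.choice(len(SPECTRUM_CLASSES), size=n_mut,
                                p=np.asarray(spec.spectrum))
    purine_strand = rng.random(n_mut) < 0.5
    positions = rng.integers(1, GENOME_LENGTH + 1, size=n_mut)
    genes = rng.choice(_GENE_POOL, size=n_mut)

    mutations = []
    for i in range(n_mut):
        cls = SPECTRUM_CLASSES[spectrum_class[i]]
        ref, alt = (_PURINE_EQUIVALENT[cls] if purine_strand[i]
                    else _PYRIMIDINE[cls])
        mutations.append(
            MutationRecord(
                sample_id=sample_id,
                chrom="1",
                pos=int(positions[i]),
                ref_allele=ref,
                alt_allele=alt,
                ref_count=int(depths[i] - alt_counts[i]),
                alt_count=int(alt_counts[i]),
                polyphen_class=str(classes[i]),
                gene=str(genes[i]),
            )
        )
    return mutations, segments, purity


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate the full input bundle for a cohort spec.

    Per sample: archetype drawn by proportion; data via
    :func:`simulate_sample`; survival time exponential with hazard
    ``baseline * multiplier[archetype]``, censored by an independent
    exponential clock.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mutations: list[MutationRecord] = []
    segments: list[CNVSegment] = []
    clinical: list[ClinicalRecord] = []
    truth: dict[str, int] = {}
    width = max(4, len(str(max(spec.n_samples, 1))))
    arch_idx = rng.choice(len(spec.archetypes), size=spec.n_samples,
                          p=np.asarray(spec.proportions))
    for i in range(spec.n_samples):
        sample_id = f"SYN-{i:0{width}d}"
        a = int(arch_idx[i])
        arch = spec.archetypes[a]
        muts, segs, purity = simulate_sample(arch, rng, sample_id=sample_id)
        mutations.extend(muts)
        segments.extend(segs)
        truth[sample_id] = arch.label

        hazard = spec.baseline_hazard * spec.hazard_multipliers[a]
        event_time = rng.exponential(1.0 / hazard)
        censor_time = rng.exponential(1.0 / spec.censoring_hazard)
        observed = min(event_time, censor_time)
        clinical.append(
            ClinicalRecord(
                sample_id=sample_id,
                cancer_type=spec.cancer_type,
                purity=round(purity, 4),
                survival_days=round(float(observed), 1),
                event=int(event_time <= censor_time),
                age=float(np.clip(round(rng.normal(spec.age_mean, spec.age_sd), 1),
                                  25.0, 90.0)),
                gender=str(rng.choice(["female", "male"])),
                stage=str(rng.choice(["I", "II", "III", "IV"],
                                     p=[0.3, 0.3, 0.25, 0.15])),
                smoking=str(rng.choice(["never", "former", "current"],
                                       p=[0.5, 0.3, 0.2])),
            )
        )
    return SimulatedCohort(
        mutations=mutations, segments=segments, clinical=clinical,
        truth=truth, spec=spec,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the dialects the readers consume, plus the
    truth table.  Returns the paths keyed by table name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": out / "mutations.maf.tsv",
        "segments": out / "segments.seg.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth_labels.tsv",
    }
    write_mutations(cohort.mutations, paths["mutations"])
    write_segments(cohort.segments, paths["segments"])
    write_clinical(cohort.clinical, paths["clinical"])
    with open(paths["truth"], "w") as fh:
        fh.write("sample_id\tarchetype\n")
        for sample_id in sorted(cohort.truth):
            fh.write(f"{sample_id}\t{cohort.truth[sample_id]}\n")
    return paths
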