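"""Seeded generator of Orphadata-like disorder registries.

The generator produces registries with controllable statistical structure so
every pipeline stage is testable without external downloads, and doubles as
a parameter-recovery harness: each knob it exposes (per-class disorder
counts, per-category inheritance mixtures, phenotyped fractions, occurrence
mixtures, natural-history level mixtures, gene-count distributions) is a
quantity the downstream analytics estimate, so recovered estimates can be
compared against the configured truth.

Default parameters emulate the published margins of the 2020 rare-disorder
spectrum: 3,524 disorders split 145/412/2967 across the borderline-common /
rare / ultra-rare categories, autosomal-recessive shares rising with rarity
(0.20 -> 0.425), multigenic/multifactorial shares falling (0.145 -> 0.003),
expressivity mixtures targeting obligate/very-frequent ratio medians around
0.22/0.25/0.33, and phenotyped fractions of 0.90/0.94/0.64.

Determinism: one root seed feeds a counter-based stream split — disorder
``i`` always draws from ``SeedSequence(seed, spawn_key=(1, i))`` — so
insertion order cannot perturb downstream draws and identical configs yield
byte-identical bundles.

A pathway annotation (GMT) is co-generated over the same gene pool, with one
pathway over-represented in one category's gene draws as a known positive
control for the over-representation analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import numpy as np

from .classification import (
    CATEGORY_OF_CLASS,
    Category,
    SPECTRUM_CATEGORIES,
    round_half_up,
)
from .enrichment import PathwayAnnotation
from .registry import (
    AssociationType,
    DisorderGroup,
    DisorderRecord,
    DisorderRegistry,
    DisorderType,
    GeneAssociation,
    GeographicScope,
    HPOAnnotation,
    Inheritance,
    Occurrence,
    PrevalenceClass,
    PrevalenceKind,
    PrevalenceRecord,
    Provenance,
    RARITY_ORDER,
)

__all__ = [
    "IntDistribution",
    "CategoryParams",
    "NoiseConfig",
    "GMTConfig",
    "GeneratorConfig",
    "GenerationManifest",
    "default_config",
    "generate",
    "generate_gmt",
    "inject_edge_cases",
    "ONSET_LEVELS",
    "DEATH_LEVELS",
]

_MIXTURE_TOL = 1e-9

#: Interval average-age-of-onset levels (infancy = 4 weeks-23 months,
#: childhood = 2-11 years, adolescence = 12-18, adulthood = 19-65,
#: elderly = after 65, all ages = from birth to adulthood).
ONSET_LEVELS = (
    "infancy",
    "childhood",
    "adolescence",
    "adulthood",
    "elderly",
    "all_ages",
)

#: Interval average-age-of-death levels; adds normal life expectancy and
#: death at any age to the onset age bands.
DEATH_LEVELS = (
    "infancy",
    "childhood",
    "adolescence",
    "adulthood",
    "elderly",
    "normal_life_expectancy",
    "any_age",
)

_CONTINENTS = ("Europe", "North America", "Asia", "Africa", "South America")


@dataclass(frozen=True)
class IntDistribution:
    """A small family of integer distributions for count draws.

    kinds: ``constant`` (params: value), ``geometric`` (params: p; support
    1, 2, ...), ``negative_binomial`` (params: r, mu; support 0, 1, ...).
    ``shift`` is added to every draw.
    """

    kind: str
    params: dict[str, float] = field(default_factory=dict)
    shift: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "geometric", "negative_binomial"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "constant":
            value = int(self.params["value"])
        elif self.kind == "geometric":
            value = int(rng.geometric(self.params["p"]))
        else:
            r = self.params["r"]
            mu = self.params["mu"]
            value = int(rng.negative_binomial(r, r / (r + mu)))
        return value + self.shift


def _check_mixture(name: str, mixture: Mapping[str, float]) -> None:
    total = sum(mixture.values())
    if abs(total - 1.0) > _MIXTURE_TOL:
        raise ValueError(f"{name}: mixture sums to {total!r}, expected 1")
    if any(v < 0 for v in mixture.values()):
        raise ValueError(f"{name}: negative mixture weight")


def _draw(rng: np.random.Generator, mixture: Mapping[str, float]) -> str:
    labels = list(mixture)
    weights = np.array([mixture[l] for l in labels], dtype=float)
    return labels[rng.choice(len(labels), p=weights / weights.sum())]


@dataclass
class CategoryParams:
    """Generation parameters for one spectrum category."""

    inheritance: dict[str, float]
    disorder_type_mixture: dict[str, float]
    parent_mixture: dict[str, float]
    gene_zero_prob: float
    gene_count: IntDistribution
    phenotyped_fraction: float
    hpo_count: IntDistribution
    occurrence_mixture: dict[str, float]
    onset_available: float
    onset_mixture: dict[str, float]
    death_available: float
    death_mixture: dict[str, float]
    term_bias_window: tuple[int, int] = (0, 0)
    term_bias: float = 1.0

    def validate(self, label: str) -> None:
        for name, mix in (
            ("disorder_type_mixture", self.disorder_type_mixture),
            ("parent_mixture", self.parent_mixture),
            ("occurrence_mixture", self.occurrence_mixture),
            ("onset_mixture", self.onset_mixture),
            ("death_mixture", self.death_mixture),
        ):
            _check_mixture(f"{label}.{name}", mix)
        for prob_name in ("gene_zero_prob", "phenotyped_fraction",
                          "onset_available", "death_available"):
            v = getattr(self, prob_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label}.{prob_name} outside [0, 1]")
        for inh, v in self.inheritance.items():
            Inheritance(inh)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label}.inheritance[{inh}] outside [0, 1]")

    def conditional_occurrence_targets(self) -> tuple[float, float]:
        """Implied (obligate+very-frequent, occasional+very-rare) ratios
        conditional on an annotation not being 'excluded'."""
        m = self.occurrence_mixture
        keep = 1.0 - m.get(Occurrence.EXCLUDED.value, 0.0)
        q1 = (
            m.get(Occurrence.OBLIGATE.value, 0.0)
            + m.get(Occurrence.VERY_FREQUENT.value, 0.0)
        ) / keep
        q2 = (
            m.get(Occurrence.OCCASIONAL.value, 0.0)
            + m.get(Occurrence.VERY_RARE.value, 0.0)
        ) / keep
        return q1, q2


@dataclass
class NoiseConfig:
    """Prevalence-record noise exercising the mode/tie resolution logic."""

    continent_only_fraction: float = 0.3
    conflict_prob: float = 0.1
    birth_record_prob: float = 0.1
    synonym_prob: float = 0.3


@dataclass
class GMTConfig:
    """Co-generated pathway annotation with one positive-control signal."""

    n_pathways: int = 50
    pathway_size: int = 40
    extra_overlap: int = 10
    signal_category: str = Category.ULTRA_RARE.value
    signal_strength: float = 0.3


@dataclass
class GeneratorConfig:
    seed: int
    class_counts: dict[PrevalenceClass, int]
    categories: dict[Category, CategoryParams]
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    gmt: GMTConfig = field(default_factory=GMTConfig)
    vocab_size: int = 400

    def validate(self) -> None:
        for cls, n in self.class_counts.items():
            cls = PrevalenceClass(cls)
            if n < 0:
                raise ValueError(f"negative disorder count for {cls.value}")
            if CATEGORY_OF_CLASS.get(cls) not in SPECTRUM_CATEGORIES:
                raise ValueError(
                    f"class {cls.value} lies outside the spectrum"
                )
        for category, params in self.categories.items():
            params.validate(Category(category).value)
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "vocab_size": self.vocab_size,
            "class_counts": {
                PrevalenceClass(k).value: v for k, v in self.class_counts.items()
            },
            "categories": {
                Category(k).value: asdict(v) for k, v in self.categories.items()
            },
            "noise": asdict(self.noise),
            "gmt": asdict(self.gmt),
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "GeneratorConfig":
        categories = {}
        for label, block in data["categories"].items():
            block = dict(block)
            block["gene_count"] = IntDistribution(**block["gene_count"])
            block["hpo_count"] = IntDistribution(**block["hpo_count"])
            block["term_bias_window"] = tuple(block["term_bias_window"])
            categories[Category(label)] = CategoryParams(**block)
        return cls(
            seed=int(data["seed"]),
            vocab_size=int(data.get("vocab_size", 400)),
            class_counts={
                PrevalenceClass(k): int(v)
                for k, v in data["class_counts"].items()
            },
            categories=categories,
            noise=NoiseConfig(**data.get("noise", {})),
            gmt=GMTConfig(**data.get("gmt", {})),
        )


@dataclass
class GenerationManifest:
    """Echo of the configuration plus realized counts; together with the
    config it suffices to regenerate the bundle byte-identically."""

    seed: int
    config: dict[str, Any]
    class_counts: dict[str, int]
    category_counts: dict[str, int]
    realized: dict[str, Any]
    vocab_size: int
    n_genes: int
    edge_case_tags: dict[str, int] = field(default_factory=dict)


def _occurrence_mixture(q1: float, qf: float, q2: float, p_excluded: float) -> dict:
    keep = 1.0 - p_excluded
    mix = {
        Occurrence.OBLIGATE.value: 0.2 * q1 * keep,
        Occurrence.VERY_FREQUENT.value: 0.8 * q1 * keep,
        Occurrence.FREQUENT.value: qf * keep,
        Occurrence.OCCASIONAL.value: 0.65 * q2 * keep,
        Occurrence.VERY_RARE.value: 0.35 * q2 * keep,
        Occurrence.EXCLUDED.value: p_excluded,
    }
    total = sum(mix.values())
    return {k: v / total for k, v in mix.items()}


def _type_mixture(**named: float) -> dict[str, float]:
    rest = 1.0 - sum(named.values())
    mix = dict(named)
    mix[DisorderType.DISEASE.value] = mix.get(DisorderType.DISEASE.value, 0.0) + rest
    return mix


_PARENTS = (
    "rare developmental defect during embryogenesis",
    "rare neurologic disease",
    "rare inborn errors of metabolism",
    "rare bone disease",
    "rare skin disease",
    "rare systemic or rheumatologic disease",
)


def _parent_mixture(*weights: float) -> dict[str, float]:
    mix = dict(zip(_PARENTS, weights))
    mix["other rare disease"] = 1.0 - sum(weights)
    return mix


def default_config(seed: int, scale: float = 1.0) -> GeneratorConfig:
    """Study-condition defaults.

    Per-class disorder counts reproduce the published spectrum: category
    totals 145/412/2967, with the within-category split (48 + 97 and
    30 + 382) reconstructed from the published cohort prevalences.  ``scale``
    multiplies every class count (half-up rounded) for faster smoke runs.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")

    def scaled(n: int) -> int:
        return int(round_half_up(n * scale))

    class_counts = {
        PrevalenceClass.SIX_NINE_IN_10000: scaled(48),
        PrevalenceClass.ONE_FIVE_IN_10000: scaled(97),
        PrevalenceClass.ONE_NINE_IN_100000: scaled(30),
        PrevalenceClass.ONE_NINE_IN_1000000: scaled(382),
        PrevalenceClass.LESS_THAN_1_IN_1000000: scaled(2967),
    }

    def inh(ar, ad, xlr, xld, mito, semi, y, oligo, multi):
        return {
            Inheritance.AUTOSOMAL_RECESSIVE.value: ar,
            Inheritance.AUTOSOMAL_DOMINANT.value: ad,
            Inheritance.X_LINKED_RECESSIVE.value: xlr,
            Inheritance.X_LINKED_DOMINANT.value: xld,
            Inheritance.MITOCHONDRIAL.value: mito,
            Inheritance.SEMI_DOMINANT.value: semi,
            Inheritance.Y_LINKED.value: y,
            Inheritance.OLIGOGENIC.value: oligo,
            Inheritance.MULTIGENIC_MULTIFACTORIAL.value: multi,
        }

    borderline = CategoryParams(
        inheritance=inh(0.20, 0.2897, 0.0414, 0.0069, 0.0138, 0.0069, 0.0069, 0.0, 0.1448),
        disorder_type_mixture=_type_mixture(
            malformation_syndrome=0.1103,
            morphological_anomaly=0.1172,
            particular_clinical_situation=0.1379,
            clinical_syndrome=0.0207,
        ),
        parent_mixture=_parent_mixture(0.2138, 0.0897, 0.0138, 0.0138, 0.0552, 0.1034),
        gene_zero_prob=0.25,
        gene_count=IntDistribution("geometric", {"p": 0.21}),
        phenotyped_fraction=131 / 145,
        hpo_count=IntDistribution("negative_binomial", {"r": 2.0, "mu": 18.0}, shift=1),
        occurrence_mixture=_occurrence_mixture(0.22, 0.34, 0.44, 0.04),
        onset_available=0.963,
        onset_mixture={
            "infancy": 0.18, "childhood": 0.17, "adolescence": 0.08,
            "adulthood": 0.32, "elderly": 0.07, "all_ages": 0.18,
        },
        death_available=0.642,
        death_mixture={
            "infancy": 0.04, "childhood": 0.03, "adolescence": 0.03,
            "adulthood": 0.12, "elderly": 0.13,
            "normal_life_expectancy": 0.50, "any_age": 0.15,
        },
        term_bias_window=(0, 130),
        term_bias=3.0,
    )
    rare = CategoryParams(
        inheritance=inh(0.3981, 0.3228, 0.0874, 0.0194, 0.0121, 0.0, 0.0, 0.0024, 0.0631),
        disorder_type_mixture=_type_mixture(
            malformation_syndrome=0.1578,
            morphological_anomaly=0.0437,
            particular_clinical_situation=0.0243,
            clinical_syndrome=0.0073,
        ),
        parent_mixture=_parent_mixture(0.2112, 0.2282, 0.1189, 0.0437, 0.0558, 0.0631),
        gene_zero_prob=0.25,
        gene_count=IntDistribution("geometric", {"p": 0.55}),
        phenotyped_fraction=387 / 412,
        hpo_count=IntDistribution("negative_binomial", {"r": 2.0, "mu": 25.0}, shift=1),
        occurrence_mixture=_occurrence_mixture(0.25, 0.39, 0.36, 0.04),
        onset_available=0.963,
        onset_mixture={
            "infancy": 0.25, "childhood": 0.20, "adolescence": 0.10,
            "adulthood": 0.25, "elderly": 0.05, "all_ages": 0.15,
        },
        death_available=0.642,
        death_mixture={
            "infancy": 0.07, "childhood": 0.05, "adolescence": 0.06,
            "adulthood": 0.18, "elderly": 0.14,
            "normal_life_expectancy": 0.38, "any_age": 0.12,
        },
        term_bias_window=(100, 260),
        term_bias=3.0,
    )
    ultra = CategoryParams(
        inheritance=inh(0.4247, 0.2545, 0.0627, 0.0142, 0.0040, 0.0010, 0.0003, 0.0, 0.0030),
        disorder_type_mixture=_type_mixture(
            malformation_syndrome=0.4260,
            morphological_anomaly=0.0162,
            particular_clinical_situation=0.0003,
            clinical_syndrome=0.0017,
            biological_anomaly=0.0017,
        ),
        parent_mixture=_parent_mixture(0.4112, 0.2026, 0.0735, 0.0822, 0.0556, 0.0179),
        gene_zero_prob=0.25,
        gene_count=IntDistribution("geometric", {"p": 0.85}),
        phenotyped_fraction=1912 / 2967,
        hpo_count=IntDistribution("negative_binomial", {"r": 2.0, "mu": 20.0}, shift=1),
        occurrence_mixture=_occurrence_mixture(0.33, 0.49, 0.18, 0.04),
        onset_available=0.963,
        onset_mixture={
            "infancy": 0.45, "childhood": 0.25, "adolescence": 0.05,
            "adulthood": 0.12, "elderly": 0.02, "all_ages": 0.11,
        },
        death_available=0.642,
        death_mixture={
            "infancy": 0.22, "childhood": 0.15, "adolescence": 0.05,
            "adulthood": 0.12, "elderly": 0.08,
            "normal_life_expectancy": 0.30, "any_age": 0.08,
        },
        term_bias_window=(180, 400),
        term_bias=3.0,
    )
    config = GeneratorConfig(
        seed=int(seed),
        class_counts=class_counts,
        categories={
            Category.BORDERLINE_COMMON: borderline,
            Category.RARE: rare,
            Category.ULTRA_RARE: ultra,
        },
    )
    config.validate()
    return config


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _gene_pool(config: GeneratorConfig) -> list[str]:
    n = config.gmt.n_pathways * config.gmt.pathway_size
    return [f"SYNG{i:05d}" for i in range(n)]


def generate_gmt(config: GeneratorConfig) -> tuple[list[PathwayAnnotation], set[str]]:
    """Synthetic pathway annotation over the generator's gene pool.

    Pathway ``i`` owns a disjoint core block of the pool plus a few random
    extra genes (overlap); pathway 0 is the positive-control signal set.
    Returns ``(pathways, background)`` where background is the full pool.
    """
    pool = _gene_pool(config)
    size = config.gmt.pathway_size
    pathways = []
    for i in range(config.gmt.n_pathways):
        rng = _rng_for(config.seed, 2, i)
        core = pool[i * size : (i + 1) * size]
        extras = [
            pool[j]
            for j in rng.choice(
                len(pool), size=config.gmt.extra_overlap, replace=False
            )
        ]
        pathways.append(
            PathwayAnnotation(
                pathway_id=f"SPW{i:04d}",
                pathway_name=f"synthetic pathway {i}",
                genes=frozenset(core) | frozenset(extras),
            )
        )
    return pathways, set(pool)


def signal_pathway_id() -> str:
    return "SPW0000"


def _sample_terms(
    rng: np.random.Generator, params: CategoryParams, vocab_size: int, n: int
) -> list[int]:
    weights = np.ones(vocab_size)
    lo, hi = params.term_bias_window
    weights[lo:hi] *= params.term_bias
    weights /= weights.sum()
    n = min(n, vocab_size)
    return sorted(rng.choice(vocab_size, size=n, replace=False, p=weights))


def _sample_genes(
    rng: np.random.Generator,
    config: GeneratorConfig,
    category: Category,
    pool: list[str],
    signal_genes: list[str],
    n: int,
) -> list[str]:
    chosen: set[str] = set()
    is_signal = category.value == config.gmt.signal_category
    attempts = 0
    while len(chosen) < n and attempts < 20 * n + 20:
        attempts += 1
        if is_signal and rng.random() < config.gmt.signal_strength:
            chosen.add(signal_genes[rng.integers(len(signal_genes))])
        else:
            chosen.add(pool[rng.integers(len(pool))])
    return sorted(chosen)


def _generate_disorder(
    idx: int,
    cls: PrevalenceClass,
    config: GeneratorConfig,
    pool: list[str],
    signal_genes: list[str],
) -> DisorderRecord:
    rng = _rng_for(config.seed, 1, idx)
    category = CATEGORY_OF_CLASS[cls]
    params = config.categories[category]
    orphacode = 100001 + idx
    noise = config.noise

    name = f"Synthetic disorder {orphacode}"
    synonyms = (
        [f"SD-{orphacode} variant form"] if rng.random() < noise.synonym_prob else []
    )

    # prevalence records
    prevalence: list[PrevalenceRecord] = []
    if rng.random() < noise.continent_only_fraction:
        conflict = rng.random() < noise.conflict_prob
        n_major = int(rng.integers(2, 4))
        continents = list(_CONTINENTS)
        for i in range(n_major):
            prevalence.append(
                PrevalenceRecord(
                    PrevalenceKind.POINT, cls, GeographicScope.CONTINENT,
                    continents[i],
                )
            )
        if conflict:
            # minority class one step away within the spectrum; the modal
            # class (the configured one) still wins the resolution
            i = RARITY_ORDER.index(cls)
            neighbor = RARITY_ORDER[i + 1] if i + 1 <= 5 else RARITY_ORDER[i - 1]
            if CATEGORY_OF_CLASS.get(neighbor) not in SPECTRUM_CATEGORIES:
                neighbor = RARITY_ORDER[i + 1]
            prevalence.append(
                PrevalenceRecord(
                    PrevalenceKind.POINT, neighbor, GeographicScope.CONTINENT,
                    continents[n_major],
                )
            )
    else:
        prevalence.append(
            PrevalenceRecord(
                PrevalenceKind.POINT, cls, GeographicScope.WORLDWIDE, "Worldwide"
            )
        )
    if rng.random() < noise.birth_record_prob:
        birth_cls = RARITY_ORDER[int(rng.integers(1, 6))]
        prevalence.append(
            PrevalenceRecord(
                PrevalenceKind.BIRTH, birth_cls, GeographicScope.WORLDWIDE,
                "Worldwide",
            )
        )

    disorder_type = DisorderType(_draw(rng, params.disorder_type_mixture))
    parent = _draw(rng, params.parent_mixture)

    inheritance = {
        Inheritance(label)
        for label, prob in params.inheritance.items()
        if rng.random() < prob
    }

    onset: set[str] = set()
    if rng.random() < params.onset_available:
        onset.add(_draw(rng, params.onset_mixture))
    death: set[str] = set()
    if rng.random() < params.death_available:
        death.add(_draw(rng, params.death_mixture))

    annotations: list[HPOAnnotation] = []
    if rng.random() < params.phenotyped_fraction:
        n_terms = max(1, params.hpo_count.sample(rng))
        for term_idx in _sample_terms(rng, params, config.vocab_size, n_terms):
            occurrence = Occurrence(_draw(rng, params.occurrence_mixture))
            annotations.append(
                HPOAnnotation(
                    hpo_id=f"HP:{9000001 + term_idx:07d}",
                    term_label=f"Synthetic phenotype {term_idx}",
                    occurrence=occurrence,
                )
            )

    genes: list[GeneAssociation] = []
    if rng.random() >= params.gene_zero_prob:
        n_genes = max(1, params.gene_count.sample(rng))
        for symbol in _sample_genes(
            rng, config, category, pool, signal_genes, n_genes
        ):
            r = rng.random()
            if r < 0.90:
                a_type = AssociationType.DISEASE_CAUSING
            elif r < 0.95:
                a_type = AssociationType.MODIFIER
            elif r < 0.99:
                a_type = AssociationType.SUSCEPTIBILITY
            else:
                a_type = AssociationType.OTHER
            genes.append(GeneAssociation(symbol, a_type))

    return DisorderRecord(
        orphacode=orphacode,
        name=name,
        synonyms=synonyms,
        disorder_group=DisorderGroup.DISORDER,
        disorder_type=disorder_type,
        linearisation_parent=parent,
        inheritance_types=inheritance,
        onset_intervals=onset,
        death_intervals=death,
        prevalence_records=prevalence,
        hpo_annotations=annotations,
        gene_associations=genes,
    )


def generate(config: GeneratorConfig) -> tuple[DisorderRegistry, GenerationManifest]:
    """Generate a registry (and manifest) from a validated config."""
    config.validate()
    pool = _gene_pool(config)
    signal_genes = pool[: config.gmt.pathway_size]

    records: list[DisorderRecord] = []
    true_class: list[PrevalenceClass] = []
    idx = 0
    for cls in RARITY_ORDER:
        count = config.class_counts.get(cls, 0)
        for _ in range(count):
            records.append(
                _generate_disorder(idx, cls, config, pool, signal_genes)
            )
            true_class.append(cls)
            idx += 1

    registry = DisorderRegistry(
        records, provenance=Provenance("rdspectrum-simulate", "")
    )

    category_counts = {c.value: 0 for c in SPECTRUM_CATEGORIES}
    inh_freq: dict[str, dict[str, float]] = {}
    phenotyped = {c.value: 0 for c in SPECTRUM_CATEGORIES}
    for cls, count in config.class_counts.items():
        category_counts[CATEGORY_OF_CLASS[PrevalenceClass(cls)].value] += count
    for record, cls in zip(records, true_class):
        cat = CATEGORY_OF_CLASS[cls].value
        freq = inh_freq.setdefault(cat, {i.value: 0 for i in Inheritance})
        for i in record.inheritance_types:
            freq[i.value] += 1
        if any(
            a.occurrence is not Occurrence.EXCLUDED for a in record.hpo_annotations
        ):
            phenotyped[cat] += 1
    for cat, freq in inh_freq.items():
        n = category_counts[cat]
        inh_freq[cat] = {k: v / n for k, v in freq.items()} if n else freq

    manifest = GenerationManifest(
        seed=config.seed,
        config=config.to_dict(),
        class_counts={
            PrevalenceClass(k).value: v for k, v in config.class_counts.items()
        },
        category_counts=category_counts,
        realized={
            "inheritance_frequencies": inh_freq,
            "phenotyped_counts": phenotyped,
        },
        vocab_size=config.vocab_size,
        n_genes=len(pool),
    )
    return registry, manifest


# ---------------------------------------------------------------------------
# Edge-case battery
# ---------------------------------------------------------------------------


def inject_edge_cases(
    registry: DisorderRegistry, start_code: int = 99000001
) -> tuple[DisorderRegistry, dict[str, int]]:
    """Append a fixed battery of boundary records for filter/classification
    tests.

    Returns the enlarged registry and a tag -> orphacode map: a
    group-of-disorders record, a birth-prevalence-only record, an
    excluded-parent record, a >1/1,000 record, an excluded-only-HPO record
    and a continent modal-tie record.
    """
    worldwide_point = PrevalenceRecord(
        PrevalenceKind.POINT,
        PrevalenceClass.ONE_NINE_IN_100000,
        GeographicScope.WORLDWIDE,
        "Worldwide",
    )
    battery = {
        "group_of_disorders": DisorderRecord(
            orphacode=start_code,
            name="Edge case: group of disorders",
            disorder_group=DisorderGroup.GROUP_OF_DISORDERS,
            prevalence_records=[worldwide_point],
        ),
        "birth_prevalence_only": DisorderRecord(
            orphacode=start_code + 1,
            name="Edge case: birth prevalence only",
            prevalence_records=[
                PrevalenceRecord(
                    PrevalenceKind.BIRTH,
                    PrevalenceClass.ONE_NINE_IN_100000,
                    GeographicScope.WORLDWIDE,
                    "Worldwide",
                )
            ],
        ),
        "excluded_parent": DisorderRecord(
            orphacode=start_code + 2,
            name="Edge case: excluded linearisation parent",
            linearisation_parent="rare infectious disease",
            prevalence_records=[worldwide_point],
        ),
        "excluded_common": DisorderRecord(
            orphacode=start_code + 3,
            name="Edge case: above the rare threshold",
            prevalence_records=[
                PrevalenceRecord(
                    PrevalenceKind.POINT,
                    PrevalenceClass.MORE_THAN_1_IN_1000,
                    GeographicScope.WORLDWIDE,
                    "Worldwide",
                )
            ],
        ),
        "excluded_only_hpo": DisorderRecord(
            orphacode=start_code + 4,
            name="Edge case: excluded-only phenotype",
            prevalence_records=[worldwide_point],
            hpo_annotations=[
                HPOAnnotation("HP:9999001", "absent phenotype", Occurrence.EXCLUDED)
            ],
        ),
        "continent_tie": DisorderRecord(
            orphacode=start_code + 5,
            name="Edge case: continent modal tie",
            prevalence_records=[
                PrevalenceRecord(
                    PrevalenceKind.POINT,
                    PrevalenceClass.ONE_FIVE_IN_10000,
                    GeographicScope.CONTINENT,
                    "Europe",
                ),
                PrevalenceRecord(
                    PrevalenceKind.POINT,
                    PrevalenceClass.ONE_NINE_IN_100000,
                    GeographicScope.CONTINENT,
                    "Asia",
                ),
            ],
        ),
    }
    out = DisorderRegistry(
        list(registry) + list(battery.values()), provenance=registry.provenance
    )
    tags = {tag: rec.orphacode for tag, rec in battery.items()}
    return out, tags
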