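"""Shared fixtures: a tiny handcrafted registry and a full-size synthetic
study (generated once per session) used by the recovery and acceptance
tests."""

from __future__ import annotations

import pytest

from rdspectrum.classification import classify_registry
from rdspectrum.registry import (
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
)
from rdspectrum.simulate import default_config, generate, generate_gmt

STUDY_SEED = 7


def _point(cls, scope=GeographicScope.WORLDWIDE, label="Worldwide"):
    return PrevalenceRecord(PrevalenceKind.POINT, cls, scope, label)


@pytest.fixture
def toy_registry() -> DisorderRegistry:
    """Three disorders exercising every record facet."""
    return DisorderRegistry(
        [
            DisorderRecord(
                orphacode=101,
                name="Alpha syndrome",
                synonyms=["alpha disease"],
                disorder_type=DisorderType.MALFORMATION_SYNDROME,
                linearisation_parent="rare bone disease",
                inheritance_types={Inheritance.AUTOSOMAL_RECESSIVE},
                onset_intervals={"infancy"},
                death_intervals={"normal_life_expectancy"},
                prevalence_records=[_point(PrevalenceClass.ONE_NINE_IN_100000)],
                hpo_annotations=[
                    HPOAnnotation("HP:0001250", "Seizures", Occurrence.OBLIGATE),
                    HPOAnnotation(
                        "HP:0004322", "Short stature", Occurrence.OCCASIONAL
                    ),
                ],
                gene_associations=[GeneAssociation("ABC1")],
            ),
            DisorderRecord(
                orphacode=202,
                name="Beta disease",
                prevalence_records=[
                    _point(
                        PrevalenceClass.ONE_FIVE_IN_10000,
                        GeographicScope.CONTINENT,
                        "Europe",
                    ),
                    _point(
                        PrevalenceClass.ONE_FIVE_IN_10000,
                        GeographicScope.CONTINENT,
                        "Asia",
                    ),
                ],
                hpo_annotations=[
                    HPOAnnotation("HP:0001250", "Seizures", Occurrence.FREQUENT)
                ],
            ),
            DisorderRecord(
                orphacode=303,
                name="Gamma anomaly",
                disorder_group=DisorderGroup.DISORDER,
                prevalence_records=[
                    _point(PrevalenceClass.LESS_THAN_1_IN_1000000)
                ],
            ),
        ]
    )


@pytest.fixture(scope="session")
def study():
    """Full-scale synthetic study under the default conditions.

    Generated once per session: the default-config registry (3,524
    disorders), its classification, and the co-generated pathway annotation.
    """
    config = default_config(seed=STUDY_SEED, scale=1.0)
    registry, manifest = generate(config)
    result = classify_registry(registry)
    pathways, background = generate_gmt(config)
    return {
        "config": config,
        "registry": registry,
        "manifest": manifest,
        "classification": result,
        "assignments": result.by_orphacode,
        "pathways": pathways,
        "background": background,
    }
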