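"""Tabular registry bundle I/O.

The canonical on-disk form of a registry is a directory of UTF-8
tab-separated files, one per facet, diffable and language-neutral:

========================  =====================================================
file                      columns
========================  =====================================================
disorders.tsv             orphacode, name, synonyms, disorder_group,
                          disorder_type, linearisation_parent
prevalence.tsv            orphacode, kind, prevalence_class, geographic_scope,
                          scope_label
inheritance.tsv           orphacode, inheritance_type
natural_history.tsv       orphacode, axis (onset|death), level
hpo_annotations.tsv       orphacode, hpo_id, term_label, occurrence
gene_associations.tsv     orphacode, gene_symbol, association_type
========================  =====================================================

``synonyms`` is pipe-joined.  Prevalence-class strings are the exact interval
labels (e.g. ``1-9/100,000``).  Rows are emitted in deterministic order
(orphacode, then the facet's natural key) so two writes of the same registry
are byte-identical.  A small ``provenance.json`` records the source label and
snapshot date.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

from .registry import (
    DisorderRecord,
    DisorderRegistry,
    GeneAssociation,
    HPOAnnotation,
    PrevalenceRecord,
    Provenance,
)

__all__ = ["BundleError", "write_bundle", "load_registry", "BUNDLE_FILES"]

logger = logging.getLogger(__name__)

BUNDLE_FILES = {
    "disorders.tsv": [
        "orphacode",
        "name",
        "synonyms",
        "disorder_group",
        "disorder_type",
        "linearisation_parent",
    ],
    "prevalence.tsv": [
        "orphacode",
        "kind",
        "prevalence_class",
        "geographic_scope",
        "scope_label",
    ],
    "inheritance.tsv": ["orphacode", "inheritance_type"],
    "natural_history.tsv": ["orphacode", "axis", "level"],
    "hpo_annotations.tsv": ["orphacode", "hpo_id", "term_label", "occurrence"],
    "gene_associations.tsv": ["orphacode", "gene_symbol", "association_type"],
}


class BundleError(Exception):
    """Raised for missing bundle files, malformed rows or broken references."""


def write_bundle(registry: DisorderRegistry, out_path: str | Path) -> list[Path]:
    """Write ``registry`` to ``out_path`` as the canonical TSV bundle.

    Returns the list of files written.  Writing is deterministic: the same
    registry always yields byte-identical files.
    """
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)

    tables: dict[str, list[list[str]]] = {name: [] for name in BUNDLE_FILES}
    for rec in registry:  # iteration is orphacode-sorted
        code = str(rec.orphacode)
        tables["disorders.tsv"].append(
            [
                code,
                rec.name,
                "|".join(rec.synonyms),
                rec.disorder_group.value,
                rec.disorder_type.value,
                rec.linearisation_parent,
            ]
        )
        for p in rec.prevalence_records:
            tables["prevalence.tsv"].append(
                [
                    code,
                    p.kind.value,
                    p.prevalence_class.value,
                    p.geographic_scope.value,
                    p.scope_label,
                ]
            )
        for inh in sorted(i.value for i in rec.inheritance_types):
            tables["inheritance.tsv"].append([code, inh])
        for level in sorted(rec.onset_intervals):
            tables["natural_history.tsv"].append([code, "onset", level])
        for level in sorted(rec.death_intervals):
            tables["natural_history.tsv"].append([code, "death", level])
        for ann in rec.hpo_annotations:
            tables["hpo_annotations.tsv"].append(
                [code, ann.hpo_id, ann.term_label, ann.occurrence.value]
            )
        for g in rec.gene_associations:
            tables["gene_associations.tsv"].append(
                [code, g.gene_symbol, g.association_type.value]
            )

    written: list[Path] = []
    for name, header in BUNDLE_FILES.items():
        path = out / name
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(tables[name])
        written.append(path)

    prov_path = out / "provenance.json"
    prov_path.write_text(
        json.dumps(
            {
                "source": registry.provenance.source,
                "snapshot_date": registry.provenance.snapshot_date,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    written.append(prov_path)
    logger.info("wrote bundle with %d records to %s", len(registry), out)
    return written


def _read_rows(path: Path, expected_header: list[str]) -> list[tuple[int, dict]]:
    if not path.is_file():
        raise BundleError(f"missing mandatory bundle file: {path.name}")
    rows: list[tuple[int, dict]] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise BundleError(f"{path.name}: empty file (expected header row)")
        if header != expected_header:
            raise BundleError(
                f"{path.name}: unexpected header {header!r}, "
                f"expected {expected_header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected_header):
                raise BundleError(
                    f"{path.name}:{lineno}: expected "
                    f"{len(expected_header)} fields, got {len(row)}"
                )
            rows.append((lineno, dict(zip(expected_header, row))))
    return rows


def load_registry(bundle_path: str | Path, strict: bool = True) -> DisorderRegistry:
    """Load a registry from a bundle directory.

    In strict mode an orphacode appearing in a facet file but absent from
    disorders.tsv is an error; in lenient mode the row is skipped with a
    warning.  Malformed rows (bad enum labels, non-integer orphacodes) raise
    :class:`BundleError` naming the file and line.
    """
    bundle = Path(bundle_path)
    raw = {
        name: _read_rows(bundle / name, header)
        for name, header in BUNDLE_FILES.items()
    }

    def parse(name: str, lineno: int, fn, *args):
        try:
            return fn(*args)
        except (ValueError, KeyError) as exc:
            raise BundleError(f"{name}:{lineno}: {exc}") from exc

    partial: dict[int, dict] = {}
    for lineno, row in raw["disorders.tsv"]:
        code = parse("disorders.tsv", lineno, int, row["orphacode"])
        if code in partial:
            raise BundleError(
                f"disorders.tsv:{lineno}: duplicate orphacode {code}"
            )
        partial[code] = {
            "orphacode": code,
            "name": row["name"],
            "synonyms": row["synonyms"].split("|") if row["synonyms"] else [],
            "disorder_group": row["disorder_group"],
            "disorder_type": row["disorder_type"],
            "linearisation_parent": row["linearisation_parent"],
            "inheritance_types": set(),
            "onset_intervals": set(),
            "death_intervals": set(),
            "prevalence_records": [],
            "hpo_annotations": [],
            "gene_associations": [],
        }

    def resolve(name: str, lineno: int, row: dict) -> dict | None:
        code = parse(name, lineno, int, row["orphacode"])
        if code not in partial:
            if strict:
                raise BundleError(
                    f"{name}:{lineno}: orphacode {code} not in disorders.tsv"
                )
            logger.warning(
                "%s:%d: skipping row for unknown orphacode %d", name, lineno, code
            )
            return None
        return partial[code]

    for lineno, row in raw["prevalence.tsv"]:
        entry = resolve("prevalence.tsv", lineno, row)
        if entry is not None:
            entry["prevalence_records"].append(
                parse(
                    "prevalence.tsv",
                    lineno,
                    PrevalenceRecord,
                    row["kind"],
                    row["prevalence_class"],
                    row["geographic_scope"],
                    row["scope_label"],
                )
            )
    for lineno, row in raw["inheritance.tsv"]:
        entry = resolve("inheritance.tsv", lineno, row)
        if entry is not None:
            entry["inheritance_types"].add(row["inheritance_type"])
    for lineno, row in raw["natural_history.tsv"]:
        entry = resolve("natural_history.tsv", lineno, row)
        if entry is None:
            continue
        axis = row["axis"]
        if axis == "onset":
            entry["onset_intervals"].add(row["level"])
        elif axis == "death":
            entry["death_intervals"].add(row["level"])
        else:
            raise BundleError(
                f"natural_history.tsv:{lineno}: unknown axis {axis!r}"
            )
    for lineno, row in raw["hpo_annotations.tsv"]:
        entry = resolve("hpo_annotations.tsv", lineno, row)
        if entry is not None:
            entry["hpo_annotations"].append(
                parse(
                    "hpo_annotations.tsv",
                    lineno,
                    HPOAnnotation,
                    row["hpo_id"],
                    row["term_label"],
                    row["occurrence"],
                )
            )
    for lineno, row in raw["gene_associations.tsv"]:
        entry = resolve("gene_associations.tsv", lineno, row)
        if entry is not None:
            entry["gene_associations"].append(
                parse(
                    "gene_associations.tsv",
                    lineno,
                    GeneAssociation,
                    row["gene_symbol"],
                    row["association_type"],
                )
            )

    provenance = Provenance()
    prov_path = bundle / "provenance.json"
    if prov_path.is_file():
        meta = json.loads(prov_path.read_text(encoding="utf-8"))
        provenance = Provenance(
            source=meta.get("source", "unknown"),
            snapshot_date=meta.get("snapshot_date", ""),
        )

    records = []
    for code in sorted(partial):
        try:
            records.append(DisorderRecord(**partial[code]))
        except ValueError as exc:
            raise BundleError(f"orphacode {code}: {exc}") from exc
    registry = DisorderRegistry(records, provenance=provenance)
    logger.info("loaded %d records from %s", len(registry), bundle)
    return registry
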