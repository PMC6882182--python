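"""Loaders for the editable analysis configuration tables.

All interpretation content lives in plain-text tables (YAML for structured
rules, TSV for the marker panel) so it can be audited and replaced without
touching code.  Packaged defaults under ``variome/data`` are illustrative
and non-diagnostic.
"""

from __future__ import annotations

import os
from importlib import resources

import yaml

from .analyses import (
    AimMarker,
    AncestryPanel,
    PgxRow,
    PgxRule,
    RiskModel,
    Site,
    TraitModel,
)
from .errors import ConfigError


def _site(d: dict) -> Site:
    try:
        return Site(
            contig=str(d["contig"]),
            pos=int(d["pos"]),
            ref=str(d["ref"]),
            alt=str(d["alt"]),
            rsid=d.get("rsid"),
        )
    except KeyError as exc:
        raise ConfigError(f"site entry missing key {exc}: {d}") from exc


def load_trait_model(path: str | os.PathLike) -> TraitModel:
    """YAML: name, variants (list of sites), phenotypes (joint key -> label).

    Joint keys are comma-separated zygosity values in variant order, e.g.
    ``het,hom_ref``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        variants = [_site(v) for v in doc["variants"]]
        phenotype_map = {
            tuple(k.replace(" ", "").split(",")): str(v)
            for k, v in doc["phenotypes"].items()
        }
        return TraitModel(
            name=str(doc["name"]),
            variants=variants,
            phenotype_map=phenotype_map,
            default_phenotype=doc.get("default"),
            absent_hom_ref=bool(doc.get("absent_hom_ref", False)),
        )
    except KeyError as exc:
        raise ConfigError(f"trait config {path}: missing key {exc}") from exc


def load_risk_model(path: str | os.PathLike) -> RiskModel:
    """YAML: disease, pre_test_probability, variants with per-zygosity LRs."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        entries = {}
        for v in doc["variants"]:
            site = _site(v)
            lrs = {str(k): float(x) for k, x in v["lr"].items()}
            entries[site] = lrs
        return RiskModel(
            disease=str(doc["disease"]),
            pre_test_probability=float(doc["pre_test_probability"]),
            entries=entries,
            absent_hom_ref=bool(doc.get("absent_hom_ref", False)),
        )
    except KeyError as exc:
        raise ConfigError(f"risk config {path}: missing key {exc}") from exc


def load_pgx_rule(path: str | os.PathLike) -> PgxRule:
    """YAML: drug, gene, sites, diplotypes (joint zygosity key -> row)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        sites = [_site(s) for s in doc["sites"]]
        table = {}
        for key, row in doc["diplotypes"].items():
            k = tuple(key.replace(" ", "").split(","))
            if len(k) != len(sites):
                raise ConfigError(
                    f"pgx config {path}: key {key!r} has {len(k)} entries for "
                    f"{len(sites)} site(s)"
                )
            table[k] = PgxRow(
                diplotype=str(row["diplotype"]),
                phenotype=str(row["phenotype"]),
                recommendation=str(row["recommendation"]),
                source=str(row.get("source", "CPIC")),
            )
        return PgxRule(
            drug=str(doc["drug"]),
            gene=str(doc["gene"]),
            sites=sites,
            diplotype_table=table,
            absent_hom_ref=bool(doc.get("absent_hom_ref", False)),
        )
    except KeyError as exc:
        raise ConfigError(f"pgx config {path}: missing key {exc}") from exc


def load_ancestry_panel(
    panel_path: str | os.PathLike, background_path: str | os.PathLike | None = None
) -> AncestryPanel:
    """TSV panel: ``#markers=N`` header line, then
    contig, pos, ref, alt, frequency, loading_pc1, loading_pc2 columns.

    Optional background TSV: sample, population, pc1, pc2.
    """
    declared = None
    markers: list[AimMarker] = []
    with open(panel_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#markers="):
                    declared = int(line.split("=", 1)[1])
                continue
            cols = line.split("\t")
            if cols[0] == "contig":
                continue
            contig, pos, ref, alt, freq, l1, l2 = cols[:7]
            site = Site(contig, int(pos), ref, alt)
            markers.append(
                AimMarker(site, alt, float(freq), float(l1), float(l2))
            )
    if declared is None:
        declared = len(markers)
    if declared != len(markers):
        raise ConfigError(
            f"ancestry panel {panel_path} declares {declared} markers but "
            f"contains {len(markers)}"
        )
    background = []
    if background_path:
        with open(background_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("sample\t"):
                    continue
                sample, pop, pc1, pc2 = line.split("\t")[:4]
                background.append((sample, pop, float(pc1), float(pc2)))
    return AncestryPanel(markers=markers, declared_markers=declared, background=background)


def packaged_data_path(name: str):
    """Path to a packaged default table under ``variome/data``."""
    return resources.files("variome") / "data" / name
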