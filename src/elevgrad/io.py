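"""CSV/YAML readers and writers for site tables and communities.

CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory header row;
metadata (package version, seed, configuration hash) is written as
'#'-prefixed comment lines above the header and skipped on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import SiteTable, TaxonCommunity, ValidationError


def _metadata_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in metadata.items())


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(metadata))
        df.to_csv(fh, index=index)


def read_site_table(path) -> SiteTable:
    """Read and validate a site table CSV.

    Requires columns ``site_id`` and ``elevation_m``; any further columns
    are preserved as covariates.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("site_id", "elevation_m"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    return SiteTable(df)


def write_site_table(sites: SiteTable, path, metadata: dict | None = None) -> None:
    write_table(sites.data, path, metadata)


def read_community(path, taxon_name: str, kingdom: str,
                   is_census: bool = False,
                   sites: SiteTable | None = None) -> TaxonCommunity:
    """Read a site-by-species count matrix CSV (first column site_id)."""
    df = pd.read_csv(path, comment="#")
    if df.columns[0] != "site_id":
        raise ValidationError(f"{path}: first column must be site_id")
    df = df.set_index("site_id")
    df.index.name = None
    for col in df.columns:
        bad = df[col][(df[col] < 0) | (df[col] != df[col].round())]
        if len(bad):
            raise ValidationError(
                f"{path}: non-integer or negative count at site {bad.index[0]!r}, "
                f"species {col!r}"
            )
    community = TaxonCommunity(taxon_name, kingdom, df, is_census)
    if sites is not None:
        community.check_alignment(sites)
    return community


def write_community(community: TaxonCommunity, path,
                    metadata: dict | None = None) -> None:
    df = community.matrix.copy()
    df.index.name = "site_id"
    write_table(df.reset_index(), path, metadata)


def write_manifest(communities: list[TaxonCommunity], path,
                   extra: dict | None = None) -> None:
    """YAML manifest listing taxa, kingdoms and census flags."""
    doc = {
        "taxa": [
            {"name": c.taxon_name, "kingdom": c.kingdom,
             "is_census": bool(c.is_census), "file": f"{c.taxon_name}.csv"}
            for c in communities
        ],
    }
    if extra:
        doc.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_assemblage(directory) -> tuple[SiteTable, list[TaxonCommunity]]:
    """Read sites.csv, manifest.yaml and the listed community CSVs."""
    directory = Path(directory)
    if not directory.is_dir():
        raise ValidationError(f"community directory {directory} does not exist")
    sites = read_site_table(directory / "sites.csv")
    with open(directory / "manifest.yaml", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    communities = [
        read_community(directory / entry["file"], entry["name"], entry["kingdom"],
                       entry.get("is_census", False), sites=sites)
        for entry in manifest["taxa"]
    ]
    return sites, communities


def write_assemblage(sites: SiteTable, communities: list[TaxonCommunity],
                     directory, metadata: dict | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_site_table(sites, directory / "sites.csv", metadata)
    for c in communities:
        write_community(c, directory / f"{c.taxon_name}.csv", metadata)
    write_manifest(communities, directory / "manifest.yaml",
                   extra={"metadata": metadata or {}})
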