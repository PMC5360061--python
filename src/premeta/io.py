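"""Readers and writers for the package's plain-text formats.

Everything is tab-delimited UTF-8 with '.' decimals: expression matrices
(first column = probe/gene id, remaining columns = sample ids), two-column
probe maps, phenotype tables keyed by sample id, ground-truth tables keyed by
gene id, GMT gene-set files and one-symbol-per-line driver lists.  A JSON
manifest ties a simulated bundle together.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_probe_map",
    "write_probe_map",
    "read_pheno",
    "write_pheno",
    "read_gmt",
    "write_gmt",
    "read_driver_list",
    "write_driver_list",
    "read_manifest",
    "write_manifest",
]

_FLOAT_FMT = "%.10g"


def read_matrix(path) -> pd.DataFrame:
    """Read a probes/genes-by-samples TSV matrix (first column = row id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_probe_map(path) -> pd.Series:
    """Read a two-column probe->gene TSV into a Series indexed by probe."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)


def write_probe_map(mapping: pd.Series, path) -> None:
    frame = mapping.rename("gene").rename_axis("probe").to_frame()
    frame.to_csv(path, sep="\t")


def read_pheno(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_pheno(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_gmt(path) -> dict[str, dict]:
    """Parse a GMT file: set id, description, member genes (tab-separated)."""
    sets: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (needs >=3 fields): {line[:60]!r}")
            set_id, desc = parts[0], parts[1]
            members = sorted({g for g in parts[2:] if g})
            if not members:
                raise ValueError(f"gene set {set_id!r} has no members")
            sets[set_id] = {"description": desc, "genes": members}
    return sets


def write_gmt(sets: dict[str, dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, entry in sets.items():
            fh.write("\t".join([set_id, entry.get("description", "")] + list(entry["genes"])))
            fh.write("\n")


def read_driver_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_driver_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
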