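"""Schema validation for the pipeline's tabular inputs.

Each validator returns a list of violations; a violation is a dict with
``table``, ``row`` (0-based data row, or None for table-level rules) and
``rule``.  ``validate_inputs`` aggregates across the files named in a
pipeline configuration and fails fast on unreadable files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "validate_map",
    "validate_genotypes",
    "validate_eggcounts",
    "validate_qpcr",
    "validate_traits",
    "validate_inputs",
]


class ValidationError(Exception):
    def __init__(self, violations):
        self.violations = violations
        lines = [f"{v['table']}: row {v['row']}: {v['rule']}" for v in violations]
        super().__init__("input validation failed:\n" + "\n".join(lines))


def _v(table, row, rule):
    return {"table": table, "row": row, "rule": rule}


def _require_columns(df, cols, name, out):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        out.append(_v(name, None, f"missing columns: {missing}"))
    return not missing


def validate_map(df: pd.DataFrame, name="map.csv") -> list:
    out = []
    if not _require_columns(df, ["marker", "chrom", "cm"], name, out):
        return out
    for i in np.flatnonzero(df["marker"].duplicated().to_numpy()):
        out.append(_v(name, int(i), f"duplicate marker id {df['marker'].iloc[i]!r}"))
    for i in np.flatnonzero((df["cm"] < 0).to_numpy()):
        out.append(_v(name, int(i), "cM position < 0"))
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["cm"].to_numpy(float)
        bad = np.flatnonzero(np.diff(pos) <= 0)
        for b in bad:
            out.append(
                _v(name, int(sub.index[b + 1]), f"position not increasing on chrom {chrom}")
            )
    return out


def validate_genotypes(df: pd.DataFrame, map_df: pd.DataFrame | None = None,
                       name="genotypes.csv") -> list:
    out = []
    if "line" in df.columns:
        df = df.set_index("line")
    if df.index.duplicated().any():
        out.append(_v(name, None, "duplicate line ids"))
    vals = df.to_numpy(object)
    ok = pd.isna(vals) | np.isin(vals, ("A", "B"))
    for i, j in zip(*np.nonzero(~ok)):
        out.append(_v(name, int(i), f"invalid genotype {vals[i, j]!r} at marker {df.columns[j]}"))
    if map_df is not None and "marker" in map_df.columns:
        extra = [c for c in df.columns if c not in set(map_df["marker"])]
        for c in extra:
            out.append(_v(name, None, f"marker {c!r} absent from map"))
    return out


def validate_eggcounts(df: pd.DataFrame, name="eggcounts.tsv") -> list:
    out = []
    cols = ["line", "genotype_class", "environment", "vial", "fly", "day", "eggs"]
    if not _require_columns(df, cols, name, out):
        return out
    for i in np.flatnonzero((df["eggs"] < 0).to_numpy()):
        out.append(_v(name, int(i), "eggs < 0"))
    for i in np.flatnonzero((df["day"] < 1).to_numpy()):
        out.append(_v(name, int(i), "day < 1"))
    dup = df.duplicated(subset=["fly", "day"]).to_numpy()
    for i in np.flatnonzero(dup):
        out.append(_v(name, int(i), "duplicate (fly, day) record"))
    return out


def validate_qpcr(df: pd.DataFrame, name="qpcr.csv") -> list:
    out = []
    cols = ["sample", "group", "tissue", "gene", "bio_rep", "tech_rep", "ct"]
    if not _require_columns(df, cols, name, out):
        return out
    for i in np.flatnonzero((df["ct"] <= 0).to_numpy()):
        out.append(_v(name, int(i), "ct <= 0"))
    dup = df.duplicated(subset=["sample", "gene", "bio_rep", "tech_rep"]).to_numpy()
    for i in np.flatnonzero(dup):
        out.append(_v(name, int(i), "duplicate (sample, gene, bio_rep, tech_rep)"))
    return out


def validate_traits(df: pd.DataFrame, name="traits.tsv") -> list:
    out = []
    if "line" not in df.columns:
        out.append(_v(name, None, "missing column 'line'"))
    return out


_VALIDATORS = {
    "map": validate_map,
    "genotypes": validate_genotypes,
    "eggcounts": validate_eggcounts,
    "qpcr": validate_qpcr,
    "traits": validate_traits,
}

_READERS = {
    "map": pd.read_csv,
    "genotypes": pd.read_csv,
    "eggcounts": lambda p: pd.read_csv(p, sep="\t"),
    "qpcr": pd.read_csv,
    "traits": lambda p: pd.read_csv(p, sep="\t"),
}


def validate_inputs(config: dict) -> list:
    """Validate every input table named in a pipeline config.

    ``config`` maps table kind ('map', 'genotypes', 'eggcounts', 'qpcr',
    'traits') to a file path; unknown kinds are reported as violations.
    """
    out = []
    tables = {}
    for kind, path in config.items():
        if kind not in _VALIDATORS:
            out.append(_v(str(path), None, f"unknown input kind {kind!r}"))
            continue
        try:
            tables[kind] = _READERS[kind](path)
        except Exception as exc:  # unreadable file is itself a violation
            out.append(_v(str(path), None, f"unreadable: {exc}"))
    for kind, df in tables.items():
        if kind == "genotypes":
            out.extend(validate_genotypes(df, tables.get("map"), name=str(config[kind])))
        else:
            out.extend(_VALIDATORS[kind](df, name=str(config[kind])))
    return out
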