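"""Genetic maps, RIL genotype matrices and map functions.

A :class:`GeneticMap` holds ordered marker positions in centimorgans on one
or more chromosomes; a :class:`GenotypeMatrix` holds the two-way RIL calls
(parental alleles ``A``/``B``, missing allowed) aligned to such a map.
Recombination fractions are obtained from cM distances with the Haldane
(default) or Kosambi map function, and expanded to the recombinant-inbred
scale with the standard 2r/(1+2r) transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALLELES = ("A", "B")

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "haldane",
    "kosambi",
    "ril_expand",
    "recombination_fraction",
]


def haldane(d_cm):
    """Haldane map function: r = 0.5 * (1 - exp(-2d)), d in Morgans."""
    d = np.asarray(d_cm, dtype=float)
    return 0.5 * (1.0 - np.exp(-0.02 * d))


def kosambi(d_cm):
    """Kosambi map function: r = 0.5 * tanh(2d), d in Morgans."""
    d = np.asarray(d_cm, dtype=float)
    return 0.5 * np.tanh(0.02 * d)


_MAP_FUNCTIONS = {"haldane": haldane, "kosambi": kosambi}


def ril_expand(r):
    """Map-expansion of a meiotic recombination fraction to the 2-way RIL
    scale: r* = 2r / (1 + 2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def recombination_fraction(d_cm, map_function: str = "haldane", ril: bool = True):
    """Recombination fraction for a cM distance, optionally RIL-expanded."""
    try:
        f = _MAP_FUNCTIONS[map_function]
    except KeyError:
        raise ValueError(
            f"unknown map function {map_function!r}; choose from {sorted(_MAP_FUNCTIONS)}"
        ) from None
    r = f(d_cm)
    return ril_expand(r) if ril else r


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions (cM) on named chromosomes.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker``, ``chrom``, ``cm``. Positions must be >= 0 and
        strictly increasing within each chromosome; marker ids unique.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"marker", "chrom", "cm"}
        if missing := required - set(t.columns):
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise ValueError("empty genetic map")
        if t["marker"].duplicated().any():
            dups = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker ids: {dups}")
        if (t["cm"] < 0).any():
            raise ValueError("map positions must be >= 0")
        for chrom, sub in t.groupby("chrom", sort=False):
            d = np.diff(sub["cm"].to_numpy(float))
            if len(d) and (d <= 0).any():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    @property
    def chromosomes(self) -> list:
        return list(self.table["chrom"].unique())

    def chromosome(self, chrom) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return sub

    @classmethod
    def evenly_spaced(
        cls, chrom_lengths_cm: dict, n_markers: int, prefix: str = "m"
    ) -> "GeneticMap":
        """Deterministic map with markers evenly spaced along each
        chromosome, allocated proportionally to chromosome length."""
        total = sum(chrom_lengths_cm.values())
        rows = []
        names = list(chrom_lengths_cm)
        alloc = {c: max(2, int(round(n_markers * L / total))) for c, L in chrom_lengths_cm.items()}
        # nudge allocation so the total matches exactly
        drift = n_markers - sum(alloc.values())
        order = sorted(names, key=lambda c: -chrom_lengths_cm[c])
        i = 0
        while drift != 0:
            c = order[i % len(order)]
            if drift > 0:
                alloc[c] += 1
                drift -= 1
            elif alloc[c] > 2:
                alloc[c] -= 1
                drift += 1
            i += 1
        k = 0
        for c in names:
            for pos in np.linspace(0.0, chrom_lengths_cm[c], alloc[c]):
                rows.append((f"{prefix}{k:03d}", c, round(float(pos), 4)))
                k += 1
        return cls(pd.DataFrame(rows, columns=["marker", "chrom", "cm"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path))


def default_ril_map(n_markers: int = 102) -> GeneticMap:
    """Map emulating a ~102-SNP panel on the X, 2nd and 3rd chromosomes of
    D. melanogaster (approximate map lengths 66, 108 and 106 cM)."""
    return GeneticMap.evenly_spaced({"X": 66.0, "2": 108.0, "3": 106.0}, n_markers)


@dataclass
class GenotypeMatrix:
    """RIL genotype calls aligned to a :class:`GeneticMap`.

    ``calls`` is a lines x markers DataFrame with values ``"A"``, ``"B"`` or
    NaN (missing); column order follows the map.
    """

    calls: pd.DataFrame
    gmap: GeneticMap = field(repr=False)

    def __post_init__(self):
        map_markers = list(self.gmap.markers)
        if list(self.calls.columns) != map_markers:
            if set(self.calls.columns) != set(map_markers):
                raise ValueError("genotype columns do not match map markers")
            self.calls = self.calls[map_markers]
        vals = self.calls.to_numpy(object)
        ok = pd.isna(vals) | np.isin(vals, ALLELES)
        if not ok.all():
            bad = sorted({str(v) for v in vals[~ok]})
            raise ValueError(f"invalid genotype codes: {bad}; expected A/B/missing")

    @property
    def line_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def n_lines(self) -> int:
        return len(self.calls)

    def codes(self) -> np.ndarray:
        """Integer codes: 0 = A, 1 = B, -1 = missing; shape (lines, markers)."""
        vals = self.calls.to_numpy(object)
        out = np.full(vals.shape, -1, dtype=np.int8)
        out[vals == "A"] = 0
        out[vals == "B"] = 1
        return out

    def to_csv(self, path) -> None:
        self.calls.to_csv(path, index_label="line")

    @classmethod
    def read_csv(cls, path, gmap: GeneticMap) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col="line")
        return cls(df, gmap)
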