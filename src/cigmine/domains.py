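"""Domain annotation table: the static description of the N haploid macrodomains.

A macrodomain is a multi-megabase chromatin segment treated as a sphere in the
structure model. Each domain carries a chromosome index L1 (order of first
appearance of the chromosome) and a within-chromosome index L2 (1-based, genomic
order), so every diploid node is addressed by the triplet L1-L2-L3 with
L3 in {A, B} naming the homolog copy.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

CATEGORIES = ("centromeric", "active", "inactive", "other")

REQUIRED_COLUMNS = ("chrom", "start", "end", "domain_id", "radius", "category")
OPTIONAL_COLUMNS = ("gene_density", "expression")


class DomainTable:
    """Validated table of the N haploid domains, ordered by (L1, L2).

    Parameters
    ----------
    df : pandas.DataFrame
        Must provide columns ``chrom, start, end, domain_id, radius, category``
        (plus optional ``gene_density``, ``expression``). Genomic coordinates
        are 0-based half-open. ``L1``/``L2`` are assigned here: L1 by order of
        first appearance of ``chrom`` in the input, L2 by genomic order within
        each chromosome, both 1-based.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"domain table missing columns: {missing}")

        dup = df["domain_id"][df["domain_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate domain_id values: {sorted(set(dup))}")
        if (df["end"] <= df["start"]).any():
            bad = df.loc[df["end"] <= df["start"], "domain_id"].tolist()
            raise ValidationError(f"end <= start for domains {bad}")
        if (df["radius"] <= 0).any():
            bad = df.loc[df["radius"] <= 0, "domain_id"].tolist()
            raise ValidationError(f"non-positive radius for domains {bad}")
        unknown = set(df["category"]) - set(CATEGORIES)
        if unknown:
            raise ValidationError(
                f"unknown categories {sorted(unknown)}; allowed: {CATEGORIES}"
            )

        chrom_order = {c: i + 1 for i, c in enumerate(pd.unique(df["chrom"]))}
        df["L1"] = df["chrom"].map(chrom_order).astype(int)
        df = df.sort_values(["L1", "start"], kind="stable").reset_index(drop=True)
        df["L2"] = df.groupby("L1").cumcount() + 1

        # non-overlap within each chromosome (0-based half-open intervals)
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(f"overlapping domains on chromosome {chrom}")

        self.df = df
        self._id_to_index = {d: i for i, d in enumerate(df["domain_id"])}

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def domain_ids(self) -> list[str]:
        return self.df["domain_id"].tolist()

    @property
    def radii(self) -> np.ndarray:
        return self.df["radius"].to_numpy(float)

    @property
    def categories(self) -> np.ndarray:
        return self.df["category"].to_numpy()

    @property
    def L1(self) -> np.ndarray:
        return self.df["L1"].to_numpy(int)

    @property
    def L2(self) -> np.ndarray:
        return self.df["L2"].to_numpy(int)

    @property
    def chroms(self) -> list[str]:
        """Chromosome names in L1 order."""
        return list(pd.unique(self.df["chrom"]))

    def index_of(self, domain_id: str) -> int:
        return self._id_to_index[domain_id]

    def indices_of(self, domain_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._id_to_index[d] for d in domain_ids], dtype=int)

    def label_of(self, index: int) -> tuple[int, int]:
        """(L1, L2) of the domain at positional ``index``."""
        row = self.df.iloc[index]
        return int(row["L1"]), int(row["L2"])

    def index_of_label(self, L1: int, L2: int) -> int:
        mask = (self.df["L1"] == L1) & (self.df["L2"] == L2)
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) != 1:
            raise KeyError(f"no domain with (L1, L2) = ({L1}, {L2})")
        return int(idx[0])

    # -- centromere geometry --------------------------------------------
    def centromere_midpoint(self, chrom: str) -> float:
        """Midpoint (bp) of the span of centromeric-category domains on ``chrom``."""
        grp = self.df[(self.df["chrom"] == chrom) & (self.df["category"] == "centromeric")]
        if grp.empty:
            raise KeyError(f"chromosome {chrom} has no centromeric domain")
        return 0.5 * (grp["start"].min() + grp["end"].max())

    def centromere_reference_index(self, chrom: str) -> int:
        """Positional index of the centromeric domain nearest the centromere midpoint."""
        mid = self.centromere_midpoint(chrom)
        grp = self.df[(self.df["chrom"] == chrom) & (self.df["category"] == "centromeric")]
        mids = 0.5 * (grp["start"] + grp["end"])
        return int((mids - mid).abs().idxmin())

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return f"DomainTable({self.n} domains, {len(self.chroms)} chromosomes)"
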