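"""Gene-neighborhoods: the protein-coding genes immediately flanking a lincRNA.

A lincRNA's gene-neighborhood is defined as its immediately flanking
protein-coding genes on the same chromosome — the nearest coding gene wholly
to the left and wholly to the right, strand ignored, genes overlapping the
lincRNA excluded.  LincRNAs with no flanking gene expressed during
neurogenesis are discarded before conservation scoring.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted on read and write, BED passes through.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidInputError, LookupError_

__all__ = [
    "GenomeAnnotation",
    "NeighborPair",
    "flanking_genes",
    "neighbor_distance_stats",
    "filter_expressed_neighbors",
]

_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]


class GenomeAnnotation:
    """Ordered gene intervals with biotypes for one species.

    Backed by a DataFrame with columns gene_id, chrom, start, end, strand,
    biotype (``protein_coding``, ``lincRNA`` or ``other``); intervals are
    0-based half-open and unique by gene_id.
    """

    def __init__(self, genes: pd.DataFrame, species: str = "unknown"):
        missing = [c for c in _COLUMNS if c not in genes.columns]
        if missing:
            raise InvalidInputError(f"annotation missing columns {missing}")
        df = genes[_COLUMNS].copy()
        if (df["end"] <= df["start"]).any():
            raise InvalidInputError("annotation has intervals with end <= start")
        if df["gene_id"].duplicated().any():
            raise InvalidInputError("gene ids are not unique")
        self.genes = df.sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)
        self.species = species
        self._by_id = self.genes.set_index("gene_id")

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> pd.Series:
        try:
            return self._by_id.loc[gene_id]
        except KeyError as exc:
            raise LookupError_(f"unknown gene id {gene_id!r}") from exc

    def lincrna_ids(self) -> list[str]:
        return list(self.genes.loc[self.genes["biotype"] == "lincRNA", "gene_id"])

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_gff3(cls, path, species: str = "unknown") -> "GenomeAnnotation":
        """Read gene features from GFF3 (1-based inclusive -> half-open)."""
        import gffutils.iterators

        rows = []
        for feat in gffutils.iterators.DataIterator(str(path)):
            if feat.featuretype != "gene":
                continue
            rows.append(
                {
                    "gene_id": feat.attributes.get("ID", [feat.id])[0],
                    "chrom": feat.seqid,
                    "start": feat.start - 1,
                    "end": feat.end,
                    "strand": feat.strand if feat.strand in "+-" else "+",
                    "biotype": feat.attributes.get("biotype", ["other"])[0],
                }
            )
        return cls(pd.DataFrame(rows, columns=_COLUMNS), species=species)

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, g in self.genes.iterrows():
                attrs = f"ID={g.gene_id};biotype={g.biotype}"
                fh.write(
                    f"{g.chrom}\tlincsynteny\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_bed(cls, path, species: str = "unknown") -> "GenomeAnnotation":
        """Read BED6(+1): chrom, start, end, name, score, strand[, biotype]."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        out = pd.DataFrame(
            {
                "gene_id": df[3],
                "chrom": df[0],
                "start": df[1],
                "end": df[2],
                "strand": df[5] if df.shape[1] > 5 else "+",
                "biotype": df[6] if df.shape[1] > 6 else "other",
            }
        )
        return cls(out, species=species)

    def to_bed(self, path) -> None:
        cols = self.genes
        with open(path, "w") as fh:
            for _, g in cols.iterrows():
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.biotype}\n"
                )


@dataclass
class NeighborPair:
    """Flanking protein-coding genes of one lincRNA, with edge distances."""

    linc_id: str
    upstream: str | None  # nearest coding gene wholly left of the lincRNA
    downstream: str | None
    upstream_distance: float = np.nan  # bp between nearest interval edges
    downstream_distance: float = np.nan

    @property
    def neighbors(self) -> list[str]:
        return [g for g in (self.upstream, self.downstream) if g is not None]

    @property
    def nearest_distance(self) -> float:
        ds = [
            d
            for d in (self.upstream_distance, self.downstream_distance)
            if np.isfinite(d)
        ]
        return min(ds) if ds else np.nan


def flanking_genes(annotation: GenomeAnnotation, linc_id: str) -> NeighborPair:
    """Immediately flanking protein-coding genes of a lincRNA.

    Upstream = the protein-coding gene with the largest end <= lincRNA start
    on the same chromosome; downstream = smallest start >= lincRNA end.
    Strand is ignored; genes overlapping the lincRNA are not flanking; ties
    on the nearest edge break deterministically to the smaller gene id.
    """
    linc = annotation.gene(linc_id)
    df = annotation.genes
    coding = df[(df["chrom"] == linc["chrom"]) & (df["biotype"] == "protein_coding")]

    up = coding[coding["end"] <= linc["start"]]
    upstream, up_d = None, np.nan
    if len(up):
        best_end = up["end"].max()
        cand = up[up["end"] == best_end].sort_values("gene_id")
        upstream = cand.iloc[0]["gene_id"]
        up_d = float(linc["start"] - best_end)

    down = coding[coding["start"] >= linc["end"]]
    downstream, down_d = None, np.nan
    if len(down):
        best_start = down["start"].min()
        cand = down[down["start"] == best_start].sort_values("gene_id")
        downstream = cand.iloc[0]["gene_id"]
        down_d = float(best_start - linc["end"])

    return NeighborPair(linc_id, upstream, downstream, up_d, down_d)


def neighbor_distance_stats(pairs: Iterable[NeighborPair]) -> dict:
    """Median and maximum of per-lincRNA nearest-neighbor distances (bp)."""
    dists = [p.nearest_distance for p in pairs if np.isfinite(p.nearest_distance)]
    if not dists:
        raise InvalidInputError("no neighbor pairs with finite distances")
    return {
        "n": len(dists),
        "median": float(np.median(dists)),
        "max": float(np.max(dists)),
    }


def filter_expressed_neighbors(
    pairs: Iterable[NeighborPair], expressed_gene_set: set[str]
) -> set[str]:
    """LincRNAs with at least one flanking gene in the expressed set."""
    if not expressed_gene_set:
        raise InvalidInputError("expressed gene set is empty")
    return {
        p.linc_id
        for p in pairs
        if any(g in expressed_gene_set for g in p.neighbors)
    }


def pairs_to_table(pairs: Iterable[NeighborPair]) -> pd.DataFrame:
    """Neighbor pairs as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "lincRNA": p.linc_id,
                "upstream": p.upstream,
                "downstream": p.downstream,
                "upstream_distance": p.upstream_distance,
                "downstream_distance": p.downstream_distance,
            }
            for p in pairs
        ]
    )
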