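"""Microsynteny conservation scoring and the lincRNA x species matrix.

A lincRNA's neighborhood counts as conserved in a species (score 1) when at
least one of its human flanking protein-coding genes has a 1-to-1 ortholog
among the protein-coding genes immediately flanking the lincRNA's placed
locus in that species.  Chromosome identity is not required.  When the locus
cannot be placed, or no annotated coding gene lies within the adjacency
window on either side, the entry is missing (unassessable) rather than 0 —
the dolphin precedent: per-species fractions use assessed counts as the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InvalidInputError
from .homology import AlignmentHit
from .neighborhood import GenomeAnnotation, NeighborPair

__all__ = ["OrthologMap", "ConservationMatrix", "score_one", "build_matrix"]

DEFAULT_ADJACENCY_WINDOW = 5_000_000  # bp; beyond this, adjacency is denied


class OrthologMap:
    """1-to-1 ortholog pairs (reference_gene, species, ortholog_gene)."""

    def __init__(self, table: pd.DataFrame):
        need = {"reference_gene", "species", "ortholog_gene"}
        if not need <= set(table.columns):
            raise InvalidInputError(f"ortholog map needs columns {sorted(need)}")
        for col in ("reference_gene", "ortholog_gene"):
            dup = table.duplicated(subset=["species", col])
            if dup.any():
                raise DataError(
                    f"ortholog map is not 1-to-1: duplicated {col} within a species"
                )
        self.table = table.reset_index(drop=True)
        self._lookup = {
            (r.species, r.reference_gene): r.ortholog_gene
            for r in table.itertuples()
        }

    def ortholog(self, species: str, reference_gene: str) -> str | None:
        return self._lookup.get((species, reference_gene))

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _adjacent_genes(
    annotation: GenomeAnnotation,
    chrom: str,
    start: int,
    end: int,
    window: int,
) -> list[str]:
    """Nearest protein-coding gene on each side of an interval, within window.

    Mirrors the reference flanking-gene definition: nearest coding gene
    wholly left and wholly right of the placed locus; overlapping genes are
    also accepted as adjacent (the placed locus may land inside or clip a
    neighbor).  Returns up to two gene ids.
    """
    df = annotation.genes
    coding = df[(df["chrom"] == chrom) & (df["biotype"] == "protein_coding")]
    if coding.empty:
        return []
    out = []
    left = coding[coding["end"] <= start]
    if len(left):
        best = left["end"].max()
        if start - best <= window:
            out.append(left[left["end"] == best].sort_values("gene_id").iloc[0]["gene_id"])
    right = coding[coding["start"] >= end]
    if len(right):
        best = right["start"].min()
        if best - end <= window:
            out.append(
                right[right["start"] == best].sort_values("gene_id").iloc[0]["gene_id"]
            )
    overlapping = coding[(coding["start"] < end) & (coding["end"] > start)]
    out.extend(overlapping["gene_id"].tolist())
    return out


def score_one(
    pair: NeighborPair,
    species: str,
    placed_locus: AlignmentHit | None,
    ortholog_map: OrthologMap,
    species_annotation: GenomeAnnotation,
    window: int = DEFAULT_ADJACENCY_WINDOW,
) -> float:
    """Conservation score for one lincRNA in one species: 1, 0 or NaN.

    1 when at least one reference flanking gene's ortholog is among the
    genes immediately flanking the placed locus; 0 when the locus is placed
    but no neighbor ortholog is adjacent; NaN (missing/unassessable) when
    the locus could not be placed or the placed region has no annotated
    coding gene within the window.
    """
    if placed_locus is None:
        return np.nan
    adjacent = _adjacent_genes(
        species_annotation,
        placed_locus.target_id,
        placed_locus.target_start,
        placed_locus.target_end,
        window,
    )
    if not adjacent:
        return np.nan
    orthologs = {
        ortholog_map.ortholog(species, g) for g in pair.neighbors
    } - {None}
    return 1.0 if orthologs & set(adjacent) else 0.0


@dataclass
class ConservationMatrix:
    """Binary (or missing) conservation scores, lincRNAs x species."""

    scores: pd.DataFrame  # entries 1.0, 0.0 or NaN; columns = species

    def __post_init__(self):
        vals = self.scores.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise InvalidInputError("conservation entries must be 0, 1 or missing")

    @property
    def species(self) -> list[str]:
        return list(self.scores.columns)

    def totals(self) -> pd.Series:
        """Per-species conserved counts over assessed (non-missing) rows."""
        return self.scores.sum(axis=0, skipna=True)

    def assessed_counts(self) -> pd.Series:
        return self.scores.notna().sum(axis=0)

    def fractions(self) -> pd.Series:
        """Conserved fraction per species with assessed rows as denominator."""
        return self.totals() / self.assessed_counts()

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = "lincRNA"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "ConservationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        df.index.name = None
        return cls(df.astype(float))

    @classmethod
    def from_s2_table(cls, path, index_col: int = 0) -> "ConservationMatrix":
        """Load a conservation table shaped like the study's S2 supplement.

        Accepts .xlsx (first sheet; lincRNA ids in the first column, one
        column per species, entries 0/1/blank) or CSV/TSV with the same
        layout.
        """
        path = str(path)
        if path.endswith((".xlsx", ".xlsm")):
            df = pd.read_excel(path, index_col=index_col)
        else:
            sep = "\t" if path.endswith((".tsv", ".txt")) else ","
            df = pd.read_csv(path, sep=sep, index_col=index_col)
        return cls(df.astype(float))


def build_matrix(
    pairs: Mapping[str, NeighborPair],
    species_list: Sequence[str],
    placements: Mapping[tuple[str, str], AlignmentHit | None],
    ortholog_map: OrthologMap,
    annotations: Mapping[str, GenomeAnnotation],
    reference: str = "human",
    window: int = DEFAULT_ADJACENCY_WINDOW,
) -> ConservationMatrix:
    """Assemble the conservation matrix for all lincRNAs and species.

    ``placements`` maps (linc_id, species) to the best placed locus (or
    None).  The reference species column is all 1 by construction.
    """
    lincs = sorted(pairs)
    data = {}
    for sp in species_list:
        if sp == reference:
            data[sp] = pd.Series(1.0, index=lincs)
            continue
        col = {}
        for linc in lincs:
            col[linc] = score_one(
                pairs[linc],
                sp,
                placements.get((linc, sp)),
                ortholog_map,
                annotations[sp],
                window=window,
            )
        data[sp] = pd.Series(col)
    frame = pd.DataFrame(data, index=lincs, columns=list(species_list))
    return ConservationMatrix(frame)
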