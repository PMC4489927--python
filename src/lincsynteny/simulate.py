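"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emits a self-consistent world: an ultrametric pure-birth tree
with a designated reference leaf ("human"); per-species gene orders in which
each lincRNA sits between two protein-coding flanks, lost on a lineage with
probability 1 - exp(-rate * divergence) (clade-specific rates model the
selective-loss hypothesis: neighborhoods of neurodevelopmental lincRNAs are
purged faster along small-brained, low-GI lineages); 1-to-1 ortholog maps;
genome sequences in which the lincRNA locus is conserved (optionally
diverged) so the homology stage can re-place it; NB-distributed zone counts
with a configurable fold change for truly differential lincRNAs; species
traits correlated with the gyrencephaly index; and per-base conservation
tracks whose mean is shifted for TF-adjacent lincRNAs.

Every stage draws from a child generator derived from the master seed by a
fixed per-stage offset, so regeneration with the same configuration is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .neighborhood import GenomeAnnotation
from .phylo import Phylogeny
from .synteny import OrthologMap

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "assign_clades",
    "simulate_synteny_loss",
    "simulate_sequences",
    "simulate_counts",
    "simulate_tracks",
    "simulate_traits",
    "simulate_all",
    "SyntheticBundle",
]

ZONES = ("VZ", "ISVZ", "OSVZ", "CP")
# fixed per-stage offsets for child RNGs (design: one master seed)
_STAGE = {"tree": 1, "loss": 2, "counts": 3, "tracks": 4, "traits": 5, "seqs": 6}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Stated world of the synthetic cohort.

    Defaults mirror the study design where it states values (142
    neurodevelopmental and 178 control lincRNAs; 4 zones; GI threshold 1.5;
    46 kb median neighbor distance) and field-realistic choices elsewhere
    (documented in the methods note).
    """

    n_species: int = 24
    n_neuro_linc: int = 142
    n_other_linc: int = 178
    loss_rate_high: float = 0.5  # synteny losses per unit branch length, high-GI
    loss_rate_low: float = 1.5   # low-GI clades: 3x faster loss
    clade_assignment: dict[str, str] | None = None  # species -> 'high'/'low'
    de_fraction: float = 0.3
    nb_dispersion: float = 0.05
    tf_effect: float = 0.2
    seed: int = 0
    # world-shape knobs beyond the headline parameters
    n_replicates: int = 5
    log2_fold_change: float = 2.0
    base_mean: float = 100.0
    median_distance_bp: int = 46_000  # log-normal neighbor-distance median
    distance_sigma: float = 1.0       # log-normal sigma (natural log scale)
    gene_length: int = 1000
    linc_length: int = 500
    subst_rate: float = 0.0  # substitutions per site per unit branch length
    tf_fraction: float = 0.5
    enhancer_fraction: float = 0.3
    missing_fraction: float = 0.0  # dolphin-style unassessable loci
    reference: str = "human"

    def __post_init__(self):
        if self.n_species < 4:
            raise InvalidConfigError("n_species must be >= 4")
        for name in ("loss_rate_high", "loss_rate_low", "subst_rate"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        for name in (
            "de_fraction", "tf_fraction", "enhancer_fraction", "missing_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise InvalidConfigError("nb_dispersion must be >= 0")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE[stage]])


@dataclass
class GroundTruth:
    """What the generator actually did, for truth-table tests."""

    true_conservation: pd.DataFrame  # lincRNA x species, entries in {0,1}
    true_de_set: set[str]
    true_tf_adjacent: set[str]
    de_zone_map: dict[str, tuple[str, ...]] = field(default_factory=dict)
    neuro_ids: list[str] = field(default_factory=list)
    other_ids: list[str] = field(default_factory=list)
    enhancer_overlap: set[str] = field(default_factory=set)
    missing_loci: set[tuple[str, str]] = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "true_conservation": {
                linc: {sp: int(v) for sp, v in row.items()}
                for linc, row in self.true_conservation.iterrows()
            },
            "true_de_set": sorted(self.true_de_set),
            "true_tf_adjacent": sorted(self.true_tf_adjacent),
            "de_zone_map": {k: list(v) for k, v in self.de_zone_map.items()},
            "neuro_ids": self.neuro_ids,
            "other_ids": self.other_ids,
            "enhancer_overlap": sorted(self.enhancer_overlap),
            "missing_loci": sorted(map(list, self.missing_loci)),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# tree


def simulate_tree(n_species: int, seed: int, reference: str = "human") -> Phylogeny:
    """Pure-birth (Yule) tree rescaled to depth 1.0; ultrametric by construction.

    Leaves are named ``human, sp01, sp02, ...``; branch lengths are strictly
    positive.
    """
    if n_species < 4:
        raise InvalidConfigError("n_species must be >= 4")
    rng = np.random.default_rng([int(seed), _STAGE["tree"]])

    class _Node:
        __slots__ = ("birth", "split", "children", "name")

        def __init__(self, birth):
            self.birth = birth
            self.split = None
            self.children = []
            self.name = None

    root = _Node(0.0)
    root.split = 0.0
    root.children = [_Node(0.0), _Node(0.0)]
    active = list(root.children)
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        node.split = t
        node.children = [_Node(t), _Node(t)]
        active.extend(node.children)
    t_end = t + rng.exponential(1.0 / n_species)

    names = [reference] + [f"sp{i:02d}" for i in range(1, n_species)]
    order = rng.permutation(n_species)
    for slot, leaf in zip(order, active):
        leaf.name = names[slot]

    def newick(node) -> str:
        if not node.children:
            return f"{node.name}:{(t_end - node.birth) / t_end:.10f}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{(node.split - node.birth) / t_end:.10f}"

    nwk = f"({','.join(newick(c) for c in root.children)});"
    return Phylogeny.from_newick(nwk, tree_id=f"yule_n{n_species}_s{seed}")


def assign_clades(
    tree: Phylogeny, reference: str = "human", target_fraction: float = 0.5
) -> dict[str, str]:
    """Clade-structured GI labels: the reference's clade is high-GI.

    Walks from the reference leaf toward the root and labels 'high' the
    smallest enclosing clade whose size is at least ``target_fraction`` of
    the leaves; everything else is 'low'.
    """
    dtree = tree._tree  # package-internal access to the dendropy tree
    leaf = next(
        nd for nd in dtree.leaf_node_iter() if nd.taxon.label == reference
    )
    want = max(2, int(round(target_fraction * tree.n_leaves)))
    node, best = leaf, None
    while node.parent_node is not None:
        node = node.parent_node
        size = sum(1 for _ in node.leaf_iter())
        if size < tree.n_leaves:
            best = node  # largest proper clade containing the reference so far
            if size >= want:
                break
    if best is None:  # reference hangs directly off the root
        high = {reference}
    else:
        high = {nd.taxon.label for nd in best.leaf_iter()}
    return {sp: ("high" if sp in high else "low") for sp in tree.leaves}


# ---------------------------------------------------------------------------
# synteny loss, gene orders, ortholog map


def _linc_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    neuro = [f"XLOC_{i:06d}" for i in range(1, config.n_neuro_linc + 1)]
    other = [f"XLOC_O{i:05d}" for i in range(1, config.n_other_linc + 1)]
    return neuro, other


def simulate_synteny_loss(
    tree: Phylogeny, config: SimulationConfig
) -> tuple[dict[str, GenomeAnnotation], OrthologMap, GroundTruth]:
    """Per-species gene orders after clade-contrasted neighborhood loss.

    Each lincRNA occupies its own chromosome between flanking coding genes
    (``up``/``dn``) with distal genes (``farL``/``farR``) beyond them.  The
    neighborhood survives on the lineage to species *i* with probability
    exp(-rate_i * d(reference, i)); on loss, both flanking orthologs are
    relocated to a junk chromosome and the distal genes become the locus's
    neighbors.  The reference retains every neighborhood.  Control ("other")
    lincRNAs lose at the clade-averaged rate in all species, so their
    conservation is explained by divergence alone.
    """
    clades = config.clade_assignment or assign_clades(tree, config.reference)
    unlabeled = [s for s in tree.leaves if s not in clades]
    if unlabeled:
        raise InvalidConfigError(f"species without clade label: {unlabeled[:5]}")
    bad = {v for v in clades.values()} - {"high", "low"}
    if bad:
        raise InvalidConfigError(f"clade labels must be 'high'/'low', got {sorted(bad)}")

    rng = config.rng("loss")
    neuro, other = _linc_ids(config)
    all_lincs = neuro + other
    ref = config.reference
    dref = tree.distances_from(ref)
    rate_other = 0.5 * (config.loss_rate_high + config.loss_rate_low)

    # survival draws, reference always 1
    conserved = pd.DataFrame(1, index=all_lincs, columns=tree.leaves, dtype=int)
    for sp in tree.leaves:
        if sp == ref:
            continue
        d = float(dref[sp])
        rate_neuro = (
            config.loss_rate_high if clades[sp] == "high" else config.loss_rate_low
        )
        p_neuro = np.exp(-rate_neuro * d)
        p_other = np.exp(-rate_other * d)
        conserved.loc[neuro, sp] = (rng.random(len(neuro)) < p_neuro).astype(int)
        conserved.loc[other, sp] = (rng.random(len(other)) < p_other).astype(int)

    tf_adjacent = {
        linc for linc in all_lincs if rng.random() < config.tf_fraction
    }
    enhancer = {linc for linc in all_lincs if rng.random() < config.enhancer_fraction}
    de_set = {linc for linc in neuro if rng.random() < config.de_fraction}
    de_zone_map = {}
    up_zones = ("ISVZ", "OSVZ", "CP")
    for linc in sorted(de_set):
        zones = [up_zones[int(rng.integers(3))]]
        if rng.random() < 0.2:  # some lincRNAs up in two germinal zones
            second = up_zones[int(rng.integers(3))]
            if second not in zones:
                zones.append(second)
        de_zone_map[linc] = tuple(zones)

    missing = set()
    if config.missing_fraction > 0:
        for linc in all_lincs:
            for sp in tree.leaves:
                if sp != ref and rng.random() < config.missing_fraction:
                    missing.add((linc, sp))

    # spacer distances: log-normal calibrated to the configured median,
    # drawn once per (lincRNA, gap) and reused across species so the
    # reference layout is the ancestral layout
    mu = np.log(config.median_distance_bp)
    spacers = rng.lognormal(mu, config.distance_sigma, size=(len(all_lincs), 4))
    spacers = np.maximum(spacers.astype(int), 50)

    annotations: dict[str, GenomeAnnotation] = {}
    ortho_rows = []
    glen, llen = config.gene_length, config.linc_length
    for sp in tree.leaves:
        rows = []
        relo_cursor = 0
        for k, linc in enumerate(all_lincs):
            chrom = f"chr_{linc}"
            stem = f"G{k:05d}"
            lost = conserved.at[linc, sp] == 0
            prefix = "" if sp == ref else f"{sp}_"
            pos = 100
            order = (
                [("farL", glen), ("up", glen), ("linc", llen), ("dn", glen), ("farR", glen)]
                if not lost
                else [("farL", glen), ("linc", llen), ("farR", glen)]
            )
            gap_iter = iter(spacers[k])
            for part, (role, length) in enumerate(order):
                if part > 0:
                    pos += int(next(gap_iter))
                start, end = pos, pos + length
                if role == "linc":
                    rows.append((linc, chrom, start, end, "+", "lincRNA"))
                else:
                    rows.append(
                        (f"{prefix}{stem}_{role}", chrom, start, end, "+", "protein_coding")
                    )
                pos = end
            if lost:  # relocated flanks on the junk chromosome
                for role in ("up", "dn"):
                    start = 100 + relo_cursor
                    rows.append(
                        (f"{prefix}{stem}_{role}", "chr_relo", start, start + glen,
                         "+", "protein_coding")
                    )
                    relo_cursor += glen + 2000
        annotations[sp] = GenomeAnnotation(
            pd.DataFrame(
                rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
            ),
            species=sp,
        )
        if sp != ref:
            for k in range(len(all_lincs)):
                stem = f"G{k:05d}"
                for role in ("farL", "up", "dn", "farR"):
                    ortho_rows.append((f"{stem}_{role}", sp, f"{sp}_{stem}_{role}"))

    ortholog_map = OrthologMap(
        pd.DataFrame(ortho_rows, columns=["reference_gene", "species", "ortholog_gene"])
    )
    truth = GroundTruth(
        true_conservation=conserved,
        true_de_set=de_set,
        true_tf_adjacent=tf_adjacent,
        de_zone_map=de_zone_map,
        neuro_ids=neuro,
        other_ids=other,
        enhancer_overlap=enhancer,
        missing_loci=missing,
    )
    return annotations, ortholog_map, truth


# ---------------------------------------------------------------------------
# sequences


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with a uniformly different base with prob p."""
    if p <= 0:
        return seq.copy()
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < p)[0]
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def simulate_sequences(
    annotations: dict[str, GenomeAnnotation],
    tree: Phylogeny,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[dict[str, dict[str, str]], dict[str, str]]:
    """Genome sequences consistent with the annotations.

    Returns ``(genomes, linc_seqs)`` where ``genomes[species][chrom]`` is the
    chromosome sequence and ``linc_seqs`` the reference lincRNA sequences
    (the homology queries).  LincRNA loci carry the reference sequence
    mutated at per-site probability ``1 - exp(-subst_rate * d)``; all other
    sequence is species-private random DNA.  Loci listed in
    ``truth.missing_loci`` are replaced by random sequence (unassessable,
    the dolphin precedent).
    """
    rng = config.rng("seqs")
    ref = config.reference
    dref = tree.distances_from(ref)
    linc_rows = annotations[ref].genes
    linc_ids = list(linc_rows.loc[linc_rows["biotype"] == "lincRNA", "gene_id"])
    linc_ref = {linc: _random_seq(rng, config.linc_length) for linc in linc_ids}
    missing = truth.missing_loci if truth is not None else set()

    genomes: dict[str, dict[str, str]] = {}
    for sp in sorted(annotations):
        d = 0.0 if sp == ref else float(dref[sp])
        p_sub = 1.0 - np.exp(-config.subst_rate * d)
        chroms: dict[str, str] = {}
        df = annotations[sp].genes
        for chrom, grp in df.groupby("chrom", sort=True):
            length = int(grp["end"].max()) + 100
            seq = _random_seq(rng, length)
            for row in grp.itertuples():
                if row.biotype == "lincRNA" and (row.gene_id, sp) not in missing:
                    seq[row.start : row.end] = _mutate(linc_ref[row.gene_id], p_sub, rng)
            chroms[chrom] = seq.tobytes().decode("ascii")
        genomes[sp] = chroms
    return genomes, {k: v.tobytes().decode("ascii") for k, v in linc_ref.items()}


# ---------------------------------------------------------------------------
# expression counts


def _nb_draw(rng, mean, dispersion, size):
    """NB draws parameterized by mean and dispersion (Var = mu + phi mu^2)."""
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_counts(
    linc_ids: list[str],
    config: SimulationConfig,
    de_zone_map: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB count matrix over the four zones with the configured DE structure.

    Returns (counts genes x samples, zone map).  Truly differential
    lincRNAs (keys of ``de_zone_map``) have their mean multiplied by
    ``2**log2_fold_change`` in their assigned zones' samples.
    """
    if config.n_replicates < 2:
        raise InvalidConfigError("need >= 2 replicates per zone")
    rng = config.rng("counts")
    samples = [f"{z}_{r + 1}" for z in ZONES for r in range(config.n_replicates)]
    zone_map = pd.Series(
        [s.rsplit("_", 1)[0] for s in samples], index=samples, name="zone"
    )
    if de_zone_map is None:
        de_zone_map = {}
    base = rng.lognormal(np.log(config.base_mean), 1.0, size=len(linc_ids))
    counts = np.zeros((len(linc_ids), len(samples)), dtype=int)
    fold = 2.0 ** config.log2_fold_change
    for gi, linc in enumerate(linc_ids):
        up = set(de_zone_map.get(linc, ()))
        for sj, sample in enumerate(samples):
            mu = base[gi] * (fold if zone_map[sample] in up else 1.0)
            counts[gi, sj] = _nb_draw(rng, mu, config.nb_dispersion, None)
    return (
        pd.DataFrame(counts, index=linc_ids, columns=samples),
        zone_map,
    )


# ---------------------------------------------------------------------------
# conservation tracks


def simulate_tracks(
    linc_ids: list[str],
    true_tf_adjacent: set[str],
    config: SimulationConfig,
):
    """Per-base PhastCons-like and PhyloP-like tracks with a TF-adjacency shift.

    Each lincRNA gets a latent per-lincRNA baseline (between-lincRNA SD 0.15
    for PhastCons, 0.3 for PhyloP) shifted additively by ``tf_effect`` when
    TF-adjacent, plus per-base noise; PhastCons-like values are clipped to
    [0, 1].
    """
    from .stats import ScoreTrack

    rng = config.rng("tracks")
    values = {}
    for linc in linc_ids:
        tf = linc in true_tf_adjacent
        base_pc = rng.normal(0.4, 0.15) + (config.tf_effect if tf else 0.0)
        base_pp = rng.normal(0.5, 0.3) + (config.tf_effect if tf else 0.0)
        pc = np.clip(rng.normal(base_pc, 0.2, size=config.linc_length), 0.0, 1.0)
        pp = rng.normal(base_pp, 1.0, size=config.linc_length)
        values[linc] = {"phastcons": pc, "phylop": pp}
    return ScoreTrack(values, {l for l in linc_ids if l in true_tf_adjacent})


# ---------------------------------------------------------------------------
# species traits


def simulate_traits(
    tree: Phylogeny,
    clade_assignment: dict[str, str],
    seed: int,
) -> pd.DataFrame:
    """Species trait table: GI, body weight, longevity, molecular rate.

    High-GI species draw GI uniformly from (1.6, 3.2), low-GI from
    (1.05, 1.45) — never exactly the 1.5 threshold.  log10 body weight and
    longevity increase with GI plus noise; the molecular-rate deviation is
    independent noise (the confound the rate regressions test against).
    """
    unlabeled = [s for s in tree.leaves if s not in clade_assignment]
    if unlabeled:
        raise InvalidConfigError(f"species without clade label: {unlabeled[:5]}")
    rng = np.random.default_rng([int(seed), _STAGE["traits"]])
    rows = {}
    for sp in tree.leaves:
        high = clade_assignment[sp] == "high"
        gi = rng.uniform(1.6, 3.2) if high else rng.uniform(1.05, 1.45)
        log10_bw = 1.0 + 1.5 * gi + rng.normal(0, 0.5)
        longevity = max(1.0, 10.0 * gi + rng.normal(0, 3.0))
        rows[sp] = {
            "GI": gi,
            "body_weight_g": 10.0 ** log10_bw,
            "longevity_y": longevity,
            "rate_deviation": rng.normal(0.0, 0.02),
            "gi_class": "high" if high else "low",
        }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[tree.leaves]
    out.index.name = "species"
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SyntheticBundle:
    """Everything one simulated world contains."""

    config: SimulationConfig
    tree: Phylogeny
    clades: dict[str, str]
    annotations: dict[str, GenomeAnnotation]
    ortholog_map: OrthologMap
    truth: GroundTruth
    genomes: dict[str, dict[str, str]]
    linc_seqs: dict[str, str]
    counts: pd.DataFrame
    zone_map: pd.Series
    tracks: object  # ScoreTrack
    traits: pd.DataFrame

    def write(self, outdir) -> None:
        """Write the bundle in standard text formats (Newick, GFF3, BED,
        FASTA, TSV, bedGraph, JSON)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        ann_dir = out / "annotations"
        ann_dir.mkdir(exist_ok=True)
        for sp, ann in self.annotations.items():
            ann.to_gff3(ann_dir / f"{sp}.gff3")
            ann.to_bed(ann_dir / f"{sp}.bed")
        self.ortholog_map.to_tsv(out / "orthologs.tsv")
        self.truth.to_json(out / "ground_truth.json")
        fasta_dir = out / "genomes"
        fasta_dir.mkdir(exist_ok=True)
        for sp, chroms in self.genomes.items():
            with open(fasta_dir / f"{sp}.fa", "w") as fh:
                for chrom in sorted(chroms):
                    fh.write(f">{chrom}\n")
                    seq = chroms[chrom]
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i : i + 80] + "\n")
        with open(out / "linc_queries.fa", "w") as fh:
            for linc in sorted(self.linc_seqs):
                fh.write(f">{linc}\n{self.linc_seqs[linc]}\n")
        self.counts.rename_axis("gene").to_csv(out / "counts.tsv", sep="\t")
        self.zone_map.rename_axis("sample").to_csv(out / "zones.tsv", sep="\t")
        self.traits.to_csv(out / "traits.tsv", sep="\t")
        self.tracks.to_bedgraph(
            out / "phastcons.bedgraph", out / "phylop.bedgraph", out / "tracks.bed"
        )


def simulate_all(config: SimulationConfig, with_sequences: bool = True) -> SyntheticBundle:
    """Generate a full synthetic world from one configuration."""
    tree = simulate_tree(config.n_species, config.seed, reference=config.reference)
    clades = config.clade_assignment or assign_clades(tree, config.reference)
    cfg = config if config.clade_assignment else _with_clades(config, clades)
    annotations, ortholog_map, truth = simulate_synteny_loss(tree, cfg)
    if with_sequences:
        genomes, linc_seqs = simulate_sequences(annotations, tree, cfg, truth)
    else:
        genomes, linc_seqs = {}, {}
    counts, zone_map = simulate_counts(truth.neuro_ids, cfg, truth.de_zone_map)
    tracks = simulate_tracks(truth.neuro_ids, truth.true_tf_adjacent, cfg)
    traits = simulate_traits(tree, clades, cfg.seed)
    return SyntheticBundle(
        config=cfg,
        tree=tree,
        clades=clades,
        annotations=annotations,
        ortholog_map=ortholog_map,
        truth=truth,
        genomes=genomes,
        linc_seqs=linc_seqs,
        counts=counts,
        zone_map=zone_map,
        tracks=tracks,
        traits=traits,
    )


def _with_clades(config: SimulationConfig, clades: dict[str, str]) -> SimulationConfig:
    from dataclasses import replace

    return replace(config, clade_assignment=clades)
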