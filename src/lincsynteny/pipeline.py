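"""End-to-end orchestration: simulate -> DE -> neighborhoods -> homology ->
conservation scoring -> OU expectation -> comparative statistics -> report.

The pipeline is driven from Python (see ``examples/``); every stage writes a
TSV table plus a JSON provenance record (parameters, seeds, thresholds) into
the run directory, and ``run_pipeline`` is deterministic given the seed.  A
replication mode starts from an existing conservation matrix and per-lincRNA
score table (the layout of the study's supplementary tables) and runs only
the expectation and statistics stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import call_zone_specific, nb_test, size_factors
from .errors import InvalidConfigError
from .homology import Scoring, best_locus, default_calibration, search_genome, DISCONTIGUOUS_PATTERN
from .neighborhood import (
    filter_expressed_neighbors,
    flanking_genes,
    neighbor_distance_stats,
    pairs_to_table,
)
from .phylo import Phylogeny, deviation_scores, expected_scores, fit_ou_expectation, read_newick
from .simulate import SimulationConfig, simulate_all
from .stats import (
    GI_THRESHOLD,
    aggregate_track,
    compare_dependent_correlations,
    r_squared,
    rate_confound_regression,
    replicate_fig3,
    two_proportion_z,
    two_sample_t,
)
from .synteny import ConservationMatrix, build_matrix

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "replicate_from_tables"]


@dataclass
class PipelineConfig:
    """Configuration for a synthetic end-to-end run.

    Thresholds default to the analysis's stated values: DE alpha 0.05,
    query coverage > 0.20, E-value < 1e-4, adjacency window 5 Mb.
    """

    outdir: str = "runs/synthetic"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    de_alpha: float = 0.05
    min_cover: float = 0.20
    max_evalue: float = 1e-4
    adjacency_window: int = 5_000_000
    log_predictors: bool = True  # log10 body weight / longevity in regressions
    stages: tuple[str, ...] = (
        "simulate", "de", "neighbors", "homology", "score", "expect", "stats",
    )

    def __post_init__(self):
        if not (0 < self.de_alpha < 1) or not (0 <= self.min_cover < 1):
            raise InvalidConfigError("thresholds outside documented ranges")
        if self.max_evalue <= 0 or self.adjacency_window <= 0:
            raise InvalidConfigError("thresholds outside documented ranges")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        sim = d["simulation"]
        if isinstance(sim.get("clade_assignment"), dict):
            sim["clade_assignment"] = dict(sim["clade_assignment"])
        return d


def _provenance(outdir: Path, stage: str, params: dict) -> None:
    rec = {"stage": stage, "package_version": __version__, "parameters": params}
    (outdir / f"{stage}.provenance.json").write_text(json.dumps(rec, indent=1, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages on a synthetic world; returns a summary dict.

    The summary carries the key tables (deviations, test results) in memory;
    everything is also written under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    summary: dict = {"outdir": str(out), "seed": config.seed}

    # -- simulate ----------------------------------------------------------
    bundle = simulate_all(sim_cfg, with_sequences="homology" in config.stages)
    if "simulate" in config.stages:
        bundle.write(out / "synthetic")
        _provenance(out, "simulate", dataclasses.asdict(sim_cfg))

    ref = sim_cfg.reference
    neuro = bundle.truth.neuro_ids

    # -- differential expression ------------------------------------------
    factors = size_factors(bundle.counts)
    de_results = {
        zone: nb_test(bundle.counts, bundle.zone_map, "VZ", zone, factors)
        for zone in ("ISVZ", "OSVZ", "CP")
    }
    zone_sets = call_zone_specific(de_results, alpha=config.de_alpha)
    expressed_lincs = sorted(zone_sets["union"]) or neuro
    if "de" in config.stages:
        for zone, table in de_results.items():
            table.rename_axis("gene").to_csv(out / f"de_{zone}_vs_VZ.tsv", sep="\t")
        _provenance(out, "de", {"alpha": config.de_alpha,
                                "n_union": len(zone_sets["union"])})
    summary["n_de_lincs"] = len(zone_sets["union"])

    # -- neighborhoods -----------------------------------------------------
    ref_ann = bundle.annotations[ref]
    pairs = {l: flanking_genes(ref_ann, l) for l in expressed_lincs}
    dstats = neighbor_distance_stats(pairs.values())
    # every protein-coding gene flanking an expressed lincRNA counts as
    # expressed during neurogenesis in the synthetic world
    expressed_genes = {g for p in pairs.values() for g in p.neighbors}
    shortlist = sorted(filter_expressed_neighbors(pairs.values(), expressed_genes))
    if "neighbors" in config.stages:
        pairs_to_table(pairs.values()).to_csv(out / "neighbors.tsv", sep="\t", index=False)
        _provenance(out, "neighbors", {"distance_stats": dstats,
                                       "n_shortlist": len(shortlist)})
    summary["neighbor_distance_stats"] = dstats
    summary["n_shortlist"] = len(shortlist)

    # -- homology + scoring ------------------------------------------------
    species = bundle.tree.leaves
    if "homology" in config.stages:
        scoring = Scoring()
        calib = default_calibration(scoring)
        placements = {}
        for sp in species:
            if sp == ref:
                continue
            genome = bundle.genomes[sp]
            for linc in shortlist:
                hits = search_genome(
                    bundle.linc_seqs[linc], genome, scoring, query_id=linc,
                    calibration=calib, species=sp,
                )
                placements[(linc, sp)] = best_locus(
                    hits, min_cover=config.min_cover, max_e=config.max_evalue,
                    fallback_search=lambda l=linc, g=genome, s=sp: search_genome(
                        bundle.linc_seqs[l], g, scoring, query_id=l,
                        seed_pattern=DISCONTIGUOUS_PATTERN, calibration=calib, species=s,
                    ),
                )
        matrix = build_matrix(
            {l: pairs[l] for l in shortlist}, species, placements,
            bundle.ortholog_map, bundle.annotations, reference=ref,
            window=config.adjacency_window,
        )
        _provenance(out, "homology", {"min_cover": config.min_cover,
                                      "max_evalue": config.max_evalue})
    else:
        # score directly from the simulated truth (homology disabled)
        matrix = ConservationMatrix(
            bundle.truth.true_conservation.loc[shortlist, species].astype(float)
        )
    if "score" in config.stages:
        matrix.to_tsv(out / "conservation_matrix.tsv")
        _provenance(out, "score", {"window": config.adjacency_window})
    summary["per_species_totals"] = matrix.totals().to_dict()

    # -- OU expectation ----------------------------------------------------
    totals = matrix.totals()
    fit = fit_ou_expectation(totals, bundle.tree, reference=ref)
    expected = expected_scores([fit], [bundle.tree])
    deviations = deviation_scores(
        totals.drop(ref), expected, gi_class=bundle.traits["gi_class"]
    )
    if "expect" in config.stages:
        deviations.to_csv(out / "deviations.tsv", sep="\t")
        _provenance(out, "expect", {"alpha": fit.alpha, "theta": fit.theta,
                                    "sigma2": fit.sigma2,
                                    "log_likelihood": fit.log_likelihood})
    summary["ou_fit"] = {"alpha": fit.alpha, "theta": fit.theta, "sigma2": fit.sigma2}
    summary["deviations"] = deviations

    # -- comparative statistics -------------------------------------------
    if "stats" in config.stages:
        traits = bundle.traits.drop(index=ref, errors="ignore")
        sp_idx = deviations.index
        y = matrix.fractions().loc[sp_idx]
        gi = traits.loc[sp_idx, "GI"]
        bw = traits.loc[sp_idx, "body_weight_g"]
        lon = traits.loc[sp_idx, "longevity_y"]
        if config.log_predictors:
            bw, lon = np.log10(bw), np.log10(lon)
        tests = {
            "r2_gi": r_squared(gi, y),
            "r2_body_weight": r_squared(bw, y),
            "r2_longevity": r_squared(lon, y),
        }
        n = len(sp_idx)
        r_gi, r_bw, r_lon = (t.extra["r"] for t in
                             (tests["r2_gi"], tests["r2_body_weight"], tests["r2_longevity"]))
        tests["steiger_gi_vs_bw"] = compare_dependent_correlations(
            r_gi, r_bw, float(np.corrcoef(gi, bw)[0, 1]), n
        )
        tests["steiger_gi_vs_longevity"] = compare_dependent_correlations(
            r_gi, r_lon, float(np.corrcoef(gi, lon)[0, 1]), n
        )
        tests["rate_confound"] = rate_confound_regression(
            y, traits.loc[sp_idx, "rate_deviation"], traits.loc[sp_idx, "gi_class"]
        )
        # sequence conservation vs TF-adjacency
        agg = aggregate_track(bundle.tracks)
        with_tf = agg[agg["tf_adjacent"]]
        without_tf = agg[~agg["tf_adjacent"]]
        for col in ("mean_phastcons", "mean_phylop", "median_phastcons", "median_phylop"):
            if len(with_tf) >= 2 and len(without_tf) >= 2:
                tests[f"t_{col}"] = two_sample_t(without_tf[col], with_tf[col])
        # enhancer-overlap enrichment, neuro vs control set
        enh = bundle.truth.enhancer_overlap
        k1 = len(enh & set(bundle.truth.neuro_ids))
        k2 = len(enh & set(bundle.truth.other_ids))
        if bundle.truth.other_ids:
            tests["enhancer_z"] = two_proportion_z(
                k1, len(bundle.truth.neuro_ids), k2, len(bundle.truth.other_ids)
            )
        rows = []
        for name, res in tests.items():
            if isinstance(res, dict):
                for cls, sub in res.items():
                    rows.append((f"{name}_{cls}", sub.kind, sub.statistic, sub.pvalue))
            else:
                rows.append((name, res.kind, res.statistic, res.pvalue))
        pd.DataFrame(rows, columns=["test", "kind", "statistic", "pvalue"]).to_csv(
            out / "stats.tsv", sep="\t", index=False
        )
        _provenance(out, "stats", {"log_predictors": config.log_predictors,
                                   "gi_threshold": GI_THRESHOLD})
        summary["tests"] = tests

    (out / "summary.json").write_text(
        json.dumps(
            {k: v for k, v in summary.items()
             if k in ("outdir", "seed", "n_de_lincs", "neighbor_distance_stats",
                      "n_shortlist", "per_species_totals", "ou_fit")},
            indent=1, default=str,
        )
    )
    return summary


def replicate_from_tables(
    matrix_path,
    tree_paths: list,
    s3_path=None,
    reference: str = "human",
    gi_table: pd.DataFrame | None = None,
    outdir=None,
) -> dict:
    """Replication mode: start from an existing conservation matrix.

    ``matrix_path`` is a conservation table in the layout of the study's S2
    supplement; ``tree_paths`` are Newick supertrees; ``s3_path`` (optional)
    is a per-lincRNA PhastCons/PhyloP score table with TF-adjacency, on
    which the Fig 3 t-tests are run.  Fits one OU expectation per tree,
    averages expectations, and returns deviations plus test results.
    """
    matrix = ConservationMatrix.from_s2_table(matrix_path)
    totals = matrix.totals()
    trees = [read_newick(p) for p in tree_paths]
    fits = []
    for tr in trees:
        keep = [s for s in totals.index if s in tr.leaves]
        fits.append(fit_ou_expectation(totals[keep], tr, reference=reference))
    expected = expected_scores(fits, trees, species=[s for s in totals.index if s != reference])
    deviations = deviation_scores(totals.drop(reference, errors="ignore"), expected)
    if gi_table is not None and "GI" in gi_table.columns:
        deviations["gi_class"] = np.where(
            gi_table["GI"].reindex(deviations.index) > GI_THRESHOLD, "high", "low"
        )
    out = {"deviations": deviations,
           "fits": [{"alpha": f.alpha, "theta": f.theta, "sigma2": f.sigma2} for f in fits]}
    if s3_path is not None:
        out["fig3_t_tests"] = replicate_fig3(s3_path)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        deviations.to_csv(Path(outdir) / "deviations.tsv", sep="\t")
    return out


def validate_inputs(
    tree: Phylogeny | None = None,
    matrix: ConservationMatrix | None = None,
    traits: pd.DataFrame | None = None,
    annotations: dict | None = None,
) -> list[str]:
    """Cross-reference and sanity checks; returns findings, never raises.

    Checks species-name agreement between tree, conservation matrix and
    trait table, and interval sanity in annotations.
    """
    findings: list[str] = []
    if tree is not None and matrix is not None:
        missing = [s for s in matrix.species if s not in tree.leaves]
        if missing:
            findings.append(f"species in matrix missing from tree: {missing}")
    if tree is not None and traits is not None:
        missing = [s for s in tree.leaves if s not in traits.index]
        if missing:
            findings.append(f"species in tree missing from traits: {missing}")
    if traits is not None and "GI" in traits.columns and (traits["GI"] <= 0).any():
        findings.append("non-positive GI values in trait table")
    if annotations:
        for sp, ann in annotations.items():
            bad = ann.genes[ann.genes["end"] <= ann.genes["start"]]
            if len(bad):
                findings.append(f"{sp}: {len(bad)} features with end <= start")
    return findings


def plot_deviations(deviations: pd.DataFrame, traits: pd.DataFrame, path) -> None:
    """Summary figure: percentage deviation vs GI, colored by GI class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    common = deviations.index.intersection(traits.index)
    gi = traits.loc[common, "GI"]
    dev = deviations.loc[common, "deviation_pct"]
    colors = np.where(gi > GI_THRESHOLD, "crimson", "steelblue")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.axhline(0, color="grey", lw=0.8)
    ax.scatter(gi, dev, c=colors, s=30)
    ax.set_xlabel("gyrencephaly index (GI)")
    ax.set_ylabel("deviation from OU expectation (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
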