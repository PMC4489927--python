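"""Comparative and sequence-conservation statistics.

Downstream tests: per-lincRNA aggregation of PhastCons/PhyloP tracks,
pooled-variance t-tests contrasting transcription-factor-adjacent
neighborhoods, OLS R-squared of conservation on species traits, Steiger's Z
for comparing dependent correlations sharing one variable, a pooled
two-proportion Z for enhancer-overlap enrichment, and the molecular-rate
confound regressions (adjusted R-squared per GI class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = [
    "TestResult",
    "ScoreTrack",
    "aggregate_track",
    "two_sample_t",
    "r_squared",
    "compare_dependent_correlations",
    "two_proportion_z",
    "rate_confound_regression",
    "replicate_fig3",
]

GI_THRESHOLD = 1.5  # gyrencephaly index separating high- from low-GI species


@dataclass
class TestResult:
    """Statistic, p-value and bookkeeping for one hypothesis test."""

    statistic: float
    pvalue: float
    kind: str  # 't', 'Z', 'R2', ...
    tails: int = 2
    n1: int | None = None
    n2: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.pvalue) and not (0.0 <= self.pvalue <= 1.0):
            raise InvalidInputError("p-value outside [0, 1]")


class ScoreTrack:
    """Per-base conservation values over lincRNA intervals.

    ``values`` maps lincRNA id -> {'phastcons': array in [0,1],
    'phylop': unbounded array}; ``tf_adjacent`` labels neighborhoods that
    contain at least one transcription factor.
    """

    SCORE_TYPES = ("phastcons", "phylop")

    def __init__(self, values: Mapping[str, Mapping[str, np.ndarray]], tf_adjacent: set[str]):
        for linc, tracks in values.items():
            for st in self.SCORE_TYPES:
                arr = np.asarray(tracks[st], dtype=float)
                if arr.size == 0:
                    raise InvalidInputError(f"empty track for {linc}/{st}")
                if st == "phastcons" and ((arr < 0) | (arr > 1)).any():
                    raise InvalidInputError("PhastCons-like values must lie in [0, 1]")
        self.values = {
            k: {st: np.asarray(v[st], dtype=float) for st in self.SCORE_TYPES}
            for k, v in values.items()
        }
        self.tf_adjacent = set(tf_adjacent)

    def linc_ids(self) -> list[str]:
        return sorted(self.values)

    # -- bedGraph + BED-sidecar I/O ---------------------------------------

    def to_bedgraph(self, phastcons_path, phylop_path, labels_path) -> None:
        """Write per-base tracks as bedGraph (one line per base) plus a BED
        sidecar carrying interval extents and TF-adjacency labels."""
        for st, path in (("phastcons", phastcons_path), ("phylop", phylop_path)):
            with open(path, "w") as fh:
                for linc in self.linc_ids():
                    for i, v in enumerate(self.values[linc][st]):
                        fh.write(f"{linc}\t{i}\t{i + 1}\t{v:.6g}\n")
        with open(labels_path, "w") as fh:
            for linc in self.linc_ids():
                n = len(self.values[linc]["phastcons"])
                tf = 1 if linc in self.tf_adjacent else 0
                fh.write(f"{linc}\t0\t{n}\tTF={tf}\t{tf}\t+\n")

    @classmethod
    def from_bedgraph(cls, phastcons_path, phylop_path, labels_path) -> "ScoreTrack":
        values: dict[str, dict[str, list]] = {}
        for st, path in (("phastcons", phastcons_path), ("phylop", phylop_path)):
            df = pd.read_csv(path, sep="\t", header=None, names=["id", "s", "e", "v"])
            for linc, grp in df.groupby("id", sort=False):
                values.setdefault(linc, {})[st] = grp.sort_values("s")["v"].to_numpy()
        bed = pd.read_csv(labels_path, sep="\t", header=None)
        tf = set(bed.loc[bed[4] == 1, 0])
        return cls(values, tf)


def aggregate_track(track: ScoreTrack) -> pd.DataFrame:
    """Per-lincRNA mean and median of per-base values for both score types.

    Returns a table indexed by lincRNA with columns mean_phastcons,
    median_phastcons, mean_phylop, median_phylop and tf_adjacent.
    """
    rows = {}
    for linc in track.linc_ids():
        row = {}
        for st in ScoreTrack.SCORE_TYPES:
            vals = track.values[linc][st]
            row[f"mean_{st}"] = float(np.mean(vals))
            row[f"median_{st}"] = float(np.median(vals))
        row["tf_adjacent"] = linc in track.tf_adjacent
        rows[linc] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "lincRNA"
    return out


def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
    label_a: str = "without_tf",
    label_b: str = "with_tf",
) -> TestResult:
    """Two-sample t-test, group A minus group B, two-tailed.

    Student's pooled-variance flavor by default (``welch=True`` for the
    unequal-variance sensitivity check).  Zero pooled variance with equal
    means yields T = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        return TestResult(0.0, 1.0, "t", 2, len(a), len(b),
                          {"order": f"{label_a} - {label_b}", "welch": welch})
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult(
        float(t), float(p), "t", 2, len(a), len(b),
        {"order": f"{label_a} - {label_b}", "welch": welch},
    )


def r_squared(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """OLS R-squared of y on x, with the slope-t p-value.

    ``extra`` also carries the adjusted R-squared and the Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n or not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidInputError("need n >= 3 finite paired values")
    if np.var(x) == 0:
        raise UndefinedStatisticError("zero variance in predictor")
    fit = sps.linregress(x, y)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return TestResult(
        float(r2), float(fit.pvalue), "R2", 2, n,
        extra={"adjusted_r2": float(adj), "r": float(fit.rvalue),
               "slope": float(fit.slope)},
    )


def compare_dependent_correlations(
    r1: float, r2: float, r12: float, n: int
) -> TestResult:
    """Steiger's Z for two dependent correlations sharing one variable.

    ``r1`` and ``r2`` correlate the shared variable with each of two
    predictors whose mutual correlation is ``r12``.  One-tailed p for the
    alternative r1 > r2.
    """
    for r in (r1, r2, r12):
        if not -1.0 < r < 1.0:
            raise InvalidInputError("correlations must lie strictly in (-1, 1)")
    if n <= 3:
        raise InvalidInputError("need n > 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar = (r1 + r2) / 2.0
    # pooled covariance term (Steiger 1980, via Dunn & Clark)
    psi = r12 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r12**2)
    c = psi / (1.0 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))
    p = float(sps.norm.sf(z))
    return TestResult(float(z), p, "Z", 1, n, extra={"r1": r1, "r2": r2, "r12": r12})


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pooled two-proportion Z, one-tailed for enrichment of group 1.

    Degenerate pooled proportions (0 or 1) give Z = 0, p = 1 when the two
    sample proportions are equal, and are an error otherwise.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise InvalidInputError("need 0 <= k <= n with n > 0 in both groups")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        if p1 == p2:
            return TestResult(0.0, 1.0, "Z", 1, n1, n2)
        raise UndefinedStatisticError("degenerate pooled proportion with unequal groups")
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return TestResult(float(z), float(sps.norm.sf(z)), "Z", 1, n1, n2,
                      extra={"p1": p1, "p2": p2, "pooled": pooled})


def rate_confound_regression(
    conservation_scores: pd.Series,
    rate_deviations: pd.Series,
    class_labels: pd.Series,
) -> dict[str, TestResult]:
    """Per-GI-class OLS of conservation on molecular-rate deviation.

    Reports the adjusted R-squared (which may be negative under the null)
    with the slope p-value; classes with fewer than 3 species are skipped
    with a warning entry.
    """
    import warnings

    out: dict[str, TestResult] = {}
    for cls in sorted(class_labels.dropna().unique()):
        members = class_labels.index[class_labels == cls]
        members = members.intersection(conservation_scores.index).intersection(
            rate_deviations.index
        )
        if len(members) < 3:
            warnings.warn(f"class {cls!r} has < 3 species; skipped", RuntimeWarning)
            continue
        res = r_squared(rate_deviations[members], conservation_scores[members])
        out[cls] = TestResult(
            res.extra["adjusted_r2"], res.pvalue, "adjR2", 2, len(members),
            extra={"r2": res.statistic},
        )
    return out


def replicate_fig3(table_path, welch: bool = False) -> dict[str, TestResult]:
    """TF-adjacency t-tests on a per-lincRNA conservation-score table.

    The table (xlsx, csv or tsv; the layout of the study's S3 supplement)
    must provide a ``tf_adjacent`` column (0/1) plus mean/median PhastCons
    and PhyloP columns.  Returns the four t-tests (group order: lincRNAs
    without a TF neighbor minus lincRNAs with one).
    """
    path = str(table_path)
    if path.endswith((".xlsx", ".xlsm")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t" if path.endswith((".tsv", ".txt")) else ",")
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    if "tf_adjacent" not in df.columns:
        raise InvalidInputError("table needs a tf_adjacent column")
    with_tf = df[df["tf_adjacent"].astype(float) > 0]
    without_tf = df[df["tf_adjacent"].astype(float) == 0]
    out = {}
    for col in ("mean_phastcons", "median_phastcons", "mean_phylop", "median_phylop"):
        if col not in df.columns:
            continue
        out[col] = two_sample_t(
            without_tf[col].astype(float), with_tf[col].astype(float), welch=welch
        )
    return out
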