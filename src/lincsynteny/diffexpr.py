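"""Negative-binomial differential expression across fetal neocortex zones.

A deliberately minimal DESeq-style stage: median-of-ratios size factors,
per-gene method-of-moments NB dispersion (no shrinkage trend), and a Wald
test on the log ratio of group means.  Contrasts follow the study design:
each of ISVZ, OSVZ and CP is tested against the VZ, and a lincRNA is called
zone-specific where it is significantly up in that zone (BH q below alpha).
The union of the zone sets is the "expressed during neurogenesis" set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidContrastError, NormalizationError, InvalidInputError

__all__ = ["ZONES", "size_factors", "nb_test", "call_zone_specific"]

ZONES = ("VZ", "ISVZ", "OSVZ", "CP")
_DISPERSION_FLOOR = 1e-8


def _check_zones(zone_map: pd.Series) -> None:
    bad = set(zone_map) - set(ZONES)
    if bad:
        raise InvalidInputError(f"unknown zone labels {sorted(bad)}; expected {ZONES}")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled so the median factor is 1.

    The reference is the per-gene geometric mean over genes positive in all
    samples; each sample's factor is the median of its count/reference
    ratios.  Rescaling by the median factor fixes the arbitrary overall
    scale (it cancels in all fold changes and tests) so that, e.g., doubling
    one sample's library yields factor 2 for it and 1 for the others.
    """
    positive = counts.loc[(counts > 0).all(axis=1)]
    if positive.empty:
        raise NormalizationError(
            "no gene has positive counts in every sample; size factors undefined"
        )
    arr = positive.to_numpy(dtype=float)
    geo_mean = np.exp(np.log(arr).mean(axis=1, keepdims=True))
    factors = np.median(arr / geo_mean, axis=0)
    factors = factors / np.median(factors)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_stats(norm: np.ndarray):
    """Per-gene mean and unbiased variance of normalized counts (columns)."""
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    return mean, var


def _mom_dispersion(normA: np.ndarray, normB: np.ndarray) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion per gene.

    phi = sum_g (n_g - 1) (s_g^2 - m_g) / sum_g (n_g - 1) m_g^2, floored.
    """
    out_num = np.zeros(normA.shape[0])
    out_den = np.zeros(normA.shape[0])
    for grp in (normA, normB):
        n = grp.shape[1]
        m, v = _group_stats(grp)
        out_num += (n - 1) * (v - m)
        out_den += (n - 1) * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = out_num / out_den
    phi = np.where(np.isfinite(phi), phi, 0.0)
    return np.maximum(phi, _DISPERSION_FLOOR)


def nb_test(
    counts: pd.DataFrame,
    zone_map: pd.Series,
    zone_a: str,
    zone_b: str,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of NB means between two zones, gene by gene.

    Group means are estimated as the mean of size-factor-normalized counts
    (which makes fold changes exactly invariant to rescaling any single
    sample together with its factor); the Wald
    statistic is the difference of log means over its delta-method standard
    error with the per-gene method-of-moments dispersion.  Genes with zero
    counts in both groups get p = 1 by convention; a group with zero total
    is continuity-corrected by half a normalized count.  BH-adjusted
    q-values are computed across all tested genes.

    Returns a table indexed by gene with columns ``log2fc`` (zone_b over
    zone_a), ``pvalue``, ``qvalue``, ``zone_a``, ``zone_b``.
    """
    _check_zones(zone_map)
    for z in (zone_a, zone_b):
        if z not in set(zone_map):
            raise InvalidContrastError(f"zone {z!r} has no samples")
    samples_a = zone_map.index[zone_map == zone_a]
    samples_b = zone_map.index[zone_map == zone_b]
    if factors is None:
        factors = size_factors(counts)
    sf_a = factors[samples_a].to_numpy()
    sf_b = factors[samples_b].to_numpy()
    raw_a = counts[samples_a].to_numpy(dtype=float)
    raw_b = counts[samples_b].to_numpy(dtype=float)
    norm_a = raw_a / sf_a
    norm_b = raw_b / sf_b
    phi = _mom_dispersion(norm_a, norm_b)

    def group_mean_and_var(norm, sf):
        n = norm.shape[1]
        mu = norm.mean(axis=1)
        zero = mu == 0
        mu = np.where(zero, 0.5 / (n * sf.mean()), mu)  # continuity correction
        # Var(mu_hat) = (1/n^2) sum_j Var(y_j)/s_j^2 with Var(y_j) NB
        var_mu = (mu[:, None] / sf[None, :] + phi[:, None] * mu[:, None] ** 2).sum(
            axis=1
        ) / n**2
        var_log = var_mu / mu**2
        return mu, var_log, zero

    mu_a, vlog_a, zero_a = group_mean_and_var(norm_a, sf_a)
    mu_b, vlog_b, zero_b = group_mean_and_var(norm_b, sf_b)
    z = (np.log(mu_b) - np.log(mu_a)) / np.sqrt(vlog_a + vlog_b)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    all_zero = zero_a & zero_b
    pvals = np.where(all_zero, 1.0, pvals)
    log2fc = np.where(all_zero, 0.0, np.log2(mu_b / mu_a))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
            "zone_a": zone_a,
            "zone_b": zone_b,
        },
        index=counts.index,
    )


def call_zone_specific(
    results: dict[str, pd.DataFrame], alpha: float = 0.05
) -> dict[str, set[str]]:
    """Zone-labeled lincRNA sets from the three contrasts against the VZ.

    A lincRNA is assigned to every zone where q < alpha with positive fold
    change (it may appear in both ISVZ and OSVZ); the ``"union"`` entry is
    the set expressed during neurogenesis.
    """
    sets: dict[str, set[str]] = {}
    union: set[str] = set()
    for zone, table in results.items():
        if table.empty:
            sets[zone] = set()
            continue
        hit = table[(table["qvalue"] < alpha) & (table["log2fc"] > 0)]
        sets[zone] = set(hit.index)
        union |= sets[zone]
    sets["union"] = union
    return sets
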