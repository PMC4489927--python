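"""Phylogenetic expectation model for per-species conservation counts.

The number of lincRNA gene-neighborhoods conserved in a species decays with
its divergence time from the reference (human): close relatives retain nearly
all neighborhoods, distant species approach a plateau.  We model the expected
count as exponential decay from the reference count ``N`` toward a single
optimum ``theta``,

    E[S_i] = theta + (N - theta) * exp(-alpha * d_i),

where ``d_i`` is the patristic distance from the reference leaf, with
residuals covarying according to an Ornstein-Uhlenbeck (OU) process on the
tree.  The fit is by profile maximum likelihood: for each candidate ``alpha``
the optimum ``theta`` has a closed-form GLS solution and the diffusion
variance ``sigma2`` a closed-form ML solution; ``alpha`` is chosen on a log
grid refined by bounded 1-D optimization.

Observed minus expected counts, expressed as signed percentages, are the
deviation scores used to contrast high- versus low-GI (gyrencephaly index)
species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .errors import InvalidInputError, ModelAssumptionError, UndefinedStatisticError

__all__ = [
    "Phylogeny",
    "OUFit",
    "read_newick",
    "ou_covariance",
    "fit_ou_expectation",
    "expected_scores",
    "deviation_scores",
]

_ALPHA_BOUNDS = (1e-4, 50.0)  # per unit tree depth
_SIGMA2_FLOOR = 1e-12


class Phylogeny:
    """A rooted tree with branch lengths and cached patristic distances.

    Thin wrapper around :class:`dendropy.Tree` exposing the quantities the
    OU machinery needs: leaf names, the patristic distance matrix ``d(i,j)``,
    tree depth, and shared root-to-MRCA times on ultrametric trees.
    """

    def __init__(self, tree: dendropy.Tree, tree_id: str = "tree"):
        if any(e.length is None for e in tree.preorder_edge_iter() if e.head_node.parent_node):
            raise InvalidInputError("tree has edges without branch lengths")
        self._tree = tree
        self.tree_id = tree_id
        self.leaves = sorted(t.label for t in tree.taxon_namespace if t is not None)
        if len(self.leaves) != len(set(self.leaves)):
            raise InvalidInputError("leaf names are not unique")
        self._dist = None

    @classmethod
    def from_newick(cls, newick: str, tree_id: str = "tree") -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises assorted parse errors
            raise InvalidInputError(f"malformed Newick: {exc}") from exc
        return cls(tree, tree_id=tree_id)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def distance_matrix(self) -> pd.DataFrame:
        """Patristic distance matrix as a DataFrame indexed by leaf name."""
        if self._dist is None:
            pdm = self._tree.phylogenetic_distance_matrix()
            n = self.n_leaves
            taxa = {t.label: t for t in self._tree.taxon_namespace}
            mat = np.zeros((n, n))
            for i, a in enumerate(self.leaves):
                for j, b in enumerate(self.leaves):
                    if j > i:
                        mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
            self._dist = pd.DataFrame(mat, index=self.leaves, columns=self.leaves)
        return self._dist

    def depths(self) -> pd.Series:
        """Root-to-leaf path length per leaf."""
        out = {}
        for leaf in self._tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return pd.Series(out).loc[self.leaves]

    @property
    def depth(self) -> float:
        return float(self.depths().max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths()
        return bool((d.max() - d.min()) <= rel_tol * max(d.max(), 1e-300))

    def distances_from(self, reference: str) -> pd.Series:
        """Patristic distance of every other leaf from ``reference``."""
        if reference not in self.leaves:
            raise InvalidInputError(f"reference leaf {reference!r} not in tree")
        col = self.distance_matrix()[reference]
        return col.drop(reference)


def read_newick(path) -> Phylogeny:
    """Load a Newick file with branch lengths into a :class:`Phylogeny`."""
    with open(path) as fh:
        text = fh.read()
    return Phylogeny.from_newick(text, tree_id=str(path))


@dataclass
class OUFit:
    """Fitted OU expectation curve for one tree.

    alpha and sigma2 are on the tree's original time scale; ``theta`` is the
    expected conservation count at infinite divergence, ``n_reference`` the
    reference species' (human) count anchoring the curve at distance 0.
    """

    alpha: float
    sigma2: float
    theta: float
    log_likelihood: float
    n_reference: float
    reference: str
    tree_id: str = "tree"
    at_bound: bool = False

    def predict(self, distances: pd.Series) -> pd.Series:
        """Expected counts at the given patristic distances from the reference."""
        return self.theta + (self.n_reference - self.theta) * np.exp(
            -self.alpha * distances.astype(float)
        )


def ou_covariance(
    tree: Phylogeny,
    alpha: float,
    sigma2: float,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """OU residual covariance among leaves of an ultrametric tree.

    V_ij = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij)),
    with ``d_ij`` the patristic distance and ``t_ij`` the shared time from
    the root to the most recent common ancestor.  As ``alpha -> 0`` this
    reduces to the Brownian-motion covariance ``sigma2 * t_ij``.
    """
    if alpha < 0:
        raise InvalidInputError("alpha must be >= 0")
    if sigma2 <= 0:
        raise InvalidInputError("sigma2 must be > 0")
    if not tree.is_ultrametric(rel_tol=1e-4):
        raise ModelAssumptionError("OU covariance requires an ultrametric tree")
    d = tree.distance_matrix()
    if species is not None:
        d = d.loc[list(species), list(species)]
    T = tree.depth
    dmat = d.to_numpy()
    tshared = T - dmat / 2.0  # root-to-MRCA time; T on the diagonal
    if alpha < 1e-10:
        v = sigma2 * tshared
    else:
        v = (sigma2 / (2.0 * alpha)) * np.exp(-alpha * dmat) * (
            1.0 - np.exp(-2.0 * alpha * tshared)
        )
    return pd.DataFrame(v, index=d.index, columns=d.columns)


def _profile_at_alpha(alpha, dref, dmat, tshared, s_obs, n_ref):
    """Profile out theta and sigma2 at fixed alpha (unit-depth time scale).

    Returns (log-likelihood, theta_hat, sigma2_hat).
    """
    n = len(s_obs)
    corr = np.exp(-alpha * dmat) * (1.0 - np.exp(-2.0 * alpha * tshared)) / (2.0 * alpha)
    try:
        cho = linalg.cho_factor(corr, lower=True)
    except linalg.LinAlgError as exc:
        raise ModelAssumptionError(
            f"singular OU covariance at alpha={alpha:g}; "
            f"condition number ~ {np.linalg.cond(corr):.3g}"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    decay = np.exp(-alpha * dref)
    x = 1.0 - decay                     # dE/dtheta
    b = n_ref * decay                   # fixed offset from the anchor at d=0
    cinv_x = linalg.cho_solve(cho, x)
    denom = float(x @ cinv_x)
    if denom < 1e-12:
        theta = float(np.mean(s_obs - b))
    else:
        theta = float(cinv_x @ (s_obs - b) / denom)
    # the optimum is itself a conservation count: constrain to [0, N]
    theta = float(np.clip(theta, 0.0, n_ref))
    resid = s_obs - (theta * x + b)
    sigma2 = float(resid @ linalg.cho_solve(cho, resid)) / n
    sigma2 = max(sigma2, _SIGMA2_FLOOR)
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return ll, theta, sigma2


def fit_ou_expectation(
    totals: pd.Series,
    tree: Phylogeny,
    reference: str = "human",
    n_reference: float | None = None,
    alpha_bounds: tuple[float, float] = _ALPHA_BOUNDS,
    grid_size: int = 41,
) -> OUFit:
    """Fit the OU decay expectation to per-species conservation totals.

    ``totals`` must contain every non-reference leaf of ``tree``.  The
    reference species is excluded from the residual likelihood (its count is
    the curve's anchor ``N`` at distance zero); ``n_reference`` defaults to
    ``totals[reference]``.

    The tree is rescaled to unit depth for the search and the parameters are
    transformed back, so ``alpha_bounds`` are per unit tree depth.
    """
    if n_reference is None:
        if reference not in totals.index:
            raise InvalidInputError(
                "n_reference not given and reference missing from totals"
            )
        n_reference = float(totals[reference])
    species = [s for s in tree.leaves if s != reference]
    missing = [s for s in species if s not in totals.index]
    if missing:
        raise InvalidInputError(f"totals missing species: {missing[:5]}")
    if not tree.is_ultrametric(rel_tol=1e-4):
        raise ModelAssumptionError("OU fit requires an ultrametric tree")

    T = tree.depth
    d_all = tree.distance_matrix().loc[species, species].to_numpy() / T
    dref = tree.distances_from(reference).loc[species].to_numpy() / T
    tshared = 1.0 - d_all / 2.0
    s_obs = totals.loc[species].to_numpy(dtype=float)

    lo, hi = alpha_bounds
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), grid_size))
    lls = np.array(
        [_profile_at_alpha(a, dref, d_all, tshared, s_obs, n_reference)[0] for a in grid]
    )
    k = int(np.argmax(lls))
    bracket_lo = grid[max(k - 1, 0)]
    bracket_hi = grid[min(k + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda la: -_profile_at_alpha(np.exp(la), dref, d_all, tshared, s_obs, n_reference)[0],
        bounds=(np.log(bracket_lo), np.log(bracket_hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    alpha_hat = float(np.exp(res.x))
    ll_hat, theta_hat, sigma2_hat = _profile_at_alpha(
        alpha_hat, dref, d_all, tshared, s_obs, n_reference
    )
    if ll_hat < lls[k]:  # refinement must never lose to the grid
        alpha_hat = float(grid[k])
        ll_hat, theta_hat, sigma2_hat = _profile_at_alpha(
            alpha_hat, dref, d_all, tshared, s_obs, n_reference
        )
    at_bound = alpha_hat <= lo * 1.01 or alpha_hat >= hi * 0.99
    if at_bound:
        warnings.warn(
            f"alpha estimate {alpha_hat:.3g} at search bound for tree {tree.tree_id}",
            RuntimeWarning,
            stacklevel=2,
        )
    return OUFit(
        alpha=alpha_hat / T,
        sigma2=sigma2_hat / T,
        theta=theta_hat,
        log_likelihood=float(ll_hat),
        n_reference=float(n_reference),
        reference=reference,
        tree_id=tree.tree_id,
        at_bound=at_bound,
    )


def expected_scores(
    fits: Iterable[OUFit],
    trees: Iterable[Phylogeny],
    species: Sequence[str] | None = None,
) -> pd.Series:
    """Per-species expected totals averaged over trees.

    Each fit is evaluated on its own tree's reference distances; a species
    absent from a tree is excluded from that tree's average with a warning.
    """
    fits = list(fits)
    trees = list(trees)
    if not fits or len(fits) != len(trees):
        raise InvalidInputError("need one fitted model per tree, at least one tree")
    per_tree = []
    for fit, tree in zip(fits, trees):
        d = tree.distances_from(fit.reference)
        per_tree.append(fit.predict(d))
    frame = pd.concat(per_tree, axis=1)
    if species is not None:
        absent = frame.loc[list(species)].isna().any(axis=None)
        if absent:
            warnings.warn(
                "some species missing from one or more trees; averaging over "
                "the trees that contain them",
                RuntimeWarning,
                stacklevel=2,
            )
        frame = frame.loc[list(species)]
    return frame.mean(axis=1, skipna=True)


def deviation_scores(
    observed: pd.Series,
    expected: pd.Series,
    gi_class: pd.Series | None = None,
) -> pd.DataFrame:
    """Signed percentage deviations 100*(observed - expected)/expected.

    Returns a table with columns ``observed``, ``expected``, ``deviation_pct``
    and, when supplied, ``gi_class``.  Undefined when any expected value is
    not strictly positive.
    """
    common = observed.index.intersection(expected.index)
    if len(common) == 0:
        raise InvalidInputError("observed and expected share no species")
    obs = observed.loc[common].astype(float)
    exp_ = expected.loc[common].astype(float)
    if (exp_ <= 0).any():
        bad = list(exp_.index[exp_ <= 0])
        raise UndefinedStatisticError(f"expected <= 0 for species {bad[:5]}")
    out = pd.DataFrame(
        {
            "observed": obs,
            "expected": exp_,
            "deviation_pct": 100.0 * (obs - exp_) / exp_,
        }
    )
    if gi_class is not None:
        out["gi_class"] = gi_class.reindex(common)
    out.index.name = "species"
    return out
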