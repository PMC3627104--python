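"""Robustness analysis of a behavioural posterior via PCA.

The principal components of the weighted covariance matrix of the posterior
sample rank the directions of parameter space by how tightly the required
behaviour constrains them.  The component with the *smallest* eigenvalue is
the stiffest: moving along it changes the dynamics fastest, so the parameters
that dominate it are the ones that must be controlled to keep the behaviour.
Components with large eigenvalues are "sloppy" — the behaviour barely cares.
Per-parameter contributions to a component are squared-loading shares, which
sum to 100% because loadings are unit vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import Population

__all__ = ["PCAResult", "pca_posterior", "pc_contribution",
           "posterior_summaries", "weighted_covariance"]


@dataclass(frozen=True)
class PCAResult:
    """Eigen-decomposition of a (weighted) posterior covariance matrix.

    Eigenvalues are sorted descending, so ``loadings[-1]`` — the last
    component — is the stiffest direction.  Loading rows are unit-norm and
    mutually orthogonal.
    """

    eigenvalues: np.ndarray      # (d,), nonincreasing, >= 0
    loadings: np.ndarray         # (d, d): row k = component k
    param_names: tuple[str, ...]
    weighted: bool = True
    rank_deficient: bool = False

    def contributions(self, mode: str = "squared") -> pd.DataFrame:
        """Per-parameter contribution (%) to each component.

        ``squared`` (default): 100·loading²; rows sum to 100 exactly.
        ``absolute``: 100·|loading|/Σ|loading| — available for sensitivity
        checks only.
        """
        if mode == "squared":
            contrib = 100.0 * self.loadings ** 2
        elif mode == "absolute":
            a = np.abs(self.loadings)
            contrib = 100.0 * a / a.sum(axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return pd.DataFrame(contrib, columns=list(self.param_names),
                            index=[f"PC{i + 1}" for i in range(len(self.eigenvalues))])

    def to_json(self, path=None) -> str:
        payload = {
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.loadings.tolist(),
            "param_names": list(self.param_names),
            "weighted": self.weighted,
            "rank_deficient": self.rank_deficient,
            "contributions_pct": self.contributions().to_dict(orient="index"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def weighted_covariance(thetas: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Covariance of the sample under normalized weights (Σw = 1)."""
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    mean = weights @ thetas
    centred = thetas - mean
    return (centred * weights[:, None]).T @ centred


def pca_posterior(population: Population, ess_floor: float = 50.0) -> PCAResult:
    """PCA of the weighted posterior sample.

    Eigen-decomposes the weighted covariance matrix of the particle parameter
    vectors on the raw [0, 1] prior scale (no standardization: all free rates
    share the same prior, and the covariance — not the correlation — matrix
    is the object of interest).  Zero eigenvalues are permitted but flag the
    result as rank-deficient.
    """
    thetas = np.asarray(population.thetas, dtype=float)
    if len(np.unique(thetas, axis=0)) < 2:
        raise ValueError("PCA needs at least 2 distinct particles")
    if population.ess < ess_floor:
        warnings.warn(
            f"effective sample size {population.ess:.1f} < {ess_floor}; "
            "PCA of the posterior may be unstable", stacklevel=2)
    cov = weighted_covariance(thetas, population.weights)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    order = np.argsort(evals)[::-1]         # descending: last = stiffest
    evals = evals[order]
    loadings = evecs[:, order].T
    rank_def = bool(np.any(evals < 1e-12 * max(evals[0], 1e-300)))
    evals = np.clip(evals, 0.0, None)
    names = population.param_names or tuple(
        f"p{i}" for i in range(thetas.shape[1]))
    return PCAResult(evals, loadings, tuple(names),
                     weighted=True, rank_deficient=rank_def)


def pc_contribution(pca: PCAResult, component_index: int,
                    param_subset, mode: str = "squared") -> float:
    """Joint contribution (%) of a parameter subset to one component.

    ``component_index`` indexes the descending-eigenvalue order, so ``-1`` is
    the stiffest (least-variance) component and ``-2`` the second stiffest.
    """
    contrib = pca.contributions(mode=mode)
    unknown = set(param_subset) - set(pca.param_names)
    if unknown:
        raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
    row = contrib.iloc[component_index]
    return float(sum(row[p] for p in param_subset))


def posterior_summaries(population: Population,
                        lows=None, highs=None,
                        n_bins: int = 20,
                        pair_bins: int = 20) -> dict:
    """Weighted 1-D histograms and pairwise 2-D densities of the posterior.

    Histograms use ``n_bins`` fixed bins over the prior support, with masses
    normalized to sum to 1; every parameter pair gets a 2-D density grid.
    Returns ``{"histograms": {name: DataFrame}, "pairs": {(n1, n2): DataFrame}}``.
    """
    if population.n == 0:
        raise ValueError("empty population")
    thetas = population.thetas
    w = population.weights
    d = thetas.shape[1]
    names = population.param_names or tuple(f"p{i}" for i in range(d))
    lows = np.zeros(d) if lows is None else np.asarray(lows, dtype=float)
    highs = np.ones(d) if highs is None else np.asarray(highs, dtype=float)

    hists = {}
    for j, name in enumerate(names):
        edges = np.linspace(lows[j], highs[j], n_bins + 1)
        mass, _ = np.histogram(thetas[:, j], bins=edges, weights=w)
        hists[name] = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "mass": mass})

    pairs = {}
    for i in range(d):
        for j in range(i + 1, d):
            H, xe, ye = np.histogram2d(
                thetas[:, i], thetas[:, j], bins=pair_bins,
                range=[[lows[i], highs[i]], [lows[j], highs[j]]], weights=w)
            pairs[(names[i], names[j])] = pd.DataFrame(
                H, index=xe[:-1], columns=ye[:-1])
    return {"histograms": hists, "pairs": pairs}


def marginal_entropy(hist: pd.DataFrame) -> float:
    """Shannon entropy (nats) of a 1-D histogram's mass column.

    Flat (prior-like) marginals have maximal entropy; tightly inferred
    parameters have low entropy.
    """
    p = hist["mass"].to_numpy()
    p = p[p > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())
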