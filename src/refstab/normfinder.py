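"""Model-based reference-gene stability (the NormFinder approach).

The model decomposes a candidate gene's log2 expression into a sample-wide
abundance term (removed by centering every sample across genes), a systematic
group difference d, and intragroup noise with variance sigma^2.  Moment
estimators give bias-corrected intragroup variances per (gene, group) and raw
group differences d_hat; the spread of true differences across genes, tau^2,
is estimated by moments and used to shrink each d_hat towards zero
(an empirical-Bayes weight tau^2 / (tau^2 + sigma^2/n)).  A gene's stability
value combines the magnitude of its shrunk difference with the posterior
uncertainty of that difference:

    rho_ig = |d_tilde_ig| + sqrt( (sigma2_ig/n_g) * tau2 / (tau2 + sigma2_ig/n_g) )

averaged over groups; the lowest rho is the most stable gene.  Candidate
pairs are scored by the same formula applied to the pseudo-gene with averaged
differences and quartered variance, so two genes with opposite biases can
beat any single gene.

With a single group the intergroup machinery is skipped and stability reduces
to the intragroup SD.  Negative moment estimates are truncated at zero and
the truncation logged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


def _validate_log2_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        genes = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D samples x genes matrix")
        genes = [f"g{i}" for i in range(arr.shape[1])]
    if arr.ndim != 2 or not np.all(np.isfinite(arr)):
        raise ValueError("log2 expression matrix must be 2-D, finite and complete")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names in input")
    return arr, genes


def _center_rows(arr: np.ndarray) -> np.ndarray:
    # remove per-sample global abundance: subtract each sample's mean over genes
    return arr - arr.mean(axis=1, keepdims=True)


def _pair_rho(d_hat_pair, sigma2_pair, tau2, n_g) -> float:
    """Stability of a (pseudo-)gene from its per-group d_hat and sigma2 rows."""
    noise = sigma2_pair / n_g
    if tau2 == 0.0:
        return 0.0
    w = tau2 / (tau2 + noise)
    rho_g = np.abs(d_hat_pair * w) + np.sqrt(noise * w)
    return float(rho_g.mean())


class NormFinder(BaseEstimator):
    """Variance-component stability estimator for reference-gene selection.

    Fit on a samples x genes matrix of log2 expression (a DataFrame supplies
    gene names) and a per-sample group label vector ``y``; omit ``y`` (or pass
    a single label) for the one-group analysis.

    Attributes
    ----------
    genes_ : list of str
    groups_ : list of group labels in order of first appearance.
    n_per_group_ : pd.Series, samples per group.
    sigma2_ : genes x groups frame of bias-corrected intragroup variances (log2^2).
    d_hat_ : genes x groups frame of raw intergroup differences (log2); None for G = 1.
    d_tilde_ : shrunk differences; None for G = 1.
    tau2_ : float, variance of true intergroup differences; None for G = 1.
    rho_group_ : genes x groups frame of group stabilities; None for G = 1.
    stability_ : pd.Series, per-gene stability value (lower = more stable).
    ranking_ : list of genes, ascending stability.
    best_gene_ : str.
    best_pair_ : tuple (gene_a, gene_b); None for G = 1.
    best_pair_stability_ : float; None for G = 1.
    truncations_ : list of str, zero-truncation events of moment estimates.
    """

    def fit(self, X, y=None):
        arr, genes = _validate_log2_matrix(X)
        n_samples, I = arr.shape
        if I < 3:
            raise ValueError(
                "the variance bias correction requires at least 3 genes"
            )
        if y is None:
            labels = np.array(["all"] * n_samples, dtype=object)
        else:
            labels = np.asarray(pd.Series(y).to_numpy(), dtype=object)
            if labels.shape[0] != n_samples:
                raise ValueError("group labels must match the number of samples")
        groups = list(pd.unique(labels))
        G = len(groups)
        n_g = pd.Series({g: int((labels == g).sum()) for g in groups})
        if (n_g < 2).any():
            small = list(n_g.index[n_g < 2])
            raise ValueError(f"group(s) {small} have fewer than 2 samples")

        z = _center_rows(arr)
        truncations: list[str] = []

        # per-(gene, group) sample variance and mean of the centered data
        s2 = np.empty((I, G))
        zbar = np.empty((I, G))
        for gi, g in enumerate(groups):
            block = z[labels == g]
            s2[:, gi] = block.var(axis=0, ddof=1)
            zbar[:, gi] = block.mean(axis=0)

        # bias-correct for the gene-centering: E[s2_ig] = sigma2_ig(1-2/I) + mean contamination
        raw = (I / (I - 2)) * (s2 - s2.sum(axis=0) / (I * (I - 1)))
        sigma2 = np.maximum(raw, 0.0)
        for i, g in zip(*np.nonzero(raw < 0)):
            truncations.append(f"sigma2 truncated to 0 for gene {genes[i]}, group {groups[g]}")

        gene_idx = pd.Index(genes, name="gene")
        grp_idx = pd.Index(groups, name="group")
        self.genes_ = genes
        self.n_features_in_ = I
        self.groups_ = groups
        self.n_per_group_ = n_g
        self.sigma2_ = pd.DataFrame(sigma2, index=gene_idx, columns=grp_idx)

        if G == 1:
            self.d_hat_ = None
            self.d_tilde_ = None
            self.tau2_ = None
            self.rho_group_ = None
            stability = np.sqrt(sigma2[:, 0])
            self.best_pair_ = None
            self.best_pair_stability_ = None
        else:
            d_hat = zbar - zbar.mean(axis=1, keepdims=True)
            n_vec = n_g.to_numpy(dtype=float)
            tau2_raw = (d_hat**2).sum() / (G * (I - 1)) - (sigma2 / n_vec).sum() / (G * I)
            tau2 = max(tau2_raw, 0.0)
            if tau2_raw < 0:
                truncations.append("tau2 truncated to 0")
            noise = sigma2 / n_vec
            if tau2 == 0.0:
                d_tilde = np.zeros_like(d_hat)
                rho_group = np.zeros_like(d_hat)
            else:
                w = tau2 / (tau2 + noise)
                d_tilde = d_hat * w
                rho_group = np.abs(d_tilde) + np.sqrt(noise * w)
            stability = rho_group.mean(axis=1)
            self.d_hat_ = pd.DataFrame(d_hat, index=gene_idx, columns=grp_idx)
            self.d_tilde_ = pd.DataFrame(d_tilde, index=gene_idx, columns=grp_idx)
            self.tau2_ = float(tau2)
            self.rho_group_ = pd.DataFrame(rho_group, index=gene_idx, columns=grp_idx)

            best_pair, best_val = None, np.inf
            for a, b in itertools.combinations(range(I), 2):
                val = _pair_rho(
                    (d_hat[a] + d_hat[b]) / 2.0,
                    (sigma2[a] + sigma2[b]) / 4.0,
                    tau2,
                    n_vec,
                )
                if val < best_val:
                    best_pair, best_val = (genes[a], genes[b]), val
            self.best_pair_ = best_pair
            self.best_pair_stability_ = float(best_val)

        self.stability_ = pd.Series(stability, index=gene_idx, name="stability")
        order = sorted(genes, key=lambda g: (self.stability_[g], g))
        self.ranking_ = order
        self.best_gene_ = order[0]
        self.truncations_ = truncations
        return self

    def pair_stability(self, gene_a: str, gene_b: str) -> float:
        """Stability of the two-gene pseudo-gene (averaged d, quartered variance)."""
        if self.d_hat_ is None:
            raise ValueError("pair stability requires at least two groups")
        d = (self.d_hat_.loc[gene_a] + self.d_hat_.loc[gene_b]).to_numpy() / 2.0
        s = (self.sigma2_.loc[gene_a] + self.sigma2_.loc[gene_b]).to_numpy() / 4.0
        return _pair_rho(d, s, self.tau2_, self.n_per_group_.to_numpy(dtype=float))


@dataclass
class NormFinderFit:
    """Fitted variance components and stability values of a NormFinder run."""

    genes: list[str]
    groups: list
    n_g: pd.Series
    sigma2: pd.DataFrame
    d_hat: pd.DataFrame | None
    d_tilde: pd.DataFrame | None
    tau2: float | None
    rho_ig: pd.DataFrame | None
    rho: pd.Series
    ranking: list[str]
    best_gene: str
    best_pair: tuple[str, str] | None
    best_pair_stability: float | None
    truncations: list[str] = field(default_factory=list)

    @classmethod
    def from_estimator(cls, est: NormFinder) -> "NormFinderFit":
        return cls(
            genes=est.genes_,
            groups=est.groups_,
            n_g=est.n_per_group_,
            sigma2=est.sigma2_,
            d_hat=est.d_hat_,
            d_tilde=est.d_tilde_,
            tau2=est.tau2_,
            rho_ig=est.rho_group_,
            rho=est.stability_,
            ranking=est.ranking_,
            best_gene=est.best_gene_,
            best_pair=est.best_pair_,
            best_pair_stability=est.best_pair_stability_,
            truncations=est.truncations_,
        )

    def stability_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"gene": self.ranking, "stability": [self.rho[g] for g in self.ranking]}
        )
        out["rank"] = np.arange(1, len(self.ranking) + 1)
        return out


def center_samples(y: pd.DataFrame, groups=None) -> pd.DataFrame:
    """Remove each sample's mean log2 expression across genes (idempotent).

    ``y`` is genes x samples; the group assignment is accepted for interface
    symmetry but centering is group-free.
    """
    return y.sub(y.mean(axis=0), axis=1)


def fit_variance_model(y: pd.DataFrame, groups: pd.Series) -> NormFinderFit:
    """Fit the full variance model on a genes x samples log2 matrix."""
    assignment = pd.Series(groups).loc[list(y.columns)]
    est = NormFinder().fit(y.T, assignment.to_numpy())
    return NormFinderFit.from_estimator(est)


def stability_values(fit: NormFinderFit) -> pd.Series:
    """Per-gene stability values, ascending (lowest = most stable)."""
    return fit.rho.loc[fit.ranking]


def best_pair(fit: NormFinderFit) -> tuple[str, str, float]:
    """The unordered gene pair minimising the pair stability."""
    if len(fit.genes) < 2:
        raise ValueError("pair selection needs at least 2 genes")
    if fit.best_pair is None:
        raise ValueError("pair selection requires at least two groups")
    a, b = fit.best_pair
    return a, b, fit.best_pair_stability
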