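"""Parametric empirical-Bayes batch correction (ComBat).

The adjustment removes additive (location) and multiplicative (scale)
batch effects from a merged genes x samples matrix while retaining the
biological group (control/case) contrast as a covariate. Per-batch,
per-gene location and scale estimates are shrunk towards batch-level
priors — a normal prior on the location, an inverse-gamma prior on the
scale — with hyperparameters estimated by method of moments, following
the canonical parametric algorithm.

Conventions mirror the reference R implementation (sva::ComBat): pooled
variance uses an N denominator, per-batch scale estimates use ddof=1,
and the posterior location/scale pair is solved by fixed-point iteration
to 1e-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_CONV = 1e-4
_MAX_ITER = 500


@dataclass
class CombatModel:
    """Fit of the parametric ComBat model to one merged matrix.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Genes x samples expression matrix (all batches merged).
    batch : sequence of str
        Batch label per sample (matrix column order).
    group : sequence of str, optional
        Biological group per sample, retained as a covariate during
        standardization so case/control signal is not removed.

    After :meth:`fit`, per-batch raw (``gamma_hat``, ``delta2_hat``) and
    shrunk (``gamma_star``, ``delta2_star``) location/scale estimates and
    the prior hyperparameters are available as attributes;
    :meth:`transform` returns the adjusted matrix.
    """

    matrix: pd.DataFrame
    batch: list[str]
    group: list[str] | None = None

    # populated by fit()
    batches_: list[str] = field(default_factory=list, init=False)
    gamma_hat: pd.DataFrame | None = field(default=None, init=False)
    delta2_hat: pd.DataFrame | None = field(default=None, init=False)
    gamma_star: pd.DataFrame | None = field(default=None, init=False)
    delta2_star: pd.DataFrame | None = field(default=None, init=False)
    priors_: pd.DataFrame | None = field(default=None, init=False)
    zero_variance_genes_: pd.Index | None = field(default=None, init=False)

    def __post_init__(self) -> None:
        self.batch = [str(b) for b in self.batch]
        if len(self.batch) != self.matrix.shape[1]:
            raise ValueError("batch labels must match matrix columns")
        if self.group is not None:
            self.group = [str(g) for g in self.group]
            if len(self.group) != self.matrix.shape[1]:
                raise ValueError("group labels must match matrix columns")

    def fit(self) -> "CombatModel":
        X = self.matrix.to_numpy(dtype=float)
        batches = sorted(set(self.batch))
        self.batches_ = batches
        if len(batches) < 2:
            # nothing to correct; transform() is the identity
            self._adjusted = self.matrix.copy()
            return self

        batch_arr = np.asarray(self.batch)
        masks = [batch_arr == b for b in batches]
        for b, m in zip(batches, masks):
            if m.sum() < 2:
                raise ValueError(f"batch '{b}' has fewer than 2 samples")

        group = self.group
        if group is not None:
            confounded = [b for b, m in zip(batches, masks)
                          if len(set(np.asarray(group)[m])) < 2]
            if confounded:
                logger.warning(
                    "batch(es) %s contain a single group; fitting without "
                    "the group covariate", confounded)
                group = None

        n_array = X.shape[1]
        design_cols = [m.astype(float) for m in masks]
        if group is not None:
            levels = sorted(set(group))
            garr = np.asarray(group)
            # reference-coded group dummies (first level as reference)
            design_cols += [(garr == lv).astype(float) for lv in levels[1:]]
        design = np.column_stack(design_cols)  # N x (I + ncov)
        n_batch = len(batches)
        n_batches = np.array([m.sum() for m in masks], dtype=float)

        # gene-wise OLS: B_hat is (I + ncov) x G
        B_hat, *_ = np.linalg.lstsq(design, X.T, rcond=None)
        grand_mean = (n_batches / n_array) @ B_hat[:n_batch]  # alpha_g
        resid = X - (design @ B_hat).T
        var_pooled = (resid**2).mean(axis=1)  # sigma^2_g, N denominator

        zero_var = var_pooled <= 1e-12 * np.maximum(1.0, grand_mean**2)
        self.zero_variance_genes_ = self.matrix.index[zero_var]
        if zero_var.any():
            logger.warning("%d gene(s) with zero pooled variance passed "
                           "through unadjusted", int(zero_var.sum()))
        sd = np.sqrt(np.where(zero_var, 1.0, var_pooled))

        stand_mean = np.tile(grand_mean[:, None], (1, n_array))
        if design.shape[1] > n_batch:
            cov_design = design.copy()
            cov_design[:, :n_batch] = 0.0
            stand_mean = stand_mean + (cov_design @ B_hat).T
        Z = (X - stand_mean) / sd[:, None]

        gamma_hat = np.column_stack([Z[:, m].mean(axis=1) for m in masks])
        delta2_hat = np.column_stack([Z[:, m].var(axis=1, ddof=1) for m in masks])

        gamma_bar = gamma_hat.mean(axis=0)
        tau2 = gamma_hat.var(axis=0, ddof=1)
        m_d = delta2_hat.mean(axis=0)
        s2_d = delta2_hat.var(axis=0, ddof=1)
        # method-of-moments inverse-gamma hyperparameters
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = (2.0 * s2_d + m_d**2) / s2_d
            theta = (m_d * s2_d + m_d**3) / s2_d

        gamma_star = np.empty_like(gamma_hat)
        delta2_star = np.empty_like(delta2_hat)
        for i, mask in enumerate(masks):
            if s2_d[i] <= 0 or not np.isfinite(lam[i]):
                # degenerate inverse-gamma prior (identical scale estimates
                # across genes): posterior scale collapses to the common
                # value and the location posterior is closed-form
                d_star = np.full_like(delta2_hat[:, i], m_d[i])
                n_i = mask.sum()
                g_star = ((tau2[i] * n_i * gamma_hat[:, i]
                           + d_star * gamma_bar[i])
                          / (tau2[i] * n_i + d_star))
            else:
                g_star, d_star = _eb_iterate(
                    Z[:, mask], gamma_hat[:, i], delta2_hat[:, i],
                    gamma_bar[i], tau2[i], lam[i], theta[i])
            gamma_star[:, i] = g_star
            delta2_star[:, i] = d_star

        genes = self.matrix.index
        self.gamma_hat = pd.DataFrame(gamma_hat, index=genes, columns=batches)
        self.delta2_hat = pd.DataFrame(delta2_hat, index=genes, columns=batches)
        self.gamma_star = pd.DataFrame(gamma_star, index=genes, columns=batches)
        self.delta2_star = pd.DataFrame(delta2_star, index=genes, columns=batches)
        self.priors_ = pd.DataFrame(
            {"gamma_bar": gamma_bar, "tau2": tau2, "lambda": lam, "theta": theta},
            index=batches)

        adjusted = Z.copy()
        for i, mask in enumerate(masks):
            adjusted[:, mask] = (
                (Z[:, mask] - gamma_star[:, i][:, None])
                / np.sqrt(delta2_star[:, i])[:, None]
            )
        adjusted = adjusted * sd[:, None] + stand_mean
        adjusted[zero_var, :] = X[zero_var, :]
        self._adjusted = pd.DataFrame(adjusted, index=genes,
                                      columns=self.matrix.columns)
        return self

    def transform(self) -> pd.DataFrame:
        if not hasattr(self, "_adjusted"):
            raise RuntimeError("call fit() first")
        return self._adjusted.copy()


def _eb_iterate(Z_batch, g_hat, d2_hat, g_bar, tau2, lam, theta):
    """Fixed-point solve of the coupled posterior location/scale."""
    n = Z_batch.shape[1]
    g_old = g_hat.copy()
    d_old = d2_hat.copy()
    for _ in range(_MAX_ITER):
        g_new = (tau2 * n * g_hat + d_old * g_bar) / (tau2 * n + d_old)
        sum2 = ((Z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (theta + 0.5 * sum2) / (n / 2.0 + lam - 1.0)
        change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-300)),
                     np.max(np.abs(d_new - d_old) / np.abs(d_old + 1e-300)))
        g_old, d_old = g_new, d_new
        if change < _CONV:
            break
    return g_old, d_old


def combat_adjust(matrix: pd.DataFrame, batch_labels, group_labels=None) -> pd.DataFrame:
    """Adjust a merged genes x samples matrix for batch effects.

    With a single batch the input is returned unchanged. The group label,
    when supplied, is retained as a covariate so the case/control
    contrast survives the correction.
    """
    model = CombatModel(matrix, list(batch_labels),
                        list(group_labels) if group_labels is not None else None)
    return model.fit().transform()


def batch_variance_report(matrix: pd.DataFrame, batch_labels) -> pd.DataFrame:
    """Per-gene one-way ANOVA F across batches plus a constant-gene flag.

    Returns a DataFrame indexed by gene with columns F, p and constant.
    Genes constant across all samples get F = 0 and constant = True.
    """
    batch_arr = np.asarray([str(b) for b in batch_labels])
    batches = sorted(set(batch_arr))
    if len(batches) < 2:
        raise ValueError("need >=2 batches")
    X = matrix.to_numpy(dtype=float)
    N = X.shape[1]
    I = len(batches)
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for b in batches:
        sub = X[:, batch_arr == b]
        mb = sub.mean(axis=1)
        ssb += sub.shape[1] * (mb - grand) ** 2
        ssw += ((sub - mb[:, None]) ** 2).sum(axis=1)
    constant = (ssb + ssw) <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (I - 1)) / (ssw / (N - I))
    F = np.where(constant, 0.0, F)
    F = np.where(np.isfinite(F), F, np.inf)
    p = np.where(constant, 1.0, stats.f.sf(F, I - 1, N - I))
    return pd.DataFrame({"F": F, "p": p, "constant": constant}, index=matrix.index)


def batch_variance_summary(report: pd.DataFrame) -> dict[str, float]:
    """Quantile summary of the per-gene batch F statistics."""
    q = report["F"].quantile([0.25, 0.5, 0.75, 0.95])
    return {
        "median_F": float(q.loc[0.5]),
        "q25_F": float(q.loc[0.25]),
        "q75_F": float(q.loc[0.75]),
        "q95_F": float(q.loc[0.95]),
        "frac_p_lt_05": float((report["p"] < 0.05).mean()),
    }
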