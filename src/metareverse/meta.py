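"""Per-gene cross-cohort random-effects meta-analysis.

Each cohort contributes a standardized mean difference (Hedges' g,
case minus control) per gene; cohorts are combined per gene with the
DerSimonian-Laird (DL) random-effects estimator. Heterogeneity is
quantified with Cochran's Q, significance by a two-sided normal test on
the combined effect, and multiplicity by Benjamini-Hochberg (BH) FDR.
Genes with FDR below ``alpha`` (default 0.05) are the DEGs.

The module exposes both the elementary estimators (``hedges_g``,
``cochran_q``, ``random_effects_combine``, ``bh_adjust``) and a
statsmodels-style model: ``ExpressionMetaAnalysis(datasets).fit()``
returning :class:`MetaAnalysisResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary estimators
# ---------------------------------------------------------------------------

def hedges_g(control_values, case_values):
    """Hedges' g (case - control) and its sampling variance.

    d = (mean_case - mean_control) / s_pooled, corrected by
    J = 1 - 3/(4 df - 1) with df = n1 + n2 - 2, so g = J d and
    var_g = (n1 + n2)/(n1 n2) + g^2 / (2 (n1 + n2)).

    Returns (g, var_g). Raises ValueError on zero pooled variance.
    """
    control = np.asarray(control_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    if control.size < 2 or case.size < 2:
        raise ValueError("need >=2 values per group")
    g, var_g = _hedges_g_matrix(control[None, :], case[None, :])
    if not np.isfinite(g[0]):
        raise ValueError("zero pooled variance: effect size undefined")
    return float(g[0]), float(var_g[0])


def _hedges_g_matrix(control: np.ndarray, case: np.ndarray):
    """Vectorized Hedges' g over genes (rows). Returns NaN where s_pooled=0."""
    n1 = control.shape[1]
    n2 = case.shape[1]
    m1 = control.mean(axis=1)
    m2 = case.mean(axis=1)
    v1 = control.var(axis=1, ddof=1)
    v2 = case.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s2_pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m2 - m1) / np.sqrt(s2_pooled)
    d = np.where(s2_pooled > 0, d, np.nan)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    var_g = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))
    return g, var_g


def cochran_q(effects: Sequence[tuple[float, float]]):
    """Cochran's Q homogeneity test for k >= 2 study effects.

    ``effects`` is a sequence of (g, var_g). Returns (Q, df, p_Q) where
    p_Q is the chi-square upper tail on k-1 degrees of freedom.
    """
    arr = np.asarray(effects, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("Cochran's Q requires >=2 studies")
    g = arr[:, 0][None, :]
    var = arr[:, 1][None, :]
    Q, df = _cochran_q_matrix(g, var)
    p_Q = float(stats.chi2.sf(Q[0], df))
    return float(Q[0]), int(df), p_Q


def _cochran_q_matrix(g: np.ndarray, var: np.ndarray):
    """Vectorized Q over genes (rows) x studies (columns)."""
    w = 1.0 / var
    ybar = (w * g).sum(axis=1) / w.sum(axis=1)
    Q = (w * (g - ybar[:, None]) ** 2).sum(axis=1)
    return Q, g.shape[1] - 1


def random_effects_combine(effects: Sequence[tuple[float, float]]):
    """DerSimonian-Laird random-effects combination of study effects.

    tau2 = max(0, (Q - df) / (Sum w - Sum w^2 / Sum w)) with fixed-effect
    weights w = 1/var; the combined effect uses w* = 1/(var + tau2).

    Returns a dict with tau2, combined_es, se, z, p (and Q, df, p_Q when
    k >= 2; for a single study the effect is passed through).
    """
    arr = np.asarray(effects, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need >=1 study effect")
    g = arr[:, 0][None, :]
    var = arr[:, 1][None, :]
    if arr.shape[0] == 1:
        se = float(np.sqrt(var[0, 0]))
        es = float(g[0, 0])
        z = es / se
        return {
            "tau2": 0.0, "combined_es": es, "se": se, "z": z,
            "p": float(2.0 * stats.norm.sf(abs(z))),
            "Q": 0.0, "df": 0, "p_Q": 1.0,
        }
    out = _dl_combine_matrix(g, var)
    return {k: (float(v[0]) if k != "df" else int(v)) for k, v in out.items()}


def _dl_combine_matrix(g: np.ndarray, var: np.ndarray):
    """Vectorized DL combination over genes (rows) x studies (columns)."""
    Q, df = _cochran_q_matrix(g, var)
    w = 1.0 / var
    sw = w.sum(axis=1)
    denom = sw - (w**2).sum(axis=1) / sw
    tau2 = np.maximum(0.0, (Q - df) / denom)
    wstar = 1.0 / (var + tau2[:, None])
    combined = (wstar * g).sum(axis=1) / wstar.sum(axis=1)
    se = wstar.sum(axis=1) ** -0.5
    z = combined / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return {
        "Q": Q, "df": df, "p_Q": stats.chi2.sf(Q, df),
        "tau2": tau2, "combined_es": combined, "se": se, "z": z, "p": p,
    }


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjustment (same order as input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class StudyEffect:
    """One cohort's contribution for one gene."""

    gene: str
    dataset_id: str
    g: float
    var_g: float
    fc: float
    p_study: float
    fdr_study: float


class ExpressionMetaAnalysis:
    """Random-effects meta-analysis model over >=1 expression cohorts.

    Parameters
    ----------
    datasets : sequence of ExpressionDataset
        Cohorts, typically batch-corrected beforehand. The analysis runs
        on the intersection gene universe; genes present in only one
        dataset are excluded (logged).

    Examples
    --------
    >>> results = ExpressionMetaAnalysis([ds1, ds2]).fit()
    >>> degs = results.call_degs(alpha=0.05)
    """

    def __init__(self, datasets: Sequence[ExpressionDataset]):
        if len(datasets) < 1:
            raise ValueError("need at least one dataset")
        self.datasets = list(datasets)
        universe = self.datasets[0].genes
        for ds in self.datasets[1:]:
            universe = universe.intersection(ds.genes)
        n_union = len(set().union(*(set(ds.genes) for ds in self.datasets)))
        excluded = n_union - len(universe)
        if excluded:
            logger.info("excluded %d genes absent from >=1 dataset", excluded)
        self.universe = universe.sort_values()

    @classmethod
    def from_merged(cls, matrix: pd.DataFrame, manifest: pd.DataFrame):
        """Build from one merged matrix whose manifest carries batch ids."""
        datasets = []
        for batch, sub in manifest.groupby("batch", sort=True):
            datasets.append(
                ExpressionDataset(
                    dataset_id=str(batch),
                    matrix=matrix.loc[:, list(sub["sample_id"])],
                    manifest=sub.reset_index(drop=True),
                )
            )
        return cls(datasets)

    def fit(self) -> "MetaAnalysisResults":
        genes = self.universe
        k = len(self.datasets)
        G = np.empty((len(genes), k))
        V = np.empty((len(genes), k))
        per_study: dict[str, pd.DataFrame] = {}
        for j, ds in enumerate(self.datasets):
            sub = ds.matrix.loc[genes]
            ctrl = sub[ds.group_samples("control")].to_numpy()
            case = sub[ds.group_samples("case")].to_numpy()
            g, var_g = _hedges_g_matrix(ctrl, case)
            G[:, j] = g
            V[:, j] = var_g
            fc = case.mean(axis=1) - ctrl.mean(axis=1)
            with np.errstate(invalid="ignore"):
                z = g / np.sqrt(var_g)
            p_study = 2.0 * stats.norm.sf(np.abs(z))
            ok = np.isfinite(p_study)
            fdr_study = np.full_like(p_study, np.nan)
            if ok.any():
                fdr_study[ok] = bh_adjust(p_study[ok])
            per_study[ds.dataset_id] = pd.DataFrame(
                {"g": g, "var_g": var_g, "fc": fc,
                 "p_study": p_study, "fdr_study": fdr_study},
                index=genes,
            )

        defined = np.isfinite(G).all(axis=1)
        n_dropped = int((~defined).sum())
        if n_dropped:
            logger.info("excluded %d genes with undefined effect (zero pooled variance)", n_dropped)

        table = pd.DataFrame(index=genes[defined])
        table.index.name = "gene"
        Gd, Vd = G[defined], V[defined]
        if k >= 2:
            combined = _dl_combine_matrix(Gd, Vd)
            table["Q"] = combined["Q"]
            table["df"] = combined["df"]
            table["p_Q"] = combined["p_Q"]
            table["tau2"] = combined["tau2"]
        else:
            combined = {
                "combined_es": Gd[:, 0], "se": np.sqrt(Vd[:, 0]),
            }
            combined["z"] = combined["combined_es"] / combined["se"]
            combined["p"] = 2.0 * stats.norm.sf(np.abs(combined["z"]))
            table["Q"] = 0.0
            table["df"] = 0
            table["p_Q"] = 1.0
            table["tau2"] = 0.0
        table["combined_es"] = combined["combined_es"]
        table["se"] = combined["se"]
        table["z"] = combined["z"]
        table["p"] = combined["p"]
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table["direction"] = np.where(table["combined_es"] >= 0, "up", "down")
        for ds in self.datasets:
            st = per_study[ds.dataset_id].loc[table.index]
            table[f"{ds.dataset_id}_FC"] = st["fc"]
            table[f"{ds.dataset_id}_g"] = st["g"]
            table[f"{ds.dataset_id}_AdjPval"] = st["fdr_study"]
        return MetaAnalysisResults(model=self, table=table, n_excluded=n_dropped)


class MetaAnalysisResults:
    """Results of :class:`ExpressionMetaAnalysis.fit`.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per gene of the intersection universe with a defined
        effect: per-study FC/g/adjusted p, Q, df, p_Q, tau2, combined_es,
        se, z, p, fdr, direction.
    """

    def __init__(self, model: ExpressionMetaAnalysis, table: pd.DataFrame,
                 n_excluded: int = 0):
        self.model = model
        self.table = table
        self.n_excluded = n_excluded

    @property
    def dataset_ids(self) -> list[str]:
        return [ds.dataset_id for ds in self.model.datasets]

    def call_degs(self, alpha: float = 0.05) -> pd.DataFrame:
        """Genes with BH FDR < alpha, split by direction of combined ES."""
        if not (0 < alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        degs = self.table[self.table["fdr"] < alpha].copy()
        return degs.sort_values("fdr")

    def top_table(self, direction: str, k: int = 20,
                  alpha: float = 0.05) -> pd.DataFrame:
        """Top-k DEGs of one direction, ranked by |combined ES| descending."""
        degs = self.call_degs(alpha)
        sub = degs[degs["direction"] == direction].copy()
        sub = sub.reindex(sub["combined_es"].abs().sort_values(ascending=False).index)
        cols = (
            [f"{d}_FC" for d in self.dataset_ids]
            + [f"{d}_AdjPval" for d in self.dataset_ids]
            + ["combined_es", "fdr"]
        )
        return sub[cols].head(k)

    def summary(self, alpha: float = 0.05) -> str:
        degs = self.call_degs(alpha)
        n_up = int((degs["direction"] == "up").sum())
        n_down = int((degs["direction"] == "down").sum())
        lines = [
            "Random-effects expression meta-analysis (DerSimonian-Laird)",
            "=" * 60,
            f"datasets:            {', '.join(self.dataset_ids)}",
            f"genes analysed:      {len(self.table)}",
            f"genes excluded:      {self.n_excluded} (zero pooled variance)",
            f"median tau2:         {self.table['tau2'].median():.4g}",
            f"heterogeneous genes: {int((self.table['p_Q'] < 0.05).sum())} (p_Q < 0.05)",
            f"DEGs (FDR < {alpha:g}):   {len(degs)} ({n_up} up, {n_down} down)",
        ]
        return "\n".join(lines)
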