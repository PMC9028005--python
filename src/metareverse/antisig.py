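"""Anti-signature drug screen: cosine matching with a permutation null.

Each drug consensus signature is scored against the signed disease
signature (DEG combined effect sizes) by cosine similarity on the DEG
genes. Significance of *anti*-similarity (negative cosine) is assessed
one-sided against a permutation null built by re-drawing, for each of
``n_perm`` permutations, a uniformly random gene subset of the library
universe of the same size as the disease vector while keeping the
disease values fixed; the empirical p uses the add-one estimator
p = (1 + #{null <= observed}) / (n_perm + 1), so p is never zero. BH
correction is applied jointly across drugs, hits are the drugs with
negative cosine and FDR below alpha, and hits are finally annotated (or
filtered) by blood-brain-barrier permeability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drugsig import DrugMetaSignature, meta_signature_matrix
from .io import BBBTable
from .meta import bh_adjust

logger = logging.getLogger(__name__)

#: drugs sharing fewer genes with the disease vector are flagged and
#: excluded from the screen by default
MIN_OVERLAP = 10


@dataclass
class SignatureVector:
    """Gene-indexed signed disease signature (combined effect sizes)."""

    genes: pd.Index
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) == 0:
            raise ValueError("empty signature vector")
        if self.genes.has_duplicates:
            raise ValueError("duplicate genes in signature vector")
        if len(self.genes) != self.values.shape[0]:
            raise ValueError("genes and values length mismatch")
        if not np.any(self.values != 0):
            raise ValueError("signature vector is identically zero")

    def __len__(self) -> int:
        return len(self.genes)


def build_disease_vector(deg_table: pd.DataFrame, universe) -> SignatureVector:
    """Signed disease signature from a DEG table, restricted to a universe.

    ``deg_table`` is indexed by gene with a ``combined_es`` column; genes
    outside the drug-library universe are dropped with a logged count.
    """
    if deg_table.empty:
        raise ValueError("empty DEG table")
    universe = pd.Index(universe)
    keep = deg_table.index.intersection(universe)
    dropped = len(deg_table) - len(keep)
    if dropped:
        logger.info("dropped %d DEGs outside the drug-library universe", dropped)
    if len(keep) == 0:
        raise ValueError("no DEGs overlap the drug-library universe")
    sub = deg_table.loc[keep]
    return SignatureVector(genes=sub.index, values=sub["combined_es"].to_numpy())


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (||u|| ||v||); raises on zero-norm input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 1:
        raise ValueError("need two equal-length 1-D vectors")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


def _observed_cosines(values: np.ndarray, idx: np.ndarray,
                      D: np.ndarray) -> np.ndarray:
    """Cosine of the disease values against every drug column of D[idx]."""
    sub = D[idx, :]                      # m x n_drugs
    num = values @ sub
    denom = np.linalg.norm(values) * np.linalg.norm(sub, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, num / denom, np.nan)


def permutation_antisimilarity(disease_vec: SignatureVector,
                               meta_signatures: list[DrugMetaSignature] | pd.DataFrame,
                               n_perm: int = 1000,
                               seed: int = 0,
                               universe=None,
                               tail: str = "lower",
                               null: str = "gene_subset",
                               min_overlap: int = MIN_OVERLAP) -> pd.DataFrame:
    """Score drugs against the disease signature with a permutation null.

    Returns one record per drug: cosine, p_emp, fdr, n_perm, n_overlap.
    ``tail='lower'`` tests anti-similarity (the default screen);
    ``'two-sided'`` is available for sensitivity analysis. The null is
    either ``'gene_subset'`` (random DEG-identity redraw, default) or
    ``'rotation'`` (disease values assigned to a random permutation of
    themselves across drugs' gene axis — a drug-agnostic label rotation).
    """
    if isinstance(meta_signatures, pd.DataFrame):
        D_df = meta_signatures
    else:
        if universe is None:
            raise ValueError("universe required with a list of meta-signatures")
        D_df = meta_signature_matrix(meta_signatures, universe)
    # canonical order: results are invariant to input gene/drug ordering
    D_df = D_df.sort_index().sort_index(axis=1)
    univ = D_df.index
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    keep = disease_vec.genes.isin(univ)
    genes = disease_vec.genes[keep]
    values = disease_vec.values[keep]
    if len(genes) > len(univ):
        raise ValueError("disease vector larger than the library universe")
    if len(genes) == 0:
        raise ValueError("disease vector does not overlap the universe")

    D = D_df.to_numpy(dtype=float)
    drugs = list(D_df.columns)
    pos = pd.Index(univ).get_indexer(genes)
    m = len(pos)

    overlap = np.full(len(drugs), m)
    low_overlap = overlap < min_overlap
    observed = _observed_cosines(values, pos, D)

    rng = np.random.default_rng(seed)
    count_le = np.zeros(len(drugs))
    count_ge = np.zeros(len(drugs))
    for _ in range(n_perm):
        if null == "gene_subset":
            idx = rng.choice(len(univ), size=m, replace=False)
            null_cos = _observed_cosines(values, idx, D)
        elif null == "rotation":
            null_cos = _observed_cosines(rng.permutation(values), pos, D)
        else:
            raise ValueError(f"unknown null scheme '{null}'")
        count_le += null_cos <= observed
        count_ge += null_cos >= observed

    if tail == "lower":
        p_emp = (1.0 + count_le) / (n_perm + 1.0)
    elif tail == "two-sided":
        p_one = np.minimum(count_le, count_ge)
        p_emp = np.minimum(1.0, 2.0 * (1.0 + p_one) / (n_perm + 1.0))
    else:
        raise ValueError(f"unknown tail '{tail}'")

    records = pd.DataFrame({
        "drug": drugs,
        "cosine": observed,
        "p_emp": p_emp,
        "n_perm": n_perm,
        "n_overlap": overlap,
        "low_overlap": low_overlap,
    })
    tested = ~records["low_overlap"]
    records["fdr"] = np.nan
    if tested.any():
        records.loc[tested, "fdr"] = bh_adjust(records.loc[tested, "p_emp"].to_numpy())
    if low_overlap.any():
        logger.info("excluded %d drugs sharing <%d genes with the disease vector",
                    int(low_overlap.sum()), min_overlap)
    return records


def select_hits(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Anti-similar hits: cosine < 0 and FDR <= alpha, cosine ascending."""
    if not (0 <= alpha < 1):
        raise ValueError("alpha must be in [0, 1)")
    ok = (records["cosine"] < 0) & (records["fdr"] <= alpha)
    ok &= ~records.get("low_overlap", False)
    return records[ok.fillna(False)].sort_values("cosine").reset_index(drop=True)


def bbb_annotate(records: pd.DataFrame, bbb_table: BBBTable,
                 permeable_only: bool = False) -> pd.DataFrame:
    """Join BBB permeability by case-insensitive drug name.

    Unmatched drugs are labelled ``unknown`` (and excluded when
    ``permeable_only`` is set).
    """
    out = records.copy()
    out["bbb"] = [bbb_table.lookup(d) for d in out["drug"]]
    if permeable_only:
        out = out[out["bbb"] == "permeable"].reset_index(drop=True)
    return out


class AntiSignatureScreen:
    """Model-style front end to the anti-signature screen.

    Parameters
    ----------
    disease_vector : SignatureVector
        Signed DEG signature (see :func:`build_disease_vector`).
    meta_signatures : pandas.DataFrame
        Genes x drugs consensus z-score matrix.
    n_perm : int
        Permutations for the null (default 1000).
    seed : int
        Seed for the permutation stream.
    """

    def __init__(self, disease_vector: SignatureVector,
                 meta_signatures: pd.DataFrame, n_perm: int = 1000,
                 seed: int = 0, tail: str = "lower",
                 null: str = "gene_subset", min_overlap: int = MIN_OVERLAP):
        self.disease_vector = disease_vector
        self.meta_signatures = meta_signatures
        self.n_perm = n_perm
        self.seed = seed
        self.tail = tail
        self.null = null
        self.min_overlap = min_overlap

    def fit(self) -> "ScreenResults":
        records = permutation_antisimilarity(
            self.disease_vector, self.meta_signatures, n_perm=self.n_perm,
            seed=self.seed, tail=self.tail, null=self.null,
            min_overlap=self.min_overlap)
        return ScreenResults(model=self, records=records)


class ScreenResults:
    """Results of :class:`AntiSignatureScreen.fit`."""

    def __init__(self, model: AntiSignatureScreen, records: pd.DataFrame):
        self.model = model
        self.records = records

    def select_hits(self, alpha: float = 0.05) -> pd.DataFrame:
        return select_hits(self.records, alpha)

    def bbb_annotate(self, bbb_table: BBBTable,
                     permeable_only: bool = False) -> pd.DataFrame:
        return bbb_annotate(self.records, bbb_table, permeable_only)

    def summary(self, alpha: float = 0.05) -> str:
        hits = self.select_hits(alpha)
        lines = [
            "Anti-signature drug screen (cosine, permutation null)",
            "=" * 60,
            f"drugs screened:     {len(self.records)}",
            f"disease vector:     {len(self.model.disease_vector)} genes",
            f"permutations:       {self.model.n_perm}",
            f"hits (cos<0, FDR<={alpha:g}): {len(hits)}",
        ]
        if len(hits):
            top = hits.iloc[0]
            lines.append(
                f"top hit:            {top['drug']} "
                f"(cosine {top['cosine']:.3f}, FDR {top['fdr']:.3g})")
        return "\n".join(lines)
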