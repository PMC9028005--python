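"""Drug consensus meta-signatures from replicate z-score signatures.

A drug's perturbational profile is observed as replicate z-score vectors
over a common gene universe (one per experiment). The consensus
meta-signature combines replicates per gene with Stouffer's method,
z_meta = sum(z_i)/sqrt(k), unweighted; under i.i.d. standard-normal
replicates the consensus is again standard normal per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _norm_name(name: str) -> str:
    return name.strip().casefold()


@dataclass
class DrugSignatureLibrary:
    """Per-drug replicate z-vectors over an ordered gene universe."""

    universe: pd.Index
    replicates: dict[str, np.ndarray]  # drug -> (k, n_genes)
    fda_approved: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe = pd.Index(self.universe, name="gene")
        norm_names = [_norm_name(d) for d in self.replicates]
        if len(set(norm_names)) != len(norm_names):
            raise ValueError("drug names not unique after normalization")
        for drug, reps in self.replicates.items():
            reps = np.atleast_2d(np.asarray(reps, dtype=float))
            if reps.shape[0] < 1:
                raise ValueError(f"drug '{drug}' has no replicates")
            if reps.shape[1] != len(self.universe):
                raise ValueError(
                    f"drug '{drug}': replicate length {reps.shape[1]} != "
                    f"universe size {len(self.universe)}")
            self.replicates[drug] = reps
        for drug in self.replicates:
            self.fda_approved.setdefault(drug, True)

    @property
    def drug_names(self) -> list[str]:
        return sorted(self.replicates)

    def __len__(self) -> int:
        return len(self.replicates)


@dataclass
class DrugMetaSignature:
    """Consensus signature of one drug over the library universe."""

    drug: str
    z_meta: np.ndarray
    n_replicates: int


def stouffer_combine(replicate_vectors) -> np.ndarray:
    """Unweighted Stouffer combination: per gene, sum(z_i) / sqrt(k)."""
    Z = np.atleast_2d(np.asarray(replicate_vectors, dtype=float))
    if Z.shape[0] < 1:
        raise ValueError("need >=1 replicate vector")
    lengths = {row.shape[0] for row in Z}
    if len(lengths) != 1:
        raise ValueError("replicate vectors have mismatched lengths")
    return Z.sum(axis=0) / np.sqrt(Z.shape[0])


def stouffer_combine_weighted(replicate_vectors, weights) -> np.ndarray:
    """Weighted Stouffer: sum(w_i z_i) / sqrt(sum w_i^2)."""
    Z = np.atleast_2d(np.asarray(replicate_vectors, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != Z.shape[0]:
        raise ValueError("one weight per replicate required")
    return (w[:, None] * Z).sum(axis=0) / np.sqrt((w**2).sum())


def build_meta_signatures(library: DrugSignatureLibrary,
                          fda_only: bool = True) -> list[DrugMetaSignature]:
    """One Stouffer consensus per drug passing the FDA filter (name-sorted)."""
    out: list[DrugMetaSignature] = []
    for drug in library.drug_names:
        if fda_only and not library.fda_approved.get(drug, False):
            continue
        reps = library.replicates[drug]
        out.append(DrugMetaSignature(drug=drug,
                                     z_meta=stouffer_combine(reps),
                                     n_replicates=reps.shape[0]))
    if not out:
        raise ValueError("no drugs pass the FDA-approved filter")
    logger.info("built %d meta-signatures (fda_only=%s) from %d drugs",
                len(out), fda_only, len(library))
    return out


def meta_signature_matrix(signatures: list[DrugMetaSignature],
                          universe: pd.Index) -> pd.DataFrame:
    """Genes x drugs matrix of consensus z-scores."""
    data = {s.drug: s.z_meta for s in signatures}
    return pd.DataFrame(data, index=pd.Index(universe, name="gene"))
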