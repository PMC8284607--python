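"""Comparison of spectra to an SBS signature catalog and exposure refitting.

The catalog is a fixed, named set of 96-channel probability vectors (the
COSMIC SBS format). Comparison uses cosine similarity with an 0.80 "high
similarity" threshold and average-linkage clustering for display order;
decomposition refits non-negative exposures against the fixed catalog by
non-negative least squares, which is the deterministic one-sided special
case of NMF with known basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .spectrum import CHANNELS_96, Spectrum96

HIGH_SIMILARITY_THRESHOLD = 0.80


@dataclass
class SignatureCatalog:
    """Named signatures x 96 channels; each column a probability vector."""

    names: tuple[str, ...]
    matrix: np.ndarray  # (96, n_signatures)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError("matrix must be 96 x n_signatures")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate signature names")
        if self.matrix.shape[1] == 0:
            raise ValueError("catalog has no signatures")
        if (self.matrix < 0).any():
            raise ValueError("negative signature entries")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("signature columns must sum to 1")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(CHANNELS_96), columns=list(self.names))


def read_signature_catalog(path) -> SignatureCatalog:
    """Read a COSMIC-style SBS tab-separated matrix.

    Accepts either a first column of "A[C>A]A"-style keys (any of the usual
    header names) or the older separate Type ("C>A") / Subtype ("ACA")
    dialect. Rows are reordered to the canonical channel order; columns are
    renormalized when within 1e-3 of 1, otherwise rejected.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    key_col = next(
        (c for c in cols if c.lower() in
         {"type", "mutationtype", "mutation type", "mutation_type", "channel"}),
        cols[0],
    )
    if "Subtype" in cols and "[" not in str(df[key_col].iloc[0]):
        # Type ("C>A") + Subtype ("ACA") dialect
        keys = [
            f"{sub[0]}[{typ}]{sub[2]}"
            for typ, sub in zip(df[key_col].astype(str), df["Subtype"].astype(str))
        ]
        value_cols = [c for c in cols if c not in (key_col, "Subtype")]
    else:
        keys = df[key_col].astype(str).tolist()
        value_cols = [c for c in cols if c != key_col]
    df = df[value_cols].copy()
    df.index = keys

    missing = [c for c in CHANNELS_96 if c not in df.index]
    if missing:
        raise ValueError(f"catalog missing channel(s): {missing[:5]}")
    df = df.loc[list(CHANNELS_96)]
    matrix = df.to_numpy(dtype=float)
    if (matrix < 0).any():
        raise ValueError("negative entries in signature catalog")
    sums = matrix.sum(axis=0)
    off = np.abs(sums - 1.0) > 1e-3
    if off.any():
        bad = [value_cols[i] for i in np.flatnonzero(off)]
        raise ValueError(f"signature column(s) do not sum to 1: {bad}")
    matrix = matrix / sums
    return SignatureCatalog(tuple(value_cols), matrix)


def write_signature_catalog(catalog: SignatureCatalog, path) -> None:
    frame = catalog.to_frame()
    frame.insert(0, "Type", frame.index)
    frame.to_csv(path, sep="\t", index=False)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (|a| |b|) for non-negative 96-vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if (a < 0).any() or (b < 0).any():
        raise ValueError("cosine similarity defined here for non-negative vectors")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an all-zero vector")
    return float(a @ b / (na * nb))


@dataclass
class SimilarityResult:
    """Cosine similarities of spectra against a catalog."""

    matrix: pd.DataFrame  # spectra x signatures
    best_hits: pd.DataFrame  # spectrum, signature, similarity, high, tied
    leaf_order: tuple[str, ...]  # signatures ordered by clustering
    threshold: float


def _as_vector(spectrum) -> np.ndarray:
    if isinstance(spectrum, Spectrum96):
        return spectrum.proportions()
    return np.asarray(spectrum, dtype=float)


def similarity_matrix(
    spectra: Mapping[str, Spectrum96] | Mapping[str, np.ndarray],
    catalog: SignatureCatalog,
    threshold: float = HIGH_SIMILARITY_THRESHOLD,
) -> SimilarityResult:
    """Full cosine matrix, per-spectrum best hits, and a clustering order.

    Best hit ties resolve to the first catalog column and are flagged.
    Signatures are ordered by average-linkage hierarchical clustering on
    1 - cosine distance (plain dendrogram leaf order, no optimal-leaf
    reordering); a single-signature catalog keeps its order.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    names = list(spectra)
    vectors = np.stack([_as_vector(spectra[n]) for n in names])
    sims = np.array(
        [[cosine_similarity(v, catalog.matrix[:, j]) for j in range(len(catalog.names))]
         for v in vectors]
    )
    matrix = pd.DataFrame(sims, index=names, columns=list(catalog.names))

    rows = []
    for i, name in enumerate(names):
        best_j = int(np.argmax(sims[i]))
        best = sims[i, best_j]
        tied = int(np.sum(np.isclose(sims[i], best, rtol=0, atol=1e-12))) > 1
        rows.append(
            {"spectrum": name, "signature": catalog.names[best_j],
             "similarity": float(best), "high": bool(best >= threshold),
             "tied": tied}
        )
    best_hits = pd.DataFrame(rows)

    if len(catalog.names) > 1:
        dist = pdist(catalog.matrix.T, metric="cosine")  # 1 - cosine
        order = leaves_list(linkage(dist, method="average"))
        leaf_order = tuple(catalog.names[i] for i in order)
    else:
        leaf_order = catalog.names
    return SimilarityResult(matrix, best_hits, leaf_order, threshold)


@dataclass
class ExposureVector:
    """Non-negative signature exposures summing to 1."""

    weights: dict[str, float]
    residual_cosine: float

    def as_percentages(self) -> dict[str, float]:
        return {k: 100 * v for k, v in self.weights.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"signature": list(self.weights),
             "weight_pct": [100 * v for v in self.weights.values()]}
        )


def refit_exposures(
    spectrum: Spectrum96 | np.ndarray,
    catalog: SignatureCatalog,
    min_weight: float = 0.0,
) -> ExposureVector:
    """Solve min ||spectrum - catalog @ w||_2 s.t. w >= 0 and report
    fractional weights.

    Weights below ``min_weight`` (as a fraction, after normalization) are
    zeroed and the rest renormalized. ``residual_cosine`` is the cosine
    between the input and its reconstruction.
    """
    target = _as_vector(spectrum)
    w, _rnorm = nnls(catalog.matrix, target)
    total = w.sum()
    if total == 0:
        raise ValueError("refit produced all-zero exposures (orthogonal catalog?)")
    frac = w / total
    if min_weight > 0:
        frac = np.where(frac >= min_weight, frac, 0.0)
        if frac.sum() == 0:
            raise ValueError("min_weight removed every exposure")
        frac = frac / frac.sum()
    recon = catalog.matrix @ (frac * total)
    residual = cosine_similarity(target, recon)
    weights = dict(zip(catalog.names, frac.astype(float)))
    return ExposureVector(weights, residual)
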