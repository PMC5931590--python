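"""Cosine-similarity comparison of extracted signatures against reference
catalogs (e.g. the 30 COSMIC substitution signatures, or the six breast-cancer
rearrangement signatures RS1–RS6)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extract import SignatureProfile
from .variant_io import SignatureCatalog


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (||u|| ||v||); in [0, 1] for non-negative inputs."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class SimilarityReport:
    """All per-reference cosines for one query signature, ranked descending
    (ties keep the catalog's reference order, so the ranking is stable)."""

    query: str
    cosines: dict[str, float]

    @property
    def ranked(self) -> list[tuple[str, float]]:
        names = list(self.cosines)
        return sorted(((n, self.cosines[n]) for n in names),
                      key=lambda item: (-item[1], names.index(item[0])))

    @property
    def best_match(self) -> tuple[str, float]:
        return self.ranked[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranked, columns=["reference", "cosine"])


def compare_to_catalog(signature: SignatureProfile,
                       catalog: SignatureCatalog,
                       query_name: str = "query") -> SimilarityReport:
    """Cosine of the query against every reference signature in the catalog.

    The report keeps all cosines, not just the maximum: runner-up
    similarities matter when several related reference signatures (e.g. the
    mismatch-repair group) score highly.
    """
    if signature.taxonomy.name != catalog.taxonomy.name:
        raise ValueError(
            f"signature taxonomy {signature.taxonomy.name!r} does not match "
            f"catalog taxonomy {catalog.taxonomy.name!r}"
        )
    cosines = {
        name: cosine_similarity(signature.weights, catalog.matrix[:, j])
        for j, name in enumerate(catalog.names)
    }
    return SimilarityReport(query_name, cosines)
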