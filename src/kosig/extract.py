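"""Step 3 — background-exposure estimation and knockout-signature extraction.

The subclone centroid spectrum is modelled as a linear combination of the
pooled parental (background) profile and the knockout profile:

    M_s_bar ≈ e_p · P_p_bar + e_ko · P_ko

The background exposure e_p starts at the centroid total and is decremented
until bootstrapped background profiles of size e_p become compatible with the
per-channel bootstrap boundaries of the subclone spectrum; the knockout
signature is then the clipped, renormalized residual
P_ko ≈ (M_s_bar − e_p · P_p_bar) / e_ko.

Compatibility is judged against the upper channel boundaries: the background
component of a channel can never exceed what the subclone spectrum
accommodates, but it may legitimately fall below the lower boundary wherever
the knockout process contributes the remainder. (Requiring the two-sided
interval in every channel would make the iteration unsatisfiable whenever the
knockout signature has support the background lacks; the lower boundaries are
still computed and can be enforced with ``enforce_lower=True`` for
diagnostics.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .catalog import CatalogMatrix
from .taxonomy import ChannelTaxonomy


@dataclass
class SignatureProfile:
    """A non-negative, unit-sum channel weight vector."""

    taxonomy: ChannelTaxonomy
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.taxonomy.K,):
            raise ValueError(
                f"expected {self.taxonomy.K} weights, got {self.weights.shape}"
            )
        if (self.weights < 0).any():
            raise ValueError("signature weights must be non-negative")
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("signature weights sum to zero")
        if abs(s - 1.0) > 1e-9:
            self.weights = self.weights / s

    def to_tsv(self, path, name: str = "signature"):
        import pandas as pd

        pd.DataFrame({name: self.weights}, index=list(self.taxonomy.labels)).to_csv(
            path, sep="\t", index_label="channel", float_format="%.8g")


@dataclass
class ChannelBoundaries:
    """Per-channel lower/upper count bounds (99% CI by default) obtained by
    multinomial bootstrap of the subclone centroid."""

    lower: np.ndarray
    upper: np.ndarray
    ci_level: float

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=np.int64)
        self.upper = np.asarray(self.upper, dtype=np.int64)
        if (self.lower > self.upper).any():
            raise ValueError("lower boundary exceeds upper boundary")
        if (self.lower < 0).any():
            raise ValueError("boundaries must be non-negative integers")


@dataclass
class ExtractionResult:
    e_p: int
    e_ko: int
    signature: SignatureProfile
    iterations: int = 0
    acceptance_fraction: float = float("nan")

    @property
    def centroid_total(self) -> int:
        return self.e_p + self.e_ko


def parental_mean_profile(parental_catalog: CatalogMatrix) -> SignatureProfile:
    """Pooled parental background profile P_p_bar.

    Pooling weights each clone by its mutation total (sum of counts over
    clones, normalized), not an average of per-clone proportions.
    """
    pooled = parental_catalog.pooled_counts().astype(float)
    if pooled.sum() <= 0:
        raise ValueError("parental clones have no mutations to pool")
    return SignatureProfile(parental_catalog.taxonomy, pooled / pooled.sum())


def centroid_total_of(subclone_catalog: CatalogMatrix) -> int:
    """Rounded mean of the subclone totals (the centroid's mutation number)."""
    return int(round(float(subclone_catalog.totals().mean())))


def subclone_channel_boundaries(subclone_catalog: CatalogMatrix,
                                n_boot: int = 10_000,
                                ci_level: float = 0.99,
                                rng: np.random.Generator | None = None,
                                per_subclone: bool = False
                                ) -> ChannelBoundaries:
    """Empirical per-channel count boundaries of the subclone spectrum.

    By default bootstraps the centroid count vector (multinomial of size =
    rounded mean total with the centroid proportions) and takes the outer
    (1−ci)/2 and 1−(1−ci)/2 order statistics per channel. With
    ``per_subclone=True`` each subclone is bootstrapped at its own total and
    proportions and the replicate distributions are pooled, giving wider
    bounds that also reflect between-subclone variation.
    """
    if len(subclone_catalog) == 0:
        raise ValueError("no subclones")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    total = centroid_total_of(subclone_catalog)
    if total <= 0:
        raise ValueError("subclone centroid total is zero")
    if per_subclone:
        n_each = max(n_boot // len(subclone_catalog), 1)
        reps = np.concatenate([
            rng.multinomial(s.total, s.counts / s.total, size=n_each)
            for s in subclone_catalog.samples
        ])
    else:
        probs = subclone_catalog.centroid()
        reps = rng.multinomial(total, probs, size=n_boot)
    tail = (1.0 - ci_level) / 2.0
    lower = np.percentile(reps, 100 * tail, axis=0, method="lower")
    upper = np.percentile(reps, 100 * (1 - tail), axis=0, method="higher")
    return ChannelBoundaries(lower, upper, ci_level)


def estimate_background_exposure(P_p: SignatureProfile | np.ndarray,
                                 centroid_total: int,
                                 boundaries: ChannelBoundaries,
                                 n_profiles: int = 100,
                                 accept_min: int = 5,
                                 step: int = 1,
                                 rng: np.random.Generator | None = None,
                                 enforce_lower: bool = False,
                                 _block: int = 64) -> tuple[int, dict]:
    """Iterative quantile search for the background exposure e_p.

    Starting at e_p = centroid_total, each iteration draws ``n_profiles``
    multinomial background profiles of size e_p from P_p; the first e_p at
    which at least ``accept_min`` profiles fall within the subclone channel
    boundaries is returned. If no e_p satisfies the criterion the search ends
    at 0 with a warning. Candidate values are evaluated in fixed descending
    order against a single RNG stream (profiles for blocks of consecutive
    candidates are drawn in one vectorised call), so a given seed always
    reproduces the same e_p.

    Returns ``(e_p, info)`` where info carries the iteration count and the
    acceptance fraction at the stopping value.
    """
    if step <= 0:
        raise ValueError("step must be a positive integer")
    probs = P_p.weights if isinstance(P_p, SignatureProfile) else np.asarray(P_p, float)
    if rng is None:
        rng = np.random.default_rng()
    candidates = np.arange(int(centroid_total), 0, -int(step), dtype=np.int64)
    iterations = 0
    for start in range(0, len(candidates), _block):
        block = candidates[start:start + _block]
        sizes = np.repeat(block, n_profiles)
        draws = rng.multinomial(sizes, probs)
        inside = (draws <= boundaries.upper[None, :]).all(axis=1)
        if enforce_lower:
            inside &= (draws >= boundaries.lower[None, :]).all(axis=1)
        accepted = inside.reshape(len(block), n_profiles).sum(axis=1)
        for j, e_p in enumerate(block):
            iterations += 1
            if accepted[j] >= accept_min:
                return int(e_p), {
                    "iterations": iterations,
                    "acceptance_fraction": float(accepted[j]) / n_profiles,
                }
    warnings.warn(
        "no background exposure satisfied the boundary criterion; returning 0",
        RuntimeWarning,
    )
    return 0, {"iterations": iterations, "acceptance_fraction": 0.0}


def extract_signature(subclone_catalog: CatalogMatrix,
                      P_p: SignatureProfile,
                      e_p: int,
                      iterations: int = 0,
                      acceptance_fraction: float = float("nan")
                      ) -> ExtractionResult:
    """Knockout signature from the subclone centroid by background removal.

    The residual M_s_bar − e_p · P_p_bar is clipped at zero per channel and
    renormalized to unit sum. e_ko = centroid_total − e_p, exactly.
    """
    total = centroid_total_of(subclone_catalog)
    if e_p > total:
        raise ValueError(f"e_p ({e_p}) exceeds the centroid total ({total})")
    e_ko = total - int(e_p)
    if e_ko == 0:
        raise ValueError("no knockout exposure; extraction undefined")
    centroid_counts = subclone_catalog.centroid() * total
    residual = np.clip(centroid_counts - e_p * P_p.weights, 0.0, None)
    if residual.sum() <= 0:
        raise ValueError("background removal left an empty residual")
    signature = SignatureProfile(subclone_catalog.taxonomy,
                                 residual / residual.sum())
    return ExtractionResult(int(e_p), e_ko, signature, iterations,
                            acceptance_fraction)


def extract_knockout_signature(subclone_catalog: CatalogMatrix,
                               parental_catalog: CatalogMatrix,
                               n_boot: int = 10_000,
                               ci_level: float = 0.99,
                               n_profiles: int = 100,
                               accept_min: int = 5,
                               step: int = 1,
                               rng: np.random.Generator | None = None
                               ) -> ExtractionResult:
    """Full step-3 pipeline: boundaries → e_p search → residual signature."""
    if rng is None:
        rng = np.random.default_rng()
    P_p = parental_mean_profile(parental_catalog)
    bounds = subclone_channel_boundaries(subclone_catalog, n_boot, ci_level, rng)
    total = centroid_total_of(subclone_catalog)
    e_p, info = estimate_background_exposure(
        P_p, total, bounds, n_profiles, accept_min, step, rng)
    return extract_signature(subclone_catalog, P_p, e_p,
                             iterations=info["iterations"],
                             acceptance_fraction=info["acceptance_fraction"])


def mutations_per_division(e_ko: float, divisions: float) -> float:
    """Knockout-attributed mutations per cell division.

    e_ko is per-centroid (a per-subclone average), so the rate is simply
    e_ko / divisions; the experimental design corresponds to roughly 36
    divisions over one month of culture.
    """
    if divisions <= 0:
        raise ValueError("divisions must be positive")
    return float(e_ko) / float(divisions)
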