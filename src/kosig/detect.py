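"""Steps 1 and 2 of the knockout-signature workflow.

Step 1 (spectrum shift): multinomial bootstrap clouds are built around the
parental clones and around each knockout's subclones; a knockout's spectrum is
called shifted when the observed parental↔subclone centroid distance d_ps
exceeds both empirical 1% null thresholds, d_ps > d_pc_0.01 and
d_ps > d_sc_0.01 (strict inequalities; ties are non-shifted).

Step 2 (count elevation): per-subclone de novo totals of all non-shifted
knockouts form a baseline pool; bootstrap aggregates from that pool give an
empirical p-value for a knockout's observed aggregate count.

Distances are Euclidean (Frobenius) norms between unit-sum profile centroids,
making them comparable across samples with different mutation burdens; raw
count-space distances are available behind ``normalize=False`` for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import CatalogMatrix


@dataclass
class BootstrapConfig:
    """Bootstrap sizes for the spectrum-shift and count-elevation tests.

    Defaults are the published procedure: 7000 replicates per parental clone
    (nine clones → one shared 63,000-replicate pool), 9000 per subclone,
    draws of 7 from the parental pool and 9 from the subclone pool, 10,000
    distance samples, and alpha = 0.01. The draw sizes of 7 and 9 are kept as
    printed even though they look swapped relative to the group sizes; both
    are configurable.
    """

    n_reps_per_parental: int = 7000
    n_reps_per_subclone: int = 9000
    n_draw_parental: int = 7
    n_draw_subclone: int = 9
    n_distance_samples: int = 10_000
    n_count_boot: int = 10_000
    alpha: float = 0.01
    seed: int | None = None
    normalize: bool = True

    def __post_init__(self):
        for name in ("n_reps_per_parental", "n_reps_per_subclone",
                     "n_draw_parental", "n_draw_subclone",
                     "n_distance_samples", "n_count_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ShiftTestResult:
    d_ps: float
    d_pc_alpha: float
    d_sc_alpha: float
    d_pc_distribution: np.ndarray
    d_sc_distribution: np.ndarray
    alpha: float

    @property
    def shifted(self) -> bool:
        return bool(self.d_ps > self.d_pc_alpha and self.d_ps > self.d_sc_alpha)


@dataclass
class CountTestResult:
    observed_aggregate: float
    p_value: float
    n_target: int
    baseline_mean: float
    baseline_quantiles: dict = field(default_factory=dict)


@dataclass
class ClassCall:
    """Decision for one knockout in one mutation class."""

    shifted: bool
    count_p_value: float
    alpha: float
    shift: ShiftTestResult | None = None
    count: CountTestResult | None = None

    @property
    def has_signature(self) -> bool:
        return bool(self.shifted and self.count_p_value < self.alpha)

    @property
    def reason(self) -> str:
        if self.has_signature:
            return "spectrum shifted and mutation count elevated"
        if not self.shifted and self.count_p_value < self.alpha:
            return "count elevated but no spectrum shift"
        if self.shifted:
            return (f"spectrum shifted but count not elevated "
                    f"(p = {self.count_p_value:.4g} >= {self.alpha})")
        return "no spectrum shift and no count elevation"


@dataclass
class KnockoutCall:
    """Per-class decisions for one gene knockout."""

    knockout: str
    calls: dict[str, ClassCall] = field(default_factory=dict)

    def has_signature(self, mutation_class: str) -> bool:
        return self.calls[mutation_class].has_signature


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def normalize_profile(counts) -> np.ndarray:
    """Unit-sum proportion vector of a non-negative count vector."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot normalize an all-zero count vector")
    return counts / total


def profile_distance(a_counts, b_counts, normalize: bool = True) -> float:
    """Euclidean (Frobenius) distance between two profiles.

    With ``normalize=True`` (default) both inputs are first scaled to unit
    sum, so the distance lives in spectrum space and is burden-independent.
    """
    a = np.asarray(a_counts, dtype=float)
    b = np.asarray(b_counts, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share one taxonomy")
    if normalize:
        a, b = normalize_profile(a), normalize_profile(b)
    return float(np.linalg.norm(a - b))


def bootstrap_profiles(counts, n_reps: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial bootstrap replicates of one sample's channel counts.

    Each replicate is a multinomial draw of size equal to the sample total
    with probabilities equal to the sample proportions, so replicate totals
    conserve the original total exactly.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("cannot bootstrap a zero-total sample")
    return rng.multinomial(total, counts / total, size=n_reps)


def empirical_upper_quantile(values: np.ndarray, alpha: float) -> float:
    """Floor-rank empirical (1 - alpha) quantile of a distance distribution."""
    values = np.sort(np.asarray(values, dtype=float))
    idx = int(np.floor((1.0 - alpha) * len(values)))
    return float(values[min(idx, len(values) - 1)])


def _centroid_distance_distribution(pool_props: np.ndarray, n_draw: int,
                                    n_samples: int, ref_centroid: np.ndarray,
                                    rng: np.random.Generator) -> np.ndarray:
    """Distances from centroids of random pool draws to a reference centroid.

    Each of ``n_samples`` rounds selects ``n_draw`` distinct replicates from
    the pool; duplicates within a round are resampled so each round is a
    without-replacement draw.
    """
    n_pool = pool_props.shape[0]
    if n_draw > n_pool:
        raise ValueError("draw size exceeds pool size")
    idx = rng.integers(0, n_pool, size=(n_samples, n_draw))
    # reject rounds containing duplicate replicates and redraw them
    for _ in range(64):
        srt = np.sort(idx, axis=1)
        bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
        if not bad.any():
            break
        idx[bad] = rng.integers(0, n_pool, size=(int(bad.sum()), n_draw))
    centroids = pool_props[idx].mean(axis=1)
    return np.linalg.norm(centroids - ref_centroid[None, :], axis=1)


# ---------------------------------------------------------------------------
# step 1: spectrum shift
# ---------------------------------------------------------------------------


@dataclass
class ParentalNull:
    """The shared parental bootstrap cloud and its distance threshold.

    The pool spans all parental clones jointly (nine clones → one pooled
    63,000-replicate distribution), so d_pc_alpha is global across knockouts.
    """

    centroid: np.ndarray
    d_pc_alpha: float
    d_pc_distribution: np.ndarray
    alpha: float


def build_parental_null(parental_catalog: CatalogMatrix,
                        config: BootstrapConfig,
                        rng: np.random.Generator | None = None) -> ParentalNull:
    """Bootstrap the parental clones and locate the d_pc alpha threshold."""
    if len(parental_catalog) < 2:
        raise ValueError("need at least two parental clones")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    reps = np.concatenate([
        bootstrap_profiles(s.counts, config.n_reps_per_parental, rng)
        for s in parental_catalog.samples
    ])
    props = (reps / reps.sum(axis=1, keepdims=True) if config.normalize
             else reps.astype(float))
    centroid = (parental_catalog.centroid() if config.normalize
                else parental_catalog.centroid_counts())
    d_pc = _centroid_distance_distribution(
        props, config.n_draw_parental, config.n_distance_samples, centroid, rng)
    return ParentalNull(centroid, empirical_upper_quantile(d_pc, config.alpha),
                        d_pc, config.alpha)


def spectrum_shift_test(parental_catalog: CatalogMatrix,
                        subclone_catalog: CatalogMatrix,
                        config: BootstrapConfig | None = None,
                        parental_null: ParentalNull | None = None,
                        rng: np.random.Generator | None = None) -> ShiftTestResult:
    """Decide whether a knockout's subclones diverge in mutation spectrum.

    ``parental_null`` can be precomputed once with :func:`build_parental_null`
    and shared across knockouts; when omitted it is built here from the
    parental catalog.
    """
    config = config or BootstrapConfig()
    if parental_catalog.taxonomy.name != subclone_catalog.taxonomy.name:
        raise ValueError("parental and subclone catalogs use different taxonomies")
    if len(subclone_catalog) < 2:
        raise ValueError("need at least two subclones")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if parental_null is None:
        parental_null = build_parental_null(parental_catalog, config, rng)

    reps = np.concatenate([
        bootstrap_profiles(s.counts, config.n_reps_per_subclone, rng)
        for s in subclone_catalog.samples
    ])
    props = (reps / reps.sum(axis=1, keepdims=True) if config.normalize
             else reps.astype(float))
    sub_centroid = (subclone_catalog.centroid() if config.normalize
                    else subclone_catalog.centroid_counts())
    d_sc = _centroid_distance_distribution(
        props, config.n_draw_subclone, config.n_distance_samples, sub_centroid, rng)

    d_ps = float(np.linalg.norm(parental_null.centroid - sub_centroid))
    return ShiftTestResult(
        d_ps=d_ps,
        d_pc_alpha=parental_null.d_pc_alpha,
        d_sc_alpha=empirical_upper_quantile(d_sc, config.alpha),
        d_pc_distribution=parental_null.d_pc_distribution,
        d_sc_distribution=d_sc,
        alpha=config.alpha,
    )


# ---------------------------------------------------------------------------
# step 2: count elevation
# ---------------------------------------------------------------------------


def count_elevation_test(target_subclone_totals, baseline_subclone_totals,
                         n_boot: int = 10_000,
                         rng: np.random.Generator | None = None) -> CountTestResult:
    """Empirical p-value for an elevated aggregate de novo mutation count.

    The baseline pool holds per-subclone totals of all knockouts without a
    spectrum shift. Each bootstrap aggregate sums ``len(target)`` draws with
    replacement from the pool; the p-value uses the add-one estimator
    p = (1 + #{aggregate >= observed}) / (1 + n_boot), so it is never zero.
    """
    target = np.asarray(target_subclone_totals, dtype=float)
    baseline = np.asarray(baseline_subclone_totals, dtype=float)
    if baseline.size == 0:
        raise ValueError(
            "empty baseline pool: no knockouts without a spectrum shift; "
            "supply an external baseline of per-subclone de novo totals"
        )
    if rng is None:
        rng = np.random.default_rng()
    observed = float(target.sum())
    aggregates = rng.choice(baseline, size=(n_boot, target.size), replace=True).sum(axis=1)
    p = (1.0 + float((aggregates >= observed).sum())) / (1.0 + n_boot)
    qs = np.quantile(aggregates, [0.01, 0.05, 0.5, 0.95, 0.99])
    return CountTestResult(
        observed_aggregate=observed,
        p_value=p,
        n_target=int(target.size),
        baseline_mean=float(baseline.mean()),
        baseline_quantiles={q: float(v) for q, v in zip((0.01, 0.05, 0.5, 0.95, 0.99), qs)},
    )


# ---------------------------------------------------------------------------
# combined call
# ---------------------------------------------------------------------------


def call_knockout(shift_result: ShiftTestResult, count_result: CountTestResult,
                  alpha: float = 0.01) -> ClassCall:
    """Combine both tests: a knockout has a signature in this mutation class
    only when the spectrum is shifted AND the count p-value is strictly below
    alpha. A shift without count elevation (or the converse) is a negative
    call with the reason recorded."""
    if shift_result is None or count_result is None:
        raise ValueError("both test results are required")
    return ClassCall(
        shifted=shift_result.shifted,
        count_p_value=count_result.p_value,
        alpha=alpha,
        shift=shift_result,
        count=count_result,
    )
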