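"""Self-contained evaluation studies of the pipeline on synthetic data.

Each study simulates data under known generating conditions with the
package's own generator, runs the relevant part of the pipeline, and returns
summary numbers (error rates, detection rates, recovery accuracy). They are
used by the acceptance checks and are convenient for sensitivity analyses.

Study problem sizes default to reduced bootstrap sizes (1000 replicates per
sample, 2000 distance samples) so a full battery runs in minutes on one core;
the detection behaviour at these sizes is indistinguishable from the full
published sizes for the effect magnitudes studied here.
"""

from __future__ import annotations

import numpy as np

from .catalog import build_catalog
from .detect import (
    BootstrapConfig,
    build_parental_null,
    call_knockout,
    count_elevation_test,
    spectrum_shift_test,
)
from .extract import centroid_total_of, extract_knockout_signature
from .similarity import cosine_similarity
from .simulate import (
    ToyGenome,
    make_toy_genome,
    msh6_like_substitution_profile,
    scenario_config,
    simulate_catalogs,
    simulate_variant_records,
)
from .topography import (
    StrandAssignment,
    strand_asymmetry_test,
    timing_density,
)
from .variant_io import SubstitutionRecord

REDUCED_SIZES = dict(n_reps_per_parental=1000, n_reps_per_subclone=1000,
                     n_distance_samples=2000)


def null_type1_study(n_knockouts: int = 200,
                     classes=("substitution", "indel", "rearrangement"),
                     alpha: float = 0.01,
                     seed: int = 0) -> dict[str, float]:
    """False-positive rate of the combined call on null knockouts.

    Simulates one shared parental set and ``n_knockouts`` knockouts whose
    subclones carry background mutagenesis only (e_ko = 0) at study-scale
    burdens, runs the full two-step decision per class, and returns the
    fraction of knockouts called as having a signature.
    """
    rng = np.random.default_rng(seed)
    fractions = {}
    for cls in classes:
        boot = BootstrapConfig(alpha=alpha, **REDUCED_SIZES)
        parental, _, _ = simulate_catalogs(scenario_config("null", cls), rng)
        null = build_parental_null(parental, boot, rng)
        shifts, catalogs = [], []
        for _ in range(n_knockouts):
            _, sub, _ = simulate_catalogs(scenario_config("null", cls), rng)
            catalogs.append(sub)
            shifts.append(spectrum_shift_test(parental, sub, boot,
                                              parental_null=null, rng=rng))
        baseline = np.concatenate([
            c.totals() for c, s in zip(catalogs, shifts) if not s.shifted
        ]) if any(not s.shifted for s in shifts) else np.array([])
        hits = 0
        for sub, shift in zip(catalogs, shifts):
            if not shift.shifted:
                continue  # conjunction already fails
            count = count_elevation_test(sub.totals(), baseline, rng=rng)
            hits += call_knockout(shift, count, alpha).has_signature
        fractions[cls] = hits / n_knockouts
    return fractions


def power_recovery_study(n_runs: int = 100, seed: int = 0,
                         alpha: float = 0.01) -> dict[str, float]:
    """Detection power and extraction accuracy on a strong MMR-like effect.

    Each run simulates a knockout with substitution exposure three times the
    background mean and a knockout profile nearly orthogonal to the
    background, alongside three null knockouts that provide the count-test
    baseline. Returns the detection rate, the median cosine between the
    extracted and generating knockout signature, and the median relative
    error of the recovered background exposure e_p against the generating
    background mean.
    """
    rng = np.random.default_rng(seed)
    boot = BootstrapConfig(alpha=alpha, **REDUCED_SIZES)
    parental, _, _ = simulate_catalogs(
        scenario_config("null", "substitution"), rng)
    null = build_parental_null(parental, boot, rng)
    truth_profile = msh6_like_substitution_profile().weights
    detected, cosines, ep_errors = 0, [], []
    for _ in range(n_runs):
        cfg = scenario_config("msh6", "substitution")
        _, target, truth = simulate_catalogs(cfg, rng)
        baseline = np.concatenate([
            simulate_catalogs(scenario_config("null", "substitution"),
                              rng)[1].totals()
            for _ in range(3)
        ])
        shift = spectrum_shift_test(parental, target, boot,
                                    parental_null=null, rng=rng)
        count = count_elevation_test(target.totals(), baseline, rng=rng)
        call = call_knockout(shift, count, alpha)
        detected += call.has_signature
        ext = extract_knockout_signature(target, parental, rng=rng)
        assert ext.e_p + ext.e_ko == centroid_total_of(target)
        cosines.append(cosine_similarity(ext.signature.weights, truth_profile))
        ep_errors.append(ext.e_p / cfg.background_mean - 1.0)
    return {
        "n_runs": n_runs,
        "detection_rate": detected / n_runs,
        "median_signature_cosine": float(np.median(cosines)),
        "median_ep_relative_error": float(np.median(ep_errors)),
        "true_e_ko": scenario_config("msh6", "substitution").e_ko,
    }


def replication_asymmetry_study(n_seeds: int = 100, fold: float = 1.4,
                                leading_mean: float = 100.0,
                                n_subclones: int = 7,
                                seed: int = 0) -> dict[str, float]:
    """Recovery of a planted lagging-strand excess.

    Each seed draws per-subclone C>T counts as Poisson(leading_mean) on the
    leading strand and Poisson(fold * leading_mean) on the lagging strand,
    then runs the paired strand-asymmetry test. Returns the median estimated
    fold and the fraction of seeds with fold in [fold-0.15, fold+0.15] and
    p < 0.05.
    """
    rng = np.random.default_rng(seed)
    rec = SubstitutionRecord("sim1", 2, "C", "T")
    folds, ok = [], 0
    for _ in range(n_seeds):
        data = {}
        for i in range(n_subclones):
            n_lag = int(rng.poisson(fold * leading_mean))
            n_lead = int(rng.poisson(leading_mean))
            data[f"s{i}"] = (
                [StrandAssignment(rec, "lagging", "C>T")] * n_lag
                + [StrandAssignment(rec, "leading", "C>T")] * n_lead)
        res = strand_asymmetry_test(data, "replication")["C>T"]
        folds.append(res.fold)
        ok += (fold - 0.15 <= res.fold <= fold + 0.15) and res.p_value < 0.05
    return {
        "n_seeds": n_seeds,
        "median_fold": float(np.median(folds)),
        "success_fraction": ok / n_seeds,
    }


def flat_timing_study(n_records: int = 20_000, seed: int = 0,
                      genome: ToyGenome | None = None) -> dict[str, float]:
    """Normalized timing densities for uniformly placed mutations.

    Uniform positions over a genome with ten equal timing deciles should give
    normalized densities near 1 in every decile; returns the maximum absolute
    deviation from 1.
    """
    rng = np.random.default_rng(seed)
    genome = genome or make_toy_genome(length=200_000, seed=7)
    contig = next(iter(genome.contigs))
    length = len(genome.contigs[contig])
    seq = genome.contigs[contig]
    records = []
    for p in rng.integers(2, length, size=n_records):
        records.append(SubstitutionRecord(contig, int(p), seq[int(p) - 1],
                                          "A" if seq[int(p) - 1] != "A" else "C"))
    td = timing_density(records, genome.timing_track)
    return {
        "n_records": n_records,
        "max_abs_deviation": float(np.max(np.abs(td.densities - 1.0))),
    }


def record_roundtrip_study(seed: int = 0,
                           genome: ToyGenome | None = None) -> dict[str, int]:
    """Exactness of the record-level round trip per mutation class.

    Simulates variant records for each class, rebuilds the channel catalog
    from them, and counts the classes whose rebuilt counts equal the
    generating counts in every sample and channel.
    """
    genome = genome or make_toy_genome(length=200_000, seed=7)
    exact = 0
    scenarios = {"substitution": "msh6", "indel": "fancc",
                 "rearrangement": "exo1"}
    for cls, scen in scenarios.items():
        cfg = scenario_config(scen, cls, seed=seed)
        cfg.n_parental, cfg.n_subclones = 2, 3
        records, _, truth = simulate_variant_records(cfg, genome)
        cat = build_catalog(records, cls, reference=genome.reference)
        if not cat.rejects and all(
                (s.counts == truth.channel_counts[s.sample_id]).all()
                for s in cat.samples):
            exact += 1
    return {"classes_tested": len(scenarios), "classes_exact": exact}
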