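"""Synthetic clone/subclone data with known ground truth.

The generator emulates the experimental design this package analyses: a set
of parental clones (default nine) sharing a pervasive culture background
signature, and seven subclones per knockout that carry the same background
plus, optionally, a knockout signature mixed in at a chosen exposure.

Two levels are supported:

* channel-count level (:func:`simulate_catalogs`) — multinomial channel
  counts with negative-binomial between-sample burden variability, the input
  the statistical pipeline actually consumes;
* variant-record level (:func:`simulate_variant_records`) — concrete
  substitution/indel/rearrangement records placed on a toy genome whose
  sites are chosen so every record classifies back to the channel drawn for
  it, exercising the full classification path end to end.

Default background burdens are ~1200 substitutions, ~60 indels and ~6
rearrangements per sample — the background levels the experimental system
exhibits — and the default substitution background concentrates on C>A
channels with its tallest peaks at TCT, GCA, GCT and ACA in decreasing
order, echoing the culture (oxidative-damage-like) signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .catalog import CatalogMatrix, SampleCatalog, classify_indel
from .extract import SignatureProfile
from .taxonomy import (
    BASES,
    ChannelTaxonomy,
    INDEL_8,
    REARRANGEMENT_10,
    SUBSTITUTION_96,
    get_taxonomy,
    revcomp,
)
from .variant_io import (
    DomainTrack,
    IndelRecord,
    InMemoryReference,
    RearrangementRecord,
    SignatureCatalog,
    SubstitutionRecord,
)

BACKGROUND_MEANS = {"substitution": 1200.0, "indel": 60.0, "rearrangement": 6.0}


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

_BG_SUB_PEAKS = {  # decreasing order, on top of a modest C>A plateau
    "T[C>A]T": 0.14,
    "G[C>A]A": 0.12,
    "G[C>A]T": 0.10,
    "A[C>A]A": 0.08,
}
_BG_SUB_CA_PLATEAU = 0.025  # the other twelve C>A channels
_BG_SUB_FLOOR_MASS = 0.26  # spread over the remaining 80 channels


def default_background_profile(taxonomy: str | ChannelTaxonomy) -> SignatureProfile:
    """The culture-background substitution profile used by default.

    A C>A-dominated 96-channel profile (aggregate C>A mass 0.74) whose four
    tallest peaks are T[C>A]T > G[C>A]A > G[C>A]T > A[C>A]A, with a small
    uniform floor elsewhere.
    """
    taxonomy = get_taxonomy(taxonomy) if isinstance(taxonomy, str) else taxonomy
    if taxonomy.name != "substitution":
        raise ValueError(
            f"no default background profile for taxonomy {taxonomy.name!r}"
        )
    w = np.full(taxonomy.K, _BG_SUB_FLOOR_MASS / 80.0)
    for label in taxonomy.labels:
        if "[C>A]" in label:
            w[taxonomy.index(label)] = _BG_SUB_CA_PLATEAU
    for label, weight in _BG_SUB_PEAKS.items():
        w[taxonomy.index(label)] = weight
    return SignatureProfile(taxonomy, w)


def _profile_from_dict(taxonomy: ChannelTaxonomy,
                       weights: Mapping[str, float],
                       floor: float = 0.0) -> SignatureProfile:
    w = np.full(taxonomy.K, floor, dtype=float)
    for label, value in weights.items():
        w[taxonomy.index(label)] = value
    return SignatureProfile(taxonomy, w / w.sum())


def _sub_type_block(sub: str, weight_each: float) -> dict[str, float]:
    return {label: weight_each for label in SUBSTITUTION_96.labels
            if f"[{sub}]" in label}


def msh6_like_substitution_profile() -> SignatureProfile:
    """A mismatch-repair-deficiency-like profile: C>T and T>C dominated,
    nearly orthogonal to the C>A-rich background (cosine < 0.1)."""
    weights = {**_sub_type_block("C>T", 0.04), **_sub_type_block("T>C", 0.02)}
    return _profile_from_dict(SUBSTITUTION_96, weights, floor=0.000625)


def exo1_like_substitution_profile() -> SignatureProfile:
    """C>A-leaning profile with peaks at GCT, GCC and TCT plus smaller
    C>G/C>T/T>C contributions."""
    weights = {
        "G[C>A]T": 0.12, "G[C>A]C": 0.10, "T[C>A]T": 0.09,
        **_sub_type_block("C>G", 0.012),
        **_sub_type_block("C>T", 0.015),
        **_sub_type_block("T>C", 0.012),
    }
    return _profile_from_dict(SUBSTITUTION_96, weights, floor=0.002)


DEFAULT_BACKGROUND_INDEL = _profile_from_dict(INDEL_8, {
    "ins_1bp": 0.35, "ins_ge2bp": 0.05, "del_mh_2bp": 0.03, "del_mh_ge3bp": 0.07,
    "del_rep_1bp": 0.30, "del_rep_ge2bp": 0.10, "del_other": 0.08, "complex": 0.02,
})

MSH6_LIKE_INDEL = _profile_from_dict(INDEL_8, {
    "ins_1bp": 0.05, "ins_ge2bp": 0.01, "del_mh_2bp": 0.01, "del_mh_ge3bp": 0.01,
    "del_rep_1bp": 0.75, "del_rep_ge2bp": 0.13, "del_other": 0.03, "complex": 0.01,
})

FANCC_LIKE_INDEL = _profile_from_dict(INDEL_8, {
    "ins_1bp": 0.02, "ins_ge2bp": 0.02, "del_mh_2bp": 0.10, "del_mh_ge3bp": 0.70,
    "del_rep_1bp": 0.05, "del_rep_ge2bp": 0.05, "del_other": 0.05, "complex": 0.01,
})

DEFAULT_BACKGROUND_REARRANGEMENT = _profile_from_dict(REARRANGEMENT_10, {
    "deletion_1-10kb": 0.15, "deletion_10kb-1Mb": 0.10, "deletion_>1Mb": 0.05,
    "inversion_1-10kb": 0.10, "inversion_10kb-1Mb": 0.05, "inversion_>1Mb": 0.05,
    "tandem-duplication_1-10kb": 0.15, "tandem-duplication_10kb-1Mb": 0.10,
    "tandem-duplication_>1Mb": 0.05, "translocation": 0.20,
})

EXO1_LIKE_REARRANGEMENT = _profile_from_dict(REARRANGEMENT_10, {
    "deletion_1-10kb": 0.05, "deletion_10kb-1Mb": 0.03, "deletion_>1Mb": 0.02,
    "inversion_1-10kb": 0.05, "inversion_10kb-1Mb": 0.03, "inversion_>1Mb": 0.02,
    "tandem-duplication_1-10kb": 0.10, "tandem-duplication_10kb-1Mb": 0.60,
    "tandem-duplication_>1Mb": 0.05, "translocation": 0.05,
})

FANCC_LIKE_REARRANGEMENT = _profile_from_dict(REARRANGEMENT_10, {
    "deletion_1-10kb": 0.30, "deletion_10kb-1Mb": 0.15, "deletion_>1Mb": 0.05,
    "inversion_1-10kb": 0.10, "inversion_10kb-1Mb": 0.05, "inversion_>1Mb": 0.05,
    "tandem-duplication_1-10kb": 0.15, "tandem-duplication_10kb-1Mb": 0.05,
    "tandem-duplication_>1Mb": 0.05, "translocation": 0.05,
})

DEFAULT_BACKGROUNDS = {
    "substitution": None,  # built lazily by default_background_profile
    "indel": DEFAULT_BACKGROUND_INDEL,
    "rearrangement": DEFAULT_BACKGROUND_REARRANGEMENT,
}


def background_profile(mutation_class: str) -> SignatureProfile:
    if mutation_class == "substitution":
        return default_background_profile(SUBSTITUTION_96)
    return DEFAULT_BACKGROUNDS[mutation_class]


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Generating conditions for one knockout in one mutation class.

    ``background_mean`` is the expected background burden per sample;
    between-sample totals follow a negative binomial with coefficient of
    variation ``background_cv`` (default 0.15, matching the between-subclone
    consistency of the experimental system; a Poisson is used when the target
    variance does not exceed the mean). ``e_ko`` is the knockout exposure per
    subclone (0 for null scenarios).
    """

    taxonomy: ChannelTaxonomy
    p_bg: SignatureProfile
    p_ko: SignatureProfile | None = None
    background_mean: float = 1200.0
    background_cv: float = 0.15
    e_ko: int = 0
    n_parental: int = 9
    n_subclones: int = 7
    seed: int | None = None
    name: str = "KO"

    def __post_init__(self):
        if self.e_ko < 0 or self.background_mean <= 0:
            raise ValueError("exposures must be non-negative and mean positive")
        if self.background_cv < 0:
            raise ValueError("invalid dispersion")
        if self.e_ko > 0 and self.p_ko is None:
            raise ValueError("e_ko > 0 requires a knockout profile")


@dataclass
class SimulationTruth:
    """The generating configuration plus realized per-sample exposures."""

    config: SimulationConfig
    parental_totals: np.ndarray
    subclone_background_totals: np.ndarray
    subclone_ko_exposures: np.ndarray
    channel_counts: dict = field(default_factory=dict)  # record-level sims only


def _draw_totals(mean: float, cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    var = (cv * mean) ** 2
    if var <= mean:
        return rng.poisson(mean, size=n).astype(np.int64)
    k = mean * mean / (var - mean)
    return rng.negative_binomial(k, k / (k + mean), size=n).astype(np.int64)


def simulate_catalogs(config: SimulationConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[CatalogMatrix, CatalogMatrix, SimulationTruth]:
    """Channel-count catalogs for parental clones and knockout subclones.

    Parental samples draw a background total and distribute it multinomially
    over the background profile; each subclone additionally receives a
    multinomial knockout component of size ``e_ko``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_bg = config.p_bg.weights
    par_totals = np.maximum(
        _draw_totals(config.background_mean, config.background_cv,
                     config.n_parental, rng), 1)
    parental = [
        SampleCatalog(f"P{i + 1}", rng.multinomial(int(t), p_bg), role="parental")
        for i, t in enumerate(par_totals)
    ]
    sub_bg_totals = np.maximum(
        _draw_totals(config.background_mean, config.background_cv,
                     config.n_subclones, rng), 1)
    ko_exposures = np.full(config.n_subclones, config.e_ko, dtype=np.int64)
    subclones = []
    for i, t in enumerate(sub_bg_totals):
        counts = rng.multinomial(int(t), p_bg)
        if config.e_ko > 0:
            counts = counts + rng.multinomial(config.e_ko, config.p_ko.weights)
        subclones.append(SampleCatalog(f"{config.name}_S{i + 1}", counts,
                                       role="subclone", knockout=config.name))
    truth = SimulationTruth(config, par_totals, sub_bg_totals, ko_exposures)
    return (CatalogMatrix(config.taxonomy, parental),
            CatalogMatrix(config.taxonomy, subclones), truth)


def scenario_config(scenario: str, mutation_class: str, seed: int | None = None,
                    name: str | None = None) -> SimulationConfig:
    """Named generating conditions.

    * ``null`` — background only (e_ko = 0);
    * ``msh6`` — strong mismatch-repair-like effect: e_ko three times the
      background mean for substitutions and indels, none for rearrangements;
    * ``exo1`` — modest elevation (1× background mean) in all classes;
    * ``fancc`` — indel (1×) and rearrangement (3×) effects only.
    """
    mean = BACKGROUND_MEANS[mutation_class]
    p_bg = background_profile(mutation_class)
    ko_profiles = {
        ("msh6", "substitution"): msh6_like_substitution_profile(),
        ("msh6", "indel"): MSH6_LIKE_INDEL,
        ("exo1", "substitution"): exo1_like_substitution_profile(),
        ("exo1", "indel"): MSH6_LIKE_INDEL,
        ("exo1", "rearrangement"): EXO1_LIKE_REARRANGEMENT,
        ("fancc", "indel"): FANCC_LIKE_INDEL,
        ("fancc", "rearrangement"): FANCC_LIKE_REARRANGEMENT,
    }
    multipliers = {
        ("msh6", "substitution"): 3.0, ("msh6", "indel"): 3.0,
        ("exo1", "substitution"): 1.0, ("exo1", "indel"): 1.0,
        ("exo1", "rearrangement"): 1.0,
        ("fancc", "indel"): 1.0, ("fancc", "rearrangement"): 3.0,
    }
    if scenario == "null":
        e_ko, p_ko = 0, None
    else:
        key = (scenario, mutation_class)
        if key not in multipliers:
            e_ko, p_ko = 0, None
        else:
            e_ko = int(round(multipliers[key] * mean))
            p_ko = ko_profiles[key]
    return SimulationConfig(
        taxonomy=get_taxonomy(mutation_class), p_bg=p_bg, p_ko=p_ko,
        background_mean=mean, e_ko=e_ko, seed=seed,
        name=name or scenario.upper(),
    )


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------


@dataclass
class ToyGenome:
    """A small synthetic genome with gene/replication/timing annotations.

    ``contigs`` hold actual sequence (used for substitution context and indel
    junction analysis). ``sv_contig_lengths`` declare coordinate space for
    rearrangement breakpoints only — rearrangement classification never
    consults sequence, so those contigs carry no bases.
    """

    contigs: dict[str, str]
    sv_contig_lengths: dict[str, int]
    gene_track: DomainTrack
    replication_track: DomainTrack
    timing_track: DomainTrack
    seed: int | None = None

    @property
    def reference(self) -> InMemoryReference:
        return InMemoryReference(self.contigs)


def make_toy_genome(length: int = 1_000_000, seed: int = 0,
                    gene_fraction: float = 0.10,
                    sv_contig_length: int = 6_000_000) -> ToyGenome:
    """Deterministic toy genome: one random contig with planted repeat
    tracts, 10% gene coverage (alternating strands), alternating 50 kb
    leading/lagging replication blocks and ten equal timing deciles."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length)
    # plant poly-A and CAG tracts so repeat-mediated deletion channels always
    # have eligible sites even on small genomes
    for start in range(200, length - 20, 2000):
        seq[start:start + 6] = list("AAAAAA")
        seq[start + 10:start + 19] = list("CAGCAGCAG")
    contig = "sim1"
    sequence = "".join(seq)

    window = max(length // 100, 100)
    gene_every = max(int(round(1.0 / gene_fraction)), 1)
    genes = []
    for i, start in enumerate(range(0, length - window + 1, window)):
        if i % gene_every == 0:
            genes.append((contig, start, start + window,
                          "+" if (i // gene_every) % 2 == 0 else "-"))
    repl_window = max(length // 20, 100)
    replication = [
        (contig, start, min(start + repl_window, length),
         "leading" if (start // repl_window) % 2 == 0 else "lagging")
        for start in range(0, length, repl_window)
    ]
    decile_len = length // 10
    timing = [(contig, d * decile_len,
               (d + 1) * decile_len if d < 9 else length, str(d + 1))
              for d in range(10)]
    return ToyGenome(
        contigs={contig: sequence},
        sv_contig_lengths={"sv1": sv_contig_length, "sv2": sv_contig_length},
        gene_track=DomainTrack(genes),
        replication_track=DomainTrack(replication),
        timing_track=DomainTrack(timing),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# record-level simulation
# ---------------------------------------------------------------------------

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _substitution_site_index(sequence: str) -> dict[tuple[str, str, str], np.ndarray]:
    """Map pyrimidine-frame (5', ref, 3') contexts to arrays of
    (1-based position, strand flag) over one contig."""
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8)
    to_idx = np.zeros(256, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        to_idx[ord(b)] = i
    comp_map = np.zeros(4, dtype=np.int64)  # complement in index space
    comp_map[[to_idx[ord(b)] for b in BASES]] = [to_idx[ord("T")], to_idx[ord("G")],
                                                 to_idx[ord("C")], to_idx[ord("A")]]
    five = to_idx[codes[:-2]]
    mid = to_idx[codes[1:-1]]
    three = to_idx[codes[2:]]
    is_pyr = (mid == _BASE_INDEX["C"]) | (mid == _BASE_INDEX["T"])
    # pyrimidine-frame context: flip purine-centred sites to the - strand
    f = np.where(is_pyr, five, comp_map[three])
    m = np.where(is_pyr, mid, comp_map[mid])
    t = np.where(is_pyr, three, comp_map[five])
    key_id = (m == _BASE_INDEX["T"]).astype(np.int64) * 16 + f * 4 + t
    positions = np.arange(2, len(sequence))  # 1-based middle position
    strands = np.where(is_pyr, 1, -1)
    order = np.argsort(key_id, kind="stable")
    sorted_keys = key_id[order]
    index: dict[tuple[str, str, str], np.ndarray] = {}
    bounds = np.searchsorted(sorted_keys, np.arange(33))
    for kid in range(32):
        lo, hi = bounds[kid], bounds[kid + 1]
        if lo == hi:
            continue
        ref = "T" if kid >= 16 else "C"
        f_b = BASES[(kid % 16) // 4]
        t_b = BASES[kid % 4]
        sel = order[lo:hi]
        index[(f_b, ref, t_b)] = np.stack(
            [positions[sel], strands[sel]], axis=1)
    return {k: v for k, v in index.items()}


def _emit_substitutions(channel_counts: np.ndarray, contig: str,
                        site_index, rng) -> list[SubstitutionRecord]:
    records = []
    for ch_idx, count in enumerate(channel_counts):
        if count == 0:
            continue
        label = SUBSTITUTION_96.labels[ch_idx]
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        sites = site_index.get((five, ref, three))
        if sites is None or len(sites) == 0:
            raise ValueError(f"no eligible site for channel {label}")
        pick = rng.choice(len(sites), size=int(count),
                          replace=len(sites) < int(count))
        for j in pick:
            pos, strand = sites[j]
            if strand == 1:
                records.append(SubstitutionRecord(contig, int(pos), ref, alt))
            else:
                records.append(SubstitutionRecord(contig, int(pos),
                                                  revcomp(ref), revcomp(alt)))
    return records


def _indel_site_masks(sequence: str) -> dict[str, np.ndarray]:
    """Candidate left-aligned indel sites per channel (0-based index of the
    first affected base)."""
    b = np.frombuffer(sequence.encode(), dtype=np.uint8)
    n = len(b)
    i = np.arange(1, n - 8)  # room for motif + junction scan on the right
    left_ok1 = b[i - 1] != b[i]
    rep1 = left_ok1 & (b[i + 1] == b[i])
    other1 = left_ok1 & (b[i + 1] != b[i])
    left_ok2 = b[i - 1] != b[i + 1]
    rep2 = left_ok2 & (b[i + 2] == b[i]) & (b[i + 3] == b[i + 1])
    mh2 = left_ok2 & (b[i + 2] == b[i]) & (b[i + 3] != b[i + 1])
    left_ok3 = b[i - 1] != b[i + 2]
    full3 = (b[i + 3] == b[i]) & (b[i + 4] == b[i + 1]) & (b[i + 5] == b[i + 2])
    mh3 = left_ok3 & (b[i + 3] == b[i]) & ~full3
    return {
        "del_rep_1bp": i[rep1],
        "del_other": i[other1],
        "del_rep_ge2bp": i[rep2],
        "del_mh_2bp": i[mh2 & ~rep2],
        "del_mh_ge3bp": i[mh3],
    }


_DEL_LENGTH = {"del_rep_1bp": 1, "del_other": 1, "del_rep_ge2bp": 2,
               "del_mh_2bp": 2, "del_mh_ge3bp": 3}


def _emit_indels(channel_counts: np.ndarray, contig: str, sequence: str,
                 masks, reference, rng) -> list[IndelRecord]:
    records = []
    for ch_idx, count in enumerate(channel_counts):
        if count == 0:
            continue
        label = INDEL_8.labels[ch_idx]
        for _ in range(int(count)):
            rec = None
            for _attempt in range(50):
                if label == "ins_1bp":
                    p = int(rng.integers(2, len(sequence) - 2))
                    rec = IndelRecord(contig, p, sequence[p - 1],
                                      sequence[p - 1] + rng.choice(list("ACGT")))
                elif label == "ins_ge2bp":
                    p = int(rng.integers(2, len(sequence) - 2))
                    ins = "".join(rng.choice(list("ACGT"),
                                             size=int(rng.integers(2, 4))))
                    rec = IndelRecord(contig, p, sequence[p - 1],
                                      sequence[p - 1] + ins)
                elif label == "complex":
                    p = int(rng.integers(2, len(sequence) - 4))
                    ref = sequence[p - 1 : p + 1]
                    alt = ref[0] + rng.choice([x for x in "ACGT" if x != ref[1]])
                    rec = IndelRecord(contig, p, ref, alt)
                else:
                    sites = masks[label]
                    if len(sites) == 0:
                        raise ValueError(f"no eligible site for channel {label}")
                    s = int(sites[rng.integers(0, len(sites))])  # 0-based
                    L = _DEL_LENGTH[label]
                    ref = sequence[s - 1 : s + L]
                    rec = IndelRecord(contig, s, ref, ref[0])
                if classify_indel(rec, reference) == label:
                    break
                rec = None
            if rec is None:
                raise ValueError(f"could not construct a record for channel {label}")
            records.append(rec)
    return records


_SPAN_RANGES = {"1-10kb": (1_000, 10_000), "10kb-1Mb": (10_001, 1_000_000),
                ">1Mb": (1_000_001, None)}


def _emit_rearrangements(channel_counts: np.ndarray,
                         sv_lengths: Mapping[str, int],
                         rng) -> list[RearrangementRecord]:
    names = list(sv_lengths)
    if len(names) < 2:
        raise ValueError("need at least two SV contigs for translocations")
    records = []
    for ch_idx, count in enumerate(channel_counts):
        if count == 0:
            continue
        label = REARRANGEMENT_10.labels[ch_idx]
        for _ in range(int(count)):
            if label == "translocation":
                c1, c2 = rng.choice(names, size=2, replace=False)
                records.append(RearrangementRecord(
                    str(c1), int(rng.integers(1, sv_lengths[str(c1)])),
                    str(c2), int(rng.integers(1, sv_lengths[str(c2)])),
                    "translocation"))
            else:
                svclass, size = label.rsplit("_", 1)
                chrom = str(rng.choice(names))
                length = sv_lengths[chrom]
                lo, hi = _SPAN_RANGES[size]
                hi = min(hi or length - 2, length - 2)
                if lo >= hi:
                    raise ValueError(
                        f"no eligible span for channel {label} on {chrom}")
                span = int(rng.integers(lo, hi + 1))
                pos1 = int(rng.integers(1, length - span))
                records.append(RearrangementRecord(chrom, pos1, chrom,
                                                   pos1 + span, svclass))
    return records


def simulate_variant_records(config: SimulationConfig, toy_genome: ToyGenome,
                             rng: np.random.Generator | None = None
                             ) -> tuple[dict[str, list], dict[str, str],
                                        SimulationTruth]:
    """Per-sample variant records on the toy genome with recorded truth.

    Channel counts are drawn exactly as in :func:`simulate_catalogs`; each
    mutation is then placed at a genomic site whose context matches its
    channel, so rebuilding the catalog from the emitted records reproduces
    the drawn channel counts exactly. Returns (records_by_sample,
    roles_by_sample, truth); truth.channel_counts holds the per-sample
    generating counts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parental_cat, subclone_cat, truth = simulate_catalogs(config, rng)
    contig = next(iter(toy_genome.contigs))
    sequence = toy_genome.contigs[contig]
    cls = config.taxonomy.name
    if cls == "substitution":
        site_index = _substitution_site_index(sequence)
        emit = lambda counts: _emit_substitutions(counts, contig, site_index, rng)
    elif cls == "indel":
        masks = _indel_site_masks(sequence)
        reference = toy_genome.reference
        emit = lambda counts: _emit_indels(counts, contig, sequence, masks,
                                           reference, rng)
    else:
        emit = lambda counts: _emit_rearrangements(
            counts, toy_genome.sv_contig_lengths, rng)

    records_by_sample: dict[str, list] = {}
    roles: dict[str, str] = {}
    for cat, role in ((parental_cat, "parental"), (subclone_cat, "subclone")):
        for s in cat.samples:
            records_by_sample[s.sample_id] = emit(s.counts)
            roles[s.sample_id] = role
            truth.channel_counts[s.sample_id] = s.counts.copy()
    return records_by_sample, roles, truth


# ---------------------------------------------------------------------------
# synthetic reference catalogs
# ---------------------------------------------------------------------------


def synthetic_reference_catalog(taxonomy: str | ChannelTaxonomy,
                                n_signatures: int = 30,
                                seed: int = 0,
                                concentration: float = 0.2,
                                embed: Mapping[str, SignatureProfile] | None = None,
                                prefix: str = "SynthSig") -> SignatureCatalog:
    """A synthetic stand-in for a reference signature catalog.

    Columns are sparse Dirichlet draws (plus any explicitly embedded
    profiles), shaped like a published channel × signature matrix; useful for
    exercising the comparison machinery when the real catalogs are not
    available.
    """
    taxonomy = get_taxonomy(taxonomy) if isinstance(taxonomy, str) else taxonomy
    rng = np.random.default_rng(seed)
    names, columns = [], []
    for name, profile in (embed or {}).items():
        names.append(name)
        columns.append(profile.weights)
    for j in range(n_signatures - len(names)):
        names.append(f"{prefix}{j + 1}")
        columns.append(rng.dirichlet(np.full(taxonomy.K, concentration)))
    return SignatureCatalog(taxonomy, names, np.stack(columns, axis=1))
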