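"""Topography of knockout-associated mutations: transcriptional and
replication strand asymmetry, and mutation density across replication-timing
deciles.

Strand bookkeeping follows the pyrimidine convention: every substitution is
first flipped to its C/T-reference representation, and the strand carrying
that pyrimidine is compared with the annotated gene strand (transcription
mode) or with the annotated leading/lagging orientation of the + reference
strand (replication mode). A pyrimidine lying on the coding (non-template)
strand of a gene is "untranscribed"; the template strand carries the
complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import PYRIMIDINES, SUBSTITUTION_TYPES, COMPLEMENT
from .variant_io import DomainTrack, SubstitutionRecord

STRAND_PAIRS = {
    "transcription": ("transcribed", "untranscribed"),
    "replication": ("lagging", "leading"),
}


@dataclass(frozen=True)
class StrandAssignment:
    record: SubstitutionRecord
    strand: str  # transcribed | untranscribed | leading | lagging | unassigned
    mutation_type: str  # one of the six pyrimidine substitution types


def pyrimidine_type(record: SubstitutionRecord) -> tuple[str, str]:
    """(substitution type, strand of the pyrimidine) for a record.

    Returns e.g. ("C>T", "+") if the reference base is already a pyrimidine
    on the + strand, or the complemented type with strand "-" otherwise.
    """
    if record.ref in PYRIMIDINES:
        return f"{record.ref}>{record.alt}", "+"
    return f"{COMPLEMENT[record.ref]}>{COMPLEMENT[record.alt]}", "-"


def assign_strand(records: Sequence[SubstitutionRecord], track: DomainTrack,
                  mode: str) -> list[StrandAssignment]:
    """Assign each substitution a transcriptional or replicative strand label.

    Records outside annotated regions, or under overlapping conflicting
    annotations, are "unassigned". In transcription mode the track labels are
    gene strands {+, -}; in replication mode they give the orientation
    {leading, lagging} of the + reference strand.
    """
    if mode not in STRAND_PAIRS:
        raise ValueError(f"mode must be one of {sorted(STRAND_PAIRS)}")
    expected = {"+", "-"} if mode == "transcription" else {"leading", "lagging"}
    if track.labels and not track.labels <= expected:
        raise ValueError(
            f"track labels {sorted(track.labels)} do not match mode {mode!r}"
        )
    out = []
    for rec in records:
        mut_type, pyr_strand = pyrimidine_type(rec)
        label = track.label_at(rec.chrom, rec.pos)
        if label is None:
            strand = "unassigned"
        elif mode == "transcription":
            # pyrimidine on the gene's own (coding) strand => untranscribed
            strand = "untranscribed" if pyr_strand == label else "transcribed"
        else:
            strand = label if pyr_strand == "+" else (
                "lagging" if label == "leading" else "leading")
        out.append(StrandAssignment(rec, strand, mut_type))
    return out


@dataclass
class AsymmetryResult:
    """Strand asymmetry of one pyrimidine substitution type across subclones.

    ``fold`` is mean(count on strand1) / mean(count on strand2) with the
    strand order taken from STRAND_PAIRS (transcribed/untranscribed, or
    lagging/leading); ``p_value`` is from a two-sided paired t-test on the
    per-subclone strand counts (NaN when degenerate)."""

    mutation_type: str
    strands: tuple[str, str]
    counts: pd.DataFrame  # index = subclone, columns = the two strands
    fold: float
    p_value: float


def strand_asymmetry_test(assignments_by_subclone:
                          Mapping[str, Sequence[StrandAssignment]],
                          mode: str) -> dict[str, AsymmetryResult]:
    """Per-mutation-type strand asymmetry across subclones.

    Counts the two strand labels per subclone and mutation type, then tests
    the natural subclone pairing of the two counts with a paired t-test.
    Requires at least two subclones.
    """
    s1, s2 = STRAND_PAIRS[mode]
    subclones = list(assignments_by_subclone)
    if len(subclones) < 2:
        raise ValueError("need at least two subclones for a t-test")
    results: dict[str, AsymmetryResult] = {}
    for mut_type in SUBSTITUTION_TYPES:
        rows = []
        for sub in subclones:
            a = [x for x in assignments_by_subclone[sub]
                 if x.mutation_type == mut_type]
            rows.append((sum(x.strand == s1 for x in a),
                         sum(x.strand == s2 for x in a)))
        counts = pd.DataFrame(rows, index=subclones, columns=[s1, s2])
        m1, m2 = counts[s1].mean(), counts[s2].mean()
        if m1 == 0 or m2 == 0:
            fold, p = float("nan"), float("nan")
        else:
            fold = float(m1 / m2)
            diffs = counts[s1] - counts[s2]
            if np.allclose(diffs, diffs.iloc[0]) and diffs.std() == 0:
                p = float("nan") if diffs.iloc[0] != 0 else 1.0
            else:
                p = float(stats.ttest_rel(counts[s1], counts[s2]).pvalue)
        results[mut_type] = AsymmetryResult(mut_type, (s1, s2), counts, fold, p)
    return results


@dataclass
class TimingDensity:
    """Normalized mutation density per replication-timing decile (1 = early
    ... 10 = late), corrected for each decile's genomic size and scaled so
    the mean over the ten deciles is 1."""

    densities: np.ndarray  # length 10, deciles 1..10
    counts: np.ndarray
    lengths: np.ndarray
    unassigned: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.densities, index=[str(d) for d in range(1, 11)])


def timing_density(records: Sequence[SubstitutionRecord],
                   decile_track: DomainTrack) -> TimingDensity:
    """Size-corrected mutation density across replication-timing deciles."""
    decile_labels = [str(d) for d in range(1, 11)]
    lengths_by_label = decile_track.label_lengths()
    missing = [d for d in decile_labels if d not in lengths_by_label]
    if missing:
        raise ValueError(f"decile track is missing deciles {missing}")
    lengths = np.array([lengths_by_label[d] for d in decile_labels], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("decile with zero genomic length")
    counts = np.zeros(10, dtype=np.int64)
    unassigned = 0
    for rec in records:
        label = decile_track.label_at(rec.chrom, rec.pos)
        if label in lengths_by_label:
            counts[decile_labels.index(label)] += 1
        else:
            unassigned += 1
    density = counts / lengths
    mean = density.mean()
    if mean > 0:
        density = density / mean
    return TimingDensity(density, counts, lengths, unassigned)
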