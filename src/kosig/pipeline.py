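"""Orchestration of the full knockout-signature workflow.

For each mutation class the stages run in the order the method requires:

1. spectrum-shift test for every knockout against the shared parental cloud
   (so the set of non-shifted knockouts is known before any count test);
2. count-elevation test for every knockout against the baseline pool built
   from the non-shifted knockouts' per-subclone totals;
3. signature extraction, only for knockouts called as having a signature;
4. optional cosine comparison of extracted signatures to reference catalogs.

The baseline is computed per mutation class independently: a knockout can be
non-shifted for rearrangements while shifted for substitutions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import __version__
from .catalog import CatalogMatrix
from .detect import (
    BootstrapConfig,
    ClassCall,
    KnockoutCall,
    build_parental_null,
    call_knockout,
    count_elevation_test,
    spectrum_shift_test,
)
from .extract import ExtractionResult, extract_knockout_signature
from .similarity import SimilarityReport, compare_to_catalog
from .variant_io import SignatureCatalog

logger = logging.getLogger("kosig")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    classes: tuple[str, ...] = ("substitution", "indel", "rearrangement")
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    alpha: float = 0.01
    ci_level: float = 0.99
    n_boundary_boot: int = 10_000
    n_extract_profiles: int = 100
    extract_accept_min: int = 5
    divisions: float = 36.0
    seed: int | None = None


@dataclass
class ClassReport:
    """All results for one mutation class."""

    mutation_class: str
    calls: dict[str, ClassCall] = field(default_factory=dict)
    extractions: dict[str, ExtractionResult] = field(default_factory=dict)
    similarity: dict[str, SimilarityReport] = field(default_factory=dict)
    rates_per_division: dict[str, float] = field(default_factory=dict)
    baseline_pool: list[float] = field(default_factory=list)
    error: str | None = None


@dataclass
class RunReport:
    config: RunConfig
    knockouts: dict[str, KnockoutCall] = field(default_factory=dict)
    classes: dict[str, ClassReport] = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        out = {
            "version": self.version,
            "seed": self.config.seed,
            "alpha": self.config.alpha,
            "classes": {},
        }
        for cls, rep in self.classes.items():
            cls_out = {"error": rep.error, "knockouts": {}}
            for ko, call in rep.calls.items():
                entry = {
                    "shifted": call.shifted,
                    "d_ps": call.shift.d_ps if call.shift else None,
                    "d_pc_alpha": call.shift.d_pc_alpha if call.shift else None,
                    "d_sc_alpha": call.shift.d_sc_alpha if call.shift else None,
                    "count_p_value": call.count_p_value,
                    "has_signature": call.has_signature,
                    "reason": call.reason,
                }
                if ko in rep.extractions:
                    ext = rep.extractions[ko]
                    entry["e_p"] = ext.e_p
                    entry["e_ko"] = ext.e_ko
                    entry["rate_per_division"] = rep.rates_per_division.get(ko)
                    entry["signature"] = ext.signature.weights.tolist()
                if ko in rep.similarity:
                    entry["similarity"] = dict(rep.similarity[ko].cosines)
                cls_out["knockouts"][ko] = entry
            out["classes"][cls] = cls_out
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def checksum(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def run(parental: Mapping[str, CatalogMatrix],
        subclones: Mapping[str, Mapping[str, CatalogMatrix]],
        config: RunConfig | None = None,
        reference_catalogs: Mapping[str, SignatureCatalog] | None = None
        ) -> RunReport:
    """Execute the full workflow on in-memory catalogs.

    ``parental`` maps mutation class -> CatalogMatrix of all parental clones;
    ``subclones`` maps knockout -> mutation class -> CatalogMatrix of its
    subclones. Reference catalogs, when given per class, trigger cosine
    comparison of every extracted signature.
    """
    config = config or RunConfig()
    report = RunReport(config)
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.classes))
    for cls, seed_seq in zip(config.classes, seeds):
        if cls not in parental:
            continue
        rng = np.random.default_rng(seed_seq)
        cls_report = ClassReport(cls)
        report.classes[cls] = cls_report
        boot = BootstrapConfig(**{**config.bootstrap.__dict__,
                                  "alpha": config.alpha})
        null = build_parental_null(parental[cls], boot, rng)

        kos = [ko for ko in subclones if cls in subclones[ko]]
        shift_results = {}
        for ko in kos:
            shift_results[ko] = spectrum_shift_test(
                parental[cls], subclones[ko][cls], boot, parental_null=null,
                rng=rng)
            logger.info("stage=shift class=%s knockout=%s shifted=%s",
                        cls, ko, shift_results[ko].shifted)

        baseline = np.concatenate([
            subclones[ko][cls].totals() for ko in kos
            if not shift_results[ko].shifted
        ]) if any(not shift_results[ko].shifted for ko in kos) else np.array([])
        cls_report.baseline_pool = [float(x) for x in baseline]
        if baseline.size == 0:
            cls_report.error = (
                "no non-shifted knockouts: the count-test baseline is empty; "
                "supply an external baseline of per-subclone de novo totals"
            )
            for ko in kos:
                cls_report.calls[ko] = ClassCall(
                    shifted=shift_results[ko].shifted,
                    count_p_value=float("nan"), alpha=config.alpha,
                    shift=shift_results[ko])
            continue

        for ko in kos:
            count_result = count_elevation_test(
                subclones[ko][cls].totals(), baseline,
                n_boot=boot.n_count_boot, rng=rng)
            call = call_knockout(shift_results[ko], count_result, config.alpha)
            cls_report.calls[ko] = call
            logger.info("stage=count class=%s knockout=%s p=%.4g has_signature=%s",
                        cls, ko, count_result.p_value, call.has_signature)
            if not call.has_signature:
                continue
            ext = extract_knockout_signature(
                subclones[ko][cls], parental[cls],
                n_boot=config.n_boundary_boot, ci_level=config.ci_level,
                n_profiles=config.n_extract_profiles,
                accept_min=config.extract_accept_min, rng=rng)
            cls_report.extractions[ko] = ext
            cls_report.rates_per_division[ko] = ext.e_ko / config.divisions
            logger.info("stage=extract class=%s knockout=%s e_p=%d e_ko=%d",
                        cls, ko, ext.e_p, ext.e_ko)
            if reference_catalogs and cls in reference_catalogs:
                cls_report.similarity[ko] = compare_to_catalog(
                    ext.signature, reference_catalogs[cls], query_name=ko)

    for ko in subclones:
        ko_call = KnockoutCall(ko)
        for cls, cls_report in report.classes.items():
            if ko in cls_report.calls:
                ko_call.calls[cls] = cls_report.calls[ko]
        report.knockouts[ko] = ko_call
    return report
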