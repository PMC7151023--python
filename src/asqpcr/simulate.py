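"""Mechanistic simulator of allele-specific qPCR experiments.

The generative model follows the physics the comparative-Cq method
assumes.  A reaction seeded with ``T`` effective template copies and
amplification efficiency ``E`` crosses threshold at

    Cq = c0 - ln(T) / ln(1 + E) + eps,   eps ~ Normal(0, noise_sd)

where ``c0`` is the Cq of a single template copy (with E = 1 this is
``c0 - log2(T)``).  A sample with ``N`` total allele copies and true
mutant fraction ``p`` contributes ``m`` mutant copies — Binomial(N, p)
per extraction, shared by the two paired reactions, or exactly ``N*p``
in deterministic mode — and ``w = N - m`` wild-type copies.  Each
allele-specific primer also extends the wrong allele, only delayed by
``crosstalk_delta`` cycles, so the effective templates are

    mutant-specific reaction:    m + w * 2^-crosstalk_delta
    wild-type-specific reaction: w + m * 2^-crosstalk_delta

Crosstalk is what turns a truly negative sample into a late false
positive, the phenomenon behind the Cq cut-off rule.  A reaction whose
effective template falls below one copy, or whose noisy Cq exceeds the
run length, reports ``undetermined``.  RNase P amplifies from all ``N``
genome copies at efficiency 1 with its own single-copy Cq.

Randomness: every public function takes the seed from its config (or an
explicit ``numpy.random.Generator``); draws occur in a fixed order —
per subject, then per pair (binomial first), then the four Cq noises
(wt, mut, rp_wt, rp_mut) — so identical seeds give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .core import (
    UNDETERMINED,
    CqValue,
    QcPolicy,
    ReactionPairRecord,
    Specimen,
    is_undetermined,
)
from .validation import DetectionTable

__all__ = [
    "SimulationConfig",
    "PairedSpecimenConfig",
    "PairedSpecimenResult",
    "simulate_reaction_pair",
    "simulate_dilution_series",
    "standard_curve_points",
    "simulate_lod_panel",
    "simulate_paired_specimens",
    "serum_fraction",
]

#: 25 ng of genomic DNA per reaction at 0.0033 ng per haploid genome.
DEFAULT_ALLELE_COPIES = round(25.0 / 0.0033)  # 7576


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated AS-qPCR sample.

    true_mutant_fraction
        p in [0, 1]: fraction of mutant alleles in the extract.
    total_allele_copies
        N: allele copies per reaction (default 7576 = 25 ng input).
    efficiency_wt / efficiency_mut
        Per-cycle amplification efficiency of each allele-specific
        reaction (1.0 = perfect doubling).
    single_copy_cq
        c0: Cq at which one template copy would cross threshold.
    rp_single_copy_cq
        Same, for the RNase P reference target.
    noise_sd
        SD (cycles) of Gaussian technical noise added to every Cq.
    crosstalk_delta
        Cycles by which the wrong allele's extension lags; ``inf`` means
        a perfectly specific primer.
    total_cycles
        Run length; Cq beyond it is reported undetermined.
    sampling
        "stochastic" (Binomial allele sampling) or "deterministic"
        (m = N*p exactly, for closed-form checks).
    """

    true_mutant_fraction: float = 0.0
    total_allele_copies: int = DEFAULT_ALLELE_COPIES
    efficiency_wt: float = 1.0
    efficiency_mut: float = 1.0
    single_copy_cq: float = 42.0
    rp_single_copy_cq: float = 42.0
    noise_sd: float = 0.15
    crosstalk_delta: float = 18.0
    total_cycles: float = 45.0
    sampling: str = "stochastic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_mutant_fraction <= 1.0:
            raise ValueError("true_mutant_fraction must lie in [0, 1]")
        if self.total_allele_copies < 1:
            raise ValueError("total_allele_copies must be >= 1")
        if self.efficiency_wt <= 0 or self.efficiency_mut <= 0:
            raise ValueError("efficiencies must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.crosstalk_delta <= 0:
            raise ValueError("crosstalk_delta must be > 0 (inf allowed)")
        if self.sampling not in ("stochastic", "deterministic"):
            raise ValueError("sampling must be 'stochastic' or 'deterministic'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _cq_from_template(
    template: float,
    efficiency: float,
    c0: float,
    noise: float,
    total_cycles: float,
) -> CqValue:
    # below one effective copy there is nothing to amplify
    if template < 1.0:
        return UNDETERMINED
    cq = c0 - math.log(template) / math.log(1.0 + efficiency) + noise
    if cq > total_cycles:
        return UNDETERMINED
    return max(cq, 1e-9)


def _draw_mutant_copies(config: SimulationConfig, rng: np.random.Generator) -> float:
    n = config.total_allele_copies
    p = config.true_mutant_fraction
    if config.sampling == "deterministic":
        return n * p
    return float(rng.binomial(n, p))


def simulate_reaction_pair(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    specimen: Specimen = Specimen.OTHER,
    scale: float = 1.0,
) -> ReactionPairRecord:
    """Simulate one sample's Cq quartet.

    ``scale`` multiplies the template amounts (used by the dilution
    series); allele sampling happens at the undiluted copy number and
    the dilution is applied to the drawn copies, mimicking serial
    dilution of a single extract.
    """
    if rng is None:
        rng = config.rng()
    m = _draw_mutant_copies(config, rng)
    w = config.total_allele_copies - m
    atten = 0.0 if math.isinf(config.crosstalk_delta) else 2.0 ** (-config.crosstalk_delta)
    template_wt = (w + m * atten) * scale
    template_mut = (m + w * atten) * scale
    template_rp = config.total_allele_copies * scale

    # fixed draw order keeps seeded streams reproducible even when some
    # reactions come out undetermined
    noise = (
        rng.normal(0.0, config.noise_sd, size=4)
        if config.noise_sd > 0
        else np.zeros(4)
    )
    cq_wt = _cq_from_template(
        template_wt, config.efficiency_wt, config.single_copy_cq, noise[0], config.total_cycles
    )
    cq_mut = _cq_from_template(
        template_mut, config.efficiency_mut, config.single_copy_cq, noise[1], config.total_cycles
    )
    cq_rp_wt = _cq_from_template(
        template_rp, 1.0, config.rp_single_copy_cq, noise[2], config.total_cycles
    )
    cq_rp_mut = _cq_from_template(
        template_rp, 1.0, config.rp_single_copy_cq, noise[3], config.total_cycles
    )
    return ReactionPairRecord(
        sample_id=sample_id,
        cq_wt=cq_wt,
        cq_mut=cq_mut,
        cq_rp_wt=cq_rp_wt,
        cq_rp_mut=cq_rp_mut,
        specimen=specimen,
    )


def simulate_dilution_series(
    config: SimulationConfig,
    dilution_factors: Sequence[float],
    replicates: int = 1,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, ReactionPairRecord]]:
    """Serial dilution of one sample for efficiency estimation.

    ``dilution_factors`` are relative concentrations, strictly
    decreasing from 1 (e.g. ``[1, 0.1, 0.01]``).  Template is rescaled
    per point while the mutant fraction stays fixed; points diluted
    below one template copy come back with undetermined Cqs rather than
    raising.  Output rows are (relative concentration, record) and feed
    :func:`asqpcr.validation.fit_standard_curve` via
    :func:`standard_curve_points`.
    """
    factors = list(dilution_factors)
    if not factors or factors[0] != 1:
        raise ValueError("dilution_factors must start at 1")
    if any(b >= a for a, b in zip(factors, factors[1:])):
        raise ValueError("dilution_factors must be strictly decreasing")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if rng is None:
        rng = config.rng()
    out: list[tuple[float, ReactionPairRecord]] = []
    for factor in factors:
        for rep in range(replicates):
            record = simulate_reaction_pair(
                config,
                rng=rng,
                sample_id=f"dil{factor:g}_r{rep + 1}",
                scale=factor,
            )
            out.append((factor, record))
    return out


def standard_curve_points(
    series: Sequence[tuple[float, ReactionPairRecord]], reaction: str = "wt"
) -> list[tuple[float, float]]:
    """Extract (log10 relative concentration, Cq) pairs for one reaction,
    dropping undetermined points."""
    attr = {"wt": "cq_wt", "mut": "cq_mut", "rp_wt": "cq_rp_wt", "rp_mut": "cq_rp_mut"}[reaction]
    points = []
    for conc, record in series:
        cq = getattr(record, attr)
        if not is_undetermined(cq):
            points.append((math.log10(conc), float(cq)))
    return points


def simulate_lod_panel(
    base: SimulationConfig,
    fractions: Sequence[float],
    replicates: int = 9,
    policy: QcPolicy = QcPolicy(),
    rng: np.random.Generator | None = None,
) -> DetectionTable:
    """Replicate detection panel across decreasing mutant fractions.

    A replicate counts as detected when its mutant-specific reaction
    amplified below the Cq cut-off — the raw positive-signal criterion
    from which a limit of detection is subsequently *estimated* (the
    validated LOD threshold cannot enter its own estimation).
    """
    fracs = list(fractions)
    if any(b >= a for a, b in zip(fracs, fracs[1:])):
        raise ValueError("fractions must be strictly decreasing")
    if rng is None:
        rng = base.rng()
    detected_counts = []
    for p in fracs:
        config = replace(base, true_mutant_fraction=p)
        detected = 0
        for _ in range(replicates):
            record = simulate_reaction_pair(config, rng=rng)
            if not is_undetermined(record.cq_mut) and float(record.cq_mut) < policy.cq_cutoff:
                detected += 1
        detected_counts.append(detected)
    return DetectionTable(
        levels_percent=[100.0 * p for p in fracs],
        n_tested=[replicates] * len(fracs),
        n_detected=detected_counts,
    )


def serum_fraction(blood_fraction: float, logit_shift: float) -> float:
    """True serum mutant fraction under a log-odds enrichment model.

    logistic(logit(p) + delta): the shift vanishes at p = 0 and p = 1
    and is largest mid-range, matching the observation that specimens
    with high burden drive most of the serum-minus-blood difference.
    """
    if blood_fraction in (0.0, 1.0):
        return blood_fraction
    return float(expit(logit(blood_fraction) + logit_shift))


@dataclass(frozen=True)
class PairedSpecimenConfig:
    """One subject in a paired whole-blood / serum cohort."""

    blood_fraction: float
    logit_shift: float = 0.25
    base: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.blood_fraction <= 1.0:
            raise ValueError("blood_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PairedSpecimenResult:
    subject_id: str
    true_blood_fraction: float
    true_serum_fraction: float
    blood: ReactionPairRecord
    serum: ReactionPairRecord


def simulate_paired_specimens(
    cohort: Sequence[PairedSpecimenConfig], seed: int = 0
) -> list[PairedSpecimenResult]:
    """Paired whole-blood and serum measurements for a cohort.

    Per subject the blood extract is simulated at its true fraction and
    the serum extract at the logit-shifted fraction; blood draws come
    before serum draws in the seeded stream.  Output feeds
    :func:`asqpcr.validation.method_comparison` after classification.
    """
    rng = np.random.default_rng(seed)
    results = []
    for i, subject in enumerate(cohort):
        p_blood = subject.blood_fraction
        p_serum = serum_fraction(p_blood, subject.logit_shift)
        sid = f"subj{i + 1:03d}"
        blood = simulate_reaction_pair(
            replace(subject.base, true_mutant_fraction=p_blood),
            rng=rng,
            sample_id=sid,
            specimen=Specimen.WHOLE_BLOOD,
        )
        serum = simulate_reaction_pair(
            replace(subject.base, true_mutant_fraction=p_serum),
            rng=rng,
            sample_id=sid,
            specimen=Specimen.SERUM,
        )
        results.append(
            PairedSpecimenResult(
                subject_id=sid,
                true_blood_fraction=p_blood,
                true_serum_fraction=p_serum,
                blood=blood,
                serum=serum,
            )
        )
    return results
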