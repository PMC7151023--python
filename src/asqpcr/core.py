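"""Comparative-Cq (2^-ddCq) quantification of a somatic mutant allele.

An allele-specific qPCR (AS-qPCR) assay runs two independent reactions on
the same DNA extract: one whose primer matches the wild-type allele, one
whose primer matches the mutant allele (JAK2 V617F in the motivating
assay).  Because both reactions start from the same tube, the difference
of their quantification cycles (Cq) measures the log2 ratio of allele
abundances, and the mutant-allele percentage follows without any standard
curve:

    mut% = 100 / (2^-(Cq_wt - Cq_mut) + 1)

optionally normalised to a co-amplified single-copy reference gene
(RNase P) to absorb pipetting differences between the two reactions:

    mut% = 100 / (2^-((Cq_wt - Cq_RP,wt) - (Cq_mut - Cq_RP,mut)) + 1)

This module also carries the absolute-quantification arithmetic used to
normalise DNA input (standard-curve inversion to copies per reaction and
conversion to ng/uL via the haploid genome mass).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Union

__all__ = [
    "UNDETERMINED",
    "Undetermined",
    "CqValue",
    "Specimen",
    "ReactionPairRecord",
    "QcPolicy",
    "CallStatus",
    "MutantFractionResult",
    "StandardCurveModel",
    "GenomeConstants",
    "InvalidSampleError",
    "is_undetermined",
    "parse_cq",
    "mutant_percent_simple",
    "mutant_percent_corrected",
    "classify_result",
    "copies_from_cq",
    "dna_concentration_from_copies",
    "format_percent",
]


class Undetermined:
    """Sentinel for a reaction with no amplification within the run.

    Distinct from missing data: an ``undetermined`` Cq is a real
    observation (the fluorescence never crossed threshold), whereas a
    missing Cq means the reaction was not run or not recorded.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "UNDETERMINED"

    def __bool__(self) -> bool:
        return False


UNDETERMINED = Undetermined()

#: A Cq observation: cycles (positive float) or the no-amplification sentinel.
CqValue = Union[float, Undetermined]

_SENTINEL_STRINGS = {"undetermined", "na", ""}


def is_undetermined(cq: CqValue) -> bool:
    return isinstance(cq, Undetermined)


def parse_cq(text: str) -> CqValue:
    """Parse an instrument-export Cq field.

    Accepts a decimal number or one of the sentinel strings
    ``"Undetermined"`` (case-insensitive), ``"NA"``, ``""``.  Anything
    else raises ``ValueError`` so bad exports fail loudly rather than
    silently becoming missing data.
    """
    stripped = text.strip()
    if stripped.lower() in _SENTINEL_STRINGS:
        return UNDETERMINED
    try:
        value = float(stripped)
    except ValueError:
        raise ValueError(f"unrecognised Cq field {text!r}") from None
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"Cq must be a finite positive number, got {text!r}")
    return value


class Specimen(str, enum.Enum):
    WHOLE_BLOOD = "whole_blood"
    SERUM = "serum"
    OTHER = "other"


@dataclass(frozen=True)
class ReactionPairRecord:
    """One sample's Cq quartet from the two independent AS-qPCR reactions.

    ``cq_wt``/``cq_mut`` are the allele targets in the wild-type-specific
    and mutant-specific reactions; ``cq_rp_wt``/``cq_rp_mut`` are the
    RNase P reference co-amplified in each tube.
    """

    sample_id: str
    cq_wt: CqValue
    cq_mut: CqValue
    cq_rp_wt: CqValue = UNDETERMINED
    cq_rp_mut: CqValue = UNDETERMINED
    specimen: Specimen = Specimen.OTHER


@dataclass(frozen=True)
class QcPolicy:
    """Quality-control and reporting thresholds.

    cq_cutoff
        Mutant-reaction Cq at or beyond which the signal is treated as
        late unspecific amplification of the wrong allele (cycles).
    total_cycles
        Cycles in the run; numeric Cq must not exceed it.
    lod_percent / loq_percent
        Validated detection and quantification limits (% mutant allele).
        Results below the LOD are negative; in [LOD, LOQ) they are
        "detected" but not reportable as a quantity.
    rp_delta_warn
        Warn when the two reference Cqs differ by more than this
        (pipetting imbalance between the paired reactions).
    rp_max_cq
        Warn when either reference Cq is above this (low/poor template).
    """

    cq_cutoff: float = 42.0
    total_cycles: float = 45.0
    lod_percent: float = 0.15
    loq_percent: float = 1.16
    rp_delta_warn: float = 1.0
    rp_max_cq: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.lod_percent <= self.loq_percent < 100):
            raise ValueError("need 0 < lod_percent <= loq_percent < 100")
        if self.cq_cutoff > self.total_cycles:
            raise ValueError("cq_cutoff must not exceed total_cycles")


class CallStatus(str, enum.Enum):
    NOT_DETECTED = "not_detected"
    DETECTED_BELOW_LOQ = "detected_below_loq"
    QUANTIFIED = "quantified"
    INVALID_NO_REFERENCE = "invalid_no_reference"


@dataclass(frozen=True)
class MutantFractionResult:
    """Mutant-allele call for one sample.

    ``percent`` is present only for detected/quantified results;
    ``delta_cq`` is Cq_wt - Cq_mut and ``delta_delta_cq`` the
    reference-corrected version (None when the simple formula was used).
    """

    sample_id: str
    status: CallStatus
    formula: str
    percent: float | None = None
    delta_cq: float | None = None
    delta_delta_cq: float | None = None
    specimen: Specimen = Specimen.OTHER
    warnings: tuple[str, ...] = field(default_factory=tuple)


class InvalidSampleError(ValueError):
    """The wild-type reaction failed: inhibition or no template.

    Distinct from a negative call — a valid negative still amplifies the
    wild-type allele.
    """


def _require_numeric(name: str, cq: CqValue, total_cycles: float = 45.0) -> float:
    if is_undetermined(cq):
        raise ValueError(f"{name} is undetermined; route through classify_result")
    cq = float(cq)
    if not (0 < cq <= total_cycles):
        raise ValueError(f"{name}={cq} outside (0, {total_cycles}]")
    return cq


def mutant_percent_simple(cq_wt: float, cq_mut: float, total_cycles: float = 45.0) -> float:
    """Mutant-allele percentage from the two allele-specific Cqs.

    100 / (2^-(cq_wt - cq_mut) + 1).  Equal Cqs give exactly 50%; each
    extra cycle of delay of the mutant reaction roughly halves its share.
    """
    cq_wt = _require_numeric("cq_wt", cq_wt, total_cycles)
    cq_mut = _require_numeric("cq_mut", cq_mut, total_cycles)
    delta = cq_wt - cq_mut
    return 100.0 / (2.0 ** (-delta) + 1.0)


def mutant_percent_corrected(
    cq_wt: float,
    cq_mut: float,
    cq_rp_wt: float,
    cq_rp_mut: float,
    total_cycles: float = 45.0,
) -> float:
    """Reference-normalised mutant-allele percentage.

    100 / (2^-((cq_wt - cq_rp_wt) - (cq_mut - cq_rp_mut)) + 1).
    Reduces to :func:`mutant_percent_simple` when the reference Cqs are
    equal; otherwise the reference absorbs template-input differences
    between the two physically independent reactions.
    """
    cq_wt = _require_numeric("cq_wt", cq_wt, total_cycles)
    cq_mut = _require_numeric("cq_mut", cq_mut, total_cycles)
    cq_rp_wt = _require_numeric("cq_rp_wt", cq_rp_wt, total_cycles)
    cq_rp_mut = _require_numeric("cq_rp_mut", cq_rp_mut, total_cycles)
    ddcq = (cq_wt - cq_rp_wt) - (cq_mut - cq_rp_mut)
    return 100.0 / (2.0 ** (-ddcq) + 1.0)


def classify_result(
    record: ReactionPairRecord,
    policy: QcPolicy = QcPolicy(),
    formula: str = "auto",
) -> MutantFractionResult:
    """Turn a Cq quartet into a qualitative call and (when valid) a percent.

    Decision sequence:

    1. wild-type reaction undetermined -> :class:`InvalidSampleError`
       (the sample did not amplify at all; not a negative).
    2. mutant reaction undetermined, or its Cq at/past ``cq_cutoff``
       -> ``not_detected`` (late signal is wrong-allele crosstalk).
    3. otherwise compute the percent with the selected formula;
       below the LOD -> ``not_detected``; in [LOD, LOQ) ->
       ``detected_below_loq``; at/above the LOQ -> ``quantified``.

    ``formula`` is ``"simple"``, ``"corrected"`` (RNase P-normalised) or
    ``"auto"`` (corrected when both reference Cqs are numeric, else
    simple).  Reference-Cq imbalance or weak reference amplification is
    reported in ``warnings``, never as an error.
    """
    if formula not in ("auto", "simple", "corrected"):
        raise ValueError(f"unknown formula {formula!r}")
    if is_undetermined(record.cq_wt):
        raise InvalidSampleError(
            f"sample {record.sample_id!r}: wild-type reaction did not amplify"
        )

    rp_ok = not (is_undetermined(record.cq_rp_wt) or is_undetermined(record.cq_rp_mut))
    if formula == "auto":
        formula = "corrected" if rp_ok else "simple"
    if formula == "corrected" and not rp_ok:
        return MutantFractionResult(
            sample_id=record.sample_id,
            status=CallStatus.INVALID_NO_REFERENCE,
            formula="corrected",
            specimen=record.specimen,
            warnings=("reference (RNase P) Cq missing in at least one reaction",),
        )

    warnings: list[str] = []
    if rp_ok:
        rp_wt, rp_mut = float(record.cq_rp_wt), float(record.cq_rp_mut)
        if abs(rp_wt - rp_mut) > policy.rp_delta_warn:
            warnings.append(
                f"reference Cq differs by {abs(rp_wt - rp_mut):.2f} cycles "
                f"between reactions (warn at {policy.rp_delta_warn})"
            )
        if max(rp_wt, rp_mut) > policy.rp_max_cq:
            warnings.append(
                f"reference Cq {max(rp_wt, rp_mut):.2f} above {policy.rp_max_cq} "
                "(low template or inhibition)"
            )

    def result(**kw) -> MutantFractionResult:
        return MutantFractionResult(
            sample_id=record.sample_id,
            formula=formula,
            specimen=record.specimen,
            warnings=tuple(warnings),
            **kw,
        )

    if is_undetermined(record.cq_mut) or float(record.cq_mut) >= policy.cq_cutoff:
        return result(status=CallStatus.NOT_DETECTED)

    cq_wt = float(record.cq_wt)
    cq_mut = float(record.cq_mut)
    delta_cq = cq_wt - cq_mut
    if formula == "corrected":
        ddcq = (cq_wt - float(record.cq_rp_wt)) - (cq_mut - float(record.cq_rp_mut))
        percent = mutant_percent_corrected(
            cq_wt, cq_mut, float(record.cq_rp_wt), float(record.cq_rp_mut),
            policy.total_cycles,
        )
        deltas = {"delta_cq": delta_cq, "delta_delta_cq": ddcq}
    else:
        percent = mutant_percent_simple(cq_wt, cq_mut, policy.total_cycles)
        deltas = {"delta_cq": delta_cq}

    if percent < policy.lod_percent:
        return result(status=CallStatus.NOT_DETECTED, **deltas)
    if percent < policy.loq_percent:
        return result(status=CallStatus.DETECTED_BELOW_LOQ, percent=percent, **deltas)
    return result(status=CallStatus.QUANTIFIED, percent=percent, **deltas)


@dataclass(frozen=True)
class StandardCurveModel:
    """Fitted qPCR calibration line Cq = slope * log10(conc) + intercept."""

    slope: float
    intercept: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("an amplifying assay has a negative slope")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency E = 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def cq_at(self, log10_conc: float) -> float:
        return self.slope * log10_conc + self.intercept


def copies_from_cq(cq: float, curve: StandardCurveModel) -> float:
    """Invert a standard curve: template copies per reaction for a Cq."""
    if is_undetermined(cq):
        raise ValueError("cannot invert an undetermined Cq")
    return 10.0 ** ((float(cq) - curve.intercept) / curve.slope)


@dataclass(frozen=True)
class GenomeConstants:
    """Constants converting genome copies to DNA mass concentration.

    haploid_genome_ng: mass of one haploid human genome (ng);
    ds_correction: single-copy target counted once per strand of dsDNA;
    reaction_input_volume: DNA volume per reaction (uL).
    """

    haploid_genome_ng: float = 0.0033
    ds_correction: float = 2.0
    reaction_input_volume: float = 5.0

    def __post_init__(self) -> None:
        if min(self.haploid_genome_ng, self.ds_correction, self.reaction_input_volume) <= 0:
            raise ValueError("all genome constants must be strictly positive")


def dna_concentration_from_copies(
    copies: float, constants: GenomeConstants = GenomeConstants()
) -> float:
    """ng/uL of genomic DNA from single-copy target copies per reaction."""
    if copies < 0:
        raise ValueError("copies must be non-negative")
    return copies * constants.haploid_genome_ng / constants.ds_correction / constants.reaction_input_volume


def format_percent(percent: float) -> str:
    """Render a mutant-allele percent: 2 decimals at >=1%, 4 significant
    digits below 1% (trace fractions like 0.0015% keep their digits)."""
    if percent >= 1.0:
        return f"{percent:.2f}"
    return f"{percent:.4g}"
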