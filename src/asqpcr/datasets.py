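"""Built-in validation datasets for the JAK2 V617F AS-qPCR assay.

These are the published summary tables of the assay's validation
experiments, packaged so the detection-limit and quantification-limit
analyses can be rerun from scratch without raw instrument exports.
"""

from __future__ import annotations

from .core import StandardCurveModel
from .validation import DetectionTable, LoqLevel

__all__ = [
    "detection_panel",
    "loq_summary_levels",
    "rnasep_calibration_curve",
]

# 2-fold dilution of the mutant allele from 1.16%, nine replicates per
# level; counts of replicates with a positive mutant signal.
_PANEL_LEVELS = (1.160, 0.580, 0.290, 0.145, 0.073, 0.036, 0.018, 0.009)
_PANEL_DETECTED = (9, 9, 9, 8, 4, 0, 0, 0)


def detection_panel() -> DetectionTable:
    """The assay's replicate detection panel (9 tested per level)."""
    return DetectionTable(
        levels_percent=_PANEL_LEVELS,
        n_tested=(9,) * len(_PANEL_LEVELS),
        n_detected=_PANEL_DETECTED,
    )


# Observed mean +/- SD of the quantified percent at the four levels that
# were detected in at least eight of nine replicates.
_LOQ_SUMMARIES = (
    # (level %, observed mean, observed sd, n, detected, tested)
    (1.16, 1.03, 0.25, 9, 9, 9),
    (0.58, 0.19, 0.06, 9, 9, 9),
    (0.29, 0.048, 0.037, 9, 9, 9),
    (0.15, 0.0098, 0.0053, 9, 8, 9),
)


def loq_summary_levels() -> list[LoqLevel]:
    """Observed-vs-expected summaries feeding the LOQ assessment."""
    return [
        LoqLevel(
            level_percent=level,
            mean=mean,
            sd=sd,
            n=n,
            n_detected=det,
            n_tested=tot,
        )
        for level, mean, sd, n, det, tot in _LOQ_SUMMARIES
    ]


def rnasep_calibration_curve() -> StandardCurveModel:
    """The RNase P absolute-quantification calibration line
    (Cq = -3.26 * log10(copies) + 29.75, R^2 = 0.998)."""
    return StandardCurveModel(slope=-3.26, intercept=29.75, r_squared=0.998)
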