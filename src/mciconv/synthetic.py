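"""Synthetic MCI cohorts with group-level cortical atrophy.

Emulates the statistical structure the classification pipeline assumes:
converters (MCIc) carry a focal cortical-thickness reduction in a designated
set of "effect" ROIs, which produces (a) direct mean differences in the CT
and CV columns of those ROIs and (b) emergent differences in thickness-
similarity-network topology, because a shifted ROI sits further (in thickness
space) from every other ROI and therefore loses edges under a fixed
connection cost.

Generative model, per subject:

* CT ~ equicorrelated Gaussian: ``ct = ct_mean + sd*(sqrt(rho)*z0 +
  sqrt(1-rho)*z_i)`` with a shared factor ``z0`` per subject; converters have
  ``effect_size_ct`` subtracted in the effect ROIs; values are floored at
  0.5 mm rather than resampled so a single seed stream stays deterministic.
* CS ~ independent Gaussian (mm2), floored positive.
* CV = coupling * CT * CS + Gaussian noise (mm3), floored positive —
  volume is approximately thickness times area.

Default group sizes (83 non-converters vs 76 converters) mirror the
baseline-scan diagnostic pair of the motivating cohort, reproducing the class
imbalance the evaluation metrics must handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import Cohort, SubjectRecord, NETWORK_CATEGORIES
from .rois import ALL_ROI_NAMES, N_ROIS, ROIName

__all__ = ["SynthConfig", "GroundTruth", "generate_cohort", "permute_labels"]

#: Thickness floor (mm): Gaussian draws are clipped here, never resampled.
CT_FLOOR = 0.5
CS_FLOOR = 100.0
CV_FLOOR = 100.0

#: Default effect ROIs — left inferior parietal, middle temporal, precuneus,
#: regions consistently implicated in MCI-to-AD conversion.
DEFAULT_EFFECT_ROIS = ("IPC_L", "MTG_L", "PCUN_L")


@dataclass
class SynthConfig:
    """Parameters of the synthetic-cohort generator.

    Units: ``ct_mean``/``ct_sd``/``effect_size_ct`` in mm, ``cs_mean``/
    ``cs_sd`` in mm2, ``cv_noise_sd`` in mm3; ``roi_correlation`` is the
    within-subject equicorrelation of ROI thicknesses; ``cv_cs_coupling`` is
    the dimensionless factor in CV = coupling * CT * CS + noise.
    """

    n_mcinc: int = 83
    n_mcic: int = 76
    effect_rois: tuple[str, ...] = DEFAULT_EFFECT_ROIS
    effect_size_ct: float = 0.5
    ct_mean: float = 2.5
    ct_sd: float = 0.25
    roi_correlation: float = 0.3
    cs_mean: float = 2000.0
    cs_sd: float = 250.0
    cv_cs_coupling: float = 1.0
    cv_noise_sd: float = 250.0
    pair_tag: str = "mixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mcinc < 2 or self.n_mcic < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not 0.0 <= self.roi_correlation < 1.0:
            raise ValueError("roi_correlation must lie in [0, 1)")
        if self.effect_size_ct > 0 and not self.effect_rois:
            raise ValueError("effect_size_ct > 0 requires non-empty effect_rois")
        if self.effect_size_ct >= self.ct_mean:
            raise ValueError(
                "effect_size_ct >= ct_mean would push mean thickness non-positive"
            )
        for roi in self.effect_rois:
            ROIName.parse(roi)  # validates

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_rois"] = list(self.effect_rois)
        return d


@dataclass
class GroundTruth:
    """Column names that carry injected group signal.

    CT and CV columns of the effect ROIs carry the direct atrophy signal
    (CV inherits it through the coupling); the ND/NL columns of the same ROIs
    carry the emergent network signal.  CS is unaffected by construction.
    """

    effect_columns: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def for_rois(cls, effect_rois: tuple[str, ...]) -> "GroundTruth":
        cats = ("CT", "CV") + NETWORK_CATEGORIES
        return cls(frozenset(f"{c}:{roi}" for c in cats for roi in effect_rois))


def generate_cohort(config: SynthConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort from the generative model; identical seed, identical cohort."""
    rng = np.random.default_rng(config.seed)
    n = config.n_mcinc + config.n_mcic
    labels = np.r_[np.full(config.n_mcinc, -1), np.full(config.n_mcic, 1)]

    rho = config.roi_correlation
    shared = rng.standard_normal((n, 1))
    idio = rng.standard_normal((n, N_ROIS))
    ct = config.ct_mean + config.ct_sd * (
        np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * idio
    )
    effect_idx = [ALL_ROI_NAMES.index(r) for r in config.effect_rois]
    if config.effect_size_ct > 0:
        ct[np.ix_(labels == 1, effect_idx)] -= config.effect_size_ct
    ct = np.maximum(ct, CT_FLOOR)

    cs = np.maximum(
        config.cs_mean + config.cs_sd * rng.standard_normal((n, N_ROIS)), CS_FLOOR
    )
    cv = np.maximum(
        config.cv_cs_coupling * ct * cs
        + config.cv_noise_sd * rng.standard_normal((n, N_ROIS)),
        CV_FLOOR,
    )

    subjects = []
    n_nc = config.n_mcinc
    for i in range(n):
        group, k = ("MCInc", i) if i < n_nc else ("MCIc", i - n_nc)
        subjects.append(
            SubjectRecord(
                subject_id=f"{group}_{k:03d}",
                label=int(labels[i]),
                ct=ct[i],
                cv=cv[i],
                cs=cs[i],
                pair_tag=config.pair_tag,
            )
        )
    return Cohort(subjects, pair_tag=config.pair_tag), GroundTruth.for_rois(
        tuple(config.effect_rois)
    )


def permute_labels(cohort: Cohort, seed: int) -> Cohort:
    """Randomly permute diagnostic labels across subjects, features untouched.

    Label counts are conserved, making this the null-calibration harness for
    the nested-CV pipeline: any systematic above-chance accuracy on permuted
    labels would indicate information leaking from held-out subjects.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects to permute")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cohort))
    labels = cohort.labels[perm]
    subjects = [
        SubjectRecord(
            subject_id=s.subject_id,
            label=int(labels[i]),
            ct=s.ct,
            cv=s.cv,
            cs=s.cs,
            pair_tag=s.pair_tag,
        )
        for i, s in enumerate(cohort.subjects)
    ]
    return Cohort(subjects, pair_tag=cohort.pair_tag)
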