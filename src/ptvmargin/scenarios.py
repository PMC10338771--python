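"""Validation scenarios: adaptive first-fraction margins and covariance envelopes.

Scenario 1 (:func:`adaptive_margins`): the first fraction is planned with the
covariance-free extended recipe; its covariance estimate is then frozen and
applied to every later fraction via the covariance-augmented recipe
(components re-estimated per fraction).  A variant freezes the correlation
coefficient instead, rescaling by each later fraction's stream SDs.

Scenario 2 (:func:`covariance_envelope`): per patient and direction, the
signed min/max covariance across fractions and the margins/relative
differences at both ends, computed against fixed patient-level components so
the envelope brackets every per-fraction margin by monotonicity.

Covariances estimated in one fraction are clipped to the admissibility bound
of the components they are combined with (the raw estimate is recorded).
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .correlation import estimate_fraction_covariance
from .errors import ErrorComponents, StaticUncertaintyTable, fraction_components, patient_components
from .exceptions import ScenarioNotApplicableError
from .logio import FractionLog
from .margins import COV_TOL, MarginResult, mvhf, relative_difference, vhf_extended

__all__ = ["AdaptivePlan", "CovarianceEnvelope", "adaptive_margins", "covariance_envelope"]


def _clip_admissible(cov: np.ndarray, c: ErrorComponents) -> np.ndarray:
    """Clip a covariance vector into the admissible range of ``c``'s random SDs."""
    bound = c.rand_mod * c.rand_pred
    clipped = np.clip(cov, -bound, bound)
    if np.any(np.abs(cov) > bound + COV_TOL):
        warnings.warn(
            "covariance estimate exceeds the admissibility bound of the target "
            "components; clipped to +-sigma_mod*sigma_pred",
            stacklevel=3,
        )
    return clipped


def _nan_to_zero(cov: np.ndarray) -> np.ndarray:
    if np.any(~np.isfinite(cov)):
        warnings.warn("undefined covariance direction(s) treated as 0", stacklevel=3)
        return np.where(np.isfinite(cov), cov, 0.0)
    return cov


@dataclass(frozen=True)
class AdaptivePlan:
    """First-fraction margin plus covariance-informed margins for later fractions."""

    patient_id: str
    fraction_1_index: int
    fraction_1_margin: MarginResult  # covariance-free extended recipe
    later_fraction_indices: list[int]
    later_fraction_margins: list[MarginResult]  # covariance-augmented
    cov_from_fraction_1: np.ndarray  # (3,) mm^2, raw estimate
    applied_cov: list[np.ndarray]  # per later fraction, after admissibility clipping
    freeze: str  # "cov" or "r"


def adaptive_margins(
    patient_fractions: Sequence[FractionLog],
    static: StaticUncertaintyTable | None = None,
    *,
    penumbra_sd: float = 6.4,
    beta: float = 0.84,
    pairing: str = "nearest_in_time",
    freeze: str = "cov",
) -> AdaptivePlan:
    """Scenario 1: first-fraction covariance feeds the later-fraction margins."""
    if freeze not in ("cov", "r"):
        raise ScenarioNotApplicableError(f"freeze must be 'cov' or 'r', got {freeze!r}")
    fracs = sorted(patient_fractions, key=lambda f: f.fraction_index)
    if len(fracs) < 2:
        raise ScenarioNotApplicableError(
            f"adaptive scenario needs >= 2 fractions, got {len(fracs)}"
        )
    indices = [f.fraction_index for f in fracs]
    if len(set(indices)) != len(indices):
        raise ScenarioNotApplicableError(f"tied fraction indices: {indices}")
    pids = {f.patient_id for f in fracs}
    if len(pids) != 1:
        raise ScenarioNotApplicableError(f"fractions span several patients: {sorted(pids)}")

    first, later = fracs[0], fracs[1:]
    est1 = estimate_fraction_covariance(first, pairing)
    cov1 = _nan_to_zero(est1.cov.copy())
    r1 = np.where(np.isfinite(est1.pearson_r), est1.pearson_r, 0.0)

    comp1 = fraction_components(first, static, penumbra_sd=penumbra_sd, beta=beta)
    m1 = vhf_extended(comp1)

    later_margins: list[MarginResult] = []
    applied: list[np.ndarray] = []
    for f in later:
        comp = fraction_components(f, static, penumbra_sd=penumbra_sd, beta=beta)
        cov = cov1 if freeze == "cov" else r1 * comp.rand_mod * comp.rand_pred
        cov = _clip_admissible(cov, comp)
        applied.append(cov)
        later_margins.append(mvhf(comp, cov))
    return AdaptivePlan(
        patient_id=first.patient_id,
        fraction_1_index=first.fraction_index,
        fraction_1_margin=m1,
        later_fraction_indices=[f.fraction_index for f in later],
        later_fraction_margins=later_margins,
        cov_from_fraction_1=est1.cov,
        applied_cov=applied,
        freeze=freeze,
    )


@dataclass(frozen=True)
class CovarianceEnvelope:
    """Min/max covariance across a patient's fractions and the margins at both."""

    patient_id: str
    site: str
    components: ErrorComponents  # fixed patient-level components
    cov_min: np.ndarray  # (3,) mm^2 (after admissibility clipping)
    cov_max: np.ndarray  # (3,)
    vhf_margin: np.ndarray  # (3,) mm, covariance-free reference
    margin_at_min: np.ndarray  # (3,) mm
    margin_at_max: np.ndarray  # (3,) mm
    rel_diff_min: np.ndarray  # (3,) percent
    rel_diff_max: np.ndarray  # (3,) percent
    per_fraction_cov: list[np.ndarray]  # clipped, one (3,) per usable fraction
    per_fraction_margins: list[np.ndarray]  # covariance-augmented, same components
    fraction_indices: list[int]


def covariance_envelope(
    patient_fractions: Sequence[FractionLog],
    static: StaticUncertaintyTable | None = None,
    *,
    penumbra_sd: float = 6.4,
    beta: float = 0.84,
    pairing: str = "nearest_in_time",
) -> CovarianceEnvelope:
    """Scenario 2: signed covariance envelope and margins at its ends."""
    fracs = sorted(patient_fractions, key=lambda f: f.fraction_index)
    if not fracs:
        raise ScenarioNotApplicableError("need >= 1 fraction")
    comp = patient_components(fracs, static, penumbra_sd=penumbra_sd, beta=beta)

    covs: list[np.ndarray] = []
    kept: list[int] = []
    for f in fracs:
        est = estimate_fraction_covariance(f, pairing)
        cov = _clip_admissible(_nan_to_zero(est.cov.copy()), comp)
        covs.append(cov)
        kept.append(f.fraction_index)
    cov_stack = np.array(covs)
    cov_min = cov_stack.min(axis=0)
    cov_max = cov_stack.max(axis=0)

    vhf_m = vhf_extended(comp).margin_mm
    m_min = mvhf(comp, cov_min).margin_mm
    m_max = mvhf(comp, cov_max).margin_mm
    return CovarianceEnvelope(
        patient_id=fracs[0].patient_id,
        site=fracs[0].site,
        components=comp,
        cov_min=cov_min,
        cov_max=cov_max,
        vhf_margin=vhf_m,
        margin_at_min=m_min,
        margin_at_max=m_max,
        rel_diff_min=relative_difference(m_min, vhf_m),
        rel_diff_max=relative_difference(m_max, vhf_m),
        per_fraction_cov=covs,
        per_fraction_margins=[mvhf(comp, cv).margin_mm for cv in covs],
        fraction_indices=kept,
    )
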