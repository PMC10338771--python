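"""Systematic/random error decomposition and static per-source uncertainties.

The decomposition follows the standard preparation/execution split: the
systematic SD is the SD of per-patient mean errors, the random SD is the RMS
of the per-fraction SDs.  Sample SDs use denominator n-1 throughout.

Static components (segmentation, deformation, robot targeting) are assigned
from :class:`StaticUncertaintyTable`, not estimated from the logs.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, InsufficientCohortError, InsufficientDataError
from .logio import CK_VERSIONS, DIRECTIONS, FractionLog, SOURCES

__all__ = [
    "StreamSummary",
    "FractionSummary",
    "PopulationErrors",
    "StaticUncertaintyTable",
    "ErrorComponents",
    "summarize_fraction",
    "population_errors",
    "assign_static",
    "total_tracking_error",
    "fraction_components",
    "patient_components",
    "cohort_components",
]


def _dir3(x, name: str) -> np.ndarray:
    """Coerce a scalar or length-3 sequence to a float (3,) array."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(3, float(arr))
    if arr.shape != (3,):
        raise ConfigurationError(f"{name} must be a scalar or 3-vector (SI, LR, AP), got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"{name} must be finite, got {arr}")
    return arr


@dataclass(frozen=True)
class StreamSummary:
    """Per-direction mean and sample SD (ddof=1) of one error stream."""

    mean: np.ndarray  # (3,) mm
    sd: np.ndarray  # (3,) mm
    n: int


@dataclass(frozen=True)
class FractionSummary:
    """Mean/SD/n of the model and prediction streams of one fraction."""

    patient_id: str
    fraction_index: int
    model: StreamSummary
    prediction: StreamSummary

    def stream(self, source: str) -> StreamSummary:
        return self.model if source == "model" else self.prediction


@dataclass(frozen=True)
class PopulationErrors:
    """Cohort-level systematic (Sigma) and random (sigma) SDs per direction."""

    sys_mod: np.ndarray
    sys_pred: np.ndarray
    rand_mod: np.ndarray
    rand_pred: np.ndarray
    n_patients: int
    n_fractions: int


def _default_e2e_mean() -> dict[str, tuple[float, float, float]]:
    return {
        "G3_6_2_3": (0.5, 0.5, 0.5),
        "VSI_8_5": (0.37, 0.12, 0.15),
        "VSI_9_5": (0.37, 0.12, 0.15),
    }


def _default_e2e_sd() -> dict[str, tuple[float, float, float]]:
    return {
        "G3_6_2_3": (0.3, 0.3, 0.3),
        "VSI_8_5": (0.53, 0.19, 0.36),
        "VSI_9_5": (0.53, 0.19, 0.36),
    }


@dataclass(frozen=True)
class StaticUncertaintyTable:
    """Static per-source uncertainty assignments.

    Defaults: isotropic segmentation SD 0.54 mm; deformation SD 1.5 mm for
    tumor motion below 2 cm and 2.5 mm above; end-to-end (E2E) targeting
    mean/SD per delivery-system version and direction.
    """

    segmentation_sd_mm: float = 0.54
    deformation_threshold_cm: float = 2.0
    deformation_low_mm: float = 1.5
    deformation_high_mm: float = 2.5
    e2e_mean_mm: Mapping[str, tuple[float, float, float]] = field(default_factory=_default_e2e_mean)
    e2e_sd_mm: Mapping[str, tuple[float, float, float]] = field(default_factory=_default_e2e_sd)

    def __post_init__(self):
        scalars = (
            self.segmentation_sd_mm,
            self.deformation_threshold_cm,
            self.deformation_low_mm,
            self.deformation_high_mm,
        )
        if any(not (v >= 0) for v in scalars):
            raise ConfigurationError("all static-uncertainty entries must be >= 0")
        for table in (self.e2e_mean_mm, self.e2e_sd_mm):
            for ver, vals in table.items():
                if ver not in CK_VERSIONS:
                    raise ConfigurationError(f"unknown ck_version {ver!r} in E2E table")
                if len(vals) != 3 or any(not (v >= 0) for v in vals):
                    raise ConfigurationError(f"E2E entry for {ver!r} must be 3 values >= 0")

    def to_file(self, path) -> None:
        lines = [
            f"segmentation_sd_mm={self.segmentation_sd_mm!r}",
            f"deformation_threshold_cm={self.deformation_threshold_cm!r}",
            f"deformation_low_mm={self.deformation_low_mm!r}",
            f"deformation_high_mm={self.deformation_high_mm!r}",
        ]
        for ver in CK_VERSIONS:
            if ver in self.e2e_mean_mm:
                lines.append(f"e2e_mean_{ver}=" + ",".join(repr(float(v)) for v in self.e2e_mean_mm[ver]))
            if ver in self.e2e_sd_mm:
                lines.append(f"e2e_sd_{ver}=" + ",".join(repr(float(v)) for v in self.e2e_sd_mm[ver]))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "StaticUncertaintyTable":
        kwargs: dict = {}
        e2e_mean = _default_e2e_mean()
        e2e_sd = _default_e2e_sd()
        with open(path, "r", encoding="utf-8") as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                try:
                    if key.startswith("e2e_mean_"):
                        e2e_mean[key.removeprefix("e2e_mean_")] = tuple(float(v) for v in val.split(","))  # type: ignore[assignment]
                    elif key.startswith("e2e_sd_"):
                        e2e_sd[key.removeprefix("e2e_sd_")] = tuple(float(v) for v in val.split(","))  # type: ignore[assignment]
                    elif key in (
                        "segmentation_sd_mm",
                        "deformation_threshold_cm",
                        "deformation_low_mm",
                        "deformation_high_mm",
                    ):
                        kwargs[key] = float(val)
                    else:
                        raise ConfigurationError(f"unknown static-table key {key!r}")
                except ValueError:
                    raise ConfigurationError(f"non-numeric value for {key!r}: {val!r}") from None
        return cls(e2e_mean_mm=e2e_mean, e2e_sd_mm=e2e_sd, **kwargs)


@dataclass(frozen=True)
class ErrorComponents:
    """All inputs of the extended margin recipes, per direction (SI, LR, AP).

    Five systematic SDs (segmentation, deformation, model, prediction,
    targeting), two random SDs (model, prediction), the effective penumbra
    width ``penumbra_sd`` (default 6.4 mm) and dose-level coefficient
    ``beta`` (default 0.84).
    """

    sys_seg: np.ndarray
    sys_def: np.ndarray
    sys_mod: np.ndarray
    sys_pred: np.ndarray
    sys_tar: np.ndarray
    rand_mod: np.ndarray
    rand_pred: np.ndarray
    penumbra_sd: float = 6.4
    beta: float = 0.84

    def __post_init__(self):
        for name in ("sys_seg", "sys_def", "sys_mod", "sys_pred", "sys_tar", "rand_mod", "rand_pred"):
            arr = _dir3(getattr(self, name), name)
            if np.any(arr < 0):
                raise ConfigurationError(f"{name} must be >= 0, got {arr}")
            object.__setattr__(self, name, arr)
        if not (0 < self.beta <= 2.5):
            raise ConfigurationError(f"beta must lie in (0, 2.5], got {self.beta}")
        if not (self.penumbra_sd > 0):
            raise ConfigurationError(f"penumbra_sd must be > 0, got {self.penumbra_sd}")

    def scaled(self, c: float) -> "ErrorComponents":
        """Multiply every SD input (including the penumbra width) by c > 0."""
        if not c > 0:
            raise ConfigurationError("scale factor must be > 0")
        return replace(
            self,
            sys_seg=self.sys_seg * c,
            sys_def=self.sys_def * c,
            sys_mod=self.sys_mod * c,
            sys_pred=self.sys_pred * c,
            sys_tar=self.sys_tar * c,
            rand_mod=self.rand_mod * c,
            rand_pred=self.rand_pred * c,
            penumbra_sd=self.penumbra_sd * c,
        )


def summarize_fraction(log: FractionLog) -> FractionSummary:
    """Per-direction, per-source arithmetic mean and sample SD (ddof=1).

    Raises :class:`InsufficientDataError` if a stream has fewer than 2 samples.
    """
    stats: dict[str, StreamSummary] = {}
    for source in SOURCES:
        _, errs = log.stream(source)
        if errs.shape[0] < 2:
            raise InsufficientDataError(
                f"patient {log.patient_id} fraction {log.fraction_index}: "
                f"{source} stream has {errs.shape[0]} sample(s), need >= 2"
            )
        stats[source] = StreamSummary(
            mean=errs.mean(axis=0), sd=errs.std(axis=0, ddof=1), n=errs.shape[0]
        )
    return FractionSummary(
        patient_id=log.patient_id,
        fraction_index=log.fraction_index,
        model=stats["model"],
        prediction=stats["prediction"],
    )


def population_errors(summaries: Iterable[FractionSummary]) -> PopulationErrors:
    """Cohort Sigma/sigma for the model and prediction streams.

    Grouped by ``patient_id``: each patient's mean is the mean of its fraction
    means; Sigma is the SD (ddof=1) over patient means and sigma the RMS over
    all fraction SDs.  Requires >= 2 patients.
    """
    by_patient: dict[str, list[FractionSummary]] = {}
    for s in summaries:
        by_patient.setdefault(s.patient_id, []).append(s)
    if len(by_patient) < 2:
        raise InsufficientCohortError(f"need >= 2 patients, got {len(by_patient)}")

    out: dict[str, np.ndarray] = {}
    n_frac = sum(len(v) for v in by_patient.values())
    for source in SOURCES:
        patient_means = np.array(
            [np.mean([s.stream(source).mean for s in frs], axis=0) for frs in by_patient.values()]
        )  # (P, 3)
        fraction_sds = np.array(
            [s.stream(source).sd for frs in by_patient.values() for s in frs]
        )  # (F, 3)
        out[f"sys_{source}"] = patient_means.std(axis=0, ddof=1)
        out[f"rand_{source}"] = np.sqrt(np.mean(fraction_sds**2, axis=0))
    return PopulationErrors(
        sys_mod=out["sys_model"],
        sys_pred=out["sys_prediction"],
        rand_mod=out["rand_model"],
        rand_pred=out["rand_prediction"],
        n_patients=len(by_patient),
        n_fractions=n_frac,
    )


def assign_static(
    site_log: FractionLog, table: StaticUncertaintyTable | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign (segmentation, deformation, targeting) systematic SDs, mm, (3,).

    Deformation follows the motion-amplitude rule: below the threshold the
    low value applies, above it the high value.  Motion exactly at the
    threshold is not covered by the rule; it maps to the low branch with a
    warning.  Targeting Sigma is the E2E SD for the log's system version.
    """
    table = table or StaticUncertaintyTable()
    seg = np.full(3, table.segmentation_sd_mm)
    motion = site_log.motion_amplitude_cm
    if motion == table.deformation_threshold_cm:
        warnings.warn(
            f"motion amplitude exactly at {table.deformation_threshold_cm} cm threshold; "
            "assigned to the low deformation branch",
            stacklevel=2,
        )
    deform = np.full(3, table.deformation_low_mm if motion <= table.deformation_threshold_cm else table.deformation_high_mm)
    if site_log.ck_version not in table.e2e_sd_mm:
        raise ConfigurationError(f"no E2E entry for ck_version {site_log.ck_version!r}")
    tar = np.asarray(table.e2e_sd_mm[site_log.ck_version], dtype=float)
    return seg, deform, tar


def total_tracking_error(
    summary: FractionSummary,
    e2e_mean: Sequence[float] | np.ndarray,
    e2e_sd: Sequence[float] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Total tracking error: model, prediction and E2E combined in quadrature.

    Returns per-direction (mean, SD), each the square root of the sum of the
    squares of the three contributors.
    """
    e2e_mean = _dir3(e2e_mean, "e2e_mean")
    e2e_sd = _dir3(e2e_sd, "e2e_sd")
    mean = np.sqrt(summary.model.mean**2 + summary.prediction.mean**2 + e2e_mean**2)
    sd = np.sqrt(summary.model.sd**2 + summary.prediction.sd**2 + e2e_sd**2)
    return mean, sd


def fraction_components(
    log: FractionLog,
    table: StaticUncertaintyTable | None = None,
    *,
    penumbra_sd: float = 6.4,
    beta: float = 0.84,
) -> ErrorComponents:
    """Single-fraction error components.

    With only one fraction there is no between-fraction spread, so the
    systematic model/prediction SDs are taken as the magnitude of the
    fraction's mean errors (the realized systematic offset) and the random
    SDs as the within-fraction stream SDs.
    """
    summary = summarize_fraction(log)
    seg, deform, tar = assign_static(log, table)
    return ErrorComponents(
        sys_seg=seg,
        sys_def=deform,
        sys_mod=np.abs(summary.model.mean),
        sys_pred=np.abs(summary.prediction.mean),
        sys_tar=tar,
        rand_mod=summary.model.sd,
        rand_pred=summary.prediction.sd,
        penumbra_sd=penumbra_sd,
        beta=beta,
    )


def patient_components(
    fractions: Sequence[FractionLog],
    table: StaticUncertaintyTable | None = None,
    *,
    penumbra_sd: float = 6.4,
    beta: float = 0.84,
) -> ErrorComponents:
    """Patient-level error components over >= 1 fractions.

    Sigma_mod/Sigma_pred = SD (ddof=1) of the fraction means (single
    fraction: |mean|, as in :func:`fraction_components`); sigma = RMS of the
    fraction SDs.  Static components use the fraction with the largest motion
    amplitude (conservative deformation branch).
    """
    if not fractions:
        raise InsufficientDataError("need >= 1 fraction")
    versions = {f.ck_version for f in fractions}
    if len(versions) > 1:
        raise ConfigurationError(f"mixed ck_versions within one patient: {sorted(versions)}")
    summaries = [summarize_fraction(f) for f in fractions]
    ref = max(fractions, key=lambda f: f.motion_amplitude_cm)
    seg, deform, tar = assign_static(ref, table)

    sys_sd: dict[str, np.ndarray] = {}
    rand_sd: dict[str, np.ndarray] = {}
    for source in SOURCES:
        means = np.array([s.stream(source).mean for s in summaries])
        sds = np.array([s.stream(source).sd for s in summaries])
        sys_sd[source] = means.std(axis=0, ddof=1) if len(summaries) >= 2 else np.abs(means[0])
        rand_sd[source] = np.sqrt(np.mean(sds**2, axis=0))
    return ErrorComponents(
        sys_seg=seg,
        sys_def=deform,
        sys_mod=sys_sd["model"],
        sys_pred=sys_sd["prediction"],
        sys_tar=tar,
        rand_mod=rand_sd["model"],
        rand_pred=rand_sd["prediction"],
        penumbra_sd=penumbra_sd,
        beta=beta,
    )


def cohort_components(
    fractions: Sequence[FractionLog],
    table: StaticUncertaintyTable | None = None,
    *,
    penumbra_sd: float = 6.4,
    beta: float = 0.84,
) -> ErrorComponents:
    """Cohort-level (e.g. per-site) components from >= 2 patients."""
    pop = population_errors(summarize_fraction(f) for f in fractions)
    versions = {f.ck_version for f in fractions}
    if len(versions) > 1:
        raise ConfigurationError(f"mixed ck_versions within one cohort group: {sorted(versions)}")
    ref = max(fractions, key=lambda f: f.motion_amplitude_cm)
    seg, deform, tar = assign_static(ref, table)
    return ErrorComponents(
        sys_seg=seg,
        sys_def=deform,
        sys_mod=pop.sys_mod,
        sys_pred=pop.sys_pred,
        sys_tar=tar,
        rand_mod=pop.rand_mod,
        rand_pred=pop.rand_pred,
        penumbra_sd=penumbra_sd,
        beta=beta,
    )
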