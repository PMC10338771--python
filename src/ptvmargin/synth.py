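"""Synthetic tracking-log cohorts with controlled statistical structure.

The generator emulates the cadence of real tracking logs: sparse model-error
samples (one per model update, default every 60 s) and a dense prediction-
error stream (default every 40 ms).  Errors are Gaussian: each patient draws
a per-direction systematic offset for both streams; within a fraction, the
(model, prediction) value at each model timestamp comes from a bivariate
normal with configurable correlation ``rho``, and prediction samples between
model updates come from the prediction marginal.

Randomness is split per patient/fraction via ``numpy`` seed sequences, so a
cohort is byte-reproducible from its seed and extending ``n_patients`` never
perturbs existing patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .logio import CK_VERSIONS, CohortLog, FractionLog, SITES, TRACKING_MODES, TrackingSample

__all__ = ["SynthConfig", "simulate_cohort", "preset_cohort", "PRESETS"]


def _vec3(x, name: str) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(3, float(arr))
    if arr.shape != (3,) or not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"{name} must be a finite scalar or 3-vector, got {x!r}")
    return tuple(float(v) for v in arr)


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic cohort (all SDs in mm, per SI/LR/AP)."""

    n_patients: int
    fractions_per_patient: int
    fraction_duration_s: float
    model_cadence_s: float = 60.0
    prediction_cadence_s: float = 0.04
    systematic_sd_model: tuple[float, float, float] = (0.5, 0.5, 0.5)
    systematic_sd_pred: tuple[float, float, float] = (0.3, 0.3, 0.3)
    random_sd_model: tuple[float, float, float] = (1.0, 1.0, 1.0)
    random_sd_pred: tuple[float, float, float] = (0.5, 0.5, 0.5)
    rho: tuple[float, float, float] = (0.0, 0.0, 0.0)
    site: str = "lower_left_lung"
    tracking_mode: str = "XLT"
    ck_version: str = "VSI_8_5"
    motion_amplitude_cm: float = 1.5
    seed: int = 0
    patient_prefix: str = "P"

    def __post_init__(self):
        if self.n_patients < 1 or self.fractions_per_patient < 1:
            raise ConfigurationError("n_patients and fractions_per_patient must be >= 1")
        if not (self.model_cadence_s > 0 and self.prediction_cadence_s > 0):
            raise ConfigurationError("cadences must be > 0")
        if self.fraction_duration_s < self.model_cadence_s:
            raise ConfigurationError("fraction_duration_s must cover at least one model cadence")
        for name in ("systematic_sd_model", "systematic_sd_pred", "random_sd_model", "random_sd_pred"):
            vec = _vec3(getattr(self, name), name)
            if any(v < 0 for v in vec):
                raise ConfigurationError(f"{name} must be >= 0, got {vec}")
            object.__setattr__(self, name, vec)
        rho = _vec3(self.rho, "rho")
        if any(abs(r) > 1 for r in rho):
            raise ConfigurationError(f"rho must lie in [-1, 1], got {rho}")
        object.__setattr__(self, "rho", rho)
        if self.site not in SITES:
            raise ConfigurationError(f"unknown site {self.site!r}")
        if self.tracking_mode not in TRACKING_MODES:
            raise ConfigurationError(f"unknown tracking_mode {self.tracking_mode!r}")
        if self.ck_version not in CK_VERSIONS:
            raise ConfigurationError(f"unknown ck_version {self.ck_version!r}")
        if not (self.motion_amplitude_cm >= 0):
            raise ConfigurationError("motion_amplitude_cm must be >= 0")


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn_key))


def _simulate_fraction(
    cfg: SynthConfig,
    patient_idx: int,
    fraction_idx: int,
    off_model: np.ndarray,
    off_pred: np.ndarray,
) -> FractionLog:
    rng = _rng(cfg.seed, patient_idx, fraction_idx)
    mc, pc, dur = cfg.model_cadence_s, cfg.prediction_cadence_s, cfg.fraction_duration_s
    n_m = int(np.floor(dur / mc + 1e-9))
    n_p = int(np.floor(dur / pc + 1e-9))
    t_model = mc * np.arange(1, n_m + 1)
    t_pred = pc * np.arange(1, n_p + 1)

    sd_m = np.asarray(cfg.random_sd_model)
    sd_p = np.asarray(cfg.random_sd_pred)
    rho = np.asarray(cfg.rho)

    # correlated pair at every model timestamp
    z1 = rng.standard_normal((n_m, 3))
    z2 = rng.standard_normal((n_m, 3))
    e_model = off_model + sd_m * z1
    e_pred_at_model = off_pred + sd_p * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)

    # prediction-grid samples: marginal draws, except where the grid lands on
    # a model timestamp (there the correlated value is used instead)
    ratio = t_pred / mc
    near = np.rint(ratio)
    on_model = (np.abs(ratio - near) < 1e-9) & (near >= 1) & (near <= n_m)
    e_pred_grid = off_pred + sd_p * rng.standard_normal((n_p, 3))
    model_slot = (near[on_model] - 1).astype(int)
    e_pred_grid[on_model] = e_pred_at_model[model_slot]
    t_pred = t_pred.copy()
    t_pred[on_model] = t_model[model_slot]  # snap to the exact model timestamp

    samples = [
        TrackingSample(time=float(t), source="model", error=tuple(e))
        for t, e in zip(t_model, e_model)
    ]
    samples += [
        TrackingSample(time=float(t), source="prediction", error=tuple(e))
        for t, e in zip(t_pred, e_pred_grid)
    ]
    # model timestamps not on the prediction grid still carry their paired
    # prediction sample, so the covariance is estimable at every model update
    covered = set(model_slot.tolist())
    for j in range(n_m):
        if j not in covered:
            samples.append(
                TrackingSample(
                    time=float(t_model[j]), source="prediction", error=tuple(e_pred_at_model[j])
                )
            )
    return FractionLog(
        patient_id=f"{cfg.patient_prefix}{patient_idx + 1:04d}",
        fraction_index=fraction_idx + 1,
        site=cfg.site,
        tracking_mode=cfg.tracking_mode,
        ck_version=cfg.ck_version,
        motion_amplitude_cm=cfg.motion_amplitude_cm,
        samples=samples,
    )


def simulate_cohort(config: SynthConfig) -> CohortLog:
    """Generate a cohort of fraction logs, fully reproducible from the seed."""
    fractions: list[FractionLog] = []
    for p in range(config.n_patients):
        rng_off = _rng(config.seed, p)
        off_model = rng_off.normal(0.0, config.systematic_sd_model)
        off_pred = rng_off.normal(0.0, config.systematic_sd_pred)
        for f in range(config.fractions_per_patient):
            fractions.append(_simulate_fraction(config, p, f, off_model, off_pred))
    return CohortLog(fractions=fractions)


# Presets are tuned so the total tracking-error SD (model, prediction and E2E
# combined in quadrature) falls in the ~0.9-1.5 mm band typical of clinical
# tracking logs.  The prediction cadence is coarsened from the hardware rate
# (40 ms) to keep demonstration cohorts small; it is configurable.
PRESETS: dict[str, SynthConfig] = {
    "lung_like": SynthConfig(
        n_patients=10,
        fractions_per_patient=3,
        fraction_duration_s=1800.0,
        model_cadence_s=60.0,
        prediction_cadence_s=2.0,
        systematic_sd_model=(0.5, 0.5, 0.5),
        systematic_sd_pred=(0.3, 0.3, 0.3),
        random_sd_model=(1.0, 1.0, 0.95),
        random_sd_pred=(0.5, 0.5, 0.5),
        rho=(0.3, 0.3, 0.3),
        site="lower_left_lung",
        tracking_mode="XLT",
        ck_version="VSI_8_5",
        motion_amplitude_cm=1.5,
        seed=0,
    ),
    "liver_like": SynthConfig(
        n_patients=10,
        fractions_per_patient=3,
        fraction_duration_s=1800.0,
        model_cadence_s=60.0,
        prediction_cadence_s=2.0,
        systematic_sd_model=(0.4, 0.4, 0.4),
        systematic_sd_pred=(0.25, 0.25, 0.25),
        random_sd_model=(0.75, 0.8, 0.75),
        random_sd_pred=(0.4, 0.45, 0.4),
        rho=(0.2, 0.2, 0.2),
        site="upper_liver",
        tracking_mode="FTT",
        ck_version="VSI_8_5",
        motion_amplitude_cm=1.0,
        seed=0,
    ),
}


def preset_cohort(name: str) -> SynthConfig:
    """Return a documented preset configuration (``lung_like`` or ``liver_like``)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
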