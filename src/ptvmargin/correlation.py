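"""Correlation, covariance and distance correlation between error streams.

The model-error stream is sparse (one sample per imaging/model update) while
the prediction-error stream is dense, so the two are first paired in time.
Per fraction, the Pearson coefficient of the paired samples is combined with
the full-stream SDs into a covariance (cov = r * sd_model * sd_prediction);
distance correlation is computed on the same pairs as a non-linear
dependence diagnostic.

Cohort aggregation mirrors the per-patient strategy: the per-fraction
estimate largest in magnitude (sign retained) is kept per patient, then
averaged over patients.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InsufficientDataError, UndefinedCorrelationError
from .logio import DIRECTIONS, CohortLog, FractionLog

__all__ = [
    "PairedSeries",
    "CovarianceEstimate",
    "CohortCovarianceRow",
    "PAIRING_RULES",
    "pair_streams",
    "pearson",
    "covariance",
    "distance_correlation",
    "estimate_fraction_covariance",
    "patient_covariance_extrema",
    "cohort_covariance",
]

PAIRING_RULES = ("nearest_in_time", "window_mean")

MIN_PAIRS = 3  # minimum pairs for any correlation estimate


@dataclass(frozen=True)
class PairedSeries:
    """Time-matched (model, prediction) error pairs; arrays of shape (n, 3)."""

    model: np.ndarray
    prediction: np.ndarray
    pairing_rule: str

    @property
    def n_pairs(self) -> int:
        return self.model.shape[0]


@dataclass(frozen=True)
class CovarianceEstimate:
    """Per-direction dependence estimates for one fraction.

    ``pearson_r``/``cov`` are NaN in directions where the correlation is
    undefined (constant marginal); ``dcorr`` is 0 there by convention.
    ``sd_model``/``sd_pred`` are the full-stream sample SDs entering the
    covariance product.
    """

    pearson_r: np.ndarray  # (3,)
    cov: np.ndarray  # (3,) mm^2
    dcorr: np.ndarray  # (3,) in [0, 1]
    n_pairs: int
    sd_model: np.ndarray  # (3,) mm
    sd_pred: np.ndarray  # (3,) mm


def pair_streams(log: FractionLog, rule: str = "nearest_in_time") -> PairedSeries:
    """Pair each model sample with prediction information close in time.

    ``nearest_in_time``: the prediction sample closest in time (ties resolved
    to the earlier sample).  ``window_mean``: the mean prediction error over
    the interval since the previous model sample (model samples whose window
    contains no prediction sample are dropped).
    """
    if rule not in PAIRING_RULES:
        raise DomainError(f"unknown pairing rule {rule!r}; expected one of {PAIRING_RULES}")
    mt, me = log.stream("model")
    pt, pe = log.stream("prediction")
    if mt.size == 0 or pt.size == 0:
        raise InsufficientDataError(
            f"patient {log.patient_id} fraction {log.fraction_index}: empty stream, cannot pair"
        )

    if rule == "nearest_in_time":
        idx_right = np.searchsorted(pt, mt, side="left")
        pairs_p = np.empty_like(me)
        for i, (t, ir) in enumerate(zip(mt, idx_right)):
            il = ir - 1
            if il < 0:
                j = ir
            elif ir >= pt.size:
                j = il
            else:
                dl, dr = t - pt[il], pt[ir] - t
                j = il if dl <= dr else ir  # tie -> earlier
            pairs_p[i] = pe[j]
        return PairedSeries(model=me, prediction=pairs_p, pairing_rule=rule)

    # window_mean
    model_rows, pred_rows = [], []
    prev = 0.0
    for i, t in enumerate(mt):
        lo = np.searchsorted(pt, prev, side="right") if i > 0 else 0
        hi = np.searchsorted(pt, t, side="right")
        if hi > lo:
            model_rows.append(me[i])
            pred_rows.append(pe[lo:hi].mean(axis=0))
        prev = t
    return PairedSeries(
        model=np.array(model_rows).reshape(len(model_rows), 3),
        prediction=np.array(pred_rows).reshape(len(pred_rows), 3),
        pairing_rule=rule,
    )


def _pearson_1d(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < MIN_PAIRS:
        raise InsufficientDataError(f"need >= {MIN_PAIRS} pairs, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("constant marginal: Pearson correlation undefined")
    r = float(xc @ yc) / (sx * sy)
    return min(1.0, max(-1.0, r))


def pearson(series: PairedSeries) -> np.ndarray:
    """Product-moment correlation per direction, each in [-1, 1].

    Raises :class:`UndefinedCorrelationError` on a constant marginal (the
    value is reported as missing, never coerced to 0).
    """
    return np.array([_pearson_1d(series.model[:, d], series.prediction[:, d]) for d in range(3)])


def covariance(sd_model: float, sd_prediction: float, r: float) -> float:
    """cov = r * sd_model * sd_prediction (mm^2)."""
    if sd_model < 0 or sd_prediction < 0:
        raise DomainError("SDs must be >= 0")
    if abs(r) > 1:
        raise DomainError(f"|r| must be <= 1, got {r}")
    return r * sd_model * sd_prediction


def _dcorr_1d(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation via double-centered pairwise distances."""
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()
    B = b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()
    dvar_x = float((A * A).mean())
    dvar_y = float((B * B).mean())
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    dcov2 = float((A * B).mean())
    return math.sqrt(max(dcov2, 0.0) / math.sqrt(dvar_x * dvar_y))


def distance_correlation(series: PairedSeries) -> np.ndarray:
    """Sample distance correlation per direction, each in [0, 1].

    Returns 0 in a direction whose distance variance vanishes (constant
    marginal).
    """
    if series.n_pairs < MIN_PAIRS:
        raise InsufficientDataError(f"need >= {MIN_PAIRS} pairs, got {series.n_pairs}")
    return np.array(
        [_dcorr_1d(series.model[:, d], series.prediction[:, d]) for d in range(3)]
    )


def estimate_fraction_covariance(
    log: FractionLog, rule: str = "nearest_in_time"
) -> CovarianceEstimate:
    """Pearson r, covariance and distance correlation for one fraction.

    The covariance uses the full-stream sample SDs, so the Cauchy-Schwarz
    bound |cov| <= sd_model * sd_pred holds by construction.
    """
    series = pair_streams(log, rule)
    if series.n_pairs < MIN_PAIRS:
        raise InsufficientDataError(
            f"patient {log.patient_id} fraction {log.fraction_index}: "
            f"{series.n_pairs} pairs < {MIN_PAIRS}"
        )
    _, me = log.stream("model")
    _, pe = log.stream("prediction")
    if me.shape[0] < 2 or pe.shape[0] < 2:
        raise InsufficientDataError("need >= 2 samples per stream for stream SDs")
    sd_m = me.std(axis=0, ddof=1)
    sd_p = pe.std(axis=0, ddof=1)

    r = np.full(3, np.nan)
    for d in range(3):
        try:
            r[d] = _pearson_1d(series.model[:, d], series.prediction[:, d])
        except UndefinedCorrelationError:
            pass  # stays NaN: reported as missing
    cov = r * sd_m * sd_p
    dcorr = distance_correlation(series)
    return CovarianceEstimate(
        pearson_r=r, cov=cov, dcorr=dcorr, n_pairs=series.n_pairs, sd_model=sd_m, sd_pred=sd_p
    )


def _max_by_magnitude(values: Sequence[float]) -> float:
    """Largest absolute value with its sign retained."""
    return max(values, key=abs)


@dataclass(frozen=True)
class CohortCovarianceRow:
    """Aggregated covariance summary for one (site, direction)."""

    site: str
    direction: str
    n_patients: int
    n_fractions: int
    n_undefined: int  # fraction-direction estimates skipped as undefined
    avg_max_r: float
    avg_max_cov: float  # mm^2
    min_cov: float  # mm^2, over all per-patient minima
    max_cov: float  # mm^2, over all per-patient maxima


def patient_covariance_extrema(
    fractions: Sequence[FractionLog], rule: str = "nearest_in_time"
) -> dict[str, dict[str, float]]:
    """Per-direction covariance/correlation extrema over a patient's fractions.

    Returns, per direction key: ``max_r`` and ``max_cov`` (largest in
    magnitude, sign retained), signed ``min_cov``/``max_cov_signed``, and the
    number of valid fractions.  Directions with no defined estimate are
    omitted.
    """
    per_dir: dict[str, dict[str, list[float]]] = {d: {"r": [], "cov": []} for d in DIRECTIONS}
    for f in fractions:
        try:
            est = estimate_fraction_covariance(f, rule)
        except InsufficientDataError:
            continue
        for d, name in enumerate(DIRECTIONS):
            if np.isfinite(est.pearson_r[d]):
                per_dir[name]["r"].append(float(est.pearson_r[d]))
                per_dir[name]["cov"].append(float(est.cov[d]))
    out: dict[str, dict[str, float]] = {}
    for name, vals in per_dir.items():
        if not vals["cov"]:
            continue
        out[name] = {
            "max_r": _max_by_magnitude(vals["r"]),
            "max_cov": _max_by_magnitude(vals["cov"]),
            "min_cov_signed": min(vals["cov"]),
            "max_cov_signed": max(vals["cov"]),
            "n_valid": len(vals["cov"]),
        }
    return out


def cohort_covariance(
    cohort: CohortLog, rule: str = "nearest_in_time"
) -> list[CohortCovarianceRow]:
    """Aggregate per-fraction covariance estimates over a cohort.

    Per patient and direction the maximum-magnitude correlation and
    covariance across fractions are kept (sign retained); the cohort value is
    the arithmetic mean of the per-patient maxima.  Directions/fractions with
    undefined correlation are skipped and counted.
    """
    rows: list[CohortCovarianceRow] = []
    any_valid = False
    for site, fracs in sorted(cohort.by_site().items()):
        by_patient: dict[str, list[FractionLog]] = {}
        for f in fracs:
            by_patient.setdefault(f.patient_id, []).append(f)
        n_fractions = len(fracs)

        per_dir_max_r: dict[str, list[float]] = {d: [] for d in DIRECTIONS}
        per_dir_max_cov: dict[str, list[float]] = {d: [] for d in DIRECTIONS}
        per_dir_min: dict[str, list[float]] = {d: [] for d in DIRECTIONS}
        per_dir_max_signed: dict[str, list[float]] = {d: [] for d in DIRECTIONS}
        n_undefined = {d: 0 for d in DIRECTIONS}
        for pid, pfracs in sorted(by_patient.items()):
            extrema = patient_covariance_extrema(pfracs, rule)
            for d in DIRECTIONS:
                if d in extrema:
                    per_dir_max_r[d].append(extrema[d]["max_r"])
                    per_dir_max_cov[d].append(extrema[d]["max_cov"])
                    per_dir_min[d].append(extrema[d]["min_cov_signed"])
                    per_dir_max_signed[d].append(extrema[d]["max_cov_signed"])
                    n_undefined[d] += len(pfracs) - int(extrema[d]["n_valid"])
                else:
                    n_undefined[d] += len(pfracs)
        for d in DIRECTIONS:
            n_pat = len(per_dir_max_cov[d])
            if n_pat:
                any_valid = True
            rows.append(
                CohortCovarianceRow(
                    site=site,
                    direction=d,
                    n_patients=n_pat,
                    n_fractions=n_fractions,
                    n_undefined=n_undefined[d],
                    avg_max_r=float(np.mean(per_dir_max_r[d])) if n_pat else float("nan"),
                    avg_max_cov=float(np.mean(per_dir_max_cov[d])) if n_pat else float("nan"),
                    min_cov=min(per_dir_min[d]) if n_pat else float("nan"),
                    max_cov=max(per_dir_max_signed[d]) if n_pat else float("nan"),
                )
            )
    if not any_valid:
        raise InsufficientDataError("no fraction yielded a defined covariance estimate")
    return rows
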