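"""PTV margin recipes.

Four formalisms, all per direction and in mm:

* ``vhf_basic``    -- 2.5*Sigma + 0.7*sigma
* ``vhf_recipe``   -- 2.5*Sigma + beta*sqrt(sigma^2 + penumbra^2) - beta*penumbra
* ``vhf_extended`` -- five systematic components in quadrature; model and
  prediction random errors combined assuming independence
* ``mvhf``         -- as extended, but the random combination carries the
  model/prediction covariance term (sigma_new^2 = sM^2 + sP^2 + 2*cov)

Quadratures are evaluated with ``hypot`` so closed-form limits (zero random
error, a single systematic component, cov = 0) hold exactly in floating
point.  Covariance admissibility |cov| <= sM*sP is enforced with a 1e-12
absolute tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ErrorComponents
from .exceptions import DomainError

__all__ = [
    "MarginResult",
    "COV_TOL",
    "vhf_basic",
    "vhf_recipe",
    "combined_sd",
    "vhf_extended",
    "mvhf",
    "relative_difference",
]

COV_TOL = 1e-12  # absolute slack on the Cauchy-Schwarz admissibility bound

FORMALISMS = ("VHF1", "VHF2", "VHF_EXT", "MVHF")


@dataclass(frozen=True)
class MarginResult:
    """Per-direction margin with the formalism and inputs recorded."""

    margin_mm: np.ndarray  # (3,)
    formalism: str
    components: ErrorComponents
    cov: np.ndarray | None = None  # (3,) mm^2, MVHF only


def _check_nonneg(**kwargs) -> None:
    for name, val in kwargs.items():
        arr = np.asarray(val, dtype=float)
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise DomainError(f"{name} must be finite and >= 0, got {val}")


def vhf_basic(sigma_sys, sigma_rand):
    """Margin = 2.5*Sigma + 0.7*sigma."""
    _check_nonneg(sigma_sys=sigma_sys, sigma_rand=sigma_rand)
    return 2.5 * np.asarray(sigma_sys, dtype=float) + 0.7 * np.asarray(sigma_rand, dtype=float)


def vhf_recipe(sigma_sys, sigma_rand, penumbra_sd: float = 6.4, beta: float = 0.84):
    """Margin = 2.5*Sigma + beta*sqrt(sigma^2 + penumbra^2) - beta*penumbra."""
    _check_nonneg(sigma_sys=sigma_sys, sigma_rand=sigma_rand, penumbra_sd=penumbra_sd, beta=beta)
    s = np.asarray(sigma_sys, dtype=float)
    r = np.asarray(sigma_rand, dtype=float)
    # hypot(0, p) == p exactly, so the penumbra term cancels exactly at sigma = 0
    return 2.5 * s + beta * (np.hypot(r, penumbra_sd) - penumbra_sd)


def combined_sd(sigma_mod, sigma_pred, cov=None):
    """Combined model+prediction random SD, with or without covariance.

    Without ``cov`` (or cov identically 0): sqrt(sM^2 + sP^2) via hypot.
    With ``cov``: sqrt(sM^2 + sP^2 + 2*cov), admissible only when
    |cov| <= sM*sP (+1e-12); violations raise :class:`DomainError`.
    """
    _check_nonneg(sigma_mod=sigma_mod, sigma_pred=sigma_pred)
    m = np.asarray(sigma_mod, dtype=float)
    p = np.asarray(sigma_pred, dtype=float)
    if cov is None:
        return np.hypot(m, p)
    c = np.asarray(cov, dtype=float)
    if not np.all(np.isfinite(c)):
        raise DomainError(f"cov must be finite, got {cov}")
    if np.any(np.abs(c) > m * p + COV_TOL):
        raise DomainError(
            f"inadmissible covariance {cov}: Cauchy-Schwarz requires |cov| <= "
            f"sigma_mod*sigma_pred = {m * p}"
        )
    if np.all(c == 0):
        return np.hypot(m, p)  # exact agreement with the independent combination
    var = m**2 + p**2 + 2.0 * c
    return np.sqrt(np.maximum(var, 0.0))


def _systematic_quadrature(c: ErrorComponents) -> np.ndarray:
    # nested hypot: exact when all but one component vanish
    return np.hypot(np.hypot(np.hypot(c.sys_seg, c.sys_def), np.hypot(c.sys_mod, c.sys_pred)), c.sys_tar)


def vhf_extended(c: ErrorComponents) -> MarginResult:
    """Five-component extension of the margin recipe (independent random errors)."""
    sigma_comb = combined_sd(c.rand_mod, c.rand_pred)
    margin = 2.5 * _systematic_quadrature(c) + c.beta * (np.hypot(sigma_comb, c.penumbra_sd) - c.penumbra_sd)
    return MarginResult(margin_mm=margin, formalism="VHF_EXT", components=c)


def mvhf(c: ErrorComponents, cov) -> MarginResult:
    """Covariance-augmented margin (modified recipe).

    ``cov`` is the per-direction model/prediction covariance in mm^2 (scalar
    broadcasts); cov = 0 reproduces :func:`vhf_extended` exactly.
    """
    cov_arr = np.broadcast_to(np.asarray(cov, dtype=float), (3,)).copy()
    sigma_comb = combined_sd(c.rand_mod, c.rand_pred, cov_arr)
    margin = 2.5 * _systematic_quadrature(c) + c.beta * (np.hypot(sigma_comb, c.penumbra_sd) - c.penumbra_sd)
    return MarginResult(margin_mm=margin, formalism="MVHF", components=c, cov=cov_arr)


def relative_difference(m_mvhf, m_vhf):
    """100 * (m_mvhf - m_vhf) / m_vhf, percent."""
    a = np.asarray(m_mvhf, dtype=float)
    b = np.asarray(m_vhf, dtype=float)
    if np.any(b <= 0):
        raise DomainError("undefined ratio: reference margin must be > 0")
    return 100.0 * (a - b) / b
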