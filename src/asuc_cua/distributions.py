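"""Moment-matched input distributions for probabilistic sensitivity analysis.

Utilities (and other quantities bounded in (0, 1)) are drawn from a Beta
distribution and costs from a Gamma distribution, each parameterised by the
(mean, SE) reported for the input — the standard method-of-moments
construction used in decision-analytic modelling.
"""

from __future__ import annotations

from .errors import ValidationError


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Return ``(alpha, beta)`` of the Beta distribution with given mean and SE.

    Uses alpha = mean * nu, beta = (1 - mean) * nu with
    nu = mean (1 - mean) / se**2 - 1.  Feasibility requires
    se**2 < mean (1 - mean).

    >>> beta_from_moments(0.8, 0.1)
    (12.0, 3.0)
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"beta mean must lie in (0, 1); got {mean}")
    if se <= 0.0:
        raise ValidationError(f"beta se must be positive; got {se}")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValidationError(
            f"beta infeasible: se^2={var:.6g} >= mean(1-mean)="
            f"{mean * (1 - mean):.6g}; reduce the SE"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Return ``(shape, scale)`` of the Gamma distribution with given mean and SE.

    shape = mean**2 / se**2, scale = se**2 / mean, so shape*scale = mean and
    shape*scale**2 = se**2 exactly.

    >>> gamma_from_moments(1000.0, 200.0)
    (25.0, 40.0)
    """
    if mean <= 0.0:
        raise ValidationError(f"gamma mean must be positive; got {mean}")
    if se <= 0.0:
        raise ValidationError(f"gamma se must be positive; got {se}")
    return mean * mean / (se * se), se * se / mean
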