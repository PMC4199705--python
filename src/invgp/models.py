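"""Prior-variance structures and hyperparameter defaults for the four models.

All four models place N(0, lam_i) priors on the spectral coefficients b_i
and differ only in how lam_i is built:

* BIRR — a single shared variance, lam_i = sigma2_b (inverse analogue of
  Bayesian ridge regression);
* BAI  — one variance per coefficient, lam_i = sigma2_b_i, a scaled-t
  (normal / scaled-inverse-chi-square mixture) marginal prior;
* BIR1 — polynomial decay in the coefficient index, lam_i = phi * (i^(-1-2*alpha) + h),
  with smoothing parameter h preventing overshrinkage of the tail;
* BIR2 — decay tied to the singular values themselves, lam_i = phi * s_i^alpha.

The spectrum-decay models deliberately mimic the decay of the singular
values in the prior, shrinking exactly the coefficients whose least-squares
estimates are noise-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "ErrorPrior",
    "ModelSpec",
    "decay_profile",
    "default_h",
    "default_hyperparameters",
]

MODEL_NAMES = ("BIRR", "BAI", "BIR1", "BIR2")


@dataclass(frozen=True)
class ErrorPrior:
    """Scaled-inverse-chi-square prior for the error variance sigma2_e.

    Density proportional to x^(-df/2-1) exp(-df*scale/(2x)); prior mean is
    df*scale/(df-2) for df > 2.
    """

    df_e: float
    scale_e: float

    def __post_init__(self) -> None:
        if not self.df_e > 0:
            raise ValueError("error-prior degrees of freedom must be positive")
        if not self.scale_e > 0:
            raise ValueError("error-prior scale must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Which prior structure to use, plus its hyperparameters.

    Fields left as ``None`` are filled by :func:`default_hyperparameters`
    from the data scale; explicitly set values are never overwritten.
    ``hyper_bound`` is the upper limit A of the uniform (0, A) hyperprior on
    the scale parameter (Sc_b for BIRR/BAI, Sc_phi for BIR1/BIR2).
    """

    model: str
    df_b: float | None = None
    hyper_bound: float | None = None
    df_phi: float | None = None
    alpha: float | None = None
    h: float | None = None
    error_prior: ErrorPrior | None = None

    def __post_init__(self) -> None:
        name = self.model.upper()
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")
        object.__setattr__(self, "model", name)
        if self.df_b is not None and not self.df_b > 0:
            # df_b = 0 would make the coefficient prior improper
            raise ValueError("df_b must be positive")
        if self.df_phi is not None and not self.df_phi > 0:
            raise ValueError("df_phi must be positive")
        if self.hyper_bound is not None and not self.hyper_bound > 0:
            raise ValueError("hyper_bound must be positive")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.h is not None and self.h < 0:
            raise ValueError("h must be non-negative")

    @property
    def is_resolved(self) -> bool:
        if self.hyper_bound is None or self.error_prior is None:
            return False
        if self.model in ("BIRR", "BAI") and self.df_b is None:
            return False
        if self.model in ("BIR1", "BIR2"):
            if self.df_phi is None or self.alpha is None:
                return False
            if self.model == "BIR1" and self.h is None:
                return False
        return True


def decay_profile(spec: ModelSpec, s: np.ndarray) -> np.ndarray:
    """Unit-scale prior-variance profile g with lam_i = scale * g_i.

    BIRR is flat (g = 1); BIR1 decays polynomially in the coefficient index,
    g_i = i^(-1-2*alpha) + h; BIR2 follows the spectrum, g_i = s_i^alpha.
    BAI has independent per-coefficient variances and no shared profile.
    """
    s = np.asarray(s, dtype=float)
    if spec.model == "BAI":
        raise ValueError("BAI has per-coefficient variances, not a shared profile")
    if spec.model == "BIRR":
        return np.ones_like(s)
    if spec.model == "BIR1":
        if spec.alpha is None or spec.h is None:
            raise ValueError("BIR1 profile needs alpha and h resolved")
        idx = np.arange(1, s.size + 1, dtype=float)
        return idx ** (-1.0 - 2.0 * spec.alpha) + spec.h
    if spec.alpha is None:
        raise ValueError("BIR2 profile needs alpha resolved")
    return s**spec.alpha


def default_h(s: np.ndarray) -> float:
    """Default smoothing parameter h = 1/s1 (reciprocal largest singular value)."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty singular-value vector")
    if np.any(s <= 0):
        raise ValueError("singular values must be positive")
    return float(1.0 / s[0])


def default_hyperparameters(spec: ModelSpec, d: np.ndarray, s: np.ndarray) -> ModelSpec:
    """Fill unset hyperparameters from the scale of the rotated data.

    Degrees of freedom default to 3 for every variance prior.  The error
    scale is anchored at half the variance of d, so the prior mode of
    sigma2_e sits at half the phenotypic variance.  The uniform hyperprior
    bound A scales with var(d) and the prior-variance profile, so defaults
    are covariant under rescaling of the phenotypes.  alpha defaults to 1
    for BIR2 and 0.5 for BIR1; h defaults to 1/s1.
    """
    d = np.asarray(d, dtype=float)
    s = np.asarray(s, dtype=float)
    if d.size == 0:
        raise ValueError("empty transformed data")
    var_d = float(np.var(d, ddof=1)) if d.size > 1 else float(d[0] ** 2)
    if var_d <= 0:
        raise ValueError("constant phenotype: var(d) = 0")

    out = spec
    if out.df_b is None:
        out = replace(out, df_b=3.0)
    if out.df_phi is None:
        out = replace(out, df_phi=3.0)
    if out.model == "BIR1":
        if out.alpha is None:
            out = replace(out, alpha=0.5)
        if out.h is None:
            out = replace(out, h=default_h(s))
    if out.model == "BIR2" and out.alpha is None:
        out = replace(out, alpha=1.0)
    if out.error_prior is None:
        out = replace(out, error_prior=ErrorPrior(df_e=3.0, scale_e=var_d / 2.0))
    if out.hyper_bound is None:
        if out.model == "BAI":
            g = np.ones_like(s)
        else:
            g = decay_profile(out, s)
        bound = 10.0 * var_d * float(np.median(1.0 / g))
        out = replace(out, hyper_bound=max(bound, 10.0 * var_d))
    return out
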