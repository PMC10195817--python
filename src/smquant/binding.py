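"""Quadratic tight-binding isotherms and dissociation-constant fitting.

At concentrations comparable to the KD, free-ligand depletion makes the
hyperbolic isotherm invalid; the bound-complex concentration instead
follows the quadratic ("tight-binding") solution of the mass-action
equilibrium. Two signal models are supported: the plain quadratic (eq1)
and a variant with an additive linear baseline term (eq2) for curves with
a non-saturating tail. Self-association titrations (e.g. microscale
thermophoresis of a labelled species against unlabelled titrant) use the
same quadratic with the fixed labelled species in the partner role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from smquant.io import ParameterError
from smquant.simulate import TitrationCurve


def eq1_bound(pt, dt, kd):
    """Bound-complex concentration from the quadratic isotherm (µM).

    [PD] = ((pt + dt + kd) − sqrt((pt + dt + kd)² − 4·pt·dt)) / 2, with the
    root evaluated as 2·pt·dt / (s + sqrt(disc)) to avoid catastrophic
    cancellation when the discriminant is small (tight binding). Satisfies
    0 ≤ [PD] ≤ min(pt, dt).
    """
    pt = np.asarray(pt, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(pt < 0) or np.any(dt < 0):
        raise ParameterError("concentrations must be >= 0")
    if np.any(np.asarray(kd) <= 0):
        raise ParameterError("kd must be > 0")
    s = pt + dt + kd
    disc = s ** 2 - 4.0 * pt * dt
    disc = np.maximum(disc, 0.0)
    root = np.sqrt(disc)
    # stable alternative form: (s - root)/2 == 2·pt·dt/(s + root)
    out = np.where(s + root > 0, 2.0 * pt * dt / (s + root), 0.0)
    return np.minimum(out, np.minimum(pt, dt))


@dataclass
class BindingModel:
    """Signal model for a titration at fixed partner concentration."""

    kd: float
    partner_total: float       # µM, the fixed (limiting/labelled) species
    f_free: float
    f_bound: float
    a: float | None = None     # eq2 baseline offset
    b: float | None = None     # eq2 baseline slope (per µM of the linear species)
    model_id: str = "eq1"
    linear_in: str = "partner"  # 'partner' (as printed) or 'titrant' variant

    def signal(self, titrant_total) -> np.ndarray:
        if self.partner_total <= 0:
            raise ParameterError("partner_total must be > 0 (fraction bound undefined)")
        bound = eq1_bound(np.asarray(titrant_total, float), self.partner_total,
                          self.kd)
        sig = self.f_free + (self.f_bound - self.f_free) * bound / self.partner_total
        if self.model_id == "eq2":
            if self.a is None or self.b is None:
                raise ParameterError("model eq2 requires a and b")
            lin = (self.partner_total if self.linear_in == "partner"
                   else np.asarray(titrant_total, float))
            sig = sig + self.a + self.b * lin
        return sig


def eq2_signal(model: BindingModel, titrant_total) -> np.ndarray:
    """Signal under the baseline-augmented quadratic model (eq2)."""
    if model.model_id != "eq2":
        raise ParameterError("eq2_signal requires model_id='eq2'")
    return model.signal(titrant_total)


@dataclass
class BindingFit:
    kd: float                  # µM
    kd_se: float
    f_free: float
    f_bound: float
    a: float | None
    b: float | None
    model_id: str
    residual_rms: float
    ill_conditioned: bool = False
    replicate_kds: list | None = None
    kd_sem: float | None = None


def fit_kd(
    curve: TitrationCurve,
    model_id: str = "eq1",
    init: dict | None = None,
    linear_in: str = "partner",
) -> BindingFit:
    """Nonlinear least-squares KD fit of one titration curve.

    Free parameters are (kd, f_free, f_bound) plus (a, b) for eq2; the
    standard error on KD comes from the fit covariance. Designs with no
    curvature around the half-saturation point are flagged ill-conditioned.
    """
    x = curve.titrant_total
    y = curve.signal
    if len(x) < 6:
        raise ParameterError("need at least 6 titration points")
    init = init or {}
    kd0 = init.get("kd", float(np.sqrt(x[0] * x[-1])))
    ff0 = init.get("f_free", float(y[0]))
    fb0 = init.get("f_bound", float(y[-1]))
    pt = curve.fixed_partner

    if model_id == "eq1":
        def model(xx, kd, ff, fb):
            return ff + (fb - ff) * eq1_bound(xx, pt, kd) / pt
        p0 = (kd0, ff0, fb0)
    elif model_id == "eq2":
        if linear_in == "partner":
            # a and b·partner are degenerate at fixed partner: fold into one
            # offset and report it as a (b fixed at 0) unless titrant-linear.
            def model(xx, kd, ff, fb, a):
                return ff + (fb - ff) * eq1_bound(xx, pt, kd) / pt + a
            p0 = (kd0, ff0, fb0, init.get("a", 0.0))
        else:
            def model(xx, kd, ff, fb, a, b):
                return (ff + (fb - ff) * eq1_bound(xx, pt, kd) / pt
                        + a + b * xx)
            p0 = (kd0, ff0, fb0, init.get("a", 0.0), init.get("b", 0.0))
    else:
        raise ParameterError(f"unknown model_id: {model_id!r}")

    popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000,
                           bounds=([1e-9] + [-np.inf] * (len(p0) - 1),
                                   [np.inf] * len(p0)))
    resid = y - model(x, *popt)
    kd = float(popt[0])
    kd_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    # no curvature: the half-saturation point lies outside the design
    ill = not (x[0] <= kd <= x[-1])
    a_fit = float(popt[3]) if model_id == "eq2" else None
    b_fit = (float(popt[4]) if model_id == "eq2" and linear_in != "partner"
             else (0.0 if model_id == "eq2" else None))
    return BindingFit(
        kd=kd, kd_se=kd_se, f_free=float(popt[1]), f_bound=float(popt[2]),
        a=a_fit, b=b_fit, model_id=model_id,
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        ill_conditioned=ill,
    )


def fit_kd_replicates(
    curves: list[TitrationCurve],
    model_id: str = "eq1",
    **kwargs,
) -> BindingFit:
    """Fit each replicate separately and pool.

    Reports the pooled-fit parameters together with the replicate-wise KDs
    as mean ± SEM, the convention for n independent experiments.
    """
    fits = [fit_kd(c, model_id=model_id, **kwargs) for c in curves]
    kds = [f.kd for f in fits]
    pooled = TitrationCurve(
        titrant_total=curves[0].titrant_total,
        signal=np.mean([c.signal for c in curves], axis=0),
        fixed_partner=curves[0].fixed_partner,
    )
    out = fit_kd(pooled, model_id=model_id, **kwargs)
    out.replicate_kds = kds
    out.kd = float(np.mean(kds))
    out.kd_sem = float(np.std(kds, ddof=1) / np.sqrt(len(kds))) if len(kds) > 1 else 0.0
    return out
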