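"""Enzyme-modulation kinetics: velocities, Michaelis–Menten, activation, EC50.

The assay readout is product formation over time (chromogenic substrate
absorbance); initial velocities are the linear slope over the first
seconds of each trace.  Velocity–substrate data fit the Michaelis–Menten
model

    v = kcat·[E]·[S] / (Km + [S])

and velocity–modulator data fit a two-parameter mixed-activation model in
which a modulator A binds the enzyme–substrate complex with dissociation
constant K_act and rescales catalytic output by a factor β:

    v = kcat·[E]·[S]·(1 + β·[A]/K_act) / (Km + [S]·(1 + [A]/K_act))

At [A] = 0 this reduces exactly to Michaelis–Menten; at saturating [A]
the velocity tends to β·kcat·[E].  The apparent catalytic efficiency
kcat/Km scales as (1 + β·[A]/K_act), so any β > 0 raises the efficiency:
a compound with β ≤ 1 can still activate at sub-saturating substrate
through the apparent-Km shift even though it lowers the saturating rate.
Dose-response data (relative velocity vs [A]) fit a
one-site hyperbola with the baseline fixed at 1:

    v_rel = 1 + a·[A] / (EC50 + [A])

where the sign of the amplitude a distinguishes activators from
inhibitors.  Plate screens are triaged by two rules: dose-dependent
activity, and a maximal effect of at least 20% of the same-plate
no-compound control.

Each model follows the Model → fit() → Results idiom: results carry the
point estimates, standard errors from the fit covariance, diagnostics and
a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigError, ContractError, FitError, InsufficientDataError

__all__ = [
    "mm_velocity",
    "activation_velocity",
    "dose_response_curve",
    "AssayTrace",
    "initial_velocity",
    "KineticParameters",
    "MichaelisMentenModel",
    "ActivationModel",
    "DoseResponseModel",
    "call_hits",
    "efficiency_change",
]


# ---------------------------------------------------------------------------
# Model functions


def mm_velocity(S, kcat: float, km: float, enzyme_conc: float):
    """Michaelis–Menten velocity (units of kcat·[E]) at substrate S (μM)."""
    S = np.asarray(S, dtype=float)
    return kcat * enzyme_conc * S / (km + S)


def activation_velocity(S, A, kcat: float, km: float, beta: float, kact: float,
                        enzyme_conc: float):
    """Mixed-activation model velocity at substrate S and modulator A (μM)."""
    S = np.asarray(S, dtype=float)
    A = np.asarray(A, dtype=float)
    occ = A / kact
    return kcat * enzyme_conc * S * (1.0 + beta * occ) / (km + S * (1.0 + occ))


def dose_response_curve(A, ec50: float, amplitude: float):
    """Relative velocity 1 + a·[A]/(EC50+[A])."""
    A = np.asarray(A, dtype=float)
    return 1.0 + amplitude * A / (ec50 + A)


# ---------------------------------------------------------------------------
# Traces and initial velocities


@dataclass(frozen=True)
class AssayCondition:
    enzyme_conc: float = 0.0  # μM
    substrate_conc: float = 0.0  # μM
    compound_conc: float = 0.0  # μM
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if min(self.enzyme_conc, self.substrate_conc, self.compound_conc) < 0:
            raise ContractError("concentrations must be non-negative")


@dataclass(frozen=True)
class AssayTrace:
    """A time course of signal (absorbance AU, or μM product) at one condition."""

    times: tuple[float, ...]  # seconds, strictly increasing
    signal: tuple[float, ...]
    condition: AssayCondition = AssayCondition()
    signal_unit: str = "AU"
    conversion_factor: float | None = None  # AU → μM

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) != len(self.signal):
            raise ContractError("times and signal must be the same length")
        if len(t) and (t.min() < 0 or np.any(np.diff(t) <= 0)):
            raise ContractError("times must be non-negative and strictly increasing")


def initial_velocity(trace: AssayTrace, window: float = 10.0) -> float:
    """Least-squares slope of signal vs time over the first ``window`` seconds.

    Free intercept (the assay baseline need not be zero).  Returns the
    velocity in signal units per second, converted to μM/s when the trace
    declares a conversion factor.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.signal, dtype=float)
    mask = t <= window
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} points within the first {window:g} s; need >= 3"
        )
    slope = np.polyfit(t[mask], y[mask], 1)[0]
    if trace.conversion_factor is not None:
        slope *= trace.conversion_factor
    return float(slope)


# ---------------------------------------------------------------------------
# Fit plumbing


def _multistart_curve_fit(f, x, y, starts, bounds):
    """curve_fit from several starting points; keep the lowest-SSR solution."""
    best = None
    last_err: Exception | None = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    f, x, y, p0=p0, bounds=bounds, maxfev=20000,
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        ssr = float(np.sum((np.asarray(f(x, *popt)) - y) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        raise FitError(f"nonlinear fit failed from all starts: {last_err}")
    return best


def _stderr(pcov: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.diag(pcov))


# ---------------------------------------------------------------------------
# Michaelis–Menten


@dataclass(frozen=True)
class KineticParameters:
    """Fitted kcat (s⁻¹), Km (μM), standard errors, and kcat/Km (μM⁻¹ s⁻¹)."""

    kcat: float
    km: float
    kcat_se: float = float("nan")
    km_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.km <= 0:
            raise ContractError("kcat and Km must be positive")

    @property
    def efficiency(self) -> float:
        return self.kcat / self.km

    @property
    def efficiency_se(self) -> float:
        # independent-error propagation of the ratio
        rel = math.hypot(
            self.kcat_se / self.kcat if np.isfinite(self.kcat_se) else 0.0,
            self.km_se / self.km if np.isfinite(self.km_se) else 0.0,
        )
        return self.efficiency * rel


class MichaelisMentenModel:
    """Nonlinear least-squares Michaelis–Menten fit of (substrate, velocity) data.

    Parameters
    ----------
    substrate, velocity : array-like
        Substrate concentrations (μM) and matched initial velocities
        (velocity units set kcat's units: μM/s data give kcat in s⁻¹).
    enzyme_conc : float
        Total enzyme concentration in μM; must be positive.
    """

    def __init__(self, substrate, velocity, enzyme_conc: float):
        self.substrate = np.asarray(substrate, dtype=float)
        self.velocity = np.asarray(velocity, dtype=float)
        if enzyme_conc <= 0:
            raise ContractError("enzyme_conc must be positive")
        self.enzyme_conc = float(enzyme_conc)
        if self.substrate.shape != self.velocity.shape:
            raise ContractError("substrate and velocity must be aligned")
        if len(np.unique(self.substrate)) < 3:
            raise InsufficientDataError("need >= 3 distinct substrate concentrations")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, enzyme_conc: float,
                       substrate_col: str = "substrate_uM",
                       velocity_col: str = "velocity") -> "MichaelisMentenModel":
        return cls(df[substrate_col], df[velocity_col], enzyme_conc)

    def fit(self) -> "MichaelisMentenResults":
        vmax0 = float(self.velocity.max())
        if vmax0 <= 0:
            raise FitError("velocities are non-positive; nothing to fit")
        kcat0 = vmax0 / self.enzyme_conc
        km0 = float(np.median(self.substrate))
        f = lambda S, kcat, km: mm_velocity(S, kcat, km, self.enzyme_conc)
        starts = [(kcat0, km0), (2 * kcat0, 4 * km0), (1.2 * kcat0, km0 / 4)]
        popt, pcov, ssr = _multistart_curve_fit(
            f, self.substrate, self.velocity, starts, bounds=(0, np.inf)
        )
        se = _stderr(pcov)
        params = KineticParameters(
            kcat=float(popt[0]), km=float(popt[1]),
            kcat_se=float(se[0]), km_se=float(se[1]),
        )
        # Km far outside the probed substrate range (flat or saturated design)
        # cannot be pinned by these data, whatever the covariance says
        s_lo, s_hi = float(self.substrate.min()), float(self.substrate.max())
        ill_determined = (
            not np.isfinite(se[1])
            or se[1] > params.km
            or params.km < s_lo / 10
            or params.km > s_hi * 10
        )
        if ill_determined:
            warnings.warn(
                "Km is poorly determined (saturated or flat design); "
                "standard errors are unreliable",
                stacklevel=2,
            )
        return MichaelisMentenResults(
            model=self, params=params, ssr=ssr, cov=pcov, ill_determined=ill_determined
        )


@dataclass
class MichaelisMentenResults:
    model: MichaelisMentenModel
    params: KineticParameters
    ssr: float
    cov: np.ndarray
    ill_determined: bool = False

    def predict(self, substrate) -> np.ndarray:
        return mm_velocity(substrate, self.params.kcat, self.params.km,
                           self.model.enzyme_conc)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Michaelis-Menten fit",
            "=" * 44,
            f"n points          {len(self.model.velocity):>10d}",
            f"[E] (uM)          {self.model.enzyme_conc:>10.4g}",
            f"kcat (1/s)        {p.kcat:>10.4g}  +/- {p.kcat_se:.3g}",
            f"Km (uM)           {p.km:>10.4g}  +/- {p.km_se:.3g}",
            f"kcat/Km (1/uM/s)  {p.efficiency:>10.4g}  +/- {p.efficiency_se:.3g}",
            f"SSR               {self.ssr:>10.4g}",
        ]
        if self.ill_determined:
            lines.append("warning: Km poorly determined")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Activation model


class ActivationModel:
    """Two-parameter (β, K_act) fit of the mixed-activation model.

    Km is fixed to the value fitted from compound-free data, and kcat is
    by default anchored from the [A] = 0 points (policy ``'anchor'``); with
    policy ``'free'`` kcat is co-fit as a third parameter.

    Parameters
    ----------
    substrate, compound, velocity : array-like
        Per-observation substrate and modulator concentrations (μM) and
        initial velocities.
    km_fixed : float
        Km (μM) from the compound-free Michaelis–Menten fit.
    enzyme_conc : float
        Enzyme concentration (μM).
    """

    def __init__(self, substrate, compound, velocity, km_fixed: float,
                 enzyme_conc: float, kcat_policy: Literal["anchor", "free"] = "anchor"):
        self.substrate = np.asarray(substrate, dtype=float)
        self.compound = np.asarray(compound, dtype=float)
        self.velocity = np.asarray(velocity, dtype=float)
        if not (self.substrate.shape == self.compound.shape == self.velocity.shape):
            raise ContractError("substrate, compound and velocity must be aligned")
        if km_fixed <= 0:
            raise ContractError("km_fixed must be positive")
        if enzyme_conc <= 0:
            raise ContractError("enzyme_conc must be positive")
        if kcat_policy not in ("anchor", "free"):
            raise ConfigError("kcat_policy must be 'anchor' or 'free'")
        if len(np.unique(self.compound)) < 3:
            raise InsufficientDataError("need >= 3 distinct modulator concentrations")
        if kcat_policy == "anchor" and not np.any(self.compound == 0):
            raise ContractError("kcat anchoring requires [A] = 0 points")
        self.km_fixed = float(km_fixed)
        self.enzyme_conc = float(enzyme_conc)
        self.kcat_policy = kcat_policy

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, km_fixed: float, enzyme_conc: float,
                       **kwargs) -> "ActivationModel":
        return cls(df["substrate_uM"], df["compound_uM"], df["velocity"],
                   km_fixed, enzyme_conc, **kwargs)

    def _anchor_kcat(self) -> float:
        m = self.compound == 0
        S, v = self.substrate[m], self.velocity[m]
        return float(np.mean(v * (self.km_fixed + S) / (self.enzyme_conc * S)))

    def fit(self) -> "ActivationResults":
        Amax = float(self.compound.max())
        kact_starts = [Amax / 4, Amax, 4 * Amax]
        beta_starts = [0.5, 2.0]
        x = np.vstack([self.substrate, self.compound])

        if self.kcat_policy == "anchor":
            kcat = self._anchor_kcat()

            def f(x, beta, kact):
                return activation_velocity(x[0], x[1], kcat, self.km_fixed,
                                           beta, kact, self.enzyme_conc)

            starts = [(b, k) for b in beta_starts for k in kact_starts]
            popt, pcov, ssr = _multistart_curve_fit(
                f, x, self.velocity, starts, bounds=(0, np.inf))
            beta, kact = popt
            se = _stderr(pcov)
            beta_se, kact_se = se
            kcat_se = float("nan")
        else:
            kcat0 = float(self.velocity.max()) / self.enzyme_conc

            def f(x, kcat, beta, kact):
                return activation_velocity(x[0], x[1], kcat, self.km_fixed,
                                           beta, kact, self.enzyme_conc)

            starts = [(kcat0, b, k) for b in beta_starts for k in kact_starts]
            popt, pcov, ssr = _multistart_curve_fit(
                f, x, self.velocity, starts, bounds=(0, np.inf))
            kcat, beta, kact = popt
            se = _stderr(pcov)
            kcat_se, beta_se, kact_se = se

        if kact <= 0 or beta <= 0:
            raise FitError("fit collapsed to non-positive beta or K_act")
        # K_act far beyond the tested dose range means the fit ran onto the
        # β–K_act ridge (model linear in [A]); the estimate is not trustworthy
        identifiable = kact <= 10 * Amax
        if not identifiable:
            warnings.warn(
                f"K_act {kact:.3g} uM lies far beyond the tested dose range "
                f"(max {Amax:g} uM); beta and K_act are not separately "
                "identifiable from these data", stacklevel=2)
        return ActivationResults(
            model=self, beta=float(beta), kact=float(kact), kcat=float(kcat),
            beta_se=float(beta_se), kact_se=float(kact_se), kcat_se=float(kcat_se),
            ssr=ssr, cov=pcov, identifiable=identifiable,
        )


@dataclass
class ActivationResults:
    model: ActivationModel
    beta: float  #: catalytic rescaling of the modulator-bound complex
    kact: float  #: modulator dissociation constant from the ES complex (μM)
    kcat: float  #: anchored or co-fit kcat (s⁻¹)
    beta_se: float
    kact_se: float
    kcat_se: float
    ssr: float
    cov: np.ndarray
    identifiable: bool = True

    @property
    def km_fixed(self) -> float:
        return self.model.km_fixed

    def predict(self, substrate, compound) -> np.ndarray:
        return activation_velocity(substrate, compound, self.kcat, self.km_fixed,
                                   self.beta, self.kact, self.model.enzyme_conc)

    def summary(self) -> str:
        lines = [
            "Mixed-activation model fit (Km fixed)",
            "=" * 44,
            f"n points          {len(self.model.velocity):>10d}",
            f"Km fixed (uM)     {self.km_fixed:>10.4g}",
            f"kcat ({self.model.kcat_policy})     {self.kcat:>10.4g}",
            f"beta              {self.beta:>10.4g}  +/- {self.beta_se:.3g}",
            f"K_act (uM)        {self.kact:>10.4g}  +/- {self.kact_se:.3g}",
            f"SSR               {self.ssr:>10.4g}",
        ]
        if not self.identifiable:
            lines.append("warning: K_act beyond the tested dose range; ridge fit")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Dose-response


class DoseResponseModel:
    """Hyperbolic dose-response fit of relative velocity vs modulator dose.

    The baseline is fixed at 1 (relative velocity at [A] = 0 is 1 by
    construction) and the Hill coefficient at 1 by default; ``hill='free'``
    co-fits it.  ``direction`` constrains the amplitude sign ('activator'
    ≥ 0, 'inhibitor' ≤ 0, 'auto' unconstrained).
    """

    def __init__(self, compound, rel_velocity,
                 direction: Literal["auto", "activator", "inhibitor"] = "auto",
                 hill: Literal["fixed", "free"] = "fixed"):
        self.compound = np.asarray(compound, dtype=float)
        self.rel_velocity = np.asarray(rel_velocity, dtype=float)
        if self.compound.shape != self.rel_velocity.shape:
            raise ContractError("compound and rel_velocity must be aligned")
        if len(np.unique(self.compound)) < 4:
            raise InsufficientDataError("need >= 4 distinct modulator concentrations")
        if direction not in ("auto", "activator", "inhibitor"):
            raise ConfigError("direction must be auto|activator|inhibitor")
        self.direction = direction
        self.hill = hill

    def fit(self) -> "DoseResponseResults":
        A, y = self.compound, self.rel_velocity
        Amax = float(A.max())
        # rough amplitude from the high-dose tail
        tail = float(np.mean(y[A >= np.quantile(A[A > 0], 0.75)]) - 1.0)
        a0 = tail if abs(tail) > 1e-9 else 0.1
        if self.direction == "activator":
            lo_a, hi_a = 0.0, 10.0
            a0 = max(a0, 1e-3)
        elif self.direction == "inhibitor":
            lo_a, hi_a = -10.0, 0.0
            a0 = min(a0, -1e-3)
        else:
            lo_a, hi_a = -10.0, 10.0
        ec50_starts = [Amax / 10, float(np.median(A[A > 0])), Amax]

        if self.hill == "fixed":
            f = lambda A, ec50, a: dose_response_curve(A, ec50, a)
            starts = [(e, a0) for e in ec50_starts]
            bounds = ([1e-9, lo_a], [np.inf, hi_a])
        else:
            def f(A, ec50, a, n):
                A = np.asarray(A, dtype=float)
                An = np.power(A, n, where=A > 0, out=np.zeros_like(A))
                return 1.0 + a * An / (ec50**n + An)
            starts = [(e, a0, 1.0) for e in ec50_starts]
            bounds = ([1e-9, lo_a, 0.1], [np.inf, hi_a, 10.0])

        popt, pcov, ssr = _multistart_curve_fit(f, A, y, starts, bounds)
        se = _stderr(pcov)
        ec50, amplitude = float(popt[0]), float(popt[1])
        extrapolated = ec50 > 10 * Amax or ec50 < float(A[A > 0].min()) / 10
        if extrapolated:
            warnings.warn(
                f"EC50 {ec50:.3g} uM lies far outside the tested range; "
                "treat as an extrapolation", stacklevel=2)
        return DoseResponseResults(
            model=self, ec50=ec50, amplitude=amplitude,
            ec50_se=float(se[0]), amplitude_se=float(se[1]),
            hill=float(popt[2]) if self.hill == "free" else 1.0,
            ssr=ssr, cov=pcov, extrapolated=extrapolated,
        )


@dataclass
class DoseResponseResults:
    model: DoseResponseModel
    ec50: float  #: μM
    amplitude: float  #: fractional maximal change; + activator, − inhibitor
    ec50_se: float
    amplitude_se: float
    hill: float
    ssr: float
    cov: np.ndarray
    extrapolated: bool = False

    def predict(self, compound) -> np.ndarray:
        return dose_response_curve(compound, self.ec50, self.amplitude)

    def summary(self) -> str:
        kind = "activator" if self.amplitude >= 0 else "inhibitor"
        lines = [
            "Dose-response fit (baseline 1)",
            "=" * 44,
            f"n points          {len(self.model.rel_velocity):>10d}",
            f"EC50 (uM)         {self.ec50:>10.4g}  +/- {self.ec50_se:.3g}",
            f"amplitude         {self.amplitude:>+10.4g}  +/- {self.amplitude_se:.3g}  ({kind})",
            f"Hill coefficient  {self.hill:>10.4g}",
            f"SSR               {self.ssr:>10.4g}",
        ]
        if self.extrapolated:
            lines.append("warning: EC50 extrapolated beyond the tested doses")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Screen hit calling


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    concentrations: tuple[float, ...]  # μM, ascending
    effects: tuple[float, ...]  # relative velocity change vs control
    dose_dependent: bool
    max_effect: float
    is_hit: bool


def call_hits(
    plate: pd.DataFrame,
    control_id: str = "control",
    threshold: float = 0.20,
) -> list[HitCall]:
    """Call screen hits from replicate plate velocities.

    ``plate`` needs columns compound_id, compound_uM, velocity; rows with
    ``compound_id == control_id`` are the same-plate no-compound controls.
    The effect at each concentration is the relative change of the mean
    velocity versus the mean control velocity.  A compound is
    dose-dependent when all effects share one sign and |effect| is
    non-decreasing with concentration within one pooled standard error;
    it is a hit when additionally max |effect| ≥ ``threshold``.

    Because effects are ratios, hit calls are invariant to rescaling every
    velocity on the plate by a common positive factor.
    """
    required = {"compound_id", "compound_uM", "velocity"}
    if not required <= set(plate.columns):
        raise ContractError(f"plate table needs columns {sorted(required)}")
    ctrl = plate.loc[plate["compound_id"] == control_id, "velocity"]
    if ctrl.empty:
        raise ContractError(f"no control rows (compound_id == {control_id!r}) on plate")
    v_ctrl = float(ctrl.mean())
    if v_ctrl <= 0:
        raise ContractError("control velocity must be positive")

    calls: list[HitCall] = []
    for cid, grp in plate[plate["compound_id"] != control_id].groupby("compound_id"):
        per_conc = grp.groupby("compound_uM")["velocity"]
        concs = np.array(sorted(per_conc.groups))
        if len(concs) < 2:
            raise ContractError(
                f"compound {cid!r} tested at {len(concs)} concentration(s); need >= 2")
        means = per_conc.mean().reindex(concs).to_numpy()
        sems = (per_conc.std(ddof=1) / np.sqrt(per_conc.count())).reindex(concs).to_numpy()
        effects = (means - v_ctrl) / v_ctrl
        effect_sems = np.nan_to_num(sems / v_ctrl)
        pooled_se = float(np.sqrt(np.mean(effect_sems**2)))

        same_sign = np.all(effects >= 0) or np.all(effects <= 0)
        monotone = np.all(np.diff(np.abs(effects)) >= -pooled_se)
        dose_dependent = bool(same_sign and monotone)
        max_effect = float(effects[np.argmax(np.abs(effects))])
        calls.append(
            HitCall(
                compound_id=str(cid),
                concentrations=tuple(float(c) for c in concs),
                effects=tuple(float(e) for e in effects),
                dose_dependent=dose_dependent,
                max_effect=max_effect,
                is_hit=bool(dose_dependent and abs(max_effect) >= threshold),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Efficiency changes


def efficiency_change(
    with_compound: KineticParameters, without: KineticParameters
) -> tuple[float, float]:
    """Percent change in kcat/Km with vs without compound, and its SE.

    Returns ``100·((kcat/Km)_with / (kcat/Km)_without − 1)`` with the
    uncertainty propagated from both fits' standard errors (independent
    errors assumed).
    """
    ratio = with_compound.efficiency / without.efficiency
    rel = math.hypot(
        with_compound.efficiency_se / with_compound.efficiency,
        without.efficiency_se / without.efficiency,
    )
    return 100.0 * (ratio - 1.0), 100.0 * ratio * rel
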