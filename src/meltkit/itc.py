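"""Single-site isothermal titration calorimetry: model, simulator, fitter.

The 1:1 binding model for a perfusion-cell calorimeter.  A macromolecule M
at concentration ``cell_conc`` (with n equivalent sites) sits in an active
cell volume V0; ligand X at ``syringe_conc`` is added in a series of small
injections.  After injection i the total concentrations, corrected for
displacement of cell liquid by the injectant, are

    M_t(i) = M0 * (1 - dV_i/(2 V0)) / (1 + dV_i/(2 V0))
    X_t(i) = X0 * (dV_i/V0)        / (1 + dV_i/(2 V0))

with dV_i the cumulative injected volume.  The bound-site fraction theta
solves the mass-action quadratic

    S theta^2 - (X_t + S + K_D) theta + X_t = 0,   S = n * M_t,

(the root in [0, 1]), the cumulative heat is Q_i = n theta_i M_t dH V0,
and the observed heat of injection i is the displaced-volume-corrected
difference

    dQ_i = Q_i - Q_{i-1} + (v_i / V0) * (Q_i + Q_{i-1}) / 2 + q_dil

where v_i is the volume of injection i and q_dil a constant heat of
dilution.  With concentrations in mol/l, volumes in µl and dH in cal/mol,
heats come out in µcal.

Fitting follows the usual model/results pattern:
``SingleSiteBindingModel(thermogram, protocol).fit()`` returns a
``SingleSiteFitResult`` with estimates, standard errors and a summary
table.  Least squares runs over (n, log10 K, dH, q_dil); K = 1/K_D.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "TitrationProtocol", "BindingParams", "Thermogram",
    "total_concentrations", "bound_fraction", "cumulative_heat",
    "injection_heats", "injection_heat", "simulate_thermogram",
    "SingleSiteBindingModel", "SingleSiteFitResult",
    "fit_single_site", "fold_change", "wiseman_c",
    "REFERENCE_AFFINITIES", "default_protocol",
]

#: Reported dissociation constants (mol/l) for the budding-yeast
#: Bub1(289-359)-Bub3 / MELT-phosphopeptide interactions, used as ground
#: truths in parameter-recovery simulations.
REFERENCE_AFFINITIES: dict[str, float] = {
    "MELT2P_wildtype": 200e-9,
    "MELT4P_wildtype": 1.3e-6,
    "MELT2P_R217A": 2.7e-6,
    "MELT2P_R239A": 5.0e-6,
    "MELT2P_Bub3_alone": 2.0e-6,
}


@dataclass(frozen=True)
class TitrationProtocol:
    """Titration description: concentrations in mol/l, volumes in µl."""

    cell_conc: float                          # M0, mol/l
    syringe_conc: float                       # X0, mol/l
    injection_volumes_ul: tuple[float, ...]   # one entry per injection
    cell_volume_ul: float = 200.0             # V0, active cell volume
    temperature_c: float = 25.0

    def __post_init__(self):
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.cell_volume_ul <= 0:
            raise ValueError("cell volume must be positive")
        if not self.injection_volumes_ul or min(self.injection_volumes_ul) <= 0:
            raise ValueError("injection volumes must be positive")
        total = sum(self.injection_volumes_ul)
        if total > self.cell_volume_ul:
            raise ValueError("total injected volume exceeds the cell volume")
        if total > 0.5 * self.cell_volume_ul:
            import warnings
            warnings.warn("total injected volume exceeds 50% of the cell "
                          "volume; dilution corrections become large",
                          stacklevel=2)

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)


def default_protocol(cell_conc: float = 30e-6, syringe_conc: float = 400e-6,
                     n_injections: int = 35, injection_volume_ul: float = 2.0,
                     **kw) -> TitrationProtocol:
    """The protocol used throughout: 30 µM in the cell titrated with
    thirty-five 2-µl injections of 400 µM ligand at 25 °C."""
    return TitrationProtocol(cell_conc=cell_conc, syringe_conc=syringe_conc,
                             injection_volumes_ul=(injection_volume_ul,) * n_injections,
                             **kw)


@dataclass(frozen=True)
class BindingParams:
    """Thermodynamic parameters of the single-site model.

    kd in mol/l; dh_cal in cal/mol of injectant bound; q_dil_ucal is the
    constant per-injection heat of dilution in µcal.
    """

    kd: float
    n: float = 1.0
    dh_cal: float = -12000.0
    q_dil_ucal: float = -0.1

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.n <= 0:
            raise ValueError("n must be positive")


@dataclass
class Thermogram:
    """Observed or simulated per-injection heats (µcal)."""

    heats_ucal: np.ndarray
    injection_volumes_ul: np.ndarray
    skip_first: bool = False

    def __post_init__(self):
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        self.injection_volumes_ul = np.asarray(self.injection_volumes_ul, dtype=float)
        if self.heats_ucal.shape != self.injection_volumes_ul.shape:
            raise ValueError("heats and volumes must have matching lengths")

    def __len__(self) -> int:
        return self.heats_ucal.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"injection": np.arange(1, len(self) + 1),
                             "volume_ul": self.injection_volumes_ul,
                             "heat_ucal": self.heats_ucal})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, skip_first: bool = False) -> "Thermogram":
        df = pd.read_csv(path)
        return cls(df["heat_ucal"].to_numpy(),
                   df["volume_ul"].to_numpy(), skip_first=skip_first)


# ---------------------------------------------------------------------------
# forward model

def total_concentrations(protocol: TitrationProtocol):
    """Per-injection total concentrations (M_t, X_t) in the cell, mol/l,
    under the perfusion-cell displacement convention."""
    dv = np.cumsum(protocol.injection_volumes_ul)
    v0 = protocol.cell_volume_ul
    mt = protocol.cell_conc * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
    xt = protocol.syringe_conc * (dv / v0) / (1 + dv / (2 * v0))
    return mt, xt


def bound_fraction(mt, xt, n: float, kd: float):
    """Bound-site fraction theta of the 1:1 mass-action model (vectorized).

    Root in [0, 1] of  S theta^2 - (X_t + S + K_D) theta + X_t = 0 with
    S = n * M_t; clamped against floating-point rounding.
    """
    s = n * np.asarray(mt, dtype=float)
    xt = np.asarray(xt, dtype=float)
    b = xt + s + kd
    disc = b * b - 4.0 * s * xt
    theta = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * s)
    return np.clip(theta, 0.0, 1.0)


def cumulative_heat(protocol: TitrationProtocol, params: BindingParams,
                    i: int | None = None):
    """Cumulative heat Q_i (µcal) after injection i (1-based); the full
    array for i=None."""
    mt, xt = total_concentrations(protocol)
    theta = bound_fraction(mt, xt, params.n, params.kd)
    q = params.n * theta * mt * params.dh_cal * protocol.cell_volume_ul
    if i is None:
        return q
    if not (1 <= i <= protocol.n_injections):
        raise IndexError("injection index out of range")
    return float(q[i - 1])


def injection_heats(protocol: TitrationProtocol, params: BindingParams):
    """Displaced-volume-corrected heats of all injections (µcal)."""
    q = cumulative_heat(protocol, params)
    qprev = np.concatenate([[0.0], q[:-1]])
    v = np.asarray(protocol.injection_volumes_ul, dtype=float)
    return (q - qprev + (v / protocol.cell_volume_ul) * (q + qprev) / 2.0
            + params.q_dil_ucal)


def injection_heat(protocol: TitrationProtocol, params: BindingParams,
                   i: int) -> float:
    if not (1 <= i <= protocol.n_injections):
        raise IndexError("injection index out of range")
    return float(injection_heats(protocol, params)[i - 1])


def simulate_thermogram(protocol: TitrationProtocol, params: BindingParams,
                        noise_sd: float = 0.0, seed: int = 0) -> Thermogram:
    """Model heats plus i.i.d. Gaussian noise; deterministic per seed."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    heats = injection_heats(protocol, params)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x17c]))
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return Thermogram(heats, np.asarray(protocol.injection_volumes_ul))


def wiseman_c(protocol: TitrationProtocol, params: BindingParams) -> float:
    """Wiseman sigmoidicity parameter c = n * M0 / K_D."""
    return params.n * protocol.cell_conc / params.kd


# ---------------------------------------------------------------------------
# fitting

class SingleSiteFitResult:
    """Estimates, uncertainties and diagnostics of a single-site fit."""

    def __init__(self, params: BindingParams, bse: dict[str, float],
                 ssr: float, converged: bool, no_binding: bool,
                 nobs: int, model: "SingleSiteBindingModel",
                 lmfit_result=None):
        self.params = params
        self.bse = bse
        self.ssr = ssr
        self.converged = converged
        self.no_binding = no_binding
        self.nobs = nobs
        self.model = model
        self.lmfit_result = lmfit_result

    @property
    def kd(self) -> float:
        return self.params.kd

    def fittedvalues(self) -> np.ndarray:
        return injection_heats(self.model.protocol, self.params)[self.model.used]

    def resid(self) -> np.ndarray:
        return self.model.heats - self.fittedvalues()

    def summary(self) -> str:
        p, se = self.params, self.bse
        lines = [
            "Single-site binding model (isothermal titration calorimetry)",
            "=" * 62,
            f"Observations (injections used): {self.nobs}",
            f"Converged: {self.converged}    No binding: {self.no_binding}",
            f"Sum of squared residuals: {self.ssr:.5g} ucal^2",
            "-" * 62,
            f"{'parameter':<14}{'estimate':>16}{'std err':>16}",
            f"{'n (sites)':<14}{p.n:>16.4g}{se.get('n', float('nan')):>16.3g}",
            f"{'K_D (M)':<14}{p.kd:>16.4g}{se.get('kd', float('nan')):>16.3g}",
            f"{'dH (cal/mol)':<14}{p.dh_cal:>16.6g}{se.get('dh_cal', float('nan')):>16.3g}",
            f"{'q_dil (ucal)':<14}{p.q_dil_ucal:>16.4g}{se.get('q_dil_ucal', float('nan')):>16.3g}",
            "-" * 62,
            f"Wiseman c = {wiseman_c(self.model.protocol, p):.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"n": self.params.n, "kd": self.params.kd,
                "dh_cal": self.params.dh_cal,
                "q_dil_ucal": self.params.q_dil_ucal,
                "bse": self.bse, "ssr": self.ssr,
                "converged": self.converged, "no_binding": self.no_binding,
                "nobs": self.nobs}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


class SingleSiteBindingModel:
    """Least-squares single-site model bound to one thermogram.

    Optimizes (n, log10 K, dH, q_dil); standard errors come from the local
    curvature (covariance of the least-squares solution).  A fit whose
    saturation amplitude |n dH M0 V0| is smaller than three residual
    standard deviations of a constant-only fit is flagged ``no_binding``.
    """

    MIN_INJECTIONS = 8

    def __init__(self, thermogram: Thermogram, protocol: TitrationProtocol):
        if len(thermogram) != protocol.n_injections:
            raise ValueError("thermogram length does not match protocol")
        self.thermogram = thermogram
        self.protocol = protocol
        self.used = np.ones(protocol.n_injections, dtype=bool)
        if thermogram.skip_first:
            self.used[0] = False
        if int(self.used.sum()) < self.MIN_INJECTIONS:
            raise ValueError(f"need >= {self.MIN_INJECTIONS} usable injections")
        self.heats = thermogram.heats_ucal[self.used]

    # -- initialization ----------------------------------------------------
    def _initial_guess(self) -> BindingParams:
        heats = self.thermogram.heats_ucal
        mt, xt = total_concentrations(self.protocol)
        ratio = xt / mt
        q_dil0 = float(np.mean(heats[-5:]))
        # n: molar ratio at the steepest change of the heat curve
        d = np.diff(heats)
        n0 = float(np.clip(ratio[np.argmax(np.abs(d)) + 1], 0.2, 5.0))
        # dH: early (first-quartile) heats above baseline, per mole injected
        nq = max(1, len(heats) // 4)
        moles_per_inj = (self.protocol.syringe_conc
                         * float(np.mean(self.protocol.injection_volumes_ul[:nq])))
        dh0 = (float(np.mean(heats[:nq])) - q_dil0) / moles_per_inj
        if not np.isfinite(dh0) or dh0 == 0:
            dh0 = -1000.0
        kd0 = n0 * self.protocol.cell_conc / 10.0   # neutral start at c = 10
        return BindingParams(kd=kd0, n=n0, dh_cal=dh0, q_dil_ucal=q_dil0)

    def predict(self, params: BindingParams) -> np.ndarray:
        return injection_heats(self.protocol, params)

    # -- fitting -----------------------------------------------------------
    def fit(self, start: BindingParams | None = None,
            xtol: float = 1e-12, ftol: float = 1e-12) -> SingleSiteFitResult:
        start = start or self._initial_guess()
        pars = lmfit.Parameters()
        pars.add("n", value=start.n, min=0.05, max=10.0)
        pars.add("log10_k", value=-math.log10(start.kd), min=2.0, max=12.0)
        pars.add("dh_cal", value=start.dh_cal)
        pars.add("q_dil_ucal", value=start.q_dil_ucal)

        used = self.used

        def residual(p):
            bp = BindingParams(kd=10.0 ** (-p["log10_k"].value),
                               n=p["n"].value, dh_cal=p["dh_cal"].value,
                               q_dil_ucal=p["q_dil_ucal"].value)
            return injection_heats(self.protocol, bp)[used] - self.heats

        res = lmfit.minimize(residual, pars, method="leastsq",
                             xtol=xtol, ftol=ftol)
        v = res.params.valuesdict()
        fitted = BindingParams(kd=10.0 ** (-v["log10_k"]), n=v["n"],
                               dh_cal=v["dh_cal"], q_dil_ucal=v["q_dil_ucal"])
        bse = {}
        for name in ("n", "dh_cal", "q_dil_ucal"):
            err = res.params[name].stderr
            bse[name] = float(err) if err is not None else float("nan")
        lk_err = res.params["log10_k"].stderr
        # delta method: K_D = 10^(-log10_k)
        bse["kd"] = (float(abs(fitted.kd * math.log(10) * lk_err))
                     if lk_err is not None else float("nan"))
        ssr = float(np.sum(res.residual ** 2))

        # no-binding rule: the realized binding signal (range of the fitted
        # curve; the dilution constant cancels) must exceed three times the
        # residual noise of the fit.  The range is used rather than the
        # saturation amplitude n*dH*M0*V0 because in the weak-binding limit
        # dH and K compensate, inflating the amplitude while the observable
        # curve stays flat; the full-fit residual sd is used rather than a
        # constant-only fit because for genuine binding the latter is
        # dominated by the curve itself.
        predicted = injection_heats(self.protocol, fitted)[used]
        amp = float(predicted.max() - predicted.min())
        dof = max(1, int(used.sum()) - 4)
        resid_sd = math.sqrt(ssr / dof)
        no_binding = bool(amp <= 3.0 * resid_sd + 1e-9)

        return SingleSiteFitResult(fitted, bse, ssr,
                                   converged=bool(res.success),
                                   no_binding=no_binding,
                                   nobs=int(used.sum()), model=self,
                                   lmfit_result=res)


def fit_single_site(thermogram: Thermogram, protocol: TitrationProtocol,
                    **options) -> SingleSiteFitResult:
    """Convenience wrapper: build the model and fit it."""
    return SingleSiteBindingModel(thermogram, protocol).fit(**options)


def fold_change(fit_a: SingleSiteFitResult, fit_b: SingleSiteFitResult) -> float:
    """Affinity fold change K_D(b) / K_D(a); errors on flagged fits."""
    for which, fr in (("a", fit_a), ("b", fit_b)):
        if not fr.converged:
            raise ValueError(f"fit {which} did not converge")
        if fr.no_binding:
            raise ValueError(f"fit {which} is flagged no_binding")
    return fit_b.kd / fit_a.kd
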