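"""One-site ITC: forward model, nonlinear fitting, thermodynamic relations.

Thermodynamic conventions match the usual calorimetric bookkeeping:
heats in ucal, dH and dG in kcal/mol, dS in cal/(mol K), K_d in uM,
K_b = 1/K_d in M^-1, and

    dG = -R T ln K_b,   dG = dH - T dS,   R = 1.9872e-3 kcal/(mol K).

The injection model follows the perfusion-cell (constant active volume)
convention of titration microcalorimeters: each injection of volume dv
displaces an equal volume of cell content, diluting existing species by
(1 - dv/V0), and the measured heat per injection is

    q_i = dH * ( V0 * ([PL]_i - [PL]_{i-1}) + dv * ([PL]_i + [PL]_{i-1}) / 2 )
          + dilution_offset,

where the dv term credits the complex carried out with the displaced volume
at the mean of the pre- and post-injection bound concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from sklearn.base import BaseEstimator

from .binding import bound_fraction

__all__ = [
    "R_KCAL",
    "ITCProtocol",
    "Thermogram",
    "ThermoParams",
    "derive_thermo",
    "simulate_injection_heats",
    "ITCOneSiteModel",
    "ITCFitReport",
    "fit_one_site",
    "paper_protocol",
]

R_KCAL = 1.9872e-3  # kcal/(mol K); 8.314 J/(mol K) in calorimetric units


@dataclass
class ITCProtocol:
    """Titration protocol: what sits in the cell and what gets injected."""

    cell_conc: float                 # uM, analyte in the cell
    syringe_conc: float              # uM, titrant
    cell_volume: float               # uL, active cell volume V0
    injection_volumes: list[float]   # uL per injection
    temperature: float = 298.0       # K

    def __post_init__(self) -> None:
        if min(self.cell_conc, self.syringe_conc, self.cell_volume) <= 0:
            raise ValueError("concentrations and cell volume must be > 0")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be > 0")
        if not (273.0 <= self.temperature <= 373.0):
            raise ValueError("temperature outside [273, 373] K")


def paper_protocol(n_injections: int = 20, injection_volume: float = 2.0) -> ITCProtocol:
    """The titration layout used throughout: 1 mM titrant injected into a
    50 uM cell sample (20 x 2 uL by default, 40 x 1 uL as the alternative),
    200 uL active cell volume, 298 K."""
    return ITCProtocol(
        cell_conc=50.0,
        syringe_conc=1000.0,
        cell_volume=200.0,
        injection_volumes=[injection_volume] * n_injections,
        temperature=298.0,
    )


@dataclass
class Thermogram:
    injection_heats: list[float]     # ucal per injection
    protocol: ITCProtocol

    def __post_init__(self) -> None:
        if len(self.injection_heats) != len(self.protocol.injection_volumes):
            raise ValueError("one heat per injection volume required")
        if not np.all(np.isfinite(self.injection_heats)):
            raise ValueError("injection heats must be finite")


@dataclass(frozen=True)
class ThermoParams:
    """Complete, self-consistent one-site thermodynamic parameter set."""

    K_d: float    # uM
    K_b: float    # 1/M
    dH: float     # kcal/mol
    dS: float     # cal/(mol K)
    dG: float     # kcal/mol
    n: float = 1.0
    T: float = 298.0

    def __post_init__(self) -> None:
        if self.K_d <= 0 or self.K_b <= 0:
            raise ValueError("K_d and K_b must be > 0")
        _check_rel("K_b vs 1/K_d", self.K_b, 1.0 / (self.K_d * 1e-6))
        _check_rel("dG vs dH - T dS", self.dG, self.dH - self.T * self.dS / 1000.0)
        _check_rel("dG vs -RT ln K_b", self.dG, -R_KCAL * self.T * np.log(self.K_b))


def _check_rel(what: str, a: float, b: float, tol: float = 1e-9) -> None:
    scale = max(abs(a), abs(b), 1e-30)
    if abs(a - b) > tol * scale:
        raise ValueError(f"ThermoParams invariant violated ({what}): {a} vs {b}")


def derive_thermo(K_d: float | None = None, dH: float | None = None,
                  dS: float | None = None, T: float = 298.0,
                  n: float = 1.0) -> ThermoParams:
    """Complete the thermodynamic set from exactly two of {K_d, dH, dS}.

    Uses dG = -RT ln K_b and dG = dH - T dS with R = 1.9872e-3 kcal/(mol K).
    """
    given = [v is not None for v in (K_d, dH, dS)]
    if sum(given) != 2:
        raise ValueError("supply exactly two of K_d, dH, dS")
    if K_d is not None:
        if K_d <= 0:
            raise ValueError("K_d must be > 0")
        K_b = 1.0 / (K_d * 1e-6)
        dG = -R_KCAL * T * np.log(K_b)
        if dH is None:
            dH = dG + T * dS / 1000.0
        else:
            dS = (dH - dG) / T * 1000.0
    else:
        dG = dH - T * dS / 1000.0
        K_b = np.exp(-dG / (R_KCAL * T))
        K_d = 1e6 / K_b
    return ThermoParams(K_d=float(K_d), K_b=float(K_b), dH=float(dH),
                        dS=float(dS), dG=float(dG), n=n, T=T)


# ---------------------------------------------------------------------------
# forward model

def _heats_ucal(K_d: float, dH: float, n: float, protocol: ITCProtocol,
                dilution_offset: float) -> np.ndarray:
    """Per-injection heats (ucal) from the perfusion one-site model."""
    V0 = protocol.cell_volume * 1e-6          # L
    M = protocol.cell_conc * 1e-6             # mol/L analyte in cell
    Xs = protocol.syringe_conc * 1e-6         # mol/L titrant in syringe
    kd = K_d * 1e-6                           # mol/L
    dH_ucal = dH * 1e9                        # ucal/mol
    X = 0.0
    pl_prev = 0.0
    heats = np.empty(len(protocol.injection_volumes))
    for i, dv_ul in enumerate(protocol.injection_volumes):
        dv = dv_ul * 1e-6
        fdil = 1.0 - dv / V0
        M *= fdil
        X = X * fdil + Xs * dv / V0
        sites = n * M
        # bound_fraction is unit-agnostic; all three arguments here are mol/L
        pl = bound_fraction(sites, X, kd) * sites if sites > 0 else 0.0
        heats[i] = dH_ucal * (V0 * (pl - pl_prev) + dv * (pl + pl_prev) / 2.0)
        heats[i] += dilution_offset
        pl_prev = pl
    return heats


def simulate_injection_heats(params: ThermoParams, protocol: ITCProtocol,
                             dilution_offset: float = 0.0) -> Thermogram:
    """Noise-free thermogram for a parameter set under a protocol."""
    heats = _heats_ucal(params.K_d, params.dH, params.n, protocol, dilution_offset)
    return Thermogram(list(heats), protocol)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class ITCFitReport:
    converged: bool
    chisqr: float
    dilution_offset: float
    n_injections_used: int
    message: str = ""
    residuals: np.ndarray = field(default=None, repr=False)


class ITCOneSiteModel(BaseEstimator):
    """One-site ITC fit over (K_b, dH, dilution offset), n fixed to 1 by default.

    Parameters
    ----------
    protocol : ITCProtocol
        Injection layout and concentrations (required before `fit`).
    fix_n : bool
        Keep the stoichiometry at 1 (default); otherwise n is a free
        parameter.
    discard_first : bool
        Drop the first injection from the fit (standard practice: the first
        aliquot is corrupted by syringe diffusion during equilibration).
    n_starts : int
        Multi-start count over log-spaced K_b initial values.
    kd_bounds : (float, float)
        K_d search bounds in uM.

    Attributes
    ----------
    thermo_ : ThermoParams or None
        Full derived parameter set (None when the fit did not converge).
    dilution_offset_ : float
    converged_ : bool
    report_ : ITCFitReport
    """

    def __init__(self, protocol: ITCProtocol | None = None, fix_n: bool = True,
                 discard_first: bool = True, n_starts: int = 5,
                 kd_bounds: tuple[float, float] = (1e-3, 1e5)):
        self.protocol = protocol
        self.fix_n = fix_n
        self.discard_first = discard_first
        self.n_starts = n_starts
        self.kd_bounds = kd_bounds

    def _resolve_protocol(self) -> ITCProtocol:
        if self.protocol is None:
            raise ValueError("protocol must be set before fitting")
        return self.protocol

    def fit(self, X, y=None):
        """Fit injection heats.

        ``X`` may be a `Thermogram`, or an array of heats (ucal) matching the
        protocol's injections (``y`` is then ignored).
        """
        if isinstance(X, Thermogram):
            protocol = X.protocol
            heats = np.asarray(X.injection_heats, dtype=float)
            self.protocol = protocol
        else:
            protocol = self._resolve_protocol()
            heats = np.asarray(X, dtype=float).ravel()
        if len(heats) != len(protocol.injection_volumes):
            raise ValueError("heat count does not match protocol injections")
        use = np.ones(len(heats), dtype=bool)
        if self.discard_first:
            use[0] = False
        if use.sum() < 5:
            raise ValueError("need at least 5 usable injections")
        y_obs = heats[use]

        if np.ptp(y_obs) < 1e-12:
            # flat thermogram: dH and K_b are unidentifiable
            self.thermo_ = None
            self.dilution_offset_ = float(np.mean(y_obs))
            self.converged_ = False
            self.report_ = ITCFitReport(False, float(np.sum((y_obs - np.mean(y_obs)) ** 2)),
                                        self.dilution_offset_, int(use.sum()),
                                        "degenerate thermogram: no binding signal")
            return self

        moles_inj = protocol.injection_volumes[0] * 1e-6 * protocol.syringe_conc * 1e-6
        dh0 = np.clip(y_obs[0] / (moles_inj * 1e9), -50, 50)
        lo, hi = np.log10(self.kd_bounds)

        def residual(p):
            model = _heats_ucal(10.0 ** p["log10_kd"].value, p["dH"].value,
                                p["n"].value, protocol, p["offset"].value)
            return model[use] - y_obs

        best = None
        for start in np.linspace(max(lo, -1.0), min(hi, 3.0), self.n_starts):
            p = lmfit.Parameters()
            p.add("log10_kd", value=start, min=lo, max=hi)
            p.add("dH", value=dh0 if dh0 != 0 else -1.0, min=-100, max=100)
            p.add("offset", value=0.0, min=-50, max=50)
            p.add("n", value=1.0, vary=not self.fix_n, min=0.1, max=10.0)
            try:
                res = lmfit.minimize(residual, p, method="leastsq")
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            self.thermo_ = None
            self.converged_ = False
            self.report_ = ITCFitReport(False, np.inf, 0.0, int(use.sum()),
                                        "optimizer failed from every start")
            return self
        bp = best.params
        log_kd = bp["log10_kd"].value
        at_bound = (log_kd - lo < 1e-6) or (hi - log_kd < 1e-6)
        converged = bool(best.success) and not at_bound
        self.thermo_ = derive_thermo(K_d=10.0 ** log_kd, dH=bp["dH"].value,
                                     T=protocol.temperature, n=bp["n"].value)
        self.dilution_offset_ = float(bp["offset"].value)
        self.converged_ = converged
        self.report_ = ITCFitReport(converged, float(best.chisqr),
                                    self.dilution_offset_, int(use.sum()),
                                    "" if converged else "fit hit bounds or failed",
                                    residuals=np.asarray(best.residual))
        return self

    def predict(self, X=None) -> np.ndarray:
        """Model heats (ucal) for the fitted parameters under the protocol."""
        if getattr(self, "thermo_", None) is None:
            raise ValueError("model not fitted or not converged")
        protocol = self.protocol if X is None else (
            X.protocol if isinstance(X, Thermogram) else self.protocol
        )
        return _heats_ucal(self.thermo_.K_d, self.thermo_.dH, self.thermo_.n,
                           protocol, self.dilution_offset_)


def fit_one_site(thermogram: Thermogram, fix_n: bool = True,
                 discard_first: bool = True) -> tuple[ThermoParams | None, ITCFitReport]:
    """Fit a thermogram with the one-site model (thin wrapper).

    Returns the derived thermodynamic parameters (None if the fit did not
    converge — never silent defaults) and a fit report.
    """
    model = ITCOneSiteModel(fix_n=fix_n, discard_first=discard_first).fit(thermogram)
    return model.thermo_, model.report_
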