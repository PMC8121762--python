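"""One-compartment pharmacokinetics for synthesised peptide candidates.

Closed-form solutions: an i.v. bolus decays mono-exponentially,
C(t) = (D/V) e^(-ke t); a subcutaneous dose follows the Bateman
function C(t) = F D ka / (V (ka - ke)) (e^(-ke t) - e^(-ka t)).
Fitting is least squares on log concentrations with multi-start over
(ka, ke); the extravascular fit identifies V/F, not V, and the flip-flop
ambiguity (ka and ke exchangeable with a rescaled V/F) is resolved by
reporting the labelling with ka > ke.  Non-compartmental AUC uses the
linear-up/log-down trapezoid with a terminal log-linear lambda_z.
Bioavailability is the dose-normalised AUC ratio of the s.c. and i.v.
arms, and steady-state infusion planning inverts Css = rate / (CL/F).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import linregress

LN2 = float(np.log(2.0))
MIN_PER_DAY = 1440.0


@dataclass
class PKDataset:
    """A concentration-time profile for one analyte and one route."""

    route: str  # 'iv' or 'sc'
    dose: float  # mg/kg
    times: np.ndarray  # min, strictly increasing, >= 0
    concentrations: np.ndarray  # same length, >= 0
    unit: str = "ng/mL"  # or 'nM'
    analyte: str = ""
    molecular_weight: float | None = None  # g/mol

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.route not in ("iv", "sc"):
            raise ValueError(f"route must be 'iv' or 'sc', got {self.route!r}")
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have the same length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if self.dose <= 0:
            raise ValueError("dose must be positive")

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.concentrations > 0))


@dataclass
class PKFit:
    """Fitted one-compartment parameters (V and CL are apparent, /F)."""

    route: str
    ke: float  # 1/min
    V_over_F: float  # dose units per concentration unit
    ka: float | None = None  # 1/min, sc only
    residual_norm: float = 0.0
    unit: str = "ng/mL"
    flip_flop_ambiguous: bool = False

    @property
    def t_half(self) -> float:
        """Terminal elimination half-life, min (= ln 2 / ke)."""
        return LN2 / self.ke

    @property
    def CL_over_F(self) -> float:
        """Apparent clearance per kg: ke * V/F (= dose / AUC_0_inf)."""
        return self.ke * self.V_over_F

    def auc_0_inf(self, dose: float) -> float:
        """Model AUC from 0 to infinity for a given dose."""
        return dose / self.CL_over_F


def simulate(
    ke: float,
    V_over_F: float,
    dose: float,
    route: str,
    times: np.ndarray,
    ka: float | None = None,
) -> np.ndarray:
    """Closed-form one-compartment concentrations at ``times``.

    For the s.c. route, ``V_over_F`` is the apparent volume V/F so the
    bioavailability fraction is folded in; ``ka == ke`` uses the
    limiting form C(t) = (D ka t / (V/F)) e^(-ka t).
    """
    times = np.asarray(times, dtype=float)
    if ke <= 0 or V_over_F <= 0 or dose <= 0:
        raise ValueError("ke, V_over_F and dose must be positive")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if route == "iv":
        return (dose / V_over_F) * np.exp(-ke * times)
    if route != "sc":
        raise ValueError(f"unknown route {route!r}")
    if ka is None or ka <= 0:
        raise ValueError("sc simulation requires ka > 0")
    if np.isclose(ka, ke, rtol=1e-12, atol=0):
        return (dose * ka / V_over_F) * times * np.exp(-ka * times)
    coef = dose * ka / (V_over_F * (ka - ke))
    return coef * (np.exp(-ke * times) - np.exp(-ka * times))


def _fit_iv(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    # log C = log(D/V) - ke t: exact linear regression
    res = linregress(t, logc)
    ke = -res.slope
    if ke <= 0:
        raise RuntimeError("i.v. fit produced non-positive elimination rate")
    resid = logc - (res.intercept + res.slope * t)
    return ke, float(np.exp(res.intercept)), float(np.linalg.norm(resid))


def fit(ds: PKDataset, n_starts: int = 6) -> PKFit:
    """Fit the one-compartment model by log-scale least squares.

    Zero concentrations are excluded (below limit of quantification);
    at least three positive points are required.  The s.c. fit
    multi-starts over a grid of (ka, ke) initial values and reports the
    ka > ke labelling; when the flipped labelling fits equally well a
    ``flip_flop_ambiguous`` flag is set (the data alone cannot say which
    rate is absorption).
    """
    if ds.n_positive < 3:
        raise ValueError("need at least 3 positive concentrations to fit")
    mask = ds.concentrations > 0
    t = ds.times[mask]
    c = ds.concentrations[mask]
    logc = np.log(c)

    if ds.route == "iv":
        ke, c0, rnorm = _fit_iv(t, logc)
        return PKFit(
            route="iv", ke=ke, V_over_F=ds.dose / c0, residual_norm=rnorm, unit=ds.unit
        )

    # s.c.: nonlinear fit of (ka, ke, V/F) on log concentrations
    tmax_obs = t[np.argmax(c)]
    ke0_grid = LN2 / np.array([10.0, 20.0, 40.0, 80.0])
    ka_mult_grid = [2.0, 5.0, 10.0]

    def resid(params: np.ndarray) -> np.ndarray:
        lka, lke, lV = params
        pred = simulate(np.exp(lke), np.exp(lV), ds.dose, "sc", t, ka=np.exp(lka))
        pred = np.maximum(pred, 1e-300)
        return np.log(pred) - logc

    best = None
    starts = list(itertools.product(ke0_grid, ka_mult_grid))[: max(n_starts, 1) * 2]
    for ke0, mult in starts:
        ka0 = mult * ke0
        # crude V/F guess from Cmax
        coef0 = ka0 / (ka0 - ke0)
        cmax_model = coef0 * (
            np.exp(-ke0 * tmax_obs) - np.exp(-ka0 * tmax_obs)
        )
        v0 = max(ds.dose * cmax_model / max(c.max(), 1e-12), 1e-9)
        try:
            sol = optimize.least_squares(
                resid,
                x0=np.log([ka0, ke0, v0]),
                method="lm",
                max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("s.c. fit failed to converge from any start")

    ka, ke, V = np.exp(best.x)
    # flip-flop: (ka, ke, V) and (ke, ka, V*ke/ka) trace the same curve
    if ka < ke:
        ka, ke, V = ke, ka, V * ke / ka
    rnorm = float(np.sqrt(2 * best.cost))
    ambiguous = np.isclose(ka, ke, rtol=0.05)
    return PKFit(
        route="sc",
        ke=ke,
        ka=ka,
        V_over_F=V,
        residual_norm=rnorm,
        unit=ds.unit,
        flip_flop_ambiguous=bool(ambiguous),
    )


def fit_replicates(datasets: list[PKDataset]) -> PKFit:
    """Joint fit of one model to replicate profiles of the same experiment.

    All replicates must share route, dose and unit; the model is fitted
    by least squares over the pooled (time, log concentration) points,
    which is the standard way to use replicate animals when no
    between-animal variability model is wanted.
    """
    if not datasets:
        raise ValueError("no datasets")
    first = datasets[0]
    if any(
        d.route != first.route or d.dose != first.dose or d.unit != first.unit
        for d in datasets
    ):
        raise ValueError("replicates must share route, dose and unit")
    times = np.concatenate([d.times for d in datasets])
    concs = np.concatenate([d.concentrations for d in datasets])
    order = np.argsort(times, kind="stable")
    times, concs = times[order], concs[order]
    # collapse duplicate time points by geometric mean of positive values
    out_t, out_c = [], []
    i = 0
    while i < len(times):
        j = i
        while j < len(times) and times[j] == times[i]:
            j += 1
        vals = concs[i:j][concs[i:j] > 0]
        out_t.append(times[i])
        out_c.append(float(np.exp(np.mean(np.log(vals)))) if vals.size else 0.0)
        i = j
    pooled = PKDataset(
        route=first.route,
        dose=first.dose,
        times=np.array(out_t),
        concentrations=np.array(out_c),
        unit=first.unit,
        analyte=first.analyte,
        molecular_weight=first.molecular_weight,
    )
    return fit(pooled)


def nca_auc(ds: PKDataset, n_terminal: int = 3) -> tuple[float, float | None]:
    """Non-compartmental (AUC_0_last, AUC_0_inf).

    Linear trapezoid on rising/flat segments, log trapezoid on falling
    segments; AUC_0_inf adds C_last / lambda_z with lambda_z from a
    log-linear regression on the last ``n_terminal`` (>= 3) positive
    points.  AUC_0_inf is None when lambda_z cannot be estimated.

    When the first sample is taken after t=0 the profile is anchored at
    t=0 following standard NCA practice: an i.v. bolus is
    back-extrapolated log-linearly from the first two positive points
    (C0), an extravascular profile starts at C(0)=0.
    """
    if len(ds.times) < 2:
        raise ValueError("need at least 2 time points")
    t, c = ds.times, ds.concentrations
    if t[0] > 0:
        if ds.route == "iv":
            pos = np.flatnonzero(c > 0)
            if pos.size >= 2 and c[pos[0]] > c[pos[1]]:
                i0, i1 = pos[0], pos[1]
                slope = (np.log(c[i1]) - np.log(c[i0])) / (t[i1] - t[i0])
                c0 = float(np.exp(np.log(c[i0]) - slope * t[i0]))
            else:
                c0 = float(c[0])
        else:
            c0 = 0.0
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[c0], c])
    auc_last = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc_last += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            auc_last += dt * (c1 + c2) / 2.0
    pos = c > 0
    if np.sum(pos) < n_terminal:
        return float(auc_last), None
    tp, cp = t[pos][-n_terminal:], c[pos][-n_terminal:]
    res = linregress(tp, np.log(cp))
    lam_z = -res.slope
    if lam_z <= 0:
        return float(auc_last), None
    c_last = c[pos][-1]
    return float(auc_last), float(auc_last + c_last / lam_z)


def bioavailability(iv: PKDataset, sc: PKDataset) -> float:
    """F = (AUC_sc / D_sc) / (AUC_iv / D_iv), as a fraction.

    Uses AUC_0_inf from :func:`nca_auc`; an all-zero s.c. profile gives
    F = 0, and an inestimable i.v. AUC is an error.
    """
    if iv.route != "iv" or sc.route != "sc":
        raise ValueError("arguments must be (iv dataset, sc dataset)")
    if iv.unit != sc.unit:
        raise ValueError(f"unit mismatch: {iv.unit} vs {sc.unit}")
    sc_last, sc_inf = nca_auc(sc)
    if sc_last == 0:
        return 0.0
    iv_last, iv_inf = nca_auc(iv)
    if iv_inf is None or sc_inf is None:
        raise ValueError("AUC_0_inf undefined on one arm; cannot compute bioavailability")
    return float((sc_inf / sc.dose) / (iv_inf / iv.dose))


def steady_state_rate(
    target_css_nM: float, fit: PKFit, mw: float | None = None
) -> float:
    """Infusion rate (mg/kg/day) sustaining a steady-state target.

    rate = Css x CL/F x 1440 min/day, with Css converted from nM to the
    fit's concentration unit.  For a mass-unit fit (ng/mL) the analyte's
    molecular weight (g/mol) is required: Css[ng/mL] = Css[nM] x MW / 1000.
    CL/F carries units (mg/kg) per (concentration unit x min), so the
    product is mg/kg/min before the per-day conversion.
    """
    if target_css_nM < 0:
        raise ValueError("target Css must be >= 0")
    if fit.unit == "nM":
        css = target_css_nM
    elif fit.unit == "ng/mL":
        if mw is None or mw <= 0:
            raise ValueError("molecular weight required to convert nM to ng/mL")
        css = target_css_nM * mw / 1000.0
    else:
        raise ValueError(f"unsupported concentration unit {fit.unit!r}")
    return float(css * fit.CL_over_F * MIN_PER_DAY)
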