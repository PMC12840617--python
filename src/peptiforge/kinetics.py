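"""Enzyme-inhibition kinetics and assay arithmetic.

Michaelis-Menten velocities are fitted by nonlinear least squares, with
Lineweaver-Burk (double-reciprocal) regression used only for
initialization and diagnostics — double-reciprocal fitting amplifies
noise at low substrate concentrations and is not used as the estimator.

Inhibition models (velocity as a function of substrate S and inhibitor
I, all parameters positive):

* ``michaelis_menten``  v = Vmax*S / (Km + S)
* ``competitive``       v = Vmax*S / (Km*(1 + I/Ki) + S)
* ``noncompetitive``    v = (Vmax / (1 + I/Ki)) * S / (Km + S)
* ``uncompetitive``     v = Vmax*S / (Km + S*(1 + I/Ki))
* ``mixed``             v = Vmax*S / (Km*(1 + I/Ki) + S*(1 + I/(alpha*Ki)))

``fit_inhibition_global`` fits each candidate globally (one Km, Vmax,
Ki shared across all inhibitor levels) and orders the fits by AICc.
Because the mixed model nests both the competitive (alpha -> inf) and
non-competitive (alpha = 1) forms, ``select_model`` applies a parsimony
window: among models within 2 AICc units of the minimum, the one with
the fewest parameters wins.

Closed-form inhibition constants from apparent parameters:

* competitive:      Km_app  = Km * (1 + I/Ki)   =>  Ki = I / (Km_app/Km - 1)
* non-competitive:  Vmax_app = Vmax / (1 + I/Ki) =>  Ki = I / (Vmax/Vmax_app - 1)

The module also houses the surrounding assay arithmetic: inhibition
percentage from progress-curve slopes, degree of hydrolysis (OPA
method), Kjeldahl protein content, size-exclusion molecular-weight
calibration and logistic IC50 fitting.  Units are carried as labels
(velocities in delta-A/h, concentrations as supplied) and never
converted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

MODEL_N_PARAMS = {
    "michaelis_menten": 2,
    "competitive": 3,
    "noncompetitive": 3,
    "uncompetitive": 3,
    "mixed": 4,
}

INHIBITION_MODELS = ("competitive", "noncompetitive", "uncompetitive", "mixed")


def velocity(model: str, S, I, Km: float, Vmax: float, Ki: float | None = None, alpha: float | None = None):
    """Model velocity for substrate S and inhibitor I (vectorized)."""
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if model == "michaelis_menten":
        return Vmax * S / (Km + S)
    if Ki is None:
        raise ValueError(f"model {model!r} requires Ki")
    if model == "competitive":
        return Vmax * S / (Km * (1 + I / Ki) + S)
    if model == "noncompetitive":
        return (Vmax / (1 + I / Ki)) * S / (Km + S)
    if model == "uncompetitive":
        return Vmax * S / (Km + S * (1 + I / Ki))
    if model == "mixed":
        if alpha is None:
            raise ValueError("mixed model requires alpha")
        return Vmax * S / (Km * (1 + I / Ki) + S * (1 + I / (alpha * Ki)))
    raise ValueError(f"unknown model {model!r}")


@dataclass
class KineticsDataset:
    """Initial-velocity measurements: (S, I, v) triples.

    S: substrate concentration (assay units); I: inhibitor concentration
    (uM); v: initial velocity (delta-A/h).  All S > 0, I >= 0, v > 0.
    """

    S: np.ndarray
    I: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (self.S.shape == self.I.shape == self.v.shape):
            raise ValueError("S, I, v must have identical shapes")
        if np.any(self.S <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.any(self.I < 0):
            raise ValueError("inhibitor concentrations must be non-negative")
        if np.any(self.v <= 0):
            raise ValueError("velocities must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "KineticsDataset":
        missing = {"S", "I_uM", "v"} - set(df.columns)
        if missing:
            raise ValueError(f"kinetics table missing columns: {sorted(missing)}")
        return cls(df["S"].to_numpy(), df["I_uM"].to_numpy(), df["v"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "KineticsDataset":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls.from_dataframe(pd.read_csv(path, sep=sep))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"S": self.S, "I_uM": self.I, "v": self.v})

    @property
    def inhibitor_levels(self) -> np.ndarray:
        return np.unique(self.I)

    def at_level(self, level: float) -> "KineticsDataset":
        mask = self.I == level
        return KineticsDataset(self.S[mask], self.I[mask], self.v[mask])


@dataclass
class InhibitionFit:
    """A fitted kinetic model with parameters, SEs, RSS and AICc."""

    model: str
    Km: float
    Vmax: float
    Ki: float | None = None
    alpha: float | None = None
    standard_errors: dict = field(default_factory=dict)
    rss: float = float("nan")
    aicc: float = float("nan")
    n_obs: int = 0

    @property
    def n_params(self) -> int:
        return MODEL_N_PARAMS[self.model]

    def predict(self, S, I=0.0):
        return velocity(self.model, S, I, self.Km, self.Vmax, self.Ki, self.alpha)


@dataclass
class LineweaverBurkLine:
    """Per-inhibitor-level OLS line of 1/v against 1/S."""

    inhibitor: float
    slope: float
    y_intercept: float

    @property
    def x_intercept(self) -> float:
        return -self.y_intercept / self.slope


def lineweaver_burk(data: KineticsDataset) -> dict[float, LineweaverBurkLine]:
    """Double-reciprocal regression for each inhibitor level."""
    out = {}
    for level in data.inhibitor_levels:
        sub = data.at_level(level)
        if len(sub.S) < 2:
            raise ValueError(f"inhibitor level {level}: need >= 2 points for a line")
        slope, intercept = np.polyfit(1.0 / sub.S, 1.0 / sub.v, 1)
        out[float(level)] = LineweaverBurkLine(float(level), float(slope), float(intercept))
    return out


def _aicc(rss: float, n: int, k: int, v_scale: float) -> float:
    # RSS floored at the square of a relative numerical tolerance so that
    # noiseless data do not produce -inf log-likelihoods and nested models
    # are separated by the parameter penalty alone.
    rss_eff = max(rss, n * (1e-8 * v_scale) ** 2)
    if n - k - 1 <= 0:
        return float("inf")
    return n * math.log(rss_eff / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_michaelis_menten(S, v) -> InhibitionFit:
    """Nonlinear least-squares Michaelis-Menten fit (uninhibited data).

    Initial values come from the Lineweaver-Burk linearization.  Returns
    Km and Vmax with asymptotic standard errors.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(np.unique(S)) < 3:
        raise ValueError("Michaelis-Menten fit needs >= 3 distinct substrate concentrations")
    slope, intercept = np.polyfit(1.0 / S, 1.0 / v, 1)
    vmax0 = 1.0 / intercept if intercept > 0 else float(v.max())
    km0 = slope * vmax0 if slope * vmax0 > 0 else float(np.median(S))

    def f(S, Km, Vmax):
        return Vmax * S / (Km + S)

    try:
        popt, pcov = optimize.curve_fit(
            f, S, v, p0=[km0, vmax0], bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    resid = v - f(S, *popt)
    rss = float(resid @ resid)
    perr = np.sqrt(np.diag(pcov))
    fit = InhibitionFit(
        model="michaelis_menten",
        Km=float(popt[0]),
        Vmax=float(popt[1]),
        standard_errors={"Km": float(perr[0]), "Vmax": float(perr[1])},
        rss=rss,
        n_obs=len(S),
    )
    fit.aicc = _aicc(rss, len(S), 2, float(np.mean(np.abs(v))))
    return fit


def _initial_ki(data: KineticsDataset, model: str, km0: float, vmax0: float) -> float:
    """Heuristic Ki start from per-level apparent parameters at the top level."""
    levels = data.inhibitor_levels
    top = levels[levels > 0].max()
    try:
        app = fit_michaelis_menten(data.at_level(top).S, data.at_level(top).v)
        if model in ("competitive", "mixed") and app.Km > km0 * 1.001:
            return top / (app.Km / km0 - 1.0)
        if model in ("noncompetitive", "uncompetitive", "mixed") and 0 < app.Vmax < vmax0 * 0.999:
            return top / (vmax0 / app.Vmax - 1.0)
    except (RuntimeError, ValueError):
        pass
    return float(top)


def fit_inhibition_global(
    data: KineticsDataset, models=INHIBITION_MODELS
) -> list[InhibitionFit]:
    """Globally fit candidate inhibition models; return fits ordered by AICc.

    Each candidate is fitted with Km, Vmax and Ki (and alpha for the
    mixed model) shared across all inhibitor levels.  Requires at least
    two inhibitor levels including I = 0; with only uninhibited data the
    problem reduces to a plain Michaelis-Menten fit.
    """
    levels = data.inhibitor_levels
    if 0.0 not in levels:
        raise ValueError("data must include the uninhibited (I = 0) level")
    if len(levels) == 1:
        return [fit_michaelis_menten(data.S, data.v)]

    base = fit_michaelis_menten(data.at_level(0.0).S, data.at_level(0.0).v)
    v_scale = float(np.mean(np.abs(data.v)))
    n = len(data.v)
    fits: list[InhibitionFit] = []
    for model in models:
        k = MODEL_N_PARAMS[model]
        if len(levels) < 2 or n <= k:
            raise ValueError(f"model {model!r}: not enough data for {k} parameters")
        ki0 = _initial_ki(data, model, base.Km, base.Vmax)
        x0 = [math.log(base.Km), math.log(base.Vmax), math.log(max(ki0, 1e-9))]
        if model == "mixed":
            x0.append(0.0)  # log alpha = 0 -> alpha = 1

        def resid(x, model=model):
            # transient over/underflow during line search is harmless: the
            # optimizer backtracks away from such steps
            with np.errstate(all="ignore"):
                Km, Vmax, Ki = np.exp(x[:3])
                alpha = np.exp(x[3]) if model == "mixed" else None
                return velocity(model, data.S, data.I, Km, Vmax, Ki, alpha) - data.v

        sol = optimize.least_squares(resid, x0, method="lm", max_nfev=20000)
        params = np.exp(sol.x[:3])
        alpha = float(np.exp(sol.x[3])) if model == "mixed" else None
        rss = float(2 * sol.cost)

        # Asymptotic SEs on the log scale, delta method back to linear.
        dof = max(n - len(sol.x), 1)
        try:
            cov_log = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        except np.linalg.LinAlgError:
            se_log = np.full(len(sol.x), float("nan"))
        ses = {
            "Km": float(params[0] * se_log[0]),
            "Vmax": float(params[1] * se_log[1]),
            "Ki": float(params[2] * se_log[2]),
        }
        if model == "mixed":
            ses["alpha"] = float(alpha * se_log[3])

        fit = InhibitionFit(
            model=model,
            Km=float(params[0]),
            Vmax=float(params[1]),
            Ki=float(params[2]),
            alpha=alpha,
            standard_errors=ses,
            rss=rss,
            n_obs=n,
        )
        fit.aicc = _aicc(rss, n, len(sol.x), v_scale)
        fits.append(fit)
    fits.sort(key=lambda f: f.aicc)
    return fits


def select_model(fits: list[InhibitionFit], aicc_window: float = 2.0) -> InhibitionFit:
    """Pick the inhibition mode: lowest AICc, with a parsimony window.

    Among fits within ``aicc_window`` of the best AICc, the one with the
    fewest parameters wins (the mixed model nests the simpler modes, so
    raw AICc alone would over-select it under noise).
    """
    if not fits:
        raise ValueError("no fits to select from")
    best_aicc = min(f.aicc for f in fits)
    contenders = [f for f in fits if f.aicc <= best_aicc + aicc_window]
    return min(contenders, key=lambda f: (f.n_params, f.aicc))


# ---------------------------------------------------------------------------
# Closed-form inhibition constants


def ki_competitive(Km: float, Km_app: float, I: float) -> float:
    """Ki from the competitive relation Km_app = Km * (1 + I/Ki)."""
    if Km <= 0 or I <= 0:
        raise ValueError("Km and I must be positive")
    if Km_app <= Km:
        raise ValueError("Km_app must exceed Km (no competitive inhibition signal)")
    return I / (Km_app / Km - 1.0)


def ki_noncompetitive(Vmax: float, Vmax_app: float, I: float) -> float:
    """Ki from the non-competitive relation Vmax_app = Vmax / (1 + I/Ki)."""
    if Vmax <= 0 or I <= 0:
        raise ValueError("Vmax and I must be positive")
    if not 0 < Vmax_app < Vmax:
        raise ValueError("need 0 < Vmax_app < Vmax (no non-competitive inhibition signal)")
    return I / (Vmax / Vmax_app - 1.0)


def apparent_km(Km: float, Ki: float, I: float) -> float:
    """Competitive apparent Km: Km * (1 + I/Ki)."""
    return Km * (1.0 + I / Ki)


def apparent_vmax(Vmax: float, Ki: float, I: float) -> float:
    """Non-competitive apparent Vmax: Vmax / (1 + I/Ki)."""
    return Vmax / (1.0 + I / Ki)


# ---------------------------------------------------------------------------
# Assay arithmetic


def inhibition_percent(slope_sample: float, slope_control: float) -> float:
    """Inhibition % = 100 * (1 - slope_sample / slope_control).

    Slopes are from the time-absorbance progress curves of sample and
    uninhibited control.  A negative result (sample faster than control)
    is returned as-is with a warning rather than clamped.
    """
    if slope_control <= 0:
        raise ValueError("control slope must be positive")
    pct = 100.0 * (1.0 - slope_sample / slope_control)
    if pct < 0:
        warnings.warn("negative inhibition percentage (sample slope exceeds control)")
    return pct


def dh_percent(free_amino: float, V1: float, m1: float, total_amino: float, V: float, m: float) -> float:
    """Degree of hydrolysis (%) by the OPA free-amino-group method.

    DH = 100 * ([NH2] * V1 * m) / ([NH2]_tot * V * m1), where [NH2] and
    V1, m1 describe the hydrolysate sample and [NH2]_tot, V, m the
    completely hydrolyzed reference.
    """
    if min(V1, m1, total_amino, V, m) <= 0 or free_amino < 0:
        raise ValueError("volumes, masses and total amino concentration must be positive")
    return 100.0 * (free_amino * V1 * m) / (total_amino * V * m1)


def protein_content_kjeldahl(
    V1: float, V2: float, c: float, m: float, V_aliquot: float, F: float = 5.7
) -> float:
    """Kjeldahl protein content in g/100 g.

    X = (V1 - V2) * c * 0.014 * F * 100 / (m * V_aliquot/100), where V1/V2
    are the titration volumes (mL) for sample and blank, c the acid
    molarity, m the sample mass (g), V_aliquot the volume (mL) of the
    100 mL digestion solution taken for distillation, and F the
    nitrogen-to-protein factor (5.7 for blood proteins here).
    """
    if V1 < V2:
        raise ValueError("V1 must be >= V2 (sample titration cannot be below blank)")
    if min(c, m, V_aliquot, F) <= 0:
        raise ValueError("c, m, V_aliquot and F must be positive")
    return (V1 - V2) * c * 0.014 * F * 100.0 / (m * V_aliquot / 100.0)


def mw_from_sec(standards, sample_rt: float) -> tuple[float, bool]:
    """Molecular weight from a size-exclusion calibration curve.

    ``standards`` is a sequence of (MW in Da, retention time in min)
    pairs.  A line of log10(MW) against RT is fitted; the sample MW is
    10**(a*rt + b).  Returns (MW, extrapolated) where ``extrapolated``
    flags a sample RT outside the calibrated range.
    """
    standards = list(standards)
    if len(standards) < 2:
        raise ValueError("need >= 2 standards for a calibration line")
    mw = np.array([s[0] for s in standards], dtype=float)
    rt = np.array([s[1] for s in standards], dtype=float)
    if np.any(mw <= 0):
        raise ValueError("standard molecular weights must be positive")
    if len(np.unique(rt)) < 2:
        raise ValueError("degenerate standards: retention times are all equal")
    a, b = np.polyfit(rt, np.log10(mw), 1)
    extrapolated = not (rt.min() <= sample_rt <= rt.max())
    return float(10 ** (a * sample_rt + b)), extrapolated


# ---------------------------------------------------------------------------
# Dose-response / IC50


@dataclass
class DoseResponse:
    """Logistic dose-response fit: residual activity % against concentration."""

    ic50: float
    hill: float
    bottom: float
    top: float
    concentrations: np.ndarray
    responses: np.ndarray
    rss: float
    in_range: bool

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (conc / self.ic50) ** self.hill)


def fit_ic50(concentrations, activity_pct, free_asymptotes: bool = False) -> DoseResponse:
    """Fit a logistic curve of residual activity (%) vs log concentration.

    By default the asymptotes are fixed at 0 and 100 (activity is
    normalized to the uninhibited control); ``free_asymptotes=True``
    releases them.  IC50 is the concentration at 50 % activity; the Hill
    slope is free.  A non-monotone dose-response beyond noise triggers a
    warning.
    """
    conc = np.asarray(concentrations, dtype=float)
    act = np.asarray(activity_pct, dtype=float)
    if len(conc) != len(act):
        raise ValueError("length mismatch")
    if len(conc) < 4:
        raise ValueError("need >= 4 concentrations spanning the transition")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    order = np.argsort(conc)
    diffs = np.diff(act[order])
    if np.any(diffs > 0.1 * (act.max() - act.min() + 1e-12)):
        warnings.warn("dose-response is not monotone beyond noise")

    logc = np.log10(conc)
    ic50_0 = float(np.interp(50.0, act[order][::-1], conc[order][::-1])) if act.min() < 50 < act.max() else float(
        10 ** np.median(logc)
    )

    if free_asymptotes:

        def f(logc, log_ic50, h, bottom, top):
            return bottom + (top - bottom) / (1.0 + 10 ** (h * (logc - log_ic50)))

        p0 = [math.log10(ic50_0), 1.0, 0.0, 100.0]
    else:

        def f(logc, log_ic50, h):
            return 100.0 / (1.0 + 10 ** (h * (logc - log_ic50)))

        p0 = [math.log10(ic50_0), 1.0]

    try:
        popt, _ = optimize.curve_fit(f, logc, act, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"IC50 fit did not converge: {exc}") from exc
    resid = act - f(logc, *popt)
    ic50 = float(10 ** popt[0])
    bottom, top = (float(popt[2]), float(popt[3])) if free_asymptotes else (0.0, 100.0)
    return DoseResponse(
        ic50=ic50,
        hill=float(popt[1]),
        bottom=bottom,
        top=top,
        concentrations=conc,
        responses=act,
        rss=float(resid @ resid),
        in_range=bool(conc.min() <= ic50 <= conc.max()),
    )
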