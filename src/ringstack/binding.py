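"""Fluorescence-polarization binding analysis.

Polarization is P = (I∥ − I⊥)/(I∥ + I⊥), reported in millipolarization
(mP = 1000·P).  Two isotherm models are supported for titrations of a
fixed fluorescent probe with a receptor:

* a four-parameter logistic (Boltzmann) sigmoid in x = log10[titrant],
  with plateaus A1 (zero binding) and A2 (saturation), midpoint x0
  (= log10 of the apparent dissociation constant) and width dx in
  decades; the Hill coefficient is n_H = 1/(dx·ln 10);
* a three-parameter single-site quadratic isotherm that accounts for
  depletion of the fixed species.  Neglecting depletion inflates the
  apparent K_d by half the fixed species' total concentration, which
  ``compare_fits`` reports for context.

Fits are unweighted nonlinear least squares over replicate-level data
(lmfit underneath), with automatic initial guesses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "FPDataset",
    "Logistic4Params",
    "DepletionParams",
    "BindingFit",
    "polarization",
    "eval_logistic4",
    "eval_depletion",
    "fit_model",
    "compare_fits",
]

LN10 = math.log(10.0)


def polarization(i_parallel, i_perp) -> dict:
    """Polarization from parallel/perpendicular emission intensities."""
    ipar = np.asarray(i_parallel, float)
    iperp = np.asarray(i_perp, float)
    if np.any(ipar < 0) or np.any(iperp < 0):
        raise ValueError("intensities must be non-negative")
    total = ipar + iperp
    if np.any(total <= 0):
        raise ValueError("total intensity must be positive")
    P = (ipar - iperp) / total
    return {"P": P if P.ndim else float(P), "mP": 1000.0 * P if P.ndim else 1000.0 * float(P)}


@dataclass(frozen=True)
class Logistic4Params:
    """A1/A2 plateaus (mP), midpoint x0 (log10 M) and width dx (decades)."""

    A1: float
    A2: float
    x0: float
    dx: float

    def __post_init__(self) -> None:
        if self.dx == 0:
            raise ValueError("dx must be nonzero")

    @property
    def kd_app(self) -> float:
        return 10.0 ** self.x0

    @property
    def hill(self) -> float:
        return 1.0 / (abs(self.dx) * LN10)


@dataclass(frozen=True)
class DepletionParams:
    """Single-site quadratic isotherm: baseline A1, saturation A2, K_d (M)
    and total concentration of the fixed (probe) species (M)."""

    A1: float
    A2: float
    Kd: float
    probe_total: float

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")
        if self.probe_total <= 0:
            raise ValueError("probe_total must be positive")


def eval_logistic4(x, params: Logistic4Params):
    """Boltzmann sigmoid in log10-concentration: A1 at low x, A2 at high x,
    (A1+A2)/2 exactly at x = x0."""
    x = np.asarray(x, float)
    val = params.A2 + (params.A1 - params.A2) / (1.0 + np.exp((x - params.x0) / params.dx))
    return val if val.ndim else float(val)


def bound_fraction(titrant_total, Kd: float, probe_total: float):
    """Fraction of the fixed species bound, from the exact 1:1 quadratic."""
    T = np.asarray(titrant_total, float)
    L = probe_total
    s = T + L + Kd
    disc = s * s - 4.0 * T * L
    if np.any(disc < -1e-12 * np.max(s * s)):
        raise ValueError("negative discriminant in quadratic isotherm")
    f = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * L)
    return f if f.ndim else float(f)


def eval_depletion(titrant_total, params: DepletionParams):
    """mP = A1 + (A2 − A1)·f with the exact single-site bound fraction f."""
    f = bound_fraction(titrant_total, params.Kd, params.probe_total)
    val = params.A1 + (params.A2 - params.A1) * np.asarray(f)
    return val if val.ndim else float(val)


@dataclass
class FPDataset:
    """Replicate titration: rows (titrant_conc [M], replicate, mP)."""

    data: pd.DataFrame
    probe_total: float | None = None
    metadata: dict = field(default_factory=dict)

    REQUIRED = ("titrant_conc", "replicate", "mP")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"FPDataset missing column {col!r}")
        if np.any(self.data["titrant_conc"] <= 0):
            raise ValueError("titrant concentrations must be positive")
        if not np.all(np.isfinite(self.data["mP"])):
            raise ValueError("mP values must be finite")

    @classmethod
    def from_rows(cls, rows, probe_total=None, metadata=None) -> "FPDataset":
        df = pd.DataFrame(rows, columns=list(cls.REQUIRED))
        return cls(data=df, probe_total=probe_total, metadata=metadata or {})

    @classmethod
    def from_csv(cls, path, probe_total=None) -> "FPDataset":
        """Read (conc_M, replicate, mP) or (conc_M, I_par, I_perp) CSV."""
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "i_par" in cols and "i_perp" in cols:
            mp = polarization(df[cols["i_par"]], df[cols["i_perp"]])["mP"]
            out = pd.DataFrame(
                {
                    "titrant_conc": df[cols.get("conc_m", "conc_M")],
                    "replicate": df[cols["replicate"]] if "replicate" in cols else 1,
                    "mP": mp,
                }
            )
        else:
            out = df.rename(
                columns={cols.get("conc_m", "conc_M"): "titrant_conc", cols.get("mp", "mP"): "mP"}
            )
            if "replicate" not in out.columns:
                out["replicate"] = 1
        return cls(data=out[list(cls.REQUIRED)], probe_total=probe_total)

    def averaged(self) -> "FPDataset":
        """Replicate-averaged copy (one row per concentration)."""
        g = self.data.groupby("titrant_conc", as_index=False)["mP"].mean()
        g["replicate"] = 1
        return FPDataset(data=g[list(self.REQUIRED)], probe_total=self.probe_total,
                         metadata={**self.metadata, "averaged": True})


@dataclass
class BindingFit:
    model_kind: str
    params: dict
    stderr: dict
    rss: float
    n_points: int
    converged: bool
    kd: float
    hill_report: dict | None = None
    lmfit_result: object = None

    def predict(self, titrant_conc):
        if self.model_kind == "logistic4":
            return eval_logistic4(np.log10(np.asarray(titrant_conc, float)),
                                  Logistic4Params(**self.params))
        return eval_depletion(titrant_conc,
                              DepletionParams(**self.params))


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Plateaus from the extreme quartiles, midpoint from the half-height
    crossing of the concentration-sorted response."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    q = max(1, len(xs) // 4)
    a1 = float(np.mean(ys[:q]))
    a2 = float(np.mean(ys[-q:]))
    half = 0.5 * (a1 + a2)
    sign = 1.0 if a2 >= a1 else -1.0
    crossing = xs[-1]
    for i in range(len(xs) - 1):
        if (ys[i] - half) * sign <= 0 <= (ys[i + 1] - half) * sign:
            # linear interpolation in x
            if ys[i + 1] != ys[i]:
                t = (half - ys[i]) / (ys[i + 1] - ys[i])
            else:
                t = 0.5
            crossing = xs[i] + t * (xs[i + 1] - xs[i])
            break
    return a1, a2, float(crossing)


def fit_model(data: FPDataset, model_kind: str, initial_guess: dict | None = None,
              average_replicates: bool = False) -> BindingFit:
    """Nonlinear least-squares fit of either isotherm to a titration.

    Replicate-level points are fitted by default.  For the logistic model
    the apparent K_d (M) is 10^x0; for the depletion model K_d is a direct
    parameter and ``data.probe_total`` must be set (or supplied via
    ``initial_guess['probe_total']``).
    """
    if model_kind not in ("logistic4", "depletion"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    ds = data.averaged() if average_replicates else data
    conc = ds.data["titrant_conc"].to_numpy(float)
    y = ds.data["mP"].to_numpy(float)
    if len(np.unique(conc)) < 6:
        raise ValueError("need at least 6 distinct concentrations")
    x = np.log10(conc)
    a1, a2, x0 = _initial_guess(x, y)
    if not (x.min() <= x0 <= x.max()) or x0 in (x.min(), x.max()):
        warnings.warn("binding transition may not be bracketed by the data", UserWarning)

    if model_kind == "logistic4":
        model = lmfit.Model(
            lambda x, A1, A2, x0, dx: A2 + (A1 - A2) / (1.0 + np.exp((x - x0) / dx)),
            independent_vars=["x"],
        )
        p = model.make_params(A1=a1, A2=a2, x0=x0, dx=0.4)
        if initial_guess:
            for k, v in initial_guess.items():
                if k in p:
                    p[k].set(value=v)
        result = model.fit(y, p, x=x)
        params = {k: float(result.params[k].value) for k in ("A1", "A2", "x0", "dx")}
        stderr = {k: (float(result.params[k].stderr) if result.params[k].stderr else float("nan"))
                  for k in params}
        dx = params["dx"]
        fit = BindingFit(
            model_kind=model_kind,
            params=params,
            stderr=stderr,
            rss=float(np.sum(result.residual ** 2)),
            n_points=len(y),
            converged=bool(result.success),
            kd=10.0 ** params["x0"],
            hill_report={"dx": dx, "n_H": 1.0 / (abs(dx) * LN10)},
            lmfit_result=result,
        )
    else:
        probe_total = (initial_guess or {}).get("probe_total", ds.probe_total)
        if probe_total is None:
            raise ValueError("depletion fit requires probe_total on the dataset")
        model = lmfit.Model(
            lambda conc, A1, A2, Kd: A1 + (A2 - A1) * bound_fraction(conc, Kd, probe_total),
            independent_vars=["conc"],
        )
        p = model.make_params(A1=a1, A2=a2, Kd=max(10.0 ** x0, 1e-15))
        p["Kd"].set(min=1e-18)
        if initial_guess:
            for k, v in initial_guess.items():
                if k in p:
                    p[k].set(value=v)
        result = model.fit(y, p, conc=conc)
        params = {k: float(result.params[k].value) for k in ("A1", "A2", "Kd")}
        params["probe_total"] = float(probe_total)
        stderr = {k: (float(result.params[k].stderr) if result.params[k].stderr else float("nan"))
                  for k in ("A1", "A2", "Kd")}
        fit = BindingFit(
            model_kind=model_kind,
            params=params,
            stderr=stderr,
            rss=float(np.sum(result.residual ** 2)),
            n_points=len(y),
            converged=bool(result.success),
            kd=params["Kd"],
            lmfit_result=result,
        )
    return fit


def compare_fits(fit_logistic: BindingFit, fit_depletion: BindingFit) -> dict:
    """Side-by-side comparison of the two isotherm fits on one dataset.

    Reports both K_d estimates, their percent difference, residual sums,
    the Hill coefficient of the logistic fit, and — for context — the
    depletion offset probe_total/2 that the quadratic model predicts the
    logistic apparent K_d to carry.
    """
    if fit_logistic.model_kind == fit_depletion.model_kind:
        raise ValueError("compare_fits needs one fit from each model")
    if fit_logistic.model_kind != "logistic4":
        fit_logistic, fit_depletion = fit_depletion, fit_logistic
    kd_log = fit_logistic.kd
    kd_dep = fit_depletion.kd
    probe_total = fit_depletion.params.get("probe_total")
    return {
        "kd_logistic_M": kd_log,
        "kd_depletion_M": kd_dep,
        "percent_difference": 100.0 * (kd_log - kd_dep) / kd_log,
        "rss_logistic": fit_logistic.rss,
        "rss_depletion": fit_depletion.rss,
        "hill_report": fit_logistic.hill_report,
        "predicted_depletion_offset_M": (probe_total / 2.0) if probe_total else None,
    }
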