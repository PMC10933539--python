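"""Allometric models: published giant-sequoia/conifer forms and UK refits.

Five published models map stem diameter (DBH, DTB, fDBH), height and crown
volume to stem volume or aboveground biomass (AGB).  Four UK-specific
two-parameter power-law forms — a(DBH²H)^b, a(DTB²H)^b, aDBH^b, aH^b —
are fitted to TLS-derived AGB by nonlinear least squares in arithmetic
space (no log transform, so no back-transform bias correction), and their
uncertainty is characterised by a parametric bootstrap.

Coefficients are stored exactly as published.  The UK forms take diameters
and heights in metres and return AGB in Mg; volume-returning published
models are converted to AGB with a declared wood density (0.34 Mg m⁻³ by
default).  The native calibration units of the US-published models are not
re-derived here — coefficients are applied to metric inputs as declared in
the registry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError
from .metrics import StructuralMetrics

WOOD_DENSITY_DEFAULT = 0.34


@dataclass(frozen=True)
class AllometricModel:
    """One allometric form with published coefficients and declared units."""

    model_id: str
    form: str                      # human-readable formula
    coefficients: dict             # a, b and optionally c, d, as published
    inputs: tuple                  # subset of {"dbh","dtb","fdbh","h","crown_volume"}
    output: str                    # "volume_m3" or "agb_mg"
    density_for_conversion: float = WOOD_DENSITY_DEFAULT
    source: str = ""

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "form": self.form,
            "coefficients": self.coefficients,
            "inputs": list(self.inputs),
            "output": self.output,
            "density_for_conversion": self.density_for_conversion,
            "source": self.source,
        }


def _eval_parks(c: dict, v: dict) -> float:
    return 10.0 ** (c["a"] * math.log10(v["dbh"] ** 2 * v["h"]) - c["b"])


def _eval_two_term(x1: str, x2: str) -> Callable[[dict, dict], float]:
    def f(c: dict, v: dict) -> float:
        return c["a"] * v[x1] ** c["b"] + c["c"] * v[x2] ** c["d"]
    return f


def _eval_jenkins(c: dict, v: dict) -> float:
    return math.exp(c["a"] + c["b"] * math.log(v["dbh"]))


def _eval_power(x: str) -> Callable[[dict, dict], float]:
    def f(c: dict, v: dict) -> float:
        return c["a"] * v[x] ** c["b"]
    return f


def _eval_power_d2h(d: str) -> Callable[[dict, dict], float]:
    def f(c: dict, v: dict) -> float:
        return c["a"] * (v[d] ** 2 * v["h"]) ** c["b"]
    return f


_FORM_EVALUATORS: dict[str, Callable[[dict, dict], float]] = {
    "parks": _eval_parks,
    "chojnacky": _eval_two_term("dtb", "fdbh"),
    "jenkins": _eval_jenkins,
    "sillett2019": _eval_two_term("dtb", "crown_volume"),
    "sillett2015": _eval_two_term("dtb", "crown_volume"),
    "uk_dbh_h": _eval_power_d2h("dbh"),
    "uk_dtb_h": _eval_power_d2h("dtb"),
    "uk_dbh": _eval_power("dbh"),
    "uk_h": _eval_power("h"),
}

#: the built-in registry, coefficients exactly as published
MODEL_REGISTRY: dict[str, AllometricModel] = {
    m.model_id: m
    for m in [
        AllometricModel(
            "parks", "log10(V) = a*log10(DBH^2*H) - b",
            {"a": 0.9246, "b": 0.4147}, ("dbh", "h"), "volume_m3",
            source="Parks giant-sequoia volume model",
        ),
        AllometricModel(
            "chojnacky", "AGB = a*DTB^b + c*fDBH^d",
            {"a": 3.9656e-4, "b": 2.3122, "c": 1.9583e-3, "d": 1.8657},
            ("dtb", "fdbh"), "agb_mg",
            source="Chojnacky generalized conifer model",
        ),
        AllometricModel(
            "jenkins", "ln(AGB) = a + b*ln(DBH)",
            {"a": -2.0336, "b": 2.2592}, ("dbh",), "agb_mg",
            source="Jenkins generalized conifer model",
        ),
        AllometricModel(
            "sillett2019", "V = a*DTB^b + c*CV^d",
            {"a": 1.1588e-3, "b": 2.1562, "c": 1.0898e-4, "d": 1.4963},
            ("dtb", "crown_volume"), "volume_m3",
            source="Sillett crown-mapped giant-sequoia model (later calibration)",
        ),
        AllometricModel(
            "sillett2015", "V = a*DTB^b + c*CV^d",
            {"a": 1.95e-3, "b": 2.1, "c": 1.78e-4, "d": 1.43},
            ("dtb", "crown_volume"), "volume_m3",
            source="Sillett crown-mapped giant-sequoia model (earlier calibration)",
        ),
        AllometricModel(
            "uk_dbh_h", "AGB = a*(DBH^2*H)^b",
            {"a": 0.374, "b": 0.697}, ("dbh", "h"), "agb_mg",
            source="UK giant-sequoia refit, DBH and H",
        ),
        AllometricModel(
            "uk_dtb_h", "AGB = a*(DTB^2*H)^b",
            {"a": 0.423, "b": 0.750}, ("dtb", "h"), "agb_mg",
            source="UK giant-sequoia refit, DTB and H",
        ),
        AllometricModel(
            "uk_dbh", "AGB = a*DBH^b",
            {"a": 3.542, "b": 1.956}, ("dbh",), "agb_mg",
            source="UK giant-sequoia refit, DBH only",
        ),
        AllometricModel(
            "uk_h", "AGB = a*H^b",
            {"a": 0.021, "b": 1.663}, ("h",), "agb_mg",
            source="UK giant-sequoia refit, H only",
        ),
    ]
}


def save_registry(path, models: Optional[dict] = None) -> None:
    """Write the model registry as versioned JSON."""
    models = models or MODEL_REGISTRY
    payload = {"version": 1, "models": [m.to_dict() for m in models.values()]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_registry(path) -> dict[str, AllometricModel]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    out = {}
    for m in payload["models"]:
        out[m["model_id"]] = AllometricModel(
            m["model_id"], m["form"], m["coefficients"], tuple(m["inputs"]),
            m["output"], m.get("density_for_conversion", WOOD_DENSITY_DEFAULT),
            m.get("source", ""),
        )
    return out


def _metric_values(metrics: StructuralMetrics | dict) -> dict:
    if isinstance(metrics, dict):
        return metrics
    return {
        "dbh": metrics.dbh,
        "dtb": metrics.dtb,
        "fdbh": metrics.fdbh,
        "h": metrics.height,
        "crown_volume": metrics.crown_volume,
    }


def predict(model: AllometricModel, metrics: StructuralMetrics | dict) -> float:
    """Evaluate a model on one tree's metrics, in the model's native output."""
    values = _metric_values(metrics)
    for name in model.inputs:
        v = values.get(name)
        if v is None:
            raise ValueError(f"model {model.model_id!r} requires metric {name!r}")
        if v <= 0:
            raise ValueError(
                f"model {model.model_id!r}: metric {name!r} must be positive, got {v}"
            )
    return float(_FORM_EVALUATORS[model.model_id](model.coefficients, values))


def predict_agb(model: AllometricModel, metrics: StructuralMetrics | dict) -> float:
    """Evaluate a model and convert volume outputs to AGB (Mg) if needed."""
    y = predict(model, metrics)
    if model.output == "volume_m3":
        return y * model.density_for_conversion
    return y


# ---------------------------------------------------------------------------
# UK model fitting
# ---------------------------------------------------------------------------

UK_FORMS = {
    "dbh_h": ("uk_dbh_h", lambda m: m["dbh"] ** 2 * m["h"]),
    "dtb_h": ("uk_dtb_h", lambda m: m["dtb"] ** 2 * m["h"]),
    "dbh_only": ("uk_dbh", lambda m: m["dbh"]),
    "h_only": ("uk_h", lambda m: m["h"]),
}


@dataclass
class FitResult:
    """A fitted two-parameter power law y = a * x^b and its diagnostics."""

    form: str
    a: float
    b: float
    r2: float
    rmse: float
    bias_pct: float
    residual_sd: float
    n: int
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(x, dtype=float) ** self.b


def fit_power_law(x: Sequence[float], y: Sequence[float], form: str = "power",
                  max_iter: int = 200) -> FitResult:
    """Fit y = a·x^b by nonlinear least squares in arithmetic space.

    Initialised at a = mean(y)/mean(x), b = 1; converged when the relative
    cost change falls below 1e-12 (or after ``max_iter`` iterations).
    Fitting in arithmetic space avoids the log-transform bias correction a
    log-log regression would need.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 5:
        raise FitError(f"power-law fit needs >= 5 trees, got {len(x)}")
    if np.any(x <= 0):
        raise FitError("predictors must be positive for a power-law fit")
    if np.ptp(x) == 0:
        raise FitError("degenerate predictor: zero variance in x")

    def residuals(p: np.ndarray) -> np.ndarray:
        return y - p[0] * x ** p[1]

    p0 = np.array([y.mean() / x.mean(), 1.0])
    sol = optimize.least_squares(
        residuals, p0, method="lm", ftol=1e-12, xtol=1e-12, gtol=1e-12,
        max_nfev=max_iter * 3,
    )
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise FitError(
            f"power-law fit did not converge: {sol.message}; final cost {sol.cost:.3e}"
        )
    a, b = float(sol.x[0]), float(sol.x[1])
    pred = a * x**b
    resid = y - pred
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / len(y)))
    bias = float(np.mean((pred - y) / y) * 100.0)
    resid_sd = float(resid.std(ddof=2)) if len(y) > 2 else 0.0
    return FitResult(form, a, b, r2, rmse, bias, resid_sd, len(y), x=x, y=y)


def fit_uk_model(form: str,
                 trees: Sequence[tuple[StructuralMetrics | dict, float]]) -> FitResult:
    """Fit one UK model form to (metrics, observed AGB) pairs.

    ``form`` is one of ``dbh_h``, ``dtb_h``, ``dbh_only``, ``h_only``; the
    two-variable forms regress AGB on the combined predictor D²H.
    """
    if form not in UK_FORMS:
        raise ValueError(f"unknown UK form {form!r}; choose from {sorted(UK_FORMS)}")
    _, xfun = UK_FORMS[form]
    xs, ys = [], []
    for metrics, agb in trees:
        values = _metric_values(metrics)
        try:
            xs.append(float(xfun(values)))
        except (KeyError, TypeError):
            raise ValueError(f"form {form!r}: required metric missing for a tree")
        ys.append(float(agb))
    return fit_power_law(xs, ys, form=form)


# ---------------------------------------------------------------------------
# evaluation and bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelEvaluation:
    """Predicted-vs-observed comparison: OLS line, RMSE, r², slope SE."""

    gradient: float
    intercept: float
    rmse: float
    r2: float
    std_error: float
    n: int


def evaluate_model(predicted: Sequence[float],
                   observed: Sequence[float]) -> ModelEvaluation:
    """Regress predicted AGB on observed (TLS-derived) AGB.

    Gradient/intercept describe the fitted line of the predicted-vs-observed
    scatter (the 1:1 line being perfect agreement); RMSE is the root mean
    squared difference between the two.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if len(p) < 3:
        raise ValueError("evaluation requires >= 3 trees")
    res = stats.linregress(o, p)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    return ModelEvaluation(
        gradient=float(res.slope),
        intercept=float(res.intercept),
        rmse=rmse,
        r2=float(res.rvalue**2),
        std_error=float(res.stderr),
        n=len(p),
    )


@dataclass
class BootstrapEnvelope:
    """Per-abscissa envelope of parametric-bootstrap refit predictions."""

    x_grid: np.ndarray
    lo: np.ndarray       # min over refits
    hi: np.ndarray       # max over refits
    p2_5: np.ndarray
    p97_5: np.ndarray
    n_boot: int
    n_failed: int


def parametric_bootstrap(fit: FitResult, n_boot: int = 100, seed: int = 0,
                         x_grid: Optional[np.ndarray] = None) -> BootstrapEnvelope:
    """Parametric bootstrap of a fitted power law.

    Draws ``n_boot`` synthetic datasets from the fitted curve plus Gaussian
    residuals (sd = the fit's residual sd), refits each, and summarises the
    refit predictions per abscissa as min/max and 2.5/97.5 percentiles.
    Seeded and reproducible; refit failures are counted, not hidden.
    """
    if fit.x is None or fit.y is None:
        raise ValueError("fit must retain its training data for bootstrapping")
    rng = np.random.default_rng(seed)
    if x_grid is None:
        x_grid = np.linspace(fit.x.min(), fit.x.max(), 50)
    x_grid = np.asarray(x_grid, dtype=float)
    preds = []
    n_failed = 0
    base = fit.predict(fit.x)
    for _ in range(n_boot):
        y_sim = base + rng.normal(0.0, fit.residual_sd, size=len(fit.x))
        try:
            refit = fit_power_law(fit.x, y_sim, form=fit.form)
        except FitError:
            n_failed += 1
            continue
        preds.append(refit.predict(x_grid))
    if not preds:
        raise FitError(f"all {n_boot} bootstrap refits failed")
    P = np.vstack(preds)
    return BootstrapEnvelope(
        x_grid=x_grid,
        lo=P.min(axis=0),
        hi=P.max(axis=0),
        p2_5=np.percentile(P, 2.5, axis=0),
        p97_5=np.percentile(P, 97.5, axis=0),
        n_boot=n_boot,
        n_failed=n_failed,
    )
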