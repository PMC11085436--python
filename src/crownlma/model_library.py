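"""The catalogue of 13 parametric LMA model forms, evaluable and fittable.

Models 1-7 are univariate: linear, exponential, quadratic and power shapes
in RDINC (1-4), a quadratic in development time D = DOY - 120 (5), and
linear / power shapes in LDMC (6-7).  Models 8-13 are bivariate
reparameterizations in which a parent model's coefficients become linear or
polynomial functions of a second covariate (the parameter-prediction
method), e.g. Model 13:

    LMA = (m0*RDINC + m1) + (m2*RDINC + m3)*D + m4*D^2

Forms that are linear in their parameters (1, 3, 5, 6, 8, 9, 11, 13) are
fitted exactly by ordinary least squares on the basis expansion; the
genuinely nonlinear forms (2, 4, 7, 10, 12) are fitted by
Levenberg-Marquardt iteration from deterministic log-linearisation starts.

The published coefficient sets ship as a versioned JSON fixture and are
available through :func:`published_fixture`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .data_model import Dataset
from .metrics import FitReport, fit_report

__all__ = [
    "ModelForm",
    "FittedModel",
    "MODEL_FORMS",
    "PARENT_MODEL",
    "get_form",
    "evaluate",
    "fit",
    "published_fixture",
]

#: Reparameterized model -> univariate parent whose basis it nests.
PARENT_MODEL = {8: 6, 9: 6, 10: 7, 11: 6, 12: 7, 13: 1}


@dataclass(frozen=True)
class ModelForm:
    """One parametric LMA equation: structure, predictors, fitting strategy."""

    model_id: Union[int, str]
    structure: str
    predictors: tuple  # subset of ("rdinc", "d", "ldmc")
    parameter_names: tuple
    linear_in_parameters: bool
    func: Callable = field(repr=False)  # func(params, data) -> lma
    basis: Optional[Callable] = field(default=None, repr=False)  # linear forms
    start: Optional[Callable] = field(default=None, repr=False)  # nonlinear forms

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)


@dataclass
class FittedModel:
    """A model form bound to a coefficient vector (fitted or published)."""

    form: ModelForm
    coefficients: np.ndarray
    fit_report: Optional[FitReport] = None
    source: str = "fitted"

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != self.form.n_parameters:
            raise ValueError(
                f"model {self.form.model_id}: expected "
                f"{self.form.n_parameters} coefficients, got {self.coefficients.size}"
            )

    @property
    def coefficients_printed(self) -> np.ndarray:
        """Coefficients in the printed table layout.

        Canonical order is (quadratic, linear, constant) for the D-quadratic
        Model 5; the printed equation lists the intercept first.
        """
        if self.form.model_id == 5:
            return self.coefficients[::-1]
        return self.coefficients

    def predict(self, rdinc=None, doy=None, ldmc=None):
        return evaluate(self, rdinc=rdinc, doy=doy, ldmc=ldmc)

    def to_dict(self) -> dict:
        return {
            "model_id": self.form.model_id,
            "structure": self.form.structure,
            "parameter_names": list(self.form.parameter_names),
            "coefficients": [float(c) for c in self.coefficients],
            "source": self.source,
            "fit_report": self.fit_report.to_dict() if self.fit_report else None,
        }


# --- form definitions -------------------------------------------------------

def _col(*arrs):
    return np.column_stack(arrs)


def _ones(d):
    return np.ones_like(d["lead"])


_FORMS = {}


def _register(form: ModelForm):
    _FORMS[form.model_id] = form
    return form


def _loglin_start(ydata, xcols):
    """OLS of log(y) on columns -> exponentiated leading coefficient start."""
    X = np.column_stack([np.ones_like(ydata)] + list(xcols))
    beta, *_ = np.linalg.lstsq(X, np.log(ydata), rcond=None)
    return beta


_register(ModelForm(
    1, "linear in RDINC", ("rdinc",), ("a0", "a1"), True,
    func=lambda c, d: c[0] * d["rdinc"] + c[1],
    basis=lambda d: _col(d["rdinc"], np.ones_like(d["rdinc"])),
))

_register(ModelForm(
    2, "exponential in RDINC", ("rdinc",), ("b0", "b1"), False,
    func=lambda c, d: c[0] * np.exp(c[1] * d["rdinc"]),
    start=lambda d, y: (lambda b: [np.exp(b[0]), b[1]])(_loglin_start(y, [d["rdinc"]])),
))

_register(ModelForm(
    3, "quadratic in RDINC", ("rdinc",), ("c0", "c1", "c2"), True,
    func=lambda c, d: c[0] * d["rdinc"] ** 2 + c[1] * d["rdinc"] + c[2],
    basis=lambda d: _col(d["rdinc"] ** 2, d["rdinc"], np.ones_like(d["rdinc"])),
))

_register(ModelForm(
    4, "power in RDINC", ("rdinc",), ("d0", "d1"), False,
    func=lambda c, d: c[0] * d["rdinc"] ** c[1],
    start=lambda d, y: (lambda b: [np.exp(b[0]), b[1]])(
        _loglin_start(y, [np.log(d["rdinc"])])),
))

_register(ModelForm(
    5, "quadratic in development time D = DOY - 120", ("d",),
    ("e0", "e1", "e2"), True,
    func=lambda c, d: c[0] * d["d"] ** 2 + c[1] * d["d"] + c[2],
    basis=lambda d: _col(d["d"] ** 2, d["d"], np.ones_like(d["d"])),
))

_register(ModelForm(
    6, "linear in LDMC", ("ldmc",), ("f0", "f1"), True,
    func=lambda c, d: c[0] * d["ldmc"] + c[1],
    basis=lambda d: _col(d["ldmc"], np.ones_like(d["ldmc"])),
))

_register(ModelForm(
    7, "power in LDMC", ("ldmc",), ("g0", "g1"), False,
    func=lambda c, d: c[0] * d["ldmc"] ** c[1],
    start=lambda d, y: (lambda b: [np.exp(b[0]), b[1]])(
        _loglin_start(y, [np.log(d["ldmc"])])),
))

# The exponential LDMC shape originally declared for model 7; kept available
# alongside the power law actually fitted in the published table.
_register(ModelForm(
    "7exp", "exponential in LDMC", ("ldmc",), ("g0", "g1"), False,
    func=lambda c, d: c[0] * np.exp(c[1] * d["ldmc"]),
    start=lambda d, y: (lambda b: [np.exp(b[0]), b[1]])(_loglin_start(y, [d["ldmc"]])),
))

_register(ModelForm(
    8, "LDMC slope and offset linear in D", ("d", "ldmc"),
    ("h0", "h1", "h2", "h3"), True,
    func=lambda c, d: (c[0] * d["d"] + c[1]) * d["ldmc"] + c[2] * d["d"] + c[3],
    basis=lambda d: _col(d["d"] * d["ldmc"], d["ldmc"], d["d"],
                         np.ones_like(d["d"])),
))

_register(ModelForm(
    9, "LDMC slope linear in RDINC", ("rdinc", "ldmc"), ("i0", "i1", "i2"), True,
    func=lambda c, d: (c[0] * d["rdinc"] + c[1]) * d["ldmc"] + c[2],
    basis=lambda d: _col(d["rdinc"] * d["ldmc"], d["ldmc"],
                         np.ones_like(d["ldmc"])),
))


def _start_10(d, y):
    b = _loglin_start(y, [np.log(d["ldmc"])])
    j2 = b[1]
    X = _col(d["rdinc"] * d["ldmc"] ** j2, d["ldmc"] ** j2)
    j01, *_ = np.linalg.lstsq(X, y, rcond=None)
    return [j01[0], j01[1], j2]


_register(ModelForm(
    10, "power-LDMC scale linear in RDINC", ("rdinc", "ldmc"),
    ("j0", "j1", "j2"), False,
    func=lambda c, d: (c[0] * d["rdinc"] + c[1]) * d["ldmc"] ** c[2],
    start=_start_10,
))

_register(ModelForm(
    11, "LDMC slope cubic in D", ("d", "ldmc"),
    ("k0", "k1", "k2", "k3", "k4"), True,
    func=lambda c, d: (c[0] * d["d"] ** 3 + c[1] * d["d"] ** 2
                       + c[2] * d["d"] + c[3]) * d["ldmc"] + c[4],
    basis=lambda d: _col(d["d"] ** 3 * d["ldmc"], d["d"] ** 2 * d["ldmc"],
                         d["d"] * d["ldmc"], d["ldmc"],
                         np.ones_like(d["d"])),
))


def _start_12(d, y):
    b = _loglin_start(y, [np.log(d["ldmc"])])
    l3 = b[1]
    L = d["ldmc"] ** l3
    X = _col(d["d"] ** 2 * L, d["d"] * L, L)
    l012, *_ = np.linalg.lstsq(X, y, rcond=None)
    return [l012[0], l012[1], l012[2], l3]


_register(ModelForm(
    12, "power-LDMC scale quadratic in D", ("d", "ldmc"),
    ("l0", "l1", "l2", "l3"), False,
    func=lambda c, d: (c[0] * d["d"] ** 2 + c[1] * d["d"] + c[2])
                      * d["ldmc"] ** c[3],
    start=_start_12,
))

_register(ModelForm(
    13, "RDINC-linear level, RDINC-linear D slope, D quadratic",
    ("rdinc", "d"), ("m0", "m1", "m2", "m3", "m4"), True,
    func=lambda c, d: (c[0] * d["rdinc"] + c[1])
                      + (c[2] * d["rdinc"] + c[3]) * d["d"]
                      + c[4] * d["d"] ** 2,
    basis=lambda d: _col(d["rdinc"], np.ones_like(d["rdinc"]),
                         d["rdinc"] * d["d"], d["d"], d["d"] ** 2),
))

MODEL_FORMS: Mapping = dict(_FORMS)

_POWER_IN_RDINC = {4}


def get_form(model_id) -> ModelForm:
    """Look up a model form by catalogue id (1-13 or "7exp")."""
    try:
        return _FORMS[model_id]
    except KeyError:
        raise ValueError(f"unknown model id {model_id!r}") from None


# --- evaluation -------------------------------------------------------------

def _predictor_data(form: ModelForm, rdinc, doy, ldmc, validate: bool = True) -> dict:
    supplied = {"rdinc": rdinc, "doy": doy, "ldmc": ldmc}
    data = {}
    for pred in form.predictors:
        src = "doy" if pred == "d" else pred
        if supplied[src] is None:
            raise ValueError(
                f"model {form.model_id} requires predictor {src!r}"
            )
        arr = np.asarray(supplied[src], dtype=float)
        if validate:
            if src == "rdinc":
                if np.any((arr < 0) | (arr > 1)):
                    raise ValueError("rdinc out of [0, 1]")
                if form.model_id in _POWER_IN_RDINC and np.any(arr == 0):
                    raise ValueError(
                        f"model {form.model_id} is singular at rdinc = 0"
                    )
            elif src == "doy":
                if np.any(arr < 120):
                    raise ValueError("doy must be >= 120 (budburst) for dynamic forms")
            elif src == "ldmc":
                if np.any((arr <= 0) | (arr >= 1)):
                    raise ValueError("ldmc out of (0, 1)")
        data[pred] = arr - 120.0 if pred == "d" else arr
    data["lead"] = data[form.predictors[0]]
    return data


def evaluate(model: FittedModel, rdinc=None, doy=None, ldmc=None):
    """Evaluate a fitted model at the given predictors (vectorised).

    Returns a scalar for scalar inputs, an ndarray otherwise.
    """
    data = _predictor_data(model.form, rdinc, doy, ldmc)
    out = model.form.func(model.coefficients, data)
    if np.ndim(out) == 0 or (hasattr(out, "size") and out.size == 1
                             and all(np.ndim(v) == 0 for v in (rdinc, doy, ldmc)
                                     if v is not None)):
        return float(np.asarray(out).reshape(-1)[0])
    return np.asarray(out)


# --- fitting ----------------------------------------------------------------

def _arrays_from(dataset) -> dict:
    if isinstance(dataset, Dataset):
        df = dataset.df
        return {
            "lma": df["lma_g_m2"].to_numpy(float),
            "rdinc": df["rdinc"].to_numpy(float),
            "doy": df["doy"].to_numpy(float),
            "ldmc": df["ldmc_g_g"].to_numpy(float),
        }
    return {k: np.asarray(v, dtype=float) for k, v in dict(dataset).items()}


def fit(form: Union[ModelForm, int, str], dataset, max_iter: int = 200,
        method: str = "auto") -> FittedModel:
    """Least-squares fit of a model form to a dataset.

    Linear-in-parameter forms are solved exactly on the basis expansion;
    nonlinear forms use Levenberg-Marquardt from log-linearisation starts.
    ``method="iterative"`` forces the Levenberg-Marquardt path even for
    linear forms (cross-check of the two solution paths).

    ``dataset`` may be a :class:`~crownlma.data_model.Dataset` or a mapping
    with keys ``lma`` and the required predictors (``rdinc``/``doy``/``ldmc``).
    """
    if not isinstance(form, ModelForm):
        form = get_form(form)
    arrs = _arrays_from(dataset)
    y = arrs["lma"]
    n, p = y.size, form.n_parameters
    if n <= p:
        raise ValueError(f"model {form.model_id}: need more than {p} records, got {n}")
    data = _predictor_data(
        form,
        arrs.get("rdinc"),
        arrs.get("doy"),
        arrs.get("ldmc"),
        validate=False,
    )

    if form.linear_in_parameters:
        X = form.basis(data)
        if np.linalg.matrix_rank(X) < p:
            raise ValueError(
                f"model {form.model_id}: singular design matrix "
                "(constant or collinear predictor)"
            )
    if form.linear_in_parameters and method != "iterative":
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        if form.linear_in_parameters:
            x0 = np.zeros(p)
        else:
            x0 = np.asarray(form.start(data, y), dtype=float)

        def resid(c):
            return form.func(c, data) - y

        sol = least_squares(resid, x0, method="lm", max_nfev=max_iter * (p + 1),
                            ftol=1e-14, xtol=1e-14, gtol=1e-14)
        if not sol.success:
            raise RuntimeError(
                f"model {form.model_id}: nonlinear fit did not converge; "
                f"last iterate {sol.x}, residual norm {np.linalg.norm(sol.fun):.6g}"
            )
        coef = sol.x

    yhat = form.func(coef, data)
    return FittedModel(form, coef, fit_report=fit_report(y, yhat, p), source="fitted")


# --- published fixtures -----------------------------------------------------

def _load_fixture_file() -> dict:
    text = resources.files("crownlma.fixtures").joinpath(
        "published_models.json").read_text()
    return json.loads(text)


_FIXTURE_CACHE: Optional[dict] = None


def published_fixture(model_id: int) -> FittedModel:
    """The published coefficient set for catalogue model 1-13.

    Coefficients carry the printed (rounded) digits; the fit report is
    populated from the printed R2a / RMSE / AIC (and, for the bivariate
    models, the printed validation ME / MAE / FI).
    """
    global _FIXTURE_CACHE
    if _FIXTURE_CACHE is None:
        raw = _load_fixture_file()
        _FIXTURE_CACHE = {m["model_id"]: m for m in raw["models"]}
    if model_id not in _FIXTURE_CACHE:
        raise ValueError(f"no published fixture for model id {model_id!r}")
    entry = _FIXTURE_CACHE[model_id]
    report = FitReport(
        r2_adjusted=entry.get("ra2"),
        rmse=entry.get("rmse"),
        aic=entry.get("aic"),
        me=entry.get("me"),
        mae=entry.get("mae"),
        fi=entry.get("fi"),
    )
    return FittedModel(
        get_form(model_id),
        np.asarray(entry["coefficients"], dtype=float),
        fit_report=report,
        source="published",
    )
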