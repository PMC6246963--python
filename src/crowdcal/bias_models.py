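"""Regression analyses of estimation bias.

Four registered linear mixed-effects models, each with crossed random
intercepts for participant and food:

* ``reference_object``        |e|  ~ has_reference_object
* ``density_bias``            e    ~ centred log energy density
* ``bmi_density_interaction`` eta  ~ (BMI - 25) x centred log energy density
* ``demographics``            |e|  ~ gender + age-bin midpoint

plus the Pearson correlation between food energy density and mass, and the
per-food density-bias curve.

The crossed design (every response belongs to one participant *and* one food)
is fitted by exact profiled REML: with variance ratios ``g_u = s_u^2/s^2``,
``g_v = s_v^2/s^2`` the marginal covariance is ``s^2 W`` with
``W = I + g_u Zu Zu' + g_v Zv Zv'``, and all quantities needed for the REML
criterion reduce, via the Woodbury identity, to factorisations of the
(p + f)-dimensional capacitance matrix — cheap even for thousands of
participants.  The two variance ratios are optimised numerically; fixed-effect
p-values use the large-sample normal approximation.  ``r_squared`` is the
squared Pearson correlation between the outcome and the model's conditional
predictions (fixed effects plus predicted random intercepts): the proportion
of outcome variance described by the model's predicted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .quiz_model import Gender, Participant, QuizSpec

__all__ = [
    "BiasFitResult",
    "REGISTERED_MODELS",
    "density_mass_correlation",
    "fit_bias_model",
    "fit_crossed_lmm",
    "density_bias_curve",
]


@dataclass
class BiasFitResult:
    """One fitted bias model: coefficients, uncertainty, fit diagnostics."""

    model_name: str
    outcome: str
    coefficients: dict[str, dict[str, float]]  # term -> estimate/std_error/p_value
    r_squared: float
    n_obs: int
    converged: bool
    sigma2: float = float("nan")
    var_participant: float = float("nan")
    var_food: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "outcome": self.outcome,
            "coefficients": self.coefficients,
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "sigma2": self.sigma2,
            "var_participant": self.var_participant,
            "var_food": self.var_food,
        }


def density_mass_correlation(quiz: QuizSpec) -> float:
    """Pearson correlation between energy density (kcal/g) and mass (g).

    Returns NaN (missing) when either variable has zero variance.  On the
    packaged 20-food quiz this is -0.70: heavier quiz items are systematically
    less energy-dense.  With exactly two foods the correlation is trivially
    +/-1.
    """
    if len(quiz) < 2:
        raise ValueError("need at least 2 foods for a correlation")
    density = np.array([f.energy_kcal / f.mass_g for f in quiz.foods])
    mass = np.array([f.mass_g for f in quiz.foods])
    if np.ptp(density) == 0 or np.ptp(mass) == 0:
        return float("nan")
    return float(stats.pearsonr(density, mass).statistic)


# ---------------------------------------------------------------------------
# Crossed random-intercepts REML
# ---------------------------------------------------------------------------


@dataclass
class _LmmFit:
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    sigma2: float
    var_u: float
    var_v: float
    fitted: np.ndarray
    converged: bool


class _CrossedREML:
    """Profiled REML for y = X b + Zu u + Zv v + e with crossed intercepts."""

    def __init__(self, y: np.ndarray, X: np.ndarray, pc: np.ndarray, fc: np.ndarray):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.pc = np.asarray(pc)
        self.fc = np.asarray(fc)
        self.n, self.k = self.X.shape
        self.p = int(self.pc.max()) + 1
        self.f = int(self.fc.max()) + 1
        # sufficient statistics, computed once
        self.a = np.bincount(self.pc, minlength=self.p).astype(float)  # Zu'Zu diag
        self.m = np.bincount(self.fc, minlength=self.f).astype(float)  # Zv'Zv diag
        self.N = np.zeros((self.p, self.f))  # Zu'Zv incidence
        np.add.at(self.N, (self.pc, self.fc), 1.0)
        self.ZuX = np.zeros((self.p, self.k))
        np.add.at(self.ZuX, self.pc, self.X)
        self.ZvX = np.zeros((self.f, self.k))
        np.add.at(self.ZvX, self.fc, self.X)
        self.Zuy = np.bincount(self.pc, weights=self.y, minlength=self.p)
        self.Zvy = np.bincount(self.fc, weights=self.y, minlength=self.f)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def _solve_parts(self, gu: float, gv: float):
        """Factor the capacitance matrix and return GLS building blocks."""
        su, sv = np.sqrt(gu), np.sqrt(gv)
        q = self.p + self.f
        C = np.empty((q, q))
        C[: self.p, : self.p] = gu * np.diag(self.a)
        C[self.p :, self.p :] = gv * np.diag(self.m)
        C[: self.p, self.p :] = su * sv * self.N
        C[self.p :, : self.p] = (su * sv * self.N).T
        C[np.diag_indices(q)] += 1.0
        cf = linalg.cho_factor(C, lower=True, check_finite=False)
        logdetW = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))

        AtX = np.vstack([su * self.ZuX, sv * self.ZvX])  # A'X, A = U D^{1/2}
        Aty = np.concatenate([su * self.Zuy, sv * self.Zvy])
        CiAtX = linalg.cho_solve(cf, AtX, check_finite=False)
        CiAty = linalg.cho_solve(cf, Aty, check_finite=False)
        XtWiX = self.XtX - AtX.T @ CiAtX
        XtWiy = self.Xty - AtX.T @ CiAty
        ytWiy = self.yty - Aty @ CiAty
        return cf, logdetW, XtWiX, XtWiy, ytWiy

    def _criterion(self, log_g: np.ndarray) -> float:
        gu, gv = np.exp(log_g)
        try:
            _, logdetW, XtWiX, XtWiy, ytWiy = self._solve_parts(gu, gv)
            beta = linalg.solve(XtWiX, XtWiy, assume_a="pos")
        except (linalg.LinAlgError, ValueError):
            return 1e300
        rss = ytWiy - beta @ XtWiy
        if rss <= 0:
            return 1e300
        dof = self.n - self.k
        sign, logdet_xx = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return 1e300
        return dof * np.log(rss / dof) + logdetW + logdet_xx

    def fit(self) -> _LmmFit:
        if np.linalg.matrix_rank(self.XtX) < self.k:
            # Unidentifiable design (e.g. a covariate constant in the data):
            # report minimum-norm estimates with no uncertainty, flagged.
            beta = np.linalg.lstsq(self.X, self.y, rcond=None)[0]
            resid = self.y - self.X @ beta
            nan = np.full(self.k, np.nan)
            return _LmmFit(
                beta=beta, se=nan, pvalues=nan,
                sigma2=float(resid @ resid / max(self.n - self.k, 1)),
                var_u=float("nan"), var_v=float("nan"),
                fitted=self.X @ beta, converged=False,
            )
        # Second start from a larger ratio guards against the flat boundary
        # region when a variance component is near zero.
        starts = [(-2.3, -2.3), (0.0, 0.0)]
        best = None
        for s in starts:
            res = optimize.minimize(
                self._criterion,
                np.array(s),
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 250},
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.fun < 1e299 and s == starts[0]:
                break
        gu, gv = np.exp(best.x)
        # Snap tiny ratios to exactly zero when that does not hurt the fit.
        for trial in ((0.0, gv), (gu, 0.0), (0.0, 0.0)):
            with np.errstate(divide="ignore"):
                crit = self._criterion(np.log(np.maximum(trial, 1e-300)))
            if crit <= best.fun + 1e-6:
                gu, gv = trial
                break

        cf, _, XtWiX, XtWiy, ytWiy = self._solve_parts(gu, gv)
        beta = linalg.solve(XtWiX, XtWiy, assume_a="pos")
        # rss can round to a tiny negative under an exact fit
        rss = max(ytWiy - beta @ XtWiy, 0.0)
        sigma2 = rss / (self.n - self.k)
        cov = sigma2 * linalg.inv(XtWiX)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))

        # BLUPs: E[u|y] = g_u Zu' W^-1 r (and likewise for v).
        r = self.y - self.X @ beta
        su, sv = np.sqrt(gu), np.sqrt(gv)
        Atr = np.concatenate(
            [
                su * np.bincount(self.pc, weights=r, minlength=self.p),
                sv * np.bincount(self.fc, weights=r, minlength=self.f),
            ]
        )
        CiAtr = linalg.cho_solve(cf, Atr, check_finite=False)
        Wir = r - (su * CiAtr[: self.p][self.pc] + sv * CiAtr[self.p :][self.fc])
        u = gu * np.bincount(self.pc, weights=Wir, minlength=self.p)
        v = gv * np.bincount(self.fc, weights=Wir, minlength=self.f)
        fitted = self.X @ beta + u[self.pc] + v[self.fc]
        return _LmmFit(
            beta=beta,
            se=se,
            pvalues=pvals,
            sigma2=float(sigma2),
            var_u=float(gu * sigma2),
            var_v=float(gv * sigma2),
            fitted=fitted,
            converged=bool(best.success),
        )


def fit_crossed_lmm(
    y: np.ndarray,
    X: np.ndarray,
    participant_codes: np.ndarray,
    food_codes: np.ndarray,
) -> _LmmFit:
    """REML fit of a linear model with crossed participant/food intercepts.

    ``participant_codes`` and ``food_codes`` are dense integer codes (0-based)
    of the two grouping factors, one per row of ``X``.
    """
    return _CrossedREML(y, X, participant_codes, food_codes).fit()


# ---------------------------------------------------------------------------
# Registered bias models
# ---------------------------------------------------------------------------

REGISTERED_MODELS = (
    "reference_object",
    "density_bias",
    "bmi_density_interaction",
    "demographics",
)


def _centered_log_density(quiz: QuizSpec, use_log: bool) -> dict[str, float]:
    density = np.array([f.energy_kcal / f.mass_g for f in quiz.foods])
    x = np.log(density) if use_log else density
    x = x - x.mean()
    return dict(zip(quiz.food_ids, x))


def _design(
    metrics: pd.DataFrame,
    participants: Sequence[Participant],
    quiz: QuizSpec,
    model_name: str,
    use_log_density: bool,
) -> tuple[np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    df = metrics.copy()
    pinfo = {p.participant_id: p for p in participants}
    unknown = set(df["participant_id"]) - set(pinfo)
    if unknown:
        raise KeyError(f"metrics reference unknown participant(s): {sorted(unknown)[:5]}")
    cld = _centered_log_density(quiz, use_log_density)
    df["cld"] = df["food_id"].map(cld)

    if model_name == "reference_object":
        ref = {f.food_id: float(f.has_reference_object) for f in quiz.foods}
        df["x_ref"] = df["food_id"].map(ref)
        terms, outcome = ["has_reference_object"], "abs_e"
        cols = ["x_ref"]
    elif model_name == "density_bias":
        terms, outcome = ["centered_log_density"], "e"
        cols = ["cld"]
    elif model_name == "bmi_density_interaction":
        bmi = {p.participant_id: p.bmi_kg_m2 for p in participants}
        df["bmi_c"] = df["participant_id"].map(bmi).astype(float) - 25.0
        df = df.dropna(subset=["bmi_c"])
        df["bmi_x_cld"] = df["bmi_c"] * df["cld"]
        terms, outcome = ["bmi_centered", "centered_log_density", "bmi_x_density"], "eta"
        cols = ["bmi_c", "cld", "bmi_x_cld"]
    elif model_name == "demographics":
        male = {
            p.participant_id: (1.0 if p.gender is Gender.MALE else 0.0)
            if p.gender is not Gender.MISSING
            else np.nan
            for p in participants
        }
        age = {p.participant_id: p.age_midpoint for p in participants}
        df["x_male"] = df["participant_id"].map(male)
        df["x_age"] = df["participant_id"].map(age).astype(float)
        df = df.dropna(subset=["x_male", "x_age"])
        terms, outcome = ["male", "age_midpoint"], "abs_e"
        cols = ["x_male", "x_age"]
    else:
        raise ValueError(
            f"unknown model {model_name!r}; registered models: {REGISTERED_MODELS}"
        )

    y = df[outcome].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), df[cols].to_numpy(float)])
    return y, X, ["intercept", *terms], df


def fit_bias_model(
    metrics: pd.DataFrame,
    participants: Sequence[Participant],
    quiz: QuizSpec,
    model_name: str,
    use_log_density: bool = True,
) -> BiasFitResult:
    """Fit one registered bias model on a metrics table.

    Rows whose participants lack a required covariate (BMI, gender or age for
    the models that use them) are dropped; ``n_obs`` reports what was fitted.
    Non-convergence of the variance-ratio optimisation is reported via
    ``converged=False``, never silently.
    """
    y, X, names, df = _design(metrics, participants, quiz, model_name, use_log_density)
    if df["participant_id"].nunique() < 2 or df["food_id"].nunique() < 2:
        raise ValueError("need at least 2 participants and 2 foods to fit")
    pc = pd.Categorical(df["participant_id"]).codes
    fc = pd.Categorical(df["food_id"]).codes
    fit = fit_crossed_lmm(y, X, pc, fc)

    if np.ptp(y) == 0 or np.ptp(fit.fitted) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(y, fit.fitted)[0, 1] ** 2)
    coeffs = {
        name: {
            "estimate": float(b),
            "std_error": float(s),
            "p_value": float(p),
        }
        for name, b, s, p in zip(names, fit.beta, fit.se, fit.pvalues)
    }
    outcome = {"reference_object": "abs_e", "density_bias": "e",
               "bmi_density_interaction": "eta", "demographics": "abs_e"}[model_name]
    return BiasFitResult(
        model_name=model_name,
        outcome=outcome,
        coefficients=coeffs,
        r_squared=r2,
        n_obs=len(y),
        converged=fit.converged,
        sigma2=fit.sigma2,
        var_participant=fit.var_u,
        var_food=fit.var_v,
    )


def density_bias_curve(
    metrics: pd.DataFrame, quiz: QuizSpec, use_log_density: bool = True
) -> pd.DataFrame:
    """Per-food mean signed error against energy density, ordered by density.

    The tabular form of the under-/over-estimation pattern: calorie-sparse
    foods sit at negative mean error, calorie-dense foods at positive, when a
    density bias is present.
    """
    density = {f.food_id: f.energy_kcal / f.mass_g for f in quiz.foods}
    g = metrics.groupby("food_id", sort=False)
    out = g.agg(mean_e=("e", "mean"), mean_eta=("eta", "mean"), n=("e", "size")).reset_index()
    out["energy_density_kcal_g"] = out["food_id"].map(density)
    cld = _centered_log_density(quiz, use_log_density)
    out["centered_log_density"] = out["food_id"].map(cld)
    return (
        out[["food_id", "energy_density_kcal_g", "centered_log_density", "n", "mean_e", "mean_eta"]]
        .sort_values("energy_density_kcal_g", kind="stable")
        .reset_index(drop=True)
    )
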