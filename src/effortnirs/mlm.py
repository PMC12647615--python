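"""Multilevel models for trial-level HbDiff with nested-model inference.

The outcome is the trial x subregion HbDiff window mean; repeated measures are
absorbed by a per-participant random intercept and fixed effects are estimated
by full maximum likelihood so nested models can be compared with likelihood
ratio tests. Categorical predictors are dummy-coded against the study's
reference levels: standard program, left-lateral subregion, left-handedness.

The module follows the Model/Results convention: ``HbDiffModel`` is built from
the long table (``from_dataframe``) and ``fit()`` returns ``HbDiffResults``
carrying estimates, standard errors, approximate degrees of freedom,
log-likelihood, AIC and variance components, with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

REFERENCES = {"condition": "standard", "subregion": "left_lateral", "handedness": "left"}


class ConvergenceError(RuntimeError):
    """Mixed-model optimizer failed; carries the optimizer trace."""


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one model in the nested hierarchy.

    All models share the participant random intercept; nested specs differ
    only by added fixed terms.
    """

    program: bool = False
    subregion: bool = False
    interaction: bool = False
    handedness: bool = False
    effort: bool = False
    references: dict = field(default_factory=lambda: dict(REFERENCES))

    def __post_init__(self):
        if self.interaction and not (self.program and self.subregion):
            raise ValueError("interaction requires both program and subregion main effects")

    @property
    def terms(self) -> list[str]:
        t = []
        if self.program:
            t.append(f"C(condition, Treatment('{self.references['condition']}'))")
        if self.subregion:
            t.append(f"C(subregion, Treatment('{self.references['subregion']}'))")
        if self.interaction:
            t.append(
                f"C(condition, Treatment('{self.references['condition']}'))"
                f":C(subregion, Treatment('{self.references['subregion']}'))"
            )
        if self.handedness:
            t.append(f"C(handedness, Treatment('{self.references['handedness']}'))")
        if self.effort:
            t.append("effort")
        return t

    def formula(self, outcome: str = "hbdiff") -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{outcome} ~ {rhs}"

    def columns(self) -> list[str]:
        cols = []
        if self.program or self.interaction:
            cols.append("condition")
        if self.subregion or self.interaction:
            cols.append("subregion")
        if self.handedness:
            cols.append("handedness")
        if self.effort:
            cols.append("effort")
        return cols

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms)


# spec hierarchy used in the analysis: unconditional -> main effect -> interaction
UNCONDITIONAL = ModelSpec()
MAIN_EFFECT = ModelSpec(program=True, handedness=True)
INTERACTION = ModelSpec(program=True, subregion=True, interaction=True, handedness=True)


def _prettify(name: str) -> str:
    """Compact labels for patsy dummy-column names."""
    out = name
    out = out.replace("C(condition, Treatment('standard'))", "program")
    out = out.replace("C(subregion, Treatment('left_lateral'))", "subregion")
    out = out.replace("C(handedness, Treatment('left'))", "handedness")
    out = out.replace("[T.", "[").replace("]", "]")
    return out


class HbDiffModel:
    """Mixed model for HbDiff with a participant random intercept."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec | None = None, outcome: str = "hbdiff", groups: str = "participant"):
        self.spec = spec or UNCONDITIONAL
        self.outcome = outcome
        self.groups = groups
        needed = [outcome, groups] + self.spec.columns()
        missing = [c for c in needed if c not in table.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        self.table = table.dropna(subset=needed).reset_index(drop=True)
        if not len(self.table):
            raise ValueError("no complete rows for this model")

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, spec: ModelSpec | None = None, **kw) -> "HbDiffModel":
        return cls(table, spec=spec, **kw)

    def fit(self) -> "HbDiffResults":
        formula = self.spec.formula(self.outcome)
        y = self.table[self.outcome].to_numpy(float)
        if float(np.var(y)) == 0.0:
            # degenerate data: the model is exactly the constant; all slopes 0
            return HbDiffResults._degenerate(self, float(y[0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=self.table, groups=self.table[self.groups])
            try:
                res = model.fit(reml=False)
                if not np.isfinite(res.llf) or not getattr(res, "converged", True):
                    res = model.fit(reml=False, method="powell")
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"mixed-model fit failed: {exc}") from exc
        if not np.isfinite(res.llf) or not getattr(res, "converged", True):
            raise ConvergenceError(
                "mixed-model optimizer did not converge; trace:\n" + str(res.summary())
            )
        return HbDiffResults(self, res)


class HbDiffResults:
    """Fitted-model view: fixed effects, variance components, fit statistics.

    Denominator degrees of freedom use a containment-style approximation:
    terms constant within participants (the intercept, handedness) are tested
    against participant-level df, within-participant terms against
    observation-level df.
    """

    def __init__(self, model: HbDiffModel, res):
        self.model = model
        self._res = res
        self.spec = model.spec
        self.n_obs = int(res.nobs)
        self.n_groups = self.model.table[model.groups].nunique()
        self.fe_params = res.fe_params
        self.bse = res.bse_fe
        self.llf = float(res.llf)
        # likelihood parameters: fixed effects + random-intercept variance + residual
        self.k_params = len(self.fe_params) + 2
        self.aic = 2 * self.k_params - 2 * self.llf
        self.var_participant = float(np.asarray(res.cov_re).ravel()[0])
        self.var_residual = float(res.scale)
        self._exog = pd.DataFrame(res.model.exog, columns=self.fe_params.index)
        self._df = self._approx_df()

    @classmethod
    def _degenerate(cls, model: HbDiffModel, const: float) -> "HbDiffResults":
        """Exact fit for a zero-variance outcome: intercept only, slopes 0."""
        from patsy import dmatrices

        obj = cls.__new__(cls)
        obj.model = model
        obj._res = None
        obj.spec = model.spec
        _, X = dmatrices(model.spec.formula(model.outcome), model.table, return_type="dataframe")
        obj.n_obs = len(X)
        obj.n_groups = model.table[model.groups].nunique()
        obj.fe_params = pd.Series(0.0, index=X.columns)
        obj.fe_params.iloc[0] = const
        obj.bse = pd.Series(np.nan, index=X.columns)
        obj.llf = np.nan
        obj.k_params = len(X.columns) + 2
        obj.aic = np.nan
        obj.var_participant = 0.0
        obj.var_residual = 0.0
        obj._exog = X
        obj._df = obj._approx_df()
        return obj

    # -- degrees of freedom -------------------------------------------------
    def _is_between(self, name: str) -> bool:
        """A design column is 'between' if constant within every participant."""
        g = self.model.table[self.model.groups].to_numpy()
        col = self._exog[name].to_numpy()
        per_group_var = pd.Series(col).groupby(g).nunique()
        return bool((per_group_var <= 1).all())

    def _approx_df(self) -> pd.Series:
        names = list(self.fe_params.index)
        n_between = sum(self._is_between(n) for n in names)
        df = {}
        for n in names:
            if self._is_between(n):
                df[n] = max(self.n_groups - n_between, 1)
            else:
                df[n] = max(self.n_obs - len(names) - self.n_groups + 1, 1)
        return pd.Series(df)

    # -- inference ----------------------------------------------------------
    @property
    def tvalues(self) -> pd.Series:
        return self.fe_params / self.bse

    @property
    def df(self) -> pd.Series:
        return self._df

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), self._df), index=self.fe_params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = stats.t.ppf(1 - alpha / 2, self._df)
        return pd.DataFrame(
            {"low": self.fe_params - tcrit * self.bse, "high": self.fe_params + tcrit * self.bse}
        )

    def fixed_effects(self) -> pd.DataFrame:
        ci = self.conf_int()
        out = pd.DataFrame(
            {
                "estimate": self.fe_params,
                "se": self.bse,
                "df": self._df,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_low": ci["low"],
                "ci_high": ci["high"],
            }
        )
        out.index = [_prettify(n) for n in out.index]
        return out

    def cov_fe(self) -> pd.DataFrame:
        k = len(self.fe_params)
        cov = np.asarray(self._res.cov_params())[:k, :k]
        return pd.DataFrame(cov, index=self.fe_params.index, columns=self.fe_params.index)

    def summary(self) -> str:
        fe = self.fixed_effects()
        lines = [
            "Mixed model for HbDiff (participant random intercept, ML)",
            f"formula: {self.spec.formula(self.model.outcome)}",
            f"n_obs={self.n_obs}  participants={self.n_groups}  "
            f"loglik={self.llf:.1f}  AIC={self.aic:.1f}",
            f"variance components: participant={self.var_participant:.2f}  "
            f"residual={self.var_residual:.2f}",
            "",
            fe.round(4).to_string(),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        fe = self.fixed_effects()
        return {
            "formula": self.spec.formula(self.model.outcome),
            "n_obs": self.n_obs,
            "n_participants": self.n_groups,
            "loglik": self.llf,
            "aic": self.aic,
            "variance_participant": self.var_participant,
            "variance_residual": self.var_residual,
            "fixed_effects": fe.reset_index().rename(columns={"index": "term"}).to_dict("records"),
        }


def fit_mlm(trial_table: pd.DataFrame, spec: ModelSpec) -> HbDiffResults:
    """Convenience wrapper: build and fit in one call."""
    return HbDiffModel(trial_table, spec).fit()


def compare_nested(small: HbDiffResults, big: HbDiffResults) -> dict:
    """Likelihood ratio test of two nested ML fits on the same rows."""
    if not small.spec.is_nested_in(big.spec):
        raise ValueError("models are not nested (small's fixed terms must be a subset)")
    if small.n_obs != big.n_obs:
        raise ValueError("nested comparison requires identical observation sets")
    df = len(big.fe_params) - len(small.fe_params)
    chi2 = max(2.0 * (big.llf - small.llf), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"chi2": float(chi2), "df": int(df), "p": p, "delta_aic": big.aic - small.aic}


def nested_hierarchy(trial_table: pd.DataFrame) -> dict:
    """Fit the unconditional / main-effect / interaction hierarchy on common rows.

    Rows are restricted to those complete for the largest model so the
    likelihoods are comparable.
    """
    # handedness enters only when the sample actually contains both groups
    use_handed = "handedness" in trial_table.columns and trial_table["handedness"].nunique() > 1
    main_spec = MAIN_EFFECT if use_handed else ModelSpec(program=True)
    inter_spec = (
        INTERACTION
        if use_handed
        else ModelSpec(program=True, subregion=True, interaction=True)
    )
    cols = ["hbdiff", "participant"] + inter_spec.columns()
    table = trial_table.dropna(subset=cols).reset_index(drop=True)
    results = {
        "unconditional": HbDiffModel(table, UNCONDITIONAL).fit(),
        "main_effect": HbDiffModel(table, main_spec).fit(),
        "interaction": HbDiffModel(table, inter_spec).fit(),
    }
    comparisons = {
        "interaction_vs_unconditional": compare_nested(results["unconditional"], results["interaction"]),
        "interaction_vs_main": compare_nested(results["main_effect"], results["interaction"]),
        "main_vs_unconditional": compare_nested(results["unconditional"], results["main_effect"]),
    }
    return {"results": results, "comparisons": comparisons}


# ---------------------------------------------------------------------------
# simple slopes


def _program_term(spec: ModelSpec) -> str:
    ref = spec.references["condition"]
    other = "dnn" if ref == "standard" else "standard"
    return f"C(condition, Treatment('{ref}'))[T.{other}]"


def simple_slopes(results: HbDiffResults, method: str = "refit") -> pd.DataFrame:
    """Program effect at each subregion from a fitted interaction model.

    ``refit`` re-parameterizes by refitting with each subregion as the
    reference level; ``contrast`` forms the same slopes as linear combinations
    of the fitted coefficients (slope_r = beta_program + beta_program:region_r)
    with delta-method standard errors. The two agree algebraically.
    """
    spec = results.spec
    if not spec.interaction:
        raise ValueError("simple slopes requires a fitted interaction model")
    subregions = sorted(results.model.table["subregion"].unique())
    rows = []
    if method == "refit":
        for sub in subregions:
            rspec = replace(spec, references={**spec.references, "subregion": sub})
            rres = HbDiffModel(results.model.table, rspec, outcome=results.model.outcome).fit()
            term = _program_term(rspec)
            ci = rres.conf_int().loc[term]
            rows.append(
                {
                    "subregion": sub,
                    "estimate": float(rres.fe_params[term]),
                    "se": float(rres.bse[term]),
                    "df": float(rres.df[term]),
                    "t": float(rres.tvalues[term]),
                    "p": float(rres.pvalues[term]),
                    "ci_low": float(ci["low"]),
                    "ci_high": float(ci["high"]),
                }
            )
    elif method == "contrast":
        term = _program_term(spec)
        cov = results.cov_fe()
        names = list(results.fe_params.index)
        ref_sub = spec.references["subregion"]
        for sub in subregions:
            vec = pd.Series(0.0, index=names)
            vec[term] = 1.0
            if sub != ref_sub:
                inter = [
                    n for n in names if term.split("]")[0] + "]" in n and f"[T.{sub}]" in n and ":" in n
                ]
                if len(inter) != 1:
                    raise ValueError(f"could not locate interaction term for {sub}")
                vec[inter[0]] = 1.0
            est = float(vec @ results.fe_params)
            se = float(np.sqrt(vec @ cov.values @ vec))
            dof = float(results.df[term])
            t = est / se
            tcrit = stats.t.ppf(0.975, dof)
            rows.append(
                {
                    "subregion": sub,
                    "estimate": est,
                    "se": se,
                    "df": dof,
                    "t": t,
                    "p": float(2 * stats.t.sf(abs(t), dof)),
                    "ci_low": est - tcrit * se,
                    "ci_high": est + tcrit * se,
                }
            )
    else:
        raise ValueError("method must be 'refit' or 'contrast'")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# brain-behaviour model


def brain_behaviour_model(
    trial_table: pd.DataFrame, correct_only: bool = True, subregion: str = "left_lateral"
) -> dict:
    """Effort -> HbDiff slope in one subregion, optionally on correct trials only.

    Fits HbDiff ~ effort with a participant random intercept and compares it
    to the unconditional model on the same rows by likelihood ratio test.
    """
    rows = trial_table[trial_table["subregion"] == subregion]
    if correct_only:
        rows = rows[rows["correct"].astype(bool)]
        if not len(rows):
            raise ValueError("no correct trials to analyse")
    rows = rows.dropna(subset=["hbdiff", "effort"]).reset_index(drop=True)
    effort_res = HbDiffModel(rows, ModelSpec(effort=True)).fit()
    null_res = HbDiffModel(rows, UNCONDITIONAL).fit()
    lrt = compare_nested(null_res, effort_res)
    return {"result": effort_res, "null": null_res, "lrt": lrt, "slope": float(effort_res.fe_params["effort"])}
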