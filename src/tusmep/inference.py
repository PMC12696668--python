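"""Statistical layer: baseline tests, trial-level LMMs, rm-ANOVA, power.

The trial-level linear mixed model predicts square-root-transformed MEP
amplitude from TUS condition, timepoint and their interaction, with
by-participant random effects.  Estimation is REML via statsmodels MixedLM;
term F-tests use either Satterthwaite denominator degrees of freedom
(computed here from the REML log-likelihood curvature, combined across
multi-df terms with the eigendecomposition recipe used by lmerTest) or the
cheap between-within approximation (denominator df = participants - 1, the
convention behind printed F(1,14)-style statistics) for simulation studies.

The repeated-measures ANOVA replication runs on raw participant-level means
with Greenhouse-Geisser correction (pingouin).  Power calculations
implement the G*Power noncentral-F repeated-measures formulations
("between", "within", "interaction" families).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PowerSpec",
    "FitResult",
    "baseline_paired_tests",
    "fit_trial_lmm",
    "rm_anova",
    "eta_from_F",
    "cohens_f_from_eta",
    "rm_anova_power",
    "required_sample_size",
    "overlap_regression",
    "accuracy_subgroup",
]


# --------------------------------------------------------------------------
# effect sizes

def eta_from_F(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic and its dfs."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    return F * df1 / (F * df1 + df2)


def cohens_f_from_eta(eta_p2: float) -> float:
    """Cohen's f = sqrt(eta_p2 / (1 - eta_p2))."""
    if not (0.0 <= eta_p2 < 1.0):
        raise ValueError("partial eta squared must lie in [0, 1)")
    return float(np.sqrt(eta_p2 / (1.0 - eta_p2)))


# --------------------------------------------------------------------------
# baseline paired tests

def baseline_paired_tests(
    values: pd.DataFrame,
    measure_col: str = "measure",
    value_col: str = "value",
    conditions: tuple[str, str] = ("verum", "sham"),
) -> pd.DataFrame:
    """Two-sided paired t-tests (condition A - condition B) per measure.

    ``values`` is long: participant, condition, measure, value.  Cohen's d
    is mean(diff)/sd(diff); zero-variance differences are flagged.
    """
    out = []
    for measure, grp in values.groupby(measure_col, sort=False):
        wide = grp.pivot(index="participant", columns="condition",
                         values=value_col)
        if not set(conditions) <= set(wide.columns):
            raise ValueError(f"measure {measure!r} lacks both conditions")
        wide = wide.dropna(subset=list(conditions))
        diff = (wide[conditions[0]] - wide[conditions[1]]).to_numpy()
        n = diff.size
        if n < 2:
            raise ValueError(f"measure {measure!r}: need >=2 complete pairs")
        sd = diff.std(ddof=1)
        degenerate = sd == 0
        if degenerate:
            t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
            p = 1.0 if diff.mean() == 0 else 0.0
            d = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
        else:
            t, p = stats.ttest_rel(wide[conditions[0]], wide[conditions[1]])
            d = diff.mean() / sd
        out.append({
            "measure": measure, "t": float(t), "df": n - 1, "p": float(p),
            "cohens_d": float(d), "zero_variance": bool(degenerate),
            f"mean_{conditions[0]}": float(wide[conditions[0]].mean()),
            f"se_{conditions[0]}": float(wide[conditions[0]].sem()),
            f"mean_{conditions[1]}": float(wide[conditions[1]].mean()),
            f"se_{conditions[1]}": float(wide[conditions[1]].sem()),
        })
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# trial-level LMM

@dataclass
class FitResult:
    """Term table plus marginal means for one fitted model."""

    anova_table: pd.DataFrame  # term, F, df1, df2, p, eta_p2 (+ GG cols)
    emmeans: pd.DataFrame | None = None
    random_structure: str | None = None
    df_method: str | None = None
    converged: bool = True
    fallback_used: bool = False
    extras: dict = field(default_factory=dict)


class _RemlSurface:
    """Block-diagonal REML log-likelihood over (cov_re, vcomp, scale).

    Used only to compute Satterthwaite dfs around a statsmodels MixedLM
    fit.  Variance parameters are packed as the log-Cholesky factor of the
    correlated random-effects covariance, the log variance of each variance
    component (iid cell effects), and log(residual variance).
    """

    def __init__(self, result):
        model = result.model
        X = np.asarray(model.exog)
        y = np.asarray(model.endog)
        labels = np.asarray(model.groups)
        Zre = (np.asarray(model.exog_re) if model.exog_re is not None
               else np.ones((len(y), 1)))
        self.p = X.shape[1]
        self.k = Zre.shape[1]
        vc = model.exog_vc
        self.n_vc = len(vc.names) if vc is not None else 0
        self.blocks = []
        for gi, g in enumerate(pd.unique(labels)):
            m = labels == g
            mats = ([np.asarray(vc.mats[t][gi]) for t in range(self.n_vc)]
                    if self.n_vc else [])
            self.blocks.append((X[m], y[m], Zre[m], mats))

    def pack(self, cov_re: np.ndarray, vcomp: np.ndarray, scale: float) -> np.ndarray:
        L = np.linalg.cholesky(cov_re + 1e-12 * np.eye(self.k))
        params = []
        for i in range(self.k):
            for j in range(i + 1):
                params.append(np.log(L[i, j]) if i == j else L[i, j])
        for v in np.atleast_1d(vcomp)[:self.n_vc]:
            params.append(np.log(max(float(v), 1e-10)))
        params.append(np.log(scale))
        return np.asarray(params)

    def unpack(self, theta: np.ndarray):
        L = np.zeros((self.k, self.k))
        pos = 0
        for i in range(self.k):
            for j in range(i + 1):
                L[i, j] = np.exp(theta[pos]) if i == j else theta[pos]
                pos += 1
        vcomp = np.exp(theta[pos:pos + self.n_vc])
        scale = float(np.exp(theta[pos + self.n_vc]))
        return L @ L.T, vcomp, scale

    def _normal_eqs(self, theta):
        cov_re, vcomp, scale = self.unpack(theta)
        num = np.zeros((self.p, self.p))
        rhs = np.zeros(self.p)
        pieces = []
        logdet = 0.0
        for Xb, yb, Zb, mats in self.blocks:
            V = Zb @ cov_re @ Zb.T + scale * np.eye(len(yb))
            for t, M in enumerate(mats):
                V += vcomp[t] * (M @ M.T)
            cf = np.linalg.cholesky(V)
            logdet += 2.0 * np.log(np.diag(cf)).sum()
            Vinv_X = np.linalg.solve(cf.T, np.linalg.solve(cf, Xb))
            Vinv_y = np.linalg.solve(cf.T, np.linalg.solve(cf, yb))
            num += Xb.T @ Vinv_X
            rhs += Xb.T @ Vinv_y
            pieces.append((yb, Vinv_y, Xb, Vinv_X))
        return num, rhs, pieces, logdet

    def loglike(self, theta: np.ndarray) -> float:
        num, rhs, pieces, logdet = self._normal_eqs(theta)
        beta = np.linalg.solve(num, rhs)
        quad = 0.0
        for yb, Vinv_y, Xb, Vinv_X in pieces:
            r = yb - Xb @ beta
            quad += r @ (Vinv_y - Vinv_X @ beta)
        sign, logdet_num = np.linalg.slogdet(num)
        return -0.5 * (logdet + quad + logdet_num)

    def cov_beta(self, theta: np.ndarray) -> np.ndarray:
        num, _, _, _ = self._normal_eqs(theta)
        return np.linalg.inv(num)


def _numeric_hessian(f, x0: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    n = x0.size
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        for j in range(i + 1):
            if i == j:
                H[i, i] = (f(x0 + ei) - 2.0 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                ej = np.zeros(n); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def _numeric_gradient(f, x0: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    n = x0.size
    h = rel_step * np.maximum(1.0, np.abs(x0))
    g = np.empty(n)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        g[i] = (f(x0 + ei) - f(x0 - ei)) / (2.0 * h[i])
    return g


def _satterthwaite_df(surface: _RemlSurface, theta: np.ndarray,
                      vcov_theta: np.ndarray, contrast: np.ndarray) -> float:
    def c_of(th):
        return float(contrast @ surface.cov_beta(th) @ contrast)

    c0 = c_of(theta)
    g = _numeric_gradient(c_of, theta)
    var_c = float(g @ vcov_theta @ g)
    if var_c <= 0:
        return np.inf
    return 2.0 * c0 ** 2 / var_c


_RE_LADDER = (
    # "maximal" tractable analogue: correlated intercept + condition +
    # timepoint slopes plus an iid condition x timepoint cell effect
    ("intercept+condition+timepoint slopes+cell",
     "~C(condition) + C(timepoint)", True),
    ("intercept+condition slope+cell", "~C(condition)", True),
    ("intercept+condition slope", "~C(condition)", False),
    ("intercept only", "1", False),
)


def fit_trial_lmm(
    trials: pd.DataFrame,
    dv: str = "amp_sqrt",
    df_method: str = "satterthwaite",
    random_structure: str = "auto",
    emmeans_factor: str = "condition",
) -> FitResult:
    """Condition x Timepoint mixed model on trial-level amplitudes.

    ``trials`` needs columns participant, condition, timepoint and ``dv``
    (pre-transformed).  ``random_structure`` is 'auto' (fallback ladder:
    correlated intercept + condition + timepoint slopes, then intercept +
    condition slope, then intercept only), or one of 'maximal',
    'condition', 'intercept'.
    """
    if trials["participant"].nunique() < 2:
        raise ValueError("need at least two participants")
    data = trials.copy()
    data["condition"] = pd.Categorical(
        data["condition"], categories=sorted(data["condition"].unique()))
    tps = list(pd.unique(data["timepoint"]))
    if "Baseline" in tps:
        tps = ["Baseline"] + [t for t in tps if t != "Baseline"]
    data["timepoint"] = pd.Categorical(data["timepoint"], categories=tps)

    if random_structure == "auto":
        ladder = _RE_LADDER
    else:
        picks = {"maximal": 0, "condition+cell": 1, "condition": 2,
                 "intercept": 3}
        if random_structure not in picks:
            raise ValueError(f"unknown random_structure {random_structure!r}")
        ladder = (_RE_LADDER[picks[random_structure]],)

    # sum-to-zero contrasts so each term's Wald F is the Type III test of
    # the corresponding main effect / interaction
    formula = f"{dv} ~ C(condition, Sum) * C(timepoint, Sum)"
    data["_cell"] = (data["condition"].astype(str) + ":"
                     + data["timepoint"].astype(str))
    result = None
    used_name = None
    fallback = False
    for i, (name, re_formula, use_cell_vc) in enumerate(ladder):
        vc_formula = {"cell": "0 + C(_cell)"} if use_cell_vc else None
        model = sm.MixedLM.from_formula(
            formula, data=data, groups="participant", re_formula=re_formula,
            vc_formula=vc_formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
            except (np.linalg.LinAlgError, ValueError):
                fallback = True
                continue
        ok = bool(res.converged) and np.isfinite(res.fe_params).all()
        if ok and res.cov_re.size:
            # boundary fits (singular random-effects covariance) are not
            # trusted: fall down the ladder
            ev = np.linalg.eigvalsh(np.atleast_2d(np.asarray(res.cov_re)))
            ok = ev.min() > 1e-8 * max(res.scale, 1e-12)
        if ok or i == len(ladder) - 1:
            result, used_name = res, name
            break
        fallback = True
    if result is None:
        raise RuntimeError("mixed model failed to converge at every level")

    design_info = result.model.data.design_info
    beta = np.asarray(result.fe_params)
    cov_beta = np.asarray(result.cov_params())[:len(beta), :len(beta)]
    n_groups = data["participant"].nunique()

    surface = None
    vcov_theta = None
    theta = None
    method_used = df_method
    if df_method == "satterthwaite":
        try:
            surface = _RemlSurface(result)
            theta = surface.pack(np.atleast_2d(np.asarray(result.cov_re)),
                                 np.asarray(result.vcomp),
                                 float(result.scale))
            H = _numeric_hessian(surface.loglike, theta)
            vcov_theta = np.linalg.pinv(-H)
            cov_beta = surface.cov_beta(theta)
        except np.linalg.LinAlgError:
            method_used = "between-within"
    elif df_method != "between-within":
        raise ValueError(f"unknown df_method {df_method!r}")

    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        L = np.zeros((sl.stop - sl.start, len(beta)))
        for r, cidx in enumerate(range(sl.start, sl.stop)):
            L[r, cidx] = 1.0
        q = L.shape[0]
        M = L @ cov_beta @ L.T
        Lb = L @ beta
        F = float(Lb @ np.linalg.solve(M, Lb) / q)
        if method_used == "satterthwaite":
            # lmerTest recipe: eigen-decompose the contrast covariance,
            # Satterthwaite df per eigen-contrast, then pool
            evals, evecs = np.linalg.eigh(M)
            dfs = []
            for j in range(q):
                lj = evecs[:, j] @ L
                dfs.append(_satterthwaite_df(surface, theta, vcov_theta, lj))
            dfs = np.asarray(dfs)
            finite = dfs[np.isfinite(dfs) & (dfs > 2.0)]
            if finite.size == q:
                E = float(np.sum(finite / (finite - 2.0)))
                df2 = 2.0 * E / (E - q) if E > q else np.inf
            else:
                df2 = float(n_groups - 1)
        else:
            df2 = float(n_groups - 1)
        p = float(stats.f.sf(F, q, df2)) if np.isfinite(df2) else float(
            stats.chi2.sf(F * q, q))
        rows.append({"term": term, "F": F, "df1": q, "df2": df2, "p": p,
                     "eta_p2": eta_from_F(F, q, df2) if np.isfinite(df2)
                     else np.nan})
    table = pd.DataFrame(rows)

    emmeans = _marginal_means(result, data, emmeans_factor, cov_beta)
    return FitResult(
        anova_table=table, emmeans=emmeans, random_structure=used_name,
        df_method=method_used, converged=bool(result.converged),
        fallback_used=fallback,
        extras={"scale": float(result.scale),
                "cov_re": np.atleast_2d(np.asarray(result.cov_re)).tolist()},
    )


def _marginal_means(result, data: pd.DataFrame, factor: str,
                    cov_beta: np.ndarray) -> pd.DataFrame:
    """Estimated marginal means over the factorial cells (balanced weights)."""
    from patsy import build_design_matrices

    design_info = result.model.data.design_info
    conditions = list(data["condition"].cat.categories)
    timepoints = list(data["timepoint"].cat.categories)
    cells = pd.DataFrame(
        [(c, t) for c in conditions for t in timepoints],
        columns=["condition", "timepoint"])
    X = np.asarray(build_design_matrices([design_info], cells)[0])
    beta = np.asarray(result.fe_params)
    rows = []
    for level in cells[factor].unique():
        w = (cells[factor] == level).to_numpy()
        x_bar = X[w].mean(axis=0)
        est = float(x_bar @ beta)
        se = float(np.sqrt(x_bar @ cov_beta @ x_bar))
        rows.append({factor: level, "emmean": est, "se": se})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# repeated-measures ANOVA

def rm_anova(
    means: pd.DataFrame,
    dv: str = "mean_single",
    subject: str = "participant",
    within: tuple[str, str] = ("condition", "timepoint"),
) -> FitResult:
    """Two-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    Runs on raw participant-level means (no square-root correction).  The
    returned table carries uncorrected and GG-corrected dfs and p-values.
    """
    counts = means.groupby([subject, *within], observed=True).size()
    if (counts != 1).any():
        raise ValueError("expect exactly one mean per subject and cell")
    per_subject = means.groupby(subject, observed=True).size()
    if per_subject.nunique() != 1:
        raise ValueError("missing cells: unbalanced within-subject design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(data=means, dv=dv, within=list(within),
                          subject=subject, detailed=True, effsize="np2")
    aov = aov.rename(columns={"Source": "term", "p_unc": "p",
                              "p_GG_corr": "p_gg", "np2": "eta_p2",
                              "ddof1": "df1", "ddof2": "df2"})
    aov["df1_gg"] = aov["df1"] * aov["eps"]
    aov["df2_gg"] = aov["df2"] * aov["eps"]
    cols = ["term", "F", "df1", "df2", "p", "eps", "df1_gg", "df2_gg",
            "p_gg", "eta_p2"]
    return FitResult(anova_table=aov[cols].copy(), df_method="greenhouse-geisser")


# --------------------------------------------------------------------------
# power for repeated-measures ANOVA (G*Power formulations)

@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a G*Power repeated-measures ANOVA power analysis.

    ``family`` selects the tested effect: 'between' (between-subjects
    factor), 'within' (repeated factor) or 'interaction'.  ``eta_p2`` and
    Cohen's f are interchangeable; exactly the usual f = sqrt(eta/(1-eta))
    conversion links them.
    """

    eta_p2: float = 0.602
    alpha: float = 0.05
    power_target: float = 0.8
    n_groups: int = 2
    n_measurements: int = 4
    rho_rm: float = 0.5
    epsilon: float = 1.0
    family: str = "between"

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_p2 < 1.0):
            raise ValueError("eta_p2 must lie in [0, 1)")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power_target < 1.0):
            raise ValueError("alpha and power_target must lie in (0, 1)")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in (0, 1]")
        if self.family not in ("between", "within", "interaction"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def f(self) -> float:
        return cohens_f_from_eta(self.eta_p2)


def rm_anova_power(spec: PowerSpec, n_total: int) -> float:
    """Noncentral-F power of the selected repeated-measures effect at N."""
    g, m = spec.n_groups, spec.n_measurements
    if n_total <= g:
        raise ValueError("total N must exceed the number of groups")
    f2 = spec.f ** 2
    rho, eps = spec.rho_rm, spec.epsilon
    if spec.family == "between":
        lam = f2 * n_total * m / (1.0 + (m - 1) * rho)
        df1, df2 = g - 1, n_total - g
    else:
        lam = f2 * n_total * m * eps / (1.0 - rho)
        base = (m - 1) * eps
        df1 = base if spec.family == "within" else (g - 1) * base
        df2 = (n_total - g) * base
    crit = stats.f.isf(spec.alpha, df1, df2)
    if lam < 1e-12:  # ncf is numerically unstable at zero noncentrality
        return float(stats.f.sf(crit, df1, df2))
    return float(stats.ncf.sf(crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, n_max: int = 10000) -> int:
    """Smallest total N (stepping by n_groups) reaching the target power."""
    n = 2 * spec.n_groups  # smallest N with df2 > 0 in every family
    while n <= n_max:
        if rm_anova_power(spec, n) >= spec.power_target:
            return n
        n += spec.n_groups
    raise ValueError(f"target power not reached by N = {n_max}")


# --------------------------------------------------------------------------
# targeting-accuracy statistics

def overlap_regression(
    data: pd.DataFrame,
    x: str = "overlap_pct",
    y: str = "baseline_ratio",
    by: str = "timepoint",
) -> pd.DataFrame:
    """Per-timepoint OLS of the MEP baseline ratio on focus-ROI overlap %."""
    rows = []
    for level, grp in data.groupby(by, sort=False):
        grp = grp.dropna(subset=[x, y])
        if len(grp) < 3:
            raise ValueError(f"{by}={level!r}: need >=3 participants")
        if grp[x].nunique() == 1:
            raise ValueError(f"{by}={level!r}: constant predictor")
        X = sm.add_constant(grp[x].to_numpy())
        fit = sm.OLS(grp[y].to_numpy(), X).fit()
        rows.append({by: level, "slope": float(fit.params[1]),
                     "intercept": float(fit.params[0]),
                     "t": float(fit.tvalues[1]),
                     "df": int(fit.df_resid), "p": float(fit.pvalues[1]),
                     "n": int(len(grp))})
    return pd.DataFrame(rows)


def accuracy_subgroup(
    focus_df: pd.DataFrame,
    ratios: pd.DataFrame | None = None,
    threshold: float = 20.0,
) -> dict:
    """Partition participants by focus-ROI overlap above ``threshold`` %.

    ``focus_df`` needs participant, overlap_pct, roi_peak_isppa; ``ratios``
    (optional) participant, timepoint, baseline_ratio.  Empty subgroups are
    reported as empty, never raised.
    """
    above = focus_df.loc[focus_df["overlap_pct"] > threshold]
    out = {
        "threshold_pct": float(threshold),
        "n_total": int(len(focus_df)),
        "n_overlapping": int((focus_df["overlap_pct"] > 0).sum()),
        "n_above_threshold": int(len(above)),
        "roi_peak_mean": (float(above["roi_peak_isppa"].mean())
                          if len(above) else None),
        "roi_peak_sd": (float(above["roi_peak_isppa"].std(ddof=1))
                        if len(above) > 1 else None),
    }
    if ratios is not None and len(above):
        sub = ratios.loc[ratios["participant"].isin(above["participant"])]
        out["subgroup_mep_ratio"] = {
            str(tp): float(v) for tp, v in
            sub.groupby("timepoint", sort=False)["baseline_ratio"].mean().items()
        }
    return out
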