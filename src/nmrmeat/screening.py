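"""Per-metabolite univariate and mixed-model screening.

Two linear mixed models are screened per metabolite (concentrations in
µmol/g, aging time as a numeric covariate in days):

* model 1: ``conc ~ day * (cattle_type + aging_type)`` with random
  intercepts for animal nested in aging run;
* model 2: ``conc ~ cattle_type`` with a random animal intercept.

Fixed effects are removed by backward selection: at each step the
least-significant removable term (main effects only once their interactions
are gone) is dropped when its likelihood-ratio p-value exceeds alpha, and
the model is refit until every retained term is significant.  LR tests
compare nested maximum-likelihood fits; the final reported model is refit
by REML.  The aging-run intercept is dropped automatically when its
variance estimate collapses to the boundary.

The nonparametric track provides Spearman rank correlation against aging
day, Friedman tests over complete (animal × aging type) blocks, and
Kruskal–Wallis with Dunn-style pairwise z-tests under Bonferroni
correction, gated by a Shapiro–Wilk normality check.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenResult",
    "mixed_model_screen",
    "screen_table",
    "spearman",
    "friedman",
    "kruskal_wallis_posthoc",
    "normality_gate",
    "MODEL1_TERMS",
    "MODEL2_TERMS",
]

MODEL1_TERMS = ("day", "cattle", "aging", "day:cattle", "day:aging")
MODEL2_TERMS = ("cattle",)

# each term maps to exactly one numeric design column (indicators precomputed),
# so every LR test has one degree of freedom and coding never depends on
# which other terms survive backward selection
_TERM_FORMULA = {
    "day": "aging_day",
    "cattle": "is_cow",
    "aging": "is_dry",
    "day:cattle": "day_x_cow",
    "day:aging": "day_x_dry",
}


@dataclass
class ScreenResult:
    """Screening outcome for one metabolite."""

    metabolite: str
    model: str
    retained_terms: list[str]
    term_p: dict[str, float]  # LR p of dropping each retained term from the final model
    factor_p: dict[str, float]  # LR p of dropping *all* terms involving a factor
    run_re_dropped: bool = False
    error: str | None = None
    spearman_r: float = float("nan")
    spearman_p: float = float("nan")
    friedman_stat: float = float("nan")
    friedman_p: float = float("nan")
    kruskal_h: float = float("nan")
    kruskal_p: float = float("nan")
    pairwise: pd.DataFrame | None = None
    normal: bool | None = None

    def affected_by(self, factor: str, alpha: float = 0.05, n_tests: int = 1) -> bool:
        """Is the factor retained and significant after Bonferroni over metabolites?"""
        involved = [t for t in self.retained_terms if factor in t]
        if not involved:
            return False
        p = self.factor_p.get(factor, float("nan"))
        return bool(np.isfinite(p) and min(p * n_tests, 1.0) <= alpha)


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; NaN-flagged if constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def friedman(blocked: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test on a complete subjects × conditions table."""
    blocked = np.asarray(blocked, dtype=float)
    if blocked.ndim != 2 or blocked.shape[0] < 2 or blocked.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(blocked)):
        raise ValueError("blocks must be complete (no missing cells)")
    cols = [blocked[:, j] for j in range(blocked.shape[1])]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = stats.friedmanchisquare(*cols)
    except ValueError:  # identical columns: zero variance in ranks
        return 0.0, 1.0
    if not np.isfinite(stat):
        return 0.0, 1.0
    return float(stat), float(p)


def kruskal_wallis_posthoc(
    values, labels, alpha: float = 0.05
) -> tuple[float, float, pd.DataFrame]:
    """Tie-corrected Kruskal–Wallis H plus Dunn pairwise z-tests (Bonferroni).

    Pairwise p-values are multiplied by the number of pairs and capped at 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    groups = [values[labels == u] for u in uniq]
    if min(len(g) for g in groups) < 2:
        raise ValueError("every group needs at least two members")
    if np.ptp(values) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    # Dunn: pooled mid-ranks, normal approximation with tie correction
    n = values.size
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    mean_ranks = {u: ranks[labels == u].mean() for u in uniq}
    sizes = {u: int(np.sum(labels == u)) for u in uniq}
    pairs = list(itertools.combinations(uniq, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_raw": raw,
                "p_bonferroni": min(raw * len(pairs), 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["significant"] = table["p_bonferroni"] <= alpha
    return float(h), float(p), table


def normality_gate(values, alpha: float = 0.05) -> str:
    """Shapiro–Wilk decision: 'normal' (fail to reject) or 'non-normal'."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("constant vector: normality undefined")
    _, p = stats.shapiro(values)
    return "normal" if p > alpha else "non-normal"


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def _fit_lmm(
    df: pd.DataFrame,
    terms: tuple[str, ...] | list[str],
    with_run: bool,
    reml: bool = False,
):
    """Fit a linear mixed model with the given fixed terms.

    Random structure: animal within aging run (groups=run + animal variance
    component) when ``with_run``; otherwise a plain animal intercept.
    """
    import statsmodels.formula.api as smf

    rhs = " + ".join([_TERM_FORMULA[t] for t in terms]) if terms else "1"
    formula = f"conc ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if with_run:
            md = smf.mixedlm(
                formula,
                df,
                groups="aging_run",
                re_formula="1",
                vc_formula={"animal": "0 + C(animal_id)"},
            )
        else:
            md = smf.mixedlm(formula, df, groups="animal_id", re_formula="1")
        # variance components on the boundary can make an optimizer's Hessian
        # singular or its reported likelihood infinite; accept the first
        # converged finite fit, else the best finite one
        best = None
        last_exc: Exception | None = None
        for method in ("lbfgs", "powell", "nm", "cg"):
            try:
                res = md.fit(reml=reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if not np.isfinite(res.llf):
                continue
            if res.converged:
                return res
            if best is None or res.llf > best.llf:
                best = res
        if best is not None:
            return best
        raise last_exc if last_exc is not None else RuntimeError("mixed model fit failed")


def _lrt(res_full, res_reduced, df_diff: int) -> float:
    stat = 2.0 * (res_full.llf - res_reduced.llf)
    stat = max(stat, 0.0)
    return float(stats.chi2.sf(stat, df_diff))


def _term_df(term: str) -> int:
    return 1  # all factors here are binary or numeric: one parameter per term


def _containment_df(df: pd.DataFrame, term: str) -> int:
    """Containment degrees of freedom for a fixed term's t reference.

    Cattle type varies between animals (df ≈ animals − between-params);
    everything else varies within animals.  A plain z reference is
    anticonservative for between-animal contrasts with 15 animals.
    """
    n = len(df)
    n_animal = df["animal_id"].nunique()
    if term == "cattle":
        return max(n_animal - 2, 1)
    return max(n - n_animal - 4, 1)


def _wald_p(res, df: pd.DataFrame, term: str) -> float:
    col = _TERM_FORMULA[term]
    try:
        t = float(res.tvalues[col])
    except (KeyError, TypeError):
        return float("nan")
    if not np.isfinite(t):
        return float("nan")
    return float(2.0 * stats.t.sf(abs(t), _containment_df(df, term)))


def _removable(terms: list[str]) -> list[str]:
    out = []
    for t in terms:
        if ":" in t:
            out.append(t)
        else:
            if not any(":" in o and t in o.split(":") for o in terms):
                out.append(t)
    return out


def _backward_select(
    df: pd.DataFrame, start_terms: tuple[str, ...], with_run: bool, alpha: float
):
    """Backward selection of fixed effects; returns retained terms, p-values, flags.

    The scan uses Wald p-values from the current fit (no extra fits); the
    p-values reported for the surviving terms are LR tests of nested ML
    fits.  Returns ``(terms, term_p, run_flag, final_fit)``.
    """
    terms = list(start_terms)
    run_flag = with_run
    res = _fit_lmm(df, terms, run_flag)
    # drop the run intercept when its variance estimate sits on the boundary
    if run_flag:
        try:
            run_var = float(res.cov_re.iloc[0, 0])
            if not np.isfinite(run_var) or run_var < 1e-4 * float(res.scale):
                run_flag = False
                res = _fit_lmm(df, terms, run_flag)
        except Exception:
            run_flag = False
            res = _fit_lmm(df, terms, run_flag)

    while terms:
        candidates = _removable(terms)
        wald = {t: _wald_p(res, df, t) for t in candidates}
        worst = max(wald, key=lambda t: (np.nan_to_num(wald[t], nan=1.0)))
        if np.nan_to_num(wald[worst], nan=1.0) > alpha:
            terms = [x for x in terms if x != worst]
            res = _fit_lmm(df, terms, run_flag)
        else:
            break

    term_p: dict[str, float] = {}
    for t in _removable(terms):
        res_red = _fit_lmm(df, [x for x in terms if x != t], run_flag)
        term_p[t] = _lrt(res, res_red, _term_df(t))
    for t in terms:  # mains shielded by interactions: Wald p from the final fit
        if t not in term_p:
            term_p[t] = _wald_p(res, df, t)
    return terms, term_p, run_flag, res


def _factor_p(
    df: pd.DataFrame, terms: list[str], factor: str, with_run: bool, res_full
) -> float:
    """LR p-value of removing every term involving a factor from the final model."""
    involved = [t for t in terms if factor in t]
    if not involved:
        return float("nan")
    reduced = [t for t in terms if factor not in t]
    res_red = _fit_lmm(df, reduced, with_run)
    return _lrt(res_full, res_red, len(involved))


def mixed_model_screen(
    conc: pd.DataFrame,
    metabolite: str,
    model: str = "model1",
    alpha: float = 0.05,
) -> ScreenResult:
    """Screen one metabolite with the chosen mixed model plus the nonparametric track.

    ``conc`` must carry the design covariates (animal_id, cattle_type,
    aging_day, aging_type, aging_run) and one column per metabolite.
    """
    if model not in ("model1", "model2"):
        raise ValueError("model must be 'model1' or 'model2'")
    needed = {"animal_id", "cattle_type", "aging_day", "aging_type", "aging_run", metabolite}
    missing = needed - set(conc.columns)
    if missing:
        raise ValueError(f"concentration table lacks columns: {sorted(missing)}")
    df = conc[sorted(needed - {metabolite})].copy()
    vals_raw = conc[metabolite].to_numpy(dtype=float)
    # standardize the response for optimizer conditioning; LR and Wald
    # p-values are invariant to a linear rescaling of y
    sd = vals_raw.std()
    df["conc"] = (vals_raw - vals_raw.mean()) / (sd if sd > 0 else 1.0)
    df["aging_day"] = df["aging_day"].astype(float)
    df["is_cow"] = (df["cattle_type"] == "cow").astype(float)
    df["is_dry"] = (df["aging_type"] == "dry").astype(float)
    df["day_x_cow"] = df["aging_day"] * df["is_cow"]
    df["day_x_dry"] = df["aging_day"] * df["is_dry"]
    for ct in ("cow", "heifer"):
        if (df["cattle_type"] == ct).sum() > 0 and df.loc[df["cattle_type"] == ct, "animal_id"].nunique() < 2:
            return ScreenResult(
                metabolite, model, [], {}, {}, error=f"fewer than two {ct}s: unidentifiable"
            )

    start = MODEL1_TERMS if model == "model1" else MODEL2_TERMS
    with_run = model == "model1"
    try:
        terms, term_p, run_flag, res_fit = _backward_select(df, start, with_run, alpha)
        factor_p = {
            f: _factor_p(df, terms, f, run_flag, res_fit)
            for f in ("day", "cattle", "aging")
        }
        res = ScreenResult(
            metabolite=metabolite,
            model=model,
            retained_terms=terms,
            term_p={t: term_p.get(t, float("nan")) for t in terms},
            factor_p=factor_p,
            run_re_dropped=with_run and not run_flag,
        )
    except Exception as exc:  # unidentifiable fits are reported, not fatal
        res = ScreenResult(metabolite, model, [], {}, {}, error=str(exc))

    # nonparametric track
    vals = df["conc"].to_numpy()
    day = df["aging_day"].to_numpy(dtype=float)
    if np.ptp(vals) > 0:
        res.normal = normality_gate(vals) == "normal"
        res.spearman_r, res.spearman_p = spearman(day, vals)
        res.kruskal_h, res.kruskal_p, res.pairwise = kruskal_wallis_posthoc(
            vals, day.astype(int), alpha
        )
        wide = df.pivot_table(
            index=["animal_id", "aging_type"], columns="aging_day", values="conc"
        )
        if wide.notna().all(axis=None) and wide.shape[1] >= 2 and wide.shape[0] >= 2:
            res.friedman_stat, res.friedman_p = friedman(wide.to_numpy())
    return res


def screen_table(
    conc: pd.DataFrame,
    metabolites: list[str],
    model: str = "model1",
    alpha: float = 0.05,
) -> tuple[list[ScreenResult], pd.DataFrame]:
    """Screen every metabolite; summary row per metabolite with Bonferroni flags.

    The Bonferroni gate multiplies each factor's LR p-value by the number of
    screened metabolites before comparing with alpha.
    """
    results = [mixed_model_screen(conc, m, model, alpha) for m in metabolites]
    n_tests = len(metabolites)
    rows = []
    for r in results:
        rows.append(
            {
                "metabolite": r.metabolite,
                "retained": "+".join(r.retained_terms) if r.retained_terms else "",
                "p_day": r.factor_p.get("day", float("nan")),
                "p_cattle": r.factor_p.get("cattle", float("nan")),
                "p_aging": r.factor_p.get("aging", float("nan")),
                "sig_day": r.affected_by("day", alpha, n_tests),
                "sig_cattle": r.affected_by("cattle", alpha, n_tests),
                "sig_aging": r.affected_by("aging", alpha, n_tests),
                "spearman_r": r.spearman_r,
                "spearman_p": r.spearman_p,
                "friedman_p": r.friedman_p,
                "kruskal_p": r.kruskal_p,
                "normal": r.normal,
                "error": r.error or "",
            }
        )
    return results, pd.DataFrame(rows)
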