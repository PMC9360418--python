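"""Mixed-model inference on N1 amplitudes and brain-behavior correlations.

The primary model is a linear mixed model with a per-subject random
intercept on N1 cluster mean amplitudes and the full-factorial fixed effects
hemisphere x condition x timepoint.  Observations whose normalized
(conditional Pearson) residuals exceed +/-3 are excluded once and the model
refit; per-timepoint condition contrasts are signed digits-minus-control so
digit sensitivity appears as negative t values.  Brain-behavior associations
use Spearman rank correlations with Benjamini-Hochberg FDR control over the
whole grid of tests, reported before and after a median/MAD outlier screen
of the neural measures.

Model estimation itself is delegated to :class:`statsmodels` MixedLM; the
factor marshaling, F-tests, exclusion-and-refit loop and contrast machinery
live here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

CONTRAST_PAIRS = (("DIG", "FF"), ("DIG", "LET"), ("LET", "FF"))


@dataclass
class LmmSpec:
    """Specification of the amplitude mixed model."""

    response: str = "n1_mean_amplitude"
    factors: tuple[str, ...] = ("hemisphere", "condition", "timepoint")
    group: str = "subject"
    reml: bool = True
    outlier_threshold: float = 3.0


@dataclass
class LmmFit:
    """One fitted model plus the pieces needed for contrasts."""

    result: object  # statsmodels MixedLMResults
    design_info: object
    den_df: int
    n_obs: int
    n_groups: int
    anova: pd.DataFrame  # F-tests per fixed term


@dataclass
class LmmResult:
    """Initial fit, refit after residual exclusion, and the exclusion log."""

    spec: LmmSpec
    initial: LmmFit
    refit: LmmFit
    excluded: pd.DataFrame  # rows dropped by the +/-threshold rule
    data: pd.DataFrame  # data used for the refit

    @property
    def anova(self) -> pd.DataFrame:
        return self.refit.anova

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def _check_factors(table: pd.DataFrame, spec: LmmSpec) -> list[str]:
    factors = []
    for f in spec.factors:
        if f not in table.columns:
            raise ValueError(f"factor column {f!r} missing from table")
        n_levels = table[f].nunique()
        if n_levels >= 2:
            factors.append(f)
    if not factors:
        raise ValueError("no factor has at least two levels")
    return factors


def _fit_once(table: pd.DataFrame, spec: LmmSpec, factors: list[str]) -> LmmFit:
    # Sum (deviation) coding so term-wise Wald tests are the classical
    # main-effect / interaction F-tests
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    formula = f"{spec.response} ~ {terms}"
    model = smf.mixedlm(formula, table, groups=table[spec.group])
    try:
        result = model.fit(reml=spec.reml)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError(f"singular design: {err}") from err
    design_info = model.data.design_info
    k_fe = len(result.fe_params)
    n_obs = len(table)
    n_groups = table[spec.group].nunique()
    den_df = n_obs - n_groups - (k_fe - 1)
    if den_df <= 0:
        raise ValueError("not enough observations for within-group F-tests")

    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[:k_fe, :k_fe]
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(k_fe)[sl]
        L = np.zeros((idx.size, k_fe))
        L[np.arange(idx.size), idx] = 1.0
        lb = L @ beta
        lvl = L @ cov @ L.T
        fstat = float(lb @ np.linalg.solve(lvl, lb) / idx.size)
        p = float(sstats.f.sf(fstat, idx.size, den_df))
        rows.append(
            {"term": term.replace(", Sum", ""), "F": fstat, "df_num": idx.size,
             "df_den": den_df, "p": p}
        )
    anova = pd.DataFrame(rows)
    return LmmFit(result=result, design_info=design_info, den_df=den_df,
                  n_obs=n_obs, n_groups=n_groups, anova=anova)


def fit_lmm(table: pd.DataFrame, spec: LmmSpec | None = None) -> LmmResult:
    """Fit the amplitude LMM with one normalized-residual exclusion pass.

    Conditional residuals (observation minus fixed plus predicted random
    effects) are standardized by the estimated residual SD; observations with
    ``|r| >`` ``spec.outlier_threshold`` are dropped and the model refit once.
    Both fits and the exclusion log are returned.
    """
    spec = spec or LmmSpec()
    table = table.reset_index(drop=True)
    if table[spec.group].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    factors = _check_factors(table, spec)
    for f in factors:
        counts = table.groupby(f, observed=False).size()
        empty = counts[counts == 0]
        if len(empty):
            raise ValueError(f"factor {f!r} has empty level(s) {list(empty.index)}")

    initial = _fit_once(table, spec, factors)
    resid = np.asarray(initial.result.resid)
    sigma = math.sqrt(float(initial.result.scale))
    z = resid / sigma
    drop = np.abs(z) > spec.outlier_threshold
    excluded = table.loc[drop].copy()
    excluded["normalized_residual"] = z[drop]
    if drop.any():
        kept = table.loc[~drop].reset_index(drop=True)
        refit = _fit_once(kept, spec, factors)
    else:
        kept = table
        refit = initial
    return LmmResult(spec=spec, initial=initial, refit=refit, excluded=excluded, data=kept)


def _contrast_vector(fit: LmmFit, data: pd.DataFrame, fixed: dict, factors: list[str]) -> np.ndarray:
    """Fixed-effects row predicting the cell mean at `fixed`, averaged over
    the remaining factor levels."""
    from patsy import build_design_matrices

    free = [f for f in factors if f not in fixed]
    level_sets = [sorted(data[f].unique()) for f in free]
    rows = []
    for combo in itertools.product(*level_sets) if free else [()]:
        rec = dict(fixed)
        rec.update(dict(zip(free, combo)))
        rows.append(rec)
    new = pd.DataFrame(rows)
    (X,) = build_design_matrices([fit.design_info], new)
    return np.asarray(X).mean(axis=0)


def posthoc_contrasts(
    lmm: LmmResult,
    pairs: tuple[tuple[str, str], ...] = CONTRAST_PAIRS,
    by: str = "timepoint",
    use_refit: bool = True,
) -> pd.DataFrame:
    """Pairwise condition contrasts per timepoint, signed digits-minus-control.

    Estimates are differences of model cell means (first minus second member
    of each pair) averaged over the factors not involved, with t statistics
    on the within-group degrees of freedom.  Digit sensitivity therefore
    shows up as negative t values.
    """
    fit = lmm.refit if use_refit else lmm.initial
    data = lmm.data if use_refit else None
    if data is None:
        data = lmm.data
    factors = [f for f in lmm.spec.factors if f in data.columns and data[f].nunique() >= 2]
    conditions = set(data["condition"].unique())
    k_fe = len(fit.result.fe_params)
    beta = np.asarray(fit.result.fe_params)
    cov = np.asarray(fit.result.cov_params())[:k_fe, :k_fe]
    by_levels = sorted(data[by].unique()) if by in factors else [None]

    rows = []
    for a, b in pairs:
        if a not in conditions or b not in conditions:
            raise ValueError(f"unknown contrast pair ({a}, {b}); have {sorted(conditions)}")
        for tp in by_levels:
            fixed_a: dict = {"condition": a}
            fixed_b: dict = {"condition": b}
            if tp is not None:
                fixed_a[by] = tp
                fixed_b[by] = tp
            La = _contrast_vector(fit, data, fixed_a, factors)
            Lb = _contrast_vector(fit, data, fixed_b, factors)
            L = La - Lb
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se
            p = float(2.0 * sstats.t.sf(abs(t), df=fit.den_df))
            rows.append(
                {by: tp, "contrast": f"{a}-{b}", "estimate": est, "se": se,
                 "t": t, "df": fit.den_df, "p": p}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank correlations and multiplicity


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    The p-value uses the exact permutation distribution for ``n <= exact_max_n``
    and the t approximation otherwise.  Returns ``(nan, nan)`` when either
    variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        pm_c = perms - perms.mean(axis=1, keepdims=True)
        num = pm_c @ rx_c
        den = np.sqrt((pm_c**2).sum(axis=1) * (rx_c**2).sum())
        rho_perm = num / den
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, 1e-15))
        p = float(2.0 * sstats.t.sf(abs(t), df=n - 2))
    return rho, p


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mad_outliers(values: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    """Boolean mask of values with ``|v - median| > n_mad * MAD``.

    MAD is the raw median absolute deviation (no normal-consistency scaling).
    A zero MAD flags nothing.
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return np.zeros(v.shape, dtype=bool)
    return np.abs(v - med) > n_mad * mad


#: default 36-test grid: 2 hemispheres x 2 contrasts x 9 behavior@timepoint cells
DEFAULT_GRID_BEHAVIORS = (
    ("number_knowledge", "T1"),
    ("arithmetic_pr", "T4"),
    ("reading_word_pr", "T4"),
    ("reading_pseudoword_pr", "T4"),
    ("reading_average_pr", "T4"),
    ("arithmetic_pr", "T5"),
    ("reading_word_pr", "T5"),
    ("reading_pseudoword_pr", "T5"),
    ("reading_average_pr", "T5"),
)


@dataclass
class GridSpec:
    """Which (hemisphere, contrast, behavior@timepoint) cells to test."""

    hemispheres: tuple[str, ...] = ("LOT", "ROT")
    contrasts: tuple[str, ...] = ("coarse", "fine")
    behaviors: tuple[tuple[str, str], ...] = DEFAULT_GRID_BEHAVIORS
    min_n: int = 5
    mad_threshold: float = 3.0

    def cells(self):
        for hemi in self.hemispheres:
            for contrast in self.contrasts:
                for measure, tp in self.behaviors:
                    yield hemi, contrast, measure, tp

    @property
    def n_tests(self) -> int:
        return len(self.hemispheres) * len(self.contrasts) * len(self.behaviors)


def correlation_grid(
    differences: pd.DataFrame,
    behavior: pd.DataFrame,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Spearman rho / p / p_FDR per grid cell, with and without neural outliers.

    ``differences`` is the output of
    :func:`n1dev.erp.sensitivity_differences` (subject, timepoint,
    hemisphere, coarse, fine); ``behavior`` is long-format (subject,
    timepoint, measure, score).  BH-FDR is applied across the whole grid,
    separately for the unfiltered and the outlier-screened variants.
    """
    grid = grid or GridSpec()
    rows = []
    for hemi, contrast, measure, tp in grid.cells():
        neural = differences.query("hemisphere == @hemi and timepoint == @tp")[
            ["subject", contrast]
        ]
        behav = behavior.query("measure == @measure and timepoint == @tp")[
            ["subject", "score"]
        ]
        merged = neural.merge(behav, on="subject").dropna()
        row = {
            "hemisphere": hemi, "contrast": contrast, "measure": measure,
            "timepoint": tp, "n": len(merged),
        }
        if len(merged) < grid.min_n:
            row.update({"rho": np.nan, "p": np.nan, "insufficient": True,
                        "n_excluded": 0, "rho_excl": np.nan, "p_excl": np.nan})
        else:
            rho, p = spearman(merged[contrast], merged["score"])
            out = mad_outliers(merged[contrast].to_numpy(), grid.mad_threshold)
            kept = merged.loc[~out]
            if len(kept) >= grid.min_n and out.any():
                rho_e, p_e = spearman(kept[contrast], kept["score"])
            else:
                rho_e, p_e = rho, p
            row.update({"rho": rho, "p": p, "insufficient": False,
                        "n_excluded": int(out.sum()), "rho_excl": rho_e, "p_excl": p_e})
        rows.append(row)
    out_df = pd.DataFrame(rows)
    for col, adj in (("p", "p_fdr"), ("p_excl", "p_fdr_excl")):
        mask = out_df[col].notna()
        out_df[adj] = np.nan
        if mask.any():
            out_df.loc[mask, adj] = bh_fdr(out_df.loc[mask, col].to_numpy())
    return out_df


def report_lines(lmm: LmmResult, contrasts: pd.DataFrame | None = None,
                 grid: pd.DataFrame | None = None) -> list[str]:
    """Human-readable run report mirroring standard ERP-paper notation."""
    lines = ["Linear mixed model (random intercept per subject)"]
    lines.append(
        f"  observations: {lmm.refit.n_obs} (excluded {lmm.n_excluded} with |normalized residual| > "
        f"{lmm.spec.outlier_threshold:g})"
    )
    for _, r in lmm.anova.iterrows():
        ptxt = "< 0.001" if r["p"] < 0.001 else f"= {r['p']:.3f}"
        lines.append(
            f"  {r['term']}: F({int(r['df_num'])},{int(r['df_den'])}) = {r['F']:.2f}, p {ptxt}"
        )
    if contrasts is not None:
        lines.append("Per-timepoint contrasts (digits minus control):")
        for _, r in contrasts.iterrows():
            ptxt = "< 0.001" if r["p"] < 0.001 else f"= {r['p']:.3f}"
            lines.append(
                f"  {r.get('timepoint', 'all')} {r['contrast']}: est = {r['estimate']:.2f} uV, "
                f"t = {r['t']:.2f}, p {ptxt}"
            )
    if grid is not None:
        lines.append("Brain-behavior Spearman grid (BH-FDR over "
                     f"{int(grid['p'].notna().sum())} tests):")
        for _, r in grid.iterrows():
            if r.get("insufficient", False):
                continue
            lines.append(
                f"  {r['hemisphere']} {r['contrast']} vs {r['measure']}@{r['timepoint']}: "
                f"rho = {r['rho']:.2f}, p = {r['p']:.3f}, p_FDR = {r['p_fdr']:.3f} (n = {int(r['n'])})"
            )
    return lines
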