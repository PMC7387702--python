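"""Line means (BLUEs), variance components, heritability and correlations.

Entry means are estimated by fixed-effect least squares (entry fixed,
environment and replicate-within-environment as sum-to-zero nuisance
effects) and variance components by ANOVA method-of-moments from the
expected mean squares of the balanced genotype x location x year x
replicate model.  For balanced data both coincide with the corresponding
mixed-model answers; no iterative solver is involved.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "compute_blue",
    "entry_means_per_env",
    "balanced_anova",
    "anova_variance_components",
    "broad_sense_heritability",
    "testcross_gain",
    "correlation_with_significance",
    "correlation_table",
]

PHENO_COLUMNS = ["entry", "population", "location", "year", "rep", "trait", "value"]


def _trait_slice(pheno: pd.DataFrame, trait: str, population=None) -> pd.DataFrame:
    df = pheno[pheno["trait"] == trait]
    if population is not None:
        pops = [population] if isinstance(population, str) else list(population)
        df = df[df["population"].isin(pops)]
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    return df


# ---------------------------------------------------------------------------
# BLUEs

def compute_blue(pheno: pd.DataFrame, trait: str, population=None) -> pd.Series:
    """Per-entry adjusted means on the grand-mean scale.

    Least squares under ``value = entry + env + rep(env) + error`` with
    environment = location x year and sum-to-zero nuisance coding, so the
    entry coefficients are directly the adjusted entry means.  For fully
    balanced data this reduces to the raw entry mean.  Entries with no
    usable observations are dropped with a warning.
    """
    df = _trait_slice(pheno, trait, population)
    entries = pd.unique(df["entry"])
    env = df["location"].astype(str) + ":" + df["year"].astype(str)
    rep = env + ":" + df["rep"].astype(str)
    envs = pd.unique(env)
    y = df["value"].to_numpy(float)
    n = len(df)

    e_idx = pd.Categorical(df["entry"], categories=entries).codes
    X_entry = np.zeros((n, len(entries)))
    X_entry[np.arange(n), e_idx] = 1.0

    blocks = [X_entry]
    if len(envs) > 1:
        blocks.append(_sum_to_zero(env, envs))
    # replicate within environment, sum-to-zero within each env
    rep_cols = []
    for e in envs:
        mask = (env == e).to_numpy()
        reps_here = pd.unique(rep[env == e])
        if len(reps_here) > 1:
            Z = _sum_to_zero(rep[env == e], reps_here)
            full = np.zeros((n, Z.shape[1]))
            full[mask] = Z
            rep_cols.append(full)
    if rep_cols:
        blocks.append(np.hstack(rep_cols))

    X = np.hstack(blocks)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    blues = pd.Series(beta[: len(entries)], index=pd.Index(entries, name="entry"), name=trait)
    missing = blues.index[blues.isna()]
    if len(missing):
        log.warning("dropping %d entries with no estimable mean for %s", len(missing), trait)
        blues = blues.dropna()
    return blues


def _sum_to_zero(values: pd.Series, levels) -> np.ndarray:
    """Sum-to-zero (effects) coding: one column per non-reference level."""
    levels = list(levels)
    ref = levels[-1]
    cols = []
    arr = np.asarray(values)
    for lev in levels[:-1]:
        col = np.where(arr == lev, 1.0, np.where(arr == ref, -1.0, 0.0))
        cols.append(col)
    return np.column_stack(cols)


def entry_means_per_env(pheno: pd.DataFrame, trait: str, population=None) -> pd.DataFrame:
    """Raw entry means per location:year environment (columns) for one trait."""
    df = _trait_slice(pheno, trait, population)
    env = df["location"].astype(str) + ":" + df["year"].astype(str)
    out = df.assign(env=env).pivot_table(index="entry", columns="env", values="value", aggfunc="mean")
    out.columns.name = None
    return out


# ---------------------------------------------------------------------------
# balanced factorial ANOVA (Moebius decomposition over factor subsets)

def balanced_anova(df: pd.DataFrame, response: str, factors: list) -> pd.DataFrame:
    """Sum of squares, df and mean square for every non-empty subset of
    crossed factors, assuming (near-)balance.

    Effects are computed recursively: the effect for factor subset S is
    the S-margin mean minus all nested sub-effects and the grand mean.
    SS_S = (N / #cells_S) * sum(effect^2); df_S = prod(levels_f - 1).
    Factors with a single level are skipped.  Returns a frame indexed by
    a ``+``-joined source name.
    """
    work = df.dropna(subset=[response])
    n_total = len(work)
    grand = work[response].mean()
    levels = {f: work[f].nunique() for f in factors}
    active = [f for f in factors if levels[f] > 1]

    effects: dict = {(): None}
    margin_cache: dict = {}

    def margin(subset: tuple) -> pd.Series:
        if subset not in margin_cache:
            margin_cache[subset] = work.groupby(list(subset), observed=True)[response].mean()
        return margin_cache[subset]

    rows = []
    for size in range(1, len(active) + 1):
        for subset in itertools.combinations(active, size):
            m = margin(subset)
            eff = m - grand
            for k in range(1, size):
                for sub in itertools.combinations(subset, k):
                    sub_eff = effects[sub]
                    # broadcast the sub-effect over the finer margin index
                    if len(sub) == 1:
                        key = m.index.get_level_values(sub[0]) if size > 1 else m.index
                        eff = eff - sub_eff.reindex(key).to_numpy()
                    else:
                        key = pd.MultiIndex.from_arrays(
                            [m.index.get_level_values(f) for f in sub]
                        )
                        eff = eff - sub_eff.reindex(key).to_numpy()
            effects[subset] = eff
            n_cells = len(m)
            ss = (n_total / n_cells) * float(np.sum(eff.to_numpy() ** 2))
            dof = int(np.prod([levels[f] - 1 for f in subset]))
            rows.append(("+".join(subset), subset, ss, dof))

    out = pd.DataFrame(rows, columns=["source", "subset", "ss", "df"]).set_index("source")
    out["ms"] = out["ss"] / out["df"].replace(0, np.nan)
    return out


# ---------------------------------------------------------------------------
# variance components and heritability

@dataclass
class VarianceComponents:
    """Method-of-moments components for the G x L x Y x rep model.

    ``None`` marks a component that is not estimable with the available
    strata (e.g. sigma2_gy when only one year was observed).  Negative
    moment solutions are truncated at zero.
    """

    sigma2_g: float | None
    sigma2_gl: float | None
    sigma2_gy: float | None
    sigma2_gly: float | None
    sigma2_e: float | None
    n_locations: int
    n_years: int
    n_reps: int
    mean_squares: dict

    def as_dict(self) -> dict:
        return {
            "sigma2_g": self.sigma2_g,
            "sigma2_gl": self.sigma2_gl,
            "sigma2_gy": self.sigma2_gy,
            "sigma2_gly": self.sigma2_gly,
            "sigma2_e": self.sigma2_e,
            "L": self.n_locations,
            "Y": self.n_years,
            "R": self.n_reps,
        }


def _trunc(x: float | None) -> float | None:
    if x is None:
        return None
    return max(0.0, float(x))


def anova_variance_components(
    pheno: pd.DataFrame, trait: str, population=None
) -> VarianceComponents:
    """Moment estimates of genotypic and G x E variance components.

    Mean squares come from the balanced decomposition over genotype,
    location, year and replicate-within-environment strata; components
    solve the standard random-model expected-mean-square equations:

        MS_GLY = s2_e + R s2_GLY
        MS_GY  = MS_GLY + R L s2_GY
        MS_GL  = MS_GLY + R Y s2_GL
        MS_G   = MS_GL + MS_GY - MS_GLY + R L Y s2_G

    The error mean square pools within-cell variation after removing
    replicate (block) effects.  Components needing an absent stratum are
    returned as ``None``.
    """
    df = _trait_slice(pheno, trait, population)
    L = df["location"].nunique()
    Y = df["year"].nunique()
    R = df["rep"].nunique()
    G = df["entry"].nunique()
    table = balanced_anova(df, "value", ["entry", "location", "year", "rep"])

    def ms(*subset) -> float | None:
        key = "+".join(subset)
        return float(table.loc[key, "ms"]) if key in table.index else None

    # error: all subsets containing both entry and rep
    err_ss = err_df = 0.0
    blk_ss = blk_df = 0.0
    for src, row in table.iterrows():
        subset = row["subset"]
        if "rep" in subset and "entry" in subset:
            err_ss += row["ss"]
            err_df += row["df"]
        elif "rep" in subset:
            blk_ss += row["ss"]
            blk_df += row["df"]
    ms_e = err_ss / err_df if err_df > 0 else None

    ms_g = ms("entry")
    ms_gl = ms("entry", "location")
    ms_gy = ms("entry", "year")
    ms_gly = ms("entry", "location", "year")

    s2_gly = s2_gl = s2_gy = s2_g = None
    if ms_e is None:
        pass
    elif L > 1 and Y > 1:
        s2_gly = (ms_gly - ms_e) / R
        s2_gy = (ms_gy - ms_gly) / (R * L)
        s2_gl = (ms_gl - ms_gly) / (R * Y)
        s2_g = (ms_g - ms_gl - ms_gy + ms_gly) / (R * L * Y)
    elif L > 1:  # single year
        s2_gl = (ms_gl - ms_e) / R
        s2_g = (ms_g - ms_gl) / (R * L)
    elif Y > 1:  # single location
        s2_gy = (ms_gy - ms_e) / R
        s2_g = (ms_g - ms_gy) / (R * Y)
    elif ms_g is not None:
        s2_g = (ms_g - ms_e) / R

    mean_squares = {src: float(row["ms"]) for src, row in table.iterrows()}
    mean_squares["error"] = ms_e if ms_e is not None else float("nan")
    if blk_df > 0:
        mean_squares["block(env)"] = blk_ss / blk_df
    return VarianceComponents(
        sigma2_g=_trunc(s2_g),
        sigma2_gl=_trunc(s2_gl),
        sigma2_gy=_trunc(s2_gy),
        sigma2_gly=_trunc(s2_gly),
        sigma2_e=_trunc(ms_e),
        n_locations=L,
        n_years=Y,
        n_reps=R,
        mean_squares=mean_squares,
    )


def broad_sense_heritability(vc: VarianceComponents) -> float | None:
    """Entry-mean broad-sense heritability (Knapp's plot-mean formula):

        H2 = s2_G / (s2_G + s2_GL/L + s2_GY/Y + s2_GLY/(L Y) + s2_E/(L Y R))

    Non-estimable components count as zero.  Returns ``None`` when every
    component is zero (H2 undefined).
    """
    g = vc.sigma2_g or 0.0
    gl = vc.sigma2_gl or 0.0
    gy = vc.sigma2_gy or 0.0
    gly = vc.sigma2_gly or 0.0
    e = vc.sigma2_e or 0.0
    L, Y, R = vc.n_locations, vc.n_years, vc.n_reps
    denom = g + gl / L + gy / Y + gly / (L * Y) + e / (L * Y * R)
    if denom == 0:
        return None
    return g / denom


# ---------------------------------------------------------------------------
# descriptive statistics

def testcross_gain(pheno: pd.DataFrame, trait: str, population_pair=("TC", "RIL")) -> float:
    """Percent mean difference of a testcross population over the RILs:
    100 * (mean(testcross) - mean(base)) / mean(base)."""
    test_pop, base_pop = population_pair
    t = _trait_slice(pheno, trait, test_pop)["value"].mean()
    b = _trait_slice(pheno, trait, base_pop)["value"].mean()
    if b == 0:
        raise ZeroDivisionError("baseline population mean is zero")
    return 100.0 * (t - b) / b


def correlation_with_significance(x, y) -> tuple:
    """Pearson r, two-sided p (t distribution, n-2 df) and a star code
    ('**' if p < 0.01, '*' if p < 0.05, '' otherwise).

    Returns ``(nan, nan, '')`` when n < 3 or either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"), float("nan"), "")
    r, p = stats.pearsonr(x, y)
    stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
    return (float(r), float(p), stars)


def correlation_table(frame_a: pd.DataFrame, frame_b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise trait correlations between two per-entry tables sharing an
    index, one row per common trait, with star annotations."""
    common = frame_a.index.intersection(frame_b.index)
    rows = []
    for trait in frame_a.columns:
        if trait not in frame_b.columns:
            continue
        r, p, stars = correlation_with_significance(
            frame_a.loc[common, trait], frame_b.loc[common, trait]
        )
        rows.append((trait, r, p, stars, len(common)))
    return pd.DataFrame(rows, columns=["trait", "r", "p", "stars", "n"]).set_index("trait")
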