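"""General and specific combining ability from an NCII testcross table.

GCA effects are the line (or tester) margins of the hybrid cell means,
expressed as deviations from the grand mean; SCA is the cell residual
after removing both margins.  Variance components for the line GCA, the
tester GCA and the SCA come from the expected mean squares of the
balanced lines x testers x environments x replicates random model, with
environments = location x year cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantgen import balanced_anova, compute_blue, _trait_slice
from .simdata import NCIIDesign

log = logging.getLogger(__name__)

__all__ = [
    "GCAEstimates",
    "TestcrossVarianceTable",
    "estimate_combining_ability",
    "ncii_anova",
    "gca_phenotype_vector",
]


@dataclass
class GCAEstimates:
    """Grand mean, line and tester GCA effects and the SCA matrix.

    On balanced data the effects are zero-sum and reconstruct the cell
    means exactly: cell(k, l) = mu + gca_line[k] + gca_tester[l] + sca[k, l].
    Lines with no hybrid data carry NaN and are excluded from the
    zero-sum basis.
    """

    mu: float
    gca_line: pd.Series
    gca_tester: pd.Series
    sca: pd.DataFrame  # lines x testers

    def reconstruct(self) -> pd.DataFrame:
        """Cell means implied by the decomposition."""
        base = np.add.outer(self.gca_line.to_numpy(), self.gca_tester.to_numpy())
        return pd.DataFrame(
            self.mu + base + self.sca.to_numpy(),
            index=self.sca.index,
            columns=self.sca.columns,
        )


def _hybrid_cell_means(hybrid_pheno: pd.DataFrame, design: NCIIDesign, trait: str) -> pd.DataFrame:
    """Line x tester table of environment-adjusted hybrid means.

    Each hybrid's value is its BLUE over environments and replicates
    (equal to the raw hybrid mean when balanced), mapped back onto the
    crossing grid.
    """
    blues = compute_blue(hybrid_pheno, trait)
    parents = design.hybrid_parents().set_index("hybrid")
    cells = pd.DataFrame(
        np.nan, index=pd.Index(design.line_ids, name="line"),
        columns=pd.Index(design.tester_ids, name="tester"),
    )
    for h, val in blues.items():
        if h not in parents.index:
            continue
        k, t = parents.loc[h, "line"], parents.loc[h, "tester"]
        cells.loc[k, t] = val
    return cells


def estimate_combining_ability(
    hybrid_pheno: pd.DataFrame, design: NCIIDesign, trait: str
) -> GCAEstimates:
    """Decompose hybrid cell means into mu + GCA(line) + GCA(tester) + SCA.

    Balanced estimators on the cell-mean grid:
    ``gca_line[k] = mean_k - grand``, ``gca_tester[l] = mean_l - grand``,
    ``sca[k,l] = cell - mean_k - mean_l + grand``.  The grand mean and
    tester margins are computed over lines with a complete tester set so
    partially crossed lines do not bias the basis.
    """
    if len(design.tester_ids) < 2 or len(design.line_ids) < 2:
        raise ValueError("need >= 2 lines and >= 2 testers")
    cells = _hybrid_cell_means(hybrid_pheno, design, trait)
    complete = cells.dropna(how="any")
    if complete.empty:
        raise ValueError("no line has data for every tester")
    dropped = len(cells) - len(complete)
    if dropped:
        log.warning("%d lines lack complete tester data; GCA reported missing", dropped)
    mu = float(complete.to_numpy().mean())
    gca_tester = complete.mean(axis=0) - mu
    # complete lines: plain margin; partial lines: tester-adjusted margin
    gca_line = (complete.mean(axis=1) - mu).reindex(cells.index)
    partial = cells.index[cells.notna().any(axis=1) & cells.isna().any(axis=1)]
    for k in partial:
        avail = cells.loc[k].dropna()
        gca_line.loc[k] = float((avail - mu - gca_tester[avail.index]).mean())
    sca = cells.sub(gca_line, axis=0).sub(gca_tester, axis=1) - mu
    return GCAEstimates(mu=mu, gca_line=gca_line, gca_tester=gca_tester, sca=sca)


@dataclass
class TestcrossVarianceTable:
    """Mean squares for every source of the joint testcross model plus
    moment estimates of the GCA/SCA variance components.

    ``ratio`` is sigma2_gca(line) / sigma2_sca.  When the SCA component
    truncates to zero the ratio is undefined: ``ratio`` is NaN and
    ``ratio_flag`` distinguishes ``'sca_zero'`` (GCA present, ratio
    unbounded) from ``'undefined'`` (no genetic variance at all).
    """

    mean_squares: pd.DataFrame
    sigma2_gca_line: float
    sigma2_gca_tester: float
    sigma2_sca: float
    sigma2_line_env: float
    sigma2_sca_env: float
    sigma2_error: float
    ratio: float
    ratio_flag: str
    h2_testcross: float
    n_lines: int
    n_testers: int
    n_envs: int
    n_reps: int


def ncii_anova(hybrid_pheno: pd.DataFrame, design: NCIIDesign, trait: str) -> TestcrossVarianceTable:
    """Combined testcross ANOVA and GCA/SCA variance components.

    Mean squares are reported for the full source list (location, year,
    blocks, line GCA, tester GCA, SCA and all their environment
    interactions).  Component estimation collapses location x year into
    E environments and solves the balanced random-model EMS:

        s2_sca       = (MS_sca  - MS_sca.env) / (E R)
        s2_gca_line  = (MS_line - MS_line.env - MS_sca + MS_sca.env) / (T E R)
        s2_gca_tester symmetric with K in place of T.

    Testcross heritability applies the plot-mean formula to the
    hybrid-side components (GCA variance over its entry-mean error).
    """
    if len(design.tester_ids) < 2:
        raise ValueError("SCA not estimable with a single tester")
    df = _trait_slice(hybrid_pheno, trait).copy()
    parents = design.hybrid_parents().set_index("hybrid")
    df["line"] = df["entry"].map(parents["line"])
    df["tester"] = df["entry"].map(parents["tester"])
    df = df.dropna(subset=["line", "tester"])
    # restrict to lines with both testers so the factorial stays balanced
    complete = set(design.complete_lines())
    df = df[df["line"].isin(complete)]
    df["env"] = df["location"].astype(str) + ":" + df["year"].astype(str)

    K = df["line"].nunique()
    T = df["tester"].nunique()
    E = df["env"].nunique()
    R = df["rep"].nunique()

    table = balanced_anova(df, "value", ["line", "tester", "location", "year", "rep"])

    def agg(pred) -> tuple:
        ss = dof = 0.0
        for _, row in table.iterrows():
            if pred(set(row["subset"])):
                ss += row["ss"]
                dof += row["df"]
        return (ss / dof if dof > 0 else float("nan"), dof)

    env_factors = {"location", "year"}
    ms_line = float(table.loc["line", "ms"]) if "line" in table.index else float("nan")
    ms_tester = float(table.loc["tester", "ms"]) if "tester" in table.index else float("nan")
    ms_sca = float(table.loc["line+tester", "ms"]) if "line+tester" in table.index else float("nan")
    ms_line_env, _ = agg(lambda s: "line" in s and "tester" not in s and "rep" not in s and s & env_factors)
    ms_tester_env, _ = agg(lambda s: "tester" in s and "line" not in s and "rep" not in s and s & env_factors)
    ms_sca_env, _ = agg(lambda s: {"line", "tester"} <= s and "rep" not in s and s & env_factors)
    ms_error, err_df = agg(lambda s: "rep" in s and ({"line", "tester"} & s))
    ms_block, _ = agg(lambda s: "rep" in s and not ({"line", "tester"} & s))

    def trunc(x: float) -> float:
        return max(0.0, x) if math.isfinite(x) else 0.0

    have_env = E > 1
    s2_sca_env = trunc((ms_sca_env - ms_error) / R) if have_env else 0.0
    base = ms_sca_env if have_env else ms_error
    s2_sca = trunc((ms_sca - base) / (E * R))
    line_base = ms_line_env if have_env else ms_error
    s2_line_env = trunc((line_base - (ms_sca_env if have_env else ms_error)) / (T * R)) if have_env else 0.0
    s2_gca_line = trunc((ms_line - (line_base + ms_sca - base)) / (T * E * R))
    tester_base = ms_tester_env if have_env else ms_error
    s2_gca_tester = trunc((ms_tester - (tester_base + ms_sca - base)) / (K * E * R))
    s2_error = trunc(ms_error)

    if s2_sca > 0:
        ratio = s2_gca_line / s2_sca
        flag = "ok"
    elif s2_gca_line > 0:
        ratio, flag = float("nan"), "sca_zero"
    else:
        ratio, flag = float("nan"), "undefined"

    denom = (
        s2_gca_line
        + s2_sca / T
        + s2_line_env / E
        + s2_sca_env / (E * T)
        + s2_error / (E * T * R)
    )
    h2_tc = s2_gca_line / denom if denom > 0 else float("nan")

    # human-readable source table
    pretty = {
        "location": "L", "year": "Y", "location+year": "LxY",
        "line": "GCA(line)", "tester": "GCA(tester)", "line+tester": "SCA",
    }
    ms_rows = []
    for src, row in table.iterrows():
        name = pretty.get(src, src.replace("line", "GCA(line)").replace("tester", "GCA(tester)"))
        ms_rows.append((name, row["df"], row["ss"], row["ms"]))
    squares = pd.DataFrame(ms_rows, columns=["source", "df", "ss", "ms"]).set_index("source")

    return TestcrossVarianceTable(
        mean_squares=squares,
        sigma2_gca_line=s2_gca_line,
        sigma2_gca_tester=s2_gca_tester,
        sigma2_sca=s2_sca,
        sigma2_line_env=s2_line_env,
        sigma2_sca_env=s2_sca_env,
        sigma2_error=s2_error,
        ratio=ratio,
        ratio_flag=flag,
        h2_testcross=h2_tc,
        n_lines=K,
        n_testers=T,
        n_envs=E,
        n_reps=R,
    )


def gca_phenotype_vector(
    hybrid_pheno: pd.DataFrame, design: NCIIDesign, trait: str
) -> pd.DataFrame:
    """Per-line GCA responses for QTL scans: one column per environment
    plus a ``joint`` column from environment-adjusted hybrid means.

    Each column is the line margin of the hybrid values (pooled over
    testers), centered over the lines present, so it carries the same
    sign convention as the GCA effects themselves.
    """
    df = _trait_slice(hybrid_pheno, trait).copy()
    parents = design.hybrid_parents().set_index("hybrid")
    df["line"] = df["entry"].map(parents["line"])
    df = df.dropna(subset=["line"])
    df["env"] = df["location"].astype(str) + ":" + df["year"].astype(str)

    cols = {}
    for env, sub in df.groupby("env"):
        m = sub.groupby("line", observed=True)["value"].mean()
        cols[env] = m - m.mean()
    est = estimate_combining_ability(hybrid_pheno, design, trait)
    cols["joint"] = est.gca_line.dropna()
    out = pd.DataFrame(cols)
    out.index.name = "line"
    return out
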