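"""Synthetic RIL x tester data with known generative truth.

Everything downstream (BLUEs, combining-ability estimation, QTL scans,
co-localization) is exercised against data produced here, so the
generator returns its own ground truth (per-line combining-ability
values, genetic variances, QTL positions) alongside the phenotypes.

Defaults mirror a maize RIL testcross study layout: 328 lines crossed to
2 testers, evaluated at 2 locations x 2 years with 2 replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genmap import (
    CODE_HET,
    CODE_P1,
    CODE_P2,
    GeneticMap,
    GenotypeMatrix,
    haldane_to_r,
    ril_recomb,
)

__all__ = [
    "NCIIDesign",
    "QTLEffect",
    "TraitArchitecture",
    "EnvSpec",
    "SimulatedPhenotypes",
    "build_ncii_design",
    "make_genetic_map",
    "paper_like_map",
    "simulate_ril_genomes",
    "simulate_phenotypes",
    "residual_sd_for_h2",
    "DEFAULT_N_LINES",
    "DEFAULT_TESTERS",
]

DEFAULT_N_LINES = 328
DEFAULT_TESTERS = ("T1", "T2")


class DesignError(ValueError):
    """Raised for invalid crossing-design inputs."""


@dataclass
class NCIIDesign:
    """Factorial crossing table of male lines x testers.

    ``hybrid_table`` maps each completed (line, tester) pair to its hybrid
    identifier; failed crosses are simply absent.
    """

    line_ids: list
    tester_ids: list
    hybrid_table: dict  # (line, tester) -> hybrid id
    failed_crosses: set = field(default_factory=set)

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrid_table)

    @property
    def hybrid_ids(self) -> list:
        return list(self.hybrid_table.values())

    def parents_of(self, hybrid_id) -> tuple:
        for pair, h in self.hybrid_table.items():
            if h == hybrid_id:
                return pair
        raise DesignError(f"unknown hybrid id {hybrid_id!r}")

    def hybrid_parents(self) -> pd.DataFrame:
        """Long table (hybrid, line, tester)."""
        rows = [(h, k, t) for (k, t), h in self.hybrid_table.items()]
        return pd.DataFrame(rows, columns=["hybrid", "line", "tester"])

    def complete_lines(self) -> list:
        """Lines successfully crossed to every tester."""
        return [
            k
            for k in self.line_ids
            if all((k, t) in self.hybrid_table for t in self.tester_ids)
        ]


def build_ncii_design(line_ids, tester_ids, failed_crosses=()) -> NCIIDesign:
    """Enumerate all non-failed line x tester crosses, lines major.

    Hybrid ids are ``<line>/<tester>``.  Duplicate line or tester ids are
    a validation error; so is a failed cross naming unknown parents.
    """
    line_ids = list(line_ids)
    tester_ids = list(tester_ids)
    if len(set(line_ids)) != len(line_ids):
        raise DesignError("duplicate line ids in design")
    if len(set(tester_ids)) != len(tester_ids):
        raise DesignError("duplicate tester ids in design")
    failed = {tuple(fc) for fc in failed_crosses}
    universe = {(k, t) for k in line_ids for t in tester_ids}
    if not failed <= universe:
        raise DesignError(f"failed crosses outside the design: {sorted(failed - universe)}")
    table = {
        (k, t): f"{k}/{t}"
        for k in line_ids
        for t in tester_ids
        if (k, t) not in failed
    }
    return NCIIDesign(line_ids, tester_ids, table, failed)


# ---------------------------------------------------------------------------
# maps

def make_genetic_map(
    n_chromosomes: int = 10,
    markers_per_chrom: int = 30,
    chrom_length_cm: float = 150.0,
    mb_per_cm: float = 1.0,
    wobble: float = 0.3,
) -> GeneticMap:
    """Evenly spaced markers with a smooth, strictly monotone cM->Mb warp.

    The warp keeps dMb/dcM within ``1 +/- wobble`` so physical intervals
    are distorted (exercising Mb-based co-localization rules) but never
    fold back.
    """
    ids, chroms, cms, mbs = [], [], [], []
    for c in range(1, n_chromosomes + 1):
        cm = np.linspace(0.0, chrom_length_cm, markers_per_chrom)
        L = max(chrom_length_cm, 1e-9)
        # antiderivative of 1 + wobble*sin(2*pi*cm/L): strictly increasing
        mb = 1.0 + mb_per_cm * (cm + wobble * L / (2 * np.pi) * (1 - np.cos(2 * np.pi * cm / L)))
        ids.extend(f"c{c}m{j+1}" for j in range(markers_per_chrom))
        chroms.extend([c] * markers_per_chrom)
        cms.extend(cm)
        mbs.extend(mb)
    return GeneticMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                      np.array(cms), np.array(mbs))


def paper_like_map(total_cm: float = 1533.72, n_markers: int = 4602,
                   n_chromosomes: int = 10) -> GeneticMap:
    """A 10-chromosome map with the printed genome totals: markers spread
    evenly, chromosome lengths equal up to rounding of marker counts."""
    base = n_markers // n_chromosomes
    counts = [base + (1 if c < n_markers % n_chromosomes else 0) for c in range(n_chromosomes)]
    length = total_cm / n_chromosomes
    ids, chroms, cms, mbs = [], [], [], []
    for c, cnt in enumerate(counts, start=1):
        cm = np.linspace(0.0, length, cnt)
        mb = 1.0 + cm  # ~1 Mb per cM
        ids.extend(f"c{c}m{j+1}" for j in range(cnt))
        chroms.extend([c] * cnt)
        cms.extend(cm)
        mbs.extend(mb)
    return GeneticMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                      np.array(cms), np.array(mbs))


# ---------------------------------------------------------------------------
# RIL genome simulation

def _slice_segments(breaks, labels, a, b):
    """Sub-segments of a piecewise-constant homolog on the open span (a, b)."""
    i = np.searchsorted(breaks, a, side="right")
    j = np.searchsorted(breaks, b, side="left")
    return list(breaks[i:j]), list(labels[i : j + 1])


def _gamete(h1, h2, length_cm, rng):
    """One meiotic product: Poisson crossovers (Haldane, no interference)
    at rate length/100 Morgans, alternating between the two homologs."""
    n_x = rng.poisson(length_cm / 100.0)
    start = int(rng.integers(2))
    homs = (h1, h2)
    if n_x == 0:
        br, lab = homs[start]
        return (list(br), list(lab))
    cuts = np.sort(rng.uniform(0.0, length_cm, n_x))
    breaks, labels = [], []
    cur = start
    left = 0.0
    bounds = list(cuts) + [length_cm]
    for right in bounds:
        hbr, hlab = homs[cur]
        sb, sl = _slice_segments(np.asarray(hbr), np.asarray(hlab, dtype=object), left, right)
        if labels and sl and labels[-1] == sl[0]:
            breaks.extend(sb)
            labels.extend(sl[1:])
        else:
            if labels:
                breaks.append(left)
            breaks.extend(sb)
            labels.extend(sl)
        cur = 1 - cur
        left = right
    return (breaks, labels)


def _eval_segments(breaks, labels, positions):
    idx = np.searchsorted(np.asarray(breaks), positions, side="right")
    lab = np.asarray(labels, dtype=np.int8)
    return lab[idx]


def simulate_ril_genomes(
    gmap: GeneticMap,
    n_lines: int,
    generations: int = 11,
    seed=None,
    method: str = "meiosis",
) -> GenotypeMatrix:
    """Simulate RIL genotypes by single-seed descent from a biparental F1.

    ``generations`` is the filial generation number: F2 arises from the
    first selfing, so F_g means ``g - 1`` rounds of selfing and an
    expected residual heterozygosity of ``(1/2)**(g-1)`` per locus.

    ``method='meiosis'`` runs explicit per-generation meioses (Poisson
    crossovers under the Haldane model, no interference).  The
    ``'markov'`` shortcut draws fully inbred genotypes from the marginal
    RIL Markov chain with switch probabilities ``2r/(1+2r)`` between
    adjacent markers — orders of magnitude faster, with no residual
    heterozygosity; use it where only the marginal structure matters.
    """
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if generations < 2:
        raise ValueError("need at least generation F2 (one selfing)")
    rng = np.random.default_rng(seed)
    if method == "markov":
        return _simulate_markov(gmap, n_lines, rng)
    if method != "meiosis":
        raise ValueError(f"unknown method {method!r}")

    chrom_info = []
    for chromosome in gmap.chromosomes:
        idx = gmap.chrom_indices(chromosome)
        cm = gmap.cm[idx] - gmap.cm[idx][0]
        chrom_info.append((idx, cm, float(cm[-1]) if len(cm) > 1 else 0.0))

    codes = np.empty((n_lines, gmap.n_markers), dtype=np.int8)
    for li in range(n_lines):
        for idx, cm, length in chrom_info:
            hA = ([], [CODE_P1])  # breaks, labels over [0, length]
            hB = ([], [CODE_P2])
            for _ in range(generations - 1):
                g1 = _gamete(hA, hB, length, rng)
                g2 = _gamete(hA, hB, length, rng)
                hA, hB = g1, g2
            a = _eval_segments(hA[0], hA[1], cm)
            b = _eval_segments(hB[0], hB[1], cm)
            out = np.where(a == b, a, CODE_HET)
            codes[li, idx] = out
    line_ids = np.array([f"L{i+1:04d}" for i in range(n_lines)], dtype=object)
    return GenotypeMatrix(line_ids, gmap.marker_ids, codes)


def _simulate_markov(gmap: GeneticMap, n_lines: int, rng) -> GenotypeMatrix:
    codes = np.empty((n_lines, gmap.n_markers), dtype=np.int8)
    for chromosome in gmap.chromosomes:
        idx = gmap.chrom_indices(chromosome)
        cm = gmap.cm[idx]
        switch = ril_recomb(haldane_to_r(np.diff(cm)))
        state = rng.integers(0, 2, size=n_lines)
        cols = np.empty((n_lines, len(idx)), dtype=np.int8)
        cols[:, 0] = state
        for j, s in enumerate(switch, start=1):
            flip = rng.random(n_lines) < s
            state = np.where(flip, 1 - state, state)
            cols[:, j] = state
        codes[:, idx] = np.where(cols == 1, CODE_P2, CODE_P1)
    line_ids = np.array([f"L{i+1:04d}" for i in range(n_lines)], dtype=object)
    return GenotypeMatrix(line_ids, gmap.marker_ids, codes)


# ---------------------------------------------------------------------------
# phenotype simulation

@dataclass
class QTLEffect:
    """One causal locus: additive effect for the line per se trait and a
    per-tester additive effect for hybrid performance.

    Effects follow the signed-dosage convention: a line homozygous for
    the male-parent (P2) allele deviates by ``+a`` and a P1 homozygote by
    ``-a``, so the homozygote contrast is ``2a``.
    """

    chrom: object
    pos_cm: float
    add_perse: float = 0.0
    add_tester: dict = field(default_factory=dict)  # tester id -> effect

    def tester_effect(self, tester) -> float:
        return float(self.add_tester.get(tester, 0.0))


@dataclass
class TraitArchitecture:
    """Generative model for one trait: intercepts, QTL and variance terms.

    All standard deviations are on the trait scale and must be
    non-negative.  ``sca_sd`` injects a line x tester interaction drawn
    once per hybrid (a pure specific-combining-ability term);
    ``gxe_sd`` is the SD of each genotype x environment interaction
    stratum (G x L, G x Y and G x L x Y each get this SD unless the
    specific fields are set).
    """

    trait: str
    mean: float = 0.0
    hybrid_mean: float | None = None  # defaults to `mean`
    tester_effects: dict = field(default_factory=dict)
    qtl: list = field(default_factory=list)
    env_sd: float = 0.0
    gxe_sd: float = 0.0
    gxl_sd: float | None = None
    gxy_sd: float | None = None
    gxly_sd: float | None = None
    block_sd: float = 0.0
    sca_sd: float = 0.0
    resid_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("env_sd", "gxe_sd", "block_sd", "sca_sd", "resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gxl_sd", "gxy_sd", "gxly_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def sd_gl(self) -> float:
        return self.gxe_sd if self.gxl_sd is None else self.gxl_sd

    @property
    def sd_gy(self) -> float:
        return self.gxe_sd if self.gxy_sd is None else self.gxy_sd

    @property
    def sd_gly(self) -> float:
        return self.gxe_sd if self.gxly_sd is None else self.gxly_sd


@dataclass
class EnvSpec:
    """Trial layout: locations x years, with replicates nested in each
    location-year environment."""

    locations: list = field(default_factory=lambda: ["loc1", "loc2"])
    years: list = field(default_factory=lambda: ["y1", "y2"])
    reps_per_env: int = 2

    def __post_init__(self) -> None:
        if not self.locations or not self.years or self.reps_per_env < 1:
            raise ValueError("need >= 1 location, year and replicate")

    @property
    def n_envs(self) -> int:
        return len(self.locations) * len(self.years)


@dataclass
class SimulatedPhenotypes:
    """Phenotype records plus the generative truth used to score recovery."""

    phenotypes: pd.DataFrame  # entry, population, location, year, rep, trait, value
    true_gca: pd.DataFrame    # line x trait, centered over lines
    true_genetic_perse: pd.DataFrame  # line x trait genetic values
    truth: dict               # variance components, per-trait H2, QTL specs

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2, default=str)


def _qtl_signed_dosage(genotypes: GenotypeMatrix, gmap: GeneticMap, q: QTLEffect) -> np.ndarray:
    """Signed dosage in {-1, 0, +1} at the marker nearest the QTL position."""
    idx = gmap.chrom_indices(q.chrom)
    if len(idx) == 0:
        raise ValueError(f"QTL chromosome {q.chrom!r} absent from map")
    cm = gmap.cm[idx]
    if not (cm[0] <= q.pos_cm <= cm[-1]):
        raise ValueError(f"QTL position {q.pos_cm} cM off the map on chromosome {q.chrom}")
    j = idx[int(np.argmin(np.abs(cm - q.pos_cm)))]
    col = genotypes.codes[:, j].astype(float)
    s = np.where(col == CODE_P2, 1.0, np.where(col == CODE_P1, -1.0, 0.0))
    return s


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    architectures,
    design: NCIIDesign,
    env_spec: EnvSpec,
    seed=None,
) -> SimulatedPhenotypes:
    """Draw per se (RIL) and hybrid phenotype records for every replicate.

    Per se record:  mu + sum_q a_q s_q + env + GxL + GxY + GxLxY + block + e.
    Hybrid record:  mu_H + tester + sum_q a_q^(t) s_q + sca + (same env
    strata, drawn independently per hybrid entry) + e.

    Environment and block effects are drawn once per (location, year) and
    per replicate-within-environment and shared between the RIL and
    hybrid trials (they are grown in the same fields).  True per-line
    combining ability is the tester-average of the hybrid genetic values,
    centered over lines, and is returned as ground truth.
    """
    if isinstance(architectures, TraitArchitecture):
        architectures = [architectures]
    rng = np.random.default_rng(seed)
    lines = list(genotypes.line_ids)
    envs = [(loc, yr) for loc in env_spec.locations for yr in env_spec.years]
    reps = list(range(1, env_spec.reps_per_env + 1))
    tester_pop = _population_tags(design.tester_ids)

    records = []
    gca_cols, perse_cols = {}, {}
    truth = {"traits": {}, "design": {
        "n_lines": len(lines),
        "testers": list(design.tester_ids),
        "locations": list(env_spec.locations),
        "years": list(env_spec.years),
        "reps_per_env": env_spec.reps_per_env,
    }}

    for arch in architectures:
        dosages = [_qtl_signed_dosage(genotypes, gmap, q) for q in arch.qtl]
        g_perse = np.zeros(len(lines))
        for q, s in zip(arch.qtl, dosages):
            g_perse += q.add_perse * s
        # hybrid genetic value per (line, tester)
        g_hyb = {}
        for t in design.tester_ids:
            gt = np.zeros(len(lines))
            for q, s in zip(arch.qtl, dosages):
                gt += q.tester_effect(t) * s
            g_hyb[t] = gt
        gca_raw = np.mean([g_hyb[t] for t in design.tester_ids], axis=0)
        true_gca = gca_raw - gca_raw.mean()
        gca_cols[arch.trait] = true_gca
        perse_cols[arch.trait] = g_perse

        env_eff = {e: rng.normal(0.0, arch.env_sd) for e in envs}
        block_eff = {
            (e, r): rng.normal(0.0, arch.block_sd) for e in envs for r in reps
        }
        hyb_mean = arch.mean if arch.hybrid_mean is None else arch.hybrid_mean

        # --- RIL per se records
        gxl = {(i, loc): rng.normal(0.0, arch.sd_gl) for i in range(len(lines)) for loc in env_spec.locations}
        gxy = {(i, yr): rng.normal(0.0, arch.sd_gy) for i in range(len(lines)) for yr in env_spec.years}
        gxly = {(i, e): rng.normal(0.0, arch.sd_gly) for i in range(len(lines)) for e in envs}
        for e in envs:
            loc, yr = e
            for r in reps:
                noise = rng.normal(0.0, arch.resid_sd, len(lines))
                vals = (
                    arch.mean
                    + g_perse
                    + env_eff[e]
                    + np.array([gxl[(i, loc)] + gxy[(i, yr)] + gxly[(i, e)] for i in range(len(lines))])
                    + block_eff[(e, r)]
                    + noise
                )
                for i, line in enumerate(lines):
                    records.append((line, "RIL", loc, yr, r, arch.trait, vals[i]))

        # --- hybrid records
        line_pos = {line: i for i, line in enumerate(lines)}
        hybrids = [(k, t, h) for (k, t), h in design.hybrid_table.items() if k in line_pos]
        sca_eff = {h: rng.normal(0.0, arch.sca_sd) for (_, _, h) in hybrids}
        hxl = {(h, loc): rng.normal(0.0, arch.sd_gl) for (_, _, h) in hybrids for loc in env_spec.locations}
        hxy = {(h, yr): rng.normal(0.0, arch.sd_gy) for (_, _, h) in hybrids for yr in env_spec.years}
        hxly = {(h, e): rng.normal(0.0, arch.sd_gly) for (_, _, h) in hybrids for e in envs}
        for e in envs:
            loc, yr = e
            for r in reps:
                noise = rng.normal(0.0, arch.resid_sd, len(hybrids))
                for j, (k, t, h) in enumerate(hybrids):
                    val = (
                        hyb_mean
                        + float(arch.tester_effects.get(t, 0.0))
                        + g_hyb[t][line_pos[k]]
                        + sca_eff[h]
                        + env_eff[e]
                        + hxl[(h, loc)] + hxy[(h, yr)] + hxly[(h, e)]
                        + block_eff[(e, r)]
                        + noise[j]
                    )
                    records.append((h, tester_pop[t], loc, yr, r, arch.trait, val))

        L, Y, R = len(env_spec.locations), len(env_spec.years), env_spec.reps_per_env
        var_g = float(np.var(g_perse))
        denom = (
            var_g
            + arch.sd_gl**2 / L
            + arch.sd_gy**2 / Y
            + arch.sd_gly**2 / (L * Y)
            + arch.resid_sd**2 / (L * Y * R)
        )
        truth["traits"][arch.trait] = {
            "mean": arch.mean,
            "qtl": [
                {"chrom": q.chrom, "pos_cm": q.pos_cm, "add_perse": q.add_perse,
                 "add_tester": dict(q.add_tester)}
                for q in arch.qtl
            ],
            "var_genetic_perse": var_g,
            "var_gca": float(np.var(true_gca)),
            "h2_perse": var_g / denom if denom > 0 else float("nan"),
            "sd": {"env": arch.env_sd, "gxl": arch.sd_gl, "gxy": arch.sd_gy,
                   "gxly": arch.sd_gly, "block": arch.block_sd,
                   "sca": arch.sca_sd, "resid": arch.resid_sd},
        }

    pheno = pd.DataFrame(
        records, columns=["entry", "population", "location", "year", "rep", "trait", "value"]
    )
    idx = pd.Index(lines, name="line")
    return SimulatedPhenotypes(
        phenotypes=pheno,
        true_gca=pd.DataFrame(gca_cols, index=idx),
        true_genetic_perse=pd.DataFrame(perse_cols, index=idx),
        truth=truth,
    )


def _population_tags(tester_ids) -> dict:
    """Population tag per tester: TC/TM for the canonical 2-tester design."""
    if len(tester_ids) == 2:
        return {tester_ids[0]: "TC", tester_ids[1]: "TM"}
    return {t: f"T{i+1}" for i, t in enumerate(tester_ids)}


def residual_sd_for_h2(
    genetic_var: float,
    h2: float,
    env_spec: EnvSpec,
    gxl_sd: float = 0.0,
    gxy_sd: float = 0.0,
    gxly_sd: float = 0.0,
) -> float:
    """Residual SD that yields a target entry-mean heritability
    ``h2 = V_G / (V_G + V_GL/L + V_GY/Y + V_GLY/LY + V_E/LYR)`` given the
    genetic variance and interaction SDs."""
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    L, Y, R = len(env_spec.locations), len(env_spec.years), env_spec.reps_per_env
    interaction = gxl_sd**2 / L + gxy_sd**2 / Y + gxly_sd**2 / (L * Y)
    var_e = (genetic_var / h2 - genetic_var - interaction) * (L * Y * R)
    if var_e < 0:
        raise ValueError("target h2 unreachable with these interaction variances")
    return float(np.sqrt(var_e))
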