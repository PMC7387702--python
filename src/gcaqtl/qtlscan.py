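"""Interval-mapping scans of per-line responses with permutation
thresholds, composite-interval covariates, support intervals, PVE and
signed additive effects.

Scans use Haley-Knott regression on expected P2 dosage: at each
evaluation position the response is regressed on the dosage (plus any
covariates) and LOD = (n/2) log10(RSS0 / RSS1) where RSS0 is the
covariate-only fit.  For homozygous RILs on dense maps this is
numerically indistinguishable from full-likelihood interval mapping and
is exactly checkable against a per-marker OLS oracle.

Sign convention: a positive additive effect means the male-parent (P2)
allele increases the trait; the reported effect is half the homozygote
contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genmap import GeneticMap, GenotypeMatrix, GenotypeProbabilities

log = logging.getLogger(__name__)

__all__ = [
    "ScanResult",
    "QTLRecord",
    "LOD_CAP",
    "scan_hk",
    "select_cofactors",
    "cim_scan",
    "permutation_threshold",
    "support_interval",
    "fit_qtl_model",
    "additive_effect",
    "call_qtl",
]

#: LOD ceiling for degenerate zero-residual fits (keeps peaks ordered, no inf)
LOD_CAP = 50.0
_EPS = 1e-300


@dataclass
class ScanResult:
    """LOD and additive-effect profiles over the evaluation grid."""

    positions: pd.DataFrame  # chrom, cm, mb, marker
    lod: np.ndarray
    additive: np.ndarray
    trait: str = ""
    dataset: str = ""
    n: int = 0
    covariates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.lod) != len(self.positions) or len(self.additive) != len(self.positions):
            raise ValueError("profile length does not match positions")

    def to_frame(self) -> pd.DataFrame:
        out = self.positions.copy()
        out["lod"] = self.lod
        out["add"] = self.additive
        return out


@dataclass
class QTLRecord:
    """One detected QTL in both coordinate systems, Table-style fields."""

    trait: str
    dataset: str
    name: str
    chrom: object
    peak_cm: float
    peak_mb: float
    lo_cm: float
    hi_cm: float
    lo_mb: float
    hi_mb: float
    lod: float
    pve: float
    additive: float

    def __post_init__(self) -> None:
        if not (self.lo_cm <= self.peak_cm <= self.hi_cm):
            raise ValueError("support interval does not contain the peak")


def _as_vector(y, line_ids) -> np.ndarray:
    if isinstance(y, pd.Series):
        y = y.reindex(line_ids)
        if y.isna().any():
            raise ValueError("response missing for some lines in the probability grid")
        return y.to_numpy(float)
    arr = np.asarray(y, dtype=float)
    if len(arr) != len(line_ids):
        raise ValueError("response length does not match the line set")
    return arr


def _covariate_matrix(covariates, n) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match the line set")
    return np.hstack([np.ones((n, 1)), C])


def _residualize(C: np.ndarray, *mats):
    """Residuals of each matrix after projecting out columns of C."""
    Q, _ = np.linalg.qr(C)
    return tuple(m - Q @ (Q.T @ m) for m in mats)


def scan_hk(
    probs: GenotypeProbabilities,
    y,
    covariates=None,
    subset: np.ndarray | None = None,
) -> ScanResult:
    """Single-pass regression scan over every evaluation position.

    ``subset`` restricts the scan to a boolean/index subset of positions
    (used internally by the composite scan).  A constant response yields
    an all-zero LOD profile with a warning; zero-residual fits are capped
    at :data:`LOD_CAP`.
    """
    yv = _as_vector(y, probs.line_ids)
    n = len(yv)
    X = probs.p2 if subset is None else probs.p2[:, subset]
    C = _covariate_matrix(covariates, n)
    ry, RX = _residualize(C, yv[:, None], X)
    ry = ry[:, 0]
    rss0 = float(ry @ ry)
    pos = probs.positions if subset is None else probs.positions.iloc[subset]

    if np.std(yv) == 0 or rss0 <= _EPS:
        warnings.warn("response has no residual variance; LOD set to zero")
        z = np.zeros(X.shape[1])
        return ScanResult(pos.reset_index(drop=True), z, z.copy(), n=n)

    var = np.einsum("ij,ij->j", RX, RX)
    cov = RX.T @ ry
    ok = var > 1e-12
    slope = np.zeros_like(var)
    slope[ok] = cov[ok] / var[ok]
    rss1 = rss0 - np.where(ok, cov * slope, 0.0)
    rss1 = np.maximum(rss1, 0.0)
    with np.errstate(divide="ignore"):
        lod = (n / 2.0) * (np.log10(rss0) - np.log10(np.maximum(rss1, _EPS)))
    lod = np.minimum(np.maximum(lod, 0.0), LOD_CAP)
    return ScanResult(pos.reset_index(drop=True), lod, slope / 2.0, n=n)


def select_cofactors(
    genotypes: GenotypeMatrix, y, n_cofactors: int, gmap: GeneticMap | None = None
) -> list:
    """Forward stepwise marker selection by residual sum of squares.

    Returns up to ``n_cofactors`` marker ids in selection order; ties are
    broken toward the lowest marker index.  Missing genotypes are imputed
    at the marker mean dosage for selection purposes only.
    """
    if n_cofactors < 0:
        raise ValueError("n_cofactors must be >= 0")
    if n_cofactors == 0:
        return []
    D = genotypes.dosage()
    col_mean = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    D = np.where(nan_mask, np.broadcast_to(col_mean, D.shape), D)
    yv = _as_vector(y, genotypes.line_ids)
    n, m = D.shape
    if n_cofactors > m:
        warnings.warn(f"n_cofactors={n_cofactors} exceeds {m} markers; capped")
        n_cofactors = m

    # orthogonalize progressively against the chosen columns + intercept
    ry = yv - yv.mean()
    RX = D - D.mean(axis=0)
    chosen: list = []
    for _ in range(n_cofactors):
        var = np.einsum("ij,ij->j", RX, RX)
        cov = RX.T @ ry
        gain = np.where(var > 1e-12, cov**2 / np.maximum(var, 1e-12), 0.0)
        gain[[genotypes.marker_ids.tolist().index(c) for c in chosen]] = -1.0
        best = int(np.argmax(gain))  # argmax takes the first (lowest index) tie
        if gain[best] <= 0:
            break
        chosen.append(genotypes.marker_ids[best])
        u = RX[:, best].copy()
        norm = u @ u
        if norm <= 1e-12:
            break
        u /= np.sqrt(norm)
        ry = ry - u * (u @ ry)
        RX = RX - np.outer(u, u @ RX)
    return chosen


def cim_scan(
    probs: GenotypeProbabilities,
    y,
    cofactors: list,
    window_cm: float = 10.0,
    genotypes: GenotypeMatrix | None = None,
) -> ScanResult:
    """Composite scan: cofactor markers enter as covariates except within
    ``window_cm`` of the test position on its own chromosome.

    With an empty cofactor list this is exactly :func:`scan_hk`.
    Cofactor dosages are taken from the probability grid at the cofactor
    markers.
    """
    if not cofactors:
        return scan_hk(probs, y)
    cof_cols = [probs.marker_column(c) for c in cofactors]
    cof_chrom = [probs.positions["chrom"].iloc[j] for j in cof_cols]
    cof_cm = [float(probs.positions["cm"].iloc[j]) for j in cof_cols]
    cof_dos = probs.p2[:, cof_cols]

    chroms = probs.positions["chrom"].to_numpy()
    cms = probs.positions["cm"].to_numpy(float)
    n_pos = len(chroms)
    # bitmask of excluded cofactors per position -> group identical masks
    masks = np.zeros(n_pos, dtype=np.int64)
    for k, (cc, ccm) in enumerate(zip(cof_chrom, cof_cm)):
        hit = (chroms == cc) & (np.abs(cms - ccm) < window_cm)
        masks[hit] |= 1 << k

    lod = np.empty(n_pos)
    add = np.empty(n_pos)
    n = 0
    for mask in np.unique(masks):
        subset = np.flatnonzero(masks == mask)
        keep = [k for k in range(len(cofactors)) if not (mask >> k) & 1]
        C = cof_dos[:, keep] if keep else None
        part = scan_hk(probs, y, covariates=C, subset=subset)
        lod[subset] = part.lod
        add[subset] = part.additive
        n = part.n
    return ScanResult(probs.positions.copy(), lod, add, n=n, covariates=list(cofactors))


def permutation_threshold(
    probs: GenotypeProbabilities,
    y,
    covariates=None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """Empirical genome-wide LOD threshold from response permutations.

    The response is shuffled over lines ``n_perm`` times; the
    ``1 - alpha`` quantile of the per-permutation maximum LOD is returned
    (linear/type-7 interpolation).  Covariates, when given, stay fixed
    and permuted responses are re-residualized against them.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives an unstable threshold")
    rng = np.random.default_rng(seed)
    yv = _as_vector(y, probs.line_ids)
    n = len(yv)
    C = _covariate_matrix(covariates, n)
    Yp = np.empty((n, n_perm))
    for j in range(n_perm):
        Yp[:, j] = yv[rng.permutation(n)]
    RY, RX = _residualize(C, Yp, probs.p2)
    var = np.einsum("ij,ij->j", RX, RX)
    ok = var > 1e-12
    RXn = np.zeros_like(RX)
    RXn[:, ok] = RX[:, ok] / np.sqrt(var[ok])
    rss0 = np.einsum("ij,ij->j", RY, RY)
    max_lod = np.empty(n_perm)
    chunk = max(1, int(2e7 // max(RX.shape[1], 1)))
    for start in range(0, n_perm, chunk):
        sl = slice(start, min(start + chunk, n_perm))
        cov = RXn.T @ RY[:, sl]  # m x chunk
        r2 = cov**2 / np.maximum(rss0[sl][None, :], _EPS)
        r2max = r2.max(axis=0)
        max_lod[sl] = np.minimum(
            -(n / 2.0) * np.log10(np.maximum(1.0 - r2max, _EPS)), LOD_CAP
        )
    return float(np.quantile(max_lod, 1.0 - alpha, method="linear"))


def support_interval(scan: ScanResult, peak_index: int, drop: float = 1.5) -> dict:
    """LOD-drop support interval around a peak, on its chromosome.

    The interval is the contiguous run of positions with
    ``LOD >= peak - drop`` around the peak, extended outward by one
    evaluated position at each end (a drop of exactly 0 degenerates to
    the peak itself).  Bounds are reported in both cM and Mb.
    """
    if drop < 0:
        raise ValueError("drop must be >= 0")
    chrom = scan.positions["chrom"].iloc[peak_index]
    on_chrom = np.flatnonzero((scan.positions["chrom"] == chrom).to_numpy())
    local = scan.lod[on_chrom]
    k = int(np.flatnonzero(on_chrom == peak_index)[0])
    if drop == 0:
        lo = hi = k
    else:
        thr = local[k] - drop
        lo = k
        while lo > 0 and local[lo - 1] >= thr:
            lo -= 1
        hi = k
        while hi < len(local) - 1 and local[hi + 1] >= thr:
            hi += 1
        lo = max(0, lo - 1)
        hi = min(len(local) - 1, hi + 1)
    cm = scan.positions["cm"].to_numpy(float)[on_chrom]
    mb = scan.positions["mb"].to_numpy(float)[on_chrom]
    return {
        "lo_cm": float(cm[lo]),
        "hi_cm": float(cm[hi]),
        "lo_mb": float(mb[lo]),
        "hi_mb": float(mb[hi]),
    }


def fit_qtl_model(probs: GenotypeProbabilities, y, position_indices: list) -> pd.DataFrame:
    """Joint linear model on the dosages at a set of peak positions.

    Returns one row per retained position with the drop-one PVE (percent
    of total variance lost when that term is removed), the joint model
    PVE (same for all rows) and the signed additive effect from the
    joint fit.  Peaks whose dosage columns are nearly collinear
    (|r| > 0.99) are merged onto the first one with a warning.
    """
    yv = _as_vector(y, probs.line_ids)
    n = len(yv)
    idx = list(position_indices)
    if not idx:
        return pd.DataFrame(columns=["position", "pve", "model_pve", "additive"])
    X = probs.p2[:, idx]
    keep = [0]
    for j in range(1, X.shape[1]):
        cors = [abs(np.corrcoef(X[:, j], X[:, k])[0, 1]) for k in keep]
        if any(c > 0.99 for c in cors):
            warnings.warn(f"merging collinear peak at column {idx[j]}")
            continue
        keep.append(j)
    idx = [idx[j] for j in keep]
    X = X[:, keep]

    ones = np.ones((n, 1))
    tss = float(np.sum((yv - yv.mean()) ** 2))

    def rss(mat) -> float:
        beta, *_ = np.linalg.lstsq(mat, yv, rcond=None)
        resid = yv - mat @ beta
        return float(resid @ resid)

    full = np.hstack([ones, X])
    beta, *_ = np.linalg.lstsq(full, yv, rcond=None)
    rss_full = rss(full)
    model_pve = 100.0 * (1.0 - rss_full / tss) if tss > 0 else 0.0

    rows = []
    for j in range(X.shape[1]):
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        pve_j = 100.0 * (rss(others) - rss_full) / tss if tss > 0 else 0.0
        rows.append((idx[j], max(0.0, pve_j), model_pve, beta[1 + j] / 2.0))
    return pd.DataFrame(rows, columns=["position", "pve", "model_pve", "additive"])


def additive_effect(probs: GenotypeProbabilities, y, position_index: int) -> float:
    """Marginal signed additive effect at one position: half the
    regression slope of the response on P2 dosage."""
    yv = _as_vector(y, probs.line_ids)
    x = probs.p2[:, position_index]
    vx = np.var(x)
    if vx == 0:
        return 0.0
    return float(np.cov(x, yv, bias=True)[0, 1] / vx / 2.0)


def call_qtl(
    scan: ScanResult,
    threshold: float,
    probs: GenotypeProbabilities,
    y,
    trait: str = "",
    dataset: str = "",
    drop: float = 1.5,
    merge_cm: float = 20.0,
) -> list:
    """Declare QTL from a scan: local maxima above the threshold, maxima
    closer than ``merge_cm`` on a chromosome merged onto the higher LOD.

    Support intervals use the LOD-drop rule; PVE and additive effects
    come from the joint fit over all declared peaks.  Names follow
    ``q<TRAIT><chrom>-<ordinal>`` with ordinals in cM order.
    """
    chroms = scan.positions["chrom"].to_numpy()
    cms = scan.positions["cm"].to_numpy(float)
    peaks = []
    for chromosome in pd.unique(chroms):
        on = np.flatnonzero(chroms == chromosome)
        lod = scan.lod[on]
        for k in range(len(on)):
            left = lod[k - 1] if k > 0 else -np.inf
            right = lod[k + 1] if k < len(on) - 1 else -np.inf
            if lod[k] >= threshold and lod[k] >= left and lod[k] > right:
                peaks.append(on[k])
    # merge nearby maxima, strongest first
    peaks.sort(key=lambda i: -scan.lod[i])
    kept: list = []
    for i in peaks:
        if all(
            chroms[i] != chroms[j] or abs(cms[i] - cms[j]) >= merge_cm for j in kept
        ):
            kept.append(i)
    kept.sort(key=lambda i: (str(chroms[i]), cms[i]))
    if not kept:
        return []

    fit = fit_qtl_model(probs, y, kept).set_index("position")
    counters: dict = {}
    records = []
    for i in kept:
        si = support_interval(scan, i, drop=drop)
        chromosome = chroms[i]
        counters[chromosome] = counters.get(chromosome, 0) + 1
        name = f"q{trait.upper()}{chromosome}-{counters[chromosome]}"
        pve = float(fit.loc[i, "pve"]) if i in fit.index else 0.0
        add = float(fit.loc[i, "additive"]) if i in fit.index else additive_effect(probs, y, i)
        records.append(
            QTLRecord(
                trait=trait,
                dataset=dataset,
                name=name,
                chrom=chromosome,
                peak_cm=float(cms[i]),
                peak_mb=float(scan.positions["mb"].iloc[i]),
                lo_cm=si["lo_cm"],
                hi_cm=si["hi_cm"],
                lo_mb=si["lo_mb"],
                hi_mb=si["hi_mb"],
                lod=float(scan.lod[i]),
                pve=pve,
                additive=add,
            )
        )
    return records
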