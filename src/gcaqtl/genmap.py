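"""Genetic maps, genotype matrices and ancestry probabilities.

Coordinates follow two systems that travel together: genetic positions in
centiMorgans (0-based within chromosome) and physical positions in Mb
(1-based).  Genotype codes refer to parental origin in a biparental cross:
``P1`` (female parent), ``P2`` (male parent), ``Het`` (residual
heterozygote) and ``Missing``.  The additive dosage convention is
x in {0, 0.5, 1} for {P1, Het, P2}.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CODE_P1",
    "CODE_HET",
    "CODE_P2",
    "CODE_MISSING",
    "GeneticMap",
    "GenotypeMatrix",
    "GenotypeProbabilities",
    "MapSummary",
    "haldane_to_r",
    "r_to_haldane",
    "ril_recomb",
    "genotype_probabilities",
    "map_summary",
    "mean_spacing_from_totals",
    "read_cross_csv",
    "write_cross_csv",
    "read_map_tsv",
    "write_map_tsv",
]

CODE_P1 = 0
CODE_HET = 1
CODE_P2 = 2
CODE_MISSING = -1

#: canonical text labels for genotype codes (``-`` marks missing on disk)
CODE_TO_LABEL = {CODE_P1: "P1", CODE_HET: "Het", CODE_P2: "P2", CODE_MISSING: "-"}
LABEL_TO_CODE = {"P1": CODE_P1, "Het": CODE_HET, "P2": CODE_P2, "-": CODE_MISSING, "": CODE_MISSING}

_DOSAGE = {CODE_P1: 0.0, CODE_HET: 0.5, CODE_P2: 1.0, CODE_MISSING: np.nan}


class MapError(ValueError):
    """Raised for invalid genetic-map structures or malformed map files."""


class GenotypeError(ValueError):
    """Raised for genotype matrices inconsistent with their map."""


@dataclass
class GeneticMap:
    """Ordered marker map: id, chromosome, cM and Mb position per marker.

    Within each chromosome cM positions must be non-decreasing and Mb
    positions strictly increasing along the cM order.  Marker ids are
    unique genome-wide.
    """

    marker_ids: np.ndarray
    chrom: np.ndarray
    cm: np.ndarray
    mb: np.ndarray

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.cm = np.asarray(self.cm, dtype=float)
        self.mb = np.asarray(self.mb, dtype=float)
        n = len(self.marker_ids)
        if not (len(self.chrom) == len(self.cm) == len(self.mb) == n):
            raise MapError("map columns have unequal lengths")
        if n == 0:
            raise MapError("empty genetic map")
        if len(set(self.marker_ids)) != n:
            raise MapError("marker ids are not unique genome-wide")
        for c in self.chromosomes:
            idx = self.chrom_indices(c)
            cm = self.cm[idx]
            mb = self.mb[idx]
            if np.any(np.diff(cm) < 0):
                raise MapError(f"cM positions decrease on chromosome {c}")
            if np.any(np.diff(mb) <= 0):
                raise MapError(f"Mb positions not strictly increasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_indices(self, chromosome) -> np.ndarray:
        return np.flatnonzero(self.chrom == chromosome)

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_ids == marker_id)
        if len(hits) == 0:
            raise MapError(f"unknown marker id {marker_id!r}")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker_ids, "chrom": self.chrom, "cm": self.cm, "mb": self.mb}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        return cls(
            df["marker"].to_numpy(),
            df["chrom"].to_numpy(),
            df["cm"].to_numpy(float),
            df["mb"].to_numpy(float),
        )

    def interp_mb(self, chromosome, cm_positions) -> np.ndarray:
        """Physical position at arbitrary cM positions by piecewise-linear
        interpolation between flanking markers (clamped at chromosome ends)."""
        idx = self.chrom_indices(chromosome)
        if len(idx) == 0:
            raise MapError(f"unknown chromosome {chromosome!r}")
        cm = self.cm[idx]
        mb = self.mb[idx]
        # np.interp needs strictly increasing x; collapse cM ties
        ux, first = np.unique(cm, return_index=True)
        return np.interp(np.asarray(cm_positions, dtype=float), ux, mb[first])


@dataclass
class GenotypeMatrix:
    """Line x marker parental-origin codes, column-aligned with a map."""

    line_ids: np.ndarray
    marker_ids: np.ndarray
    codes: np.ndarray  # int8, lines x markers

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise GenotypeError("codes shape does not match line/marker ids")
        valid = {CODE_P1, CODE_HET, CODE_P2, CODE_MISSING}
        observed = set(np.unique(self.codes).tolist())
        if not observed <= valid:
            raise GenotypeError(f"invalid genotype codes present: {sorted(observed - valid)}")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise GenotypeError("duplicate line ids")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def dosage(self) -> np.ndarray:
        """Additive dosage in {0, 0.5, 1}; NaN where missing."""
        out = np.empty(self.codes.shape, dtype=float)
        for code, d in _DOSAGE.items():
            out[self.codes == code] = d
        return out

    def line_index(self, line_id: str) -> int:
        hits = np.flatnonzero(self.line_ids == line_id)
        if len(hits) == 0:
            raise GenotypeError(f"unknown line id {line_id!r}")
        return int(hits[0])


@dataclass
class GenotypeProbabilities:
    """P2-ancestry probabilities at markers and interleaved pseudomarkers.

    ``positions`` has columns ``chrom``, ``cm``, ``mb`` and ``marker``
    (marker id at observed markers, empty string at pseudomarkers);
    ``p2`` is the lines x positions probability matrix.  P(P1) = 1 - P(P2).
    """

    line_ids: np.ndarray
    positions: pd.DataFrame
    p2: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        if self.p2.shape != (len(self.line_ids), len(self.positions)):
            raise GenotypeError("probability matrix shape mismatch")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def dosage(self) -> np.ndarray:
        """Expected additive dosage (equals P(P2) for a 2-state model)."""
        return self.p2

    def marker_column(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.positions["marker"] == marker_id).to_numpy())
        if len(hits) == 0:
            raise GenotypeError(f"marker {marker_id!r} absent from probability grid")
        return int(hits[0])


# ---------------------------------------------------------------------------
# map functions

def haldane_to_r(d_cm):
    """Haldane map function: r = 0.5 (1 - exp(-2 d/100)) for distance in cM."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


def r_to_haldane(r):
    """Inverse Haldane: d (cM) = -50 ln(1 - 2r)."""
    rr = np.asarray(r, dtype=float)
    if np.any((rr < 0) | (rr >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * rr)
    return float(d) if np.isscalar(r) else d


def ril_recomb(r):
    """Map-expansion for selfed RILs: observed fraction r* = 2r / (1 + 2r)."""
    rr = np.asarray(r, dtype=float)
    if np.any((rr < 0) | (rr > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    out = 2.0 * rr / (1.0 + 2.0 * rr)
    return float(out) if np.isscalar(r) else out


# ---------------------------------------------------------------------------
# ancestry probabilities

def _ril_step_prob(d_cm: float) -> float:
    """Probability that ancestry switches across a gap of d cM on the
    RIL-observed scale."""
    return ril_recomb(haldane_to_r(d_cm))


def genotype_probabilities(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    step_cm: float = 1.0,
) -> GenotypeProbabilities:
    """P2-ancestry probability per line at markers plus a pseudomarker grid.

    At an observed non-missing marker the probability is pinned to the
    observation (Het pinned at 0.5, the additive dosage convention).
    Elsewhere the value is the exact conditional for a 2-state Markov
    chain given the two nearest informative flanking markers, with
    per-interval switch probabilities on the RIL-observed scale.  Lines
    with no informative marker on a chromosome get 0.5 throughout it.
    """
    if step_cm <= 0:
        raise ValueError("step_cm must be positive")
    if not np.array_equal(genotypes.marker_ids, gmap.marker_ids):
        raise GenotypeError("genotype matrix marker order does not match map")

    pos_rows = []
    col_chunks = []
    n_lines = genotypes.n_lines
    for chromosome in gmap.chromosomes:
        midx = gmap.chrom_indices(chromosome)
        mcm = gmap.cm[midx]
        grid = np.arange(mcm[0], mcm[-1], step_cm) if mcm[-1] > mcm[0] else np.array([])
        eval_cm = np.unique(np.concatenate([mcm, grid]))
        # marker label per eval position (first marker at a tied cM wins)
        label = {}
        for j, i in enumerate(midx):
            label.setdefault(mcm[j], gmap.marker_ids[i])
        eval_mb = gmap.interp_mb(chromosome, eval_cm)
        for c, b in zip(eval_cm, eval_mb):
            pos_rows.append((chromosome, c, b, label.get(c, "")))

        chunk = np.full((n_lines, len(eval_cm)), 0.5)
        obs = genotypes.codes[:, midx]
        # fast path: every eval position sits on a marker and the line has
        # no missing calls -> probabilities are just the observed dosages
        marker_grid = np.array_equal(eval_cm, np.unique(mcm))
        if marker_grid:
            col_of = np.searchsorted(mcm, eval_cm)  # first marker at each cM
            complete = ~np.any(obs == CODE_MISSING, axis=1)
            dose = np.array([0.0, 0.5, 1.0])
            chunk[complete] = dose[obs[np.ix_(complete, col_of)]]
            rest = np.flatnonzero(~complete)
        else:
            rest = np.arange(n_lines)
        for li in rest:
            chunk[li] = _line_chrom_probs(obs[li], mcm, eval_cm)
        col_chunks.append(chunk)

    positions = pd.DataFrame(pos_rows, columns=["chrom", "cm", "mb", "marker"])
    return GenotypeProbabilities(genotypes.line_ids, positions, np.hstack(col_chunks))


def _line_chrom_probs(obs: np.ndarray, mcm: np.ndarray, eval_cm: np.ndarray) -> np.ndarray:
    """Conditional P(P2) along one chromosome for one line."""
    informative = np.flatnonzero(obs != CODE_MISSING)
    out = np.full(len(eval_cm), 0.5)
    if len(informative) == 0:
        return out

    icm = mcm[informative]
    # evidence likelihood over states (P1, P2) at each informative marker
    like = np.empty((len(informative), 2))
    for k, j in enumerate(informative):
        if obs[j] == CODE_P1:
            like[k] = (1.0, 0.0)
        elif obs[j] == CODE_P2:
            like[k] = (0.0, 1.0)
        else:  # Het: carries both parental alleles, uninformative for ancestry
            like[k] = (0.5, 0.5)

    right_of = np.searchsorted(icm, eval_cm, side="left")
    for i, p in enumerate(eval_cm):
        ridx = right_of[i]
        lidx = ridx - 1
        # exact hit on an informative marker -> pin to the observation
        if ridx < len(icm) and icm[ridx] == p:
            w = like[ridx]
            out[i] = w[1] / (w[0] + w[1])
            continue
        num = np.array([0.5, 0.5])  # uniform chain prior over states
        if lidx >= 0:
            s = _ril_step_prob(p - icm[lidx])
            wl = like[lidx]
            num = num * np.array(
                [wl[0] * (1 - s) + wl[1] * s, wl[0] * s + wl[1] * (1 - s)]
            )
        if ridx < len(icm):
            s = _ril_step_prob(icm[ridx] - p)
            wr = like[ridx]
            num = num * np.array(
                [wr[0] * (1 - s) + wr[1] * s, wr[0] * s + wr[1] * (1 - s)]
            )
        tot = num.sum()
        out[i] = num[1] / tot if tot > 0 else 0.5
    return out


# ---------------------------------------------------------------------------
# summaries

@dataclass
class MapSummary:
    """Per-chromosome and genome-wide map totals."""

    per_chrom: pd.DataFrame
    total_cm: float
    n_markers: int
    n_chromosomes: int
    mean_spacing_cm: float          # total / (markers - chromosomes)
    mean_spacing_simple_cm: float   # total / markers, for cross-checking


def map_summary(gmap: GeneticMap) -> MapSummary:
    """Chromosome lengths, marker counts and mean inter-marker spacing.

    Spacing uses ``markers - chromosomes`` gaps (spacing is undefined
    across chromosome breaks); the naive ``total / markers`` figure is
    reported alongside.
    """
    rows = []
    for c in gmap.chromosomes:
        idx = gmap.chrom_indices(c)
        cm = gmap.cm[idx]
        rows.append((c, len(idx), float(cm[-1] - cm[0]), float(gmap.mb[idx][0]), float(gmap.mb[idx][-1])))
    per = pd.DataFrame(rows, columns=["chrom", "n_markers", "length_cm", "mb_start", "mb_end"])
    total = float(per["length_cm"].sum())
    n = gmap.n_markers
    k = len(per)
    return MapSummary(
        per_chrom=per,
        total_cm=total,
        n_markers=n,
        n_chromosomes=k,
        mean_spacing_cm=mean_spacing_from_totals(total, n, k),
        mean_spacing_simple_cm=total / n,
    )


def mean_spacing_from_totals(total_cm: float, n_markers: int, n_chromosomes: int) -> float:
    """Mean inter-marker spacing from printed totals: total / (markers - chromosomes)."""
    gaps = n_markers - n_chromosomes
    if gaps <= 0:
        raise ValueError("need more markers than chromosomes to define spacing")
    return total_cm / gaps


# ---------------------------------------------------------------------------
# file I/O: rotated "cross" CSV and map TSV

def write_cross_csv(
    path,
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame | None = None,
) -> None:
    """Write the rotated cross CSV: four header rows (marker id, chromosome,
    cM, Mb), then one row per line with phenotype columns first.

    ``phenotypes`` is a wide per-line table indexed by line id.
    """
    if phenotypes is None:
        phenotypes = pd.DataFrame(index=pd.Index(genotypes.line_ids, name="id"))
    phenotypes = phenotypes.reindex(genotypes.line_ids)
    pcols = list(phenotypes.columns)
    buf = io.StringIO()
    blank = [""] * len(pcols)
    buf.write(",".join(["id"] + pcols + [str(m) for m in gmap.marker_ids]) + "\n")
    buf.write(",".join(["chrom"] + blank + [str(c) for c in gmap.chrom]) + "\n")
    buf.write(",".join(["cm"] + blank + [repr(float(v)) for v in gmap.cm]) + "\n")
    buf.write(",".join(["mb"] + blank + [repr(float(v)) for v in gmap.mb]) + "\n")
    labels = np.empty(genotypes.codes.shape, dtype=object)
    for code, lab in CODE_TO_LABEL.items():
        labels[genotypes.codes == code] = lab
    for i, line in enumerate(genotypes.line_ids):
        pvals = ["" if pd.isna(v) else repr(float(v)) for v in phenotypes.iloc[i]]
        buf.write(",".join([str(line)] + pvals + list(labels[i])) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_cross_csv(path):
    """Read the rotated cross CSV written by :func:`write_cross_csv`.

    Returns ``(gmap, genotypes, phenotypes)``.  Raises :class:`MapError`
    or :class:`GenotypeError` with row/column positions on malformed input.
    """
    with open(path) as fh:
        raw = [line.rstrip("\n") for line in fh]
    if len(raw) < 4:
        raise MapError(f"{path}: expected at least 4 header rows, got {len(raw)} lines")
    header = [row.split(",") for row in raw[:4]]
    ids_row, chrom_row, cm_row, mb_row = header
    for want, row, ln in (("id", ids_row, 1), ("chrom", chrom_row, 2), ("cm", cm_row, 3), ("mb", mb_row, 4)):
        if row[0] != want:
            raise MapError(f"{path}: line {ln}: expected leading cell {want!r}, got {row[0]!r}")
    # phenotype columns are those with empty chromosome cells
    n_cols = len(ids_row)
    geno_start = 1
    while geno_start < n_cols and chrom_row[geno_start] == "":
        geno_start += 1
    pcols = ids_row[1:geno_start]
    marker_ids = ids_row[geno_start:]
    try:
        cm = np.array([float(v) for v in cm_row[geno_start:]])
        mb = np.array([float(v) for v in mb_row[geno_start:]])
    except ValueError as exc:
        raise MapError(f"{path}: non-numeric map position in header rows: {exc}") from exc
    gmap = GeneticMap(np.array(marker_ids, dtype=object), np.array(chrom_row[geno_start:], dtype=object), cm, mb)

    line_ids, pheno_rows, code_rows = [], [], []
    for ln, row in enumerate(raw[4:], start=5):
        if not row:
            continue
        cells = row.split(",")
        if len(cells) != n_cols:
            raise MapError(f"{path}: line {ln}: expected {n_cols} cells, got {len(cells)}")
        line_ids.append(cells[0])
        pheno_rows.append([float(v) if v != "" else np.nan for v in cells[1:geno_start]])
        codes = []
        for col, lab in enumerate(cells[geno_start:], start=geno_start + 1):
            if lab not in LABEL_TO_CODE:
                raise GenotypeError(
                    f"{path}: line {ln}, column {col}: unknown genotype code {lab!r}"
                )
            codes.append(LABEL_TO_CODE[lab])
        code_rows.append(codes)
    genotypes = GenotypeMatrix(
        np.array(line_ids, dtype=object), gmap.marker_ids, np.array(code_rows, dtype=np.int8)
    )
    phenotypes = pd.DataFrame(pheno_rows, index=pd.Index(line_ids, name="id"), columns=pcols)
    return gmap, genotypes, phenotypes


def write_map_tsv(path, gmap: GeneticMap) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    missing = {"marker", "chrom", "cm", "mb"} - set(df.columns)
    if missing:
        raise MapError(f"{path}: missing columns {sorted(missing)}")
    return GeneticMap.from_frame(df)
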