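"""Cross-environment consolidation, co-localization and per se vs
combining-ability classification of QTL.

Two QTL on the same chromosome are considered the same locus when their
physical support intervals overlap (closed intervals) or their peaks lie
within 20 Mb of each other.  Pleiotropy grouping takes the transitive
closure of this pairwise relation, so chained overlaps coalesce into one
component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qtlscan import QTLRecord

log = logging.getLogger(__name__)

__all__ = [
    "QTLMatch",
    "ConsolidatedQTL",
    "DEFAULT_PEAK_DIST_MB",
    "records_match",
    "colocalize",
    "consolidate_environments",
    "classify_perse_vs_gca",
    "pleiotropy_report",
]

DEFAULT_PEAK_DIST_MB = 20.0


@dataclass
class QTLMatch:
    """One co-localized pair and the geometric basis for the match."""

    qtl_a: QTLRecord
    qtl_b: QTLRecord
    basis: str  # 'interval-overlap' | 'peak-distance'
    peak_distance_mb: float


@dataclass
class ConsolidatedQTL:
    """A locus surviving consolidation, with provenance.

    ``record`` is the representative (the joint-analysis record when one
    exists, else the highest-LOD environment record); ``datasets`` lists
    every dataset tag the locus appeared in.
    """

    record: QTLRecord
    datasets: list
    sources: list = field(default_factory=list)

    @property
    def trait(self) -> str:
        return self.record.trait


def _has_mb(rec: QTLRecord) -> bool:
    return all(
        v is not None and np.isfinite(v) for v in (rec.peak_mb, rec.lo_mb, rec.hi_mb)
    )


def records_match(a: QTLRecord, b: QTLRecord, max_peak_dist_mb: float = DEFAULT_PEAK_DIST_MB):
    """Return a :class:`QTLMatch` if the two records co-localize, else None."""
    if a.chrom != b.chrom:
        return None
    if not (_has_mb(a) and _has_mb(b)):
        warnings.warn("record lacks Mb coordinates; skipped in co-localization")
        return None
    dist = abs(a.peak_mb - b.peak_mb)
    if a.lo_mb <= b.hi_mb and b.lo_mb <= a.hi_mb:
        return QTLMatch(a, b, "interval-overlap", dist)
    if dist <= max_peak_dist_mb:
        return QTLMatch(a, b, "peak-distance", dist)
    return None


def colocalize(qtls_a, qtls_b, max_peak_dist_mb: float = DEFAULT_PEAK_DIST_MB) -> list:
    """All co-localized pairs between two QTL sets."""
    out = []
    for a in qtls_a:
        for b in qtls_b:
            m = records_match(a, b, max_peak_dist_mb)
            if m is not None:
                out.append(m)
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _components(records: list, max_peak_dist_mb: float) -> list:
    """Transitive closure of pairwise matches; returns index groups."""
    uf = _UnionFind(len(records))
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if records_match(records[i], records[j], max_peak_dist_mb):
                uf.union(i, j)
    groups: dict = {}
    for i in range(len(records)):
        groups.setdefault(uf.find(i), []).append(i)
    return list(groups.values())


def consolidate_environments(
    env_records: dict,
    joint_records: list,
    max_peak_dist_mb: float = DEFAULT_PEAK_DIST_MB,
) -> list:
    """Keep loci detected in >= 2 environments or present in the joint
    analysis.

    ``env_records`` maps environment label -> QTL records.  Records are
    clustered per trait by the co-localization relation (transitive
    closure across environments and the joint set).  Each surviving
    cluster is represented by its joint record when one exists, else the
    highest-LOD environment record.
    """
    tagged = []
    for env, recs in env_records.items():
        tagged.extend((env, r) for r in recs)
    tagged.extend(("joint", r) for r in joint_records)

    out = []
    traits = sorted({r.trait for _, r in tagged})
    for trait in traits:
        subset = [(env, r) for env, r in tagged if r.trait == trait]
        recs = [r for _, r in subset]
        for group in _components(recs, max_peak_dist_mb):
            members = [subset[i] for i in group]
            envs = [env for env, _ in members]
            n_envs = len({e for e in envs if e != "joint"})
            has_joint = "joint" in envs
            if n_envs < 2 and not has_joint:
                continue
            if has_joint:
                rep = max((r for e, r in members if e == "joint"), key=lambda r: r.lod)
            else:
                rep = max((r for _, r in members), key=lambda r: r.lod)
            out.append(ConsolidatedQTL(record=rep, datasets=sorted(set(envs)), sources=[r for _, r in members]))
    return out


def classify_perse_vs_gca(
    perse_loci: list,
    gca_loci: list,
    max_peak_dist_mb: float = DEFAULT_PEAK_DIST_MB,
) -> pd.DataFrame:
    """Label consolidated loci as detected for per se performance only,
    combining ability only, or both, per trait.

    Inputs may be :class:`ConsolidatedQTL` or bare :class:`QTLRecord`.
    For "both" loci the sign-concordance flag records whether the
    additive effects of the matched records agree in direction.
    """

    def rec(x) -> QTLRecord:
        return x.record if isinstance(x, ConsolidatedQTL) else x

    rows = []
    traits = sorted({rec(x).trait for x in list(perse_loci) + list(gca_loci)})
    for trait in traits:
        ps = [rec(x) for x in perse_loci if rec(x).trait == trait]
        gc = [rec(x) for x in gca_loci if rec(x).trait == trait]
        matched_g: set = set()
        for p in ps:
            partners = [
                (j, records_match(p, g, max_peak_dist_mb)) for j, g in enumerate(gc)
            ]
            partners = [(j, m) for j, m in partners if m is not None]
            if partners:
                j, m = min(partners, key=lambda jm: jm[1].peak_distance_mb)
                matched_g.add(j)
                concordant = bool(np.sign(p.additive) == np.sign(gc[j].additive))
                rows.append((trait, p.name, gc[j].name, "both", p.chrom, concordant))
            else:
                rows.append((trait, p.name, None, "per-se-only", p.chrom, None))
        for j, g in enumerate(gc):
            if j not in matched_g:
                rows.append((trait, None, g.name, "gca-only", g.chrom, None))
    return pd.DataFrame(
        rows,
        columns=["trait", "perse_qtl", "gca_qtl", "category", "chrom", "sign_concordant"],
    )


def pleiotropy_report(
    records: list, max_peak_dist_mb: float = DEFAULT_PEAK_DIST_MB
) -> pd.DataFrame:
    """Group QTL across traits into pleiotropic components.

    Components are connected sets under the co-localization relation
    (transitive closure).  One row per component with member names, the
    distinct traits touched and their count.
    """
    recs = [x.record if isinstance(x, ConsolidatedQTL) else x for x in records]
    rows = []
    for cid, group in enumerate(_components(recs, max_peak_dist_mb), start=1):
        members = [recs[i] for i in group]
        traits = sorted({r.trait for r in members})
        rows.append(
            (
                cid,
                members[0].chrom,
                [r.name for r in members],
                traits,
                len(traits),
                len(members),
            )
        )
    return pd.DataFrame(
        rows, columns=["component", "chrom", "qtl_names", "traits", "n_traits", "n_qtl"]
    )
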