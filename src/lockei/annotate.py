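"""Relate EIs to genes and to each other.

Covers TSS association (an EI "contains" a gene if the strand-aware TSS
point falls inside the EI interval), cross-cell-type EI comparison
(set-relative three-way Venn classes), gene stratification into
EI / LOCK-not-EI / non-LOCK categories with per-category expression
vectors, and mean-signal meta-profiles around EI midpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, IntervalSet, ProbeTrack

__all__ = ["GeneModel", "read_gene_models", "associate_tss",
           "compare_ei_sets", "stratify_genes", "meta_profile"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")


def read_gene_models(path, layout: GenomeLayout | None = None) -> list[GeneModel]:
    """Read a refFlat-like TSV (gene, chrom, strand, txStart, txEnd).

    The TSS is the strand-aware 5' end: txStart for + genes, txEnd - 1
    for - genes (0-based position of the first transcribed base).
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene", "chrom", "strand", "txStart", "txEnd"])
    genes = []
    lens = layout.lengths if layout is not None else None
    for row in df.itertuples(index=False):
        tss = int(row.txStart) if row.strand == "+" else int(row.txEnd) - 1
        if lens is not None and not (0 <= tss < lens.get(row.chrom, 0)):
            raise ValueError(f"TSS of {row.gene} outside {row.chrom}")
        genes.append(GeneModel(str(row.gene), str(row.chrom),
                               str(row.strand), tss))
    return genes


def _tss_in_set(genes: list[GeneModel], iv_set: IntervalSet,
                slop_bp: int = 0) -> np.ndarray:
    """Boolean per gene: TSS point (+- slop) inside any interval.

    Point-in-union is what is asked, so the set is merged first; this also
    handles overlapping feature sets correctly.
    """
    from .intervals import merge_intervals

    hits = np.zeros(len(genes), dtype=bool)
    merged = merge_intervals(iv_set) if len(iv_set) else iv_set
    by_chrom = {c: merged.arrays(c) for c in merged.chroms()}
    for i, g in enumerate(genes):
        if g.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[g.chrom]
        lo, hi = g.tss - slop_bp, g.tss + slop_bp + 1
        idx = int(np.searchsorted(starts, hi, side="left")) - 1
        hits[i] = idx >= 0 and ends[idx] > lo
    return hits


def associate_tss(eis, genes: list[GeneModel],
                  slop_bp: int = 0) -> tuple[float, list[str]]:
    """(fraction of EIs containing >= 1 TSS, sorted unique associated genes)."""
    iv = eis if isinstance(eis, IntervalSet) else eis.intervals
    if len(iv) == 0:
        raise ValueError("associate_tss: empty EI set")
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_sorted = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    n_with_tss = 0
    for chrom in iv.chroms():
        starts, ends = iv.arrays(chrom)
        pts = tss_sorted.get(chrom)
        if pts is None:
            continue
        lo = np.searchsorted(pts, starts - slop_bp, side="left")
        hi = np.searchsorted(pts, ends + slop_bp, side="left")
        n_with_tss += int((hi > lo).sum())

    gene_hits = _tss_in_set(genes, iv, slop_bp)
    associated = sorted({genes[i].gene_id for i in np.nonzero(gene_hits)[0]})
    return n_with_tss / len(iv), associated


def compare_ei_sets(sets: dict[str, "IntervalSet"]) -> pd.DataFrame:
    """Three-way comparison of EI sets by >= 1 bp overlap.

    For each set, each of its EIs is classified by which of the other two
    sets it overlaps, giving set-relative counts of the 4 membership classes
    (own-only, shared with each other set, shared with both). Counts are
    set-relative because interval overlap is not transitive: the three
    per-set tallies need not agree on the "shared" classes.
    """
    from .intervals import merge_intervals, _overlap_flags

    if len(sets) != 3:
        raise ValueError("compare_ei_sets expects exactly 3 sets")
    names = list(sets)
    ivs = {k: (v if isinstance(v, IntervalSet) else v.intervals)
           for k, v in sets.items()}
    merged = {k: merge_intervals(v) if len(v) else v for k, v in ivs.items()}

    rows = []
    for k in names:
        others = [o for o in names if o != k]
        iv = ivs[k]
        flags = {}
        for o in others:
            hit = np.zeros(len(iv), dtype=bool)
            pos = 0
            for chrom in iv.chroms():
                qs, qe = iv.arrays(chrom)
                fs, fe = merged[o].arrays(chrom)
                hit[pos:pos + len(qs)] = _overlap_flags(qs, qe, fs, fe)
                pos += len(qs)
            flags[o] = hit
        a, b = others
        rows.append({
            "set": k,
            "other_a": a,
            "other_b": b,
            "total": len(iv),
            "specific": int((~flags[a] & ~flags[b]).sum()),
            "shared_a_only": int((flags[a] & ~flags[b]).sum()),
            "shared_b_only": int((flags[b] & ~flags[a]).sum()),
            "shared_all": int((flags[a] & flags[b]).sum()),
        })
    return pd.DataFrame(rows)


def stratify_genes(genes: list[GeneModel], locks, eis,
                   expr: dict[str, float] | pd.Series,
                   ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Assign each gene's TSS to EI / LOCK-not-EI / non-LOCK.

    EI membership takes precedence (EIs lie inside LOCKs). Genes missing
    from the expression table are excluded from the expression vectors with
    a logged count but keep their category in the returned frame.
    """
    lock_iv = locks if isinstance(locks, IntervalSet) else locks.intervals
    ei_iv = eis if isinstance(eis, IntervalSet) else eis.intervals
    in_ei = _tss_in_set(genes, ei_iv)
    in_lock = _tss_in_set(genes, lock_iv)
    category = np.where(in_ei, "EI",
                        np.where(in_lock, "LOCK-not-EI", "non-LOCK"))
    df = pd.DataFrame({
        "gene": [g.gene_id for g in genes],
        "category": category,
    })
    if isinstance(expr, pd.Series):
        expr = expr.to_dict()
    df["expression"] = [expr.get(g.gene_id, np.nan) for g in genes]
    n_missing = int(df["expression"].isna().sum())
    if n_missing:
        logger.info("stratify_genes: %d genes absent from expression table",
                    n_missing)
    vectors = {
        cat: df.loc[(df["category"] == cat) & df["expression"].notna(),
                    "expression"].to_numpy()
        for cat in ("EI", "LOCK-not-EI", "non-LOCK")
    }
    return df, vectors


def meta_profile(anchors, track: ProbeTrack, flank_bp: int = 50_000,
                 n_bins: int = 50) -> pd.DataFrame:
    """Mean signal in position bins around anchor midpoints.

    Each anchor's midpoint is position 0; probes whose midpoint lies within
    +- flank_bp are binned into ``n_bins`` equal-width bins; the profile is
    the per-bin mean over all anchors. Bins that receive no probes are NaN.
    """
    iv = anchors if isinstance(anchors, IntervalSet) else anchors.intervals
    if len(iv) == 0:
        raise ValueError("meta_profile: empty anchor set")
    edges = np.linspace(-flank_bp, flank_bp, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in iv.chroms():
        if chrom not in track.probes:
            continue
        mids = track.midpoints(chrom)
        vals = track.probes[chrom]["value"]
        starts, ends = iv.arrays(chrom)
        centers = (starts + ends) / 2.0
        for c in centers:
            lo = np.searchsorted(mids, c - flank_bp, side="left")
            hi = np.searchsorted(mids, c + flank_bp, side="right")
            rel = mids[lo:hi] - c
            b = np.clip(np.digitize(rel, edges) - 1, 0, n_bins - 1)
            np.add.at(sums, b, vals[lo:hi])
            np.add.at(counts, b, 1)
    mean = np.divide(sums, counts, out=np.full(n_bins, np.nan),
                     where=counts > 0)
    return pd.DataFrame({
        "bin_center_bp": (edges[:-1] + edges[1:]) / 2.0,
        "mean_signal": mean,
        "n_probes": counts,
    })
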