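"""Peak-to-gene assignment, genomic-context annotation, locus complexity.

Five assignment strategies: nearest TSS (one gene per peak), symmetric
window (default +/-50 kb), promoter (+/-1.5 kb), distal (20 kb < |d| <=
50 kb), and TAD co-membership. Distances are measured from the peak
reference point (summit if provided, else interval midpoint) to the
canonical TSS; upstream distances are negative. Assignment distances are
strand-agnostic — strand matters only for the "downstream" annotation
category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import GeneModel, GenomicInterval, TadDomain

__all__ = [
    "PeakGeneAssignment",
    "PeakAnnotation",
    "LocusComplexity",
    "peak_reference_point",
    "assign_peaks",
    "annotate_peaks",
    "locus_complexity",
]

WINDOW_HALFWIDTH = 50_000
PROMOTER_HALFWIDTH = 1_500
DISTAL_INNER = 20_000

_METHODS = ("nearest", "window", "promoter", "distal", "tad")


@dataclass
class PeakGeneAssignment:
    """Peak-gene links for one method; distance = reference point - TSS."""

    method: str
    links: pd.DataFrame  # columns: peak_id, gene_id, distance

    def peaks_for_gene(self, gene_id: str) -> list[str]:
        return self.links.loc[self.links["gene_id"] == gene_id, "peak_id"].tolist()

    def gene_to_peaks(self) -> dict[str, list[str]]:
        return {
            g: grp["peak_id"].tolist() for g, grp in self.links.groupby("gene_id")
        }

    def __len__(self) -> int:
        return len(self.links)


@dataclass(frozen=True)
class PeakAnnotation:
    peak_id: str
    category: str  # promoter | gene_body | downstream | intergenic
    anchor_gene: str | None


@dataclass(frozen=True)
class LocusComplexity:
    gene_id: str
    n_peaks: int
    complexity: str  # "high" | "low"
    cutoff: int


def peak_reference_point(peak: GenomicInterval, summit: int | None = None) -> int:
    """Summit position when known, else the floor midpoint of the peak."""
    return summit if summit is not None else peak.midpoint


def _sorted_tss(genes: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, list[GeneModel]]]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        out[chrom] = (np.array([g.tss for g in gs]), gs)
    return out


def _nearest_gene(tss: np.ndarray, gs: list[GeneModel], pos: int) -> GeneModel:
    """Nearest TSS; ties go to the smaller TSS, then lexicographic gene_id."""
    i = int(np.searchsorted(tss, pos))
    candidates = []
    if i > 0:
        candidates.append(gs[i - 1])
    if i < len(gs):
        candidates.append(gs[i])
    # include equal-TSS neighbors so the gene_id tie-break sees all of them
    best = min(candidates, key=lambda g: (abs(pos - g.tss), g.tss, g.gene_id))
    lo = int(np.searchsorted(tss, best.tss, side="left"))
    hi = int(np.searchsorted(tss, best.tss, side="right"))
    return min(gs[lo:hi], key=lambda g: g.gene_id)


def assign_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    method: str = "nearest",
    window_halfwidth: int = WINDOW_HALFWIDTH,
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    distal_inner: int = DISTAL_INNER,
    distal_outer: int = WINDOW_HALFWIDTH,
    tads: Sequence[TadDomain] | None = None,
    summits: dict[str, int] | None = None,
) -> PeakGeneAssignment:
    """Link peaks to genes under one of the five strategies.

    nearest: each peak to the single gene minimizing |distance| on its
    chromosome. window/promoter: all genes with |distance| <= halfwidth.
    distal: distal_inner < |distance| <= distal_outer. tad: gene TSS and
    peak reference point strictly inside the same domain. Peaks matching
    nothing are simply unassigned.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if method == "tad" and not tads:
        raise ValueError("tad method requires TAD intervals")
    summits = summits or {}
    index = _sorted_tss(genes)
    peak_chroms = {p.chrom for p in peaks}
    if peak_chroms.isdisjoint(index.keys()) and peaks and genes:
        import warnings

        warnings.warn(
            "no chromosome shared between peaks and genes; "
            "check chromosome naming", stacklevel=2
        )

    rows: list[tuple[str, str, int]] = []
    if method == "tad":
        tad_of_gene: dict[str, TadDomain] = {}
        for g in genes:
            for d in tads:
                if d.contains(g.chrom, g.tss):
                    tad_of_gene[g.gene_id] = d
                    break
        for p in peaks:
            ref = peak_reference_point(p, summits.get(p.label))
            peak_tad = next((d for d in tads if d.contains(p.chrom, ref)), None)
            if peak_tad is None:
                continue
            for g in genes:
                if tad_of_gene.get(g.gene_id) is peak_tad:
                    rows.append((p.label, g.gene_id, ref - g.tss))
    else:
        if method == "nearest":
            lo_bound, hi_bound = None, None
        elif method == "window":
            lo_bound, hi_bound = 0, window_halfwidth
        elif method == "promoter":
            lo_bound, hi_bound = 0, promoter_halfwidth
        else:  # distal
            lo_bound, hi_bound = distal_inner, distal_outer
        for p in peaks:
            if p.chrom not in index:
                continue
            tss, gs = index[p.chrom]
            ref = peak_reference_point(p, summits.get(p.label))
            if method == "nearest":
                g = _nearest_gene(tss, gs, ref)
                rows.append((p.label, g.gene_id, ref - g.tss))
            else:
                lo = int(np.searchsorted(tss, ref - hi_bound, side="left"))
                hi = int(np.searchsorted(tss, ref + hi_bound, side="right"))
                for g in gs[lo:hi]:
                    d = ref - g.tss
                    if lo_bound < abs(d) <= hi_bound or (lo_bound == 0 and d == 0):
                        rows.append((p.label, g.gene_id, d))
    links = pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])
    return PeakGeneAssignment(method=method, links=links)


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 3_000,
    downstream_extent: int = 3_000,
    summits: dict[str, int] | None = None,
) -> list[PeakAnnotation]:
    """Classify each peak as promoter / gene_body / downstream / intergenic.

    Priority order promoter > gene_body > downstream > intergenic; the
    anchor is the gene triggering the chosen category (nearest on ties).
    Downstream means within ``downstream_extent`` past the strand-aware gene
    end (gene_end on +, gene_start on -).
    """
    summits = summits or {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out = []
    for p in peaks:
        ref = peak_reference_point(p, summits.get(p.label))
        gs = by_chrom.get(p.chrom, [])
        promoter: list[tuple[int, GeneModel]] = []
        body: list[tuple[int, GeneModel]] = []
        downstream: list[tuple[int, GeneModel]] = []
        for g in gs:
            d_tss = abs(ref - g.tss)
            if d_tss <= promoter_halfwidth:
                promoter.append((d_tss, g))
                continue
            if g.gene_start <= ref < g.gene_end:
                body.append((d_tss, g))
                continue
            tail = g.gene_end if g.strand == "+" else g.gene_start
            offset = ref - tail if g.strand == "+" else tail - ref
            if 0 <= offset <= downstream_extent:
                downstream.append((offset, g))
        for category, hits in (
            ("promoter", promoter),
            ("gene_body", body),
            ("downstream", downstream),
        ):
            if hits:
                _, anchor = min(hits, key=lambda t: (t[0], t[1].gene_id))
                out.append(PeakAnnotation(p.label, category, anchor.gene_id))
                break
        else:
            out.append(PeakAnnotation(p.label, "intergenic", None))
    return out


def locus_complexity(
    assignment: PeakGeneAssignment,
    cutoff_mode: str = "tertile",
    genes: Sequence[GeneModel] | None = None,
) -> list[LocusComplexity]:
    """Per-gene peak counts under the nearest rule, split high/low.

    cutoff_mode "tertile": cutoff = nearest-rank 67th percentile of the
    count distribution over genes with >= 1 assigned peak; "fixed:k":
    cutoff = k. A gene is high-complexity iff n_peaks > cutoff. Genes given
    via ``genes`` but absent from the assignment count as 0.
    """
    if assignment.method != "nearest":
        raise ValueError("locus complexity is defined on the nearest assignment")
    if len(assignment.links) == 0:
        raise ValueError("empty assignment")
    counts = assignment.links.groupby("gene_id").size().to_dict()
    if genes is not None:
        for g in genes:
            counts.setdefault(g.gene_id, 0)
    nonzero = np.array([c for c in counts.values() if c > 0])
    if cutoff_mode == "tertile":
        # nearest-rank percentile: smallest value with >= 67% of mass at or below
        rank = int(np.ceil(0.67 * len(nonzero)))
        cutoff = int(np.sort(nonzero)[rank - 1])
    elif cutoff_mode.startswith("fixed:"):
        cutoff = int(cutoff_mode.split(":", 1)[1])
    else:
        raise ValueError(f"cutoff_mode must be 'tertile' or 'fixed:k', got {cutoff_mode!r}")
    return [
        LocusComplexity(g, n, "high" if n > cutoff else "low", cutoff)
        for g, n in sorted(counts.items())
    ]
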