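"""Windowed Weir-Cockerham FST scan with a simulated neutral null.

Per-site variance components follow the two-population Weir & Cockerham
(1984) estimator: a (among populations), b (among individuals within
populations), c (within individuals), computed from sample sizes, allele
frequencies and observed heterozygosity.  Window estimates are the
ratio-of-sums Sum(a)/Sum(a+b+c) over the polymorphic sites in each
non-overlapping 10-kb window (the VCFtools "weighted" convention).
Negative estimates are kept as-is; the estimator is not clamped.

Outlier windows exceed the 99% quantile of window FST from 10-kb
sequences simulated under the best-fit neutral demography; genes
overlapping any outlier window are selection candidates, tested for GO
overrepresentation with one-sided hypergeometric (Fisher) tests and
Benjamini-Hochberg correction (classic per-term Fisher; no GO-graph
decorrelation, results are labelled classic-Fisher).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .coalsim import DemographicModel, LocusConfig, simulate_windows
from .genomatrix import GeneRecord, GenotypeMatrix, PopulationMap


@dataclass
class FstWindow:
    chrom: str
    start: int
    end: int
    n_sites: int
    fst: float


@dataclass
class EnrichmentRow:
    term: str
    annotated_universe: int
    annotated_candidates: int
    p: float
    q: float
    significant: bool
    method: str = "classic-Fisher"


def site_fst(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham variance components (a, b, c) for one biallelic
    site and two populations.

    Parameters are per population: ``n`` called diploids, ``p`` allele
    frequency, ``h`` observed heterozygote *frequency* (het count / n).
    Monomorphic sites (p identical and 0/1) are the caller's
    responsibility to skip.
    """
    n1 = np.asarray(n1, dtype=float)
    r = 2.0
    n = np.stack([np.asarray(n1, float), np.asarray(n2, float)])
    p = np.stack([np.asarray(p1, float), np.asarray(p2, float)])
    h = np.stack([np.asarray(h1, float), np.asarray(h2, float)])
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    a = nbar / nc * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def _pop_site_stats(gm: GenotypeMatrix, sample_idx):
    sub = gm.calls[:, sample_idx, :]
    ok = (sub >= 0).all(axis=2)
    n = ok.sum(axis=1).astype(float)
    alt = np.where(ok[:, :, None], sub, 0).sum(axis=(1, 2)).astype(float)
    het = (ok & (sub[:, :, 0] != sub[:, :, 1])).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2 * n)
        h = het / n
    return n, p, h


def _usable_components(calls_stats):
    """(a, b, c, usable mask) from two per-population stat triples."""
    (n1, p1, h1), (n2, p2, h2) = calls_stats
    usable = (n1 >= 2) & (n2 >= 2)
    ntot = 2 * (n1 + n2)
    alt_tot = 2 * n1 * p1 + 2 * n2 * p2
    poly = (alt_tot > 0) & (alt_tot < ntot)
    usable &= np.nan_to_num(poly, nan=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        a, b, c = site_fst(n1, p1, h1, n2, p2, h2)
    return a, b, c, usable


def window_fst(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pops: tuple[str, str],
    window_size: int = 10_000,
) -> list[FstWindow]:
    """Ratio-of-sums window FST between two groups, tiling each contig
    from 0 in non-overlapping windows; windows with no usable site are
    omitted."""
    idx1 = gm.sample_index([s for s in pm.group_samples(pops[0]) if s in gm.samples])
    idx2 = gm.sample_index([s for s in pm.group_samples(pops[1]) if s in gm.samples])
    stats = (_pop_site_stats(gm, idx1), _pop_site_stats(gm, idx2))
    a, b, c, usable = _usable_components(stats)
    pos = np.array([v.pos for v in gm.variants])
    out = []
    for chrom, sl in gm.chrom_slices().items():
        idx = np.arange(sl.start, sl.stop)
        idx = idx[usable[idx]]
        if idx.size == 0:
            continue
        w = pos[idx] // window_size
        for wi in np.unique(w):
            sub = idx[w == wi]
            denom = (a[sub] + b[sub] + c[sub]).sum()
            fst = a[sub].sum() / denom if denom != 0 else np.nan
            out.append(
                FstWindow(
                    chrom,
                    int(wi) * window_size,
                    (int(wi) + 1) * window_size,
                    int(sub.size),
                    float(fst),
                )
            )
    return out


def fst_from_calls(calls: np.ndarray, labels, pops: tuple[str, str]):
    """Window FST for one simulated window given raw calls and labels;
    returns nan when no usable polymorphic site."""
    labels = np.asarray(labels)
    stats = []
    for g in pops:
        sub = calls[:, labels == g, :]
        ok = (sub >= 0).all(axis=2)
        n = ok.sum(axis=1).astype(float)
        alt = np.where(ok[:, :, None], sub, 0).sum(axis=(1, 2)).astype(float)
        het = (ok & (sub[:, :, 0] != sub[:, :, 1])).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            stats.append((n, alt / (2 * n), het / n))
    a, b, c, usable = _usable_components(tuple(stats))
    if not usable.any():
        return np.nan
    denom = (a[usable] + b[usable] + c[usable]).sum()
    return float(a[usable].sum() / denom) if denom != 0 else np.nan


def null_distribution(
    model: DemographicModel,
    pops: tuple[str, str],
    n_windows: int,
    rng: np.random.Generator,
    window_length: int = 10_000,
    q: float = 0.99,
):
    """Simulate ``n_windows`` neutral 10-kb windows under ``model`` and
    return (sorted window FST values, q-quantile).  Monomorphic windows
    are excluded, mirroring the empirical emission rule."""
    locus = LocusConfig(n_windows, window_length, mode="window")
    vals = []
    for calls, labels in simulate_windows(model, locus, rng, groups=list(pops)):
        fst = fst_from_calls(calls, labels, pops)
        if np.isfinite(fst):
            vals.append(fst)
    if not vals:
        raise ValueError(
            "all simulated windows monomorphic; increase mu*L or window count"
        )
    vals = np.sort(np.array(vals))
    return vals, float(np.quantile(vals, q))


def outlier_genes(
    windows: list[FstWindow], threshold: float, genes: list[GeneRecord]
) -> pd.DataFrame:
    """Genes overlapped by any window with fst > threshold (half-open
    interval overlap); one row per gene with its max overlapping-window
    FST."""
    hits: dict[str, float] = {}
    outliers = [w for w in windows if np.isfinite(w.fst) and w.fst > threshold]
    for g in genes:
        best = None
        for w in outliers:
            if w.chrom == g.chrom and w.start < g.end and g.start < w.end:
                best = w.fst if best is None else max(best, w.fst)
        if best is not None:
            hits[g.gene_id] = best
    return pd.DataFrame(
        {"gene": list(hits.keys()), "max_window_fst": list(hits.values())}
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def go_enrichment(
    candidates,
    universe,
    gene_terms: dict[str, set],
    p_cutoff: float = 0.05,
    fdr: float = 0.05,
) -> list[EnrichmentRow]:
    """Per-term one-sided hypergeometric overrepresentation test.

    ``gene_terms`` maps gene -> set of GO terms.  Terms annotating zero
    universe genes are skipped; BH q-values are computed over all tested
    terms, then rows with p <= ``p_cutoff`` are reported, flagged
    significant at q <= ``fdr``.
    """
    candidates = set(candidates)
    universe = set(universe)
    if not candidates <= universe:
        raise ValueError("candidates must be a subset of the universe")
    n_univ, n_cand = len(universe), len(candidates)
    term_univ: dict[str, int] = {}
    term_cand: dict[str, int] = {}
    for gene in universe:
        for t in gene_terms.get(gene, ()):
            term_univ[t] = term_univ.get(t, 0) + 1
            if gene in candidates:
                term_cand[t] = term_cand.get(t, 0) + 1
    terms = sorted(term_univ)
    ps = np.array(
        [
            hypergeom.sf(term_cand.get(t, 0) - 1, n_univ, term_univ[t], n_cand)
            for t in terms
        ]
    )
    qs = bh_adjust(ps)
    rows = [
        EnrichmentRow(t, term_univ[t], term_cand.get(t, 0), float(p), float(q),
                      bool(q <= fdr))
        for t, p, q in zip(terms, ps, qs)
        if p <= p_cutoff
    ]
    rows.sort(key=lambda r: r.p)
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "annotated_universe": r.annotated_universe,
                "annotated_candidates": r.annotated_candidates,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
                "method": r.method,
            }
            for r in rows
        ]
    )
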