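"""PLINK-style runs-of-homozygosity detection, F_ROH, group comparison.

The scanning-window heuristic: every window of ``window_snp`` consecutive
sites is homozygous-compatible iff it contains at most ``window_het``
heterozygous and ``window_missing`` missing calls; a site is eligible iff
the fraction of compatible windows among the windows containing it is at
least ``window_threshold``; maximal runs of eligible sites are split at
physical gaps above ``max_gap_kb``, broken so that no segment carries
more than ``max_het_in_segment`` heterozygous calls, and kept when they
satisfy the length, site-count and density limits.

Three published parameterizations are exposed as presets: (1) window 20
SNPs, threshold 0.05; (2) window 50 SNPs; (3) window 20, threshold 0.25 —
all with at most 1 het and 5 missing per window, >= 20 SNPs and >= 1000
kb per segment, density <= 100 kb/SNP, gap <= 1000 kb.

F_ROH is the summed segment length divided by the genome length (from
configuration, the summed analyzed contig lengths).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .genomatrix import GenotypeMatrix, PopulationMap


@dataclass(frozen=True)
class RohParams:
    window_snp: int = 20
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 20
    max_het_in_segment: int = 1
    max_density: float = 100.0  # kb per SNP
    min_kb: float = 1000.0
    max_gap_kb: float = 1000.0

    def __post_init__(self):
        if min(self.window_snp, self.window_het, self.window_missing,
               self.min_snp, self.max_het_in_segment) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must be in (0, 1]")
        if self.min_kb <= 0:
            raise ValueError("min_kb must be > 0")


#: the three published scanning parameterizations (window 20/50, threshold 0.05/0.25)
PRESETS = {
    1: RohParams(window_snp=20, window_threshold=0.05),
    2: RohParams(window_snp=50, window_threshold=0.05),
    3: RohParams(window_snp=20, window_threshold=0.25),
}


@dataclass(frozen=True)
class RohSegment:
    sample: str
    chrom: str
    start: int  # 0-based, first eligible site position
    end: int    # half-open, last eligible site position + 1
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def filter_genotyping_rate(gm: GenotypeMatrix, min_rate: float = 0.9) -> np.ndarray:
    """Indices of sites whose across-sample genotyping rate >= min_rate."""
    called = (gm.calls >= 0).all(axis=2).mean(axis=1)
    return np.flatnonzero(called >= min_rate)


def detect_roh(gm: GenotypeMatrix, sample: str, params: RohParams) -> list[RohSegment]:
    """Detect ROH segments for one sample (see module docstring).

    Chromosomes with fewer than ``window_snp`` sites yield no calls.
    """
    j = gm.samples.index(sample)
    calls = gm.calls[:, j, :]
    pos_all = np.array([v.pos for v in gm.variants])
    segments: list[RohSegment] = []
    for chrom, sl in gm.chrom_slices().items():
        c = calls[sl]
        pos = pos_all[sl]
        miss = (c < 0).any(axis=1)
        het = ~miss & (c[:, 0] != c[:, 1])
        eligible = _eligible_sites(het, miss, params)
        if eligible is None:
            continue
        for i, k in _segment_runs(eligible, het, pos, params):
            segments.append(
                RohSegment(sample, chrom, int(pos[i]), int(pos[k]) + 1, k - i + 1)
            )
    return segments


def _eligible_sites(het, miss, params: RohParams):
    n = het.size
    W = params.window_snp
    if n < W:
        return None
    cs_het = np.concatenate([[0], np.cumsum(het)])
    cs_mis = np.concatenate([[0], np.cumsum(miss)])
    het_w = cs_het[W:] - cs_het[:-W]     # per window start 0..n-W
    mis_w = cs_mis[W:] - cs_mis[:-W]
    compat = (het_w <= params.window_het) & (mis_w <= params.window_missing)
    cs_comp = np.concatenate([[0], np.cumsum(compat)])
    i = np.arange(n)
    lo = np.maximum(0, i - W + 1)
    hi = np.minimum(i, n - W)
    n_windows = hi - lo + 1
    hits = cs_comp[hi + 1] - cs_comp[lo]
    rate = hits / n_windows
    # >= at the boundary (PLINK uses strict >; declared divergence)
    return rate >= params.window_threshold


def _segment_runs(eligible, het, pos, params: RohParams):
    """Yield (first, last) site-index pairs of filtered segments."""
    n = eligible.size
    i = 0
    pieces = []
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        k = i
        while k + 1 < n and eligible[k + 1]:
            k += 1
        pieces.append((i, k))
        i = k + 1
    max_gap_bp = params.max_gap_kb * 1000
    gap_pieces = []
    for i, k in pieces:
        start = i
        for t in range(i, k + 1):
            end_here = t == k
            split = (not end_here) and (pos[t + 1] - pos[t] > max_gap_bp)
            if end_here or split:
                gap_pieces.append((start, t))
                start = t + 1
    for i, k in gap_pieces:
        yield from _split_at_hets(i, k, het, pos, params)


def _split_at_hets(i, k, het, pos, params: RohParams):
    """Break a candidate run so each piece holds <= max_het_in_segment
    heterozygous calls (a violating het starts the next piece), then
    apply the site-count / length / density filters."""
    start = i
    count = 0
    for t in range(i, k + 1):
        if het[t]:
            if count + 1 > params.max_het_in_segment:
                yield from _emit(start, t - 1, pos, params)
                start, count = t, 1
            else:
                count += 1
    yield from _emit(start, k, pos, params)


def _emit(i, k, pos, params: RohParams):
    if k < i:
        return
    n_snps = k - i + 1
    length_kb = (pos[k] - pos[i] + 1) / 1000.0
    if n_snps < params.min_snp:
        return
    if length_kb < params.min_kb:
        return
    if length_kb / n_snps > params.max_density:
        return
    yield (i, k)


def froh(segments: list[RohSegment], genome_length_bp: float) -> float:
    """Fraction of the genome in ROH for one individual."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be > 0")
    return sum(s.length_bp for s in segments) / genome_length_bp


def summarize(
    gm: GenotypeMatrix, params: RohParams, genome_length_bp: float,
    samples=None, prefilter: bool = True,
) -> tuple[pd.DataFrame, list[RohSegment]]:
    """Per-sample F_ROH and long-ROH counts (> 2 Mb, > 5 Mb).

    With ``prefilter`` the matrix is first reduced to sites with >= 90%
    genotyping rate across samples.
    """
    if prefilter:
        gm = gm.subset_variants(filter_genotyping_rate(gm, 0.9))
    samples = list(samples) if samples is not None else list(gm.samples)
    rows, all_segments = [], []
    for s in samples:
        segs = detect_roh(gm, s, params)
        all_segments.extend(segs)
        rows.append(
            {
                "sample": s,
                "froh": froh(segs, genome_length_bp),
                "n_segments": len(segs),
                "n_gt_2mb": sum(sg.length_bp > 2_000_000 for sg in segs),
                "n_gt_5mb": sum(sg.length_bp > 5_000_000 for sg in segs),
            }
        )
    return pd.DataFrame(rows), all_segments


def compare_groups(froh_by_sample: dict[str, float], pm: PopulationMap) -> pd.DataFrame:
    """Pairwise Welch t-tests of F_ROH between groups, Bonferroni-adjusted.

    Groups of size < 2 are excluded with a warning.
    """
    values: dict[str, list[float]] = {}
    for s, v in froh_by_sample.items():
        g = pm.assignments.get(s)
        if g is not None:
            values.setdefault(g, []).append(v)
    usable = {g: np.array(v) for g, v in values.items() if len(v) >= 2}
    dropped = set(values) - set(usable)
    if dropped:
        warnings.warn(f"groups excluded (size < 2): {sorted(dropped)}")
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    pairs = list(itertools.combinations(sorted(usable), 2))
    rows = []
    for g1, g2 in pairs:
        t, p = ttest_ind(usable[g1], usable[g2], equal_var=False)
        rows.append({"group1": g1, "group2": g2, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p"] * len(pairs), 1.0)
    return df
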