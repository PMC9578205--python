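"""Patterson's D (ABBA-BABA), admixture fraction f-hat, block jackknife.

Frequency-weighted site patterns on the four-taxon tree (((P1,P2),P3),O):

    abba = (1-p1) * p2 * p3 * (1-p4)
    baba = p1 * (1-p2) * p3 * (1-p4)

with p_i the derived-allele frequency in taxon i.  For these statistics
the ancestral allele at a site is the majority allele among called
outgroup alleles (sites with a polymorphic outgroup are retained with p4
the outgroup derived frequency; a 50/50 outgroup tie is uninformative and
skipped).  Significance comes from a delete-one block jackknife over
contiguous equal-site-count blocks (20 by default, i.e. each replicate
retains 95% of the data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .genomatrix import GenotypeMatrix, PopulationMap


@dataclass
class DStatResult:
    scope: str                 # "genome", chromosome id, or "chrom:start-end"
    sum_abba: float
    sum_baba: float
    d: float                   # nan when no informative sites
    se: float
    z: float
    p: float
    n_sites: int
    n_blocks: int
    per_block_d: np.ndarray
    f_hat: float | None = None
    f_ci: tuple | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.d)

    def significant(self, z_threshold: float = 3.0) -> bool:
        return self.defined and np.isfinite(self.z) and abs(self.z) > z_threshold


def site_patterns(p1, p2, p3, p4):
    """ABBA/BABA frequency weights from per-site derived frequencies."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def _derived_freqs(gm: GenotypeMatrix, pm: PopulationMap, groups):
    """Per-site derived-allele frequency per group, outgroup-polarized.

    Returns (freqs dict group->array, informative mask, skip counts).
    Sites where any group is fully missing, or where the outgroup is
    fully missing or tied 50/50, are masked out.
    """
    out_group = pm.role_group("outgroup")
    counts = {}
    for g in set(groups) | {out_group}:
        idx = gm.sample_index([s for s in pm.group_samples(g) if s in gm.samples])
        sub = gm.calls[:, idx, :].reshape(gm.n_variants, -1)
        ok = sub >= 0
        called = ok.sum(axis=1)
        alt = np.where(ok, sub, 0).sum(axis=1)
        counts[g] = (called, alt)
    called_o, alt_o = counts[out_group]
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq_o = alt_o / called_o
    usable = called_o > 0
    tied = usable & (alt_o * 2 == called_o)
    # ancestral = outgroup majority allele
    anc_is_ref = np.where(usable, alt_freq_o < 0.5, True)
    skip = {"outgroup_missing": int((~usable).sum()), "outgroup_tied": int(tied.sum())}
    mask = usable & ~tied
    freqs = {}
    for g, (called, alt) in counts.items():
        mask &= called > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            af = alt / called
        freqs[g] = np.where(anc_is_ref, af, 1 - af)
    skip["group_missing"] = int(gm.n_variants - skip["outgroup_missing"]
                                - skip["outgroup_tied"] - mask.sum())
    return freqs, mask, skip


def make_blocks(n_sites: int, n_blocks: int) -> list[np.ndarray]:
    """Contiguous equal-site-count blocks over genome-ordered sites."""
    if n_sites < n_blocks:
        n_blocks = max(1, n_sites)
    return [b for b in np.array_split(np.arange(n_sites), n_blocks) if b.size]


def block_jackknife(terms: dict, blocks: list, stat) -> tuple:
    """Delete-one block jackknife of ``stat`` (a function of summed terms).

    ``terms`` maps name -> per-site array; ``stat`` maps a dict of totals
    to the statistic.  Blocks whose terms are all zero carry no
    information and are merged into their right neighbor.  Returns
    (se, z, p, per_block_values, theta).
    """
    merged: list[np.ndarray] = []
    carry = np.array([], dtype=int)
    for b in blocks:
        b = np.concatenate([carry, b])
        if any(np.abs(v[b]).sum() > 0 for v in terms.values()):
            merged.append(b)
            carry = np.array([], dtype=int)
        else:
            carry = b
    if carry.size and merged:
        merged[-1] = np.concatenate([merged[-1], carry])
    elif carry.size:
        merged = [carry]
    if len(merged) < len(blocks):
        warnings.warn(
            f"{len(blocks) - len(merged)} empty jackknife blocks merged"
        )
    totals = {k: float(v.sum()) for k, v in terms.items()}
    theta = stat(totals)
    bsums = {k: np.array([v[b].sum() for b in merged]) for k, v in terms.items()}
    n_b = len(merged)
    if n_b < 2:
        return np.nan, np.nan, np.nan, np.array([theta]), theta
    loo = np.array(
        [stat({k: totals[k] - bsums[k][i] for k in totals}) for i in range(n_b)]
    )
    se = float(np.sqrt((n_b - 1) / n_b * ((loo - loo.mean()) ** 2).sum()))
    if se == 0:
        return 0.0, np.nan, np.nan, loo, theta
    z = theta / se
    p = float(2 * norm.sf(abs(z)))
    return se, float(z), p, loo, theta


def _d_stat(t):
    den = t["abba"] + t["baba"]
    return (t["abba"] - t["baba"]) / den if den > 0 else np.nan


def dstat(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    scope: str = "genome",
    window_size: int = 100_000,
    n_blocks: int = 20,
) -> list[DStatResult]:
    """D-statistic genome-wide, per chromosome, or in physical windows.

    ``scope`` is "genome", "chromosome", or "window" (non-overlapping
    ``window_size``-bp windows; 100 kb default).  One result per scope
    unit; units with no informative sites carry ``d = nan``.
    """
    roles = [pm.role_group(r) for r in ("P1", "P2", "P3")]
    freqs, mask, _ = _derived_freqs(gm, pm, roles)
    p4g = pm.role_group("outgroup")
    abba, baba = site_patterns(
        freqs[roles[0]], freqs[roles[1]], freqs[roles[2]], freqs[p4g]
    )
    abba = np.where(mask, abba, 0.0)
    baba = np.where(mask, baba, 0.0)

    units: list[tuple[str, np.ndarray]] = []
    if scope == "genome":
        units.append(("genome", np.arange(gm.n_variants)))
    elif scope == "chromosome":
        for chrom, sl in gm.chrom_slices().items():
            units.append((chrom, np.arange(sl.start, sl.stop)))
    elif scope == "window":
        pos = np.array([v.pos for v in gm.variants])
        for chrom, sl in gm.chrom_slices().items():
            idx = np.arange(sl.start, sl.stop)
            w = pos[idx] // window_size
            for wi in np.unique(w):
                sub = idx[w == wi]
                units.append(
                    (f"{chrom}:{wi * window_size}-{(wi + 1) * window_size}", sub)
                )
    else:
        raise ValueError(f"unknown scope {scope!r}")

    results = []
    for name, idx in units:
        a, b = abba[idx], baba[idx]
        tot_a, tot_b = float(a.sum()), float(b.sum())
        n_inf = int(((a + b) > 0).sum())
        if tot_a + tot_b == 0:
            results.append(
                DStatResult(name, tot_a, tot_b, np.nan, np.nan, np.nan,
                            np.nan, n_inf, 0, np.array([]))
            )
            continue
        blocks = make_blocks(idx.size, n_blocks)
        se, z, p, loo, theta = block_jackknife(
            {"abba": a, "baba": b}, blocks, _d_stat
        )
        results.append(
            DStatResult(name, tot_a, tot_b, theta, se, z, p, n_inf,
                        len(loo), loo)
        )
    return results


def f_hat(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    rng: np.random.Generator,
    n_blocks: int = 20,
) -> DStatResult:
    """Green et al. admixture-fraction estimator with a split donor.

    f = S(P1,P2,P3,O) / S(P1,P3a,P3b,O) where S sums the ABBA-BABA
    numerator and the donor P3 is randomly split into halves (P3a
    replacing the recipient P2, P3b the donor).  The CI is
    f +/- 1.96 * jackknife SE of the ratio.
    """
    p1g, p2g, p3g = (pm.role_group(r) for r in ("P1", "P2", "P3"))
    og = pm.role_group("outgroup")
    p3_samples = [s for s in pm.group_samples(p3g) if s in gm.samples]
    if len(p3_samples) < 2:
        raise ValueError("P3 needs >= 2 samples to be split")
    if len(p3_samples) % 2:
        left_out = p3_samples[-1]
        warnings.warn(f"odd P3 size; sample {left_out!r} left out of the split")
        p3_samples = p3_samples[:-1]
    perm = rng.permutation(len(p3_samples))
    half = len(p3_samples) // 2
    p3a = [p3_samples[i] for i in perm[:half]]
    p3b = [p3_samples[i] for i in perm[half:]]

    sub_pm = PopulationMap(
        {
            **{s: "P1g" for s in pm.group_samples(p1g)},
            **{s: "P2g" for s in pm.group_samples(p2g)},
            **{s: "P3a" for s in p3a},
            **{s: "P3b" for s in p3b},
            **{s: "Og" for s in pm.group_samples(og)},
        },
        {"Og": "outgroup"},
    )
    freqs, mask, _ = _derived_freqs(gm, sub_pm, ["P1g", "P2g", "P3a", "P3b"])
    p1, p2 = freqs["P1g"], freqs["P2g"]
    pa, pb, p4 = freqs["P3a"], freqs["P3b"], freqs["Og"]
    p3 = (pa + pb) / 2
    num = np.where(mask, (p2 - p1) * p3 * (1 - p4), 0.0)
    den = np.where(mask, (pa - p1) * pb * (1 - p4), 0.0)

    blocks = make_blocks(gm.n_variants, n_blocks)
    stat = lambda t: t["num"] / t["den"] if t["den"] != 0 else np.nan
    se, z, p, loo, theta = block_jackknife(
        {"num": num, "den": den}, blocks, stat
    )
    ci = (theta - 1.96 * se, theta + 1.96 * se) if np.isfinite(se) else None
    return DStatResult(
        "genome", float(num.sum()), float(den.sum()), theta, se, z, p,
        int(mask.sum()), len(loo), loo, f_hat=theta, f_ci=ci,
    )
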