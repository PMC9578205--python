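"""Joint (multidimensional) site-frequency spectra.

The observed SFS is polarized by an outgroup (ancestral = the allele fixed
among called outgroup alleles) and projected down to fixed haploid sample
sizes by expected hypergeometric downsampling, accumulating fractional
mass per cell — the same convention easySFS/dadi use.  The joint SFS is
the summary statistic compared between observed data and coalescent
simulations during demographic model choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .genomatrix import GenotypeMatrix, PopulationMap


class JointSFS:
    """Nonnegative real counts indexed by per-group derived-allele count.

    ``shape[i] = haploid size of group i + 1``.  The monomorphic corner
    cells (all-zero and all-maximal) carry no information about
    polymorphism and are masked from distance computations.
    """

    def __init__(self, groups, cells, polarized=True):
        self.groups = list(groups)
        self.cells = np.asarray(cells, dtype=float)
        if self.cells.ndim != len(self.groups):
            raise ValueError("cells rank != number of groups")
        if (self.cells < 0).any():
            raise ValueError("negative SFS cell")
        self.polarized = bool(polarized)

    @property
    def shape(self):
        return self.cells.shape

    @property
    def haploid_sizes(self):
        return tuple(s - 1 for s in self.shape)

    def corner_mass(self) -> float:
        lo = self.cells[(0,) * self.cells.ndim]
        hi = self.cells[tuple(s - 1 for s in self.shape)]
        return float(lo + hi)

    def total(self) -> float:
        return float(self.cells.sum())

    def flat_no_corners(self) -> np.ndarray:
        """Row-major flattened cells with the two corner cells removed."""
        flat = self.cells.ravel()
        return np.delete(flat, [0, flat.size - 1])

    def __add__(self, other):
        if self.groups != other.groups or self.shape != other.shape:
            raise ValueError("incompatible spectra")
        return JointSFS(self.groups, self.cells + other.cells, self.polarized)

    # -- plain-text serialization ------------------------------------------
    def save(self, path):
        with open(path, "w") as fh:
            fh.write("#felipop-sfs\t" + "\t".join(self.groups) + "\n")
            fh.write("#shape\t" + "\t".join(map(str, self.shape)) + "\n")
            fh.write(" ".join(f"{x:.17g}" for x in self.cells.ravel()) + "\n")

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            shape = tuple(int(x) for x in fh.readline().split("\t")[1:])
            cells = np.array(fh.readline().split(), dtype=float).reshape(shape)
        return cls(header[1:], cells)

    @classmethod
    def load_dadi(cls, path, groups=None):
        """Read a dadi-style .fs file (shape line, data line, mask line)."""
        with open(path) as fh:
            lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
        shape = tuple(int(t) for t in lines[0].split() if t.isdigit())
        cells = np.array(lines[1].split(), dtype=float).reshape(shape)
        if groups is None:
            groups = [f"pop{i}" for i in range(len(shape))]
        return cls(groups, cells)


@dataclass
class Polarization:
    """Per-site derived-allele designation; ``derived_is_alt[i]`` for kept
    site index ``kept[i]``."""

    kept: np.ndarray
    derived_is_alt: np.ndarray
    dropped: list = field(default_factory=list)  # (variant index, reason)


def polarize(gm: GenotypeMatrix, pm: PopulationMap, outgroup: str) -> Polarization:
    """Designate ancestral/derived alleles using the outgroup.

    Ancestral = the allele fixed among called outgroup alleles; sites with
    a polymorphic or fully-missing outgroup are dropped with a reason.
    """
    if outgroup not in pm.groups:
        raise KeyError(f"outgroup group {outgroup!r} absent from population map")
    out_idx = gm.sample_index(
        [s for s in pm.group_samples(outgroup) if s in gm.samples]
    )
    sub = gm.calls[:, out_idx, :].reshape(gm.n_variants, -1)
    kept, derived_alt, dropped = [], [], []
    for i in range(gm.n_variants):
        alleles = sub[i][sub[i] >= 0]
        if alleles.size == 0:
            dropped.append((i, "outgroup fully missing"))
        elif (alleles == alleles[0]).all():
            kept.append(i)
            derived_alt.append(alleles[0] == 0)  # ancestral=ref -> derived=alt
        else:
            dropped.append((i, "outgroup polymorphic"))
    return Polarization(
        np.array(kept, dtype=int), np.array(derived_alt, dtype=bool), dropped
    )


def _group_derived_counts(gm, pm, groups):
    """Per (site, group): number of called alleles and derived... helper
    returning called and alt counts; polarization applied by caller."""
    called = np.empty((gm.n_variants, len(groups)), dtype=int)
    alt = np.empty((gm.n_variants, len(groups)), dtype=int)
    for gi, g in enumerate(groups):
        idx = gm.sample_index([s for s in pm.group_samples(g) if s in gm.samples])
        if idx.size == 0:
            raise ValueError(f"group {g!r} has zero samples in the matrix")
        sub = gm.calls[:, idx, :].reshape(gm.n_variants, -1)
        ok = sub >= 0
        called[:, gi] = ok.sum(axis=1)
        alt[:, gi] = np.where(ok, sub, 0).sum(axis=1)
    return called, alt


def build_sfs(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    groups,
    project_to,
    polarization: Polarization | None = None,
    outgroup: str | None = None,
) -> JointSFS:
    """Build the joint SFS with expected hypergeometric projection.

    Each retained site contributes, to cell (k_1..k_g), the product over
    groups of the hypergeometric probability of drawing k derived alleles
    when sampling ``project_to[g]`` alleles without replacement from the
    group's called alleles.  Sites where any group has fewer called
    alleles than its target are dropped.
    """
    if polarization is None:
        if outgroup is None:
            raise ValueError("need a Polarization or an outgroup group id")
        polarization = polarize(gm, pm, outgroup)
    project_to = tuple(int(t) for t in project_to)
    called, alt = _group_derived_counts(gm, pm, groups)
    shape = tuple(t + 1 for t in project_to)
    cells = np.zeros(shape)
    for site, der_is_alt in zip(polarization.kept, polarization.derived_is_alt):
        n = called[site]
        if (n < np.array(project_to)).any():
            continue
        k = alt[site] if der_is_alt else n - alt[site]
        probs = [
            hypergeom.pmf(np.arange(t + 1), n[g], k[g], t)
            for g, t in enumerate(project_to)
        ]
        contrib = probs[0]
        for p in probs[1:]:
            contrib = np.multiply.outer(contrib, p)
        cells += contrib
    return JointSFS(list(groups), cells, polarized=True)


def project_sfs(jsfs: JointSFS, new_sizes) -> JointSFS:
    """Hypergeometric projection of an existing spectrum to smaller
    haploid sizes (axis-wise expected downsampling)."""
    cells = jsfs.cells
    for axis, (old_p1, new) in enumerate(zip(jsfs.shape, new_sizes)):
        old = old_p1 - 1
        if new > old:
            raise ValueError("cannot project up")
        # transition[k_old, k_new] = P(draw k_new | k_old of old)
        trans = np.array(
            [hypergeom.pmf(np.arange(new + 1), old, k, new) for k in range(old + 1)]
        )
        cells = np.tensordot(cells, trans, axes=([axis], [0]))
        cells = np.moveaxis(cells, -1, axis)
    return JointSFS(jsfs.groups, cells, jsfs.polarized)
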