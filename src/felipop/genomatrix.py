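"""Genotype, population-map and gene-annotation containers and IO.

All internal coordinates are 0-based half-open; VCF positions are converted
on ingest and restored on output.  A diploid call is a pair of allele
indices in {0, 1}; a half-called genotype ("./1") is treated as fully
missing (-1, -1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING = -1

ROLES = ("P1", "P2", "P3", "outgroup")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP. ``pos`` is the 0-based coordinate."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"not a SNP at {self.chrom}:{self.pos}: {self.ref}>{self.alt}"
            )


class GenotypeMatrix:
    """Samples x biallelic variants with per-haplotype allele indices.

    Parameters
    ----------
    variants:
        Variants sorted by (chrom, pos); duplicates rejected.
    samples:
        Ordered sample identifiers.
    calls:
        int8 array of shape (n_variants, n_samples, 2); -1 = missing.
    phased:
        True only when every original call was phased; haplotype-level
        queries refuse to run on unphased matrices.
    """

    def __init__(self, variants, samples, calls, phased=False):
        self.variants: list[Variant] = list(variants)
        self.samples: list[str] = list(samples)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.variants), len(self.samples), 2):
            raise ValueError(
                f"calls shape {calls.shape} != "
                f"({len(self.variants)}, {len(self.samples)}, 2)"
            )
        self.calls = calls
        self.phased = bool(phased)
        keys = [(v.chrom, v.pos) for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) in variant list")
        if keys != sorted(keys):
            raise ValueError("variants must be sorted by (chrom, pos)")

    # -- basic properties -------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        return np.array([idx[n] for n in names], dtype=int)

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage per (variant, sample); NaN where missing."""
        d = self.calls.sum(axis=2).astype(float)
        d[(self.calls < 0).any(axis=2)] = np.nan
        return d

    def haplotypes(self, sample_idx=None) -> np.ndarray:
        """(n_variants, 2*n) haplotype alleles; requires phased data."""
        if not self.phased:
            raise ValueError("haplotype-level query on unphased matrix")
        c = self.calls if sample_idx is None else self.calls[:, sample_idx, :]
        return c.reshape(c.shape[0], -1)

    def subset_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            [self.variants[i] for i in index],
            self.samples,
            self.calls[index],
            phased=self.phased,
        )

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous variant-index slice per chromosome, in input order."""
        out: dict[str, slice] = {}
        start = 0
        for i, v in enumerate(self.variants):
            if v.chrom != self.variants[start].chrom:
                out[self.variants[start].chrom] = slice(start, i)
                start = i
        if self.variants:
            out[self.variants[start].chrom] = slice(start, self.n_variants)
        return out

    def __eq__(self, other):
        return (
            isinstance(other, GenotypeMatrix)
            and self.variants == other.variants
            and self.samples == other.samples
            and self.phased == other.phased
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PopulationMap:
    """sample -> group assignment plus optional four-taxon roles."""

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)  # group -> role

    def __post_init__(self):
        seen = {}
        for grp, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for group {grp!r}")
            if role in seen:
                raise ValueError(f"role {role!r} claimed by both "
                                 f"{seen[role]!r} and {grp!r}")
            seen[role] = grp

    @property
    def groups(self) -> list[str]:
        out = []
        for g in self.assignments.values():
            if g not in out:
                out.append(g)
        return out

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def role_group(self, role: str) -> str:
        for g, r in self.roles.items():
            if r == role:
                return g
        raise KeyError(f"no group assigned role {role!r}")


@dataclass(frozen=True)
class GeneRecord:
    """Gene interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval for {self.gene_id}: "
                f"{self.start}..{self.end}"
            )


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

def read_vcf(path, region=None, biallelic_only=True) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    With ``biallelic_only`` set, only PASS (or unfiltered) biallelic SNP
    records are kept.  Phasing is preserved: the matrix is flagged phased
    only when every retained call uses the ``|`` separator.  ``region`` is
    ``"chrom"`` or ``"chrom:start-end"`` with a 1-based inclusive span.
    """
    from cyvcf2 import VCF

    rchrom = rlo = rhi = None
    if region is not None:
        if ":" in region:
            rchrom, span = region.split(":", 1)
            lo, hi = span.split("-")
            rlo, rhi = int(lo), int(hi)
        else:
            rchrom = region

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants, rows = [], []
    all_phased = True
    for rec in vcf:
        if rchrom is not None and rec.CHROM != rchrom:
            continue
        if rlo is not None and not (rlo <= rec.POS <= rhi):
            continue
        if biallelic_only:
            if rec.FILTER is not None:  # cyvcf2: None == PASS/'.'
                continue
            if len(rec.ALT) != 1 or not rec.is_snp:
                continue
        else:
            if len(rec.ALT) != 1 or not rec.is_snp:
                warnings.warn(
                    f"record {rec.CHROM}:{rec.POS} is not a biallelic SNP; "
                    "retained but unusable downstream"
                )
                continue
        gts = rec.genotypes  # [a0, a1, phased] per sample
        row = np.empty((len(samples), 2), dtype=np.int8)
        for j, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                row[j] = (MISSING, MISSING)
            else:
                row[j] = (a0, a1)
                if not g[-1]:
                    all_phased = False
        alt = rec.ALT[0] if rec.ALT else "N"
        variants.append(Variant(rec.CHROM, rec.POS - 1, rec.REF, alt))
        rows.append(row)
    vcf.close()
    calls = (
        np.stack(rows) if rows else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    order = np.array(
        sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos)),
        dtype=int,
    )
    variants = [variants[i] for i in order]
    calls = calls[order] if len(order) else calls
    return GenotypeMatrix(variants, samples, calls, phased=all_phased and bool(rows))


def write_vcf(gm: GenotypeMatrix, path, contig_lengths=None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 text file."""
    sep = "|" if gm.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=felipop\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(v.chrom for v in gm.variants):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, v in enumerate(gm.variants):
            gts = []
            for j in range(gm.n_samples):
                a0, a1 = gm.calls[i, j]
                if a0 < 0 or a1 < 0:
                    gts.append(f".{sep}.")
                else:
                    gts.append(f"{a0}{sep}{a1}")
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def validate(gm: GenotypeMatrix) -> None:
    """Raise if the matrix violates its structural invariants."""
    GenotypeMatrix(gm.variants, gm.samples, gm.calls, gm.phased)
    bad = (gm.calls > 1) | ((gm.calls < 0) & (gm.calls != MISSING))
    if bad.any():
        raise ValueError("allele indices outside {0,1,missing}")
    half = (gm.calls < 0).sum(axis=2) == 1
    if half.any():
        raise ValueError("half-called genotypes present; expected fully missing")


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_popmap(path) -> PopulationMap:
    """Read a 2/3-column TSV: sample, group[, role]."""
    assignments: dict[str, str] = {}
    roles: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: need at least 2 columns")
            sample, group = parts[0], parts[1]
            if sample in assignments:
                raise ValueError(f"{path}:{ln}: duplicate sample {sample!r}")
            assignments[sample] = group
            if len(parts) >= 3 and parts[2] and parts[2].lower() != "none":
                role = parts[2]
                if group in roles and roles[group] != role:
                    raise ValueError(
                        f"{path}:{ln}: group {group!r} given two roles"
                    )
                if role in roles.values() and roles.get(group) != role:
                    raise ValueError(f"{path}:{ln}: role {role!r} claimed twice")
                roles[group] = role
    return PopulationMap(assignments, roles)


def write_popmap(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for s, g in pm.assignments.items():
            role = pm.roles.get(g, "")
            fh.write(f"{s}\t{g}\t{role}\n".rstrip() + "\n" if role else f"{s}\t{g}\n")


def check_samples(gm: GenotypeMatrix, pm: PopulationMap) -> list[str]:
    """Return matrix samples missing from the map (warned, excluded)."""
    missing = [s for s in gm.samples if s not in pm.assignments]
    if missing:
        warnings.warn(
            f"{len(missing)} samples absent from population map, excluded: "
            + ", ".join(missing[:5])
        )
    return missing


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def read_genes(path, fmt=None) -> list[GeneRecord]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based,
    closed; ``gene`` features).  Output is unified 0-based half-open and
    sorted by (chrom, start)."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if fmt == "bed":
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
                strand = f[5] if len(f) > 5 else "+"
            else:
                if len(f) < 9 or f[2] != "gene":
                    continue
                chrom = f[0]
                start, end = int(f[3]) - 1, int(f[4])
                strand = f[6]
                name = _gff_attr(f[8], "ID") or f"{chrom}:{start}-{end}"
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end for {name!r}")
            genes.append(GeneRecord(name, chrom, start, end, strand))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _gff_attr(attrs: str, key: str):
    for kv in attrs.split(";"):
        kv = kv.strip()
        if kv.startswith(key + "="):
            return kv[len(key) + 1:]
    return None
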