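"""Neutral-site selection and LD pruning.

Fourfold-degenerate third codon positions serve as a proxy for neutrally
evolving sites; variants are additionally pruned for linkage
disequilibrium before demographic inference (r^2 > 0.1) and structure
analyses (r^2 > 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .genomatrix import GenotypeMatrix

_STOPS = set(standard_dna_table.stop_codons)


def _aa(codon: str):
    codon = codon.upper()
    if codon in _STOPS:
        return "*"
    return standard_dna_table.forward_table.get(codon)


def _fourfold_prefixes() -> set[str]:
    """Dinucleotide prefixes whose four codons encode one amino acid."""
    out = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {_aa(b1 + b2 + b3) for b3 in "ACGT"}
            if len(aas) == 1 and None not in aas:
                out.add(b1 + b2)
    return out


FOURFOLD_PREFIXES = _fourfold_prefixes()  # e.g. GC (Ala), GG (Gly), CT (Leu)...


@dataclass(frozen=True)
class LdParams:
    """LD-pruning parameters: strict r^2 cutoff within a sliding window of
    ``window`` sites (pairs further apart are never tested)."""

    r2_threshold: float
    window: int = 50

    def __post_init__(self):
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window < 2:
            raise ValueError("window must be >= 2")


def read_cds_features(gff3_path):
    """Parse CDS features from GFF3, grouped by parent transcript.

    Returns {parent_id: [(chrom, start0, end0, strand, phase), ...]} with
    exons in translation order (genomic order on +, reversed on -).
    """
    groups: dict[str, list] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8 or f[2] != "CDS":
                continue
            chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
            phase = int(f[7]) if f[7] in "012" else 0
            attrs = f[8] if len(f) > 8 else ""
            parent = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                for key in ("Parent=", "ID="):
                    if kv.startswith(key):
                        parent = kv.split("=", 1)[1]
                        break
                if parent:
                    break
            parent = parent or f"{chrom}:{start}"
            groups.setdefault(parent, []).append((chrom, start, end, strand, phase))
    for parent, exons in groups.items():
        exons.sort(key=lambda e: e[1])
        if exons[0][3] == "-":
            exons.reverse()
    return groups


def fourfold_sites(reference, cds_gff3) -> set[tuple[str, int]]:
    """Genomic coordinates (chrom, 0-based pos) of fourfold-degenerate
    third codon positions, strand-aware.

    ``reference`` is a FASTA path or a {contig: sequence} mapping.  CDS
    groups whose phase-adjusted length is not a multiple of 3 are skipped
    with a warning; a CDS on an absent contig is an error.
    """
    if isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
        from pyfaidx import Fasta

        fa = Fasta(str(reference))
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        seqs = {k: str(v) for k, v in reference.items()}

    sites: set[tuple[str, int]] = set()
    for parent, exons in read_cds_features(cds_gff3).items():
        for chrom, *_ in exons:
            if exons[0][0] not in seqs:
                raise KeyError(f"CDS {parent!r} references absent contig "
                               f"{exons[0][0]!r}")
        strand = exons[0][3]
        # coordinates in translation order, one per base
        coords: list[tuple[str, int]] = []
        seq_parts: list[str] = []
        for chrom, start, end, _, _ in exons:
            part = seqs[chrom][start:end]
            pos = list(range(start, end))
            if strand == "-":
                part = reverse_complement(part)
                pos = pos[::-1]
            seq_parts.append(part)
            coords.extend((chrom, p) for p in pos)
        cds_seq = "".join(seq_parts).upper()
        phase = exons[0][4]
        cds_seq = cds_seq[phase:]
        coords = coords[phase:]
        if len(cds_seq) % 3 != 0:
            warnings.warn(f"CDS {parent!r} length not divisible by 3; skipped")
            continue
        for i in range(0, len(cds_seq) - 2, 3):
            if cds_seq[i:i + 2] in FOURFOLD_PREFIXES:
                sites.add(coords[i + 2])
    return sites


def ld_prune(gm: GenotypeMatrix, params: LdParams) -> list[int]:
    """Greedy left-to-right LD pruning on diploid dosages.

    A later variant is dropped when its squared Pearson correlation with
    any of the last ``params.window - 1`` retained variants exceeds
    (strictly) the threshold; defining the window over retained sites
    makes pruning idempotent.  Missing genotypes are excluded pairwise;
    monomorphic variants are retained untested (correlation undefined).
    Returns retained variant indices in order.
    """
    dos = gm.dosage()
    retained: list[int] = []
    for i in range(gm.n_variants):
        xi = dos[i]
        drop = False
        for j in reversed(retained[-(params.window - 1):]):
            r2 = _pairwise_r2(xi, dos[j])
            if r2 is not None and r2 > params.r2_threshold:
                drop = True
                break
        if not drop:
            retained.append(i)
    return retained


def _pairwise_r2(x: np.ndarray, y: np.ndarray):
    m = ~(np.isnan(x) | np.isnan(y))
    if m.sum() < 2:
        return None
    xs, ys = x[m], y[m]
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return None
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)
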