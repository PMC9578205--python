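"""Synthetic-data generation: genotype scenarios under the competing
demographies, implanted introgression tracts and homozygous runs, and
gene/GO/reference annotations.

Every generator is a pure function of (parameters, seed/generator).  The
default scenario scale mirrors the ABC sample configuration (8+8+8+5
diploids over four demes) on a few synthetic contigs, small enough for
desk-scale end-to-end runs while preserving the analysis semantics of the
full study design (47 wildcats + 37 domestic cats were sequenced in the
real data; scaled down here).
"""

from __future__ import annotations

import numpy as np

from .coalsim import DemographicModel, LocusConfig, simulate_windows
from .genomatrix import GeneRecord, GenotypeMatrix, PopulationMap, Variant

DEFAULT_ROLES = {"Cs": "P1", "Ws": "P2", "Ec": "P3", "MEc": "outgroup"}
_BASES = np.array(list("ACGT"))

#: contig layout for the introgression calibration scenario (16 Mb total)
CALIBRATION_CONTIGS = {f"chr{i}": 4_000_000 for i in range(1, 5)}


def calibration_model(donor_pool: bool = True) -> DemographicModel:
    """Fixed demography for known-truth D / f-hat calibration runs.

    Large-Ne wildcat demes (Ws, Cs; recent split) keep the recipient side
    of the four-taxon tree symmetric, while the European domestic deme
    (Ec) passes a strong domestication bottleneck so that donor
    haplotypes carry drifted allele frequencies — the signal both
    Patterson's D and the f-hat denominator rely on.  With
    ``donor_pool`` the Ec sample is doubled so half can act as implant
    donors outside the analysed P3 panel (keeping the f-hat denominator
    independent of the implanted haplotypes).
    """
    return DemographicModel(
        demes=["Ws", "Cs", "Ec", "MEc"],
        sizes={"Ws": 20000, "Cs": 20000, "Ec": 1000, "MEc": 20000},
        splits=[
            (100.0, "Cs", "Ws"),
            (2000.0, "Ec", "MEc"),
            (10000.0, "Ws", "MEc"),
        ],
        size_changes=[(10000.0, "MEc", 30000.0)],
        samples={"Ws": 16, "Cs": 16, "Ec": 32 if donor_pool else 16, "MEc": 10},
    )


def donor_split_popmap(pm: PopulationMap, group: str = "Ec",
                       n_analysis: int = 8,
                       donor_group: str = "EcDonor") -> PopulationMap:
    """Move all but the first ``n_analysis`` diploids of ``group`` into a
    separate donor group excluded from the four-taxon roles."""
    assignments = dict(pm.assignments)
    for s, g in pm.assignments.items():
        if g == group and int(s.rsplit("_", 1)[1]) >= n_analysis:
            assignments[s] = donor_group
    return PopulationMap(assignments, dict(pm.roles))


def make_recombining_scenario(
    model: DemographicModel,
    contigs: dict[str, int],
    rng: np.random.Generator,
    recombination_rate: float = 1e-8,
    roles: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Simulate whole recombining contigs under the model.

    Each contig is one msprime ancestry simulation with uniform
    recombination and infinite-sites mutation at the model's mu; this is
    the realistic layout for statistics that rely on between-site
    independence (D/f-hat calibration).  Returns a phased matrix plus a
    population map carrying the default four-taxon roles.
    """
    import msprime

    from .coalsim import _seed

    groups = [g for g in model.demes if model.samples.get(g, 0) > 0]
    samples = [f"{g}_{i}" for g in groups for i in range(model.samples[g] // 2)]
    variants, rows = [], []
    for chrom in sorted(contigs):
        ts = msprime.sim_ancestry(
            samples={g: model.samples[g] // 2 for g in groups},
            demography=model.to_demography(),
            sequence_length=int(contigs[chrom]),
            recombination_rate=recombination_rate,
            random_seed=_seed(rng),
        )
        mts = msprime.sim_mutations(
            ts, rate=model.mu, random_seed=_seed(rng), discrete_genome=False
        )
        pop_by_name = {mts.population(i).metadata["name"]: i
                       for i in range(mts.num_populations)}
        order = np.concatenate(
            [mts.samples(population=pop_by_name[g]) for g in groups]
        )
        gmat = mts.genotype_matrix()[:, order]
        pos = np.floor(
            np.array([s.position for s in mts.sites()])
        ).astype(int)
        seen = set()
        for si in range(pos.size):
            p = int(pos[si])
            if p in seen:
                continue
            seen.add(p)
            ref, alt = rng.choice(4, size=2, replace=False)
            variants.append(
                Variant(chrom, p, str(_BASES[ref]), str(_BASES[alt]))
            )
            rows.append(gmat[si].reshape(-1, 2).astype(np.int8))
    calls = (
        np.stack(rows)
        if rows else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    gm = GenotypeMatrix(variants, samples, calls, phased=True)
    roles = roles if roles is not None else DEFAULT_ROLES
    pm = PopulationMap(
        {s: s.rsplit("_", 1)[0] for s in samples},
        {g: r for g, r in roles.items() if g in groups},
    )
    return gm, pm


def make_scenario(
    model: DemographicModel,
    n_loci: int,
    locus_length: int,
    contigs: dict[str, int],
    rng: np.random.Generator,
    roles: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Simulate ``n_loci`` unlinked loci and lay them out on contigs.

    Loci occupy consecutive ``locus_length``-bp slots per contig (no
    intra-locus recombination, free recombination between loci); an error
    is raised when the layout cannot hold all loci.  Returns a phased
    matrix plus a population map carrying the default four-taxon roles.
    """
    slots = []
    for chrom, length in contigs.items():
        for k in range(int(length) // int(locus_length)):
            slots.append((chrom, k * int(locus_length)))
    if len(slots) < n_loci:
        raise ValueError(
            f"contig layout holds {len(slots)} loci of {locus_length} bp, "
            f"need {n_loci}"
        )
    groups = [g for g in model.demes if model.samples.get(g, 0) > 0]
    samples = [f"{g}_{i}" for g in groups for i in range(model.samples[g] // 2)]

    variants, rows = [], []
    locus = LocusConfig(n_loci, locus_length, mode="window")
    for (chrom, offset), (calls, labels) in zip(
        slots, simulate_windows(model, locus, rng, groups=groups)
    ):
        if calls.shape[0] == 0:
            continue
        # site coordinates within the locus slot, unique and sorted
        n_sites = calls.shape[0]
        pos = np.sort(
            rng.choice(int(locus_length), size=min(n_sites, int(locus_length)),
                       replace=False)
        )
        for si in range(pos.size):
            ref, alt = rng.choice(4, size=2, replace=False)
            variants.append(
                Variant(chrom, int(offset + pos[si]),
                        str(_BASES[ref]), str(_BASES[alt]))
            )
            rows.append(calls[si])
    order = sorted(range(len(variants)),
                   key=lambda i: (variants[i].chrom, variants[i].pos))
    variants = [variants[i] for i in order]
    calls = (
        np.stack([rows[i] for i in order])
        if rows else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    gm = GenotypeMatrix(variants, samples, calls, phased=True)
    roles = roles if roles is not None else DEFAULT_ROLES
    pm = PopulationMap(
        {s: s.rsplit("_", 1)[0] for s in samples},
        {g: r for g, r in roles.items() if g in groups},
    )
    return gm, pm


def implant_introgression(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    source_group: str,
    target_group: str,
    f_true: float,
    tract_length: int,
    contigs: dict[str, int],
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, list[tuple]]:
    """Copy source haplotypes over random target-haplotype tracts.

    Tracts are ``tract_length``-bp slots chosen without replacement over
    (haplotype, slot) pairs so the implanted fraction matches ``f_true``
    up to slot granularity.  Returns the modified matrix and the truth
    intervals [(sample, hap, chrom, start, end), ...].
    """
    if not 0 <= f_true <= 1:
        raise ValueError("f_true must be in [0, 1]")
    if not gm.phased:
        raise ValueError("implanting tracts requires phased input")
    calls = gm.calls.copy()
    if f_true == 0:
        return GenotypeMatrix(gm.variants, gm.samples, calls, True), []
    tgt = [s for s in pm.group_samples(target_group) if s in gm.samples]
    src = [s for s in pm.group_samples(source_group) if s in gm.samples]
    tgt_idx = gm.sample_index(tgt)
    src_idx = gm.sample_index(src)
    slots = []
    for chrom, length in contigs.items():
        for k in range(int(length) // int(tract_length)):
            slots.append((chrom, k * int(tract_length)))
    pairs = [(j, h, s) for j in tgt_idx for h in (0, 1) for s in range(len(slots))]
    n_tracts = int(round(f_true * len(pairs)))
    chosen = rng.choice(len(pairs), size=n_tracts, replace=False)
    pos = np.array([v.pos for v in gm.variants])
    chroms = np.array([v.chrom for v in gm.variants])
    truth = []
    for c in chosen:
        j, h, si = pairs[c]
        chrom, start = slots[si]
        end = start + int(tract_length)
        donor_j = int(rng.choice(src_idx))
        donor_h = int(rng.integers(2))
        m = (chroms == chrom) & (pos >= start) & (pos < end)
        calls[m, j, h] = calls[m, donor_j, donor_h]
        truth.append((gm.samples[j], h, chrom, start, end))
    return GenotypeMatrix(gm.variants, gm.samples, calls, True), truth


def implant_roh(
    gm: GenotypeMatrix,
    sample: str,
    intervals: list[tuple[str, int, int]],
    contigs: dict[str, int],
) -> GenotypeMatrix:
    """Force perfect homozygosity for ``sample`` inside ``intervals``
    (chrom, start, end) by copying haplotype 0 over haplotype 1."""
    calls = gm.calls.copy()
    j = gm.samples.index(sample)
    pos = np.array([v.pos for v in gm.variants])
    chroms = np.array([v.chrom for v in gm.variants])
    for chrom, start, end in intervals:
        if chrom not in contigs or start < 0 or end > contigs[chrom]:
            raise ValueError(f"interval {chrom}:{start}-{end} outside contigs")
        m = (chroms == chrom) & (pos >= start) & (pos < end)
        calls[m, j, 1] = calls[m, j, 0]
    return GenotypeMatrix(gm.variants, gm.samples, calls, gm.phased)


# ---------------------------------------------------------------------------
# Annotations: genes, CDS, reference, GO
# ---------------------------------------------------------------------------

def make_annotation(
    contigs: dict[str, int],
    n_genes: int,
    n_terms: int,
    rng: np.random.Generator,
    gene_length: int = 3000,
    terms_per_gene: int = 3,
    enriched_fraction: float = 0.1,
):
    """Non-overlapping genes with valid CDS, a matching random reference,
    and random GO assignments with one designated enriched term.

    Returns (genes, reference {contig: seq}, gff3_lines, gene_terms,
    enriched_term, enriched_genes).  The enriched term is attached to a
    designated gene subset so that querying exactly those genes as
    candidates must rank it first.
    """
    gene_length = int(gene_length) // 3 * 3
    slots = []
    for chrom, length in contigs.items():
        step = gene_length * 2
        for k in range((int(length) - gene_length) // step):
            slots.append((chrom, k * step + gene_length // 2))
    if len(slots) < n_genes:
        raise ValueError(f"{n_genes} genes do not fit the contig layout")
    reference = {
        chrom: rng.choice(4, size=int(length))
        for chrom, length in contigs.items()
    }
    genes, gff = [], ["##gff-version 3"]
    for gi in range(n_genes):
        chrom, start = slots[gi]
        end = start + gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        codons = _random_cds_codons(gene_length // 3, rng)
        seq = "".join(codons)
        arr = np.array([_BASES.tolist().index(b) for b in seq])
        if strand == "-":
            arr = 3 - arr[::-1]  # reverse complement (A<->T, C<->G)
        reference[chrom][start:end] = arr
        name = f"gene{gi}"
        genes.append(GeneRecord(name, chrom, start, end, strand))
        gff.append(
            f"{chrom}\tsynth\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={name}"
        )
        gff.append(
            f"{chrom}\tsynth\tCDS\t{start + 1}\t{end}\t.\t{strand}\t0\t"
            f"ID={name}.cds;Parent={name}"
        )
    ref_str = {c: "".join(_BASES[a] for a in arr) for c, arr in reference.items()}
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    enriched_term = terms[0]
    n_enr = max(2, int(round(enriched_fraction * n_genes)))
    enriched_genes = [g.gene_id for g in genes[:n_enr]]
    gene_terms: dict[str, set] = {g.gene_id: set() for g in genes}
    for g in genes:
        for t in rng.choice(terms[1:], size=min(terms_per_gene, n_terms - 1),
                            replace=False):
            gene_terms[g.gene_id].add(str(t))
    for g in enriched_genes:
        gene_terms[g].add(enriched_term)
    return genes, ref_str, gff, gene_terms, enriched_term, enriched_genes


def _random_cds_codons(n_codons: int, rng) -> list[str]:
    """ATG + random non-stop codons + stop codon."""
    stops = {"TAA", "TAG", "TGA"}
    body = []
    while len(body) < n_codons - 2:
        codon = "".join(_BASES[rng.integers(4)] for _ in range(3))
        if codon not in stops:
            body.append(codon)
    return ["ATG"] + body + ["TAA"]


# -- plain-text writers ------------------------------------------------------

def write_fasta(reference: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(genes: list[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\n")


def write_gff3(gff_lines: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")


def write_gene_terms(gene_terms: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene_terms):
            for t in sorted(gene_terms[gene]):
                fh.write(f"{gene}\t{t}\n")


def read_gene_terms(path) -> dict[str, set]:
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out
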