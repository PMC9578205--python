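"""Structured coalescent simulation of joint SFS replicates and 10-kb
sequence windows.

Demographic models are piecewise-constant-size deme structures with clean
population splits (backwards in time, all lineages of the child deme move
into the parent) and one-way admixture pulses (forwards in time a fraction
alpha of the target deme's ancestry derives from the source at time T;
backwards, each target lineage migrates to the source with probability
alpha).  Genealogies are generated by msprime; mutations follow the
infinite-sites model.

SFS replicates exploit the fact that, conditional on the genealogy, the
number of infinite-sites mutations subtending each derived-count cell is
Poisson with mean ``mu * (branch length subtending the cell)`` and
independent across cells: the branch-mode allele-frequency spectrum is
computed once per locus and Poisson noise is added per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .sfs import JointSFS


@dataclass(frozen=True)
class Pulse:
    """One-way admixture: at ``time`` (generations ago) a fraction
    ``alpha`` of ``target``'s ancestry derives from ``source``."""

    time: float
    source: str
    target: str
    alpha: float


@dataclass(frozen=True)
class Split:
    """Backwards in time at ``time`` all lineages in ``child`` move to
    ``parent`` (forward-time divergence of child from parent)."""

    time: float
    child: str
    parent: str


@dataclass
class DemographicModel:
    demes: list[str]
    sizes: dict[str, float]  # present-day diploid Ne per deme
    splits: list[Split] = field(default_factory=list)
    pulses: list[Pulse] = field(default_factory=list)
    size_changes: list[tuple[float, str, float]] = field(default_factory=list)
    mu: float = 1e-8
    gen_time: float = 2.0
    samples: dict[str, int] = field(default_factory=dict)  # haploid sizes

    def __post_init__(self):
        self.splits = [Split(*s) if not isinstance(s, Split) else s
                       for s in self.splits]
        self.pulses = [Pulse(*p) if not isinstance(p, Pulse) else p
                       for p in self.pulses]
        self.validate()

    # -- validation -------------------------------------------------------
    def _death_time(self, deme: str) -> float:
        for s in self.splits:
            if s.child == deme:
                return s.time
        return np.inf

    def validate(self) -> None:
        for s in self.splits:
            if s.time <= 0:
                raise ValueError(f"split time must be > 0, got {s.time}")
            if s.child not in self.demes or s.parent not in self.demes:
                raise ValueError(f"split references unknown deme: {s}")
        for p in self.pulses:
            if p.time <= 0:
                raise ValueError(f"pulse time must be > 0, got {p.time}")
            if not 0 <= p.alpha < 1:
                raise ValueError(f"pulse proportion must be in [0, 1): {p.alpha}")
            for deme in (p.source, p.target):
                if deme not in self.demes:
                    raise ValueError(f"pulse references unknown deme {deme!r}")
                if p.time >= self._death_time(deme):
                    raise ValueError(
                        f"pulse at t={p.time} references deme {deme!r} which "
                        f"merged at t={self._death_time(deme)}"
                    )
        children = {s.child for s in self.splits}
        roots = [d for d in self.demes if d not in children]
        if len(roots) != 1:
            raise ValueError(
                f"model must leave exactly one root deme, found {roots}; "
                "lineages would be stranded"
            )
        for d in self.demes:
            if self.sizes.get(d, 0) <= 0:
                raise ValueError(f"deme {d!r} needs a positive size")

    # -- msprime bridge ---------------------------------------------------
    def to_demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for d in self.demes:
            dem.add_population(name=d, initial_size=self.sizes[d])
        for t, deme, size in self.size_changes:
            dem.add_population_parameters_change(
                time=t, population=deme, initial_size=size
            )
        for p in self.pulses:
            # backwards in time: lineages in target move to source w.p. alpha
            dem.add_mass_migration(
                time=p.time, source=p.target, dest=p.source, proportion=p.alpha
            )
        for s in self.splits:
            dem.add_mass_migration(
                time=s.time, source=s.child, dest=s.parent, proportion=1.0
            )
        dem.sort_events()
        return dem

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "demes": list(self.demes),
            "sizes": dict(self.sizes),
            "splits": [[s.time, s.child, s.parent] for s in self.splits],
            "pulses": [[p.time, p.source, p.target, p.alpha] for p in self.pulses],
            "size_changes": [list(x) for x in self.size_changes],
            "mu": self.mu,
            "gen_time": self.gen_time,
            "samples": dict(self.samples),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            demes=list(d["demes"]),
            sizes={k: float(v) for k, v in d["sizes"].items()},
            splits=[Split(float(t), c, p) for t, c, p in d.get("splits", [])],
            pulses=[Pulse(float(t), s, g, float(a))
                    for t, s, g, a in d.get("pulses", [])],
            size_changes=[(float(t), dm, float(n))
                          for t, dm, n in d.get("size_changes", [])],
            mu=float(d.get("mu", 1e-8)),
            gen_time=float(d.get("gen_time", 2.0)),
            samples={k: int(v) for k, v in d.get("samples", {}).items()},
        )

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


@dataclass(frozen=True)
class LocusConfig:
    n_loci: int
    locus_length: float
    mode: str = "sfs"  # "sfs" | "window"

    def __post_init__(self):
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("need n_loci >= 1 and locus_length >= 1")
        if self.mode not in ("sfs", "window"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _sample_sets(model, groups=None):
    groups = list(groups) if groups is not None else [
        g for g in model.demes if model.samples.get(g, 0) > 0
    ]
    for g in groups:
        n = model.samples.get(g, 0)
        if n <= 0:
            raise ValueError(f"no samples configured for deme {g!r}")
        if n % 2:
            raise ValueError(f"haploid sample size for {g!r} must be even")
    return groups


def _ancestry_reps(model, groups, length, n_reps, rng):
    sample_spec = {g: model.samples[g] // 2 for g in groups}  # diploids
    return msprime.sim_ancestry(
        samples=sample_spec,
        demography=model.to_demography(),
        sequence_length=length,
        recombination_rate=0,
        num_replicates=n_reps,
        random_seed=_seed(rng),
    )


def simulate_genealogy(model: DemographicModel, rng, groups=None):
    """One coalescent genealogy (a tskit Tree; branch lengths in
    generations) under the model, single locus, no recombination."""
    groups = _sample_sets(model, groups)
    ts = next(_ancestry_reps(model, groups, 1, 1, rng))
    return ts.first()


def simulate_sfs(
    model: DemographicModel, locus: LocusConfig, rng, groups=None
) -> JointSFS:
    """Joint SFS aggregated over ``locus.n_loci`` independent loci.

    Per locus the branch-mode joint allele-frequency spectrum is scaled by
    mu and Poisson-sampled per cell (exact for infinite-sites mutation
    dropped uniformly on branches).
    """
    groups = _sample_sets(model, groups)
    shape = tuple(model.samples[g] + 1 for g in groups)
    expected = np.zeros(shape)
    for ts in _ancestry_reps(model, groups, locus.locus_length, locus.n_loci, rng):
        pop_by_name = {ts.population(i).metadata["name"]: i
                       for i in range(ts.num_populations)}
        sample_sets = [ts.samples(population=pop_by_name[g]) for g in groups]
        afs = ts.allele_frequency_spectrum(
            sample_sets=sample_sets,
            mode="branch",
            polarised=True,
            span_normalise=False,
        )
        expected += afs
    cells = rng.poisson(model.mu * expected).astype(float)
    return JointSFS(groups, cells, polarized=True)


def simulate_windows(
    model: DemographicModel, locus: LocusConfig, rng, groups=None
):
    """Yield per-window genotype sets for the FST null distribution.

    Each window is one genealogy (no intra-window recombination) with
    infinite-sites mutations; yields ``(calls, pop_labels)`` where
    ``calls`` has shape (n_sites, n_diploids, 2) and ``pop_labels`` gives
    the deme of each diploid.  Monomorphic windows yield empty ``calls``.
    """
    groups = _sample_sets(model, groups)
    for ts in _ancestry_reps(model, groups, locus.locus_length, locus.n_loci, rng):
        mts = msprime.sim_mutations(
            ts, rate=model.mu, random_seed=_seed(rng), discrete_genome=False
        )
        pop_by_name = {mts.population(i).metadata["name"]: i
                       for i in range(mts.num_populations)}
        labels = []
        order = []
        for g in groups:
            nodes = mts.samples(population=pop_by_name[g])
            order.extend(nodes)
            labels.extend([g] * (len(nodes) // 2))
        order = np.array(order, dtype=int)
        gmat = mts.genotype_matrix()  # (n_sites, n_sample_nodes)
        if gmat.size:
            gmat = gmat[:, order]
            calls = gmat.reshape(gmat.shape[0], -1, 2).astype(np.int8)
        else:
            calls = np.empty((0, len(labels), 2), dtype=np.int8)
        yield calls, labels


def mean_pairwise_diversity(model, locus, rng, groups=None) -> float:
    """Monte-Carlo mean pairwise diversity per locus (mutation-based),
    for calibration against the panmictic expectation 4*N*mu*L."""
    groups = _sample_sets(model, groups)
    tot = 0.0
    for ts in _ancestry_reps(model, groups, locus.locus_length, locus.n_loci, rng):
        mts = msprime.sim_mutations(
            ts, rate=model.mu, random_seed=_seed(rng), discrete_genome=False
        )
        tot += mts.diversity(span_normalise=False)
    return tot / locus.n_loci
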