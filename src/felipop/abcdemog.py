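"""Demographic model choice by rejection ABC on the joint SFS.

Four competing demographic histories for the two German wildcat demes
(Ws = Western, Cs = Central) and two domestic-cat demes (Ec = European,
MEc = Middle Eastern, which also polarizes the SFS):

* M1 — early Ws/Cs split, differential introgression (two independent
  pulses Ec->Ws and Ec->Cs);
* M2 — early split, one late pulse (Ec->Ws);
* M3 — late split, early pulse (necessarily into the ancestral wildcat
  deme, since the pulse predates the split);
* M4 — late split, late pulse; the pulse targets the ancestral wildcat
  deme whenever the drawn pulse time predates the split time, else Ws.

Topology is ((Ws,Cs),(Ec,MEc)) with Ec branching from MEc.  Summary
statistic: the flattened joint SFS with monomorphic corner cells removed,
each coordinate standardized by its median absolute deviation over the
pooled reference table; rejection acceptance of the closest
``tolerance`` fraction by Euclidean distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .coalsim import DemographicModel, LocusConfig, Pulse, Split, simulate_sfs
from .sfs import JointSFS

MU = 1e-8          # per bp per generation
GEN_TIME = 2.0     # years

DEFAULT_SAMPLES = {"Ws": 16, "Cs": 16, "Ec": 16, "MEc": 10}

# prior stand-ins; bounds in generations / diploids
DEFAULT_PRIORS = {
    "late_split": ("uniform", 50.0, 500.0),
    "early_split": ("uniform", 2000.0, 5000.0),
    "late_pulse": ("uniform", 250.0, 1100.0),
    "early_pulse": ("uniform", 900.0, 1500.0),
    "ne": ("loguniform", 1e2, 1e5),
    "alpha": ("uniform", 0.01, 0.5),
    "t_dom": ("uniform", 3000.0, 8000.0),
    "t_root": ("loguniform", 2e4, 1e5),
}


@dataclass(frozen=True)
class Prior:
    dist: str  # "uniform" | "loguniform"
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"prior needs lo < hi, got {self.lo}, {self.hi}")
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior family {self.dist!r}")

    def draw(self, rng) -> float:
        if self.dist == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))


@dataclass
class ModelSpec:
    """A named demography template: priors plus a builder mapping a
    parameter draw to a concrete :class:`DemographicModel`."""

    name: str
    prior: dict[str, Prior]
    builder: "callable"
    samples: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLES))

    def draw_params(self, rng) -> dict[str, float]:
        return {k: p.draw(rng) for k, p in self.prior.items()}

    def build(self, params: dict[str, float]) -> DemographicModel:
        return self.builder(params, self.samples)


def _base(params, samples, splits, pulses):
    size_changes = [
        (params["T_split"], "Ws", params["N_ancW"]),
        (params["T_root"], "MEc", params["N_root"]),
    ]
    return DemographicModel(
        demes=["Ws", "Cs", "Ec", "MEc"],
        sizes={
            "Ws": params["N_Ws"],
            "Cs": params["N_Cs"],
            "Ec": params["N_Ec"],
            "MEc": params["N_MEc"],
        },
        splits=splits,
        pulses=pulses,
        size_changes=size_changes,
        mu=MU,
        gen_time=GEN_TIME,
        samples=dict(samples),
    )


def _splits(params):
    return [
        Split(params["T_split"], "Cs", "Ws"),
        Split(params["T_dom"], "Ec", "MEc"),
        Split(params["T_root"], "Ws", "MEc"),
    ]


def _build_m1(params, samples):
    pulses = [
        Pulse(params["T_intro_Ws"], "Ec", "Ws", params["alpha_Ws"]),
        Pulse(params["T_intro_Cs"], "Ec", "Cs", params["alpha_Cs"]),
    ]
    return _base(params, samples, _splits(params), pulses)


def _build_single_pulse(params, samples):
    # pulse lands in the ancestral wildcat deme (carried by Ws) whenever
    # it predates the Ws/Cs split
    target = "Ws"
    pulses = [Pulse(params["T_intro"], "Ec", target, params["alpha"])]
    return _base(params, samples, _splits(params), pulses)


def builtin_models(samples=None, priors=None) -> list[ModelSpec]:
    """The four competing demographic model templates M1..M4."""
    samples = dict(samples or DEFAULT_SAMPLES)
    pr = dict(DEFAULT_PRIORS)
    if priors:
        pr.update(priors)
    P = {k: Prior(*v) for k, v in pr.items()}
    ne_block = {
        "N_Ws": P["ne"], "N_Cs": P["ne"], "N_Ec": P["ne"], "N_MEc": P["ne"],
        "N_ancW": P["ne"], "N_root": P["ne"],
    }
    shared = {**ne_block, "T_dom": P["t_dom"], "T_root": P["t_root"]}
    m1 = ModelSpec(
        "M1",
        {**shared, "T_split": P["early_split"],
         "T_intro_Ws": P["late_pulse"], "T_intro_Cs": P["late_pulse"],
         "alpha_Ws": P["alpha"], "alpha_Cs": P["alpha"]},
        _build_m1, samples,
    )
    m2 = ModelSpec(
        "M2",
        {**shared, "T_split": P["early_split"],
         "T_intro": P["late_pulse"], "alpha": P["alpha"]},
        _build_single_pulse, samples,
    )
    m3 = ModelSpec(
        "M3",
        {**shared, "T_split": P["late_split"],
         "T_intro": P["early_pulse"], "alpha": P["alpha"]},
        _build_single_pulse, samples,
    )
    m4 = ModelSpec(
        "M4",
        {**shared, "T_split": P["late_split"],
         "T_intro": P["late_pulse"], "alpha": P["alpha"]},
        _build_single_pulse, samples,
    )
    return [m1, m2, m3, m4]


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    model_ids: np.ndarray          # (n,) str
    params: pd.DataFrame           # (n, union of parameter names)
    stats: np.ndarray              # (n, d) float32, corner cells removed
    groups: list[str]
    shape: tuple[int, ...]

    def to_tsv(self, path):
        df = pd.concat(
            [pd.Series(self.model_ids, name="model"), self.params], axis=1
        )
        stats = pd.DataFrame(
            self.stats, columns=[f"s{i}" for i in range(self.stats.shape[1])]
        )
        out = pd.concat([df, stats], axis=1)
        out.attrs = {}
        with open(path, "w") as fh:
            fh.write("#groups\t" + "\t".join(self.groups) + "\n")
            fh.write("#shape\t" + "\t".join(map(str, self.shape)) + "\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path):
        with open(path) as fh:
            groups = fh.readline().rstrip("\n").split("\t")[1:]
            shape = tuple(int(x) for x in fh.readline().split("\t")[1:])
            df = pd.read_csv(fh, sep="\t")
        stat_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
        param_cols = [c for c in df.columns if c != "model" and c not in stat_cols]
        return cls(
            df["model"].to_numpy(),
            df[param_cols],
            df[stat_cols].to_numpy(dtype=np.float32),
            groups,
            shape,
        )


def run_reference_table(
    models: list[ModelSpec],
    n_per_model: int,
    locus: LocusConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> ReferenceTable:
    """Simulate ``n_per_model`` prior draws per model to joint spectra.

    Each row stores the drawn parameters and the flattened spectrum with
    corner cells removed.  Draws violating model invariants are redrawn
    (capped); deterministic given the generator state.
    """
    sample_cfgs = {tuple(sorted(m.samples.items())) for m in models}
    if len(sample_cfgs) != 1:
        raise ValueError("all models must share one sample configuration")
    model_ids, rows, stats = [], [], []
    shape = groups = None
    for spec in models:
        for _ in range(n_per_model):
            model = None
            for _attempt in range(max_retries):
                params = spec.draw_params(rng)
                try:
                    model = spec.build(params)
                    break
                except ValueError:
                    continue
            if model is None:
                raise RuntimeError(
                    f"no valid draw for {spec.name} in {max_retries} tries"
                )
            jsfs = simulate_sfs(model, locus, rng)
            shape, groups = jsfs.shape, jsfs.groups
            model_ids.append(spec.name)
            rows.append(params)
            stats.append(jsfs.flat_no_corners().astype(np.float32))
    return ReferenceTable(
        np.array(model_ids),
        pd.DataFrame(rows),
        np.vstack(stats),
        groups,
        shape,
    )


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------

@dataclass
class AbcResult:
    tolerance: float
    accepted: pd.DataFrame            # model, distance, parameters
    model_posteriors: dict[str, float]
    best_model: str
    param_summary: pd.DataFrame       # median / q2.5 / q97.5 per parameter

    def posterior(self, model_id: str) -> float:
        return self.model_posteriors.get(model_id, 0.0)


def abc_reject(table: ReferenceTable, observed: JointSFS, tolerance: float) -> AbcResult:
    """Rejection-ABC model choice against the observed joint SFS."""
    if observed.shape != table.shape:
        raise ValueError(
            f"observed shape {observed.shape} != table shape {table.shape}"
        )
    n = len(table.model_ids)
    n_acc = int(round(tolerance * n))
    if n_acc < 1:
        raise ValueError(f"tolerance {tolerance} accepts zero of {n} rows")
    obs = observed.flat_no_corners().astype(np.float64)
    stats = table.stats.astype(np.float64)
    mad = median_abs_deviation(stats, axis=0)
    keep = mad > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-MAD summary coordinates dropped"
        )
    if not keep.any():
        raise ValueError("every summary coordinate has zero spread")
    z = (stats[:, keep] - obs[keep]) / mad[keep]
    dist = np.sqrt((z**2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:n_acc]
    acc = table.params.iloc[order].copy()
    acc.insert(0, "model", table.model_ids[order])
    acc.insert(1, "distance", dist[order])
    post = {
        m: float((table.model_ids[order] == m).sum()) / n_acc
        for m in pd.unique(table.model_ids)
    }
    best = max(post, key=post.get)
    best_rows = acc[acc["model"] == best]
    summ = {}
    for col in table.params.columns:
        vals = best_rows[col].dropna().to_numpy()
        if vals.size:
            summ[col] = {
                "median": float(np.median(vals)),
                "q2.5": float(np.quantile(vals, 0.025)),
                "q97.5": float(np.quantile(vals, 0.975)),
            }
    return AbcResult(
        tolerance=tolerance,
        accepted=acc.reset_index(drop=True),
        model_posteriors=post,
        best_model=best,
        param_summary=pd.DataFrame(summ).T,
    )


def goodness_of_fit(
    result: AbcResult,
    models: list[ModelSpec],
    observed: JointSFS,
    locus: LocusConfig,
    rng: np.random.Generator,
    max_draws: int = 200,
) -> dict:
    """Posterior-predictive envelope check for the best model.

    Re-simulates spectra at accepted parameter draws of the best model and
    reports, per summary cell, the 2.5-97.5% envelope and the fraction of
    observed cells falling inside it.
    """
    spec = {m.name: m for m in models}[result.best_model]
    rows = result.accepted[result.accepted["model"] == result.best_model]
    if len(rows) == 0:
        raise ValueError("no accepted draws for the best model")
    rows = rows.head(max_draws)
    sims = []
    for _, row in rows.iterrows():
        params = {
            k: row[k] for k in spec.prior if k in row and np.isfinite(row[k])
        }
        sims.append(
            simulate_sfs(spec.build(params), locus, rng).flat_no_corners()
        )
    sims = np.vstack(sims)
    lo = np.quantile(sims, 0.025, axis=0)
    hi = np.quantile(sims, 0.975, axis=0)
    obs = observed.flat_no_corners()
    inside = (obs >= lo) & (obs <= hi)
    return {
        "envelope_lo": lo,
        "envelope_hi": hi,
        "fraction_inside": float(inside.mean()),
        "n_draws": int(len(rows)),
    }
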