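"""Generative model for barcoded-tumor immunotherapy experiments.

Emulates the statistical structure of a ClonTracer-style lineage tracing
study in syngeneic mice: a ~2,000-barcode library transduced into a cancer
line, 250,000 cells transplanted per flank (two flanks per mouse), a severe
engraftment bottleneck, exponential clonal growth with treatment- and
cluster-specific selection, a per-mouse host immune effect shared by the two
flank tumors, Gaussian noise on log clone frequency, and multinomial read
sampling at fixed depth.

Clonal frequencies follow the forward form of the logistic selection model:
a clone with fitness advantage x grows as exp((1+x)(b_p-d_p)t) relative to a
bulk growing as exp((b_p-d_p)t), so its harvest frequency is proportional to
its founder count times exp(beta), where beta = x*(b_p-d_p)*t is the total
treatment effect on its log frequency. Latent growth-pattern clusters assign
each barcode a pair of treatment coefficients (anti-PD-1, anti-CTLA-4); the
per-mouse host effect h ~ N(0, host_sd) multiplies those coefficients by
exp(h) (stronger immune pressure, stronger clonal selection) and shrinks
bulk tumor size, producing the responder phenotype: smaller tumors with more
uneven, resistant-clone-enriched barcode distributions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TrueState",
    "SimOutput",
    "simulate_experiment",
    "simulate_expression",
    "write_sim_output",
    "random_barcode_library",
]

ARM_CONTROL = "IgG"
ARM_PD1 = "antiPD1"
ARM_CTLA4 = "antiCTLA4"

#: default latent growth-pattern clusters: (proportion, beta_PD1, beta_CTLA4)
#: betas are total effects on the natural-log harvest frequency under each arm
DEFAULT_CLUSTER_SPEC: tuple[tuple[float, float, float], ...] = (
    (0.10, -2.0, -2.0),
    (0.15, -1.2, -1.2),
    (0.20, -0.6, -0.6),
    (0.35, 0.0, 0.0),
    (0.12, 0.8, 0.8),
    (0.08, 1.6, 1.6),
)


@dataclass
class SimConfig:
    """Configuration of a simulated barcoded-tumor experiment.

    Parameters
    ----------
    library_size
        Number of distinct barcodes in the library.
    cells_transplanted
        Cells injected per flank tumor.
    engraft_prob
        Mean per-cell probability of surviving the engraftment bottleneck.
    engraft_dispersion
        Lognormal sigma of the clone-intrinsic engraftability multiplier
        (mean 1, drawn once per experiment). Positive values make the same
        clones engraft, or fail to, across tumors — the consistent absence
        of most library clones in vivo; 0 gives an independent per-tumor
        lottery at exactly ``engraft_prob``.
    net_growth
        Bulk net growth rate b_p - d_p, per day.
    t_days
        Total in vivo growth duration (days).
    treat_start_day
        Day treatment begins; affects the tumor-size trajectory only
        (cluster betas are defined as total effects on log final frequency).
    mice_per_arm
        Mapping treatment arm -> number of mice (two flank tumors each).
    cluster_spec
        Sequence of (proportion, beta_pd1, beta_ctla4) triples.
    host_sd
        Standard deviation of the per-mouse host effect on the natural-log
        scale; exp(host effect) multiplies the treatment coefficients.
    host_clone_coupling
        Fraction of ``host_sd`` acting as a host-specific clone-level
        selection effect shared by the two flank tumors of one mouse
        (immune recognition of individual clones), applied to both the
        engraftment probability and the growth-phase log frequency;
        0 removes it.
    obs_sd
        Residual s.d. of natural-log clone frequency per tumor.
    read_depth
        Sequencing reads per sample (multinomial total).
    library_log_sd
        Lognormal sigma of library barcode frequencies (0 = uniform).
    icb_kill_rate
        Bulk extra death rate per day under treatment at host multiplier 1.
    size_obs_sd
        Measurement noise s.d. on natural-log tumor size.
    volume_per_cell
        mm^3 per cell used to report tumor size.
    """

    library_size: int = 2000
    cells_transplanted: int = 250_000
    engraft_prob: float = 0.0013
    engraft_dispersion: float = 0.0
    net_growth: float = 0.5
    t_days: float = 10.0
    treat_start_day: float = 7.0
    mice_per_arm: Mapping[str, int] = field(
        default_factory=lambda: {ARM_CONTROL: 10, ARM_PD1: 15, ARM_CTLA4: 10}
    )
    cluster_spec: Sequence[tuple[float, float, float]] = DEFAULT_CLUSTER_SPEC
    host_sd: float = 0.6
    host_clone_coupling: float = 1.0
    obs_sd: float = 0.3
    read_depth: int = 1_000_000
    library_log_sd: float = 0.0
    icb_kill_rate: float = 0.3
    size_obs_sd: float = 0.1
    volume_per_cell: float = 1e-6

    def validate(self) -> None:
        props = [c[0] for c in self.cluster_spec]
        if abs(sum(props) - 1.0) > 1e-8:
            raise ValueError(f"cluster proportions sum to {sum(props)}, not 1")
        if any(p < 0 for p in props):
            raise ValueError("cluster proportions must be non-negative")
        if not 0.0 <= self.engraft_prob <= 1.0:
            raise ValueError("engraft_prob must lie in [0, 1]")
        for name in ("library_size", "cells_transplanted", "read_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.net_growth <= 0 or self.t_days <= 0:
            raise ValueError("net_growth and t_days must be positive")
        if not 0.0 <= self.treat_start_day <= self.t_days:
            raise ValueError("treat_start_day must lie within [0, t_days]")
        for name in ("host_sd", "host_clone_coupling", "obs_sd",
                     "library_log_sd", "size_obs_sd", "icb_kill_rate",
                     "engraft_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if ARM_CONTROL not in self.mice_per_arm:
            raise ValueError(f"mice_per_arm must include the {ARM_CONTROL!r} arm")
        if any(n <= 0 for n in self.mice_per_arm.values()):
            raise ValueError("mice per arm must be positive")

    def arm_beta(self, arm: str) -> np.ndarray:
        """Per-cluster total log-frequency coefficient for a treatment arm."""
        if arm == ARM_PD1:
            return np.array([c[1] for c in self.cluster_spec])
        if arm == ARM_CTLA4:
            return np.array([c[2] for c in self.cluster_spec])
        return np.zeros(len(self.cluster_spec))

    @property
    def resistant_clusters(self) -> list[int]:
        """Indices (0-based) of clusters with a positive mean treatment beta."""
        return [
            i for i, c in enumerate(self.cluster_spec) if (c[1] + c[2]) / 2 > 0
        ]


@dataclass
class TrueState:
    """Ground truth recorded by the simulator."""

    clone_cluster: pd.Series  # barcode -> 0-based cluster index
    clone_x: pd.DataFrame  # barcodes x arms, fitness advantage x_k
    host_effect: pd.Series  # mouse -> h
    founder_counts: pd.DataFrame  # barcodes x samples, engrafted founders
    harvest_freq: pd.DataFrame  # barcodes x samples, pre-sequencing frequency
    library_freq: pd.Series  # barcode -> library frequency
    engraftability: pd.Series  # barcode -> clone-intrinsic engraftment multiplier


@dataclass
class SimOutput:
    """A simulated experiment: observed tables plus the generating truth."""

    counts: pd.DataFrame  # barcodes x samples, sequencing read counts
    sizes: pd.DataFrame  # long format: sample, day, size (mm^3)
    meta: pd.DataFrame  # sample, mouse, flank, arm, size_end
    truth: TrueState
    config: SimConfig
    expression: pd.DataFrame | None = None


def random_barcode_library(n: int, rng: np.random.Generator,
                           length: int = 30) -> list[str]:
    """Draw ``n`` distinct (WS)^(length/2) barcodes (W={A,T}, S={C,G})."""
    weak = np.array(list("AT"))
    strong = np.array(list("CG"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        w = weak[rng.integers(0, 2, size=length // 2)]
        s = strong[rng.integers(0, 2, size=length // 2)]
        bc = "".join(np.char.add(w, s))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_experiment(config: SimConfig | None = None, seed: int = 0) -> SimOutput:
    """Simulate one barcoded-tumor experiment.

    Two flank tumors per mouse share the mouse's host effect. Harvest
    frequencies follow the forward selection model (founder count times
    exp(beta * exp(h)) under treatment), then receive lognormal observation
    noise and multinomial read sampling.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    L = config.library_size
    n_clusters = len(config.cluster_spec)

    barcodes = random_barcode_library(L, rng)
    props = np.array([c[0] for c in config.cluster_spec], dtype=float)
    props = props / props.sum()
    cluster = rng.choice(n_clusters, size=L, p=props)

    if config.library_log_sd > 0:
        w = rng.lognormal(-config.library_log_sd**2 / 2, config.library_log_sd, L)
    else:
        w = np.ones(L)
    lib_freq = w / w.sum()
    if config.engraft_dispersion > 0:
        engraftability = rng.lognormal(
            -config.engraft_dispersion**2 / 2, config.engraft_dispersion, L
        )
    else:
        engraftability = np.ones(L)

    gt = config.net_growth * config.t_days
    arms = list(config.mice_per_arm)
    beta_by_arm = {arm: config.arm_beta(arm)[cluster] for arm in arms}
    clone_x = pd.DataFrame(
        {arm: beta_by_arm[arm] / gt for arm in arms}, index=barcodes
    )

    t_treat = config.t_days - config.treat_start_day
    days = np.arange(0, math.floor(config.t_days) + 1, dtype=float)
    if days[-1] < config.t_days:
        days = np.append(days, config.t_days)

    samples, meta_rows, size_rows = [], [], []
    counts_cols, founders_cols, harvest_cols = {}, {}, {}
    host_effects = {}

    for arm in arms:
        for i_mouse in range(config.mice_per_arm[arm]):
            mouse = f"{arm}_m{i_mouse + 1:02d}"
            h = rng.normal(0.0, config.host_sd)
            host_effects[mouse] = h
            m_host = math.exp(h)
            treated = arm != ARM_CONTROL
            # host-specific clone-level selection, shared by both flanks;
            # its magnitude scales with the overall host variability
            u_sd = config.host_sd * config.host_clone_coupling
            u_clone = rng.normal(0.0, u_sd, L) if u_sd > 0 else np.zeros(L)
            # per-cell engraftment probability for this host: clone-intrinsic
            # engraftability modulated by the host-specific clone effect
            p_engraft = np.minimum(
                1.0, config.engraft_prob * engraftability * np.exp(u_clone)
            )
            for flank in ("L", "R"):
                sample = f"{mouse}_{flank}"
                founders = rng.multinomial(config.cells_transplanted, lib_freq)
                surv = rng.binomial(founders, p_engraft)
                present = surv > 0
                if not present.any():
                    raise RuntimeError(
                        f"no clone engrafted in {sample}; "
                        "increase engraft_prob or cells_transplanted"
                    )
                growth = np.zeros(L)
                beta_eff = (
                    beta_by_arm[arm][present] * (m_host if treated else 1.0)
                    + u_clone[present]
                )
                growth[present] = np.exp(beta_eff - beta_eff.max())
                weights = surv * growth
                freq = weights / weights.sum()
                if config.obs_sd > 0:
                    noise = np.exp(rng.normal(0.0, config.obs_sd, present.sum()))
                    freq[present] = freq[present] * noise
                    freq = freq / freq.sum()
                counts = rng.multinomial(config.read_depth, freq)

                # bulk size: engrafted cells grow at net_growth; treatment adds
                # a kill term scaled by the host multiplier; -h is the additive
                # host effect on log size
                kill = config.icb_kill_rate * m_host if treated else 0.0
                log_cells0 = math.log(surv.sum())
                for d in days:
                    t_kill = max(0.0, d - config.treat_start_day)
                    log_size = (
                        log_cells0
                        + config.net_growth * d
                        - kill * t_kill
                        - h
                        + math.log(config.volume_per_cell)
                    )
                    if config.size_obs_sd > 0:
                        log_size += rng.normal(0.0, config.size_obs_sd)
                    size_rows.append((sample, float(d), math.exp(log_size)))

                samples.append(sample)
                meta_rows.append((sample, mouse, flank, arm))
                counts_cols[sample] = counts
                founders_cols[sample] = surv
                harvest_cols[sample] = freq

    counts = pd.DataFrame(counts_cols, index=barcodes)
    sizes = pd.DataFrame(size_rows, columns=["sample", "day", "size"])
    meta = pd.DataFrame(meta_rows, columns=["sample", "mouse", "flank", "arm"])
    end_sizes = (
        sizes[sizes["day"] == sizes["day"].max()].set_index("sample")["size"]
    )
    meta["size_end"] = meta["sample"].map(end_sizes).to_numpy()

    truth = TrueState(
        clone_cluster=pd.Series(cluster, index=barcodes, name="cluster"),
        clone_x=clone_x,
        host_effect=pd.Series(host_effects, name="host_effect"),
        founder_counts=pd.DataFrame(founders_cols, index=barcodes),
        harvest_freq=pd.DataFrame(harvest_cols, index=barcodes),
        library_freq=pd.Series(lib_freq, index=barcodes, name="library_freq"),
        engraftability=pd.Series(engraftability, index=barcodes,
                                 name="engraftability"),
    )
    return SimOutput(counts=counts, sizes=sizes, meta=meta, truth=truth,
                     config=config)


def simulate_expression(
    sim: SimOutput,
    n_genes: int = 400,
    seed: int = 0,
    n_immune: int = 25,
    n_intrinsic: int = 25,
    immune_slope: float = 1.5,
    intrinsic_slope: float = 6.0,
    gene_noise_sd: float = 0.5,
    return_truth: bool = False,
):
    """Simulate a log2-TPM expression matrix tied to the simulated truth.

    Two designated blocks carry signal: ``IMM*`` genes (plus GZMA and PRF1)
    scale with the per-mouse host effect (immune infiltration), and ``RES*``
    genes scale with each tumor's cumulative resistant-cluster frequency
    (the cancer-cell-intrinsic resistance signature). Each signal gene has
    its own effect size (slope), drawn uniformly between 0.5x and 1.5x the
    block mean, so signature scoring sees a gene-level pattern and not a
    uniform shift. Remaining genes are noise around per-gene baselines.

    With ``return_truth=True`` also returns a per-gene table of block
    membership and generating slope.
    """
    n_designated = n_immune + n_intrinsic + 2
    if n_genes < n_designated:
        raise ValueError(
            f"n_genes={n_genes} smaller than designated blocks ({n_designated})"
        )
    rng = np.random.default_rng(seed)
    samples = list(sim.meta["sample"])
    h = sim.meta["mouse"].map(sim.truth.host_effect).to_numpy()

    res_clusters = sim.config.resistant_clusters
    is_res = sim.truth.clone_cluster.isin(res_clusters).to_numpy()
    rf = sim.truth.harvest_freq.loc[:, samples].to_numpy()[is_res].sum(axis=0)

    genes = (
        ["GZMA", "PRF1"]
        + [f"IMM{i:04d}" for i in range(n_immune)]
        + [f"RES{i:04d}" for i in range(n_intrinsic)]
        + [f"BG{i:04d}" for i in range(n_genes - n_designated)]
    )
    blocks = (
        ["cytolytic"] * 2
        + ["immune"] * n_immune
        + ["intrinsic"] * n_intrinsic
        + ["background"] * (n_genes - n_designated)
    )
    slopes = np.zeros(n_genes)
    slopes[: 2 + n_immune] = immune_slope * rng.uniform(0.5, 1.5, 2 + n_immune)
    slopes[2 + n_immune : n_designated] = intrinsic_slope * rng.uniform(
        0.5, 1.5, n_intrinsic
    )
    base = rng.normal(5.0, 2.0, size=n_genes)
    base[:2] = 3.0  # GZMA/PRF1 baseline log2-TPM
    E = base[:, None] + rng.normal(0.0, gene_noise_sd, size=(n_genes, len(samples)))
    E[: 2 + n_immune] += slopes[: 2 + n_immune, None] * h[None, :]
    E[2 + n_immune : n_designated] += (
        slopes[2 + n_immune : n_designated, None] * rf[None, :]
    )
    expr = pd.DataFrame(E, index=genes, columns=samples)
    if return_truth:
        gene_truth = pd.DataFrame(
            {"block": blocks, "slope": slopes},
            index=pd.Index(genes, name="gene"),
        )
        return expr, gene_truth
    return expr


def write_sim_output(sim: SimOutput, outdir: str | Path) -> None:
    """Write a simulated experiment as plain-text tables plus a truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim.counts.rename_axis("barcode").to_csv(outdir / "counts.tsv", sep="\t")
    sim.meta.to_csv(outdir / "samples.csv", index=False)
    sim.sizes.to_csv(outdir / "sizes.csv", index=False)
    if sim.expression is not None:
        sim.expression.rename_axis("gene").to_csv(
            outdir / "expression.tsv", sep="\t"
        )
    truth = {
        "clone_cluster": sim.truth.clone_cluster.to_dict(),
        "clone_x": sim.truth.clone_x.round(6).to_dict(orient="index"),
        "host_effect": sim.truth.host_effect.round(6).to_dict(),
        "config": _config_to_jsonable(sim.config),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _config_to_jsonable(config: SimConfig) -> dict:
    d = asdict(config)
    d["mice_per_arm"] = dict(config.mice_per_arm)
    d["cluster_spec"] = [list(c) for c in config.cluster_spec]
    return d
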