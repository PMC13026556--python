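"""Two-condition count simulator with planted differential hubs and survival.

The generator emulates the data the pipeline was designed for: a small gene
panel measured by RNA-seq in a tumor cohort and a healthy control cohort.
Counts are negative-binomial draws coupled through a Gaussian copula, so
rank correlations can be planted precisely while marginals stay realistic
integer counts.  A "hub" gene correlates with each of its neighbors only in
the tumor condition (one-factor construction: neighbors share the hub's
latent variable, so neighbor-neighbor correlation is the square of the
hub-neighbor one — the price of positive-definiteness).  Optional extras:
genes with true log2 mean shifts (differential expression), genes whose
expected totals sit below the low-count filter, and exponential survival
times whose hazard is raised for a planted "high" subject group whose
marker-gene means are shifted up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import ExpressionMatrix, Family, GenePanel
from .stratify_survival import SurvivalTable

__all__ = [
    "HubSpec",
    "SurvivalConfig",
    "SimulationConfig",
    "GroundTruth",
    "make_panel",
    "generate_two_condition_counts",
    "generate_survival",
]


@dataclass(frozen=True)
class HubSpec:
    """One planted hub: its latent correlation to each of its neighbors."""

    hub: str
    n_neighbors: int
    rho: float

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("latent hub correlation must lie in (0, 1)")
        if self.n_neighbors < 1:
            raise ValueError("a hub needs at least one neighbor")


@dataclass(frozen=True)
class SurvivalConfig:
    """Exponential survival linked to a planted high/low subject split.

    ``baseline_hazard`` is events per month for the low group;
    ``hazard_ratio`` multiplies it for the high group.  ``censoring_rate``
    is the probability a subject is censored (at a uniform fraction of
    their event time).  ``group_shift`` is the log2 mean shift applied to
    the marker genes of high-group subjects so stratification can recover
    the planted split from expression.
    """

    baseline_hazard: float = 0.055  # ~12.6-month median survival
    hazard_ratio: float = 4.0
    censoring_rate: float = 0.2
    group_shift: float = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic two-cohort experiment.

    Defaults mirror the design the pipeline targets: a 39-gene panel,
    145 tumor vs 255 control samples, one planted hub with 8 neighbors at
    latent correlation 0.7, negative-binomial counts.
    """

    n_genes: int = 39
    n_tumor: int = 145
    n_control: int = 255
    hub_spec: tuple[HubSpec, ...] = (HubSpec("G001", 8, 0.7),)
    background_rho: float = 0.0
    nb_mean: float = 100.0
    nb_dispersion: float = 0.5
    n_lowcount_genes: int = 0
    n_de_genes: int = 0
    de_log2_shift: float = 3.0
    survival: SurvivalConfig = SurvivalConfig()
    marker_genes: tuple[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor <= 3 or self.n_control <= 3:
            raise ValueError("cohorts need more than 3 samples")
        if not 0 <= self.background_rho < 1:
            raise ValueError("background_rho must lie in [0, 1)")
        used = sum(1 + h.n_neighbors for h in self.hub_spec)
        if used + self.n_lowcount_genes > self.n_genes:
            raise ValueError("hub neighborhoods plus low-count genes exceed panel size")

    @property
    def genes(self) -> list[str]:
        return [f"G{i + 1:03d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """What was planted: edges, hubs, DE genes, low-count genes, groups."""

    planted_edges: set[tuple[str, str]]
    planted_hubs: set[str]
    de_genes: dict[str, float]
    lowcount_genes: set[str]
    survival_groups: pd.Series  # tumor subject -> "high" | "low"
    marker_genes: tuple[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_edges": sorted(map(list, self.planted_edges)),
            "planted_hubs": sorted(self.planted_hubs),
            "de_genes": self.de_genes,
            "lowcount_genes": sorted(self.lowcount_genes),
            "survival_groups": self.survival_groups.to_dict(),
            "marker_genes": list(self.marker_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        groups = pd.Series(d["survival_groups"], name="group")
        groups = groups.sort_index()
        return cls(
            planted_edges={tuple(e) for e in d["planted_edges"]},
            planted_hubs=set(d["planted_hubs"]),
            de_genes={k: float(v) for k, v in d["de_genes"].items()},
            lowcount_genes=set(d["lowcount_genes"]),
            survival_groups=groups,
            marker_genes=tuple(d["marker_genes"]),
        )


def make_panel(genes: list[str]) -> GenePanel:
    """Annotate a gene list with lectin-family labels, round-robin."""
    fams = [Family.SIGLEC, Family.GALECTIN, Family.CTYPE]
    return GenePanel(tuple((g, fams[i % 3]) for i, g in enumerate(genes)))


def _assign_roles(cfg: SimulationConfig) -> tuple[dict[str, list[str]], list[str]]:
    """Map each hub to its neighbor genes; return (hub->neighbors, lowcount)."""
    genes = cfg.genes
    hub_names = [h.hub for h in cfg.hub_spec]
    if len(set(hub_names)) != len(hub_names):
        raise ValueError("duplicate hub genes in hub_spec")
    pool = [g for g in genes if g not in hub_names]
    neighbors: dict[str, list[str]] = {}
    idx = 0
    for h in cfg.hub_spec:
        if h.hub not in genes:
            raise ValueError(f"hub {h.hub!r} not in the simulated panel")
        neighbors[h.hub] = pool[idx: idx + h.n_neighbors]
        idx += h.n_neighbors
    lowcount = pool[idx: idx + cfg.n_lowcount_genes]
    return neighbors, lowcount


def _latent_correlation(cfg: SimulationConfig, tumor: bool) -> np.ndarray:
    genes = cfg.genes
    g = len(genes)
    pos = {name: i for i, name in enumerate(genes)}
    corr = np.full((g, g), cfg.background_rho)
    np.fill_diagonal(corr, 1.0)
    if tumor:
        neighbors, _ = _assign_roles(cfg)
        for h in cfg.hub_spec:
            hi = pos[h.hub]
            nbr_idx = [pos[n] for n in neighbors[h.hub]]
            for j in nbr_idx:
                corr[hi, j] = corr[j, hi] = h.rho
            for a in nbr_idx:
                for b in nbr_idx:
                    if a != b:
                        corr[a, b] = h.rho**2
    # guard: the one-factor construction is PSD for background_rho=0; with
    # background the combination can lose definiteness
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-10:
        raise ValueError("latent correlation matrix is not positive semidefinite")
    return corr


def _copula_counts(
    latent: np.ndarray, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Map standard-normal latents to NB(mean, dispersion) counts per gene.

    ``means`` is genes x samples (per-sample means allow planted subject
    groups); var = mu + dispersion * mu^2.
    """
    u = stats.norm.cdf(latent)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    size = 1.0 / dispersion
    p = size / (size + means)
    return stats.nbinom.ppf(u, size, p)


def generate_two_condition_counts(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Simulate tumor and control count matrices plus their ground truth."""
    genes = cfg.genes
    g = len(genes)
    neighbors, lowcount = _assign_roles(cfg)
    rng = np.random.default_rng([cfg.seed, 101])

    corr_T = _latent_correlation(cfg, tumor=True)
    corr_C = _latent_correlation(cfg, tumor=False)
    chol_T = np.linalg.cholesky(corr_T + 1e-12 * np.eye(g))
    chol_C = np.linalg.cholesky(corr_C + 1e-12 * np.eye(g))
    z_T = chol_T @ rng.standard_normal((g, cfg.n_tumor))
    z_C = chol_C @ rng.standard_normal((g, cfg.n_control))

    # per-gene base means; low-count genes sit well under the 500 filter
    base = np.full(g, cfg.nb_mean)
    lc_set = set(lowcount)
    for i, name in enumerate(genes):
        if name in lc_set:
            base[i] = min(0.5, 400.0 / max(cfg.n_tumor, cfg.n_control))

    # DE genes: log2 shift applied to tumor means (skip hubs/neighbors/lowcount)
    structured = set(h.hub for h in cfg.hub_spec)
    for nbrs in neighbors.values():
        structured.update(nbrs)
    de_pool = [x for x in genes if x not in structured and x not in lc_set]
    de_genes = {x: cfg.de_log2_shift for x in de_pool[: cfg.n_de_genes]}
    if cfg.n_de_genes > len(de_pool):
        raise ValueError("not enough unstructured genes for the requested DE genes")

    means_T = np.tile(base[:, None], (1, cfg.n_tumor))
    means_C = np.tile(base[:, None], (1, cfg.n_control))
    for i, name in enumerate(genes):
        if name in de_genes:
            means_T[i] *= 2.0 ** de_genes[name]

    # planted survival groups: random half of tumor subjects, marker genes
    # shifted up for the high group
    tumor_ids = [f"T{i + 1:03d}" for i in range(cfg.n_tumor)]
    control_ids = [f"C{i + 1:03d}" for i in range(cfg.n_control)]
    grp_rng = np.random.default_rng([cfg.seed, 202])
    high = grp_rng.random(cfg.n_tumor) < 0.5
    groups = pd.Series(np.where(high, "high", "low"), index=tumor_ids, name="group")
    if cfg.marker_genes is not None:
        markers = cfg.marker_genes
    else:
        # default markers are unstructured genes so the survival shift does
        # not perturb planted hub correlations
        marker_pool = [x for x in de_pool[cfg.n_de_genes:]] or genes[-2:]
        if len(marker_pool) < 2:
            marker_pool = genes[-2:]
        markers = (marker_pool[0], marker_pool[1])
    for mk in markers:
        i = genes.index(mk)
        means_T[i, high] *= 2.0 ** cfg.survival.group_shift

    counts_T = _copula_counts(z_T, means_T, cfg.nb_dispersion)
    counts_C = _copula_counts(z_C, means_C, cfg.nb_dispersion)

    mat_T = ExpressionMatrix(
        pd.DataFrame(counts_T, index=genes, columns=tumor_ids),
        condition="tumor", units="raw_counts")
    mat_C = ExpressionMatrix(
        pd.DataFrame(counts_C, index=genes, columns=control_ids),
        condition="control", units="raw_counts")

    planted_edges = {
        tuple(sorted((h.hub, n))) for h in cfg.hub_spec for n in neighbors[h.hub]
    }
    truth = GroundTruth(
        planted_edges=planted_edges,
        planted_hubs={h.hub for h in cfg.hub_spec},
        de_genes=de_genes,
        lowcount_genes=lc_set,
        survival_groups=groups,
        marker_genes=markers,
    )
    return mat_T, mat_C, truth


def generate_survival(truth: GroundTruth, cfg: SimulationConfig) -> SurvivalTable:
    """Exponential event times; the planted high group has elevated hazard."""
    sv = cfg.survival
    if sv.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    rng = np.random.default_rng([cfg.seed, 303])
    groups = truth.survival_groups
    rate = np.where(groups == "high",
                    sv.baseline_hazard * sv.hazard_ratio, sv.baseline_hazard)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(len(groups)) < sv.censoring_rate
    time = np.where(censored, rng.uniform(0, t_event), t_event)
    time = np.maximum(time, 1e-6)
    df = pd.DataFrame({
        "time": time,
        "event": ~censored,
        "group": groups.to_numpy(),
    }, index=groups.index)
    return SurvivalTable(df)
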