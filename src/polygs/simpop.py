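"""Synthetic polycross populations with tetrasomic inheritance.

Emulates the data-generating process of a recurrent-selection trial in
an autotetraploid outcrosser: a polycross of ``n_dams`` female parents
(a subset of the ``n_sires`` male parents) producing half-sib families
of known dam and unrecorded-but-simulated sire; biallelic marker
dosages transmitted through bivalent tetrasomic meiosis (hypergeometric
gametes, optional double reduction); GBS-like read depths with a
per-read miscall rate; and a split-plot randomized complete block
trial phenotyped over repeated harvests, with apomictic check cultivars
entering as clones.

Phenotypes follow the same effect structure the stage-1 analysis
assumes: fixed harvest effects, random block / whole-plot / interaction
effects nested in harvests, a marker-determined additive genetic value
with a compound-symmetry correlation across harvests, and residuals
drawn from a configurable covariance structure across harvests.  True
marker effects and genetic values are returned alongside so recovery
can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from polygs.dosage import MISSING, DosageMatrix, ReadCountTable
from polygs.phenomodel import PhenotypeTable, VcovStructure, build_vcov

__all__ = [
    "SimConfig",
    "Pedigree",
    "TrialSimulation",
    "simulate_founders",
    "simulate_gamete",
    "simulate_polycross",
    "simulate_read_counts",
    "sprinkle_missing",
    "simulate_trial",
    "simulate_population",
]


@dataclass
class SimConfig:
    """Study-design and generative parameters of the synthetic population.

    Defaults mirror the trial the analysis targets: 19 dams drawn from a
    set of 20 parents, 19 half-sib families of 30 offspring (570 sexual
    plants), a six-block split-plot layout with three apomictic check
    cultivars and five plants per plot, and repeated harvests.
    """

    n_dams: int = 19
    n_sires: int = 20
    family_size: int = 30
    ploidy: int = 4
    n_markers: int = 500
    n_blocks: int = 6
    n_checks: int = 3
    plants_per_plot: int = 5
    n_harvests: int = 4
    # genetics
    prop_nonzero: float = 0.1  # fraction of markers with an effect
    heritability: float = 0.5  # plot-level h2 of the harvest-mean value
    genetic_rho: float = 0.8  # CS correlation of genetic effects across harvests
    residual_vcov_spec: VcovStructure | None = None
    sigma2_block: float = 0.1
    sigma2_parent: float = 0.05
    sigma2_block_parent: float = 0.05
    sigma2_harvest: float = 0.25  # spread of fixed harvest effects
    sigma2_check: float = 0.25  # spread of fixed check-cultivar effects
    mu: float = 10.0
    # sequencing
    mean_depth: float = 60.0
    depth_dispersion: float = np.inf  # NB size parameter; inf -> Poisson
    seq_error: float = 0.005
    missing_rate: float = 0.0
    double_reduction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy < 2 or self.ploidy % 2:
            raise ValueError("ploidy must be an even integer >= 2")
        if not 0.0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if not 0.0 <= self.double_reduction <= 1.0:
            raise ValueError("double_reduction must lie in [0, 1]")
        if self.n_dams > self.n_sires:
            raise ValueError("dams are a subset of the parent set: n_dams <= n_sires")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must lie in (0, 1)")
        if self.residual_vcov_spec is None:
            self.residual_vcov_spec = VcovStructure(
                "AR1", self.n_harvests, {"sigma2": 1.0, "rho": 0.4}
            )

    @property
    def n_offspring(self) -> int:
        return self.n_dams * self.family_size

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Pedigree:
    """Records (id, dam, sire, ploidy); founders carry unknown parents.

    Rows are topologically ordered: parents precede offspring.
    """

    records: pd.DataFrame  # columns: id, dam, sire, ploidy

    def __post_init__(self) -> None:
        req = {"id", "dam", "sire", "ploidy"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"pedigree needs columns {sorted(req)}")
        seen: set = set()
        for row in self.records.itertuples(index=False):
            for parent in (row.dam, row.sire):
                if parent is not None and not _is_na(parent) and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {row.id!r} does not precede it"
                    )
            if row.id in seen:
                raise ValueError(f"duplicate pedigree id {row.id!r}")
            seen.add(row.id)

    @property
    def ids(self) -> list:
        return self.records["id"].tolist()

    def parents_of(self, individual) -> tuple:
        row = self.records.loc[self.records["id"] == individual].iloc[0]
        return row["dam"], row["sire"]


def _is_na(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or x is pd.NA


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None) -> DosageMatrix:
    """Founder parents with dosages Binomial(ploidy, p), p ~ U(0.05, 0.95)."""
    if config.n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = config.rng() if rng is None else rng
    p = rng.uniform(0.05, 0.95, size=config.n_markers)
    doses = rng.binomial(config.ploidy, p, size=(config.n_sires, config.n_markers))
    ids = [f"P{i + 1:02d}" for i in range(config.n_sires)]
    markers = [f"M{j + 1:05d}" for j in range(config.n_markers)]
    meta = pd.DataFrame(
        {
            "reference": "sim",
            "chrom": "chr1",
            "pos": np.arange(1, config.n_markers + 1) * 1000,
        },
        index=pd.Index(markers, name="marker"),
    )
    return DosageMatrix(doses.astype(np.int8), pd.Index(ids), pd.Index(markers), config.ploidy, meta)


def simulate_gamete(
    parent_dosage: np.ndarray | int,
    ploidy: int,
    rng: np.random.Generator,
    double_reduction: float = 0.0,
) -> np.ndarray | int:
    """Gamete dosage under bivalent tetrasomic meiosis.

    A gamete receives ``ploidy/2`` of the parent's ``ploidy`` homologs
    drawn without replacement (hypergeometric).  With probability
    ``double_reduction`` (tetraploids only) both gamete copies descend
    from a single randomly chosen homolog instead.
    """
    d = np.asarray(parent_dosage)
    if (d < 0).any() or (d > ploidy).any():
        raise ValueError("parent dosage outside 0..ploidy")
    gam = rng.hypergeometric(d, ploidy - d, ploidy // 2)
    if double_reduction > 0.0:
        if ploidy != 4:
            raise ValueError("double reduction implemented for tetraploids only")
        dr = rng.random(size=d.shape) < double_reduction
        dup = 2 * rng.binomial(1, d / ploidy)
        gam = np.where(dr, dup, gam)
    if np.isscalar(parent_dosage):
        return int(gam)
    return gam


def simulate_polycross(
    founders: DosageMatrix, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[DosageMatrix, Pedigree]:
    """Mate dams to random sires; returns offspring dosages and the pedigree.

    The first ``n_dams`` founders act as dams; every founder can serve
    as a sire.  Each offspring's sire is drawn uniformly with
    replacement from the sire set excluding its own dam (no selfing).
    """
    rng = config.rng() if rng is None else rng
    if founders.n_individuals < 2:
        raise ValueError("need at least two founders to avoid selfing")
    if config.n_dams > founders.n_individuals:
        raise ValueError("more dams requested than founders available")
    ploidy = founders.ploidy
    fdat = founders.data
    n_mark = founders.n_markers

    off_rows, off_ids, dams, sires = [], [], [], []
    for di in range(config.n_dams):
        dam_id = founders.individuals[di]
        candidates = np.array([k for k in range(founders.n_individuals) if k != di])
        for o in range(config.family_size):
            si = int(rng.choice(candidates))
            dam_gam = simulate_gamete(fdat[di], ploidy, rng, config.double_reduction)
            sire_gam = simulate_gamete(fdat[si], ploidy, rng, config.double_reduction)
            off_rows.append(dam_gam + sire_gam)
            off_ids.append(f"F{di + 1:02d}-{o + 1:02d}")
            dams.append(dam_id)
            sires.append(founders.individuals[si])

    offspring = DosageMatrix(
        np.asarray(off_rows, dtype=np.int8),
        pd.Index(off_ids),
        founders.markers,
        ploidy,
        founders.metadata,
    )
    ped_founders = pd.DataFrame(
        {
            "id": list(founders.individuals),
            "dam": [None] * founders.n_individuals,
            "sire": [None] * founders.n_individuals,
            "ploidy": ploidy,
        }
    )
    ped_off = pd.DataFrame({"id": off_ids, "dam": dams, "sire": sires, "ploidy": ploidy})
    pedigree = Pedigree(pd.concat([ped_founders, ped_off], ignore_index=True))
    return offspring, pedigree


def simulate_read_counts(
    dosages: DosageMatrix,
    mean_depth: float = 60.0,
    depth_dispersion: float = np.inf,
    seq_error: float = 0.005,
    rng: np.random.Generator | None = None,
) -> ReadCountTable:
    """GBS-like reference/alternative depths for every dosage cell.

    Total depth per cell is negative-binomial with the given mean and
    size (dispersion) parameter — Poisson in the infinite-size limit.
    Reference reads are Binomial(depth, q) with
    q = (d/ploidy)(1 - seq_error) + (1 - d/ploidy) seq_error.
    Missing dosages yield zero depth.
    """
    if not 0.0 <= seq_error < 0.5:
        raise ValueError("seq_error must lie in [0, 0.5)")
    rng = np.random.default_rng(rng)
    shape = dosages.data.shape
    if np.isinf(depth_dispersion):
        depth = rng.poisson(mean_depth, size=shape)
    else:
        k = depth_dispersion
        depth = rng.negative_binomial(k, k / (k + mean_depth), size=shape)
    miss = dosages.missing_mask
    depth = np.where(miss, 0, depth)
    frac = dosages.data.clip(min=0) / dosages.ploidy
    q = frac * (1.0 - seq_error) + (1.0 - frac) * seq_error
    ref = rng.binomial(depth, q)
    return ReadCountTable(
        ref, depth - ref, dosages.individuals, dosages.markers, dosages.metadata
    )


def sprinkle_missing(
    dosages: DosageMatrix, rate: float, rng: np.random.Generator | None = None
) -> DosageMatrix:
    """Set entries missing completely at random at the given rate."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    data = dosages.data.copy()
    data[rng.random(data.shape) < rate] = MISSING
    return DosageMatrix(data, dosages.individuals, dosages.markers, dosages.ploidy, dosages.metadata)


@dataclass
class TrialSimulation:
    """Simulated trial records plus the generative truth."""

    phenotypes: PhenotypeTable
    beta: np.ndarray  # true marker effects (on the shared genetic component)
    genetic_values: pd.Series  # true harvest-mean genetic value per offspring
    genetic_matrix: pd.DataFrame  # offspring x harvest genetic effects
    harvest_effects: np.ndarray
    check_effects: pd.DataFrame
    block_effects: np.ndarray
    parent_effects: np.ndarray
    residual_vcov: np.ndarray
    layout: pd.DataFrame  # plant, parent, block, is_check


def _trial_layout(offspring: DosageMatrix, config: SimConfig) -> pd.DataFrame:
    """Assign offspring and check clones to blocks (one plot per entry per block)."""
    if offspring.n_individuals != config.n_offspring:
        raise ValueError(
            f"offspring count {offspring.n_individuals} != n_dams*family_size {config.n_offspring}"
        )
    if config.family_size != config.n_blocks * config.plants_per_plot:
        raise ValueError(
            "family_size must equal n_blocks * plants_per_plot so each offspring "
            "is phenotyped in exactly one plot"
        )
    rows = []
    for di in range(config.n_dams):
        fam = f"FAM{di + 1:02d}"
        fam_plants = offspring.individuals[
            di * config.family_size : (di + 1) * config.family_size
        ]
        for k in range(config.n_blocks):
            plot = fam_plants[k * config.plants_per_plot : (k + 1) * config.plants_per_plot]
            for plant in plot:
                rows.append({"plant": plant, "parent": fam, "block": k + 1, "is_check": False})
    for c in range(config.n_checks):
        cult = f"CHK{c + 1}"
        for k in range(config.n_blocks):
            for r in range(config.plants_per_plot):
                rows.append(
                    {
                        "plant": f"{cult}-B{k + 1}-{r + 1}",
                        "parent": cult,
                        "block": k + 1,
                        "is_check": True,
                    }
                )
    return pd.DataFrame(rows)


def simulate_trial(
    offspring: DosageMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TrialSimulation:
    """Generate trial phenotypes over harvests for offspring plus check clones.

    The genetic value of offspring ``i`` at harvest ``l`` is
    ``g_il = sqrt(rho) a_i + sqrt(1-rho) u_il`` with ``a_i`` the
    standardized marker score ``X beta`` and ``u_il`` iid — i.e. a
    compound-symmetry genetic covariance with correlation
    ``genetic_rho`` and variance ``sigma2_g`` chosen so the harvest-mean
    heritability against the mean residual variance matches
    ``config.heritability``.  Residual vectors per plant follow the
    configured across-harvest structure.
    """
    rng = config.rng() if rng is None else rng
    L = config.n_harvests
    layout = _trial_layout(offspring, config)

    R_L = build_vcov(config.residual_vcov_spec)
    mean_res_var = float(np.diag(R_L).mean())
    h2 = config.heritability
    sigma2_g = h2 / (1.0 - h2) * mean_res_var

    # marker-determined shared component, standardized then scaled
    X = offspring.data.astype(float)
    Xc = X - X.mean(axis=0)
    beta = np.zeros(offspring.n_markers)
    nz = rng.random(offspring.n_markers) < config.prop_nonzero
    if not nz.any():
        nz[rng.integers(offspring.n_markers)] = True
    beta[nz] = rng.normal(0.0, 1.0, size=int(nz.sum()))
    a_raw = Xc @ beta
    sd = a_raw.std()
    if sd > 0:
        scale = np.sqrt(sigma2_g) / sd
    else:
        scale = 0.0
    a = a_raw * scale
    beta_scaled = beta * scale

    rho = config.genetic_rho
    u = rng.normal(0.0, 1.0, size=(offspring.n_individuals, L)) * np.sqrt(
        (1.0 - rho) * sigma2_g
    )
    if rho < 1.0:
        g = np.sqrt(rho) * a[:, None] + u
    else:
        g = np.tile(a[:, None], (1, L))

    h_eff = rng.normal(0.0, np.sqrt(config.sigma2_harvest), size=L)
    c_eff = rng.normal(0.0, np.sqrt(config.sigma2_check), size=(config.n_checks, L))
    b_eff = rng.normal(0.0, np.sqrt(config.sigma2_block), size=(config.n_blocks, L))
    parents = sorted(layout["parent"].unique())
    p_eff = rng.normal(0.0, np.sqrt(config.sigma2_parent), size=(len(parents), L))
    bp_eff = rng.normal(
        0.0, np.sqrt(config.sigma2_block_parent), size=(config.n_blocks, len(parents), L)
    )

    chol_R = np.linalg.cholesky(R_L + 1e-10 * np.eye(L))
    parent_pos = {p: i for i, p in enumerate(parents)}
    off_pos = {p: i for i, p in enumerate(offspring.individuals)}
    check_pos = {f"CHK{c + 1}": c for c in range(config.n_checks)}

    records = []
    for row in layout.itertuples(index=False):
        e = chol_R @ rng.normal(0.0, 1.0, size=L)
        k = row.block - 1
        j = parent_pos[row.parent]
        if row.is_check:
            t = c_eff[check_pos[row.parent]]
        else:
            t = g[off_pos[row.plant]]
        y = config.mu + h_eff + b_eff[k] + p_eff[j] + bp_eff[k, j] + t + e
        for l in range(L):
            records.append(
                {
                    "plant": row.plant,
                    "parent": row.parent,
                    "block": row.block,
                    "harvest": l + 1,
                    "is_check": row.is_check,
                    "value": y[l],
                }
            )
    phen = PhenotypeTable(pd.DataFrame(records))
    return TrialSimulation(
        phenotypes=phen,
        beta=beta_scaled,
        genetic_values=pd.Series(g.mean(axis=1), index=offspring.individuals),
        genetic_matrix=pd.DataFrame(
            g, index=offspring.individuals, columns=np.arange(1, L + 1)
        ),
        harvest_effects=h_eff,
        check_effects=pd.DataFrame(
            c_eff, index=[f"CHK{c + 1}" for c in range(config.n_checks)],
            columns=np.arange(1, L + 1),
        ),
        block_effects=b_eff,
        parent_effects=p_eff,
        residual_vcov=R_L,
        layout=layout,
    )


def simulate_population(config: SimConfig):
    """One-call convenience: founders -> polycross -> reads -> trial.

    Returns a dict with founders, offspring, pedigree, read counts and
    the trial simulation, all driven by a single seed.
    """
    rng = config.rng()
    founders = simulate_founders(config, rng)
    offspring, pedigree = simulate_polycross(founders, config, rng)
    observed = (
        sprinkle_missing(offspring, config.missing_rate, rng)
        if config.missing_rate > 0
        else offspring
    )
    reads = simulate_read_counts(
        observed, config.mean_depth, config.depth_dispersion, config.seq_error, rng
    )
    trial = simulate_trial(offspring, config, rng)
    return {
        "founders": founders,
        "offspring": offspring,
        "pedigree": pedigree,
        "reads": reads,
        "trial": trial,
        "config": config,
    }
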