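"""Synthetic stands, genotypes, trait panels and tracheidograms.

Everything downstream of the field work is testable against this module:
it simulates a clonal white-spruce stand with known ground truth — the
spatial/clonal group layout, multilocus SSR genotypes, per-tree-year
ring traits drawn from an explicit variance-component model, and
cell-level tracheid records whose aggregation reproduces the ring
traits.

The default population mirrors the study design this package targets:
47 trees in 11 spatially clustered groups (pairwise distance ≤ 3 m
within a group), 35 of them in 9 clonal groups (5 spatial groups clonal
only, 4 mixed) and 12 non-clonal trees, observed over 2007–2017.

The trait model for tree i (genet j, spatial group k) in year t is

    y_ijkt = μ + year_t + β·cDBH_it + g_j + s_k + u_i + e_ijkt

with g ~ N(0, σG²), s ~ N(0, σS²), u ~ N(0, σtree²), and e a stationary
AR(1) series within each tree (coefficient ρ, marginal variance σR²
scaled by a per-spatial-group SD multiplier).  Because layering makes
clone-mates grow next to each other, the default layout nests clonal
groups inside spatial groups — the confounding the study design cannot
escape; ``confounded=False`` crosses the two factors instead, giving the
clean design against which the confounded one can be compared.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .anatomy import TRAIT_COLUMNS, hydraulic_diameter
from .cloneid import NULL, Genotype

__all__ = [
    "PopulationConfig", "VarianceConfig", "TreeMeta",
    "simulate_population", "simulate_genotypes", "simulate_trait_panel",
    "simulate_cell_data", "default_trait_panel",
    "DEFAULT_TRAIT_MEANS", "DEFAULT_TRAIT_CV",
]


class ConfigError(ValueError):
    pass


@dataclass
class PopulationConfig:
    """Stand layout. Defaults reproduce the 47-tree study design."""

    n_spatial_groups: int = 11
    n_clonal_groups: int = 9
    clone_group_sizes: list | None = None   # default: 35 trees split 5,4,4,...
    n_nonclonal: int = 12
    n_clone_only_groups: int = 5
    n_nonclonal_only_groups: int = 2
    years: tuple = (2007, 2017)
    confounded: bool = True
    seed: int = 0

    def resolved_sizes(self) -> list:
        if self.clone_group_sizes is not None:
            sizes = list(self.clone_group_sizes)
            if len(sizes) != self.n_clonal_groups:
                raise ConfigError("clone_group_sizes length != n_clonal_groups")
            return sizes
        # 35 trees over 9 groups -> 8 groups of 4 and one of 3
        base, extra = divmod(35, self.n_clonal_groups) if \
            self.n_clonal_groups else (0, 0)
        return [base + (1 if i < extra else 0)
                for i in range(self.n_clonal_groups)]

    def validate(self) -> None:
        if self.n_spatial_groups < 1 or self.n_clonal_groups < 1:
            raise ConfigError("need at least one spatial and one clonal group")
        if self.n_nonclonal < 0:
            raise ConfigError("n_nonclonal must be >= 0")
        if self.years[0] > self.years[1]:
            raise ConfigError("empty year range")
        if any(s < 2 for s in self.resolved_sizes()):
            raise ConfigError("clonal groups need >= 2 ramets")
        hosting = self.n_spatial_groups - self.n_nonclonal_only_groups
        if self.confounded and hosting < 1 and self.n_clonal_groups > 0:
            raise ConfigError("no spatial groups left to host clonal groups")
        if (self.n_clone_only_groups + self.n_nonclonal_only_groups
                > self.n_spatial_groups):
            raise ConfigError("more clone-only + nonclonal-only groups than "
                              "spatial groups")
        if self.n_nonclonal > 0 and \
                self.n_spatial_groups - self.n_clone_only_groups < 1:
            raise ConfigError("n_nonclonal > 0 but no spatial group can host "
                              "non-clonal trees")


@dataclass
class VarianceConfig:
    """Ground-truth variance components of the trait model (trait units²)."""

    mu: float = 0.0
    sigma2_G: float = 0.0
    sigma2_S: float = 0.0
    sigma2_tree: float = 0.0
    sigma2_R: float = 1.0
    rho: float = 0.0
    beta_dbh: float = 0.0
    year_effects: dict = field(default_factory=dict)
    group_var_multipliers: dict = field(default_factory=dict)  # spatial grp -> SD ratio

    def validate(self) -> None:
        for name in ("sigma2_G", "sigma2_S", "sigma2_tree", "sigma2_R"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not -1 < self.rho < 1:
            raise ConfigError("|rho| must be < 1")
        if any(m <= 0 for m in self.group_var_multipliers.values()):
            raise ConfigError("variance multipliers must be > 0")


@dataclass
class TreeMeta:
    tree_id: str
    spatial_group: str
    clonal_group: str | None   # None for non-clonal trees
    x: float
    y: float
    cdbh_by_year: dict

    @property
    def genetic_group(self) -> str:
        """Genet label: clonal group id, or the tree's own id if non-clonal."""
        return self.clonal_group if self.clonal_group is not None else self.tree_id


_GROUP_RADIUS = 1.4   # m; keeps within-group pairwise distances under 3 m
_GROUP_SPACING = 25.0


def simulate_population(config: PopulationConfig) -> list[TreeMeta]:
    """Simulate tree metadata for a clustered clonal stand.

    Spatial groups sit on a coarse grid; members are scattered inside a
    1.4 m disc so all within-group pairwise distances stay below the 3 m
    clustering rule.  Clonal groups are nested in spatial groups
    (``confounded=True``) or dealt round-robin across them.  cDBH grows
    linearly with a tree-specific rate and is strictly non-decreasing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = config.resolved_sizes()
    years = list(range(config.years[0], config.years[1] + 1))

    spatial_ids = [f"S{k + 1:02d}" for k in range(config.n_spatial_groups)]
    n_host = config.n_spatial_groups - config.n_nonclonal_only_groups
    host_groups = spatial_ids[:n_host]
    nonclonal_hosts = spatial_ids[config.n_clone_only_groups:]

    assignments = []  # (clonal_group | None) per tree, with its spatial group
    if config.confounded:
        host_cycle = itertools.cycle(host_groups)
        for j, size in enumerate(sizes):
            sg = next(host_cycle)
            assignments.extend((f"G{j + 1:02d}", sg) for _ in range(size))
    else:
        # crossed design: ramets of a genet are spread over spatial groups
        sg_cycle = itertools.cycle(spatial_ids)
        for j, size in enumerate(sizes):
            assignments.extend((f"G{j + 1:02d}", next(sg_cycle))
                               for _ in range(size))
    nc_cycle = itertools.cycle(nonclonal_hosts if config.confounded
                               else spatial_ids)
    assignments.extend((None, next(nc_cycle))
                       for _ in range(config.n_nonclonal))

    centers = {
        sg: (_GROUP_SPACING * (k % 4), _GROUP_SPACING * (k // 4))
        for k, sg in enumerate(spatial_ids)
    }
    trees = []
    for i, (cg, sg) in enumerate(assignments):
        r = _GROUP_RADIUS * math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        cx, cy = centers[sg]
        dbh0 = max(rng.normal(11.0, 1.0), 4.0)
        rate = max(rng.normal(0.1, 0.02), 0.01)
        cdbh = {t: dbh0 + rate * j for j, t in enumerate(years)}
        trees.append(TreeMeta(
            tree_id=f"T{i + 1:03d}", spatial_group=sg, clonal_group=cg,
            x=cx + r * math.cos(phi), y=cy + r * math.sin(phi),
            cdbh_by_year=cdbh,
        ))
    return trees


# ---------------------------------------------------------------------------
# genotypes

def _default_allele_freqs(n_loci: int, n_alleles: int = 8) -> list:
    """Equifrequent allele pools per locus (fragment sizes in bp)."""
    return [
        {180 + 10 * l + 2 * a: 1.0 / n_alleles for a in range(n_alleles)}
        for l in range(n_loci)
    ]


def simulate_genotypes(trees: list[TreeMeta], n_loci: int = 11,
                       allele_freqs: list | None = None,
                       error_rate: float = 0.0, null_rate: float = 0.0,
                       seed: int = 0) -> list[Genotype]:
    """SSR genotypes: clone-mates share a founder, then per-locus noise.

    Each genet (clonal group, or each non-clonal tree) gets a founder
    genotype drawn from ``allele_freqs``.  Every tree's call at every
    locus is then independently perturbed with probability ``error_rate``
    (one allele replaced by a different allele from the locus pool) and
    flagged as null-allele-containing with probability ``null_rate``.
    """
    if n_loci < 1:
        raise ConfigError("n_loci must be >= 1")
    if not 0 <= error_rate <= 1 or not 0 <= null_rate <= 1:
        raise ConfigError("rates must be in [0, 1]")
    if allele_freqs is None:
        allele_freqs = _default_allele_freqs(n_loci)
    if len(allele_freqs) != n_loci or any(len(f) == 0 for f in allele_freqs):
        raise ConfigError("allele_freqs must list non-empty pools per locus")

    rng = np.random.default_rng(seed)
    pools = [sorted(f) for f in allele_freqs]
    probs = [np.array([f[a] for a in sorted(f)]) / sum(f.values())
             for f in allele_freqs]

    founders: dict = {}
    for tree in trees:
        genet = tree.genetic_group
        if genet not in founders:
            founders[genet] = [
                (rng.choice(pools[l], p=probs[l]),
                 rng.choice(pools[l], p=probs[l]))
                for l in range(n_loci)
            ]

    genotypes = []
    for tree in trees:
        calls = []
        for l, (a1, a2) in enumerate(founders[tree.genetic_group]):
            a1, a2 = int(a1), int(a2)
            if rng.uniform() < error_rate:
                which = rng.integers(2)
                old = a1 if which == 0 else a2
                others = [a for a in pools[l] if a != old]
                new = int(rng.choice(others)) if others else old
                a1, a2 = (new, a2) if which == 0 else (a1, new)
            pair: set = {a1, a2}
            if rng.uniform() < null_rate:
                pair = {a1, NULL}
            calls.append(frozenset(pair))
        genotypes.append(Genotype(tree_id=tree.tree_id, locus_calls=calls))
    return genotypes


# ---------------------------------------------------------------------------
# trait panel

def simulate_trait_panel(trees: list[TreeMeta], var_config: VarianceConfig,
                         seed: int = 0, trait: str = "value") -> pd.DataFrame:
    """One trait observed on every tree in every year, per the LMM model.

    Returns a long panel with columns ``tree_id, year, cDBH,
    genetic_group, spatial_group, clonal`` and the trait column.
    """
    var_config.validate()
    rng = np.random.default_rng(seed)
    years = sorted(next(iter(trees)).cdbh_by_year) if trees else []

    genets = sorted({t.genetic_group for t in trees})
    sgroups = sorted({t.spatial_group for t in trees})
    g_eff = dict(zip(genets, rng.normal(0, math.sqrt(var_config.sigma2_G),
                                        len(genets))))
    s_eff = dict(zip(sgroups, rng.normal(0, math.sqrt(var_config.sigma2_S),
                                         len(sgroups))))
    rows = []
    rho = var_config.rho
    for tree in trees:
        u = rng.normal(0, math.sqrt(var_config.sigma2_tree))
        mult = var_config.group_var_multipliers.get(tree.spatial_group, 1.0)
        sd = math.sqrt(var_config.sigma2_R) * mult
        # stationary AR(1) residual series
        e = rng.normal(0, sd)
        for t in years:
            y = (var_config.mu
                 + var_config.year_effects.get(t, 0.0)
                 + var_config.beta_dbh * tree.cdbh_by_year[t]
                 + g_eff[tree.genetic_group] + s_eff[tree.spatial_group]
                 + u + e)
            rows.append({
                "tree_id": tree.tree_id, "year": t,
                "cDBH": tree.cdbh_by_year[t],
                "genetic_group": tree.genetic_group,
                "spatial_group": tree.spatial_group,
                "clonal": tree.clonal_group is not None,
                trait: y,
            })
            e = rho * e + rng.normal(0, sd * math.sqrt(1 - rho ** 2))
    return pd.DataFrame(rows)


#: Realistic ring-trait means for treeline white spruce (trait units).
#: The DEN entries are informational: anatomical density is derived from
#: CWT, DH and a latent density tendency (see :func:`default_trait_panel`)
#: because the wall-band cell geometry nearly determines DEN given the
#: other two — independent DEN draws would be geometrically infeasible.
DEFAULT_TRAIT_MEANS = {
    "EWW": 450.0, "LWW": 150.0,
    "CWT.ew": 2.5, "CWT.lw": 3.5,
    "DEN.ew": 0.333, "DEN.lw": 0.765,
    "DH.ew": 30.0, "DH.lw": 9.0,
}

#: Total trait SD as a fraction of the mean (directly simulated traits).
DEFAULT_TRAIT_CV = {
    "EWW": 0.20, "LWW": 0.20,
    "CWT.ew": 0.04, "CWT.lw": 0.04,
    "DH.ew": 0.04, "DH.lw": 0.04,
}

#: Unit-total variance decomposition used by :func:`default_trait_panel`.
DEFAULT_FRACTIONS = {
    "sigma2_G": 0.15, "sigma2_S": 0.25, "sigma2_tree": 0.15, "sigma2_R": 0.45,
}

#: SD of the common year effects relative to the random-component total
#: SD: the year-to-year climate signal in ring traits is of the same
#: order as all tree-level variation combined.
YEAR_EFFECT_FRACTION = 0.8

#: Searchable half-spread of the within-zone lumen-diameter ramp.  The
#: earlywood bound keeps the thinnest earlywood cell below the Mork
#: boundary; latewood tolerates a wider spread.
_GAMMA_RANGE = {"ew": (0.02, 0.50), "lw": (0.02, 0.80)}
#: Latent density tendencies are mapped inside these (safely interior)
#: gamma bands, so derived DEN targets are always realizable.
_GAMMA_CENTER = {"ew": 0.26, "lw": 0.40}
_GAMMA_HALFWIDTH = {"ew": 0.20, "lw": 0.30}
_CELLS_PER_ZONE_NOMINAL = 15


def _nominal_shapes(cwt: float, dh: float, gamma: float,
                    n: int = _CELLS_PER_ZONE_NOMINAL):
    """Noise-free per-cell (diameter, wall) profiles for one zone."""
    ramp = np.linspace(1.0, -1.0, n)
    cshape = 1.0 + _CWT_RAMP * np.linspace(-1.0, 1.0, n)
    c = cwt * cshape / cshape.mean()
    shape = np.clip(1.0 + gamma * ramp, 0.05, None)
    d = shape * (dh / hydraulic_diameter(math.pi * shape ** 2 / 4.0))
    return d, c


def gamma_cap(cwt: float, dh: float, zone: str,
              buffer: float = 0.015) -> float:
    """Largest diameter-ramp spread keeping every cell of the zone on its
    side of the Mork boundary (noise-free profile)."""
    lo, hi = _GAMMA_RANGE[zone]

    def margin(g: float) -> float:
        d, c = _nominal_shapes(cwt, dh, g)
        mork = 4.0 * c / d
        return (1.0 - mork.max()) if zone == "ew" else (mork.min() - 1.0)

    if margin(lo) <= buffer:
        return lo
    if margin(hi) > buffer:
        return hi
    return optimize.brentq(lambda g: margin(g) - buffer, lo, hi, xtol=1e-6)


def implied_density(cwt: float, dh: float, gamma: float,
                    n: int = _CELLS_PER_ZONE_NOMINAL) -> float:
    """Anatomical density implied by the noise-free zone profile.

    For the canonical within-zone shapes (linear lumen-diameter ramp of
    half-spread ``gamma``, linear wall ramp) scaled to hit ``cwt`` and
    ``dh`` exactly, the zone density is a deterministic function — this
    is it.  Used to derive feasible DEN targets for the trait panel.
    """
    d, c = _nominal_shapes(cwt, dh, gamma, n)
    la = math.pi * d ** 2 / 4.0
    cwa = 4.0 * c * (d + c)
    return float(cwa.sum() / (cwa.sum() + la.sum()))


def default_trait_panel(trees: list[TreeMeta], seed: int = 0,
                        fractions: dict | None = None,
                        rho: float = 0.3) -> pd.DataFrame:
    """Panel of all eight ring traits at realistic scales.

    Widths, zone CWT and zone DH are simulated independently from the
    variance-component model with total variance (CV·mean)² split per
    ``fractions``.  Zone DEN is derived per ring from its CWT and DH via
    a latent unit-variance density tendency (same variance structure)
    mapped into the feasible diameter-spread band — so cell-level data
    generated from the panel can always realize the DEN target, and DEN
    inherits clonal/spatial/tree structure both directly and through
    CWT and DH.
    """
    fractions = dict(DEFAULT_FRACTIONS if fractions is None else fractions)
    direct = ["EWW", "LWW", "CWT.ew", "CWT.lw", "DH.ew", "DH.lw"]
    years = sorted(next(iter(trees)).cdbh_by_year) if trees else []
    year_rng = np.random.default_rng(seed + 104729)
    panel = None
    for i, trait in enumerate(direct):
        mean = DEFAULT_TRAIT_MEANS[trait]
        total = (DEFAULT_TRAIT_CV[trait] * mean) ** 2
        year_sd = YEAR_EFFECT_FRACTION * math.sqrt(total)
        vc = VarianceConfig(
            mu=mean, rho=rho,
            year_effects=dict(zip(years, year_rng.normal(0, year_sd,
                                                         len(years)))),
            **{k: f * total for k, f in fractions.items()},
        )
        one = simulate_trait_panel(trees, vc, seed=seed + 7919 * (i + 1),
                                   trait=trait)
        if panel is None:
            panel = one
        else:
            panel[trait] = one[trait]
    for j, zone in enumerate(("ew", "lw")):
        latent_vc = VarianceConfig(
            mu=0.0, rho=rho,
            year_effects=dict(zip(years, year_rng.normal(
                0, YEAR_EFFECT_FRACTION, len(years)))),
            **{k: f for k, f in fractions.items()})
        z = simulate_trait_panel(trees, latent_vc,
                                 seed=seed + 7919 * (7 + j),
                                 trait="z")["z"].to_numpy()
        lo = _GAMMA_RANGE[zone][0] + 0.03
        dens = []
        for cwt, dh, zi in zip(panel[f"CWT.{zone}"], panel[f"DH.{zone}"], z):
            # the cap buffer absorbs realization-time jitter (which can
            # erode the worst cell's Mork margin by ~0.1)
            hi = min(_GAMMA_CENTER[zone] + _GAMMA_HALFWIDTH[zone],
                     gamma_cap(cwt, dh, zone, buffer=0.12) - 0.02)
            g = (lo + (max(hi, lo) - lo) * (math.tanh(0.5 * zi) + 1.0) / 2.0)
            dens.append(implied_density(cwt, dh, g))
        panel[f"DEN.{zone}"] = dens
    return panel[["tree_id", "year", "cDBH", "genetic_group",
                  "spatial_group", "clonal"] + TRAIT_COLUMNS]


# ---------------------------------------------------------------------------
# cell-level tracheidograms

class InfeasibleRingError(ValueError):
    """Raised when a ring's trait targets cannot be realized by any
    monotone tracheidogram under the wall-band cell geometry."""


_CWT_RAMP = 0.12              # wall-thickness ramp half-spread within a zone
_DEN_TOLERANCE = 0.02         # documented DEN round-trip tolerance


def _zone_cells(n: int, cwt_target: float, dh_target: float,
                den_target: float, width: float, zone: str,
                rng: np.random.Generator, noise: float):
    """Construct one zone's (d, c, extent) hitting CWT/DH exactly, DEN by
    a root find over the diameter-ramp spread."""
    ramp = np.linspace(1.0, -1.0, n)           # radial: wide -> narrow lumen
    cw_ramp = np.linspace(-1.0, 1.0, n)        # thin -> thick walls
    jit_d = rng.normal(0.0, noise, n)
    jit_c = rng.normal(0.0, noise, n)

    def wall_profile(flatten: float) -> np.ndarray:
        cshape = 1.0 + flatten * (_CWT_RAMP * cw_ramp + jit_c)
        cshape = np.clip(cshape, 0.3, None)
        return cwt_target * cshape / cshape.mean()   # zone mean CWT exact

    def diameters(gamma: float) -> np.ndarray:
        shape = np.clip(1.0 + gamma * ramp + jit_d, 0.05, None)
        return shape * (dh_target / hydraulic_diameter(
            math.pi * shape ** 2 / 4.0))       # DH exact by scale equivariance

    lo, hi = _GAMMA_RANGE[zone]
    buffer = 0.01

    def class_margin(gamma: float, c: np.ndarray) -> float:
        # distance of the worst cell's Mork index from the zone boundary;
        # widening the diameter ramp always erodes it
        mork = 4.0 * c / diameters(gamma)
        return (1.0 - mork.max()) if zone == "ew" else (mork.min() - 1.0)

    # Mork-marginal targets cannot afford the full wall gradient: flatten
    # it (keeping the zone-mean CWT exact) until the boundary cell stays
    # on its side of the index threshold
    for flatten in (1.0, 0.5, 0.25, 0.0):
        c = wall_profile(flatten)
        if class_margin(lo, c) > buffer:
            break
    else:
        raise InfeasibleRingError(
            f"CWT {cwt_target:.2f} / DH {dh_target:.1f} put "
            f"{'early' if zone == 'ew' else 'late'}wood cells on the wrong "
            "side of the Mork boundary at any profile spread")
    if class_margin(hi, c) <= buffer:
        hi = optimize.brentq(lambda g: class_margin(g, c) - buffer, lo, hi,
                             xtol=1e-6)

    def den_gap(gamma: float) -> float:
        d = diameters(gamma)
        la = math.pi * d ** 2 / 4.0
        cwa = 4.0 * c * (d + c)
        return float(cwa.sum() / (cwa.sum() + la.sum())) - den_target
    f_lo, f_hi = den_gap(lo), den_gap(hi)
    if f_lo * f_hi > 0:
        # target outside the achievable band; a shortfall within the
        # documented DEN round-trip tolerance clamps to the band edge
        gap = min(abs(f_lo), abs(f_hi))
        if gap <= _DEN_TOLERANCE:
            gamma = lo if abs(f_lo) <= abs(f_hi) else hi
        else:
            reach = sorted((den_target + f_lo, den_target + f_hi))
            raise InfeasibleRingError(
                f"DEN target {den_target:.3f} outside achievable range "
                f"[{reach[0]:.3f}, {reach[1]:.3f}] for CWT={cwt_target:.2f}, "
                f"DH={dh_target:.1f}")
    else:
        gamma = optimize.brentq(den_gap, lo, hi, xtol=1e-10)
    d = diameters(gamma)
    extents = np.full(n, width / n)
    return d, c, extents


def simulate_cell_data(panel: pd.DataFrame, cells_per_ring: int = 30,
                       seed: int = 0, noise: float = 0.02) -> pd.DataFrame:
    """Cell table whose per-ring aggregation reproduces the panel traits.

    Within each ring, lumen diameter decreases and wall thickness
    increases (monotone ramps plus jitter) along the radial position, so
    Mork's index crosses 1 at the earlywood/latewood boundary.  Zone
    widths and zone-mean CWT are reproduced exactly, DH exactly (scale
    equivariance), and DEN to root-finding tolerance; infeasible targets
    raise :class:`InfeasibleRingError`.
    """
    if cells_per_ring < 4:
        raise ConfigError("cells_per_ring must be >= 4")
    rng = np.random.default_rng(seed)
    records = []
    for _, row in panel.iterrows():
        wid_e, wid_l = float(row["EWW"]), float(row["LWW"])
        n_ew = max(2, min(cells_per_ring - 2,
                          round(cells_per_ring * wid_e / (wid_e + wid_l))))
        n_lw = cells_per_ring - n_ew
        parts = []
        for zone, n, wkey in (("ew", n_ew, "EWW"), ("lw", n_lw, "LWW")):
            d, c, ext = _zone_cells(
                n, float(row[f"CWT.{zone}"]), float(row[f"DH.{zone}"]),
                float(row[f"DEN.{zone}"]), float(row[wkey]),
                zone=zone, rng=rng, noise=noise)
            mork = 4.0 * c / d
            if zone == "ew" and np.any(mork >= 1.0):
                raise InfeasibleRingError(
                    f"tree {row['tree_id']} year {row['year']}: generated "
                    "earlywood cell classifies as latewood; targets too close "
                    "to the Mork boundary")
            if zone == "lw" and np.any(mork < 1.0):
                raise InfeasibleRingError(
                    f"tree {row['tree_id']} year {row['year']}: generated "
                    "latewood cell classifies as earlywood; targets too close "
                    "to the Mork boundary")
            parts.append((d, c, ext))
        d = np.concatenate([p[0] for p in parts])
        c = np.concatenate([p[1] for p in parts])
        ext = np.concatenate([p[2] for p in parts])
        pos = np.concatenate(([0.0], np.cumsum(ext)[:-1]))
        la = math.pi * d ** 2 / 4.0
        for j in range(len(d)):
            records.append({
                "tree_id": row["tree_id"], "year": int(row["year"]),
                "radial_position_um": pos[j], "radial_extent_um": ext[j],
                "lumen_area_um2": la[j], "cwt_um": c[j],
            })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# named study scenarios

def _all_clonal_population(n_groups: int, ramets: int, seed: int,
                           years: tuple = (2007, 2017)) -> PopulationConfig:
    """One clonal group per spatial group, no singletons: the fully
    confounded layout in which genetic and spatial partitions coincide."""
    return PopulationConfig(
        n_spatial_groups=n_groups, n_clonal_groups=n_groups,
        clone_group_sizes=[ramets] * n_groups, n_nonclonal=0,
        n_clone_only_groups=n_groups, n_nonclonal_only_groups=0,
        years=years, seed=seed,
    )


def scenario(name: str, seed: int) -> tuple[list[TreeMeta], VarianceConfig]:
    """Named ground-truth scenarios for simulation studies.

    * ``h2_recovery`` — 34 clonal groups of 3 ramets (102 trees), clone
      variance 0.3 and residual 0.7, no spatial/tree/serial structure:
      the clean case in which H² = 0.3 by construction.
    * ``h2_null`` — same stand, no genetic variance at all.
    * ``confounded`` — clonal groups coincide with spatial groups and
      all structure (0.3) is spatial: any positive H² estimate is
      micro-environment masquerading as heritability.
    * ``spatial_only`` — the 47-tree study layout with strong spatial
      group variance (0.6), weak tree variance (0.1), residual 0.3,
      AR(1) 0.3 and year effects: the spatial model should win.
    * ``no_structure`` — the study layout with tree and residual
      variance only: the null model should win by parsimony.
    """
    rng = np.random.default_rng(seed + 65537)
    years = list(range(2007, 2018))
    year_effects = dict(zip(years, rng.normal(0.0, 0.5, len(years))))
    if name == "h2_recovery":
        pop = _all_clonal_population(34, 3, seed)
        vc = VarianceConfig(sigma2_G=0.3, sigma2_R=0.7)
    elif name == "h2_null":
        pop = _all_clonal_population(34, 3, seed)
        vc = VarianceConfig(sigma2_G=0.0, sigma2_R=1.0)
    elif name == "confounded":
        pop = _all_clonal_population(34, 3, seed)
        vc = VarianceConfig(sigma2_G=0.0, sigma2_S=0.3, sigma2_R=0.7)
    elif name == "spatial_only":
        pop = PopulationConfig(seed=seed)
        vc = VarianceConfig(sigma2_S=0.6, sigma2_tree=0.1, sigma2_R=0.3,
                            rho=0.3, year_effects=year_effects)
    elif name == "no_structure":
        pop = PopulationConfig(seed=seed)
        vc = VarianceConfig(sigma2_tree=0.3, sigma2_R=0.7, rho=0.3,
                            year_effects=year_effects)
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return simulate_population(pop), vc
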