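"""Replicated simulation studies over the named ground-truth scenarios.

These are the package's calibration experiments: each function simulates
many stands from a :func:`xyloherit.synthio.scenario`, runs the relevant
estimator or model-selection procedure, and returns the per-replicate
results.  They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .cloneid import cluster_clones
from .compare import classify_verdict, fit_model_suite
from .herit import h2_mod
from .lmm import ModelSpec, extract_variance_components, fit_reml, term_significance
from .synthio import (PopulationConfig, VarianceConfig, scenario,
                      simulate_genotypes, simulate_population,
                      simulate_trait_panel)

#: Model used for the model-based heritability estimate: year and size as
#: fixed effects, the clonal group as the random intercept.
H2_MOD_SPEC = ModelSpec(response="y", fixed_terms=["year", "cDBH"],
                        random_factor="genetic_group", ar1=False)


def h2_mod_study(scenario_name: str, n_reps: int, seed: int) -> np.ndarray:
    """Per-replicate model-based H² under a named scenario."""
    out = []
    for rep in range(n_reps):
        trees, vc = scenario(scenario_name, seed=seed + rep)
        panel = simulate_trait_panel(trees, vc, seed=seed + 50_000 + rep,
                                     trait="y")
        fit = fit_reml(H2_MOD_SPEC, panel, n_restarts=1)
        s2g, s2r = extract_variance_components(fit)
        out.append(h2_mod(s2g, s2r) if s2g + s2r > 0 else 0.0)
    return np.asarray(out)


def model_selection_study(scenario_name: str, n_reps: int,
                          seed: int) -> list:
    """Winning model label per replicate under a named scenario."""
    labels = []
    for rep in range(n_reps):
        trees, vc = scenario(scenario_name, seed=seed + rep)
        panel = simulate_trait_panel(trees, vc, seed=seed + 60_000 + rep,
                                     trait="y")
        fits = fit_model_suite(panel, "y", n_restarts=1)
        verdict = classify_verdict("y", fits["null"].aicc,
                                   fits["genetic"].aicc,
                                   fits["spatial"].aicc)
        labels.append(verdict.best_model)
    return labels


#: Stand and variance structure for the significance-calibration study:
#: a small all-clonal stand with tree-level and serially correlated
#: residual variance but no genetic-group effect at all.
_TYPE1_YEARS = (2007, 2012)
_TYPE1_VC = VarianceConfig(
    sigma2_tree=0.4, sigma2_R=1.0, rho=0.4,
    year_effects={2007: 0.5, 2008: -0.3, 2009: 0.2, 2010: 0.0,
                  2011: -0.4, 2012: 0.1})


def type1_error_study(n_reps: int, seed: int) -> float:
    """Rejection rate of the genetic-group F test when no genetic effect
    exists; should sit at the nominal 5% level."""
    pop = PopulationConfig(
        n_spatial_groups=6, n_clonal_groups=6, clone_group_sizes=[3] * 6,
        n_nonclonal=0, n_clone_only_groups=6, n_nonclonal_only_groups=0,
        years=_TYPE1_YEARS)
    spec = ModelSpec(response="y",
                     fixed_terms=["genetic_group", "year", "cDBH"],
                     random_factor="tree_id", ar1=True)
    rejections = 0
    for rep in range(n_reps):
        pop.seed = seed + rep
        trees = simulate_population(pop)
        panel = simulate_trait_panel(trees, _TYPE1_VC,
                                     seed=seed + 70_000 + rep, trait="y")
        fit = fit_reml(spec, panel, n_restarts=1)
        anova = term_significance(fit, panel)
        row = anova.loc[anova["term"] == "genetic_group"]
        rejections += bool(row["significant"].iloc[0])
    return rejections / n_reps


def clone_recovery_study(n_reps: int, seed: int,
                         error_rate: float = 0.05) -> float:
    """Fraction of trees assigned to their true clone, across
    noisy-genotype replicates of the default stand.

    A clonal tree counts as correctly assigned when it is clustered with
    at least one true clone-mate and with no foreign tree; a non-clonal
    tree when it stays a singleton.  (A ramet that splits off its genet
    is one error; it does not invalidate the rest of the genet.)
    """
    correct = total = 0
    for rep in range(n_reps):
        trees = simulate_population(PopulationConfig(seed=seed + rep))
        genotypes = simulate_genotypes(trees, error_rate=error_rate,
                                       seed=seed + 80_000 + rep)
        assignment = cluster_clones(genotypes, max_mismatch=2)
        truth: dict = {}
        for t in trees:
            truth.setdefault(t.genetic_group, set()).add(t.tree_id)
        recovered: dict = {}
        for tid, grp in assignment.group_of.items():
            recovered.setdefault(grp, set()).add(tid)
        for t in trees:
            total += 1
            cluster = recovered[assignment.group_of[t.tree_id]]
            genet = truth[t.genetic_group]
            if len(genet) == 1:
                correct += cluster == genet
            else:
                correct += len(cluster) >= 2 and cluster <= genet
    return correct / total
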