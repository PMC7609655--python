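"""Broad-sense heritability estimators for clonal trait panels.

Clones are genetically identical, so the among-genet variance of a trait
is an estimate of its total genetic variance σG² and broad-sense
heritability is the genetic fraction of phenotypic variance.  Three
estimators are computed per trait, all restricted to trees growing in
clonal groups:

* ``H2_raw`` — σG²/σP² on the raw tree-year trait values, with σG² the
  among-clone variance component from a one-way ANOVA (method of
  moments, unequal group sizes) and σP² the total sample variance of
  the observations.
* ``H2_pred`` — the same estimator applied to fixed-effects model
  predictions on a size-standardized dataset (every tree following the
  population-average cDBH trajectory), removing size-driven variance.
* ``H2_mod`` — σG²/(σG²+σR²) from the REML variance components of a
  mixed model with the clonal group as the random effect.

Each estimate is accompanied by the coefficient of variation CV = σG²/x̄
(the genetic variance over the trait mean, as conventionally reported
with these estimates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import (ModelSpec, extract_variance_components, fit_reml,
                  predict_standardized, standardized_newdata)

logger = logging.getLogger(__name__)


@dataclass
class HeritabilityReport:
    """Per-trait heritability estimates from the three methods."""

    trait: str
    H2_raw: float
    H2_pred: float
    H2_mod: float
    CV_raw: float
    CV_pred: float
    CV_mod: float
    sigma2_G: dict = field(default_factory=dict)   # per method
    sigma2_P: dict = field(default_factory=dict)
    trait_mean: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def as_rows(self) -> list:
        return [
            {"trait": self.trait, "method": m,
             "H2": getattr(self, f"H2_{m}"), "CV": getattr(self, f"CV_{m}"),
             "sigma2_G": self.sigma2_G.get(m),
             "sigma2_denominator": self.sigma2_P.get(m),
             "flags": ";".join(f for f in self.flags if f.startswith(m))}
            for m in ("raw", "pred", "mod")
        ]


def _anova_sigma2_g(values: np.ndarray, labels: np.ndarray) -> tuple[float, bool]:
    """Among-group variance component, one-way ANOVA method of moments.

    Uses the unequal-group-size correction: σ̂G² = (MSB − MSW)/n₀ with
    n₀ = (N − Σnᵢ²/N)/(a−1).  Negative estimates are truncated to 0
    (flagged by the second return value).
    """
    df = pd.DataFrame({"y": values, "g": labels})
    groups = df.groupby("g")["y"]
    sizes = groups.size().to_numpy(dtype=float)
    a = len(sizes)
    n = sizes.sum()
    if a < 2:
        raise ValueError("need at least 2 clones")
    grand = df["y"].mean()
    ssb = float((sizes * (groups.mean().to_numpy() - grand) ** 2).sum())
    ssw = float((groups.var(ddof=1).fillna(0.0).to_numpy()
                 * (sizes - 1)).sum())
    msb = ssb / (a - 1)
    msw = ssw / (n - a) if n > a else 0.0
    n0 = (n - (sizes ** 2).sum() / n) / (a - 1)
    sigma2_g = (msb - msw) / n0
    if sigma2_g < 0:
        return 0.0, True
    return sigma2_g, False


def h2_from_values(values, clone_labels) -> tuple[float, dict]:
    """H² = σG²/σP² from values and clone labels (raw/pred estimator).

    Requires at least two clones with at least two ramets each.  σP² is
    the total sample variance; the ratio is clamped to [0, 1].  Returns
    (H², details) where details carries σG², σP², the mean, CV and flags.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(clone_labels)
    counts = pd.Series(labels).value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 clones with >= 2 members each")
    sigma2_g, truncated = _anova_sigma2_g(values, labels)
    sigma2_p = float(np.var(values, ddof=1))
    h2 = sigma2_g / sigma2_p if sigma2_p > 0 else 0.0
    flags = []
    if truncated:
        flags.append("negative_sigma2_G_truncated")
    if h2 > 1.0:
        flags.append("H2_clamped")
        h2 = 1.0
    mean = float(values.mean())
    details = {"sigma2_G": sigma2_g, "sigma2_P": sigma2_p, "mean": mean,
               "CV": cv(sigma2_g, mean), "flags": flags}
    return h2, details


def h2_mod(sigma2_G: float, sigma2_R: float) -> float:
    """Model-based H² = σG² / (σG² + σR²)."""
    if sigma2_G < 0 or sigma2_R < 0:
        raise ValueError("variance components must be >= 0")
    if sigma2_G + sigma2_R == 0:
        raise ValueError("σG² + σR² must be positive")
    return sigma2_G / (sigma2_G + sigma2_R)


def cv(sigma2_G: float, trait_mean: float, sqrt_variant: bool = False) -> float:
    """Dispersion measure CV = σG²/x̄ (variance over mean, as reported).

    ``sqrt_variant=True`` returns √σG²/x̄ (the conventional CV form)
    for sensitivity checks; default off.
    """
    if trait_mean == 0:
        raise ValueError("trait mean must be nonzero")
    num = np.sqrt(sigma2_G) if sqrt_variant else sigma2_G
    return float(num / trait_mean)


def heritability_suite(panel: pd.DataFrame, traits: list,
                       ar1: bool = True,
                       heteroscedastic: bool = True) -> list[HeritabilityReport]:
    """All three H² estimators (and CVs) for each trait.

    ``panel`` must be a long tree-year table with ``tree_id, year, cDBH,
    genetic_group, clonal`` and the trait columns.  Only trees growing
    in clonal groups enter the estimation.  The prediction model is
    trait ~ clonal group + year + cDBH with a random tree intercept
    (AR(1) and per-clone residual multipliers optional); the variance
    model is trait ~ year + cDBH with the clonal group random.
    """
    clonal = panel.loc[panel["clonal"]].copy()
    if clonal.empty:
        raise ValueError("no clonal trees in panel")
    reports = []
    for trait in traits:
        flags: list = []

        # raw estimator on tree-year values: sigma2_P is the total
        # phenotypic variance of the observations, so on clean data the
        # raw and model-based estimators target the same quantity
        h2_raw, raw_info = h2_from_values(clonal[trait],
                                          clonal["genetic_group"])
        flags += [f"raw:{f}" for f in raw_info["flags"]]

        pred_spec = ModelSpec(
            response=trait,
            fixed_terms=["genetic_group", "year", "cDBH"],
            random_factor="tree_id", ar1=ar1,
            heteroscedastic_by="genetic_group" if heteroscedastic else None,
        )
        pred_model = fit_reml(pred_spec, clonal)
        preds = predict_standardized(pred_model,
                                     standardized_newdata(clonal, pred_spec))
        # predictions vary within a clone only through the year effects,
        # so the ANOVA runs on tree-year predictions (averaging them per
        # tree would leave zero within-clone variance and H2 == 1)
        h2_pred, pred_info = h2_from_values(preds,
                                            clonal["genetic_group"])
        flags += [f"pred:{f}" for f in pred_info["flags"]]

        mod_spec = ModelSpec(response=trait, fixed_terms=["year", "cDBH"],
                             random_factor="genetic_group", ar1=False)
        mod_model = fit_reml(mod_spec, clonal)
        s2g, s2r = extract_variance_components(mod_model)
        h2m = h2_mod(s2g, s2r) if s2g + s2r > 0 else 0.0
        mod_mean = float(clonal[trait].mean())

        reports.append(HeritabilityReport(
            trait=trait,
            H2_raw=h2_raw, H2_pred=h2_pred, H2_mod=h2m,
            CV_raw=raw_info["CV"], CV_pred=pred_info["CV"],
            CV_mod=cv(s2g, mod_mean),
            sigma2_G={"raw": raw_info["sigma2_G"],
                      "pred": pred_info["sigma2_G"], "mod": s2g},
            sigma2_P={"raw": raw_info["sigma2_P"],
                      "pred": pred_info["sigma2_P"], "mod": s2g + s2r},
            trait_mean={"raw": raw_info["mean"], "pred": pred_info["mean"],
                        "mod": mod_mean},
            flags=flags,
        ))
    return reports


def reports_to_frame(reports: list[HeritabilityReport]) -> pd.DataFrame:
    """Long heritability table: one row per trait × method."""
    return pd.DataFrame([r for rep in reports for r in rep.as_rows()])
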