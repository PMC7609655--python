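"""Null vs genetic vs spatial model comparison per trait.

Because clone-mates grow next to each other, genetic and spatial
grouping cannot be separated in one model; instead three candidate
mixed models are fitted per trait on the full stand (clonal and
non-clonal trees) and compared by AICc:

* null    — trait ~ year + cDBH, random tree intercept, AR(1);
* genetic — + genetic group as a fixed effect, residual variance
            heteroscedastic by genetic group;
* spatial — + spatial group as a fixed effect, residual variance
            heteroscedastic by spatial group.

A model wins outright only when its AICc is lowest by more than four
units against both competitors; when genetic and spatial are within four
units of each other but both beat the null by more than four, the
verdict is "grouped"; everything else falls back to the null model by
parsimony.  The spatial-vs-genetic AICc gap is additionally classified
as none (≤ 4), considerable (4–10] or essential (> 10); boundary values
resolve to the lower class.  Grouping-term significance (sequential
ANOVA at α = 0.05) is reported independently of the AICc verdict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .lmm import FittedLMM, ModelSpec, fit_reml, term_significance

logger = logging.getLogger(__name__)

AICC_GAP = 4.0
DELTA_CONSIDERABLE = 4.0
DELTA_ESSENTIAL = 10.0


@dataclass
class ComparisonVerdict:
    trait: str
    aicc_null: float
    aicc_genetic: float
    aicc_spatial: float
    delta_spatial_vs_genetic: float
    best_model: str          # null | genetic | spatial | grouped
    delta_class: str         # none | considerable | essential
    genetic_significant: bool | None = None
    spatial_significant: bool | None = None
    failed: bool = False

    def as_row(self) -> dict:
        return {
            "trait": self.trait, "AICc_null": self.aicc_null,
            "AICc_genetic": self.aicc_genetic,
            "AICc_spatial": self.aicc_spatial,
            "delta_spatial_vs_genetic": self.delta_spatial_vs_genetic,
            "best_model": self.best_model, "delta_class": self.delta_class,
            "genetic_significant": self.genetic_significant,
            "spatial_significant": self.spatial_significant,
            "failed": self.failed,
        }


def model_suite_specs(trait: str, ar1: bool = True,
                      heteroscedastic: bool = True) -> dict:
    het = heteroscedastic
    return {
        "null": ModelSpec(response=trait, fixed_terms=["year", "cDBH"],
                          random_factor="tree_id", ar1=ar1),
        "genetic": ModelSpec(response=trait,
                             fixed_terms=["genetic_group", "year", "cDBH"],
                             random_factor="tree_id", ar1=ar1,
                             heteroscedastic_by="genetic_group" if het else None),
        "spatial": ModelSpec(response=trait,
                             fixed_terms=["spatial_group", "year", "cDBH"],
                             random_factor="tree_id", ar1=ar1,
                             heteroscedastic_by="spatial_group" if het else None),
    }


def fit_model_suite(data: pd.DataFrame, trait: str, ar1: bool = True,
                    heteroscedastic: bool = True,
                    n_restarts: int = 3) -> dict[str, FittedLMM]:
    """REML fits of the null, genetic and spatial models for one trait."""
    for col in ("genetic_group", "spatial_group"):
        if col not in data.columns:
            raise ValueError(f"missing grouping column {col!r}")
    return {
        name: fit_reml(spec, data, n_restarts=n_restarts)
        for name, spec in model_suite_specs(trait, ar1, heteroscedastic).items()
    }


def classify_verdict(trait: str, aicc_null: float, aicc_genetic: float,
                     aicc_spatial: float, gap: float = AICC_GAP,
                     genetic_significant: bool | None = None,
                     spatial_significant: bool | None = None) -> ComparisonVerdict:
    """Apply the AICc decision rules to one trait's three model scores."""
    scores = {"null": aicc_null, "genetic": aicc_genetic,
              "spatial": aicc_spatial}
    if not all(math.isfinite(v) for v in scores.values()):
        raise ValueError(f"non-finite AICc for trait {trait!r}: {scores}")

    best = None
    for name, val in scores.items():
        if all(other - val > gap for o, other in scores.items() if o != name):
            best = name
            break
    if best is None:
        both_beat_null = (aicc_null - aicc_genetic > gap
                          and aicc_null - aicc_spatial > gap)
        close = abs(aicc_spatial - aicc_genetic) <= gap
        best = "grouped" if (both_beat_null and close) else "null"

    delta = abs(aicc_spatial - aicc_genetic)
    if delta <= DELTA_CONSIDERABLE:
        delta_class = "none"
    elif delta <= DELTA_ESSENTIAL:
        delta_class = "considerable"
    else:
        delta_class = "essential"

    return ComparisonVerdict(
        trait=trait, aicc_null=aicc_null, aicc_genetic=aicc_genetic,
        aicc_spatial=aicc_spatial,
        delta_spatial_vs_genetic=aicc_spatial - aicc_genetic,
        best_model=best, delta_class=delta_class,
        genetic_significant=genetic_significant,
        spatial_significant=spatial_significant,
    )


def compare_trait(data: pd.DataFrame, trait: str, ar1: bool = True,
                  heteroscedastic: bool = True,
                  alpha: float = 0.05) -> ComparisonVerdict:
    """Fit the three models for one trait and classify the outcome.

    A failed fit yields a flagged verdict rather than aborting the run.
    """
    try:
        fits = fit_model_suite(data, trait, ar1, heteroscedastic)
        sig = {}
        for name, col in (("genetic", "genetic_group"),
                          ("spatial", "spatial_group")):
            anova = term_significance(fits[name], data, alpha=alpha)
            row = anova.loc[anova["term"] == col]
            sig[name] = bool(row["significant"].iloc[0]) if len(row) else None
        return classify_verdict(
            trait, fits["null"].aicc, fits["genetic"].aicc,
            fits["spatial"].aicc,
            genetic_significant=sig["genetic"],
            spatial_significant=sig["spatial"],
        )
    except Exception as exc:  # noqa: BLE001 — robustness across traits
        logger.warning("trait %s: model comparison failed (%s)", trait, exc)
        return ComparisonVerdict(
            trait=trait, aicc_null=math.nan, aicc_genetic=math.nan,
            aicc_spatial=math.nan, delta_spatial_vs_genetic=math.nan,
            best_model="failed", delta_class="failed", failed=True,
        )


def comparison_table(verdicts: list[ComparisonVerdict]) -> pd.DataFrame:
    """One row per trait with the full verdict fields."""
    if not verdicts:
        raise ValueError("need at least one verdict")
    return pd.DataFrame([v.as_row() for v in verdicts])


def format_comparison(table: pd.DataFrame) -> str:
    """Plain-text rendering of the comparison table."""
    lines = [f"{'trait':10s} {'best':8s} {'dAICc(S-G)':>11s} {'class':12s} "
             f"{'sig':>5s}"]
    for _, r in table.iterrows():
        sig = ("S" if r["spatial_significant"] else "") + \
              ("G" if r["genetic_significant"] else "")
        delta = r["delta_spatial_vs_genetic"]
        delta_s = f"{delta:11.1f}" if pd.notna(delta) else f"{'--':>11s}"
        lines.append(f"{r['trait']:10s} {r['best_model']:8s} {delta_s} "
                     f"{r['delta_class']:12s} {sig or '-':>5s}")
    return "\n".join(lines)
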