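"""Stringency criteria and cell-type-specificity calls.

A transcript is called *Sertoli-specific* when germ-cell ablation enriches it
(fold change strictly above the busulfan floor: the cell type survives the
first ablation), Sertoli ablation then depletes it (residual fraction of the
germ-free level at or below the ceiling), and the depletion is statistically
significant at the configured FDR.  A transcript is called *germ-specific*
when germ-cell ablation alone removes more than the configured fraction of
it (residual strictly below the germ ceiling) with a significant reduction.

Two presets mirror common usage: ``relaxed`` (fold change > 2 after germ
ablation, >= 70% loss after Sertoli ablation) trades some purity for
sensitivity; ``strict`` (> 5-fold, >= 90% loss) is high-purity.  Boundary
behavior is deliberate and config-visible: the fold-change floor is a strict
inequality, the residual ceiling inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

CATEGORIES = ("sertoli_specific", "germ_specific", "unclassified")


@dataclass(frozen=True)
class StringencyCriteria:
    """Thresholds of the ablation-response classifier.

    Attributes
    ----------
    min_busulfan_fc
        Fold-change floor (strict) on the germ-ablation contrast for a
        Sertoli call; must exceed 1 (the call requires apparent enrichment).
    max_dtx_residual
        Ceiling (inclusive) on the fraction of the germ-free level remaining
        after Sertoli ablation, in (0, 1); 0.30 encodes "a 70% decrease".
    require_significant_dtx
        Demand a significant reduction on the Sertoli-ablation contrast.
    significance_mode
        ``busulfan_or_dtx``: at least one of the two contrasts significant
        (in addition to the mandatory Sertoli-ablation significance when
        ``require_significant_dtx``); ``dtx_only``: only the
        Sertoli-ablation contrast is consulted.
    alpha, fdr
        Per-test significance level and BH false-discovery rate.
    germ_max_residual
        Ceiling (strict) on the fraction of control remaining after germ
        ablation for a germ call; 0.10 encodes "> 90% reduction".
    """

    min_busulfan_fc: float = 2.0
    max_dtx_residual: float = 0.30
    require_significant_dtx: bool = True
    significance_mode: str = "busulfan_or_dtx"
    alpha: float = 0.05
    fdr: float = 0.05
    germ_max_residual: float = 0.10

    def __post_init__(self) -> None:
        if not self.min_busulfan_fc > 1:
            raise ValueError("min_busulfan_fc must exceed 1")
        if not 0 < self.max_dtx_residual < 1:
            raise ValueError("max_dtx_residual must lie in (0, 1)")
        if not 0 < self.germ_max_residual < 1:
            raise ValueError("germ_max_residual must lie in (0, 1)")
        if not (0 < self.alpha < 1 and 0 < self.fdr < 1):
            raise ValueError("alpha and fdr must lie in (0, 1)")
        if self.significance_mode not in ("dtx_only", "busulfan_or_dtx"):
            raise ValueError("significance_mode must be 'dtx_only' or 'busulfan_or_dtx'")


PRESETS: Mapping[str, StringencyCriteria] = {
    "relaxed": StringencyCriteria(min_busulfan_fc=2.0, max_dtx_residual=0.30),
    "strict": StringencyCriteria(min_busulfan_fc=5.0, max_dtx_residual=0.10),
}


def make_criteria(preset: str | None = None, **overrides: object) -> StringencyCriteria:
    """Build criteria from a preset name and/or explicit field overrides."""
    if preset is None:
        return StringencyCriteria(**overrides)  # type: ignore[arg-type]
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}")
    return replace(PRESETS[preset], **overrides)  # type: ignore[arg-type]


def _aligned(
    bus_contrast: pd.DataFrame, dtx_contrast: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if not bus_contrast.index.equals(dtx_contrast.index):
        common = bus_contrast.index.intersection(dtx_contrast.index)
        if len(common) != len(bus_contrast) or len(common) != len(dtx_contrast):
            raise ValueError("contrasts must share one transcript universe")
        dtx_contrast = dtx_contrast.loc[bus_contrast.index]
    return bus_contrast, dtx_contrast


def classify_sertoli_specific(
    bus_contrast: pd.DataFrame,
    dtx_contrast: pd.DataFrame,
    criteria: StringencyCriteria,
) -> pd.DataFrame:
    """Call Sertoli-specific transcripts from the two ablation contrasts.

    ``bus_contrast`` is germ-ablated vs control, ``dtx_contrast`` is
    (germ+Sertoli)-ablated vs germ-ablated; both must carry populated
    q-values and share a transcript universe.  Transcripts whose germ-
    ablation fold change is undefined (zero control mean) are unclassified:
    the rule requires an observed increase.

    Returns a frame indexed like the contrasts with columns ``category``,
    ``busulfan_fc``, ``dtx_residual``, ``significant_bus``, ``significant_dtx``.
    """
    bus, dtx = _aligned(bus_contrast, dtx_contrast)
    if bus["q_value"].isna().all() or dtx["q_value"].isna().all():
        raise ValueError("q-values must be populated before classification")

    bus_fc = bus["fold_change"].to_numpy(dtype=float)
    # Residual fraction of the germ-free level after Sertoli ablation.
    dtx_residual = dtx["fold_change"].to_numpy(dtype=float)
    # Significance calls: a significant *reduction* on the DTX contrast.
    sig_bus = (bus["q_value"].to_numpy(dtype=float) <= criteria.fdr) & ~np.isnan(
        bus["q_value"].to_numpy(dtype=float)
    )
    q_dtx = dtx["q_value"].to_numpy(dtype=float)
    reduced_dtx = dtx["mean_alt"].to_numpy() < dtx["mean_ref"].to_numpy()
    sig_dtx = (q_dtx <= criteria.fdr) & ~np.isnan(q_dtx) & reduced_dtx

    passes_fc = ~np.isnan(bus_fc) & (bus_fc > criteria.min_busulfan_fc)
    passes_residual = ~np.isnan(dtx_residual) & (
        dtx_residual <= criteria.max_dtx_residual
    )
    if criteria.significance_mode == "busulfan_or_dtx":
        passes_sig = sig_bus | sig_dtx
    else:
        passes_sig = sig_dtx
    if criteria.require_significant_dtx:
        passes_sig = passes_sig & sig_dtx

    called = passes_fc & passes_residual & passes_sig
    return pd.DataFrame(
        {
            "category": np.where(called, "sertoli_specific", "unclassified"),
            "busulfan_fc": bus_fc,
            "dtx_residual": dtx_residual,
            "significant_bus": sig_bus,
            "significant_dtx": sig_dtx,
        },
        index=bus.index,
    )


def classify_germ_specific(
    bus_contrast: pd.DataFrame, criteria: StringencyCriteria
) -> pd.DataFrame:
    """Call germ-cell-specific transcripts from the germ-ablation contrast.

    A transcript qualifies when its residual fraction after germ ablation
    (germ-ablated mean / control mean) is strictly below
    ``criteria.germ_max_residual`` with a significant reduction at the FDR.
    """
    if bus_contrast["q_value"].isna().all():
        raise ValueError("q-values must be populated before classification")
    residual = bus_contrast["fold_change"].to_numpy(dtype=float)
    q = bus_contrast["q_value"].to_numpy(dtype=float)
    reduced = bus_contrast["mean_alt"].to_numpy() < bus_contrast["mean_ref"].to_numpy()
    called = (
        ~np.isnan(residual)
        & (residual < criteria.germ_max_residual)
        & ~np.isnan(q)
        & (q <= criteria.fdr)
        & reduced
    )
    return pd.DataFrame(
        {
            "category": np.where(called, "germ_specific", "unclassified"),
            "busulfan_residual": residual,
            "significant_bus": ~np.isnan(q) & (q <= criteria.fdr),
        },
        index=bus_contrast.index,
    )


def summarize_biotypes(
    calls: pd.DataFrame, annotation: pd.Series | Mapping[str, str]
) -> pd.Series:
    """Count called transcripts per biotype; unannotated entries go to 'other'.

    ``calls`` is the output of a classify function; only rows whose category
    is not ``unclassified`` are counted.  Counts always cover the four
    categories {protein_coding, non_coding, pseudogene, other} and sum to
    the number of called transcripts.
    """
    from .io import BIOTYPES

    ann = pd.Series(annotation, dtype="string")
    called_ids = calls.index[calls["category"] != "unclassified"]
    biotypes = ann.reindex(called_ids).fillna("other")
    biotypes = biotypes.where(biotypes.isin(BIOTYPES), "other")
    counts = biotypes.value_counts().reindex(BIOTYPES, fill_value=0).astype(int)
    counts.name = "count"
    return counts
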