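"""Per-transcript two-group statistics for the sequential-ablation design.

The core contrasts are germ-cell ablation vs control ("busulfan vs control")
and Sertoli ablation on a germ-free background ("busulfan+DTX vs busulfan").
Each contrast yields per-transcript group means, a fold change
(``mean_alt / mean_ref``), a p-value from a two-sample test, and a
Benjamini–Hochberg q-value adjusted across all transcripts of the contrast
(one family per contrast).

Undefined ratios are flagged with NaN, never patched with pseudocounts: a
fold change is undefined when the reference mean is zero, and a log2 fold
change additionally when the alternative mean is zero (e.g. a transcript
fully extinguished by Sertoli ablation).
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger("sertoliseq")

TESTS = ("welch_t", "student_t", "one_way_anova")


def compute_group_contrast(
    matrix: ExpressionMatrix,
    ref_group: str,
    alt_group: str,
    test: str = "welch_t",
    adjust: bool = True,
) -> pd.DataFrame:
    """Two-group contrast for every transcript of ``matrix``.

    Parameters
    ----------
    matrix
        Expression matrix with grouped replicates.
    ref_group, alt_group
        Group labels; fold change is ``mean(alt) / mean(ref)``.
    test
        ``welch_t`` (default; replicate numbers may differ between groups),
        ``student_t`` (pooled variance) or ``one_way_anova`` (equivalent to
        the pooled t for two groups).
    adjust
        If True, fill ``q_value`` by BH adjustment across all transcripts
        with a defined p-value.

    Notes
    -----
    Transcripts with all-zero values in both groups get an undefined fold
    change and p = 1 (kept, not dropped, so transcript universes remain
    aligned between contrasts).  Transcripts with zero within-group variance
    in both groups get p = 1 if the means agree and p = 0 otherwise.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    ref = matrix.group_values(ref_group).to_numpy(dtype=float)
    alt = matrix.group_values(alt_group).to_numpy(dtype=float)
    n_ref, n_alt = ref.shape[1], alt.shape[1]
    if min(n_ref, n_alt) < 2:
        raise ValueError(
            f"need >=2 replicates per group, got {n_ref} vs {n_alt}"
        )

    mean_ref = ref.mean(axis=1)
    mean_alt = alt.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_change = np.where(mean_ref > 0, mean_alt / mean_ref, np.nan)
        log2fc = np.where(
            (mean_ref > 0) & (mean_alt > 0), np.log2(mean_alt) - np.log2(mean_ref), np.nan
        )

    if test == "welch_t":
        res = stats.ttest_ind(alt, ref, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    elif test == "student_t":
        res = stats.ttest_ind(alt, ref, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        res = stats.f_oneway(alt, ref, axis=1)
        p = np.asarray(res.pvalue, dtype=float)

    # Degenerate rows: zero variance in both groups gives NaN from the test.
    var_zero = (ref.var(axis=1) == 0) & (alt.var(axis=1) == 0)
    p = np.where(var_zero & (mean_ref == mean_alt), 1.0, p)
    p = np.where(var_zero & (mean_ref != mean_alt), 0.0, p)
    n_undef = int(np.isnan(p).sum())
    if n_undef:
        logger.info("%d transcripts with undefined p-value in %s vs %s",
                    n_undef, alt_group, ref_group)

    out = pd.DataFrame(
        {
            "gene_symbol": (
                matrix.gene_symbols
                if matrix.gene_symbols is not None
                else pd.Series(pd.NA, index=matrix.transcript_ids, dtype="string")
            ),
            "mean_ref": mean_ref,
            "mean_alt": mean_alt,
            "fold_change": fold_change,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": np.nan,
        },
        index=matrix.transcript_ids,
    )
    if adjust:
        out["q_value"] = adjust_fdr_bh(out["p_value"].to_numpy())
    return out


def adjust_fdr_bh(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order-preserving.

    NaN (undefined) p-values are excluded from the family and returned NaN.
    Values are monotone non-decreasing in p-rank and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    defined = ~np.isnan(p)
    if ((p[defined] < 0) | (p[defined] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if defined.any():
        q[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return q


def scatter_coordinates(
    bus_contrast: pd.DataFrame, dtx_contrast: pd.DataFrame
) -> pd.DataFrame:
    """Coordinates of the two-ablation log-ratio scatter.

    x is the log2 fold change of germ ablation vs control, y the log2 fold
    change of Sertoli ablation vs germ-ablated.  When the Sertoli-ablated
    group mean is zero with a positive germ-ablated mean, y cannot be
    computed and ``undefined_y`` is set instead of substituting a value
    (the plot marks such transcripts with an arrow at the axis).
    Transcripts present in only one contrast are excluded and logged.
    """
    common = bus_contrast.index.intersection(dtx_contrast.index)
    dropped = (len(bus_contrast) - len(common)) + (len(dtx_contrast) - len(common))
    if dropped:
        logger.warning("%d transcripts present in only one contrast; excluded", dropped)
    bus = bus_contrast.loc[common]
    dtx = dtx_contrast.loc[common]
    return pd.DataFrame(
        {
            "x": bus["log2fc"],
            "y": dtx["log2fc"],
            "undefined_y": (dtx["mean_alt"] == 0) & (dtx["mean_ref"] > 0),
        },
        index=common,
    )


class EnrichmentEstimate(NamedTuple):
    """Apparent somatic enrichment after germ-cell ablation, from a marker panel."""

    mean_fc: float
    min_fc: float
    max_fc: float
    n_used: int


def estimate_enrichment_from_markers(
    bus_contrast: pd.DataFrame,
    marker_panel: Sequence[str],
    average: str = "arithmetic",
) -> EnrichmentEstimate:
    """Mean and range of busulfan fold change over a somatic marker panel.

    Germ-cell ablation leaves somatic transcripts relatively enriched in the
    renormalized (FPKM-like) bulk profile; their fold change over control
    estimates that enrichment.  Panel symbols are matched case-insensitively
    against the contrast's ``gene_symbol`` column; only markers with a
    defined fold change contribute.
    """
    if average not in ("arithmetic", "geometric"):
        raise ValueError("average must be 'arithmetic' or 'geometric'")
    panel = {s.strip().casefold() for s in marker_panel}
    symbols = bus_contrast["gene_symbol"].astype("string").str.strip().str.casefold()
    matched = bus_contrast.loc[symbols.isin(panel), "fold_change"].dropna()
    if matched.empty:
        raise ValueError("no marker-panel member matched with a defined fold change")
    fc = matched.to_numpy(dtype=float)
    mean_fc = float(np.exp(np.mean(np.log(fc)))) if average == "geometric" else float(fc.mean())
    return EnrichmentEstimate(mean_fc, float(fc.min()), float(fc.max()), int(fc.size))
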