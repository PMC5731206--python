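"""Hormone dependence of Sertoli-cell transcripts: normalization + factorial ANOVA.

Knockout of the FSH receptor (FSHRKO) or of the androgen receptor in Sertoli
cells (SCARKO) changes both Sertoli cell number and testis volume, so raw
whole-testis signal confounds per-cell expression with Sertoli mRNA
*enrichment*.  The enrichment factor of genotype X is the ratio of Sertoli
cell densities,

    EF(X) = [Sertoli cells in X / testis volume of X]
          / [control Sertoli cells / control volume],

and dividing each sample by its genotype's EF expresses abundance per
Sertoli cell (EF(control) = 1 by construction).

The normalized data are then analyzed transcript-by-transcript with a
two-factor ANOVA (factors: FSHR knockout, Sertoli AR knockout, with
interaction) over the 2x2 genotype design {control, FSHRKO, SCARKO,
FSHRKO_SCARKO}.  A significant interaction means the double knockout departs
from additivity (synergy or antagonism); in that case per-genotype p-values
come from Tukey honest-significant-difference post-hoc comparisons, and the
transcript's compact-letter display is reported.  Main-effect and
interaction p-values are BH-adjusted across transcripts, one family per
effect.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import adjust_fdr_bh
from .io import ExpressionMatrix

logger = logging.getLogger("sertoliseq")

GENOTYPES = ("control", "FSHRKO", "SCARKO", "FSHRKO_SCARKO")


@dataclass(frozen=True)
class FactorialDesign:
    """2x2 knockout design: genotype -> (fshr_ko, ar_ko) factor coding."""

    coding: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "control": (0, 0),
            "FSHRKO": (1, 0),
            "SCARKO": (0, 1),
            "FSHRKO_SCARKO": (1, 1),
        }
    )

    def __post_init__(self) -> None:
        cells = set(self.coding.values())
        if cells != {(0, 0), (1, 0), (0, 1), (1, 1)}:
            raise ValueError("design must cover all four factor cells exactly once")

    @property
    def genotypes(self) -> list[str]:
        return list(self.coding)

    def genotype_for_cell(self, fshr_ko: int, ar_ko: int) -> str:
        for g, cell in self.coding.items():
            if cell == (fshr_ko, ar_ko):
                return g
        raise KeyError((fshr_ko, ar_ko))


def compute_enrichment_factor(
    morphometry: pd.DataFrame, genotype: str, control: str = "control"
) -> float:
    """Sertoli-cell-density ratio of ``genotype`` over ``control``."""
    for g in (genotype, control):
        if g not in morphometry.index:
            raise KeyError(f"genotype {g!r} missing from morphometry table")
    cells = morphometry["sertoli_cells_per_testis"]
    vol = morphometry["testis_volume"]
    if (cells.loc[[genotype, control]] <= 0).any() or (vol.loc[[genotype, control]] <= 0).any():
        raise ValueError("Sertoli counts and testis volumes must be positive")
    return float(
        (cells[genotype] / vol[genotype]) / (cells[control] / vol[control])
    )


def enrichment_factors(
    morphometry: pd.DataFrame, control: str = "control"
) -> pd.Series:
    """Enrichment factor for every genotype in the table (control -> 1.0)."""
    return pd.Series(
        {g: compute_enrichment_factor(morphometry, g, control) for g in morphometry.index},
        name="enrichment_factor",
    )


def normalize_to_sertoli_number(
    matrix: ExpressionMatrix, factors: Mapping[str, float] | pd.Series
) -> ExpressionMatrix:
    """Divide each sample by its genotype's (group's) enrichment factor."""
    factors = pd.Series(factors, dtype=float)
    meta = matrix.sample_meta.loc[list(matrix.values.columns)]
    missing = sorted(set(meta["group"]) - set(factors.index))
    if missing:
        raise KeyError(f"no enrichment factor for genotype(s) {missing}")
    per_sample = meta["group"].map(factors)
    return matrix.with_values(matrix.values.div(per_sample, axis=1))


# -- 2x2 factorial ANOVA -------------------------------------------------------


def _balanced_cube(
    matrix: ExpressionMatrix, design: FactorialDesign
) -> tuple[np.ndarray, int] | None:
    """Stack values into (transcripts, 2, 2, n) if the design is balanced."""
    counts = {g: len(matrix.samples_in_group(g)) for g in design.genotypes}
    n = counts[design.genotypes[0]]
    if any(c != n for c in counts.values()):
        return None
    t = len(matrix.transcript_ids)
    cube = np.empty((t, 2, 2, n), dtype=float)
    for g, (a, b) in design.coding.items():
        cube[:, a, b, :] = matrix.group_values(g).to_numpy(dtype=float)
    return cube, n


def _anova_balanced(cube: np.ndarray, n: int) -> dict[str, np.ndarray]:
    """Closed-form balanced 2x2 factorial ANOVA, vectorized over transcripts.

    With a balanced design the classical (Type I/II/III) sums of squares
    coincide, so the factorial decomposition can be computed directly from
    cell means.
    """
    cell_means = cube.mean(axis=3)                      # (t, 2, 2)
    grand = cell_means.mean(axis=(1, 2))                # (t,)
    a_means = cell_means.mean(axis=2)                   # (t, 2) over factor A
    b_means = cell_means.mean(axis=1)                   # (t, 2) over factor B
    ss_a = 2 * n * ((a_means - grand[:, None]) ** 2).sum(axis=1)
    ss_b = 2 * n * ((b_means - grand[:, None]) ** 2).sum(axis=1)
    inter_dev = (
        cell_means
        - a_means[:, :, None]
        - b_means[:, None, :]
        + grand[:, None, None]
    )
    ss_ab = n * (inter_dev ** 2).sum(axis=(1, 2))
    ss_err = ((cube - cell_means[..., None]) ** 2).sum(axis=(1, 2, 3))
    df_err = 4 * (n - 1)
    mse = ss_err / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        f_a, f_b, f_ab = ss_a / mse, ss_b / mse, ss_ab / mse
    out = {}
    for key, f in (("fshr", f_a), ("ar", f_b), ("interaction", f_ab)):
        p = stats.f.sf(f, 1, df_err)
        p = np.where(np.isfinite(f), p, np.nan)  # zero residual variance
        out[f"F_{key}"], out[f"p_{key}"] = f, p
    out["ss_fshr"], out["ss_ar"], out["ss_interaction"] = ss_a, ss_b, ss_ab
    out["mse"], out["df_err"] = mse, np.full_like(mse, df_err)
    return out


def _anova_unbalanced(
    matrix: ExpressionMatrix, design: FactorialDesign, transform: str | None = None
) -> dict[str, np.ndarray]:
    """Type-II sums of squares via per-transcript OLS model comparison."""
    import statsmodels.api as sm
    from statsmodels.stats.anova import anova_lm

    meta = matrix.sample_meta.loc[list(matrix.values.columns)]
    a = meta["group"].map({g: c[0] for g, c in design.coding.items()}).to_numpy(float)
    b = meta["group"].map({g: c[1] for g, c in design.coding.items()}).to_numpy(float)
    Y = matrix.values.to_numpy(dtype=float)
    if transform == "log2":
        with np.errstate(divide="ignore", invalid="ignore"):
            Y = np.where(Y > 0, np.log2(np.where(Y > 0, Y, 1.0)), np.nan)
    t = Y.shape[0]
    res = {k: np.full(t, np.nan) for k in
           ("F_fshr", "p_fshr", "F_ar", "p_ar", "F_interaction", "p_interaction",
            "ss_fshr", "ss_ar", "ss_interaction", "mse", "df_err")}

    for i in range(t):
        if np.isnan(Y[i]).any():
            continue
        data = pd.DataFrame({"y": Y[i], "a": a, "b": b})
        fit = sm.OLS.from_formula("y ~ a * b", data).fit()
        if fit.df_resid <= 0 or fit.mse_resid == 0:
            continue
        table = anova_lm(fit, typ=2)
        for key, row in (("fshr", "a"), ("ar", "b"), ("interaction", "a:b")):
            res[f"F_{key}"][i] = table.loc[row, "F"]
            res[f"p_{key}"][i] = table.loc[row, "PR(>F)"]
            res[f"ss_{key}"][i] = table.loc[row, "sum_sq"]
        res["mse"][i] = fit.mse_resid
        res["df_err"][i] = fit.df_resid
    return res


def _tukey_pairwise_p(
    means: np.ndarray, counts: np.ndarray, mse: float, df_err: float
) -> np.ndarray:
    """All-pairs Tukey HSD p-value matrix for k group means sharing one MSE."""
    k = means.size
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(mse / 2 * (1 / counts[i] + 1 / counts[j]))
        q = abs(means[i] - means[j]) / se if se > 0 else np.inf
        pij = float(stats.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
        p[i, j] = p[j, i] = pij
    return p


def _compact_letters(p: np.ndarray, alpha: float, labels: list[str]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly different.

    Insert-and-absorb construction over the significant-difference graph.
    """
    k = len(labels)
    letter_sets: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if p[i, j] > alpha:
            continue
        for s in [s for s in letter_sets if i in s and j in s]:
            letter_sets.remove(s)
            s_i, s_j = s - {j}, s - {i}
            for cand in (s_i, s_j):
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
    letter_sets.sort(key=lambda s: (min(s), -len(s)))
    out = {lab: "" for lab in labels}
    for letter, s in zip("abcdefghij", letter_sets):
        for idx in sorted(s):
            out[labels[idx]] += letter
    return out


def per_transcript_two_factor_anova(
    matrix: ExpressionMatrix,
    design: FactorialDesign | None = None,
    fdr: float = 0.05,
    posthoc: bool = True,
    transform: str | None = None,
) -> pd.DataFrame:
    """Two-factor ANOVA with interaction for every transcript.

    Parameters
    ----------
    matrix
        Normalized expression matrix whose groups are the four genotypes.
    design
        Genotype/factor coding; defaults to the standard 2x2 knockout design.
    transform
        ``None`` (default) analyses the normalized linear-scale signal;
        ``"log2"`` log-transforms first (additivity is scale-dependent:
        multiplicative knockout effects are additive on the log scale).
        Transcripts with zeros get undefined p-values under ``"log2"``.
    fdr
        BH false-discovery rate; each effect (FSHR, AR, interaction) forms
        its own family across transcripts.
    posthoc
        Compute Tukey HSD letters and post-hoc main-effect p-values for
        transcripts whose interaction is significant (q <= fdr).  Where the
        interaction is not significant the effective main-effect p-values
        are taken directly from the ANOVA.

    Returns
    -------
    DataFrame indexed by transcript with the four normalized genotype means,
    raw ANOVA p-values (``p_*_anova``), effective p-values (``p_fshr``,
    ``p_ar``: post-hoc genotype-vs-control where the interaction is
    significant), q-values, Tukey letters, and ``effect_mode``
    (``interaction`` or ``additive``).

    Notes
    -----
    Transcripts with zero residual variance get undefined (NaN) p-values and
    are logged.  Unbalanced designs are accepted (Type-II sums of squares)
    with a warning; with balanced data the classical decompositions coincide.
    """
    design = design or FactorialDesign()
    for g in design.genotypes:
        if len(matrix.samples_in_group(g)) < 2:
            raise ValueError(f"genotype {g!r} needs >=2 replicates")
    if transform not in (None, "log2"):
        raise ValueError("transform must be None or 'log2'")

    analysis_matrix = matrix
    if transform == "log2":
        vals = matrix.values.to_numpy(dtype=float)
        n_zero = int((vals <= 0).any(axis=1).sum())
        if n_zero:
            logger.info("%d transcripts with non-positive values: p undefined "
                        "under log2 transform", n_zero)

    cube_n = _balanced_cube(analysis_matrix, design)
    if cube_n is not None:
        cube, n = cube_n
        if transform == "log2":
            with np.errstate(divide="ignore", invalid="ignore"):
                cube = np.where(cube > 0, np.log2(np.where(cube > 0, cube, 1.0)), np.nan)
        res = _anova_balanced(cube, n)
    else:
        logger.warning("unbalanced design: falling back to per-transcript Type-II OLS")
        res = _anova_unbalanced(analysis_matrix, design, transform)

    ids = matrix.transcript_ids
    out = pd.DataFrame(index=ids)
    group_means = matrix.group_means()
    counts = np.array([len(matrix.samples_in_group(g)) for g in design.genotypes])
    for g in design.genotypes:
        out[f"mean_{g}"] = group_means[g]
    out["p_fshr_anova"] = res["p_fshr"]
    out["p_ar_anova"] = res["p_ar"]
    out["p_interaction"] = res["p_interaction"]
    for key in ("fshr", "ar", "interaction"):
        out[f"F_{key}"] = res[f"F_{key}"]
        out[f"ss_{key}"] = res[f"ss_{key}"]
    n_undef = int(np.isnan(res["p_interaction"]).sum())
    if n_undef:
        logger.info("%d transcripts with zero residual variance: p undefined", n_undef)

    out["q_interaction"] = adjust_fdr_bh(out["p_interaction"].to_numpy())

    p_fshr_eff = out["p_fshr_anova"].to_numpy(dtype=float).copy()
    p_ar_eff = out["p_ar_anova"].to_numpy(dtype=float).copy()
    letters = pd.Series("", index=ids, dtype="string")

    if posthoc:
        sig_inter = (out["q_interaction"].to_numpy() <= fdr) & ~np.isnan(
            out["q_interaction"].to_numpy()
        )
        labels = design.genotypes
        control = design.genotype_for_cell(0, 0)
        g_fshr = design.genotype_for_cell(1, 0)
        g_ar = design.genotype_for_cell(0, 1)
        means_arr = group_means[labels].to_numpy(dtype=float)
        i_ctrl = labels.index(control)
        for idx in np.flatnonzero(sig_inter):
            pmat = _tukey_pairwise_p(
                means_arr[idx], counts, float(res["mse"][idx]), float(res["df_err"][idx])
            )
            p_fshr_eff[idx] = pmat[i_ctrl, labels.index(g_fshr)]
            p_ar_eff[idx] = pmat[i_ctrl, labels.index(g_ar)]
            cld = _compact_letters(pmat, 0.05, labels)
            letters.iloc[idx] = "/".join(cld[g] for g in labels)

    out["p_fshr"] = p_fshr_eff
    out["p_ar"] = p_ar_eff
    out["q_fshr"] = adjust_fdr_bh(p_fshr_eff)
    out["q_ar"] = adjust_fdr_bh(p_ar_eff)
    out["posthoc_letters"] = letters
    out["effect_mode"] = np.where(
        (out["q_interaction"] <= fdr) & out["q_interaction"].notna(),
        "interaction",
        "additive",
    )

    control = design.genotype_for_cell(0, 0)
    for key, g in (("fshr", design.genotype_for_cell(1, 0)),
                   ("ar", design.genotype_for_cell(0, 1))):
        sig = (out[f"q_{key}"] <= fdr) & out[f"q_{key}"].notna()
        direction = np.sign(out[f"mean_{g}"] - out[f"mean_{control}"])
        out[f"regulation_{key}"] = np.where(
            ~sig, "unchanged", np.where(direction < 0, "down", "up")
        )
    return out


def classify_regulation(
    records: pd.DataFrame,
    design: FactorialDesign | None = None,
    fdr: float = 0.05,
    deep_decrease_residual: float = 0.10,
) -> dict:
    """Summarize per-factor regulation and additivity over ANOVA records.

    Returns counts of significantly down/up-regulated transcripts per factor
    (direction: single-knockout normalized mean vs control), counts of
    additive vs interaction transcripts, and the transcripts showing a
    deep (>90% by default) decrease in the double knockout among the
    interaction-significant ones.
    """
    design = design or FactorialDesign()
    control = design.genotype_for_cell(0, 0)
    double = design.genotype_for_cell(1, 1)
    summary: dict = {"n_transcripts": int(len(records))}
    for key in ("fshr", "ar"):
        reg = records[f"regulation_{key}"]
        summary[f"{key}_down"] = int((reg == "down").sum())
        summary[f"{key}_up"] = int((reg == "up").sum())
        summary[f"{key}_altered"] = summary[f"{key}_down"] + summary[f"{key}_up"]
    summary["additive"] = int((records["effect_mode"] == "additive").sum())
    summary["interaction"] = int((records["effect_mode"] == "interaction").sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = records[f"mean_{double}"] / records[f"mean_{control}"]
    deep = records.index[
        (records["effect_mode"] == "interaction") & (ratio <= deep_decrease_residual)
    ]
    summary["deep_double_ko_decrease"] = list(deep)
    return summary
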