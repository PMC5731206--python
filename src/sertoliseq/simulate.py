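"""Ground-truthed synthetic testis expression data.

Bulk testis expression is modeled as a composition-weighted mixture of
cell-type transcriptome profiles.  Each cell type c carries a per-cell
expression vector e_{t,c}; its *profile* p_{t,c} = e_{t,c} / sum_t e_{t,c}
is the fraction of that cell type's mRNA contributed by transcript t.  A
bulk sample under condition k with mRNA mass fractions w_c(k) (summing to 1)
has expected relative abundance

    x_t(k)  ∝  sum_c  w_c(k) · p_{t,c},

renormalized to a fixed per-sample total — the FPKM-like constraint that
makes *relative* somatic enrichment appear when germ-cell mRNA is removed.
With germ mass fraction f_germ in control, complete germ ablation multiplies
every purely somatic transcript by exactly 1 / (1 − f_germ); the default
f_germ = 1 − 1/6.49 ≈ 0.846 puts that apparent enrichment at the 6.5-fold
scale observed for somatic markers in germ-cell-ablated testes.

The knockout (array-style) simulator instead keeps absolute per-testis
signal: the Sertoli mixture weight scales with the genotype's Sertoli-cell
density from the morphometry table, and per-cell Sertoli expression is
multiplied by the transcript's FSHR-knockout and AR-knockout effects (and an
interaction multiplier in the double knockout).  Un-normalized data thus
exhibit the enrichment artifact the analysis pipeline must undo by dividing
by the enrichment factor.

Replicate noise is multiplicative lognormal, parameterized by a coefficient
of variation (mean-one, so expectations are unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hormones import GENOTYPES, enrichment_factors
from .io import ExpressionMatrix, validate_morphometry

CELL_TYPES = ("germ", "sertoli", "leydig", "other_somatic")

TRUTH_CATEGORIES = (
    "germ_exclusive",
    "sertoli_exclusive",
    "leydig_exclusive",
    "other_somatic_exclusive",
    "shared",
    "sertoli_dependent_other",
)

#: Germ-cell share of control testis mRNA mass.  Set so that complete germ
#: ablation gives a 1/(1-f) = 6.49-fold apparent enrichment of somatic
#: transcripts, the scale measured for somatic marker panels.
DEFAULT_GERM_FRACTION = 1.0 - 1.0 / 6.49

#: How control somatic mRNA mass splits between somatic cell types.
DEFAULT_SOMATIC_SPLIT = {"sertoli": 0.45, "leydig": 0.25, "other_somatic": 0.30}

ABLATION_CONDITIONS = ("control", "busulfan", "busulfan_dtx")


@dataclass(frozen=True)
class TruthConfig:
    """Composition of the synthetic transcript universe and effect models.

    Class fractions must sum to <= 1; the remainder is "shared" transcripts
    expressed in every cell type.  Knockout effect multipliers act on the
    Sertoli component only and are assigned to Sertoli-exclusive transcripts
    (1 = no effect; < 1 = expression lost on knockout).
    """

    frac_germ_exclusive: float = 0.30
    frac_sertoli_exclusive: float = 0.10
    frac_leydig_exclusive: float = 0.05
    frac_other_exclusive: float = 0.05
    frac_sertoli_dependent_other: float = 0.0
    #: lognormal parameters of per-cell transcript abundance (arbitrary units)
    abundance_meanlog: float = np.log(30.0)
    abundance_sdlog: float = 1.2
    #: replicate noise coefficient of variation (lognormal, mean-one)
    cv: float = 0.2
    #: fraction of Sertoli-exclusive transcripts affected by each knockout
    frac_fshr_affected: float = 0.5
    frac_ar_affected: float = 0.5
    #: down-regulation multiplier ranges (log-uniform draws)
    fshr_effect_range: tuple[float, float] = (0.2, 0.5)
    ar_effect_range: tuple[float, float] = (0.2, 0.5)
    #: rare up-regulated transcripts (one or two per study in practice)
    frac_fshr_up: float = 0.02
    frac_ar_up: float = 0.02
    up_effect_range: tuple[float, float] = (1.5, 2.5)
    #: synergistic interactions among affected transcripts
    frac_interaction: float = 0.25
    interaction_range: tuple[float, float] = (0.2, 0.6)
    #: residual per-cell expression of confounder transcripts after Sertoli loss
    sertoli_dependence_residual: float = 0.05

    def __post_init__(self) -> None:
        fracs = (
            self.frac_germ_exclusive,
            self.frac_sertoli_exclusive,
            self.frac_leydig_exclusive,
            self.frac_other_exclusive,
            self.frac_sertoli_dependent_other,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("class fractions must be non-negative and sum to <= 1")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset.

    Attributes
    ----------
    expression
        Per-cell-type expression (transcripts x cell types, abundance units).
    category
        Transcript class (exclusive classes, shared, or confounder).
    fshr_effect, ar_effect, interaction_multiplier
        Positive multipliers on Sertoli per-cell expression under FSHR
        knockout, Sertoli-AR knockout, and their combination (the double
        knockout sees fshr_effect * ar_effect * interaction_multiplier).
    config, seed
        Generating configuration and seed (same seed -> identical truth).
    """

    expression: pd.DataFrame
    category: pd.Series
    fshr_effect: pd.Series
    ar_effect: pd.Series
    interaction_multiplier: pd.Series
    config: TruthConfig
    seed: int

    @property
    def transcript_ids(self) -> pd.Index:
        return self.expression.index

    def profiles(self) -> pd.DataFrame:
        """Column-normalized expression: each cell type's mRNA mass fractions."""
        totals = self.expression.sum(axis=0)
        return self.expression.div(totals.where(totals > 0, 1.0), axis=1)

    def ids_in_category(self, category: str) -> pd.Index:
        if category not in TRUTH_CATEGORIES:
            raise ValueError(f"unknown truth category {category!r}")
        return self.expression.index[self.category == category]

    def marker_panel(self, n: int = 25, seed: int = 0) -> list[str]:
        """A reproducible panel of somatic-exclusive marker transcripts."""
        somatic = self.expression.index[
            self.category.isin(
                ["sertoli_exclusive", "leydig_exclusive", "other_somatic_exclusive"]
            )
        ]
        if len(somatic) < n:
            raise ValueError(f"only {len(somatic)} somatic-exclusive transcripts available")
        rng = np.random.default_rng(seed)
        return sorted(rng.choice(somatic.to_numpy(), size=n, replace=False).tolist())


def generate_truth(
    n_transcripts: int,
    config: TruthConfig | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a ground-truth transcript universe.

    Exactly ``round(frac * n_transcripts)`` transcripts are assigned to each
    exclusive class (in declaration order); the remainder are shared.
    Abundances are lognormal per transcript and cell type; knockout effect
    multipliers are drawn for Sertoli-exclusive transcripts per the config.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    cfg = config or TruthConfig()
    rng = np.random.default_rng(seed)
    ids = pd.Index(
        [f"SYN{i:06d}" for i in range(1, n_transcripts + 1)], name="transcript_id"
    )

    counts = {
        "germ_exclusive": int(round(cfg.frac_germ_exclusive * n_transcripts)),
        "sertoli_exclusive": int(round(cfg.frac_sertoli_exclusive * n_transcripts)),
        "leydig_exclusive": int(round(cfg.frac_leydig_exclusive * n_transcripts)),
        "other_somatic_exclusive": int(round(cfg.frac_other_exclusive * n_transcripts)),
        "sertoli_dependent_other": int(
            round(cfg.frac_sertoli_dependent_other * n_transcripts)
        ),
    }
    if sum(counts.values()) > n_transcripts:
        raise ValueError("class fractions leave no room; reduce them or raise n")
    labels: list[str] = []
    for cat, k in counts.items():
        labels.extend([cat] * k)
    labels.extend(["shared"] * (n_transcripts - len(labels)))
    category = pd.Series(labels, index=ids, name="category")

    home_cell = {
        "germ_exclusive": "germ",
        "sertoli_exclusive": "sertoli",
        "leydig_exclusive": "leydig",
        "other_somatic_exclusive": "other_somatic",
        "sertoli_dependent_other": "other_somatic",
    }
    expr = np.zeros((n_transcripts, len(CELL_TYPES)), dtype=float)
    draw = lambda size: rng.lognormal(cfg.abundance_meanlog, cfg.abundance_sdlog, size)
    for i, cat in enumerate(labels):
        if cat == "shared":
            # Broadly expressed transcripts vary moderately (< ~2-fold)
            # between cell types; strongly cell-biased multi-cell transcripts
            # are modeled by the explicit confounder class instead.
            expr[i, :] = draw(1)[0] * rng.uniform(0.6, 1.4, len(CELL_TYPES))
        else:
            expr[i, CELL_TYPES.index(home_cell[cat])] = draw(1)[0]
    expression = pd.DataFrame(expr, index=ids, columns=list(CELL_TYPES))

    ones = np.ones(n_transcripts)
    fshr = ones.copy()
    ar = ones.copy()
    inter = ones.copy()
    sert = np.flatnonzero(category.to_numpy() == "sertoli_exclusive")

    def _draw_effects(target: np.ndarray, frac_down, down_range, frac_up, up_range):
        for i in sert:
            u = rng.random()
            if u < frac_down:
                lo, hi = np.log(down_range[0]), np.log(down_range[1])
                target[i] = np.exp(rng.uniform(lo, hi))
            elif u < frac_down + frac_up:
                target[i] = rng.uniform(*up_range)

    _draw_effects(fshr, cfg.frac_fshr_affected, cfg.fshr_effect_range,
                  cfg.frac_fshr_up, cfg.up_effect_range)
    _draw_effects(ar, cfg.frac_ar_affected, cfg.ar_effect_range,
                  cfg.frac_ar_up, cfg.up_effect_range)
    for i in sert:
        if (fshr[i] != 1 or ar[i] != 1) and rng.random() < cfg.frac_interaction:
            lo, hi = np.log(cfg.interaction_range[0]), np.log(cfg.interaction_range[1])
            inter[i] = np.exp(rng.uniform(lo, hi))

    return SyntheticTruth(
        expression=expression,
        category=category,
        fshr_effect=pd.Series(fshr, index=ids, name="fshr_effect"),
        ar_effect=pd.Series(ar, index=ids, name="ar_effect"),
        interaction_multiplier=pd.Series(inter, index=ids, name="interaction_multiplier"),
        config=cfg,
        seed=int(seed),
    )


# -- condition compositions ----------------------------------------------------


def default_ablation_compositions(
    f_germ: float = DEFAULT_GERM_FRACTION,
    somatic_split: Mapping[str, float] | None = None,
    germ_removal: float = 1.0,
    sertoli_removal: float = 1.0,
) -> pd.DataFrame:
    """mRNA mass fractions per cell type for the three ablation conditions.

    Germ ablation removes ``germ_removal`` of the germ mass, Sertoli
    ablation (on the germ-free background) additionally removes
    ``sertoli_removal`` of the Sertoli mass; each condition renormalizes to
    sum 1 (the bulk sample is compositional).
    """
    split = dict(somatic_split or DEFAULT_SOMATIC_SPLIT)
    if not 0 < f_germ < 1:
        raise ValueError("f_germ must lie in (0, 1)")
    if abs(sum(split.values()) - 1.0) > 1e-9:
        raise ValueError("somatic split must sum to 1")
    control = {"germ": f_germ, **{c: (1 - f_germ) * s for c, s in split.items()}}
    bus = dict(control)
    bus["germ"] = control["germ"] * (1 - germ_removal)
    dtx = dict(bus)
    dtx["sertoli"] = bus["sertoli"] * (1 - sertoli_removal)
    comp = pd.DataFrame(
        {k: pd.Series(v) for k, v in
         (("control", control), ("busulfan", bus), ("busulfan_dtx", dtx))}
    ).T.reindex(columns=list(CELL_TYPES))
    return comp.div(comp.sum(axis=1), axis=0)


def default_morphometry() -> pd.DataFrame:
    """Preset per-genotype Sertoli cell numbers and testis volumes.

    Chosen so every knockout genotype shows Sertoli mRNA enrichment relative
    to control (factors 1.4, 1.42 and 2.0), as testis volume falls faster
    than Sertoli cell number in these models.
    """
    df = pd.DataFrame(
        {
            "sertoli_cells_per_testis": [2.0e7, 1.4e7, 1.9e7, 1.2e7],
            "testis_volume": [30.0, 15.0, 20.0, 9.0],
        },
        index=pd.Index(list(GENOTYPES), name="genotype"),
    )
    return validate_morphometry(df)


#: Mixture mass fractions of the immature (20-day) testis used by the
#: knockout simulator before genotype-specific Sertoli scaling.
DEFAULT_JUVENILE_COMPOSITION = {
    "germ": 0.55,
    "sertoli": 0.25,
    "leydig": 0.08,
    "other_somatic": 0.12,
}


# -- noise ---------------------------------------------------------------------


def _lognormal_noise(rng: np.random.Generator, cv: float, shape: tuple[int, ...]) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv ** 2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), shape))


def _as_matrix(
    expected: pd.DataFrame,
    groups: Sequence[str],
    n_replicates: int,
    rng: np.random.Generator,
    cv: float,
    symbols: pd.Series,
) -> ExpressionMatrix:
    cols, data, meta = [], [], []
    for g in groups:
        mu = expected[g].to_numpy(dtype=float)[:, None]
        noisy = mu * _lognormal_noise(rng, cv, (len(mu), n_replicates))
        for r in range(1, n_replicates + 1):
            cols.append(f"{g}_{r}")
            meta.append((f"{g}_{r}", g, r))
        data.append(noisy)
    values = pd.DataFrame(
        np.concatenate(data, axis=1), index=expected.index, columns=cols
    )
    sample_meta = pd.DataFrame(
        meta, columns=["sample_id", "group", "replicate"]
    ).set_index("sample_id")
    return ExpressionMatrix(values, sample_meta, symbols)


# -- simulators ----------------------------------------------------------------


def simulate_ablation_study(
    truth: SyntheticTruth,
    n_replicates: int = 5,
    seed: int = 1,
    compositions: pd.DataFrame | None = None,
    total: float = 1.0e6,
) -> ExpressionMatrix:
    """Simulate the three-condition sequential-ablation RNAseq experiment.

    Conditions: untreated control, germ-cell-ablated ("busulfan"), and
    germ+Sertoli-ablated ("busulfan_dtx").  Expected abundance is the
    composition-weighted mixture of cell-type profiles renormalized to a
    fixed per-sample ``total`` (FPKM-like), so removing germ mRNA inflates
    every surviving transcript by the renormalization factor.  Confounder
    transcripts ("Sertoli-dependent in another cell type") additionally lose
    per-cell expression after Sertoli ablation.
    """
    comp = compositions if compositions is not None else default_ablation_compositions()
    profiles = truth.profiles()
    dep = np.where(
        truth.category.to_numpy() == "sertoli_dependent_other",
        truth.config.sertoli_dependence_residual,
        1.0,
    )
    expected = {}
    for cond in comp.index:
        x = np.zeros(len(profiles), dtype=float)
        for c in CELL_TYPES:
            x = x + comp.loc[cond, c] * profiles[c].to_numpy()
        if cond == "busulfan_dtx":
            x = x * dep
        s = x.sum()
        expected[cond] = total * x / s if s > 0 else x
    expected_df = pd.DataFrame(expected, index=profiles.index)
    rng = np.random.default_rng(seed)
    symbols = pd.Series(truth.transcript_ids, index=truth.transcript_ids, dtype="string")
    return _as_matrix(expected_df, list(comp.index), n_replicates,
                      rng, truth.config.cv, symbols)


def simulate_knockout_study(
    truth: SyntheticTruth,
    morphometry: pd.DataFrame | None = None,
    n_replicates: int = 4,
    seed: int = 2,
    base_composition: Mapping[str, float] | None = None,
    total: float = 1.0e6,
) -> ExpressionMatrix:
    """Simulate the 2x2 knockout array experiment on whole testes.

    Per-testis signal of transcript t in genotype g is

        x_t(g) = total · [ Σ_{c≠sertoli} w_c · p_{t,c}
                           + w_sertoli · EF(g) · p_{t,sertoli} · m_t(g) ],

    with m_t(g) the product of the transcript's knockout effect multipliers
    for that genotype and EF(g) the Sertoli-density enrichment factor from
    the morphometry table.  No per-sample renormalization is applied: the
    array contract is absolute signal per testis, and dividing by EF(g)
    (the pipeline's normalization step) recovers per-Sertoli-cell abundance.
    """
    morph = morphometry if morphometry is not None else default_morphometry()
    for g in GENOTYPES:
        if g not in morph.index:
            raise KeyError(f"genotype {g!r} missing from morphometry")
    base = dict(base_composition or DEFAULT_JUVENILE_COMPOSITION)
    ef = enrichment_factors(morph)
    profiles = truth.profiles()
    p_sert = profiles["sertoli"].to_numpy()
    non_sert = np.zeros(len(profiles))
    for c in CELL_TYPES:
        if c != "sertoli":
            non_sert = non_sert + base[c] * profiles[c].to_numpy()

    effects = {
        "control": np.ones(len(profiles)),
        "FSHRKO": truth.fshr_effect.to_numpy(),
        "SCARKO": truth.ar_effect.to_numpy(),
        "FSHRKO_SCARKO": (
            truth.fshr_effect * truth.ar_effect * truth.interaction_multiplier
        ).to_numpy(),
    }
    expected = {
        g: total * (non_sert + base["sertoli"] * ef[g] * p_sert * effects[g])
        for g in GENOTYPES
    }
    expected_df = pd.DataFrame(expected, index=profiles.index)
    rng = np.random.default_rng(seed)
    symbols = pd.Series(truth.transcript_ids, index=truth.transcript_ids, dtype="string")
    return _as_matrix(expected_df, list(GENOTYPES), n_replicates,
                      rng, truth.config.cv, symbols)


# -- evaluation against truth --------------------------------------------------


@dataclass(frozen=True)
class TruthEvaluation:
    """Confusion counts of calls against ground truth for one category."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


_CALL_TO_TRUTH = {
    "sertoli_specific": "sertoli_exclusive",
    "germ_specific": "germ_exclusive",
}


def evaluate_calls(
    calls: pd.DataFrame,
    truth: SyntheticTruth,
    category: str = "sertoli_specific",
) -> TruthEvaluation:
    """Score classifier calls against the generating truth.

    ``calls`` must cover exactly the truth's transcript universe and carry a
    ``category`` column; truth positives are the transcripts exclusive to
    the corresponding cell type.
    """
    if category not in _CALL_TO_TRUTH:
        raise ValueError(f"unknown call category {category!r}")
    if set(calls.index) != set(truth.transcript_ids):
        raise ValueError("calls and truth must share one transcript universe")
    calls = calls.reindex(truth.transcript_ids)
    predicted = (calls["category"] == category).to_numpy()
    actual = (truth.category == _CALL_TO_TRUTH[category]).to_numpy()
    tp = int((predicted & actual).sum())
    fp = int((predicted & ~actual).sum())
    fn = int((~predicted & actual).sum())
    tn = int((~predicted & ~actual).sum())
    return TruthEvaluation(tp=tp, fp=fp, tn=tn, fn=fn)
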