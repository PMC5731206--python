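"""Tabular input/output for expression matrices, contrasts and annotations.

All on-disk formats are plain TSV (UTF-8, one header line).  An expression
matrix travels as two files: the matrix itself (``transcript_id``, optional
``gene_symbol``, then one column per sample) and a sidecar *design* file
mapping each sample to its experimental group (``sample_id``, ``group``,
``replicate``).  Gene lists are one symbol per line with ``#`` comments.

Abundance values are treated as opaque non-negative reals (FPKM-scale for
RNAseq, fluorescence-scale for arrays, per-testis relative units for
spike-normalized qPCR); no unit conversion is ever attempted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sertoliseq")

#: Recognized transcript biotype categories; anything else collapses to "other".
BIOTYPES = ("protein_coding", "non_coding", "pseudogene", "other")

#: Column mapping for Cuffdiff-style pairwise contrast output.
CUFFDIFF_DIALECT: Mapping[str, str] = {
    "transcript_id": "gene_id",
    "gene_symbol": "gene",
    "mean_ref": "value_1",
    "mean_alt": "value_2",
    "p_value": "p_value",
    "q_value": "q_value",
}

#: Native dialect written by :func:`write_contrast_table`.
NATIVE_CONTRAST_DIALECT: Mapping[str, str] = {
    "transcript_id": "transcript_id",
    "gene_symbol": "gene_symbol",
    "mean_ref": "mean_ref",
    "mean_alt": "mean_alt",
    "p_value": "p_value",
    "q_value": "q_value",
}

CONTRAST_COLUMNS = [
    "gene_symbol",
    "mean_ref",
    "mean_alt",
    "fold_change",
    "log2fc",
    "p_value",
    "q_value",
]


class TableFormatError(ValueError):
    """A table on disk violates the format contract (hard error)."""


@dataclass
class ExpressionMatrix:
    """Transcripts-by-samples abundance matrix with grouped replicates.

    Parameters
    ----------
    values
        DataFrame indexed by unique ``transcript_id`` with one column per
        sample; entries are finite, non-negative reals.
    sample_meta
        DataFrame indexed by ``sample_id`` with columns ``group`` (str) and
        ``replicate`` (int).  Every sample column of ``values`` must appear.
    gene_symbols
        Optional transcript_id -> symbol mapping; missing/NaN symbols are
        allowed (unannotated transcript models).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise TableFormatError(f"duplicate transcript id {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise TableFormatError("expression values must be finite")
        if (vals < 0).any():
            t, s = np.argwhere(vals < 0)[0]
            raise TableFormatError(
                f"negative value at transcript {self.values.index[t]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        missing = [c for c in self.values.columns if c not in self.sample_meta.index]
        if missing:
            raise TableFormatError(f"samples without group assignment: {missing}")
        if "group" not in self.sample_meta.columns:
            raise TableFormatError("sample design must carry a 'group' column")
        for group, sub in self.sample_meta.loc[list(self.values.columns)].groupby("group"):
            if len(sub) < 1:  # pragma: no cover - groupby never yields empty
                raise TableFormatError(f"group {group!r} has no replicates")
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)

    # -- convenience accessors -------------------------------------------------

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> list[str]:
        meta = self.sample_meta.loc[list(self.values.columns)]
        return list(dict.fromkeys(meta["group"]))

    def samples_in_group(self, group: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.values.columns)]
        samples = meta.index[meta["group"] == group].tolist()
        if not samples:
            raise KeyError(f"unknown group label {group!r}")
        return samples

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in_group(group)]

    def group_means(self) -> pd.DataFrame:
        """Per-group mean abundance (transcripts x groups)."""
        return pd.DataFrame(
            {g: self.group_values(g).mean(axis=1) for g in self.groups}
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.sample_meta.copy(), self.gene_symbols)


# -- expression matrix round trip ----------------------------------------------


def read_expression_table(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix plus its sidecar design file.

    The matrix file's first column is ``transcript_id``; a ``gene_symbol``
    column is optional; all remaining columns are samples and must be listed
    in the design file.  Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "transcript_id":
        raise TableFormatError(
            f"first column must be 'transcript_id', got {df.columns[0]!r}"
        )
    df = df.set_index("transcript_id")
    symbols = None
    if "gene_symbol" in df.columns:
        symbols = df.pop("gene_symbol").astype("string")
    design = read_design_table(design_path)
    values = df.astype(float)
    return ExpressionMatrix(values, design, symbols)


def read_design_table(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group", "replicate"):
        if col not in design.columns:
            raise TableFormatError(f"design file missing column {col!r}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableFormatError(f"duplicate sample id {dup!r} in design")
    return design.set_index("sample_id")


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, design_path: str | Path
) -> None:
    out = matrix.values.copy()
    if matrix.gene_symbols is not None:
        out.insert(0, "gene_symbol", matrix.gene_symbols)
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
    meta = matrix.sample_meta.loc[list(matrix.values.columns)].copy()
    meta.index.name = "sample_id"
    meta.to_csv(design_path, sep="\t")


# -- contrast tables -----------------------------------------------------------


def read_contrast_table(
    path: str | Path, dialect: Mapping[str, str] = CUFFDIFF_DIALECT
) -> pd.DataFrame:
    """Read a pairwise two-group contrast table (Cuffdiff-output-like dialect).

    Returns the package's standard contrast frame: indexed by transcript_id
    with columns ``gene_symbol, mean_ref, mean_alt, fold_change, log2fc,
    p_value, q_value``.  Fold change is recomputed from the two group means;
    ``fold_change`` is NaN (undefined) when the reference mean is zero and
    ``log2fc`` is NaN when either mean is zero — no pseudocounts.

    A row where q < p is tolerated (foreign adjustment method) but logged.
    """
    raw = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {k: v for k, v in dialect.items() if k != "gene_symbol"}
    missing = [v for v in required.values() if v not in raw.columns]
    if missing:
        raise TableFormatError(f"contrast table missing columns: {missing}")
    out = pd.DataFrame(index=pd.Index(raw[dialect["transcript_id"]].astype(str),
                                      name="transcript_id"))
    sym_col = dialect.get("gene_symbol")
    out["gene_symbol"] = (
        raw[sym_col].astype("string").to_numpy() if sym_col in raw.columns else pd.NA
    )
    mean_ref = raw[dialect["mean_ref"]].astype(float).to_numpy()
    mean_alt = raw[dialect["mean_alt"]].astype(float).to_numpy()
    out["mean_ref"] = mean_ref
    out["mean_alt"] = mean_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_ref > 0, mean_alt / mean_ref, np.nan)
        l2 = np.where((mean_ref > 0) & (mean_alt > 0), np.log2(fc), np.nan)
    out["fold_change"] = fc
    out["log2fc"] = l2
    out["p_value"] = raw[dialect["p_value"]].astype(float).to_numpy()
    out["q_value"] = raw[dialect["q_value"]].astype(float).to_numpy()
    for col in ("p_value", "q_value"):
        vals = out[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise TableFormatError(f"{col} outside [0, 1] in {path}")
    n_qlp = int((out["q_value"] < out["p_value"]).sum())
    if n_qlp:
        logger.warning(
            "%d rows with q < p in %s (adjustment from a foreign method)", n_qlp, path
        )
    return out


def write_contrast_table(contrast: pd.DataFrame, path: str | Path) -> None:
    out = contrast.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_native_contrast_table(path: str | Path) -> pd.DataFrame:
    """Read a contrast table previously written by :func:`write_contrast_table`."""
    return read_contrast_table(path, NATIVE_CONTRAST_DIALECT)


# -- spike-in normalization ----------------------------------------------------


def normalize_to_spike_in(
    raw: ExpressionMatrix,
    spike_signal: Mapping[str, float] | pd.Series,
    scale: float = 1.0,
) -> ExpressionMatrix:
    """Divide each sample by its external spike-in standard signal.

    Emulates normalization to a luciferase mRNA standard added per testis at
    extraction, yielding relative transcript expression per testis:
    ``out[t, s] = raw[t, s] / spike_signal[s] * scale``.  Within-sample
    rank order is unchanged.
    """
    spike = pd.Series(spike_signal, dtype=float)
    for s in raw.values.columns:
        if s not in spike.index:
            raise TableFormatError(f"no spike-in signal for sample {s!r}")
        if not spike[s] > 0:
            raise TableFormatError(
                f"spike-in signal for sample {s!r} must be positive, got {spike[s]}"
            )
    values = raw.values.div(spike[list(raw.values.columns)], axis=1) * float(scale)
    return raw.with_values(values)


# -- morphometry, annotations and gene lists -----------------------------------


def read_morphometry(path: str | Path, control: str = "control") -> pd.DataFrame:
    """Read per-genotype Sertoli cell counts and testis volumes.

    Columns: ``genotype``, ``sertoli_cells_per_testis``, ``testis_volume``.
    Counts and volumes must be strictly positive and the control genotype
    present exactly once.
    """
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
    for col in ("genotype", "sertoli_cells_per_testis", "testis_volume"):
        if col not in df.columns:
            raise TableFormatError(f"morphometry table missing column {col!r}")
    df = df.set_index("genotype")
    return validate_morphometry(df, control=control)


def validate_morphometry(df: pd.DataFrame, control: str = "control") -> pd.DataFrame:
    if (df["sertoli_cells_per_testis"] <= 0).any() or (df["testis_volume"] <= 0).any():
        raise TableFormatError("morphometry counts and volumes must be positive")
    if list(df.index).count(control) != 1:
        raise TableFormatError(
            f"control genotype {control!r} must appear exactly once in morphometry"
        )
    return df


def write_morphometry(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "genotype"
    out.to_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    symbols: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return symbols


def write_gene_list(symbols: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(symbols) + "\n", encoding="utf-8")


def read_biotype_annotation(path: str | Path) -> pd.Series:
    """Read a two-column (id/symbol, biotype) table; unknown biotypes -> other."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableFormatError("biotype annotation needs key and biotype columns")
    key, biotype = df.columns[:2]
    ann = df.set_index(key)[biotype].str.strip()
    unknown = ~ann.isin(BIOTYPES)
    if unknown.any():
        logger.info("%d annotation entries with unrecognized biotype -> 'other'",
                    int(unknown.sum()))
        ann = ann.where(~unknown, "other")
    return ann
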