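"""Symbol-keyed comparison of external Sertoli-cell gene lists.

External catalogues of Sertoli-expressed genes (RiboTag pull-downs, FACS
sorting) are joined against the ablation contrasts purely by gene symbol —
trimmed and case-folded, with no alias or ortholog resolution.  Raw symbol
joins are what such cross-study comparisons typically use; the lack of alias
resolution is a known source of undercounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Sequence

import pandas as pd

from .classify import StringencyCriteria


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().casefold()


@dataclass(frozen=True)
class GeneListCollection:
    """A named set of gene symbols (case-normalized on construction)."""

    name: str
    symbols: frozenset[str]
    note: str = ""

    @classmethod
    def from_symbols(
        cls, name: str, symbols: Iterable[str], note: str = ""
    ) -> "GeneListCollection":
        return cls(name, frozenset(normalize_symbol(s) for s in symbols if s.strip()), note)

    def __len__(self) -> int:
        return len(self.symbols)


def align_by_symbol(
    external: GeneListCollection,
    bus_contrast: pd.DataFrame,
    dtx_contrast: pd.DataFrame,
    criteria: StringencyCriteria,
) -> pd.DataFrame:
    """Match an external gene list against the ablation contrasts.

    For every external symbol, reports whether it matched a contrast entry
    and, if so, whether that transcript (a) meets the Sertoli-ablation
    residual condition alone and (b) satisfies the full Sertoli-specificity
    criteria.  When several transcripts share a symbol, a condition counts
    as met if any of them meets it.

    Returns a frame indexed by the external (normalized) symbol with boolean
    columns ``matched``, ``passes_residual``, ``passes_full``.
    """
    from .classify import classify_sertoli_specific

    if len(external) == 0:
        raise ValueError("external gene list is empty")
    calls = classify_sertoli_specific(bus_contrast, dtx_contrast, criteria)
    symbols = bus_contrast["gene_symbol"].astype("string")
    norm = symbols.dropna().map(normalize_symbol)

    residual_ok = (
        calls["dtx_residual"].notna()
        & (calls["dtx_residual"] <= criteria.max_dtx_residual)
    )
    full_ok = calls["category"] == "sertoli_specific"

    by_symbol_residual = residual_ok.loc[norm.index].groupby(norm).any()
    by_symbol_full = full_ok.loc[norm.index].groupby(norm).any()

    ext = sorted(external.symbols)
    matched = pd.Series([s in by_symbol_residual.index for s in ext], index=ext)
    return pd.DataFrame(
        {
            "matched": matched,
            "passes_residual": by_symbol_residual.reindex(ext, fill_value=False).astype(bool),
            "passes_full": by_symbol_full.reindex(ext, fill_value=False).astype(bool),
        }
    )


def intersect_collections(
    collections: Sequence[GeneListCollection],
) -> GeneListCollection:
    """Symbols present in every collection (order-independent)."""
    if not collections:
        raise ValueError("need at least one collection to intersect")
    common = reduce(lambda a, b: a & b, (c.symbols for c in collections))
    name = " ∩ ".join(c.name for c in collections)
    return GeneListCollection(name, frozenset(common), note="intersection")
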