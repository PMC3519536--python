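"""Summary artifacts: strategy-comparison tables, phylum bar-chart data,
per-species food tables with fold ratios, and exogenous-miRNA count tables.

Every report is a pure function of classification tables and the taxonomy;
re-running on identical inputs is byte-identical.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationTable, category_fractions
from .errors import DataError, UndefinedFractionError
from .refdb import ReferenceDB


def strategy_table(
    tables: Mapping[int, ClassificationTable],
    category_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wide summary: rows = categories, columns = strategies, cells =
    percentages of processed reads rounded to 2 decimals.

    All tables must describe the same sample (identical read counts); empty
    categories render as 0.00, never omitted; each column sums to 100 within
    rounding.
    """
    if not tables:
        raise DataError("no classification tables supplied")
    sizes = {s: t.n_reads for s, t in tables.items()}
    if len(set(sizes.values())) != 1:
        raise DataError(f"inconsistent input read counts across strategies: {sizes}")
    if category_order is None:
        category_order = next(iter(tables.values())).tier_order + ["unmapped"]
    cols = {}
    for s in sorted(tables):
        frac = category_fractions(tables[s])
        cols[f"Strategy {s}"] = [round(frac.get(c, 0.0), 2) for c in category_order]
    return pd.DataFrame(cols, index=list(category_order))


@dataclass(frozen=True)
class FoldRatio:
    """Ratio of across-sample mean read counts between two species."""

    numerator: str
    denominator: str
    ratio: float
    mean_a: float
    mean_b: float
    counts_a: tuple[float, ...]
    counts_b: tuple[float, ...]


def fold_ratio(
    species_a: str,
    counts_a: Sequence[float],
    species_b: str,
    counts_b: Sequence[float],
) -> FoldRatio:
    """Across-sample mean count ratio a/b, with the per-sample counts kept
    for reporting; a zero denominator mean is an error, never a pseudocount."""
    if not counts_a or not counts_b:
        raise DataError("fold ratio needs at least one sample per species")
    mean_a = float(np.mean(counts_a))
    mean_b = float(np.mean(counts_b))
    if mean_b == 0:
        raise UndefinedFractionError(
            f"fold ratio {species_a}/{species_b} undefined: denominator mean is zero"
        )
    return FoldRatio(
        species_a, species_b, mean_a / mean_b, mean_a, mean_b,
        tuple(float(c) for c in counts_a), tuple(float(c) for c in counts_b),
    )


def mirna_count_table(
    tables: Mapping[str, ClassificationTable],
    mirna_db: ReferenceDB,
    category: str,
) -> pd.DataFrame:
    """Species x sample count table for the exogenous-miRNA tier.

    Database entries with identical mature sequences collapse into one row
    (named "a/b/c"); a read contributes one count to each distinct identity
    group among its hits.
    """
    by_seq: dict[str, list[str]] = {}
    for sid, seq in mirna_db.sequences.items():
        by_seq.setdefault(seq.upper(), []).append(sid)
    group_of = {
        sid: "/".join(sorted(names)) for names in by_seq.values() for sid in names
    }
    rows = sorted({g for g in group_of.values()})
    out = pd.DataFrame(0, index=rows, columns=sorted(tables), dtype=int)
    for sample in sorted(tables):
        for assignment in tables[sample].reads_in(category):
            groups = {
                group_of[h.seq_id]
                for h in assignment.hits
                if h.db_id == mirna_db.db_id and h.seq_id in group_of
            }
            for g in groups:
                out.loc[g, sample] += 1
    return out[out.sum(axis=1) > 0]


def log10_counts(counts: Mapping[str, float]) -> pd.Series:
    """log10 of mean counts for bar-chart export; zero counts are dropped
    (absent bars), never emitted as -inf."""
    s = pd.Series({k: v for k, v in counts.items() if v >= 1}, dtype=float)
    return np.log10(s) if len(s) else s
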