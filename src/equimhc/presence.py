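"""Gene presence/absence from per-base coverage.

The statistic is the non-zero-coverage fraction: the proportion of a gene's
positions covered by at least one read.  A gene is called absent when that
fraction is strictly below the threshold (default 0.10, i.e. at least 90%
zero-covered bases); mapping-quality filtering, if any, happens upstream of
the depth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .seq_io import DepthTable

DEFAULT_THRESHOLD = 0.10


@dataclass(frozen=True)
class PresenceCall:
    gene: str
    nonzero_fraction: float
    call: str  # "present" | "absent"
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        expected = "absent" if self.nonzero_fraction < self.threshold else "present"
        if self.call != expected:
            raise ValueError("call inconsistent with fraction and threshold")


def nonzero_coverage_fraction(depth: np.ndarray) -> float:
    """(#positions with depth >= 1) / length."""
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("empty depth vector")
    return float((depth >= 1).sum()) / depth.size


def call_presence(
    fraction: float, gene: str = "", threshold: float = DEFAULT_THRESHOLD
) -> PresenceCall:
    """Absent iff fraction < threshold (strict); threshold configurable."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    call = "absent" if fraction < threshold else "present"
    return PresenceCall(gene=gene, nonzero_fraction=fraction, call=call,
                        threshold=threshold)


def call_depth_table(
    table: DepthTable, threshold: float = DEFAULT_THRESHOLD
) -> list[PresenceCall]:
    return [
        call_presence(nonzero_coverage_fraction(vec), gene=gene, threshold=threshold)
        for gene, vec in table.depths.items()
    ]


def _integer_percent(fraction: float) -> int:
    # round-half-up to mirror integer-percent reporting
    return int(Decimal(fraction * 100).quantize(0, rounding=ROUND_HALF_UP))


def presence_report(
    tables: dict[str, DepthTable], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Genome x gene table of integer non-zero-coverage percentages plus calls.

    Rows are genomes, with one ``<gene>`` percent column and one
    ``<gene>_call`` column per gene.
    """
    rows = {}
    for genome, table in tables.items():
        row = {}
        for call in call_depth_table(table, threshold):
            row[call.gene] = _integer_percent(call.nonzero_fraction)
            row[f"{call.gene}_call"] = call.call
        rows[genome] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "genome"
    return df
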