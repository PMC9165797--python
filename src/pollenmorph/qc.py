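"""Data cleaning: the compactness QC filter and view partitioning.

The study discarded poorly focused captures by excluding every grain whose
compactness parameter fell strictly below 0.55 (values exactly at the
threshold are kept), then analysed grains in polar and equatorial view
separately (the original sorting was manual; a heuristic elongation-based
sorter is provided for unlabelled data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import pandas as pd

from .errors import SchemaError

__all__ = ["QCReport", "compactness_filter", "split_views", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.55
#: equatorial-view flattened ovals are noticeably elongated; polar ambs are not
DEFAULT_ELONGATION_CUT = 1.25


@dataclass
class QCReport:
    """Outcome of the compactness filter."""

    n_input: int
    n_discarded: int
    threshold: float
    discarded_ids: List[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_discarded

    @property
    def discard_fraction(self) -> float:
        return self.n_discarded / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_discarded": self.n_discarded,
            "n_kept": self.n_kept,
            "discard_fraction": self.discard_fraction,
            "threshold": self.threshold,
            "discarded_ids": list(self.discarded_ids),
        }


def compactness_filter(features: pd.DataFrame,
                       threshold: float = DEFAULT_THRESHOLD
                       ) -> Tuple[pd.DataFrame, QCReport]:
    """Drop grains with compactness strictly below ``threshold``.

    Returns the kept table (input row order preserved) and a
    :class:`QCReport`. Grains exactly at the threshold are kept.
    """
    if "compactness" not in features.columns:
        raise SchemaError("feature table has no 'compactness' column")
    bad = features["compactness"] < threshold
    kept = features.loc[~bad]
    if "grain_id" in features.columns:
        discarded_ids = features.loc[bad, "grain_id"].tolist()
    else:
        discarded_ids = features.index[bad].tolist()
    report = QCReport(
        n_input=len(features),
        n_discarded=int(bad.sum()),
        threshold=threshold,
        discarded_ids=discarded_ids,
    )
    return kept, report


def split_views(table: pd.DataFrame, mode: str = "truth",
                elongation_cut: float = DEFAULT_ELONGATION_CUT
                ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a grain table into (polar, equatorial) view tables.

    ``mode="truth"`` uses the ``view`` labels (mirrors the study's manual
    sorting). ``mode="heuristic"`` classifies by elongation: flattened-oval
    equatorial grains exceed ``elongation_cut``; if truth labels are present
    the disagreement rate is attached to both outputs as
    ``DataFrame.attrs["view_disagreement"]``.
    """
    if mode == "truth":
        if "view" not in table.columns:
            raise SchemaError("truth mode requires a 'view' column")
        polar = table.loc[table["view"] == "polar"]
        equatorial = table.loc[table["view"] == "equatorial"]
        return polar, equatorial
    if mode == "heuristic":
        if "elongation" not in table.columns:
            raise SchemaError("heuristic mode requires an 'elongation' column")
        is_equatorial = table["elongation"] > elongation_cut
        polar = table.loc[~is_equatorial]
        equatorial = table.loc[is_equatorial]
        if "view" in table.columns:
            pred = is_equatorial.map({True: "equatorial", False: "polar"})
            disagreement = float((pred != table["view"]).mean())
            polar = polar.copy()
            equatorial = equatorial.copy()
            polar.attrs["view_disagreement"] = disagreement
            equatorial.attrs["view_disagreement"] = disagreement
        return polar, equatorial
    raise ValueError(f"unknown split mode {mode!r}")
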