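"""Structural-alert mining by information gain and enrichment frequency.

A fragment (one column of a binary feature block, e.g. a substructure
key) is scored two ways:

* information gain — the base-2 entropy reduction of the toxicity label
  achieved by splitting on fragment presence,

      IG = Ent(D) - sum_{V in {0,1}} |D_V|/|D| * Ent(D_V),
      Ent(D) = -sum_k P_k log2 P_k;

* class-enrichment frequency —

      freq_P = (N_fragment_P * N_total) / (N_fragment_total * N_P)

  (how over-represented the fragment is among toxicants relative to its
  overall prevalence; freq_N is the symmetric non-toxicant version).

An alert is a fragment occurring more than six times in the dataset
(min_occurrences = 7 by default) and more frequent among toxicants than
non-toxicants (freq_P > freq_N), ranked by IG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featurization import FeatureBlock

__all__ = [
    "FragmentStats",
    "AlertReport",
    "AlertError",
    "information_gain",
    "fragment_frequency",
    "mine_alerts",
]


class AlertError(ValueError):
    pass


def _entropy2(labels: np.ndarray) -> float:
    """Base-2 entropy of a 0/1 label vector; empty input contributes 0."""
    n = len(labels)
    if n == 0:
        return 0.0
    p = labels.mean()
    ent = 0.0
    for q in (p, 1 - p):
        if q > 0:
            ent -= q * np.log2(q)
    return float(ent)


def information_gain(fragment_column, labels) -> float:
    """Entropy reduction of the class labels from splitting on fragment
    presence/absence (base-2)."""
    frag = np.asarray(fragment_column).astype(int)
    y = np.asarray(labels).astype(int)
    if len(frag) != len(y):
        raise AlertError("fragment column and labels must have equal length")
    n = len(y)
    ig = _entropy2(y)
    for v in (0, 1):
        part = y[frag == v]
        ig -= len(part) / n * _entropy2(part)
    return float(max(ig, 0.0))  # clamp the odd -1e-16 from float cancellation


def fragment_frequency(
    n_fragment_P: int, n_total: int, n_fragment_total: int, n_P: int
) -> float:
    """Enrichment frequency (N_fragment_P * N_total) / (N_fragment_total * N_P)."""
    if n_fragment_total <= 0 or n_P <= 0:
        raise AlertError("fragment_frequency needs non-zero denominators")
    return (n_fragment_P * n_total) / (n_fragment_total * n_P)


@dataclass(frozen=True)
class FragmentStats:
    """Occurrence counts, information gain and enrichment of one fragment."""

    fragment_id: str
    n_fragment_total: int
    n_fragment_P: int
    n_total: int
    n_P: int
    ig: float
    freq_P: float
    freq_N: float
    smarts: str | None = None


@dataclass
class AlertReport:
    """Ranked alert fragments plus the filter settings that produced them."""

    alerts: list[FragmentStats]
    min_occurrences: int
    require_positive_enrichment: bool = True
    all_stats: list[FragmentStats] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "fragment_id": a.fragment_id,
                "smarts": a.smarts,
                "n_fragment_total": a.n_fragment_total,
                "n_fragment_P": a.n_fragment_P,
                "IG": round(a.ig, 4),
                "freq_P": round(a.freq_P, 2),
                "freq_N": round(a.freq_N, 2),
            }
            for a in self.alerts
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "fragment_id", "smarts", "n_fragment_total", "n_fragment_P",
                "IG", "freq_P", "freq_N",
            ],
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _column_stats(
    frag: np.ndarray, y: np.ndarray, fragment_id: str, smarts: str | None
) -> FragmentStats:
    n_total = len(y)
    n_P = int((y == 1).sum())
    n_N = n_total - n_P
    n_ft = int(frag.sum())
    n_fP = int(frag[y == 1].sum())
    n_fN = n_ft - n_fP
    freq_P = (n_fP * n_total) / (n_ft * n_P) if n_ft > 0 and n_P > 0 else 0.0
    freq_N = (n_fN * n_total) / (n_ft * n_N) if n_ft > 0 and n_N > 0 else 0.0
    return FragmentStats(
        fragment_id=fragment_id,
        n_fragment_total=n_ft,
        n_fragment_P=n_fP,
        n_total=n_total,
        n_P=n_P,
        ig=information_gain(frag, y),
        freq_P=freq_P,
        freq_N=freq_N,
        smarts=smarts,
    )


def mine_alerts(
    fragments: FeatureBlock,
    labels,
    min_occurrences: int = 7,
    top_n: int | None = None,
    smarts_catalog: dict[str, str] | None = None,
    require_positive_enrichment: bool = True,
) -> AlertReport:
    """Score every fragment column and emit the ranked alert list.

    Filters: the fragment must occur at least ``min_occurrences`` times
    in the dataset (default 7, i.e. strictly more than six) and, when
    ``require_positive_enrichment``, be more frequent among toxicants
    (freq_P > freq_N). Ranking: IG descending, ties by freq_P descending
    then fragment id. No passing fragment yields an empty (valid) report.
    """
    if fragments.kind != "binary":
        raise AlertError("alert mining needs a binary fragment block")
    y = np.asarray(labels).astype(int)
    if len(y) != fragments.n_molecules:
        raise AlertError("labels must align with fragment block rows")
    if len(np.unique(y)) < 2:
        raise AlertError("alert mining needs both classes present")

    catalog = smarts_catalog or {}
    all_stats = [
        _column_stats(
            fragments.matrix[:, j].astype(int), y, name, catalog.get(name)
        )
        for j, name in enumerate(fragments.feature_names)
    ]
    passing = [
        s for s in all_stats
        if s.n_fragment_total >= min_occurrences
        and (not require_positive_enrichment or s.freq_P > s.freq_N)
    ]
    passing.sort(key=lambda s: (-s.ig, -s.freq_P, s.fragment_id))
    if top_n is not None:
        passing = passing[:top_n]
    return AlertReport(
        alerts=passing,
        min_occurrences=min_occurrences,
        require_positive_enrichment=require_positive_enrichment,
        all_stats=all_stats,
    )
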