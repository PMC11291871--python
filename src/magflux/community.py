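"""Community dissimilarities and shared-taxa fractions.

Bray-Curtis (abundance-weighted) and binary Jaccard (presence/absence)
sample-by-sample distance matrices for export to external ordination and
PERMANOVA tools, and the fraction of each sample's abundance contributed
by taxa detected in *both* media (seawater and sediment) of its zone —
the habitat-overlap summary behind "shared community members".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable, MEDIA, SampleInfo, TableError, logger

METRICS = ("bray_curtis", "binary_jaccard")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix in [0, 1]."""

    values: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
            raise TableError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0):
            raise TableError("distance matrix must have a zero diagonal")
        if (arr < 0).any() or (arr > 1 + 1e-12).any():
            raise TableError("distances must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(), checks=False)


@dataclass(frozen=True)
class SharedFractionReport:
    """Per-sample fraction of abundance carried by cross-medium taxa.

    ``fractions`` has columns sample_id, group, shared_abundance_fraction;
    ``detection_threshold`` is the abundance above which a taxon counts as
    detected in a medium-zone.
    """

    fractions: pd.DataFrame
    detection_threshold: float


SHARED_COLUMNS = ["sample_id", "group", "shared_abundance_fraction"]


def distance_matrix(table: AbundanceTable, metric: str) -> DistanceMatrix:
    """Pairwise sample distances under the named metric.

    Bray-Curtis is sum|x-y| / sum(x+y); binary Jaccard is one minus the
    ratio of shared to combined presences.  A pair of two all-zero samples
    is defined as distance 0 (with a warning for Bray-Curtis, where the
    formula is 0/0).
    """
    if metric not in METRICS:
        raise TableError(f"unknown metric {metric!r}; expected one of {METRICS}")
    data = table.matrix.T  # samples x taxa
    if data.shape[0] < 2:
        raise TableError("need at least two samples for a distance matrix")
    if metric == "bray_curtis":
        condensed = pdist(data, "braycurtis")
        if np.isnan(condensed).any():
            logger.warning("pairs of all-zero samples: Bray-Curtis defined as 0")
            condensed = np.nan_to_num(condensed, nan=0.0)
    else:
        condensed = pdist(data > 0, "jaccard")
    square = squareform(condensed)
    return DistanceMatrix(
        values=pd.DataFrame(square, index=table.sample_ids, columns=table.sample_ids),
        metric=metric,
    )


def shared_fraction(
    table: AbundanceTable,
    samples: Sequence[SampleInfo],
    detection_threshold: float = 0.0,
) -> SharedFractionReport:
    """Fraction of each sample's abundance due to taxa shared across media.

    Within each zone, a taxon is "detected" in a medium when its abundance
    exceeds ``detection_threshold`` in at least one sample of that
    medium-zone; the shared set is the intersection over both media.  A
    zone represented by a single medium is skipped with a warning, and an
    empty sample reports fraction 0.
    """
    by_sample = {s.sample_id: s for s in samples}
    missing = [s for s in table.sample_ids if s not in by_sample]
    if missing:
        raise TableError(f"metadata misses samples: {missing[:5]}")

    zones: dict[str, list[SampleInfo]] = {}
    for sid in table.sample_ids:
        info = by_sample[sid]
        zones.setdefault(info.zone, []).append(info)

    rows = []
    for zone, infos in zones.items():
        media_cols = {
            m: [s.sample_id for s in infos if s.medium == m] for m in MEDIA
        }
        if any(not cols for cols in media_cols.values()):
            logger.warning("zone %r has only one medium; skipped", zone)
            continue
        detected_both = np.ones(len(table.taxon_ids), dtype=bool)
        for cols in media_cols.values():
            detected = (table.values[cols].to_numpy() > detection_threshold).any(axis=1)
            detected_both &= detected
        for info in infos:
            col = table.values[info.sample_id].to_numpy()
            total = col.sum()
            frac = float(col[detected_both].sum() / total) if total > 0 else 0.0
            rows.append(
                {
                    "sample_id": info.sample_id,
                    "group": info.group,
                    "shared_abundance_fraction": frac,
                }
            )
    return SharedFractionReport(
        fractions=pd.DataFrame(rows, columns=SHARED_COLUMNS),
        detection_threshold=detection_threshold,
    )
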