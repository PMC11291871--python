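"""Movement flux, net flux and mixture index between sample pairs.

Each species-level MAG is proxied to originate from a single sample — the
sample in which its representative genome was recovered, approximated here
by the sample of maximum abundance (genomes assemble most readily where
coverage is highest).  Given an origin map, the movement flux from sample
A to sample B,

    f_AB = mean abundance in B of the taxa whose origin is A,

averages over *all* of A's taxa, including those absent (abundance 0) in B.
The derived pair statistics are

    F_AB = f_AB - f_BA          (net flux; sign gives the direction)
    M_AB = (f_AB + f_BA) / 2    (mixture index; bidirectional exchange)

F is antisymmetric, M symmetric, and |F| <= 2 M because f >= 0.  Both are
computed in the abundance table's native unit (RPKM in the intended use)
and never converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import AbundanceTable, TableError, logger


@dataclass(frozen=True)
class OriginMap:
    """Assignment of every taxon to the single sample it is proxied from."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))

    def __getitem__(self, taxon: str) -> str:
        return self.mapping[taxon]

    def __len__(self) -> int:
        return len(self.mapping)

    def __iter__(self):
        return iter(self.mapping)

    def origin_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for origin in self.mapping.values():
            counts[origin] = counts.get(origin, 0) + 1
        return counts

    def validate_against(self, table: AbundanceTable) -> None:
        taxa = set(table.taxon_ids)
        unknown = [t for t in self.mapping if t not in taxa]
        if unknown:
            raise TableError(f"origin map references unknown taxa: {unknown[:5]}")
        missing = [t for t in table.taxon_ids if t not in self.mapping]
        if missing:
            raise TableError(f"origin map misses taxa: {missing[:5]}")
        samples = set(table.sample_ids)
        bad = [s for s in self.mapping.values() if s not in samples]
        if bad:
            raise TableError(f"origin map references unknown samples: {sorted(set(bad))[:5]}")


@dataclass(frozen=True)
class FluxMatrix:
    """Directed flux f[origin][destination] plus per-origin taxon counts.

    Rows (and the symmetric columns) follow the abundance table's sample
    order.  A sample that contributes zero origin taxa yields an all-zero
    row flagged in ``undefined_sources`` rather than an error, so that the
    pairwise matrices stay total.
    """

    f: pd.DataFrame
    n_origin: pd.Series
    unit: str
    undefined_sources: tuple[str, ...] = field(default=())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.f.index)


@dataclass(frozen=True)
class PairSummary:
    """Net flux and mixture index for one unordered sample pair.

    The pair is oriented lexicographically (``sample_a < sample_b``); F is
    reported for the a->b direction and ``net_source`` names the sample the
    net movement leaves from (``None`` when F = 0).
    """

    sample_a: str
    sample_b: str
    f_ab: float
    f_ba: float
    net_flux: float
    mixture: float
    net_source: str | None
    n_a: int
    n_b: int
    unit: str

    @property
    def undefined(self) -> bool:
        """True when neither sample contributes any origin taxon."""
        return self.n_a == 0 and self.n_b == 0


def assign_origins(
    table: AbundanceTable, explicit: Mapping[str, str] | None = None
) -> OriginMap:
    """Proxy each taxon's origin as its sample of maximum abundance.

    ``explicit`` assignments (e.g. the dereplication software's actual
    representative-genome sample) override the argmax proxy.  Ties break to
    the lexicographically smallest sample id; a taxon that is zero
    everywhere and has no explicit origin is an error, because no origin is
    defensible for it.
    """
    if not table.taxon_ids or not table.sample_ids:
        raise TableError("cannot assign origins on an empty table")
    explicit = dict(explicit or {})
    samples = set(table.sample_ids)
    for taxon, origin in explicit.items():
        if origin not in samples:
            raise TableError(f"explicit origin {origin!r} for {taxon!r} is not a sample")

    # argmax over lexicographically sorted columns makes the first maximal
    # column the smallest sample id, which is the documented tie-break
    ordered = sorted(table.sample_ids)
    arr = table.values[ordered].to_numpy(dtype=float)
    argmax = np.argmax(arr, axis=1)
    maxima = arr[np.arange(arr.shape[0]), argmax]

    mapping: dict[str, str] = {}
    all_zero: list[str] = []
    for i, taxon in enumerate(table.taxon_ids):
        if taxon in explicit:
            mapping[taxon] = explicit[taxon]
        elif maxima[i] <= 0:
            all_zero.append(taxon)
        else:
            mapping[taxon] = ordered[argmax[i]]
    if all_zero:
        raise TableError(
            f"taxa with all-zero abundance and no explicit origin: {all_zero[:10]}"
        )
    return OriginMap(mapping)


def movement_flux(table: AbundanceTable, origins: OriginMap) -> FluxMatrix:
    """Average abundance in each destination of every origin's taxa.

    ``f.loc[A, B]`` is the arithmetic mean over all taxa with origin A of
    their abundance in B, zeros included; the diagonal (self-flux) is
    computed too but excluded from pair summaries downstream.
    """
    origins.validate_against(table)
    sample_ids = table.sample_ids
    sample_idx = {s: i for i, s in enumerate(sample_ids)}
    X = table.matrix
    origin_idx = np.array([sample_idx[origins[t]] for t in table.taxon_ids])

    n_samples = len(sample_ids)
    f = np.zeros((n_samples, n_samples))
    counts = np.bincount(origin_idx, minlength=n_samples)
    np.add.at(f, origin_idx, X)
    nonzero = counts > 0
    f[nonzero] /= counts[nonzero, None]

    undefined = tuple(s for s, c in zip(sample_ids, counts) if c == 0)
    if undefined:
        logger.warning(
            "samples contributing no origin taxa (flux rows set to 0): %s", list(undefined)
        )
    return FluxMatrix(
        f=pd.DataFrame(f, index=sample_ids, columns=sample_ids),
        n_origin=pd.Series(counts, index=sample_ids, name="n_origin"),
        unit=table.unit,
        undefined_sources=undefined,
    )


def net_flux_and_mixture(flux: FluxMatrix) -> list[PairSummary]:
    """Pair summaries F = f_ab - f_ba and M = (f_ab + f_ba)/2.

    One summary per unordered pair, lexicographically oriented and sorted.
    """
    pairs = []
    for a, b in iter_pairs(flux.sample_ids):
        f_ab = float(flux.f.loc[a, b])
        f_ba = float(flux.f.loc[b, a])
        F = f_ab - f_ba
        M = (f_ab + f_ba) / 2.0
        pairs.append(
            PairSummary(
                sample_a=a,
                sample_b=b,
                f_ab=f_ab,
                f_ba=f_ba,
                net_flux=F,
                mixture=M,
                net_source=a if F > 0 else (b if F < 0 else None),
                n_a=int(flux.n_origin[a]),
                n_b=int(flux.n_origin[b]),
                unit=flux.unit,
            )
        )
    return pairs


def iter_pairs(sample_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered sample pairs, lexicographically oriented and sorted."""
    ordered = sorted(sample_ids)
    return [(a, b) for i, a in enumerate(ordered) for b in ordered[i + 1 :]]


def pair_summary_records(pairs: Sequence[PairSummary]) -> list[dict]:
    return [
        {
            "pair_a": p.sample_a,
            "pair_b": p.sample_b,
            "f_ab": p.f_ab,
            "f_ba": p.f_ba,
            "net_flux": p.net_flux,
            "mixture": p.mixture,
            "net_source": p.net_source or "",
            "n_a": p.n_a,
            "n_b": p.n_b,
            "unit": p.unit,
        }
        for p in pairs
    ]


PAIR_SUMMARY_COLUMNS = [
    "pair_a", "pair_b", "f_ab", "f_ba", "net_flux", "mixture",
    "net_source", "n_a", "n_b", "unit",
]
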