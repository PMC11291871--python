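"""Permutation null over MAG origins and sample-pair classification.

The null model permutes the origin labels across taxa (a uniform multiset
permutation: per-sample origin counts are preserved, taxa are reassigned)
and recomputes the pair statistics F and M under each permuted origin map.
A single shared stream of permutations serves every pair of one run.

A pair of samples is labelled, in order of precedence:

* ``Isolated``     — observed M lower than ``level`` of the permuted M values
                     (less exchange than random origin placement);
* ``Transmitted``  — observed |F| higher than ``level`` of the permuted
                     values and the pair is not Isolated; the sign of the
                     observed F names the net source;
* ``Mixed``        — observed M higher than ``level`` of the permuted M
                     values and the pair is not Transmitted;
* ``Others``       — indistinguishable from random permutations.

"higher/lower than" is a strict inequality against at least
``ceil(level * n_perm)`` of the null draws, so ties count against
significance.  An exhaustive enumerator over all distinct origin
arrangements provides an exact oracle for small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .flux import FluxMatrix, OriginMap, iter_pairs, movement_flux
from .tables import AbundanceTable, RunConfig, SampleInfo, TableError, logger

LABELS = ("Isolated", "Transmitted", "Mixed", "Others")

#: Hard cap on the number of distinct arrangements the exhaustive
#: enumerator will visit.
EXHAUSTIVE_GUARD = 1_000_000


@dataclass(frozen=True)
class PairClassification:
    """Permutation-based label and exceedance fractions for one pair.

    ``exceed_f`` is the fraction of permutations whose null statistic is
    strictly below the observed |F| (or signed F when requested);
    ``exceed_m_high`` / ``exceed_m_low`` are the fractions with null M
    strictly below / above the observed M.
    """

    sample_a: str
    sample_b: str
    f_ab: float
    f_ba: float
    net_flux: float
    mixture: float
    net_source: str | None
    label: str
    exceed_f: float
    exceed_m_high: float
    exceed_m_low: float
    n_perm: int
    level: float
    seed: int | None
    method: str


CLASSIFICATION_COLUMNS = [
    "pair_a", "pair_b", "f_ab", "f_ba", "net_flux", "mixture", "net_source",
    "label", "exceed_f", "exceed_m_high", "exceed_m_low",
    "n_perm", "level", "seed", "method",
]


def classification_records(classifications: Sequence[PairClassification]) -> list[dict]:
    return [
        {
            "pair_a": c.sample_a,
            "pair_b": c.sample_b,
            "f_ab": c.f_ab,
            "f_ba": c.f_ba,
            "net_flux": c.net_flux,
            "mixture": c.mixture,
            "net_source": c.net_source or "",
            "label": c.label,
            "exceed_f": c.exceed_f,
            "exceed_m_high": c.exceed_m_high,
            "exceed_m_low": c.exceed_m_low,
            "n_perm": c.n_perm,
            "level": c.level,
            "seed": "" if c.seed is None else c.seed,
            "method": c.method,
        }
        for c in classifications
    ]


def permute_origins(origins: OriginMap, rng: np.random.Generator) -> OriginMap:
    """Uniform multiset permutation of the origin labels across taxa."""
    taxa = list(origins)
    labels = [origins[t] for t in taxa]
    perm = rng.permutation(len(labels))
    return OriginMap({t: labels[p] for t, p in zip(taxa, perm)})


def _origin_indices(table: AbundanceTable, origins: OriginMap) -> np.ndarray:
    sample_idx = {s: i for i, s in enumerate(table.sample_ids)}
    return np.array([sample_idx[origins[t]] for t in table.taxon_ids], dtype=np.intp)


def _flux_from_labels(X: np.ndarray, labels: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """f[A, B] = mean over taxa labelled A of column B (0 when count 0)."""
    n_samples = counts.shape[0]
    f = np.zeros((n_samples, n_samples))
    np.add.at(f, labels, X)
    nz = counts > 0
    f[nz] /= counts[nz, None]
    return f


def _stratum_index_groups(
    table: AbundanceTable,
    origin_idx: np.ndarray,
    samples: Sequence[SampleInfo] | None,
    stratify_by: str | None,
) -> list[np.ndarray]:
    """Taxon index groups within which origin labels may be shuffled."""
    if stratify_by is None:
        return [np.arange(origin_idx.shape[0])]
    if samples is None:
        raise TableError("stratified permutation requires sample metadata")
    by_sample = {s.sample_id: s for s in samples}
    missing = [s for s in table.sample_ids if s not in by_sample]
    if missing:
        raise TableError(f"metadata misses samples: {missing[:5]}")
    strata = []
    for s in table.sample_ids:
        info = by_sample[s]
        strata.append(getattr(info, stratify_by))
    strata = np.array(strata)
    taxon_strata = strata[origin_idx]
    return [np.nonzero(taxon_strata == s)[0] for s in np.unique(taxon_strata)]


def _decide(
    cnt_f: int, cnt_m_high: int, cnt_m_low: int, n_null: int, level: float
) -> str:
    k = math.ceil(level * n_null)
    if cnt_m_low >= k:
        return "Isolated"
    if cnt_f >= k:
        return "Transmitted"
    if cnt_m_high >= k:
        return "Mixed"
    return "Others"


def classify_pairs(
    table: AbundanceTable,
    origins: OriginMap,
    config: RunConfig,
    *,
    use_signed_f: bool = False,
    samples: Sequence[SampleInfo] | None = None,
    stratify_by: str | None = None,
    _chunk: int = 512,
) -> list[PairClassification]:
    """Monte-Carlo classification of every unordered sample pair.

    ``use_signed_f`` switches the Transmitted statistic from |F| (the
    orientation-invariant default) to the signed F.  ``stratify_by``
    (``"medium"``, ``"zone"`` or ``"group"``) constrains permutations to
    shuffle origins within the named metadata stratum instead of globally;
    the global permutation is the default.
    """
    origins.validate_against(table)
    table = table.threshold(config.detection_threshold)
    sample_ids = table.sample_ids
    X = table.matrix
    origin_idx = _origin_indices(table, origins)
    n_samples = len(sample_ids)
    counts = np.bincount(origin_idx, minlength=n_samples).astype(float)

    f_obs = _flux_from_labels(X, origin_idx, counts)
    F_obs = f_obs - f_obs.T
    M_obs = (f_obs + f_obs.T) / 2.0
    stat_obs = F_obs if use_signed_f else np.abs(F_obs)

    groups = _stratum_index_groups(table, origin_idx, samples, stratify_by)
    rng = np.random.default_rng(config.seed)

    cnt_f = np.zeros((n_samples, n_samples), dtype=np.int64)
    cnt_m_high = np.zeros_like(cnt_f)
    cnt_m_low = np.zeros_like(cnt_f)

    done = 0
    labels = origin_idx.copy()
    while done < config.n_perm:
        todo = min(_chunk, config.n_perm - done)
        for _ in range(todo):
            for idx in groups:
                labels[idx] = origin_idx[idx][rng.permutation(idx.shape[0])]
            f_null = _flux_from_labels(X, labels, counts)
            F_null = f_null - f_null.T
            M_null = (f_null + f_null.T) / 2.0
            stat_null = F_null if use_signed_f else np.abs(F_null)
            cnt_f += stat_null < stat_obs
            cnt_m_high += M_null < M_obs
            cnt_m_low += M_null > M_obs
        done += todo

    return _build_classifications(
        sample_ids, f_obs, F_obs, M_obs, counts,
        cnt_f, cnt_m_high, cnt_m_low,
        n_null=config.n_perm, level=config.level,
        seed=config.seed, method="monte_carlo",
    )


def count_arrangements(origins: OriginMap) -> int:
    """Number of distinct multiset permutations of the origin labels."""
    counts = list(origins.origin_counts().values())
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def classify_pairs_exhaustive(
    table: AbundanceTable,
    origins: OriginMap,
    level: float = 0.95,
    *,
    use_signed_f: bool = False,
) -> list[PairClassification]:
    """Exact classification enumerating every distinct origin arrangement.

    All distinct arrangements of the origin-label multiset are equally
    likely under a uniform permutation, so each is visited exactly once
    with equal weight.  Instances above :data:`EXHAUSTIVE_GUARD`
    arrangements are refused; use Monte-Carlo for those.
    """
    origins.validate_against(table)
    n_arr = count_arrangements(origins)
    if n_arr > EXHAUSTIVE_GUARD:
        raise TableError(
            f"{n_arr} distinct arrangements exceed the exhaustive guard "
            f"({EXHAUSTIVE_GUARD}); use classify_pairs (Monte-Carlo)"
        )

    sample_ids = table.sample_ids
    X = table.matrix
    origin_idx = _origin_indices(table, origins)
    n_samples = len(sample_ids)
    counts = np.bincount(origin_idx, minlength=n_samples).astype(float)

    f_obs = _flux_from_labels(X, origin_idx, counts)
    F_obs = f_obs - f_obs.T
    M_obs = (f_obs + f_obs.T) / 2.0
    stat_obs = F_obs if use_signed_f else np.abs(F_obs)

    cnt_f = np.zeros((n_samples, n_samples), dtype=np.int64)
    cnt_m_high = np.zeros_like(cnt_f)
    cnt_m_low = np.zeros_like(cnt_f)
    seen = 0
    for arrangement in multiset_permutations(origin_idx.tolist()):
        labels = np.asarray(arrangement, dtype=np.intp)
        f_null = _flux_from_labels(X, labels, counts)
        F_null = f_null - f_null.T
        M_null = (f_null + f_null.T) / 2.0
        stat_null = F_null if use_signed_f else np.abs(F_null)
        cnt_f += stat_null < stat_obs
        cnt_m_high += M_null < M_obs
        cnt_m_low += M_null > M_obs
        seen += 1
    assert seen == n_arr

    return _build_classifications(
        sample_ids, f_obs, F_obs, M_obs, counts,
        cnt_f, cnt_m_high, cnt_m_low,
        n_null=n_arr, level=level, seed=None, method="exhaustive",
    )


def _build_classifications(
    sample_ids, f_obs, F_obs, M_obs, counts,
    cnt_f, cnt_m_high, cnt_m_low, *, n_null, level, seed, method,
) -> list[PairClassification]:
    idx = {s: i for i, s in enumerate(sample_ids)}
    out = []
    for a, b in iter_pairs(sample_ids):
        i, j = idx[a], idx[b]
        F = float(F_obs[i, j])
        undefined = counts[i] == 0 and counts[j] == 0
        if undefined:
            logger.warning("pair (%s, %s): no origin taxa on either side -> Others", a, b)
            label = "Others"
        else:
            label = _decide(
                int(cnt_f[i, j]), int(cnt_m_high[i, j]), int(cnt_m_low[i, j]),
                n_null, level,
            )
        out.append(
            PairClassification(
                sample_a=a,
                sample_b=b,
                f_ab=float(f_obs[i, j]),
                f_ba=float(f_obs[j, i]),
                net_flux=F,
                mixture=float(M_obs[i, j]),
                net_source=a if F > 0 else (b if F < 0 else None),
                label=label,
                exceed_f=cnt_f[i, j] / n_null,
                exceed_m_high=cnt_m_high[i, j] / n_null,
                exceed_m_low=cnt_m_low[i, j] / n_null,
                n_perm=n_null,
                level=level,
                seed=seed,
                method=method,
            )
        )
    return out


@dataclass(frozen=True)
class HabitatPairSummary:
    """Habitat-level aggregation of the sample-pair classifications.

    ``regime`` condenses the cross-habitat pair labels into one call:

    * ``Transmitted`` — at least one cross pair Transmitted and all such
      pairs agree on the source habitat (named in ``net_source``);
    * ``Mixed``       — no Transmitted pair, at least one Mixed pair;
    * ``Isolated``    — every cross pair Isolated;
    * ``Others``      — anything else (including conflicting directions).

    ``mean_net_flux`` is the mean F oriented habitat_a -> habitat_b over
    all cross pairs; ``mean_net_flux_transmitted`` restricts it to pairs
    labelled Transmitted (NaN when there are none).
    """

    habitat_a: str
    habitat_b: str
    n_pairs: int
    label_counts: Mapping[str, int]
    mean_net_flux: float
    mean_net_flux_transmitted: float
    regime: str
    net_source: str | None


def summarize_habitat_pair(
    classifications: Sequence[PairClassification],
    samples: Sequence[SampleInfo],
    habitat_a: str,
    habitat_b: str,
) -> HabitatPairSummary:
    """Condense the pair labels between two habitat groups into one regime."""
    group = {s.sample_id: s.group for s in samples}
    cross = [
        c
        for c in classifications
        if {group.get(c.sample_a), group.get(c.sample_b)} == {habitat_a, habitat_b}
    ]
    if not cross:
        raise TableError(f"no sample pairs between {habitat_a!r} and {habitat_b!r}")

    label_counts = {label: 0 for label in LABELS}
    fluxes, fluxes_t = [], []
    t_src_a = t_src_b = 0
    for c in cross:
        label_counts[c.label] += 1
        oriented = c.net_flux if group[c.sample_a] == habitat_a else -c.net_flux
        fluxes.append(oriented)
        if c.label == "Transmitted":
            fluxes_t.append(oriented)
            if c.net_source is not None and group[c.net_source] == habitat_a:
                t_src_a += 1
            else:
                t_src_b += 1

    if t_src_a + t_src_b > 0:
        if t_src_a and not t_src_b:
            regime, src = "Transmitted", habitat_a
        elif t_src_b and not t_src_a:
            regime, src = "Transmitted", habitat_b
        else:
            regime, src = "Others", None
    elif label_counts["Mixed"] > 0:
        regime, src = "Mixed", None
    elif label_counts["Isolated"] == len(cross):
        regime, src = "Isolated", None
    else:
        regime, src = "Others", None

    return HabitatPairSummary(
        habitat_a=habitat_a,
        habitat_b=habitat_b,
        n_pairs=len(cross),
        label_counts=label_counts,
        mean_net_flux=float(np.mean(fluxes)),
        mean_net_flux_transmitted=float(np.mean(fluxes_t)) if fluxes_t else float("nan"),
        regime=regime,
        net_source=src,
    )
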