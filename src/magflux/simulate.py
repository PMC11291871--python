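"""Synthetic hadal metacommunity generator with known ground truth.

The generator emulates the statistical structure the movement-flux
analysis assumes: every sample seeds its own cohort of taxa whose base
abundance is log-normal (metagenome abundance tables are heavy-tailed),
directional transmission copies a controllable fraction of each source
taxon's abundance into every sample of a destination habitat group with
multiplicative log-normal noise, low abundances are zeroed below a
detection threshold (emulating coverage-fraction cutoffs), and a chosen
fraction of taxa can have their maximum displaced off-origin to stress the
origin-assignment proxy.  Default shape mirrors a 33-sample, four-group
trench survey (3 + 9 slope, 7 + 14 bottom samples, ~360 taxa).

Transmission is habitat-to-habitat: all samples of a habitat share the
same outgoing fraction tau[A][B], because the scientific conclusions the
statistic supports are at habitat-pair level.  Samples of the *same*
habitat exchange nothing (the tau diagonal is ignored): each taxon's
within-habitat support stays concentrated in its origin sample, mirroring
the observation that MAGs peak in the sample they were assembled from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .flux import OriginMap
from .tables import AbundanceTable, GeneCountTable, GROUPS, SampleInfo, TableError, logger

#: Sample counts per habitat group in the default (survey-shaped) scenario.
DEFAULT_HABITATS = (
    ("slope_seawater", 3),
    ("slope_sediment", 9),
    ("bottom_seawater", 7),
    ("bottom_sediment", 14),
)


@dataclass(frozen=True)
class Regime:
    """True exchange regime of a pair: a label and, for one-way
    transmission, the source (habitat or sample) it leaves from."""

    label: str
    source: str | None = None


@dataclass(frozen=True)
class Scenario:
    """Full parameterization of a synthetic metacommunity.

    ``transmission`` maps ordered habitat pairs (source, destination) to
    the expected fraction of a source taxon's origin abundance appearing
    in each destination sample; unlisted pairs transmit nothing.
    ``noise_cv`` is the coefficient of variation of the multiplicative
    log-normal noise on transmitted abundances.  ``origin_violation_rate``
    is the fraction of taxa whose maximum is deliberately swapped into a
    random non-origin sample.  ``regime_margin`` is the tau value a
    direction must exceed to count as true transmission when deriving
    ground-truth pair regimes.
    """

    seed: int = 0
    habitats: tuple[tuple[str, int], ...] = DEFAULT_HABITATS
    taxa_per_sample: int = 11
    base_log_mean: float = 2.0
    base_log_sd: float = 1.0
    transmission: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_cv: float = 0.2
    detection_threshold: float = 0.0
    origin_violation_rate: float = 0.0
    regime_margin: float = 0.0

    def __post_init__(self) -> None:
        labels = [h for h, _ in self.habitats]
        if len(set(labels)) != len(labels):
            raise TableError("duplicate habitat labels in scenario")
        unknown = [h for h in labels if h not in GROUPS]
        if unknown:
            raise TableError(f"unknown habitat group labels: {unknown}")
        if any(n < 1 for _, n in self.habitats):
            raise TableError("every habitat needs at least one sample")
        if self.taxa_per_sample < 1:
            raise TableError("taxa_per_sample must be positive")
        if self.noise_cv < 0 or self.detection_threshold < 0:
            raise TableError("noise_cv and detection_threshold must be non-negative")
        if not (0 <= self.origin_violation_rate <= 1):
            raise TableError("origin_violation_rate must lie in [0, 1]")
        for (src, dst), tau in self.transmission.items():
            if src not in labels or dst not in labels:
                raise TableError(f"transmission references unknown habitat: {(src, dst)}")
            if not (0 <= tau <= 1):
                raise TableError(f"transmission fraction {tau} outside [0, 1]")
            if src == dst and tau > 0:
                logger.debug("transmission diagonal (%s) ignored", src)

    def tau(self, src: str, dst: str) -> float:
        if src == dst:
            return 0.0
        return float(self.transmission.get((src, dst), 0.0))

    @property
    def habitat_labels(self) -> list[str]:
        return [h for h, _ in self.habitats]


@dataclass(frozen=True)
class GroundTruth:
    """True origins and true pair regimes of a simulated scenario."""

    origins: OriginMap
    sample_regimes: Mapping[tuple[str, str], Regime]
    habitat_regimes: Mapping[tuple[str, str], Regime]
    regime_margin: float


def _derive_regime(tau_ab: float, tau_ba: float, a: str, b: str, margin: float) -> Regime:
    above_ab, above_ba = tau_ab > margin, tau_ba > margin
    if above_ab and above_ba:
        return Regime("Mixed")
    if above_ab:
        return Regime("Transmitted", source=a)
    if above_ba:
        return Regime("Transmitted", source=b)
    return Regime("Isolated")


def simulate_communities(
    scenario: Scenario,
) -> tuple[AbundanceTable, list[SampleInfo], GroundTruth]:
    """Draw one metacommunity realization; fully reproducible from the seed."""
    rng = np.random.default_rng(scenario.seed)

    samples: list[SampleInfo] = []
    habitat_of: dict[str, str] = {}
    for habitat, n in scenario.habitats:
        zone, medium = habitat.split("_", 1)
        for k in range(1, n + 1):
            sid = f"{habitat}_{k:02d}"
            samples.append(SampleInfo(sample_id=sid, medium=medium, zone=zone))
            habitat_of[sid] = habitat
    sample_ids = [s.sample_id for s in samples]
    n_samples = len(sample_ids)

    taxa: list[str] = []
    origin: dict[str, str] = {}
    for sid in sample_ids:
        for j in range(1, scenario.taxa_per_sample + 1):
            tid = f"{sid}_mag{j:02d}"
            taxa.append(tid)
            origin[tid] = sid
    n_taxa = len(taxa)

    sigma2 = np.log1p(scenario.noise_cv**2)
    sigma = np.sqrt(sigma2)

    X = np.zeros((n_taxa, n_samples))
    row = 0
    for si, sid in enumerate(sample_ids):
        base = rng.lognormal(scenario.base_log_mean, scenario.base_log_sd,
                             scenario.taxa_per_sample)
        rows = slice(row, row + scenario.taxa_per_sample)
        X[rows, si] = base
        for bi, bid in enumerate(sample_ids):
            if bi == si:
                continue
            tau = scenario.tau(habitat_of[sid], habitat_of[bid])
            if tau > 0:
                noise = rng.lognormal(-sigma2 / 2, sigma, scenario.taxa_per_sample)
                X[rows, bi] = tau * base * noise
        row += scenario.taxa_per_sample

    if scenario.detection_threshold > 0:
        X[X < scenario.detection_threshold] = 0.0

    if scenario.origin_violation_rate > 0:
        n_viol = int(round(scenario.origin_violation_rate * n_taxa))
        chosen = rng.choice(n_taxa, size=n_viol, replace=False)
        origin_idx = {sid: i for i, sid in enumerate(sample_ids)}
        for t in chosen:
            oi = origin_idx[origin[taxa[t]]]
            others = [i for i in range(n_samples) if i != oi]
            bi = int(rng.choice(others))
            X[t, oi], X[t, bi] = X[t, bi], X[t, oi]

    table = AbundanceTable(
        values=pd.DataFrame(X, index=taxa, columns=sample_ids), unit="RPKM"
    )

    habitat_regimes: dict[tuple[str, str], Regime] = {}
    labels = scenario.habitat_labels
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            habitat_regimes[(a, b)] = _derive_regime(
                scenario.tau(a, b), scenario.tau(b, a), a, b, scenario.regime_margin
            )
    sample_regimes: dict[tuple[str, str], Regime] = {}
    for i, a in enumerate(sorted(sample_ids)):
        for b in sorted(sample_ids)[i + 1 :]:
            ha, hb = habitat_of[a], habitat_of[b]
            if ha == hb:
                sample_regimes[(a, b)] = Regime("Isolated")
            else:
                key = (ha, hb) if (ha, hb) in habitat_regimes else (hb, ha)
                reg = habitat_regimes[key]
                src = None
                if reg.label == "Transmitted":
                    src = a if habitat_of[a] == reg.source else b
                sample_regimes[(a, b)] = Regime(reg.label, source=src)

    truth = GroundTruth(
        origins=OriginMap(origin),
        sample_regimes=sample_regimes,
        habitat_regimes=habitat_regimes,
        regime_margin=scenario.regime_margin,
    )
    return table, samples, truth


def two_habitat_scenario(
    tau_ab: float,
    tau_ba: float,
    *,
    seed: int = 0,
    n_samples: int = 3,
    taxa_per_sample: int = 50,
    habitat_a: str = "bottom_seawater",
    habitat_b: str = "slope_seawater",
    **kwargs,
) -> Scenario:
    """Reference two-habitat scenario used for benchmark and calibration runs."""
    return Scenario(
        seed=seed,
        habitats=((habitat_a, n_samples), (habitat_b, n_samples)),
        taxa_per_sample=taxa_per_sample,
        transmission={(habitat_a, habitat_b): tau_ab, (habitat_b, habitat_a): tau_ba},
        **kwargs,
    )


def simulate_gene_counts(
    n_genes: int,
    samples: Sequence[SampleInfo],
    effect_spec: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    *,
    mean_log_reads: float = 5.0,
    read_log_sd: float = 1.0,
    dispersion: float = 10.0,
) -> GeneCountTable:
    """Negative-binomial gene read counts with per-group fold-changes.

    Gene lengths are uniform on [300, 3000] bp; each gene's expected count
    is a log-normal per-kilobase rate times its length, scaled by the
    fold-change ``effect_spec[gene_id][group]`` (default 1) for the
    sample's habitat group.  ``dispersion`` is the negative-binomial shape
    parameter r (larger = closer to Poisson).
    """
    if n_genes < 1:
        raise TableError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    lengths = rng.integers(300, 3001, size=n_genes)
    rate_per_kb = rng.lognormal(mean_log_reads, read_log_sd, size=n_genes)
    effect_spec = effect_spec or {}

    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, info in enumerate(samples):
        folds = np.array(
            [effect_spec.get(g, {}).get(info.group, 1.0) for g in gene_ids]
        )
        mean = rate_per_kb * (lengths / 1000.0) * folds
        p = dispersion / (dispersion + mean)
        counts[:, j] = rng.negative_binomial(dispersion, p)

    return GeneCountTable(
        counts=pd.DataFrame(counts, index=gene_ids,
                            columns=[s.sample_id for s in samples]),
        lengths_bp=pd.Series(lengths, index=gene_ids, name="length"),
    )
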