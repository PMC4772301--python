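"""Synthetic hologenome inputs with planted, recoverable structure.

Three generators emulate the statistical structure the analysis stages
assume, so the whole pipeline is testable without any sequence download:

* ``gen_panel`` — per-domain occurrence counts for the focal sponge
  genomes plus a multi-species eukaryote background panel, with planted
  lineage-specific domain expansions (negative-binomial counts).
* ``gen_srcr_sequences`` — clusters of SRCR-like domain instances built
  on a shared cysteine scaffold over cluster-specific variable columns.
* ``gen_meta_counts`` — homology-group x sample metatranscriptome read
  counts for two communities with planted differentially expressed
  groups carrying planted enriched domains.

Every generator is a pure function of its spec (seed included): the same
spec yields byte-identical output. Truth labels are returned alongside
the data, never embedded in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meta_enrichment import GroupCountTable
from .repertoire import DomainCountMatrix
from .srcr_profile import AA20

NON_CYS = tuple(a for a in AA20 if a != "C")


def _neg_binom(
    rng: np.random.Generator,
    mean: np.ndarray | float,
    dispersion: float,
    size=None,
) -> np.ndarray:
    """Negative-binomial draw with var = mean + dispersion * mean**2.

    Dispersion 0 degenerates to deterministic counts (rounded mean).
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size or np.shape(mean))
    if dispersion <= 0:
        return np.rint(mean).astype(int)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(int)


@dataclass(frozen=True)
class PanelSpec:
    """Domain-count panel: focal sponge genomes + eukaryote background.

    ``dispersion`` governs count noise between the (comparable) focal
    genomes; ``background_dispersion`` the much wider spread across the
    diverse background eukaryotes. Planted expansions multiply the
    baseline mean of one (species, domain) cell by ``fold``.
    """

    n_species: int = 40  # background panel size
    n_domains: int = 60
    focal_species: tuple[str, ...] = ("SC", "XT", "AQ")
    mean_range: tuple[float, float] = (100.0, 1000.0)
    dispersion: float = 0.01
    background_dispersion: float = 0.3
    planted_expansions: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    @property
    def domain_ids(self) -> list[str]:
        return [f"D{i:04d}" for i in range(self.n_domains)]

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_domains < 1:
            raise ValueError("need >= 2 background species and >= 1 domain")
        domains = set(self.domain_ids)
        for sp, dom, fold in self.planted_expansions:
            if fold < 1:
                raise ValueError(f"planted fold must be >= 1, got {fold}")
            if sp not in self.focal_species:
                raise ValueError(f"unknown focal species {sp!r}")
            if dom not in domains:
                raise ValueError(f"unknown domain {dom!r}")


def gen_panel(spec: PanelSpec) -> tuple[DomainCountMatrix, pd.DataFrame]:
    """Generate focal-species counts and the background panel.

    Returns (focal DomainCountMatrix, background domains x species frame).
    Planted (species, domain) cells have expected count fold x baseline.
    """
    rng = np.random.default_rng(spec.seed)
    domains = spec.domain_ids
    lo, hi = spec.mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_domains))

    fold = pd.DataFrame(1.0, index=list(spec.focal_species), columns=domains)
    for sp, dom, f in spec.planted_expansions:
        fold.loc[sp, dom] *= f

    focal = pd.DataFrame(
        _neg_binom(
            rng,
            fold.to_numpy() * means[None, :],
            spec.dispersion,
            size=(len(spec.focal_species), spec.n_domains),
        ),
        index=list(spec.focal_species),
        columns=domains,
    )
    background = pd.DataFrame(
        _neg_binom(
            rng,
            np.tile(means[:, None], (1, spec.n_species)),
            spec.background_dispersion,
            size=(spec.n_domains, spec.n_species),
        ),
        index=domains,
        columns=[f"BG{i:03d}" for i in range(spec.n_species)],
    )
    return DomainCountMatrix(counts=focal), background


@dataclass(frozen=True)
class SrcrClusterSpec:
    """Clusters of domain instances over a shared cysteine scaffold.

    Each cluster draws its own per-column residue distribution for
    non-cysteine columns from a symmetric Dirichlet whose concentration
    parameter ``variable_column_concentration`` (kappa) controls
    conservation: columns are sampled from Dirichlet(1/kappa), so
    kappa -> infinity gives identical members and kappa -> 0 uniform
    noise. Expected within-cluster per-column identity is
    (1 + kappa) / (19 + kappa); the default 240 gives ~0.93, well above
    the 90%-positives homology criterion, while independent scaffolds
    keep between-cluster identity near chance (~13% including the shared
    cysteine columns). Cysteine columns carry C with probability
    ``cysteine_retention``.
    """

    n_clusters: int = 5
    members_per_cluster: Mapping[str, int] = field(
        default_factory=lambda: {"SC": 4, "AQ": 4, "XT": 2}
    )
    scaffold_length: int = 100
    cysteine_positions: tuple[int, ...] = (5, 17, 34, 46, 62, 75, 88, 96)
    cysteine_retention: float = 0.95
    variable_column_concentration: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("need >= 1 cluster")
        if self.scaffold_length < len(self.cysteine_positions):
            raise ValueError("scaffold shorter than the cysteine scaffold")
        if any(not (0 <= p < self.scaffold_length) for p in self.cysteine_positions):
            raise ValueError("cysteine positions must lie within the scaffold")
        if not (0 < self.cysteine_retention <= 1):
            raise ValueError("cysteine_retention must be in (0, 1]")
        if self.variable_column_concentration <= 0:
            raise ValueError("variable_column_concentration must be positive")
        if any(m < 0 for m in self.members_per_cluster.values()):
            raise ValueError("negative member count")


def _column_distribution(rng: np.random.Generator, kappa: float) -> np.ndarray:
    if kappa >= 1e6:  # numerically a point mass
        p = np.zeros(len(NON_CYS))
        p[rng.integers(len(NON_CYS))] = 1.0
        return p
    p = rng.dirichlet(np.full(len(NON_CYS), 1.0 / kappa))
    if not np.isfinite(p).all() or p.sum() == 0:
        p = np.zeros(len(NON_CYS))
        p[rng.integers(len(NON_CYS))] = 1.0
    return p


def gen_srcr_sequences(
    spec: SrcrClusterSpec,
) -> tuple[dict[str, str], dict[str, int]]:
    """Generate labelled SRCR-like domain instances.

    Returns (id -> sequence, id -> true cluster index). Ids follow the
    ``species|protein|domain|index`` convention.
    """
    rng = np.random.default_rng(spec.seed)
    cys = set(spec.cysteine_positions)
    non_cys_arr = np.array(list(NON_CYS))
    seqs: dict[str, str] = {}
    truth: dict[str, int] = {}
    counter: dict[str, int] = {sp: 0 for sp in spec.members_per_cluster}
    for c in range(spec.n_clusters):
        columns = {
            pos: _column_distribution(rng, spec.variable_column_concentration)
            for pos in range(spec.scaffold_length)
            if pos not in cys
        }
        for sp in spec.members_per_cluster:
            for _ in range(spec.members_per_cluster[sp]):
                chars = []
                for pos in range(spec.scaffold_length):
                    if pos in cys:
                        if rng.random() < spec.cysteine_retention:
                            chars.append("C")
                        else:
                            chars.append(str(rng.choice(non_cys_arr)))
                    else:
                        chars.append(str(rng.choice(non_cys_arr, p=columns[pos])))
                counter[sp] += 1
                name = f"{sp}|p{counter[sp]:04d}|SRCR|{c}"
                seqs[name] = "".join(chars)
                truth[name] = c
    return seqs, truth


@dataclass(frozen=True)
class MetaSpec:
    """Metatranscriptome group x sample counts for two communities.

    Planted DE groups have their mean multiplied by 2**log2_fold in the
    *second* community. Planted enriched domains are present in
    ``enriched_presence`` of DE groups but only ``background_presence``
    of the rest; all other domains are present uniformly at the
    background rate.
    """

    n_groups: int = 500
    n_samples: tuple[int, int] = (4, 4)
    communities: tuple[str, str] = ("SC", "XT")
    mean_range: tuple[float, float] = (50.0, 500.0)
    dispersion: float = 0.1
    planted_de: tuple[tuple[str, float], ...] = ()
    n_domains: int = 40
    planted_enriched_domains: tuple[str, ...] = ()
    enriched_presence: float = 0.8
    background_presence: float = 0.1
    domain_assignment: Mapping[str, Sequence[str]] | None = None
    seed: int = 0

    @property
    def group_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_groups)]

    @property
    def domain_ids(self) -> list[str]:
        return [f"PF{i:05d}" for i in range(1, self.n_domains + 1)]

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_samples):
            raise ValueError("each community needs >= 1 sample")
        groups = set(self.group_ids)
        for g, lfc in self.planted_de:
            if g not in groups:
                raise ValueError(f"unknown group {g!r} in planted_de")
            if not np.isfinite(lfc):
                raise ValueError("planted log2 folds must be finite")
        domains = set(self.domain_ids)
        for d in self.planted_enriched_domains:
            if d not in domains:
                raise ValueError(f"unknown domain {d!r}")

    @classmethod
    def with_planted(
        cls,
        n_de: int = 25,
        log2_fold: float = 3.0,
        n_enriched: int = 3,
        seed: int = 0,
        **kwargs,
    ) -> "MetaSpec":
        """Convenience constructor planting the first n_de groups and
        n_enriched domains."""
        base = cls(seed=seed, **kwargs)
        rng = np.random.default_rng(seed + 101)
        de_idx = rng.choice(base.n_groups, size=n_de, replace=False)
        planted = tuple((base.group_ids[i], log2_fold) for i in sorted(de_idx))
        enriched = tuple(base.domain_ids[:n_enriched])
        return cls(
            seed=seed,
            planted_de=planted,
            planted_enriched_domains=enriched,
            **kwargs,
        )


def gen_meta_counts(
    spec: MetaSpec,
) -> tuple[GroupCountTable, dict]:
    """Generate the group count table plus truth sets.

    Returns (GroupCountTable, truth) where truth holds ``de_groups``,
    ``enriched_domains``, ``group_domains`` and ``log2_folds``.
    """
    rng = np.random.default_rng(spec.seed)
    groups = spec.group_ids
    ca, cb = spec.communities
    na, nb = spec.n_samples
    lo, hi = spec.mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_groups))
    lfc = pd.Series(0.0, index=groups)
    for g, f in spec.planted_de:
        lfc[g] = f
    de_groups = {g for g, f in spec.planted_de if f != 0}

    samples = [f"{ca}_{i + 1}" for i in range(na)] + [f"{cb}_{i + 1}" for i in range(nb)]
    community = {s: ca for s in samples[:na]} | {s: cb for s in samples[na:]}
    mean_a = means
    mean_b = means * np.power(2.0, lfc.to_numpy())
    counts = np.empty((spec.n_groups, na + nb), dtype=int)
    for j in range(na):
        counts[:, j] = _neg_binom(rng, mean_a, spec.dispersion, size=(spec.n_groups,))
    for j in range(nb):
        counts[:, na + j] = _neg_binom(rng, mean_b, spec.dispersion, size=(spec.n_groups,))
    table = GroupCountTable(
        counts=pd.DataFrame(counts, index=groups, columns=samples),
        sample_community=community,
    )

    if spec.domain_assignment is not None:
        group_domains = {g: list(d) for g, d in spec.domain_assignment.items()}
    else:
        group_domains = {g: [] for g in groups}
        enriched = set(spec.planted_enriched_domains)
        for d in spec.domain_ids:
            for g in groups:
                p = (
                    spec.enriched_presence
                    if (d in enriched and g in de_groups)
                    else spec.background_presence
                )
                if rng.random() < p:
                    group_domains[g].append(d)

    truth = {
        "de_groups": de_groups,
        "enriched_domains": set(spec.planted_enriched_domains),
        "group_domains": group_domains,
        "log2_folds": lfc,
    }
    return table, truth
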