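"""Host-side domain repertoire comparison.

Counts domain occurrences per genome, selects immunity/symbiosis-related
domains by keyword, calls fold-change expansions between species, ranks
over/under-representation against a multi-species background panel by
Z-score, and correlates repertoires between species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ProteinDomainTable

#: keywords used to pull host-microbe-interaction domains out of
#: functional annotations
DEFAULT_KEYWORDS = (
    "symbio",
    "innate immunity",
    "antimicrobial peptides",
    "antibacterial",
)

DEFAULT_FOLD_THRESHOLD = 1.5


@dataclass(frozen=True)
class RepertoireParams:
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not self.keywords or any(not k for k in self.keywords):
            raise ValueError("keywords must be non-empty strings")


@dataclass
class DomainCountMatrix:
    """Species x domain occurrence counts.

    ``counts[s, d]`` is the number of domain occurrences in the genome,
    the primary statistic; ``gene_counts[s, d]`` is the number of distinct
    proteins containing the domain (the bracketed secondary statistic).
    """

    counts: pd.DataFrame
    gene_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.gene_counts is not None:
            gc = self.gene_counts.reindex_like(self.counts).fillna(0)
            if (gc.values > self.counts.values).any():
                raise ValueError("gene_counts cannot exceed occurrence counts")

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def domains(self) -> list[str]:
        return list(self.counts.columns)


def count_domains(tables: Iterable[ProteinDomainTable]) -> DomainCountMatrix:
    """Tally domain occurrences and distinct domain-bearing genes per species."""
    tables = list(tables)
    all_domains = sorted({d for t in tables for d in t.domains()})
    counts = pd.DataFrame(
        0, index=[t.species_id for t in tables], columns=all_domains, dtype=int
    )
    gene_counts = counts.copy()
    for t in tables:
        occ: dict[str, int] = {}
        genes: dict[str, set[str]] = {}
        for rec in t.records:
            occ[rec.domain_id] = occ.get(rec.domain_id, 0) + 1
            genes.setdefault(rec.domain_id, set()).add(rec.protein_id)
        for d, c in occ.items():
            counts.loc[t.species_id, d] = c
            gene_counts.loc[t.species_id, d] = len(genes[d])
    return DomainCountMatrix(counts=counts, gene_counts=gene_counts)


def select_keyword_domains(
    annotations: Mapping[str, str | Sequence[str]],
    params: RepertoireParams | None = None,
) -> set[str]:
    """Select domains whose functional annotation matches any keyword.

    Matching is case-insensitive substring over every annotation string of
    the domain (description and GO-term names alike).
    """
    if params is None:
        params = RepertoireParams()
    if not annotations:
        raise ValueError("annotations mapping is empty")
    keywords = [k.lower() for k in params.keywords]
    selected = set()
    for domain, ann in annotations.items():
        strings = [ann] if isinstance(ann, str) else list(ann)
        for s in strings:
            s_low = s.lower()
            if any(k in s_low for k in keywords):
                selected.add(domain)
                break
    return selected


def fold_change_selection(
    matrix: DomainCountMatrix,
    species_a: str,
    species_b: str,
    params: RepertoireParams | None = None,
) -> set[tuple[str, str]]:
    """Call domains expanded >= fold_threshold-fold in one species over the other.

    Returns (domain, direction) pairs where direction is the species with
    the larger repertoire. The inequality form ``count_a >= t * count_b``
    avoids division: any positive count against zero is selected, and a
    domain absent from both species is never reported.
    """
    if params is None:
        params = RepertoireParams()
    t = params.fold_threshold
    ca = matrix.counts.loc[species_a]
    cb = matrix.counts.loc[species_b]
    out: set[tuple[str, str]] = set()
    for d in matrix.domains:
        a, b = ca[d], cb[d]
        if a == 0 and b == 0:
            continue
        if a >= t * b:
            out.add((d, species_a))
        elif b >= t * a:
            out.add((d, species_b))
    return out


def zscore_representation(
    focal_counts: pd.Series,
    background: pd.DataFrame,
) -> pd.DataFrame:
    """Rank focal-species domain counts against a background panel by Z-score.

    ``background`` is a domains x species table of counts across the panel.
    For each domain with panel standard deviation sigma > 0,
    z = (x - mu) / sigma with the sample (S-1) deviation. Domains with
    sigma = 0 or absent from the panel are flagged unscorable rather than
    given infinite scores. Output is sorted by z, descending, with
    unscorable domains last.
    """
    rows = []
    for domain, x in focal_counts.items():
        if domain not in background.index:
            rows.append((domain, x, np.nan, np.nan, np.nan, "absent_from_background"))
            continue
        panel = background.loc[domain].to_numpy(dtype=float)
        if panel.size < 2:
            raise ValueError(f"background for {domain!r} has fewer than 2 species")
        mu = panel.mean()
        sigma = panel.std(ddof=1)
        if sigma == 0:
            rows.append((domain, x, mu, 0.0, np.nan, "zero_variance"))
        else:
            rows.append((domain, x, mu, sigma, (x - mu) / sigma, "ok"))
    df = pd.DataFrame(rows, columns=["domain", "x", "mu", "sigma", "z", "flag"])
    return df.sort_values("z", ascending=False, na_position="last").reset_index(drop=True)


def correlate_species(
    matrix: DomainCountMatrix,
    species_a: str,
    species_b: str,
    domain_subset: Iterable[str],
) -> float:
    """Pearson correlation of two species' counts over a domain subset."""
    subset = sorted(set(domain_subset))
    if len(subset) < 3:
        raise ValueError("domain subset must contain at least 3 domains")
    x = matrix.counts.loc[species_a, subset].to_numpy(dtype=float)
    y = matrix.counts.loc[species_b, subset].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a count vector")
    return float(stats.pearsonr(x, y).statistic)
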