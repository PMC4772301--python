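"""Symbiont-side metatranscriptome pipeline.

Reads are filtered against rRNA references (removed when both alignment
coverage and identity reach 90%), assigned to MCL homology groups via
their best-hit reference, summed into a group x sample count table,
quantile-normalised across samples, and tested for differential
expression between the two host communities. Protein domains carried by
the differentially expressed groups are then tested for enrichment with
an upper-tail hypergeometric test under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .graph_clustering import Clustering, MclParams, mcl_cluster

RRNA_COVERAGE_THRESHOLD = 0.90
RRNA_IDENTITY_THRESHOLD = 0.90

ASSIGNMENT_COLUMNS = ("read", "sample", "community", "ref")

UNASSIGNED = "__unassigned__"


@dataclass
class GroupCountTable:
    """Homology-group x sample read counts with a sample -> community map."""

    counts: pd.DataFrame  # groups x samples, non-negative integers
    sample_community: dict[str, str]
    unassigned: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_community)
        if missing:
            raise ValueError(f"samples without a community label: {sorted(missing)}")

    @property
    def communities(self) -> list[str]:
        return sorted(set(self.sample_community.values()))

    def samples_of(self, community: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_community[s] == community]


def rrna_filter(assignments: pd.DataFrame) -> pd.DataFrame:
    """Drop reads matching an rRNA reference at >= 90% coverage AND identity.

    ``assignments`` must carry ``rrna_coverage`` and ``rrna_identity``
    columns (best alignment against the rRNA database; NaN when the read
    hit nothing). Thresholds are inclusive.
    """
    for col in ("rrna_coverage", "rrna_identity"):
        if col not in assignments.columns:
            raise ValueError(f"assignments table lacks required column {col!r}")
    cov = assignments["rrna_coverage"].astype(float)
    ident = assignments["rrna_identity"].astype(float)
    for name, series in (("coverage", cov), ("identity", ident)):
        vals = series.dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"rrna_{name} values must lie in [0, 1]")
    is_rrna = (cov >= RRNA_COVERAGE_THRESHOLD) & (ident >= RRNA_IDENTITY_THRESHOLD)
    return assignments.loc[~is_rrna.fillna(False)].copy()


def build_homology_groups(
    similarity: nx.Graph | Sequence[tuple[Hashable, Hashable, float]],
    inflation: float = 3.6,
) -> Clustering:
    """Cluster best-hit reference sequences into homology groups (MCL)."""
    if not isinstance(similarity, nx.Graph):
        from .graph_clustering import graph_from_edges

        similarity = graph_from_edges(similarity)
    return mcl_cluster(similarity, MclParams(inflation=inflation))


def aggregate_counts(
    assignments: pd.DataFrame,
    groups: Clustering | Mapping[Hashable, Iterable[Hashable]],
) -> GroupCountTable:
    """Sum reads per homology group and sample via best-hit membership.

    Reads whose best hit falls outside every group are tallied into an
    ``unassigned`` bucket (reported, never silently lost), so that
    assigned + unassigned equals the number of retained reads.
    """
    for col in ASSIGNMENT_COLUMNS:
        if col not in assignments.columns:
            raise ValueError(f"assignments table lacks required column {col!r}")
    if isinstance(groups, Clustering):
        ref_to_group: dict[Hashable, str] = {}
        for gi, cluster in enumerate(groups):
            for ref in cluster:
                ref_to_group[ref] = f"G{gi:05d}"
    else:
        ref_to_group = {}
        for gname, refs in groups.items():
            for ref in refs:
                if ref in ref_to_group:
                    raise ValueError(f"reference {ref!r} in more than one group")
                ref_to_group[ref] = str(gname)

    samples = sorted(assignments["sample"].unique())
    community = (
        assignments[["sample", "community"]].drop_duplicates().set_index("sample")
    )
    if community.index.duplicated().any():
        raise ValueError("a sample maps to more than one community")
    group_ids = sorted(set(ref_to_group.values()))
    counts = pd.DataFrame(0, index=group_ids, columns=samples, dtype=int)
    unassigned = pd.Series(0, index=samples, dtype=int)
    grouped = assignments.groupby(["sample", "ref"]).size()
    for (sample, ref), n in grouped.items():
        g = ref_to_group.get(ref)
        if g is None:
            unassigned[sample] += n
        else:
            counts.loc[g, sample] += n
    return GroupCountTable(
        counts=counts,
        sample_community=community["community"].to_dict(),
        unassigned=unassigned,
    )


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalisation across samples (columns).

    Each rank's value is replaced by the cross-sample mean of the values
    at that rank; tied values within a sample receive the mean of the
    reference values over their tied rank range. Afterwards every
    sample's sorted value vector is identical.
    """
    if table.shape[1] < 2:
        warnings.warn("quantile normalisation needs >= 2 samples; returning input")
        return table.astype(float).copy()
    values = table.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        ref_for_col = np.empty_like(reference)
        # walk runs of equal values; each run gets the mean reference value
        start = 0
        while start < len(sorted_col):
            end = start
            while end + 1 < len(sorted_col) and sorted_col[end + 1] == sorted_col[start]:
                end += 1
            ref_for_col[start : end + 1] = reference[start : end + 1].mean()
            start = end + 1
        out[order, j] = ref_for_col
    return pd.DataFrame(out, index=table.index, columns=table.columns)


@dataclass
class DifferentialResult:
    """Per-group differential-expression calls between the two communities."""

    table: pd.DataFrame  # group, log2fc, p, q, de, direction
    method: str
    fdr_threshold: float

    @property
    def de_groups(self) -> set[str]:
        return set(self.table.loc[self.table["de"], "group"])


def size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (robust to a minority of DE groups).

    Each sample's factor is the median, over groups observed in every
    sample, of its count divided by the group's geometric mean. Falls
    back to library-size ratios when no group is shared by all samples.
    """
    with np.errstate(divide="ignore"):
        logg = np.log(raw.where(raw > 0))
    ref = logg.mean(axis=1)
    ok = np.isfinite(ref)
    if ok.sum() == 0:
        libs = raw.sum(axis=0).astype(float)
        return libs / np.exp(np.log(libs).mean())
    sf = np.exp(logg.loc[ok].sub(ref[ok], axis=0).median(axis=0))
    return sf


def _moderated_ttest(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Empirical-Bayes moderated two-sample t-test (per row).

    The pooled within-group variance of each row is shrunk towards a
    common prior estimated by moment-matching the marginal scaled-F
    distribution of the sample variances; the t statistic uses the
    posterior variance with augmented degrees of freedom.
    """
    na, nb = a.shape[1], b.shape[1]
    dg = na + nb - 2
    diff = b.mean(axis=1) - a.mean(axis=1)
    s2 = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / dg
    positive = s2 > 0
    if positive.sum() < 2:
        res = stats.ttest_ind(a, b, axis=1, equal_var=True)
        pvals = np.asarray(res.pvalue, dtype=float)
        bad = ~np.isfinite(pvals)
        pvals[bad] = np.where(np.isclose(diff[bad], 0), 1.0, 0.0)
        return pvals
    z = np.log(s2[positive])
    mean_z, var_z = z.mean(), z.var(ddof=1)
    excess = var_z - special.polygamma(1, dg / 2)
    if excess <= 0:
        d0 = np.inf
    else:
        d0 = optimize.brentq(
            lambda d: special.polygamma(1, d / 2) - excess, 1e-3, 1e9
        )
    if np.isinf(d0):
        s0_sq = np.exp(mean_z - special.digamma(dg / 2) + np.log(dg / 2))
        s2_post = np.full_like(s2, s0_sq)
        df = np.inf
    else:
        s0_sq = np.exp(
            mean_z
            - special.digamma(dg / 2)
            + np.log(dg / 2)
            + special.digamma(d0 / 2)
            - np.log(d0 / 2)
        )
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df = d0 + dg
    t = diff / np.sqrt(s2_post * (1 / na + 1 / nb))
    if np.isinf(df):
        return 2 * stats.norm.sf(np.abs(t))
    return 2 * stats.t.sf(np.abs(t), df)


def call_differential(
    table: GroupCountTable,
    fdr_threshold: float = 0.05,
    method: str = "auto",
    pseudocount: float = 1.0,
) -> DifferentialResult:
    """Call differentially expressed homology groups between two communities.

    method
        "moderated_t": empirical-Bayes moderated t-test on
        log2(size-factor-scaled count + pseudocount) across replicate
        samples, with median-of-ratios size factors. The default whenever
        both communities have >= 2 samples: honest under biological
        overdispersion and robust to composition shifts from strongly
        expressed groups.
        "binomial": exact two-sided rate test on summed community counts
        conditioned on totals (binomial form); the fallback when a
        community has a single sample (assumes Poisson sampling only).
        "auto": pick between the two on replicate availability.

    Groups with zero counts in both communities are excluded from
    testing. Benjamini-Hochberg correction across tested groups; DE iff
    q <= fdr_threshold. Direction is the community with the higher
    scaled mean.
    """
    comms = table.communities
    if len(comms) != 2:
        raise ValueError(f"expected exactly 2 communities, found {comms}")
    ca, cb = comms
    sa, sb = table.samples_of(ca), table.samples_of(cb)
    if not sa or not sb:
        raise ValueError("each community needs at least one sample")
    if method == "auto":
        method = "moderated_t" if (len(sa) >= 2 and len(sb) >= 2) else "binomial"
    if method == "moderated_t" and (len(sa) < 2 or len(sb) < 2):
        raise ValueError("the moderated t-test requires >= 2 samples per community")
    if method not in ("moderated_t", "binomial"):
        raise ValueError(f"unknown method {method!r}")

    raw = table.counts
    tested = raw.index[(raw[sa].sum(axis=1) + raw[sb].sum(axis=1)) > 0]
    scaled = raw / size_factors(raw)
    log_scaled = np.log2(scaled + pseudocount)
    log2fc = (
        log_scaled.loc[tested, sa].mean(axis=1)
        - log_scaled.loc[tested, sb].mean(axis=1)
    )

    if method == "moderated_t":
        a = log_scaled.loc[tested, sa].to_numpy()
        b = log_scaled.loc[tested, sb].to_numpy()
        pvals = _moderated_ttest(a, b)
    else:
        xa = raw.loc[tested, sa].sum(axis=1).to_numpy()
        xb = raw.loc[tested, sb].sum(axis=1).to_numpy()
        ta, tb = raw[sa].values.sum(), raw[sb].values.sum()
        p0 = ta / (ta + tb)
        pvals = np.array(
            [
                stats.binomtest(int(x1), int(x1 + x2), p0).pvalue
                for x1, x2 in zip(xa, xb)
            ]
        )

    rejected, qvals, _, _ = multipletests(pvals, alpha=fdr_threshold, method="fdr_bh")
    de = qvals <= fdr_threshold
    out = pd.DataFrame(
        {
            "group": tested,
            "log2fc": log2fc.to_numpy(),
            "p": pvals,
            "q": qvals,
            "de": de,
            "direction": np.where(log2fc.to_numpy() >= 0, ca, cb),
        }
    ).reset_index(drop=True)
    return DifferentialResult(table=out, method=method, fdr_threshold=fdr_threshold)


def injected_differential(
    de_groups: Iterable[str],
    table: GroupCountTable | None = None,
    fdr_threshold: float = 0.05,
) -> DifferentialResult:
    """Wrap an externally produced DE list (e.g. from a dedicated caller)
    so the downstream enrichment stage can consume it unchanged."""
    groups = sorted(set(de_groups))
    out = pd.DataFrame(
        {
            "group": groups,
            "log2fc": np.nan,
            "p": np.nan,
            "q": np.nan,
            "de": True,
            "direction": "",
        }
    )
    return DifferentialResult(table=out, method="injected", fdr_threshold=fdr_threshold)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if k > min(K, n):
        raise ValueError("k cannot exceed min(K, n)")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def domain_enrichment(
    de_groups: Iterable[str],
    group_domains: Mapping[str, Iterable[str]],
    fdr_threshold: float = 0.05,
    universe: str = "annotated",
    all_groups: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of domains among differentially expressed groups.

    For each domain present in >= 1 DE group: N = groups in the universe,
    K = universe groups carrying the domain, n = DE groups in the
    universe, k = DE groups carrying the domain; p is the upper
    hypergeometric tail and q the BH-adjusted value. ``universe`` is
    "annotated" (groups with >= 1 domain; the default, since unannotated
    groups are uninformative for a domain test) or "all" (requires
    ``all_groups``).
    """
    de_set = set(de_groups)
    annotated = {g: set(d) for g, d in group_domains.items() if d}
    if universe == "annotated":
        universe_groups = set(annotated)
    elif universe == "all":
        if all_groups is None:
            raise ValueError("universe='all' requires all_groups")
        universe_groups = set(all_groups)
        if not set(annotated) <= universe_groups:
            raise ValueError("annotated groups missing from all_groups")
    else:
        raise ValueError("universe must be 'annotated' or 'all'")

    N = len(universe_groups)
    de_universe = de_set & universe_groups
    n = len(de_universe)
    domain_K: dict[str, int] = {}
    domain_k: dict[str, int] = {}
    for g in universe_groups:
        for d in annotated.get(g, ()):
            domain_K[d] = domain_K.get(d, 0) + 1
            if g in de_universe:
                domain_k[d] = domain_k.get(d, 0) + 1

    tested = sorted(domain_k)  # domains present in >= 1 DE group
    rows = []
    for d in tested:
        K, k = domain_K[d], domain_k[d]
        if k > K or n > N:
            raise ValueError("inconsistent enrichment counts")
        rows.append((d, N, K, n, k, hypergeom_upper_tail(N, K, n, k)))
    df = pd.DataFrame(rows, columns=["domain", "N", "K", "n", "k", "p"])
    if len(df):
        _, qvals, _, _ = multipletests(df["p"], alpha=fdr_threshold, method="fdr_bh")
        df["q"] = qvals
    else:
        df["q"] = pd.Series(dtype=float)
    df["enriched"] = df["q"] <= fdr_threshold
    return df.sort_values(["q", "p", "domain"]).reset_index(drop=True)


def log2_heatmap_matrix(
    normalised: pd.DataFrame,
    enrichment: pd.DataFrame,
    group_domains: Mapping[str, Iterable[str]],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(normalised count + pseudocount) for groups carrying enriched
    domains, indexed (domain, group) so rows come grouped by domain."""
    enriched = list(enrichment.loc[enrichment["enriched"], "domain"])
    rows = []
    index = []
    for d in enriched:
        for g in sorted(group_domains):
            if d in set(group_domains[g]) and g in normalised.index:
                rows.append(np.log2(normalised.loc[g] + pseudocount))
                index.append((d, g))
    if not rows:
        return pd.DataFrame(
            columns=normalised.columns,
            index=pd.MultiIndex.from_tuples([], names=["domain", "group"]),
        )
    out = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["domain", "group"]))
    return out
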