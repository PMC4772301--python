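"""SRCR-like domain family analysis.

Scavenger Receptor Cysteine-Rich (SRCR)-like domains are pattern-
recognition modules whose family members are highly variable in sequence
except for a scaffold of conserved cysteines. This module runs the
family-level analysis: exact Smith-Waterman all-vs-all alignment, a
positive-scoring-fraction homology criterion, MCL clustering on bit
scores, per-cluster progressive (center-star) multiple alignment,
per-column residue-frequency / cysteine-conservation profiles, and
lineage-specific expansion tables.

Alignment scoring is BLOSUM62 with affine gaps (open 11, extend 1, so a
gap of length L costs 11 + L); X scores 0 against everything. Raw scores
are rescaled to bit scores with the standard gapped Karlin-Altschul
constants lambda = 0.267, K = 0.041.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .graph_clustering import Clustering, MclParams, mcl_cluster
from .io_formats import AA_ALPHABET

KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@lru_cache(maxsize=None)
def blosum62_x0() -> substitution_matrices.Array:
    """BLOSUM62 with the ambiguity residue X scoring 0 against everything."""
    m = substitution_matrices.load("BLOSUM62").copy()
    for a in m.alphabet:
        m["X", a] = 0.0
        m[a, "X"] = 0.0
    return m


def _aligner(mode: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = blosum62_x0()
    aligner.mode = mode
    # Biopython charges open+extend for the first gap position; the
    # open + L*extend convention used here folds the first extension in.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def bit_score(raw_score: float) -> float:
    """Karlin-Altschul bit score of a raw alignment score."""
    return (KARLIN_LAMBDA * raw_score - math.log(KARLIN_K)) / math.log(2)


@dataclass
class AlignmentResult:
    """Optimal local alignment between two domain sequences."""

    query_id: str
    subject_id: str
    score: float
    aligned_pairs: list[tuple[int, int]]
    n_positive: int
    n_identical: int

    @property
    def bit_score(self) -> float:
        return bit_score(self.score)

    @property
    def n_aligned_columns(self) -> int:
        return len(self.aligned_pairs)

    @property
    def positives_fraction(self) -> float:
        """Positive-scoring aligned pairs over aligned residue-residue
        columns (gap columns excluded); 0 for an empty alignment."""
        if not self.aligned_pairs:
            return 0.0
        return self.n_positive / len(self.aligned_pairs)

    @property
    def identity_fraction(self) -> float:
        if not self.aligned_pairs:
            return 0.0
        return self.n_identical / len(self.aligned_pairs)


def _check_seq(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"empty sequence {name!r}")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"sequence {name!r} has invalid residues {sorted(bad)}")


def local_align(
    seq1: str,
    seq2: str,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Exact Smith-Waterman local alignment with affine gaps.

    Returns the optimal score and the first optimal traceback (the
    aligner's canonical deterministic order). A best score of 0 is
    reported as an empty alignment.
    """
    _check_seq(seq1, query_id)
    _check_seq(seq2, subject_id)
    aligner = _aligner("local", gap_open, gap_extend)
    alignments = aligner.align(seq1, seq2)
    score = float(alignments.score)
    pairs: list[tuple[int, int]] = []
    n_pos = n_id = 0
    if score > 0 and len(alignments) > 0:
        m = blosum62_x0()
        blocks = alignments[0].aligned
        for (qs, qe), (ss, se) in zip(blocks[0], blocks[1]):
            for di in range(qe - qs):
                a, b = seq1[qs + di], seq2[ss + di]
                pairs.append((qs + di, ss + di))
                if m[a, b] > 0:
                    n_pos += 1
                if a == b:
                    n_id += 1
    else:
        score = max(score, 0.0)
    return AlignmentResult(query_id, subject_id, score, pairs, n_pos, n_id)


def global_align(
    seq1: str,
    seq2: str,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> tuple[float, str, str]:
    """Needleman-Wunsch global alignment; returns (score, row1, row2)."""
    _check_seq(seq1, "seq1")
    _check_seq(seq2, "seq2")
    aligner = _aligner("global", gap_open, gap_extend)
    alignments = aligner.align(seq1, seq2)
    aln = alignments[0]
    return float(alignments.score), str(aln[0]), str(aln[1])


def homology_graph(
    seqs: Mapping[str, str],
    positives_threshold: float = 0.90,
    denominator: str = "shorter",
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> nx.Graph:
    """All-vs-all local alignment; edges where the positive-scoring
    fraction reaches the homology threshold, weighted by bit score.

    ``denominator`` selects what the positive count is divided by:
    "shorter" (length of the shorter sequence; the default, so that 90%
    of the shorter domain must be positive-scoring — an alignment-length
    denominator would let any shared high-scoring tripeptide qualify as
    homology) or "aligned" (aligned residue-residue columns, the Blastp
    "Positives" convention).
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if denominator not in ("aligned", "shorter"):
        raise ValueError("denominator must be 'aligned' or 'shorter'")
    g = nx.Graph()
    g.add_nodes_from(seqs)
    ids = sorted(seqs)
    for i, j in combinations(ids, 2):
        res = local_align(
            seqs[i], seqs[j], gap_open, gap_extend, query_id=i, subject_id=j
        )
        if res.score <= 0:
            continue
        if denominator == "aligned":
            frac = res.positives_fraction
        else:
            frac = res.n_positive / min(len(seqs[i]), len(seqs[j]))
        if frac >= positives_threshold:
            g.add_edge(i, j, weight=res.bit_score, positives=frac)
    return g


def default_species_parser(member_id: str) -> str:
    """Species label from the ``species|protein|domain|index`` id convention."""
    return member_id.split("|")[0]


@dataclass
class DomainCluster:
    cluster_id: int
    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DomainClusterSet:
    """Size-filtered MCL clusters of domain sequences.

    ``clusters`` hold the retained clusters ranked by size (descending,
    ties by smallest member id); ``small_clusters`` keep everything below
    the size threshold so nothing is silently dropped.
    """

    clusters: list[DomainCluster]
    small_clusters: list[tuple[str, ...]]
    species_of: Callable[[str], str] = default_species_parser

    def all_partition(self) -> Clustering:
        parts = [c.members for c in self.clusters] + list(self.small_clusters)
        return Clustering(clusters=[tuple(p) for p in parts])


def cluster_srcr(
    seqs: Mapping[str, str],
    mcl_params: MclParams | None = None,
    min_cluster_size: int = 5,
    positives_threshold: float = 0.90,
    denominator: str = "shorter",
    species_of: Callable[[str], str] = default_species_parser,
) -> DomainClusterSet:
    """Cluster domain sequences into families.

    Builds the 90%-positives homology graph (bit-score weighted), runs
    MCL, retains clusters with >= ``min_cluster_size`` members ranked by
    size, and reports smaller clusters separately.
    """
    if mcl_params is None:
        mcl_params = MclParams(inflation=2.0)
    graph = homology_graph(seqs, positives_threshold, denominator)
    clustering = mcl_cluster(graph, mcl_params)
    retained = [c for c in clustering if len(c) >= min_cluster_size]
    small = [c for c in clustering if len(c) < min_cluster_size]
    clusters = [
        DomainCluster(cluster_id=rank, members=tuple(c))
        for rank, c in enumerate(retained)
    ]
    return DomainClusterSet(clusters=clusters, small_clusters=small, species_of=species_of)


def _merge_into_msa(
    master_center: list[str],
    rows: dict[str, list[str]],
    center_aln: str,
    member_id: str,
    member_aln: str,
) -> list[str]:
    """Merge a new center/member pairwise alignment into the growing MSA.

    Follows "once a gap, always a gap": gap columns already in the master
    center are kept; new member-insertion columns are added to every row.
    Returns the updated master center row.
    """
    new_master: list[str] = []
    new_rows: dict[str, list[str]] = {rid: [] for rid in rows}
    member_row: list[str] = []
    i = j = 0
    while i < len(master_center) or j < len(center_aln):
        mi = master_center[i] if i < len(master_center) else None
        cj = center_aln[j] if j < len(center_aln) else None
        if mi == GAP:
            new_master.append(GAP)
            for rid in rows:
                new_rows[rid].append(rows[rid][i])
            member_row.append(GAP)
            i += 1
        elif cj == GAP:
            new_master.append(GAP)
            for rid in rows:
                new_rows[rid].append(GAP)
            member_row.append(member_aln[j])
            j += 1
        else:
            # both consume the same center residue
            new_master.append(mi)  # type: ignore[arg-type]
            for rid in rows:
                new_rows[rid].append(rows[rid][i])
            member_row.append(member_aln[j])
            i += 1
            j += 1
    for rid in rows:
        rows[rid] = new_rows[rid]
    rows[member_id] = member_row
    return new_master


def progressive_msa(
    seqs: Mapping[str, str],
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> dict[str, str]:
    """Center-star progressive multiple alignment.

    The center is the member with the maximal summed pairwise global
    score (ties: smallest id); every other member is aligned to the
    center pairwise and gaps are merged ("once a gap, always a gap").
    A single-member input is returned as-is.
    """
    ids = sorted(seqs)
    if not ids:
        raise ValueError("no sequences to align")
    if len(ids) == 1:
        return {ids[0]: seqs[ids[0]]}

    scores = {i: 0.0 for i in ids}
    pair_rows: dict[tuple[str, str], tuple[str, str]] = {}
    for i, j in combinations(ids, 2):
        s, r1, r2 = global_align(seqs[i], seqs[j], gap_open, gap_extend)
        scores[i] += s
        scores[j] += s
        pair_rows[(i, j)] = (r1, r2)

    # deterministic center choice: highest summed score, then smallest id
    best = max(scores.values())
    center = min(i for i in ids if scores[i] == best)

    master_center = list(seqs[center])
    rows: dict[str, list[str]] = {}
    for member in ids:
        if member == center:
            continue
        key = (center, member) if (center, member) in pair_rows else (member, center)
        r1, r2 = pair_rows[key]
        center_aln, member_aln = (r1, r2) if key[0] == center else (r2, r1)
        master_center = _merge_into_msa(master_center, rows, center_aln, member, member_aln)

    out = {center: "".join(master_center)}
    for rid, row in rows.items():
        out[rid] = "".join(row)
    lengths = {len(v) for v in out.values()}
    assert len(lengths) == 1, "MSA rows have unequal lengths"
    return {i: out[i] for i in ids}


@dataclass
class ClusterProfile:
    """Per-column residue-frequency profile of an aligned cluster."""

    cluster_id: int
    members: tuple[str, ...]
    alignment: dict[str, str]
    frequencies: pd.DataFrame  # symbols (20 aa + X + gap) x columns
    conservation: np.ndarray  # max residue frequency per column (gap excluded)
    cysteine_conservation: np.ndarray  # frequency of C per column
    species_composition: dict[str, int]


def conservation_profile(
    alignment: Mapping[str, str],
    cluster_id: int = 0,
    species_of: Callable[[str], str] = default_species_parser,
) -> ClusterProfile:
    """Residue frequencies, conservation and cysteine conservation per column.

    Frequencies (including the gap symbol) sum to 1 in every column;
    conservation is the maximum amino-acid frequency.
    """
    rows = list(alignment.values())
    if not rows:
        raise ValueError("empty alignment")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    symbols = list(AA20) + ["X", GAP]
    sym_index = {s: k for k, s in enumerate(symbols)}
    freq = np.zeros((len(symbols), length))
    for row in rows:
        for col, ch in enumerate(row):
            freq[sym_index[ch], col] += 1
    freq /= len(rows)
    fdf = pd.DataFrame(freq, index=symbols, columns=range(length))
    conservation = freq[:-1].max(axis=0)  # gap excluded
    cys = freq[sym_index["C"]]
    comp: dict[str, int] = {}
    for rid in alignment:
        sp = species_of(rid)
        comp[sp] = comp.get(sp, 0) + 1
    return ClusterProfile(
        cluster_id=cluster_id,
        members=tuple(alignment),
        alignment=dict(alignment),
        frequencies=fdf,
        conservation=conservation,
        cysteine_conservation=cys,
        species_composition=comp,
    )


def profile_clusters(
    cluster_set: DomainClusterSet,
    seqs: Mapping[str, str],
) -> list[ClusterProfile]:
    """Align each retained cluster and compute its conservation profile."""
    profiles = []
    for cluster in cluster_set.clusters:
        aln = progressive_msa({m: seqs[m] for m in cluster.members})
        profiles.append(
            conservation_profile(aln, cluster.cluster_id, cluster_set.species_of)
        )
    return profiles


def lineage_expansion(
    cluster_set: DomainClusterSet,
    species_order: Sequence[str] | None = None,
    dominance_threshold: float = 0.5,
) -> pd.DataFrame:
    """Cluster x species member-count table with a dominant-species flag.

    A species is flagged dominant when its share of the cluster strictly
    exceeds ``dominance_threshold`` (an even split has no dominant
    lineage).
    """
    rows = []
    all_species: list[str] = list(species_order) if species_order else []
    counts_per_cluster = []
    for cluster in cluster_set.clusters:
        counts: dict[str, int] = {}
        for m in cluster.members:
            sp = cluster_set.species_of(m)
            counts[sp] = counts.get(sp, 0) + 1
            if sp not in all_species:
                all_species.append(sp)
        counts_per_cluster.append(counts)
    for cluster, counts in zip(cluster_set.clusters, counts_per_cluster):
        total = len(cluster)
        dominant = ""
        for sp, c in sorted(counts.items()):
            if c / total > dominance_threshold:
                dominant = sp
        row = {sp: counts.get(sp, 0) for sp in all_species}
        row["cluster"] = cluster.cluster_id
        row["size"] = total
        row["dominant"] = dominant
        rows.append(row)
    cols = ["cluster", "size"] + list(all_species) + ["dominant"]
    return pd.DataFrame(rows, columns=cols)
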