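"""Pairwise ANI estimation and dereplication into species clusters.

Species are conventionally delimited at >95 % average nucleotide identity
(ANI).  Two routes are supported:

* external ANI tables (three-column TSV: query, reference, ANI — the first
  three columns of FastANI output) consumed verbatim, with asymmetric pairs
  averaged and self-pairs forced to 100; and
* a built-in Mash-style MinHash estimator (canonical k-mers, bottom sketch,
  fixed hash seed) for fully offline work: with bottom-sketch Jaccard
  similarity j, the Mash distance is d = -ln(2j/(1+j))/k and ANI = 100(1-d).

Clustering is single linkage: species clusters are the connected components
of the graph whose edges join genome pairs with ANI strictly above the
threshold.  A cluster representative is the member maximizing the
completeness - 5x contamination quality score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .assembly import AssemblyRecord
from .qc import QualityMetrics

__all__ = [
    "AniMatrix",
    "SpeciesCluster",
    "estimate_ani",
    "minhash_sketch",
    "ani_matrix_from_assemblies",
    "read_ani_table",
    "cluster_by_ani",
    "select_representative",
    "dereplicate",
    "DEFAULT_K",
    "DEFAULT_SKETCH_SIZE",
    "SPECIES_ANI_THRESHOLD",
]

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 5000
#: Conventional species-delimitation threshold (percent identity).
SPECIES_ANI_THRESHOLD = 95.0

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _BASE_CODE[b] = i
    _BASE_CODE[b + 32] = i  # lowercase


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer; a fixed, high-quality 64-bit mix."""
    x = x.astype(np.uint64, copy=True)
    x += np.uint64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer integers (2-bit packed) for one sequence; windows
    containing ambiguous bases are dropped."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[raw]
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
    win_ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    with np.errstate(over="ignore"):
        fwd = win @ powers
        rev = (np.uint64(3) - win) @ powers[::-1]
    return np.minimum(fwd, rev)[win_ok]


def minhash_sketch(
    assembly: AssemblyRecord, k: int = DEFAULT_K, sketch_size: int = DEFAULT_SKETCH_SIZE
) -> np.ndarray:
    """Bottom sketch: the ``sketch_size`` smallest distinct hashes over the
    canonical k-mers of every contig.  Deterministic (fixed hash)."""
    if assembly.total_length < 10 * k:
        raise ValueError(
            f"assembly too short for ANI estimation: {assembly.total_length} bp "
            f"< {10 * k} bp"
        )
    parts = [_kmer_codes(seq, k) for _, seq in assembly.contigs]
    kmers = np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)
    if kmers.size == 0:
        raise ValueError("no unambiguous k-mers in assembly")
    hashes = np.unique(_splitmix64(kmers))
    return hashes[:sketch_size]


def _mash_ani(sketch_a: np.ndarray, sketch_b: np.ndarray, k: int, s: int) -> Optional[float]:
    # bottom-s of the union; Jaccard estimated as the fraction also shared
    union = np.union1d(sketch_a, sketch_b)[:s]
    shared = np.intersect1d(sketch_a, sketch_b, assume_unique=True)
    n_shared = int(np.isin(union, shared, assume_unique=True).sum())
    if n_shared == 0:
        return None
    j = n_shared / union.size
    d = -math.log(2.0 * j / (1.0 + j)) / k
    return float(min(100.0, max(0.0, 100.0 * (1.0 - d))))


def estimate_ani(
    a: AssemblyRecord,
    b: AssemblyRecord,
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
) -> Optional[float]:
    """MinHash ANI estimate between two assemblies, in percent.

    Returns ``None`` (no estimate) when the sketches share no hashes, as for
    unrelated genomes.  Both assemblies must be at least 10·k bases long.
    The estimate of a genome against itself is exactly 100.
    """
    sa = minhash_sketch(a, k, sketch_size)
    sb = minhash_sketch(b, k, sketch_size)
    return _mash_ani(sa, sb, k, sketch_size)


@dataclass(frozen=True)
class AniMatrix:
    """Symmetric matrix of pairwise ANI percentages; NaN marks pairs without
    an estimate (unalignable / no shared sketch)."""

    genome_ids: tuple[str, ...]
    values: np.ndarray  # float, shape (n, n)

    def __post_init__(self) -> None:
        n = len(self.genome_ids)
        if self.values.shape != (n, n):
            raise ValueError("ANI matrix shape does not match genome ids")
        if len(set(self.genome_ids)) != n:
            raise ValueError("duplicate genome ids")
        with np.errstate(invalid="ignore"):
            if not np.all(np.diag(self.values) == 100.0):
                raise ValueError("ANI matrix diagonal must be 100")
            finite = ~np.isnan(self.values)
            if not np.array_equal(finite, finite.T) or not np.allclose(
                np.nan_to_num(self.values), np.nan_to_num(self.values.T)
            ):
                raise ValueError("ANI matrix must be symmetric")

    def get(self, a: str, b: str) -> Optional[float]:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        v = self.values[i, j]
        return None if np.isnan(v) else float(v)


def ani_matrix_from_assemblies(
    assemblies: Mapping[str, AssemblyRecord],
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
) -> AniMatrix:
    """All-vs-all MinHash ANI over a set of assemblies (sketch once each)."""
    ids = tuple(assemblies.keys())
    sketches = {g: minhash_sketch(assemblies[g], k, sketch_size) for g in ids}
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ani = _mash_ani(sketches[ids[i]], sketches[ids[j]], k, sketch_size)
            values[i, j] = values[j, i] = np.nan if ani is None else ani
    return AniMatrix(genome_ids=ids, values=values)


def read_ani_table(path: Union[str, Path]) -> AniMatrix:
    """Read a pairwise ANI table (TSV: query, reference, ANI; header
    optional, extra columns ignored — FastANI's layout).

    Asymmetric pairs are averaged; self-pairs are forced to 100; missing
    pairs stay absent.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    first = str(df.iloc[0, 2])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    df = df.iloc[:, :3]
    df.columns = ["query", "reference", "ani"]
    df["ani"] = df["ani"].astype(float)
    ids = tuple(dict.fromkeys(list(df["query"].astype(str)) + list(df["reference"].astype(str))))
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n))
    sums = np.zeros((n, n))
    for _, row in df.iterrows():
        i, j = index[str(row["query"])], index[str(row["reference"])]
        if i == j:
            continue
        sums[i, j] += row["ani"]
        counts[i, j] += 1
    for i in range(n):
        for j in range(i + 1, n):
            c = counts[i, j] + counts[j, i]
            if c:
                values[i, j] = values[j, i] = (sums[i, j] + sums[j, i]) / c
    np.fill_diagonal(values, 100.0)
    return AniMatrix(genome_ids=ids, values=values)


@dataclass(frozen=True)
class SpeciesCluster:
    members: tuple[str, ...]
    representative: str

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a cluster member")


def cluster_by_ani(
    matrix: AniMatrix, threshold: float = SPECIES_ANI_THRESHOLD
) -> list[SpeciesCluster]:
    """Single-linkage species clusters: connected components of the graph
    with edges where ANI > threshold.  Members are ordered by input id order;
    clusters by their first member.  The provisional representative is the
    first member (reassign with :func:`select_representative`)."""
    if not 0.0 < threshold <= 100.0:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    g = nx.Graph()
    g.add_nodes_from(matrix.genome_ids)
    n = len(matrix.genome_ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.values[i, j]
            if not np.isnan(v) and v > threshold:
                g.add_edge(matrix.genome_ids[i], matrix.genome_ids[j])
    order = {gid: i for i, gid in enumerate(matrix.genome_ids)}
    clusters = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp, key=order.__getitem__))
        clusters.append(SpeciesCluster(members=members, representative=members[0]))
    return sorted(clusters, key=lambda c: order[c.members[0]])


def select_representative(
    cluster: SpeciesCluster, quality_by_id: Mapping[str, QualityMetrics]
) -> str:
    """Pick the member maximizing completeness - 5x contamination (the usual
    dereplication quality score); ties break by ascending id."""
    missing = [m for m in cluster.members if m not in quality_by_id]
    if missing:
        raise KeyError(f"missing quality metrics for {missing}")

    def score(member: str) -> float:
        q = quality_by_id[member]
        comp = q.completeness_pct if q.completeness_pct is not None else 0.0
        cont = q.contamination_pct if q.contamination_pct is not None else 0.0
        return comp - 5.0 * cont

    return min(cluster.members, key=lambda m: (-score(m), m))


def dereplicate(
    matrix: AniMatrix,
    threshold: float = SPECIES_ANI_THRESHOLD,
    quality_by_id: Optional[Mapping[str, QualityMetrics]] = None,
) -> list[SpeciesCluster]:
    """Cluster and, when quality metrics are supplied, choose the best-scored
    member of each cluster as its representative."""
    clusters = cluster_by_ani(matrix, threshold)
    if quality_by_id is None:
        return clusters
    return [
        SpeciesCluster(members=c.members,
                       representative=select_representative(c, quality_by_id))
        for c in clusters
    ]
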