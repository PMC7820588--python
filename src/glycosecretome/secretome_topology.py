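"""Signed-vector secretome topology: distances, heterogeneity, overlaps, networks.

Each (dataset x subcellular category) group is encoded as a signed vector
over the union of glycoforms significant in at least one dataset: +1 for a
glycoform up-regulated in that dataset whose protein belongs to the
category, -1 for down-regulated, 0 otherwise.  Pairwise Euclidean distances
between these vectors quantify how convergent or divergent the regulation
of each compartment is across genotypes, sexes and brain regions; upset
pattern counts and overlap percentages summarise dataset concordance, and
glycan-protein edge tables expose the heterogeneity of glycosylation per
site and per protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from glycosecretome.differential_stats import DifferentialRecord

__all__ = [
    "SignedGroupVector",
    "build_signed_vectors",
    "euclidean_distance_matrix",
    "glycans_per_site",
    "sites_per_protein",
    "intersect_datasets",
    "overlap_fraction",
    "glycan_protein_network",
    "network_graph",
]

GlycoformKey = tuple  # (protein_id, site, composition)


@dataclass(frozen=True)
class SignedGroupVector:
    """A +/-1/0 regulation vector for one (dataset, category) group."""

    dataset: str
    category: str
    dims: tuple
    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int8)
        object.__setattr__(self, "entries", entries)
        if len(entries) != len(self.dims):
            raise ValueError("entries and dims must have equal length")
        if not np.isin(entries, (-1, 0, 1)).all():
            raise ValueError("entries must be -1, 0 or +1")

    @property
    def label(self) -> str:
        return f"{self.dataset}|{self.category}"


def _protein_of(feature: object) -> object:
    return feature[0] if isinstance(feature, tuple) else feature


def build_signed_vectors(
    diff: Mapping[str, Sequence[DifferentialRecord]],
    assignment: Mapping[str, Iterable[str]],
    categories: Sequence[str],
) -> list[SignedGroupVector]:
    """Build signed regulation vectors per (dataset x category).

    The dimension set is the sorted union of glycoform keys significant in
    at least one of the supplied datasets.  An entry is +1 (-1) when the
    glycoform is significantly up- (down-) regulated in the dataset AND
    its protein is assigned to the category, else 0.
    """
    from glycosecretome.subcellular_annotation import SUBCELLULAR_CATEGORIES

    bad = [c for c in categories if c not in SUBCELLULAR_CATEGORIES]
    if bad:
        raise ValueError(f"unknown category labels: {bad}")

    dims = sorted(
        {r.feature for records in diff.values() for r in records if r.significant},
        key=repr,
    )
    index = {key: i for i, key in enumerate(dims)}

    vectors = []
    for dataset, records in diff.items():
        signs = np.zeros(len(dims), dtype=np.int8)
        proteins = np.empty(len(dims), dtype=object)
        for record in records:
            if not record.significant:
                continue
            i = index[record.feature]
            signs[i] = 1 if record.direction == "up" else -1
            proteins[i] = _protein_of(record.feature)
        for category in categories:
            entries = np.zeros(len(dims), dtype=np.int8)
            for i in np.flatnonzero(signs):
                if category in assignment.get(proteins[i], ()):
                    entries[i] = signs[i]
            vectors.append(SignedGroupVector(dataset, category, tuple(dims), entries))
    return vectors


def euclidean_distance_matrix(vectors: Sequence[SignedGroupVector]) -> pd.DataFrame:
    """Pairwise Euclidean distance matrix over signed group vectors.

    All vectors must share identical dims.  Returns a symmetric, labelled
    square DataFrame with zero diagonal.
    """
    if not vectors:
        raise ValueError("need at least one vector")
    dims = vectors[0].dims
    for v in vectors[1:]:
        if v.dims != dims:
            raise ValueError(
                f"dimension mismatch between {vectors[0].label} and {v.label}"
            )
    labels = [v.label for v in vectors]
    matrix = np.stack([v.entries.astype(float) for v in vectors])
    if len(vectors) == 1:
        dist = np.zeros((1, 1))
    else:
        dist = squareform(pdist(matrix, metric="euclidean"))
    return pd.DataFrame(dist, index=labels, columns=labels)


def glycans_per_site(sig: pd.DataFrame) -> dict:
    """Distribution of distinct significant glycan compositions per glycosite.

    ``sig`` needs columns ``protein_id``, ``site`` and ``composition``.
    Returns per-site counts keyed by (protein, site), the number of sites
    carrying exactly one / more than one significant glycan, and the
    fraction of multi-glycan sites (0 when there are no sites).
    """
    counts: dict[tuple, set] = {}
    for row in sig.itertuples(index=False):
        counts.setdefault((row.protein_id, row.site), set()).add(row.composition)
    per_site = {key: len(comps) for key, comps in counts.items()}
    n_multi = sum(1 for n in per_site.values() if n > 1)
    n_sites = len(per_site)
    return {
        "per_site": per_site,
        "n_single": n_sites - n_multi,
        "n_multi": n_multi,
        "fraction_multi": (n_multi / n_sites) if n_sites else 0.0,
    }


def sites_per_protein(sig: pd.DataFrame) -> dict:
    """Distribution of distinct significant glycosites per protein.

    Analogous to :func:`glycans_per_site` but keyed by protein: sites are
    counted once regardless of how many glycans they carry.
    """
    counts: dict[object, set] = {}
    for row in sig.itertuples(index=False):
        counts.setdefault(row.protein_id, set()).add(row.site)
    per_protein = {protein: len(sites) for protein, sites in counts.items()}
    n_multi = sum(1 for n in per_protein.values() if n > 1)
    n_proteins = len(per_protein)
    return {
        "per_protein": per_protein,
        "n_single": n_proteins - n_multi,
        "n_multi": n_multi,
        "fraction_multi": (n_multi / n_proteins) if n_proteins else 0.0,
    }


def intersect_datasets(sig_sets: Mapping[str, Iterable[object]]) -> dict:
    """Exact-membership intersection pattern counts (upset semantics).

    For every non-empty subset S of dataset names, counts the ids whose
    membership pattern is exactly S.  Returns ``patterns`` mapping a
    frozenset of names to its count (all 2^k - 1 patterns, zeros
    included) and ``totals`` with per-set sizes.
    """
    names = list(sig_sets)
    if len(names) != len(set(names)):
        raise ValueError("duplicate dataset names")
    if len(names) < 2:
        raise ValueError("need at least 2 named sets")
    sets = {name: set(members) for name, members in sig_sets.items()}

    membership: dict[object, frozenset] = {}
    for name, members in sets.items():
        for item in members:
            membership[item] = membership.get(item, frozenset()) | {name}

    patterns = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in combinations(names, r)
    }
    for pattern in membership.values():
        patterns[pattern] += 1
    return {
        "patterns": patterns,
        "totals": {name: len(members) for name, members in sets.items()},
    }


def overlap_fraction(
    a: Iterable[object], b: Iterable[object], denominator: str = "union"
) -> float:
    """Percent overlap of two id sets: 100 * |a & b| / |denominator set|.

    ``denominator`` is one of ``union`` (default), ``min`` (the smaller
    set), ``a`` or ``b``.
    """
    a, b = set(a), set(b)
    if denominator == "union":
        denom = len(a | b)
    elif denominator == "min":
        denom = min(len(a), len(b))
    elif denominator == "a":
        denom = len(a)
    elif denominator == "b":
        denom = len(b)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("empty denominator set")
    return 100.0 * len(a & b) / denom


def glycan_protein_network(sig: pd.DataFrame) -> pd.DataFrame:
    """Edge table of the significant glycan-composition <-> protein network.

    One edge per distinct significant (composition, protein) pair; each
    edge carries the glycan type and the protein's number of significant
    glycosites (the grouping variable for network layout).  ``sig`` needs
    columns ``protein_id``, ``site``, ``composition`` and ``glycan_type``.
    """
    if sig.empty:
        return pd.DataFrame(
            columns=["composition", "protein_id", "glycan_type", "n_sig_sites"]
        )
    n_sites = sites_per_protein(sig)["per_protein"]
    edges = (
        sig[["composition", "protein_id", "glycan_type"]]
        .drop_duplicates(subset=["composition", "protein_id"])
        .reset_index(drop=True)
    )
    edges["n_sig_sites"] = edges["protein_id"].map(n_sites)
    return edges


def network_graph(edges: pd.DataFrame) -> nx.Graph:
    """Bipartite networkx graph built from a glycan-protein edge table."""
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_node(("glycan", row.composition), kind="glycan",
                       glycan_type=row.glycan_type)
        graph.add_node(("protein", row.protein_id), kind="protein",
                       n_sig_sites=row.n_sig_sites)
        graph.add_edge(("glycan", row.composition), ("protein", row.protein_id),
                       glycan_type=row.glycan_type)
    return graph
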