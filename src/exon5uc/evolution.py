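"""Cross-species counting and ortholog-sharing dendrograms.

Species are compared by the overlap of their 5UC-ASE gene sets under an
ortholog mapping (symmetrised Jaccard distance) and clustered with Ward's
minimum-variance algorithm (ward.D2 convention: Lance-Williams updates on
squared distances, heights on the distance scale, deterministic ties broken
toward the smallest leaf index).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .classify import classify_all
from .models import CodingType, GeneModel, SpliceClass
from .splicing import generate_se_events


@dataclass
class SpeciesExonStats:
    """One row of the per-species count table."""

    species: str
    coding_genes: int
    transcripts: int
    exons: int
    alternative_exons: int
    fiveuc_ase_genes: int
    fiveuc_ase_transcripts: int
    fiveuc_ases: int

    def as_dict(self) -> dict:
        return {
            "species": self.species,
            "coding_genes": self.coding_genes,
            "transcripts": self.transcripts,
            "exons": self.exons,
            "alternative_exons": self.alternative_exons,
            "5uc_ase_genes": self.fiveuc_ase_genes,
            "5uc_ase_transcripts": self.fiveuc_ase_transcripts,
            "5uc_ases": self.fiveuc_ases,
        }


def species_5uc_stats(
    genes: Sequence[GeneModel], species: str
) -> tuple[SpeciesExonStats, set[str]]:
    """Count coding genes, isoforms, exons and 5UC-ASEs for one species.

    Returns the stats row and the set of 5UC-ASE gene IDs (the substrate of
    the ortholog-sharing comparison). Annotations without any CDS feature
    cannot be typed and raise.
    """
    if not any(t.is_coding for g in genes for t in g.transcripts):
        raise ValueError(f"{species}: annotation has no CDS features")
    classified, _ = classify_all(genes)
    fiveuc_ases = [
        e
        for e in classified
        if e.coding_type is CodingType.TYPE2_5UC
        and e.splice_class is SpliceClass.ASE
    ]
    ase_genes = {e.gene_id for e in fiveuc_ases}
    n_tx = sum(len(g.transcripts) for g in genes)
    n_exons = len(
        {e.coords() for g in genes for t in g.transcripts for e in t.exons}
    )
    n_alt = sum(e.splice_class is not SpliceClass.CONSTITUTIVE for e in classified)
    n_ase_tx = sum(
        len(g.transcripts) for g in genes if g.gene_id in ase_genes
    )
    stats = SpeciesExonStats(
        species=species,
        coding_genes=len(genes),
        transcripts=n_tx,
        exons=n_exons,
        alternative_exons=n_alt,
        fiveuc_ase_genes=len(ase_genes),
        fiveuc_ase_transcripts=n_ase_tx,
        fiveuc_ases=len(fiveuc_ases),
    )
    return stats, ase_genes


def read_ortholog_tsv(path: str | Path) -> dict[tuple[str, str], dict[str, set[str]]]:
    """Read (species_a, gene_a, species_b, gene_b) rows into directional maps."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["species_a", "gene_a", "species_b", "gene_b"],
        comment="#",
        dtype=str,
    )
    maps: dict[tuple[str, str], dict[str, set[str]]] = {}
    for row in df.itertuples(index=False):
        fwd = maps.setdefault((row.species_a, row.species_b), {})
        fwd.setdefault(row.gene_a, set()).add(row.gene_b)
        rev = maps.setdefault((row.species_b, row.species_a), {})
        rev.setdefault(row.gene_b, set()).add(row.gene_a)
    return maps


def sharing_distance(
    sets: Mapping[str, set[str]],
    maps: Mapping[tuple[str, str], Mapping[str, set[str]]],
) -> pd.DataFrame:
    """Symmetrised Jaccard distance between species gene sets under orthology.

    shared(A,B) counts genes of A's set with >= 1 ortholog inside B's set;
    the symmetrised count is the mean of both directions and
    d = 1 - shared / (|A| + |B| - shared). Identical sets under identity
    orthology give 0; sets without cross-orthologs give 1.
    """
    species = sorted(sets)
    k = len(species)
    dist = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        a, b = species[i], species[j]
        if (a, b) not in maps or (b, a) not in maps:
            raise KeyError(f"missing ortholog map for pair ({a}, {b})")

        def shared(src: str, dst: str) -> int:
            m = maps[(src, dst)]
            return sum(
                1
                for g in sets[src]
                if m.get(g) and m[g] & sets[dst]
            )

        sym = 0.5 * (shared(a, b) + shared(b, a))
        denom = len(sets[a]) + len(sets[b]) - sym
        d = 1.0 - sym / denom if denom > 0 else 0.0
        dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=species, columns=species)


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``merges`` holds (k-1) tuples (cluster_i, cluster_j, height, size) in
    scipy linkage convention: leaves are 0..k-1, merge m creates cluster
    k+m.  Heights are non-decreasing (Ward monotonicity).
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def to_linkage(self) -> np.ndarray:
        return np.array(
            [[i, j, h, s] for i, j, h, s in self.merges], dtype=float
        )

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        k = len(self.labels)
        node_h = {i: 0.0 for i in range(k)}
        newick = {i: self.labels[i] for i in range(k)}
        for m, (i, j, h, _size) in enumerate(self.merges):
            bl_i = h - node_h[i]
            bl_j = h - node_h[j]
            node = k + m
            newick[node] = f"({newick[i]}:{bl_i:.6g},{newick[j]}:{bl_j:.6g})"
            node_h[node] = h
        return newick[k + len(self.merges) - 1] + ";"

    def leaf_sets(self) -> list[frozenset[str]]:
        """Clades (as label sets) defined by each merge."""
        k = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(k)
        }
        out = []
        for m, (i, j, _h, _s) in enumerate(self.merges):
            members[k + m] = members[i] | members[j]
            out.append(members[k + m])
        return out


def ward_cluster(dist: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> Dendrogram:
    """Agglomerative Ward clustering of a distance matrix (ward.D2).

    Lance-Williams update on squared distances; merge heights are reported
    on the distance scale.  Ties are broken deterministically toward the
    pair whose smallest original leaf indices come first.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = list(dist.index)
        dist = dist.to_numpy(dtype=float)
    dist = np.asarray(dist, dtype=float)
    k = dist.shape[0]
    if dist.shape != (k, k) or not np.allclose(dist, dist.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if k < 2:
        raise ValueError("need at least two leaves")
    if labels is None:
        labels = [f"leaf{i}" for i in range(k)]
    d2 = dist.astype(float) ** 2
    active: dict[int, dict] = {
        i: {"size": 1, "min_leaf": i} for i in range(k)
    }
    sq: dict[frozenset[int], float] = {
        frozenset((i, j)): d2[i, j] for i, j in combinations(range(k), 2)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = k
    while len(active) > 1:
        best = None
        for pair, v in sq.items():
            i, j = sorted(pair, key=lambda c: active[c]["min_leaf"])
            key = (v, active[i]["min_leaf"], active[j]["min_leaf"])
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij2 = sq.pop(frozenset((i, j)))
        ni, nj = active[i]["size"], active[j]["size"]
        new = {
            "size": ni + nj,
            "min_leaf": min(active[i]["min_leaf"], active[j]["min_leaf"]),
        }
        for c in active:
            if c in (i, j):
                continue
            nc = active[c]["size"]
            dic2 = sq.pop(frozenset((i, c)))
            djc2 = sq.pop(frozenset((j, c)))
            upd = (
                (ni + nc) * dic2 + (nj + nc) * djc2 - nc * dij2
            ) / (ni + nj + nc)
            sq[frozenset((next_id, c))] = upd
        del active[i], active[j]
        active[next_id] = new
        merges.append((i, j, float(np.sqrt(max(dij2, 0.0))), new["size"]))
        next_id += 1
    return Dendrogram(labels=list(labels), merges=merges)


def same_topology(newick_a: str, newick_b: str) -> bool:
    """True when two trees share the same unrooted topology (RF distance 0)."""
    taxa = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=taxa)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=taxa)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return (
        dendropy.calculate.treecompare.symmetric_difference(ta, tb) == 0
    )


def species_table(stats: Iterable[SpeciesExonStats]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in stats]).set_index("species")
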