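"""Independent oracles used to cross-check the package implementations.

These deliberately use the slowest, most literal formulation of each
computation so they cannot share a bug with the optimised code paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_rohs(track: pd.DataFrame, genomic_avg: float, min_bins: int = 20, frac: float = 0.33):
    """Enumerate every candidate window and keep maximal qualifying runs."""
    cutoff = frac * genomic_avg
    segs = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        qual = [
            bool(r.retained and r.scaled_snp_count < cutoff)
            for r in sub.itertuples(index=False)
        ]
        n = len(sub)
        for i in range(n):
            for j in range(i, n):
                if not all(qual[i : j + 1]):
                    continue
                # maximality
                if i > 0 and qual[i - 1]:
                    continue
                if j < n - 1 and qual[j + 1]:
                    continue
                if j - i + 1 >= min_bins:
                    segs.append(
                        {
                            "chrom": chrom,
                            "start": int(sub["start"][i]),
                            "end": int(sub["end"][j]),
                            "n_bins": j - i + 1,
                            "length": int(sub["end"][j] - sub["start"][i]),
                        }
                    )
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "n_bins", "length"])


def random_track(rng: np.random.Generator, n_bins: int, bin_size: int = 10_000) -> pd.DataFrame:
    """A random scaled bin track with low-SNP stretches and coverage holes."""
    scaled = rng.poisson(12, size=n_bins).astype(float)
    # carve a few low-diversity stretches of random length
    for _ in range(rng.integers(1, 4)):
        start = int(rng.integers(0, n_bins))
        length = int(rng.integers(5, 60))
        scaled[start : start + length] = rng.poisson(0.5, size=len(scaled[start : start + length]))
    covered = rng.choice([0, 500, 5000, 10000], p=[0.02, 0.03, 0.05, 0.9], size=n_bins)
    track = pd.DataFrame(
        {
            "chrom": "1",
            "start": np.arange(n_bins) * bin_size,
            "end": (np.arange(n_bins) + 1) * bin_size,
            "covered_sites": covered,
            "raw_snp_count": scaled.astype(int),
            "scaled_snp_count": scaled,
            "retained": covered >= 1000,
        }
    )
    return track


def _ancestor_paths(parents: dict[str, tuple[str, str]], start: str) -> list[list[str]]:
    paths: list[list[str]] = []

    def rec(node: str, path: list[str]) -> None:
        path = path + [node]
        paths.append(path)
        for p in parents.get(node, ()):
            if p != "WILD" and p in parents:
                rec(p, path)

    rec(start, [])
    return paths


def wright_inbreeding(parents: dict[str, tuple[str, str]], individual: str) -> float:
    """Wright's path-counting F: Σ (1/2)^(n_s + n_d + 1) (1 + F_A)."""
    sire, dam = parents[individual]
    if sire == "WILD" or dam == "WILD" or sire not in parents or dam not in parents:
        return 0.0
    total = 0.0
    for p1 in _ancestor_paths(parents, sire):
        for p2 in _ancestor_paths(parents, dam):
            if p1[-1] != p2[-1]:
                continue
            if set(p1[:-1]) & set(p2[:-1]):
                continue  # paths may share only the common ancestor
            n1, n2 = len(p1) - 1, len(p2) - 1
            total += 0.5 ** (n1 + n2 + 1) * (1.0 + wright_inbreeding(parents, p1[-1]))
    return total


def random_pedigree(rng: np.random.Generator, n_individuals: int = 20) -> pd.DataFrame:
    """Random acyclic pedigree: parents always precede children."""
    n_founders = int(rng.integers(3, 7))
    rows = []
    ids = []
    for i in range(n_founders):
        ident = f"P{i}"
        rows.append({"id": ident, "sire": "WILD", "dam": "WILD", "birth_date": "2000", "origin": "sim"})
        ids.append(ident)
    for i in range(n_founders, n_individuals):
        sire, dam = rng.choice(len(ids), size=2, replace=False)
        ident = f"P{i}"
        rows.append(
            {
                "id": ident,
                "sire": ids[int(sire)],
                "dam": ids[int(dam)],
                "birth_date": str(2000 + 5 * (i // n_founders)),
                "origin": "sim",
            }
        )
        ids.append(ident)
    return pd.DataFrame(rows)


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree with positive branch lengths, via dendropy.

    Returns (tree, labelled patristic-distance DataFrame).
    """
    import dendropy

    labels = [f"t{i}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=ns.get_taxon(lab)) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = float(rng.uniform(0.05, 1.0))
        nodes[j].edge.length = float(rng.uniform(0.05, 1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[0])
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    mat = np.zeros((n_leaves, n_leaves))
    for a in range(n_leaves):
        for b in range(n_leaves):
            if a != b:
                mat[a, b] = pdm.patristic_distance(ns.get_taxon(labels[a]), ns.get_taxon(labels[b]))
    return tree, pd.DataFrame(mat, index=labels, columns=labels)


def patristic_frame(tree, labels):
    """Leaf-to-leaf path lengths of a dendropy tree as a DataFrame."""
    import numpy as np

    pdm = tree.phylogenetic_distance_matrix()
    ns = tree.taxon_namespace
    mat = np.zeros((len(labels), len(labels)))
    for a, la in enumerate(labels):
        for b, lb in enumerate(labels):
            if a != b:
                mat[a, b] = pdm.patristic_distance(ns.get_taxon(la), ns.get_taxon(lb))
    return pd.DataFrame(mat, index=labels, columns=labels)
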