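"""Ortholog placement analysis: wanderer genes, syntenic blocks, and the
minimum signed-reversal (inversion) distance with scenario
reconstruction and an exhaustive breadth-first-search oracle."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ORTHOLOG_COLUMNS = ("gene_id", "species", "element", "scaffold", "position", "strand")


@dataclass
class OrthologTable:
    """Long-format ortholog placements: one row per (gene, species)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(ORTHOLOG_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
        bad = set(self.data["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"invalid strands: {sorted(bad)}")
        dup = self.data.duplicated(subset=["species", "element", "position"])
        if dup.any():
            raise ValueError("duplicate (species, element, position)")

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def placements(self, species: str) -> pd.DataFrame:
        return self.data[self.data["species"] == species].set_index("gene_id")

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, lineterminator="\n",
                         columns=list(ORTHOLOG_COLUMNS))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "species": str,
                                                "element": str, "scaffold": str,
                                                "strand": str})
        return cls(df)


@dataclass
class WandererReport:
    wanderers: pd.DataFrame      # gene_id, species_a, species_b, from_element, to_element
    other_moves: pd.DataFrame    # element changes not touching the focal element
    unplaced: pd.DataFrame       # gene_id, species missing the gene


def find_wanderers(table: OrthologTable, focal_element: str = "F") -> WandererReport:
    """Genes on the focal element in one species but on a different
    element in another.  Moves between two non-focal elements are
    reported separately, as are genes absent from a species."""
    species = table.species
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    placed = {sp: table.placements(sp) for sp in species}
    all_genes = sorted(set(table.data["gene_id"]))
    wanderers, others, unplaced = [], [], []
    for g in all_genes:
        for sp in species:
            if g not in placed[sp].index:
                unplaced.append({"gene_id": g, "species": sp})
    for a, b in [(x, y) for i, x in enumerate(species) for y in species[i + 1:]]:
        for g in all_genes:
            if g not in placed[a].index or g not in placed[b].index:
                continue
            ea = placed[a].loc[g, "element"]
            eb = placed[b].loc[g, "element"]
            if ea == eb:
                continue
            row = {
                "gene_id": g, "species_a": a, "species_b": b,
                "from_element": ea, "to_element": eb,
            }
            if focal_element in (ea, eb):
                wanderers.append(row)
            else:
                others.append(row)
    cols = ["gene_id", "species_a", "species_b", "from_element", "to_element"]
    return WandererReport(
        wanderers=pd.DataFrame(wanderers, columns=cols),
        other_moves=pd.DataFrame(others, columns=cols),
        unplaced=pd.DataFrame(unplaced, columns=["gene_id", "species"]),
    )


def wanderer_hotspots(
    wanderers: pd.DataFrame,
    table: OrthologTable,
    species: str,
    window_genes: int = 10,
) -> pd.DataFrame:
    """Count wanderer genes per fixed-width positional window of the
    given species' gene order (descriptive hotspot summary)."""
    placed = table.placements(species).sort_values(["element", "position"])
    wset = set(wanderers["gene_id"])
    rows = []
    for element, sub in placed.groupby("element"):
        ids = list(sub.index)
        for w0 in range(0, len(ids), window_genes):
            chunk = ids[w0 : w0 + window_genes]
            count = sum(1 for g in chunk if g in wset)
            rows.append({
                "element": element, "window_start_rank": w0,
                "n_genes": len(chunk), "n_wanderers": count,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Signed gene orders

def shared_signed_order(
    table: OrthologTable, species_a: str, species_b: str, element: str = "F"
) -> tuple[list[int], list[str]]:
    """Signed permutation of species_b's order of the genes shared on
    ``element`` between both species, relative to species_a.

    Gene k (1-based rank in species_a order) appears as +-k in species_b
    order; the sign is + when the strands agree.  Returns (order,
    gene ids in species_a rank order).
    """
    pa = table.placements(species_a)
    pb = table.placements(species_b)
    shared = [
        g for g in pa.index
        if pa.loc[g, "element"] == element
        and g in pb.index and pb.loc[g, "element"] == element
    ]
    if len(shared) < 2:
        raise ValueError(f"< 2 shared genes on element {element}")
    a_order = sorted(shared, key=lambda g: pa.loc[g, "position"])
    rank = {g: i + 1 for i, g in enumerate(a_order)}
    b_order = sorted(shared, key=lambda g: pb.loc[g, "position"])
    signed = [
        rank[g] if pa.loc[g, "strand"] == pb.loc[g, "strand"] else -rank[g]
        for g in b_order
    ]
    return signed, a_order


def _check_signed_permutation(order: Sequence[int]) -> None:
    n = len(order)
    if sorted(abs(x) for x in order) != list(range(1, n + 1)):
        raise ValueError("not a signed permutation of 1..n")


def syntenic_blocks(order: Sequence[int]) -> tuple[list[list[int]], float]:
    """Split a signed order into maximal co-conserved runs.

    A block extends while consecutive entries increase by one with the
    same sign: (+3, +4) continues an upright block and (-5, -4) an
    inverted one — exactly the patterns a reversal of a conserved
    segment produces.  Returns (blocks, mean genes per block).
    """
    _check_signed_permutation(order)
    if not order:
        raise ValueError("empty order")
    blocks: list[list[int]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        if cur == prev + 1 and (prev > 0) == (cur > 0):
            blocks[-1].append(cur)
        else:
            blocks.append([cur])
    return blocks, len(order) / len(blocks)


# ---------------------------------------------------------------------------
# Hannenhalli-Pevzner reversal distance (linear chromosome, fixed ends)

def _breakpoint_cycles(order: Sequence[int]):
    """Breakpoint-graph bookkeeping for a framed signed permutation.

    Each gene g becomes (2g-1, 2g) when positive, (2|g|, 2|g|-1) when
    negative, framed by 0 and 2n+1.  Black edges join sequence positions
    (2i, 2i+1); gray edges join values (2i, 2i+1).  Returns the vertex
    sequence, per-vertex position, and the list of cycles (as lists of
    gray edges, each a value pair).
    """
    n = len(order)
    seq = [0]
    for g in order:
        a = abs(g)
        seq.extend((2 * a - 1, 2 * a) if g > 0 else (2 * a, 2 * a - 1))
    seq.append(2 * n + 1)
    pos = {v: i for i, v in enumerate(seq)}
    black = {}
    for i in range(n + 1):
        u, v = seq[2 * i], seq[2 * i + 1]
        black[u] = v
        black[v] = u
    gray = {}
    for i in range(n + 1):
        gray[2 * i] = 2 * i + 1
        gray[2 * i + 1] = 2 * i
    cycles = []
    seen: set[int] = set()
    for start in seq:
        if start in seen:
            continue
        cyc_grays = []
        v = start
        while True:
            seen.add(v)
            w = black[v]
            seen.add(w)
            g2 = gray[w]
            cyc_grays.append((min(w, g2), max(w, g2)))
            v = g2
            if v == start:
                break
        cycles.append(cyc_grays)
    return seq, pos, cycles


def _hurdles_and_fortress(pos, cycles) -> tuple[int, int]:
    """Count hurdles and detect a fortress among unoriented components."""
    # non-trivial cycles only (trivial = one black + one gray edge)
    nontrivial = [c for c in cycles if len(c) > 1]
    if not nontrivial:
        return 0, 0
    # a gray edge is oriented iff its endpoints sit at same-parity positions
    def edge_span(e):
        a, b = pos[e[0]], pos[e[1]]
        return (a, b) if a < b else (b, a)

    def edge_oriented(e):
        return (pos[e[0]] - pos[e[1]]) % 2 == 0

    # union-find over cycles joined by crossing gray edges
    parent = list(range(len(nontrivial)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    spans = [[edge_span(e) for e in c] for c in nontrivial]
    for i in range(len(nontrivial)):
        for j in range(i + 1, len(nontrivial)):
            if find(i) == find(j):
                continue
            crossing = any(
                (a1 < a2 < b1 < b2) or (a2 < a1 < b2 < b1)
                for a1, b1 in spans[i]
                for a2, b2 in spans[j]
            )
            if crossing:
                union(i, j)

    comp_cycles: dict[int, list[int]] = {}
    for i in range(len(nontrivial)):
        comp_cycles.setdefault(find(i), []).append(i)
    unoriented = []
    for cyc_ids in comp_cycles.values():
        if not any(edge_oriented(e) for i in cyc_ids for e in nontrivial[i]):
            unoriented.append(cyc_ids)
    if not unoriented:
        return 0, 0

    # circular membership sequence over positions of unoriented components
    pos_to_comp: dict[int, int] = {}
    for ci, cyc_ids in enumerate(unoriented):
        for i in cyc_ids:
            for e in nontrivial[i]:
                pos_to_comp[pos[e[0]]] = ci
                pos_to_comp[pos[e[1]]] = ci
    ring = [pos_to_comp[p] for p in sorted(pos_to_comp)]

    def circular_runs(seq_ids: list[int], comp: int) -> int:
        runs = 0
        m = len(seq_ids)
        for idx in range(m):
            if seq_ids[idx] == comp and seq_ids[idx - 1] != comp:
                runs += 1
        if runs == 0 and seq_ids and seq_ids[0] == comp:
            runs = 1  # the whole ring is one component
        return runs

    n_comps = len(unoriented)
    hurdles = [c for c in range(n_comps) if circular_runs(ring, c) == 1]
    h = len(hurdles)
    if h == 0 or h % 2 == 0:
        return h, 0
    # fortress: odd number of hurdles, all of them super-hurdles
    non_hurdles = [c for c in range(n_comps) if c not in hurdles]
    all_super = True
    for hu in hurdles:
        reduced = [c for c in ring if c != hu]
        protects = any(circular_runs(reduced, v) == 1 for v in non_hurdles)
        if not protects:
            all_super = False
            break
    return h, 1 if (all_super and h >= 3) else 0


def reversal_distance(order: Sequence[int]) -> int:
    """Exact minimum number of signed reversals sorting ``order`` to the
    identity (+1 .. +n), for a linear chromosome with fixed orientation:
    d = (n + 1) - cycles + hurdles + fortress."""
    _check_signed_permutation(order)
    n = len(order)
    if n == 0:
        return 0
    _, pos, cycles = _breakpoint_cycles(order)
    c = len(cycles)
    h, f = _hurdles_and_fortress(pos, cycles)
    return (n + 1) - c + h + f


def apply_reversal(order: Sequence[int], i: int, j: int) -> list[int]:
    """Reverse (and sign-flip) the segment order[i..j], 0-based inclusive."""
    out = list(order)
    out[i : j + 1] = [-x for x in reversed(out[i : j + 1])]
    return out


def reversal_scenario(order: Sequence[int]) -> list[tuple[int, int]]:
    """A minimum-length sequence of reversals (as 0-based inclusive
    index pairs) transforming ``order`` into the identity, found by
    greedily applying any distance-reducing reversal."""
    _check_signed_permutation(order)
    current = list(order)
    d = reversal_distance(current)
    scenario: list[tuple[int, int]] = []
    n = len(current)
    while d > 0:
        found = False
        for i in range(n):
            for j in range(i, n):
                candidate = apply_reversal(current, i, j)
                if reversal_distance(candidate) == d - 1:
                    scenario.append((i, j))
                    current = candidate
                    d -= 1
                    found = True
                    break
            if found:
                break
        if not found:  # cannot happen for a correct distance
            raise RuntimeError("no distance-reducing reversal found")
    return scenario


# ---------------------------------------------------------------------------
# Brute-force oracle

def bfs_distance_table(n: int) -> dict[tuple[int, ...], int]:
    """Exact reversal distances of every signed permutation of 1..n via
    breadth-first search from the identity (vectorized).  Intended as an
    independent oracle for small n (n <= 7 is practical)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = 2 * n + 1
    weights = (base ** np.arange(n)).astype(np.int64)

    def encode(arr: np.ndarray) -> np.ndarray:
        return (arr.astype(np.int64) + n) @ weights

    identity = np.arange(1, n + 1, dtype=np.int8)[None, :]
    dist: dict[int, int] = {int(encode(identity)[0]): 0}
    frontier = identity
    level = 0
    revs = [(i, j) for i in range(n) for j in range(i, n)]
    while len(frontier):
        level += 1
        neighbors = []
        for i, j in revs:
            new = frontier.copy()
            new[:, i : j + 1] = -new[:, i : j + 1][:, ::-1]
            neighbors.append(new)
        cand = np.vstack(neighbors)
        codes = encode(cand)
        codes, idx = np.unique(codes, return_index=True)
        fresh = [k for k, c in enumerate(codes) if int(c) not in dist]
        if not fresh:
            break
        for k in fresh:
            dist[int(codes[k])] = level
        frontier = cand[idx[fresh]]

    def tuple_encode(perm) -> int:
        return int((np.asarray(perm, dtype=np.int64) + n) @ weights)

    return _BfsTable(dist, tuple_encode)


class _BfsTable(dict):
    """dict-like wrapper keyed by signed-permutation tuples."""

    def __init__(self, codes: dict[int, int], encode):
        super().__init__()
        self._codes = codes
        self._encode = encode

    def __getitem__(self, perm) -> int:
        return self._codes[self._encode(perm)]

    def __contains__(self, perm) -> bool:
        return self._encode(perm) in self._codes

    def __len__(self) -> int:
        return len(self._codes)


def all_signed_permutations(n: int) -> Iterable[tuple[int, ...]]:
    for perm in permutations(range(1, n + 1)):
        for signs in product((1, -1), repeat=n):
            yield tuple(p * s for p, s in zip(perm, signs))
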