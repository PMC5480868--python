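"""(6,6) body-bar pebble game: independence, floppy modes, rigid clusters.

Each body carries six pebbles (its six rigid-body degrees of freedom). A bar
between bodies u and v is independent exactly when seven pebbles can be
gathered onto {u, v} before the bar is placed; placing it pays one pebble.
After all bars are processed, two bodies are mutually rigid when a virtual
seventh-pebble test between them fails, and the set of bodies visited by
that failed search is precisely their rigid cluster, which gives a
near-linear cluster decomposition.

A brute-force generic rigidity-matrix rank oracle is provided for
validation on small networks; the two routes must agree bar-for-bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Bar, ConstraintNetwork

K_PEBBLES = 6          # pebbles per body
L_SHIFT = 6            # a bar is independent iff L_SHIFT+1 pebbles gather


@dataclass
class RigidityResult:
    """Rigid-cluster partition and constraint counting of one network."""

    n_bodies: int
    cluster_ids: np.ndarray            # cluster id per body
    independent_bars: int
    redundant_bars: int
    floppy_modes_internal: int         # summed over connected components
    floppy_modes_per_component: dict[int, int] = field(default_factory=dict)
    largest_cluster_id: int = 0
    network: ConstraintNetwork | None = None

    @property
    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for body, cid in enumerate(self.cluster_ids):
            out.setdefault(int(cid), []).append(body)
        return out

    def cluster_sizes(self) -> dict[int, int]:
        return {cid: len(m) for cid, m in self.clusters.items()}

    def largest_members(self) -> frozenset[int]:
        return frozenset(self.clusters[self.largest_cluster_id])

    def in_largest(self, body: int) -> bool:
        return int(self.cluster_ids[body]) == self.largest_cluster_id

    def partition_key(self) -> tuple:
        """Canonical form of the partition, independent of cluster ids."""
        groups = sorted(tuple(sorted(m)) for m in self.clusters.values())
        return tuple(groups)


class _PebbleGame:
    """Mutable pebble-game state over a fixed body set."""

    def __init__(self, n: int):
        self.n = n
        self.pebbles = [K_PEBBLES] * n
        # out[u][v] = number of directed (pebble-covered) edges u -> v
        self.out: list[dict[int, int]] = [dict() for _ in range(n)]

    def _search(self, u: int, v: int):
        """DFS from {u, v} for a body with a free pebble.

        Returns (w, parent) on success, (None, visited) on failure.
        """
        visited = {u, v}
        stack = [u, v]
        parent: dict[int, int] = {}
        while stack:
            x = stack.pop()
            for y in self.out[x]:
                if self.out[x][y] <= 0 or y in visited:
                    continue
                visited.add(y)
                parent[y] = x
                if self.pebbles[y] > 0:
                    return y, parent
                stack.append(y)
        return None, visited

    def _reverse_path(self, w: int, parent: dict[int, int]):
        """Move the free pebble at w back to the search root."""
        x = w
        while x in parent:
            p = parent[x]
            # reverse one directed edge p -> x
            self.out[p][x] -= 1
            if self.out[p][x] == 0:
                del self.out[p][x]
            self.out[x][p] = self.out[x].get(p, 0) + 1
            x = p
        self.pebbles[w] -= 1
        self.pebbles[x] += 1

    def gather(self, u: int, v: int, target: int):
        """Try to collect ``target`` pebbles on {u, v}.

        Returns (True, None) or (False, visited_set_of_failed_search).
        """
        while self.pebbles[u] + self.pebbles[v] < target:
            w, res = self._search(u, v)
            if w is None:
                return False, res
            self._reverse_path(w, res)
        return True, None

    def insert_edge(self, u: int, v: int):
        if self.pebbles[u] == 0:
            u, v = v, u
        assert self.pebbles[u] > 0
        self.pebbles[u] -= 1
        self.out[u][v] = self.out[u].get(v, 0) + 1


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def pebble_game_decompose(net: ConstraintNetwork) -> RigidityResult:
    """Run the (6,6) pebble game and decompose into rigid clusters.

    Bars are processed in sorted order, which together with the intrinsic
    order-independence of the underlying matroid makes the result
    deterministic. Floppy modes are counted per connected component as
    6 V_c - 6 - (independent bars in the component) and summed.
    """
    n = net.n_bodies
    if n == 0:
        raise ValueError("empty network")
    game = _PebbleGame(n)
    comp = _UnionFind(n)
    independent = 0
    redundant = 0
    indep_edges: list[tuple[int, int]] = []
    for bar in net.sorted_bars():
        u, v = bar.i, bar.j
        comp.union(u, v)
        for _ in range(bar.multiplicity):
            ok, _vis = game.gather(u, v, L_SHIFT + 1)
            if ok:
                game.insert_edge(u, v)
                independent += 1
                indep_edges.append((u, v))
            else:
                redundant += 1

    # rigid clusters: flood-fill over failed seventh-pebble tests
    rigid = _UnionFind(n)
    seen_pairs: set[tuple[int, int]] = set()
    for bar in net.sorted_bars():
        u, v = bar.i, bar.j
        if rigid.find(u) == rigid.find(v):
            continue
        pair = (min(u, v), max(u, v))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        ok, visited = game.gather(u, v, L_SHIFT + 1)
        if not ok:
            members = list(visited)
            for m in members[1:]:
                rigid.union(members[0], m)

    cluster_of = {}
    cluster_ids = np.empty(n, dtype=int)
    next_id = 0
    for body in range(n):
        root = rigid.find(body)
        if root not in cluster_of:
            cluster_of[root] = next_id
            next_id += 1
        cluster_ids[body] = cluster_of[root]

    # floppy modes per connected component
    comp_v: dict[int, int] = {}
    for body in range(n):
        comp_v[comp.find(body)] = comp_v.get(comp.find(body), 0) + 1
    comp_indep: dict[int, int] = {r: 0 for r in comp_v}
    for u, _v in indep_edges:
        comp_indep[comp.find(u)] += 1
    floppy_per = {r: 6 * comp_v[r] - 6 - comp_indep[r] for r in comp_v
                  if comp_v[r] > 1}
    total_floppy = sum(floppy_per.values())

    sizes: dict[int, int] = {}
    for body in range(n):
        sizes[int(cluster_ids[body])] = sizes.get(int(cluster_ids[body]), 0) + 1
    # largest cluster; ties broken toward the cluster holding the smallest
    # body index (cluster ids are assigned in body order, so min id wins)
    largest = min(sorted(sizes), key=lambda c: (-sizes[c], c))

    return RigidityResult(
        n_bodies=n, cluster_ids=cluster_ids,
        independent_bars=independent, redundant_bars=redundant,
        floppy_modes_internal=total_floppy,
        floppy_modes_per_component=floppy_per,
        largest_cluster_id=int(largest), network=net)


def largest_rigid_cluster(res: RigidityResult) -> frozenset[int]:
    """Members of the biggest rigid cluster (ties: smallest body index)."""
    return res.largest_members()


# ---------------------------------------------------------------------------
# Brute-force generic rank oracle
# ---------------------------------------------------------------------------

def _rigidity_matrix(net: ConstraintNetwork, rng: np.random.Generator,
                     extra: tuple[int, int] | None = None) -> np.ndarray:
    """Generic body-bar rigidity matrix: one row per bar.

    Bodies get random generic placements; each bar gets random attachment
    points on its two bodies. Row of a bar between i and j with world
    attachment points a, b and direction d = b - a:
    columns of i: [d, (a - x_i) x d], columns of j: -[d, (b - x_j) x d].
    """
    n = net.n_bodies
    pos = rng.normal(size=(n, 3)) * 10.0
    rows = []
    bars = [(b.i, b.j, b.multiplicity) for b in net.sorted_bars()]
    if extra is not None:
        bars.append((extra[0], extra[1], 1))
    for i, j, mult in bars:
        for _ in range(mult):
            a = pos[i] + rng.normal(size=3)
            b = pos[j] + rng.normal(size=3)
            d = b - a
            row = np.zeros(6 * n)
            row[6 * i:6 * i + 3] = d
            row[6 * i + 3:6 * i + 6] = np.cross(a - pos[i], d)
            row[6 * j:6 * j + 3] = -d
            row[6 * j + 3:6 * j + 6] = -np.cross(b - pos[j], d)
            rows.append(row)
    return np.array(rows) if rows else np.zeros((0, 6 * n))


def _matrix_rank(m: np.ndarray) -> int:
    if m.size == 0:
        return 0
    s = np.linalg.svd(m, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int((s > 1e-8 * s[0]).sum())


def brute_force_rank(net: ConstraintNetwork, seed: int = 0) -> int:
    """Generic rigidity-matrix rank; the definitional count of independent
    bars. Two random placements are tried and the maximum taken, guarding
    against an accidentally non-generic draw. Intended for networks of at
    most a few dozen bodies."""
    if net.n_bodies > 60:
        raise ValueError("rank oracle is restricted to small networks")
    ranks = []
    for s in (seed, seed + 104729):
        rng = np.random.default_rng(s)
        ranks.append(_matrix_rank(_rigidity_matrix(net, rng)))
    return max(ranks)


def mutually_rigid_oracle(net: ConstraintNetwork, u: int, v: int,
                          seed: int = 0) -> bool:
    """Rank test of mutual rigidity: a virtual generic bar between u and v
    is redundant exactly when the pair is already mutually rigid."""
    if u == v:
        return True
    results = []
    for s in (seed, seed + 104729):
        # same seed for both matrices: shared rows are identical, so the
        # augmented rank can only differ by the one extra generic bar
        base = _matrix_rank(_rigidity_matrix(net,
                                             np.random.default_rng(s)))
        aug = _matrix_rank(_rigidity_matrix(net,
                                            np.random.default_rng(s),
                                            extra=(u, v)))
        results.append(aug == base)
    return all(results)


def oracle_partition(net: ConstraintNetwork, seed: int = 0) -> tuple:
    """Cluster partition computed purely from pairwise rank tests."""
    n = net.n_bodies
    uf = _UnionFind(n)
    for u in range(n):
        for v in range(u + 1, n):
            if uf.find(u) == uf.find(v):
                continue
            if mutually_rigid_oracle(net, u, v, seed):
                uf.union(u, v)
    groups: dict[int, list[int]] = {}
    for b in range(n):
        groups.setdefault(uf.find(b), []).append(b)
    return tuple(sorted(tuple(sorted(m)) for m in groups.values()))


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------

def cluster_table(res: RigidityResult) -> "pandas.DataFrame":
    import pandas as pd

    rows = []
    for body in range(res.n_bodies):
        cid = int(res.cluster_ids[body])
        label = (res.network.body_labels[body]
                 if res.network and res.network.body_labels else (None, ""))
        rows.append({"body": body, "nucleotide": label[0],
                     "atom": label[1], "cluster": cid,
                     "in_largest": cid == res.largest_cluster_id})
    return pd.DataFrame(rows)
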