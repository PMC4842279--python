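import numpy as np
import pandas as pd
import pytest

from awmnet.datatypes import GenotypeMatrix, TraitTable
from awmnet.simulate import SimConfig, simulate_dataset


def make_genotypes(dosages, chroms=None, positions=None, sample_ids=None):
    """Small GenotypeMatrix literal for unit tests."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    info = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "B",
        },
        index=pd.Index([f"snp{i + 1}" for i in range(m)], name="snp"),
    )
    ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages, info, ids)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared desk-scale simulated dataset for cross-module tests."""
    cfg = SimConfig(
        n_breeds=2,
        n_per_breed=200,
        n_snps=800,
        n_genes=80,
        n_traits=5,
        n_causal_genes=12,
        h2=0.5,
        seed=11,
    )
    return simulate_dataset(cfg)


def pcit_oracle(r: np.ndarray):
    """Exhaustive triple-loop PCIT, kept independent of the package's
    vectorized implementation: returns the boolean kept-edge matrix."""
    r = np.asarray(r, float)
    n = r.shape[0]
    eliminated = np.zeros((n, n), bool)
    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            rxy = r[x, y]
            for z in range(n):
                if z == x or z == y:
                    continue
                rxz, ryz = r[x, z], r[y, z]
                d1 = (1 - rxz**2) * (1 - ryz**2)
                d2 = (1 - rxy**2) * (1 - ryz**2)
                d3 = (1 - rxy**2) * (1 - rxz**2)
                if d1 <= 0 or d2 <= 0 or d3 <= 0:
                    continue  # collinear trio skipped
                p_xy = (rxy - rxz * ryz) / np.sqrt(d1)
                p_xz = (rxz - rxy * ryz) / np.sqrt(d2)
                p_yz = (ryz - rxy * rxz) / np.sqrt(d3)
                ratios = []
                for partial, direct in ((p_xy, rxy), (p_xz, rxz), (p_yz, ryz)):
                    if direct != 0:
                        ratios.append(partial / direct)
                if not ratios:
                    continue
                eps = sum(ratios) / len(ratios)
                if abs(rxy) < abs(eps * rxz) and abs(rxy) < abs(eps * ryz):
                    eliminated[x, y] = True
                    break
    kept = ~(eliminated | eliminated.T)
    np.fill_diagonal(kept, False)
    return kept


def betweenness_oracle(edges, nodes):
    """Brute-force betweenness via explicit shortest-path enumeration
    (BFS counting), unnormalized, independent of networkx."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def shortest_paths(src):
        # returns dist and number-of-shortest-paths maps
        from collections import deque

        dist = {src: 0}
        count = {src: 1}
        preds = {src: []}
        q = deque([src])
        while q:
            v = q.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    count[w] = 0
                    preds[w] = []
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    count[w] += count[v]
                    preds[w].append(v)
        return dist, count, preds

    bet = {v: 0.0 for v in nodes}
    node_list = sorted(nodes)
    for i, s in enumerate(node_list):
        dist_s, cnt_s, _ = shortest_paths(s)
        for t in node_list[i + 1 :]:
            if t not in dist_s or cnt_s[t] == 0:
                continue
            dist_t, cnt_t, _ = shortest_paths(t)
            for v in nodes:
                if v in (s, t) or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == dist_s[t]:
                    bet[v] += cnt_s[v] * cnt_t[v] / cnt_s[t]
    return bet
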