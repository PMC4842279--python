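"""Gene-gene co-association network: PCIT inference, reduction,
topology, centrality, and regulator ranking.

PCIT (partial correlation and information theory) removes an edge (x,y)
when some third gene z explains it: with first-order partial
correlations

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

and cyclic variants, the trio tolerance is the average of the ratios of
partial to direct correlation,

    eps = (1/3) (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz),

and (x,y) is flagged non-significant if |r_xy| < |eps * r_xz| and
|r_xy| < |eps * r_yz| for some z. Ratios with a zero direct correlation
are excluded from the average; a trio whose partial-correlation
denominator is non-positive (collinearity) is skipped and counted.

The surviving network is then reduced to the strongest co-associations:
edges with |r| >= mean(|r|) + k * SD(|r|) computed over the
PCIT-significant edges (k = 2 by default, sample SD).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from awmnet.awm import Awm
from awmnet.datatypes import (
    GeneAnnotation,
    REGULATOR_CLASSES,
    ValidationError,
)

#: two-sided 1 % normal quantile: |z| above this marks a trait as
#: co-associated with a gene's AWM row
TRAIT_Z_THRESHOLD = 2.5758293035489004


def correlation_matrix(awm: Awm) -> pd.DataFrame:
    """Pearson correlation between AWM rows (gene effect profiles)."""
    m = awm.values.to_numpy()
    if m.shape[1] < 3:
        raise ValidationError("row correlation needs >= 3 trait columns")
    sd = m.std(axis=1, ddof=1)
    bad = [awm.gene_ids[i] for i in np.nonzero(sd == 0)[0]]
    if bad:
        raise ValidationError(f"constant AWM row(s), correlation undefined: {bad[:5]}")
    c = np.corrcoef(m)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(np.clip(c, -1.0, 1.0), index=awm.gene_ids, columns=awm.gene_ids)


@dataclass
class PcitResult:
    """Outcome of the PCIT pass over a correlation matrix.

    ``kept`` is a boolean gene x gene matrix of significant edges;
    ``margin[i, j]`` is |r_ij| minus the strongest elimination threshold
    any trio imposed (negative for removed edges); ``removing_z`` and
    ``removing_eps`` describe that strongest trio (-1 / NaN when no
    valid trio touched the edge). ``n_skipped_trios`` counts collinear
    trios that were skipped.
    """

    labels: list[str]
    corr: np.ndarray
    kept: np.ndarray
    margin: np.ndarray
    removing_z: np.ndarray
    removing_eps: np.ndarray
    n_skipped_trios: int = 0

    def kept_edges(self) -> pd.DataFrame:
        return self.edge_table().query("pcit_kept")

    def edge_table(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.labels), k=1)
        lab = np.asarray(self.labels)
        return pd.DataFrame(
            {
                "gene1": lab[iu[0]],
                "gene2": lab[iu[1]],
                "r": self.corr[iu],
                "pcit_kept": self.kept[iu],
                "margin": self.margin[iu],
            }
        )


def pcit(corr: pd.DataFrame | np.ndarray) -> PcitResult:
    """Run PCIT on a square symmetric correlation matrix.

    Vectorized over the third node z: for each z an n x n tolerance
    matrix and elimination threshold are computed with array ops, giving
    O(n^3) work without a Python triple loop.
    """
    if isinstance(corr, pd.DataFrame):
        labels = list(corr.index)
        r = corr.to_numpy(float)
    else:
        r = np.asarray(corr, float)
        labels = [f"n{i}" for i in range(r.shape[0])]
    n = r.shape[0]
    if r.shape != (n, n) or not np.allclose(r, r.T, atol=1e-8):
        raise ValidationError("PCIT input must be a square symmetric matrix")
    if np.nanmax(np.abs(r)) > 1.0 + 1e-12:
        raise ValidationError("correlations outside [-1, 1]")
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)

    thr_best = np.full((n, n), -np.inf)
    z_best = np.full((n, n), -1, dtype=int)
    eps_best = np.full((n, n), np.nan)
    n_skipped = 0

    off_diag = ~np.eye(n, dtype=bool)
    one_minus_r2 = 1.0 - r * r

    for z in range(n):
        c = r[:, z]
        omc2 = 1.0 - c * c  # 1 - r_xz^2, per node
        # trio validity: all three partial denominators positive
        with np.errstate(divide="ignore", invalid="ignore"):
            valid = (
                (omc2[:, None] > 0.0)
                & (omc2[None, :] > 0.0)
                & (one_minus_r2 > 0.0)
            )
            p_xy = (r - np.outer(c, c)) / np.sqrt(np.outer(omc2, omc2))
            p_xz = (c[:, None] - r * c[None, :]) / np.sqrt(
                one_minus_r2 * omc2[None, :]
            )
            p_yz = (c[None, :] - r * c[:, None]) / np.sqrt(
                one_minus_r2 * omc2[:, None]
            )
            ratios = np.stack([p_xy / r, p_xz / c[:, None], p_yz / c[None, :]])
            directs = np.stack(
                [
                    np.broadcast_to(r, (n, n)),
                    np.broadcast_to(c[:, None], (n, n)),
                    np.broadcast_to(c[None, :], (n, n)),
                ]
            )
        include = (directs != 0.0) & valid[None, :, :]
        n_inc = include.sum(axis=0)
        eps = np.where(
            n_inc > 0,
            np.where(include, ratios, 0.0).sum(axis=0) / np.maximum(n_inc, 1),
            np.nan,
        )

        pair_mask = valid & off_diag & (n_inc > 0)
        pair_mask[z, :] = False
        pair_mask[:, z] = False
        # count skipped (collinear) trios: unordered pairs x<y, both != z
        invalid_pairs = (~valid) & off_diag
        invalid_pairs[z, :] = False
        invalid_pairs[:, z] = False
        n_skipped += int(np.triu(invalid_pairs, 1).sum())

        thr = np.abs(eps) * np.minimum(np.abs(c)[:, None], np.abs(c)[None, :])
        thr = np.where(pair_mask, thr, -np.inf)
        better = thr > thr_best
        thr_best = np.where(better, thr, thr_best)
        z_best = np.where(better, z, z_best)
        eps_best = np.where(better, eps, eps_best)

    finite = np.isfinite(thr_best)
    margin = np.where(finite, np.abs(r) - thr_best, np.abs(r))
    kept = ~(finite & (np.abs(r) < thr_best))
    np.fill_diagonal(kept, False)
    kept = kept & off_diag
    return PcitResult(
        labels=labels,
        corr=r,
        kept=kept,
        margin=margin,
        removing_z=z_best,
        removing_eps=eps_best,
        n_skipped_trios=n_skipped,
    )


@dataclass
class CoassocNetwork:
    """Co-association network with PCIT and reduction provenance."""

    nodes: pd.DataFrame  # index gene, columns: gene_class, awm_row
    edges: pd.DataFrame  # gene1, gene2, r, pcit_kept, reduced_kept
    threshold: float
    k: float
    pcit: PcitResult = field(repr=False, default=None)

    def reduced_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["reduced_kept"]]

    def graph(self, reduced: bool = True) -> nx.Graph:
        g = nx.Graph()
        edges = self.reduced_edges() if reduced else self.edges[self.edges["pcit_kept"]]
        for _, e in edges.iterrows():
            g.add_edge(e["gene1"], e["gene2"], weight=float(e["r"]))
        for node in g.nodes:
            if node in self.nodes.index:
                g.nodes[node]["gene_class"] = self.nodes.loc[node, "gene_class"]
        return g


def reduce_network(
    decisions: PcitResult,
    k: float = 2.0,
    ann: GeneAnnotation | None = None,
    awm: Awm | None = None,
    population_sd: bool = False,
) -> CoassocNetwork:
    """Keep only the strongest PCIT-significant co-associations.

    Threshold t = mean(|r|) + k * SD(|r|) over PCIT-significant edges
    (sample SD by default); edges with |r| >= t are retained. With
    fewer than 2 significant edges the reduction is skipped with a
    warning and all significant edges are retained.
    """
    edges = decisions.edge_table()
    sig = edges[edges["pcit_kept"]]
    if len(sig) < 2:
        import warnings

        warnings.warn("fewer than 2 PCIT-significant edges: reduction skipped")
        threshold = np.nan
        edges["reduced_kept"] = edges["pcit_kept"]
    else:
        absr = np.abs(sig["r"].to_numpy())
        sd = absr.std(ddof=0 if population_sd else 1)
        threshold = float(absr.mean() + k * sd)
        edges["reduced_kept"] = edges["pcit_kept"] & (
            np.abs(edges["r"]) >= threshold
        )

    classes = {}
    if ann is not None:
        classes = ann.genes["gene_class"].to_dict()
    rows = {}
    if awm is not None:
        rows = {g: i for i, g in enumerate(awm.gene_ids)}
    nodes = pd.DataFrame(
        {
            "gene_class": [
                classes.get(g, "protein_coding") for g in decisions.labels
            ],
            "awm_row": [rows.get(g, -1) for g in decisions.labels],
        },
        index=pd.Index(decisions.labels, name="gene"),
    )
    return CoassocNetwork(
        nodes=nodes, edges=edges, threshold=threshold, k=k, pcit=decisions
    )


def topology_stats(net: CoassocNetwork) -> dict:
    """Node/edge counts, degree distribution and components of the
    reduced network (isolated genes are not counted as nodes)."""
    g = net.graph(reduced=True)
    degrees = dict(g.degree())
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "mean_degree": (
            float(np.mean(list(degrees.values()))) if degrees else 0.0
        ),
        "degree_distribution": {str(n): int(d) for n, d in sorted(degrees.items())},
        "n_components": nx.number_connected_components(g) if degrees else 0,
        "reduction_threshold": net.threshold,
    }


def centrality(net: CoassocNetwork) -> pd.DataFrame:
    """Degree, closeness and betweenness centrality per connected node.

    Unweighted shortest-path definitions; betweenness is reported as
    raw pair counts (unnormalized), closeness within each component.
    """
    g = net.graph(reduced=True)
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["degree", "closeness", "betweenness"])
    deg = dict(g.degree())
    clo = nx.closeness_centrality(g)
    bet = nx.betweenness_centrality(g, normalized=False)
    return pd.DataFrame(
        {
            "degree": pd.Series(deg),
            "closeness": pd.Series(clo),
            "betweenness": pd.Series(bet),
        }
    ).sort_index()


def rank_regulators(
    net: CoassocNetwork,
    ann: GeneAnnotation,
    awm: Awm,
    z_threshold: float = TRAIT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Connectivity-based regulator exploration and greedy selection.

    Every network node annotated as TF/miRNA/lncRNA is scored by its
    degree in the reduced network, the number of traits its AWM row is
    co-associated with (|z| >= ``z_threshold``), and its neighbor set.
    A greedy maximum-coverage pass then picks a minimal regulator
    subset: at each step the regulator adding the most not-yet-covered
    neighbors is selected (ties: higher degree, then lexicographic gene
    id), stopping when the marginal gain hits zero.
    """
    g = net.graph(reduced=True)
    classes = ann.genes["gene_class"]
    reg_nodes = [
        node
        for node in g.nodes
        if node in classes.index and classes.loc[node] in REGULATOR_CLASSES
    ]
    if not reg_nodes:
        import warnings

        warnings.warn("no regulator (TF/miRNA/lncRNA) nodes in the network")
        return pd.DataFrame(
            columns=[
                "gene_class", "degree", "n_traits", "neighbors",
                "selected", "coverage_gain", "rank",
            ]
        )

    zmat = awm.values
    info = {}
    for node in reg_nodes:
        nbrs = frozenset(g.neighbors(node))
        n_traits = (
            int((zmat.loc[node].abs() >= z_threshold).sum())
            if node in zmat.index
            else 0
        )
        info[node] = {
            "gene_class": classes.loc[node],
            "degree": g.degree(node),
            "n_traits": n_traits,
            "neighbors": nbrs,
        }

    covered: set = set()
    gains: dict[str, int] = {}
    order: list[str] = []
    candidates = sorted(reg_nodes)
    while candidates:
        # candidates are in lexicographic order, so on full ties the
        # smallest gene id wins (strict > keeps the first maximum)
        best, best_key = None, (0, -1)
        for node in candidates:
            gain = len(info[node]["neighbors"] - covered)
            key = (gain, info[node]["degree"])
            if key > best_key:
                best, best_key = node, key
        if best is None or best_key[0] == 0:
            break
        order.append(best)
        gains[best] = best_key[0]
        covered |= set(info[best]["neighbors"])
        candidates.remove(best)

    rows = []
    for node in reg_nodes:
        rows.append(
            {
                "gene": node,
                "gene_class": info[node]["gene_class"],
                "degree": info[node]["degree"],
                "n_traits": info[node]["n_traits"],
                "neighbors": ",".join(sorted(info[node]["neighbors"])),
                "selected": node in gains,
                "coverage_gain": gains.get(node, 0),
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out = out.sort_values(
        ["coverage_gain", "degree", "n_traits"], ascending=False, kind="stable"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def write_network(net: CoassocNetwork, out_dir, ann=None, awm=None) -> None:
    """Export edge list TSV, GraphML, topology JSON, and (if annotation
    and AWM are given) the regulator table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net.edges.to_csv(out / "edges.tsv", sep="\t", index=False, float_format="%.10g")
    nx.write_graphml(net.graph(reduced=True), out / "network.graphml")
    topo = topology_stats(net)
    (out / "topology.json").write_text(json.dumps(topo, indent=2, default=float))
    if ann is not None and awm is not None:
        rank_regulators(net, ann, awm).to_csv(out / "regulators.tsv", sep="\t")
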