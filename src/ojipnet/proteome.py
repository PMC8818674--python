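"""Label-free proteome fold-change classification and correlation networks.

The workflow mirrors a standard label-free quantification comparison of a
control and a treated condition:

1. partition proteins by detection into condition-specific and common sets;
2. classify the common set by the treated/control abundance ratio into
   high-abundance (HAP, fold >= 2), low-abundance (LAP, fold <= 0.5) and
   unchanged species — the classical two-fold rule, boundaries inclusive;
3. bin proteins into functional groups via a static accession->group map;
4. build an undirected Pearson correlation network over the per-replicate
   fold profiles of the differential proteins, keeping edges with
   |r| >= 0.99 and p <= 0.05, and report degree, Watts-Strogatz local
   clustering, and component-scaled closeness centrality;
5. hierarchically cluster the correlation matrix (average linkage on
   d = 1 - r) with a deterministic smallest-index tie break.

Fold profiles are intentionally simple — replicate-wise treated/control
ratios — and the correlated dimension is configurable (``profile='raw'``
correlates raw replicate abundances instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

STATUS_CONTROL = "control_specific"
STATUS_TREATED = "treated_specific"
STATUS_COMMON = "common"

CLASS_HAP = "HAP"
CLASS_LAP = "LAP"
CLASS_UNCHANGED = "unchanged"


@dataclass
class AbundanceTable:
    """A per-protein label-free quantification table.

    ``data`` holds protein_id, accession, description, optionally
    functional_group, plus the replicate abundance columns named in
    ``control_cols`` and ``treated_cols``.  Missing values are treated as
    non-detection (0); abundances are non-negative.
    """

    data: pd.DataFrame
    control_cols: list[str]
    treated_cols: list[str]

    def __post_init__(self) -> None:
        df = self.data
        for col in ["protein_id", "accession", "description"]:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        for col in self.control_cols + self.treated_cols:
            if col not in df.columns:
                raise ValueError(f"missing replicate column {col!r}")
        if df["protein_id"].duplicated().any():
            dups = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        reps = df[self.control_cols + self.treated_cols]
        if (reps.fillna(0).to_numpy() < 0).any():
            raise ValueError("negative abundances are not allowed")
        self.data = df.reset_index(drop=True)

    @property
    def n_proteins(self) -> int:
        return len(self.data)

    @property
    def n_replicates(self) -> int:
        return len(self.control_cols)

    def control_matrix(self) -> np.ndarray:
        return self.data[self.control_cols].fillna(0).to_numpy(dtype=float)

    def treated_matrix(self) -> np.ndarray:
        return self.data[self.treated_cols].fillna(0).to_numpy(dtype=float)


def read_abundance_table(
    path: str | Path,
    control_cols: Sequence[str] | None = None,
    treated_cols: Sequence[str] | None = None,
) -> AbundanceTable:
    """Read a CSV/TSV abundance export.

    If the replicate columns are not given explicitly they are detected by
    the prefixes ``control`` and ``treated``.  Blank cells become 0
    (non-detection).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if control_cols is None:
        control_cols = [c for c in df.columns if c.lower().startswith("control")]
    if treated_cols is None:
        treated_cols = [c for c in df.columns if c.lower().startswith("treated")]
    if not control_cols or not treated_cols:
        raise ValueError("could not identify control/treated replicate columns")
    for col in list(control_cols) + list(treated_cols):
        df[col] = pd.to_numeric(df[col], errors="raise").fillna(0.0)
    if "functional_group" not in df.columns:
        df["functional_group"] = pd.NA
    return AbundanceTable(df, list(control_cols), list(treated_cols))


def write_abundance_table(tbl: AbundanceTable, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    tbl.data.to_csv(path, sep=sep, index=False)
    return path


def partition_presence(
    tbl: AbundanceTable, detection_min_reps: int = 1
) -> pd.Series:
    """Assign each protein a presence status.

    A protein is detected in a condition when at least ``detection_min_reps``
    of its replicates are positive.  Proteins detected in neither condition
    are dropped (the count is logged).  Returns a Series indexed by
    protein_id with values control_specific / treated_specific / common.
    """
    if detection_min_reps < 1 or detection_min_reps > tbl.n_replicates:
        raise ValueError("detection_min_reps must be in [1, n_replicates]")
    in_control = (tbl.control_matrix() > 0).sum(axis=1) >= detection_min_reps
    in_treated = (tbl.treated_matrix() > 0).sum(axis=1) >= detection_min_reps
    status = np.where(
        in_control & in_treated,
        STATUS_COMMON,
        np.where(in_control, STATUS_CONTROL, STATUS_TREATED),
    )
    detected = in_control | in_treated
    n_dropped = int((~detected).sum())
    if n_dropped:
        logger.info("dropped %d proteins detected in neither condition", n_dropped)
    return pd.Series(
        status[detected], index=tbl.data.loc[detected, "protein_id"], name="status"
    )


@dataclass
class FoldChangeClassification:
    """Presence partition plus HAP/LAP/unchanged classes for common proteins.

    ``table`` has one row per detected protein: protein_id, status,
    fold_change (NaN for condition-specific proteins), cls, flag.
    """

    table: pd.DataFrame
    low: float
    high: float

    def class_counts(self) -> pd.Series:
        common = self.table[self.table["status"] == STATUS_COMMON]
        return common["cls"].value_counts()

    def proteins_in_class(self, cls: str) -> list[str]:
        t = self.table
        return t.loc[
            (t["status"] == STATUS_COMMON) & (t["cls"] == cls), "protein_id"
        ].tolist()


def classify_fold_change(
    tbl: AbundanceTable,
    low: float = 0.5,
    high: float = 2.0,
    detection_min_reps: int = 1,
) -> FoldChangeClassification:
    """Classify common proteins by mean(treated)/mean(control) fold change.

    Boundaries are inclusive: FC >= ``high`` -> HAP, FC <= ``low`` -> LAP,
    anything between is unchanged.  A common protein whose control mean is
    zero (possible when ``detection_min_reps`` < replicate count) is an
    infinite-fold increase: classed HAP and flagged.
    """
    if not (0 < low < high):
        raise ValueError("thresholds must satisfy 0 < low < high")
    status = partition_presence(tbl, detection_min_reps)
    df = tbl.data.set_index("protein_id").loc[status.index]
    cm = df[tbl.control_cols].fillna(0).mean(axis=1)
    tm = df[tbl.treated_cols].fillna(0).mean(axis=1)

    rows = []
    for pid in status.index:
        st = status.loc[pid]
        fc = np.nan
        cls = None
        flag = ""
        if st == STATUS_COMMON:
            if cm.loc[pid] == 0:
                fc = np.inf
                cls = CLASS_HAP
                flag = "control_mean_zero"
            else:
                fc = tm.loc[pid] / cm.loc[pid]
                if fc >= high:
                    cls = CLASS_HAP
                elif fc <= low:
                    cls = CLASS_LAP
                else:
                    cls = CLASS_UNCHANGED
        rows.append(
            {
                "protein_id": pid,
                "accession": df.loc[pid, "accession"],
                "status": st,
                "fold_change": fc,
                "cls": cls,
                "flag": flag,
            }
        )
    return FoldChangeClassification(
        table=pd.DataFrame(rows), low=low, high=high
    )


def summarize_categories(
    cls: FoldChangeClassification,
    group_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class percentages over the common set, and functional-group counts.

    ``group_map`` maps accession to one of the functional categories
    (e.g. the 28 metabolic-pathway groups of a GO-based annotation);
    unmapped accessions fall into "unassigned".  Returns
    ``(class_summary, group_summary)``.
    """
    t = cls.table
    common = t[t["status"] == STATUS_COMMON]
    counts = common["cls"].value_counts()
    n_common = len(common)
    class_rows = [
        {
            "cls": c,
            "count": int(counts.get(c, 0)),
            "percent": 100.0 * counts.get(c, 0) / n_common if n_common else np.nan,
        }
        for c in (CLASS_HAP, CLASS_LAP, CLASS_UNCHANGED)
    ]
    group_map = dict(group_map or {})
    groups = t["accession"].map(lambda a: group_map.get(a, "unassigned"))
    group_rows = (
        pd.DataFrame({"functional_group": groups})
        .value_counts()
        .rename("count")
        .reset_index()
    )
    return pd.DataFrame(class_rows), group_rows


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column accession -> functional group TSV/CSV mapping."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("mapping file needs accession and group columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def fold_profiles(
    tbl: AbundanceTable,
    proteins: Sequence[str] | None = None,
    profile: str = "fold",
) -> pd.DataFrame:
    """Per-protein profile vectors used for correlation.

    ``profile='fold'`` (default): replicate-wise treated/control ratios,
    one value per replicate pair.  ``profile='raw'``: the concatenated raw
    replicate abundances.  Returns proteins x profile-points.
    """
    df = tbl.data.set_index("protein_id")
    if proteins is not None:
        df = df.loc[list(proteins)]
    c = df[tbl.control_cols].fillna(0).to_numpy(dtype=float)
    t = df[tbl.treated_cols].fillna(0).to_numpy(dtype=float)
    if profile == "fold":
        with np.errstate(divide="ignore", invalid="ignore"):
            mat = t / c
        mat[~np.isfinite(mat)] = np.nan
        cols = [f"fold_rep{i + 1}" for i in range(mat.shape[1])]
    elif profile == "raw":
        mat = np.hstack([c, t])
        cols = tbl.control_cols + tbl.treated_cols
    else:
        raise ValueError(f"unknown profile kind {profile!r}")
    return pd.DataFrame(mat, index=df.index, columns=cols)


def protein_correlation_matrix(
    tbl: AbundanceTable,
    proteins: Sequence[str] | None = None,
    profile: str = "fold",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p matrices over protein profiles.

    p-values come from the exact t transform t = r sqrt((n-2)/(1-r^2)) on
    n - 2 degrees of freedom (two-sided).  Zero-variance or incomplete
    profiles give NaN rows/columns, which network construction skips.
    """
    prof = fold_profiles(tbl, proteins, profile)
    mat = prof.to_numpy(dtype=float)
    n_points = mat.shape[1]
    if n_points < 3:
        raise ValueError("need at least 3 profile points per protein")
    valid = np.isfinite(mat).all(axis=1) & (np.nanstd(mat, axis=1) > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_full = np.corrcoef(mat)
    r_full[~valid, :] = np.nan
    r_full[:, ~valid] = np.nan
    np.fill_diagonal(r_full, np.where(valid, 1.0, np.nan))

    with np.errstate(invalid="ignore", divide="ignore"):
        rr = np.clip(r_full, -1.0, 1.0)
        tstat = rr * np.sqrt((n_points - 2) / (1.0 - rr**2))
    p = 2.0 * sps.t.sf(np.abs(tstat), n_points - 2)
    p[np.isclose(np.abs(rr), 1.0)] = 0.0
    p[np.isnan(r_full)] = np.nan
    np.fill_diagonal(p, 0.0)
    idx = prof.index
    return (
        pd.DataFrame(r_full, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def build_correlation_network(
    r_matrix: pd.DataFrame,
    p_matrix: pd.DataFrame,
    r_threshold: float = 0.99,
    p_threshold: float = 0.05,
) -> nx.Graph:
    """Thresholded undirected correlation graph.

    Edge (i, j) exists iff |r_ij| >= ``r_threshold`` and
    p_ij <= ``p_threshold``.  Nodes are all proteins with a defined
    correlation row; the graph is simple (no self loops, paired edges
    combined).
    """
    if list(r_matrix.index) != list(r_matrix.columns):
        raise ValueError("r matrix must be square with matching labels")
    if r_matrix.shape != p_matrix.shape:
        raise ValueError("r and p matrices must have the same shape")
    g = nx.Graph()
    labels = list(r_matrix.index)
    r = r_matrix.to_numpy()
    p = p_matrix.to_numpy()
    valid = ~np.all(np.isnan(r) | np.eye(len(labels), dtype=bool), axis=1)
    for lab, ok in zip(labels, valid):
        if ok:
            g.add_node(lab)
    for i in range(len(labels)):
        if not valid[i]:
            continue
        for j in range(i + 1, len(labels)):
            if not valid[j] or np.isnan(r[i, j]):
                continue
            if abs(r[i, j]) >= r_threshold and p[i, j] <= p_threshold:
                g.add_edge(labels[i], labels[j], r=float(r[i, j]))
    return g


def graph_statistics(g: nx.Graph) -> dict:
    """Degree, clustering and closeness summary of a correlation graph.

    mean_degree = 2E/N; the clustering coefficient is the Watts-Strogatz
    local coefficient (0 for degree < 2) averaged over all nodes; closeness
    uses the Wasserman-Faust component-scaled normalization so disconnected
    graphs remain well-defined.  Node attributes (degree, clustering,
    closeness) are written onto the graph as a side effect.
    """
    n = g.number_of_nodes()
    if n == 0:
        return {
            "n_nodes": 0,
            "n_edges": 0,
            "mean_degree": 0.0,
            "avg_clustering": 0.0,
            "closeness": {},
            "empty": True,
        }
    e = g.number_of_edges()
    clustering = nx.clustering(g)
    closeness = nx.closeness_centrality(g, wf_improved=True)
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    nx.set_node_attributes(g, clustering, "clustering")
    nx.set_node_attributes(g, closeness, "closeness")
    return {
        "n_nodes": n,
        "n_edges": e,
        "mean_degree": 2.0 * e / n,
        "avg_clustering": sum(clustering.values()) / n,
        "closeness": closeness,
        "empty": False,
    }


def degree_classes(
    g: nx.Graph, boundaries: tuple[float, float] = (40.0, 50.0)
) -> dict:
    """Bin nodes into low/mid/high connectivity classes by degree.

    Nodes with degree <= boundaries[0] are 'low', degree in
    (boundaries[0], boundaries[1]] are 'mid', above that 'high'.  The class
    is also stored as the node attribute ``degree_class``.
    """
    lo, hi = boundaries
    if not lo < hi:
        raise ValueError("boundaries must be increasing")
    out = {}
    for node, deg in g.degree():
        if deg <= lo:
            cls = "low"
        elif deg <= hi:
            cls = "mid"
        else:
            cls = "high"
        out[node] = cls
    nx.set_node_attributes(g, out, "degree_class")
    return out


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` lists (id_a, id_b, height, size) in merge order using the
    scipy convention: leaves are 0..n-1, the k-th merge creates cluster
    n + k.  ``labels`` maps leaf ids to protein ids and ``leaf_order`` is
    the left-to-right display order.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]
    leaf_order: list[str]


def hierarchical_cluster(r_matrix: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomerative clustering of d = 1 - r.

    Deterministic: at every step the pair with minimal average distance is
    merged, ties broken by the lexicographically smallest (id_a, id_b)
    pair.  Undefined (NaN) matrix entries are rejected with the offending
    proteins listed.
    """
    labels = list(r_matrix.index)
    r = r_matrix.to_numpy(dtype=float)
    if np.isnan(r).any():
        bad = [labels[i] for i in sorted(set(np.argwhere(np.isnan(r))[:, 0]))]
        raise ValueError(f"undefined correlation entries for proteins: {bad}")
    d = 1.0 - r
    n = len(labels)
    # active clusters: id -> set of leaf indices
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    next_id = n
    merges: list[tuple[int, int, float, int]] = []

    def avg_dist(a: int, b: int) -> float:
        ia, ib = clusters[a], clusters[b]
        return float(d[np.ix_(ia, ib)].mean())

    while len(clusters) > 1:
        ids = sorted(clusters)
        best: tuple[float, int, int] | None = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dist = avg_dist(a, b)
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
        assert best is not None
        dist, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        children[next_id] = (a, b)
        merges.append((a, b, dist, len(clusters[next_id])))
        next_id += 1

    # leaf order by depth-first traversal of the final tree
    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return walk(a) + walk(b)

    root = next_id - 1 if n > 1 else 0
    order = walk(root)
    return Dendrogram(
        merges=merges, labels=labels, leaf_order=[labels[i] for i in order]
    )


def export_graph(g: nx.Graph, path: str | Path, format: str = "graphml") -> Path:
    """Write a graph with all node/edge attributes.

    ``format='graphml'`` writes a single GraphML file; ``format='tsv'``
    writes ``<path>`` as an edge list (source, target, r) plus
    ``<path>.nodes.tsv`` with one row per node and its attributes.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "tsv":
        edges = pd.DataFrame(
            [
                {"source": u, "target": v, **data}
                for u, v, data in g.edges(data=True)
            ],
            columns=["source", "target"]
            + sorted({k for _, _, d in g.edges(data=True) for k in d}),
        )
        edges.to_csv(path, sep="\t", index=False)
        nodes = pd.DataFrame(
            [{"node": u, **data} for u, data in g.nodes(data=True)]
        )
        if nodes.empty:
            nodes = pd.DataFrame(columns=["node"])
        nodes.to_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown graph format {format!r}")
    return path


def import_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read back a graph written by :func:`export_graph`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "tsv":
        edges = pd.read_csv(path, sep="\t")
        nodes = pd.read_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t")
        g = nx.Graph()
        for _, row in nodes.iterrows():
            attrs = {k: v for k, v in row.items() if k != "node" and pd.notna(v)}
            g.add_node(row["node"], **attrs)
        for _, row in edges.iterrows():
            attrs = {
                k: v for k, v in row.items() if k not in ("source", "target")
            }
            g.add_edge(row["source"], row["target"], **attrs)
        return g
    raise ValueError(f"unknown graph format {format!r}")
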