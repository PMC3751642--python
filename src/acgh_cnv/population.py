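"""Per-line occurrence matrices, fixed / line-specific CNVR classification,
and CNV-genotype clustering of samples.

A CNVR is *fixed* in a line when every sampled animal of that line carries
some member CNV of the region (region-level carrier status: members of one
region differ in exact extent across samples, so exact-coordinate identity
would under-count).  It is *line-specific* when it is fixed in exactly one
line and, in the default strict mode, no animal outside that line carries
it at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .calling import UniqueCnv
from .regions import CnvRegion

__all__ = [
    "LOSS",
    "NONE",
    "GAIN",
    "LineCatalog",
    "RegionClassification",
    "ClusterResult",
    "occurrence_matrix",
    "classify_regions",
    "cluster_samples",
    "linkage_to_newick",
]

LOSS, NONE, GAIN = -1, 0, 1
_STATE_NAME = {LOSS: "loss", NONE: "none", GAIN: "gain"}


@dataclass
class LineCatalog:
    """Sample-to-line assignment for a cohort."""

    sample_to_line: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sample_to_line:
            raise ValueError("empty line catalog")

    @property
    def lines(self) -> list[str]:
        return sorted(set(self.sample_to_line.values()))

    @property
    def samples(self) -> list[str]:
        return sorted(self.sample_to_line)

    def samples_of(self, line: str) -> list[str]:
        out = [s for s, l in sorted(self.sample_to_line.items()) if l == line]
        if not out:
            raise KeyError(f"line {line!r} has no samples")
        return out


@dataclass
class RegionClassification:
    """Fixation status of one CNVR across the cohort's lines."""

    cnvr_id: str
    fixed_lines: set[str] = field(default_factory=set)
    is_fixed: bool = False
    is_line_specific: bool = False
    specific_line: str | None = None


def occurrence_matrix(
    regions: list[CnvRegion],
    cnvs: list[UniqueCnv],
    line_catalog: LineCatalog,
) -> pd.DataFrame:
    """Samples x regions matrix of states (-1 loss, 0 none, +1 gain).

    A sample's state for a region is the class of the member CNVs it
    carries; if it carries both classes within one region the class of the
    largest-overlap (i.e. largest, since members lie inside the region)
    member wins, ties broken by leftmost start then loss before gain.
    """
    cnv_by_id = {c.cnv_id: c for c in cnvs}
    samples = line_catalog.samples
    mat = pd.DataFrame(
        np.zeros((len(samples), len(regions)), dtype=np.int8),
        index=samples,
        columns=[r.cnvr_id for r in regions],
    )
    for region in regions:
        best: dict[str, tuple[int, int, str]] = {}  # sample -> (size, -start, class)
        for cnv_id in region.member_cnvs:
            cnv = cnv_by_id[cnv_id]
            for sample in cnv.carrier_samples:
                if sample not in line_catalog.sample_to_line:
                    raise KeyError(f"sample {sample!r} missing from line catalog")
                key = (cnv.size_bp, -cnv.start, cnv.cnv_class)
                prev = best.get(sample)
                # bigger member wins; then leftmost; then "gain" < "loss"
                # lexicographically so max() prefers loss on full ties
                if prev is None or key > prev:
                    best[sample] = key
        for sample, (_, _, cls) in best.items():
            mat.loc[sample, region.cnvr_id] = GAIN if cls == "gain" else LOSS
    return mat


def classify_regions(
    matrix: pd.DataFrame,
    line_catalog: LineCatalog,
    strict_specific: bool = True,
) -> list[RegionClassification]:
    """Classify each CNVR as fixed and/or line-specific.

    Fixed in line L: every sample of L has a non-none state.  Line-specific:
    fixed in exactly one line and (strict mode) carried by no sample outside
    that line; the lenient mode drops the outside-carrier condition.
    """
    for line in line_catalog.lines:
        line_catalog.samples_of(line)  # raises on empty lines
    missing = set(matrix.index) - set(line_catalog.sample_to_line)
    if missing:
        raise KeyError(f"samples missing from line catalog: {sorted(missing)}")
    out: list[RegionClassification] = []
    line_rows = {line: line_catalog.samples_of(line) for line in line_catalog.lines}
    for cnvr_id in matrix.columns:
        col = matrix[cnvr_id]
        fixed = {line for line, rows in line_rows.items() if (col.loc[rows] != NONE).all()}
        cls = RegionClassification(cnvr_id=cnvr_id, fixed_lines=fixed, is_fixed=bool(fixed))
        if len(fixed) == 1:
            (line,) = fixed
            outside = [s for s in matrix.index if line_catalog.sample_to_line[s] != line]
            no_outside_carriers = not (col.loc[outside] != NONE).any()
            if no_outside_carriers or not strict_specific:
                cls.is_line_specific = True
                cls.specific_line = line
        out.append(cls)
    return out


@dataclass
class ClusterResult:
    """Hierarchical clustering of samples by CNV genotype."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray
    distance: str
    linkage: str

    def flat_clusters(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in labels)))

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage_matrix, self.sample_ids)


def _pairwise_distance(states: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance matrix over sample rows of a state matrix.

    jaccard: 1 - |carriers in both| / |carriers in either| on non-none
    indicators, with the empty-union distance defined as 0 (two samples
    with no CNV at all are identical).  hamming: fraction of regions with
    differing three-valued states.
    """
    n = states.shape[0]
    dist = np.zeros((n, n))
    carrier = states != NONE
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "jaccard":
                union = np.sum(carrier[i] | carrier[j])
                inter = np.sum(carrier[i] & carrier[j])
                d = 0.0 if union == 0 else 1.0 - inter / union
            elif metric == "hamming":
                d = float(np.mean(states[i] != states[j])) if states.shape[1] else 0.0
            else:
                raise ValueError(f"unknown distance {metric!r}")
            dist[i, j] = dist[j, i] = d
    return squareform(dist, checks=False)


def cluster_samples(
    matrix: pd.DataFrame,
    distance: str = "jaccard",
    linkage: str = "average",
) -> ClusterResult:
    """Cluster samples hierarchically on their CNV genotypes.

    Samples are ordered lexicographically before computing distances, which
    fixes the dendrogram under ties; identical samples merge at height 0.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 samples to cluster")
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    ordered = matrix.sort_index()
    condensed = _pairwise_distance(ordered.to_numpy(), distance)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterResult(
        sample_ids=list(ordered.index),
        linkage_matrix=Z,
        distance=distance,
        linkage=linkage,
    )


def linkage_to_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage_matrix)

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
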