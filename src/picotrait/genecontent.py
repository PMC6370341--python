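"""Pangenome presence/absence analysis with genome-recovery correction.

Single-cell genome assemblies are partial, so a gene cluster shared by every
*cell* still appears in only a fraction of *assemblies*.  The core threshold
here corrects for that: with n genomes at median recovery M, a cluster found
in at least floor(n * M) genomes is operationally core.  Clusters that are
core, or too rare to be informative (< 3 genomes by default), are excluded
before covariation and enrichment analysis of the remaining flexible genes.

Enrichment of flexible clusters in a marker-positive genome set (e.g. genomes
carrying the nitrate reductase gene) uses hypergeometric tails in both
directions with Benjamini-Hochberg correction, and the PCR-vs-annotation
concordance report quantifies how well a presence/absence screen agrees with
partial-assembly annotations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenePresenceTable",
    "EnrichmentRow",
    "ConcordanceCounts",
    "ConcordanceReport",
    "core_threshold",
    "filter_flexible",
    "jaccard_linkage",
    "linkage_to_newick",
    "marker_enrichment",
    "concordance_stats",
    "read_presence_table",
]


@dataclass
class GenePresenceTable:
    """Genome x gene-cluster binary matrix with per-genome recovery fractions.

    matrix
        DataFrame indexed by genome id, columns are gene-cluster ids,
        entries in {0, 1}.
    recovery
        Estimated assembly completeness per genome, in (0, 1].
    marker
        Optional boolean per genome (e.g. narB present by PCR or annotation).
    """

    matrix: pd.DataFrame
    recovery: pd.Series
    marker: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0 or 1")
        if self.matrix.index.duplicated().any() or self.matrix.columns.duplicated().any():
            raise ValueError("genome and gene-cluster ids must be unique")
        self.recovery = self.recovery.reindex(self.matrix.index)
        if self.recovery.isna().any():
            missing = list(self.matrix.index[self.recovery.isna()])
            raise ValueError(f"recovery fraction missing for genomes: {missing}")
        if ((self.recovery <= 0) | (self.recovery > 1)).any():
            raise ValueError("recovery fractions must be in (0, 1]")
        if self.marker is not None:
            self.marker = self.marker.reindex(self.matrix.index).astype(bool)

    @property
    def genomes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def gene_clusters(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def median_recovery(self) -> float:
        return float(self.recovery.median())


def read_presence_table(matrix_path, recovery_path, marker_path=None) -> GenePresenceTable:
    """Assemble a GenePresenceTable from TSV files (genomes as rows)."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    rec = pd.read_csv(recovery_path, sep="\t", index_col=0).iloc[:, 0]
    marker = None
    if marker_path is not None:
        marker = pd.read_csv(marker_path, sep="\t", index_col=0).iloc[:, 0].astype(bool)
    return GenePresenceTable(matrix=matrix, recovery=rec, marker=marker)


def core_threshold(n_genomes: int, median_recovery: float) -> int:
    """Minimum genome count at which a cluster is classified core.

    ``floor(n_genomes * median_recovery)``: e.g. 22 genomes at median
    recovery 0.87 gives 19.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if not (0 < median_recovery <= 1):
        raise ValueError("median_recovery must be in (0, 1]")
    return math.floor(round(n_genomes * median_recovery, 9))


def filter_flexible(table: GenePresenceTable, min_genomes: int = 3) -> GenePresenceTable:
    """Drop core clusters and clusters present in fewer than ``min_genomes``.

    Genomes are unchanged; idempotent.  Emits a warning (not an error) when
    no flexible cluster survives.
    """
    threshold = core_threshold(len(table.genomes), table.median_recovery)
    counts = table.matrix.sum(axis=0)
    keep = counts.index[(counts >= min_genomes) & (counts < threshold)]
    if len(keep) == 0:
        warnings.warn("no flexible gene clusters survive filtering", stacklevel=2)
    return GenePresenceTable(
        matrix=table.matrix[keep].copy(),
        recovery=table.recovery.copy(),
        marker=None if table.marker is None else table.marker.copy(),
    )


def jaccard_linkage(table: GenePresenceTable):
    """Average-linkage (UPGMA) clustering of gene clusters by Jaccard distance.

    Distance between two clusters is 1 - |A∩B| / |A∪B| over their
    genome-presence sets.  Returns ``(linkage_matrix, labels)`` in scipy
    linkage format (deterministic for a given table).
    """
    if table.matrix.shape[1] < 2:
        raise ValueError("need >= 2 gene clusters to build a dendrogram")
    counts = table.matrix.sum(axis=0)
    empties = list(counts.index[counts == 0])
    if empties:
        raise ValueError(
            f"Jaccard distance undefined for clusters present in zero genomes: {empties}"
        )
    X = table.matrix.to_numpy(dtype=bool).T  # clusters x genomes
    d = pdist(X, metric="jaccard")
    Z = linkage(d, method="average")
    return Z, list(table.matrix.columns)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as Newick with merge heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"


@dataclass
class EnrichmentRow:
    gene_cluster: str
    k: int  # count in marker-positive genomes
    n: int  # marker-positive genomes
    K: int  # count in all genomes
    N: int  # all genomes
    p: float
    q: float
    direction: str  # "over" | "under"


def marker_enrichment(table: GenePresenceTable) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of each cluster in marker-positive genomes.

    Over- and under-representation are assessed separately (upper and lower
    hypergeometric tails) and BH-corrected across clusters within each
    direction, mirroring how GO-style enrichment tools report the two sides.
    Rows are returned sorted by q then cluster id.
    """
    if table.marker is None:
        raise ValueError("table has no marker flags")
    marker = table.marker.to_numpy()
    n = int(marker.sum())
    N = len(table.genomes)
    if n == 0 or n == N:
        raise ValueError("need >= 1 marker-positive and >= 1 marker-negative genome")
    clusters = table.gene_clusters
    K = table.matrix.sum(axis=0).to_numpy()
    k = table.matrix.to_numpy()[marker].sum(axis=0)
    p_over = hypergeom.sf(k - 1, N, K, n)
    p_under = hypergeom.cdf(k, N, K, n)
    rows: list[EnrichmentRow] = []
    for direction, pvals in (("over", p_over), ("under", p_under)):
        pvals = np.clip(pvals, 0.0, 1.0)
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        qvals = np.maximum(qvals, pvals)  # BH q never below p
        for j, cluster in enumerate(clusters):
            rows.append(
                EnrichmentRow(
                    gene_cluster=cluster,
                    k=int(k[j]),
                    n=n,
                    K=int(K[j]),
                    N=N,
                    p=float(pvals[j]),
                    q=float(qvals[j]),
                    direction=direction,
                )
            )
    rows.sort(key=lambda r: (r.q, r.p, r.gene_cluster, r.direction))
    return rows


@dataclass
class ConcordanceCounts:
    """Screen-vs-annotation 2x2 counts for a marker gene.

    total genomes screened; ``annotated`` positive by assembly annotation;
    ``pcr`` positive by the PCR screen; ``both`` positive by both.
    """

    total: int
    annotated: int
    pcr: int
    both: int

    def __post_init__(self) -> None:
        if self.both > min(self.annotated, self.pcr):
            raise ValueError("both-positive count exceeds a marginal count")
        if max(self.annotated, self.pcr) > self.total:
            raise ValueError("marginal count exceeds total")
        if self.annotated + self.pcr - self.both > self.total:
            raise ValueError("counts imply a negative both-negative cell")


def _round_half_up(x: float) -> Optional[int]:
    if math.isnan(x):
        return None
    return math.floor(x + 0.5)


@dataclass
class ConcordanceReport:
    counts: ConcordanceCounts
    agreement: float
    agreement_pct: int
    pcr_pos_given_annotated: float
    pcr_pos_given_annotated_pct: Optional[int]
    annotated_given_pcr_pos: float
    annotated_given_pcr_pos_pct: Optional[int]
    expected_annotated: int
    false_negative_rate: Optional[float]
    false_negative_rate_pct: Optional[int]


def concordance_stats(
    counts: ConcordanceCounts, median_recovery_pcr_pos: float
) -> ConcordanceReport:
    """Concordance arithmetic between a PCR screen and assembly annotations.

    Agreement counts genomes where both methods agree (positive or negative).
    Because assemblies are partial, only ``round(pcr-positive x median
    recovery)`` annotated positives are *expected*; the shortfall of observed
    double-positives against that expectation gives a post hoc false-negative
    rate for the screen.  Integer percents use round-half-up; raw fractions
    are retained alongside.
    """
    c = counts
    both_neg = c.total - (c.annotated + c.pcr - c.both)
    agreement = (c.both + both_neg) / c.total
    frac_ann_pcr = c.both / c.annotated if c.annotated else float("nan")
    frac_pcr_ann = c.both / c.pcr if c.pcr else float("nan")
    expected = _round_half_up(c.pcr * median_recovery_pcr_pos)
    if expected == 0:
        fn_rate: Optional[float] = None
        fn_pct: Optional[int] = None
    else:
        fn_rate = (expected - c.both) / expected
        fn_pct = _round_half_up(100 * fn_rate)
    return ConcordanceReport(
        counts=c,
        agreement=agreement,
        agreement_pct=_round_half_up(100 * agreement),
        pcr_pos_given_annotated=frac_ann_pcr,
        pcr_pos_given_annotated_pct=_round_half_up(100 * frac_ann_pcr),
        annotated_given_pcr_pos=frac_pcr_ann,
        annotated_given_pcr_pos_pct=_round_half_up(100 * frac_pcr_ann),
        expected_annotated=expected,
        false_negative_rate=fn_rate,
        false_negative_rate_pct=fn_pct,
    )
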