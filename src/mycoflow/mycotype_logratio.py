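"""Mycotype construction and compositional log-ratio analysis.

Starting from a conditional co-occurrence matrix between fungal genera and
another data modality (bacterial genera or immune cell fractions, e.g. as
produced by a neural co-occurrence model), rows are z-scored, entries
inconsistent across data-submission centers are filtered out, and fungal
genera are partitioned into three "mycotypes" (F1/F2/F3) by average-linkage
hierarchical clustering. Features of the other modality are then assigned
to the mycotype whose fungal members give them the largest co-occurrence.

Downstream, per-sample abundances are compared between mycotypes by
pairwise log-ratios of group sums with a pseudocount of one added to each
sum — a reference-frame-stable compositional statistic that does not depend
on total sequencing depth in the large-count limit.

A published three-mycotype fungal model (F1 = Malassezia, Ramularia,
Trichosporon; F2 = Candida, Aspergillus; F3 = 18 further genera) ships with
the package so log-ratio analyses can run without re-deriving clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import FeatureTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CoocMatrix",
    "MycotypeModel",
    "LogRatioResult",
    "zscore_rows",
    "center_consistency_filter",
    "hierarchical_partition",
    "assign_cross_domain",
    "mycotype_logratio",
    "load_published_model",
]


@dataclass
class CoocMatrix:
    """Conditional co-occurrence matrix (one domain's features x another's)."""

    data: pd.DataFrame
    center: str = ""
    zscored: bool = False
    flagged_rows: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Matrix preparation
# ---------------------------------------------------------------------------

def zscore_rows(m: CoocMatrix) -> CoocMatrix:
    """Standardize each row by its own mean and population SD.

    Zero-variance rows are set to all zeros and flagged rather than
    producing NaNs.
    """
    if m.data.shape[1] < 2:
        raise ValidationError("z-scoring needs at least 2 columns")
    values = m.data.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD (ddof=0)
    flat = (sd[:, 0] == 0)
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat, :] = 0.0
    flagged = [str(r) for r in m.data.index[flat]]
    if flagged:
        logger.warning("zero-variance rows set to 0: %s", flagged)
    return CoocMatrix(data=pd.DataFrame(z, index=m.data.index,
                                        columns=m.data.columns),
                      center=m.center, zscored=True, flagged_rows=flagged)


def center_consistency_filter(matrices: list[CoocMatrix],
                              criterion: str = "literal"
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep entries consistent across submission centers; return the median.

    For every entry, the median and the standard error of the mean (SEM,
    sample SD with n-1) are computed across centers. The default "literal"
    criterion retains entries with |median| < SEM; the "strict" alternative
    retains entries whose per-center values all lie within one SEM of the
    median. Returns ``(mask, median_matrix)`` where the median matrix is
    NaN outside the retained mask. A single center passes through unchanged
    (identity filter, logged).
    """
    if not matrices:
        raise ValidationError("no matrices given")
    index, columns = matrices[0].data.index, matrices[0].data.columns
    for m in matrices[1:]:
        if not (m.data.index.equals(index) and m.data.columns.equals(columns)):
            raise ValidationError("matrices must have aligned feature sets")
    if len(matrices) == 1:
        logger.warning("single center: consistency filter is the identity")
        mask = pd.DataFrame(True, index=index, columns=columns)
        return mask, matrices[0].data.copy()

    stack = np.stack([m.data.to_numpy(dtype=float) for m in matrices])
    median = np.median(stack, axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    if criterion == "literal":
        keep = np.abs(median) < sem
    elif criterion == "strict":
        keep = (np.abs(stack - median) <= sem).all(axis=0)
    else:
        raise ValidationError(f"unknown criterion {criterion!r}")
    mask = pd.DataFrame(keep, index=index, columns=columns)
    med = pd.DataFrame(np.where(keep, median, np.nan), index=index,
                       columns=columns)
    return mask, med


# ---------------------------------------------------------------------------
# Clustering and assignment
# ---------------------------------------------------------------------------

def hierarchical_partition(m: CoocMatrix, n_clusters: int = 3) -> dict[str, int]:
    """Average-linkage / Euclidean agglomeration cut to ``n_clusters``.

    Rows are sorted lexicographically by feature id before linkage so the
    partition is deterministic and invariant to input row order; cluster
    labels are renumbered 1..k by order of first appearance in that sorted
    order.
    """
    if m.data.shape[0] < n_clusters:
        raise ValidationError(
            f"{m.data.shape[0]} rows cannot form {n_clusters} clusters")
    order = sorted(m.data.index)
    values = m.data.loc[order].to_numpy(dtype=float)
    if n_clusters == len(order):
        return {fid: i + 1 for i, fid in enumerate(order)}
    link = hierarchy.linkage(pdist(values, metric="euclidean"),
                             method="average")
    raw = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for fid, lab in zip(order, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[fid] = relabel[lab]
    return labels


def assign_cross_domain(cooc: CoocMatrix, fungal_labels: dict[str, int],
                        mode: str = "mean") -> dict[str, int]:
    """Assign each column feature to a mycotype by within-cluster co-occurrence.

    ``cooc`` has fungal features as rows and the other domain as columns.
    Each column goes to the cluster whose fungal members give it the maximal
    mean co-occurrence ("mean" mode, default) or maximal single
    co-occurrence ("max" mode). Exact ties break toward the lower-numbered
    mycotype and are logged.
    """
    missing = set(cooc.data.index) - set(fungal_labels)
    if missing:
        raise ValidationError(f"fungal rows without labels: {sorted(missing)}")
    if mode not in ("mean", "max"):
        raise ValidationError(f"unknown mode {mode!r}")
    clusters = sorted(set(fungal_labels.values()))
    members = {c: [f for f in cooc.data.index if fungal_labels[f] == c]
               for c in clusters}
    out: dict[str, int] = {}
    for col in cooc.data.columns:
        scores = []
        for c in clusters:
            vals = cooc.data.loc[members[c], col].to_numpy(dtype=float)
            scores.append(vals.mean() if mode == "mean" else vals.max())
        scores = np.asarray(scores)
        best = scores.max()
        winners = [clusters[i] for i in np.flatnonzero(scores >= best)]
        if len(winners) > 1:
            logger.warning("tie for %s between mycotypes %s; taking %s",
                           col, winners, winners[0])
        out[str(col)] = winners[0]
    return out


# ---------------------------------------------------------------------------
# Mycotype model and log-ratios
# ---------------------------------------------------------------------------

@dataclass
class MycotypeModel:
    """Genus -> mycotype assignment for one or more domains."""

    assignments: pd.DataFrame  # columns: genus, domain, mycotype
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        needed = {"genus", "domain", "mycotype"}
        if not needed <= set(self.assignments.columns):
            raise ValidationError(
                f"model needs columns {sorted(needed)}, got "
                f"{list(self.assignments.columns)}")
        if self.assignments.duplicated(["genus", "domain"]).any():
            raise ValidationError("duplicate genus/domain rows in model")

    def members(self, mycotype: str, domain: str = "fungus") -> list[str]:
        sel = ((self.assignments["mycotype"] == mycotype)
               & (self.assignments["domain"] == domain))
        return self.assignments.loc[sel, "genus"].tolist()

    @classmethod
    def from_tsv(cls, path) -> "MycotypeModel":
        return cls(assignments=pd.read_csv(path, sep="\t"),
                   provenance={"source": str(path)})

    def to_tsv(self, path) -> None:
        self.assignments.to_csv(path, sep="\t", index=False)


def load_published_model() -> MycotypeModel:
    """The published pan-cancer F1/F2/F3 fungal mycotype memberships."""
    ref = resources.files("mycoflow.data") / "mycotypes_f123.tsv"
    with resources.as_file(ref) as path:
        model = MycotypeModel.from_tsv(path)
    model.provenance = {"source": "bundled published model"}
    return model


@dataclass
class LogRatioResult:
    """Per-sample log-ratio of two mycotype group sums."""

    values: pd.Series  # indexed by sample id
    numerator: str
    denominator: str
    pseudocount: float

    def to_frame(self) -> pd.DataFrame:
        return self.values.rename(
            f"log_ratio_{self.numerator}_{self.denominator}").to_frame()


def mycotype_logratio(table: FeatureTable, model: MycotypeModel,
                      numerator: str, denominator: str,
                      domain: str = "fungus", pseudocount: float = 1.0
                      ) -> LogRatioResult:
    """Per-sample ln((sum over numerator group + c) / (sum over denominator
    group + c)) with pseudocount c added to each group sum.

    Features are matched to model genera by the genus rank of their lineage
    when taxonomy is attached, falling back to exact feature-id match. An
    empty intersection for either group is an error naming the genera.
    """
    if numerator == denominator:
        raise ValidationError("numerator and denominator must differ")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")

    def genus_of(fid: str) -> str:
        if table.taxonomy and fid in table.taxonomy:
            return table.taxonomy[fid].name_at("genus")
        return fid

    feature_genus = pd.Series({fid: genus_of(fid) for fid in table.feature_ids})
    sums = {}
    for group in (numerator, denominator):
        genera = set(model.members(group, domain))
        if not genera:
            raise ValidationError(f"model has no {domain} genera for {group!r}")
        hit = feature_genus.index[feature_genus.isin(genera)]
        if len(hit) == 0:
            raise ValidationError(
                f"none of the {group!r} genera {sorted(genera)} are in the table")
        sums[group] = table.counts.loc[hit].sum(axis=0)
    # difference of logs (not log of ratio) so LR(A,B) == -LR(B,A) bit-exactly
    values = (np.log(sums[numerator] + pseudocount)
              - np.log(sums[denominator] + pseudocount))
    return LogRatioResult(values=values, numerator=numerator,
                          denominator=denominator, pseudocount=pseudocount)
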