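"""Co-occurrence networks from presence/absence via normalized mutual information.

For each tissue, every pair of taxa (fungus-fungus FF, bacterium-bacterium
BB, fungus-bacterium FB) is scored by the normalized mutual information of
their binary presence vectors over the tissue's M samples,

    NMI(X, Y) = I(X, Y) / sqrt(H(X) H(Y)),   I = H(X) + H(Y) - H(X, Y),

with plug-in Shannon entropies. NMI lies in [0, 1]; 0 means no association
and 1 a deterministic relationship (always together or always apart — the
sign is supplied separately by the Pearson correlation of the two vectors).

Significance comes from a richness-weighted permutation null: each
realization independently reshuffles both presence vectors across samples,
keeping each taxon's total presence count and placing presences with
probability proportional to per-sample observed richness

    w_i = (# observed taxa in sample i) / (# observed taxa in all samples),

so that sample-richness structure — a strong driver of spurious
co-occurrence in presence data — is preserved under the null. The p-value
is the fraction of realizations whose shuffled NMI meets or exceeds the
observed one. Benjamini-Hochberg correction runs within each (tissue,
edge class) p-value list and edges with q <= 0.2 are retained.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_io import FeatureTable, NmiEdge, NmiNetwork, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceMatrix",
    "binary_entropy",
    "nmi",
    "compute_weights",
    "weighted_shuffle",
    "permutation_pvalue",
    "build_network",
]


@dataclass
class PresenceMatrix:
    """Binary taxa-by-samples matrix with a domain label per taxon."""

    data: pd.DataFrame  # boolean, taxa x samples
    domain: str  # "fungus" or "bacterium"

    def __post_init__(self):
        values = self.data.to_numpy()
        if values.size and not np.isin(values, [0, 1]).all():
            raise ValidationError("presence matrix entries must be 0/1")
        self.data = self.data.astype(bool)
        if self.domain not in ("fungus", "bacterium"):
            raise ValidationError(f"unknown domain {self.domain!r}")

    @classmethod
    def from_table(cls, table: FeatureTable, domain: str) -> "PresenceMatrix":
        if table.state not in ("floored", "floored_normalized"):
            raise ValidationError(
                "presence is defined on floored tables; got state "
                f"{table.state!r}")
        return cls(data=table.presence(), domain=domain)


# ---------------------------------------------------------------------------
# Entropy and NMI
# ---------------------------------------------------------------------------

def _plogp(p: np.ndarray | float) -> np.ndarray | float:
    """-p*log(p) with the 0*log(0) := 0 convention (natural log)."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = -p[nz] * np.log(p[nz])
    return out


def binary_entropy(x) -> float:
    """Plug-in Shannon entropy (nats) of a binary vector."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValidationError("entropy of an empty vector is undefined")
    p1 = float(np.count_nonzero(x)) / x.size
    return float(_plogp(p1) + _plogp(1.0 - p1))


def _nmi_from_counts(m: int, kx, ky, n11):
    """NMI from the 2x2 joint determined by (M, sum x, sum y, x.y).

    Vectorized over n11 (and kx/ky when arrays). Returns NaN where either
    margin is constant (H = 0 makes the ratio undefined).
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    n11 = np.asarray(n11, dtype=float)
    # canonical margin order makes nmi(x, y) == nmi(y, x) bit-exactly
    kx, ky = np.minimum(kx, ky), np.maximum(kx, ky)
    p11 = n11 / m
    p10 = (kx - n11) / m
    p01 = (ky - n11) / m
    p00 = 1.0 - p11 - p10 - p01
    hxy = _plogp(p11) + _plogp(p10) + _plogp(p01) + _plogp(np.clip(p00, 0, 1))
    hx = _plogp(kx / m) + _plogp(1 - kx / m)
    hy = _plogp(ky / m) + _plogp(1 - ky / m)
    with np.errstate(divide="ignore", invalid="ignore"):
        value = (hx + hy - hxy) / np.sqrt(hx * hy)
    value = np.where((hx <= 0) | (hy <= 0), np.nan, value)
    return np.clip(value, 0.0, 1.0)


def nmi(x, y) -> float:
    """Normalized mutual information of two equal-length binary vectors.

    Returns NaN when either vector is constant (zero entropy)."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("nmi requires two equal-length vectors")
    m = x.size
    if m == 0:
        raise ValidationError("nmi of empty vectors is undefined")
    return float(_nmi_from_counts(m, int(x.sum()), int(y.sum()),
                                  int((x & y).sum())))


# ---------------------------------------------------------------------------
# Weighted shuffling null
# ---------------------------------------------------------------------------

def compute_weights(fungal: PresenceMatrix, bacterial: PresenceMatrix | None = None
                    ) -> np.ndarray:
    """Per-sample shuffle weights from observed richness.

    Richness counts taxa over the combined fungal+bacterial presence matrix;
    weights are normalized to sum to 1.
    """
    frames = [fungal.data]
    if bacterial is not None:
        if list(bacterial.data.columns) != list(fungal.data.columns):
            raise ValidationError("presence matrices must share sample sets")
        frames.append(bacterial.data)
    richness = sum(f.sum(axis=0).to_numpy(dtype=float) for f in frames)
    total = richness.sum()
    if total == 0:
        raise ValidationError("all-zero cohort; shuffle weights undefined")
    return richness / total


def _gumbel_keys(log_w: np.ndarray, size: tuple, rng: np.random.Generator
                 ) -> np.ndarray:
    return log_w + rng.gumbel(size=size)


def _batch_weighted_placements(k: int, w: np.ndarray, n: int,
                               rng: np.random.Generator) -> np.ndarray:
    """n independent placements of k presences over len(w) samples.

    Uses Gumbel-top-k keys, equivalent to sequential weighted sampling
    without replacement with probabilities proportional to the remaining
    weights. Returns a boolean (n, M) matrix with exactly k True per row.
    """
    m = w.size
    if k <= 0:
        return np.zeros((n, m), dtype=bool)
    if k >= m:
        return np.ones((n, m), dtype=bool)
    n_pos = int(np.count_nonzero(w))
    if k > n_pos:
        logger.warning(
            "presence count %d exceeds the %d samples with positive weight; "
            "zero-weight samples included in the shuffle", k, n_pos)
    with np.errstate(divide="ignore"):
        log_w = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -1e12)
    keys = _gumbel_keys(log_w, (n, m), rng)
    top = np.argpartition(-keys, k - 1, axis=1)[:, :k]
    out = np.zeros((n, m), dtype=bool)
    np.put_along_axis(out, top, True, axis=1)
    return out


def weighted_shuffle(x, w, rng: np.random.Generator) -> np.ndarray:
    """Reshuffle a presence vector across samples with weighted placement.

    The presence count sum(x) is conserved exactly; presences land on
    samples with probability proportional to ``w`` (sequential sampling
    without replacement).
    """
    x = np.asarray(x).astype(bool)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise ValidationError("x and w must have the same length")
    return _batch_weighted_placements(int(x.sum()), w, 1, rng)[0]


def permutation_pvalue(x, y, w, n_shuffles: int = 1000,
                       rng: np.random.Generator | None = None,
                       smoothed: bool = False) -> float:
    """Permutation p-value for the observed NMI under the weighted null.

    Both vectors are independently reshuffled in every realization; p is
    the fraction of realizations with shuffled NMI >= observed. With
    ``smoothed`` the (b+1)/(m+1) estimator is used instead of the raw
    fraction, giving a nonzero floor.
    """
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    w = np.asarray(w, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    m = x.size
    observed = nmi(x, y)
    if np.isnan(observed):
        return float("nan")
    kx, ky = int(x.sum()), int(y.sum())
    xs = _batch_weighted_placements(kx, w, n_shuffles, rng)
    ys = _batch_weighted_placements(ky, w, n_shuffles, rng)
    n11 = (xs & ys).sum(axis=1)
    null = _nmi_from_counts(m, kx, ky, n11)
    hits = int(np.count_nonzero(null >= observed - 1e-12))
    if smoothed:
        return (hits + 1) / (n_shuffles + 1)
    return hits / n_shuffles


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _pair_rng(seed: int, a: str, b: str) -> np.random.Generator:
    """Deterministic per-pair substream independent of iteration order."""
    digest = hashlib.blake2b(f"{min(a, b)}|{max(a, b)}".encode(),
                             digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "little")]))


def _pearson_sign(x: np.ndarray, y: np.ndarray) -> str:
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x.astype(float), y.astype(float))[0, 1]
    return "+" if (np.isnan(r) or r >= 0) else "-"


def build_network(fungal: FeatureTable, bacterial: FeatureTable,
                  metadata: pd.DataFrame, tissue: str | None = None,
                  n_shuffles: int = 1000, fdr: float = 0.2,
                  seed: int = 0) -> NmiNetwork:
    """Score all FF, BB and FB pairs and keep BH-significant signed edges.

    Tables must be floored (presence = count > 0) and aggregated to the
    desired level. When ``tissue`` is given, only tissue-class samples of
    that condition enter; shuffle weights are recomputed within that sample
    set from the combined fungal+bacterial richness. Constant taxa have
    undefined NMI and are excluded from their pair lists. Results are
    reproducible given ``seed`` and independent of pair iteration order.
    """
    if set(fungal.sample_ids) != set(bacterial.sample_ids):
        raise ValidationError("fungal and bacterial tables must share samples")
    samples = list(fungal.sample_ids)
    if tissue is not None:
        md = metadata.loc[samples]
        keep = md.index[(md["sample_class"] == "tissue")
                        & (md["condition"] == tissue)]
        if len(keep) == 0:
            raise ValidationError(f"no tissue samples for condition {tissue!r}")
        samples = list(keep)
    fp = PresenceMatrix.from_table(fungal.subset_samples(samples), "fungus")
    bp = PresenceMatrix.from_table(bacterial.subset_samples(samples), "bacterium")
    w = compute_weights(fp, bp)

    domains = {"FF": (fp, fp), "BB": (bp, bp), "FB": (fp, bp)}
    edges: list[NmiEdge] = []
    for edge_class, (pa, pb) in domains.items():
        taxa_a = sorted(pa.data.index)
        taxa_b = sorted(pb.data.index)
        if edge_class in ("FF", "BB"):
            pairs = [(taxa_a[i], taxa_a[j])
                     for i in range(len(taxa_a))
                     for j in range(i + 1, len(taxa_a))]
        else:
            pairs = [(a, b) for a in taxa_a for b in taxa_b]
        records = []
        for a, b in pairs:
            x = pa.data.loc[a].to_numpy()
            y = pb.data.loc[b].to_numpy()
            value = nmi(x, y)
            if np.isnan(value):
                continue
            p = permutation_pvalue(x, y, w, n_shuffles=n_shuffles,
                                   rng=_pair_rng(seed, a, b))
            records.append((a, b, value, p, _pearson_sign(x, y)))
        if not records:
            continue
        pvals = np.array([r[3] for r in records])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for (a, b, value, p, sign), q in zip(records, qvals):
            if q <= fdr:
                edges.append(NmiEdge(source=a, target=b, edge_class=edge_class,
                                     nmi=value, p=float(p), q=float(q),
                                     sign=sign))
    return NmiNetwork(edges=edges, tissue=tissue or "", n_shuffles=n_shuffles,
                      fdr_threshold=fdr, seed=seed)
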