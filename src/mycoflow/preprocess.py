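"""Flooring, normalization and taxonomic aggregation of amplicon counts.

Low-biomass amplicon runs suffer from index hopping: reads leak between
multiplexed samples and produce spurious low-count features. Empirically the
per-feature read distribution is bimodal around ~1000 reads, so counts below
a floor are zeroed sample-wise before anything else. Two normalizations
follow: a per-sequencing-library depth correction (each library's mean
reads/sample is brought to the cohort grand mean) and a per-sample dilution
correction (samples diluted before sequencing are multiplied back by their
dilution factor). Finally ASVs are aggregated up the taxonomy, with features
lacking a classification at the target rank grouped by their lowest known
rank and labeled "Other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    OTHER,
    RANKS,
    FeatureTable,
    TaxonomyLineage,
    ValidationError,
    check_table_metadata,
)

__all__ = [
    "LibraryFactors",
    "floor_counts",
    "compute_library_factors",
    "library_normalize",
    "dilution_normalize",
    "aggregate_taxonomy",
    "normalize_pipeline",
]


def floor_counts(table: FeatureTable, threshold: int = 1000) -> FeatureTable:
    """Zero every count below ``threshold``; counts >= threshold are kept.

    Operates on raw integer tables only; flooring an already-floored or
    normalized table is an error (the floor is defined on raw reads).
    """
    if table.state != "raw":
        raise ValidationError(
            f"flooring requires a raw table, got state {table.state!r}"
        )
    if threshold < 1:
        raise ValidationError("floor threshold must be >= 1")
    counts = table.counts.copy()
    counts[counts < threshold] = 0
    prov = dict(table.provenance)
    prov["floor_threshold"] = int(threshold)
    return table.replace(counts=counts, state="floored", provenance=prov)


@dataclass(frozen=True)
class LibraryFactors:
    """Per-sequencing-library depth factors.

    ``factors[l]`` is the fold change of library *l*'s mean reads/sample
    relative to the grand mean reads/sample over all samples; the
    library-size-weighted mean of the factors is 1 by construction.
    """

    factors: dict[str, float]
    grand_mean: float
    library_means: dict[str, float]
    library_sizes: dict[str, int]


def compute_library_factors(table: FeatureTable, metadata: pd.DataFrame
                            ) -> LibraryFactors:
    """Depth factor per library: (library mean reads/sample) / (grand mean).

    Empty samples count toward the means with zero reads. A library whose
    samples carry no reads at all has an undefined factor and is an error.
    """
    check_table_metadata(table, metadata)
    totals = table.counts.sum(axis=0)
    libs = metadata.loc[table.sample_ids, "library_id"]
    grand_mean = float(totals.mean())
    if grand_mean == 0:
        raise ValidationError("table has no reads; library factors undefined")
    means = totals.groupby(libs).mean()
    sizes = totals.groupby(libs).size()
    if (means == 0).any():
        dead = means.index[means == 0].tolist()
        raise ValidationError(f"libraries with zero total reads: {dead}")
    factors = (means / grand_mean).to_dict()
    return LibraryFactors(
        factors={str(k): float(v) for k, v in factors.items()},
        grand_mean=grand_mean,
        library_means={str(k): float(v) for k, v in means.items()},
        library_sizes={str(k): int(v) for k, v in sizes.items()},
    )


def library_normalize(table: FeatureTable, factors: LibraryFactors,
                      metadata: pd.DataFrame) -> FeatureTable:
    """Divide each sample's counts by its library's depth factor.

    Deep libraries are scaled down and shallow ones up, so that afterwards
    every library's mean reads/sample equals the grand mean.
    """
    check_table_metadata(table, metadata)
    libs = metadata.loc[table.sample_ids, "library_id"]
    unknown = sorted(set(libs) - set(factors.factors))
    if unknown:
        raise ValidationError(f"samples in unknown libraries: {unknown}")
    scale = libs.map(factors.factors).astype(float)
    counts = table.counts.astype(float).div(scale, axis=1)
    state = ("floored_normalized" if table.state in ("floored", "floored_normalized")
             else "unfloored_normalized")
    prov = dict(table.provenance)
    prov["library_normalized"] = True
    return table.replace(counts=counts, state=state, provenance=prov)


def dilution_normalize(table: FeatureTable, metadata: pd.DataFrame
                       ) -> FeatureTable:
    """Multiply each sample's counts by its dilution factor.

    Samples diluted before sequencing (factors of 5-20) are restored to
    their original load; undiluted samples have factor 1 and are unchanged.
    """
    check_table_metadata(table, metadata)
    dil = metadata.loc[table.sample_ids, "dilution_factor"].astype(float)
    if (dil <= 0).any():
        bad = dil.index[dil <= 0].tolist()
        raise ValidationError(f"non-positive dilution factors for: {bad}")
    counts = table.counts.mul(dil, axis=1)
    if table.counts.to_numpy().dtype.kind in "iu" and (dil % 1 == 0).all():
        counts = counts.astype(table.counts.to_numpy().dtype)
    state = ("floored_normalized" if table.state in ("floored", "floored_normalized")
             else ("unfloored_normalized" if table.state in ("raw", "unfloored_normalized")
                   else table.state))
    prov = dict(table.provenance)
    prov["dilution_normalized"] = True
    return table.replace(counts=counts, state=state, provenance=prov)


def aggregate_taxonomy(table: FeatureTable, target_level: str) -> FeatureTable:
    """Sum features sharing a lineage down to ``target_level``.

    Features classified to the target rank aggregate under their lineage;
    features known only to a higher rank group under that rank's name with
    ``Other`` filling the unknown ranks (e.g. ``g__Cladosporium;s__Other``).
    The grand total of reads is conserved exactly.
    """
    if target_level not in RANKS:
        raise ValidationError(
            f"target level must be one of {RANKS}, got {target_level!r}"
        )
    if table.level != "ASV":
        src = RANKS.index(table.level) if table.level in RANKS else -1
        if table.level in RANKS and RANKS.index(target_level) >= src:
            raise ValidationError(
                f"cannot aggregate {table.level}-level table down to "
                f"{target_level}"
            )
    if not table.taxonomy:
        raise ValidationError("aggregation requires a taxonomy for every feature")
    missing = set(table.feature_ids) - set(table.taxonomy)
    if missing:
        raise ValidationError(f"features without a lineage: {sorted(missing)}")

    group_ids = [table.taxonomy[fid].group_id(target_level)
                 for fid in table.feature_ids]
    counts = table.counts.groupby(pd.Index(group_ids, name="feature_id"),
                                  sort=True).sum()
    taxonomy = {}
    for fid, gid in zip(table.feature_ids, group_ids):
        taxonomy[gid] = table.taxonomy[fid].truncate(target_level)
    prov = dict(table.provenance)
    prov["aggregated_from"] = table.level
    return FeatureTable(counts=counts, taxonomy=taxonomy, state=table.state,
                        level=target_level, provenance=prov)


def normalize_pipeline(raw: FeatureTable, metadata: pd.DataFrame,
                       floor_threshold: int = 1000, level: str | None = "species",
                       ) -> tuple[FeatureTable, FeatureTable]:
    """Run the standard two-branch pipeline from a raw ASV table.

    Returns ``(floored_normalized, unfloored_normalized)`` tables, both
    library- and dilution-normalized and optionally aggregated to ``level``.
    The unfloored branch feeds the abundance (rank-sum) decontamination test;
    the floored branch defines presence everywhere else. Library factors are
    computed on the floored, pre-dilution counts.
    """
    floored = floor_counts(raw, floor_threshold)
    factors = compute_library_factors(floored, metadata)
    fl_norm = dilution_normalize(
        library_normalize(floored, factors, metadata), metadata)
    unfl_norm = dilution_normalize(
        library_normalize(raw.replace(state="raw"), factors, metadata), metadata)
    unfl_norm = unfl_norm.replace(state="unfloored_normalized")
    if level is not None and level != "ASV":
        fl_norm = aggregate_taxonomy(fl_norm, level)
        unfl_norm = aggregate_taxonomy(unfl_norm, level)
    return fl_norm, unfl_norm
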