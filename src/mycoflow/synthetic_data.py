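"""Seeded generators emulating a low-biomass tumor amplicon cohort.

The cohort generator reproduces the statistical structure the pipeline
assumes: a bimodal per-feature read distribution (genuine signal well above
a 1000-read floor, index-hopping noise well below it), per-sequencing-library
depth offsets, pre-sequencing dilution of strongly amplifying samples,
contaminant taxa present uniformly across tissues and negative controls,
condition-enriched true taxa, planted fungus-bacterium co-dependencies, and
mycotype abundance shifts. Every generator is a pure function of its spec
and seed and returns ground-truth annotations for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FeatureTable, TaxonomyLineage, ValidationError
from .mycotype_logratio import MycotypeModel, load_published_model

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "simulate_amplicon_cohort",
    "codependent_joint",
    "simulate_codependent_pair",
    "simulate_mycotype_dataset",
]


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    Defaults describe the standard benchmark cohort: two tissue conditions
    of 100 samples each, 50 extraction and 50 paraffin controls, six
    sequencing libraries with distinct depths, a fifth of tissue samples
    diluted 5-20x, 20 condition-enriched true fungal species, 5 uniform
    contaminants, 30 bacterial species and 5 planted fungus-bacterium
    co-dependent pairs.
    """

    conditions: dict[str, int] = field(
        default_factory=lambda: {"breast tumor": 100, "colon tumor": 100})
    n_extraction_controls: int = 50
    n_paraffin_controls: int = 50
    library_depth_multipliers: tuple[float, ...] = (0.6, 0.8, 1.0, 1.0, 1.25, 1.5)
    fraction_diluted: float = 0.2
    dilution_range: tuple[int, int] = (5, 20)
    n_true_species: int = 20
    true_prevalence: float = 0.4
    off_condition_prevalence: float = 0.05
    n_contaminant_species: int = 5
    contaminant_prevalence: float = 0.35
    n_bacterial_species: int = 30
    bacterial_prevalence: float = 0.3
    n_codependent_pairs: int = 5
    codependence_odds_ratio: float = 20.0
    codependent_prevalence: float = 0.4
    signal_median: float = 20_000.0
    signal_sigma: float = 1.0
    noise_median: float = 100.0
    noise_sigma: float = 0.7
    noise_rate: float = 0.05
    floor_threshold: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if not self.conditions or min(self.conditions.values()) < 1:
            raise ValidationError("at least one condition with >= 1 sample")
        if self.n_codependent_pairs > min(self.n_true_species,
                                          self.n_bacterial_species):
            raise ValidationError("more co-dependent pairs than species")
        lo, hi = self.dilution_range
        if lo < 1 or hi < lo:
            raise ValidationError("invalid dilution range")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, keyed by species-level ids."""

    true_species: list[str]
    contaminant_species: list[str]
    bacterial_species: list[str]
    enrichment: dict[str, str]
    codependent_pairs: list[tuple[str, str, float]]
    predilution_fungal: pd.DataFrame
    predilution_bacterial: pd.DataFrame


def _fungal_lineage(i: int, genus_only: bool) -> TaxonomyLineage:
    names = {
        "kingdom": "Fungi",
        "phylum": "Ascomycota" if i % 2 == 0 else "Basidiomycota",
        "class": f"Fungiclass{i % 4 + 1}",
        "order": f"Fungiorder{i % 8 + 1}",
        "family": f"Fungifamily{i % 10 + 1}",
        "genus": f"Fungigenus{i + 1}",
    }
    if not genus_only:
        names["species"] = f"Fungigenus{i + 1} sp{i + 1}"
    return TaxonomyLineage.from_names(names)


def _bacterial_lineage(j: int) -> TaxonomyLineage:
    return TaxonomyLineage.from_names({
        "kingdom": "Bacteria",
        "phylum": f"Bactphylum{j % 3 + 1}",
        "class": f"Bactclass{j % 5 + 1}",
        "order": f"Bactorder{j % 6 + 1}",
        "family": f"Bactfamily{j % 8 + 1}",
        "genus": f"Bactgenus{j + 1}",
        "species": f"Bactgenus{j + 1} sp",
    })


def codependent_joint(prevalence_x: float, prevalence_y: float,
                      odds_ratio: float) -> tuple[float, float, float, float]:
    """Closed-form 2x2 joint (p11, p10, p01, p00) with the given margins
    and odds ratio (p11*p00)/(p10*p01)."""
    px, py, theta = prevalence_x, prevalence_y, odds_ratio
    for name, v in (("prevalence_x", px), ("prevalence_y", py)):
        if not (0 < v < 1):
            raise ValidationError(f"{name} must be in (0,1), got {v}")
    if theta <= 0:
        raise ValidationError("odds_ratio must be > 0")
    if theta == 1.0:
        p11 = px * py
    else:
        a = theta - 1.0
        b = -(a * (px + py) + 1.0)
        c = theta * px * py
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValidationError("infeasible margins/odds-ratio combination")
        p11 = (-b - np.sqrt(disc)) / (2 * a)
    lo, hi = max(0.0, px + py - 1.0), min(px, py)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValidationError("infeasible margins/odds-ratio combination")
    p11 = float(np.clip(p11, lo, hi))
    return p11, px - p11, py - p11, 1.0 - px - py + p11


def simulate_codependent_pair(m: int, prevalence_x: float, prevalence_y: float,
                              odds_ratio: float,
                              rng: np.random.Generator | int = 0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Draw a binary presence pair of length ``m`` from the 2x2 joint with
    the given margins and odds ratio."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    p11, p10, p01, p00 = codependent_joint(prevalence_x, prevalence_y,
                                           odds_ratio)
    cells = rng.choice(4, size=m, p=[p11, p10, p01, p00])
    x = (cells == 0) | (cells == 1)
    y = (cells == 0) | (cells == 2)
    return x.astype(np.int8), y.astype(np.int8)


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

def _signal_counts(n: int, spec: CohortSpec, rng) -> np.ndarray:
    """Above-floor read counts for genuinely present organisms.

    Log-normal with the spec's median; truncated below at the floor so that
    flooring removes noise only, matching the bimodal histogram the floor
    threshold sits between.
    """
    draws = rng.lognormal(np.log(spec.signal_median), spec.signal_sigma, n)
    return np.maximum(draws, spec.floor_threshold)


def _noise_counts(n: int, spec: CohortSpec, rng) -> np.ndarray:
    draws = rng.lognormal(np.log(spec.noise_median), spec.noise_sigma, n)
    return np.minimum(draws, spec.floor_threshold - 1)


def simulate_amplicon_cohort(
        spec: CohortSpec | None = None
) -> tuple[FeatureTable, FeatureTable, pd.DataFrame, GroundTruth]:
    """Simulate raw fungal and bacterial ASV tables, metadata, and truth.

    Diluted samples represent strong amplifiers: their pre-dilution load is
    the emitted count times the dilution factor, so multiplying back by the
    factor (dilution normalization) restores the true load exactly. Library
    depth multipliers scale every count in a library. Outputs are
    bit-identical across runs with the same spec and seed.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)

    # --- samples and metadata ---------------------------------------------
    sample_ids: list[str] = []
    classes: list[str] = []
    conditions: list[str] = []
    for cond, n in spec.conditions.items():
        tag = cond.replace(" ", "_")
        for i in range(n):
            sample_ids.append(f"T_{tag}_{i + 1:03d}")
            classes.append("tissue")
            conditions.append(cond)
    for i in range(spec.n_extraction_controls):
        sample_ids.append(f"EC_{i + 1:03d}")
        classes.append("extraction_control")
        conditions.append("")
    for i in range(spec.n_paraffin_controls):
        sample_ids.append(f"PC_{i + 1:03d}")
        classes.append("paraffin_control")
        conditions.append("")
    n_samples = len(sample_ids)

    n_lib = len(spec.library_depth_multipliers)
    lib_assign = rng.permuted(np.arange(n_samples) % n_lib)
    lib_ids = [f"L{k + 1}" for k in lib_assign]
    lib_mult = np.array([spec.library_depth_multipliers[k] for k in lib_assign])

    is_tissue = np.array([c == "tissue" for c in classes])
    dilution = np.ones(n_samples)
    tissue_idx = np.flatnonzero(is_tissue)
    n_diluted = int(round(spec.fraction_diluted * tissue_idx.size))
    if n_diluted:
        chosen = rng.choice(tissue_idx, size=n_diluted, replace=False)
        lo, hi = spec.dilution_range
        dilution[chosen] = rng.integers(lo, hi + 1, size=n_diluted)

    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "sample_class": classes,
        "condition": conditions,
        "library_id": lib_ids,
        "dilution_factor": dilution,
    }).set_index("sample_id", drop=False)

    cond_of = np.array(conditions)
    cond_names = list(spec.conditions)

    # --- fungal species roles ---------------------------------------------
    n_fungi = spec.n_true_species + spec.n_contaminant_species
    fungal_lineages: list[TaxonomyLineage] = []
    roles: list[str] = []
    enrichment: dict[str, str] = {}
    for i in range(spec.n_true_species):
        genus_only = (i % 7 == 6)  # a minority classified only to genus
        fungal_lineages.append(_fungal_lineage(i, genus_only))
        roles.append("true")
    for i in range(spec.n_contaminant_species):
        fungal_lineages.append(_fungal_lineage(spec.n_true_species + i, False))
        roles.append("contaminant")
    species_ids = [lin.group_id("species") for lin in fungal_lineages]
    for i in range(spec.n_true_species):
        enrichment[species_ids[i]] = cond_names[i % len(cond_names)]

    bact_lineages = [_bacterial_lineage(j) for j in range(spec.n_bacterial_species)]
    bact_ids = [lin.group_id("species") for lin in bact_lineages]

    # --- presence ----------------------------------------------------------
    fungal_presence = np.zeros((n_fungi, n_samples), dtype=bool)
    for i in range(spec.n_true_species):
        prev = np.zeros(n_samples)
        own = enrichment[species_ids[i]]
        prev[is_tissue] = np.where(cond_of[is_tissue] == own,
                                   spec.true_prevalence,
                                   spec.off_condition_prevalence)
        fungal_presence[i] = rng.random(n_samples) < prev
    for i in range(spec.n_true_species, n_fungi):
        fungal_presence[i] = rng.random(n_samples) < spec.contaminant_prevalence

    bact_presence = np.zeros((spec.n_bacterial_species, n_samples), dtype=bool)
    for j in range(spec.n_bacterial_species):
        prev = np.where(is_tissue, spec.bacterial_prevalence, 0.0)
        bact_presence[j] = rng.random(n_samples) < prev

    pairs: list[tuple[str, str, float]] = []
    for k in range(spec.n_codependent_pairs):
        x, y = simulate_codependent_pair(
            int(is_tissue.sum()), spec.codependent_prevalence,
            spec.codependent_prevalence, spec.codependence_odds_ratio, rng)
        fungal_presence[k, is_tissue] = x.astype(bool)
        bact_presence[k, is_tissue] = y.astype(bool)
        pairs.append((species_ids[k], bact_ids[k],
                      spec.codependence_odds_ratio))

    # --- counts -------------------------------------------------------------
    def emit(presence: np.ndarray, spec_: CohortSpec) -> np.ndarray:
        n_taxa = presence.shape[0]
        counts = np.zeros((n_taxa, n_samples))
        on = np.flatnonzero(presence.ravel())
        counts.ravel()[on] = _signal_counts(on.size, spec_, rng)
        # index-hopping noise lands anywhere, below the floor
        noise_mask = (rng.random((n_taxa, n_samples)) < spec_.noise_rate) & ~presence
        off = np.flatnonzero(noise_mask.ravel())
        counts.ravel()[off] = _noise_counts(off.size, spec_, rng)
        counts = np.round(counts * lib_mult[None, :])
        # observed counts of genuinely present organisms sit above the
        # floor, hopped reads below it — the bimodality the floor exploits
        counts[presence] = np.maximum(counts[presence], spec_.floor_threshold)
        counts[noise_mask] = np.minimum(counts[noise_mask],
                                        spec_.floor_threshold - 1)
        return counts.astype(np.int64)

    fungal_emitted = emit(fungal_presence, spec)
    bact_emitted = emit(bact_presence, spec)
    predil_fungal = fungal_emitted * dilution[None, :]
    predil_bact = bact_emitted * dilution[None, :]

    # --- split a couple of species into two ASVs ----------------------------
    asv_rows, asv_ids, taxonomy = [], [], {}
    for i, lin in enumerate(fungal_lineages):
        row = fungal_emitted[i]
        if i < 2:  # two species carry a second, rarer amplicon variant
            minor = np.round(row * 0.3).astype(np.int64)
            minor[minor < spec.floor_threshold] = 0
            major = row - minor
            for part, suffix in ((major, "a"), (minor, "b")):
                aid = f"F_ASV_{i + 1:04d}{suffix}"
                asv_ids.append(aid)
                asv_rows.append(part)
                taxonomy[aid] = lin
        else:
            aid = f"F_ASV_{i + 1:04d}"
            asv_ids.append(aid)
            asv_rows.append(row)
            taxonomy[aid] = lin
    fungal_table = FeatureTable(
        counts=pd.DataFrame(np.vstack(asv_rows), index=asv_ids,
                            columns=sample_ids),
        taxonomy=taxonomy, state="raw", level="ASV",
        provenance={"generator": "simulate_amplicon_cohort", "seed": spec.seed})

    bact_taxonomy = {f"B_ASV_{j + 1:04d}": lin
                     for j, lin in enumerate(bact_lineages)}
    bacterial_table = FeatureTable(
        counts=pd.DataFrame(bact_emitted, index=list(bact_taxonomy),
                            columns=sample_ids),
        taxonomy=bact_taxonomy, state="raw", level="ASV",
        provenance={"generator": "simulate_amplicon_cohort", "seed": spec.seed})

    truth = GroundTruth(
        true_species=[sid for sid, r in zip(species_ids, roles) if r == "true"],
        contaminant_species=[sid for sid, r in zip(species_ids, roles)
                             if r == "contaminant"],
        bacterial_species=bact_ids,
        enrichment=enrichment,
        codependent_pairs=pairs,
        predilution_fungal=pd.DataFrame(predil_fungal, index=species_ids,
                                        columns=sample_ids),
        predilution_bacterial=pd.DataFrame(predil_bact, index=bact_ids,
                                           columns=sample_ids),
    )
    return fungal_table, bacterial_table, metadata, truth


# ---------------------------------------------------------------------------
# Mycotype benchmark
# ---------------------------------------------------------------------------

def simulate_mycotype_dataset(n_per_group: int = 100, effect: float = 4.0,
                              seed: int = 0, mean_count: float = 200.0,
                              dispersion: float = 5.0
                              ) -> tuple[FeatureTable, pd.Series, MycotypeModel]:
    """Genus-level counts for two groups with a planted F1 fold change.

    Counts are negative binomial per genus (mean ``mean_count``, shape
    ``dispersion``); in group B the F1 genera means are multiplied by
    ``effect``. Returns the count table, group labels and the bundled
    published mycotype model.
    """
    if effect <= 0:
        raise ValidationError("effect must be > 0")
    rng = np.random.default_rng(seed)
    model = load_published_model()
    genera = model.assignments.loc[model.assignments["domain"] == "fungus",
                                   ["genus", "mycotype"]]
    samples = ([f"A_{i + 1:03d}" for i in range(n_per_group)]
               + [f"B_{i + 1:03d}" for i in range(n_per_group)])
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group,
                       index=samples, name="group")
    rows = []
    for genus, mycotype in genera.itertuples(index=False):
        mu = np.full(2 * n_per_group, mean_count)
        if mycotype == "F1":
            mu[n_per_group:] *= effect
        p = dispersion / (dispersion + mu)
        rows.append(rng.negative_binomial(dispersion, p))
    taxonomy = {
        g: TaxonomyLineage.from_names({"kingdom": "Fungi", "genus": g})
        for g in genera["genus"]
    }
    table = FeatureTable(
        counts=pd.DataFrame(np.vstack(rows), index=list(genera["genus"]),
                            columns=samples),
        taxonomy=taxonomy, state="raw", level="genus",
        provenance={"generator": "simulate_mycotype_dataset", "seed": seed})
    return table, groups, model
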