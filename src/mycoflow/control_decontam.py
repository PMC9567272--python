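"""Two-stage, control-anchored decontamination of low-biomass tables.

Negative controls (water-only extraction blanks and tissue-free paraffin
samples) capture reagent and handling contamination. Species present only in
controls are discarded outright, species absent from every control are kept,
and species shared between controls and tissues go through two statistical
stages: for each condition (tissue type + tumor/NAT/normal status) a species
must look enriched in the condition relative to extraction controls, and
then again relative to paraffin controls. Enrichment in a stage is a
one-sided Fisher exact test on presence/absence (floored, normalized data)
or a one-sided rank-sum test on abundances (unfloored, normalized data);
either test with p <= alpha and Benjamini-Hochberg q <= fdr passes the
stage. Species passing both stages in at least one condition join the
retained "fungal world" together with the control-absent species.

The same machinery exposes a generic two-group differential-prevalence test
(two-sided Fisher with a prevalence floor) used by clinical contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import (
    CONTROL_CLASSES,
    FeatureTable,
    ValidationError,
    check_table_metadata,
)

__all__ = [
    "ControlPartition",
    "SpeciesConditionTest",
    "DecontamReport",
    "partition_by_control_overlap",
    "fisher_prevalence_test",
    "wilcoxon_abundance_test",
    "stage_filter",
    "two_stage_decontaminate",
    "differential_prevalence",
]

#: Combined group size at or below which the rank-sum test enumerates all
#: group assignments exactly instead of using the normal approximation.
EXACT_RANKSUM_MAX_N = 12


# ---------------------------------------------------------------------------
# Control-overlap partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControlPartition:
    """Disjoint split of all detected species by negative-control overlap."""

    unique_to_controls: frozenset[str]
    shared: frozenset[str]
    absent_from_controls: frozenset[str]

    @property
    def all_species(self) -> frozenset[str]:
        return self.unique_to_controls | self.shared | self.absent_from_controls


def partition_by_control_overlap(table: FeatureTable, metadata: pd.DataFrame
                                 ) -> ControlPartition:
    """Partition species by presence (count > 0) in controls vs tissues.

    Both control classes are pooled for the overlap determination. Species
    with zero counts everywhere are outside the partition's universe.
    """
    check_table_metadata(table, metadata)
    md = metadata.loc[table.sample_ids]
    is_ctrl = md["sample_class"].isin(CONTROL_CLASSES)
    if not is_ctrl.any():
        raise ValidationError("no control samples; decontamination is undefined")
    presence = table.presence()
    in_ctrl = presence.loc[:, md.index[is_ctrl]].any(axis=1)
    in_tissue = presence.loc[:, md.index[~is_ctrl]].any(axis=1)
    return ControlPartition(
        unique_to_controls=frozenset(presence.index[in_ctrl & ~in_tissue]),
        shared=frozenset(presence.index[in_ctrl & in_tissue]),
        absent_from_controls=frozenset(presence.index[~in_ctrl & in_tissue]),
    )


# ---------------------------------------------------------------------------
# Per-species tests
# ---------------------------------------------------------------------------

def fisher_prevalence_test(present_condition: int, n_condition: int,
                           present_control: int, n_control: int,
                           alternative: str = "greater") -> float:
    """Fisher exact p for higher prevalence in the condition vs controls.

    The 2x2 table is (present/absent) x (condition/control); the default
    one-sided alternative asks whether the species is *more* prevalent in
    the condition. Degenerate tables return p = 1.
    """
    if n_condition < 1 or n_control < 1:
        raise ValidationError("both groups need at least one sample")
    table = np.array([
        [present_condition, n_condition - present_condition],
        [present_control, n_control - present_control],
    ])
    if (table < 0).any():
        raise ValidationError("presence counts exceed group sizes")
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def _exact_ranksum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided rank-sum p by enumerating all group assignments.

    Midranks handle ties; p is the fraction of assignments whose condition
    rank sum is >= the observed one (the observed assignment included).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, nx = len(pooled), len(x)
    observed = ranks[:nx].sum()
    hits = total = 0
    for idx in itertools.combinations(range(n), nx):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_abundance_test(condition_values, control_values) -> float:
    """One-sided rank-sum p for higher abundance in the condition.

    Exact enumeration of assignments when the combined n is small
    (<= 12), tie-corrected normal approximation otherwise. Completely tied
    data (all values identical) returns p = 1.
    """
    x = np.asarray(condition_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups need at least one sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if x.size + y.size <= EXACT_RANKSUM_MAX_N:
        return _exact_ranksum_greater(x, y)
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Stage filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesConditionTest:
    """One (species, condition, control set, test) record with p and BH q."""

    species: str
    condition: str
    control_set: str  # "extraction" or "paraffin"
    test: str  # "fisher_prevalence" or "wilcoxon_abundance"
    p: float
    q: float = np.nan
    passed: bool = False


def stage_filter(tests: list[SpeciesConditionTest], alpha: float = 0.05,
                 fdr: float = 0.2) -> list[SpeciesConditionTest]:
    """BH-adjust p-values and flag passing records.

    The BH family is the set of species sharing one (condition, test,
    control_set) combination; a record passes iff p <= alpha and q <= fdr.
    """
    if not tests:
        return []
    df = pd.DataFrame([(t.species, t.condition, t.control_set, t.test, t.p)
                       for t in tests],
                      columns=["species", "condition", "control_set", "test", "p"])
    out: list[SpeciesConditionTest] = []
    for (cond, cset, test), grp in df.groupby(
            ["condition", "control_set", "test"], sort=False):
        q = multipletests(grp["p"].to_numpy(), method="fdr_bh")[1]
        for (row, qv) in zip(grp.itertuples(), q):
            passed = (row.p <= alpha) and (qv <= fdr)
            out.append(SpeciesConditionTest(
                species=row.species, condition=cond, control_set=cset,
                test=test, p=float(row.p), q=float(qv), passed=bool(passed)))
    return out


# ---------------------------------------------------------------------------
# Full two-stage procedure
# ---------------------------------------------------------------------------

FATES = ("removed_unique_to_controls", "tested_retained", "tested_removed",
         "retained_absent_from_controls")


@dataclass
class DecontamReport:
    """Per-species fates, the full test audit trail and the retained list."""

    fates: dict[str, str]
    tests: list[SpeciesConditionTest]
    fungal_world: frozenset[str]
    partition: ControlPartition
    alpha: float
    fdr: float

    def summary(self) -> dict[str, int]:
        """Bookkeeping counts: detected species and each fate's size."""
        return {
            "detected": len(self.fates),
            "unique_to_controls": len(self.partition.unique_to_controls),
            "shared_tested": len(self.partition.shared),
            "tested_retained": sum(f == "tested_retained"
                                   for f in self.fates.values()),
            "absent_from_controls": len(self.partition.absent_from_controls),
            "fungal_world": len(self.fungal_world),
        }


def _stage_tests(species: list[str], conditions: list[str],
                 presence: pd.DataFrame, abundance: pd.DataFrame,
                 cond_samples: dict[str, list[str]], ctrl_samples: list[str],
                 control_set: str) -> list[SpeciesConditionTest]:
    tests: list[SpeciesConditionTest] = []
    n_ctrl = len(ctrl_samples)
    pres_ctrl = presence.loc[species, ctrl_samples].sum(axis=1)
    for cond in conditions:
        samples = cond_samples[cond]
        pres_cond = presence.loc[species, samples].sum(axis=1)
        for sp in species:
            p_fisher = fisher_prevalence_test(
                int(pres_cond[sp]), len(samples), int(pres_ctrl[sp]), n_ctrl)
            tests.append(SpeciesConditionTest(
                species=sp, condition=cond, control_set=control_set,
                test="fisher_prevalence", p=p_fisher))
            p_wilcox = wilcoxon_abundance_test(
                abundance.loc[sp, samples].to_numpy(),
                abundance.loc[sp, ctrl_samples].to_numpy())
            tests.append(SpeciesConditionTest(
                species=sp, condition=cond, control_set=control_set,
                test="wilcoxon_abundance", p=p_wilcox))
    return tests


def two_stage_decontaminate(floored: FeatureTable, unfloored: FeatureTable,
                            metadata: pd.DataFrame, alpha: float = 0.05,
                            fdr: float = 0.2,
                            same_condition: bool = True) -> DecontamReport:
    """Run the full control-anchored decontamination.

    ``floored`` is the floored, normalized table (defines presence) and
    ``unfloored`` the normalized-but-unfloored table (defines abundance);
    both must share features and samples. With ``same_condition`` (default)
    a shared species is retained only if one and the same condition passes
    both the extraction-control and the paraffin-control stages; otherwise
    any condition may carry each stage independently.

    The procedure applies unchanged at any taxonomic level.
    """
    check_table_metadata(floored, metadata)
    check_table_metadata(unfloored, metadata)
    if set(floored.sample_ids) != set(unfloored.sample_ids):
        raise ValidationError("floored and unfloored tables have different samples")
    md = metadata.loc[floored.sample_ids]
    for cls in CONTROL_CLASSES:
        if not (md["sample_class"] == cls).any():
            raise ValidationError(f"no {cls} samples; both control classes required")

    part = partition_by_control_overlap(floored, md)
    shared = sorted(part.shared)
    tissues = md.index[md["sample_class"] == "tissue"]
    conditions = sorted(md.loc[tissues, "condition"].unique())
    cond_samples = {c: list(tissues[md.loc[tissues, "condition"] == c])
                    for c in conditions}
    extraction = list(md.index[md["sample_class"] == "extraction_control"])
    paraffin = list(md.index[md["sample_class"] == "paraffin_control"])

    presence = floored.presence()
    # union of features: a shared species may be missing from the unfloored
    # table only if ids diverge, which is an input error
    missing = set(shared) - set(unfloored.feature_ids)
    if missing:
        raise ValidationError(
            f"species absent from the unfloored table: {sorted(missing)}")
    abundance = unfloored.counts

    tests: list[SpeciesConditionTest] = []
    if shared and conditions:
        for cset, ctrl in (("extraction", extraction), ("paraffin", paraffin)):
            raw = _stage_tests(shared, conditions, presence, abundance,
                               cond_samples, ctrl, cset)
            tests.extend(stage_filter(raw, alpha=alpha, fdr=fdr))

    # stage pass per (species, condition, control_set): any passing test
    passed = {}
    for t in tests:
        if t.passed:
            passed.setdefault((t.species, t.control_set), set()).add(t.condition)

    retained_shared: set[str] = set()
    for sp in shared:
        ext = passed.get((sp, "extraction"), set())
        par = passed.get((sp, "paraffin"), set())
        ok = bool(ext & par) if same_condition else bool(ext and par)
        if ok:
            retained_shared.add(sp)

    fates: dict[str, str] = {}
    for sp in part.unique_to_controls:
        fates[sp] = "removed_unique_to_controls"
    for sp in part.absent_from_controls:
        fates[sp] = "retained_absent_from_controls"
    for sp in shared:
        fates[sp] = ("tested_retained" if sp in retained_shared
                     else "tested_removed")

    world = frozenset(retained_shared) | part.absent_from_controls
    return DecontamReport(fates=fates, tests=tests, fungal_world=world,
                          partition=part, alpha=alpha, fdr=fdr)


def reads_removed_fraction(table: FeatureTable, report: DecontamReport) -> float:
    """Fraction of the table's reads carried by non-retained species."""
    total = table.total_reads()
    if total == 0:
        return 0.0
    kept = table.counts.loc[
        table.counts.index.intersection(list(report.fungal_world))
    ].to_numpy().sum()
    return float((total - kept) / total)


def report_to_frame(report: DecontamReport) -> pd.DataFrame:
    """Audit trail as a tidy frame (one row per species/condition/test)."""
    rows = [(t.species, t.condition, t.control_set, t.test, t.p, t.q, t.passed)
            for t in report.tests]
    df = pd.DataFrame(rows, columns=["species", "condition", "control_set",
                                     "test", "p", "q", "passed"])
    fates = pd.DataFrame(sorted(report.fates.items()),
                         columns=["species", "fate"])
    return df.merge(fates, on="species", how="right")


# ---------------------------------------------------------------------------
# Generic differential prevalence (clinical contrasts)
# ---------------------------------------------------------------------------

def differential_prevalence(table: FeatureTable, group_a: list[str],
                            group_b: list[str], min_prev: float = 0.05,
                            min_count: int = 2, fdr: float = 0.2
                            ) -> pd.DataFrame:
    """Two-sided Fisher differential prevalence between two sample groups.

    Only taxa present in at least ``min_prev`` of the samples *and* at least
    ``min_count`` times in one of the groups are tested; BH correction runs
    across the tested taxa. Returns a frame indexed by taxon with presence
    counts, p, q and a ``passed`` flag (q <= fdr).
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups are not disjoint: {sorted(overlap)}")
    presence = table.presence()
    pa = presence.loc[:, list(group_a)].sum(axis=1)
    pb = presence.loc[:, list(group_b)].sum(axis=1)
    na, nb = len(group_a), len(group_b)
    eligible = (((pa >= min_count) & (pa / na >= min_prev))
                | ((pb >= min_count) & (pb / nb >= min_prev)))
    taxa = presence.index[eligible]
    records = []
    for taxon in taxa:
        p = fisher_prevalence_test(int(pa[taxon]), na, int(pb[taxon]), nb,
                                   alternative="two-sided")
        records.append((taxon, int(pa[taxon]), int(pb[taxon]), p))
    df = pd.DataFrame(records,
                      columns=["taxon", "present_a", "present_b", "p"]
                      ).set_index("taxon")
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["passed"] = df["q"] <= fdr
    else:
        df["q"] = pd.Series(dtype=float)
        df["passed"] = pd.Series(dtype=bool)
    return df
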