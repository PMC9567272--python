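import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from mycoflow import (
    CohortSpec,
    differential_prevalence,
    fisher_prevalence_test,
    partition_by_control_overlap,
    simulate_amplicon_cohort,
    stage_filter,
    two_stage_decontaminate,
    wilcoxon_abundance_test,
)
from mycoflow.control_decontam import SpeciesConditionTest
from mycoflow.core_io import FeatureTable, ValidationError
from mycoflow.preprocess import normalize_pipeline


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def hypergeom_table_prob(a: int, na: int, b: int, nb: int) -> float:
    """Probability of a 2x2 table under fixed margins (hypergeometric)."""
    k = a + b
    return comb(na, a) * comb(nb, b) / comb(na + nb, k)


def fisher_oracle(a: int, na: int, b: int, nb: int, two_sided: bool) -> float:
    """Brute-force Fisher p by enumerating all tables with the margins."""
    k = a + b
    lo, hi = max(0, k - nb), min(na, k)
    p_obs = hypergeom_table_prob(a, na, b, nb)
    total = 0.0
    for aa in range(lo, hi + 1):
        p = hypergeom_table_prob(aa, na, k - aa, nb)
        if two_sided:
            if p <= p_obs * (1 + 1e-9):
                total += p
        elif aa >= a:
            total += p
    return total


def ranksum_oracle(x, y) -> float:
    """Exact one-sided rank-sum p by enumerating all group assignments."""
    from scipy.stats import rankdata
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    observed = ranks[: len(x)].sum()
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(x)):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------

class TestPartition:
    @staticmethod
    def _cohort(presence_rows, n_ctrl=2):
        n = len(presence_rows[0])
        samples = [f"S{i}" for i in range(n)]
        classes = (["tissue"] * (n - n_ctrl)
                   + ["extraction_control", "paraffin_control"][:n_ctrl])
        md = pd.DataFrame({
            "sample_id": samples, "sample_class": classes,
            "condition": ["c" if cl == "tissue" else "" for cl in classes],
            "library_id": ["L1"] * n, "dilution_factor": [1.0] * n,
        }).set_index("sample_id", drop=False)
        counts = pd.DataFrame(
            np.asarray(presence_rows) * 1500,
            index=[f"sp{i}" for i in range(len(presence_rows))],
            columns=samples)
        table = FeatureTable(counts=counts, state="floored_normalized",
                             level="species")
        return table, md

    def test_exact_partition_on_toy(self):
        # 6 species x (4 tissues + 2 controls)
        rows = [
            [0, 0, 0, 0, 1, 1],  # only controls
            [1, 0, 1, 1, 1, 0],  # shared
            [1, 1, 0, 0, 0, 0],  # tissues only
            [0, 1, 0, 0, 0, 1],  # shared
            [0, 0, 0, 0, 0, 0],  # nowhere: outside the universe
            [1, 1, 1, 1, 0, 0],  # tissues only
        ]
        table, md = self._cohort(rows)
        part = partition_by_control_overlap(table, md)
        assert part.unique_to_controls == {"sp0"}
        assert part.shared == {"sp1", "sp3"}
        assert part.absent_from_controls == {"sp2", "sp5"}
        assert "sp4" not in part.all_species

    def test_sets_disjoint_and_exhaustive_random(self):
        rng = np.random.default_rng(11)
        rows = (rng.random((12, 10)) < 0.3).astype(int)
        table, md = self._cohort(list(rows))
        part = partition_by_control_overlap(table, md)
        union = part.all_species
        detected = set(table.counts.index[(table.counts > 0).any(axis=1)])
        assert union == detected
        assert not (part.shared & part.unique_to_controls)
        assert not (part.shared & part.absent_from_controls)
        assert not (part.unique_to_controls & part.absent_from_controls)

    def test_no_controls_is_an_error(self):
        rows = [[1, 1, 1, 1, 1, 1]]
        table, md = self._cohort(rows)
        md["sample_class"] = "tissue"
        with pytest.raises(ValidationError, match="control"):
            partition_by_control_overlap(table, md)


# ---------------------------------------------------------------------------
# Tests against oracles
# ---------------------------------------------------------------------------

class TestFisher:
    def test_wrong_direction_gives_one(self):
        assert fisher_prevalence_test(0, 10, 3, 10) == 1.0

    @pytest.mark.parametrize("a,na,b,nb", [(8, 10, 1, 10), (5, 12, 2, 9),
                                           (3, 6, 3, 6), (10, 10, 0, 10)])
    def test_one_sided_matches_hypergeometric_enumeration(self, a, na, b, nb):
        expected = fisher_oracle(a, na, b, nb, two_sided=False)
        assert fisher_prevalence_test(a, na, b, nb) == pytest.approx(expected)

    def test_equal_proportions_boundary(self):
        # identical groups: observed table is the boundary of the tail
        p = fisher_prevalence_test(5, 10, 5, 10)
        assert p == pytest.approx(fisher_oracle(5, 10, 5, 10, two_sided=False))
        assert p > 0.5


class TestWilcoxon:
    def test_complete_ties_give_one(self):
        assert wilcoxon_abundance_test([0, 0, 0], [0, 0, 0]) == 1.0

    def test_small_sample_exact_enumeration(self):
        p = wilcoxon_abundance_test([5, 6, 7], [1, 2, 3])
        assert p == pytest.approx(ranksum_oracle([5, 6, 7], [1, 2, 3]))
        assert p == pytest.approx(1 / 20)

    def test_label_swap_complement_relation(self):
        x, y = [5.0, 6.0, 9.0], [1.0, 2.0, 3.0]
        p_xy = wilcoxon_abundance_test(x, y)
        p_yx = wilcoxon_abundance_test(y, x)
        # with >= convention both tails include the observed assignment
        assert p_xy + p_yx == pytest.approx(1 + 1 / 20)

    def test_ties_handled_in_exact_mode(self):
        x, y = [2.0, 2.0, 5.0], [1.0, 2.0, 2.0]
        assert wilcoxon_abundance_test(x, y) == pytest.approx(
            ranksum_oracle(x, y))

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.0, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        p = wilcoxon_abundance_test(x, y)
        from scipy.stats import mannwhitneyu
        expected = mannwhitneyu(x, y, alternative="greater",
                                method="asymptotic").pvalue
        assert p == pytest.approx(float(expected))


class TestStageFilter:
    @staticmethod
    def _tests(pvals, test="fisher_prevalence"):
        return [SpeciesConditionTest(species=f"sp{i}", condition="c",
                                     control_set="extraction", test=test,
                                     p=p)
                for i, p in enumerate(pvals)]

    def test_bh_identity_for_single_species(self):
        out = stage_filter(self._tests([0.01]))
        assert out[0].q == pytest.approx(0.01)
        assert out[0].passed

    def test_bh_step_up_hand_values(self):
        out = stage_filter(self._tests([0.01, 0.02, 0.04, 0.9]))
        qs = {t.species: t.q for t in out}
        assert qs["sp0"] == pytest.approx(0.04)
        assert qs["sp1"] == pytest.approx(0.04)
        assert qs["sp2"] == pytest.approx(0.04 / 3 * 4)
        assert qs["sp3"] == pytest.approx(0.9)

    def test_families_are_independent(self):
        tests = (self._tests([0.01, 0.9])
                 + self._tests([0.5, 0.6], test="wilcoxon_abundance"))
        out = stage_filter(tests)
        fisher_q = [t.q for t in out if t.test == "fisher_prevalence"]
        assert fisher_q == pytest.approx([0.02, 0.9])

    def test_either_test_passes_the_stage(self):
        tests = [
            SpeciesConditionTest("sp", "c", "extraction",
                                 "fisher_prevalence", p=0.8),
            SpeciesConditionTest("sp", "c", "extraction",
                                 "wilcoxon_abundance", p=0.001),
        ]
        out = stage_filter(tests)
        assert any(t.passed for t in out)
        assert not all(t.passed for t in out)


# ---------------------------------------------------------------------------
# Full two-stage procedure
# ---------------------------------------------------------------------------

class TestTwoStage:
    def test_planted_cohort_recovery(self, small_cohort):
        fungal, _, md, truth = small_cohort
        fl, unfl = normalize_pipeline(fungal, md, level="species")
        report = two_stage_decontaminate(fl, unfl, md)
        world = report.fungal_world
        true_in = len(world & set(truth.true_species))
        cont_out = len(set(truth.contaminant_species) - world)
        assert true_in / len(truth.true_species) >= 0.9
        assert cont_out / len(truth.contaminant_species) >= 0.8
        assert world == ({s for s, f in report.fates.items()
                          if f in ("tested_retained",
                                   "retained_absent_from_controls")})

    def test_no_shared_species_world_is_control_absent_set(self):
        spec = CohortSpec(conditions={"breast tumor": 20},
                          n_extraction_controls=10, n_paraffin_controls=10,
                          n_contaminant_species=0, noise_rate=0.0, seed=3,
                          n_codependent_pairs=0)
        fungal, _, md, truth = simulate_amplicon_cohort(spec)
        fl, unfl = normalize_pipeline(fungal, md, level="species")
        report = two_stage_decontaminate(fl, unfl, md)
        assert report.partition.shared == frozenset()
        assert report.fungal_world == report.partition.absent_from_controls

    def test_monotone_in_alpha_and_fdr(self, small_cohort):
        fungal, _, md, _ = small_cohort
        fl, unfl = normalize_pipeline(fungal, md, level="species")
        loose = two_stage_decontaminate(fl, unfl, md, alpha=0.2, fdr=0.5)
        tight = two_stage_decontaminate(fl, unfl, md, alpha=0.01, fdr=0.05)
        base = two_stage_decontaminate(fl, unfl, md)
        assert tight.fungal_world <= base.fungal_world <= loose.fungal_world

    def test_missing_control_class_errors(self, small_cohort):
        fungal, _, md, _ = small_cohort
        fl, unfl = normalize_pipeline(fungal, md, level="species")
        md2 = md[md["sample_class"] != "paraffin_control"]
        fl2 = fl.subset_samples(list(md2.index))
        unfl2 = unfl.subset_samples(list(md2.index))
        with pytest.raises(ValidationError, match="paraffin"):
            two_stage_decontaminate(fl2, unfl2, md2)


# ---------------------------------------------------------------------------
# Differential prevalence
# ---------------------------------------------------------------------------

class TestDifferentialPrevalence:
    @staticmethod
    def _table(rows, samples):
        counts = pd.DataFrame(np.asarray(rows) * 1200,
                              index=[f"t{i}" for i in range(len(rows))],
                              columns=samples)
        return FeatureTable(counts=counts, state="floored_normalized",
                            level="species")

    def test_min_count_exclusion(self):
        samples = [f"S{i}" for i in range(60)]
        row = [0] * 60
        row[0] = row[30] = 1  # once in each 30-sample group
        t = self._table([row], samples)
        out = differential_prevalence(t, samples[:30], samples[30:])
        assert len(out) == 0

    def test_two_sided_fisher_matches_oracle(self):
        samples = [f"S{i}" for i in range(40)]
        row = [1] * 10 + [0] * 10 + [0] * 20
        t = self._table([row], samples)
        out = differential_prevalence(t, samples[:20], samples[20:])
        expected = fisher_oracle(10, 20, 0, 20, two_sided=True)
        assert out.loc["t0", "p"] == pytest.approx(expected)
        assert bool(out.loc["t0", "passed"])

    def test_identical_groups_nothing_flagged(self):
        samples = [f"S{i}" for i in range(40)]
        rows = [([1] * 8 + [0] * 12) * 2 for _ in range(5)]
        t = self._table(rows, samples)
        out = differential_prevalence(t, samples[:20], samples[20:])
        assert not out["passed"].any()

    def test_empty_group_errors(self):
        samples = [f"S{i}" for i in range(4)]
        t = self._table([[1, 1, 0, 0]], samples)
        with pytest.raises(ValidationError, match="non-empty"):
            differential_prevalence(t, samples[:2], [])
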