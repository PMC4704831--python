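"""The candidate funnel against a naive brute-force implementation."""

import numpy as np
import pytest

from methylfunnel import (
    BetaMatrix,
    SampleRecord,
    SimulationConfig,
    annotation_filters,
    generate_beta,
    generate_cohort,
    generate_manifest,
    intersect_common,
    monotone_filter,
    pairwise_screen,
    run_funnel,
    t_test_unpaired,
)
from methylfunnel.io import GROUPS, LocusAnnotation
from methylfunnel.screening import PAIRS, PairwiseScreen


def tiny_cohort(n_per_group: int = 4) -> list[SampleRecord]:
    out = []
    for g in GROUPS:
        for i in range(n_per_group):
            out.append(SampleRecord(sample_id=f"{g}{i}", group=g, age=70.0 + i,
                                    sex="F" if i % 2 else "M"))
    return out


def random_matrix(rng, n_loci, cohort, planted_frac=0.3):
    """Random matrix with a mix of null and strongly separated loci."""
    n = len(cohort)
    gidx = np.array([GROUPS.index(r.group) for r in cohort])
    values = rng.uniform(0.2, 0.8, size=(n_loci, n))
    n_planted = int(planted_frac * n_loci)
    profiles = rng.uniform(0.1, 0.9, size=(n_planted, 3))
    values[:n_planted] = np.clip(
        profiles[:, gidx] + rng.normal(0, 0.02, size=(n_planted, n)), 0, 1)
    return BetaMatrix([f"cg{i:06d}" for i in range(n_loci)],
                      [r.sample_id for r in cohort], values)


def brute_force_screen(beta, cohort, alpha):
    """Per-locus scalar t-tests — the quadratic reference implementation."""
    members = {g: [j for j, s in enumerate(beta.sample_ids)
                   if next(r for r in cohort if r.sample_id == s).group == g]
               for g in GROUPS}
    sets = {}
    for ga, gb in PAIRS:
        sig = set()
        for i, locus in enumerate(beta.locus_ids):
            x = beta.values[i, members[ga]]
            y = beta.values[i, members[gb]]
            if np.isnan(x).any() or np.isnan(y).any():
                continue
            if t_test_unpaired(x, y).p_value < alpha:
                sig.add(locus)
        sets[(ga, gb)] = sig
    return sets


def brute_force_monotone(beta, cohort, loci):
    members = {g: [j for j, s in enumerate(beta.sample_ids)
                   if next(r for r in cohort if r.sample_id == s).group == g]
               for g in GROUPS}
    out = {}
    for locus in loci:
        i = beta.locus_ids.index(locus)
        means = [np.nanmean(beta.values[i, members[g]]) for g in GROUPS]
        if sorted(means, reverse=True) == means and len(set(means)) == 3:
            out[locus] = "decreasing"
        elif sorted(means) == means and len(set(means)) == 3:
            out[locus] = "increasing"
    return out


class TestPairwiseScreen:
    def test_maximally_separated_locus_hits_all_three_pairs(self, rng):
        cohort = tiny_cohort()
        gidx = np.array([GROUPS.index(r.group) for r in cohort])
        profile = np.array([0.8, 0.5, 0.2])
        values = profile[gidx][None, :] + rng.normal(0, 1e-4, (1, len(cohort)))
        beta = BetaMatrix(["cg1"], [r.sample_id for r in cohort], values)
        screen = pairwise_screen(beta, cohort, alpha=0.05)
        assert all("cg1" in screen.sets[p] for p in PAIRS)

    def test_equals_brute_force_on_random_matrices(self, rng):
        cohort = tiny_cohort()
        for _ in range(5):
            beta = random_matrix(rng, 50, cohort)
            screen = pairwise_screen(beta, cohort, alpha=0.05)
            expected = brute_force_screen(beta, cohort, 0.05)
            for pair in PAIRS:
                assert screen.sets[pair] == expected[pair]

    def test_missing_values_skip_locus_for_that_pair_only(self, rng):
        cohort = tiny_cohort()
        beta = random_matrix(rng, 20, cohort, planted_frac=1.0)
        nc_col = [j for j, s in enumerate(beta.sample_ids)
                  if s.startswith("NC")][0]
        beta.values[0, nc_col] = np.nan
        screen = pairwise_screen(beta, cohort, alpha=0.05)
        assert beta.locus_ids[0] in screen.skipped[("NC", "aMCI")]
        assert beta.locus_ids[0] in screen.skipped[("NC", "AD")]
        assert beta.locus_ids[0] not in screen.skipped[("aMCI", "AD")]
        assert screen.sets == brute_force_screen(beta, cohort, 0.05)

    def test_undersized_group_rejected(self, rng):
        cohort = tiny_cohort()
        keep = [r for r in cohort if not (r.group == "AD" and r.sample_id != "AD0")]
        beta = random_matrix(rng, 5, keep)
        with pytest.raises(ValueError, match="AD"):
            pairwise_screen(beta, keep, alpha=0.05)

    def test_venn_regions_sum_to_union(self, rng):
        cohort = tiny_cohort()
        beta = random_matrix(rng, 100, cohort)
        screen = pairwise_screen(beta, cohort, alpha=0.2)
        union = set().union(*screen.sets.values())
        assert sum(screen.venn_counts.values()) == len(union)


class TestIntersectAndMonotone:
    def test_triple_intersection_examples(self):
        mk = lambda a, b, c: PairwiseScreen(
            alpha=0.05, sets=dict(zip(PAIRS, (set(a), set(b), set(c)))),
            p_values={p: {} for p in PAIRS})
        assert intersect_common(mk("ab", "bc", "b")) == {"b"}
        assert intersect_common(mk("", "bc", "b")) == set()

    def test_monotone_keeps_strict_orderings_only(self):
        cohort = tiny_cohort(2)
        values = np.array([
            [0.8, 0.8, 0.6, 0.6, 0.4, 0.4],   # decreasing
            [0.8, 0.8, 0.4, 0.4, 0.6, 0.6],   # dip: removed
            [0.2, 0.2, 0.5, 0.5, 0.9, 0.9],   # increasing
            [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],   # exact tie: removed
        ])
        beta = BetaMatrix([f"cg{i}" for i in range(4)],
                          [r.sample_id for r in cohort], values)
        result = monotone_filter(beta, cohort, set(beta.locus_ids))
        assert result == {"cg0": "decreasing", "cg2": "increasing"}

    def test_equals_brute_force_on_random_loci(self, rng):
        cohort = tiny_cohort()
        beta = random_matrix(rng, 200, cohort)
        loci = set(beta.locus_ids)
        assert monotone_filter(beta, cohort, loci) == \
            brute_force_monotone(beta, cohort, loci)

    def test_reversed_disease_order_flips_direction(self, rng):
        cohort = tiny_cohort()
        beta = random_matrix(rng, 100, cohort)
        fwd = monotone_filter(beta, cohort, set(beta.locus_ids))
        swap = {"NC": "AD", "aMCI": "aMCI", "AD": "NC"}
        mirrored = [SampleRecord(sample_id=r.sample_id, group=swap[r.group],
                                 age=r.age, sex=r.sex) for r in cohort]
        rev = monotone_filter(beta, mirrored, set(beta.locus_ids))
        assert set(fwd) == set(rev)
        flip = {"decreasing": "increasing", "increasing": "decreasing"}
        assert all(rev[k] == flip[v] for k, v in fwd.items())


class TestAnnotationFilters:
    def _manifest(self):
        return [
            LocusAnnotation("cgPromoterIsland", True,
                            ["NCAPH2", "LMF2", "NCAPH2", "NCAPH2", "NCAPH2"],
                            ["NM_152299", "NM_033200", "NM_152299", "NM_014551",
                             "NM_014551"],
                            ["1stExon", "TSS1500", "5'UTR", "5'UTR", "1stExon"],
                            "Island"),
            LocusAnnotation("cgBodyOnly", True, ["G1", "G1"], ["NM_1", "NM_2"],
                            ["Body", "Body"], "Island"),
            LocusAnnotation("cgShore", True, ["G2"], ["NM_3"], ["TSS200"],
                            "N_Shore"),
            LocusAnnotation("cgNoAccession", True, [], [], [], "Island"),
        ]

    def test_stagewise_removal(self):
        loci = {a.target_id for a in self._manifest()}
        s3, s4, s5 = annotation_filters(loci, self._manifest())
        assert s3 == loci - {"cgNoAccession"}
        assert s4 == {"cgPromoterIsland", "cgShore"}
        assert s5 == {"cgPromoterIsland"}

    def test_unknown_locus_is_an_error(self):
        with pytest.raises(KeyError, match="cgGhost"):
            annotation_filters({"cgGhost"}, self._manifest())


class TestRunFunnel:
    def test_stage_sets_are_nested_and_planted_recovered(self):
        cfg = SimulationConfig(group_sizes=(4, 4, 4), n_loci=500, n_planted=10,
                               seed=21)
        cohort = generate_cohort(cfg)
        manifest = generate_manifest(cfg)
        beta, truth = generate_beta(cohort, manifest, cfg)
        funnel = run_funnel(beta, cohort, manifest, alpha=0.05)
        assert funnel.stage5_island <= funnel.stage4_promoter \
            <= funnel.stage3_accession <= funnel.stage2_monotone \
            <= funnel.stage1_common <= funnel.cpg_set
        recovered = len(set(truth.locus_ids) & funnel.stage5_island)
        assert recovered >= 8  # 10 planted, strong effects

    def test_invariant_to_sample_and_locus_permutations(self, rng):
        cfg = SimulationConfig(group_sizes=(4, 4, 4), n_loci=120, n_planted=5,
                               seed=22)
        cohort = generate_cohort(cfg)
        manifest = generate_manifest(cfg)
        beta, _ = generate_beta(cohort, manifest, cfg)
        base = run_funnel(beta, cohort, manifest, alpha=0.05)
        sp = rng.permutation(len(beta.sample_ids))
        lp = rng.permutation(len(beta.locus_ids))
        shuffled = BetaMatrix([beta.locus_ids[i] for i in lp],
                              [beta.sample_ids[j] for j in sp],
                              beta.values[np.ix_(lp, sp)])
        perm = run_funnel(shuffled, list(reversed(cohort)), manifest, alpha=0.05)
        assert perm.stage1_common == base.stage1_common
        assert perm.directions == base.directions
        assert perm.stage5_island == base.stage5_island

    def test_matches_full_brute_force_composition(self, rng):
        cfg = SimulationConfig(group_sizes=(4, 4, 4), n_loci=200, n_planted=8,
                               seed=23)
        cohort = generate_cohort(cfg)
        manifest = generate_manifest(cfg)
        beta, _ = generate_beta(cohort, manifest, cfg)
        funnel = run_funnel(beta, cohort, manifest, alpha=0.05)

        index = {a.target_id: a for a in manifest}
        cpg = [l for l in beta.locus_ids if index[l].is_cpg]
        cpg_beta = beta.subset_loci(cpg)
        sets = brute_force_screen(cpg_beta, cohort, 0.05)
        stage1 = sets[PAIRS[0]] & sets[PAIRS[1]] & sets[PAIRS[2]]
        directions = brute_force_monotone(cpg_beta, cohort, stage1)
        stage3 = {l for l in directions if index[l].has_accession}
        stage4 = {l for l in stage3 if index[l].in_promoter}
        stage5 = {l for l in stage4 if index[l].in_island}
        assert funnel.stage1_common == stage1
        assert funnel.directions == directions
        assert funnel.stage5_island == stage5
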