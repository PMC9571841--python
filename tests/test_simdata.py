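"""Statistical structure of the synthetic bulk-segregant generator."""

import math

import numpy as np
import pytest

from emsmap import simdata
from emsmap.simdata import (
    DEFAULT_SPECTRUM,
    GC_TO_AT,
    OTHER_SUB,
    SINGLE_DEL,
    DoseResponseParams,
    build_pools,
    build_random_pools,
    default_map,
    make_reference_bundle,
    place_markers,
    simulate_dose_response,
    simulate_experiment,
    simulate_f2_population,
    simulate_gametes,
    simulate_pool_counts,
    simulate_segregation_family,
    spike_ems_mutations,
)
from emsmap.types import (
    CULTIVATED,
    INDUCED,
    MARKER,
    WILD,
    Chromosome,
    GeneticMap,
    VariantSite,
)

from conftest import uniform_individual


class TestF2Population:
    def test_zero_map_length_means_no_crossovers(self):
        gmap = GeneticMap([Chromosome("c", 1_000_000, 0.0)],
                          causal_locus=("c", 1))
        for ind in simulate_f2_population(gmap, 20, seed=0):
            for hap in ind.haplotypes["c"]:
                assert len(hap.ends) == 1  # one parental segment

    def test_single_marker_genotypes_near_1_2_1(self, tiny_map):
        """Genotype counts at any marker follow multinomial(1/4,1/2,1/4)."""
        n = 4000
        population = simulate_f2_population(tiny_map, n, seed=3)
        genos = [ind.genotype_at("chrA", 700_000) for ind in population]
        counts = {
            "CC": sum(g == (CULTIVATED, CULTIVATED) for g in genos),
            "het": sum(sorted(g) == [CULTIVATED, WILD] for g in genos),
            "WW": sum(g == (WILD, WILD) for g in genos),
        }
        for label, p in (("CC", 0.25), ("het", 0.5), ("WW", 0.25)):
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(counts[label] - n * p) <= 4 * sigma

    def test_mutant_phenotype_fraction_near_quarter(self, tiny_map):
        n = 4000
        population = simulate_f2_population(tiny_map, n, seed=5)
        n_mut = sum(ind.phenotype == "MUT" for ind in population)
        sigma = math.sqrt(n * 0.25 * 0.75)
        assert abs(n_mut - n * 0.25) <= 4 * sigma

    def test_haldane_recombinant_fraction(self):
        """Two markers d cM apart recombine at r = (1 - exp(-2d/100)) / 2."""
        chrom = Chromosome("c", 10_000_000, 50.0)
        n = 4000
        gametes = simulate_gametes(chrom, n, seed=9)
        # 10 cM apart = 1/5 of the chromosome
        p1, p2 = 4_000_000, 6_000_000
        rec = sum(h.origin_at(p1) != h.origin_at(p2) for h in gametes)
        r = (1 - math.exp(-2 * 10 / 100)) / 2
        sigma = math.sqrt(n * r * (1 - r))
        assert abs(rec - n * r) <= 4 * sigma

    def test_phenotype_requires_causal_locus(self):
        gmap = GeneticMap([Chromosome("c", 1000, 1.0)])
        with pytest.raises(ValueError, match="causal locus"):
            simulate_f2_population(gmap, 5, seed=0)
        assert simulate_f2_population(gmap, 5, seed=0,
                                      assign_phenotype=False)[0].phenotype is None


class TestPools:
    def _population(self, tiny_map):
        return simulate_f2_population(tiny_map, 200, seed=21)

    def test_default_pool_sizes(self, tiny_map):
        mut, wt = build_pools(self._population(tiny_map), seed=1)
        assert len(mut) == 15 and len(wt) == 15
        assert all(i.phenotype == "MUT" for i in mut)
        assert all(i.phenotype == "WT" for i in wt)
        assert not (set(map(id, mut)) & set(map(id, wt)))

    def test_zero_mut_pool_is_empty_not_error(self, tiny_map):
        mut, wt = build_pools(self._population(tiny_map), n_mut=0, seed=1)
        assert mut == [] and len(wt) == 15

    def test_insufficient_class_raises(self, tiny_map):
        population = self._population(tiny_map)
        n_mut = sum(i.phenotype == "MUT" for i in population)
        with pytest.raises(ValueError, match="MUT"):
            build_pools(population, n_mut=n_mut + 1, seed=1)

    def test_random_pools_are_disjoint(self, tiny_map):
        mut, wt = build_random_pools(self._population(tiny_map), seed=4)
        assert len(mut) == len(wt) == 15
        assert not (set(map(id, mut)) & set(map(id, wt)))


class TestMarkers:
    @pytest.mark.parametrize(
        "chroms,spacing,expected",
        [
            ([("c", 1_000_000)], 100_000, 10),
            ([("c", 40_000)], 50_000, 0),
            ([("c1", 5_000_000), ("c2", 5_000_000)], 50_000, 200),
        ],
    )
    def test_marker_counts(self, chroms, spacing, expected):
        gmap = GeneticMap([Chromosome(n, l, 1.0) for n, l in chroms])
        assert len(place_markers(gmap, spacing)) == expected

    def test_marker_positions_on_grid(self):
        gmap = GeneticMap([Chromosome("c", 1_000_000, 1.0)])
        sites = place_markers(gmap, 250_000)
        assert [s.pos for s in sites] == [250_000, 500_000, 750_000, 1_000_000]
        assert all(s.origin == MARKER for s in sites)


class TestSpikedMutations:
    def test_zero_mutations_empty(self):
        assert spike_ems_mutations(default_map(), 0, seed=0) == []

    def test_spectrum_category_counts_multinomial(self):
        from emsmap.variants import classify_substitution

        n = 10_000
        spectrum = {GC_TO_AT: 0.9, OTHER_SUB: 0.05, SINGLE_DEL: 0.05}
        sites = spike_ems_mutations(default_map(), n, spectrum, seed=13)
        counts = {GC_TO_AT: 0, OTHER_SUB: 0, SINGLE_DEL: 0}
        for s in sites:
            cat = classify_substitution(s.ref, s.alt)
            if cat == "GC_to_AT_transition":
                counts[GC_TO_AT] += 1
            elif cat == "single_base_deletion":
                counts[SINGLE_DEL] += 1
            else:
                counts[OTHER_SUB] += 1
        for cat, p in spectrum.items():
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(counts[cat] - n * p) <= 4 * sigma

    def test_causal_variant_included_exactly_once(self):
        causal = VariantSite("chr2", 42_000_000, "AG", "A", origin=INDUCED)
        sites = spike_ems_mutations(default_map(), 100, seed=1, causal=causal)
        matches = [s for s in sites if s.pos == 42_000_000 and s.chrom == "chr2"]
        assert len(matches) == 1
        assert (matches[0].ref, matches[0].alt) == ("AG", "A")

    def test_bad_spectrum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            spike_ems_mutations(default_map(), 10,
                                {GC_TO_AT: 0.9, OTHER_SUB: 0.2}, seed=0)


class TestPoolCounts:
    def _site(self, pos=100):
        return VariantSite("c", pos, "A", "T", origin=MARKER)

    def _map(self):
        return GeneticMap([Chromosome("c", 1000, 1.0)], causal_locus=("c", 500))

    def test_all_homozygous_reference_gives_zero_nonref(self):
        gmap = self._map()
        pool = [uniform_individual(gmap, {"c": (CULTIVATED, CULTIVATED)})
                for _ in range(5)]
        out = simulate_pool_counts([self._site()], {"MUT": pool},
                                   depth_mean=80, error_rate=0.0, seed=0)
        ref, nonref = out[0].counts["MUT"]
        assert nonref == 0 and ref > 0

    def test_all_homozygous_nonref_gives_full_depth(self):
        gmap = self._map()
        pool = [uniform_individual(gmap, {"c": (WILD, WILD)}) for _ in range(5)]
        out = simulate_pool_counts([self._site()], {"MUT": pool},
                                   depth_mean=80, error_rate=0.0, seed=0)
        ref, nonref = out[0].counts["MUT"]
        assert ref == 0 and nonref > 0

    def test_conservation_and_determinism(self):
        result1 = simulate_experiment(seed=7)
        result2 = simulate_experiment(seed=7)
        for s1, s2 in zip(result1.sites, result2.sites):
            assert (s1.key, s1.counts) == (s2.key, s2.counts)
            for counts in s1.counts.values():
                assert counts is not None and counts[0] + counts[1] >= 0

    def test_causal_locus_mut_pool_reaches_exact_zero_without_error(self):
        """Every mutant is homozygous cultivated at the lesion, so with no
        sequencing error the wild allele is never observed there."""
        result = simulate_experiment(seed=11, error_rate=0.0)
        causal = result.truth.causal
        # nearest marker sites flank the causal position; check the causal
        # site itself via its INDUCED record (non-ref = induced allele -> AF 1)
        site = next(s for s in result.sites
                    if s.chrom == causal["chrom"] and s.pos == causal["pos"]
                    and s.origin == INDUCED)
        ref, nonref = site.counts["MUT"]
        assert ref == 0 and nonref > 0
        # and at the closest marker the wild allele count is exactly zero
        markers = [s for s in result.sites
                   if s.chrom == causal["chrom"] and s.origin == MARKER]
        closest = min(markers, key=lambda s: abs(s.pos - causal["pos"]))
        assert closest.counts["MUT"][1] == 0

    def test_empty_pool_gives_missing_counts(self):
        out = simulate_pool_counts([self._site()], {"MUT": []}, seed=0)
        assert out[0].counts["MUT"] is None

    def test_het_pool_af_unbiased_at_half(self):
        gmap = self._map()
        pool = [uniform_individual(gmap, {"c": (CULTIVATED, WILD)})
                for _ in range(15)]
        sites = [self._site(pos=p) for p in range(1, 501)]
        out = simulate_pool_counts(sites, {"MUT": pool}, depth_mean=100,
                                   error_rate=0.0, seed=3)
        afs = [s.counts["MUT"][1] / sum(s.counts["MUT"]) for s in out]
        sigma = math.sqrt(0.25 / 100 / len(afs))
        assert abs(np.mean(afs) - 0.5) <= 4 * sigma

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_pool_counts([], {}, depth_mean=0)
        with pytest.raises(ValueError):
            simulate_pool_counts([], {}, error_rate=0.5)


class TestSegregationFamily:
    def test_counts_conserve_family_size(self):
        counts = simulate_segregation_family(120, [3, 1], seed=0)
        assert counts.sum() == 120 and len(counts) == 2

    def test_degenerate_ratio_puts_all_in_one_class(self):
        counts = simulate_segregation_family(50, [1, 0], seed=0)
        assert list(counts) == [50, 0]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_segregation_family(0, [3, 1])
        with pytest.raises(ValueError):
            simulate_segregation_family(10, [0, 0])
        with pytest.raises(ValueError):
            simulate_segregation_family(10, [1])


class TestDoseResponse:
    def test_zero_dose_full_germination(self):
        params = DoseResponseParams(germination_max=1.0,
                                    germination_midpoint=5.0,
                                    germination_slope=50.0)
        table = simulate_dose_response([0.0], replicates=5, params=params, seed=0)
        assert (table["germinated"] == table["seeds"]).all()

    def test_row_count_is_doses_times_replicates(self):
        table = simulate_dose_response([0.5, 0.7, 1.0], replicates=5, seed=0)
        assert len(table) == 15
        assert (table["fertile"] <= table["germinated"]).all()
        assert (table["germinated"] <= table["seeds"]).all()

    def test_mean_germination_monotone_decreasing_in_dose(self):
        table = simulate_dose_response([0.3, 0.6, 0.9, 1.2], replicates=1000,
                                       seed=2)
        means = table.groupby("dose")["germinated"].mean()
        assert (means.diff().dropna() < 0).all()


class TestReferenceBundle:
    def test_causal_gene_harbours_the_lesion(self):
        gmap = default_map()
        bundle = make_reference_bundle(gmap, seed=0)
        model = bundle.models[0]
        chrom, pos = gmap.causal_locus
        assert model.chrom == chrom
        assert model.cds_index(pos) is not None  # inside the CDS
        cds = model.spliced_cds(bundle.genome)
        assert len(cds) % 3 == 0
        assert cds.startswith("ATG") and cds[-3:] in {"TAA", "TAG", "TGA"}
        # no premature stops in the unmutated frame
        from conftest import translate_until_stop
        assert len(translate_until_stop(cds)) == len(cds) // 3 - 1

    def test_causal_alleles_match_reference_sequence(self):
        bundle = make_reference_bundle(default_map(), seed=5)
        c = bundle.causal_site
        assert bundle.genome.fetch(c.chrom, c.pos, c.pos + 1) == c.ref
        assert c.ref[0] == c.alt
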