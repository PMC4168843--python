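import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitobarcode import SequenceAlignment, SequenceRecord
from mitobarcode.barcode_gap import (
    classify_pair,
    contrast_table,
    overlap_fraction,
    reflected_kde,
    summarize_contrasts,
    PairContrast,
)
from mitobarcode.distances import pairwise_distance_matrix
from mitobarcode.errors import UndefinedDistanceError
from mitobarcode.seqio import TaxonName, parse_taxon_label


def name(genus, epithet=None, qualifier="none"):
    return TaxonName(genus=genus, epithet=epithet, qualifier=qualifier,
                     raw_label=f"{genus} {epithet or qualifier}")


class TestClassifyPair:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (name("Agaricia", "fragilis"), name("Agaricia", "fragilis"), "intraspecific"),
            (name("Agaricia", "fragilis"), name("Agaricia", "humilis"), "intrageneric"),
            (name("Agaricia", "fragilis"), name("Pavona", "varians"), "other"),
            # a genus-only specimen can only be compared at genus level
            (name("Discosoma", qualifier="sp"), name("Discosoma", "nummiforme"), "intrageneric"),
            (name("Discosoma", qualifier="sp"), name("Discosoma", qualifier="sp"), "intrageneric"),
            # cf./aff. marks uncertain identity: never intraspecific
            (name("Pavona", "varians", "cf"), name("Pavona", "varians"), "intrageneric"),
            (name("Pavona", "varians", "aff"), name("Pavona", "varians", "aff"), "intrageneric"),
            (name("Discosoma", qualifier="sp"), name("Ricordea", "florida"), "other"),
            # case-insensitive genus/epithet matching
            (name("agaricia", "FRAGILIS"), name("Agaricia", "fragilis"), "intraspecific"),
        ],
    )
    def test_rules(self, a, b, expected):
        assert classify_pair(a, b) == expected

    @given(
        ga=st.sampled_from(["Alpha", "Beta"]),
        gb=st.sampled_from(["Alpha", "Beta"]),
        ea=st.sampled_from([None, "una", "dua"]),
        eb=st.sampled_from([None, "una", "dua"]),
        qa=st.sampled_from(["none", "sp", "cf", "aff"]),
        qb=st.sampled_from(["none", "sp", "cf", "aff"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_total(self, ga, gb, ea, eb, qa, qb):
        a, b = name(ga, ea, qa), name(gb, eb, qb)
        cat = classify_pair(a, b)
        assert cat in ("intraspecific", "intrageneric", "other")
        assert cat == classify_pair(b, a)


class TestContrastTable:
    def test_enumerates_all_six_pairs(self, tiny_alignment):
        m = pairwise_distance_matrix(tiny_alignment, min_sites=1)
        table = contrast_table(m)
        assert table.category_counts() == {
            "intraspecific": 1, "intrageneric": 2, "other": 3,
        }

    def test_two_by_two_species_structure(self):
        # 2 species x 2 seqs in each of 2 genera (8 seqs, 28 pairs)
        from mitobarcode.synthetic_data import SimulationConfig, simulate_barcode_set

        bs = simulate_barcode_set(
            SimulationConfig(seed=5, taxonomy=(2, 2, 2), qualifier_fraction=0.0)
        )
        m = pairwise_distance_matrix(bs.alignment)
        table = contrast_table(m)
        assert table.category_counts() == {
            "intraspecific": 4, "intrageneric": 8, "other": 16,
        }

    def test_single_species_combinatorics(self):
        k = 5
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        aln = SequenceAlignment([
            SequenceRecord(f"Babaia_babaa_KX{i:06d}", seq) for i in range(k)
        ])
        table = contrast_table(pairwise_distance_matrix(aln))
        assert table.category_counts()["intraspecific"] == k * (k - 1) // 2

    def test_unparseable_label_skipped_run_continues(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        aln = SequenceAlignment([
            SequenceRecord("Babaia_babaa_1", seq),
            SequenceRecord("Babaia_babaa_2", seq),
            SequenceRecord("12345", seq),
        ])
        table = contrast_table(pairwise_distance_matrix(aln))
        assert table.skipped_labels == ["12345"]
        assert table.skipped_pairs == 2
        table.assert_bookkeeping()

    def test_bookkeeping_with_missing_and_saturated(self):
        # one short-overlap pair (missing) and one saturated pair
        pad = "-" * 150
        base = "A" * 150
        aln = SequenceAlignment([
            SequenceRecord("Babaia_babaa_1", base + pad),
            SequenceRecord("Babaia_babaa_2", pad + base),          # no overlap: missing
            SequenceRecord("Babaia_cedia_3", base + "G" * 150),
            SequenceRecord("Cedia_dia_4", base + "C" * 150),       # G vs C: saturated
        ])
        m = pairwise_distance_matrix(aln, min_sites=100)
        table = contrast_table(m)
        assert table.missing_pairs >= 1
        assert table.saturated_pairs >= 1
        counts = table.category_counts()
        assert (sum(counts.values()) + table.missing_pairs
                + table.saturated_pairs + table.skipped_pairs) == 6

    def test_permutation_invariant_counts(self, tiny_alignment):
        m = pairwise_distance_matrix(tiny_alignment, min_sites=1)
        base = contrast_table(m).category_counts()
        perm = SequenceAlignment(list(reversed(tiny_alignment.records)))
        assert contrast_table(
            pairwise_distance_matrix(perm, min_sites=1)
        ).category_counts() == base


def contrasts_from(intra=(), inter=(), other=()):
    out = []
    for cat, ds in (("intraspecific", intra), ("intrageneric", inter), ("other", other)):
        out += [PairContrast(f"a{i}", f"b{i}", cat, d, 500) for i, d in enumerate(ds)]
    return out


class TestSummary:
    def test_order_statistics(self):
        s = summarize_contrasts(contrasts_from(inter=[0.01, 0.02, 0.03]))
        st_ = s.stats["intrageneric"]
        assert (st_.mean, st_.median, st_.min, st_.max) == (0.02, 0.02, 0.01, 0.03)
        assert s.stats["intraspecific"].count == 0
        assert s.densities["intraspecific"] is None

    def test_all_zero_distances_density_spikes_at_zero(self):
        s = summarize_contrasts(contrasts_from(intra=[0.0] * 10, other=[0.04]))
        dens = s.densities["intraspecific"]
        assert s.stats["intraspecific"].count == 10
        assert dens[0] == dens.max()  # mass concentrated at the boundary

    def test_truncation_affects_grid_not_statistics(self):
        contrasts = contrasts_from(intra=[0.01], other=[0.2, 0.4])
        s = summarize_contrasts(contrasts, truncation=0.05)
        assert s.grid.max() == pytest.approx(0.05)
        assert s.stats["other"].max == 0.4  # beyond the display bound

    def test_saturated_excluded_from_statistics_but_counted(self):
        contrasts = contrasts_from(intra=[0.01, 0.02]) + [
            PairContrast("x", "y", "other", math.inf, 500),
            PairContrast("x2", "y2", "other", 0.2, 500),
        ]
        s = summarize_contrasts(contrasts)
        assert s.saturated_pairs == 1
        assert s.stats["other"].count == 1 and s.stats["other"].max == 0.2

    def test_density_integrates_to_one_on_untruncated_grid(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(0.02, 0.01, size=400))
        grid = np.linspace(0, 0.2, 4001)  # well beyond the data range
        dens = reflected_kde(x, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)


class TestOverlapFraction:
    def test_separated_strata_give_zero(self):
        assert overlap_fraction(
            contrasts_from(intra=[0.001, 0.002], inter=[0.03], other=[0.1, 0.2])
        ) == 0.0

    def test_single_pair_below_max(self):
        contrasts = contrasts_from(intra=[0.01], inter=[0.005, 0.02, 0.03, 0.04])
        assert overlap_fraction(contrasts) == 0.25

    def test_identical_distribution_by_enumeration(self):
        rng = np.random.default_rng(6)
        pooled = rng.uniform(0, 0.05, size=200)
        intra, rest = pooled[:50], pooled[50:]
        contrasts = contrasts_from(intra=intra, other=rest)
        expected = np.mean(rest <= intra.max())  # brute-force count
        assert overlap_fraction(contrasts) == pytest.approx(float(expected))
        assert overlap_fraction(contrasts) > 0.5

    def test_undefined_without_intraspecific(self):
        with pytest.raises(UndefinedDistanceError):
            overlap_fraction(contrasts_from(other=[0.1]))

    def test_overlapping_simulated_strata_detected(self):
        # within-species and within-genus depths coincide: strata overlap
        from mitobarcode.synthetic_data import SimulationConfig, simulate_barcode_set

        bs = simulate_barcode_set(SimulationConfig(
            seed=9, taxonomy=(4, 3, 3), depth_params=(0.02, 0.02, 0.10),
            qualifier_fraction=0.0,
        ))
        table = contrast_table(pairwise_distance_matrix(bs.alignment))
        s = summarize_contrasts(table.contrasts)
        assert s.overlap is not None and s.overlap > 0
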