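"""13-category plant taxonomy classification and conservation profiles."""

import pytest

from cpuorf.conservation import RepresentativeSet
from cpuorf.homology import HomologHit, PutativeUorf
from cpuorf.orfs import OrfSpan
from cpuorf.search import AlignmentHit
from cpuorf.simulate import ORDER_DEFS, SimulationConfig, simulate_taxonomy
from cpuorf.taxonomy import (
    Lineage,
    TaxCategory,
    category_of,
    conservation_profile,
    read_lineage_table,
    write_lineage_table,
)

# NCBI-style lineages of the five reference angiosperms
FOCAL_LINEAGES = {
    "Arabidopsis thaliana": (
        ("Viridiplantae", "Streptophyta", "Embryophyta", "Tracheophyta",
         "Euphyllophyta", "Spermatophyta", "Magnoliophyta", "Mesangiospermae",
         "eudicotyledons", "Gunneridae", "Pentapetalae", "rosids", "malvids",
         "Brassicales", "Brassicaceae", "Arabidopsis"),
        "Brassicales",
        TaxCategory.MALVIDS,
    ),
    "Oryza sativa": (
        ("Viridiplantae", "Streptophyta", "Embryophyta", "Tracheophyta",
         "Euphyllophyta", "Spermatophyta", "Magnoliophyta", "Mesangiospermae",
         "Liliopsida", "Petrosaviidae", "commelinids", "Poales", "Poaceae",
         "Oryza"),
        "Poales",
        TaxCategory.COMMELINIDS,
    ),
    "Solanum lycopersicum": (
        ("Viridiplantae", "Streptophyta", "Embryophyta", "Tracheophyta",
         "Euphyllophyta", "Spermatophyta", "Magnoliophyta", "Mesangiospermae",
         "eudicotyledons", "Gunneridae", "Pentapetalae", "asterids", "lamiids",
         "Solanales", "Solanaceae", "Solanum"),
        "Solanales",
        TaxCategory.LAMIIDS,
    ),
    "Populus trichocarpa": (
        ("Viridiplantae", "Streptophyta", "Embryophyta", "Tracheophyta",
         "Euphyllophyta", "Spermatophyta", "Magnoliophyta", "Mesangiospermae",
         "eudicotyledons", "Gunneridae", "Pentapetalae", "rosids", "fabids",
         "Malpighiales", "Salicaceae", "Populus"),
        "Malpighiales",
        TaxCategory.FABIDS,
    ),
    # grape: rosids but neither fabids nor malvids -> the eudicots bucket
    "Vitis vinifera": (
        ("Viridiplantae", "Streptophyta", "Embryophyta", "Tracheophyta",
         "Euphyllophyta", "Spermatophyta", "Magnoliophyta", "Mesangiospermae",
         "eudicotyledons", "Gunneridae", "Pentapetalae", "rosids", "Vitales",
         "Vitaceae", "Vitis"),
        "Vitales",
        TaxCategory.EUDICOTS_OTHER,
    ),
}


class TestCategoryOf:
    def test_exactly_thirteen_categories(self):
        assert len(TaxCategory) == 13

    @pytest.mark.parametrize("name", sorted(FOCAL_LINEAGES))
    def test_reference_species_assignments(self, name):
        clades, order, expected = FOCAL_LINEAGES[name]
        assert category_of(Lineage(name, clades, order)) is expected

    @pytest.mark.parametrize(
        "clades,expected",
        [
            (("Viridiplantae", "Streptophyta", "Embryophyta", "Tracheophyta",
              "Euphyllophyta", "Magnoliophyta", "eudicotyledons", "asterids",
              "campanulids"), TaxCategory.ASTERIDS_OTHER),
            (("Viridiplantae", "Streptophyta", "Embryophyta", "Bryophyta"),
             TaxCategory.EMBRYOPHYTA_OTHER),
            (("Viridiplantae", "Streptophyta", "Charophyceae"),
             TaxCategory.STREPTOPHYTA_OTHER),
            (("Viridiplantae", "Chlorophyta"), TaxCategory.VIRIDIPLANTAE_OTHER),
            (("Viridiplantae", "Streptophyta", "Embryophyta", "Tracheophyta",
              "Euphyllophyta", "Polypodiopsida"), TaxCategory.POLYPODIOPSIDA),
            (("Viridiplantae", "Streptophyta", "Embryophyta", "Spermatophyta",
              "Acrogymnospermae", "Pinidae"), TaxCategory.GYMNOSPERMS),
            (("Viridiplantae", "Streptophyta", "Embryophyta", "Magnoliophyta",
              "Amborellales"), TaxCategory.ANGIOSPERMS_OTHER),
            (("Viridiplantae", "Streptophyta", "Embryophyta", "Magnoliophyta",
              "Liliopsida", "Asparagales"), TaxCategory.MONOCOTS_OTHER),
        ],
    )
    def test_other_than_buckets(self, clades, expected):
        assert category_of(Lineage("x", clades, clades[-1])) is expected

    def test_outside_viridiplantae_is_an_error(self):
        with pytest.raises(ValueError, match="Viridiplantae"):
            category_of(Lineage("insect", ("Metazoa", "Arthropoda"), "Diptera"))

    def test_partition_is_total_and_single_valued(self):
        cfg = SimulationConfig(species_per_order=2)
        lineages, _ = simulate_taxonomy(cfg)
        seen = set()
        for l in lineages.values():
            seen.add(category_of(l))
        assert seen == set(TaxCategory)


def _rep(order, species):
    u = AlignmentHit("q", f"s_{order}", 1, 0, 5, 0, 15, 30.0, 1e-6, 0.9)
    m = AlignmentHit("q.m", f"s_{order}", 1, 0, 5, 30, 60, 60.0, 1e-25, 0.9)
    pu = PutativeUorf(f"s_{order}", OrfSpan(0, 12, 0), "ATGGCCTGGTAG", "MAW")
    return HomologHit(u, m, pu, 30, species, order)


class TestConservationProfile:
    def _lineages(self):
        out = {}
        for order, (_, clades) in ORDER_DEFS.items():
            sp = f"{order.lower()}_sp1"
            out[sp] = Lineage(sp, ("Viridiplantae",) + clades + (order, sp), order)
        return out

    def test_counts_sum_to_number_of_orders(self):
        lineages = self._lineages()
        reps = RepresentativeSet(
            "u1",
            {
                o: _rep(o, f"{o.lower()}_sp1")
                for o in ("Solanales", "Gentianales", "Vitales", "Poales")
            },
        )
        prof = conservation_profile("u1", reps, lineages, "brassicales_sp1")
        assert sum(prof.per_category.values()) == 4
        assert prof.per_category[TaxCategory.LAMIIDS] == 2
        assert prof.per_category[TaxCategory.EUDICOTS_OTHER] == 1
        assert prof.per_category[TaxCategory.COMMELINIDS] == 1
        assert prof.original_category is TaxCategory.MALVIDS

    def test_empty_representatives_keep_the_original_category(self):
        prof = conservation_profile(
            "u1", RepresentativeSet("u1", {}), self._lineages(), "poales_sp1"
        )
        assert prof.per_category == {}
        assert prof.original_category is TaxCategory.COMMELINIDS


class TestLineageIO:
    def test_roundtrip(self, tmp_path):
        lineages = {
            "spA": Lineage("spA", ("Viridiplantae", "Streptophyta"), "Charales", 12000),
            "spB": Lineage("spB", ("Viridiplantae",), "Chlamydomonadales", None),
        }
        p = tmp_path / "lin.tsv"
        write_lineage_table(lineages, p)
        back = read_lineage_table(p)
        assert back == lineages

    def test_malformed_row_is_an_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("spA\tCharales\n")
        with pytest.raises(ValueError, match="columns"):
            read_lineage_table(p)
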