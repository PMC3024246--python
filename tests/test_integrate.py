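import numpy as np
import pytest

from cnetrace.detect import ConservedInterval
from cnetrace.integrate import assign_names, integrate_pairs, presence_matrix
from oracles import sweep_support_runs

REF = "stickleback"


def iv(qry, start, end, identity=80.0):
    return ConservedInterval(REF, qry, start, end, identity)


class TestIntegratePairs:
    def test_coincident_intervals_give_one_unpartitioned_element(self):
        intervals = [iv(sp, 200, 350) for sp in ("medaka", "zebrafish", "Takifugu")]
        (element,) = integrate_pairs(intervals)
        assert (element.start, element.end) == (200, 350)
        assert element.sub_elements == ()
        assert element.support == {REF, "medaka", "zebrafish", "Takifugu"}

    def test_touching_intervals_without_spanner_stay_separate(self):
        elements = integrate_pairs([iv("sp2", 100, 220), iv("sp3", 220, 330)])
        assert len(elements) == 2

    def test_ab_partition_when_third_species_spans(self):
        # species2 and species3 conserve non-overlapping halves; a spanning
        # species glues them into one element with a/b sub-structure
        elements = integrate_pairs(
            [iv("species2", 100, 220), iv("species3", 220, 330), iv("spanner", 100, 330)]
        )
        (element,) = elements
        named = assign_names([element], "12", "intergenic")[0]
        assert named.name.endswith("ab")
        sub_a, sub_b = named.sub_elements
        assert (sub_a.start, sub_a.end) == (100, 220)
        assert sub_a.support == {REF, "species2", "spanner"}
        assert sub_a.name == named.name[:-2] + "a"
        assert (sub_b.start, sub_b.end) == (220, 330)
        assert sub_b.support == {REF, "species3", "spanner"}

    def test_mixed_references_rejected(self):
        other = ConservedInterval("medaka", "zebrafish", 0, 120, 80.0)
        with pytest.raises(ValueError, match="mixed reference"):
            integrate_pairs([iv("zebrafish", 0, 120), other])

    def test_partition_matches_position_sweep_oracle(self, rng):
        species = [f"sp{i}" for i in range(4)]
        for _ in range(40):
            intervals = []
            triples = []
            for sp in species:
                n = rng.integers(0, 3)
                for _ in range(n):
                    start = int(rng.integers(0, 400))
                    end = start + int(rng.integers(20, 150))
                    intervals.append(iv(sp, start, end))
                    triples.append((start, end, sp))
            elements = integrate_pairs(intervals)
            for element in elements:
                members = [
                    (t[0], t[1], t[2])
                    for t in triples
                    if t[0] < element.end and element.start < t[1]
                    and any(
                        m.qry_species == t[2] and m.start == t[0] and m.end == t[1]
                        for m in intervals
                    )
                ]
                runs = [
                    (s, e, supp | {REF})
                    for s, e, supp in sweep_support_runs(
                        members, (element.start, element.end)
                    )
                ]
                if element.sub_elements:
                    got = [
                        (s.start, s.end, set(s.support))
                        for s in element.sub_elements
                    ]
                else:
                    got = [(element.start, element.end, set(element.support))]
                expected = [(s, e, set(supp)) for s, e, supp in runs]
                assert got == expected

    def test_sub_intervals_partition_element_exactly(self, rng):
        for _ in range(25):
            intervals = []
            for sp in ("a", "b", "c"):
                start = int(rng.integers(0, 200))
                intervals.append(iv(sp, start, start + int(rng.integers(30, 200))))
            for element in integrate_pairs(intervals):
                if not element.sub_elements:
                    continue
                assert element.sub_elements[0].start == element.start
                assert element.sub_elements[-1].end == element.end
                for left, right in zip(element.sub_elements, element.sub_elements[1:]):
                    assert left.end == right.start
                    assert left.support != right.support

    def test_integration_is_idempotent_on_derived_structure(self):
        intervals = [iv("sp2", 100, 220), iv("sp3", 220, 330), iv("spanner", 100, 330)]
        first = integrate_pairs(intervals)
        second = integrate_pairs(intervals)
        assert first == second


class TestAssignNames:
    def _elements(self, starts):
        return integrate_pairs([iv("medaka", s, s + 120) for s in starts])

    def test_serials_follow_start_order(self):
        named = assign_names(self._elements([500, 100, 900]), "34", "intergenic")
        assert [c.name for c in named] == ["I34.1", "I34.2", "I34.3"]
        assert [c.start for c in named] == [100, 500, 900]

    def test_flanking_elements_get_f_prefix(self):
        named = assign_names(self._elements([50]), "56", "flanking3")
        assert named[0].name == "F56.1"

    def test_adding_upstream_element_shifts_serials(self):
        base = assign_names(self._elements([500, 900]), "12", "intergenic")
        shifted = assign_names(self._elements([100, 500, 900]), "12", "intergenic")
        assert [c.name for c in base] == ["I12.1", "I12.2"]
        assert [c.name for c in shifted] == ["I12.1", "I12.2", "I12.3"]
        assert shifted[1].start == base[0].start


class TestPresenceMatrix:
    def _named(self, intervals):
        return assign_names(integrate_pairs(intervals), "56", "flanking3")

    def test_supported_everywhere_gives_row_of_ones(self):
        cnes = self._named([iv("medaka", 0, 150), iv("zebrafish", 0, 150)])
        taxa = [REF, "medaka", "zebrafish"]
        matrix = presence_matrix(cnes, taxa, {sp: [(0, 150)] for sp in taxa})
        assert list(matrix.frame.loc[:, "F56.1"]) == ["1", "1", "1"]

    def test_n_masked_region_scores_missing_not_absent(self):
        # conserved in all species whose region is sequenced; the anole
        # region is mostly N across the element, so its state is unknown
        cnes = self._named([iv("medaka", 100, 260), iv("zebrafish", 100, 260)])
        availability = {
            REF: [(0, 400)],
            "medaka": [(0, 400)],
            "zebrafish": [(0, 400)],
            "anole": [(0, 120)],  # covers only 20/160 of the element
        }
        matrix = presence_matrix(cnes, list(availability), availability)
        assert matrix.state("anole", "F56.1") is None
        assert matrix.state("zebrafish", "F56.1") == 1

    def test_sequenced_but_unsupported_scores_absent(self):
        cnes = self._named([iv("medaka", 100, 260)])
        availability = {REF: [(0, 400)], "medaka": [(0, 400)], "zebrafish": [(0, 400)]}
        matrix = presence_matrix(cnes, list(availability), availability)
        assert matrix.state("zebrafish", "F56.1") == 0

    def test_removing_a_species_region_flips_states_to_missing(self):
        cnes = self._named([iv("medaka", 100, 260), iv("zebrafish", 400, 560)])
        availability = {REF: [(0, 600)], "medaka": [(0, 600)], "zebrafish": [(0, 600)]}
        with_region = presence_matrix(cnes, list(availability), availability)
        availability["zebrafish"] = []
        without = presence_matrix(cnes, list(availability), availability)
        for char in with_region.characters:
            if with_region.state("zebrafish", char) != 1:
                assert without.state("zebrafish", char) is None

    def test_sub_elements_become_their_own_characters(self):
        cnes = self._named(
            [iv("sp2", 100, 220), iv("sp3", 220, 330), iv("spanner", 100, 330)]
        )
        taxa = [REF, "sp2", "sp3", "spanner"]
        matrix = presence_matrix(cnes, taxa, {sp: [(0, 400)] for sp in taxa})
        assert matrix.characters == ["F56.1a", "F56.1b", "F56.1ab"]
        assert matrix.state("sp2", "F56.1a") == 1
        assert matrix.state("sp2", "F56.1b") == 0
        assert matrix.state("sp2", "F56.1ab") == 1

    def test_taxon_missing_from_availability_rejected(self):
        cnes = self._named([iv("medaka", 0, 150)])
        with pytest.raises(ValueError, match="anole"):
            presence_matrix(cnes, [REF, "anole"], {REF: [(0, 150)]})
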