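import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanomock.design import (
    AbundanceSpec,
    DesignError,
    OrganismSpec,
    ResolvedAbundance,
    SampleDesign,
    TaxonSpec,
    design_from_dict,
    design_to_dict,
    distribute_subtaxa,
    largest_remainder,
    make_dilution_series,
    parse_design,
    resolve_abundances,
)
from nanomock.sim_core import LengthModel

from .oracles import bruteforce_apportion


def _org(name, mode=None, value=None, ref="x.fasta"):
    ab = None if mode is None else AbundanceSpec(mode, value)
    return OrganismSpec(name, ref, ab)


class TestAbundanceSpec:
    def test_absolute_must_be_nonneg_integer(self):
        AbundanceSpec("absolute", 0)
        AbundanceSpec("absolute", 500)
        with pytest.raises(DesignError):
            AbundanceSpec("absolute", -1)
        with pytest.raises(DesignError):
            AbundanceSpec("absolute", 1.5)

    def test_relative_range(self):
        AbundanceSpec("relative", 0.005)
        with pytest.raises(DesignError):
            AbundanceSpec("relative", 101)

    def test_random_takes_no_value(self):
        AbundanceSpec("random")
        with pytest.raises(DesignError):
            AbundanceSpec("random", 5)


class TestLargestRemainder:
    def test_hand_example(self):
        # shares 3.34 / 3.33 / 3.33: remainder unit goes to the largest frac
        assert largest_remainder([3.34, 3.33, 3.33], 10) == [4, 3, 3]

    def test_integers_pass_through(self):
        assert largest_remainder([5.0, 3.0, 2.0], 10) == [5, 3, 2]

    def test_ties_break_by_declaration_order(self):
        assert largest_remainder([1.5, 2.5], 4) == [2, 2]
        assert largest_remainder([2.5, 1.5], 4) == [3, 1]

    def test_conservation(self):
        counts = largest_remainder([0.6, 0.6, 0.8], 2)
        assert sum(counts) == 2

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=6),
        st.integers(min_value=0, max_value=1000),
    )
    def test_property_exact_total_and_one_unit_bound(self, weights, total):
        s = sum(weights)
        if s == 0:
            shares = [total / len(weights)] * len(weights)
        else:
            shares = [w / s * total for w in weights]
        counts = largest_remainder(shares, total)
        assert sum(counts) == total
        assert all(abs(c - sh) < 1 + 1e-9 for c, sh in zip(counts, shares))


class TestResolveAbundances:
    def test_all_absolute_identity(self):
        d = SampleDesign(
            entries=[_org("a", "absolute", 110_000), _org("b", "absolute", 120_000)]
        )
        r = resolve_abundances(d, seed=0)
        assert r.counts == {"a": 110_000, "b": 120_000}
        assert r.total == 230_000

    def test_single_relative_of_total(self):
        d = SampleDesign(
            entries=[_org("v", "relative", 0.5), _org("h", "random")],
            total_reads=100_000,
        )
        r = resolve_abundances(d, seed=1)
        assert r.counts["v"] == 500
        assert r.total == 100_000

    def test_largest_remainder_applied(self):
        d = SampleDesign(
            entries=[
                _org("a", "relative", 33.4),
                _org("b", "relative", 33.3),
                _org("c", "relative", 33.3),
            ],
            total_reads=10,
        )
        r = resolve_abundances(d, seed=0)
        assert list(r.counts.values()) == [4, 3, 3]

    def test_host_fill_remainder(self):
        d = SampleDesign(
            entries=[_org("virus", "absolute", 500), _org("wheat")],
            total_reads=100_000,
            host="wheat",
            fill_remainder=True,
            scenario="host_microbiome",
        )
        r = resolve_abundances(d, seed=0)
        assert r.counts == {"virus": 500, "wheat": 99_500}

    def test_random_mode_conserves_and_is_deterministic(self):
        d = SampleDesign(
            entries=[_org("a", "absolute", 100)]
            + [_org(f"r{i}", "random") for i in range(4)],
            total_reads=1100,
        )
        r1 = resolve_abundances(d, seed=5)
        r2 = resolve_abundances(d, seed=5)
        assert r1 == r2
        assert sum(r1.counts.values()) == 1100
        assert r1.counts["a"] == 100
        r3 = resolve_abundances(d, seed=6)
        assert r3.total == 1100  # different seed still conserves

    def test_over_allocation_absolute(self):
        d = SampleDesign(
            entries=[_org("a", "absolute", 200), _org("b", "random")],
            total_reads=100,
        )
        with pytest.raises(DesignError, match="exceed"):
            resolve_abundances(d, seed=0)

    def test_relative_overflow(self):
        with pytest.raises(DesignError, match="100"):
            SampleDesign(
                entries=[_org("a", "relative", 60), _org("b", "relative", 50)],
                total_reads=100,
            )

    def test_incomplete_relative_without_sink(self):
        d = SampleDesign(
            entries=[_org("a", "relative", 60), _org("b", "relative", 20)],
            total_reads=100,
        )
        with pytest.raises(DesignError, match="complete the total"):
            resolve_abundances(d, seed=0)

    def test_relative_report_consistency(self):
        d = SampleDesign(
            entries=[_org("v", "relative", 0.005), _org("h", "random")],
            total_reads=100_000,
        )
        r = resolve_abundances(d, seed=0)
        assert r.counts["v"] == 5
        assert r.counts["v"] / r.total * 100 == pytest.approx(0.005)

    @settings(max_examples=100, deadline=None)
    @given(
        n_abs=st.integers(0, 3),
        n_rand=st.integers(1, 3),
        total=st.integers(1, 10_000),
        seed=st.integers(0, 2**31),
        data=st.data(),
    )
    def test_conservation_property(self, n_abs, n_rand, total, seed, data):
        entries = []
        budget = total
        for i in range(n_abs):
            v = data.draw(st.integers(0, budget))
            budget -= v
            entries.append(_org(f"a{i}", "absolute", v))
        entries += [_org(f"r{i}", "random") for i in range(n_rand)]
        d = SampleDesign(entries=entries, total_reads=total)
        r = resolve_abundances(d, seed=seed)
        assert sum(r.counts.values()) == r.total == total
        assert all(c >= 0 for c in r.counts.values())


class TestBruteForceOracle:
    """Largest-remainder resolution must match exhaustive enumeration."""

    CASES = [
        ([100.0], 1),
        ([100.0], 50),
        ([50.0, 50.0], 3),
        ([60.0, 40.0], 10),
        ([33.4, 33.3, 33.3], 10),
        ([33.333, 33.333, 33.334], 50),
        ([70.0, 20.0, 10.0], 7),
        ([25.0, 25.0, 25.0, 25.0], 10),
        ([40.0, 30.0, 20.0, 10.0], 13),
        ([90.0, 2.5, 2.5, 2.5, 2.5], 41),
        ([17.0, 17.0, 17.0, 17.0, 16.0, 16.0], 50),
        ([0.5, 99.5], 50),
        ([10.0, 20.0, 30.0, 15.0, 15.0, 10.0], 37),
    ]

    @pytest.mark.parametrize("percentages,total", CASES)
    def test_matches_oracle(self, percentages, total):
        shares = [p / 100 * total for p in percentages]
        assert largest_remainder(shares, total) == bruteforce_apportion(
            percentages, total
        )

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(1, 6),
        total=st.integers(1, 50),
        data=st.data(),
    )
    def test_matches_oracle_property(self, n, total, data):
        raw = [
            data.draw(st.floats(min_value=0.001, max_value=1.0)) for _ in range(n)
        ]
        s = sum(raw)
        percentages = [round(w / s * 100, 3) for w in raw]
        percentages[-1] = round(100 - sum(percentages[:-1]), 3)
        if percentages[-1] < 0:
            return
        shares = [p / 100 * total for p in percentages]
        assert largest_remainder(shares, total) == bruteforce_apportion(
            percentages, total
        )


class TestDistributeSubtaxa:
    def test_equal_exact(self):
        assert distribute_subtaxa(100, 4, "equal") == [25, 25, 25, 25]

    def test_equal_remainder_to_first(self):
        assert distribute_subtaxa(10, 3, "equal") == [4, 3, 3]

    def test_random_conserves_and_deterministic(self):
        a = distribute_subtaxa(1000, 5, "random", seed=11)
        b = distribute_subtaxa(1000, 5, "random", seed=11)
        assert a == b
        assert sum(a) == 1000
        assert all(c >= 0 for c in a)

    def test_taxon_members_resolved(self, tmp_path):
        members = (_org("m1"), _org("m2"), _org("m3"))
        d = SampleDesign(
            entries=[
                TaxonSpec("complex", AbundanceSpec("absolute", 10), members),
                _org("solo", "absolute", 5),
            ]
        )
        r = resolve_abundances(d, seed=0)
        assert r.counts == {"m1": 4, "m2": 3, "m3": 3, "solo": 5}
        assert d.taxon_of("m2") == "complex"

    def test_member_abundance_rejected(self):
        with pytest.raises(DesignError, match="must not carry"):
            TaxonSpec(
                "t", AbundanceSpec("absolute", 10), (_org("m", "absolute", 5),)
            )


class TestMakeDilutionSeries:
    def _base(self):
        return SampleDesign(
            entries=[_org("virus", "absolute", 500), _org("wheat")],
            seed=99,
            sample_name="dil",
            total_reads=100_000,
            host="wheat",
            fill_remainder=True,
        )

    def test_level_count(self):
        designs = make_dilution_series(
            self._base(), "virus", [500, 100, 50, 10, 5], replicates=20
        )
        assert len(designs) == 100

    def test_every_replicate_resolves_exactly(self):
        designs = make_dilution_series(self._base(), "virus", [10], replicates=20)
        counts = [resolve_abundances(d).counts["virus"] for d in designs]
        assert counts == [10] * 20
        hosts = [resolve_abundances(d).counts["wheat"] for d in designs]
        assert hosts == [99_990] * 20

    def test_child_seeds_distinct(self):
        designs = make_dilution_series(self._base(), "virus", [10, 5], replicates=3)
        seeds = [d.seed for d in designs]
        assert len(set(seeds)) == 6

    def test_level_exceeding_total(self):
        with pytest.raises(DesignError):
            make_dilution_series(self._base(), "virus", [200_000], replicates=1)

    def test_unknown_organism(self):
        with pytest.raises(DesignError):
            make_dilution_series(self._base(), "nope", [10], replicates=1)


class TestParseDesign:
    def _write_yaml(self, tmp_path, ref_dir, text):
        p = tmp_path / "design.yaml"
        p.write_text(text.format(refs=ref_dir))
        return p

    def test_single_absolute(self, tmp_path, ref_dir):
        p = self._write_yaml(
            tmp_path,
            ref_dir,
            "entries:\n"
            "  - organism: orgA\n"
            "    reference: {refs}/orgA.fasta\n"
            "    abundance: {{mode: absolute, value: 500}}\n",
        )
        d = parse_design(p)
        assert d.total_reads == 500  # implied total
        assert d.scenario == "environmental"
        assert d.replicates == 1

    def test_relative_sum_over_100(self, tmp_path, ref_dir):
        p = self._write_yaml(
            tmp_path,
            ref_dir,
            "total_reads: 1000\n"
            "entries:\n"
            "  - organism: a\n"
            "    reference: {refs}/orgA.fasta\n"
            "    abundance: {{mode: relative, value: 60}}\n"
            "  - organism: b\n"
            "    reference: {refs}/orgB.fasta\n"
            "    abundance: {{mode: relative, value: 50}}\n",
        )
        with pytest.raises(DesignError, match="100"):
            parse_design(p)

    def test_host_pathogen_table3_shape(self, tmp_path, ref_dir):
        p = self._write_yaml(
            tmp_path,
            ref_dir,
            "total_reads: 100000\n"
            "scenario: host_microbiome\n"
            "host: wheat\n"
            "fill_remainder: true\n"
            "entries:\n"
            "  - organism: virus\n"
            "    reference: {refs}/virus.fasta\n"
            "    abundance: {{mode: absolute, value: 500}}\n"
            "  - organism: wheat\n"
            "    reference: {refs}/host.fasta\n",
        )
        r = resolve_abundances(parse_design(p))
        assert r.counts == {"virus": 500, "wheat": 99_500}

    def test_missing_reference(self, tmp_path):
        p = tmp_path / "design.yaml"
        p.write_text(
            "entries:\n"
            "  - organism: a\n"
            "    reference: missing.fasta\n"
            "    abundance: {mode: absolute, value: 5}\n"
        )
        with pytest.raises(DesignError, match="missing.fasta"):
            parse_design(p)

    def test_duplicate_names(self, tmp_path, ref_dir):
        p = self._write_yaml(
            tmp_path,
            ref_dir,
            "entries:\n"
            "  - organism: a\n"
            "    reference: {refs}/orgA.fasta\n"
            "    abundance: {{mode: absolute, value: 5}}\n"
            "  - organism: a\n"
            "    reference: {refs}/orgB.fasta\n"
            "    abundance: {{mode: absolute, value: 5}}\n",
        )
        with pytest.raises(DesignError, match="duplicate"):
            parse_design(p)

    def test_json_design(self, tmp_path, ref_dir):
        p = tmp_path / "design.json"
        p.write_text(
            json.dumps(
                {
                    "entries": [
                        {
                            "organism": "a",
                            "reference": str(ref_dir / "orgA.fasta"),
                            "abundance": {"mode": "absolute", "value": 7},
                        }
                    ]
                }
            )
        )
        assert parse_design(p).total_reads == 7

    def test_tsv_shortcut(self, tmp_path, ref_dir):
        p = tmp_path / "design.tsv"
        p.write_text(
            "organism\treference\tmode\tvalue\n"
            f"a\t{ref_dir}/orgA.fasta\tabsolute\t30\n"
            f"b\t{ref_dir}/orgB.fasta\tabsolute\t20\n"
        )
        r = resolve_abundances(parse_design(p))
        assert r.counts == {"a": 30, "b": 20}

    def test_abundance_shorthand(self, tmp_path, ref_dir):
        p = self._write_yaml(
            tmp_path,
            ref_dir,
            "total_reads: 1000\n"
            "entries:\n"
            "  - organism: a\n"
            "    reference: {refs}/orgA.fasta\n"
            "    abundance: '40%'\n"
            "  - organism: b\n"
            "    reference: {refs}/orgB.fasta\n"
            "    abundance: '60%'\n",
        )
        r = resolve_abundances(parse_design(p))
        assert r.counts == {"a": 400, "b": 600}

    def test_round_trip_via_dict(self, host_pathogen_design):
        data = design_to_dict(host_pathogen_design)
        back = design_from_dict(data, check_refs=False)
        assert design_to_dict(back) == data

    def test_length_model_parsed(self, tmp_path, ref_dir):
        p = self._write_yaml(
            tmp_path,
            ref_dir,
            "length_model: {{mean: 2000, sd: 200, min_len: 60}}\n"
            "entries:\n"
            "  - organism: a\n"
            "    reference: {refs}/orgA.fasta\n"
            "    abundance: {{mode: absolute, value: 5}}\n",
        )
        d = parse_design(p)
        assert d.length_model == LengthModel(2000, 200, min_len=60)


class TestResolvedAbundanceInvariants:
    def test_sum_mismatch_rejected(self):
        with pytest.raises(DesignError):
            ResolvedAbundance(counts={"a": 1, "b": 1}, total=3)

    def test_negative_rejected(self):
        with pytest.raises(DesignError):
            ResolvedAbundance(counts={"a": -1, "b": 4}, total=3)
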