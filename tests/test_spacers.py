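"""Amplicon spacer pipeline: size selection, repeat-anchored extraction,
d-linkage clustering against a brute-force oracle, abundance assignment and
PAM classification."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprcost.spacers import (
    AmpliconRead,
    PamRule,
    SpacerError,
    assign_abundance,
    classify_spacer,
    extract_spacers,
    filter_clusters,
    size_filter,
    swarm_cluster,
)

REPEAT = "GTTCACTGCCGTGTAGGCAGCTAAGAAA"


def levenshtein(s1, s2):
    """Plain DP edit distance; the independent oracle for clustering."""
    if len(s1) < len(s2):
        s1, s2 = s2, s1
    prev = list(range(len(s2) + 1))
    for i, c1 in enumerate(s1):
        cur = [i + 1]
        for j, c2 in enumerate(s2):
            cur.append(min(prev[j + 1] + 1, cur[j] + 1, prev[j] + (c1 != c2)))
        prev = cur
    return prev[-1]


def brute_force_components(variants, d):
    """Connected components of the <=d-edit graph via union-find."""
    seqs = list(variants)
    parent = list(range(len(seqs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if abs(len(seqs[i]) - len(seqs[j])) <= d and levenshtein(seqs[i], seqs[j]) <= d:
                parent[find(i)] = find(j)
    comps = {}
    for i, s in enumerate(seqs):
        comps.setdefault(find(i), set()).add(s)
    return {frozenset(c) for c in comps.values()}


def random_variant_set(rng, n_base=8, n_total=60, length=12):
    """Variant sets with genuine cluster structure: bases plus 1-2-edit mutants."""
    bases = ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n_base)]
    variants = {}
    for seq in bases:
        variants[seq] = int(rng.integers(2, 50))
        for _ in range(rng.integers(0, (n_total - n_base) // n_base + 1)):
            s = list(seq)
            for _ in range(rng.integers(1, 3)):
                op = rng.integers(0, 3)
                pos = rng.integers(0, len(s))
                if op == 0:
                    s[pos] = rng.choice(list("ACGT"))
                elif op == 1 and len(s) > 3:
                    del s[pos]
                else:
                    s.insert(pos, rng.choice(list("ACGT")))
            variants.setdefault("".join(s), int(rng.integers(1, 10)))
    return variants


class TestSizeFilter:
    def test_crispr1_upper_bound(self):
        read = AmpliconRead("r1", "A" * 150, "s1", "CRISPR1")
        assert size_filter([read]) == []

    def test_crispr2_lower_bound_inclusive(self):
        read = AmpliconRead("r1", "A" * 70, "s1", "CRISPR2")
        assert size_filter([read]) == [read]

    def test_empty_input(self):
        assert size_filter([]) == []

    def test_unknown_locus(self):
        with pytest.raises(SpacerError, match="locus"):
            size_filter([AmpliconRead("r1", "ACGT" * 10, "s1", "CRISPR9")])

    def test_order_preserved(self):
        reads = [AmpliconRead(f"r{i}", "A" * (30 + i), "s", "CRISPR1") for i in range(5)]
        assert [r.id for r in size_filter(reads)] == [r.id for r in reads]


class TestExtractSpacers:
    def test_single_inter_repeat_segment(self):
        read = AmpliconRead("r", REPEAT + "ACGTACGT" + REPEAT, "s", "CRISPR2")
        spacers = extract_spacers(read, REPEAT)
        assert [sp.sequence for sp in spacers] == ["ACGTACGT"]
        assert not spacers[0].partial

    def test_two_spacers_in_order(self):
        sp1, sp2 = "ACGTACGTACGTACGT", "TTGACCAGTTGACCAG"
        read = AmpliconRead("r", REPEAT + sp1 + REPEAT + sp2 + REPEAT, "s", "CRISPR2")
        out = [sp.sequence for sp in extract_spacers(read, REPEAT) if not sp.partial]
        assert out == [sp1, sp2]

    def test_no_repeat_hits(self):
        read = AmpliconRead("r", "ACGT" * 20, "s", "CRISPR2")
        assert extract_spacers(read, "TTTTTTTTGGGGGGGG", max_mismatches=0) == []

    def test_flanking_segments_flagged_partial(self):
        read = AmpliconRead("r", "AACC" + REPEAT + "ACGTACGT" + REPEAT + "GGTT",
                            "s", "CRISPR2")
        spacers = extract_spacers(read, REPEAT)
        flags = [(sp.sequence, sp.partial) for sp in spacers]
        assert flags == [("AACC", True), ("ACGTACGT", False), ("GGTT", True)]

    def test_tolerates_repeat_mismatches(self):
        mutated = "A" + REPEAT[1:]
        read = AmpliconRead("r", REPEAT + "ACGTACGT" + mutated, "s", "CRISPR2")
        assert [sp.sequence for sp in extract_spacers(read, REPEAT, 2)] == ["ACGTACGT"]

    def test_short_repeat_rejected(self):
        read = AmpliconRead("r", "ACGT" * 10, "s", "CRISPR2")
        with pytest.raises(SpacerError, match="repeat"):
            extract_spacers(read, "ACGT")


class TestSwarmCluster:
    def test_two_components(self):
        clusters = swarm_cluster({"ACGT": 10, "ACGA": 2, "TTTT": 5}, d=1)
        got = {c.centroid: (set(c.members), c.total) for c in clusters}
        assert got == {"ACGT": ({"ACGT", "ACGA"}, 12), "TTTT": ({"TTTT"}, 5)}

    def test_chain_transitivity(self):
        # ends are 2 edits apart but chained through the middle variant
        clusters = swarm_cluster({"AAAA": 5, "AAAT": 1, "AATT": 3}, d=1)
        assert len(clusters) == 1
        assert clusters[0].total == 9

    def test_singleton(self):
        clusters = swarm_cluster({"ACGTACGT": 7}, d=1)
        assert len(clusters) == 1 and clusters[0].centroid == "ACGTACGT"

    def test_centroid_is_most_abundant_member(self):
        clusters = swarm_cluster({"AAAA": 2, "AAAT": 9}, d=1)
        assert clusters[0].centroid == "AAAT"

    def test_rejects_d_zero(self):
        with pytest.raises(SpacerError):
            swarm_cluster({"ACGT": 1}, d=0)

    def test_conservation_of_counts(self):
        rng = np.random.default_rng(7)
        variants = random_variant_set(rng)
        clusters = swarm_cluster(variants, d=1)
        assert sum(c.total for c in clusters) == sum(variants.values())

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        variants = random_variant_set(rng)
        ref = swarm_cluster(variants, d=1)
        items = list(variants.items())
        random.Random(3).shuffle(items)
        alt = swarm_cluster(dict(items), d=1)
        assert [(c.centroid, c.total) for c in ref] == [(c.centroid, c.total) for c in alt]

    @pytest.mark.parametrize("d", [1, 2])
    def test_matches_brute_force_components(self, d):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            variants = random_variant_set(rng)
            ours = {frozenset(c.members) for c in swarm_cluster(variants, d=d)}
            assert ours == brute_force_components(variants, d)


class TestFilterClusters:
    def test_singleton_removed_at_default(self):
        clusters = swarm_cluster({"ACGTACGT": 1, "TTTTCCCC": 2}, d=1)
        kept = filter_clusters(clusters)
        assert [c.centroid for c in kept] == ["TTTTCCCC"]

    def test_boundary_total_two_retained(self):
        clusters = swarm_cluster({"ACGTACGT": 2}, d=1)
        assert len(filter_clusters(clusters, min_size=2)) == 1

    def test_min_size_one_is_identity(self):
        clusters = swarm_cluster({"ACGTACGT": 1, "TTTTCCCC": 1}, d=1)
        assert filter_clusters(clusters, min_size=1) == clusters


class TestAssignAbundance:
    def test_exact_match_assigned(self):
        table = assign_abundance([("ACGTACGT", "s1", 5)], ["ACGTACGT"])
        assert table.loc["ACGTACGT", "s1"] == 5
        assert table.loc["unassigned", "s1"] == 0

    def test_two_mismatches_in_100bp_unassigned_at_99pct(self):
        centroid = "AC" * 50
        query = "GG" + centroid[2:]          # 98% identity
        table = assign_abundance([(query, "s1", 3)], [centroid], min_identity=0.99)
        assert table.loc["unassigned", "s1"] == 3

    def test_one_mismatch_in_100bp_assigned_at_99pct(self):
        centroid = "AC" * 50
        query = "G" + centroid[1:]           # 99% identity
        table = assign_abundance([(query, "s1", 3)], [centroid], min_identity=0.99)
        assert table.loc[centroid, "s1"] == 3

    def test_column_sums_conserved(self):
        seqs = [("ACGTACGT", "s1", 4), ("ACGTACGT", "s2", 2), ("TTTTTTTT", "s1", 9)]
        table = assign_abundance(seqs, ["ACGTACGT"])
        assert table["s1"].sum() == 13 and table["s2"].sum() == 2

    def test_no_centroids_rejected(self):
        with pytest.raises(SpacerError):
            assign_abundance([("ACGT", "s1", 1)], [])


def _genome_with(protospacer, pam3, filler="T", length=200, at=60):
    g = list(filler * length)
    g[at:at + len(protospacer)] = protospacer
    g[at + len(protospacer):at + len(protospacer) + len(pam3)] = pam3
    return "".join(g)


class TestClassifySpacer:
    SPACER = "ACGGATTTACAGGCAACCTT"

    def test_phage_canonical(self):
        phage = _genome_with(self.SPACER, "GG")
        rec = classify_spacer(self.SPACER, phage, "A" * 100,
                              PamRule(priming_center=60))
        assert (rec.target, rec.pam, rec.coordinate, rec.strand) == ("phage", "canonical", 60, "+")

    def test_host_noncanonical(self):
        host = _genome_with(self.SPACER, "TA")
        rec = classify_spacer(self.SPACER, "A" * 100, host, PamRule(priming_center=60))
        assert (rec.target, rec.pam) == ("host", "non-canonical")

    def test_unknown_when_absent(self):
        rec = classify_spacer(self.SPACER, "A" * 100, "C" * 100)
        assert (rec.target, rec.pam, rec.coordinate) == ("unknown", "NA", -1)

    def test_reverse_complement_same_locus(self):
        from Bio.Seq import Seq

        phage = _genome_with(self.SPACER, "GG")
        fwd = classify_spacer(self.SPACER, phage, "A" * 100, PamRule(priming_center=60))
        rev = classify_spacer(str(Seq(self.SPACER).reverse_complement()), phage,
                              "A" * 100, PamRule(priming_center=60))
        assert fwd.target == rev.target
        assert fwd.coordinate == rev.coordinate
        assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_multiple_hits_resolved_to_priming_proximal(self):
        phage = (_genome_with(self.SPACER, "GG", length=120, at=10)
                 + _genome_with(self.SPACER, "TT", length=120, at=60))
        rec = classify_spacer(self.SPACER, phage, "A" * 100,
                              PamRule(priming_center=185))
        assert rec.coordinate == 180 and rec.pam == "non-canonical"

    def test_phage_searched_before_host(self):
        phage = _genome_with(self.SPACER, "GG")
        host = _genome_with(self.SPACER, "GG")
        assert classify_spacer(self.SPACER, phage, host).target == "phage"

    def test_short_spacer_rejected(self):
        with pytest.raises(SpacerError, match="short"):
            classify_spacer("ACGTACGTACGT", "A" * 50, "C" * 50)

    def test_5prime_pam_side(self):
        g = "T" * 58 + "GG" + self.SPACER + "TTTT" + "T" * 40
        rec = classify_spacer(self.SPACER, g, "A" * 100,
                              PamRule(side="5prime", priming_center=60))
        assert rec.pam == "canonical"


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.text(alphabet="ACGT", min_size=4, max_size=10), min_size=1,
                max_size=12, unique=True),
       st.integers(min_value=1, max_value=2))
def test_swarm_components_match_oracle_property(seqs, d):
    variants = {s: i + 1 for i, s in enumerate(seqs)}
    ours = {frozenset(c.members) for c in swarm_cluster(variants, d=d)}
    assert ours == brute_force_components(variants, d)
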