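import numpy as np
import pytest
from Bio.Seq import Seq

from paralogpace.io_formats import HomologyHit, Transcript
from paralogpace.trio_builder import (
    ClusterMember, HomologCluster, align_and_backtranslate, back_translate,
    build_clusters, dedupe_queries, screen_pairs, select_trios,
    star_protein_msa, trim_common_region,
)


def member(tid, species, nt, q_interval, pct_positive=90.0, align_length=None,
           evalue=1e-30):
    aa = str(Seq(nt).translate())
    return ClusterMember(
        transcript_id=tid, species=species, nt_seq=nt, aa_seq=aa,
        q_interval=q_interval, pct_positive=pct_positive,
        align_length=align_length or (q_interval[1] - q_interval[0] + 1),
        evalue=evalue,
    )


def random_cds(rng, n_codons):
    from paralogpace._codon_tables import SENSE_CODONS
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))


def mutate_cds(nt, n, rng):
    """n random single-base changes that keep codons sense."""
    from paralogpace._codon_tables import CODON_INDEX
    s = list(nt)
    done = 0
    while done < n:
        i = int(rng.integers(len(s)))
        old = s[i]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        s[i] = new
        codon_start = 3 * (i // 3)
        if "".join(s[codon_start:codon_start + 3]) in CODON_INDEX:
            done += 1
        else:
            s[i] = old
    return "".join(s)


class TestDedupe:
    def test_shared_accession_collapsed(self):
        qs = [("q1", "ACC1", "MA"), ("q2", "ACC1", "MA"), ("q3", "ACC2", "MK")]
        out = dedupe_queries(qs)
        assert [q[0] for q in out] == ["q1", "q3"]

    def test_all_distinct_identity(self):
        qs = [("q1", "A", "M"), ("q2", "B", "M")]
        assert dedupe_queries(qs) == qs


class TestBuildClusters:
    def _hit(self, qid, sid, s_start, s_end, evalue=1e-30):
        # translated search: query protein residues s_start..s_end matched;
        # contig nucleotides carried in q_start/q_end
        return HomologyHit(
            query_id=qid, subject_id=sid, pct_identity=80.0,
            align_length=s_end - s_start + 1, mismatches=0, gap_opens=0,
            q_start=0, q_end=3 * (s_end - s_start + 1), s_start=s_start,
            s_end=s_end, evalue=evalue, bitscore=100.0, pct_positive=85.0,
            frame=1,
        )

    def test_coverage_filter_at_50_percent(self, rng):
        prot = "M" * 200
        contigs = {"c1": Transcript(id="c1", sequence=random_cds(rng, 100)),
                   "c2": Transcript(id="c2", sequence=random_cds(rng, 99))}
        hits = [self._hit("q", "c1", 1, 100),   # covers 50% -> kept
                self._hit("q", "c2", 1, 99)]    # 49.5% -> discarded
        (cluster,) = build_clusters([("q", "ACC", prot)], hits, contigs)
        assert [m.transcript_id for m in cluster.members] == ["c1"]

    def test_evalue_filter(self, rng):
        prot = "M" * 100
        contigs = {"c1": Transcript(id="c1", sequence=random_cds(rng, 100))}
        hits = [self._hit("q", "c1", 1, 100, evalue=1e-9)]
        (cluster,) = build_clusters([("q", "ACC", prot)], hits, contigs)
        assert cluster.members == []

    def test_at_most_100_hits_considered(self, rng):
        prot = "M" * 100
        contigs = {f"c{i}": Transcript(id=f"c{i}", sequence=random_cds(rng, 100))
                   for i in range(120)}
        hits = [self._hit("q", f"c{i}", 1, 100, evalue=10 ** -(300 - i))
                for i in range(120)]
        (cluster,) = build_clusters([("q", "ACC", prot)], hits, contigs)
        assert len(cluster.members) == 100
        # kept hits are the 100 most significant
        assert {m.transcript_id for m in cluster.members} == {f"c{i}" for i in range(100)}

    def test_member_translation_uses_frame(self, rng):
        prot = "M" * 100
        cds = random_cds(rng, 100)
        contigs = {"c1": Transcript(id="c1", sequence=cds)}
        (cluster,) = build_clusters([("q", "ACC", prot)], [self._hit("q", "c1", 1, 100)],
                                    contigs)
        assert cluster.members[0].aa_seq == str(Seq(cds).translate())


class TestTrim:
    def test_interval_intersection(self):
        rng = np.random.default_rng(0)
        m1 = member("a", "ssal", random_cds(rng, 200), (1, 200))
        m2 = member("b", "ssal", random_cds(rng, 201), (50, 250))
        m3 = member("c", "eluc", random_cds(rng, 180), (40, 219))
        cl = trim_common_region(HomologCluster("q", "M" * 250, [m1, m2, m3]))
        assert cl.trimmed_region == (50, 200)
        assert not cl.discarded
        for m in cl.members:
            assert len(m.aa_seq) == 151
            assert len(m.nt_seq) == 453

    def test_member_that_would_shrink_region_below_minimum_removed(self):
        rng = np.random.default_rng(1)
        m1 = member("a", "ssal", random_cds(rng, 200), (1, 200))
        m2 = member("b", "ssal", random_cds(rng, 151), (50, 200))
        m3 = member("c", "eluc", random_cds(rng, 160), (41, 200))
        bad = member("d", "ssal", random_cds(rng, 81), (180, 260))  # would leave 21 aa
        cl = trim_common_region(HomologCluster("q", "M" * 260, [m1, m2, m3, bad]))
        assert cl.trimmed_region == (50, 200)
        assert "d" not in [m.transcript_id for m in cl.members]

    def test_low_positives_member_removed(self):
        rng = np.random.default_rng(2)
        m1 = member("a", "ssal", random_cds(rng, 200), (1, 200))
        m2 = member("b", "ssal", random_cds(rng, 200), (1, 200))
        m3 = member("c", "eluc", random_cds(rng, 200), (1, 200))
        weak = member("d", "ssal", random_cds(rng, 200), (1, 200), pct_positive=74.0)
        cl = trim_common_region(HomologCluster("q", "M" * 200, [m1, m2, m3, weak]))
        assert "d" not in [m.transcript_id for m in cl.members]
        assert len(cl.members) == 3

    def test_cluster_without_three_members_discarded(self):
        rng = np.random.default_rng(3)
        m1 = member("a", "ssal", random_cds(rng, 200), (1, 200))
        m2 = member("b", "ssal", random_cds(rng, 200), (1, 200))
        cl = trim_common_region(HomologCluster("q", "M" * 200, [m1, m2]))
        assert cl.discarded


class TestAlignment:
    def test_identical_proteins_gapless(self, rng):
        nt = random_cds(rng, 120)
        ms = [member(t, "ssal", nt, (1, 120)) for t in ("a", "b")]
        cl = HomologCluster("q", "M" * 120, ms)
        out = align_and_backtranslate(cl)
        assert out["a"] == out["b"] == nt

    def test_gap_pattern_threading(self):
        assert back_translate("M-A", "ATGGCA") == "ATG---GCA"
        assert back_translate("MKA", "ATGAAAGCA") == "ATGAAAGCA"

    def test_backtranslate_length_mismatch_names_member(self, rng):
        nt = random_cds(rng, 10)
        ms = [member("a", "ssal", nt, (1, 10)),
              member("b", "ssal", random_cds(rng, 30), (1, 30))]
        ms[0].aa_seq = "M" * 40  # force inconsistency
        with pytest.raises(ValueError, match="member a"):
            align_and_backtranslate(HomologCluster("q", "M" * 40, ms))

    def test_roundtrip_degap_translate(self, rng):
        """Removing gaps from each codon row and translating reproduces the
        member's protein exactly."""
        base = random_cds(rng, 150)
        seqs = {
            "a": base,
            "b": base[:300] + base[330:],            # 10-codon deletion
            "c": mutate_cds(base, 30, rng),
        }
        ms = [member(t, "ssal", s, (1, len(s) // 3)) for t, s in seqs.items()]
        out = align_and_backtranslate(HomologCluster("q", "M", ms))
        widths = {len(v) for v in out.values()}
        assert len(widths) == 1 and widths.pop() % 3 == 0
        for t, s in seqs.items():
            degapped = out[t].replace("-", "")
            assert degapped == s[:len(degapped)]
            assert str(Seq(degapped).translate()) == str(Seq(s).translate())[:len(degapped) // 3]


class TestScreen:
    def _cluster(self, rng, plant_allele=False, plant_contaminant=False,
                 plant_short=False):
        base = random_cds(rng, 200)
        members = [
            member("ssal_a", "ssal", mutate_cds(base, 60, rng), (1, 200)),
            member("ssal_b", "ssal", mutate_cds(base, 60, rng), (1, 200)),
            member("eluc_c", "eluc", mutate_cds(base, 80, rng), (1, 200)),
        ]
        if plant_allele:  # >98% identical to ssal_a
            allele = mutate_cds(members[0].nt_seq, 4, rng)
            members.append(member("ssal_allele", "ssal", allele, (1, 200)))
        if plant_contaminant:  # unrelated sequence, <60% identity
            members.append(member("ssal_contam", "ssal", random_cds(rng, 200), (1, 200)))
        if plant_short:  # aligns over <90% of the longer sequence
            members.append(member("ssal_short", "ssal", members[0].nt_seq[:480], (1, 160)))
        return HomologCluster("q", "M" * 200, members)

    def test_planted_allele_removed(self, rng):
        cl = screen_pairs(self._cluster(rng, plant_allele=True))
        ids = [m.transcript_id for m in cl.members]
        assert "ssal_allele" not in ids and len(ids) == 3

    def test_planted_contaminant_removed(self, rng):
        cl = screen_pairs(self._cluster(rng, plant_contaminant=True))
        ids = [m.transcript_id for m in cl.members]
        assert "ssal_contam" not in ids and len(ids) == 3

    def test_planted_short_aligner_removed(self, rng):
        cl = screen_pairs(self._cluster(rng, plant_short=True))
        ids = [m.transcript_id for m in cl.members]
        assert "ssal_short" not in ids and len(ids) == 3

    def test_clean_cluster_untouched_and_fixed_point(self, rng):
        cl = screen_pairs(self._cluster(rng))
        assert len(cl.members) == 3
        again = screen_pairs(cl)
        assert [m.transcript_id for m in again.members] == \
            [m.transcript_id for m in cl.members]


class TestSelectTrios:
    def _cluster_with(self, rng, n_ssal, n_eluc):
        base = random_cds(rng, 150)
        ms = []
        for i in range(n_ssal):
            ms.append(member(f"ssal_{i}", "ssal", mutate_cds(base, 40, rng), (1, 150)))
        for i in range(n_eluc):
            ms.append(member(f"eluc_{i}", "eluc", mutate_cds(base, 60, rng), (1, 150)))
        return HomologCluster(f"q{n_ssal}{n_eluc}", "M" * 150, ms)

    def test_composition_rules(self, rng):
        clusters = [
            self._cluster_with(rng, 2, 1),   # trio
            self._cluster_with(rng, 3, 1),   # surplus
            self._cluster_with(rng, 2, 0),   # no outgroup
            self._cluster_with(rng, 1, 1),   # too few paralogs
        ]
        trios, surplus = select_trios(clusters)
        assert len(trios) == 1 and surplus == 1
        t = trios[0]
        assert len(t.A) == len(t.B) == len(t.C)
        assert len(t.A) % 3 == 0

    def test_trio_translation_has_no_internal_stops(self, rng):
        trios, _ = select_trios([self._cluster_with(rng, 2, 1)])
        for seq in (trios[0].A, trios[0].B, trios[0].C):
            prot = str(Seq(seq.replace("-", "")).translate())
            assert "*" not in prot
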