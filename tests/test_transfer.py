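"""Helix-alignment classification, missing-helix inference, subdomain transfer."""

import numpy as np
import pytest

from topoclan import evo, synth, transfer
from topoclan.topology import (
    RepeatAnnotation,
    SegmentKind,
    parse_topology_string,
    propagate_sides,
    topology_label,
)
from topoclan.transfer import (
    AmbiguousTypeError,
    HelixAlignmentRecord,
    PairwiseAlignment,
    RepeatHit,
    choose_transporter_type,
    classify_helices,
    infer_final_topology,
    repeat_similarity,
    transfer_subdomains,
)


def identity_alignment(length, e_value=1e-10):
    return PairwiseAlignment.from_gapped("q", "t", "A" * length, "A" * length, e_value)


def oracle_classify(aln, q_topology, t_topology):
    """Exhaustive per-column reference for small alignments."""
    out = []
    q_helices = q_topology.helices()
    for k, th in enumerate(t_topology.helices()):
        best = 0
        for qh in q_helices:
            n = sum(
                1
                for q, t in aln.columns
                if t is not None
                and th.start <= t <= th.end
                and q is not None
                and qh.start <= q <= qh.end
            )
            best = max(best, n)
        if best >= 5:
            out.append((k, "aligned"))
            continue
        counts = {"gap": 0, "inside_loop": 0, "outside_loop": 0, "signal_peptide": 0}
        for q, t in aln.columns:
            if t is None or not (th.start <= t <= th.end):
                continue
            if q is None:
                counts["gap"] += 1
            else:
                kind = q_topology.segment_at(q).kind.value
                if kind in counts:
                    counts[kind] += 1
        winner = max(
            ["gap", "inside_loop", "outside_loop", "signal_peptide"],
            key=lambda s: (counts[s], -["gap", "inside_loop", "outside_loop", "signal_peptide"].index(s)),
        )
        out.append((k, winner))
    return out


def random_case(rng):
    """Random small (alignment, query topology, template topology) triple."""

    def random_topo():
        skeleton = "L" * rng.integers(5, 10)
        for _ in range(rng.integers(1, 3)):
            kind = "MRB"[rng.integers(3)]
            skeleton += kind * rng.integers(5, 9) + "L" * rng.integers(5, 10)
        return parse_topology_string(
            propagate_sides(skeleton, ["Nin", "Nout"][rng.integers(2)])
        )

    q_topo, t_topo = random_topo(), random_topo()
    n = min(q_topo.chain_length, t_topo.chain_length, 60)
    q_aln = ["A"] * n
    t_aln = ["A"] * n
    for k in range(n):
        r = rng.random()
        if r < 0.15:
            q_aln[k] = "-"
        elif r < 0.3:
            t_aln[k] = "-"
    # ensure both sequences stay inside their chains
    q_used = sum(1 for c in q_aln if c != "-")
    t_used = sum(1 for c in t_aln if c != "-")
    aln = PairwiseAlignment.from_gapped("q", "t", "".join(q_aln), "".join(t_aln), 1e-5)
    if q_used > q_topo.chain_length or t_used > t_topo.chain_length:
        return None
    return aln, q_topo, t_topo


class TestClassify:
    def test_five_residue_rule(self):
        # template helix aligned to a query helix over exactly 5 residues
        q = parse_topology_string("iiiii" + "M" * 12 + "ooooo")
        t = parse_topology_string("iiiiiiiiiiii" + "M" * 12 + "ooooo")
        aln = identity_alignment(22)
        recs = classify_helices(aln, q, t)
        assert recs[0].cls == "aligned" and recs[0].overlap_residues == 5

    def test_majority_loop_below_threshold(self):
        # 4 aligned helix residues, the rest of the template helix over an inside loop
        q = parse_topology_string("i" * 30 + "M" * 12 + "o" * 5)
        t = parse_topology_string("ooooo" + "M" * 18 + "i" * 24)
        aln = identity_alignment(47)
        recs = classify_helices(aln, q, t)
        assert recs[0].cls == "inside_loop"

    def test_all_gap_region(self):
        q = parse_topology_string("ii" + "M" * 12 + "oo")
        t = parse_topology_string("ii" + "M" * 12 + "oo")
        aln = PairwiseAlignment.from_gapped(
            "q", "t", "AA" + "-" * 12 + "A" * 14, "AA" + "A" * 12 + "AA" + "-" * 12, 1e-3
        )
        recs = classify_helices(aln, q, t)
        assert recs[0].cls == "gap"

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        n_checked = 0
        while n_checked < 200:
            case = random_case(rng)
            if case is None:
                continue
            aln, q_topo, t_topo = case
            got = [(r.template_helix_index, r.cls) for r in classify_helices(aln, q_topo, t_topo)]
            assert got == oracle_classify(aln, q_topo, t_topo)
            n_checked += 1


class TestChooseType:
    def test_lowest_e_value_wins(self):
        assert choose_transporter_type([("broken", 2.4e-48), ("reentrant", 3.3e-13)]) == "broken"
        assert choose_transporter_type([("reentrant", 1.8e-42), ("broken", 0.9)]) == "reentrant"

    def test_single_hit(self):
        assert choose_transporter_type([("reentrant", 0.5)]) == "reentrant"

    def test_exact_tie_requires_arbitration(self):
        with pytest.raises(AmbiguousTypeError):
            choose_transporter_type([("broken", 1e-5), ("reentrant", 1e-5)])


class TestInferFinal:
    def _blind_initial(self, fam, rep):
        mta = fam.mta(predicted=True)
        return evo.consensus_topology(mta, representative=rep)

    def test_regains_missing_reentrant_helices(self, reentrant_family):
        fam = reentrant_family
        mta = fam.mta(predicted=True)
        rep = evo.pick_representative(mta, list(mta.rows))
        initial = self._blind_initial(fam, rep)
        assert str(topology_label(initial)) == "10H-Nout"
        truth = fam.true_topology(rep)
        aln = identity_alignment(truth.chain_length, 1e-42)
        recs = classify_helices(aln, initial, truth)
        final = infer_final_topology(initial, truth, recs, aln)
        assert str(topology_label(final)) == "10H-2RH-Nout"

    def test_idempotent(self, reentrant_family):
        fam = reentrant_family
        mta = fam.mta(predicted=True)
        rep = evo.pick_representative(mta, list(mta.rows))
        initial = self._blind_initial(fam, rep)
        truth = fam.true_topology(rep)
        aln = identity_alignment(truth.chain_length, 1e-42)
        final = infer_final_topology(
            initial, truth, classify_helices(aln, initial, truth), aln
        )
        again = infer_final_topology(
            final, truth, classify_helices(aln, final, truth), aln
        )
        assert again.to_string() == final.to_string()

    def test_nothing_missing_is_noop(self, broken_family):
        t = broken_family.true_topology("seq000")
        aln = identity_alignment(t.chain_length)
        final = infer_final_topology(t, t, classify_helices(aln, t, t), aln)
        assert final.to_string() == t.to_string()

    def test_inserted_broken_helix_flips_downstream_sides(self):
        truth = parse_topology_string(
            propagate_sides("L" * 10 + "M" * 17 + "L" * 40 + "B" * 17 + "L" * 10 + "M" * 17 + "L" * 10, "Nin")
        )
        # prediction missed the broken helix: sides re-propagated without it
        blind = parse_topology_string(
            propagate_sides("L" * 10 + "M" * 17 + "L" * 67 + "M" * 17 + "L" * 10, "Nin")
        )
        aln = identity_alignment(truth.chain_length)
        recs = classify_helices(aln, blind, truth)
        final = infer_final_topology(blind, truth, recs, aln)
        assert final.to_string() == truth.to_string()
        # brute-force side propagation agrees downstream of the insertion
        bh = final.helices()[1]
        crossings = 0
        for seg in final.segments:
            if seg.kind in (SegmentKind.TM_HELIX, SegmentKind.BROKEN_HELIX):
                crossings += 1
            elif seg.start > bh.end:
                expected = "io"[crossings % 2 == 0]
                assert seg.side == ("i" if crossings % 2 == 0 else "o")

    def test_label_kind_follows_template_type(self, reentrant_family):
        fam = reentrant_family
        mta = fam.mta(predicted=True)
        rep = evo.pick_representative(mta, list(mta.rows))
        initial = self._blind_initial(fam, rep)
        truth = fam.true_topology(rep)
        aln = identity_alignment(truth.chain_length)
        final = infer_final_topology(
            initial, truth, classify_helices(aln, initial, truth), aln
        )
        assert topology_label(final).noncanonical_kind == "RH"


class TestTransferSubdomains:
    def _records_and_final(self, fam):
        mta = fam.mta(predicted=False)
        rep = evo.pick_representative(mta, list(mta.rows))
        truth = fam.true_topology(rep)
        aln = identity_alignment(truth.chain_length)
        recs = classify_helices(aln, truth, truth)
        return recs, truth, aln

    def test_one_to_one_map_copies_annotation(self, reentrant_family):
        recs, truth, aln = self._records_and_final(reentrant_family)
        ann = transfer_subdomains(reentrant_family.annotation, recs, truth, truth)
        assert ann.helix_tags == reentrant_family.annotation.helix_tags
        assert not ann.shuffled and ann.extrapolated == set()

    def test_extra_n_terminal_helix_extrapolated_as_scaffold(self):
        template = parse_topology_string(
            propagate_sides("L" * 10 + ("M" * 17 + "L" * 10) * 4, "Nin")
        )
        t_ann = RepeatAnnotation(
            n_repeat=(1, template.helices()[1].end + 5),
            c_repeat=(template.helices()[1].end + 6, template.chain_length),
            helix_tags=["scaffold", "core", "scaffold", "core"],
        )
        query = parse_topology_string(
            propagate_sides("L" * 10 + ("M" * 17 + "L" * 10) * 5, "Nout")
        )
        # template helix k aligns to query helix k+1 (query gained an N-term helix)
        q_aln = "A" * query.chain_length
        t_aln = "-" * 27 + "A" * template.chain_length + "-" * (query.chain_length - 27 - template.chain_length)
        aln = PairwiseAlignment.from_gapped("q", "t", q_aln, t_aln, 1e-8)
        recs = classify_helices(aln, query, template)
        ann = transfer_subdomains(t_ann, recs, query, template)
        assert ann.helix_tags[0] == "scaffold"
        assert 0 in ann.extrapolated

    def test_shuffled_repeats_flagged(self):
        # template: N-repeat then C-repeat; query aligns N<->C reciprocally
        template = parse_topology_string(
            propagate_sides("L" * 10 + ("M" * 17 + "L" * 10) * 4, "Nin")
        )
        cut = (template.helices()[1].end + template.helices()[2].start) // 2
        t_ann = RepeatAnnotation(
            n_repeat=(1, cut),
            c_repeat=(cut + 1, template.chain_length),
            helix_tags=["scaffold", "core", "scaffold", "core"],
        )
        half = 10 + (17 + 10) * 2
        q_aln = "A" * template.chain_length
        # query's first half aligns to the template's second half and vice versa
        t_aln = "A" * template.chain_length
        shifted_cols = list(range(half, template.chain_length)) + list(range(half))
        cols = [(q + 1, t + 1) for q, t in zip(range(template.chain_length), shifted_cols)]
        cols_q = sorted(cols)
        # build a monotone alignment from the two reciprocal blocks
        block1 = [(q, t) for q, t in cols_q if q <= half and t > half]
        block2 = [(q, t) for q, t in cols_q if q > half and t <= half]
        aln1 = PairwiseAlignment("q", "t", block1, 1e-6)
        query = parse_topology_string(
            propagate_sides("L" * 10 + ("M" * 17 + "L" * 10) * 4, "Nin")
        )
        recs = classify_helices(aln1, query, template)
        # template C-repeat helices align to query N-terminal helices
        aligned = {r.template_helix_index: r.query_helix_index for r in recs if r.cls == "aligned"}
        assert aligned == {2: 0, 3: 1}
        ann = transfer_subdomains(t_ann, recs, query, template, min_aligned_fraction=0.5)
        assert ann.shuffled


class TestRepeatSimilarity:
    def test_minimum_rule(self):
        hits = [RepeatHit("N", "C", 1e-3), RepeatHit("N", "C", 1e-8)]
        assert repeat_similarity(hits) == 1e-8

    def test_absent_when_no_cross_hits(self):
        assert repeat_similarity([]) is None
        assert repeat_similarity([RepeatHit("N", "N", 1e-20)]) is None

    def test_recent_duplication_scores_lower(self):
        # proxy: identity between N and C repeat units decays with duplication age
        from topoclan.seqprep import pairwise_identity
        from topoclan.topology import split_repeats

        bp, ann = synth.make_blueprint(10, "RH", "Nout")
        idents = []
        for extra_rounds in (0, 12):
            spec = synth.FamilySpec(
                blueprint=bp, annotation=ann, n_sequences=1,
                substitution_rate=0.08, seed=42,
            )
            fam = synth.generate_family(spec)
            seq = fam.msa["seq000"].replace("-", "")
            rng = np.random.default_rng(extra_rounds)
            n_unit, c_unit = split_repeats(fam.true_topology("seq000"), ann)
            n_seq = seq[n_unit.first_residue - 1 : n_unit.last_residue]
            c_seq = list(seq[c_unit.first_residue - 1 : c_unit.last_residue])
            # age the C repeat: extra substitution rounds decay its similarity
            for _ in range(extra_rounds):
                for k in range(len(c_seq)):
                    if rng.random() < 0.08:
                        c_seq[k] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            idents.append(pairwise_identity(n_seq, "".join(c_seq)))
        assert idents[0] > idents[1]
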