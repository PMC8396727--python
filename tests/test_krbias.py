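"""KR-window arithmetic, bias counting and topology-model selection."""

import numpy as np
import pytest

from topoclan import pipeline, synth
from topoclan.krbias import (
    KRWindowParams,
    core_helix_krbias,
    kr_bias,
    loop_windows,
    select_topology_model,
)
from topoclan.topology import (
    CROSSING_KINDS,
    SegmentKind,
    parse_topology_string,
    propagate_sides,
)


def oracle_window_positions(t, params=KRWindowParams()):
    """Brute-force per-position window membership, independent of the
    segment-walking implementation."""
    inside, outside = set(), set()
    string = t.to_string()
    helices = t.helices()
    for seg in helices:
        depth = min(params.inside_helix_depth, seg.length)
        for before in (True, False):
            positions = []
            if before:
                p = seg.start - 1
                taken = 0
                while p >= 1 and string[p - 1] in "io" and taken < params.after_helix_extent:
                    positions.append(p)
                    p -= 1
                    taken += 1
                positions += list(range(seg.start, seg.start + depth))
                flank = seg.start - 1
            else:
                positions = list(range(seg.end - depth + 1, seg.end + 1))
                p = seg.end + 1
                taken = 0
                while p <= t.chain_length and string[p - 1] in "io" and taken < params.after_helix_extent:
                    positions.append(p)
                    p += 1
                    taken += 1
                flank = seg.end + 1
            if seg.kind in CROSSING_KINDS:
                if 1 <= flank <= t.chain_length and string[flank - 1] in "io":
                    side = string[flank - 1]
                elif seg.kind is not SegmentKind.REENTRANT_HELIX:
                    side = {"in_to_out": "io", "out_to_in": "oi"}[seg.orientation][
                        0 if before else 1
                    ]
                (inside if side == "i" else outside).update(positions)
            else:  # reentrant: single side
                side = "i" if seg.reentrant_side == "in_in" else "o"
                (inside if side == "i" else outside).update(positions)
    return inside, outside


class TestWindows:
    def test_window_after_first_helix(self):
        # helix 1..21, loop 22..60, helix 61..81 (chain may start in a helix)
        from topoclan.topology import Segment, Topology

        t = Topology(
            chain_length=81,
            segments=[
                Segment(SegmentKind.TM_HELIX, 1, 21, orientation="in_to_out"),
                Segment(SegmentKind.OUTSIDE_LOOP, 22, 60),
                Segment(SegmentKind.TM_HELIX, 61, 81, orientation="out_to_in"),
            ],
        )
        wins = loop_windows(t)
        exit_win = wins[1]  # exit side of helix 1
        assert exit_win[1] == tuple(range(12, 47))  # 12..21 in-helix + 22..46 loop

    def test_short_loop_truncated(self):
        t = parse_topology_string(propagate_sides("L" * 10 + "M" * 21 + "L" * 8 + "M" * 21 + "L" * 10, "Nin"))
        wins = loop_windows(t)
        h1_exit = wins[1][1]
        # last 10 helix residues + the whole 8-residue loop, stopping at helix 2
        assert h1_exit == tuple(range(22, 40))

    def test_n_terminal_tail_window(self):
        t = parse_topology_string(propagate_sides("L" * 20 + "M" * 21 + "L" * 30, "Nin"))
        entry_side, entry_pos = loop_windows(t)[0]
        assert entry_side == "i"
        assert entry_pos == tuple(range(1, 31))  # all 20 tail + first 10 helix

    def test_reentrant_single_window(self):
        t = parse_topology_string("o" * 30 + "R" * 12 + "o" * 30)
        wins = loop_windows(t)
        assert len(wins) == 1
        side, pos = wins[0]
        assert side == "o"
        # 25 before + whole 12-helix (head+tail overlap) + 25 after
        assert pos == tuple(range(6, 68))


class TestBias:
    def test_no_kr_means_zero(self):
        t = parse_topology_string("ii" + "M" * 17 + "oo")
        assert kr_bias("A" * 21, t) == (0, 0, 0)

    def test_direct_count_in_inside_window(self):
        t = parse_topology_string("iiiii" + "M" * 17 + "ooooo")
        seq = "AKRKA" + "L" * 17 + "AAAAA"
        i_kr, o_kr, bias = kr_bias(seq, t)
        assert (i_kr, o_kr, bias) == (3, 0, 3)

    def test_length_mismatch(self):
        t = parse_topology_string("ii" + "M" * 17 + "oo")
        with pytest.raises(ValueError):
            kr_bias("AAA", t)

    def test_counts_match_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 200:
            skeleton = "L" * rng.integers(5, 40)
            for _ in range(rng.integers(1, 5)):
                kind = "MRB"[rng.integers(3)]
                skeleton += kind * rng.integers(5, 30) + "L" * rng.integers(5, 40)
            t = parse_topology_string(
                propagate_sides(skeleton, ["Nin", "Nout"][rng.integers(2)])
            )
            seq = "".join(rng.choice(list("AKRLGS"), size=t.chain_length))
            inside, outside = oracle_window_positions(t)
            want_i = sum(1 for p in inside if seq[p - 1] in "KR")
            want_o = sum(1 for p in outside if seq[p - 1] in "KR")
            assert kr_bias(seq, t) == (want_i, want_o, want_i - want_o)
            checked += 1

    def test_flipping_sides_swaps_counts(self):
        rng = np.random.default_rng(3)
        t = parse_topology_string(
            propagate_sides("L" * 20 + "M" * 21 + "L" * 15 + "R" * 12 + "L" * 15 + "M" * 21 + "L" * 20, "Nin")
        )
        flipped = parse_topology_string(
            propagate_sides("L" * 20 + "M" * 21 + "L" * 15 + "R" * 12 + "L" * 15 + "M" * 21 + "L" * 20, "Nout")
        )
        seq = "".join(rng.choice(list("AKRLGS"), size=t.chain_length))
        i1, o1, b1 = kr_bias(seq, t)
        i2, o2, b2 = kr_bias(seq, flipped)
        assert (i1, o1) == (o2, i2) and b1 == -b2


class TestModelSelection:
    def test_forced_by_mean(self):
        t = parse_topology_string(propagate_sides("L" * 10 + "M" * 17 + "L" * 10, "Nin"))
        alt = parse_topology_string(propagate_sides("L" * 10 + "M" * 17 + "L" * 10, "Nout"))
        msa = {"rep": "KKKKKKKKKK" + "L" * 17 + "AAAAAAAAAA"}
        prof = select_topology_model(msa, "rep", t, alt)
        # under the 'broken' slot (Nin) the Ks are inside; under Nout outside
        assert prof.selected_model == "broken"

    def test_equal_means_is_ambiguous(self):
        t = parse_topology_string(propagate_sides("L" * 10 + "M" * 17 + "L" * 10, "Nin"))
        msa = {"rep": "A" * 37}
        prof = select_topology_model(msa, "rep", t, t)
        assert prof.selected_model == "ambiguous"

    def test_empty_family_is_error(self):
        t = parse_topology_string("ii" + "M" * 17 + "oo")
        with pytest.raises(ValueError):
            select_topology_model({}, "rep", t, t)

    def test_recovers_generating_model(self):
        bp, ann = synth.make_blueprint(10, "RH", "Nout")
        hits = 0
        for seed in range(40):
            spec = synth.FamilySpec(
                blueprint=bp, annotation=ann, n_sequences=15, seed=seed,
                positive_inside_strength=2.0,
            )
            fam = synth.generate_family(spec)
            rep = min(fam.msa, key=lambda r: fam.msa[r].count("-"))
            truth = fam.true_topology(rep)
            alt = pipeline.alternative_model(truth)
            prof = select_topology_model(fam.msa, rep, alt, truth)
            hits += prof.selected_model == "reentrant"
        assert hits >= 36  # >= 90%

    def test_accuracy_monotone_in_strength(self):
        bp, ann = synth.make_blueprint(10, "RH", "Nout")
        rates = []
        for strength in (0.0, 1.0, 3.0):
            hits = 0
            for seed in range(25):
                spec = synth.FamilySpec(
                    blueprint=bp, annotation=ann, n_sequences=12, seed=seed,
                    positive_inside_strength=strength,
                )
                fam = synth.generate_family(spec)
                rep = min(fam.msa, key=lambda r: fam.msa[r].count("-"))
                truth = fam.true_topology(rep)
                prof = select_topology_model(
                    fam.msa, rep, pipeline.alternative_model(truth), truth
                )
                hits += prof.selected_model == "reentrant"
            rates.append(hits / 25)
        assert rates[0] <= rates[1] <= rates[2]

    def test_zero_strength_mean_bias_near_zero(self):
        bp, ann = synth.make_blueprint(10, "RH", "Nout")
        spec = synth.FamilySpec(
            blueprint=bp, annotation=ann, n_sequences=200, seed=0,
            positive_inside_strength=0.0, substitution_rate=0.15,
        )
        fam = synth.generate_family(spec)
        biases = [
            kr_bias(fam.msa[rid].replace("-", ""), fam.true_topology(rid))[2]
            for rid in fam.msa
        ]
        mean = np.mean(biases)
        se = np.std(biases, ddof=1) / np.sqrt(len(biases))
        assert abs(mean) <= 2 * max(se, 0.25)


class TestCoreHelixBias:
    def test_equals_restricted_full_bias(self, reentrant_family):
        fam = reentrant_family
        rid = "seq000"
        seq = fam.msa[rid].replace("-", "")
        t = fam.true_topology(rid)
        result = core_helix_krbias(seq, t, fam.annotation)
        assert set(result) == {"N", "C"}
        from topoclan.krbias import _helix_windows

        helices = t.helices()
        roles = fam.annotation.helix_repeat_roles(t)
        for repeat in ("N", "C"):
            core = [
                h
                for h, tag, role in zip(helices, fam.annotation.helix_tags, roles)
                if tag == "core" and role == repeat
            ]
            wins = _helix_windows(t, core[-1], KRWindowParams())
            assert result[repeat] == kr_bias(seq, t, windows=wins)[2]

    def test_no_kr_gives_zero(self):
        t = parse_topology_string(propagate_sides("L" * 10 + ("M" * 17 + "L" * 10) * 6, "Nin"))
        from topoclan.topology import RepeatAnnotation

        cut = (t.helices()[2].end + t.helices()[3].start) // 2
        ann = RepeatAnnotation(
            (1, cut), (cut + 1, t.chain_length),
            helix_tags=["scaffold", "core", "core"] * 2,
        )
        result = core_helix_krbias("A" * t.chain_length, t, ann)
        assert result == {"N": 0, "C": 0}

    def test_missing_annotation_is_error(self, reentrant_family):
        t = reentrant_family.true_topology("seq000")
        from topoclan.topology import RepeatAnnotation

        bare = RepeatAnnotation((1, 200), (201, t.chain_length))
        with pytest.raises(ValueError):
            core_helix_krbias("A" * t.chain_length, t, bare)

    def test_orientation_changes_last_core_helix_bias_sign(self):
        # same chain, opposite orientations: biases swap sign
        skeleton = "L" * 20 + ("M" * 17 + "L" * 15) * 5 + "M" * 17 + "L" * 20
        t_in = parse_topology_string(propagate_sides(skeleton, "Nin"))
        t_out = parse_topology_string(propagate_sides(skeleton, "Nout"))
        from topoclan.topology import RepeatAnnotation

        cut = (t_in.helices()[2].end + t_in.helices()[3].start) // 2
        ann = RepeatAnnotation(
            (1, cut), (cut + 1, t_in.chain_length),
            helix_tags=["scaffold", "core", "core"] * 2,
        )
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("AKRLGS"), size=t_in.chain_length))
        b_in = core_helix_krbias(seq, t_in, ann)
        b_out = core_helix_krbias(seq, t_out, ann)
        assert b_in["N"] == -b_out["N"] and b_in["C"] == -b_out["C"]
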