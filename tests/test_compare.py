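"""Superposition, domain alignment, insertions, subdomain calls, stitching."""

import numpy as np
import pytest

from c2map import compare, synth
from c2map.cartography import annotate_structure
from c2map.compare import (align_structures, call_subdomains, detect_insertions,
                           overlay_rmsd, stitch_fragments, superpose_kabsch)
from c2map.errors import AlignmentError, DegeneracyError, StitchError
from c2map.synth import SandwichSpec, build_sandwich

from conftest import quaternion_superpose_rmsd


def _annotated(seed, noise=0.1, **kw):
    s, truth = build_sandwich(SandwichSpec(seed=seed, noise_sigma=noise, **kw))
    result = annotate_structure(s)
    assert len(result.annotations) == 1
    return (result.annotations[0], result.structure), result, truth


class TestKabsch:
    def test_identical_sets_have_zero_rmsd(self):
        pts = np.random.default_rng(0).normal(size=(12, 3))
        _, _, rmsd = superpose_kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(15, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        b = a @ rot.T + np.array([3.0, -2.0, 9.0])
        r, t, rmsd = superpose_kabsch(a, b)
        assert rmsd < 1e-6
        assert np.linalg.det(r) == pytest.approx(1.0)
        assert np.allclose(a @ r.T + t, b, atol=1e-6)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            _, _, rmsd = superpose_kabsch(a, b)
            assert rmsd == pytest.approx(quaternion_superpose_rmsd(a, b),
                                         abs=1e-9)

    def test_reflection_never_chosen(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        b = a.copy()
        b[:, 0] *= -1.0  # mirrored cloud
        r, _, _ = superpose_kabsch(a, b)
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_degenerate_inputs_refused(self):
        with pytest.raises(DegeneracyError):
            superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(6.0), np.array([1.0, 0, 0]))
        with pytest.raises(DegeneracyError):
            superpose_kabsch(line, line)


class TestAlignment:
    def test_domain_vs_itself_identity(self):
        dom, _, _ = _annotated(21)
        corr = align_structures(dom, dom)
        assert corr.rmsd == pytest.approx(0.0, abs=1e-9)
        assert all(a[1] == b[1] for a, b in corr.pairs)

    def test_insertion_unpaired_strands_paired(self):
        ref, _, _ = _annotated(22)
        ins, _, truth = _annotated(23, insertions={"b6-7": (30, "coil")})
        corr = align_structures(ins, ref)
        paired_cand = {a[1] for a, _ in corr.pairs}
        (loop_name, length, interval, _), = truth.insertions
        inserted = set(range(interval[0], interval[1] + 1))
        assert length == 30
        # strand residues all paired; insertion residues unpaired (up to the
        # one-residue shift of H-bond-detected loop ends vs construction)
        for st in ins[0].strands:
            for k in range(st.first, st.last + 1):
                assert k in paired_cand
        assert len(inserted - paired_cand) >= length - 1

    def test_noise_level_sets_rmsd(self):
        a, _, _ = _annotated(24, noise=0.0)
        b, _, _ = _annotated(24, noise=0.3)
        rmsd = align_structures(a, b).rmsd
        # one clean + one noisy replica: expected CA deviation ~ sigma*sqrt(3)
        assert 0.2 < rmsd < 0.9

    def test_topology_mismatch_refused(self):
        a, _, _ = _annotated(25, connectivity=0)
        b, _, _ = _annotated(25, connectivity=1)
        with pytest.raises(AlignmentError):
            align_structures(a, b)


class TestInsertions:
    def test_reference_vs_itself_empty(self):
        dom, _, _ = _annotated(26)
        assert detect_insertions(dom, dom) == []

    @pytest.mark.parametrize("loop,length,ss", [("b6-7", 30, "coil"),
                                                ("b6-7", 60, "helix"),
                                                ("b1-2", 25, "coil")])
    def test_exact_length_recovery(self, loop, length, ss):
        ref, _, _ = _annotated(27)
        cand, _, _ = _annotated(28, insertions={loop: (length, ss)})
        records = detect_insertions(cand, ref)
        assert [(name, ln) for name, ln, _ in records] == [(loop, length)]

    def test_antisymmetry(self):
        ref, _, _ = _annotated(29)
        cand, _, _ = _annotated(30, insertions={"b6-7": (30, "coil")})
        forward = {name for name, _, _ in detect_insertions(cand, ref)}
        backward = {name for name, _, _ in detect_insertions(ref, cand)}
        assert "b6-7" in forward
        assert "b6-7" not in backward


class TestSubdomainRule:
    @staticmethod
    def _sets(lengths, ss_class="coil"):
        """Fabricate insertion sets + ss maps for rule-level tests."""
        insertion_sets, ss = {}, {}
        for k, ln in enumerate(lengths):
            name = f"paralog{k}"
            if ln > 0:
                insertion_sets[name] = [("b6-7", ln, (100, 100 + ln - 1))]
            else:
                insertion_sets[name] = []
            state = "H" if ss_class == "helix-rich" else "-"
            ss[name] = {pos: state for pos in range(100, 100 + max(ln, 1))}
        return insertion_sets, ss

    def test_length_20_never_called(self):
        calls = call_subdomains(*self._sets([20, 20, 20, 20, 20, 20]))
        assert calls == []

    def test_length_21_called(self):
        calls = call_subdomains(*self._sets([21, 21, 0, 0, 0, 0]))
        assert {c.paralog for c in calls} == {"paralog0", "paralog1"}

    def test_five_of_six_conserved(self):
        calls = call_subdomains(*self._sets([30, 30, 30, 0, 30, 30],
                                            ss_class="helix-rich"))
        assert len(calls) == 5
        assert all(len(c.conserved_in) == 5 for c in calls)
        assert all(c.ss_class == "helix-rich" for c in calls)

    def test_single_carrier_not_called(self):
        calls = call_subdomains(*self._sets([40, 0, 0, 0, 0, 0]))
        assert calls == []

    def test_single_paralog_input_unconfirmed(self):
        ins, ss = self._sets([40])
        calls = call_subdomains(ins, ss)
        assert len(calls) == 1
        assert not calls[0].confirmed

    def test_order_invariance(self):
        ins, ss = self._sets([30, 0, 30, 25, 0, 30])
        forward = call_subdomains(ins, ss)
        rev_ins = dict(reversed(list(ins.items())))
        rev_ss = dict(reversed(list(ss.items())))
        backward = call_subdomains(rev_ins, rev_ss)
        key = lambda c: (c.paralog, c.host_loop, c.length)
        assert sorted(map(key, forward)) == sorted(map(key, backward))

    def test_mixed_ss_classes_do_not_conserve(self):
        ins, ss = self._sets([30, 30])
        ss["paralog1"] = {pos: "H" for pos in ss["paralog1"]}
        assert call_subdomains(ins, ss) == []


class TestStitching:
    def test_consistent_fragments_reassemble_exactly(self, default_sandwich):
        s, _ = default_sandwich
        frags = synth.split_with_overlap(s, [60], 30)
        asm, rmsds = stitch_fragments(frags)
        assert max(rmsds) < 1e-9
        for r1, r2 in zip(s.chains["A"], asm.chains["A"]):
            for name, atom in r1.atoms.items():
                assert np.linalg.norm(atom.position -
                                      r2.atoms[name].position) < 1e-6

    def test_reposed_fragments_reassemble(self, default_sandwich):
        s, _ = default_sandwich
        frags = synth.split_with_overlap(s, [45, 85], 15, reposed=True, seed=8)
        asm, rmsds = stitch_fragments(frags)
        assert max(rmsds) < 1e-9
        for r1, r2 in zip(s.chains["A"], asm.chains["A"]):
            assert np.linalg.norm(r1.ca - r2.ca) < 1e-6

    def test_disjoint_fragments_refused(self, default_sandwich):
        s, _ = default_sandwich
        a = s.extract_region("A", 1, 50)
        b = s.extract_region("A", 70, 120)
        with pytest.raises(StitchError):
            stitch_fragments([a, b])

    def test_thin_overlap_refused(self, default_sandwich):
        s, _ = default_sandwich
        frags = synth.split_with_overlap(s, [60], 5)
        with pytest.raises(StitchError):
            stitch_fragments(frags)


class TestOverlay:
    def test_identical_domains_all_zero(self):
        dom, _, _ = _annotated(31)
        matrix, mean = overlay_rmsd([dom, dom, dom])
        assert np.allclose(matrix, 0.0, atol=1e-9)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_two_domains_equals_pairwise(self):
        a, _, _ = _annotated(32, noise=0.0)
        b, _, _ = _annotated(32, noise=0.2)
        matrix, mean = overlay_rmsd([a, b])
        assert mean == pytest.approx(align_structures(a, b).rmsd)
        assert matrix[0, 1] == matrix[1, 0] == pytest.approx(mean)

    def test_noise_replicas_match_closed_form(self):
        """Six replicas at sigma = 0.5: E[RMSD] for two structures with
        independent isotropic Gaussian displacement is sigma * sqrt(6)."""
        doms, seed = [], 100
        while len(doms) < 6:
            s, _ = build_sandwich(SandwichSpec(seed=seed, noise_sigma=0.5))
            seed += 1
            # 0.5 A is beyond the generator's guaranteed-detection envelope;
            # the statistic under test needs annotatable replicas
            result = annotate_structure(s)
            if len(result.annotations) == 1:
                doms.append((result.annotations[0], result.structure))
        _, mean = overlay_rmsd(doms)
        expected = 0.5 * np.sqrt(6.0)
        assert abs(mean - expected) < 0.35 * expected
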