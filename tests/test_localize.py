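"""De novo C=C assignment rules and isomer relative quantitation."""

import numpy as np
import pytest

from lipidcc import localize, pb, profiling
from lipidcc.chem import AcylChain, parse_species
from lipidcc.localize import CCAssignment, LocalizationConfig
from lipidcc.profiling import ChainAssignment, Composition, SubclassHit
from lipidcc.spectra import PeakMatch, Spectrum


def pb_spectrum(species, ion_intensities, extra=(), drop=()):
    """Spectrum from theoretical diagnostic ions of {positions: intensity}."""
    mzs, intens = [], []
    for (chain_idx, pos_set), intensity in ion_intensities.items():
        chain = species.chains[chain_idx]
        for pair in pb.diagnostic_pairs_for_set(species, chain, pos_set):
            for ion in (pair.fa_mz, pair.fo_mz):
                if any(abs(ion - d) < 1e-6 for d in drop):
                    continue
                mzs.append(ion)
                intens.append(intensity)
    for mz, inten in extra:
        mzs.append(mz)
        intens.append(inten)
    prec = pb.pb_precursor_mz(species)
    mzs.append(prec)
    intens.append(max(intens) if intens else 1.0)
    return Spectrum(
        np.array(mzs), np.array(intens), scan_id="pb_test", scan_type="EPI-PB",
        polarity="+" if species.subclass in ("PE", "PC") else "-",
        precursor_mz=prec, rt_min=5.7,
    )


def chain_assignment(species, ranked=None):
    hit = SubclassHit(
        700.0, 5.7, species.subclass,
        species.total_carbons, species.total_double_bonds, 1.0e5,
    )
    ranked = ranked or [(species.chains, 100.0)]
    comps = [
        Composition(chains, score, i + 1, (None, None))
        for i, (chains, score) in enumerate(ranked)
    ]
    return ChainAssignment(hit, comps)


class TestAssignCC:
    def test_coexisting_delta9_delta11_isomers(self, pe341):
        sp = pb_spectrum(pe341, {(1, (9,)): 300.0, (1, (11,)): 100.0})
        calls = localize.assign_cc(sp, chain_assignment(pe341))
        assigned = {c.positions for c in calls if c.assigned}
        assert assigned == {(9,), (11,)}
        labels = {c.label() for c in calls if c.assigned}
        assert labels == {"PE 16:0_18:1(Δ9)", "PE 16:0_18:1(Δ11)"}

    def test_pufa_single_set(self, pe394):
        truth = parse_species("PE 17:0_22:4")
        sp = pb_spectrum(pe394, {(1, (7, 10, 13, 16)): 200.0})
        calls = localize.assign_cc(sp, chain_assignment(truth))
        assigned = [c for c in calls if c.assigned]
        assert [c.positions for c in assigned] == [(7, 10, 13, 16)]

    def test_pair_completeness_rule(self, pe341):
        # F_A present but F_O missing removes the Δ9 call, keeps Δ11
        d9 = pb.diagnostic_pair(pe341, pe341.chains[1], 9)
        sp = pb_spectrum(
            pe341, {(1, (9,)): 300.0, (1, (11,)): 100.0}, drop=(d9.fo_mz,)
        )
        calls = localize.assign_cc(sp, chain_assignment(pe341))
        assert {c.positions for c in calls if c.assigned} == {(11,)}

    def test_intensity_ratio_window(self, pe341):
        # wildly dissimilar F_A/F_O intensities are not a credible pair
        d9 = pb.diagnostic_pair(pe341, pe341.chains[1], 9)
        sp = pb_spectrum(
            pe341,
            {(1, (11,)): 100.0},
            extra=[(d9.fa_mz, 1000.0), (d9.fo_mz, 10.0)],
        )
        calls = localize.assign_cc(sp, chain_assignment(pe341))
        assert {c.positions for c in calls if c.assigned} == {(11,)}

    def test_no_candidate_marks_chain_unassigned(self, pe341):
        sp = Spectrum(
            np.array([776.5799]), np.array([100.0]), scan_type="EPI-PB",
            polarity="+", precursor_mz=pb.pb_precursor_mz(pe341), rt_min=5.7,
        )
        calls = localize.assign_cc(sp, chain_assignment(pe341))
        assert len(calls) == 1 and not calls[0].assigned

    def test_low_confidence_flag_on_weak_extra_isomer(self, pe341):
        config = LocalizationConfig(low_confidence_fraction=0.05)
        sp = pb_spectrum(pe341, {(1, (9,)): 1000.0, (1, (10,)): 10.0})
        calls = localize.assign_cc(sp, chain_assignment(pe341), config)
        flags = {c.positions: c.flags for c in calls if c.assigned}
        assert "low-confidence" in flags[(10,)]
        assert "low-confidence" not in flags[(9,)]

    def test_minor_composition_collision_suppressed(self, pe341):
        # minor 16:1_18:0 shares the 18-carbon backbone: craft a minor chain
        # whose candidate ions collide with the dominant ones
        minor_chains = (AcylChain(16, 1), AcylChain(18, 0))
        assignment = chain_assignment(
            pe341, ranked=[(pe341.chains, 1000.0), (minor_chains, 10.0)]
        )
        minor_species = parse_species("PE 16:1_18:0")
        # Δ11 on the 16:1 chain yields F_A at the same m/z as Δ13 on 18:1;
        # the dominant Δ9/Δ11 ions plus a colliding minor candidate pair
        m_pair = pb.diagnostic_pair(minor_species, minor_species.chains[0], 11)
        sp = pb_spectrum(
            pe341,
            {(1, (9,)): 300.0, (1, (11,)): 100.0},
            extra=[(m_pair.fa_mz, 50.0), (m_pair.fo_mz, 50.0)],
        )
        calls = localize.assign_cc(sp, assignment)
        minor_calls = [c for c in calls if c.chain == minor_species.chains[0]]
        if minor_calls:  # either suppressed entirely or flagged not-reported
            assert all(
                {"minor-collision", "not-reported"} & c.flags or not c.assigned
                for c in minor_calls
            )
        # the true Δ9/Δ11 calls on the dominant chain survive (the colliding
        # peaks also satisfy the dominant chain's own Δ13 candidate, which is
        # precisely why the minor composition must not be reported)
        dominant = {c.positions for c in calls if c.chain == pe341.chains[1] and c.assigned}
        assert {(9,), (11,)} <= dominant

    def test_ether_chain_flag_gated(self):
        ether = parse_species("PC O-16:1_16:0")
        assignment = chain_assignment(ether)
        sp = Spectrum(
            np.array([pb.pb_precursor_mz(ether)]), np.array([10.0]),
            scan_type="EPI-PB", polarity="+",
            precursor_mz=pb.pb_precursor_mz(ether), rt_min=14.0,
        )
        calls = localize.assign_cc(sp, assignment)
        assert calls and all("ether-not-localized" in c.flags for c in calls)

    def test_precursor_mismatch_raises(self, pe341):
        sp = Spectrum(
            np.array([500.0]), np.array([1.0]), scan_type="EPI-PB", polarity="+",
            precursor_mz=700.0, rt_min=5.7,
        )
        with pytest.raises(ValueError):
            localize.assign_cc(sp, chain_assignment(pe341))


def _call(species, chain, positions, intensity, flags=frozenset()):
    fa = PeakMatch(0.0, 0.0, intensity / 2, 0.0, 0.0, 10.0)
    fo = PeakMatch(0.0, 0.0, intensity / 2, 0.0, 0.0, 10.0)
    pair = pb.diagnostic_pair(species, chain, positions[0], positions=positions)
    ev = (localize.PairEvidence(positions[0], pair, fa, fo),)
    return CCAssignment(species, chain, positions, ev, flags)


class TestIsomerRatio:
    def test_printed_formula_verbatim(self, pe341):
        # R = (I_467 + I_493) / (I_495 + I_521)
        chain = pe341.chains[1]
        a = _call(pe341, chain, (9,), 300.0 + 290.0)
        b = _call(pe341, chain, (11,), 100.0 + 95.0)
        r = localize.isomer_ratio([a, b])
        assert r.ratio == pytest.approx(590.0 / 195.0, rel=1e-9)
        assert r.positions_a == (9,) and r.positions_b == (11,)

    def test_single_isomer_yields_no_ratio(self, pe341):
        a = _call(pe341, pe341.chains[1], (9,), 500.0)
        assert localize.isomer_ratio([a]) is None

    def test_replicate_aggregation(self, pe341):
        chain = pe341.chains[1]
        reps = []
        for r in (3.0, 3.1, 2.9):
            reps.append(
                [_call(pe341, chain, (9,), r * 100.0), _call(pe341, chain, (11,), 100.0)]
            )
        out = localize.isomer_ratio(reps)
        assert out.ratio == pytest.approx(3.0, abs=1e-9)
        assert out.rsd_pct == pytest.approx(100.0 * np.std([3.0, 3.1, 2.9], ddof=1) / 3.0)

    def test_label_swap_inverts_ratio_exactly(self, pe341):
        chain = pe341.chains[1]
        a = _call(pe341, chain, (9,), 590.0)
        b = _call(pe341, chain, (11,), 195.0)
        r = localize.isomer_ratio([a, b])
        assert r.inverted().ratio == pytest.approx(1.0 / r.ratio, rel=1e-12)

    def test_collision_flagged_evidence_excluded(self, pe341):
        chain = pe341.chains[1]
        a = _call(pe341, chain, (9,), 590.0)
        b = _call(pe341, chain, (11,), 195.0, flags=frozenset({"minor-collision"}))
        assert localize.isomer_ratio([a, b]) is None

    def test_zero_denominator_flagged_not_infinite(self, pe341):
        chain = pe341.chains[1]
        a = _call(pe341, chain, (9,), 590.0)
        b = CCAssignment(pe341, chain, (11,), (), frozenset())  # no evidence
        r = localize.isomer_ratio([a, b], positions_a=(9,), positions_b=(11,))
        assert r.undefined and r.ratio is None


class TestOmegaAnnotation:
    @pytest.mark.parametrize(
        "species,positions,label",
        [
            ("PE 16:0_18:3", (9, 12, 15), "18:3 ω-3"),
            ("PE 16:0_20:2", (11, 14), "20:2 ω-6"),
            ("PE 16:0_18:1", (9,), "18:1 ω-9"),
        ],
    )
    def test_omega_labels(self, species, positions, label):
        sp = parse_species(species)
        call = _call(sp, sp.chains[1], positions, 100.0)
        assert localize.annotate_omega(call) == label

    def test_unassigned_chain_cannot_be_annotated(self, pe341):
        call = CCAssignment(pe341, pe341.chains[1], None)
        with pytest.raises(ValueError):
            localize.annotate_omega(call)
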