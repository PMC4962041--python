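"""Synthetic-data generators: digestion, planted PICS experiment, titrations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddikit.csp import fraction_bound
from ddikit.io import SequenceRecord
from ddikit.simulate import (
    GLUC,
    TRYPSIN,
    DigestionRule,
    PicsSimulationParams,
    PlantedProtease,
    TitrationSimulationParams,
    digest,
    dilution_schedule,
    make_proteome,
    perturb_ensemble,
    simulate_pics_experiment,
    simulate_titration,
)
from ddikit.structure import ensemble_precision, kabsch_superpose
from ddikit.io import AtomSelection

from conftest import make_chain

protein_strategy = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=200)


class TestMakeProteome:
    def test_seed_determinism_and_exact_length(self):
        a = make_proteome(1, mean_length=50, seed=11)
        b = make_proteome(1, mean_length=50, seed=11)
        assert a == b
        assert len(a[0].residues) == 50

    def test_degenerate_composition_all_same_letter(self):
        (rec,) = make_proteome(1, mean_length=40, composition={"A": 1.0}, seed=0)
        assert rec.residues == "A" * 40

    def test_all_zero_composition_rejected(self):
        with pytest.raises(ValueError):
            make_proteome(1, composition={aa: 0.0 for aa in "ACDEFG"}, seed=0)

    def test_frequencies_track_requested_composition(self):
        # 100 proteins x 300 residues; each observed count should sit
        # within 3 sd of the multinomial expectation
        comp = {aa: w for aa, w in zip("ACDEFGHIKLMNPQRSTVWY", range(1, 21))}
        total_w = sum(comp.values())
        records = make_proteome(100, mean_length=300, composition=comp, seed=5)
        joined = "".join(r.residues for r in records)
        n = len(joined)
        for aa, w in comp.items():
            p = w / total_w
            sd = np.sqrt(n * p * (1 - p))
            assert abs(joined.count(aa) - n * p) < 3 * sd, aa


class TestDigest:
    def test_trypsin_cuts_after_k(self):
        out = digest([SequenceRecord("p", "AAKAA")], [TRYPSIN])
        assert [p.sequence for p in out] == ["AAK", "AA"]

    def test_proline_blocks_tryptic_cut(self):
        out = digest([SequenceRecord("p", "AAKPAA")], [TRYPSIN])
        assert [p.sequence for p in out] == ["AAKPAA"]

    def test_gluc_cuts_after_e_only(self):
        out = digest([SequenceRecord("p", "AEADAA")], [GLUC])
        assert [p.sequence for p in out] == ["AE", "ADAA"]

    def test_origins_are_exact(self):
        (a, b) = digest([SequenceRecord("p", "AAKAA")], [TRYPSIN])
        assert (a.start, a.end) == (1, 3)
        assert (b.start, b.end) == (4, 5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(protein_strategy)
    def test_fragments_tile_the_protein(self, seq):
        out = digest([SequenceRecord("p", seq)], [TRYPSIN, GLUC])
        assert "".join(p.sequence for p in out) == seq

    def test_missed_cleavages_add_spanning_fragments(self):
        out = digest([SequenceRecord("p", "AAKAAKAA")], [TRYPSIN], missed_cleavages=1)
        seqs = [p.sequence for p in out]
        assert "AAKAAK" in seqs and "AAKAA" in seqs and "AAK" in seqs

    def test_empty_rule_set_rejected(self):
        with pytest.raises(ValueError):
            digest([SequenceRecord("p", "AAKAA")], [])
        with pytest.raises(ValueError):
            DigestionRule("x", frozenset())


def point_mass_protease(p1: str, p1p: str, efficiency: float = 1.0) -> PlantedProtease:
    return PlantedProtease.from_preferences(
        {"P1": {p1: 1.0}, "P1'": {p1p: 1.0}}, efficiency=efficiency
    )


class TestPicsSimulation:
    def test_point_mass_site_recovered_on_toy_proteome(self):
        # one F|E site inside a trypsin-retained peptide; digest with
        # trypsin only so the internal E survives as a P1' residue
        proteome = [
            SequenceRecord("target", "MAAAAKGGGGFEHHHHKAAAA"),
            SequenceRecord("decoy", "MLLLLKMMMMKWWWWK"),
        ]
        params = PicsSimulationParams(
            identification_probability=1.0, contaminant_rate=0.0,
            unlabeled_test_fraction=0.0, n_library_identifications=0, seed=3,
        )
        exp = simulate_pics_experiment(
            proteome, point_mass_protease("F", "E"), params, rules=[TRYPSIN]
        )
        assert len(exp.true_cuts) == 1
        cut = exp.true_cuts[0]
        assert (cut.protein_id, cut.window) == ("target", "GGGFEHHH")
        labeled = [p for p in exp.test if p.nterm_labeled]
        assert len(labeled) == 1 and labeled[0].sequence.startswith("E")

    def test_zero_efficiency_gives_background_only(self):
        proteome = make_proteome(20, mean_length=200, seed=1)
        params = PicsSimulationParams(seed=4)
        exp = simulate_pics_experiment(proteome, point_mass_protease("F", "A", 0.0), params)
        assert exp.true_cuts == []
        assert all(not p.nterm_labeled or p.confidence <= 1.0 for p in exp.test)

    def test_seed_determinism(self):
        proteome = make_proteome(10, mean_length=150, seed=2)
        planted = point_mass_protease("F", "A", 0.8)
        runs = [
            simulate_pics_experiment(proteome, planted, PicsSimulationParams(seed=9))
            for _ in range(2)
        ]
        assert runs[0].test == runs[1].test
        assert runs[0].true_cuts == runs[1].true_cuts

    def test_labeled_peptides_abut_ground_truth_cuts(self):
        proteome = make_proteome(30, mean_length=250, seed=6)
        planted = PlantedProtease.from_preferences(
            {"P1": {"F": 0.7, "L": 0.3}, "P1'": {"A": 0.7, "G": 0.3}}, efficiency=0.9
        )
        params = PicsSimulationParams(contaminant_rate=0.0, unlabeled_test_fraction=0.0, seed=7)
        exp = simulate_pics_experiment(proteome, planted, params)
        assert exp.true_cuts
        by_id = {p.identifier: p.residues for p in proteome}
        cut_starts = {(c.protein_id, c.p1_position + 1) for c in exp.true_cuts}
        for pep in exp.test:
            if not pep.nterm_labeled:
                continue
            hits = [
                (pid, i + 1)
                for pid, seq in by_id.items()
                for i in range(len(seq))
                if seq.startswith(pep.sequence, i)
            ]
            assert any(h in cut_starts for h in hits), pep.sequence

    def test_incompatible_length_window_warns_and_returns_empty(self, caplog):
        proteome = [SequenceRecord("p", "KKKKKKKK")]  # digest yields only 1-mers
        params = PicsSimulationParams(min_peptide_length=10, max_peptide_length=12, seed=0)
        exp = simulate_pics_experiment(proteome, point_mass_protease("F", "A"), params)
        assert exp.test == [] and exp.mock == []
        assert any("retained-length" in r.message for r in caplog.records)

    def test_invariant_params_validated(self):
        with pytest.raises(ValueError):
            PicsSimulationParams(min_peptide_length=3)
        with pytest.raises(ValueError):
            PlantedProtease.from_preferences({"P1": {"F": 0.0}})


class TestTitrationSimulation:
    def test_reference_point_at_free_positions_when_noiseless(self):
        params = TitrationSimulationParams(noise_h=0.0, noise_n=0.0, seed=1)
        series, truth = simulate_titration(params)
        ref = series.points[0]
        assert ref.ligand_mM == 0.0
        # spectators never move without noise
        last = series.points[-1]
        for r in series.residues:
            if r not in truth.epitope:
                assert last.peaks[r] == pytest.approx(ref.peaks[r], abs=1e-12)

    def test_stoichiometric_limit_reaches_ddmax(self):
        # K_d -> 0 with excess ligand: epitope shifts hit ddelta_max exactly
        params = TitrationSimulationParams(
            kd_mM=1e-12, noise_h=0.0, noise_n=0.0, max_excess=10.0, seed=2
        )
        series, truth = simulate_titration(params)
        ref, last = series.points[0], series.points[-1]
        r = truth.epitope[0]
        dh = last.peaks[r][0] - ref.peaks[r][0]
        assert dh == pytest.approx(truth.ddmax[r][0], rel=1e-6)

    def test_equilibrium_quadratic_worked_value(self):
        assert float(fraction_bound(0.1, 0.1, 0.1)) == pytest.approx(0.3820, abs=5e-5)

    def test_fraction_bound_monotonicity_and_bounds(self):
        P = 0.1
        kds = [0.1, 0.5, 2.0]
        ligands = np.linspace(0.01, 3.0, 40)
        for kd in kds:
            fb = fraction_bound(P, ligands, kd)
            assert np.all(np.diff(fb) > 0)  # increasing in L
            assert np.all((fb > 0) & (fb <= np.minimum(1.0, ligands / P)))
        # decreasing in K_d at fixed L
        fbs = [float(fraction_bound(P, 1.0, kd)) for kd in kds]
        assert fbs[0] > fbs[1] > fbs[2]

    def test_dilution_schedule_conserves_ratio(self):
        sched = dilution_schedule(0.1, 5.0, [0.0, 1.0, 10.0])
        assert sched[0] == (0.1, 0.0)
        for r, (P, L) in zip([0.0, 1.0, 10.0], sched):
            if r > 0:
                assert L / P == pytest.approx(r)
                assert P < 0.1  # dilution happened

    def test_seed_determinism(self):
        a, _ = simulate_titration(TitrationSimulationParams(seed=5))
        b, _ = simulate_titration(TitrationSimulationParams(seed=5))
        assert a.points[3].peaks == b.points[3].peaks


class TestPerturbEnsemble:
    def test_zero_sd_models_congruent_to_input(self):
        base = make_chain(20, seed=3)
        ens = perturb_ensemble(base, 0.0, 5, seed=4)
        for m in range(5):
            sup = kabsch_superpose(base.coords[0], ens.coords[m])
            assert sup.rmsd < 1e-9

    def test_rmsd_matches_displacement_statistics(self):
        # per-model RMSD to the mean ~ sd * sqrt(3(n-1)/n) for i.i.d.
        # Gaussian displacements
        base = make_chain(60, seed=5)
        sd, n = 0.5, 40
        ens = perturb_ensemble(base, sd, n, seed=6)
        prec = ensemble_precision(ens, AtomSelection.parse("A:1-60:backbone"))
        expected = sd * np.sqrt(3 * (n - 1) / n)
        assert prec.average_rmsd == pytest.approx(expected, rel=0.05)

    def test_seed_determinism(self):
        base = make_chain(10, seed=7)
        a = perturb_ensemble(base, 0.3, 4, seed=8)
        b = perturb_ensemble(base, 0.3, 4, seed=8)
        assert np.array_equal(a.coords, b.coords)

    def test_multi_model_input_rejected(self):
        base = make_chain(10, seed=9)
        ens = perturb_ensemble(base, 0.1, 2, seed=0)
        with pytest.raises(ValueError):
            perturb_ensemble(ens, 0.1, 2, seed=0)
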