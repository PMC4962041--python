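"""Synthetic-data generators for every pipeline input.

Nothing here requires a download: the module emulates

* a proteome (random sequences with a controllable composition),
* its digestion by working proteases (trypsin, GluC) into a blocked
  peptide library,
* cleavage of that library by a planted test protease whose P4..P4'
  specificity is known exactly, followed by labeling of the newly
  formed N-termini, noisy identification confidences and a shared
  contaminant background across runs (the ground truth every PICS
  recovery test checks against),
* NMR titrations following the 1:1 fast-exchange binding model with
  known K_d, per-residue ddelta_max, and Gaussian peak noise,
* perturbed multi-model coordinate ensembles with known displacement
  statistics.

Every generator takes an explicit integer seed; no global random state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ddikit.csp import TitrationPoint, TitrationSeries, fraction_bound
from ddikit.io import AMINO_ACIDS, SequenceRecord, StructureEnsemble
from ddikit.pics import POSITIONS, IdentifiedPeptide

logger = logging.getLogger("ddikit")


# ---------------------------------------------------------------------------
# digestion

@dataclass(frozen=True)
class DigestionRule:
    """C-terminal-side cleavage rule of a working protease."""

    enzyme: str
    cleave_after: frozenset[str]
    blocked_by_proline: bool = False

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleavage residue set must be non-empty")


TRYPSIN = DigestionRule("trypsin", frozenset({"K", "R"}), blocked_by_proline=True)
# E-only by default (ammonium-bicarbonate-style specificity); add D for
# phosphate-buffer behaviour via DigestionRule("gluc", frozenset({"E", "D"})).
GLUC = DigestionRule("gluc", frozenset({"E"}), blocked_by_proline=False)


@dataclass(frozen=True)
class DigestedPeptide:
    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    sequence: str


def _cut_sites(seq: str, rules: Sequence[DigestionRule]) -> list[int]:
    """0-based indices i such that a cut falls between seq[i] and seq[i+1]."""
    sites = []
    for i in range(len(seq) - 1):
        for rule in rules:
            if seq[i] in rule.cleave_after and not (
                rule.blocked_by_proline and seq[i + 1] == "P"
            ):
                sites.append(i)
                break
    return sites


def digest(
    proteome: Sequence[SequenceRecord],
    rules: Sequence[DigestionRule],
    missed_cleavages: int = 0,
) -> list[DigestedPeptide]:
    """Digest each protein, cutting after every P1 residue in any rule's set.

    With ``missed_cleavages=0`` the fragments tile each protein exactly;
    ``missed_cleavages`` up to 2 additionally emits fragments spanning
    that many internal sites.
    """
    if not rules:
        raise ValueError("at least one digestion rule is required")
    if not 0 <= missed_cleavages <= 2:
        raise ValueError("missed_cleavages must be 0-2")
    peptides: list[DigestedPeptide] = []
    for protein in proteome:
        seq = protein.residues
        sites = _cut_sites(seq, rules)
        bounds = [0] + [s + 1 for s in sites] + [len(seq)]
        for i in range(len(bounds) - 1):
            for span in range(1, missed_cleavages + 2):
                if i + span >= len(bounds):
                    break
                lo, hi = bounds[i], bounds[i + span]
                peptides.append(
                    DigestedPeptide(protein.identifier, lo + 1, hi, seq[lo:hi])
                )
    return peptides


# ---------------------------------------------------------------------------
# proteome

def make_proteome(
    n: int,
    mean_length: float = 300.0,
    length_sd: float = 0.0,
    composition: Mapping[str, float] | None = None,
    seed: int = 0,
    min_length: int = 20,
) -> list[SequenceRecord]:
    """Random protein sequences with i.i.d. residues.

    ``composition`` maps residue letters to weights (uniform over the 20
    canonical residues when omitted); residue frequencies converge to it
    as total length grows. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    letters = list(AMINO_ACIDS)
    if composition is None:
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        weights = np.array([float(composition.get(aa, 0.0)) for aa in letters])
        if weights.sum() <= 0 or (weights < 0).any():
            raise ValueError("composition must have non-negative weights with a positive sum")
        probs = weights / weights.sum()
    records = []
    for i in range(n):
        length = mean_length if length_sd == 0 else rng.normal(mean_length, length_sd)
        length = max(min_length, int(round(length)))
        residues = "".join(rng.choice(letters, size=length, p=probs))
        records.append(SequenceRecord(f"prot_{i + 1:04d}", residues))
    return records


# ---------------------------------------------------------------------------
# planted protease + PICS experiment

@dataclass
class PlantedProtease:
    """Ground-truth P4..P4' specificity of the simulated test protease.

    ``weights`` holds, for each of the 8 positions, a probability
    distribution over the 20 residues; the probability of cutting a
    candidate site scales with the window's likelihood relative to the
    best possible window, times ``efficiency``.
    """

    weights: dict[str, np.ndarray]  # position -> (20,) probabilities
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1] (0 disables cleavage)")
        for pos in POSITIONS:
            w = np.asarray(self.weights.get(pos), dtype=float)
            if w.shape != (20,):
                raise ValueError(f"position {pos}: expected 20 weights")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"position {pos}: weights must be >= 0 and sum to 1")
            self.weights[pos] = w

    @classmethod
    def from_preferences(
        cls, preferences: Mapping[str, Mapping[str, float]], efficiency: float = 1.0
    ) -> "PlantedProtease":
        """Build from per-position residue weights; unspecified positions
        are uniform. Weights are normalized per position."""
        weights = {}
        for pos in POSITIONS:
            pref = preferences.get(pos)
            if pref is None:
                weights[pos] = np.full(20, 0.05)
            else:
                w = np.array([float(pref.get(aa, 0.0)) for aa in AMINO_ACIDS])
                if w.sum() <= 0:
                    raise ValueError(f"position {pos}: all-zero preference")
                weights[pos] = w / w.sum()
        return cls(weights=weights, efficiency=efficiency)

    def site_probability(self, window: str) -> float:
        """Cut probability for an 8-residue P4..P4' window, in [0, efficiency]."""
        if self.efficiency == 0.0:
            return 0.0
        score = 1.0
        best = 1.0
        for pos, aa in zip(POSITIONS, window):
            idx = AMINO_ACIDS.find(aa)
            if idx < 0:
                return 0.0
            score *= self.weights[pos][idx]
            best *= self.weights[pos].max()
        return self.efficiency * score / best if best > 0 else 0.0


@dataclass
class PicsSimulationParams:
    """Study conditions for the simulated PICS experiment."""

    min_peptide_length: int = 6  # MS-observable window
    max_peptide_length: int = 30
    identification_probability: float = 0.9
    contaminant_rate: float = 0.3  # target contaminant fraction of the raw test list
    contaminant_carryover: float = 0.9  # P(pool member appears in a given run)
    unlabeled_test_fraction: float = 0.2  # blocked peptides leaking into the test list
    n_library_identifications: int = 200
    true_confidence: tuple[float, float] = (8.0, 2.0)  # Beta(a, b)
    contaminant_confidence: tuple[float, float] = (2.0, 2.0)
    digest_mode: str = "combined"  # or "pooled": separate digests, pooled
    missed_cleavages: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_peptide_length < 4:
            raise ValueError("min_peptide_length must be >= 4 (four P' residues are needed)")
        for name in ("identification_probability", "contaminant_rate",
                     "contaminant_carryover", "unlabeled_test_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.digest_mode not in ("combined", "pooled"):
            raise ValueError("digest_mode must be 'combined' or 'pooled'")


@dataclass(frozen=True)
class GroundTruthCut:
    protein_id: str
    p1_position: int  # 1-based position of P1 in the protein
    window: str  # 8 residues P4..P4'


@dataclass
class PicsExperiment:
    test: list[IdentifiedPeptide]
    mock: list[IdentifiedPeptide]
    inactive: list[IdentifiedPeptide]
    library: list[IdentifiedPeptide]
    true_cuts: list[GroundTruthCut]
    planted: PlantedProtease


def simulate_pics_experiment(
    proteome: Sequence[SequenceRecord],
    planted: PlantedProtease,
    params: PicsSimulationParams,
    rules: Sequence[DigestionRule] = (TRYPSIN, GLUC),
) -> PicsExperiment:
    """End-to-end simulated PICS run with known ground truth.

    Pipeline order mirrors the wet-lab protocol: working-protease digest
    -> all original N-termini blocked -> planted-protease cuts sampled
    inside MS-retained peptides with probability proportional to the
    window likelihood under the planted specificity -> C-terminal
    fragments of cuts labeled -> noisy confidences. Mock and inactive
    lists hold only contaminants drawn from a background pool shared
    across runs; the library list holds blocked peptides plus the same
    shared contaminants.
    """
    rng = np.random.default_rng(params.seed)
    by_id = {p.identifier: p.residues for p in proteome}

    if params.digest_mode == "combined":
        frags = digest(proteome, list(rules), params.missed_cleavages)
    else:
        frags = [f for rule in rules for f in digest(proteome, [rule], params.missed_cleavages)]

    lo, hi = params.min_peptide_length, params.max_peptide_length
    library_pool = [f for f in frags if lo <= len(f.sequence) <= hi]
    if not library_pool:
        logger.warning(
            "simulate_pics_experiment: retained-length window %d-%d keeps no digest "
            "products; returning empty lists", lo, hi,
        )
        return PicsExperiment([], [], [], [], [], planted)

    # planted cuts inside retained peptides
    test_true: list[IdentifiedPeptide] = []
    true_cuts: list[GroundTruthCut] = []
    for pep in library_pool:
        protein = by_id[pep.protein_id]
        cut_positions = []  # 1-based P1 positions within the protein
        for p1 in range(pep.start, pep.end):  # cut between p1 and p1+1, inside peptide
            if p1 < 4 or p1 + 4 > len(protein):
                continue  # need a full P4..P4' window within the protein
            window = protein[p1 - 4 : p1 + 4]
            if rng.random() < planted.site_probability(window):
                cut_positions.append(p1)
                true_cuts.append(GroundTruthCut(pep.protein_id, p1, window))
        # fragments: piece starting at original N-terminus stays blocked;
        # pieces starting at a cut carry the biotinylation-derived label
        starts = [pep.start] + [p + 1 for p in cut_positions]
        ends = cut_positions + [pep.end]
        for frag_start, frag_end in zip(starts[1:], ends[1:]):
            frag = protein[frag_start - 1 : frag_end]
            if not lo <= len(frag) <= hi:
                continue
            if rng.random() < params.identification_probability:
                test_true.append(
                    IdentifiedPeptide(
                        sequence=frag,
                        confidence=float(rng.beta(*params.true_confidence)),
                        nterm_labeled=True,
                        run_label="test",
                    )
                )

    # shared contaminant background (incompletely blocked termini that
    # survive enrichment in every run)
    n_true = len(test_true)
    rate, carry = params.contaminant_rate, params.contaminant_carryover
    pool_size = 0
    if rate > 0 and carry > 0:
        pool_size = int(np.ceil(rate / max(1.0 - rate, 1e-9) * max(n_true, 1) / carry))
    pool_size = min(pool_size, len(library_pool))
    pool_idx = rng.choice(len(library_pool), size=pool_size, replace=False) if pool_size else []
    contaminant_pool = [library_pool[i] for i in pool_idx]

    def contaminant_sample(run_label: str) -> list[IdentifiedPeptide]:
        out = []
        for f in contaminant_pool:
            if rng.random() < carry:
                out.append(
                    IdentifiedPeptide(
                        sequence=f.sequence,
                        confidence=float(rng.beta(*params.contaminant_confidence)),
                        nterm_labeled=True,
                        run_label=run_label,
                    )
                )
        return out

    test = test_true + contaminant_sample("test")
    # blocked peptides misidentified into the test run (removed by the label filter)
    n_unlabeled = int(round(params.unlabeled_test_fraction * n_true))
    if n_unlabeled and library_pool:
        for i in rng.choice(len(library_pool), size=n_unlabeled):
            test.append(
                IdentifiedPeptide(
                    sequence=library_pool[i].sequence,
                    confidence=float(rng.beta(*params.contaminant_confidence)),
                    nterm_labeled=False,
                    run_label="test",
                )
            )
    mock = contaminant_sample("mock")
    inactive = contaminant_sample("inactive")
    library = contaminant_sample("library")
    n_lib = min(params.n_library_identifications, len(library_pool))
    if n_lib:
        for i in rng.choice(len(library_pool), size=n_lib, replace=False):
            library.append(
                IdentifiedPeptide(
                    sequence=library_pool[i].sequence,
                    confidence=float(rng.beta(*params.contaminant_confidence)),
                    nterm_labeled=False,
                    run_label="library",
                )
            )
    return PicsExperiment(test, mock, inactive, library, true_cuts, planted)


# ---------------------------------------------------------------------------
# NMR titration

@dataclass
class TitrationSimulationParams:
    """Study conditions for a simulated 1:1 fast-exchange titration.

    The default schedule titrates a ligand stock into the protein so the
    ligand:protein ratio rises to ``max_excess`` over ``n_points`` while
    the protein is progressively diluted, mirroring a real titration.
    """

    kd_mM: float = 1.0
    protein_mM: float = 0.1  # starting protein concentration
    ligand_stock_mM: float = 5.0
    max_excess: float = 10.0  # final ligand:protein molar ratio
    n_points: int = 8  # including the ligand-free reference
    n_epitope: int = 10
    n_spectators: int = 20
    ddmax_h_range: tuple[float, float] = (0.05, 0.25)  # ppm
    ddmax_n_range: tuple[float, float] = (0.3, 1.0)  # ppm
    noise_h: float = 0.005  # ppm, Gaussian sd
    noise_n: float = 0.025  # ppm, Gaussian sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd_mM <= 0:
            raise ValueError("kd_mM must be positive")
        if self.protein_mM <= 0 or self.ligand_stock_mM <= 0:
            raise ValueError("concentrations must be positive")
        if self.n_points < 2:
            raise ValueError("need at least 2 titration points")


@dataclass
class TitrationTruth:
    kd_mM: float
    ddmax: dict[str, tuple[float, float]]  # residue -> (ddmax_h, ddmax_n)
    epitope: list[str]


def dilution_schedule(
    p0: float, ligand_stock: float, ratios: Sequence[float]
) -> list[tuple[float, float]]:
    """(protein, ligand) concentrations reaching each ligand:protein ratio
    by adding ligand stock to a fixed starting volume (dilution exact)."""
    out = []
    for r in ratios:
        if r < 0:
            raise ValueError("ratios must be non-negative")
        v = r * p0 / ligand_stock  # added volume per unit starting volume
        out.append((p0 / (1.0 + v), ligand_stock * v / (1.0 + v)))
    return out


def simulate_titration(
    params: TitrationSimulationParams,
) -> tuple[TitrationSeries, TitrationTruth]:
    """Forward-model a titration: ``d = d_free + fb * ddmax + noise``.

    Epitope residues get nonzero ddelta_max drawn from the configured
    ranges; spectator residues move only by noise. Returns the series
    and the exact ground truth.
    """
    rng = np.random.default_rng(params.seed)
    epitope = [f"R{i + 1}" for i in range(params.n_epitope)]
    spectators = [f"S{i + 1}" for i in range(params.n_spectators)]
    ddmax: dict[str, tuple[float, float]] = {}
    for r in epitope:
        sign = rng.choice([-1.0, 1.0], size=2)
        ddmax[r] = (
            float(sign[0] * rng.uniform(*params.ddmax_h_range)),
            float(sign[1] * rng.uniform(*params.ddmax_n_range)),
        )
    for r in spectators:
        ddmax[r] = (0.0, 0.0)
    free = {
        r: (float(rng.uniform(6.5, 10.0)), float(rng.uniform(105.0, 130.0)))
        for r in epitope + spectators
    }
    ratios = np.linspace(0.0, params.max_excess, params.n_points)
    schedule = dilution_schedule(params.protein_mM, params.ligand_stock_mM, ratios)
    points = []
    for P, L in schedule:
        fb = float(fraction_bound(P, L, params.kd_mM)) if L > 0 else 0.0
        peaks = {}
        for r in epitope + spectators:
            h = free[r][0] + fb * ddmax[r][0]
            n = free[r][1] + fb * ddmax[r][1]
            if params.noise_h > 0:
                h += rng.normal(0.0, params.noise_h)
            if params.noise_n > 0:
                n += rng.normal(0.0, params.noise_n)
            peaks[r] = (h, n)
        points.append(TitrationPoint(protein_mM=P, ligand_mM=L, peaks=peaks))
    truth = TitrationTruth(kd_mM=params.kd_mM, ddmax=ddmax, epitope=epitope)
    return TitrationSeries(points=points), truth


# ---------------------------------------------------------------------------
# coordinate ensembles

def perturb_ensemble(
    model: StructureEnsemble,
    displacement_sd: float,
    n_models: int,
    seed: int = 0,
) -> StructureEnsemble:
    """Replicate a single model with i.i.d. Gaussian atomic displacements
    plus a random rigid motion per copy (so superposition is non-trivial)."""
    if model.n_models != 1:
        raise ValueError("perturb_ensemble expects a single-model input")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    base = model.coords[0]
    out = np.empty((n_models, model.n_atoms, 3))
    for m in range(n_models):
        coords = base + rng.normal(0.0, displacement_sd, size=base.shape) if displacement_sd > 0 else base.copy()
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        t = rng.uniform(-10.0, 10.0, size=3)
        out[m] = coords @ R.T + t
    return StructureEnsemble(model.atoms, out)
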