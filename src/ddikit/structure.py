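"""Rigid-body superposition and ensemble/comparison statistics.

* Kabsch (SVD) least-squares superposition with a proper-rotation
  guarantee (no reflections);
* NMR-ensemble precision: iterative superposition onto a converged
  mean structure, per-model RMSD to that mean, and the representative
  model (closest to the mean);
* motif RMSD in two frames: fitted on the motif atoms themselves, or
  evaluated in a frame fitted on a larger selection;
* iterative cross-ortholog alignment: CA pairs seeded from a sequence
  alignment, outliers pruned until the equivalence set is stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.SeqUtils import seq1

from ddikit.io import AtomSelection, StructureEnsemble, select_coordinates, select_indices
from ddikit import seqtools


class DegenerateCoordinatesError(ValueError):
    """Point set too degenerate (collinear / too few pairs) for a unique fit."""


@dataclass(frozen=True)
class Correspondence:
    """Ordered pairs (atom index in A, atom index in B)."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        a_idx = [p[0] for p in self.pairs]
        b_idx = [p[1] for p in self.pairs]
        if len(set(a_idx)) != len(a_idx) or len(set(b_idx)) != len(b_idx):
            raise ValueError("correspondence indices must be unique within each side")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class Superposition:
    """Proper rotation + translation mapping the mobile set onto the reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _as_points(x) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    return pts


def kabsch_superpose(
    X, Y, corr: Correspondence | None = None
) -> Superposition:
    """Least-squares rigid superposition of Y onto X (SVD/Kabsch).

    ``corr`` restricts the fit to paired atoms; without it, rows are
    paired by index. At least 3 non-collinear pairs are required; a
    reflection is never returned.
    """
    X, Y = _as_points(X), _as_points(Y)
    if corr is not None:
        ia = [p[0] for p in corr.pairs]
        ib = [p[1] for p in corr.pairs]
        X, Y = X[ia], Y[ib]
    elif X.shape != Y.shape:
        raise ValueError("X and Y must have equal shapes when no correspondence is given")
    n = len(X)
    if n < 3:
        raise DegenerateCoordinatesError(f"need >= 3 atom pairs, got {n}")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xc, Y - yc
    if np.linalg.matrix_rank(Xc, tol=1e-8) < 2 or np.linalg.matrix_rank(Yc, tol=1e-8) < 2:
        raise DegenerateCoordinatesError("collinear point set: rotation is not unique")
    H = Yc.T @ Xc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = xc - R @ yc
    diff = Xc - Yc @ R.T
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


@dataclass
class EnsemblePrecision:
    mean_coords: np.ndarray  # (n_sel, 3)
    per_model_rmsd: np.ndarray  # (n_models,)
    average_rmsd: float
    representative_index: int  # model closest to the converged mean
    n_iterations: int


def ensemble_precision(
    ensemble: StructureEnsemble,
    sel: AtomSelection,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> EnsemblePrecision:
    """RMSD of each model to the converged mean structure over ``sel``.

    All models are superposed on the first, averaged, re-superposed on
    the mean, and so on until the mean moves less than ``tol`` Angstrom.
    """
    coords = select_coordinates(ensemble, sel)
    n_models = coords.shape[0]
    if n_models < 2:
        raise ValueError("ensemble precision needs at least 2 models")
    mean = coords[0].copy()
    aligned = coords.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for m in range(n_models):
            sup = kabsch_superpose(mean, coords[m])
            aligned[m] = sup.apply(coords[m])
        new_mean = aligned.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if shift < tol:
            break
    per_model = np.array(
        [kabsch_superpose(mean, coords[m]).rmsd for m in range(n_models)]
    )
    return EnsemblePrecision(
        mean_coords=mean,
        per_model_rmsd=per_model,
        average_rmsd=float(per_model.mean()),
        representative_index=int(per_model.argmin()),
        n_iterations=n_iter,
    )


def motif_rmsd(
    A: StructureEnsemble,
    B: StructureEnsemble,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    frame: str = "motif-only",
    fit_sel_a: AtomSelection | None = None,
    fit_sel_b: AtomSelection | None = None,
    name_map: dict[str, str] | None = None,
    model_a: int = 0,
    model_b: int = 0,
) -> float:
    """RMSD over a small matched motif (e.g. an active-site signature).

    Atoms are paired in selection (file) order and must agree on atom
    name after applying ``name_map`` to B's names (e.g. ``{"OG1": "OG"}``
    to equate Thr and Ser hydroxyl oxygens). ``frame="motif-only"``
    superposes on the motif atoms themselves; ``frame="global-frame"``
    superposes on the ``fit_sel_*`` selections and evaluates the motif
    RMSD without re-fitting.
    """
    if frame not in ("motif-only", "global-frame"):
        raise ValueError(f"unknown frame {frame!r}")
    ia = select_indices(A, sel_a)
    ib = select_indices(B, sel_b)
    if len(ia) != len(ib):
        raise ValueError(
            f"motif atom-count mismatch: {len(ia)} in A vs {len(ib)} in B"
        )
    nmap = name_map or {}
    mismatched = [
        (A.atoms[i].name, B.atoms[j].name)
        for i, j in zip(ia, ib)
        if A.atoms[i].name != nmap.get(B.atoms[j].name, B.atoms[j].name)
    ]
    if mismatched:
        raise ValueError(f"unmatched motif atom names: {mismatched}")
    xa = A.coords[model_a][ia]
    xb = B.coords[model_b][ib]
    if frame == "motif-only":
        return kabsch_superpose(xa, xb).rmsd
    if fit_sel_a is None or fit_sel_b is None:
        raise ValueError("global-frame requires fit_sel_a and fit_sel_b")
    fa = A.coords[model_a][select_indices(A, fit_sel_a)]
    fb = B.coords[model_b][select_indices(B, fit_sel_b)]
    if len(fa) != len(fb):
        raise ValueError(f"fit-selection atom-count mismatch: {len(fa)} vs {len(fb)}")
    sup = kabsch_superpose(fa, fb)
    diff = xa - sup.apply(xb)
    return float(np.sqrt((diff * diff).sum() / len(xa)))


_CA = AtomSelection(chain=None, res_start=-10**6, res_end=10**6, atom_names=frozenset({"CA"}))


def _ca_trace(ens: StructureEnsemble, model: int) -> tuple[list[int], str]:
    """CA atom indices and one-letter sequence for one model."""
    idx = select_indices(ens, _CA)
    seq = "".join(
        seq1(ens.atoms[i].res_name.capitalize(), undef_code="X") for i in idx
    ).upper()
    return idx, seq


def iterative_align(
    A: StructureEnsemble,
    B: StructureEnsemble,
    model_a: int = 0,
    model_b: int = 0,
    matrix: str = "BLOSUM62",
    prune_factor: float = 2.0,
    min_pairs: int = 3,
    max_iter: int = 100,
) -> tuple[Correspondence, Superposition]:
    """Sequence-seeded iterative CA alignment of two single models.

    CA pairs come from a global sequence alignment; each round fits a
    superposition and drops pairs deviating more than
    ``prune_factor x current RMSD`` (never going below ``min_pairs``),
    until the pair set is stable. Deterministic.
    """
    ia, seq_a = _ca_trace(A, model_a)
    ib, seq_b = _ca_trace(B, model_b)
    aln = seqtools.global_align(seq_a, seq_b, matrix=matrix)
    pairs: list[tuple[int, int]] = []
    pos_a = pos_b = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            pairs.append((ia[pos_a], ib[pos_b]))
        if x != "-":
            pos_a += 1
        if y != "-":
            pos_b += 1
    if len(pairs) < min_pairs:
        raise DegenerateCoordinatesError(
            f"sequence alignment yields only {len(pairs)} CA pairs"
        )
    xa_all, xb_all = A.coords[model_a], B.coords[model_b]
    for _ in range(max_iter):
        corr = Correspondence(tuple(pairs))
        sup = kabsch_superpose(xa_all, xb_all, corr)
        dev = np.linalg.norm(
            np.array([xa_all[i] for i, _ in pairs])
            - sup.apply(np.array([xb_all[j] for _, j in pairs])),
            axis=1,
        )
        # the floor keeps numerically-identical structures from pruning on
        # rounding noise (deviations far below any structural signal)
        keep = dev <= max(prune_factor * sup.rmsd, 1e-6)
        if keep.sum() < min_pairs:
            order = np.argsort(dev)[:min_pairs]
            keep = np.zeros(len(pairs), dtype=bool)
            keep[order] = True
        new_pairs = [p for p, k in zip(pairs, keep) if k]
        if new_pairs == pairs:
            return corr, sup
        pairs = new_pairs
    corr = Correspondence(tuple(pairs))
    return corr, kabsch_superpose(xa_all, xb_all, corr)
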