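"""Optimal rigid-body superposition of paired CA sets (Kabsch) and RMSD.

``kabsch`` is the closed-form SVD solution with reflection correction;
``superpose_models`` adds the iterative outlier-rejection refinement that
structure-alignment tools apply by default (fit, drop pairs deviating more
than a cutoff, refit), reporting both the raw all-pair RMSD and the
refined RMSD over retained pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RefinementCollapseError, UnderdeterminedError
from .structure import SeqStructMap, StructureModel


@dataclass(frozen=True)
class TrimPolicy:
    """Residues to discard before superposition.

    Mirrors the common practice of deleting flexible N-/C-termini before
    comparing folds; counts are applied to the paired list.
    """

    drop_n_terminal: int = 0
    drop_c_terminal: int = 0

    def __post_init__(self) -> None:
        if self.drop_n_terminal < 0 or self.drop_c_terminal < 0:
            raise ValueError("trim counts must be non-negative")


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation applied to the mobile set
    translation: np.ndarray  # 3-vector, Å
    rmsd_all: float  # Å, over all initial pairs
    rmsd_refined: float  # Å, over retained pairs after rejection cycles
    n_pairs_initial: int
    n_pairs_retained: int
    cycles_run: int = 0
    retained_indices: tuple[int, ...] = ()

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid move to mobile coordinates."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _fit(ref: np.ndarray, mob: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation+translation of mob onto ref; returns RMSD."""
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    a = ref - ref_c
    b = mob - mob_c
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])  # reflection correction
    rot = (u @ corr @ vt).T
    trans = ref_c - rot @ mob_c
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def _collinear(x: np.ndarray, tol: float = 1e-10) -> bool:
    c = x - x.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return bool(s[1] <= tol * max(s[0], 1.0))


def kabsch(coords_ref: np.ndarray, coords_mob: np.ndarray) -> SuperpositionResult:
    """Superpose ``coords_mob`` onto ``coords_ref`` (paired, equal length).

    Returns the proper rotation (determinant +1), translation and RMSD.
    Collinear inputs are degenerate (rotation about the line is free); a
    warning is emitted and the least-squares result still returned.
    """
    ref = np.asarray(coords_ref, dtype=float)
    mob = np.asarray(coords_mob, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise UnderdeterminedError("paired (n, 3) coordinate arrays required")
    n = ref.shape[0]
    if n < 3:
        raise UnderdeterminedError(f"{n} pairs: at least 3 required")
    if _collinear(ref) or _collinear(mob):
        import warnings

        warnings.warn("collinear point set: rotation is not unique", stacklevel=2)
    rot, trans, rmsd = _fit(ref, mob)
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd_all=rmsd,
        rmsd_refined=rmsd,
        n_pairs_initial=n,
        n_pairs_retained=n,
        cycles_run=0,
        retained_indices=tuple(range(n)),
    )


def superpose_models(
    ref: StructureModel,
    mob: StructureModel,
    pair_map: SeqStructMap | None = None,
    trim: TrimPolicy | None = None,
    cycles: int = 5,
    reject_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Superpose two models with iterative outlier rejection.

    Residues are paired through ``pair_map`` — (sequence position, ref
    index) pairs whose sequence positions index ``mob`` residues one-based
    — or positionally when omitted (equal-length models). After the
    initial Kabsch fit, pairs deviating more than ``reject_cutoff`` Å are
    dropped and the fit repeated, up to ``cycles`` times or until stable.
    Defaults (5 cycles, 2.0 Å) mirror the conventional align protocol.
    """
    if pair_map is not None:
        idx_mob = [p - 1 for p, _ in pair_map.pairs]
        idx_ref = [j for _, j in pair_map.pairs]
    else:
        if len(ref) != len(mob):
            raise UnderdeterminedError(
                "models differ in length; supply a sequence-structure map"
            )
        idx_mob = list(range(len(mob)))
        idx_ref = list(range(len(ref)))
    trim = trim or TrimPolicy()
    hi = len(idx_ref) - trim.drop_c_terminal
    idx_ref = idx_ref[trim.drop_n_terminal : hi]
    idx_mob = idx_mob[trim.drop_n_terminal : hi]
    if len(idx_ref) < 3:
        raise UnderdeterminedError("fewer than 3 pairs after trimming")

    ref_xyz = ref.coords[idx_ref]
    mob_xyz = mob.coords[idx_mob]
    rot, trans, rmsd_all = _fit(ref_xyz, mob_xyz)

    keep = np.arange(len(idx_ref))
    # extreme outliers (e.g. disordered loops placed far from the fold) can
    # wreck the least-squares fit before rejection starts; restart from the
    # most consistent half so the cutoff is applied against a sane fit
    dev0 = np.sqrt(np.sum((mob_xyz @ rot.T + trans - ref_xyz) ** 2, axis=1))
    if dev0.max() > max(10.0 * reject_cutoff, 10.0):
        half = max(3, len(keep) // 2)
        core = np.sort(np.argsort(dev0)[:half])
        rot, trans, _ = _fit(ref_xyz[core], mob_xyz[core])
    rmsd_refined = rmsd_all
    cycles_run = 0
    for _ in range(max(cycles, 0)):
        moved = mob_xyz[keep] @ rot.T + trans
        dev = np.sqrt(np.sum((moved - ref_xyz[keep]) ** 2, axis=1))
        retained = keep[dev <= reject_cutoff]
        if retained.size == 0:
            raise RefinementCollapseError(
                f"all pairs exceed the {reject_cutoff} Å rejection cutoff"
            )
        if retained.size == keep.size:
            break
        keep = retained
        if keep.size < 3:
            raise RefinementCollapseError("fewer than 3 pairs survived rejection")
        rot, trans, rmsd_refined = _fit(ref_xyz[keep], mob_xyz[keep])
        cycles_run += 1

    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd_all=rmsd_all,
        rmsd_refined=rmsd_refined,
        n_pairs_initial=len(idx_ref),
        n_pairs_retained=int(keep.size),
        cycles_run=cycles_run,
        retained_indices=tuple(int(i) for i in keep),
    )


def trim_outside_tm(record, pair_map: SeqStructMap) -> TrimPolicy:
    """Trim counts dropping paired residues outside the first/last TM segment."""
    if not record.tm_segments:
        return TrimPolicy()
    first = record.tm_segments[0][0]
    last = record.tm_segments[-1][1]
    positions = [p for p, _ in pair_map.pairs]
    n_head = sum(1 for p in positions if p < first)
    n_tail = sum(1 for p in positions if p > last)
    return TrimPolicy(drop_n_terminal=n_head, drop_c_terminal=n_tail)
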