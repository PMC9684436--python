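"""Synthetic membrane proteins, helical CA traces and perturbed decoys.

Everything downstream — QTY conversion, property computation, rigid
superposition, SASA — is exercised offline on fixtures from this module,
with ground truth known by construction:

* sequences alternate hydrophilic loops with LIVF-enriched transmembrane
  segments, mimicking the 10-12 TM-helix architecture of solute carrier
  transporters;
* CA traces lie on ideal alpha-helices (rise 1.5 Å, twist 100°, radius
  2.3 Å), so every consecutive CA-CA distance is exactly the analytic
  chord length (3.83 Å at the defaults);
* decoys are rigid-transformed, Gaussian-perturbed copies whose expected
  post-superposition RMSD is sigma*sqrt(3) for per-coordinate noise sigma.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .qty import ProteinRecord
from .structure import Source, StructureModel, model_from_arrays

#: loops never contain L/I/V/F, so any substitution outside a TM segment
#: is guaranteed to be a bug, not an artefact of the fixture
LOOP_ALPHABET = "GSNDKEP"
LIVF = "LIVF"
#: non-LIVF residues used to fill the remaining TM positions
TM_FILLER = "AGSTMWCY"


@dataclass(frozen=True)
class SyntheticProteinSpec:
    """Architecture of a synthetic multi-pass membrane protein.

    Defaults emulate a 12-TM solute carrier: 21-residue TM helices joined
    by 30-residue loops/termini, with half the TM positions hydrophobic
    (L/I/V/F) — matching the ~44-55% TM substitution load and the ~10-25%
    overall substitution load seen in real transporters.
    """

    n_tm_segments: int = 12
    tm_length: int = 21
    loop_length: int = 30
    livf_fraction_tm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tm_segments < 0:
            raise ParameterError("n_tm_segments must be >= 0")
        if self.tm_length < 1 or self.loop_length < 0:
            raise ParameterError("tm_length >= 1 and loop_length >= 0 required")
        if not 0.0 <= self.livf_fraction_tm <= 1.0:
            raise ParameterError("livf_fraction_tm must lie in [0, 1]")


@dataclass(frozen=True)
class HelixGeometry:
    """Ideal alpha-helix parameters."""

    rise_per_residue: float = 1.5  # Å
    twist_per_residue: float = 100.0  # degrees
    radius: float = 2.3  # Å

    def __post_init__(self) -> None:
        if min(self.rise_per_residue, self.twist_per_residue, self.radius) <= 0:
            raise ParameterError("helix parameters must be strictly positive")

    @property
    def ca_chord(self) -> float:
        """Analytic consecutive CA-CA distance."""
        half = np.radians(self.twist_per_residue) / 2.0
        return float(np.hypot(2.0 * self.radius * np.sin(half), self.rise_per_residue))


def generate_membrane_protein(spec: SyntheticProteinSpec, name: str | None = None) -> ProteinRecord:
    """Sample a loop/TM/loop/... sequence with recorded TM intervals."""
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 0

    def loop() -> None:
        nonlocal pos
        parts.append("".join(rng.choice(list(LOOP_ALPHABET), size=spec.loop_length)))
        pos += spec.loop_length

    loop()
    for _ in range(spec.n_tm_segments):
        start = pos + 1
        tm = [
            rng.choice(list(LIVF)) if rng.random() < spec.livf_fraction_tm
            else rng.choice(list(TM_FILLER))
            for _ in range(spec.tm_length)
        ]
        parts.append("".join(tm))
        pos += spec.tm_length
        segments.append((start, pos))
        loop()
    return ProteinRecord(
        id=name or f"SYN{spec.n_tm_segments}TM_s{spec.seed}",
        sequence="".join(parts),
        description=f"synthetic {spec.n_tm_segments}-TM membrane protein",
        tm_segments=tuple(segments),
    )


def generate_helix_coords(
    n_res: int,
    geom: HelixGeometry | None = None,
    sequence: str | None = None,
    model_id: str = "helix",
) -> StructureModel:
    """CA trace of an ideal straight alpha-helix along +z."""
    if n_res < 2:
        raise ParameterError("a helix needs at least 2 residues")
    geom = geom or HelixGeometry()
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ParameterError("sequence length must equal n_res")
    i = np.arange(n_res)
    theta = np.radians(geom.twist_per_residue) * i
    coords = np.column_stack(
        [geom.radius * np.cos(theta), geom.radius * np.sin(theta), geom.rise_per_residue * i]
    )
    return model_from_arrays(model_id, sequence, coords, source=Source.SYNTHETIC)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix uniform over SO(3), via a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def perturb_structure(
    model: StructureModel, noise_sd: float, seed: int, translation_scale: float = 20.0
) -> StructureModel:
    """Decoy: add isotropic Gaussian CA noise, then a random rigid move.

    Stands in for a predicted model of the same protein; after optimal
    superposition the expected RMSD against the original is noise_sd*sqrt(3).
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if len(model) == 0:
        raise ParameterError("model must be non-empty")
    rng = np.random.default_rng(seed)
    coords = model.coords + rng.normal(scale=noise_sd, size=(len(model), 3)) if noise_sd > 0 else model.coords.copy()
    rot = random_rotation(rng)
    trans = rng.uniform(-translation_scale, translation_scale, size=3)
    moved = coords @ rot.T + trans
    return model_from_arrays(
        model.id + "_decoy", model.sequence, moved, chain=model.chain, source=Source.PREDICTED
    )


def build_helix_bundle(
    n_helices: int = 7,
    n_res_per_helix: int = 21,
    geom: HelixGeometry | None = None,
    bundle_radius: float = 8.0,
    sequence: str | None = None,
    model_id: str = "bundle",
) -> StructureModel:
    """Parallel helices on a circle: gives buried and exposed residues.

    The central axis region is occluded, so per-residue SASA spans the
    buried/exposed range needed to exercise surface statistics.
    """
    if n_helices < 1:
        raise ParameterError("need at least one helix")
    geom = geom or HelixGeometry()
    single = generate_helix_coords(n_res_per_helix, geom).coords
    blocks = []
    for k in range(n_helices):
        phi = 2.0 * np.pi * k / n_helices
        offset = np.array([bundle_radius * np.cos(phi), bundle_radius * np.sin(phi), 0.0])
        blocks.append(single + offset)
    coords = np.vstack(blocks)
    n_total = n_helices * n_res_per_helix
    if sequence is None:
        sequence = "A" * n_total
    if len(sequence) != n_total:
        raise ParameterError("sequence length must equal n_helices * n_res_per_helix")
    return model_from_arrays(model_id, sequence, coords, source=Source.SYNTHETIC)


def structure_for_record(
    record: ProteinRecord, geom: HelixGeometry | None = None, bundle_radius: float = 8.0
) -> StructureModel:
    """Bundle whose helices carry the record's TM residues, loops omitted.

    Used to pair a synthetic sequence with coordinates: each TM segment
    becomes one helix of the bundle, preserving residue identities, so
    native and QTY variant share identical geometry.
    """
    if not record.tm_segments:
        raise ParameterError("record has no TM segments to place")
    tm_lengths = {end - start + 1 for start, end in record.tm_segments}
    if len(tm_lengths) != 1:
        raise ParameterError("all TM segments must have equal length for a bundle")
    tm_seq = "".join(
        record.sequence[start - 1 : end] for start, end in record.tm_segments
    )
    return build_helix_bundle(
        n_helices=len(record.tm_segments),
        n_res_per_helix=tm_lengths.pop(),
        geom=geom,
        bundle_radius=bundle_radius,
        sequence=tm_seq,
        model_id=record.id + "_bundle",
    )
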