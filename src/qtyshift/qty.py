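"""QTY-code conversion of membrane-protein sequences.

The QTY code replaces the four hydrophobic residues that dominate
transmembrane (TM) alpha-helices with neutral-polar residues of closely
matching side-chain shape:

    L -> Q,  I -> T,  V -> T,  F -> Y

Substitution is applied only inside annotated TM segments, so loops and
termini are untouched, and the charged residues D, E, K, R, H are never
modified — which is why the variant keeps essentially the native pI.

Intervals are 1-based inclusive externally (the UniProt convention) and
converted to 0-based half-open indices only at function boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import AlphabetError, AnnotationError, ComparisonError, ParameterError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AA20) | {"X"}

#: default hydrophobic -> hydrophilic substitution table
QTY_DEFAULT_MAP: dict[str, str] = {"L": "Q", "I": "T", "V": "T", "F": "Y"}

CHARGED_RESIDUES = "DEKRH"


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - _VALID
    if bad:
        raise AlphabetError(f"non-amino-acid letters in sequence: {sorted(bad)}")


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence with transmembrane-segment annotations.

    ``tm_segments`` are ``(start, end)`` pairs, 1-based inclusive, sorted
    and non-overlapping — exactly what UniProt TRANSMEM features provide.
    """

    id: str
    sequence: str
    description: str = ""
    tm_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        object.__setattr__(self, "sequence", str(self.sequence))
        segs = tuple((int(a), int(b)) for a, b in self.tm_segments)
        object.__setattr__(self, "tm_segments", segs)
        n = len(self.sequence)
        prev_end = 0
        for start, end in segs:
            if start < 1 or end > n or start > end:
                raise AnnotationError(
                    f"TM interval ({start},{end}) outside [1,{n}] or inverted"
                )
            if start <= prev_end:
                raise AnnotationError(
                    f"TM interval ({start},{end}) overlaps or is unsorted"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def tm_mask(self) -> list[bool]:
        """Per-position flag, True inside a TM segment (0-based list)."""
        mask = [False] * len(self.sequence)
        for start, end in self.tm_segments:
            for i in range(start - 1, end):
                mask[i] = True
        return mask

    @property
    def n_tm_residues(self) -> int:
        return sum(end - start + 1 for start, end in self.tm_segments)


@dataclass(frozen=True)
class QtyCodeMap:
    """Residue substitution table; residues absent from it map to themselves.

    The image residues Q, T, Y must be fixed points so the conversion is
    idempotent.
    """

    mapping: Mapping[str, str] = field(default_factory=lambda: dict(QTY_DEFAULT_MAP))

    def __post_init__(self) -> None:
        for src, dst in self.mapping.items():
            if src not in _VALID or dst not in _VALID:
                raise AlphabetError(f"substitution {src}->{dst} uses unknown letters")
            if dst in self.mapping and self.mapping[dst] != dst:
                raise AnnotationError(
                    f"image residue {dst} is not a fixed point; map not idempotent"
                )

    def __call__(self, residue: str) -> str:
        return self.mapping.get(residue, residue)


@dataclass(frozen=True)
class VariationStats:
    """Substitution-load statistics of a QTY conversion."""

    tm_residues: int
    tm_substituted: int
    sequence_length: int

    @property
    def tm_variation_pct(self) -> float:
        if self.tm_residues == 0:
            return 0.0
        return 100.0 * self.tm_substituted / self.tm_residues

    @property
    def overall_variation_pct(self) -> float:
        if self.sequence_length == 0:
            return 0.0
        return 100.0 * self.tm_substituted / self.sequence_length


@dataclass(frozen=True)
class QtyVariantResult:
    """Variant sequence plus the full per-position substitution ledger."""

    native: ProteinRecord
    variant_sequence: str
    substitutions: tuple[tuple[int, str, str], ...]  # (1-based pos, from, to)
    stats: VariationStats

    @property
    def variant_record(self) -> ProteinRecord:
        return ProteinRecord(
            id=self.native.id + "_QTY",
            sequence=self.variant_sequence,
            description=(self.native.description + " QTY variant").strip(),
            tm_segments=self.native.tm_segments,
        )


def qty_convert(record: ProteinRecord, code: QtyCodeMap | None = None) -> QtyVariantResult:
    """Apply the QTY code inside the record's TM segments.

    Positions outside TM segments are returned byte-identical; inside them
    every L/I/V/F (or whatever the supplied code maps) is replaced, and each
    replacement is logged in the substitution ledger.
    """
    code = code or QtyCodeMap()
    seq = list(record.sequence)
    ledger: list[tuple[int, str, str]] = []
    for start, end in record.tm_segments:
        for i in range(start - 1, end):
            src = seq[i]
            dst = code(src)
            if dst != src:
                ledger.append((i + 1, src, dst))
                seq[i] = dst
    variant = "".join(seq)
    stats = VariationStats(
        tm_residues=record.n_tm_residues,
        tm_substituted=len(ledger),
        sequence_length=len(record.sequence),
    )
    return QtyVariantResult(
        native=record,
        variant_sequence=variant,
        substitutions=tuple(ledger),
        stats=stats,
    )


def variation_stats(native: ProteinRecord, variant_sequence: str) -> VariationStats:
    """Count substituted TM positions of ``variant_sequence`` vs the native.

    Differences are counted only where they fall inside a TM segment; a
    difference outside one indicates the variant was not produced by the
    QTY code, and is still counted in ``tm_substituted`` only if inside TM.
    """
    if len(variant_sequence) != len(native.sequence):
        raise ComparisonError(
            f"length mismatch: native {len(native.sequence)} vs variant {len(variant_sequence)}"
        )
    mask = native.tm_mask
    n_sub = sum(
        1
        for i, (a, b) in enumerate(zip(native.sequence, variant_sequence))
        if mask[i] and a != b
    )
    return VariationStats(
        tm_residues=native.n_tm_residues,
        tm_substituted=n_sub,
        sequence_length=len(native.sequence),
    )


def round2(x: float) -> float:
    """Round half-up to 2 decimals, for report formatting only."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def render_alignment(
    native: ProteinRecord, variant_sequence: str, line_width: int = 60
) -> str:
    """Pairwise alignment text: native / marker / variant rows per block.

    The marker row uses ``|`` for identical and ``*`` for differing
    positions. A span line above each block draws ``H`` under TM columns.
    """
    if line_width < 10:
        raise ParameterError("line_width must be >= 10")
    if len(variant_sequence) != len(native.sequence):
        raise ComparisonError("sequences must have equal length")
    mask = native.tm_mask
    marker = "".join(
        "|" if a == b else "*" for a, b in zip(native.sequence, variant_sequence)
    )
    spans = "".join("H" if m else " " for m in mask)
    blocks: list[str] = []
    for off in range(0, len(native.sequence), line_width):
        sl = slice(off, off + line_width)
        blocks.append(
            "\n".join(
                [
                    f"TM      {spans[sl]}".rstrip(),
                    f"{native.id:<7.7s} {native.sequence[sl]}",
                    f"        {marker[sl]}",
                    f"{(native.id + '_QTY'):<7.7s} {variant_sequence[sl]}",
                ]
            )
        )
    return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# FASTA and TM-interval file handling


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read FASTA into records (no TM annotations; attach separately)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    lines: list[str] = []
    for rec in records:
        header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
        lines.append(f">{header}")
        for off in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[off : off + width])
    Path(path).write_text("\n".join(lines) + "\n")


_GFF_TRANSMEM = re.compile(r"^(\S+)\t\S*\tTransmembrane\t(\d+)\t(\d+)", re.IGNORECASE)


def read_tm_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Parse TM intervals from UniProt GFF feature lines or a plain TSV.

    TSV rows are ``id<TAB>start<TAB>end``; GFF rows are recognised by the
    ``Transmembrane`` feature type in column 3. Both may be mixed freely.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _GFF_TRANSMEM.match(line)
        if m:
            out.setdefault(m.group(1), []).append((int(m.group(2)), int(m.group(3))))
            continue
        parts = line.split("\t")
        if len(parts) >= 3 and parts[1].isdigit() and parts[2].isdigit():
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    for segs in out.values():
        segs.sort()
    return out


def attach_tm(record: ProteinRecord, segments: Sequence[tuple[int, int]]) -> ProteinRecord:
    """Return a copy of ``record`` carrying the given TM segments."""
    return ProteinRecord(
        id=record.id,
        sequence=record.sequence,
        description=record.description,
        tm_segments=tuple(sorted(segments)),
    )
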