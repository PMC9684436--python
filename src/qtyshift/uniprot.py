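"""UniProt retrieval with a write-through disk cache.

Sequences come from the REST FASTA endpoint and TRANSMEM intervals from
the GFF feature endpoint. Every successful fetch is cached as plain text
(``<acc>.fasta`` and ``<acc>.gff``) together with a retrieval date, so
repeat runs — and offline runs against a pre-populated cache — never touch
the network. UniProt annotations drift between releases; the recorded
retrieval date is what ties a report to its input version.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
import urllib.error
import urllib.request
from pathlib import Path

from .errors import LookupError_
from .qty import ProteinRecord, attach_tm, read_fasta

UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"
UNIPROT_GFF_URL = "https://rest.uniprot.org/uniprotkb/{acc}.gff"

_TRANSMEM_LINE = re.compile(r"^\S+\t\S+\tTransmembrane\t(\d+)\t(\d+)", re.MULTILINE)


def _fetch_url(url: str, timeout: float) -> str:
    with urllib.request.urlopen(url, timeout=timeout) as resp:  # noqa: S310
        return resp.read().decode()


def fetch_uniprot(
    accession: str,
    cache_dir: str | Path,
    timeout: float = 10.0,
    offline: bool = False,
) -> ProteinRecord:
    """Canonical sequence plus TRANSMEM intervals for a UniProt accession.

    Cache hit -> no network. Cache miss with ``offline=True`` or an
    unreachable/unknown accession -> :class:`LookupError_`.
    """
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    fasta_path = cache / f"{accession}.fasta"
    gff_path = cache / f"{accession}.gff"
    meta_path = cache / f"{accession}.meta.json"

    if not (fasta_path.exists() and gff_path.exists()):
        if offline:
            raise LookupError_(f"{accession}: not in cache and offline mode requested")
        try:
            fasta_text = _fetch_url(UNIPROT_FASTA_URL.format(acc=accession), timeout)
            gff_text = _fetch_url(UNIPROT_GFF_URL.format(acc=accession), timeout)
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            raise LookupError_(
                f"{accession}: not cached and UniProt unreachable ({exc})"
            ) from exc
        if not fasta_text.startswith(">"):
            raise LookupError_(f"{accession}: UniProt returned no FASTA record")
        fasta_path.write_text(fasta_text)
        gff_path.write_text(gff_text)
        meta_path.write_text(
            json.dumps({"accession": accession, "retrieved": _dt.date.today().isoformat()})
        )

    records = read_fasta(fasta_path)
    if not records:
        raise LookupError_(f"{accession}: cached FASTA is empty")
    rec = records[0]
    segments = [
        (int(a), int(b)) for a, b in _TRANSMEM_LINE.findall(gff_path.read_text())
    ]
    if not segments:
        import warnings

        warnings.warn(f"{accession}: no TRANSMEM features annotated", stacklevel=2)
    return attach_tm(
        ProteinRecord(id=accession, sequence=rec.sequence, description=rec.description),
        sorted(segments),
    )


def cache_record(record: ProteinRecord, cache_dir: str | Path) -> None:
    """Store a record in the cache as if it had been fetched (fixtures, tests)."""
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    (cache / f"{record.id}.fasta").write_text(
        f">{record.id} {record.description}\n{record.sequence}\n"
    )
    gff_lines = [
        f"{record.id}\tqtyshift\tTransmembrane\t{a}\t{b}\t.\t.\t.\tNote=Helical"
        for a, b in record.tm_segments
    ]
    (cache / f"{record.id}.gff").write_text("\n".join(gff_lines) + "\n")
    (cache / f"{record.id}.meta.json").write_text(
        json.dumps({"accession": record.id, "retrieved": "synthetic"})
    )
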